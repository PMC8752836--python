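import numpy as np
import pytest

from genegate import GuideRNA, TranscriptKinetics


@pytest.fixture
def guide() -> GuideRNA:
    return GuideRNA("GTCACGGTACCGAGCACAT", pam="AGG")


@pytest.fixture
def kinetics_default() -> TranscriptKinetics:
    return TranscriptKinetics(beta=10.0, k_e=1.0, lambda_n=1.0, lambda_c=0.5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_240_101)
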