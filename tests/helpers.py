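"""Independent oracles shared across test modules.

These deliberately re-derive results by the most naive route available
(exhaustive sweeps, quadratic DP, direct construction) so the tests compare
two unrelated code paths.
"""

import numpy as np

from genegate import GuideRNA
from genegate.audit import reverse_complement

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "N": "ACGT", "R": "AG", "Y": "CT",
}


def brute_force_scan(genome: dict, guide: GuideRNA, require_pam: bool = True):
    """Exhaustive per-position off-target oracle: naive character comparison."""
    hits = []
    for chrom, seq in genome.items():
        seq = seq.upper()
        for start in range(len(seq) - 21):
            window = seq[start : start + 22]
            for strand in "+-":
                site = window if strand == "+" else reverse_complement(window)
                mism = sum(
                    1 for a, b in zip(site[:19], guide.protospacer)
                    if a != b or a not in "ACGT"
                )
                pam_ok = all(
                    b in "ACGT" and b in _IUPAC[p]
                    for b, p in zip(site[19:], guide.pam_pattern)
                )
                if mism <= guide.max_mismatches and (pam_ok or not require_pam):
                    hits.append((chrom, start, strand, mism, pam_ok))
    return sorted(hits)


def lcs_dp(a: str, b: str) -> int:
    """Quadratic dynamic-programming oracle for longest common substring."""
    best = 0
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best


def pair_differing_below(cut: float, n: int, seed: int):
    """Two distance samples identical above ``cut``, different just below it.

    Sample A places 30% of its mass in [cut-0.2, cut) where B places the same
    mass in [cut-0.4, cut-0.2); both share uniform mass below cut-0.4 and a
    common tail above cut, so the full distributional difference is captured
    exactly at the ``cut`` threshold with balanced restricted samples.
    """
    rng = np.random.default_rng(seed)
    shared_low = rng.uniform(0, cut - 0.4, size=(2, int(0.2 * n)))
    tail = rng.uniform(cut, 1.5, size=(2, n - int(0.2 * n) - int(0.3 * n)))
    a_bump = rng.uniform(cut - 0.2, cut, int(0.3 * n))
    b_bump = rng.uniform(cut - 0.4, cut - 0.2, int(0.3 * n))
    a = np.concatenate([shared_low[0], a_bump, tail[0]])
    b = np.concatenate([shared_low[1], b_bump, tail[1]])
    return a, b
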