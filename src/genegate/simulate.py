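"""Synthetic data generators for every pipeline input.

Each generator emulates the statistical structure of one experimental
readout so downstream statistics can be exercised and validated without any
microscopy or sequencing data:

* :func:`gen_nuclei` — per-nucleus OSE/MYC periphery distances drawn from a
  two-component radial mixture (exponential periphery-proximal tail +
  truncated-normal interior), with a Gaussian-copula coupling that makes the
  two loci approach the periphery in a coordinated way, replication-state
  classes, and a distance-modulated RNA-FISH signal.
* :func:`gen_pulse_chase` — replicate nuclear/cytoplasmic labeled-RNA
  amounts following the two-compartment kinetic model with multiplicative
  lognormal noise.
* :func:`gen_toy_genome` — a random genome with guide-derived off-target
  sites planted at exact mismatch counts, plus the truth table.
* :func:`gen_callsets` — three caller outputs derived from a planted truth
  set by independent false-negative drops and caller-private false positives.
* :func:`gen_coculture` — exponential allele-ratio drift with noise.

All randomness flows from one explicit seed per call; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .audit import Callset, GuideRNA, Variant, reverse_complement
from .fitness import RatioSeries
from .kinetics import TranscriptKinetics, pulse_chase_solution

__all__ = [
    "NucleusSimConfig",
    "GenomeSimConfig",
    "PlantedSite",
    "gen_nuclei",
    "gen_pulse_chase",
    "gen_toy_genome",
    "gen_callsets",
    "gen_coculture",
    "radial_mixture_cdf",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class NucleusSimConfig:
    """Parameters of the per-nucleus FISH simulator.

    The radial distance of each locus from the nuclear periphery is drawn
    from a two-component mixture: with probability ``peripheral_fraction``
    an exponential of scale ``peripheral_scale_um`` (the periphery-proximal
    pool), otherwise a normal of mean ``interior_mean_um`` and spread
    ``interior_sd_um`` truncated at zero (the nucleoplasmic pool).
    ``coupling`` in [0, 1] is the Gaussian-copula correlation between the
    OSE and MYC draws of one allele pair: at 1 both loci sit at the same
    mixture quantile, driving c = b - a toward 0.  The RNA-FISH signal is
    ``background_au + signal_slope * a_um`` with multiplicative lognormal
    noise (CV ``signal_cv``), floored at 0 AU.  ``cellcycle_fractions`` are
    the probabilities of the (S/S, D/S, S/D, D/D) replication classes.
    """

    n_cells: int = 250
    genotype: str = "WT"
    peripheral_fraction: float = 0.45
    peripheral_scale_um: float = 0.35
    interior_mean_um: float = 2.0
    interior_sd_um: float = 0.8
    coupling: float = 0.8
    signal_slope: float = -120.0
    background_au: float = 60.0
    signal_cv: float = 0.2
    cellcycle_fractions: tuple[float, float, float, float] = (0.5, 0.15, 0.15, 0.2)
    alleles_per_cell: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 <= self.peripheral_fraction <= 1.0:
            raise ValueError("peripheral_fraction must lie in [0, 1]")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        if self.peripheral_scale_um < 0 or self.interior_sd_um <= 0:
            raise ValueError("scales must be positive")
        if self.interior_mean_um < 0:
            raise ValueError("interior_mean_um must be >= 0")
        f = np.asarray(self.cellcycle_fractions, dtype=float)
        if f.size != 4 or np.any(f < 0) or not np.isclose(f.sum(), 1.0):
            raise ValueError("cellcycle_fractions must be 4 probabilities summing to 1")
        if self.alleles_per_cell < 1:
            raise ValueError("alleles_per_cell must be >= 1")

    @classmethod
    def wt_like(cls, n_cells: int = 250, seed: int = 0) -> "NucleusSimConfig":
        """Gating-competent parameterisation: strong peripheral pool, tight coupling."""
        return cls(n_cells=n_cells, genotype="WT", seed=seed)

    @classmethod
    def mutant_like(
        cls, n_cells: int = 250, seed: int = 0, genotype: str = "E4"
    ) -> "NucleusSimConfig":
        """CTCFBS-edited parameterisation: depleted peripheral pool, weak coupling."""
        return cls(
            n_cells=n_cells,
            genotype=genotype,
            peripheral_fraction=0.15,
            coupling=0.2,
            signal_slope=-40.0,
            alleles_per_cell=2,
            seed=seed,
        )


def radial_mixture_cdf(config: NucleusSimConfig, x) -> np.ndarray:
    """Closed-form CDF of the configured radial-distance mixture."""
    x = np.asarray(x, dtype=float)
    pf = config.peripheral_fraction
    if config.peripheral_scale_um > 0:
        periph = stats.expon.cdf(x, scale=config.peripheral_scale_um)
    else:
        periph = (x >= 0).astype(float)
    a = (0.0 - config.interior_mean_um) / config.interior_sd_um
    interior = stats.truncnorm.cdf(
        x, a, np.inf, loc=config.interior_mean_um, scale=config.interior_sd_um
    )
    return pf * periph + (1.0 - pf) * interior


def _radial_mixture_ppf_grid(config: NucleusSimConfig, n_grid: int = 8192):
    """Dense (F(x), x) grid for quantile-transform sampling of the mixture."""
    upper = config.interior_mean_um + 8.0 * config.interior_sd_um
    if config.peripheral_scale_um > 0:
        upper = max(upper, 20.0 * config.peripheral_scale_um)
    x = np.linspace(0.0, upper, n_grid)
    cdf = radial_mixture_cdf(config, x)
    return cdf, x


def gen_nuclei(config: NucleusSimConfig) -> pd.DataFrame:
    """Simulate an allele table of paired OSE/MYC periphery distances.

    Returns one row per allele pair with columns ``cell_id``, ``allele_id``,
    ``a_um`` (OSE), ``b_um`` (MYC), ``rep_ose``, ``rep_myc``, ``signal_au``.
    Identical seeds yield identical tables.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_cells * config.alleles_per_cell

    # Coupled uniforms via a Gaussian copula: shared latent factor with
    # weight sqrt(coupling) gives latent correlation == coupling.
    z_shared = rng.standard_normal(n)
    z_a = np.sqrt(config.coupling) * z_shared + np.sqrt(1 - config.coupling) * rng.standard_normal(n)
    z_b = np.sqrt(config.coupling) * z_shared + np.sqrt(1 - config.coupling) * rng.standard_normal(n)
    u_a = stats.norm.cdf(z_a)
    u_b = stats.norm.cdf(z_b)

    cdf_grid, x_grid = _radial_mixture_ppf_grid(config)
    a_um = np.interp(u_a, cdf_grid, x_grid)
    b_um = np.interp(u_b, cdf_grid, x_grid)

    classes = rng.choice(4, size=n, p=np.asarray(config.cellcycle_fractions, dtype=float))
    rep_myc = np.where(np.isin(classes, [1, 3]), "D", "S")
    rep_ose = np.where(np.isin(classes, [2, 3]), "D", "S")

    mean_signal = config.background_au + config.signal_slope * a_um
    if config.signal_cv > 0:
        sigma = np.sqrt(np.log1p(config.signal_cv**2))
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=n)
    else:
        noise = np.ones(n)
    signal_au = np.maximum(mean_signal, 0.0) * noise

    cells = np.repeat(np.arange(config.n_cells), config.alleles_per_cell)
    alleles = np.tile(np.arange(config.alleles_per_cell), config.n_cells)
    return pd.DataFrame(
        {
            "cell_id": [f"cell_{i:05d}" for i in cells],
            "allele_id": alleles,
            "a_um": a_um,
            "b_um": b_um,
            "rep_ose": rep_ose,
            "rep_myc": rep_myc,
            "signal_au": signal_au,
        }
    )


def gen_pulse_chase(
    kinetics: TranscriptKinetics,
    pulse_min: float = 30.0,
    chase_min: float = 60.0,
    n_reps: int = 3,
    cv: float = 0.05,
    seed: int | None = None,
    sample_times: Sequence[float] | None = None,
    decay_during_pulse: bool = True,
) -> pd.DataFrame:
    """Simulate replicate pulse-chase compartment quantifications.

    Mean trajectories follow the two-compartment closed form with the
    labeling source active for ``pulse_min`` minutes then switched off for
    ``chase_min`` minutes of chase; replicates receive independent
    multiplicative lognormal noise of coefficient of variation ``cv``.
    Default sampling covers the pulse and chase at six points.
    """
    if pulse_min <= 0 or chase_min <= 0:
        raise ValueError("pulse_min and chase_min must be > 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if sample_times is None:
        sample_times = np.concatenate(
            [
                np.linspace(pulse_min / 3.0, pulse_min, 3),
                pulse_min + np.linspace(chase_min / 3.0, chase_min, 3),
            ]
        )
    times = kinetics.t0 + np.asarray(sample_times, dtype=float)
    x_mean, y_mean = pulse_chase_solution(
        kinetics, times, pulse_min, decay_during_pulse=decay_during_pulse
    )

    rng = np.random.default_rng(seed)
    rows = []
    sigma = np.sqrt(np.log1p(cv**2)) if cv > 0 else 0.0
    for rep in range(n_reps):
        if sigma > 0:
            nx = rng.lognormal(-0.5 * sigma**2, sigma, times.size)
            ny = rng.lognormal(-0.5 * sigma**2, sigma, times.size)
        else:
            nx = ny = np.ones(times.size)
        rows.append(
            pd.DataFrame(
                {
                    "replicate": rep,
                    "time_min": times,
                    "nuclear": x_mean * nx,
                    "cytoplasmic": y_mean * ny,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class PlantedSite:
    """Truth-table entry for one planted off-target site."""

    position: int  # 0-based start of the 22 bp span on the forward strand
    strand: str
    mismatches: int
    pam_valid: bool


@dataclass(frozen=True)
class GenomeSimConfig:
    """Toy-genome layout: length, base composition and planted guide sites."""

    length_bp: int = 50_000
    gc: float = 0.41
    planted_sites: tuple[PlantedSite, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length_bp < 220:
            raise ValueError("genome must be at least 10 site lengths long")
        if not 0.0 <= self.gc <= 1.0:
            raise ValueError("gc must lie in [0, 1]")
        spans = sorted((s.position, s.position + 22) for s in self.planted_sites)
        for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("planted sites must not overlap")
        for s in self.planted_sites:
            if s.position < 0 or s.position + 22 > self.length_bp:
                raise ValueError("planted site outside genome bounds")
            if s.strand not in "+-":
                raise ValueError("strand must be '+' or '-'")


def _mutate_protospacer(proto: str, n_mism: int, rng: np.random.Generator) -> str:
    positions = rng.choice(len(proto), size=n_mism, replace=False)
    seq = list(proto)
    for p in positions:
        choices = [b for b in "ACGT" if b != seq[p]]
        seq[p] = choices[rng.integers(0, 3)]
    return "".join(seq)


def _concrete_pam(pattern: str, valid: bool, rng: np.random.Generator) -> str:
    from .audit import _IUPAC  # shared IUPAC table

    if valid:
        return "".join(sorted(_IUPAC[p])[rng.integers(0, len(_IUPAC[p]))] for p in pattern)
    # Break the most constrained pattern position so the PAM cannot match.
    sizes = [len(_IUPAC[p]) for p in pattern]
    j = int(np.argmin(sizes))
    if sizes[j] == 4:
        raise ValueError("cannot plant an invalid PAM against an all-N pattern")
    bad = sorted(set("ACGT") - _IUPAC[pattern[j]])
    pam = [sorted(_IUPAC[p])[rng.integers(0, len(_IUPAC[p]))] for p in pattern]
    pam[j] = bad[rng.integers(0, len(bad))]
    return "".join(pam)


def gen_toy_genome(
    config: GenomeSimConfig, guide: GuideRNA, chrom: str = "chr_sim"
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random genome with guide-derived sites planted at exact mismatch counts.

    Each planted site embeds the guide protospacer mutated at exactly the
    requested number of positions, followed by a PAM that matches (or,
    when ``pam_valid`` is false, provably violates) the guide's PAM pattern;
    minus-strand plants insert the reverse complement.  Returns the genome
    and a truth table (position, strand, mismatches, pam_valid, site_seq).
    """
    rng = np.random.default_rng(config.seed)
    p_gc = config.gc / 2.0
    p_at = (1.0 - config.gc) / 2.0
    seq = rng.choice(_BASES, size=config.length_bp, p=[p_at, p_gc, p_gc, p_at])

    rows = []
    for site in config.planted_sites:
        if site.mismatches > len(guide.protospacer):
            raise ValueError("mismatch_count exceeds protospacer length")
        proto = _mutate_protospacer(guide.protospacer, site.mismatches, rng)
        pam = _concrete_pam(guide.pam_pattern, site.pam_valid, rng)
        site_seq = proto + pam
        if site.strand == "-":
            site_seq = reverse_complement(site_seq)
        seq[site.position : site.position + 22] = list(site_seq)
        rows.append(
            {
                "position": site.position,
                "strand": site.strand,
                "mismatches": site.mismatches,
                "pam_valid": site.pam_valid,
                "site_seq": site_seq,
            }
        )
    truth = pd.DataFrame(
        rows, columns=["position", "strand", "mismatches", "pam_valid", "site_seq"]
    )
    return {chrom: "".join(seq)}, truth


def gen_callsets(
    truth: Sequence[Variant],
    fp_rates: Sequence[float],
    fn_rates: Sequence[float],
    seed: int | None = None,
    callers: Sequence[str] = ("mutect2", "strelka2", "lofreq"),
    contig_length: int = 1_000_000,
) -> list[Callset]:
    """Derive caller outputs from a planted truth set.

    Each caller drops true variants independently with its false-negative
    rate and adds Poisson(fp_rate × n_truth) spurious calls at loci distinct
    from the truth set and from every other caller's spurious calls, so
    fn = 0 guarantees consensus == truth regardless of fp.
    """
    if len(fp_rates) != len(callers) or len(fn_rates) != len(callers):
        raise ValueError("need one fp and fn rate per caller")
    for r in (*fp_rates, *fn_rates):
        if not 0.0 <= r < 1.0:
            raise ValueError("rates must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    truth = list(truth)
    used_loci = {(v.chrom, v.pos) for v in truth}
    chroms = sorted({v.chrom for v in truth}) or ["chr_sim"]

    callsets = []
    for caller, fp, fn in zip(callers, fp_rates, fn_rates):
        kept = [v for v in truth if rng.random() >= fn]
        n_fp = rng.poisson(fp * max(len(truth), 1))
        spurious: list[Variant] = []
        while len(spurious) < n_fp:
            chrom = chroms[rng.integers(0, len(chroms))]
            pos = int(rng.integers(1, contig_length + 1))
            if (chrom, pos) in used_loci:
                continue
            used_loci.add((chrom, pos))
            ref, alt = _BASES[rng.choice(4, size=2, replace=False)]
            spurious.append(Variant(chrom, pos, str(ref), str(alt)))
        callsets.append(Callset([*kept, *spurious], caller=caller))
    return callsets


def gen_coculture(
    s: float,
    days: Sequence[float],
    r0: float = 1.0,
    cv: float = 0.0,
    seed: int | None = None,
    condition: str = "DMSO",
) -> RatioSeries:
    """Exponential WT/mutant ratio drift r(t) = r0 e^{s t} with lognormal noise."""
    if r0 <= 0:
        raise ValueError("r0 must be > 0")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    days = np.asarray(days, dtype=float)
    ratio = r0 * np.exp(s * days)
    if cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(cv**2))
        ratio = ratio * rng.lognormal(-0.5 * sigma**2, sigma, days.size)
    return RatioSeries(day=days, ratio=ratio, condition=condition)
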