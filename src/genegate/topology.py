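"""Statistics of allele positions relative to the nuclear periphery.

Works on tables of per-nucleus DNA-FISH measurements: for each allele pair,
the distance ``a`` of the super-enhancer (OSE) signal and ``b`` of the MYC
signal to the nuclear periphery (µm), their replication states (S = single,
un-replicated; D = double, replicated) and optionally an RNA-FISH intensity
in arbitrary units.  The headline statistic is the c-value ``c = b - a``: a
value near zero means both loci sit at the same radial depth, the signature
of their coordinated recruitment to the nuclear pore.

Distribution comparisons use the two-sample two-tailed Kolmogorov–Smirnov
test (significance level 0.05 by convention), with an exact enumeration mode
for small samples, plus radial-window binning with a 240 nm resolution
floor, cumulative distributions within 1 µm of the periphery, replication
and RNA-signal stratification, a periphery-threshold significance scan, and
radial profiling of in situ proximity ligation (ISPLA) signals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import special, stats

__all__ = [
    "AlleleRecord",
    "KSResult",
    "RadialBins",
    "DEFAULT_EDGES_UM",
    "FIRST_CUTOFF_UM",
    "BACKGROUND_AU",
    "c_value",
    "c_values",
    "bin_distances",
    "ks_two_sample",
    "cumulative_within",
    "RestrictedECDF",
    "stratify_replication",
    "threshold_scan",
    "ThresholdScanResult",
    "stratify_by_signal",
    "SignalGroup",
    "isp_radial_profile",
    "RadialProfile",
    "ttest_two_tailed",
]

#: Radial window edges (µm) used for periphery-distance bar diagrams.
DEFAULT_EDGES_UM: tuple[float, ...] = (0.3, 0.5, 0.7, 0.9, 1.1, 1.3, 1.5)

#: Optical resolution floor (µm): distances below this are not resolvable,
#: so the first radial window absorbs everything beneath it.
FIRST_CUTOFF_UM: float = 0.24

#: RNA-FISH intensity (AU) at or below which a signal is called background.
BACKGROUND_AU: float = 100.0

REPLICATION_CLASSES: tuple[str, ...] = ("S/S", "D/S", "S/D", "D/D")


@dataclass(frozen=True)
class AlleleRecord:
    """One allele pair: OSE and MYC periphery distances plus annotations."""

    cell_id: str
    a_um: float
    b_um: float
    rep_ose: str = "S"
    rep_myc: str = "S"
    signal_au: float | None = None

    def __post_init__(self) -> None:
        if self.a_um < 0 or self.b_um < 0:
            raise ValueError("periphery distances must be >= 0")
        if self.rep_ose not in ("S", "D") or self.rep_myc not in ("S", "D"):
            raise ValueError("replication states must be 'S' or 'D'")


def c_value(record: AlleleRecord | pd.Series) -> float:
    """Signed radial offset c = b - a (µm) between MYC and OSE signals.

    Negative values mean the MYC signal sits closer to the periphery than
    the OSE signal; c ≈ 0 indicates coordinated approach.
    """
    a = record.a_um if hasattr(record, "a_um") else record["a_um"]
    b = record.b_um if hasattr(record, "b_um") else record["b_um"]
    if a is None or b is None or math.isnan(float(a)) or math.isnan(float(b)):
        raise ValueError("both distances must be present to compute a c-value")
    return float(b) - float(a)


def c_values(records: pd.DataFrame) -> np.ndarray:
    """Vectorised c = b_um - a_um over an allele table."""
    a = records["a_um"].to_numpy(dtype=float)
    b = records["b_um"].to_numpy(dtype=float)
    if np.any(np.isnan(a)) or np.any(np.isnan(b)):
        raise ValueError("both distances must be present to compute c-values")
    return b - a


@dataclass(frozen=True)
class RadialBins:
    """Counts of periphery distances in half-open radial windows."""

    edges: tuple[float, ...]
    counts: tuple[int, ...]
    first_cutoff_um: float = FIRST_CUTOFF_UM

    @property
    def n(self) -> int:
        return int(sum(self.counts))

    @property
    def labels(self) -> tuple[str, ...]:
        e = self.edges
        inner = [f"[{e[i]:g}, {e[i + 1]:g})" for i in range(len(e) - 1)]
        return (f"<{e[0]:g}", *inner, f">={e[-1]:g}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"window_um": self.labels, "count": self.counts})


def bin_distances(
    distances,
    edges=DEFAULT_EDGES_UM,
    first_cutoff_um: float = FIRST_CUTOFF_UM,
) -> RadialBins:
    """Bin periphery distances into radial windows.

    Binning is half-open ``[e_i, e_{i+1})``; everything below the first edge
    (including the unresolvable sub-cutoff zone) falls in the first window
    and everything at or beyond the last edge in the overflow window, so the
    counts always conserve the sample size.
    """
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    edges = tuple(float(e) for e in edges)
    if len(edges) < 1 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("edges must be strictly increasing")
    if edges[0] < first_cutoff_um:
        raise ValueError(
            f"first edge {edges[0]} below the resolution floor {first_cutoff_um}"
        )
    full = np.concatenate([[-np.inf], edges, [np.inf]])
    counts, _ = np.histogram(d, bins=full)
    return RadialBins(edges=edges, counts=tuple(int(c) for c in counts),
                      first_cutoff_um=first_cutoff_um)


# ---------------------------------------------------------------------------
# Kolmogorov–Smirnov machinery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KSResult:
    D: float
    p: float
    n1: int
    n2: int
    mode: str = "asymptotic"

    def __post_init__(self) -> None:
        if not (0.0 <= self.D <= 1.0):
            raise ValueError("D must lie in [0, 1]")
        if not (0.0 < self.p <= 1.0):
            raise ValueError("p must lie in (0, 1]")


def _ks_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """sup_t |ECDF_x(t) - ECDF_y(t)| evaluated at all pooled points."""
    x = np.sort(x)
    y = np.sort(y)
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / x.size
    cdf_y = np.searchsorted(y, pooled, side="right") / y.size
    return float(np.max(np.abs(cdf_x - cdf_y)))


def _ks_exact_p(x: np.ndarray, y: np.ndarray, d_obs: float) -> float:
    """Permutation-exact p: fraction of the C(n1+n2, n1) label splits of the
    pooled sample whose KS statistic is >= the observed one.

    Enumerating index splits of the pooled multiset handles ties by weighting
    tie-consistent assignments by their multiplicity.
    """
    pooled = np.concatenate([x, y])
    n = pooled.size
    n1 = x.size
    count = 0
    total = 0
    idx = np.arange(n)
    for comb in combinations(idx, n1):
        mask = np.zeros(n, dtype=bool)
        mask[list(comb)] = True
        d = _ks_statistic(pooled[mask], pooled[~mask])
        if d >= d_obs - 1e-12:
            count += 1
        total += 1
    return count / total


_EXACT_LIMIT = 16  # C(16, 8) = 12870 splits; enumeration stays instant


def ks_two_sample(x, y, mode: str = "auto") -> KSResult:
    """Two-sample two-tailed Kolmogorov–Smirnov test.

    ``mode`` is ``"exact"`` (full enumeration of label permutations, feasible
    for n1+n2 <= 16), ``"asymptotic"`` (Kolmogorov limiting distribution of
    sqrt(n1 n2/(n1+n2)) D) or ``"auto"`` (exact when feasible).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    d = _ks_statistic(x, y)
    if mode not in ("auto", "exact", "asymptotic"):
        raise ValueError(f"unknown mode {mode!r}")
    use_exact = mode == "exact" or (mode == "auto" and x.size + y.size <= _EXACT_LIMIT)
    if use_exact:
        if x.size + y.size > 24:
            raise ValueError("exact enumeration infeasible for n1+n2 > 24")
        p = _ks_exact_p(x, y, d)
        return KSResult(D=d, p=max(p, np.finfo(float).tiny), n1=x.size, n2=y.size,
                        mode="exact")
    en = math.sqrt(x.size * y.size / (x.size + y.size))
    p = float(np.clip(special.kolmogorov(en * d), np.finfo(float).tiny, 1.0))
    return KSResult(D=d, p=p, n1=x.size, n2=y.size, mode="asymptotic")


# ---------------------------------------------------------------------------
# Cumulative distribution near the periphery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RestrictedECDF:
    """ECDF of periphery distances restricted to [0, limit].

    ``fractions`` are cumulative fractions at the sorted ``points``;
    ``convention`` records the denominator: ``"total"`` (fractions of the
    full sample, comparable across genotypes with different peripheral
    occupancy) or ``"within"`` (renormalised to alleles inside the window).
    """

    points: np.ndarray
    fractions: np.ndarray
    limit: float
    n_total: int
    n_within: int
    convention: str

    @property
    def empty(self) -> bool:
        return self.n_within == 0

    def __call__(self, t: float | np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if self.empty:
            return np.zeros_like(t)
        idx = np.searchsorted(self.points, t, side="right")
        padded = np.concatenate([[0.0], self.fractions])
        return padded[idx]


def cumulative_within(
    distances, limit: float = 1.0, renormalize: bool = False
) -> RestrictedECDF:
    """ECDF of distances within ``limit`` µm of the nuclear periphery.

    By default fractions are of the *total* sample; ``renormalize=True``
    divides by the within-window count instead.  An empty restriction is
    returned flagged (``.empty``) rather than raising.
    """
    if limit <= 0:
        raise ValueError("limit must be > 0")
    d = np.asarray(distances, dtype=float)
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    inside = np.sort(d[d <= limit])
    n_total = d.size
    n_within = inside.size
    denom = n_within if renormalize else n_total
    points, counts = np.unique(inside, return_counts=True)
    fractions = np.cumsum(counts) / denom if denom > 0 else np.array([])
    return RestrictedECDF(
        points=points,
        fractions=fractions,
        limit=limit,
        n_total=n_total,
        n_within=n_within,
        convention="within" if renormalize else "total",
    )


# ---------------------------------------------------------------------------
# Stratifications
# ---------------------------------------------------------------------------


def stratify_replication(records: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition an allele table by replication-state class.

    Classes follow the cell-cycle reading of paired FISH doublets:
    ``S/S`` un-replicated (primarily G1), ``D/S`` MYC replicated first,
    ``S/D`` OSE replicated first, ``D/D`` both replicated (late S + G2).
    The four groups are disjoint and jointly exhaust the input.
    """
    for col in ("rep_myc", "rep_ose"):
        if col not in records.columns:
            raise ValueError(f"missing column {col!r}")
        bad = ~records[col].isin(["S", "D"])
        if bad.any():
            raise ValueError(f"invalid replication states in {col!r}")
    key = records["rep_myc"].str.cat(records["rep_ose"], sep="/")
    return {cls: records[key == cls] for cls in REPLICATION_CLASSES}


@dataclass(frozen=True)
class ThresholdScanResult:
    """KS significance profile over periphery-distance thresholds."""

    thresholds: tuple[float, ...]
    results: dict[float, KSResult]
    skipped: tuple[float, ...]
    best_threshold: float

    @property
    def best(self) -> KSResult:
        return self.results[self.best_threshold]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"threshold_um": w, "D": r.D, "p": r.p, "n1": r.n1, "n2": r.n2}
            for w, r in sorted(self.results.items())
        ]
        return pd.DataFrame(rows)


def threshold_scan(
    dist_a, dist_b, thresholds=DEFAULT_EDGES_UM, mode: str = "asymptotic"
) -> ThresholdScanResult:
    """Scan periphery-distance thresholds for the most significant KS split.

    For each threshold ``w`` both samples are restricted to distances <= w
    and compared by the KS test; the scan reports the threshold minimising
    the p-value (ties resolved toward the smallest w).  Thresholds at which
    either restricted sample is empty are skipped and flagged.
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    thresholds = tuple(float(w) for w in thresholds)
    if len(thresholds) < 1:
        raise ValueError("need at least one threshold")
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    results: dict[float, KSResult] = {}
    skipped: list[float] = []
    for w in thresholds:
        ra = a[a <= w]
        rb = b[b <= w]
        if ra.size == 0 or rb.size == 0:
            skipped.append(w)
            continue
        results[w] = ks_two_sample(ra, rb, mode=mode)
    if not results:
        raise ValueError("every threshold emptied one of the samples")
    best = min(sorted(results), key=lambda w: results[w].p)
    return ThresholdScanResult(
        thresholds=thresholds,
        results=results,
        skipped=tuple(skipped),
        best_threshold=best,
    )


@dataclass(frozen=True)
class SignalGroup:
    """One RNA-signal stratum with Tukey box statistics of OSE distance."""

    label: str
    records: pd.DataFrame = field(repr=False)
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def iqr(self) -> float:
        return self.q3 - self.q1


def _box_stats(label: str, records: pd.DataFrame, value_col: str) -> SignalGroup:
    v = records[value_col].to_numpy(dtype=float)
    if v.size == 0:
        nan = float("nan")
        return SignalGroup(label, records, nan, nan, nan, nan, nan)
    # Type-7 (linear interpolation) quartiles — numpy's default; recorded in
    # output metadata because box statistics depend on the convention.
    q1, med, q3 = np.quantile(v, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    in_fence = v[(v >= q1 - 1.5 * iqr) & (v <= q3 + 1.5 * iqr)]
    return SignalGroup(
        label=label,
        records=records,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(in_fence.min()),
        whisker_high=float(in_fence.max()),
    )


def stratify_by_signal(
    records: pd.DataFrame,
    background_au: float = BACKGROUND_AU,
    class_edges=(200.0, 400.0),
    value_col: str = "a_um",
) -> dict[str, SignalGroup]:
    """Group alleles by RNA-FISH signal strength with box statistics.

    Records with ``signal_au`` below ``background_au`` form the background
    class — for these the peripheral position is still reported, determined
    by the DNA-FISH signal alone.  The remainder are grouped by ascending
    ``class_edges`` on the signal.  Each group carries median, quartiles
    (type-7) and Tukey whiskers (1.5 × IQR, clipped to observed data) of
    ``value_col``.
    """
    class_edges = tuple(float(e) for e in class_edges)
    if any(b <= a for a, b in zip(class_edges, class_edges[1:])):
        raise ValueError("class_edges must be strictly ascending")
    if "signal_au" not in records.columns:
        raise ValueError("records need a signal_au column")
    sig = records["signal_au"].to_numpy(dtype=float)
    groups: dict[str, SignalGroup] = {}
    bg_mask = sig < background_au
    groups[f"<{background_au:g} AU (background)"] = _box_stats(
        f"<{background_au:g} AU (background)", records[bg_mask], value_col
    )
    fg = records[~bg_mask]
    fg_sig = sig[~bg_mask]
    bounds = (background_au, *class_edges, np.inf)
    for lo, hi in zip(bounds, bounds[1:]):
        label = f"[{lo:g}, {hi:g}) AU" if np.isfinite(hi) else f">={lo:g} AU"
        mask = (fg_sig >= lo) & (fg_sig < hi)
        groups[label] = _box_stats(label, fg[mask], value_col)
    return groups


# ---------------------------------------------------------------------------
# ISPLA radial profile
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RadialProfile:
    """Histogram of proximity-ligation signal depths from the periphery."""

    edges: np.ndarray
    counts: np.ndarray
    modal_bins: tuple[int, ...]
    stable: bool

    @property
    def modal_band_um(self) -> tuple[float, float]:
        """Span (µm) covered by the modal bin(s)."""
        lo = min(self.modal_bins)
        hi = max(self.modal_bins)
        return float(self.edges[lo]), float(self.edges[hi + 1])


def isp_radial_profile(signal_distances, bin_width: float = 0.5) -> RadialProfile:
    """Radial shell counts of ISPLA signals and the modal depth band.

    The modal band is the bin (or bins, on ties) with maximum count; a tied
    mode is flagged as unstable (``stable=False``) since under a flat signal
    distribution the arg-max is not reproducible.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    d = np.asarray(signal_distances, dtype=float)
    if d.size == 0:
        raise ValueError("no ISPLA signals provided")
    if np.any(d < 0):
        raise ValueError("distances must be >= 0")
    n_bins = int(np.ceil(max(d.max(), bin_width) / bin_width))
    edges = bin_width * np.arange(n_bins + 1)
    # np.histogram closes the last bin; nudge so the maximum stays inside.
    counts, _ = np.histogram(d, bins=np.append(edges[:-1], edges[-1] + 1e-12))
    peak = counts.max()
    modal = tuple(int(i) for i in np.flatnonzero(counts == peak))
    return RadialProfile(edges=edges, counts=counts, modal_bins=modal,
                         stable=len(modal) == 1)


def ttest_two_tailed(x, y, equal_var: bool = True) -> tuple[float, float]:
    """Two-sample two-tailed Student's t test on replicate means.

    Pooled-variance by default (the convention for averaged independent
    experiments); ``equal_var=False`` gives Welch's form.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need at least two replicates per group")
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)
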