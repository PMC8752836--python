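# Methods

This note documents the models, statistical conventions and design choices
behind `genegate`, in the order of the analysis pipeline.

## Two-compartment mRNA kinetics

Pulse-labeled transcripts are tracked in a nuclear pool X and a cytoplasmic
pool Y:

    dX/dt = β − (k_e + λ_n)·X
    dY/dt = k_e·X − λ_c·Y,        X(t₀) = Y(t₀) = 0

with transcription rate β (molecules/min), first-order export k_e (1/min)
and compartment-specific decay λ_n, λ_c (1/min).  t₀ is the pulse-start
offset — the earliest time at which labeled transcription is measurable.
This is the minimal linear model consistent with a labeling assay whose
readout is the cytoplasmic/nuclear ratio of newly synthesised mRNA over
time; it assumes well-mixed pools, no export saturation and no bursting.
Units are minutes and arbitrary molecule units; only ratios are interpreted.

**Closed form.** The solution is written with `expm1`-based divided
differences (`(e^{−γτ} − e^{−λ_cτ})/(λ_c − γ)` evaluated via
`e^{−λ_cτ}·expm1((λ_c−γ)τ)/(λ_c−γ)`), so the degenerate eigenvalue case
λ_c = k_e + λ_n, the no-loss limits γ = 0 and λ_c = 0, and near-degenerate
parameters are all handled by the same continuous expressions; there is no
tolerance-based branch to tune.  A fixed-step RK4 integrator
(`simulate_compartments`) provides an internal cross-check with O(dt⁴)
error; an independent high-order integrator (scipy DOP853) serves as the
oracle in the tests.

**Pulse-chase.** A pulse of length p is modeled with the labeling source
active (β > 0) on [t₀, t₀+p) and zero afterwards; export and decay run
throughout.  Whether labeled RNA decays during the pulse itself is assay
dependent and not observable here, so a `decay_during_pulse` flag exists
(default on: decay active throughout).

**Steady state and expression ratios.** Y\* = β·k_e / ((k_e+λ_n)·λ_c).
When only the export rate differs between genotypes the predicted
expression ratio reduces to k_e,mut·(k_e,wt+λ_n) / (k_e,wt·(k_e,mut+λ_n)).
Note the structural consequence: with λ_n = 0 every transcript is
eventually exported and Y\* is independent of k_e, so export is an
expression lever only where nuclear decay competes with export.  The
acceptance script's illustration uses λ_n = k_e,wt, where a threefold
export reduction halves steady-state expression.

**Export-rate estimation.** `NuclearExportModel` fixes β, λ_n, λ_c (they
are measured in separate assays) and fits k_e alone by unweighted
least squares on linear-scale (X, Y) observations, using bounded scalar
minimisation (xatol 1e-12); uncertainty comes from a seeded bootstrap over
replicates (default 1000 resamples, percentile interval).  Noiseless data
are recovered to better than 1e-6; at 5 % multiplicative noise with 3
replicates the estimator's relative bias measures below 1 % over 200
simulations (recomputed by `scripts/acceptance.py`).

## Nuclear-periphery statistics

Distances arrive in µm as tabulated per-allele measurements (no image
processing).  Conventions:

* **c-value**: c = b − a with a = OSE distance, b = MYC distance to the
  periphery; c ≈ 0 with both small indicates coordinated recruitment.
* **Radial windows**: default edges 0.3–1.5 µm in 0.2 µm steps, half-open
  [e_i, e_{i+1}); the 240 nm optical resolution floor is merged into the
  first window (distances below the floor are not resolvable), and an
  overflow window catches everything ≥ the last edge, so counts always
  conserve n.
* **KS test**: two-sample, two-tailed; D is the supremum of the ECDF
  difference evaluated at all pooled points (ties handled by evaluation at
  observed values).  The exact mode enumerates all C(n1+n2, n1) label
  splits (feasible to n1+n2 = 16; C(16,8) = 12 870) and counts splits with
  D ≥ D_obs, which weights tie-consistent orderings by multiplicity.  The
  asymptotic mode uses the plain Kolmogorov limiting distribution of
  √(n1·n2/(n1+n2))·D: measured against the exact two-sample distribution at
  n1 = n2 = 50 it agrees to ~0.005, whereas the common small-sample
  effective-argument correction (designed for the one-sample statistic)
  overshoots by ~0.04 for equal n and is therefore not used.
* **Threshold scan**: for each threshold w both samples are restricted to
  distances ≤ w and compared by KS on the restricted samples (not by a
  proportion test — the scan asks where the *shape* difference near the
  periphery is sharpest); the reported window minimises p, ties resolved to
  the smallest w, thresholds emptying either sample skipped and flagged.
* **Cumulative distribution within 1 µm**: by default fractions are of the
  *total* sample, so curves are comparable across genotypes with different
  peripheral occupancy; a renormalise-within-window flag implements the
  alternative reading, and the convention is recorded on the result object.
* **Quartiles**: type-7 (linear interpolation, numpy default); whiskers at
  1.5×IQR clipped to observed data.  Recorded in the output because box
  statistics depend on the convention.
* **RNA-signal stratification**: intensities below 100 AU form a background
  class whose peripheral position is still reported (determined by the DNA
  FISH signal alone); remaining records are grouped by ascending intensity
  edges.

## CRISPR off-target audit

* **Scanner**: every 22-mer (19 nt protospacer + 3 nt PAM) on either strand
  whose protospacer differs from the guide at ≤ 5 positions (mismatches
  counted in the protospacer only) and whose PAM matches the IUPAC pattern
  (default NGG; ambiguous genome bases never match).  Minus-strand sites are
  detected on forward coordinates by matching the reverse-complement
  pattern, so reported spans are always forward-strand 0-based half-open.
  The implementation is vectorised over sliding windows; an exhaustive
  per-position brute force is the test oracle, and strand symmetry
  (scanning the reverse-complemented genome mirrors the site set exactly)
  is asserted as an invariant.  Bulged (gapped) alignments are out of scope.
* **Consensus**: a variant is accepted only when present in all callers'
  sets, keyed on (chrom, pos, ref, alt); the operation is commutative and
  associative and the consensus is a subset of every input.  Clone-shared
  variants are the key-intersection of two consensus sets, reported with
  per-class (indel/SNV) counts.
* **sgRNA association**: the 22 bp window centred on the variant (11 bp
  flank each side, clipped and flagged at contig ends — the window anchor
  is our reading, since "adjacent" does not define one) is compared with
  the 22 bp guide on both strands; the variant is associated iff the
  longest exact common substring reaches 12 nt.  This reproduces a
  100 %-identity BLAST word-size filter without a BLAST dependency; a
  quadratic dynamic-programming LCS is the test oracle.
* **Coordinates**: external 1-based inclusive, internal 0-based half-open,
  with round-trip-tested converters.  Insertion reference spans count as
  1 bp; variant/site overlap is exact intersection by default with an
  optional ±N bp proximity window.

## Co-culture fitness

Under constant exponential growth of both populations the WT/mutant allele
ratio follows r(t) = r₀·e^{s·t}; s (per day) is estimated by OLS of
log r on time.  Log-linear OLS is chosen over a nonlinear exponential fit
for identifiability at 4–8 time points; it is exact on noiseless
exponentials and scale-equivariant (rescaling all ratios moves only the
intercept).  The drug effect is summarised as the fold-change
s_control/s_treated — our operationalisation of a "reduced growth
advantage"; an endpoint-ratio alternative can be formed from
`SelectionResults.predict`.  Its confidence interval is a studentized
residual bootstrap (bootstrap-t on log fold): log-scale residuals, inflated
by √(n/(n−2)) to undo the OLS variance deficit, are resampled onto the
fitted series and the t-pivot quantiles applied — plain pairs or percentile
residual bootstraps measurably undercover at these sample sizes (88 % and
86 % vs the 92.5 % of the shipped interval at nominal 95 % in a 200-trial
simulation).  `time_to_dominance` converts (s, r₀) to the first day the WT
fraction r/(1+r) reaches a threshold via t = (logit(θ) − log r₀)/s.

## Synthetic data

The generators produce inputs with the statistical structure the analyses
assume; all randomness flows from one explicit seed per call.

* **Radial positions**: a two-component mixture — exponential near the
  periphery (scale 0.35 µm) plus a zero-truncated normal interior (mean
  2.0 µm, sd 0.8 µm).  The family is our choice; it was picked for a
  monotone periphery-proximal tail matching binned FISH histograms.  The
  gating-competent ("WT-like") parameterisation puts 45 % of alleles in the
  peripheral pool with copula coupling 0.8 between the OSE and MYC draws of
  one allele pair; the edited ("mutant-like") parameterisation reduces
  these to 15 % and 0.2.  Coupling is implemented as a shared latent
  Gaussian factor (weight √coupling) pushed through the mixture quantile
  function on a dense grid; at coupling → 1 both loci share a quantile and
  c → 0.  Replication classes (S/S, D/S, S/D, D/D; defaults 0.50/0.15/
  0.15/0.20) are sampled independently of position.  The RNA signal is
  background + slope·distance with multiplicative lognormal noise (CV 0.2),
  floored at 0 AU.  Three allele pairs per WT cell and two per mutant cell
  reflect the cell lines' copy numbers.  Noise levels are free parameters
  chosen to look like routine FISH data, not estimates of any particular
  dataset; the generator does not emulate segmentation error, optical
  anisotropy or cell-to-cell nuclear-size variation, so passing tests
  validate the statistics, not microscope pipelines.
* **Pulse-chase**: means follow the closed-form two-stage solution (30 min
  pulse, 60 min chase, six sampling points by default); replicates receive
  independent multiplicative lognormal noise with unit mean.
* **Toy genomes**: i.i.d. background at a configurable GC (default 0.41),
  with guide-derived sites planted at exact protospacer mismatch counts and
  concretely valid or provably invalid PAMs; non-overlap and in-bounds are
  enforced and the truth table is re-extractable from the sequence.
* **Callsets**: each caller drops true variants independently at its
  false-negative rate and adds Poisson(fp_rate × n_truth) spurious calls at
  loci disjoint from the truth and from other callers' spurious calls — so
  with fn = 0 the consensus provably equals the truth whatever the fp rates.
* **Co-culture**: r₀·e^{s·t} with multiplicative lognormal noise.

## Problem sizes

The shipped validation uses 50 kb toy genomes (10 planted sites), 200-draw
recovery ensembles, 400-point radial samples and 200-replicate bootstrap
intervals; all were chosen so the complete suite and the acceptance script
each run in well under a minute of CPU apiece while leaving the Monte-Carlo
margins (3–4 standard errors) comfortably resolvable.

## Known limitations

* The kinetic model is deterministic and linear: no transcriptional
  bursting, export saturation or absolute molecule calibration.
* The exact KS mode is combinatorial and capped at n1+n2 = 24.
* The off-target scanner does not model DNA/RNA bulges, alternative Cas
  PAMs beyond an IUPAC pattern, or chromatin accessibility.
* Selection coefficients assume time-constant fitness; a drug that acts
  transiently would violate the log-linear model and shows up as lack of
  fit (inspect `SelectionResults.rsquared` and residuals).
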