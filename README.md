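# genegate

Quantitative analyses of nuclear-pore **gene gating** — the recruitment of an
active gene to the nuclear pore so that transcription is coupled to
facilitated mRNA export.  The motivating system is the colorectal-cancer
oncogene *MYC* in HCT-116 cells: a CTCF binding site (CTCFBS) inside the
*CCAT1* intron of the oncogenic super-enhancer (OSE) tethers the OSE, and
with it *MYC*, to the nuclear periphery in a WNT-dependent manner.  Editing
8 bases of that CTCFBS abolishes the tether, slows *MYC* mRNA export more
than threefold, lowers steady-state *MYC* expression and costs the cells
their growth advantage in co-culture.

The package provides, for analysts working with this kind of data:

* **`genegate.kinetics`** — the two-compartment model of pulse-labeled
  nuclear (X) and cytoplasmic (Y) mRNA,

  dX/dt = β − (k_e + λ_n)·X,  dY/dt = k_e·X − λ_c·Y,  X(t₀) = Y(t₀) = 0,

  with closed-form and Runge–Kutta solutions, the cytoplasmic/nuclear export
  ratio Y/X, steady-state expression Y\* = β·k_e / ((k_e+λ_n)·λ_c), predicted
  WT-vs-mutant expression ratios, and `NuclearExportModel` — a least-squares
  inverse problem recovering the export rate k_e from pulse-chase replicates
  with a bootstrap confidence interval.
* **`genegate.topology`** — statistics of DNA-FISH allele positions relative
  to the nuclear periphery: the c-value c = b − a (MYC minus OSE distance;
  c ≈ 0 at the periphery signals coordinated recruitment), radial windows
  with a 240 nm resolution floor, two-sample two-tailed Kolmogorov–Smirnov
  tests with an exact enumeration mode, cumulative distributions within 1 µm,
  replication-state (S/S, D/S, S/D, D/D) and RNA-signal stratification with
  Tukey box statistics, a periphery-threshold significance scan, and ISPLA
  radial profiles.
* **`genegate.audit`** — a GOTI-style CRISPR off-target audit: a Cas-OFFinder
  style PAM-aware mismatch scanner (19 nt protospacer + NGG, ≤5 mismatches,
  both strands), three-caller consensus calling, clone-shared variant
  accounting, a 100 %-identity word-size (≥12 nt) sgRNA-association filter,
  variant/off-target interval overlap, and edit accounting for the printed
  CTCFBS sequences.
* **`genegate.fitness`** — selection-coefficient estimation from co-culture
  WT/mutant allele-ratio series (`SelectionModel`, log-linear OLS), drug
  fold-change of the growth advantage, and time-to-dominance.
* **`genegate.simulate`** — seeded synthetic-data generators for every input:
  radial mixture FISH tables, ODE pulse-chase replicates, toy genomes with
  planted off-target sites, caller-specific variant sets, and exponential
  allele-ratio drift.

## Worked example

```python
import numpy as np
from genegate import (TranscriptKinetics, NuclearExportModel,
                      steady_state_cytoplasmic, gen_pulse_chase,
                      gen_coculture, fit_selection)

# Forward model: MYC-like kinetics in minutes.
k = TranscriptKinetics(beta=10.0, k_e=0.2, lambda_n=0.2, lambda_c=0.03)
print(round(steady_state_cytoplasmic(k), 2))          # 166.67

# Simulate a 30 min pulse / 60 min chase with 3 replicates at 5% noise,
# then recover the export rate.
data = gen_pulse_chase(k, pulse_min=30, chase_min=60, n_reps=3, cv=0.05, seed=1)
fit = NuclearExportModel(data, beta=10.0, lambda_n=0.2, lambda_c=0.03,
                         pulse_min=30.0).fit(n_boot=200, seed=2)
print(fit.summary())
# Nuclear export rate fit (two-compartment model)
# ================================================
# observations      : 18
# replicates        : 3
# beta (fixed)      : 10 /min
# lambda_n (fixed)  : 0.2 /min
# lambda_c (fixed)  : 0.03 /min
# k_e (fitted)      : 0.202331 /min
# residual SSR      : 103.097
# bootstrap SE      : 0.00154
# 95% CI            : [0.198894, 0.204696]

# Competitive fitness from a co-culture allele-ratio series.
series = gen_coculture(s=0.3, days=np.arange(0, 15, 2.0), cv=0.1, seed=7)
print(round(fit_selection(series).s, 3))              # 0.304
```

The fitted k_e (0.20/min) recovers the simulated export rate within its
bootstrap interval; the selection coefficient 0.304/day (true value 0.3)
means the WT/mutant allele ratio grows e-fold every ~3 days, so an
equal-start co-culture passes 90 % WT within a week.

A command-line surface mirrors the library:

```bash
ggk simulate nuclei --n-cells 250 --genotype WT --seed 1 --out wt.tsv
ggk simulate nuclei --n-cells 250 --genotype E4 --seed 2 --out e4.tsv
ggk topology scan --in-a wt.tsv --in-b e4.tsv --out scan.json
ggk audit scan --genome genome.fa --guide GTCACGGTACCGAGCACAT --out sites.bed
```

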