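# Methods

This note records the models, estimators, numerical choices and known
limitations behind `refstab`, in the order data flows through the
pipeline.

## Data model

A `CpMatrix` is a targets × samples matrix of crossing points with an
explicit boolean missingness mask, a role per target (miRNA, endogenous
candidate, isolation/cDNA spike-in, interplate calibrator, U6-snRNA
reference, blank) and a plate label per sample.  Masked cells are stored
as NaN, so any computation that accidentally consumed an undetected
value would poison its output rather than silently bias it.  Cp is
treated throughout as a log2-scale quantity under the efficiency-2
amplification assumption: Cp differences are log2 expression ratios,
and no linear-scale transformation is applied anywhere (this also keeps
the ΔCt and geNorm statistics exactly comparable).

Cp tables are plain CSV/TSV with a `#` header comment documenting the
fixed 4-decimal write format; `""`, `NA`, `NaN`, `Undetermined` and
`Undet.` are all read as missing because instrument exports vary, and a
decimal-comma flag (off by default) tolerates continental-format
exports.  Both targets-in-rows (canonical) and samples-in-rows layouts
are accepted and produce identical matrices.

## Interplate calibration

Plate offset = (plate's mean IPC Cp) − (grand mean of per-plate IPC
means), subtracted from every observed Cp on the plate.  The grand-mean
reference was chosen because it is symmetric and invariant to plate
ordering, and makes offsets sum to zero; a first-plate reference is
available by flag.  Consequences worth knowing: within-plate Cp
differences are preserved exactly, and adding a constant c to one of P
plates is undone up to a global shift of c/P (exactly undone under the
first-plate reference).  Calibration precedes QC; a plate with no
observed IPC value is a hard error.

## Spike-in QC

The isolation spike-ins are mixed at 100-fold concentration steps, so
the expected Cp gap per step is log2(100) ≈ 6.64 cycles.  A sample
fails when UniSp2 Cp > 30, when UniSp4 − UniSp2 lies outside the
inclusive [5, 8] window, or when either spike-in is undetected; rule
ids are recorded per sample.  UniSp5 (spiked at a weakly-expressed
level and legitimately undetectable), UniSp6 and cel-miR-39-3p are
reported but never trigger exclusion, since no defensible threshold
exists for them.  The returned analysis matrix drops failing samples
and every control-role row.

## Missingness

Cp ≥ 35 (the limit of detection, configurable) is masked; the operation
is idempotent and monotone in the threshold.  Targets are then
classified by missing ratio: complete (0), imputable (strictly below
20%), excluded (otherwise).  The strict inequality matters at the
boundary: 18.75% of 48 samples is imputable, 20.0% is not.  Control
assays are never classified.  Missingness–covariate association uses
the binary missing indicator per target: Kruskal–Wallis for continuous
covariates, Pearson chi-squared without continuity correction for
discrete ones (the contingency table may have k > 2 columns; a
correction flag exists).  These tests are descriptive: they are
reported with no multiplicity correction and never gate imputation.  A
covariate constant across all samples is skipped with a reason; two
groups with identical non-degenerate distributions give H = 0, p = 1.

## Imputation

All four methods leave observed cells bit-identical, record the imputed
cell set, and operate on the calibrated, QC-passed, LOD-masked matrix
restricted to complete + imputable targets.

* `imp_na_35`: constant Cp 35 — encodes "absent means at the limit".
* `imp_max_one`: per-target observed max + 1 cycle.
* `imp_missF` (missForest): initialise missing cells with per-target
  means; sweep targets in ascending-missingness order, each sweep
  refitting a random-forest regression (100 trees, mtry = ⌊√p⌋) of the
  target's observed entries on all other targets and refreshing its
  imputed cells; stop when the normalised squared change
  Σ(X_new − X_old)²/ΣX_new² over imputed cells first increases,
  returning the previous sweep (or at 10 sweeps, flagged
  non-converged).  Tree seeds are drawn from one run seed, so output is
  bit-reproducible.
* `imp_VIM` (kNN): donor distance is the Gower distance — per-target
  absolute difference divided by that target's observed range
  (zero-range targets contribute 0), averaged over targets observed in
  both samples; the k = 5 nearest donors holding the target observed
  supply the median (mean by flag).  Donors lacking the target are
  skipped with the next-nearest promoted; fewer than k usable donors is
  a warning, zero is an error.

Hyperparameters follow the named algorithms' published defaults; no
pooling across multiply-imputed draws is done — each imputed dataset is
analysed singly, which is precisely the design contrast the workflow
grid exposes.

## Stability algorithms

All run on a complete-case matrix of at least 3 targets.

* **Comparative ΔCt**: mean over partner genes of the n−1 sample SD of
  the pairwise Cp difference.
* **BestKeeper**: mean absolute deviation of a gene's Cp about its
  geometric mean (the "SD [± Cp]" descriptor).  An arithmetic-SD
  variant exists behind a flag because published BestKeeper tables are
  ambiguous between the two; the MAD-about-geometric-mean default is
  the variant whose values are visibly smaller than the plain SD, which
  matches how consensus tools report it.  BestKeeper is deliberately
  *not* invariant to per-sample shifts (it never compares genes within
  a sample) — the suite asserts this differentially.
* **NormFinder** (ungrouped): with d_ig the sample-centred Cp and u_g
  its per-gene variance, total S is estimated by (G/(G−1))Σu_g and
  σ̂²_g = max(0, (u_g − S/G²)·G/(G−2)).  This moment estimator is
  consistent under the additive model; the suite checks mean recovery
  of generating σ_g within 10% at n = 200.  With a sample grouping a
  simplified grouped variant combines the mean within-group σ̂ with the
  between-group SD of the gene's centred level; it is a secondary path
  and its values are not comparable to the ungrouped ones.
* **geNorm**: M = mean pairwise-difference SD on the current gene set;
  the largest-M gene is removed (ties broken by lexicographic id,
  logged) and its M at removal is its value; the final two genes share
  the final M and jointly rank 1, with rank 3 next.  The
  pairwise-variation V(n/n+1) statistic for choosing how many
  references to use is out of scope.
* **Consensus**: competition ranks (ties share the minimum rank, the
  next rank skips) per algorithm, aggregated by unweighted geometric
  mean and re-ranked.  Verifiable by hand: (1, 8, 1, 1) → 1.682,
  (2, 1, 2, 6) → 2.213.

## Normalization and CoV

ENDO subtracts the per-sample geometric mean of the chosen stable
endogenous controls (taken over Cp values literally; an
arithmetic-mean-of-Cp flag gives the classic
geometric-mean-of-quantities alternative); U6 subtracts the single
reference assay; global mean subtracts the per-sample arithmetic mean
over all retained miRNAs, excluding U6-snRNA and controls by default
(U6 is not a miRNA; a toggle includes it).  All three are per-sample
shifts, so within-sample contrasts are untouched.  The coefficient of
variation is reported in percent, 100·SD/mean of Cp per target —
observed cells only on masked data, every cell on imputed data.

## Survival screening

Univariate Cox per miRNA on the normalized ΔCp, per 1-cycle unit,
unstandardized.  Fitting uses lifelines' partial likelihood with Efron
tie handling; the Wald p and 95% CI come from the fit, and the reported
"log-rank" p is the score test at β = 0 with Efron ties — the
continuous-covariate generalisation of the log-rank test, implemented
here and cross-checked in the suite against `survival::coxph`'s score
test in R.  Degenerate inputs (no events, constant covariate) yield
rows flagged non-estimable.  The screen applies no multiplicity
correction (a per-miRNA P < 0.05 read-out; Benjamini–Hochberg is
available but off).  The workflow grid crosses {complete cases, four
imputations} × {ENDO, U6, global mean}; the complete-case arm can only
scan complete-case targets, which is what makes candidates with
missing values visible exclusively in imputed workflows.

## Synthetic cohorts

The generator draws Cp_ig = α_g + β_i + plate_g(i) + group + ε_ig with
β_i ~ N(0, τ²) (τ = 1 cycle — wide RNA-input variation typical of FFPE
material), plate offsets ~ N(0, 0.5²), and gene noise σ_g from 0.2
(designed-stable) to 2.0.  Spike-ins carry the plate offset plus 0.1
cycles of technical noise but no sample effect (they are added at fixed
amounts after lysis); the isolation spike-ins sit 6.64 cycles apart.
Cells ≥ 35 are censored (MNAR by construction: high-Cp targets lose
cells preferentially — the mechanism that makes constant imputation
inflate the CoV), plus 1% MCAR technical dropout on miRNA assays;
spike-ins, IPC and U6-snRNA are detected in every sample by design, as
a usable reference must be.  Survival is exponential with rate
h0·exp(γ·(Cp − mean)) on the designated prognostic target, h0 =
ln 2/31.3 per month (median OS ≈ 31 months), with independent
exponential censoring tuned to a 30% censored fraction (exact for
γ = 0).  Default scale: 48 samples on 6 plates of 8, 40 miRNAs +
U6-snRNA + 6 controls + blank, matching a custom-panel tumour study.

The default prognostic effect is HR 0.5 per Cp with a baseline of 32.8
cycles, high enough to brush the detection limit (typically 5–15%
missing cells).  Because a binomial draw at n = 48 occasionally
realizes 0 or > 20% missing cells, `generate_study_cohort` redraws
deterministically from the seed until the designed condition (missing
ratio strictly between 0 and 20%) holds — analyses of the
imputed-vs-complete-case contrast are conditional on that design being
realized.

What the generator does **not** emulate: amplification-efficiency
heterogeneity between assays, FFPE degradation gradients, correlated
gene modules (genes are conditionally independent given the sample
effect), and informative censoring.  Passing tests therefore show the
pipeline recovers truth under the additive model; they cannot certify
behaviour under, e.g., efficiency drift.

## Problem sizes and numerical notes

Simulation-backed checks use deliberately modest sizes: 100 cohorts of
20 targets × 48 samples for designed-stable recovery, 100 replicates at
n = 200 for NormFinder calibration, 1000 cohorts at n = 48 for the Cox
null error rate, and 50 LOD-censored cohorts for the imputation CoV
sign test.  Stability values are ≥ 0 by construction; NormFinder
truncates negative moment estimates at 0; geNorm tie-breaks and the
kNN donor ordering are stable sorts, so all outputs are exactly
reproducible.  The acceptance script derives every child seed from the
single `--seed` via `numpy` seed sequences.

## Known limitations

* The grouped NormFinder path is a simplified variant, not the full
  published two-group estimator with shrunken group differences.
* BestKeeper's descriptor ambiguity (MAD vs SD) is resolved by flag,
  not by reconciliation against a reference implementation.
* Cox HRs on imputed data are attenuated relative to the generating
  effect because detection-limit censoring removes the most informative
  cells; this is a property of the design being studied, not a bug to
  calibrate away.
* GEO series-matrix ingestion is not implemented; external cohorts can
  be analysed by exporting them to the package's plain Cp-table format
  (a user-supplied alias map can unify assay names at that step).
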