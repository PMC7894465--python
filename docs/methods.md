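# Methods

## Problem setting

`mrscreen` implements the computational arm of a direct-reprogramming
factor discovery: given probe-level expression-array data for four cell
populations — a reprogramming **source** (e.g. dedifferentiated fat, DFAT,
cells), its **source-origin** tissue (mature adipocytes), the desired
**target** fate (hepatocytes) and the corresponding **target-stem**
population (resident liver stem cells) — find transcription factors that
are expressed in target and target-stem but absent from source and
source-origin. Such factors are candidate master regulators: forcing
their expression in the source population is expected to redirect it
toward the target fate.

The screen operates at the probe-set level of Affymetrix-style arrays,
where each transcript is interrogated by ~11 perfect-match/mismatch (PM/MM)
probe pairs, and only collapses to gene symbols at the last step.

## Preprocessing

### RMA expression values

The robust multiarray average is implemented from its definition:

1. **Background correction** (per array, PM only). Observed intensity is
   modeled as X = B + S with B ~ N(mu, sigma^2) background and
   S ~ Exp(alpha) true signal. Parameters are fitted by maximum
   likelihood of the convolution density
   f(x) = (1/alpha) exp((mu-x)/alpha + sigma^2/(2 alpha^2)) Phi((x - mu -
   sigma^2/alpha)/sigma), using L-BFGS-B on (mu, log sigma, log alpha)
   from a method-of-moments start (alpha from the third central moment).
   Intensities are rescaled by their mean before fitting, which makes
   the estimate exactly scale-equivariant for power-of-two factors and
   numerically equivariant otherwise. Each PM value is replaced by the
   posterior mean E[S | X = x] = a + sigma phi(a/sigma)/Phi(a/sigma),
   a = x - mu - sigma^2/alpha, evaluated in log space so it stays finite
   and strictly positive far below the background mean. Degenerate
   arrays (all intensities equal) are rejected with instructions to skip
   background correction.
2. **Quantile normalization** across arrays: each column is replaced,
   rank for rank, by the across-array means of the sorted columns. Ties
   keep their original order (stable sort); the operation is therefore
   idempotent and all post-normalization columns share one multiset of
   values exactly.
3. **log2 transformation.**
4. **Median polish** per probe set of the additive model
   log2(PM) = overall + probe effect + sample effect, by Tukey's
   alternating median sweeps (even-length medians are the mean of the
   central pair). The reported summary is overall + sample effect.

Numerical choice: median-polish sweeps run until the largest absolute
change of the residual matrix drops below 1e-13 (at most 2000
iterations; random blocks typically converge in ~30 sweeps, worst
observed ~320). A loose schedule of the kind some implementations use
(tolerance 0.01, 10 sweeps) was measured to leave summaries up to ~3e-2
away from the fixed point; tight convergence makes the summaries
reproducible to 1e-9 against an independently coded sweep at negligible
cost, so it is the default. Both knobs are exposed
(`median_polish_summarize(..., tol=, max_iter=)`).

Probe sets in the output matrix are sorted lexicographically, making the
result invariant to input row order; MM probes never enter this path.

### Detection calls

For each probe set and sample, probe pairs yield discrimination scores
R_i = (PM_i - MM_i)/(PM_i + MM_i) in (-1, 1). A one-sided Wilcoxon
signed-rank test of median(R) > tau gives a detection p-value p, and the
call is Present (p < alpha1), Absent (p > alpha2) or Marginal otherwise,
with the Affymetrix Statistical Algorithms defaults tau = 0.015,
alpha1 = 0.04, alpha2 = 0.06 (all exposed via `DetectionParams`). Calls
are computed on raw intensities, independently of RMA.

The signed-rank p-value is exact for n <= 12 scores after zero removal:
the null distribution of W (sum of positive ranks) over all 2^n sign
assignments is built by convolution over the doubled ranks, which also
handles midranks from tied |R - tau|. Scores equal to tau are discarded
(classic zero-removal); if every score is discarded, p = 1. Above
n = 12 a tie-corrected normal approximation without continuity
correction is used; with 11-pair probe sets the exact path is the one
real data takes. Saturation handling and probe-pair discarding rules of
the original commercial implementation are deliberately not modeled —
the synthetic data has no saturation and published analyses rarely
document those thresholds.

## The screen

With roles resolved by a `GroupDesign`, the pipeline computes:

* four **up-sets**: probe sets whose group-mean log2 expression is more
  than `fold_threshold` (default 2.0, i.e. four-fold) higher in target
  (and target-stem) than in source (and source-origin); the comparator
  is strict `>` by default and switchable to `>=`
  (`ScreenConfig.strict_inequality`), since published descriptions of
  such screens use both phrasings;
* the **fold intersection** of the four up-sets;
* four **call sets**: Present in every replicate of target and
  target-stem, Absent in every replicate of source and source-origin.
  Aggregation across replicates defaults to `all`; `majority` (> half)
  is provided for designs with single-array groups, and Marginal can
  optionally count toward either call;
* the **call intersection** and the **combined** overlap
  (fold ∩ call);
* the final **gene list**: combined probe sets mapped to gene symbols
  (case-sensitive after trimming; unannotated probe sets are dropped
  only here, with a count, so probe-set-level stage counts stay
  annotation-independent), a gene passing if any of its probe sets
  passes, intersected with a transcription-factor class list and
  returned sorted.

Monotonicity properties follow from the definitions and are enforced by
tests: raising the fold threshold or switching from majority to all
aggregation never enlarges any stage set.

## Synthetic data generator

The generator emulates the probe-level data such a four-population study
produces, with a planted ground truth. Per probe pair and sample:

    PM = bg + signal * affinity * noise_pm
    MM = bg + mm_leak * signal * affinity * noise_mm

* `bg ~ N(background_mu, background_sigma^2)` is drawn once per pair and
  shared by PM and MM — the two probes of a pair sit adjacent on the
  array, so their optical/cross-hybridization background is common.
* `signal` is `signal_scale` for an off gene and
  `signal_scale * 2**effect_log2` for an on gene (defaults 4 and 64).
* `affinity` is a per-probe log-normal sequence effect (median 1,
  log-sd 0.25) shared across samples — the probe effect that median
  polish exists to remove.
* `noise_*` are independent mean-1 log-normal noises with CV 0.1.

Three planted **regulators** are on exactly in target and target-stem;
for each of the 15 other on/off patterns over the four roles, 20 decoy
genes are planted, so every elimination path of the screen (every Venn
region) is exercised; the remaining genes are constitutively off
background. The TF annotation contains all regulators plus half of the
decoys; 5% of background probe sets are left unannotated; 10% of genes
get two probe sets (exercising gene collapse). All draws come from one
seeded generator in a fixed documented order, so datasets are
bit-reproducible.

### Calibration of the defaults

The defaults (background_mu = 200, background_sigma = 4,
signal_scale = 4, mm_leak = 0.05) were chosen once so that the
generator's stated calibration properties hold: off-gene discrimination
scores sit just below tau (median ≈ 0.95·4/(2·200) ≈ 0.0095 < 0.015,
giving Absent calls for ≥ 99% of off cells), on-gene scores sit far
above it (≈ 0.13, giving Present for ≥ 99% of on cells), and the
background scale is small enough relative to the off-gene signal that
the normexp posterior mean does not compress the planted +4 log2
difference out of its ±1 recovery envelope. This corner is cleaner than
real arrays — the constraints of simultaneously supporting MAS5-style
calls (which need off-gene scores below a 0.015 threshold) and a
quantifiable off-state after background correction force a low
background CV. Consequences for interpretation: passing tests show the
algorithms are correct and the pipeline recovers a planted truth under
faithful-but-clean conditions; they do not show robustness to
real-array phenomena the generator deliberately omits (saturation,
spatial artifacts, batch effects, sequence-dependent cross-
hybridization, heavy-tailed backgrounds).

## Validation strategy

* Signed-rank p-values are compared to brute-force enumeration over all
  2^n sign assignments, including tie and zero patterns.
* Median polish is compared to an independently coded bordered-matrix
  sweep run to 1e-13, and to exact shift equivariance on dyadic-grid
  inputs.
* Background adjustment is compared to numerical quadrature of
  E[S | X = x].
* The screen's stage sets are compared to from-definition brute-force
  set computations on a fixture containing every on/off pattern plus
  mixed-call, unannotated and multi-probe-set corner cases.
* End to end, 100 independently seeded studies at the reference
  conditions (2,000 genes, 11 pairs/probe set, 3 replicates × 4 groups,
  3 regulators at +4 log2, 20 decoys per pattern) are screened; the
  final gene list must equal the planted truth in ≥ 95 runs and contain
  every planted regulator in all runs. One study takes ~2.5 s on one
  CPU; problem sizes throughout the suite were chosen to keep full
  validation in the minutes range.

## Reproducing a published four-population screen

`mrscreen reproduce-geo` reruns the pipeline on externally converted
probe tables of deposited arrays (CEL parsing is out of scope; any CEL
reader can emit the documented TSV dialect) and prints this pipeline's
eleven stage counts next to the published reference values with
per-stage deltas. Counts are compared, never asserted: two RMA
implementations differing in background-estimator internals will not
agree bit for bit, and the final gene identity additionally depends on
the annotation and TF-class versions used.

## Known limitations

* Binary CEL/CDF parsing, GC-RMA/PLIER, MAS5 Tukey-biweight signal
  values, array QC and saturation handling are out of scope.
* The normal approximation branch of the signed-rank test (n > 12) uses
  no continuity correction; with standard 11-pair probe sets it is
  never taken.
* The generator's clean-background corner (above) understates real
  array noise; effect-size recovery margins on real data will be
  narrower.
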