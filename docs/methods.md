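# Methods

This note documents the statistical procedures `swisig` implements, the
choices made where a procedure is conventionally under-specified, and what
the synthetic-data generators do and do not emulate.

## Expression preprocessing

Counts are normalized by the weighted trimmed mean of M-values (TMM). The
reference is the sample whose upper quartile of count fractions is closest
to the mean upper quartile. For each sample, genes positive in both sample
and reference contribute a log ratio M, an average log abundance A, and an
inverse asymptotic-binomial-variance weight; after two-sided trims of 30% on
M and 5% on A the factor is two to the weighted mean of the surviving M
values, and factors are rescaled to geometric mean one.

*Numerical choice:* the double trim uses **ordinal ranks** (ties broken by
gene order). Midrank-based trimming is ill-defined when many genes share an
identical log ratio — an entire tied block can fall outside the keep window
and empty the trimmed set — which matters for near-duplicate samples and
for the exact-proportionality fixtures in the test suite.

Expression is summarised as `log2(CPM + 1)` with the effective library size
(raw depth × TMM factor); genes whose log2-CPM falls below 1 in more than
three samples are removed before testing. The three-sample rule is an
absolute threshold, exposed as a parameter, not scaled with cohort size.

## Differential testing

One empirical-Bayes moderated-t engine serves both RNA (knock-down vs
control, optional batch factor in the design) and protein (IP vs IgG)
comparisons. Per feature, an OLS fit of `value ~ group (+ batch)` yields a
coefficient, its unscaled standard error and a residual variance s² on d
degrees of freedom. The variances are shrunk toward a prior s₀² with prior
degrees of freedom d₀ obtained by moment-matching the log residual
variances (digamma/trigamma inversion, Newton iteration); the posterior
variance is `(d₀ s₀² + d s²)/(d₀ + d)` and the t statistic is referred to a
t distribution on `d + d₀` degrees of freedom. With a single feature there
is nothing to pool and d₀ falls back to 0 (ordinary t); when the
log-variance spread is no larger than its sampling noise d₀ is infinite
(fully shrunk). The implementation reproduces an independent reference
empirical-Bayes implementation to machine precision on a frozen fixture,
and its null type-I error at α = 0.05 is calibrated within (0.04, 0.06)
over 50 000 null features.

Features with missing values are fit on their observed samples; a feature
without at least two observations per group receives NA statistics.
Benjamini–Hochberg adjustment is step-up with monotonicity enforcement; NaN
p-values are ignored and do not count toward the number of tests.

This engine stands in for a count-based quasi-likelihood F-test on purpose:
the signature derivation needs a ranked table of fold changes and FDRs, not
a particular test family, and one engine shared between RNA and protein
keeps the pipeline small. The choice is recorded in the signature file
metadata.

## Signature derivation and scoring

Genes with |log2FC| ≥ 1.5 (log2 scale; the threshold is a parameter because
"fold change 1.5" is also a defensible reading at |log2FC| ≥ 0.585) and
FDR < 0.01 are ranked by FDR ascending, then |log2FC| descending, then gene
id, and truncated to the top 419. Weights default to the sign of the fold
change (`weight_mode="sign"`); the fold change itself is available behind
`weight_mode="log2fc"`. The ranking rule and weight mode are artifact
decisions — only "top N deregulated" and "weighted sum" are fixed by the
procedure being reproduced — and both are written into the signature file
header.

Scores are computed **within the cohort being scored**: each signature gene
is z-scored across the cohort's samples and the raw score is the weighted
sum of z-scores. Genes absent from the matrix or with zero variance are
skipped and logged. Raw scores are rescaled affinely so that the empirical
2.5% and 97.5% quantiles (linear, type-7 interpolation) map to −1 and +1;
constant score vectors are rejected. Quartile classes assign exactly
⌊n/4⌋ samples each to `low` and `high`, boundary ties broken by sample id.

## Association statistics

- **Fisher exact (2×2):** two-sided p sums hypergeometric probabilities
  (log-gamma evaluation) of all margin-consistent tables no more probable
  than the observed one, with 1e−7 relative slack against roundoff. The
  sample odds ratio ad/bc is reported (∞ when bc = 0). Verified against
  exact-rational enumeration and an independent library implementation.
- **Mann–Whitney U:** midranks for ties; exact p by complete enumeration of
  labelings when n ≤ 12 without ties, else normal approximation with
  tie-corrected variance and continuity correction.
- **Mann–Kendall:** S is the concordant-minus-discordant pair count over
  the series order. For tie-free series of up to 50 points the two-sided p
  is exact, from the permutation-null distribution of S computed by the
  inversion-count recursion; otherwise the normal approximation with
  tie-corrected variance and ±1 continuity correction is used. The exact
  path exists because at the series lengths this pipeline meets (deciles,
  n = 10) the normal approximation deviates from the permutation null by
  more than the accuracy the pipeline's own checks demand.
- **Two-proportion test:** pooled-variance score test whose z² equals the
  Pearson chi-square of the 2×2 table; a Yates-style continuity correction
  is available behind a flag, off by default (the variant is not fixed by
  the procedure being reproduced; both are logged).
- **Kaplan–Meier / log-rank:** product-limit estimator and the two-group
  log-rank chi-square from observed-vs-expected events over pooled risk
  sets with hypergeometric variance. Verified against an independent
  survival library. Multivariable (Cox) modeling is out of scope.

## Co-IP proteomics

Top3 roll-up sums the three largest observed peptide intensities per
protein/condition/replicate (partial sums with fewer peptides; the evidence
count is kept). Peptide "variance stabilization" is implemented as log2
transform plus cyclic median alignment across replicates, converged when
per-replicate medians of observed values agree to 1e−9; an inverse
hyperbolic sine option exists behind a flag, and the mode used is recorded
in the output. MaxLFQ roll-up is not reimplemented — LFQ columns are
accepted as input while Top3 is computed natively.

Missing values are imputed per sample (column-wise — "the sample
distribution mean" is per sample) from
`Normal(mean − downshift·sd, (width·sd)²)` over that sample's observed
values, with defaults (width, downshift) = (0.3, 1.8) at peptide level and
(0.2, 2.5) at protein level; width and downshift are in units of the
per-sample standard deviation, which is the only scale on which those
numbers are meaningful. A feature is eligible only if some replicate group
holds at least two observed values; ineligible features are dropped and
logged. Draws are seeded and reproducible.

Enrichment is the moderated t of IP vs IgG on imputed log2 intensities with
BH adjustment. Significance additionally requires clearing a hyperbolic
volcano curve: `|log2FC| > fc₀` and
`−log10(p_adj) ≥ −log10(p₀) + c/(|log2FC| − fc₀)` with p₀ = 0.05, fc₀ = 1
and c one times the overall SD of log2FC across proteins (the exact
functional form of the curve is a conventional reading, isolated in
`significance_curve` so it can be swapped; the constant can also be set
directly). At |log2FC| = fc₀ the threshold diverges; for large fold changes
it relaxes to p_adj ≤ 0.05.

Dimethyl-label quantification drops PSMs whose heavy+light signal-to-noise
sum is below 10, then proteins with fewer than 8 surviving PSMs, and
reports `log2(Σ SN_experimental / Σ SN_control)` per protein with a
denominator of 1 when the control total is zero (the theoretical ideal of a
control-absent partner).

## Synthetic data

The generators define the study conditions under which the pipeline is
exercised; all parameters are exposed in config objects, never hard-coded,
and all randomness flows through a single documented PRNG
(`numpy.random.default_rng`, PCG64), so fixed seeds give byte-identical
output.

- **Knock-down counts:** negative binomial in mean–dispersion form
  (variance = μ + φμ², default φ = 0.05, baseline log-mean 5), two arms of
  four replicates split over two batches with a multiplicative log-normal
  batch effect (SD 0.1), and 400 of 2000 genes carrying a ±2 log2FC in the
  knock-down arm — a clean, moderately deep desk-scale stand-in for a
  cell-line siRNA experiment.
- **Cohort:** log-scale expression with per-gene baselines and Gaussian
  noise (SD 1); CRPC-NE samples are shifted on each signature gene by
  `effect_size_sd × direction` noise-SD units (default 1.5). The shift is
  sign-concordant with the knock-down direction, so in the synthetic cohort
  the planted CRPC-NE group scores *high*; the association tests are
  two-sided and orientation-free, and the recovery checks measure
  separation, not sign. Gleason grade groups are drawn from a
  proportional-odds model on a latent per-sample aggressiveness
  (state rank plus noise, cutpoints 0.5/1.25/2.0/2.75), the continuous risk
  score is that latent plus noise, and optional survival times are
  exponential with hazard increasing in the latent, under uniform
  censoring.
- **Co-IP peptides:** protein log2 abundances N(20, 1.5), 3–8 peptides per
  protein with peptide offsets (SD 1) and replicate noise (SD 0.4); partner
  proteins gain +3 log2 units in the IP condition. Each cell is missing
  with probability `expit(−steepness·(log2 I − midpoint))` — logistic
  left-censoring, the mechanism downshifted imputation assumes.
- **Dimethyl PSMs:** gamma-distributed signal-to-noise (shape 2, scale 20),
  8–20 PSMs per protein, with configurable fractions of low-PSM proteins
  and low-S/N PSMs to exercise the filters, and control-absent partners to
  exercise the denominator rule.
- **LOH calls:** Bernoulli per gene/sample with planted per-state
  fractions, split evenly between hemizygous deletion and copy-neutral LOH.

What these generators do **not** emulate: read-level noise and alignment
artifacts, gene–gene correlation, cohort batch structure and platform
differences, peptide ionization biases, interactome topology beyond a flat
enriched set, and real LOH segmentation. Passing recovery tests therefore
demonstrate that the pipeline's inference machinery is correct and
calibrated under its stated assumptions — not that those assumptions hold
in any particular clinical dataset.

## Problem sizes and reproducibility

The default end-to-end run uses 2000 genes, 260 cohort samples, 400–800
proteins and completes in seconds; recovery checks use 20 seeds and the
calibration checks 50 000 null features — sizes chosen so a full
reproduction is an interactive operation on a laptop. Stage seeds derive
from the global seed by mixing with a CRC32 of the stage name, modulo 2³¹,
so each stage is reproducible independently of stage order.

## Known limitations

- The DE engine is a Gaussian moderated t on log2-CPM, not a count model;
  at very low counts its calibration degrades and a count-based engine
  would be preferable.
- `fisher_exact_2x2` enumerates one hypergeometric support and is intended
  for desk-scale tables (margins in the thousands remain fast; the exact
  test itself is the limit, not the implementation).
- The proprietary 22-marker metastasis-risk score and the published
  neuroendocrine/AR-signaling scores are consumed as given per-sample
  numbers and never computed.
- Cross-platform calibration beyond within-cohort z-scoring is not
  attempted; scores are comparable within a cohort only.
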