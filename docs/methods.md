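# Methods

This note documents the statistical model behind `dietsel`, the choices made
where the procedure was genuinely open, and what the synthetic-data tests do
and do not demonstrate about real data.

## Study structure and containers

The pipeline's currency is a samples × variables table with one group label
per sample and a block/segment annotation per variable (`SampleTable`).
The emulated design has five arms — Control, Tenebrio, Buffalo, LPS,
Tenebrio+LPS — with 8 animals each, and six variable blocks: metabolic (4),
biochemical (6), general morphometric (9), intestinal morphometric (27),
inflammatory (12), and taste-receptor relative expression (31), 89 variables
in total. Segments annotate intestinal variables (D, J, I, AC, DC), plasma
variables carry `plasma`, the rest `none`.

## Relative expression (comparative Ct)

For target gene g, reference gene r (cyclophilin-type endogenous control)
and sample s:

    ΔCt(g,s)  = Ct(g,s) − Ct(r,s)
    ΔΔCt(g,s) = ΔCt(g,s) − mean{ΔCt(g,c) : c ∈ control group}
    RE(g,s)   = 2^−ΔΔCt(g,s)

The calibrator is the *arithmetic mean* of control-group ΔCt. This is the
standard comparative-Ct formulation and has the convenient algebraic
consequence that the control group's geometric mean of RE is exactly 1 per
gene; the tests assert it to 1e−10. RE is invariant to a per-sample additive
Ct offset (plate effects cancel in ΔCt). Ct-table columns are gene×segment
variables, so normalization is effectively per gene within segment.
Amplification-efficiency correction (Pfaffl) and multi-reference-gene
normalization are out of scope.

Fold change is the ratio of arithmetic group means, FC = mean(A)/mean(B),
with B the scenario's reference group (Control for healthy, LPS for
inflammation). Arithmetic rather than geometric means are used because the
group summaries being compared are reported as mean ± SD.

## Univariate screen

Normality is assessed per group per variable with Shapiro–Wilk but is
informational only; group comparisons are always the two-sided Mann–Whitney
U test. With 7–8 animals per arm the exact permutation null of U is used
whenever both groups have ≤ 8 observations and the pooled sample is
tie-free; otherwise the normal approximation with tie correction and
continuity correction. At n = 8 vs 8 the exact test's achievable level just
below 0.05 is 0.0499, so the screen is essentially calibrated at its nominal
level. No multiple-testing correction is applied at this stage, matching the
reporting convention the pipeline reproduces (`*` p < 0.05, `#`
0.05 ≤ p < 0.1); users needing FDR control should treat the screen as
descriptive.

## Preprocessing

Fixed order: impute → prune → scale → PCA check.

* **Imputation**: missing cells ← within-group median of the variable.
  Group-wise (not global) medians preserve the group-mean structure the
  selection stage must detect.
* **Redundancy pruning**: variables scanned in annotation order; a variable
  whose |Spearman ρ| with an already-kept variable reaches 0.95 is dropped,
  with the partner and ρ recorded. Spearman is used because expression
  variables are lognormal; 0.95 targets near-duplicates only. The greedy
  order makes the result deterministic.
* **Scaling**: z-score per variable over *all* samples (ddof = 1), once,
  before any per-comparison subsetting — a single scaling pass, with
  comparisons then subsetting rows.
* **PCA check**: scores and explained variance on the scaled table;
  samples with Mahalanobis distance > 3 in the leading-2-component score
  space are flagged. Flagging is advisory (`exclude_outliers` defaults to
  off) because the emulated design excluded no animal.

## Consensus selection

For one two-group comparison (y ∈ {0, 1}):

* **Elastic net**: binomial, mixing α = 0.5, penalty chosen by stratified
  5-fold cross-validation on deviance; score = |coefficient| at the selected
  penalty (0 if shrunk out). Magnitudes are used rather than the 0/1
  selection indicator because they preserve ranking information among the
  selected variables; a `binary_scores` switch offers the indicator reading.
* **PLS-DA VIP**: PLS regression of the centred class indicator on X with
  2 components (dropped if degenerate);
  VIP_j = √(p · Σ_a w²_ja · SSY_a / Σ_a SSY_a) with unit-norm weights w_a
  and SSY_a = q²_a·‖t_a‖², the class variance explained by component a.
  Σ_j VIP²_j = p holds identically (mean VIP² = 1), which the tests assert
  to 1e−8.
* **Random forest**: 500 trees, √p candidate variables per split, fixed
  seed; score = mean decrease in Gini impurity.

The three raw vectors live on incommensurable scales (coefficients, VIPs,
impurity reductions), so each is min-max normalized to [0, 1] over variables
before summation; an all-constant vector normalizes to all-zero. The total
score ∈ [0, 3] ranks variables; ties break by the number of methods scoring
the variable positively, then lexicographically — privileging variables
selected by more methods. Min-max makes the ranking invariant to any
positive affine rescaling of a single method's raw scores, which the
property tests check.

**Kneedle cutoff.** The sorted total-score curve is normalized to the unit
square; for a decreasing curve the difference d_i = (1 − y_i) − x_i between
the flipped curve and the diagonal chord is scanned for local maxima, and a
maximum is the knee if d drops below d_max − S·(mean x-spacing) before a
higher maximum appears (offline mode, sensitivity S = 1). The returned index
counts the variables at or above the knee (knee point included). A linear or
constant curve has no knee; the full length is returned with a warning. The
implementation is checked against a brute-force maximizer of perpendicular
chord distance and against constructed two-regime curves (10 high scorers,
80 tail) where the knee must land within ±2 of the boundary.

## Integration

Per scenario, the two selections are overlapped by set algebra (Venn; the
inclusion–exclusion identity is asserted on every result), the common
variables are laid out as FC/log2FC cells against the scenario's reference
group on the *unscaled* (imputed) data, and each cell carries its univariate
flag. Correlation maps pool the scenario's groups (the control group enters
both scenarios) and score every receptor × non-receptor pair with Spearman's
ρ (mid-ranks for ties; two-sided p via the t-approximation with n−2 df,
appropriate at the scenario sizes of 14–24 samples). Stars follow the raw
0.05/0.01/0.001 convention; a clearly-labelled Benjamini–Hochberg 5% FDR
matrix is attached because 31 × 58 raw tests at 5% will star ~90 pairs by
chance alone — the worked example makes this visible (111 raw stars, 1
surviving FDR).

## Synthetic-data generator

Within a block, variables share a latent standard-normal sample factor:
x = √ρ_b·z_block + √(1−ρ_b)·ε, giving exchangeable within-block correlation
ρ_b (default 0.3) — the collinearity structure the pruning stage exists for.
Planted effects shift the affected groups' latent mean by d within-group
SDs. Gaussian blocks are then mapped to block-specific location/scale;
the expression block is exponentiated (log-scale SD 0.5), yielding positive,
right-skewed values with median 1 as 2^−ΔΔCt data are — so for expression
variables the planted d is a log-scale standardized effect. Missing values
are injected completely at random at a configurable rate (default 0; the
analysis scripts use 2%). All randomness flows from one master seed through
named substreams, making every table bit-reproducible.

The generator emulates the *structure* of a feeding trial, not its biology:
no mechanistic LPS pathophysiology, no qPCR amplification noise model, no
heavy-tailed measurement error or batch effects. Passing recovery tests
therefore show the pipeline finds standardized mean shifts of the stated
size under equicorrelated noise at n = 8/group — they do not certify
performance under real-data pathologies the generator does not model.

## Calibration and recovery checks (problem sizes)

* Type-I calibration: 200 simulated null studies (all d = 0), one
  comparison each → 17,800 exact tests; the flagged fraction must fall in
  the 95% binomial interval around 0.05. The calibration null uses
  ρ_b = 0 so variables are independent and the binomial reference
  distribution is exact; with correlated variables the marginal level is
  unchanged but the fraction's variance exceeds binomial.
* Consensus recovery: 20 seeded replicas (5×8 samples, 89 variables,
  8 discriminators planted at d = 2 for Tenebrio) must yield a median of
  ≥ 6/8 planted variables in the selected set, with a permuted-label control
  at chance-level overlap.
* Kneedle: 100 seeded two-regime curves, ≥ 95 knees within ±2 of the
  regime boundary, each consistent with the chord-distance oracle.

These sizes keep the full suite and the acceptance script to a few minutes
on one CPU while leaving the binomial and hypergeometric reference
distributions well-resolved.

## Known limitations

* Elastic-net mixing (0.5), PLS components (2), forest size (500), the
  pruning threshold (0.95) and Kneedle sensitivity (1) are defensible
  defaults, all exposed in config and logged per run — but results at
  n = 8/group are sensitive to them, and no nested cross-validation
  estimates the selection's generalization error (stability selection is
  out of scope).
* The univariate screen and the correlation stars are intentionally
  uncorrected for multiplicity; only the correlation stage carries an FDR
  companion matrix.
* Fold changes use arithmetic means; for strongly skewed expression data a
  geometric-mean ratio would be more robust but would no longer match the
  reported group summaries.
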