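# Methods

## The design being modeled

A cross-sectional two-arm cohort (disease vs healthy control) profiled
on three molecular layers over the same subjects: a serum protein panel
measured by an antibody-pair assay with a per-analyte lower limit of
detection (LLOD), and two microarray transcriptomes — peripheral blood
cells (PBC) and skin. The scientific question is whether the serum
protein profile tracks the diseased end-organ (skin) or the blood
compartment. The package implements the full analysis chain —
preprocessing, covariate-adjusted differential expression, cross-layer
effect-size concordance, PPI-network proximity statistics, and Mantel
concordance of between-sample similarities — and a synthetic generator
that plants all of these signals with known truth.

## Preprocessing

* **LLOD exclusion.** An analyte is excluded when *strictly more than
  50%* of its observations across the whole cohort fall below its LLOD
  (a feature with exactly half below is kept). For every excluded
  analyte a two-sided Fisher exact test of (below vs at-or-above LLOD) ×
  group is reported, Benjamini-Hochberg-corrected across the excluded
  set — the published analyses checked this imbalance at FDR < 5% but do
  not name the test; Fisher is chosen for the small counts involved.
* **LLOD imputation.** Remaining observations strictly below the LLOD
  are replaced by the LLOD (left-censoring imputation; idempotent).
  Order is filter → impute: imputing first would erase the censoring
  fractions the filter needs.
* **Detection filter.** Transcript probes are kept when their mean
  platform detection p-value across samples is strictly below 0.01.
* **Quantile normalization.** Values are log2-transformed (the
  generator already emits log2-scale values, so the pipeline runs with
  `log_transform=False`), then each sample's sorted values are replaced
  by the across-sample mean of order statistics. Ties within a sample
  receive the mean of the reference values their ranks span, which
  preserves within-sample rank order and keeps the grand mean invariant
  to 1e-9.
* **Gene mapping.** Proteins pair with transcripts through shared gene
  ids; when several probes map to one gene the probe with the largest
  mean expression is taken (a common deterministic collapse rule; the
  rule is a parameter of `map_features`).

## Differential expression and moderation

Per feature, ordinary least squares of expression on an intercept, a
disease indicator, and covariates (default age + sex — the covariate
set is fully configurable since published cohort analyses adjust for
"technical and biological covariates" without enumerating them). The
group-coefficient t-statistic optionally uses an empirical-Bayes
posterior variance s̃²_g = (d0·s0² + d_g·s²_g)/(d0 + d_g), with (d0, s0²)
estimated by the closed-form method of moments on log s² against a
scaled-F prior (the moment equations solved with a Newton inverse of
the trigamma function). When the observed dispersion of log s² does not
exceed its sampling expectation, d0 → ∞ and the prior variance is the
mean sample variance; the t reference is then normal. The
implementation reproduces `limma::squeezeVar` to 1e-6 on a fixture and
collapses exactly to the pooled-variance two-sample t-test when
moderation is off and no covariates are supplied.

Trait association (severity score, disease arm only) reports the model
p from expression ~ trait + age + sex, plus the plain Spearman ρ and a
partial Spearman: ranks of x, y, and covariates, ranks of x and y
residualized on covariate ranks, Pearson correlation of the residuals.
Several partial-Spearman definitions circulate; this one is used
because it reduces *exactly* to plain Spearman when the covariates are
constant. Residual norms below round-off are treated as zero partial
correlation.

Cohort-table utilities: a continuity-corrected Pearson χ² whose Yates
term |o − e| − 0.5 is clamped at zero (so near-null tables give χ² = 0,
p = 1), and a Wilcoxon-Mann-Whitney test that enumerates exactly for
tie-free samples up to n = 20 and otherwise uses the tie-corrected
normal approximation. Multivariate group separation: features are
z-scored, samples projected on the first k = 2 principal components,
two-sample Hotelling T² on the scores, p by label permutation over the
fixed scores (the projection is not refit per permutation; with the
label-agnostic PCA this is exchangeable and two orders of magnitude
cheaper).

## Cross-layer statistics

* **Effect correlation.** Spearman ρ between serum and transcript
  effect estimates on mapped pairs, after a selection rule applied to
  the serum layer (default raw p < 0.05; FDR-based and no-selection
  rules available — the study's exact selection recipe lives in
  unpublished supplementary material, so it is configuration, not a
  hard-coded guess). The permutation null relabels disease/control at
  the *subject* level, carries the permuted labels jointly into both
  layers (a subject missing from one layer simply contributes where
  present), refits both layers with the identical code path
  (`group_ols_stats`), reapplies the identical selection rule, and
  recomputes ρ. One-sided (upper) p with the add-one rule, since the
  hypothesis is positive concordance; two-sided is a parameter.
  Per-layer independent relabeling would break within-subject coupling
  and inflate significance, so it is deliberately not offered.
* **Disease-vs-trait concordance.** Among serum features passing
  FDR < 5% in either the group or the trait analysis, the fraction whose
  disease effect and trait slope agree in sign; over all features, the
  Spearman correlation of the two estimate vectors.
* **Per-gene cross-tissue correlation.** For genes measured in both
  transcript layers (probe-collapsed), Spearman across each group's
  shared subjects, BH within group, with a flag for genes whose
  correlation sign differs between groups.

## Network statistics

* **WAP score.** S(v) = Σ_{u∈N(v)} w_u with w ≥ 0 (default weight
  |moderated t| of the gene's best probe). The defining publication of
  the WAP approach is summarized rather than reproduced in the source
  study, so this package fixes the simplest statistic consistent with
  "attachment to the more differentially expressed transcripts":
  one-hop neighbor weight sum with a weight-permutation null (z, upper
  -tail empirical p with add-one, rank by ascending p with deterministic
  ties: descending z, then node id).
* **Rank comparison.** Statistic = median over the protein set of
  (rank_b − rank_a); null sets are drawn degree-decile-matched from the
  scored universe *excluding* the query set and *excluding zero-degree
  nodes*. Isolated nodes carry no attachment information and sit at
  identical tied ranks in both tissues; leaving them in puts an atom at
  zero rank difference that makes the permutation p conservative (this
  is visible as a failed uniformity check under the global null).
  Degree matching is needed because rank difference correlates with
  degree through score magnitude.
* **Edge-count test.** e_exp = Σ over unordered qualifying pairs
  {a ∈ A, b ∈ B, a ≠ b}, each counted once even when both endpoints lie
  in A ∩ B, of min(1, d_a d_b / 2m) — the expected-degrees (Chung-Lu)
  null with the graph's own degrees; p is the Poisson upper tail at
  λ = e_exp. The generator samples its networks from exactly this model
  (power-law expected degrees, exponent 2.5, truncated at n − 1), so
  the null is self-consistent and the Monte-Carlo oracle in the tests
  is exact. The Poisson approximation is accurate when no pairwise
  probability caps at 1 (w_max² ≤ Σw); on tiny graphs with extreme hubs
  the capped Poisson-binomial has a lighter tail and the approximation
  degrades — the validation therefore runs in the uncapped regime that
  matches real PPI-scale graphs.

## Mantel concordance

Similarity = Spearman correlation between full sample profiles — *all*
features, never a differential subset, to avoid variable-selection bias.
Concordance = Spearman correlation of the strictly-upper-triangle
entries of two layers' similarity matrices (Pearson available); the
null permutes the sample-to-subject assignment of one layer, applied to
rows and columns jointly; two-sided p with the add-one rule (the
published grid reports near-zero negative correlations with large p,
consistent with a two-sided reading). The 2 × 3 grid (group × layer
pair) restricts each cell to subjects present in both layers and marks
cells with fewer than 4 shared subjects unavailable without failing the
rest.

## The synthetic generator

Value model per layer (log2 scale):
x_gi = baseline_g + effect_g·1[disease] + λ_layer·u_g·l_i +
slope_g·mRSS_i + ε, with baseline_g ~ N(8, 1), loadings u_g ~ N(0, 1)
per layer, a single standard-normal latent scalar l_i per subject
shared across layers, and ε ~ N(0, noise_sd²). Defaults and what they
emulate:

| parameter | default | rationale |
| --- | --- | --- |
| n_disease / n_control | 49 / 25 | cohort arm sizes |
| serum dropout | 2 / 1 | serum available for 47/24 subjects |
| n_proteins / censored | 981 / 70 | panel size; heavily censored analytes |
| transcripts per layer | 1,500 | desk-scale stand-in for a genome-wide array |
| mapped fractions | 314/911, 448/911 | protein-transcript pairing coverage |
| planted DE (serum/pbc/skin) | 70 / 78 / 150 | serum and blood counts mirror the reported discovery counts; skin is scaled to 10% of the desk-scale layer rather than the genome-wide count |
| effect_sd | 0.8 log2 | ≈1.7-fold typical planted change, the scale of strong serum hits |
| coupling ρ (skin/pbc) | 0.6 / 0.2 | strong end-organ coupling, weak blood coupling |
| latent strength | 0.15 | yields between-sample concordance ρ ≈ 0.1-0.2, the weak-but-detectable regime such studies report |
| mrss_effect | 0.05 | trait slopes giving within-arm severity correlations ≈ 0.3-0.6 |
| llod_quantile | 0.05 | ordinary LLODs at the 5th percentile of the control distribution |

Construction details. Coupling is planted on mapped pairs where both
members carry a group effect: e_t = ρ·e_s + √(1−ρ²)·ε with
ε ~ N(0, effect_sd), so the mapped-pair effect correlation is ρ in
expectation; the realized value is recorded in the truth object.
Designated censored analytes get their LLOD at their own 55th overall
percentile (guaranteeing strictly more than half below); all other
LLODs are capped at the analyte's 40th percentile so that no planted
down-shift can accidentally push a non-designated analyte past the
exclusion threshold — the censoring pattern is a *condition*, not an
outcome. Trait slopes act on the planted serum features, signed with
their group effect, so severity associations and disease effects are
sign-concordant by construction. Detection p-values are U(0, 0.005)
for expressed probes and U(0.01, 1) for a 10% unexpressed fraction
drawn from unmapped, unplanted probes, exercising the 0.01 filter
without touching the analyzed feature set. The PPI generator draws
expected degrees from a discrete power law (exponent 2.5) and samples
edges independently with p = min(1, w_i w_j / Σw); a planted module
adds a configurable excess probability between the serum-hit genes and
the skin-hit genes (pipeline default 0.01, chosen to give the several-
fold edge-count enrichment and the clear skin-ward WAP rank shift that
define the positive-control scenario).

What the generator does **not** emulate: probe-level array artifacts,
plate/batch structure in the panel, inter-analyte correlation beyond an
optional single shared-noise block (`feature_block_rho`), missingness
other than serum dropout, and confidence-scored network edges. Passing
tests therefore demonstrate correctness and calibration of the
statistics under a clean generative model, not robustness to those
real-data complications.

## Numerical and design choices

* Permutation p-values always use the add-one rule ((1 + hits)/(n + 1));
  they are never zero.
* Per-stage seeds derive from the master seed by fixed position in the
  stage list, so adding a stage never perturbs earlier streams; rerunning
  a configuration is byte-identical.
* BH FDR is the literal step-up definition (validated against both a
  brute-force implementation and statsmodels).
* Rank-deficient designs raise an error naming the aliased columns
  (QR with pivoting).
* Degenerate inputs fail loudly with the offending feature or sample
  named: nonpositive values at the log step, zero-variance features at
  z-scoring, constant sample profiles at similarity computation.
* Problem sizes in the validation studies (200 null datasets at
  n_perm = 199 for calibration; 50 datasets for parameter recovery;
  1,000 sampled graphs for the edge-count oracle) were chosen as the
  smallest giving stable Kolmogorov-Smirnov and Monte-Carlo estimates.

## Known limitations

* The WAP functional form is one-hop and unweighted by edge confidence;
  multi-hop attachment is out of scope.
* The Poisson edge-count p is approximate when pairwise probabilities
  cap at 1 (extreme hubs on small graphs); the exact Poisson-binomial
  tail is available in the tests as a Monte-Carlo oracle but not as a
  production path.
* The multivariate separation test fixes the PCA projection across
  permutations.
* No partial Mantel test, no blocking/duplicate-correlation structure
  in the differential-expression fits, and no count-data (RNA-seq)
  handling — the layers are modeled as approximately Gaussian log2
  intensities throughout.
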