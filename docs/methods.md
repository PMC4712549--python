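# Methods

This note documents the models, rules and numerical choices implemented in
`mirkd`, the defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the known limitations.

## Data model

CT values live in a long (tidy) table keyed by (assay, sample) with plate
and duplicate-group annotation. "Undetermined" — the instrument's call when
no amplification crosses threshold within the run — is a NaN sentinel, never
a numeric cycle: the on/off rule must distinguish "not detected" from
"detected late", and substituting a number (e.g. the max cycle) at ingest
would silently destroy that distinction. Assay duplication is declared via
an explicit annotation column rather than inferred from repeated miRNA
names, so the concordance rule is testable in isolation. The instrument's
maximum cycle defaults to 40 and is configurable.

## CT → log2 expression

`value = max_cycle − CT`. One PCR cycle corresponds to one doubling, so the
flipped cycle count is a log2 abundance up to an additive constant that
cancels in every downstream contrast. Working on this scale (rather than on
raw CT) keeps "up-regulated" positive throughout; the choice is recorded in
the matrix's provenance trail.

## Cyclic loess normalization (per plate)

Reference-gene normalization is deliberately not offered for the array
stage: stable small-RNA housekeepers are hard to certify, and normalizing
to the overall behaviour of the panel is the more robust choice for
miRNA cards. Within each plate (the two 384-well cards of one profile
behave like distinct arrays and are normalized independently), every
unordered sample pair (i, j) contributes M = x_i − x_j and
A = (x_i + x_j)/2 on commonly detected features; a degree-1 loess curve of
M on A is fitted and half the fitted trend is subtracted from sample i and
added to sample j. All pair corrections of one pass are computed from a
common snapshot and applied together, which makes the result independent of
sample ordering; passes repeat until the largest fitted trend falls below
`tol` or `max_iter` passes have run.

Defaults: span 0.7, degree 1, `max_iter` 3, `tol` 1e-3, minimum 10 common
features per pair — all configurable. With only four samples, aggressive
smoothing is unstable; a wide span and few passes are the conservative
choice. The loess fit uses three robustness reweighting iterations:
genuinely differential features are large-|M| outliers, and without
downweighting they drag the trend at the abundance ranges they occupy,
which biases null features there and inflates false positives (observed
directly on simulated panels: the BH-controlled candidate list stops being
controlled without robust fitting). Features detected in only one sample of
a pair are excluded from the fit but still receive their sample's
correction, evaluated at their own abundance, so half-detected features
remain on the normalized scale.

Two properties bound what normalization can do: it preserves the per-plate
grand mean (pair corrections cancel by construction), and it removes
*systematic* intensity-dependent trends, not smoother-level noise — on a
panel where most features are differential (no null backbone), cyclic loess
removes the signal itself, which is why the all-planted test design runs
with normalization disabled.

## Detection filter, on/off rule, duplicates, candidates

* **Exclusion**: assays whose CT is above 34.5 (or undetermined) in every
  sample of *both* arms are below reliable quantification and are excluded.
* **On/off**: assays undetermined in every sample of one arm and detected
  at or below the cutoff in every sample of the other. No p-value is
  calculable. A lower-limit log2 fold change is reported by substituting
  the detection cutoff (34.5) for the undetermined CTs — the least extreme
  cycle compatible with non-detection, hence the most conservative bound;
  substituting the max cycle instead would overstate the effect. The
  substitution value is configurable.
* **Duplicates**: the 72 duplicated assays must agree in fold-change sign;
  discordant pairs remove the miRNA entirely, concordant pairs collapse to
  one record (mean log2FC, smaller p). Concordance is sign-only — no
  magnitude threshold is imposed, since any such threshold would be
  arbitrary at n = 2 per arm.
* **Candidates**: features with raw p < 0.05 plus all on/off features,
  sorted by log2FC. Raw p is the screen's operating rule; BH-adjusted
  values are always computed and reported alongside, and
  `use_adjusted=True` switches the rule. With ~350 tested features and
  only ~15 true effects, a raw 0.05 threshold necessarily admits roughly
  0.05 × (#tested nulls) ≈ 17 false positives, i.e. an expected
  false-discovery proportion near 0.4–0.5 at this design's truth density;
  the simulation suite measures exactly that. A screen run at this rule is
  a sensitivity-first candidate generator whose output is expected to be
  validated downstream (single-assay qPCR), not an error-controlled
  discovery list; the BH rule is the error-controlled variant.

## Moderated t-test

Per feature, log2FC = mean(knockdown) − mean(control) and the pooled
residual variance s²_g has d_g = n₁ + n₂ − 2 df. Hyperparameters (d₀, s₀²)
are estimated by moment matching of log s²_g against a scaled F
distribution (digamma/trigamma inversion; the trigamma inverse by Newton
iteration). The posterior variance is the df-weighted blend
(d₀ s₀² + d_g s²_g)/(d₀ + d_g) and the moderated t has d₀ + d_g df. Zero
residual variances are floored at 1e-8 before taking logs — with 2-vs-2
designs, occasional exact ties would otherwise produce −∞. If the
moment-matched spread of log-variances is no larger than its theoretical
sampling noise, d₀ = ∞ and every feature shares s₀². The implementation is
cross-checked in the test suite against an independent reference
(R/limma's `lmFit`/`eBayes`) to ~1e-13 relative agreement, and with the
prior df forced to 0 it reproduces the classical pooled two-sample t
exactly. A 1-vs-1 design has no residual df; the fit then requires an
explicit `common_variance=True` flag and shares a single variance estimated
from the cross-feature spread of fold changes (a z-score against the null
spread — clearly labelled as such in the results).

Pooled RNA (one pool per siRNA) is treated as one independent sample per
pool; the 2-vs-2 design therefore has 2 residual df per feature, and the
empirical-Bayes shrinkage is what makes testing at that depth possible.

## Single-assay ΔΔCT and validation

ΔCT = CT(target) − mean CT(references) per sample (the arithmetic mean of
reference CTs equals the geometric mean of their linear quantities);
ΔΔCT = ΔCT − mean ΔCT of the calibrator group; fold change = 2^−ΔΔCT.
Technical-replicate CTs are averaged before ΔCT. Amplification-efficiency
corrections (Pfaffl-type) are out of scope. Reference candidates are ranked
ascending by total CT variance decomposed as pooled within-group (intra)
plus between-group-means (inter) variance; ties break lexicographically.

Cross-platform agreement uses Spearman's rho on mid-ranks. The two-sided
p-value is the exact full-permutation tail for n ≤ 9 (at n = 9 the 362 880
permutations are still cheap; beyond that the t approximation with n − 2 df
is standard and accurate), with the boundary documented rather than left to
a library default.

## Signed context+ scoring

Curated (evidence-classed) and predicted (context+-scored) interactions
share one table with a source tag so the evidence and expression filters
have a single path. Duplicate predicted (miRNA, gene) rows are summed on
load with a warning — providers distribute per-gene aggregates, but
site-level exports occur. The evidence filter applies to curated rows only;
the expressed-gene restriction applies to everything, because a target not
expressed in the cellular context cannot carry the phenotype.

Per MTI the signed score is the context+ score (negative) if the targeting
miRNA is down-regulated after knockdown, and its positive mirror if
up-regulated. Gene-level signed sums with |sum| ≥ 0.4 define predicted
targets; the cutoff is the stringency/coverage trade-off knob. Term-level
sums aggregate the signed MTI scores of member genes that passed the gene
cutoff (the term describes the cutoff-filtered target list; an
`include_failing` flag lifts the restriction for exploratory use). Sign
flips of every direction negate every sum exactly — an antisymmetry the
test suite asserts. Term labels are compared case-insensitively with
whitespace collapsed, then mapped through a user synonym table, before the
cross-dataset presence/absence matrix is built (rows = terms present in
≥ 2 collections; terms absent from the gene-expression collection but
present in ≥ 2 target collections are flagged as candidate miRNA-specific
processes).

## Enrichment

Per term, with k of the n list genes and K of the N background genes
annotated: fold enrichment = (k/n)/(K/N) and p is the one-sided
hypergeometric upper tail P(X ≥ k). The default EASE variant computes the
tail at max(k − 1, 0) — a single-gene overlap can never score — and always
satisfies p_ease ≥ p_fisher. The background defaults to the expressed-gene
set of the cellular context, not the annotation universe: enrichment
against genes that could never appear in the list is anticonservative. The
screening rule keeps fold enrichment ≥ 1.5 (inclusive) and raw p < 0.1
(strict); BH-adjusted p-values are reported as an auxiliary column. Web
services that perform the same test construct their own gene universes, so
absolute counts (k, n, K, N) from such services are generally not
reproducible against user-supplied annotations; the rule, not the counts,
is the portable part.

## Synthetic data

`simulate_lda` emulates the study design: 664 distinct miRNAs of which 72
are measured in duplicate (736 assays across plates A and B, duplicate
copies on opposite plates), 2 pooled knockdown vs 2 pooled control samples,
Gaussian CT noise (default sd 0.25 cycles — multiplicative noise on the
linear scale, matching qPCR behaviour), a low-expression stratum sized so
that ~53% of the panel is detected above the filter, 15 planted
quantifiable effects with |log2FC| drawn from [1.5, 4], and 6 on/off
switches whose silent arm sits beyond the run length and is emitted as
"Undetermined", exercising the sentinel path end to end. Latent CTs above
the max cycle are emitted as undetermined. Ground truth (effect, class,
direction, duplicate group, seed) ships with every simulation; generators
are pure functions of their arguments including the seed.

What the generator does **not** emulate: amplification curves and
efficiency differences between assays, plate-position (well geometry)
effects, heteroscedastic noise at high CT, correlated miRNA co-regulation,
and pool-composition effects. Passing recovery tests therefore demonstrate
the pipeline's correctness under idealized noise, not robustness to those
real-data pathologies.

`simulate_mti` produces a random bipartite MTI table with negative context+
scores, random term memberships, directions and an expressed subset;
`simulate_expression_array` produces a one-color intensity matrix with 1–3
replicate probes per gene and gene-level planted effects for the
replicate-probe consensus rule (a gene is called only if *every* probe is
individually significant with a consistent sign; the gene log2FC is the
probe mean).

## Problem sizes used in verification

The verification battery runs the full 664-feature screen over 20 seeded
replicates (recovery of planted effects and observed false-discovery
proportion of the raw-p rule), the 21-feature all-planted design at noise
sd 0.05 (which must return exactly its 15 + 6 features — with any null
features present, a raw-p rule admits false positives with probability
near 1, so exact counts are only meaningful on the all-planted design),
1000-vector BH and 200-configuration hypergeometric enumerations, a full
8!-permutation Spearman check, and a 1000-feature null calibration
(Kolmogorov–Smirnov uniformity of p). The acceptance script uses 10 screen
replicates and reports recovery, FDP, detection rate, candidate counts,
a simulated validation correlation and the target-workflow counts.

## Known limitations

* Two-group designs only; no paired designs, covariates or >2 arms.
* Cyclic loess assumes most features are non-differential; panels violating
  that need `normalize=False` or external normalization.
* The on/off lower limit depends on the substitution convention (detection
  cutoff); it is a reporting convention, not an estimator with sampling
  theory.
* The raw-p candidate rule does not control the false discovery rate (see
  above); use `use_adjusted=True` when an error-controlled list is needed.
* TargetScan context+ scores are consumed, not computed; site prediction is
  out of scope.
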