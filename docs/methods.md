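# Methods

This note documents the statistical models behind `qgenie`, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions.

## Scoring model

The instrument is a global rating scale: 11 items on a 1–7 Likert scale, the
total score being the plain (unweighted) sum. Two scoring variants exist
because one item asks about the description of comparison groups, which is
meaningless for designs without a control group (e.g. quantitative-trait
studies): the *with-control* variant sums all 11 items (range 11–77), the
*without-control* variant drops item 3 (range 10–70). A supplied item-3
response for a no-control study is ignored with a warning rather than
rejected — the rating is valid, just out of scope for that design. Missing
required responses are an error; no imputation is ever performed, because no
defensible imputation rule exists for a quality rating.

Classification uses two integer cut-points per variant: `score ≤ low_max` is
low, `≤ moderate_max` moderate, above that high. The shipped defaults are
35/45 and 32/40; users can substitute schemes re-derived by the
standard-setting module. When several raters score the same study the
default is to classify each rater's total separately; averaging responses
over raters before classification is offered
(`mean_rating_per_study`) but not default, since classification of
individual totals is the less processed path and rounding averaged Likert
responses loses information.

## Item analysis

Item–total correlations are *corrected* (item-rest) by default: the item is
correlated with the sum of the other items, which avoids the automatic
inflation from the item's presence in its own total and matches the usual
companion statistic α-if-item-deleted. The uncorrected variant is available
via `corrected=False`. Cronbach's α uses the variance form
k/(k−1)·(1 − Σσ²ᵢ/σ²ₜₒₜ) with sample (ddof = 1) variances. Items with
ITC < 0.2 are flagged as too weakly related to the construct to
discriminate, and ITC > 0.9 as redundant with the rest of the scale; both
are flagged for exclusion review, not removed automatically.

For stratified analyses (e.g. raters familiar with genetic association
studies vs not), ratings are averaged over a group's raters to produce one
study × item matrix per group before computing ITC and α. Whether to average
or to pool per-rater rows is a genuinely open choice for data of this shape;
averaging was chosen because it yields one statistic per item per group and
keeps the study as the unit of analysis. Endorsement rates (fraction of
ratings of 6 or 7) are always computed on the raw per-rater ratings, not the
averages, since averaging destroys the scale categories.

## Generalizability theory

The rating design is fully crossed: every rater scores every study on every
item. The three-way random-effects decomposition

y₍ₚᵣᵢ₎ = μ + pₚ + rᵣ + iᵢ + (pr) + (pi) + (ri) + (pri,e)

yields seven variance components estimated by equating observed ANOVA mean
squares to their expectations, e.g. σ̂²ₚᵣᵢ,ₑ = MSₚᵣᵢ,
σ̂²ₚᵣ = (MSₚᵣ − MSₚᵣᵢ)/nᵢ,
σ̂²ₚ = (MSₚ − MSₚᵣ − MSₚᵢ + MSₚᵣᵢ)/(nᵣ·nᵢ). Negative solutions (sampling
noise, common when a true component is near zero) are truncated to zero and
flagged; the raw estimates are kept alongside because only they satisfy the
EMS algebra exactly and only they are unbiased, so recovery tests assert on
the raw values. Unbalanced or incomplete designs are rejected rather than
imputed — REML for unbalanced G-studies is out of scope.

Because the raters in hand are treated as a random sample of all possible
raters, the reported dependability coefficients are **absolute-error**
Φ = σ²τ/(σ²τ + σ²Δ): facet main effects count toward error, since an
absolute score is compared against fixed cut-points, not merely ranked.
For a fixed facet f, σ²ₚf/n_f joins the universe-score variance and every
error component involving f is averaged over its n_f observed conditions
(the mixed-design convention); random facets divide by their D-study sizes
n′. The relative (rank-order) coefficient, which drops facet main effects,
is exposed for diagnostics and is never smaller than Φ. Reported
coefficients: internal consistency (items random, raters fixed), inter-rater
(raters random, items fixed), overall (both random), each at the observed
design sizes by default. A `collapse` option averages the fixed facet out of
the data and runs a two-way analysis instead; the two paths agree when the
collapsed facet carries no interaction variance.

Inter-group ("inter-user") dependability uses the nested study × (rater :
group) design on item-summed total scores, with components σ²ₚ, σ²_g, σ²ₚ_g,
σ²ᵣ:g, σ²ₚᵣ:g,e and
Φ = σ²ₚ / (σ²ₚ + σ²_g/n_g + σ²ₚ_g/n_g + σ²ᵣ:g/(n_g nᵣ) + σ²ₚᵣ:g,e/(n_g nᵣ)).
Only balanced groups are supported. When the group components vanish this
reduces algebraically to the pooled single-facet coefficient.

## Standard setting

Borderline-groups regression: each (study, rater) total score is paired with
the rater's global-impression grade, coded numerically 1/2/3 from the 1–7
global rating (1–2 → low, 3–4 → moderate, 5–7 → high). Ordinary least
squares of score on grade gives fitted scores at the half-grade boundaries
1.5 and 2.5, which are the cut-points, rounded half-up to integers because
published schemes are integers. A non-positive slope (quality not increasing
with grade) or a single observed grade invalidates the derivation. The
global question exists only to anchor the cut-points; it is not part of the
instrument or its total. The without-control scheme is derived after
recomputing totals without item 3.

## Construct validity

Spearman ρ (midranks for ties) between total scores and impact factor,
average citations per year, and total citations. Citations per year divide
by the inclusive year count, floored at one year, so same-year publications
are well defined; self-citations can be excluded from the numerator, and
with zero self-citations the two variants are bit-identical. p-values use
the t approximation on n − 2 df, adequate at the n ≈ 30 scale these
analyses run at; an exact permutation p-value is available for n ≤ 10.

## Meta-analysis and sensitivity

Study effects are log odds ratios with standard errors; from 2×2
case-control counts the Woolf estimator is used, adding 0.5 to every cell
only when some cell is zero (tables with two or more zero cells carry no
usable effect). Pooling is inverse-variance; the default model is
DerSimonian–Laird random effects with the moment estimator
τ̂² = max(0, (Q − df)/(Σw − Σw²/Σw)), fixed-effect by option. Heterogeneity
is reported as Cochran's Q with its χ² p-value and I² = max(0,(Q−df)/Q)·100.
The I² confidence interval uses the Higgins–Thompson test-based method on
ln H (H = √(Q/df), floored at 1), with
SE(ln H) = (ln Q − ln df)/(2(√(2Q) − √(2df−1))) when Q > df and the
small-Q approximation otherwise; the H interval is transformed to
I² = (H²−1)/H² and truncated to [0, 100]. This method was chosen because it
is the standard closed-form interval for I² at small k. Display rounding
follows meta-analytic convention: whole percents for I², two decimals for
odds ratios.

The sensitivity procedure pools all studies, then only the non-low-quality
studies, and reports both results, their differences (I², Q, τ², CI width,
pooled OR) and a per-study forest table with inclusion flags. All studies
being low quality is an error.

## Synthetic data: what it emulates and what it does not

The generators mirror the instrument's validation design: 30 studies, 4
raters in 2 groups of 2, 11 items. Ratings follow the crossed normal
random-effects model above, discretized by rounding and clipping to 1–7.
Default variance components (σ²ₚ = 1.0, σ²ᵣ = 0.1, σ²ᵢ = 0.2, σ²ₚᵣ = 0.15,
σ²ₚᵢ = 0.1, σ²ᵣᵢ = 0.05, σ²ₚᵣᵢ,ₑ = 0.5 on the squared score scale) make
study quality the dominant source of variance with visible rater and item
effects — a moderately reliable instrument. Round-and-clip discretization
biases component estimates when the mean sits near a scale end, so recovery
tests use the continuous pre-discretization array (always included in the
truth record), where the EMS estimators are exactly unbiased. Real Likert
data differ in ways the generator does not model: category-specific response
styles, rater drift over time, and item-specific skew.

Global impressions are generated by thresholding latent study quality (plus
noise) at its terciles into the low/moderate/high rating bands. Impact
metrics are log-linear monotone functions of latent quality plus noise, with
self-citations a fixed fraction of totals.

The meta-analysis generator draws k = 7 dataset effects around a true odds
ratio of 1.15 with configurable between-study variance, observes them with
per-dataset standard errors uniform on (0.08, 0.2), labels one of the seven
low quality and adds a bias of 0.6 on the log-OR scale to it. These defaults
reproduce the situation the sensitivity procedure is designed for — a single
poorly conducted dataset inflating the pooled estimate (median simulated
pooled OR 1.25 falling to 1.15 on exclusion) and driving the heterogeneity
(median simulated I² ≈ 72 % falling to 0) — and were set against those
published summary values. The generator does not model genotype-level
structure (allele frequencies, Hardy–Weinberg deviation, linkage
disequilibrium); effects enter as summary statistics.

All generators are pure functions of (config, seed) using numpy's PCG64
generator; identical seeds give bit-identical outputs.

## Numerical conventions and edge cases

- Statistics that are mathematically undefined on the data (zero variance,
  zero Φ denominator, a single global grade) raise typed errors; they never
  return NaN.
- Cut-point rounding is half-up (⌊x + 0.5⌋), not banker's rounding.
- Variance truncation happens after estimation, per component, and is
  always flagged.
- Validation problem sizes: the test suite runs its recovery studies at
  500 replicates of 200 × 4 × 11 arrays for component recovery, 200
  replicates for cut-point and meta-sensitivity recovery, and 1,000 random
  component sets for Φ monotonicity — sizes at which the Monte-Carlo error
  of each check is far below its assertion margin.

## Known limitations

- Only balanced, fully crossed (or balanced nested) rating designs are
  supported; no REML, no missing-cell handling.
- The Φ mixed-facet convention (fixed-facet interactions into universe
  score) is one of two conventions in the G-theory literature; the collapse
  option exists for comparison with single-facet re-analyses.
- Exact permutation p-values for Spearman ρ are limited to n ≤ 10 by
  factorial growth.
- The instrument's item stems target case-control genetic association
  studies; applying the scores to other designs is the user's judgement.
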