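# qgenie

Quality assessment of published genetic association studies, for systematic
reviewers and meta-analysts. Pooled effect estimates in genetic epidemiology
are sensitive to the methodological quality of the contributing studies —
phenotype definition, genotyping quality, population stratification, power,
Hardy–Weinberg testing, and so on. `qgenie` implements a global quality
instrument for such studies and the statistical machinery needed to validate
an instrument of this kind and to act on its scores in a meta-analysis.

## What it computes

**Scoring.** The instrument has 11 items, each rated on a 7-point Likert
scale anchored by *poor* (1) and *excellent* (7). The total score is the sum
of the item ratings (range 11–77); for studies without a comparison group
(e.g. quantitative traits) the comparison-group item is dropped (range
10–70). Cut-points map totals to **low / moderate / high** quality: by
default `score ≤ 35` low, `35 < score ≤ 45` moderate, `> 45` high (and
32/40 for the 10-item variant).

**Item analysis.** Corrected item–total correlations
r(xᵢ, Σⱼ≠ᵢ xⱼ), Cronbach's α = k/(k−1)·(1 − Σσ²ᵢ/σ²ₜₒₜ), α-if-item-deleted,
endorsement rates (fraction of ratings 6–7), and flags for items with
ITC < 0.2 or > 0.9.

**Reliability (generalizability theory).** For the fully crossed
study × rater × item design, the seven random-effects variance components
(σ²ₚ, σ²ᵣ, σ²ᵢ, σ²ₚᵣ, σ²ₚᵢ, σ²ᵣᵢ, σ²ₚᵣᵢ,ₑ) are estimated from three-way
ANOVA mean squares via the expected-mean-square equations, and absolute-error
dependability coefficients Φ = σ²τ/(σ²τ + σ²Δ) are reported: internal
consistency (generalize over items), inter-rater (generalize over raters),
overall (both), and inter-user reliability between rater groups from the
nested study × (rater : group) design.

**Standard setting.** Cut-points are derived by borderline-groups
regression: regress total scores on the global-impression grade (1 = low,
2 = moderate, 3 = high, mapped from a 1–7 global rating as 1–2/3–4/5–7) and
read the fitted score at grades 1.5 and 2.5, rounded half-up.

**Construct validity.** Spearman ρ of total scores against journal impact
factor, average citations per year (with/without self-citations) and total
citations.

**Meta-analysis sensitivity.** Inverse-variance pooling of log odds ratios
(Woolf effects from 2×2 tables where counts are given), fixed-effect or
DerSimonian–Laird random-effects
(τ² = max(0, (Q − df)/(Σw − Σw²/Σw))), with Cochran's Q,
I² = max(0, (Q − df)/Q)·100 and its Higgins–Thompson test-based confidence
interval — then the whole analysis repeated after excluding low-quality
studies, with a forest-plot-ready table.

A seeded synthetic-data module generates every input with known ground truth
(crossed Likert rating arrays, global impressions, citation metrics, and a
7-study meta-analysis with a bias confined to low-quality studies), so all of
the above is testable by parameter recovery.

## Worked example

```python
import qgenie

# heterogeneity before and after excluding low-quality studies
print(round(qgenie.i_squared(21.1, 6)), qgenie.i_squared_ci(21.1, 6))
print(round(qgenie.i_squared(3.04, 5)), qgenie.i_squared_ci(3.04, 5))
# 72 (38.26637812443759, 86.90167287167334)
# 0 (0.0, 74.62463444204757)

# a meta-analysis with one inflated low-quality dataset
effects, _ = qgenie.simulate_meta(qgenie.SimulationConfig(), seed=1)
report = qgenie.sensitivity_by_quality(effects)
print(report.summary().to_string(index=False))
#              analysis  k  pooled_or  ci_low  ci_high     Q  i2_percent
#           all studies  7       1.23    1.04     1.45 14.19          58
# excluding low quality  6       1.13    1.01     1.26  0.99           0
```

Reading: the full 7-dataset pool shows substantial heterogeneity
(I² = 58 %) and a pooled odds ratio of 1.23 with a wide confidence
interval; dropping the one low-quality dataset removes the heterogeneity
(I² = 0 %) and yields a more precise estimate, 1.13 (1.01–1.26) — the
behaviour a useful quality instrument should produce.

The same workflow is available from the shell:

```bash
qgenie simulate ratings --seed 3 --out data/
qgenie score     --ratings data/ratings.csv --out scores.csv
qgenie itemstats --ratings data/ratings.csv --group-map data/group_map.csv --out items.csv
qgenie gtheory   --ratings data/ratings.csv --group-map data/group_map.csv --out g.json
qgenie meta      --effects effects.csv --exclude-low --out meta.json
qgenie run       --seed 0 --out run/        # full pipeline
```

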