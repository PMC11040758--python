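# Methods

## The index

The Sustainable Diet Index implemented here is a composite of 12
per-person indicators in four dimensions (nutritional, environmental,
economic, sociocultural), equally weighted per the FAO definition of
sustainable diets. Each indicator is banded into 1–5 points; a sub-index
is the mean of its member points; the total is the sum of the four
sub-indices (range 4–20, higher = more sustainable).

**Banding convention.** Bands are left-open/right-closed: a value exactly
equal to a threshold falls in the lower band. Direction matters:
nutritional indicators earn 5 in the top quintile, footprints, budget
share and frequencies in the bottom. The three frequency indicators use
the *zero rule*: an exact zero earns 5 points; nonzero values are banded
by quartiles of the nonzero distribution into 4…1. Ties at a boundary are
resolved by the ≤ rule, deterministically.

Two scoring modes exist. `fixed` applies the versioned US rubric shipped
in `data/cutpoints_us.csv`, so scores are reproducible without any survey
microdata. `derive` recomputes thresholds from the cohort at hand as
survey-weighted quantiles (quintiles; nonzero-quartiles for zero-rule
indicators). One printed-rubric irregularity is worth noting: the
freshwater 5-point bound is 161.4 L while the adjacent 4-point band is
printed as starting at 161.5 L; we implement continuous bands with the
5-point bound (161.4) authoritative, so no value is unassignable.

**Ties in derived thresholds.** On integer-valued frequency indicators,
weighted quartiles of the nonzero subset can legitimately tie (mass
concentrates on small counts). Derived threshold tuples are therefore
required to be non-decreasing rather than strictly increasing; a tied
threshold simply skips the empty band — exactly the behavior of
rank-based quantile grouping under heavy ties. Fully degenerate
thresholds (all equal) raise an error.

## Nutritional indicators

**NRF9.3** sums the percent daily values of nine nutrients to encourage
(protein, fiber, vitamins A/C/E, calcium, iron, magnesium, potassium),
each capped at 100 %DV, and subtracts the %DV of three to limit
(saturated fat, added sugar, sodium; uncapped). The index is expressed on
a *density basis*: per 100 kcal of the day's intake by default
(`per_2000kcal` and `per_day` are configuration switches). On the density
basis, isocaloric scaling of a whole diet leaves the score unchanged
provided no encourage term crosses its cap. Daily-value references ship
in `data/dv_table.csv` (FDA adult daily values) and are editable.

**MAR** is 100 × the mean of 12 nutrient adequacy ratios: 11 dietary
micronutrients (vitamin A, thiamin, B6, folate, C, E, calcium, magnesium,
iron, zinc, copper) each divided by the sex/age-band RDA
(`data/rda_table.csv`) and capped at 1, plus serum 25-hydroxyvitamin D
divided by the 50 nmol/L deficiency cut-point. The 11 dietary intakes are
first energy-adjusted by the **residual method**: a survey-weighted OLS of
intake on total energy, with the adjusted value = residual + fitted value
at the cohort's weighted mean energy, floored at zero. Serum 25(OH)D is a
biomarker, not an intake, and is not energy-adjusted. The regression is
run pooled over the post-exclusion cohort with Day-1 dietary weights;
both the weighting and the adjustment itself are switchable.

## Environmental indicators

Each reported food item is matched by food code to one of 43 food groups
via a single-valued crosswalk; six per-serving impact factors (freshwater
L, stress-weighted water L, acidifying g SO₂eq, eutrophying g PO₄³⁻eq,
GHGE kg CO₂eq, land m²) are multiplied by reported servings and summed
into per-day totals. Unmatched items (typically mixed/processed dishes)
contribute zero impact but are tallied, so every person-day carries an
observable match coverage; matched-only estimation keeps the estimator
transparent at the cost of underestimating absolute footprints.

The shipped `impact_factors_synthetic.csv` and `crosswalk_synthetic.csv`
are **synthetic** reference tables with realistic orders of magnitude
(ruminant meat ≫ dairy/poultry ≫ plant foods; stress-weighted water in
the thousands of liters per serving); the loaders accept any
user-supplied 43-group table and crosswalk, which is how real factor
databases are plugged in.

A sensitivity variant drops freshwater withdrawals (possible double
counting with stress-weighted water): the environmental sub-index then
averages 5 points instead of 6, and nothing upstream changes.

## Economic and sociocultural indicators

Annual food expenditure is 12 × the sum of four monthly amounts (grocery,
other stores, eating out, carry-out/delivery); a missing component makes
the indicator missing (and the person excludable). Family income is
reported as an ordered category; the proxy is the band midpoint, with the
top-coded band mapped to a configured value (default 1.5 × its lower
bound) in `data/income_bands.csv`. The budget share is
100 × food/income; shares above 100% are retained and flagged — the share
distribution is heavily right-skewed and truncating it would distort the
bottom quintile. The three frequency indicators are validated against
their instrument ranges (fast-food meals 0–21 per 7 days; ready-to-eat
and frozen 0–90 per 30 days), and fast-food meals may not exceed total
away-from-home meals when the latter is captured.

## Exclusion cascade

Persons are removed sequentially: pregnancy/breastfeeding → incomplete
first recall (no positive-energy nutrient day) → missing serum 25(OH)D →
missing index components (income, any expenditure amount, any frequency)
→ missing education. Each person is counted once, at the first criterion
met, so the per-step counts are disjoint and conserve
`initial − Σ removed = final`. Permuting criteria changes the attribution
but not the final sample.

## Survey-weighted estimation

Means, correlations and subgroup contrasts use per-person weights, with
variances by ultimate-cluster Taylor linearization: PSU totals of the
linearized scores are contrasted within strata,
`Var = Σ_h n_h/(n_h−1) Σ_j (z_hj − z̄_h)²`, with `df = #PSU − #strata`.
With equal weights and each unit its own PSU this reduces to the textbook
`s/√n`. Strata containing a single PSU are pooled into one synthetic
stratum (or raise, per configuration). Subgroup contrasts linearize the
difference of domain means and report a two-sided t-based p-value at the
design df; α = 0.05, no multiplicity adjustment.

## Comparison diet scores

**aMed** (0–9): one point per beneficial component (vegetables, legumes,
fruits, whole grains, nuts, fish, MUFA:SFA ratio) at or above the
sex-specific weighted cohort median (overridable), one for red/processed
meat below its median, one for alcohol inside a moderate range (default
5–25 g/day, configurable). **EAT-Lancet** (0–14): one point per
recommendation met, with grams-per-day thresholds and serving→gram
conversions in editable fixtures (`eat_lancet_criteria.csv`,
`food_group_map.csv`); the added-fats criterion uses the
unsaturated:saturated fat ratio ≥ 0.8 and added sugar uses the nutrient
total. Component amounts are rolled up from matched intake items through
the same 43 food groups used for footprints; DGA food-group summaries
(total vegetables, grains, protein foods, …) use the same map.

**Agreement between index variants** is measured by weighted quintile
cross-classification (% same class, % same-or-adjacent, % opposite
extremes; performance "good" if >50% same and <10% gross, "poor" if the
reverse, otherwise indeterminate) and by weighted kappa (linear weights
by default, quadratic switchable; bands ≥0.61 good, 0.41–0.60 acceptable,
0.21–0.40 fair, else poor). Survey weights act as fractional counts in
the confusion matrix.

## Synthetic cohort generator

The generator emulates the statistical structure the index consumes, not
any real survey's margins:

- **Latent diet quality** `q ~ N(0, 1)` loads positively on encouraged
  nutrient densities (+0.2…0.35 per SD), negatively on saturated fat,
  added sugar, sodium (−0.15…−0.3), tilts food-group choice toward plant
  groups (+0.35 logit per SD) and away from animal groups, lowers budget
  share (−0.15) and ready-made-food frequencies (−0.25). A planted shift
  (+0.8 SD by default) for ages ≥ 60 gives contrast recovery a known truth.
- **Energy and nutrients** are lognormal, nutrients conditioned on energy
  (density × energy × lognormal noise) so residual energy adjustment has
  genuine signal to remove.
- **Intake items**: ~11 items/person-day; 40% match the crosswalk (the
  remainder are synthetic mixed-dish codes), gamma-distributed servings.
- **Budget shares** are lognormal (median 20%, log-sd 0.65 → mean ≈ 24.7%,
  heavy right tail); expenditures split by a Dirichlet over the four
  questions.
- **Frequencies** are zero-inflated (45–50% exact zeros) with Poisson
  counts clipped to the instrument ranges.
- **Design**: 15 strata × 2 PSUs, lognormal weights.

Same `(params, seed)` → byte-identical CSVs. What passing tests on this
cohort demonstrate: the scoring, exclusion, estimation and agreement
machinery are arithmetically correct and the qualitative correlation
structure (each sub-index moderately, each leave-one-out index strongly
correlated with the total) emerges from a single-factor world. What they
do not demonstrate: real-data marginals, measurement error, multi-day
recall structure, or the true environmental factor magnitudes.

## Problem sizes and numerical choices

The test suite and acceptance checks use cohorts of 250–2,000 persons
(50 seeds × 250 for contrast-recovery coverage; 10,000 draws for
quantile-mass and rubric-scan checks) — large enough for stable
sampling-based assertions while keeping the default run in a couple of
minutes. Weighted quantiles use the inverse empirical CDF (smallest value
with cumulative weight ≥ target), matching the ≤-rule banding. Degenerate
inputs (zero energy variance, single-class kappa, all-identical indicator
values, single-PSU strata under the `error` policy) raise typed errors
rather than returning numbers.

## Limitations

Footprints are matched-only and per-day; absolute levels depend entirely
on the factor table supplied. The NRF9.3 basis, NAR capping, %DV
denominators, kappa weighting and the aMed alcohol window are
conventions exposed as switches, with the defaults documented above.
Income is a banded proxy; household composition does not adjust income
or expenditure. Single-recall data carry measurement error that energy
adjustment mitigates but does not remove.
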