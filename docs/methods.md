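# Methods

This note documents the models, conventions and numerical choices
behind `needscape`, and what the synthetic-data tests do and do not
establish about real data.

## Survey records and aggregate scores

A household interview is one row of a coded CSV (integer codes mapped
through a column → {code: meaning} table; the default coding lives in
`needscape.survey.DEFAULT_CODE_MAP`). Respondents self-identifying as
Rudar — a Roma subgroup not speaking Romani — are coded `roma`.
Validation enforces: ethnicity, household size and all binary flags
non-missing; time-to-water on the 0–4 scale of 15-minute intervals
(0 = source on premises, 4 = 46–60+ minutes); education grade 0–16;
one geography class per community.

The four aggregate scores **count favorable components**, so larger is
always better:

| score | range | components |
|---|---|---|
| WASH | 0–4 | indoor toilet, indoor bathroom, piped tap, secure housing |
| WASH-Safe | 0–4 | as WASH, water component = tap **or** protected well |
| healthcare | 0–4 | any immunization, no moderate/severe diarrhea (last year), PCP access, insured |
| poverty | 0–3 | electricity, gas, spends > 2 USD/person/day |

The direction is a design choice (the published tables report an
undirected "aggregate"); it makes the sign pattern of the regression
models interpretable — a *negative* WASH coefficient for the Roma
indicator means Roma households score lower. Insecure housing is both
a 0–3 deficiency count (floor, walls, roof) and a yes/no flag (≥ 1
deficient component). By construction WASH ≤ WASH-Safe ≤ WASH + 1,
with equality on the left whenever the household has a piped tap.

Two fields extend the questionnaire's core items: `n_minors` (household
members under 18), from which the three-level age structure
(no / some / majority minors) used as a tree predictor is derived, and
`property_documents`, a bare flag used only by model MOD1.

## Group statistics

Odds ratios are **adverse-oriented**: the odds of the adverse state
(lacking a toilet, suffering diarrhea, inhabiting insecure housing…)
in group 1 (Roma, or rural) over group 2 (non-Roma, or suburban+urban
pooled). This is the only orientation consistent with the full set of
published odds ratios given the published percentages. CIs use the
Woolf log-normal method; any zero cell triggers a flagged
Haldane–Anscombe +0.5 on all four cells.

The t statistic is the pooled-variance two-sample t on the 0/1
indicator with Bessel-corrected group variances nᵢpᵢ(1−pᵢ)/(nᵢ−1) and
df = n₁+n₂−2; this convention (not Welch) reproduces the published
values 2.858 and 3.323 exactly. Published sign conventions are
inconsistent, so magnitudes are the contract. Counts are rebuilt from
printed percentages as round(pct/100·n), ties away from zero.
`needscape.published` carries the printed rows and excludes two that
provably do not reconstruct (immunization OR 1.58; gas OR 2.47 vs a
reconstructed 2.08).

MOD1–MOD4 are linear probability models: OLS of the Roma indicator
(1 = Roma) with intercept and classical standard errors. Predictor
coding mixes directions deliberately — `piped_tap` favorable,
`electricity_lacking`/`insecure_housing`/`diarrhea` adverse — because
the original coefficient table's coding is not fully recoverable; only
direction/significance properties on synthetic data are asserted, not
coefficient values (those would require the study microdata).
Collinear designs are rejected with the dependent columns named (lstsq
residual < 1e-10 against the remaining columns).

## Synthetic population

Grid cells carry person counts (LandScan-style, persons not
households). Cells are attached to the commune whose polygon covers
their centroid; boundary ties go to the lexicographically lowest
region id, and uncovered centroids are a hard error listing orphans.

Within a cell, household sizes are drawn i.i.d. from the
ethnicity-mixture of truncated Poissons (support 1–12; means 5.3 Roma /
4.2 non-Roma, the calibrated study means) until the cumulative size
reaches the cell population; the last household is truncated so the
per-cell person total is **exact**. Ethnicity is assigned at household
level by a largest-remainder quota against the commune's census Roma
share, in seed-randomized order — quotas keep regional ethnic totals
exact, which downstream autocorrelation is sensitive to. Ages: one
adult always; further members are minors with probability 0.45 (Roma)
/ 0.30 (non-Roma), chosen so Roma households skew younger, consistent
with their larger sizes; individual ages are uniform within band and
cosmetic beyond the three-level age-structure class.

## CART pooling and response assignment

One multi-target tree is grown on (ethnicity, household size, age
structure) against all seven binary need indicators jointly, with mean
binary Gini impurity across indicators as the split criterion — the
pooling is a single partition, matching the single set of five response
pools the workflow calls for. Defaults: max depth 4, min leaf 1 (leaf
merging, not a leaf-size floor, handles sparsity). Splits are greedy
with deterministic tie-breaks: predictor order ethnicity <
household_size < age_structure, then lowest threshold (midpoints
between consecutive observed values).

Leaves with < 2 rows are absorbed into the pool sharing the deepest
common ancestor (the tree's own similarity notion); then the smallest
pools merge pairwise, again preferring the deepest common ancestor,
until exactly 5 pools remain (fewer, flagged, if the tree is too
shallow — the pool count is data-dependent). Pools therefore partition
both the survey rows and the predictor space: every synthetic household
routes to exactly one pool and samples one survey row uniformly with
replacement (pools of ~27 rows cannot serve 10⁵ households without
replacement). The household inherits the row's full response vector;
the seven need flags (no electricity, severe poverty, insecure housing,
no improved water, diarrhea, education ≤ grade 8, rural) are a
deterministic function of the assigned row.

## Spatial statistics

Units of analysis are commune centroids carrying region prevalences;
county layers are aggregations. Distances are planar Euclidean
(synthetic coordinates are abstract); weights are binary within a fixed
distance band. Units with no neighbor ("islands") trigger a warning
and exclude that band from incremental inference rather than being
silently zero-weighted.

Global Moran's I uses the randomization-assumption variance
(permutation moments with the sample kurtosis b₂ and the weight sums
S₀, S₁, S₂); significance is the two-sided normal z test at α = 0.05,
uncorrected by default (a Benjamini–Hochberg switch exists and is off).
Incremental autocorrelation evaluates an ascending distance grid and
takes the first z-maximum as the hot-spot neighborhood scale. The
local statistic is the Gi\* form (self-included weights, global
population SD in the denominator); z = 0 by convention where the
denominator vanishes (constant fields), and classes follow the
2.58/1.96/1.65 ladder. Region layers additionally carry
standard-deviation class breaks at ±0.5/1.5/2.5 SD around the
cross-region mean. Cumulative need counts a household's adverse flags
over an include set defaulting to the significantly autocorrelated
indicators plus severe poverty.

Both global and local statistics are verified against independent
O(n²) double-loop implementations to 1e-12, and the z test's empirical
level under label permutation is checked to stay in [0.03, 0.07].

## Synthetic-data generator

The generator emulates the study conditions: five communities of
29/30/30/30/16 households (three rural, one suburban, one urban) with
Roma counts 28/24/18/13/15 (98/135 overall); a 20×20 cell landscape
tiled into 2×2 counties of 5×5 communes; log-normal cell populations
(median 400 persons, σ = 0.3, sized so each commune holds ≥ 200
households, the regime the recovery analysis assumes); a base commune
Roma share of 0.05 with one contiguous 3-commune cluster at 0.50,
recorded as planted ground truth.

Every adverse indicator is Bernoulli with non-Roma prevalence p₀ and
Roma prevalence solved from a target odds ratio,
p₁ = OR·q/(1+OR·q), q = p₀/(1−p₀), so published effect sizes are
directly usable as calibration (e.g. insecure housing p₀ = 0.054,
OR = 6.65). Wells are drawn only for non-tap households at the rate
that makes the derived safe-water flag hit its own calibrated
prevalence. Housing components, education grade and literacy are drawn
conditional on their governing flags. Planted-need fields for recovery
testing assign each household an adverse flag at 0.6 in planted
communes vs 0.2 elsewhere.

**What the generator does not emulate**: indicators are independent
Bernoulli given ethnicity (real WASH/poverty/health items are
correlated within households); regions are rectangles; there is no
time-use or activity-schedule component, no migration, and no survey
nonresponse. Passing tests therefore demonstrate that the machinery is
correct and calibrated under these idealized conditions — not that the
substantive country-scale findings would replicate on real fused data.

## Problem sizes and determinism

Simulation-based checks use: 50,000 households per group for generator
OR calibration; 100,000 routed households — equal shares per pool, so
every pool's prevalence estimate carries the same ~0.35-point standard
error — for assignment consistency; 2000 permutations for the test
level; 10 landscape seeds (~37,000 households each) for hot-spot
recovery. A single global seed fans out to stages by fixed offsets;
same seed, same inputs ⇒ byte-identical artifacts (hashes recorded in
the run manifest).

## Known limitations

* The published multivariate coefficient table and country-scale Moran
  z-scores are not reproducible without the original fused national
  datasets; they are covered by direction/recovery properties instead.
* One printed immunization odds ratio is internally inconsistent with
  its printed percentages; it is computed and reported with a caveat
  but excluded from reproduction checks.
* The three-level age structure is an operationalization; the source
  workflow never defines "age structure of the household".
* Mixed-ethnicity households are not modeled (ethnicity is assigned at
  household level).
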