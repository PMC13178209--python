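# Methods

This note documents the statistical procedures, the synthetic-data
design, the numerical choices, and what the tests do and do not
establish.

## Management indicators

Indicators are computed per farm-year; farm-years are treated as
independent farms, since anonymised surveys cannot track farms across
years. Nutrient input per hectare is mineral fertiliser plus livestock
excretion at a single per-livestock-unit rate (defaults 135 kg N, 19 kg
P, 139 kg K per LU and year — dairy-cow equivalents, since one dairy
cow defines one livestock unit). Real excretion varies by animal type
and production system; the table is therefore a configurable
`ExcretionTable`, not a constant. The manure share is animal-based
input over total input per nutrient, undefined (missing) when the total
is zero. Rotational diversity is the Gini–Simpson index `1 − Σ pᵢ²`
over arable crop-area shares, bounded by `1 − 1/k`. Rotation
composition uses ten categories (cereals, roots and tubers, dry pulses,
sunflower, rapeseed, other industrial, fodder legumes, maize,
vegetables, leys); crop richness counts arable crops with positive
area (arable only — richness of permanent cultures is not a rotation
property). Tillage intensity weights conventional/conservation/zero
tillage areas 1/0.2/0 within a region × farm-size × farm-type cell of
an aggregate table; farms without a matching cell carry a missing
value rather than a guess.

## Predicting management at monitoring points

Farms have no coordinates, so a point inherits the management of the
farms that plausibly surround it, in three tiers: (1) same region,
altitude class (< 300, 300–600, > 600 m) and crop; (2) same region and
crop; (3) nearest farms of the same land-use class within the same
country, accumulated whole-region-by-region ordered by great-circle
distance between region centroids — individual farm distances do not
exist at this resolution. A group is usable only with ≥ 15 farms (the
anonymity cut-off of farm surveys; configurable). Unmatched points are
retained with missing management so sample accounting stays honest.

Within a group, farm *i* carries weight
`w_i = sqrt((area_i/UAA_i) · (area_i/total))`: the first factor
rewards specialisation in the crop, the second representativeness of
the regional production. Summaries are the *lower* weighted median
(smallest value whose cumulative weight reaches half the total; exact,
reproducible, no interpolation — ties in cumulative weight resolve to
the smaller value) and the frequency-weighted population standard
deviation `sqrt(Σw(x−x̄_w)²/Σw)`. The organic probability is the
organic share of the group's crop area, not the share of organic farms.

A Kruskal–Wallis rank-sum test per region, comparing farm-level
indicator values across the grouping, verifies that groups capture
within-region management structure; the summary statistic is the
percentage of regions significant at α = 0.05.

## SOC metrics

Stocks use the fixed-depth 0–20 cm equation
`stock = B_d,ref · OC · 20 · 0.1 · (1 − C_f)` with OC in g C kg⁻¹,
bulk density in g cm⁻³ and coarse fragments as a volume fraction. A
true equivalent-soil-mass correction needs depth-resolved profiles and
is out of scope; instead a *reference* bulk density — predicted from
edaphic covariates for **all** points, including those with a measured
density — standardises the soil mass compared across land uses, since
measured density itself responds to management.

The pedotransfer is a per-land-use OLS regression selected by
exhaustive AIC search over hierarchy-respecting subsets of {sand, clay,
sand × clay, total N, pH, mean annual precipitation} (40 candidates:
the interaction may enter only with both main effects). OC is banned as
a predictor — predicted density multiplies OC in the stock equation,
and admitting OC would count it twice and bias land-use comparisons.
Numerical choices: AIC is computed as `n·ln(RSS/n) + 2k` with the
residual variance floored at machine precision (1e-24) so that
exact-fit candidates on noise-free data remain finite and comparable;
candidates are enumerated smallest-first so ties favour parsimony.
Predictions are clipped to [0.1, 2.2] g cm⁻³, the plausible fine-earth
range; rows with missing covariates yield missing density rather than
an extrapolation.

Missing pedoclimatic zones are imputed by a random-forest classifier
(500 trees, minimum node size 1, 3 features per split) on OC, region,
land cover, texture, pH, precipitation and altitude, reporting the
out-of-bag error. Benchmark ratios divide the stock by the zone ×
land-use typical stock; ΔSOC is the concentration difference between
the two survey dates divided by the elapsed years.

Cleaning (all inequalities strict): organic soils with OC > 160 g C
kg⁻¹ leave every metric at the affected date; for ΔSOC, points whose
land-cover class changed between surveys and points with > 100%
relative whole-period change or > 3 g kg⁻¹ yr⁻¹ absolute change are
removed (such jumps indicate measurement error or soil movement, not
management). The filters are idempotent and per-filter counts are
logged.

## Intensity index and mixed models

The intensity composite ranks each management variable across the
whole analysis set (average ranks for ties, missing retained), min–max
rescales to [0, 1], and reverses variables that lower intensity
(organic probability, manure shares, diversity and richness,
ley + fodder share). Multi-indicator functions — nutrient input (N, P,
K), manure share (N, P, K), crop diversity (Gini–Simpson + richness) —
are averaged internally so each function carries unit weight. The index
is the weighted mean over non-missing groups; a constant variable maps
to 0.5 everywhere (the midpoint invents no contrast where the data have
none). Ranking across the full set (not per land use) keeps one common
scale; land-use-specific variables are simply missing elsewhere.
Being rank-based, the index is invariant to monotone transforms of the
raw variables.

Management effects are estimated with random-intercept linear mixed
models, `y = Xβ + u_zone + ε`, the pedoclimatic zone absorbing
between-zone baseline differences so that β reflects within-zone
management contrasts. Responses are transformed to stabilise variance:
stocks log(1+x), benchmark ratios log(x), ΔSOC asinh(x) (sign-
preserving). Three model families are configured: intensity ×
land-use; individual practices across land uses (with linear +
quadratic N input, allowing the hump-shaped grassland response); and an
arable-only model adding rotation diversity, ley/fodder share and
tillage. Backward elimination drops the least significant term with
p > 0.05 (joint Wald test per term; main effects protected while any
interaction or higher-order term containing them remains) until all
terms are significant; the final model is refitted with REML for
reporting and compared to a random-intercept-only null by a
maximum-likelihood likelihood-ratio test. Marginal effects evaluate
the fixed part over a grid with other continuous covariates at their
means and categorical covariates at their most frequent level, the
random intercept at zero, with delta-method confidence bands
back-transformed by the naive inverse (no smearing correction — a
known, documented simplification).

## Zone effects and the option space

Within each zone × land-use stratum with ≥ 20 ranked points, points
are ordered by the model's management-only linear predictor (zone
intercepts excluded; ties broken by point id), and the management
effect is the mean observed stock of the top ⌈0.1·n⌉ points minus that
of the bottom ⌈0.1·n⌉, with the standard error combining the two
decile-mean errors in quadrature (independence assumed). Management
variability per zone is the mean across indicators of the within-zone
standard deviation of the dataset-wide min–max-normalised indicator —
effects found in low-variability zones mark soils especially sensitive
to management.

Scenario totals measure each decile against the *stratum mean* stock:
best ΔC = (top-decile mean − stratum mean) × area, worst ΔC likewise
with the bottom decile, summed over strata and converted to Pg C
(10⁹ Mg). This baseline lets gains and losses be asymmetric, which is
the empirically relevant behaviour; a symmetric opposite-decile
variant is available behind a flag. Total standard errors follow the
variance formula, `SE = sqrt(Σ (area · se_stratum)²)`, with symmetric
95% intervals. By construction best − worst = Σ area × effect exactly,
and all totals are linear in the areas. The estimates are steady-state
deltas: no adoption dynamics, no transient build-up, no land-use
change.

## Synthetic data: what it emulates and what it does not

The generator mimics the *structure* of the real data sources — a
representative farm survey, an aggregate tillage table, a systematic
topsoil monitoring network, and a zone benchmark table — with a known
generative management → SOC link so that every downstream stage has a
recoverable truth. Design choices, made once:

* Farm distributions are positive and right-skewed (log-normal UAA,
  livestock densities and fertiliser rates; Dirichlet crop areas
  concentrated on a dominant crop within the farm's land-use
  specialisation; Bernoulli organic status whose probability rises
  with altitude, echoing the marginal-land pattern of organic
  farming). Arable dominates the land-cover mix, then grassland, then
  tree crops. The within-group spread of livestock and fertiliser
  draws is a free parameter (`within_group_spread`): real surveys do
  not publish it.
* Pedoclimatic zones are climate (per region) × texture class (sandy
  at ≥ 50% sand), with default 0–20 cm baseline stocks of 38–90 Mg C
  ha⁻¹, spanning Mediterranean-sandy to alpine-loamy conditions.
* A point's *true* management is the weighted group summary assigned
  by the same tiered matching procedure the prediction stage uses (at
  the default cut-off of 15). This makes the generative link operate
  through the group structure that is observable in principle, so
  slope-recovery tests measure the estimation stages rather than
  irreducible matching noise.
* Expected stock = zone baseline + Σ slope × indicator, with default
  slopes +15 Mg C ha⁻¹ per unit manure share, +25 per unit ley share
  and +10 per unit organic probability (positive, ley strongest — the
  directions the field reports), plus Gaussian noise (default SD 8 Mg
  C ha⁻¹, field-scale variability). Bulk density follows a linear
  model on pH, total N and sand × clay (default noise SD 0.05 g cm⁻³);
  the later-date OC is *back-computed* so the stock equation
  reproduces the true stock exactly, and the earlier-date OC encodes a
  configurable yearly change (default mean 0, SD 0.05 g kg⁻¹ yr⁻¹)
  plus measurement noise (default SD 0.5 g kg⁻¹). About a third of
  points carry a measured bulk density, 15% lack a zone label, and 2%
  change land cover between surveys, exercising imputation and
  cleaning.
* Typical benchmark stocks are the stratum means of expected stocks,
  so benchmark ratios centre on one by construction.

Not emulated: spatial autocorrelation of soils and management beyond
the region/zone structure, measurement-method changes between
surveys, multi-year farm panels, and any raster land-cover processing.
Passing tests therefore demonstrate internal correctness and
statistical calibration of the pipeline, not the magnitude of real
European management effects — the real microdata are access-restricted
by design.

## Test and simulation sizes

The routine suite uses 4 regions × 80–120 farms and 300–1 200 points.
The recovery simulation runs 100 replicates at 5 000 points (800
farms) with fully observed zones and checks 95% CI coverage of the
manure- and ley-share slopes; likelihood-ratio calibration uses 500
null replicates at n = 400 with 6 zones; the weighted-median oracle
enumerates 2 500 seeded vectors of length ≤ 8 against the Σw|x−m|
minimiser; noiseless end-to-end consistency runs at 1 000 points and
checks stocks to 1e-6 plus the scenario sign and additivity
identities. These sizes were chosen to make Monte-Carlo error small
relative to the tolerances while keeping the suite comfortably
runnable on a laptop.

## Known limitations

* Backward elimination uses Wald term tests from the ML fit rather
  than exact F-tests with Satterthwaite degrees of freedom; with the
  group counts and sample sizes here the difference is immaterial, but
  small-zone analyses should interpret borderline p-values carefully.
* The LRT compares models differing in fixed effects with the
  classical χ² reference; variance components are never tested on the
  boundary.
* Decile standard errors ignore the covariance induced by points
  sharing a management group; scenario intervals are accordingly
  approximate.
* Marginal-effect back-transformation is the naive inverse; predicted
  response-scale means are slightly biased low for strongly skewed
  residuals.
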