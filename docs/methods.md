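# Methods

This note documents the statistical procedures implemented in `globeseed`,
the defaults chosen where the procedure leaves freedom, what the synthetic
data generator does and does not emulate, and known limitations.

## Data model

A record is one survey observation: location (decimal degrees, WGS84,
southern latitudes negative), one of the 14 TEOW biomes, a measure
(`diversity` = species per sample, `density` = seed count, later
seeds·m⁻²), the quadrat/soil-surface area in m², the depth slice
(upper, lower) in cm with lower > upper ≥ 0, and a sampling month (1–12)
or season. Missing values are empty CSV cells and `None` in memory; no
numeric sentinels exist anywhere, so the modeling stage sees true
missingness. The covariate table carries exactly 31 named variables
(abs.latit, AMT, AP, ATR, AVWAC, BULK, CEC, CLAYC, diversity, HFP, Isoth,
npp, ORGNC, PCQ, PDM, PDQ, pH, Pseason, PWeQ, PWM, PWQ, SANDC, SILTC, TCM,
TCQ, TDQ, TDR, Tseason, TWeQ, TWM, TWQ), keyed by record id. The biome
vocabulary is closed; a biome is "(sub)tropical" when its TEOW name
contains tropical/subtropical, plus mangroves — a biome-based rule, not a
latitude cutoff.

## Standardization

Step order (configurable; default `units → season → area → depth`):

1. **Density units.** Raw seed counts are divided by the sample area to
   give seeds·m⁻²; idempotent via a per-record flag.
2. **Season.** Seasons are hemisphere-aware meteorological quarters
   (DJF = northern winter, JJA = southern winter); an explicit season field
   wins over the month. Per measure and season, the ratio
   r_s = mean(winter values) / mean(season-s values) is computed from
   non-(sub)tropical records only, and each eligible record's value is
   multiplied by r_s(its season). Winter is the fixed point (r = 1);
   tropical records are exempt but flagged as already at convention.
   The ratio-of-means form is the default because pooled survey data has
   no pairing that would support a mean of per-pair ratios; a cross-pair
   `mean_of_ratios` variant (mean over winter×season pairs of w_i/s_j) is
   available.
3. **Area (diversity only).** The species–area power law S = C·A^Z is
   fitted per biome by OLS of log S on log A (records with S ≤ 0 excluded
   and counted); values are rescaled as value·(0.01/A)^Z, which preserves
   record-level variation instead of replacing values by curve
   predictions. A pooled fit is the fallback for biomes with insufficient
   data (< 2 distinct areas or < 10 usable records); fallback use is
   reported.
4. **Depth.** Per biome and measure, log₁₀(value) is regressed on the
   upper and lower depth boundaries (the boundaries include 0 cm, so only
   the response is log-transformed); values are rescaled to the 0–5 cm
   slice as value·10^{b₁(0−u)+b₂(5−l)}. Perfectly collinear boundaries
   (constant slice thickness) fall back to a lower-boundary-only model,
   flagged reduced-rank.

**Outlier capping.** Before the species–area fit, diversity values are
screened with the generalized extreme studentized deviate (Rosner) test:
up to k = max(1, ⌈0.05·n⌉) candidates at α = 0.05 (both configurable),
skipped with a warning below n = 10. Flagged values above the sample's
95th percentile (linear-interpolation definition, computed on the full
pre-capping sample) are replaced by that percentile; low-side outliers are
flagged but untouched. By default capping affects only the fit input, not
the record values that flow onward, and is not applied to density.

**Identifiability.** All corrections are ratios or regressions estimated
from the data, so elementwise inversion of a known generating process is
exact only when (a) the latent response is constant within biomes (and
across the non-tropical biomes pooled in the season fit) and (b) the
season × area × depth design is balanced, making every stratum composition
identical. The generator's `inversion_config()` implements exactly these
conditions with σ = 0; under them the chain recovers latent values to
float precision. With unbalanced designs or latent variation the
estimators remain consistent but not elementwise exact.

## Regression forests

`RandomForestRegressor` with 100 trees (the full-model default), bootstrap
sampling and OOB scoring. Two non-sklearn defaults: minimum leaf size 5
(the regression-forest tradition, which regularizes single- and
few-variable models enough that OOB error is meaningful in the forward
selection), and all features considered at each split, which keeps null
predictors out of the trees so their partial effects stay flat and their
permutation importances center on zero. Rows with any missing covariate
are dropped and counted (complete-case); fits refuse fewer than 10 rows.
OOB pseudo-R² = 1 − OOB MSE / var(y) is the "percent variance explained"
analogue.

**Importance.** Node-purity importance is the total RSS decrease over all
split nodes and trees, computed by walking the fitted tree arrays
(gain = w·i − w_l·i_l − w_r·i_r per node); the per-variable values sum to
the forest's total split gain. Percent increase in MSE shuffles a
variable's values among each tree's OOB samples (5 shuffles per tree,
seeded), averages the per-tree MSE increase, and expresses it as percent
of the forest OOB MSE. Per-tree OOB membership is reconstructed with
scikit-learn's own bootstrap index helpers.

**Selection.** Two stages against shuffled-copy noise variables, in the
spirit of permutation-importance-based forward selection:

- *Stage 1 (screening):* candidates plus 10 shuffled copies of randomly
  chosen candidates are fitted in 2 seeded forests of 30 trees; candidates
  whose mean permutation importance (1 shuffle per tree, a cheaper
  internal ranking device than the reported 5-shuffle metric) does not
  exceed the largest noise-copy importance are discarded.
- *Stage 2 (forward):* survivors are added in rank order to 50-tree
  forests sharing one seed (paired comparisons); a variable is kept only
  when the OOB-error decrease exceeds mean + 2·sd of the |OOB-error
  changes| observed when appending noise copies to the top-ranked
  single-variable model. The first survivor must beat the intercept-only
  error (var(y)) by the same margin, so the global null yields an empty or
  single-variable selection rather than an unconditional keep.

The number of noise variables, forests, trees and the threshold multiplier
are all arguments. Final-model predictor counts are data-driven, never
fixed in advance.

**Cross-validation.** Monte-Carlo K-fold: 99 iterations each withholding a
random 10 % (defaults), refitting on the remainder, recording held-out MSE
and R². On spatially unstructured data the mean CV R² tracks the OOB R².

**Partial effects.** Partial dependence: the predictor is clamped to each
of m grid values, the other columns keep their observed training values,
and predictions are averaged. Grid points outside the training range are
computed but flagged as extrapolation. Per-observation feature-contribution
decompositions are not implemented; partial dependence is the canonical
"marginal effect" here.

**Diagnostics.** The empirical semivariogram uses great-circle (haversine)
distances; γ(h) = Σ(z_i−z_j)²/(2N(h)) over pairs in each lag bin, default
15 equal-width bins to half the maximum pairwise distance. Its
`range_estimate` is the first lag reaching 95 % of the sill (mean γ over
the upper half of the bins). Kruskal–Wallis biome contrasts use the
tie-corrected H with a χ² reference (df = groups − 1). The hemisphere
comparison runs a two-sided Mann–Whitney U per biome present in both
hemispheres (latitude 0 counts as northern); a rank test was chosen over a
t-test because standardized seed bank values are strongly right-skewed.

## Mapping

A covariate grid is a stack of aligned lat/lon layers, cell-center
registered; 5 arcmin is the reference resolution and coarse small-extent
grids are used at desk scale. Prediction flattens the stack to a table,
runs the fitted forest, and reshapes — bit-identical to tabular
prediction. Any cell missing any model covariate is nodata (no
imputation), so the output mask is the union of input masks; the mask is
taken entirely from the input stack. log₁₀ display maps non-positive cells
to nodata and flags the transform in metadata. Rasters are stored as ESRI
ASCII grids written with full float precision (`repr`), which round-trip
losslessly; layer alignment is checked on read with a per-layer extent
report.

## Synthetic worlds

The generator emulates the *statistical structure* of a compiled global
survey database: two responses, per-biome stratification with configurable
mixture weights and a tropical fraction, a northern-hemisphere sampling
bias (default 80 %), mixed seasons, quadrat areas
{0.0025…0.1} m² and depth slices {(0,5),(0,10),(5,10),(0,2),(2,5)} cm,
and mixed time reporting (month only / season only / both / neither).
Latent responses are per-biome baselines times exp(Σ effects), with effect
shapes linear, humped (Gaussian bump) or threshold on named covariates;
defaults mirror the qualitative patterns of interest (humped pH response
on diversity centered at 6.5, positive precipitation and latitude effects,
NPP- and soil-driven density). Observations are generated
multiplicatively: latent × season multiplier × (A/0.01)^Z ×
10^{b₁u+b₂(l−5)} × (A for raw density counts) × lognormal noise
(default σ = 0.3). Covariates are independent uniforms over realistic
ranges except temperature (AMT, TCM) and NPP, which are coupled to
latitude so the world has a climate gradient; grids use the same couplings
(one world) with Gaussian-smoothed noise fields whose implied variogram
reaches 95 % of its sill at 2√(ln 20)·σ ≈ 3.46 σ cells
(`grid_nominal_range_km`).

What the generator does **not** emulate: real climatology or soils,
species identities and composition, spatial autocorrelation in the
*record* responses (records are placed independently, so semivariograms of
record data are flat by construction), study-level clustering, and
reporting quirks of the literature. Passing recovery tests therefore shows
the pipeline's corrections and selections are internally consistent and
identifiable — not that the ecological conclusions from any real database
are correct.

Experiment presets fix the study conditions used by the tests and the
acceptance script: `inversion_config` (balanced, σ = 0, constant
baselines), `species_area_config` (varied areas, single depth, winter
only, σ = 0.2 — isolates the power-law fit), `modeling_config`
(already-standard conventions so observed = latent × noise). Problem
sizes (hundreds to 2000 records, 60×60 desk-scale grids, 10–20 seed
replicates) were chosen as the smallest at which the estimators' sampling
error is comfortably inside the documented tolerances.

## Numerical choices and edge cases

- All stochastic operations take an explicit seed and record it in their
  outputs; reruns with the same config and seed reproduce every number.
- OLS fits go through statsmodels; C = exp(intercept) of the log-log fit.
- Percentiles use numpy's linear interpolation definition.
- Constant responses: forests report zero node-purity importance and
  non-positive pseudo-R²; CV reports zero MSE.
- Empty lag bins carry γ = NaN with N = 0; a constant field gives γ = 0.
- Kruskal–Wallis on groups with all values identical returns H = 0.
- The units step rejects (and reports) density records with non-positive
  area; no step ever drops a record silently.

## Limitations

- Standardization uncertainty is not propagated into the forest models.
- Only random K-fold validation is provided; no spatial blocking.
- The hemisphere comparison and biome contrasts are descriptive; no
  multiple-testing correction is applied across biomes.
- GeoTIFF I/O is not included; the ASCII grid format is the interchange
  format.
- Sampling-method differences between seedling-emergence and sieving
  studies are not modeled.
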