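# Methods

`hiersdm` models the wintering habitat of a wetland bird (the motivating
case is the black stork, *Ciconia nigra*, in central China) with species
distribution models (SDMs) calibrated at two nested spatial scales, and
propagates two kinds of future change through them: climate scenarios at the
coarse scale and simulated land-use/land-cover (LULC) change at the fine
scale. This note documents the models, the parameters that matter, the
synthetic data the package is exercised on, and the numerical conventions.

## 1. Two-scale design

Climate constrains species distributions at macro scales; land cover, water
and human pressure act at landscape scales. The pipeline therefore fits

* a **national model** on a coarse grid (order 10 km cells) from bioclimatic
  variables (bio3 isothermality, bio9 mean temperature of the driest
  quarter, bio14 precipitation of the driest month, bio15 precipitation
  seasonality) plus a categorical LULC layer; and
* a **provincial model** on a fine grid (order 300 m cells) from local
  variables: aspect, elevation, slope, LULC, nightlight, distance to the
  main road, and distance to water.

Only the national model is projected to future climates: a model calibrated
on a small region samples a truncated climate niche and extrapolates badly.
The provincial model's futures instead swap only the LULC layer for maps
simulated by the land-use cellular automaton; its climate inputs do not
exist by construction. Final habitat at any date is the cell-wise
intersection of the (nearest-resampled) national binary map with the
provincial binary map; the final continuous surface keeps the provincial
suitability inside that overlap.

## 2. Ensemble SDM

Six presence-background learners are fitted per scale: gradient-boosted
trees (BRT), a spline-basis logistic model (GAM), a linear+quadratic
logistic model (GLM), a maxent-style penalised logistic on hinge+quadratic
features (MXD), a random forest (RDF), and a calibrated support vector
machine (SVM). They are deliberately simple, seeded stand-ins for the usual
R implementations: the contract is "probabilistic binary learner", and every
member exposes identical fit/predict behaviour.

For each of `n_runs` (default 10 in the field, 3–5 in the shipped
experiments; see §7) stratified 80/20 splits, every member is fitted on the
training part and scored on the held-out part. A member's True Skill
Statistic r_j, averaged over runs, becomes its weight

    W_j = r_j / Σ_j r_j ,

and the ensemble suitability is the cell-wise weighted mean of the member
predictions refit on all data. Members with r_j ≤ 0 carry no information and
are excluded before normalisation (weighting by a non-positive skill is
undefined); if no member has positive TSS the ensemble is an error, not a
map. Whether to average per-run maps or refit on the full data is a genuine
design fork; refitting was chosen because it uses all occurrences in the
final map and keeps one model per algorithm (`fit_ensemble` encapsulates the
choice).

## 3. Evaluation

Seven metrics per model: rank-based AUC (ties = ½); Kappa, TSS, Jaccard and
Sørensen at the binarisation threshold; Fpb, implemented as the F-measure on
presence-background counts 2TP/(2TP+FP+FN) — identical in form to Sørensen
with background standing in for absences, which is how the presence-
background literature defines it; and the continuous Boyce index. Metrics
with an empty margin are reported as NaN, never 0.

**MTSS threshold.** The binarisation threshold maximises sensitivity +
specificity over the unique observed scores; ties take the smallest
threshold. It is searched on *training* scores (the name says "training");
a switch allows test scores. Cells exactly at the threshold are suitable
(the ≥ convention; ties are measure-zero for continuous scores).

**Boyce.** 101 overlapping windows, each 10 % of the pooled score range,
span that range; per window the predicted/expected ratio is the presence
fraction divided by the background fraction, windows with zero expectation
are dropped, and the index is the Spearman correlation between P/E and the
window midpoint (undefined below 3 valid windows). A caution discovered
while testing: under the null (presence ≡ background distribution) the index
is centred at zero but has a standard deviation near 0.32 *regardless of
sample size*, because adjacent windows share ~90 % of their samples and the
resulting smooth noise in P/E correlates with the midpoints by chance.
Single Boyce values close to ±0.3 are therefore not evidence of calibration
or miscalibration; only the centring (mean across replicates) is stable.

**Variable importance.** Permutation importance: the mean AUC drop over
`n_reps` permutations of one predictor column, negatives clipped to zero,
normalised to sum to one per algorithm; the cross-algorithm mean μ is the
headline number. **Response curves** use the evaluation-strip method: the
target variable sweeps fixed quantile steps of its observed values while all
other predictors sit at their medians.

## 4. Land-use change simulation

A simplified patch-generating land-use model with three stages:

1. **Demand**: per class, cell counts are linearly extrapolated from the net
   change between two historical maps (D_c = A_c(t2) + ΔA_c · ahead/between),
   clamped at zero and rescaled to the total cell count by largest-remainder
   rounding. Linear extrapolation is the "transition rate stays as in the
   past decade" assumption; a Markov alternative was considered and left out
   of scope.
2. **Transition suitability** (expansion-analysis analog): per class, a
   seeded random forest is trained on driver values at cells that expanded
   into the class historically versus an equal-sized sample of cells that
   did not, and predicts P_c everywhere. Classes with no historical
   expansion get a zero surface and a warning.
3. **Allocation** (seeded-patch CA): donor cells (classes above demand) are
   visited in seeded random order; a donor may convert to an under-demand
   class c with overall probability OP_c = P_c (w·N_c + (1−w)), where N_c is
   the class-c fraction of the 3×3 Moore neighbourhood and w (default 0.8)
   pulls growth toward existing patches. Cells with no class-c neighbour may
   still seed a new patch with probability r (default 0.01) using P_c alone.
   The class is chosen by roulette over the candidate probabilities; the
   conversion is accepted when the probability meets an acceptance threshold
   that starts at 0.9 and decays by δ = 0.9 each sweep, so the most suitable
   cells convert first. Sweeps stop when every class is within ±1 % of total
   cells of its demand, or after `max_iters` (200). Total cell count is
   asserted conserved every sweep. These constants are engineering defaults,
   not canonical values of any published CA.

Validation is a hold-out loop: fit the transition model on the t0→t1 pair,
simulate t2, and compare against the actual t2 with overall accuracy and
multi-class Kappa. One behaviour worth knowing: because demand is linear
while a distance-rule frontier grows quadratically in area, the simulated
map systematically under-allocates the outermost ring; on the synthetic
truth this costs a few percent of OA, not more.

## 5. Hierarchy, refugia and reporting

Binary maps intersect by logical AND with nodata propagating (a nodata cell
is never suitable). Climate refugia are cells suitable now *and* under every
future climatic map (default: all six scenario × period maps; configurable,
since a narrower reading — current vs. each future separately — is also
defensible). Change accounting decomposes current/future pairs into
stable = cur∧fut, lost = cur∧¬fut, gain = ¬cur∧fut, which satisfy
stable+lost = current area and stable+gain = future area exactly.

Areas: on the flat synthetic grid a cell is cell_size² (exact); on lon/lat
grids each cell is weighted by cos(latitude of its row centre) on a
spherical Earth (R = 6371.0088 km). Both modes exist because the original
analysis does not state which projection its areas used. Latitude profiles
bin suitable area into half-open 0.1° bands aligned to multiples of the
bandwidth; the peak is the band of maximum area, ties resolving to the
southernmost band. Percentages are rounded half-away-from-zero at the
printed precision (2 dp for change tables, 1 dp for coverage shares) —
`round()`'s banker's rounding does not reproduce printed report tables.

## 6. Synthetic data: what it emulates and what it does not

All generators are pure functions of (parameters, seed). Smooth fields are
Gaussian-filtered white noise rescaled to a target range — the simplest
controllable spatial autocorrelation.

* **bio9** is a linear south→north gradient from +20 °C to −15 °C plus ±2 °C
  of smooth noise; **bio14** spans 0–100 mm; bio3/bio15 are pure nuisance
  fields.
* The **truth model** is a logistic in: a quadratic bio9 term with its
  optimum at 0 °C (curvature −0.10 /°C², so suitability collapses beyond
  roughly ±6 °C), a bio14 ramp that is inert below 36 mm, and land-cover
  weights that favour wetland (1.0) over cropland/grassland (0.4–0.5) and
  bare ground (0.0), scaled by 3.0; intercept −3.5. The provincial truth
  replaces the climate terms with an exponential distance-to-water decay
  (scale 2 500 m, weight 3.5), the same wetland-favouring land-cover term,
  and a mild slope penalty. The effect sizes were chosen once so that the
  generated problem is learnable but not trivial (member held-out AUC near
  0.9, not 1.0).
* **Occurrences** are cells drawn without replacement with probability
  proportional to truth suitability — so grid-cell thinning is exactly
  testable. **Scenario futures** add +0.5/+1.0/+1.5 °C (2030s) and
  +0.8/+1.5/+2.5 °C (2050s) for the optimistic/moderate/pessimistic
  pathways and scale the precipitation layers by 2–10 %; these deltas are
  stand-ins ordered as the pathways are, not GCM output.
* The **LULC series** plants an impervious core at the grid centre of a
  random six-class mosaic and converts grassland within a linearly growing
  radius of that core; current land use, distance to the core, elevation and
  white noise form the driver stack, so the rule is exactly recoverable.
* **Protected areas** are random circular blobs trimmed to the requested
  coverage fraction (±10 % relative).

What the generator does *not* emulate: bioclim derivation from monthly
climatologies, realistic GCM anomaly patterns, detection/survey bias in
occurrences, >6 land-cover classes, vector reserve boundaries, and real
coastline/province geometry. Passing tests therefore demonstrate that the
machinery recovers known truths under clean conditions; they say nothing
about transferability to biased or autocorrelated real survey data.

**Study-region geometry for the warming-shift experiment.** On a
rectangular region the MTSS-binarized suitable strip saturates whole rows
over a broad latitude plateau, so the 0.1°-band argmax is pinned by fixed
land-cover noise and cannot register a +1.5 °C shift (a quadratic response
is flat near its optimum). The warming experiment therefore evaluates the
profile over a wedge-shaped study region whose east-west width shrinks
northward (`wedge_study_region`): band area then peaks at the suitable
strip's southern boundary, which is precisely the feature that moves north
under warming (~0.6° of latitude per +1.5 °C on this gradient). The model
itself is still fitted on the full rectangle.

## 7. Problem sizes and numerical choices

The shipped experiments use a 60×80-cell national grid at 0.25° with 500
presences and 500 background points, 3 repeated splits for the headline fit
(2 for the held-out refit), a 100×100 land-use grid, and an 80×80 or
160×160 provincial grid at 0.05°; the full pipeline completes in well under
a minute on one CPU at these sizes. All stochastic stages derive their
seeds from one master seed via `numpy.random.SeedSequence`, so every map and
table is byte-reproducible. Degenerate inputs are handled explicitly:
constant predictors are dropped with a warning before correlation screening,
an all-equal score vector yields its own (flagged) MTSS threshold, empty
confusion margins yield NaN metrics, zero-expansion classes yield zero
transition surfaces, and infeasible demand is rejected at entry.

## 8. Known limitations

* Member algorithms are compact stand-ins; absolute metric values will not
  match any specific R implementation, though ranking and weighting logic
  will.
* The CA is a structural analog: single resolution, no planning/constraint
  masks, engineering defaults for w, r, δ and tolerance.
* The continuous Boyce index is intrinsically noisy under the null (§3);
  treat single values near ±0.3 as uninformative.
* Linear demand extrapolation under-allocates accelerating (frontier-style)
  growth.
* lon/lat areas use the spherical cosine approximation, adequate at the
  grid sizes used here but not survey-grade.
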