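# hiersdm

Hierarchical two-scale ensemble species distribution modelling, with
land-use change simulation and climate-scenario projection.

## The problem

Where can a wetland bird overwinter, now and under future climate and
land-use change? Climate constrains distributions at macro scales (hundreds
of kilometres), while land cover, water availability and human pressure act
at landscape scales. A model fitted only at the fine scale samples a
truncated climate niche and extrapolates future climate badly; a model
fitted only at the coarse scale misses the local conditions that actually
make a cell usable. `hiersdm` implements the hierarchical answer: fit an
ensemble SDM at each scale, binarise both, and intersect them —

    final habitat = climatically suitable (coarse) AND locally suitable (fine).

Only the coarse model is projected to future climates; the fine model's
futures swap in land-cover maps simulated by a patch-generating cellular
automaton. The package is aimed at quantitative ecologists who want the
full chain — occurrence thinning, background sampling, collinearity
screening, six-member weighted ensembles, seven-metric evaluation,
MTSS binarisation, CA land-use simulation, refugia and change accounting —
as tested, seeded, reusable Python, exercised end to end on synthetic data
with a known truth model.

## The core method

Each scale fits six presence-background learners (BRT, GAM, GLM, a
maxent-style penalised logistic, RDF, SVM) over repeated stratified 80/20
splits. Member j's True Skill Statistic r_j (sensitivity + specificity − 1,
averaged over runs) sets its weight in the ensemble mean:

    W_j = r_j / Σ_{j=1}^{h} r_j,          S(x) = Σ_j W_j p_j(x)

with members at r_j ≤ 0 excluded. The suitability surface S is binarised at
the maximum-training-sensitivity-plus-specificity (MTSS) threshold. Models
are evaluated with AUC, Kappa, TSS, Jaccard, Sørensen, Fpb and the
continuous Boyce index; variable importance is permutation-based (mean AUC
drop, normalised per algorithm); response curves use the evaluation-strip
method. Land-use futures come from demand extrapolation + random-forest
transition suitability + a seeded cellular automaton with neighbourhood
pull and patch seeding. `docs/methods.md` has the full account.

## Worked example

Fit the national-scale ensemble on synthetic data with a known truth
(bio9 optimum at 0 °C), then project a +1.5 °C scenario:

```python
import hiersdm as h
from hiersdm import synth

grid = h.GridSpec(n_rows=60, n_cols=80, x_origin=97.5, y_origin=42.5,
                  cell_size=0.25, crs_tag="lonlat")
stack = synth.make_national_environment(grid, seed=1)
suit = synth.true_suitability(stack, synth.national_truth())

presences = h.thin_occurrences(synth.sample_occurrences(suit, 500, seed=2),
                               grid, seed=3)
background = h.sample_background(grid, len(presences), presences, seed=4)
table = h.build_training_table(stack, presences, background,
                               categorical=["lulc"])
table = table.subset(h.select_predictors(table, threshold=0.75))

ensemble, reports = h.fit_ensemble(table, n_runs=3, master_seed=5)
for member, w in zip(ensemble.members, ensemble.weights):
    print(f"{member.algorithm_id}: TSS={member.tss_on_test:.3f}  weight={w:.3f}")

from hiersdm.evaluation import mtss_threshold, response_curve
thr = mtss_threshold(table.y, ensemble.predict_frame(table.X))
current = h.binarize(h.ensemble_predict(ensemble, stack), thr)
print(f"MTSS threshold: {thr:.3f}")
print(f"current climatically suitable area: {h.area_km2(current):,.0f} km2")

rc = response_curve(ensemble, "bio9", table.X)
print(f"recovered bio9 optimum: {rc['argmax']:.2f} degC (truth: 0.00)")

warm = synth.make_future_climate(
    stack, synth.ScenarioSpec("SSP585", "2030s", 1.5, 1.0))
future = h.binarize(h.ensemble_predict(ensemble, warm), thr)
rep = h.change_accounting(current, future)
print(f"+1.5 degC: stable {rep.stable_km2:,.0f}, gain {rep.gain_km2:,.0f}, "
      f"lost {rep.lost_km2:,.0f} km2 ({rep.percent_change_vs_current:+.2f}%)")
```

Output:

```
BRT: TSS=0.703  weight=0.162
GAM: TSS=0.740  weight=0.171
GLM: TSS=0.743  weight=0.172
MXD: TSS=0.723  weight=0.167
RDF: TSS=0.690  weight=0.159
SVM: TSS=0.730  weight=0.169
MTSS threshold: 0.586
current climatically suitable area: 754,461 km2
recovered bio9 optimum: 0.53 degC (truth: 0.00)
+1.5 degC: stable 655,176, gain 59,760, lost 99,285 km2 (-5.24%)
```

Reading it: the six members perform similarly on this clean synthetic
problem, so the TSS weights are near-uniform; the fitted ensemble's bio9
response curve recovers the planted 0 °C optimum to half a degree; and under
a +1.5 °C scenario habitat is lost at the warm (southern) edge faster than
it is gained at the cold edge, a net −5.2 %. The full two-scale pipeline —
both models, six scenarios, CA land-use futures, refugia, latitude profiles,
protected-area gaps and report tables — is one call:
`result = h.run_all(h.PipelineConfig(master_seed=1))`.

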