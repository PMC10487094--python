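"""End-to-end orchestration of the two-scale analysis on synthetic data.

The pipeline mirrors the full study design:

1. **National stage** -- generate the coarse climate stack and truth,
   sample and thin occurrences, screen predictors, fit the six-member
   TSS-weighted ensemble over repeated splits, find the MTSS threshold, and
   project the model to the current climate and to each warming scenario
   (only the national model is projected to future climates).
2. **Provincial stage** -- same fitting procedure on the fine local stack;
   futures swap only the land-cover layer for CA-simulated maps (climate
   layers are absent by design at this scale).
3. **Hierarchical stage** -- intersect climatic and local suitability per
   scenario, account stable/gain/loss, compute refugia, latitudinal
   profiles, and protected-area gaps.

Every stochastic step draws its seed from the master seed, so a rerun with
the same config is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import hierarchy, lulc, synth
from .ensemble import (ALGORITHMS, EnsembleModel, ensemble_predict,
                       fit_ensemble, summarize_reports)
from .evaluation import mtss_threshold, variable_importance
from .grid import GridSpec, Raster, area_km2, latitudinal_profile, write_raster
from .occurrence import (OccurrenceSet, build_training_table, sample_background,
                         select_predictors, split_train_test, thin_occurrences)


def _default_national_grid() -> GridSpec:
    # mainland-like extent: 25-42.5 N, 97.5-120 E at 0.25 degrees
    return GridSpec(n_rows=70, n_cols=90, x_origin=97.5, y_origin=42.5,
                    cell_size=0.25, crs_tag="lonlat")


def _default_provincial_grid() -> GridSpec:
    # province-like window nested in the national extent: 31-39 N, 104-112 E
    return GridSpec(n_rows=160, n_cols=160, x_origin=104.0, y_origin=39.0,
                    cell_size=0.05, crs_tag="lonlat")


@dataclass
class PipelineConfig:
    master_seed: int = 0
    national_grid: GridSpec = field(default_factory=_default_national_grid)
    provincial_grid: GridSpec = field(default_factory=_default_provincial_grid)
    provincial_cell_size_m: float = 5560.0  # metres per fine cell edge
    n_presence_national: int = 400
    n_presence_provincial: int = 300
    background_ratio: float = 1.0
    algorithms: tuple = ALGORITHMS
    n_runs: int = 5
    correlation_threshold: float = 0.75
    scenarios: tuple = synth.DEFAULT_SCENARIOS
    latband_width: float = 0.1
    pa_fractions: dict = field(default_factory=lambda: {
        "natural_reserves": 0.05, "wetland_parks": 0.01,
    })
    importance_reps: int = 3
    output_dir: Path | None = None

    def seed_for(self, stage: str) -> int:
        h = sum(ord(ch) * (k + 1) for k, ch in enumerate(stage))
        return (int(self.master_seed) * 1009 + h) % (2**31)


def load_config(path: str | Path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML mapping (missing keys default)."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs = {}
    for key in ("master_seed", "provincial_cell_size_m", "n_presence_national",
                "n_presence_provincial", "background_ratio", "n_runs",
                "correlation_threshold", "latband_width", "pa_fractions",
                "importance_reps"):
        if key in raw:
            kwargs[key] = raw[key]
    for gkey in ("national_grid", "provincial_grid"):
        if gkey in raw:
            kwargs[gkey] = GridSpec(**raw[gkey])
    if "algorithms" in raw:
        kwargs["algorithms"] = tuple(raw["algorithms"])
    if "output_dir" in raw:
        kwargs["output_dir"] = Path(raw["output_dir"])
    return PipelineConfig(**kwargs)


# ---------------------------------------------------------------------------
# National stage
# ---------------------------------------------------------------------------

@dataclass
class ScaleResult:
    """Outputs of one modelling scale."""

    ensemble: EnsembleModel
    reports: pd.DataFrame
    table: object
    predictors: list
    mtss: float
    current_suitability: Raster
    current_binary: Raster
    future_suitability: dict
    future_binary: dict
    stack: dict
    truth: synth.TruthModel
    presences: OccurrenceSet
    extras: dict = field(default_factory=dict)


def run_national(config: PipelineConfig) -> ScaleResult:
    grid = config.national_grid
    stack = synth.make_national_environment(grid, config.seed_for("national-env"))
    truth = synth.national_truth()
    suit_true = synth.true_suitability(stack, truth)
    raw = synth.sample_occurrences(suit_true, config.n_presence_national,
                                   config.seed_for("national-occ"))
    presences = thin_occurrences(raw, grid, config.seed_for("national-thin"))
    n_back = int(round(config.background_ratio * len(presences)))
    background = sample_background(grid, n_back, presences,
                                   config.seed_for("national-bg"))
    table = build_training_table(stack, presences, background,
                                 categorical=["lulc"])
    kept = select_predictors(table, config.correlation_threshold)
    table = table.subset(kept)
    ens, reports = fit_ensemble(table, algorithms=config.algorithms,
                                n_runs=config.n_runs,
                                master_seed=config.seed_for("national-fit"))
    train_scores = ens.predict_frame(table.X)
    mtss = mtss_threshold(table.y, train_scores)
    ens.mtss_threshold = mtss
    current = ensemble_predict(ens, stack)
    current_bin = hierarchy.binarize(current, mtss)
    fut_suit, fut_bin = {}, {}
    for sc in config.scenarios:
        key = (sc.scenario_id, sc.period)
        fstack = synth.make_future_climate(stack, sc)
        fsuit = ensemble_predict(ens, fstack)
        fut_suit[key] = fsuit
        fut_bin[key] = hierarchy.binarize(fsuit, mtss)
    return ScaleResult(
        ensemble=ens, reports=reports, table=table, predictors=kept,
        mtss=mtss, current_suitability=current, current_binary=current_bin,
        future_suitability=fut_suit, future_binary=fut_bin, stack=stack,
        truth=truth, presences=presences,
    )


# ---------------------------------------------------------------------------
# Provincial stage
# ---------------------------------------------------------------------------

def run_provincial(config: PipelineConfig) -> ScaleResult:
    grid = config.provincial_grid
    stack = synth.make_provincial_environment(
        grid, config.seed_for("provincial-env"),
    )
    # distance layers are generated in map units; convert to metres on
    # lonlat grids so the truth's decay scale (metres) applies
    if grid.crs_tag == "lonlat":
        per_cell_m = config.provincial_cell_size_m / grid.cell_size
        for name in ("dist_road", "dist_water"):
            r = stack[name]
            stack[name] = r.with_values(r.values * per_cell_m)
    series = synth.make_lulc_series(grid, config.seed_for("provincial-lulc"))
    stack["lulc"] = series.maps["t2"]

    truth = synth.provincial_truth()
    suit_true = synth.true_suitability(stack, truth)
    raw = synth.sample_occurrences(suit_true, config.n_presence_provincial,
                                   config.seed_for("provincial-occ"))
    presences = thin_occurrences(raw, grid, config.seed_for("provincial-thin"))
    n_back = int(round(config.background_ratio * len(presences)))
    background = sample_background(grid, n_back, presences,
                                   config.seed_for("provincial-bg"))
    table = build_training_table(stack, presences, background,
                                 categorical=["lulc"])
    kept = select_predictors(table, config.correlation_threshold)
    table = table.subset(kept)
    ens, reports = fit_ensemble(table, algorithms=config.algorithms,
                                n_runs=config.n_runs,
                                master_seed=config.seed_for("provincial-fit"))
    train_scores = ens.predict_frame(table.X)
    mtss = mtss_threshold(table.y, train_scores)
    ens.mtss_threshold = mtss
    current = ensemble_predict(ens, stack)
    current_bin = hierarchy.binarize(current, mtss)

    # CA hold-out validation: fit on t0->t1, simulate t2, compare
    trans_val = lulc.fit_transition_model(series.maps["t0"], series.maps["t1"],
                                          series.drivers,
                                          seed=config.seed_for("ca-val"))
    demand_t2 = lulc.estimate_demand(series.maps["t0"], series.maps["t1"],
                                     10.0, 10.0)
    sim_t2 = lulc.simulate_lulc(series.maps["t1"], trans_val, demand_t2,
                                seed=config.seed_for("ca-val-sim"))
    agreement = lulc.map_agreement(sim_t2, series.maps["t2"])

    # future land cover: fit on the recent pair, extrapolate demand
    trans = lulc.fit_transition_model(series.maps["t1"], series.maps["t2"],
                                      series.drivers,
                                      seed=config.seed_for("ca-future"))
    fut_suit, fut_bin = {}, {}
    lulc_maps = {}
    for period, ahead in (("2030s", 10.0), ("2050s", 30.0)):
        demand = lulc.estimate_demand(series.maps["t1"], series.maps["t2"],
                                      10.0, ahead)
        sim = lulc.simulate_lulc(series.maps["t2"], trans, demand,
                                 seed=config.seed_for(f"ca-{period}"))
        lulc_maps[period] = sim
        fstack = dict(stack)
        fstack["lulc"] = sim
        fsuit = ensemble_predict(ens, fstack)
        fut_suit[period] = fsuit
        fut_bin[period] = hierarchy.binarize(fsuit, mtss)
    return ScaleResult(
        ensemble=ens, reports=reports, table=table, predictors=kept,
        mtss=mtss, current_suitability=current, current_binary=current_bin,
        future_suitability=fut_suit, future_binary=fut_bin, stack=stack,
        truth=truth, presences=presences,
        extras={"lulc_series": series, "lulc_future": lulc_maps,
                "ca_agreement": agreement},
    )


# ---------------------------------------------------------------------------
# Hierarchical stage
# ---------------------------------------------------------------------------

@dataclass
class HierarchicalResult:
    current: hierarchy.ScenarioResult
    scenarios: dict            # (scenario_id, period) -> ScenarioResult
    change_reports: dict       # (scenario_id, period) -> ChangeReport
    refugia_map: Raster
    refugia_km2: float
    profiles: dict             # key -> LatBandProfile ("current" + scenarios)
    pa_masks: dict
    gap_percent: dict
    tables: dict               # report-shaped DataFrames


def run_hierarchical(config: PipelineConfig, national: ScaleResult,
                     provincial: ScaleResult) -> HierarchicalResult:
    current = hierarchy.combine_scales(
        national.current_binary, provincial.current_suitability,
        provincial.mtss,
    )
    scenarios, changes, profiles = {}, {}, {}
    if current.final_binary.grid.crs_tag == "lonlat":
        profiles["current"] = latitudinal_profile(current.final_binary,
                                                  config.latband_width)
    for sc in config.scenarios:
        key = (sc.scenario_id, sc.period)
        res = hierarchy.combine_scales(
            national.future_binary[key],
            provincial.future_suitability[sc.period],
            provincial.mtss,
            scenario_id=sc.scenario_id, period=sc.period,
        )
        scenarios[key] = res
        changes[key] = hierarchy.change_accounting(current.final_binary,
                                                   res.final_binary)
        if res.final_binary.grid.crs_tag == "lonlat":
            profiles[key] = latitudinal_profile(res.final_binary,
                                                config.latband_width)
    ref = hierarchy.refugia(national.current_binary,
                            list(national.future_binary.values()))
    pa_masks = {
        name: synth.make_protected_areas(
            current.final_binary.grid, frac,
            config.seed_for(f"pa-{name}"),
        )
        for name, frac in config.pa_fractions.items()
    }
    gaps = hierarchy.protected_gap(current.final_binary, pa_masks)
    tables = _report_tables(config, national, provincial, current, scenarios,
                            changes)
    return HierarchicalResult(
        current=current, scenarios=scenarios, change_reports=changes,
        refugia_map=ref, refugia_km2=area_km2(ref), profiles=profiles,
        pa_masks=pa_masks, gap_percent=gaps, tables=tables,
    )


def class_areas_km2(categorical: Raster) -> dict:
    """Area per land-cover class in km2."""
    row_area = categorical.grid.cell_area_km2()
    out = {}
    for c in np.unique(categorical.values[categorical.valid]):
        ones = (categorical.values == c) & categorical.valid
        out[int(c)] = float((ones.sum(axis=1) * row_area).sum())
    return out


def _report_tables(config, national, provincial, current, scenarios, changes):
    tables = {}
    # land-cover change summary (current vs simulated futures)
    series = provincial.extras.get("lulc_series")
    lulc_future = provincial.extras.get("lulc_future", {})
    if series is not None and lulc_future:
        cur_areas = class_areas_km2(series.maps["t2"])
        rows = []
        for cls in sorted(cur_areas):
            row = {"class": synth.LULC_NAMES.get(cls, str(cls)),
                   "current_km2": cur_areas[cls]}
            for period, m in lulc_future.items():
                areas = class_areas_km2(m)
                row[f"{period}_km2"] = areas.get(cls, 0.0)
                row[f"{period}_change_pct"] = (
                    hierarchy.percent_change(cur_areas[cls],
                                             areas.get(cls, 0.0), 2)
                    if cur_areas[cls] > 0 else float("nan")
                )
            rows.append(row)
        tables["lulc_change"] = pd.DataFrame(rows)
    # evaluation summaries per scale
    tables["evaluation"] = pd.concat(
        {
            "national": summarize_reports(national.reports),
            "provincial": summarize_reports(provincial.reports),
        },
        names=["scale"],
    ).reset_index()
    # habitat change accounting (Table-5-shaped)
    rows = []
    for (sid, period), rep in changes.items():
        rows.append({
            "scenario": sid, "period": period,
            "stable_km2": rep.stable_km2, "gain_km2": rep.gain_km2,
            "lost_km2": rep.lost_km2,
            "percent_change": rep.percent_change_vs_current,
        })
    tables["habitat_change"] = pd.DataFrame(rows)
    return tables


@dataclass
class PipelineResult:
    national: ScaleResult
    provincial: ScaleResult
    hierarchical: HierarchicalResult
    config: PipelineConfig


def run_all(config: PipelineConfig | None = None) -> PipelineResult:
    """Run national, provincial, and hierarchical stages on synthetic data."""
    config = config or PipelineConfig()
    national = run_national(config)
    provincial = run_provincial(config)
    hier = run_hierarchical(config, national, provincial)
    result = PipelineResult(national=national, provincial=provincial,
                            hierarchical=hier, config=config)
    if config.output_dir is not None:
        write_outputs(result, config.output_dir)
    return result


def write_outputs(result: PipelineResult, out_dir: str | Path) -> Path:
    """Write maps, tables, and a JSON manifest to an output directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    maps = out / "maps"
    maps.mkdir(exist_ok=True)
    write_raster(result.national.current_binary, maps / "national_current.grd")
    for (sid, period), r in result.national.future_binary.items():
        write_raster(r, maps / f"national_{sid}_{period}.grd")
    write_raster(result.hierarchical.current.final_binary,
                 maps / "final_current.grd")
    write_raster(result.hierarchical.refugia_map, maps / "refugia.grd")
    for name, df in result.hierarchical.tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    manifest = {
        "master_seed": result.config.master_seed,
        "n_runs": result.config.n_runs,
        "algorithms": list(result.config.algorithms),
        "national_mtss": result.national.mtss,
        "provincial_mtss": result.provincial.mtss,
        "refugia_km2": result.hierarchical.refugia_km2,
        "gap_percent": result.hierarchical.gap_percent,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
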