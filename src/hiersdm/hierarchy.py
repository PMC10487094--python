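"""Cross-scale combination, refugia, change accounting, and reporting.

The hierarchical step intersects the coarse climatic suitability map
(resampled to the fine grid) with the fine-scale local suitability map:
final habitat = climatically suitable AND locally suitable.  On top of that
sit climate refugia (cells suitable now and under every future scenario),
stable/gain/loss accounting between binary maps, protected-area gap
percentages, and the rounded percent-change convention used in reports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grid import GridSpec, Raster, area_km2, overlay_and, resample_nearest


def binarize(suitability: Raster, threshold: float) -> Raster:
    """1 iff suitability >= threshold; nodata preserved.

    Cells exactly at the threshold count as suitable (ties are measure-zero
    for continuous scores; the inclusive convention is documented).
    """
    values = (suitability.values >= threshold).astype(np.int64)
    values[suitability.nodata_mask] = 0
    return Raster(suitability.grid, values, suitability.nodata_mask.copy(), "binary")


@dataclass
class ScenarioResult:
    """Final habitat maps for one scenario x period."""

    scenario_id: str
    period: str
    climatically_suitable: Raster   # coarse binary
    locally_suitable: Raster        # fine binary
    final_binary: Raster            # fine binary = AND of the two
    final_continuous: Raster        # local suitability masked to the overlap


def combine_scales(national_binary: Raster, provincial_suitability: Raster,
                   provincial_threshold: float,
                   scenario_id: str = "current", period: str = "current") -> ScenarioResult:
    """Overlay the coarse climatic map with the fine local suitability.

    The national binary is nearest-resampled to the fine grid; the final
    binary is its AND with the binarised provincial map, and the final
    continuous surface keeps the provincial suitability inside the overlap
    (zero outside).
    """
    fine = provincial_suitability.grid
    national_fine = resample_nearest(national_binary, fine)
    local_binary = binarize(provincial_suitability, provincial_threshold)
    final_binary = overlay_and(national_fine, local_binary)
    cont = np.where(final_binary.values == 1, provincial_suitability.values, 0.0)
    final_continuous = Raster(fine, cont, final_binary.nodata_mask.copy(),
                              "continuous")
    return ScenarioResult(
        scenario_id=scenario_id,
        period=period,
        climatically_suitable=national_fine,
        locally_suitable=local_binary,
        final_binary=final_binary,
        final_continuous=final_continuous,
    )


def refugia(current_binary: Raster, future_binaries: list) -> Raster:
    """Climate refugia: cells suitable now AND under every future map."""
    out = current_binary.copy()
    for fut in future_binaries:
        out = overlay_and(out, fut)
    return out


@dataclass
class ChangeReport:
    """Stable / gained / lost area between a current and a future binary map."""

    stable_km2: float
    gain_km2: float
    lost_km2: float
    percent_change_vs_current: float

    @property
    def current_km2(self) -> float:
        return self.stable_km2 + self.lost_km2

    @property
    def future_km2(self) -> float:
        return self.stable_km2 + self.gain_km2


def _complement(binary: Raster) -> Raster:
    values = (1 - binary.values).astype(np.int64)
    values[binary.nodata_mask] = 0
    return Raster(binary.grid, values, binary.nodata_mask.copy(), "binary")


def change_accounting(current_binary: Raster, future_binary: Raster,
                      decimals: int = 2) -> ChangeReport:
    """Stable = current AND future; lost = current AND NOT future;
    gain = NOT current AND future; areas in km2."""
    stable = area_km2(overlay_and(current_binary, future_binary))
    lost = area_km2(overlay_and(current_binary, _complement(future_binary)))
    gain = area_km2(overlay_and(_complement(current_binary), future_binary))
    cur = stable + lost
    pct = percent_change(cur, stable + gain, decimals) if cur > 0 else float("nan")
    return ChangeReport(stable_km2=stable, gain_km2=gain, lost_km2=lost,
                        percent_change_vs_current=pct)


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of printed report tables)."""
    factor = 10.0 ** decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def percent_change(reference_area: float, new_area: float, decimals: int = 2) -> float:
    """(new - reference) / reference * 100, rounded half away from zero."""
    if reference_area == 0:
        raise ZeroDivisionError("percent change undefined for zero reference area")
    return round_half_away((new_area - reference_area) / reference_area * 100.0,
                           decimals)


def protected_gap(suitable_binary: Raster, pa_masks: dict) -> dict:
    """Per protected-area mask: percent of suitable habitat covered (1 dp)."""
    total = area_km2(suitable_binary)
    out = {}
    for name, mask in pa_masks.items():
        if total == 0:
            out[name] = float("nan")
        else:
            inside = area_km2(overlay_and(suitable_binary, mask))
            out[name] = round_half_away(inside / total * 100.0, 1)
    return out


def importance_mean(table: pd.DataFrame, decimals: int = 2) -> pd.Series:
    """Cross-algorithm mean importance per variable, rounded to ``decimals``
    (the mu column of an importance table)."""
    return table.mean(axis=1).map(lambda v: round_half_away(v, decimals))
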