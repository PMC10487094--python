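"""Simplified patch-generating land-use change simulation.

Three stages mirror the classic expansion-analysis + cellular-automata
land-use frameworks:

1. **Demand** -- per-class cell-count targets at the horizon year, linearly
   extrapolated from the net change between two historical maps and rescaled
   (largest-remainder) so the targets conserve the total cell count.
2. **Transition suitability** -- per class, a seeded random-forest
   classifier trained on driver values at cells that expanded into the class
   historically versus cells that did not, giving a probability surface
   P_c everywhere (the expansion-analysis analog).
3. **Allocation** -- a seeded cellular automaton converts cells from
   over-demand donor classes to under-demand classes.  A cell's overall
   probability for class c is ``P_c * (w * N_c + (1 - w))`` with ``N_c`` the
   class-c fraction of its 3x3 Moore neighbourhood; cells with no class-c
   neighbour may still seed a new patch with probability ``r`` using P_c
   alone.  The acceptance threshold decays by ``delta`` each sweep, so the
   most suitable cells convert first.

Validation compares a simulated map against the actual one with overall
accuracy and the multi-class Kappa coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import cohen_kappa_score, confusion_matrix

from .grid import Raster

_MOORE = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]], dtype=float)


@dataclass(frozen=True)
class CAParams:
    """Cellular-automaton allocation parameters (non-canonical defaults)."""

    neighborhood_weight: float = 0.8   # w: pull toward existing patches
    decay: float = 0.9                 # delta: acceptance-threshold decay/sweep
    seed_prob: float = 0.01            # r: spontaneous patch-seeding probability
    max_iters: int = 200
    tolerance_fraction: float = 0.01   # per-class demand tolerance (of total)
    initial_threshold: float = 0.9


@dataclass
class MapAgreementReport:
    overall_accuracy: float
    kappa: float
    matrix: np.ndarray
    classes: np.ndarray


def _class_counts(values: np.ndarray, valid: np.ndarray, classes) -> dict:
    return {int(c): int(((values == c) & valid).sum()) for c in classes}


def estimate_demand(map_t1: Raster, map_t2: Raster, years_between: float,
                    years_ahead: float) -> dict:
    """Per-class cell-count demand by linear extrapolation of net change.

    ``D_c = A_c(t2) + (A_c(t2) - A_c(t1)) * years_ahead / years_between``,
    negatives clamped to zero, then rescaled to the total valid cell count
    with largest-remainder rounding so the demand vector conserves cells.
    """
    if map_t1.grid != map_t2.grid:
        raise ValueError("demand maps must share a grid")
    if years_between <= 0:
        raise ValueError("years_between must be positive")
    valid = map_t1.valid & map_t2.valid
    classes = np.union1d(np.unique(map_t1.values[valid]),
                         np.unique(map_t2.values[valid]))
    a1 = _class_counts(map_t1.values, valid, classes)
    a2 = _class_counts(map_t2.values, valid, classes)
    ratio = years_ahead / years_between
    raw = {c: max(0.0, a2[c] + (a2[c] - a1[c]) * ratio) for c in a2}
    total = int(valid.sum())
    raw_sum = sum(raw.values())
    if raw_sum == 0:
        raise ValueError("all extrapolated demands are zero")
    scaled = {c: v * total / raw_sum for c, v in raw.items()}
    floors = {c: int(np.floor(v)) for c, v in scaled.items()}
    short = total - sum(floors.values())
    # hand the leftover cells to the largest fractional remainders
    order = sorted(scaled, key=lambda c: (scaled[c] - floors[c], -c), reverse=True)
    for c in order[:short]:
        floors[c] += 1
    return floors


def fit_transition_model(map_t1: Raster, map_t2: Raster, drivers: dict,
                         seed: int = 0, n_estimators: int = 100) -> dict:
    """Per-class transition-suitability surfaces from historical expansion.

    For each class c, positives are cells that changed *into* c between the
    two dates and negatives an equal-sized seeded sample of cells that did
    not; a random forest on the driver values yields P_c over the whole
    grid.  Classes with no expansion get a zero surface with a warning.
    """
    if map_t1.grid != map_t2.grid:
        raise ValueError("maps must share a grid")
    grid = map_t1.grid
    valid = map_t1.valid & map_t2.valid
    for r in drivers.values():
        valid &= r.valid
    names = list(drivers.keys())
    X_all = np.column_stack([drivers[n].values[valid].astype(float) for n in names])
    t1v = map_t1.values[valid]
    t2v = map_t2.values[valid]
    classes = np.unique(np.concatenate([t1v, t2v]))
    rng = np.random.default_rng(seed)
    out = {}
    for c in classes:
        expanded = (t2v == c) & (t1v != c)
        n_pos = int(expanded.sum())
        if n_pos == 0:
            warnings.warn(f"class {int(c)} has no expansion cells; P=0 surface")
            out[int(c)] = Raster(grid, np.zeros(grid.shape), ~valid, "continuous")
            continue
        neg_pool = np.flatnonzero(~expanded)
        neg = rng.choice(neg_pool, size=min(n_pos, neg_pool.size), replace=False)
        pos = np.flatnonzero(expanded)
        idx = np.concatenate([pos, neg])
        y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
        clf = RandomForestClassifier(
            n_estimators=n_estimators, min_samples_leaf=2,
            random_state=int(rng.integers(2**31)),
        )
        clf.fit(X_all[idx], y)
        p = np.zeros(grid.shape)
        p[valid] = clf.predict_proba(X_all)[:, 1]
        out[int(c)] = Raster(grid, p, ~valid, "continuous")
    return out


def simulate_lulc(map_t0: Raster, suit: dict, demand: dict,
                  params: CAParams | None = None, seed: int = 0) -> Raster:
    """Allocate land-use change with a seeded patch-generating CA.

    Donor cells (classes above demand) are visited in seeded random order;
    each may convert to an under-demand class chosen by roulette over the
    overall probabilities ``OP_c = P_c * (w N_c + (1 - w))`` (or ``P_c``
    alone with probability ``r`` when the cell has no class-c neighbour).
    A conversion is accepted when its probability meets the current
    acceptance threshold, which decays by ``delta`` every sweep.  Sweeps
    stop when every class is within tolerance of its demand or after
    ``max_iters`` sweeps.  Total cell count is conserved at every step.
    """
    params = params or CAParams()
    grid = map_t0.grid
    valid = map_t0.valid
    total = int(valid.sum())
    if sum(demand.values()) > total:
        raise ValueError(
            f"infeasible demand: {sum(demand.values())} cells demanded, "
            f"{total} available"
        )
    classes = sorted(demand)
    for c in classes:
        if c not in suit:
            raise KeyError(f"no transition suitability for class {c}")
    values = map_t0.values.copy()
    rng = np.random.default_rng(seed)
    tol = max(1, int(round(params.tolerance_fraction * total)))
    tau = params.initial_threshold
    counts = _class_counts(values, valid, classes)

    for _ in range(params.max_iters):
        deficit = {c: demand[c] - counts[c] for c in classes}
        if all(abs(d) <= tol for d in deficit.values()):
            break
        under = [c for c in classes if deficit[c] > 0]
        over = {c for c in classes if deficit[c] < 0}
        if not under or not over:
            break
        # class-c neighbourhood fractions, recomputed once per sweep
        frac = {
            c: ndimage.convolve((values == c).astype(float), _MOORE,
                                mode="constant") / 8.0
            for c in under
        }
        donor_cells = np.flatnonzero(np.isin(values, list(over)).ravel()
                                     & valid.ravel())
        rng.shuffle(donor_cells)
        need = {c: deficit[c] for c in under}
        for flat in donor_cells:
            i, j = divmod(int(flat), grid.n_cols)
            src = int(values[i, j])
            if src not in over or counts[src] <= demand[src]:
                continue
            cand_c, cand_p = [], []
            for c in under:
                if need[c] <= 0:
                    continue
                p_c = suit[c].values[i, j]
                n_c = frac[c][i, j]
                if n_c > 0:
                    p = p_c * (params.neighborhood_weight * n_c
                               + (1.0 - params.neighborhood_weight))
                elif rng.random() < params.seed_prob:
                    p = p_c  # spontaneous patch seed
                else:
                    continue
                cand_c.append(c)
                cand_p.append(p)
            if not cand_c:
                continue
            cand_p = np.asarray(cand_p)
            pick = int(rng.choice(len(cand_c), p=cand_p / cand_p.sum())) \
                if cand_p.sum() > 0 else None
            if pick is None or cand_p[pick] < tau:
                continue
            dst = cand_c[pick]
            values[i, j] = dst
            counts[src] -= 1
            counts[dst] += 1
            need[dst] -= 1
        assert sum(counts.values()) == total  # conservation at every sweep
        tau *= params.decay
    return Raster(grid, values, map_t0.nodata_mask.copy(), "categorical")


def map_agreement(simulated: Raster, actual: Raster) -> MapAgreementReport:
    """Overall accuracy and multi-class Kappa between two categorical maps."""
    if simulated.grid != actual.grid:
        raise ValueError("maps must share a grid")
    valid = simulated.valid & actual.valid
    s = simulated.values[valid]
    a = actual.values[valid]
    classes = np.union1d(np.unique(s), np.unique(a))
    matrix = confusion_matrix(a, s, labels=classes)
    oa = float(np.trace(matrix) / matrix.sum()) if matrix.sum() else float("nan")
    kappa = float(cohen_kappa_score(a, s, labels=classes)) \
        if len(classes) > 1 else float("nan")
    return MapAgreementReport(overall_accuracy=oa, kappa=kappa,
                              matrix=matrix, classes=classes)
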