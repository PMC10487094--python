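"""Occurrence thinning, background sampling, collinearity screening, splits.

Presence-only SDMs contrast presence points against background (pseudo-
absence) points.  This module prepares both: spatial thinning to one point
per grid cell (reduces survey autocorrelation), uniform background sampling
outside presence cells, greedy Pearson-correlation predictor screening at
|r| < 0.75, and stratified 80/20 train/test partitioning repeated over runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import GridSpec, Raster


@dataclass
class OccurrenceSet:
    """Point set in map coordinates with a presence/background label."""

    points: list  # [(x, y), ...]
    label: str = "presence"

    def __post_init__(self) -> None:
        if self.label not in ("presence", "background"):
            raise ValueError(f"unknown label {self.label!r}")
        if len(set(self.points)) != len(self.points):
            raise ValueError("duplicate points in OccurrenceSet")

    def __len__(self) -> int:
        return len(self.points)

    def as_arrays(self):
        if not self.points:
            return np.empty(0), np.empty(0)
        a = np.asarray(self.points, dtype=float)
        return a[:, 0], a[:, 1]

    def to_frame(self) -> pd.DataFrame:
        x, y = self.as_arrays()
        return pd.DataFrame({"lon": x, "lat": y})

    @classmethod
    def from_frame(cls, df: pd.DataFrame, label: str = "presence") -> "OccurrenceSet":
        return cls(points=list(zip(df["lon"].tolist(), df["lat"].tolist())),
                   label=label)


@dataclass
class TrainingTable:
    """Predictor matrix + 0/1 response for one modelling scale.

    ``categorical`` names the predictors holding class codes (one-hot
    encoded inside the learners); all others are treated as continuous.
    """

    frame: pd.DataFrame
    predictor_names: list
    categorical: list = field(default_factory=list)
    run_id: int = 0

    def __post_init__(self) -> None:
        missing = [p for p in self.predictor_names if p not in self.frame.columns]
        if missing:
            raise ValueError(f"predictors missing from frame: {missing}")
        if "response" not in self.frame.columns:
            raise ValueError("frame must contain a 'response' column")
        if self.frame[self.predictor_names].isna().any().any():
            raise ValueError("training table contains nodata predictor values")

    @property
    def X(self) -> pd.DataFrame:
        return self.frame[self.predictor_names]

    @property
    def y(self) -> np.ndarray:
        return self.frame["response"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)

    def subset(self, predictor_names: list) -> "TrainingTable":
        return TrainingTable(
            frame=self.frame,
            predictor_names=list(predictor_names),
            categorical=[c for c in self.categorical if c in predictor_names],
            run_id=self.run_id,
        )


def thin_occurrences(points: OccurrenceSet, grid: GridSpec, seed: int) -> OccurrenceSet:
    """Keep at most one point per grid cell, the survivor drawn uniformly
    at random (seeded) within each multi-occupied cell."""
    if len(points) == 0:
        raise ValueError("cannot thin an empty occurrence set")
    x, y = points.as_arrays()
    rows, cols = grid.cell_index(x, y)
    rng = np.random.default_rng(seed)
    by_cell: dict = {}
    for i, key in enumerate(zip(rows.tolist(), cols.tolist())):
        by_cell.setdefault(key, []).append(i)
    survivors = sorted(
        idxs[0] if len(idxs) == 1 else idxs[int(rng.integers(len(idxs)))]
        for idxs in by_cell.values()
    )
    return OccurrenceSet(points=[points.points[i] for i in survivors],
                         label=points.label)


def sample_background(grid: GridSpec, n: int, exclude: OccurrenceSet, seed: int,
                      nodata_mask: np.ndarray | None = None) -> OccurrenceSet:
    """Sample ``n`` distinct cell centers uniformly, excluding presence cells
    and nodata cells."""
    if n < 0:
        raise ValueError("n must be >= 0")
    blocked = np.zeros(grid.shape, dtype=bool)
    if nodata_mask is not None:
        blocked |= np.asarray(nodata_mask, dtype=bool)
    if len(exclude):
        x, y = exclude.as_arrays()
        rows, cols = grid.cell_index(x, y)
        inside = (rows >= 0) & (rows < grid.n_rows) & (cols >= 0) & (cols < grid.n_cols)
        blocked[rows[inside], cols[inside]] = True
    free = np.flatnonzero(~blocked.ravel())
    if n > free.size:
        raise ValueError(f"n={n} exceeds the {free.size} available background cells")
    if n == 0:
        return OccurrenceSet(points=[], label="background")
    rng = np.random.default_rng(seed)
    idx = rng.choice(free, size=n, replace=False)
    rows, cols = np.unravel_index(idx, grid.shape)
    x, y = grid.cell_center(rows, cols)
    return OccurrenceSet(points=list(zip(x.tolist(), y.tolist())), label="background")


def extract_values(stack: dict, points: OccurrenceSet) -> pd.DataFrame:
    """Predictor values at each point's cell; rows with any nodata dropped."""
    any_raster = next(iter(stack.values()))
    grid = any_raster.grid
    x, y = points.as_arrays()
    rows, cols = grid.cell_index(x, y)
    inside = (rows >= 0) & (rows < grid.n_rows) & (cols >= 0) & (cols < grid.n_cols)
    rows, cols = rows[inside], cols[inside]
    data = {}
    ok = np.ones(rows.size, dtype=bool)
    for name, r in stack.items():
        data[name] = r.values[rows, cols].astype(float)
        ok &= ~r.nodata_mask[rows, cols]
    df = pd.DataFrame(data)
    return df[ok].reset_index(drop=True)


def build_training_table(stack: dict, presences: OccurrenceSet,
                         background: OccurrenceSet,
                         categorical: list | None = None,
                         run_id: int = 0) -> TrainingTable:
    """Assemble the presence(1)/background(0) table from a raster stack."""
    pres = extract_values(stack, presences)
    back = extract_values(stack, background)
    pres["response"] = 1
    back["response"] = 0
    frame = pd.concat([pres, back], ignore_index=True)
    return TrainingTable(
        frame=frame,
        predictor_names=list(stack.keys()),
        categorical=[c for c in (categorical or []) if c in stack],
        run_id=run_id,
    )


def select_predictors(table: TrainingTable, threshold: float = 0.75,
                      keep: list | None = None) -> list:
    """Greedy collinearity screen at Pearson |r| < ``threshold``.

    While any surviving pair has |r| >= threshold, the member of the worst
    (largest |r|) pair with the larger mean absolute correlation to all other
    survivors is dropped.  Constant predictors (undefined r) are dropped
    first with a warning.  Predictors in ``keep`` (an "ecologically
    meaningful" keep-list) are never dropped.  Survivors return in input
    order.
    """
    if len(table.predictor_names) < 2:
        return list(table.predictor_names)
    if len(table) < 3:
        raise ValueError("need >= 3 rows to estimate correlations")
    keep = set(keep or [])
    names = list(table.predictor_names)
    X = table.frame[names].to_numpy(dtype=float)
    const = [n for n, col in zip(names, X.T) if np.ptp(col) == 0.0]
    for n in const:
        if n not in keep:
            warnings.warn(f"predictor {n!r} is constant; dropped before screening")
    names = [n for n in names if n not in const or n in keep]
    while True:
        if len(names) < 2:
            return [n for n in table.predictor_names if n in names]
        idx = [table.predictor_names.index(n) for n in names]
        sub = X[:, idx]
        with np.errstate(invalid="ignore"):
            r = np.abs(np.corrcoef(sub, rowvar=False))
        np.fill_diagonal(r, 0.0)
        r = np.nan_to_num(r)
        if r.max() < threshold:
            return [n for n in table.predictor_names if n in names]
        i, j = np.unravel_index(np.argmax(r), r.shape)
        mean_i, mean_j = r[i].mean(), r[j].mean()
        drop_pos = i if mean_i >= mean_j else j
        alt_pos = j if drop_pos == i else i
        if names[drop_pos] in keep:
            drop_pos = alt_pos
        if names[drop_pos] in keep:  # both protected: leave the pair in place
            r[i, j] = r[j, i] = 0.0
            if r.max() < threshold:
                return [n for n in table.predictor_names if n in names]
        names.pop(drop_pos)


def split_train_test(table: TrainingTable, fraction: float = 0.8,
                     run_id: int = 0, seed: int = 0):
    """Stratified split: round(fraction * n) training rows per response class.

    Distinct ``run_id`` values yield distinct partitions under one master
    seed.  Returns ``(train, test)`` TrainingTables; a fraction of 1.0
    produces an empty (flagged) test set.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), int(run_id)]))
    train_idx: list = []
    test_idx: list = []
    for cls in (0, 1):
        cls_idx = np.flatnonzero(table.y == cls)
        perm = rng.permutation(cls_idx)
        k = int(round(fraction * cls_idx.size))
        train_idx.extend(perm[:k].tolist())
        test_idx.extend(perm[k:].tolist())
    if not test_idx:
        warnings.warn("fraction produced an empty test set")

    def _make(idx: list) -> TrainingTable:
        return TrainingTable(
            frame=table.frame.iloc[sorted(idx)].reset_index(drop=True),
            predictor_names=list(table.predictor_names),
            categorical=list(table.categorical),
            run_id=run_id,
        )

    return _make(train_idx), _make(test_idx)
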