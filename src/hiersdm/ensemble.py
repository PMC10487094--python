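"""Ensemble species distribution model with TSS-weighted averaging.

Six probabilistic presence-background learners are fitted per scale:

====  =====================================================================
BRT   gradient-boosted trees
GAM   logistic regression on per-predictor spline bases
GLM   logistic regression with linear + quadratic terms
MXD   maxent-style penalised logistic on hinge + quadratic features
RDF   random forest
SVM   support vector machine with probability calibration
====  =====================================================================

Each algorithm is evaluated on repeated stratified 80/20 splits; its mean
True Skill Statistic r_j over the runs becomes its ensemble weight

    W_j = r_j / sum_j r_j        (members with r_j <= 0 are excluded),

and the final suitability surface is the cellwise weighted mean of the
per-algorithm predictions from models refit on all data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.calibration import CalibratedClassifierCV
from sklearn.compose import ColumnTransformer
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import (FunctionTransformer, OneHotEncoder,
                                   SplineTransformer, StandardScaler)
from sklearn.svm import SVC

from .evaluation import EvalReport, evaluate
from .grid import Raster
from .occurrence import TrainingTable, split_train_test

ALGORITHMS = ("BRT", "GAM", "GLM", "MXD", "RDF", "SVM")


def _derive_seed(*parts: int) -> int:
    """Deterministic 31-bit child seed from a tuple of integers."""
    return int(np.random.SeedSequence([int(p) for p in parts]).generate_state(1)[0]
               % (2**31))


class HingeFeatures(BaseEstimator, TransformerMixin):
    """Maxent-style feature expansion: per column, forward and reverse hinge
    features at quantile knots plus the linear and quadratic terms."""

    def __init__(self, n_knots: int = 5):
        self.n_knots = n_knots

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        qs = np.linspace(0.05, 0.95, self.n_knots)
        self.knots_ = np.quantile(X, qs, axis=0)  # (n_knots, n_cols)
        self.scale_ = np.ptp(X, axis=0)
        self.scale_[self.scale_ == 0] = 1.0
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        feats = [X / self.scale_, (X / self.scale_) ** 2]
        for k in range(self.knots_.shape[0]):
            knot = self.knots_[k]
            feats.append(np.clip(X - knot, 0.0, None) / self.scale_)
            feats.append(np.clip(knot - X, 0.0, None) / self.scale_)
        return np.hstack(feats)


def _quadratic_expansion(X):
    X = np.asarray(X, dtype=float)
    return np.hstack([X, X**2])


def _make_estimator(algorithm_id: str, continuous: list, categorical: list,
                    seed: int):
    """Build the sklearn pipeline for one member algorithm."""
    cat = ("cat", OneHotEncoder(handle_unknown="ignore"), categorical)

    def with_num(num_steps) -> ColumnTransformer:
        cols = [("num", Pipeline(num_steps), continuous)]
        if categorical:
            cols.append(cat)
        return ColumnTransformer(cols)

    if algorithm_id == "GLM":
        pre = with_num([
            ("quad", FunctionTransformer(_quadratic_expansion)),
            ("scale", StandardScaler()),
        ])
        clf = LogisticRegression(max_iter=2000)
    elif algorithm_id == "GAM":
        pre = with_num([
            ("spline", SplineTransformer(n_knots=5, degree=3)),
        ])
        clf = LogisticRegression(max_iter=2000)
    elif algorithm_id == "MXD":
        pre = with_num([("hinge", HingeFeatures(n_knots=5))])
        clf = LogisticRegression(max_iter=3000, C=1.0)
    elif algorithm_id == "RDF":
        pre = with_num([("id", FunctionTransformer())])
        clf = RandomForestClassifier(n_estimators=200, min_samples_leaf=2,
                                     random_state=seed)
    elif algorithm_id == "BRT":
        pre = with_num([("id", FunctionTransformer())])
        clf = GradientBoostingClassifier(n_estimators=150, learning_rate=0.05,
                                         max_depth=3, subsample=0.8,
                                         random_state=seed)
    elif algorithm_id == "SVM":
        pre = with_num([("scale", StandardScaler())])
        clf = CalibratedClassifierCV(SVC(C=2.0, gamma="scale",
                                         random_state=seed),
                                     ensemble=False, cv=3)
    else:
        raise ValueError(f"unknown algorithm_id {algorithm_id!r}; "
                         f"expected one of {ALGORITHMS}")
    return Pipeline([("features", pre), ("clf", clf)])


@dataclass
class MemberModel:
    """One fitted member algorithm."""

    algorithm_id: str
    pipeline: Pipeline
    predictor_names: list
    categorical: list = field(default_factory=list)
    run_id: int = 0
    tss_on_test: float = float("nan")

    def predict_frame(self, X: pd.DataFrame) -> np.ndarray:
        return self.pipeline.predict_proba(X[self.predictor_names])[:, 1]


def fit_member(algorithm_id: str, train: TrainingTable, seed: int = 0) -> MemberModel:
    """Fit one member algorithm on a training table."""
    y = train.y
    if len(np.unique(y)) < 2:
        raise ValueError("training data contains a single class")
    continuous = [p for p in train.predictor_names if p not in train.categorical]
    est = _make_estimator(algorithm_id, continuous, list(train.categorical), seed)
    est.fit(train.X, y)
    return MemberModel(
        algorithm_id=algorithm_id,
        pipeline=est,
        predictor_names=list(train.predictor_names),
        categorical=list(train.categorical),
        run_id=train.run_id,
    )


def ensemble_weights(tss_values) -> np.ndarray:
    """TSS-proportional weights W_j = r_j / sum r_j.

    Members with r_j <= 0 are excluded (weight 0) with a warning; if no
    member has positive TSS the ensemble is undefined and an error is
    raised.  Weights sum to 1 over the retained members.
    """
    r = np.asarray(tss_values, dtype=float)
    w = np.where(r > 0, r, 0.0)
    excluded = int((r <= 0).sum())
    if excluded == r.size:
        raise ValueError("all member TSS values are <= 0; ensemble undefined")
    if excluded:
        warnings.warn(f"{excluded} member(s) with TSS <= 0 excluded from ensemble")
    return w / w.sum()


@dataclass
class EnsembleModel:
    """TSS-weighted ensemble of member models (one per algorithm)."""

    members: list             # MemberModel, refit on all data
    weights: np.ndarray       # aligned with members; sums to 1
    member_tss: np.ndarray    # mean test TSS per member (the r_j)
    mtss_threshold: float = float("nan")

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.members) != self.weights.size:
            raise ValueError("weights length != number of members")
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("ensemble weights must sum to 1")

    @property
    def h(self) -> int:
        return len(self.members)

    def predict_frame(self, X: pd.DataFrame) -> np.ndarray:
        out = np.zeros(len(X))
        for w, m in zip(self.weights, self.members):
            if w > 0:
                out += w * m.predict_frame(X)
        return out


def stack_to_frame(stack: dict, predictor_names: list):
    """Flatten a raster stack into a frame over valid cells.

    Returns ``(frame, valid_mask)`` where frame rows correspond to True
    cells of the mask in row-major order.
    """
    any_raster = stack[predictor_names[0]]
    valid = np.ones(any_raster.grid.shape, dtype=bool)
    for name in predictor_names:
        valid &= stack[name].valid
    frame = pd.DataFrame(
        {name: stack[name].values[valid].astype(float) for name in predictor_names}
    )
    return frame, valid


def ensemble_predict(ensemble: EnsembleModel, stack: dict) -> Raster:
    """Predict the ensemble suitability surface over a raster stack."""
    names = ensemble.members[0].predictor_names
    missing = [n for n in names if n not in stack]
    if missing:
        raise KeyError(f"stack missing predictors: {missing}")
    frame, valid = stack_to_frame(stack, names)
    grid = stack[names[0]].grid
    values = np.zeros(grid.shape)
    values[valid] = np.clip(ensemble.predict_frame(frame), 0.0, 1.0)
    return Raster(grid, values, ~valid, "continuous")


def fit_ensemble(table: TrainingTable, algorithms=ALGORITHMS, n_runs: int = 10,
                 master_seed: int = 0, train_fraction: float = 0.8):
    """Repeated-split fitting + TSS-weighted ensemble assembly.

    For each of ``n_runs`` stratified 80/20 splits, every algorithm is
    fitted on the training part and scored on the held-out part (MTSS
    searched on training scores).  Each algorithm's TSS, averaged over
    runs, becomes its Eq-style weight; the final members are refit on all
    rows.  Returns ``(EnsembleModel, reports)`` where ``reports`` is a
    long-format frame (run, algorithm, metric columns) for Table-2-style
    summaries.
    """
    rows = []
    tss_by_alg: dict = {a: [] for a in algorithms}
    for run in range(n_runs):
        train, test = split_train_test(table, fraction=train_fraction,
                                       run_id=run, seed=master_seed)
        for k, alg in enumerate(algorithms):
            member = fit_member(alg, train, seed=_derive_seed(master_seed, run, k))
            tr_scores = member.predict_frame(train.X)
            te_scores = member.predict_frame(test.X)
            rep = evaluate(train.y, tr_scores, test.y, te_scores)
            member.tss_on_test = rep.tss
            tss_by_alg[alg].append(rep.tss)
            rows.append({"run": run, "algorithm": alg, **rep.as_dict()})
    reports = pd.DataFrame(rows)
    mean_tss = np.array([float(np.mean(tss_by_alg[a])) for a in algorithms])
    weights = ensemble_weights(mean_tss)
    full_run = TrainingTable(frame=table.frame,
                             predictor_names=list(table.predictor_names),
                             categorical=list(table.categorical), run_id=-1)
    members = [
        fit_member(alg, full_run, seed=_derive_seed(master_seed, 10_000, k))
        for k, alg in enumerate(algorithms)
    ]
    for m, t in zip(members, mean_tss):
        m.tss_on_test = float(t)
    ensemble = EnsembleModel(members=members, weights=weights, member_tss=mean_tss)
    return ensemble, reports


def summarize_reports(reports: pd.DataFrame) -> pd.DataFrame:
    """Per-algorithm means over runs (Table-2-shaped summary)."""
    cols = ["auc", "kappa", "tss", "jaccard", "sorensen", "fpb", "boyce"]
    return reports.groupby("algorithm")[cols].mean()


def save_ensemble(ensemble: EnsembleModel, directory) -> None:
    """Serialise an ensemble bundle: weights JSON + one state file per member."""
    import json
    from pathlib import Path

    import joblib

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = {
        "weights": ensemble.weights.tolist(),
        "member_tss": np.asarray(ensemble.member_tss, dtype=float).tolist(),
        "mtss_threshold": ensemble.mtss_threshold,
        "members": [
            {
                "algorithm_id": m.algorithm_id,
                "predictor_names": m.predictor_names,
                "categorical": m.categorical,
                "run_id": m.run_id,
                "tss_on_test": m.tss_on_test,
                "state_file": f"member_{m.algorithm_id}.joblib",
            }
            for m in ensemble.members
        ],
    }
    (directory / "ensemble.json").write_text(json.dumps(meta, indent=2))
    for m in ensemble.members:
        joblib.dump(m.pipeline, directory / f"member_{m.algorithm_id}.joblib")


def load_ensemble(directory) -> EnsembleModel:
    """Load an ensemble bundle written by :func:`save_ensemble`."""
    import json
    from pathlib import Path

    import joblib

    directory = Path(directory)
    meta = json.loads((directory / "ensemble.json").read_text())
    members = [
        MemberModel(
            algorithm_id=spec["algorithm_id"],
            pipeline=joblib.load(directory / spec["state_file"]),
            predictor_names=spec["predictor_names"],
            categorical=spec["categorical"],
            run_id=spec["run_id"],
            tss_on_test=spec["tss_on_test"],
        )
        for spec in meta["members"]
    ]
    return EnsembleModel(
        members=members,
        weights=np.asarray(meta["weights"]),
        member_tss=np.asarray(meta["member_tss"]),
        mtss_threshold=meta["mtss_threshold"],
    )
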