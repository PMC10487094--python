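"""Presence-background model evaluation.

Seven metrics are computed per model: AUC (rank-based), Kappa, TSS, Jaccard,
Sorensen and Fpb at the MTSS threshold, and the continuous Boyce index.
MTSS is the threshold maximising sensitivity + specificity over the observed
scores ("maximum training sensitivity plus specificity"); by default it is
searched on training scores and applied to test scores.

Also here: permutation variable importance (mean AUC drop, normalised to sum
to one per algorithm) and evaluation-strip response curves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr
from sklearn.metrics import roc_auc_score


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def n_presence(self) -> int:
        return self.TP + self.FN

    @property
    def n_background(self) -> int:
        return self.TN + self.FP

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass
class EvalReport:
    """The seven evaluation metrics plus the MTSS binarisation threshold."""

    auc: float
    kappa: float
    tss: float
    jaccard: float
    sorensen: float
    fpb: float
    boyce: float
    mtss_threshold: float

    def as_dict(self) -> dict:
        return {
            "auc": self.auc, "kappa": self.kappa, "tss": self.tss,
            "jaccard": self.jaccard, "sorensen": self.sorensen,
            "fpb": self.fpb, "boyce": self.boyce,
            "mtss_threshold": self.mtss_threshold,
        }


def confusion(obs: np.ndarray, scores: np.ndarray, threshold: float) -> ConfusionCounts:
    """Confusion counts with prediction = 1 iff score >= threshold."""
    obs = np.asarray(obs).astype(int)
    pred = np.asarray(scores, dtype=float) >= threshold
    return ConfusionCounts(
        TP=int(((obs == 1) & pred).sum()),
        FP=int(((obs == 0) & pred).sum()),
        FN=int(((obs == 1) & ~pred).sum()),
        TN=int(((obs == 0) & ~pred).sum()),
    )


def _safe_div(a: float, b: float) -> float:
    return a / b if b > 0 else float("nan")


def threshold_metrics(c: ConfusionCounts) -> dict:
    """Kappa, TSS, Jaccard, Sorensen, Fpb from confusion counts.

    Fpb is the F-measure on presence-background counts, identical in form to
    Sorensen with background standing in for true absences.  Metrics with an
    empty margin are undefined (NaN), never reported as 0.
    """
    sens = _safe_div(c.TP, c.TP + c.FN)
    spec = _safe_div(c.TN, c.TN + c.FP)
    tss = sens + spec - 1.0
    jaccard = _safe_div(c.TP, c.TP + c.FP + c.FN)
    sorensen = _safe_div(2 * c.TP, 2 * c.TP + c.FP + c.FN)
    fpb = sorensen
    n = c.total
    if n == 0 or c.n_presence == 0 or c.n_background == 0:
        kappa = float("nan")
    else:
        po = (c.TP + c.TN) / n
        pe = ((c.TP + c.FP) * (c.TP + c.FN) + (c.FN + c.TN) * (c.FP + c.TN)) / n**2
        kappa = _safe_div(po - pe, 1.0 - pe) if pe < 1.0 else float("nan")
    return {"kappa": kappa, "tss": tss, "jaccard": jaccard,
            "sorensen": sorensen, "fpb": fpb}


def auc(obs: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUC: probability a random presence outscores a random
    background point, ties counted one half."""
    obs = np.asarray(obs).astype(int)
    if len(np.unique(obs)) < 2:
        return float("nan")
    return float(roc_auc_score(obs, np.asarray(scores, dtype=float)))


def boyce(presence_scores: np.ndarray, background_scores: np.ndarray,
          n_windows: int = 101, window_width_fraction: float = 0.1) -> float:
    """Continuous Boyce index.

    Overlapping windows span the pooled score range; per window the
    predicted-to-expected ratio P/E = (presence fraction)/(background
    fraction) is computed, windows with zero expected fraction are dropped,
    and the index is the Spearman rank correlation between P/E and the
    window midpoint.  Undefined (NaN) with fewer than 3 valid windows.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    lo = min(p.min(), b.min())
    hi = max(p.max(), b.max())
    if hi == lo:
        return float("nan")
    width = window_width_fraction * (hi - lo)
    starts = np.linspace(lo, hi - width, n_windows)
    mids, ratios = [], []
    for s in starts:
        e = ((b >= s) & (b <= s + width)).mean()
        if e == 0:
            continue
        f = ((p >= s) & (p <= s + width)).mean()
        mids.append(s + width / 2.0)
        ratios.append(f / e)
    if len(mids) < 3 or np.ptp(ratios) == 0:
        return float("nan")  # undefined: too few windows or constant P/E
    rho = spearmanr(ratios, mids).statistic
    return float(rho)


def mtss_threshold(obs: np.ndarray, scores: np.ndarray) -> float:
    """Threshold maximising sensitivity + specificity.

    Candidates are the unique observed scores; ties are broken by the
    smallest threshold.  A degenerate all-equal score vector returns that
    score with a warning.
    """
    obs = np.asarray(obs).astype(int)
    scores = np.asarray(scores, dtype=float)
    cand = np.unique(scores)
    if cand.size == 1:
        warnings.warn("all scores identical; MTSS threshold is degenerate")
        return float(cand[0])
    n_pres = (obs == 1).sum()
    n_back = (obs == 0).sum()
    best_t, best_v = None, -np.inf
    for t in cand:  # ascending, so strict improvement keeps the smallest tie
        pred = scores >= t
        sens = _safe_div(((obs == 1) & pred).sum(), n_pres)
        spec = _safe_div(((obs == 0) & ~pred).sum(), n_back)
        v = sens + spec
        if v > best_v + 1e-12:
            best_v, best_t = v, float(t)
    return best_t


def evaluate(train_obs, train_scores, test_obs, test_scores,
             threshold_on: str = "train") -> EvalReport:
    """Full seven-metric report: MTSS searched on training scores (default),
    threshold metrics / AUC / Boyce computed on test scores."""
    if threshold_on == "train":
        thr = mtss_threshold(train_obs, train_scores)
    elif threshold_on == "test":
        thr = mtss_threshold(test_obs, test_scores)
    else:
        raise ValueError("threshold_on must be 'train' or 'test'")
    test_obs = np.asarray(test_obs).astype(int)
    test_scores = np.asarray(test_scores, dtype=float)
    tm = threshold_metrics(confusion(test_obs, test_scores, thr))
    return EvalReport(
        auc=auc(test_obs, test_scores),
        boyce=boyce(test_scores[test_obs == 1], test_scores[test_obs == 0]),
        mtss_threshold=thr,
        **tm,
    )


# ---------------------------------------------------------------------------
# Variable importance and response curves
# ---------------------------------------------------------------------------

@dataclass
class ImportanceTable:
    """Permutation importance per (variable, algorithm), plus the cross-
    algorithm mean.  Per-algorithm columns sum to 1 (up to rounding)."""

    table: pd.DataFrame  # index = variable, columns = algorithm ids

    @property
    def mean(self) -> pd.Series:
        return self.table.mean(axis=1)


def permutation_importance(model, table, n_reps: int = 5, seed: int = 0) -> pd.Series:
    """Mean AUC drop when each predictor column is permuted; negatives are
    clipped to 0 and the result normalised to sum to 1."""
    rng = np.random.default_rng(seed)
    X = table.X.copy()
    y = table.y
    base = auc(y, model.predict_frame(X))
    drops = {}
    for var in table.predictor_names:
        d = []
        for _ in range(n_reps):
            Xp = X.copy()
            Xp[var] = rng.permutation(Xp[var].to_numpy())
            d.append(base - auc(y, model.predict_frame(Xp)))
        drops[var] = max(0.0, float(np.mean(d)))
    s = pd.Series(drops)
    total = s.sum()
    return s / total if total > 0 else s


def variable_importance(members: dict, table, n_reps: int = 5,
                        seed: int = 0) -> ImportanceTable:
    """Permutation importance for each member algorithm on one table."""
    cols = {}
    for k, (alg, model) in enumerate(members.items()):
        cols[alg] = permutation_importance(model, table, n_reps=n_reps,
                                           seed=seed + k)
    return ImportanceTable(table=pd.DataFrame(cols))


def response_curve(model, variable: str, reference: pd.DataFrame,
                   n_steps: int = 51, threshold: float | None = None) -> dict:
    """Evaluation-strip marginal response.

    The target variable sweeps fixed quantile steps of its observed values
    while every other predictor is held at its median.  Returns the curve,
    its argmax, and (optionally) the interval where it exceeds ``threshold``.
    """
    if variable not in reference.columns:
        raise KeyError(f"variable {variable!r} not in reference data")
    qs = np.linspace(0.0, 1.0, n_steps)
    values = np.quantile(reference[variable].to_numpy(dtype=float), qs)
    strip = pd.DataFrame(
        {c: np.full(n_steps, reference[c].median()) for c in reference.columns}
    )
    strip[variable] = values
    suit = np.asarray(model.predict_frame(strip), dtype=float)
    out = {
        "values": values,
        "suitability": suit,
        "argmax": float(values[int(np.argmax(suit))]),
    }
    if threshold is not None:
        above = values[suit >= threshold]
        out["above_threshold_interval"] = (
            (float(above.min()), float(above.max())) if above.size else None
        )
    return out
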