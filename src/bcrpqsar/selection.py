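"""Staged feature reduction: variance filter, correlation filter,
train-set z-normalization, shadow-feature (Boruta-style) selection,
recursive feature elimination, and knee-point detection.

Every fitted statistic (variance, correlation, normalization means/sds,
importances) is computed on training rows only; the cascade never sees
test rows, which is what makes the repeated-split evaluation honest.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import binomtest
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .fingerprints import FeatureTable
from .records import ValidationError

logger = logging.getLogger("bcrpqsar")

__all__ = [
    "SelectionTrace",
    "RfeCurve",
    "variance_filter",
    "correlation_filter",
    "ZScaler",
    "shadow_feature_select",
    "rfe_curve",
    "find_knee",
]

#: estimator settings used for importance-driven stages (RFE per the
#: modelling protocol: depth-6 forest with 200 trees; Boruta mirrors it)
DEFAULT_RF_PARAMS = {"max_depth": 6, "n_estimators": 200}


@dataclass
class SelectionTrace:
    stage: str
    kept: List[str]
    dropped: Dict[str, str]            # feature -> reason
    params: Dict = field(default_factory=dict)

    def __post_init__(self):
        overlap = set(self.kept) & set(self.dropped)
        if overlap:
            raise ValidationError(
                f"kept/dropped overlap: {sorted(overlap)[:5]}")


def variance_filter(table: FeatureTable, threshold: float = 0.01
                    ) -> Tuple[FeatureTable, SelectionTrace]:
    """Drop columns with population variance below ``threshold``.

    For a binary bit with prevalence p the population variance is
    p(1-p), so the default 0.01 removes bits present in fewer than
    about 1% (or more than about 99%) of compounds.
    """
    if table.n < 2:
        raise ValidationError("variance filter needs n >= 2")
    var = table.matrix.var(axis=0)  # population variance (ddof=0)
    kept = [f for f, v in zip(table.feature_names, var) if v >= threshold]
    dropped = {f: f"variance {v:.6g} < {threshold}"
               for f, v in zip(table.feature_names, var) if v < threshold}
    if not kept:
        logger.warning("variance filter dropped every column")
    trace = SelectionTrace("variance", kept, dropped,
                           {"threshold": threshold})
    out = table.select(kept) if kept else FeatureTable(
        compound_ids=list(table.compound_ids), feature_names=[],
        matrix=np.zeros((table.n, 0)), provenance=[])
    return out, trace


def correlation_filter(table: FeatureTable, threshold: float = 0.8
                       ) -> Tuple[FeatureTable, SelectionTrace]:
    """Greedy de-correlation pass.

    Columns are visited in order of descending variance (the
    higher-variance member of a correlated pair is kept — deterministic
    given column order); a column is dropped iff its absolute Pearson
    correlation with an already-kept column exceeds ``threshold``.
    """
    X = table.matrix
    var = X.var(axis=0)
    if np.any(var == 0):
        raise ValidationError(
            "correlation filter requires non-constant columns "
            "(run variance_filter first)")
    order = np.argsort(-var, kind="stable")
    Xc = (X - X.mean(axis=0)) / np.sqrt(var)  # standardized columns
    n = table.n
    kept_idx: List[int] = []
    dropped: Dict[str, str] = {}
    kept_block: Optional[np.ndarray] = None
    for j in order:
        if kept_idx:
            r = np.abs(kept_block.T @ Xc[:, j]) / n
            worst = int(np.argmax(r))
            if r[worst] > threshold:
                partner = table.feature_names[kept_idx[worst]]
                dropped[table.feature_names[j]] = (
                    f"|r|={r[worst]:.4f} > {threshold} with {partner}")
                continue
        kept_idx.append(int(j))
        kept_block = Xc[:, kept_idx]
    kept_idx.sort()  # preserve original column order in the output
    kept = [table.feature_names[j] for j in kept_idx]
    trace = SelectionTrace("correlation", kept, dropped,
                           {"threshold": threshold})
    return table.select(kept), trace


class ZScaler:
    """Column-wise z-normalization fit on the training table only.

    Binary fingerprint columns bypass normalization unless
    ``normalize_binary`` is set; external descriptor columns are always
    normalized.  Transformed tables are tagged so that a second
    application (which would not be idempotent) raises.
    """

    def __init__(self, normalize_binary: bool = False):
        self.normalize_binary = normalize_binary
        self.mean_: Optional[np.ndarray] = None
        self.sd_: Optional[np.ndarray] = None
        self.cols_: Optional[List[str]] = None
        self.scaled_mask_: Optional[np.ndarray] = None

    def fit(self, train: FeatureTable) -> "ZScaler":
        if train.n == 0:
            raise ValidationError("cannot fit scaler on an empty table")
        mask = np.array([
            self.normalize_binary or pv == "external_descriptor"
            for pv in train.provenance])
        X = train.matrix
        mean = X.mean(axis=0)
        sd = X.std(axis=0)  # population sd
        if np.any(sd[mask] == 0):
            bad = [f for f, m, s in zip(train.feature_names, mask, sd)
                   if m and s == 0]
            raise ValidationError(
                f"zero-sd columns (variance-filter these first): {bad[:5]}")
        self.mean_, self.sd_ = mean, sd
        self.cols_ = list(train.feature_names)
        self.scaled_mask_ = mask
        return self

    def transform(self, table: FeatureTable) -> FeatureTable:
        if self.mean_ is None:
            raise ValidationError("scaler not fitted")
        if getattr(table, "_zscored", False):
            raise ValidationError("table already normalized "
                                  "(z-scoring is not idempotent)")
        if list(table.feature_names) != self.cols_:
            raise ValidationError("feature names differ from the fit table")
        X = table.matrix.copy()
        m = self.scaled_mask_
        X[:, m] = (X[:, m] - self.mean_[m]) / self.sd_[m]
        prov = ["external_descriptor" if (mm and pv == "fingerprint") else pv
                for mm, pv in zip(m, table.provenance)]
        out = FeatureTable(compound_ids=list(table.compound_ids),
                           feature_names=list(table.feature_names),
                           matrix=X, provenance=prov)
        out._zscored = True
        return out

    def fit_transform(self, train: FeatureTable) -> FeatureTable:
        return self.fit(train).transform(train)


def _rf_importances(X: np.ndarray, y: np.ndarray, params: Dict,
                    seed: int) -> np.ndarray:
    rf = RandomForestRegressor(random_state=seed, n_jobs=1, **params)
    rf.fit(X, y)
    return rf.feature_importances_


def shadow_feature_select(table: FeatureTable,
                          target: Sequence[float],
                          percentile: float = 80.0,
                          max_iter: int = 100,
                          seed: int = 0,
                          alpha: float = 0.05,
                          rf_params: Optional[Dict] = None,
                          keep_tentative: bool = False
                          ) -> SelectionTrace:
    """Boruta-style all-relevant selection against shuffled shadows.

    Each round appends a shuffled copy of every candidate feature, fits
    a random forest on the augmented matrix, and scores a candidate a
    "hit" when its importance exceeds the given percentile of the
    shadow importances.  Hit counts are tested against the binomial
    null (two-sided at ``alpha``): significantly many hits confirms a
    feature, significantly few rejects it (rejected features leave the
    candidate pool), the rest stay tentative until ``max_iter``.
    """
    y = np.asarray(target, dtype=float)
    if table.n <= 10:
        raise ValidationError("shadow selection needs n > 10")
    if np.all(y == y[0]):
        raise ValidationError("degenerate (constant) target")
    rf_params = dict(DEFAULT_RF_PARAMS if rf_params is None else rf_params)
    rng = np.random.default_rng(seed)
    names = list(table.feature_names)
    active = list(range(table.p))
    hits = np.zeros(table.p, dtype=int)
    trials = np.zeros(table.p, dtype=int)
    confirmed: set = set()
    rejected: Dict[int, str] = {}
    for it in range(max_iter):
        undecided = [j for j in active if j not in confirmed]
        if not undecided:
            break
        X = table.matrix[:, active]
        shadows = X.copy()
        for c in range(shadows.shape[1]):
            rng.shuffle(shadows[:, c])
        imp = _rf_importances(np.hstack([X, shadows]), y, rf_params,
                              seed=int(rng.integers(2 ** 31)))
        real_imp = imp[:X.shape[1]]
        thr = np.percentile(imp[X.shape[1]:], percentile)
        for pos, j in enumerate(active):
            trials[j] += 1
            if real_imp[pos] > thr:
                hits[j] += 1
        # binomial decisions on the undecided, Bonferroni-corrected
        alpha_eff = alpha / max(len(undecided), 1)
        for j in list(undecided):
            t = trials[j]
            if t < 5:          # too few rounds for any verdict
                continue
            res = binomtest(int(hits[j]), t, 0.5)
            if res.pvalue < alpha_eff:
                if hits[j] > t / 2:
                    confirmed.add(j)
                else:
                    rejected[j] = (f"hits {hits[j]}/{t}, p={res.pvalue:.3g}")
                    active.remove(j)
    tentative = [j for j in active if j not in confirmed]
    kept_idx = sorted(confirmed | (set(tentative) if keep_tentative
                                   else set()))
    dropped = {names[j]: reason for j, reason in rejected.items()}
    for j in tentative:
        if not keep_tentative:
            dropped[names[j]] = f"tentative after {max_iter} iterations"
    trace = SelectionTrace(
        "shadow", [names[j] for j in kept_idx], dropped,
        {"percentile": percentile, "max_iter": max_iter, "alpha": alpha,
         "seed": seed, "n_confirmed": len(confirmed),
         "n_tentative": len(tentative), "rf_params": rf_params})
    return trace


@dataclass
class RfeCurve:
    points: List[Dict]           # {k, r2, rmse, features}
    selected_k: int = -1
    no_knee: bool = False

    def ks(self) -> List[int]:
        return [p["k"] for p in self.points]


def _cv_scores(X: np.ndarray, y: np.ndarray, params: Dict, seed: int,
               n_folds: int) -> Tuple[float, float]:
    if X.shape[0] < n_folds:
        raise ValidationError(
            f"n={X.shape[0]} too small for {n_folds}-fold CV")
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pred = np.empty_like(y)
    for tr, te in kf.split(X):
        rf = RandomForestRegressor(random_state=seed, n_jobs=1, **params)
        rf.fit(X[tr], y[tr])
        pred[te] = rf.predict(X[te])
    ssres = float(np.sum((y - pred) ** 2))
    sstot = float(np.sum((y - y.mean()) ** 2))
    return 1.0 - ssres / sstot, float(np.sqrt(np.mean((y - pred) ** 2)))


def rfe_curve(table: FeatureTable, target: Sequence[float],
              grid: Optional[Sequence[int]] = None,
              estimator_params: Optional[Dict] = None,
              seed: int = 0, cv_folds: int = 5) -> RfeCurve:
    """Recursive feature elimination curve.

    The default grid runs from 700 down to 20 in steps of 10.  At each
    grid size the least-important features (depth-6 forest with 200
    trees) are discarded and the cross-validated R²/RMSE at that size
    recorded.  The grid is clipped to the table width when p < 700
    (clipping logged).
    """
    y = np.asarray(target, dtype=float)
    params = dict(DEFAULT_RF_PARAMS if estimator_params is None
                  else estimator_params)
    if grid is None:
        grid = list(range(700, 19, -10))
    grid = sorted(set(int(k) for k in grid), reverse=True)
    if grid[0] > table.p:
        logger.info("rfe grid clipped from %d to p=%d", grid[0], table.p)
        grid = [k for k in grid if k <= table.p]
        if not grid or grid[0] < table.p:
            grid = [table.p] + grid
    names = list(table.feature_names)
    current = list(range(table.p))
    points = []
    for k in grid:
        if len(current) > k:
            imp = _rf_importances(table.matrix[:, current], y, params,
                                  seed=seed)
            order = np.argsort(-imp, kind="stable")[:k]
            current = sorted(current[j] for j in order)
        r2, rm = _cv_scores(table.matrix[:, current], y, params,
                            seed=seed, n_folds=cv_folds)
        points.append({"k": k, "r2": r2, "rmse": rm,
                       "features": [names[j] for j in current]})
    return RfeCurve(points=points)


def find_knee(curve: RfeCurve) -> int:
    """Knee of the RMSE-vs-k curve.

    The knee is the grid point with maximum perpendicular distance to
    the chord joining the curve's endpoints after normalizing both axes
    to [0, 1].  Ties break toward larger k (more conservative feature
    retention); a flat or strictly linear curve has no knee, in which
    case the smallest k is returned and the curve flagged.
    """
    if len(curve.points) < 3:
        raise ValidationError("knee detection needs >= 3 points")
    ks = np.array([p["k"] for p in curve.points], dtype=float)
    rm = np.array([p["rmse"] for p in curve.points], dtype=float)
    span_k = ks.max() - ks.min()
    span_r = rm.max() - rm.min()
    if span_k == 0:
        raise ValidationError("degenerate grid")
    x = (ks - ks.min()) / span_k
    yv = (rm - rm.min()) / span_r if span_r > 0 else np.zeros_like(rm)
    x0, y0, x1, y1 = x[0], yv[0], x[-1], yv[-1]
    norm = np.hypot(x1 - x0, y1 - y0)
    dist = np.abs((y1 - y0) * x - (x1 - x0) * yv + x1 * y0 - y1 * x0) / norm
    best = float(dist.max())
    if best < 1e-8:
        logger.info("find_knee: no knee (flat/linear curve); "
                    "returning smallest k")
        curve.no_knee = True
        curve.selected_k = int(ks.min())
        return curve.selected_k
    # ties toward larger k: points are ordered by descending k, so take
    # the first index attaining the maximum within tolerance
    idx = int(np.flatnonzero(dist >= best - 1e-12)[0])
    curve.no_knee = False
    curve.selected_k = int(ks[idx])
    return curve.selected_k
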