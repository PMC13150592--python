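"""Repeated-split training, seeded hyperparameter search over a
pluggable regressor registry, and finalization on the full dataset.

The registry maps algorithm keys (RF, LGBM, Ridge, Lasso, kNN, SVM,
ANN) to estimator factories plus a small default search space.  The
tuner is a seeded random sampler scored by inner 5-fold CV RMSE on the
training partition only — test rows never enter tuning or fitting.
"""
from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import joblib
import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import Lasso, Ridge
from sklearn.model_selection import KFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from .fingerprints import FeatureTable
from .records import ValidationError

logger = logging.getLogger("bcrpqsar")

__all__ = [
    "SplitPlan",
    "TrainedModel",
    "REGISTRY",
    "make_splits",
    "nested_cv_tune",
    "fit",
    "predict",
    "finalize",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class SplitPlan:
    split_id: int
    seed: int
    train_idx: Tuple[int, ...]
    test_idx: Tuple[int, ...]

    def __post_init__(self):
        tr, te = set(self.train_idx), set(self.test_idx)
        if tr & te:
            raise ValidationError("train/test indices overlap")


def make_splits(n: int, ratio: float = 0.9, repeats: int = 10,
                base_seed: int = 0) -> List[SplitPlan]:
    """``repeats`` independent uniform train/test splits at the given
    ratio; per-split seeds are base_seed + split_id, so plans are
    deterministic given the base seed."""
    if n < 10:
        raise ValidationError(f"n={n} too small to split")
    if not (0.0 < ratio < 1.0):
        raise ValidationError("ratio must be in (0, 1)")
    n_train = int(np.floor(ratio * n))
    plans = []
    for sid in range(repeats):
        seed = base_seed + sid
        perm = np.random.default_rng(seed).permutation(n)
        plans.append(SplitPlan(
            split_id=sid, seed=seed,
            train_idx=tuple(int(i) for i in np.sort(perm[:n_train])),
            test_idx=tuple(int(i) for i in np.sort(perm[n_train:]))))
    return plans


# ---------------------------------------------------------------- registry

def _make_lgbm(params: Dict, seed: int):
    from lightgbm import LGBMRegressor
    return LGBMRegressor(random_state=seed, n_jobs=1, verbose=-1, **params)


@dataclass(frozen=True)
class _Algo:
    factory: Callable[[Dict, int], object]
    space: Dict[str, object]       # name -> list of choices or
    #                                ("loguniform"|"uniform"|"int", lo, hi)
    deterministic: bool = True


REGISTRY: Dict[str, _Algo] = {
    "RF": _Algo(
        lambda p, s: RandomForestRegressor(random_state=s, n_jobs=1, **p),
        {"n_estimators": [100, 200, 400],
         "max_depth": [4, 6, 8, None],
         "min_samples_leaf": [1, 2, 4],
         "max_features": ["sqrt", 0.3, 0.5]}),
    "LGBM": _Algo(
        _make_lgbm,
        {"n_estimators": [100, 200, 400],
         "num_leaves": [15, 31, 63],
         "learning_rate": ("loguniform", 0.01, 0.2),
         "min_child_samples": [5, 10, 20]}),
    "Ridge": _Algo(
        lambda p, s: Ridge(**p),
        {"alpha": ("loguniform", 1e-3, 1e3)}),
    "Lasso": _Algo(
        lambda p, s: Lasso(max_iter=20000, **p),
        {"alpha": ("loguniform", 1e-4, 1e1)}),
    "kNN": _Algo(
        lambda p, s: KNeighborsRegressor(**p),
        {"n_neighbors": [3, 5, 7, 9, 11, 15],
         "weights": ["uniform", "distance"]}),
    "SVM": _Algo(
        lambda p, s: SVR(**p),
        {"C": ("loguniform", 0.1, 100.0),
         "gamma": ["scale", "auto"],
         "epsilon": ("loguniform", 0.01, 0.3)}),
    "ANN": _Algo(
        lambda p, s: MLPRegressor(random_state=s, max_iter=800, **p),
        {"hidden_layer_sizes": [(32,), (64,), (64, 32)],
         "alpha": ("loguniform", 1e-5, 1e-1)},
        deterministic=False),
}


def _sample_params(space: Dict, rng: np.random.Generator) -> Dict:
    out = {}
    for name, spec in space.items():
        if isinstance(spec, list):
            out[name] = spec[int(rng.integers(len(spec)))]
        else:
            kind, lo, hi = spec
            if kind == "loguniform":
                out[name] = float(np.exp(rng.uniform(np.log(lo),
                                                     np.log(hi))))
            elif kind == "uniform":
                out[name] = float(rng.uniform(lo, hi))
            elif kind == "int":
                out[name] = int(rng.integers(lo, hi + 1))
            else:
                raise ValidationError(f"unknown space kind {kind!r}")
    return out


@dataclass
class TrainedModel:
    algorithm: str
    hyperparams: Dict
    estimator: object
    feature_names: List[str]
    training_fingerprint: str      # hash of the training matrix + target
    seed: int = 0
    meta: Dict = field(default_factory=dict)


def _data_hash(X: np.ndarray, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(X).tobytes())
    h.update(np.ascontiguousarray(y).tobytes())
    return h.hexdigest()[:16]


def nested_cv_tune(train: FeatureTable, target: Sequence[float],
                   algorithm: str, search_budget: int = 20,
                   inner_folds: int = 5, seed: int = 0
                   ) -> Tuple[Dict, float, List[Dict]]:
    """Seeded random search scored by inner k-fold CV RMSE.

    Returns (best hyperparams, best inner-CV RMSE, trial history).  The
    running best RMSE is non-increasing in the budget for a fixed seed,
    and only training rows are ever touched.
    """
    if algorithm not in REGISTRY:
        raise ValidationError(f"unknown algorithm {algorithm!r}; "
                              f"registered: {sorted(REGISTRY)}")
    if search_budget < 1:
        raise ValidationError("search_budget must be >= 1")
    y = np.asarray(target, dtype=float)
    X = train.matrix
    algo = REGISTRY[algorithm]
    rng = np.random.default_rng(seed)
    kf = KFold(n_splits=inner_folds, shuffle=True, random_state=seed)
    folds = list(kf.split(X))
    history = []
    best_params, best_rmse = None, np.inf
    for t in range(search_budget):
        params = _sample_params(algo.space, rng)
        sq = 0.0
        for tr, va in folds:
            est = algo.factory(params, seed)
            est.fit(X[tr], y[tr])
            resid = y[va] - est.predict(X[va])
            sq += float(np.sum(resid ** 2))
        rm = float(np.sqrt(sq / X.shape[0]))
        history.append({"trial": t, "params": params, "cv_rmse": rm})
        if rm < best_rmse:
            best_params, best_rmse = params, rm
    return best_params, best_rmse, history


def fit(algorithm: str, hyperparams: Dict, train: FeatureTable,
        target: Sequence[float], seed: int = 0) -> TrainedModel:
    if algorithm not in REGISTRY:
        raise ValidationError(f"unknown algorithm {algorithm!r}")
    y = np.asarray(target, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValidationError("target contains non-finite values")
    if not np.all(np.isfinite(train.matrix)):
        raise ValidationError("feature matrix contains non-finite values")
    est = REGISTRY[algorithm].factory(dict(hyperparams), seed)
    est.fit(train.matrix, y)
    return TrainedModel(
        algorithm=algorithm, hyperparams=dict(hyperparams), estimator=est,
        feature_names=list(train.feature_names),
        training_fingerprint=_data_hash(train.matrix, y), seed=seed)


def predict(model: TrainedModel, table: FeatureTable) -> np.ndarray:
    """Predict pIC50 for each row; columns are aligned by feature name,
    so column order in ``table`` is irrelevant."""
    if table.n == 0:
        return np.zeros(0)
    missing = set(model.feature_names) - set(table.feature_names)
    if missing:
        raise ValidationError(
            f"feature columns missing from input: {sorted(missing)[:5]}")
    aligned = table.select(model.feature_names)
    out = np.asarray(model.estimator.predict(aligned.matrix), dtype=float)
    if not np.all(np.isfinite(out)):
        raise ValidationError("model produced non-finite predictions")
    return out


def finalize(full_table: FeatureTable, target: Sequence[float],
             algorithm: str,
             split_results: Sequence[Dict],
             seed: int = 0) -> TrainedModel:
    """Refit on all rows with the hyperparameters of the best split.

    ``split_results`` holds per-split dicts with keys ``split_id``,
    ``hyperparams`` and ``test_r2``; the winner is the argmax of test
    R², and its identity is recorded in the model's provenance.
    """
    if not split_results:
        raise ValidationError("finalize: empty candidate list")
    winner = max(split_results, key=lambda d: d["test_r2"])
    model = fit(algorithm, winner["hyperparams"], full_table, target,
                seed=seed)
    model.meta["finalized_from_split"] = winner["split_id"]
    model.meta["winning_test_r2"] = winner["test_r2"]
    return model


def save_model(model: TrainedModel, path) -> None:
    joblib.dump({
        "algorithm": model.algorithm, "hyperparams": model.hyperparams,
        "estimator": model.estimator, "feature_names": model.feature_names,
        "training_fingerprint": model.training_fingerprint,
        "seed": model.seed, "meta": model.meta}, path)


def load_model(path) -> TrainedModel:
    d = joblib.load(path)
    return TrainedModel(**d)
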