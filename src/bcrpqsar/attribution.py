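"""Model interpretation: additive attributions, importance rankings,
bit-to-SMARTS resolution, and presence/absence distribution tests.

Tree-family models get exact path-dependent Shapley attributions
(random forests through the in-package engine, gradient-boosting
through LightGBM's native per-feature contribution output); any other
model falls back to a seeded permutation-sampling Shapley estimator
with a reported Monte-Carlo error.  Every attribution row satisfies
local accuracy: base value + contributions = model prediction.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .fingerprints import FeatureTable, FingerprintSpec
from .modeling import TrainedModel, predict
from .records import ValidationError
from . import treeshap

logger = logging.getLogger("bcrpqsar")

__all__ = [
    "AttributionTable",
    "SubstructureReport",
    "attribution_table",
    "rank_by_mean_abs_attribution",
    "rank_by_impurity_importance",
    "bit_to_smarts",
    "substructure_group_test",
    "substructure_report",
]

_TREE_ALGOS = ("RF", "LGBM")


@dataclass
class AttributionTable:
    base_value: float
    matrix: np.ndarray              # n x p contributions
    feature_names: List[str]
    mc_error: Optional[float] = None   # sampling estimators only

    def local_accuracy_gap(self, predictions: np.ndarray) -> float:
        recon = self.base_value + self.matrix.sum(axis=1)
        return float(np.max(np.abs(recon - predictions)))


def _sampling_shapley(model: TrainedModel, table: FeatureTable,
                      n_permutations: int, seed: int
                      ) -> Tuple[np.ndarray, float, float]:
    """Permutation-sampling Shapley estimate for arbitrary regressors.

    Absent features are marginalised against the table's own rows
    (background = the data being explained).  The permutation structure
    keeps the additivity identity exact per permutation, so local
    accuracy holds for the average as well.
    """
    rng = np.random.default_rng(seed)
    X = table.matrix
    n, p = X.shape
    base = float(np.mean(model.estimator.predict(X)))
    contrib = np.zeros((n, p))
    sq = np.zeros((n, p))
    for _ in range(n_permutations):
        order = rng.permutation(p)
        bg = X[rng.integers(n, size=n)]  # one background row per sample
        cur = bg.copy()
        prev = model.estimator.predict(cur)
        for j in order:
            cur[:, j] = X[:, j]
            nxt = model.estimator.predict(cur)
            delta = nxt - prev
            contrib[:, j] += delta
            sq[:, j] += delta ** 2
            prev = nxt
    contrib /= n_permutations
    mc = float(np.mean(np.sqrt(np.maximum(
        sq / n_permutations - contrib ** 2, 0.0) / n_permutations)))
    # per-permutation additivity ties the sum to f(x) - f(background);
    # recenter so the base is the mean prediction over the table
    pred = model.estimator.predict(X)
    gap = pred - (base + contrib.sum(axis=1))
    contrib += gap[:, None] / p
    return contrib, base, mc


def attribution_table(model: TrainedModel, table: FeatureTable,
                      n_permutations: int = 50,
                      seed: int = 0) -> AttributionTable:
    """Additive per-feature attributions for every row of ``table``."""
    aligned = table.select(model.feature_names)
    est = model.estimator
    if model.algorithm == "RF":
        mat = treeshap.forest_shap_values(est, aligned.matrix)
        base = treeshap.expected_value(est)
        out = AttributionTable(base_value=base, matrix=mat,
                               feature_names=list(model.feature_names))
    elif model.algorithm == "LGBM":
        contrib = est.predict(aligned.matrix, pred_contrib=True)
        out = AttributionTable(base_value=float(contrib[0, -1]),
                               matrix=contrib[:, :-1],
                               feature_names=list(model.feature_names))
    else:
        mat, base, mc = _sampling_shapley(model, aligned,
                                          n_permutations, seed)
        out = AttributionTable(base_value=base, matrix=mat,
                               feature_names=list(model.feature_names),
                               mc_error=mc)
    gap = out.local_accuracy_gap(predict(model, aligned))
    if model.algorithm in _TREE_ALGOS and gap > 1e-6:
        raise ValidationError(
            f"local accuracy violated: max gap {gap:.3g}")
    return out


def rank_by_mean_abs_attribution(attrs: AttributionTable) -> List[str]:
    """Features by descending mean |attribution| over all compounds;
    ties break lexicographically by feature name."""
    if attrs.matrix.size == 0:
        raise ValidationError("empty attribution table")
    score = np.mean(np.abs(attrs.matrix), axis=0)
    order = sorted(range(len(score)),
                   key=lambda j: (-score[j], attrs.feature_names[j]))
    return [attrs.feature_names[j] for j in order]


def rank_by_impurity_importance(model: TrainedModel) -> List[str]:
    """Features by descending impurity-based importance (tree models)."""
    if model.algorithm not in _TREE_ALGOS:
        raise ValidationError(
            f"impurity importances unsupported for {model.algorithm}")
    imp = np.asarray(model.estimator.feature_importances_, dtype=float)
    if imp.sum() > 0:
        imp = imp / imp.sum()
    order = sorted(range(len(imp)),
                   key=lambda j: (-imp[j], model.feature_names[j]))
    return [model.feature_names[j] for j in order]


def bit_to_smarts(specs: Sequence[FingerprintSpec],
                  feature_name: str) -> Tuple[str, str]:
    """Resolve a dictionary-backed feature name to its defining pattern
    and description.  Hashed or external features are not resolvable —
    that is exactly the interpretability gap the substructure
    dictionaries exist to avoid — and raise an explicit error."""
    if ":" not in feature_name:
        raise ValidationError(
            f"feature {feature_name!r} is not resolvable to a substructure "
            "(external descriptor or hashed fingerprint)")
    spec_name, idx_str = feature_name.rsplit(":", 1)
    by_name = {s.name: s for s in specs}
    if spec_name not in by_name or not idx_str.isdigit():
        raise ValidationError(
            f"feature {feature_name!r} is not resolvable: no dictionary "
            f"named {spec_name!r}")
    bdef = by_name[spec_name].describe(int(idx_str))
    if bdef.kind == "smarts":
        return bdef.pattern, bdef.description
    return f"{bdef.kind}({bdef.pattern}) >= {bdef.min_count}", \
        bdef.description


def substructure_group_test(pic50: Sequence[float],
                            presence: Sequence[int]
                            ) -> Tuple[Optional[float], Optional[float]]:
    """Two-sided two-sample t-test and KS-test p-values comparing the
    pIC50 distributions of carriers vs non-carriers of one bit.
    Returns (None, None) when either group has fewer than 2 members."""
    y = np.asarray(pic50, dtype=float)
    m = np.asarray(presence).astype(bool)
    a, b = y[m], y[~m]
    if len(a) < 2 or len(b) < 2:
        logger.info("group test untestable: sizes %d vs %d", len(a), len(b))
        return None, None
    t_p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    ks_p = float(stats.ks_2samp(a, b).pvalue)
    return t_p, ks_p


@dataclass
class SubstructureReport:
    feature_name: str
    smarts: str
    description: str
    mean_abs_attribution: float
    mean_signed_attribution: float
    attribution_presence_corr: Optional[float]
    rank_attribution: int
    rank_impurity: int
    t_p: Optional[float]
    ks_p: Optional[float]
    t_q: Optional[float] = None       # Benjamini-Hochberg adjusted
    ks_q: Optional[float] = None
    n_present: int = 0
    n_absent: int = 0


def _bh_adjust(pvals: List[Optional[float]]) -> List[Optional[float]]:
    idx = [i for i, p in enumerate(pvals) if p is not None]
    if not idx:
        return list(pvals)
    ps = np.array([pvals[i] for i in idx])
    order = np.argsort(ps)
    m = len(ps)
    q = np.empty(m)
    running = 1.0
    for rank_pos in range(m - 1, -1, -1):
        i = order[rank_pos]
        running = min(running, ps[i] * m / (rank_pos + 1))
        q[i] = running
    out: List[Optional[float]] = list(pvals)
    for j, i in enumerate(idx):
        out[i] = float(q[j])
    return out


def substructure_report(model: TrainedModel, table: FeatureTable,
                        pic50: Sequence[float],
                        specs: Sequence[FingerprintSpec],
                        attrs: Optional[AttributionTable] = None
                        ) -> List[SubstructureReport]:
    """One row per model feature: attribution and impurity ranks,
    resolved SMARTS, and presence/absence tests with BH-adjusted
    q-values alongside the raw p-values."""
    if attrs is None:
        attrs = attribution_table(model, table)
    y = np.asarray(pic50, dtype=float)
    aligned = table.select(model.feature_names)
    rank_attr = {f: i + 1
                 for i, f in enumerate(rank_by_mean_abs_attribution(attrs))}
    rank_imp = {f: i + 1
                for i, f in enumerate(rank_by_impurity_importance(model))}
    rows: List[SubstructureReport] = []
    for j, fname in enumerate(model.feature_names):
        col = aligned.matrix[:, j]
        try:
            smarts, desc = bit_to_smarts(specs, fname)
        except ValidationError:
            smarts, desc = "", "not resolvable"
        present = col > 0.5
        t_p, ks_p = substructure_group_test(y, present)
        phi = attrs.matrix[:, j]
        if np.std(col) > 0 and np.std(phi) > 0:
            corr = float(np.corrcoef(col, phi)[0, 1])
        else:
            corr = None
        rows.append(SubstructureReport(
            feature_name=fname, smarts=smarts, description=desc,
            mean_abs_attribution=float(np.mean(np.abs(phi))),
            mean_signed_attribution=float(np.mean(phi)),
            attribution_presence_corr=corr,
            rank_attribution=rank_attr[fname],
            rank_impurity=rank_imp[fname],
            t_p=t_p, ks_p=ks_p,
            n_present=int(present.sum()),
            n_absent=int((~present).sum())))
    tq = _bh_adjust([r.t_p for r in rows])
    kq = _bh_adjust([r.ks_p for r in rows])
    for r, a, b in zip(rows, tq, kq):
        r.t_q, r.ks_q = a, b
    rows.sort(key=lambda r: r.rank_attribution)
    return rows
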