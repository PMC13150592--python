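"""End-to-end orchestration: cascade -> repeated splits -> finalize ->
attribution -> applicability-domain calibration.

Two selection modes exist.  ``per_split`` (default) re-runs the whole
feature-reduction cascade inside each training partition, so no fitted
statistic ever sees test rows.  ``global`` runs the cascade once on
the full table; it exists for interpretation/replication runs where
the finalized model, not the split evaluation, is the object of
interest, and is cheaper by an order of magnitude.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .applicability import ADCalibration, calibrate
from .attribution import AttributionTable, attribution_table
from .fingerprints import FeatureTable, morgan_fingerprint
from .metrics import EvalReport, evaluate_split
from .modeling import (TrainedModel, finalize, fit, make_splits,
                       nested_cv_tune, predict)
from .records import ValidationError
from .selection import (RfeCurve, SelectionTrace, ZScaler,
                        correlation_filter, find_knee, rfe_curve,
                        shadow_feature_select, variance_filter)

logger = logging.getLogger("bcrpqsar")

__all__ = ["PipelineConfig", "PipelineResult", "run_cascade",
           "run_pipeline", "run_interpretation"]


@dataclass
class PipelineConfig:
    algorithm: str = "RF"
    seed: int = 0
    n_splits: int = 10
    split_ratio: float = 0.9
    thresholds: Tuple[float, ...] = (5.0, 5.5, 6.0, 6.5, 7.0)
    selection_mode: str = "per_split"       # or "global"
    variance_threshold: float = 0.01
    correlation_threshold: float = 0.8
    shadow_percentile: float = 80.0
    shadow_max_iter: int = 30
    shadow_keep_tentative: bool = True
    rfe_grid: Optional[Sequence[int]] = None   # default 700..20 step 10
    rfe_cv_folds: int = 5
    selection_rf_params: Dict = field(
        default_factory=lambda: {"max_depth": 6, "n_estimators": 200})
    tune_budget: int = 10
    inner_folds: int = 5
    run_shadow: bool = True
    run_rfe: bool = True
    normalize_binary: bool = False
    ad_fpr_target: float = 0.3
    ad_activity_threshold: float = 5.0
    morgan_params: Dict = field(
        default_factory=lambda: {"radius": 2, "n_bits": 2048})


@dataclass
class CascadeResult:
    selected: List[str]
    traces: List[SelectionTrace]
    curve: Optional[RfeCurve]
    scaler: Optional[ZScaler]


def run_cascade(table: FeatureTable, target: Sequence[float],
                cfg: PipelineConfig, seed: int) -> CascadeResult:
    """Variance filter -> correlation filter -> z-normalization ->
    shadow-feature selection -> RFE with knee detection."""
    y = np.asarray(target, dtype=float)
    traces: List[SelectionTrace] = []
    cur, tr = variance_filter(table, cfg.variance_threshold)
    traces.append(tr)
    cur, tr = correlation_filter(cur, cfg.correlation_threshold)
    traces.append(tr)
    scaler = None
    needs_scaling = cfg.normalize_binary or any(
        pv == "external_descriptor" for pv in cur.provenance)
    if needs_scaling:
        scaler = ZScaler(normalize_binary=cfg.normalize_binary)
        cur = scaler.fit_transform(cur)
    if cfg.run_shadow:
        tr = shadow_feature_select(
            cur, y, percentile=cfg.shadow_percentile,
            max_iter=cfg.shadow_max_iter, seed=seed,
            rf_params=cfg.selection_rf_params,
            keep_tentative=cfg.shadow_keep_tentative)
        traces.append(tr)
        if len(tr.kept) >= 5:
            cur = cur.select(tr.kept)
        else:
            logger.warning("shadow stage kept %d features; stage skipped",
                           len(tr.kept))
    curve = None
    if cfg.run_rfe and cur.p > 3:
        curve = rfe_curve(cur, y, grid=cfg.rfe_grid,
                          estimator_params=cfg.selection_rf_params,
                          seed=seed, cv_folds=cfg.rfe_cv_folds)
        if len(curve.points) >= 3:
            k = find_knee(curve)
            chosen = next(p["features"] for p in curve.points
                          if p["k"] == k)
            traces.append(SelectionTrace(
                "rfe", chosen,
                {f: f"eliminated before k={k}"
                 for f in cur.feature_names if f not in chosen},
                {"selected_k": k, "no_knee": curve.no_knee}))
            cur = cur.select(chosen)
    return CascadeResult(selected=list(cur.feature_names), traces=traces,
                         curve=curve, scaler=scaler)


def run_interpretation(table: FeatureTable, target: Sequence[float],
                       cfg: Optional[PipelineConfig] = None,
                       model_params: Optional[Dict] = None
                       ) -> Tuple[CascadeResult, TrainedModel,
                                  AttributionTable]:
    """Interpretation-only path: one cascade on the full table, a fixed
    model fit, and its attribution — no split evaluation or tuning.

    Used for planted-motif recovery studies where the object of
    interest is the finalized model's feature ranking, not held-out
    accuracy."""
    cfg = cfg or PipelineConfig()
    y = np.asarray(target, dtype=float)
    casc = run_cascade(table, y, cfg, cfg.seed)
    full = table
    if casc.scaler is not None:
        full = casc.scaler.transform(full)
    sel = full.select(casc.selected)
    params = dict(model_params or {"max_depth": 6, "n_estimators": 200})
    model = fit(cfg.algorithm, params, sel, y, seed=cfg.seed)
    attrs = attribution_table(model, sel, seed=cfg.seed)
    return casc, model, attrs


@dataclass
class PipelineResult:
    split_reports: List[EvalReport]
    split_results: List[Dict]          # split_id, hyperparams, test_r2, ...
    selected_features: List[str]       # of the finalized model
    final_model: TrainedModel
    attribution: AttributionTable
    calibration: Optional[ADCalibration]
    cascade: CascadeResult

    def mean_test_r2(self) -> float:
        return float(np.mean([r.r2 for r in self.split_reports]))

    def mean_test_rmse(self) -> float:
        return float(np.mean([r.rmse for r in self.split_reports]))


def run_pipeline(table: FeatureTable, target: Sequence[float],
                 cfg: Optional[PipelineConfig] = None,
                 smiles: Optional[Sequence[str]] = None
                 ) -> PipelineResult:
    """Run the full study on one feature table.

    ``smiles``, when given and row-aligned with ``table``, enables the
    Morgan-similarity applicability-domain calibration on the test
    splits; without it the calibration is skipped.
    """
    cfg = cfg or PipelineConfig()
    y = np.asarray(target, dtype=float)
    if table.n != y.size:
        raise ValidationError("table/target length mismatch")
    plans = make_splits(table.n, cfg.split_ratio, cfg.n_splits, cfg.seed)

    global_cascade = None
    if cfg.selection_mode == "global":
        global_cascade = run_cascade(table, y, cfg, cfg.seed)
    elif cfg.selection_mode != "per_split":
        raise ValidationError(
            f"unknown selection_mode {cfg.selection_mode!r}")

    split_reports: List[EvalReport] = []
    split_results: List[Dict] = []
    ad_splits: List[Dict] = []
    for plan in plans:
        tr_tab = table.take_rows(plan.train_idx)
        te_tab = table.take_rows(plan.test_idx)
        y_tr, y_te = y[list(plan.train_idx)], y[list(plan.test_idx)]
        casc = global_cascade or run_cascade(tr_tab, y_tr, cfg, plan.seed)
        if casc.scaler is not None and cfg.selection_mode == "per_split":
            tr_tab = casc.scaler.transform(tr_tab)
            te_tab = casc.scaler.transform(te_tab)
        tr_sel = tr_tab.select(casc.selected)
        te_sel = te_tab.select(casc.selected)
        params, cv_rmse, _ = nested_cv_tune(
            tr_sel, y_tr, cfg.algorithm, cfg.tune_budget,
            cfg.inner_folds, seed=plan.seed)
        model = fit(cfg.algorithm, params, tr_sel, y_tr, seed=plan.seed)
        pred = predict(model, te_sel)
        report = evaluate_split(plan.split_id, y_te, pred, cfg.thresholds)
        split_reports.append(report)
        split_results.append({
            "split_id": plan.split_id, "hyperparams": params,
            "inner_cv_rmse": cv_rmse, "test_r2": report.r2,
            "test_rmse": report.rmse, "selected": casc.selected})
        if smiles is not None:
            ad_splits.append({
                "split_id": plan.split_id,
                "observed": y_te, "predicted": pred,
                "test_smiles": [smiles[i] for i in plan.test_idx],
                "train_smiles": [smiles[i] for i in plan.train_idx]})

    final_cascade = global_cascade or run_cascade(table, y, cfg, cfg.seed)
    full_tab = table
    if final_cascade.scaler is not None:
        full_tab = final_cascade.scaler.transform(full_tab)
    full_sel = full_tab.select(final_cascade.selected)
    final_model = finalize(full_sel, y, cfg.algorithm, split_results,
                           seed=cfg.seed)
    attrs = attribution_table(final_model, full_sel, seed=cfg.seed)

    calibration = None
    if ad_splits:
        calibration = calibrate(ad_splits, cfg.ad_fpr_target,
                                cfg.ad_activity_threshold,
                                cfg.morgan_params)
    return PipelineResult(split_reports=split_reports,
                          split_results=split_results,
                          selected_features=final_cascade.selected,
                          final_model=final_model, attribution=attrs,
                          calibration=calibration,
                          cascade=final_cascade)
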