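"""Similarity-based applicability-domain calibration and screening.

The model's reliable region is defined through a max-Tanimoto cutoff
calibrated on the repeated test splits: test compounds called positive
at pIC50 5 are partitioned into true and false positives, the cutoff
is swept from 0.4 to 0.8 in 0.01 steps over each split, the smallest
cutoff whose retained-set false-positive rate falls below the target
(0.3) is kept, and the per-split cutoffs are averaged into the final
cutoff.  External compounds above the cutoff (strict inequality) are
in-domain; in-domain compounds predicted at or above the activity
threshold are screening candidates.

The FPR inside the sweep is FP/(TP+FP) over retained predicted
positives (the sweep population contains no negatives); the textbook
FP/(FP+TN) denominator is selectable and reported alongside.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .chem import DESCRIPTOR_FUNCS, compute_descriptors
from .fingerprints import BitVector, bulk_max_tanimoto, morgan_fingerprint
from .modeling import TrainedModel, predict
from .records import ValidationError

logger = logging.getLogger("bcrpqsar")

__all__ = [
    "ADCalibration",
    "DomainVerdict",
    "tp_fp_partition",
    "confusion_labels",
    "cutoff_sweep",
    "calibrate",
    "screen_external",
    "descriptor_range_profile",
]

DEFAULT_MORGAN = {"radius": 2, "n_bits": 2048}


def tp_fp_partition(observed: Sequence[float], predicted: Sequence[float],
                    threshold: float = 5.0) -> List[str]:
    """Label each compound TP / FP / other at the activity threshold.

    TP: observed and predicted both >= threshold.  FP: predicted >=
    threshold but observed below it.  Everything predicted negative
    (TN and FN) is "other" and excluded from the cutoff sweep.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValidationError("observed/predicted length mismatch")
    labels = []
    for o, p in zip(y, yhat):
        if p >= threshold:
            labels.append("TP" if o >= threshold else "FP")
        else:
            labels.append("other")
    return labels


def confusion_labels(observed: Sequence[float],
                     predicted: Sequence[float],
                     threshold: float = 5.0) -> List[str]:
    """Full TP/FP/TN/FN label per compound at the activity threshold."""
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValidationError("observed/predicted length mismatch")
    out = []
    for o, p in zip(y, yhat):
        if p >= threshold:
            out.append("TP" if o >= threshold else "FP")
        else:
            out.append("FN" if o >= threshold else "TN")
    return out


def _sweep_fpr(keep: np.ndarray, lab: np.ndarray, fpr_mode: str) -> float:
    fp = int(((lab == "FP") & keep).sum())
    if fpr_mode == "positives":
        tp = int(((lab == "TP") & keep).sum())
        return 0.0 if tp + fp == 0 else fp / (tp + fp)
    tn = int(((lab == "TN") & keep).sum())
    return 0.0 if tn + fp == 0 else fp / (fp + tn)


def cutoff_sweep(max_tan: Sequence[float], labels: Sequence[str],
                 grid_lo: float = 0.4, grid_hi: float = 0.8,
                 step: float = 0.01, fpr_target: float = 0.3,
                 fpr_mode: str = "positives"
                 ) -> Tuple[float, float, bool]:
    """Smallest grid cutoff whose retained-set FPR falls below target.

    Compounds with max_tan > cutoff are retained.  With the default
    ``fpr_mode="positives"`` the rate is FP/(TP+FP) over retained
    called positives (the sweep population holds no called negatives);
    ``fpr_mode="textbook"`` uses FP/(FP+TN) and requires TN labels.
    Either rate is defined as 0 once its retained denominator is
    empty.  Returns (cutoff, fpr, attained); when no grid point
    attains the target, (grid_hi, its FPR, False).
    """
    if fpr_mode not in ("positives", "textbook"):
        raise ValidationError(f"unknown fpr_mode {fpr_mode!r}")
    mt = np.asarray(max_tan, dtype=float)
    lab = np.asarray(labels)
    if mt.shape != lab.shape:
        raise ValidationError("max_tan/labels length mismatch")
    other = "TP" if fpr_mode == "positives" else "TN"
    if not (lab == "FP").any() or not (lab == other).any():
        raise ValidationError(
            f"cutoff sweep requires both FP and {other}")
    grid = np.round(np.arange(grid_lo, grid_hi + step / 2, step), 10)
    last_fpr = None
    for c in grid:
        fpr = _sweep_fpr(mt > c, lab, fpr_mode)
        last_fpr = fpr
        if fpr < fpr_target:
            return float(c), float(fpr), True
    logger.warning("cutoff sweep: FPR target %.2f never attained; "
                   "returning grid end", fpr_target)
    return float(grid[-1]), float(last_fpr), False


@dataclass
class ADCalibration:
    per_split: List[Dict]            # {split_id, cutoff, fpr_at_cutoff,
    #                                   attained}
    final_cutoff: float
    mean_fpr: float
    morgan_params: Dict = field(default_factory=lambda: dict(DEFAULT_MORGAN))
    fpr_target: float = 0.3
    activity_threshold: float = 5.0


def calibrate(splits: Sequence[Dict],
              fpr_target: float = 0.3,
              activity_threshold: float = 5.0,
              morgan_params: Optional[Dict] = None,
              grid_lo: float = 0.4, grid_hi: float = 0.8,
              step: float = 0.01,
              fpr_mode: str = "positives") -> ADCalibration:
    """Average the per-split cutoffs into the final cutoff.

    Each element of ``splits`` carries ``split_id``, ``observed``,
    ``predicted`` (test-set vectors) and either ``max_tanimoto``
    directly or ``test_smiles``/``train_smiles`` from which Morgan
    max-Tanimoto values are computed.  Splits lacking a TP or an FP
    are skipped with a warning; zero usable splits is an error.
    """
    morgan = dict(DEFAULT_MORGAN if morgan_params is None else morgan_params)
    per_split = []
    for sp in splits:
        if "max_tanimoto" in sp:
            mt = np.asarray(sp["max_tanimoto"], dtype=float)
        else:
            test_fps = [morgan_fingerprint(s, **morgan)
                        for s in sp["test_smiles"]]
            train_fps = [morgan_fingerprint(s, **morgan)
                         for s in sp["train_smiles"]]
            mt = bulk_max_tanimoto(test_fps, train_fps)
        labels = np.asarray(confusion_labels(
            sp["observed"], sp["predicted"], activity_threshold))
        try:
            cutoff, fpr, attained = cutoff_sweep(
                mt, labels, grid_lo, grid_hi, step, fpr_target,
                fpr_mode=fpr_mode)
        except ValidationError as exc:
            logger.warning("split %s skipped: %s", sp.get("split_id"), exc)
            continue
        # report both rate conventions at the chosen cutoff
        keep = mt > cutoff
        per_split.append({
            "split_id": sp.get("split_id"),
            "cutoff": cutoff, "fpr_at_cutoff": fpr,
            "fpr_positives_at_cutoff": _sweep_fpr(keep, labels,
                                                  "positives"),
            "fpr_textbook_at_cutoff": _sweep_fpr(keep, labels,
                                                 "textbook"),
            "attained": attained})
    if not per_split:
        raise ValidationError("no usable splits for AD calibration")
    final = float(np.mean([d["cutoff"] for d in per_split]))
    mean_fpr = float(np.mean([d["fpr_at_cutoff"] for d in per_split]))
    return ADCalibration(per_split=per_split, final_cutoff=final,
                         mean_fpr=mean_fpr, morgan_params=morgan,
                         fpr_target=fpr_target,
                         activity_threshold=activity_threshold)


@dataclass
class DomainVerdict:
    compound_id: str
    smiles: str
    max_tanimoto: float
    in_domain: bool                  # strict: max_tanimoto > final_cutoff
    predicted_pic50: float
    candidate: bool                  # in_domain and predicted >= threshold


def screen_external(external: Sequence[Tuple[str, str]],
                    model: TrainedModel,
                    training_fps: Sequence[BitVector],
                    calibration: ADCalibration,
                    featurizer,
                    training_smiles: Optional[Sequence[str]] = None,
                    activity_threshold: Optional[float] = None
                    ) -> Tuple[List[DomainVerdict], List[str]]:
    """Screen an external (smiles, id) list with the finalized model.

    ``featurizer`` maps a list of SMILES to a FeatureTable carrying the
    model's features.  Compounds already in the training set are
    excluded and logged; parse failures are logged per compound, not
    fatal.  Verdicts are sorted by predicted pIC50, descending.
    """
    thr = (calibration.activity_threshold if activity_threshold is None
           else activity_threshold)
    train_set = set(training_smiles or ())
    excluded: List[str] = []
    kept: List[Tuple[str, str, BitVector]] = []
    for smiles, ident in external:
        if smiles in train_set:
            excluded.append(f"{ident}: overlaps training set")
            logger.info("screen: %s excluded (training overlap)", ident)
            continue
        try:
            fp = morgan_fingerprint(smiles, **calibration.morgan_params)
        except Exception as exc:
            excluded.append(f"{ident}: {exc}")
            logger.warning("screen: %s skipped (%s)", ident, exc)
            continue
        kept.append((smiles, ident, fp))
    if not kept:
        return [], excluded
    mt = bulk_max_tanimoto([fp for _, _, fp in kept], list(training_fps))
    table = featurizer([s for s, _, _ in kept])
    preds = predict(model, table)
    verdicts = []
    for (smiles, ident, _), m, p in zip(kept, mt, preds):
        in_dom = bool(m > calibration.final_cutoff)
        verdicts.append(DomainVerdict(
            compound_id=ident, smiles=smiles, max_tanimoto=float(m),
            in_domain=in_dom, predicted_pic50=float(p),
            candidate=bool(in_dom and p >= thr)))
    verdicts.sort(key=lambda v: (-v.predicted_pic50, v.compound_id))
    return verdicts, excluded


def descriptor_range_profile(group: Sequence[str],
                             descriptors: Optional[Sequence[str]] = None
                             ) -> Dict[str, Dict[str, float]]:
    """Min/max (and quartiles) of selected 2D descriptors over a
    compound group — the 'reliable range' summary reported next to the
    similarity classification."""
    names = list(descriptors) if descriptors else list(DESCRIPTOR_FUNCS)
    values = compute_descriptors(group, names)
    out = {}
    for nm in names:
        v = np.asarray(values[nm], dtype=float)
        if v.size == 0:
            continue
        out[nm] = {"min": float(v.min()),
                   "q1": float(np.percentile(v, 25)),
                   "median": float(np.median(v)),
                   "q3": float(np.percentile(v, 75)),
                   "max": float(v.max())}
    return out
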