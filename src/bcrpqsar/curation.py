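"""Curation of raw potency records into one pIC50 entry per compound.

Rules applied, in order: assay-condition filtering (EC50 records pass
only when flagged as inhibitor potency, and are then treated as IC50),
unit standardization to μM, replicate averaging on the concentration
scale, the 3-fold consistency flag, conversion to pIC50 = -log10 of
the molar IC50, and merging of curated sets keyed by standardized
SMILES.  Entries whose replicates disagree by more than 3-fold are
flagged for manual review, not dropped.
"""
from __future__ import annotations

import logging
import math
from collections import defaultdict
from typing import Callable, Dict, Iterable, List, Sequence, Tuple

from .chem import standardize_smiles
from .records import ActivityRecord, CuratedEntry, ValidationError

logger = logging.getLogger("bcrpqsar")

__all__ = [
    "to_micromolar",
    "to_pic50",
    "pic50_to_uM",
    "filter_assay_conditions",
    "aggregate_replicates",
    "merge_datasets",
    "curate",
]

_UM_FACTORS = {"M": 1e6, "mM": 1e3, "uM": 1.0, "nM": 1e-3}

#: tag marking an EC50 measurement as inhibitor potency (treat as IC50)
INHIBITOR_POTENCY_TAG = "assay_type:inhibitor_potency"


def to_micromolar(value: float, unit: str) -> float:
    """Exact scale conversion of a concentration to μM."""
    if not (value > 0):
        raise ValidationError(f"concentration must be > 0, got {value!r}")
    try:
        return value * _UM_FACTORS[unit]
    except KeyError:
        raise ValidationError(f"unit {unit!r} not normalized") from None


def to_pic50(ic50_uM: float) -> float:
    """pIC50 = -log10(IC50 in molar); input is in μM."""
    if not (ic50_uM > 0):
        raise ValidationError(f"IC50 must be > 0, got {ic50_uM!r}")
    return -math.log10(ic50_uM * 1e-6)


def pic50_to_uM(pic50: float) -> float:
    """Inverse of :func:`to_pic50`."""
    return 10.0 ** (-pic50) * 1e6


def filter_assay_conditions(records: Sequence[ActivityRecord],
                            allowed: Callable[[frozenset], bool]
                            ) -> Tuple[List[ActivityRecord], List[str]]:
    """Keep records whose assay tags satisfy the predicate.

    EC50 records additionally require the inhibitor-potency tag; those
    lacking it are removed with a logged reason.  Returns (kept, log).
    """
    kept: List[ActivityRecord] = []
    removed: List[str] = []
    for r in records:
        if not allowed(r.assay_tags):
            removed.append(f"{r.compound_id}: assay tags excluded "
                           f"({sorted(r.assay_tags)})")
            continue
        if r.endpoint == "EC50" and INHIBITOR_POTENCY_TAG not in r.assay_tags:
            removed.append(f"{r.compound_id}: EC50 without inhibitor-potency "
                           "flag")
            continue
        kept.append(r)
    for msg in removed:
        logger.info("filtered: %s", msg)
    if not kept:
        logger.warning("assay-condition filter removed every record")
    return kept, removed


def aggregate_replicates(records: Sequence[ActivityRecord],
                         smiles_std: str,
                         geometric: bool = False) -> CuratedEntry:
    """Aggregate replicate measurements of one standardized compound.

    pIC50 comes from the arithmetic mean of the μM IC50s (geometric
    mean optionally, for users who prefer averaging on the log scale);
    fold_range = max/min flags >3-fold disagreement.
    """
    if not records:
        raise ValidationError("aggregate_replicates: empty input")
    uM = [to_micromolar(r.value, r.unit) for r in records]
    if geometric:
        mean_uM = math.exp(sum(math.log(v) for v in uM) / len(uM))
    else:
        mean_uM = sum(uM) / len(uM)
    fold = max(uM) / min(uM)
    return CuratedEntry(
        smiles_std=smiles_std,
        pic50=to_pic50(mean_uM),
        n_replicates=len(records),
        fold_range=fold,
        consistent=fold <= 3.0,
        sources=frozenset(r.source for r in records if r.source),
        compound_id=records[0].compound_id)


def merge_datasets(a: Sequence[CuratedEntry],
                   b: Sequence[CuratedEntry],
                   geometric: bool = False) -> List[CuratedEntry]:
    """Union of two curated sets keyed by standardized SMILES.

    Overlapping compounds get the mean of the per-source IC50s on the
    μM scale, re-converted to pIC50; replicate counts add and sources
    union.  |result| = |a| + |b| - |overlap|.
    """
    groups: Dict[str, List[CuratedEntry]] = defaultdict(list)
    order: List[str] = []
    for e in list(a) + list(b):
        if e.smiles_std not in groups:
            order.append(e.smiles_std)
        groups[e.smiles_std].append(e)
    out: List[CuratedEntry] = []
    for smi in order:
        es = groups[smi]
        if len(es) == 1:
            out.append(es[0])
            continue
        uMs = [pic50_to_uM(e.pic50) for e in es]
        if geometric:
            mean_uM = math.exp(sum(math.log(v) for v in uMs) / len(uMs))
        else:
            mean_uM = sum(uMs) / len(uMs)
        fold = max(max(e.fold_range for e in es),
                   max(uMs) / min(uMs))
        out.append(CuratedEntry(
            smiles_std=smi,
            pic50=to_pic50(mean_uM),
            n_replicates=sum(e.n_replicates for e in es),
            fold_range=fold,
            consistent=fold <= 3.0,
            sources=frozenset().union(*(e.sources for e in es)),
            compound_id=es[0].compound_id))
    return out


def curate(records: Iterable[ActivityRecord],
           allowed: Callable[[frozenset], bool] = lambda tags: True,
           geometric: bool = False,
           exclusion_smiles: Sequence[str] = ()) -> List[CuratedEntry]:
    """Full curation pass: filter, standardize, group, aggregate.

    ``exclusion_smiles`` removes compounds (by standardized SMILES) that
    overlap a reference list, e.g. previously reported inhibitors that
    must not leak into an external screen.
    """
    kept, _ = filter_assay_conditions(list(records), allowed)
    groups: Dict[str, List[ActivityRecord]] = defaultdict(list)
    order: List[str] = []
    for r in kept:
        smi = standardize_smiles(r.smiles).smiles_std
        if smi not in groups:
            order.append(smi)
        groups[smi].append(r)
    excluded = {standardize_smiles(s).smiles_std for s in exclusion_smiles}
    entries = []
    for smi in order:
        if smi in excluded:
            logger.info("curate: %s removed via exclusion list", smi)
            continue
        entries.append(aggregate_replicates(groups[smi], smi,
                                            geometric=geometric))
    return entries
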