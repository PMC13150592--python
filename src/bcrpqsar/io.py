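"""Readers and writers for the package's plain-text artifacts.

Formats:
  * activity CSV — ``compound_id,smiles,endpoint,value,unit,assay_type,
    substrate,cell_type,source`` (extra columns ignored; a column
    mapping can rename them);
  * SMILES list — one SMILES per line, optional tab-separated id
    (.smi dialect);
  * curated CSV, feature-table CSV, JSON reports — all round-trip
    losslessly through the matching reader.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .fingerprints import FeatureTable
from .records import (ActivityRecord, CuratedEntry, ValidationError,
                      normalize_unit)

logger = logging.getLogger("bcrpqsar")

__all__ = [
    "read_activity_table",
    "write_activity_table",
    "read_smiles_list",
    "write_smiles_list",
    "write_curated_csv",
    "read_curated_csv",
    "write_feature_table_csv",
    "read_feature_table_csv",
    "write_report",
    "read_report",
]

ACTIVITY_COLUMNS = ("compound_id", "smiles", "endpoint", "value", "unit",
                    "assay_type", "substrate", "cell_type", "source")
_TAG_COLUMNS = ("assay_type", "substrate", "cell_type")
SCHEMA_VERSION = "1"


def read_activity_table(path: str | Path,
                        schema: Optional[Dict[str, str]] = None
                        ) -> Tuple[List[ActivityRecord], List[str]]:
    """Read raw activity records from CSV.

    ``schema`` maps canonical column names to the file's column names.
    Rows with a missing value or SMILES are skipped and reported in the
    returned skip log (second element), never silently dropped.  An
    unknown unit token is an error naming the row.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    colmap = {c: c for c in ACTIVITY_COLUMNS}
    if schema:
        colmap.update(schema)
    for canonical in ("smiles", "value", "unit"):
        if colmap[canonical] not in df.columns:
            raise ValidationError(
                f"{path}: required column {colmap[canonical]!r} missing")
    records: List[ActivityRecord] = []
    skipped: List[str] = []
    for i, row in df.iterrows():
        def get(canonical, default=""):
            col = colmap.get(canonical, canonical)
            return str(row[col]).strip() if col in df.columns else default

        smiles, value = get("smiles"), get("value")
        if not smiles or not value:
            msg = f"row {i}: missing {'smiles' if not smiles else 'value'}"
            skipped.append(msg)
            logger.warning("%s: skipped %s", path.name, msg)
            continue
        try:
            val = float(value)
        except ValueError:
            skipped.append(f"row {i}: non-numeric value {value!r}")
            logger.warning("%s: skipped row %d (non-numeric value)",
                           path.name, i)
            continue
        try:
            unit = normalize_unit(get("unit"))
        except ValidationError as exc:
            raise ValidationError(f"{path} row {i}: {exc}") from exc
        tags = frozenset(f"{c}:{get(c)}" for c in _TAG_COLUMNS if get(c))
        records.append(ActivityRecord(
            compound_id=get("compound_id") or f"row{i}",
            smiles=smiles,
            endpoint=get("endpoint") or "IC50",
            value=val,
            unit=unit,
            assay_tags=tags,
            source=get("source")))
    return records, skipped


def write_activity_table(records: Sequence[ActivityRecord],
                         path: str | Path) -> None:
    rows = []
    for r in records:
        tagmap = dict(t.split(":", 1) for t in r.assay_tags)
        rows.append({
            "compound_id": r.compound_id, "smiles": r.smiles,
            "endpoint": r.endpoint, "value": r.value, "unit": r.unit,
            "assay_type": tagmap.get("assay_type", ""),
            "substrate": tagmap.get("substrate", ""),
            "cell_type": tagmap.get("cell_type", ""),
            "source": r.source})
    pd.DataFrame(rows, columns=list(ACTIVITY_COLUMNS)).to_csv(path,
                                                              index=False)


def read_smiles_list(path: str | Path) -> List[Tuple[str, str]]:
    """Read a .smi file: one SMILES per line, optional tab-separated id."""
    out = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        smiles = parts[0].strip()
        ident = parts[1].strip() if len(parts) > 1 else f"ext{i}"
        out.append((smiles, ident))
    return out


def write_smiles_list(items: Sequence[Tuple[str, str]],
                      path: str | Path) -> None:
    with open(path, "w") as fh:
        for smiles, ident in items:
            fh.write(f"{smiles}\t{ident}\n")


def write_curated_csv(entries: Sequence[CuratedEntry],
                      path: str | Path) -> None:
    rows = [{
        "smiles_std": e.smiles_std, "pic50": repr(e.pic50),
        "n_replicates": e.n_replicates, "fold_range": repr(e.fold_range),
        "consistent": e.consistent,
        "sources": ";".join(sorted(e.sources)),
    } for e in entries]
    pd.DataFrame(rows, columns=["smiles_std", "pic50", "n_replicates",
                                "fold_range", "consistent",
                                "sources"]).to_csv(path, index=False)


def read_curated_csv(path: str | Path) -> List[CuratedEntry]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = []
    for r in df.itertuples():
        out.append(CuratedEntry(
            smiles_std=r.smiles_std, pic50=float(r.pic50),
            n_replicates=int(r.n_replicates),
            fold_range=float(r.fold_range),
            consistent=r.consistent in ("True", "true", "1"),
            sources=frozenset(s for s in r.sources.split(";") if s)))
    return out


def write_feature_table_csv(table: FeatureTable, path: str | Path) -> None:
    df = table.to_frame()
    with open(path, "w") as fh:
        fh.write("# provenance: " + ",".join(table.provenance) + "\n")
        df.to_csv(fh, index=False, float_format="%.17g")


def read_feature_table_csv(path: str | Path) -> FeatureTable:
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# provenance:"):
            raise ValidationError(f"{path}: missing provenance header")
        provenance = first.split(":", 1)[1].strip().split(",")
        df = pd.read_csv(fh, float_precision="round_trip")
    return FeatureTable(
        compound_ids=[str(c) for c in df["compound_id"]],
        feature_names=[str(c) for c in df.columns[1:]],
        matrix=df.iloc[:, 1:].to_numpy(dtype=float),
        provenance=provenance)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return [_jsonable(x) for x in obj.tolist()]
    if isinstance(obj, (frozenset, set)):
        return sorted(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(x) for x in obj]
    return obj


def write_report(report, path: str | Path) -> None:
    """Emit a stage output: JSON for mappings/dataclasses, CSV for
    DataFrames and FeatureTables."""
    path = Path(path)
    if isinstance(report, FeatureTable):
        write_feature_table_csv(report, path)
        return
    if isinstance(report, pd.DataFrame):
        report.to_csv(path, index=False)
        return
    payload = {"schema_version": SCHEMA_VERSION,
               "payload": _jsonable(report)}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_report(path: str | Path):
    """Read back a JSON report written by :func:`write_report`."""
    with open(path) as fh:
        payload = json.load(fh)
    if "payload" not in payload:
        raise ValidationError(f"{path}: not a versioned report")
    return payload["payload"]
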