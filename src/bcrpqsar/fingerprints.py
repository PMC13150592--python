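"""Substructure-dictionary fingerprints, Morgan fingerprints, Tanimoto.

A :class:`FingerprintSpec` is an ordered dictionary of bit definitions.
Three bit kinds exist:

``smarts``
    bit is 1 iff the molecule contains at least ``min_count`` distinct
    matches of the SMARTS pattern;
``element_count``
    pattern is an element symbol; bit is 1 iff the molecule contains at
    least ``min_count`` atoms of that element;
``ring_count``
    pattern is ``<size>`` or ``<size>:aromatic`` / ``<size>:saturated``;
    bit is 1 iff the molecule contains at least ``min_count`` rings of
    that size (and character).

Dictionaries are data, not code: a spec round-trips through a TSV file
(`bit_index<TAB>kind<TAB>pattern<TAB>min_count<TAB>description`) so
corrected definitions can be dropped in without a code change.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence
import warnings

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFingerprintGenerator

from .chem import mol_from_smiles
from .records import ValidationError

__all__ = [
    "BitDef",
    "FingerprintSpec",
    "BitVector",
    "FeatureTable",
    "compute_fingerprint",
    "morgan_fingerprint",
    "tanimoto",
    "max_tanimoto_to_set",
    "build_feature_table",
    "load_spec_tsv",
    "save_spec_tsv",
]

BIT_KINDS = ("smarts", "element_count", "ring_count")


@dataclass(frozen=True)
class BitDef:
    index: int
    kind: str                 # smarts | element_count | ring_count
    pattern: str
    min_count: int = 1
    description: str = ""

    def __post_init__(self):
        if self.kind not in BIT_KINDS:
            raise ValidationError(f"unknown bit kind {self.kind!r}")
        if self.min_count < 1:
            raise ValidationError("min_count must be >= 1")


class FingerprintSpec:
    """Ordered, validated dictionary of fingerprint bit definitions."""

    def __init__(self, name: str, bits: Sequence[BitDef]):
        self.name = name
        self.bits = list(bits)
        for i, b in enumerate(self.bits):
            if b.index != i:
                raise ValidationError(
                    f"{name}: bit indices must be dense 0..L-1 "
                    f"(position {i} has index {b.index})")
        self._compiled: List[Optional[Chem.Mol]] = []
        for b in self.bits:
            if b.kind == "smarts":
                patt = Chem.MolFromSmarts(b.pattern)
                if patt is None:
                    raise ValidationError(
                        f"{name} bit {b.index}: SMARTS does not compile: "
                        f"{b.pattern!r}")
                self._compiled.append(patt)
            else:
                self._compiled.append(None)

    def __len__(self) -> int:
        return len(self.bits)

    def feature_names(self) -> List[str]:
        return [f"{self.name}:{b.index}" for b in self.bits]

    def describe(self, index: int) -> BitDef:
        return self.bits[index]


@dataclass
class BitVector:
    """Fixed-length binary fingerprint tied to a named spec."""

    spec_name: str
    bits: np.ndarray

    def __post_init__(self):
        self.bits = np.asarray(self.bits, dtype=np.uint8)
        if self.bits.ndim != 1:
            raise ValidationError("BitVector.bits must be 1-D")
        if not np.isin(self.bits, (0, 1)).all():
            raise ValidationError("BitVector values must be 0/1")

    def __len__(self) -> int:
        return self.bits.shape[0]


def _count_rings(mol: Chem.Mol, size: int, character: str) -> int:
    # size 0 means "any ring size"
    ri = mol.GetRingInfo()
    n = 0
    for ring in ri.AtomRings():
        if size and len(ring) != size:
            continue
        size_eff = len(ring)
        atoms = [mol.GetAtomWithIdx(i) for i in ring]
        if character == "aromatic":
            if not all(a.GetIsAromatic() for a in atoms):
                continue
        elif character == "saturated":
            if any(a.GetIsAromatic() for a in atoms):
                continue
            bonds = [mol.GetBondBetweenAtoms(ring[i],
                                             ring[(i + 1) % size_eff])
                     for i in range(size_eff)]
            if any(b.GetBondType() != Chem.BondType.SINGLE for b in bonds):
                continue
        n += 1
    return n


def _bit_value(mol: Chem.Mol, bdef: BitDef, patt: Optional[Chem.Mol]) -> int:
    if bdef.kind == "smarts":
        if bdef.min_count == 1:
            return int(mol.HasSubstructMatch(patt))
        matches = mol.GetSubstructMatches(patt, uniquify=True,
                                          maxMatches=bdef.min_count)
        return int(len(matches) >= bdef.min_count)
    if bdef.kind == "element_count":
        n = sum(1 for a in mol.GetAtoms() if a.GetSymbol() == bdef.pattern)
        return int(n >= bdef.min_count)
    # ring_count
    parts = bdef.pattern.split(":")
    size = int(parts[0])
    character = parts[1] if len(parts) > 1 else "any"
    return int(_count_rings(mol, size, character) >= bdef.min_count)


def compute_fingerprint(smiles_std: str, spec: FingerprintSpec) -> BitVector:
    """Dictionary fingerprint of one molecule: bit i = 1 iff the molecule
    contains >= min_count instances of pattern i."""
    mol = mol_from_smiles(smiles_std, f"fingerprint {spec.name}")
    bits = np.fromiter(
        (_bit_value(mol, b, p) for b, p in zip(spec.bits, spec._compiled)),
        dtype=np.uint8, count=len(spec))
    return BitVector(spec_name=spec.name, bits=bits)


def morgan_fingerprint(smiles_std: str, radius: int = 2,
                       n_bits: int = 2048) -> BitVector:
    """Hashed circular (Morgan/ECFP-like) fingerprint, for similarity only."""
    if radius < 0:
        raise ValidationError("radius must be >= 0")
    if n_bits < 1 or (n_bits & (n_bits - 1)) != 0:
        raise ValidationError("n_bits must be a power of two")
    mol = mol_from_smiles(smiles_std, "morgan fingerprint")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius,
                                                    fpSize=n_bits)
    arr = np.zeros(n_bits, dtype=np.uint8)
    on = gen.GetFingerprint(mol).GetOnBits()
    arr[list(on)] = 1
    return BitVector(spec_name=f"morgan_r{radius}_{n_bits}", bits=arr)


def tanimoto(a: BitVector, b: BitVector) -> float:
    """|a AND b| / |a OR b|.  Both-empty vectors give 0.0 (with a warning)."""
    if len(a) != len(b) or a.spec_name != b.spec_name:
        raise ValidationError(
            f"bit vectors are not comparable: "
            f"{a.spec_name}/{len(a)} vs {b.spec_name}/{len(b)}")
    inter = int(np.count_nonzero(a.bits & b.bits))
    union = int(np.count_nonzero(a.bits | b.bits))
    if union == 0:
        warnings.warn("tanimoto of two all-zero vectors defined as 0.0")
        return 0.0
    return inter / union


def max_tanimoto_to_set(query: BitVector,
                        reference: Sequence[BitVector]) -> float:
    """Maximum Tanimoto similarity of a query against a reference set."""
    if len(reference) == 0:
        raise ValidationError("reference set must be non-empty")
    return max(tanimoto(query, r) for r in reference)


def bulk_max_tanimoto(queries: Sequence[BitVector],
                      reference: Sequence[BitVector]) -> np.ndarray:
    """Vectorized max-Tanimoto of many queries against one reference set."""
    if len(reference) == 0:
        raise ValidationError("reference set must be non-empty")
    Q = np.stack([q.bits for q in queries]).astype(np.int32)
    R = np.stack([r.bits for r in reference]).astype(np.int32)
    inter = Q @ R.T
    qsum = Q.sum(axis=1, keepdims=True)
    rsum = R.sum(axis=1, keepdims=True).T
    union = qsum + rsum - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 0.0)
    return sim.max(axis=1)


@dataclass
class FeatureTable:
    """n x p model matrix with names and provenance.

    ``provenance`` marks each column as ``fingerprint`` (binary,
    dictionary-resolvable) or ``external_descriptor`` (arbitrary reals,
    accepted as-is, not resolvable to a substructure).
    """

    compound_ids: List[str]
    feature_names: List[str]
    matrix: np.ndarray
    provenance: List[str] = field(default_factory=list)

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        n, p = self.matrix.shape
        if len(self.compound_ids) != n:
            raise ValidationError("compound_ids length != row count")
        if len(self.feature_names) != p:
            raise ValidationError("feature_names length != column count")
        if len(set(self.feature_names)) != p:
            raise ValidationError("feature names must be unique")
        if not self.provenance:
            self.provenance = ["fingerprint"] * p
        if len(self.provenance) != p:
            raise ValidationError("provenance length != column count")
        fp_cols = [j for j, pv in enumerate(self.provenance)
                   if pv == "fingerprint"]
        if fp_cols:
            sub = self.matrix[:, fp_cols]
            if not np.isin(sub, (0.0, 1.0)).all():
                raise ValidationError(
                    "fingerprint-provenance columns must be binary")

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def p(self) -> int:
        return self.matrix.shape[1]

    def select(self, names: Sequence[str]) -> "FeatureTable":
        """Column subset (and reorder) by feature name."""
        idx = {f: j for j, f in enumerate(self.feature_names)}
        missing = [nm for nm in names if nm not in idx]
        if missing:
            raise ValidationError(f"unknown feature columns: {missing[:5]}")
        cols = [idx[nm] for nm in names]
        return FeatureTable(
            compound_ids=list(self.compound_ids),
            feature_names=list(names),
            matrix=self.matrix[:, cols].copy(),
            provenance=[self.provenance[j] for j in cols])

    def take_rows(self, rows: Sequence[int]) -> "FeatureTable":
        rows = list(rows)
        return FeatureTable(
            compound_ids=[self.compound_ids[i] for i in rows],
            feature_names=list(self.feature_names),
            matrix=self.matrix[rows, :].copy(),
            provenance=list(self.provenance))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.matrix, columns=self.feature_names)
        df.insert(0, "compound_id", self.compound_ids)
        return df


def build_feature_table(compounds: Sequence[str],
                        specs: Sequence[FingerprintSpec],
                        external: Optional[pd.DataFrame] = None,
                        compound_ids: Optional[Sequence[str]] = None
                        ) -> FeatureTable:
    """Concatenate fingerprint blocks (and an optional external descriptor
    block, row-aligned to ``compounds``) into one model matrix."""
    compounds = list(compounds)
    n = len(compounds)
    if compound_ids is None:
        compound_ids = [f"c{i}" for i in range(n)]
    blocks, names, prov = [], [], []
    for spec in specs:
        mat = np.zeros((n, len(spec)), dtype=float)
        for i, smi in enumerate(compounds):
            mat[i] = compute_fingerprint(smi, spec).bits
        blocks.append(mat)
        names.extend(spec.feature_names())
        prov.extend(["fingerprint"] * len(spec))
    if external is not None:
        if len(external) != n:
            raise ValidationError(
                f"external descriptor table has {len(external)} rows, "
                f"expected {n}")
        blocks.append(external.to_numpy(dtype=float))
        names.extend(str(c) for c in external.columns)
        prov.extend(["external_descriptor"] * external.shape[1])
    if not blocks:
        raise ValidationError("no feature blocks given")
    return FeatureTable(compound_ids=list(compound_ids),
                        feature_names=names,
                        matrix=np.hstack(blocks),
                        provenance=prov)


def save_spec_tsv(spec: FingerprintSpec, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("bit_index\tkind\tpattern\tmin_count\tdescription\n")
        for b in spec.bits:
            fh.write(f"{b.index}\t{b.kind}\t{b.pattern}\t{b.min_count}\t"
                     f"{b.description}\n")


def load_spec_tsv(path: str | Path, name: Optional[str] = None
                  ) -> FingerprintSpec:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    bits = [BitDef(index=int(r.bit_index), kind=r.kind, pattern=r.pattern,
                   min_count=int(r.min_count), description=r.description)
            for r in df.itertuples()]
    return FingerprintSpec(name or path.stem, bits)
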