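"""Shipped fingerprint dictionaries.

Four families are provided, totalling ~1100 interpretable bits:

``maccs166``
    the 166 MACCS structural keys, built at runtime from RDKit's
    published SMARTS table (dense indices 0..165 correspond to MACCS
    keys 1..166);
``counts``
    PubChem-style element-count and ring-count sections, enumerated
    programmatically;
``funcgroups``
    a curated functional-group / heterocycle SMARTS dictionary shipped
    as a TSV data file;
``ringsubst``
    a Klekota-Roth-style systematic enumeration of ring x substituent
    SMARTS patterns (every generated pattern is compiled; templates that
    do not compile are skipped deterministically).

All families share the TSV dictionary format of
:func:`bcrpqsar.fingerprints.load_spec_tsv`.
"""
from __future__ import annotations

from functools import lru_cache
from importlib import resources
from typing import List

from rdkit import Chem
from rdkit.Chem import MACCSkeys

from .fingerprints import BitDef, FingerprintSpec, load_spec_tsv

__all__ = [
    "maccs166_spec",
    "counts_spec",
    "funcgroups_spec",
    "ringsubst_spec",
    "default_specs",
]

# MACCS keys RDKit handles specially in code rather than via SMARTS:
# key 1 (isotope) and key 44 (exotic element) are never set for organic
# drug-like input; key 125 (>1 aromatic ring) maps onto our any-size
# aromatic ring counter; key 166 (>1 fragment) is always 0 after
# standardization keeps the largest fragment.
_NEVER_MATCH = "[#103]"


@lru_cache(maxsize=None)
def maccs166_spec() -> FingerprintSpec:
    bits: List[BitDef] = []
    for key in range(1, 167):
        smarts, count = MACCSkeys.smartsPatts[key]
        idx = key - 1
        if key == 125:
            bits.append(BitDef(idx, "ring_count", "0:aromatic", 2,
                               "MACCS 125: more than one aromatic ring"))
        elif smarts == "?":
            bits.append(BitDef(idx, "smarts", _NEVER_MATCH, 1,
                               f"MACCS {key}: placeholder (special-cased "
                               "key, vacuous after standardization)"))
        else:
            bits.append(BitDef(idx, "smarts", smarts, count + 1,
                               f"MACCS {key}"))
    return FingerprintSpec("maccs166", bits)


_ELEMENTS = [
    ("C", (2, 4, 8, 16, 24, 32)),
    ("N", (1, 2, 3, 4, 6)),
    ("O", (1, 2, 3, 4, 6, 8)),
    ("S", (1, 2)),
    ("F", (1, 2, 4)),
    ("Cl", (1, 2)),
    ("Br", (1,)),
    ("I", (1,)),
    ("P", (1,)),
    ("B", (1,)),
]

_RING_SIZES = (3, 4, 5, 6, 7, 8)


@lru_cache(maxsize=None)
def counts_spec() -> FingerprintSpec:
    bits: List[BitDef] = []
    idx = 0
    for sym, mins in _ELEMENTS:
        for m in mins:
            bits.append(BitDef(idx, "element_count", sym, m,
                               f">= {m} {sym} atoms"))
            idx += 1
    for size in _RING_SIZES:
        for character in ("any", "aromatic", "saturated"):
            pat = f"{size}" if character == "any" else f"{size}:{character}"
            for m in (1, 2):
                bits.append(BitDef(idx, "ring_count", pat, m,
                                   f">= {m} {character} {size}-rings"))
                idx += 1
    for m in (1, 2, 3, 4):
        bits.append(BitDef(idx, "ring_count", "0:aromatic", m,
                           f">= {m} aromatic rings (any size)"))
        idx += 1
    return FingerprintSpec("counts", bits)


@lru_cache(maxsize=None)
def funcgroups_spec() -> FingerprintSpec:
    ref = resources.files("bcrpqsar.data").joinpath("funcgroups.tsv")
    with resources.as_file(ref) as path:
        return load_spec_tsv(path, name="funcgroups")


# ring templates with one open substitution site marked {sub}
_RING_TEMPLATES = [
    ("benzene", "c1ccc({sub})cc1"),
    ("pyridine-2", "c1ccnc({sub})c1"),
    ("pyridine-3", "c1ccc({sub})cn1"),
    ("pyrimidine", "c1cnc({sub})nc1"),
    ("pyrazine", "c1cnc({sub})cn1"),
    ("pyrrole", "c1cc({sub})[nH]c1"),
    ("furan", "c1cc({sub})oc1"),
    ("thiophene", "c1cc({sub})sc1"),
    ("imidazole", "c1nc({sub})[nH]c1"),
    ("oxazole", "c1nc({sub})oc1"),
    ("thiazole", "c1nc({sub})sc1"),
    ("pyrazole", "c1cc({sub})n[nH]1"),
    ("naphthalene", "c1ccc2cc({sub})ccc2c1"),
    ("quinoline", "c1ccc2nc({sub})ccc2c1"),
    ("indole", "c1ccc2c(c1)cc({sub})[nH]2"),
    ("piperidine-N", "C1CCN({sub})CC1"),
    ("piperidine-C", "C1CCC({sub})NC1"),
    ("piperazine-N", "C1CN({sub})CCN1"),
    ("morpholine-N", "C1COCCN1{sub}"),
    ("pyrrolidine-N", "C1CCN1{sub}"),
    ("tetrahydrofuran", "C1CCC({sub})O1"),
    ("tetrahydropyran", "C1CCC({sub})OC1"),
    ("cyclohexane", "C1CCC({sub})CC1"),
    ("cyclopentane", "C1CCC({sub})C1"),
    ("cyclopropane", "C1CC1{sub}"),
]

_SUBSTITUENTS = [
    ("methyl", "C"),
    ("ethyl", "CC"),
    ("isopropyl", "C(C)C"),
    ("hydroxy", "O"),
    ("methoxy", "OC"),
    ("ethoxy", "OCC"),
    ("amino", "N"),
    ("dimethylamino", "N(C)C"),
    ("fluoro", "F"),
    ("chloro", "Cl"),
    ("bromo", "Br"),
    ("iodo", "I"),
    ("trifluoromethyl", "C(F)(F)F"),
    ("trifluoromethoxy", "OC(F)(F)F"),
    ("cyano", "C#N"),
    ("nitro", "[N+](=O)[O-]"),
    ("formyl", "C=O"),
    ("acetyl", "C(C)=O"),
    ("carboxy", "C(=O)O"),
    ("carboxamide", "C(=O)N"),
    ("acetamido", "NC(C)=O"),
    ("methylsulfonyl", "S(C)(=O)=O"),
    ("sulfamoyl", "S(N)(=O)=O"),
    ("thiomethyl", "SC"),
    ("hydroxymethyl", "CO"),
    ("aminomethyl", "CN"),
    ("vinyl", "C=C"),
    ("phenyl", "c1ccccc1"),
]


@lru_cache(maxsize=None)
def ringsubst_spec() -> FingerprintSpec:
    bits: List[BitDef] = []
    idx = 0
    seen = set()
    for rname, template in _RING_TEMPLATES:
        for sname, sub in _SUBSTITUENTS:
            smarts = template.format(sub=sub)
            if smarts in seen or Chem.MolFromSmarts(smarts) is None:
                continue
            seen.add(smarts)
            bits.append(BitDef(idx, "smarts", smarts, 1,
                               f"{sname}-substituted {rname}"))
            idx += 1
    return FingerprintSpec("ringsubst", bits)


def default_specs() -> List[FingerprintSpec]:
    """The four shipped dictionaries, in modelling order."""
    return [maccs166_spec(), counts_spec(), funcgroups_spec(),
            ringsubst_spec()]
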