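"""SMILES standardization and small-molecule descriptors.

Standardization contract: canonicalize, keep the largest organic
fragment (salts and counter-ions stripped), neutralize charges where
chemically valid, re-canonicalize.  The result is a fixed point of the
procedure, so merging datasets by string equality of the standardized
SMILES behaves like merging by structure.  Stereochemistry is retained.
"""
from __future__ import annotations

from typing import Callable, Dict, Iterable, List

from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors
from rdkit.Chem.MolStandardize import rdMolStandardize

from .records import StandardizedCompound, ValidationError

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "SmilesParseError",
    "standardize_smiles",
    "mol_from_smiles",
    "DESCRIPTOR_FUNCS",
    "compute_descriptors",
]


class SmilesParseError(ValueError):
    """An input SMILES failed to parse; carries the offending string."""

    def __init__(self, smiles: str, context: str = ""):
        self.smiles = smiles
        msg = f"unparseable SMILES: {smiles!r}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


def mol_from_smiles(smiles: str, context: str = "") -> Chem.Mol:
    if not smiles:
        raise SmilesParseError(smiles, context or "empty string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles, context)
    return mol


_UNCHARGER = rdMolStandardize.Uncharger()
_CHOOSER = rdMolStandardize.LargestFragmentChooser(preferOrganic=True)


def standardize_smiles(smiles: str) -> StandardizedCompound:
    """Canonicalize a SMILES: largest organic fragment, neutral charges.

    Idempotent: standardizing the output returns it unchanged.
    """
    mol = mol_from_smiles(smiles)
    mol = _CHOOSER.choose(mol)
    mol = rdMolStandardize.Cleanup(mol)
    mol = _UNCHARGER.uncharge(mol)
    Chem.SanitizeMol(mol)
    return StandardizedCompound(smiles_std=Chem.MolToSmiles(mol),
                                parent_of=smiles)


def _n_aliphatic_heterocycles(mol: Chem.Mol) -> float:
    return float(rdMolDescriptors.CalcNumAliphaticHeterocycles(mol))


#: Descriptor functions used for applicability-domain range profiling.
#: Keys follow common medicinal-chemistry naming.
DESCRIPTOR_FUNCS: Dict[str, Callable[[Chem.Mol], float]] = {
    "mol_weight": Descriptors.MolWt,
    "slogp": Crippen.MolLogP,
    "tpsa": rdMolDescriptors.CalcTPSA,
    "heavy_atoms": lambda m: float(m.GetNumHeavyAtoms()),
    "saturated_rings": lambda m: float(
        rdMolDescriptors.CalcNumSaturatedRings(m)),
    "aliphatic_heterocycles": _n_aliphatic_heterocycles,
}


def compute_descriptors(smiles_list: Iterable[str],
                        names: Iterable[str] | None = None
                        ) -> Dict[str, List[float]]:
    """Compute named 2D descriptors for a list of canonical SMILES."""
    names = list(names) if names is not None else list(DESCRIPTOR_FUNCS)
    unknown = [n for n in names if n not in DESCRIPTOR_FUNCS]
    if unknown:
        raise ValidationError(f"unknown descriptors: {unknown}")
    out: Dict[str, List[float]] = {n: [] for n in names}
    for smi in smiles_list:
        mol = mol_from_smiles(smi, "descriptor computation")
        for n in names:
            out[n].append(float(DESCRIPTOR_FUNCS[n](mol)))
    return out
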