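"""Core record types shared by every stage of the pipeline.

The records mirror the life of a potency measurement: a raw
:class:`ActivityRecord` as reported by an assay, a
:class:`StandardizedCompound` once the structure has been normalised,
and a :class:`CuratedEntry` once replicate measurements have been
aggregated into one pIC50 value per unique compound.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

__all__ = [
    "ActivityRecord",
    "StandardizedCompound",
    "CuratedEntry",
    "RunConfig",
    "UNIT_ALIASES",
    "VALID_UNITS",
    "VALID_ENDPOINTS",
    "normalize_unit",
    "ValidationError",
]


class ValidationError(ValueError):
    """Raised when an input record violates a stated invariant."""


VALID_UNITS = ("M", "mM", "uM", "nM")
VALID_ENDPOINTS = ("IC50", "EC50")

# Every spelling of a molar-concentration unit we accept.  Unknown units
# are errors, never guessed.
UNIT_ALIASES = {
    "m": "M",
    "mol/l": "M",
    "molar": "M",
    "mm": "mM",
    "millim": "mM",
    "millimolar": "mM",
    "um": "uM",
    "µm": "uM",      # micro sign µ
    "μm": "uM",      # greek mu μ
    "microm": "uM",
    "micromolar": "uM",
    "nm": "nM",
    "nanom": "nM",
    "nanomolar": "nM",
}


def normalize_unit(token: str) -> str:
    """Map a unit spelling onto one of ``M, mM, uM, nM``.

    Raises :class:`ValidationError` for anything not in the alias table.
    """
    tok = token.strip()
    if tok in VALID_UNITS:
        return tok
    canon = UNIT_ALIASES.get(tok.lower())
    if canon is None:
        raise ValidationError(f"unknown concentration unit: {token!r}")
    return canon


@dataclass(frozen=True)
class ActivityRecord:
    """One raw potency measurement from an assay source."""

    compound_id: str
    smiles: str
    endpoint: str            # IC50 or EC50
    value: float             # concentration, > 0
    unit: str                # M / mM / uM / nM
    assay_tags: frozenset = field(default_factory=frozenset)
    source: str = ""

    def __post_init__(self):
        if not self.smiles:
            raise ValidationError("ActivityRecord.smiles must be non-empty")
        if self.endpoint not in VALID_ENDPOINTS:
            raise ValidationError(f"unknown endpoint {self.endpoint!r}")
        if not (self.value > 0):
            raise ValidationError(
                f"ActivityRecord.value must be > 0, got {self.value!r}")
        if self.unit not in VALID_UNITS:
            raise ValidationError(f"unit {self.unit!r} not normalized")
        if not isinstance(self.assay_tags, frozenset):
            object.__setattr__(self, "assay_tags", frozenset(self.assay_tags))


@dataclass(frozen=True)
class StandardizedCompound:
    """A canonical structure and the raw SMILES it came from."""

    smiles_std: str
    parent_of: str


@dataclass
class CuratedEntry:
    """One compound after replicate aggregation.

    ``pic50`` is -log10 of the mean IC50 expressed in molar units.
    ``fold_range`` is max/min over the replicate IC50s; replicates that
    disagree by more than 3-fold are flagged (``consistent=False``) for
    manual review rather than dropped.
    """

    smiles_std: str
    pic50: float
    n_replicates: int
    fold_range: float
    consistent: bool
    sources: frozenset = field(default_factory=frozenset)
    compound_id: Optional[str] = None

    def __post_init__(self):
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")
        if self.fold_range < 1:
            raise ValidationError("fold_range must be >= 1")
        if self.consistent != (self.fold_range <= 3.0):
            raise ValidationError("consistent flag must equal fold_range <= 3")
        if not isinstance(self.sources, frozenset):
            self.sources = frozenset(self.sources)


@dataclass
class RunConfig:
    """Plumbing knobs for a pipeline run."""

    seed: int = 0
    n_splits: int = 10
    split_ratio: float = 0.9
    thresholds: tuple = (5.0, 5.5, 6.0, 6.5, 7.0)
    geometric_mean: bool = False          # averaging scale for replicates
    normalize_binary: bool = False        # z-score binary fingerprint bits too
    selection_mode: str = "per_split"     # or "global"
    exclusion_ids: tuple = ()             # reference inhibitors to drop

    def __post_init__(self):
        if not (0.0 < self.split_ratio < 1.0):
            raise ValidationError("split_ratio must be in (0, 1)")
        th = tuple(float(t) for t in self.thresholds)
        if any(b <= a for a, b in zip(th, th[1:])):
            raise ValidationError("thresholds must be strictly increasing")
        self.thresholds = th
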