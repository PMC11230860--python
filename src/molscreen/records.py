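"""Core record types: molecules with activity annotations and labeled datasets.

A :class:`MoleculeRecord` is one compound — an identifier, a SMILES string,
and optionally an inhibitory constant Ki (nM), a binary activity label, and
the protein target the annotation refers to.  A :class:`LabeledDataset` is a
deduplicated, fully labeled collection of records for one target, the unit
the per-target models train on.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from rdkit import Chem
from rdkit import RDLogger

# RDKit is chatty about every rejected SMILES; callers get explicit errors
# or drop-reports instead.
RDLogger.DisableLog("rdApp.*")

ACTIVE = 1
INACTIVE = 0


class InvalidSmilesError(ValueError):
    """A SMILES string that RDKit cannot parse into a molecule."""

    def __init__(self, smiles: str, context: str = ""):
        self.smiles = smiles
        msg = f"invalid SMILES: {smiles!r}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


def canonical_smiles(smiles: str) -> str:
    """Return RDKit's canonical SMILES, raising on unparseable input.

    Canonicalization is the fixed equality notion for deduplication and
    disjointness checks throughout the package: two spellings of the same
    molecule compare equal, raw-string comparison would not.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(smiles)
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class MoleculeRecord:
    """One compound with optional activity annotation.

    Parameters
    ----------
    id : str
        Opaque identifier (e.g. a database accession or a generated tag).
    smiles : str
        Non-empty SMILES string.
    ki_nM : float, optional
        Inhibitory constant in nanomolar; must be positive when present.
        Lower values denote stronger binding.
    label : int, optional
        Binary activity: 1 = active, 0 = inactive.
    target : str, optional
        The protein target the annotation refers to (e.g. "SERT").
    """

    id: str
    smiles: str
    ki_nM: float | None = None
    label: int | None = None
    target: str | None = None

    def __post_init__(self):
        if not self.smiles:
            raise ValueError(f"record {self.id!r}: empty SMILES")
        if self.ki_nM is not None and not self.ki_nM > 0:
            raise ValueError(f"record {self.id!r}: ki_nM must be > 0, got {self.ki_nM}")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"record {self.id!r}: label must be 0 or 1, got {self.label}")

    def with_label(self, label: int) -> "MoleculeRecord":
        return replace(self, label=label)


class DuplicateClassConflictError(ValueError):
    """The same molecule appears with both active and inactive labels."""


@dataclass
class LabeledDataset:
    """A fully labeled, canonically deduplicated set of molecules for one target.

    Invariants (checked at construction): every record carries a label, and
    no two records share a canonical SMILES.
    """

    records: list[MoleculeRecord]
    target: str
    _canonical: list[str] = field(default_factory=list, repr=False)

    def __post_init__(self):
        if not self._canonical:
            self._canonical = [canonical_smiles(r.smiles) for r in self.records]
        seen: dict[str, str] = {}
        for rec, can in zip(self.records, self._canonical):
            if rec.label is None:
                raise ValueError(f"record {rec.id!r} in dataset {self.target!r} lacks a label")
            if can in seen:
                raise ValueError(
                    f"duplicate canonical SMILES in dataset {self.target!r}: "
                    f"{rec.id!r} duplicates {seen[can]!r}"
                )
            seen[can] = rec.id

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def labels(self) -> list[int]:
        return [r.label for r in self.records]  # type: ignore[misc]

    @property
    def smiles(self) -> list[str]:
        return [r.smiles for r in self.records]

    @property
    def canonical(self) -> list[str]:
        return list(self._canonical)

    def subset(self, indices: Sequence[int]) -> "LabeledDataset":
        return LabeledDataset(
            records=[self.records[i] for i in indices],
            target=self.target,
            _canonical=[self._canonical[i] for i in indices],
        )

    def class_counts(self) -> tuple[int, int]:
        """(n_active, n_inactive)."""
        labs = self.labels
        return sum(1 for x in labs if x == ACTIVE), sum(1 for x in labs if x == INACTIVE)


def unique_by_canonical(records: Iterable[MoleculeRecord]) -> tuple[list[MoleculeRecord], int]:
    """Drop records whose canonical SMILES was already seen; return (kept, n_dropped)."""
    seen: set[str] = set()
    kept: list[MoleculeRecord] = []
    dropped = 0
    for rec in records:
        can = canonical_smiles(rec.smiles)
        if can in seen:
            dropped += 1
        else:
            seen.add(can)
            kept.append(rec)
    return kept, dropped
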