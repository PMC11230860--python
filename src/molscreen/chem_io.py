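"""Reading and writing molecule tables and assembling labeled training sets.

Activity tables arrive as CSV (``id,smiles,target,ki_nM,label`` by default,
remappable via :class:`ColumnMap`).  Filtering follows the potency rule used
for training-set curation: a compound is an *active* when its inhibitory
constant satisfies Ki <= threshold (boundary inclusive), with thresholds
stated in nM.  Ki values in other units are converted to nM at read time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .records import (
    ACTIVE,
    INACTIVE,
    DuplicateClassConflictError,
    InvalidSmilesError,
    LabeledDataset,
    MoleculeRecord,
    canonical_smiles,
    unique_by_canonical,
)

logger = logging.getLogger(__name__)

#: Exact scale factors to nanomolar for the units column, when present.
KI_UNIT_TO_NM = {"nM": 1.0, "uM": 1e3, "µM": 1e3, "mM": 1e6, "M": 1e9}


class FormatError(ValueError):
    """A table is missing a mandatory column or is otherwise malformed."""


@dataclass
class ColumnMap:
    """Mapping from table columns to record fields.  ``id`` and ``smiles`` are mandatory."""

    id: str = "id"
    smiles: str = "smiles"
    target: str | None = "target"
    ki: str | None = "ki_nM"
    label: str | None = "label"
    ki_units: str | None = None  # optional units column (nM/uM/mM/M)


@dataclass
class ReadReport:
    """What happened while reading a table: kept rows and dropped rows with reasons."""

    n_read: int = 0
    n_kept: int = 0
    dropped_rows: list[tuple[int, str]] = field(default_factory=list)  # (row number, reason)

    @property
    def n_dropped(self) -> int:
        return len(self.dropped_rows)


def read_molecule_table(
    path: str | Path,
    columns: ColumnMap | None = None,
) -> tuple[list[MoleculeRecord], ReadReport]:
    """Read a CSV of molecules into records, dropping unparseable rows.

    Rows whose SMILES RDKit rejects are dropped (not fatal) and reported with
    their 1-based data-row numbers.  Missing mandatory columns raise
    :class:`FormatError`; an empty data section returns an empty list with a
    logged warning.
    """
    columns = columns or ColumnMap()
    path = Path(path)
    # round_trip float parsing so write->read preserves Ki values bit-exactly
    df = pd.read_csv(path, float_precision="round_trip")
    report = ReadReport(n_read=len(df))
    for col in (columns.id, columns.smiles):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    if len(df) == 0:
        logger.warning("%s: empty data section", path)
        return [], report

    records: list[MoleculeRecord] = []
    for row_no, row in enumerate(df.itertuples(index=False), start=1):
        row_d = dict(zip(df.columns, row))
        smiles = row_d[columns.smiles]
        if not isinstance(smiles, str) or not smiles:
            report.dropped_rows.append((row_no, "empty SMILES"))
            continue
        try:
            canonical_smiles(smiles)
        except InvalidSmilesError:
            report.dropped_rows.append((row_no, f"unparseable SMILES {smiles!r}"))
            continue

        ki = _opt_float(row_d, columns.ki)
        if ki is not None and columns.ki_units and columns.ki_units in row_d:
            unit = str(row_d[columns.ki_units])
            if unit not in KI_UNIT_TO_NM:
                report.dropped_rows.append((row_no, f"unknown Ki unit {unit!r}"))
                continue
            ki *= KI_UNIT_TO_NM[unit]
        label = _opt_float(row_d, columns.label)
        target = row_d.get(columns.target) if columns.target else None
        records.append(
            MoleculeRecord(
                id=str(row_d[columns.id]),
                smiles=smiles,
                ki_nM=ki,
                label=None if label is None else int(label),
                target=None if target is None or pd.isna(target) else str(target),
            )
        )
    report.n_kept = len(records)
    if report.dropped_rows:
        logger.info(
            "%s: dropped %d of %d rows: %s", path, report.n_dropped, report.n_read,
            "; ".join(f"row {n}: {why}" for n, why in report.dropped_rows),
        )
    return records, report


def _opt_float(row: dict, col: str | None) -> float | None:
    if col is None or col not in row:
        return None
    val = row[col]
    if val is None or pd.isna(val):
        return None
    return float(val)


def write_molecule_table(records: list[MoleculeRecord], path: str | Path) -> None:
    """Write records as CSV with the canonical header ``id,smiles,target,ki_nM,label``."""
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "smiles": [r.smiles for r in records],
            "target": [r.target for r in records],
            "ki_nM": [r.ki_nM for r in records],
            "label": [r.label for r in records],
        }
    )
    df.to_csv(path, index=False)


def write_smiles_file(records: list[MoleculeRecord], path: str | Path) -> None:
    """Write one ``smiles<TAB>id`` line per record."""
    with open(path, "w") as fh:
        for r in records:
            fh.write(f"{r.smiles}\t{r.id}\n")


def filter_actives(
    records: list[MoleculeRecord], ki_threshold_nM: float
) -> list[MoleculeRecord]:
    """Keep records with a measured Ki <= threshold (nM), order preserved.

    The boundary is inclusive: a compound with Ki exactly at the threshold
    counts as active.  Records without a Ki measurement are excluded and
    counted in the log.
    """
    if not ki_threshold_nM > 0:
        raise ValueError(f"ki_threshold_nM must be > 0, got {ki_threshold_nM}")
    missing = sum(1 for r in records if r.ki_nM is None)
    if missing:
        logger.info("filter_actives: %d records lack a Ki value and were excluded", missing)
    return [r for r in records if r.ki_nM is not None and r.ki_nM <= ki_threshold_nM]


def assemble_training_set(
    actives: list[MoleculeRecord],
    decoys: list[MoleculeRecord],
    target: str,
) -> LabeledDataset:
    """Label actives 1 and decoys 0, deduplicate by canonical SMILES, and bundle.

    A molecule appearing in both classes is a curation contradiction and
    raises :class:`DuplicateClassConflictError` naming it.
    """
    if not actives or not decoys:
        raise ValueError("assemble_training_set: both classes must be non-empty")
    act, act_dropped = unique_by_canonical(actives)
    dec, dec_dropped = unique_by_canonical(decoys)
    if act_dropped or dec_dropped:
        logger.info(
            "assemble_training_set(%s): removed %d duplicate actives, %d duplicate decoys",
            target, act_dropped, dec_dropped,
        )
    act_can = {canonical_smiles(r.smiles): r for r in act}
    for r in dec:
        can = canonical_smiles(r.smiles)
        if can in act_can:
            raise DuplicateClassConflictError(
                f"molecule present in both classes for target {target!r}: "
                f"active {act_can[can].id!r} vs decoy {r.id!r} ({can})"
            )
    records = [r.with_label(ACTIVE) for r in act] + [r.with_label(INACTIVE) for r in dec]
    return LabeledDataset(records=records, target=target)


def assert_disjoint(
    train: LabeledDataset, external: list[MoleculeRecord]
) -> set[str]:
    """Canonical-SMILES collisions between a training set and an external library.

    Returns the collision set; empty means the external-validation rule —
    no validation compound may appear in training — holds.  The caller
    decides whether collisions are fatal.
    """
    train_can = set(train.canonical)
    return {canonical_smiles(r.smiles) for r in external} & train_can
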