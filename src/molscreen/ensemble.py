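"""Ensemble scoring across the three target models and library screening.

The ensemble score of a molecule is the unweighted arithmetic mean of its
per-target binding-likelihood scores:

    ensemble = (score_SERT + score_D2 + score_NMDA) / 3

A molecule is called positive when its score reaches the decision threshold
(default 0.5, boundary inclusive: score == threshold is positive).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import AffinityResults
from .records import MoleculeRecord


class MissingScoreError(ValueError):
    """A sub-score is absent; the ensemble never imputes."""


@dataclass(frozen=True)
class TargetScoreTriplet:
    """Per-target scores for one molecule, each in [0, 1]."""

    molecule_id: str
    score_sert: float
    score_d2: float
    score_nmda: float

    def __post_init__(self):
        for name in ("score_sert", "score_d2", "score_nmda"):
            v = getattr(self, name)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                raise MissingScoreError(f"{self.molecule_id}: missing {name}")
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.molecule_id}: {name}={v} outside [0, 1]")


@dataclass
class ScreeningConfig:
    """Decision threshold for binarizing ensemble scores."""

    threshold: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError(f"threshold must be in [0, 1], got {self.threshold}")


def ensemble_score(triplet: TargetScoreTriplet) -> float:
    """Arithmetic mean of the three per-target scores."""
    return (triplet.score_sert + triplet.score_d2 + triplet.score_nmda) / 3.0


def classify(score: float, cfg: ScreeningConfig | None = None) -> int:
    """1 if score >= threshold else 0 (boundary inclusive)."""
    cfg = cfg or ScreeningConfig()
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score must be in [0, 1], got {score}")
    return int(score >= cfg.threshold)


class EnsembleScreener:
    """Three fitted per-target models combined into one screening tool.

    Parameters
    ----------
    models : dict
        Target name -> :class:`AffinityResults`.  All models must share a
        featurization vocabulary.  Score columns in outputs follow the
        given target order.
    """

    def __init__(self, models: dict[str, AffinityResults]):
        if len(models) < 2:
            raise ValueError("an ensemble needs at least two models")
        specs = {m.feature_spec for m in models.values()}
        if len(specs) != 1:
            raise ValueError(f"models use incompatible feature specs: {specs}")
        self.models = dict(models)
        self.targets = list(models)

    def screen(
        self,
        library: list[MoleculeRecord],
        cfg: ScreeningConfig | None = None,
    ) -> tuple[pd.DataFrame, list[MoleculeRecord]]:
        """Score a library with every model and rank by ensemble score.

        Returns ``(table, rejects)``: the table has one row per parseable
        molecule with per-target scores, the ensemble mean, and the binary
        prediction, sorted by descending ensemble score with ties broken by
        molecule id (stable ranking); rejects are molecules whose SMILES no
        model could parse, excluded from the ranking.
        """
        cfg = cfg or ScreeningConfig()
        if not library:
            return self._empty_table(), []
        per_target = {}
        reject_pos: set[int] = set()
        for t, model in self.models.items():
            scores, rejects = model.predict_with_report(library)
            per_target[t] = scores
            reject_pos |= {i for i, _ in rejects}
        rows = []
        for i, rec in enumerate(library):
            if i in reject_pos:
                continue
            scores = {t: float(per_target[t][i]) for t in self.targets}
            ens = sum(scores.values()) / len(scores)
            rows.append({
                "id": rec.id,
                "smiles": rec.smiles,
                **{f"score_{t.lower()}": s for t, s in scores.items()},
                "ensemble": ens,
                "prediction": int(ens >= cfg.threshold),
                **({"label": rec.label} if rec.label is not None else {}),
            })
        table = pd.DataFrame(rows)
        if not table.empty:
            table = table.sort_values(
                ["ensemble", "id"], ascending=[False, True], kind="mergesort"
            ).reset_index(drop=True)
        return table, [library[i] for i in sorted(reject_pos)]

    def _empty_table(self) -> pd.DataFrame:
        cols = ["id", "smiles", *(f"score_{t.lower()}" for t in self.targets),
                "ensemble", "prediction"]
        return pd.DataFrame(columns=cols)

    def summary_counts(
        self, table: pd.DataFrame, thresholds: list[float]
    ) -> dict[float, int]:
        """Number of library molecules at or above each threshold."""
        if table.empty:
            return {th: 0 for th in thresholds}
        ens = table["ensemble"].to_numpy()
        return {th: int((ens >= th).sum()) for th in thresholds}


def screen_library(
    models: dict[str, AffinityResults],
    library: list[MoleculeRecord],
    cfg: ScreeningConfig | None = None,
) -> tuple[pd.DataFrame, list[MoleculeRecord]]:
    """Functional wrapper over :class:`EnsembleScreener`."""
    return EnsembleScreener(models).screen(library, cfg)


def write_screen_outputs(
    table: pd.DataFrame,
    thresholds: list[float],
    out_csv: str | Path,
    out_json: str | Path | None = None,
) -> None:
    """Write the ranked table as CSV and per-threshold counts as JSON."""
    table.to_csv(out_csv, index=False)
    if out_json is not None:
        ens = table["ensemble"].to_numpy() if not table.empty else np.array([])
        counts = {str(th): int((ens >= th).sum()) for th in thresholds}
        Path(out_json).write_text(json.dumps(
            {"n_molecules": int(len(table)), "positives_at_threshold": counts},
            indent=1,
        ))
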