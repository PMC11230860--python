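"""Synthetic active/decoy populations and an imbalanced screening library.

Real curation for this kind of study draws potent actives (Ki below a
nanomolar threshold) from an affinity database, guaranteed non-binders from
a decoy database, and an external screening library dominated by negatives.
None of those sources deposit a reusable snapshot, so this module generates
populations with the same statistical structure and known ground truth:

* **actives** for a target all contain a target-specific substructure motif
  (a distinct ring system per target, standing in for a pharmacophore) and
  carry potent Ki values;
* **decoys** are built on motif-free scaffolds, verified by substructure
  search to contain no target's motif, and carry weak Ki values;
* the **screening library** mixes motif-bearing positives and motif-free
  negatives at the study's imbalance (154 : 5744 by default), guaranteed
  canonically disjoint from every training molecule of the same spec.

Molecules are constructed by attaching random small decorations (alkyl,
halogen, hydroxyl, amine, ...) to a scaffold with RDKit, so the populations
are chemically valid, diverse, and deterministically reproducible from
(spec, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from rdkit import Chem

from .chem_io import assemble_training_set, write_molecule_table
from .records import ACTIVE, INACTIVE, LabeledDataset, MoleculeRecord, canonical_smiles

#: Target -> motif: three distinct fused ring systems so the three models
#: must learn three different functions.
DEFAULT_MOTIFS = {
    "SERT": "c1ccc2[nH]ccc2c1",   # indole
    "D2": "n1ccc2ccccc2c1",       # quinoline
    "NMDA": "c1ccc2occc2c1",      # benzofuran
}

#: Active/decoy counts of the reference study design.
DEFAULT_N_ACTIVES = {"SERT": 200, "D2": 200, "NMDA": 152}
DEFAULT_N_DECOYS = {"SERT": 200, "D2": 200, "NMDA": 150}

#: Motif-free scaffolds the decoys and screen negatives grow from.
DECOY_SCAFFOLDS = (
    "C1CCCCC1", "c1ccccc1", "c1ccncc1", "C1CCOC1", "C1CCNCC1",
    "CCCCC", "CC(C)CC", "C1CCCC1", "CCOCC", "CC(C)(C)C", "c1ccsc1",
    "C1CCNC1",
)

#: Small substituents attached at random positions.
DECORATIONS = (
    "C", "CC", "CCC", "C(C)C", "O", "OC", "N", "NC", "F", "Cl", "Br",
    "C(=O)C", "C(=O)O", "C#N", "CO", "CN", "S", "CF",
)


class ConfigurationError(ValueError):
    """The synthetic spec is internally inconsistent (e.g. an invalid motif)."""


class GenerationError(RuntimeError):
    """The requested population cannot be generated (e.g. disjointness
    impossible at the requested sizes)."""


def _as_target_counts(value, targets) -> dict[str, int]:
    if isinstance(value, dict):
        return {t: int(value.get(t, 0)) for t in targets}
    return {t: int(value) for t in targets}


@dataclass
class SyntheticSpec:
    """Declarative description of the synthetic study populations.

    Parameters
    ----------
    motif_per_target : dict
        Target name -> motif SMILES; actives for a target contain its motif
        as a substructure, decoys and screen negatives contain none.
    n_actives, n_decoys : int or dict
        Per-target counts (an int applies to every target).
    n_screen_pos, n_screen_neg : int
        Screening-library composition (default 154 positives, 5744
        negatives, the reference study's imbalance).
    ki_range_active, ki_range_inactive : (low, high) in nM
        Ki values are sampled log-uniformly within these intervals; the
        active interval must lie strictly below the inactive one (actives
        are more potent, i.e. lower Ki).
    seed : int
        Root seed; every generated population is a pure function of
        (spec, seed).
    """

    motif_per_target: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_MOTIFS))
    n_actives: dict[str, int] | int = field(default_factory=lambda: dict(DEFAULT_N_ACTIVES))
    n_decoys: dict[str, int] | int = field(default_factory=lambda: dict(DEFAULT_N_DECOYS))
    n_screen_pos: int = 154
    n_screen_neg: int = 5744
    ki_range_active: tuple[float, float] = (0.1, 10.0)
    ki_range_inactive: tuple[float, float] = (1_000.0, 100_000.0)
    seed: int = 0

    def __post_init__(self):
        targets = list(self.motif_per_target)
        if not targets:
            raise ConfigurationError("motif_per_target must not be empty")
        self.n_actives = _as_target_counts(self.n_actives, targets)
        self.n_decoys = _as_target_counts(self.n_decoys, targets)
        for name, count in {**self.n_actives, **self.n_decoys,
                            "n_screen_pos": self.n_screen_pos,
                            "n_screen_neg": self.n_screen_neg}.items():
            if count < 0:
                raise ConfigurationError(f"count {name} must be >= 0, got {count}")
        lo_a, hi_a = self.ki_range_active
        lo_i, hi_i = self.ki_range_inactive
        if not (0 < lo_a <= hi_a and 0 < lo_i <= hi_i):
            raise ConfigurationError("Ki ranges must be positive intervals")
        if hi_a > lo_i:
            raise ConfigurationError(
                f"active Ki range {self.ki_range_active} must lie below "
                f"inactive range {self.ki_range_inactive}"
            )
        for target, motif in self.motif_per_target.items():
            if Chem.MolFromSmiles(motif) is None:
                raise ConfigurationError(f"invalid motif SMILES for {target!r}: {motif!r}")

    @property
    def targets(self) -> list[str]:
        return list(self.motif_per_target)

    def motif_queries(self) -> dict[str, Chem.Mol]:
        return {t: Chem.MolFromSmiles(m) for t, m in self.motif_per_target.items()}

    def scaled(self, factor: float) -> "SyntheticSpec":
        """A proportionally smaller (or larger) spec for fast runs; every
        nonzero count stays at least 1."""
        def sc(n: int) -> int:
            return 0 if n == 0 else max(1, int(round(n * factor)))
        return replace(
            self,
            n_actives={t: sc(n) for t, n in self.n_actives.items()},
            n_decoys={t: sc(n) for t, n in self.n_decoys.items()},
            n_screen_pos=sc(self.n_screen_pos),
            n_screen_neg=sc(self.n_screen_neg),
        )

    def to_dict(self) -> dict:
        return {
            "motif_per_target": self.motif_per_target,
            "n_actives": self.n_actives,
            "n_decoys": self.n_decoys,
            "n_screen_pos": self.n_screen_pos,
            "n_screen_neg": self.n_screen_neg,
            "ki_range_active": list(self.ki_range_active),
            "ki_range_inactive": list(self.ki_range_inactive),
            "seed": self.seed,
        }


# ----- molecule construction ----------------------------------------------

def _attach_decorations(scaffold: Chem.Mol, rng: np.random.Generator) -> str | None:
    """Attach 1-4 random substituents at random positions; canonical SMILES
    or None when the random choice produced an unsanitizable molecule."""
    mol = Chem.RWMol(scaffold)
    n_dec = int(rng.integers(1, 5))
    for _ in range(n_dec):
        sites = [a.GetIdx() for a in mol.GetAtoms() if a.GetTotalNumHs() > 0]
        if not sites:
            break
        site = int(rng.choice(sites))
        frag = Chem.MolFromSmiles(DECORATIONS[int(rng.integers(len(DECORATIONS)))])
        offset = mol.GetNumAtoms()
        mol = Chem.RWMol(Chem.CombineMols(mol, frag))
        mol.AddBond(site, offset, Chem.BondType.SINGLE)
    out = mol.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception:
        return None
    return Chem.MolToSmiles(out)


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(math.exp(rng.uniform(math.log(lo), math.log(hi))))


def _grow_population(
    n: int,
    scaffolds: list[Chem.Mol],
    rng: np.random.Generator,
    accept,
    exclude: set[str],
    what: str,
) -> list[str]:
    """Generate n unique canonical SMILES passing ``accept``, avoiding
    ``exclude``; raises GenerationError if the space is exhausted."""
    out: list[str] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = 200 * n + 1000
    while len(out) < n:
        attempts += 1
        if attempts > max_attempts:
            raise GenerationError(
                f"could not generate {n} unique {what} after {attempts} attempts "
                f"({len(out)} found); requested size or disjointness may be infeasible"
            )
        scaffold = scaffolds[int(rng.integers(len(scaffolds)))]
        smi = _attach_decorations(scaffold, rng)
        if smi is None or smi in seen or smi in exclude:
            continue
        mol = Chem.MolFromSmiles(smi)
        if mol is None or not accept(mol):
            continue
        seen.add(smi)
        out.append(smi)
    return out


def _rng_for(spec: SyntheticSpec, role: str, target: str = "") -> np.random.Generator:
    """Independent, reproducible stream per (spec.seed, role, target)."""
    digest = [ord(c) for c in f"{role}/{target}"]
    return np.random.default_rng(np.random.SeedSequence([spec.seed, *digest]))


# ----- public generators ---------------------------------------------------

def generate_actives(
    spec: SyntheticSpec, target: str, _exclude: set[str] | None = None
) -> list[MoleculeRecord]:
    """Active molecules for one target: all contain its motif, Ki sampled
    log-uniformly within the potent range, labels set active."""
    if target not in spec.motif_per_target:
        raise ConfigurationError(f"unknown target {target!r}; have {spec.targets}")
    n = spec.n_actives[target]
    if n == 0:
        return []
    rng = _rng_for(spec, "actives", target)
    motif = Chem.MolFromSmiles(spec.motif_per_target[target])
    smiles = _grow_population(
        n, [motif], rng,
        accept=lambda m: m.HasSubstructMatch(motif),
        exclude=_exclude or set(),
        what=f"actives for {target}",
    )
    return [
        MoleculeRecord(
            id=f"{target}-act-{i:04d}", smiles=s,
            ki_nM=_log_uniform(rng, *spec.ki_range_active),
            label=ACTIVE, target=target,
        )
        for i, s in enumerate(smiles)
    ]


def generate_decoys(
    spec: SyntheticSpec, target: str | None = None, _exclude: set[str] | None = None
) -> list[MoleculeRecord]:
    """Guaranteed-inactive molecules: motif-free against *every* target's
    motif (verified by substructure search), weak Ki, labels inactive.

    ``target`` selects the per-target decoy count (and id prefix); omitted,
    one pooled set of the summed size is produced.
    """
    targets = [target] if target is not None else [None]
    if target is not None and target not in spec.motif_per_target:
        raise ConfigurationError(f"unknown target {target!r}; have {spec.targets}")
    n = spec.n_decoys[target] if target else sum(spec.n_decoys.values())
    if n == 0:
        return []
    rng = _rng_for(spec, "decoys", target or "<all>")
    queries = list(spec.motif_queries().values())
    scaffolds = [Chem.MolFromSmiles(s) for s in DECOY_SCAFFOLDS]
    smiles = _grow_population(
        n, scaffolds, rng,
        accept=lambda m: not any(m.HasSubstructMatch(q) for q in queries),
        exclude=_exclude or set(),
        what="decoys",
    )
    prefix = f"{target}-dec" if target else "dec"
    return [
        MoleculeRecord(
            id=f"{prefix}-{i:04d}", smiles=s,
            ki_nM=_log_uniform(rng, *spec.ki_range_inactive),
            label=INACTIVE, target=target,
        )
        for i, s in enumerate(smiles)
    ]


def _training_canonicals(spec: SyntheticSpec) -> set[str]:
    cans: set[str] = set()
    for t in spec.targets:
        for rec in generate_actives(spec, t):
            cans.add(canonical_smiles(rec.smiles))
        for rec in generate_decoys(spec, t):
            cans.add(canonical_smiles(rec.smiles))
    return cans


def generate_screening_library(
    spec: SyntheticSpec, _training_smiles: set[str] | None = None
) -> list[MoleculeRecord]:
    """The imbalanced external screen: motif-bearing positives (cycling
    through the targets' motifs) and motif-free negatives, shuffled, with
    ground-truth labels, canonically disjoint from every training molecule
    the same spec generates."""
    exclude = (
        set(_training_smiles) if _training_smiles is not None
        else _training_canonicals(spec)
    )
    rng = _rng_for(spec, "screen")
    queries = spec.motif_queries()
    records: list[MoleculeRecord] = []

    if spec.n_screen_pos:
        targets = spec.targets
        pos_rng = _rng_for(spec, "screen-pos")
        per_target = np.array_split(np.arange(spec.n_screen_pos), len(targets))
        idx = 0
        for t, chunk in zip(targets, per_target):
            if len(chunk) == 0:
                continue
            motif = Chem.MolFromSmiles(spec.motif_per_target[t])
            already = exclude | {canonical_smiles(r.smiles) for r in records}
            smiles = _grow_population(
                len(chunk), [motif], pos_rng,
                accept=lambda m, q=queries[t]: m.HasSubstructMatch(q),
                exclude=already,
                what=f"screen positives ({t})",
            )
            for s in smiles:
                records.append(MoleculeRecord(
                    id=f"pos-{idx:04d}", smiles=s, label=ACTIVE, target=t))
                idx += 1

    if spec.n_screen_neg:
        neg_rng = _rng_for(spec, "screen-neg")
        scaffolds = [Chem.MolFromSmiles(s) for s in DECOY_SCAFFOLDS]
        already = exclude | {canonical_smiles(r.smiles) for r in records}
        smiles = _grow_population(
            spec.n_screen_neg, scaffolds, neg_rng,
            accept=lambda m: not any(m.HasSubstructMatch(q) for q in queries.values()),
            exclude=already,
            what="screen negatives",
        )
        records += [
            MoleculeRecord(id=f"neg-{i:04d}", smiles=s, label=INACTIVE)
            for i, s in enumerate(smiles)
        ]

    order = rng.permutation(len(records))
    return [records[i] for i in order]


@dataclass
class SyntheticStudy:
    """All populations of one synthetic study: per-target training sets and
    the external screening library."""

    spec: SyntheticSpec
    training: dict[str, LabeledDataset]
    screen: list[MoleculeRecord]


def generate_study(spec: SyntheticSpec) -> SyntheticStudy:
    """Generate everything from one spec, with training/screen disjointness
    enforced by construction."""
    training: dict[str, LabeledDataset] = {}
    cans: set[str] = set()
    for t in spec.targets:
        actives = generate_actives(spec, t)
        decoys = generate_decoys(spec, t)
        training[t] = assemble_training_set(actives, decoys, t)
        cans |= set(training[t].canonical)
    screen = generate_screening_library(spec, _training_smiles=cans)
    return SyntheticStudy(spec=spec, training=training, screen=screen)


def write_study(study: SyntheticStudy, outdir: str | Path) -> dict[str, Path]:
    """Write training CSVs, the screen CSV, and a JSON provenance sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for t, ds in study.training.items():
        p = outdir / f"train_{t}.csv"
        write_molecule_table(ds.records, p)
        paths[f"train_{t}"] = p
    p = outdir / "screen.csv"
    write_molecule_table(study.screen, p)
    paths["screen"] = p
    sidecar = outdir / "spec.json"
    sidecar.write_text(json.dumps(study.spec.to_dict(), indent=1))
    paths["spec"] = sidecar
    return paths
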