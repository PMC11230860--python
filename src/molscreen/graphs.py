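"""SMILES -> molecular graph -> the four-block feature encoding the MPNN consumes.

A molecule is represented by four objects: an atom feature matrix, a
directed-arc (bond) feature matrix, the incoming-arc list of every atom, and
for every directed arc the list of arcs feeding its source atom (excluding
its own reverse).  Each chemical bond expands to two directed arcs so
message passing is directional.

Feature vocabularies (fixed across a dataset; molecules outside them fall
into catch-all slots, never exceptions):

* atom: element one-hot over {C,N,O,S,F,Cl,Br,I,P,other} (+) degree one-hot
  0-5 (+) formal charge one-hot clipped to [-2,2] (+) aromatic flag (+)
  hybridization one-hot {sp,sp2,sp3,other}  -> 26 dims
* bond: order one-hot {single,double,triple,aromatic} (+) conjugated (+)
  in-ring  -> 6 dims

Hydrogens are implicit (heavy atoms only), the SMILES convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from .records import InvalidSmilesError

logger = logging.getLogger(__name__)

ELEMENTS = ("C", "N", "O", "S", "F", "Cl", "Br", "I", "P")  # + "other"
MAX_DEGREE = 5
CHARGE_RANGE = (-2, 2)
HYBRIDIZATIONS = (
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
)  # + "other"
BOND_ORDERS = (
    Chem.BondType.SINGLE,
    Chem.BondType.DOUBLE,
    Chem.BondType.TRIPLE,
    Chem.BondType.AROMATIC,
)

ATOM_FDIM = len(ELEMENTS) + 1 + (MAX_DEGREE + 1) + 5 + 1 + len(HYBRIDIZATIONS) + 1  # 26
BOND_FDIM = len(BOND_ORDERS) + 2  # 6

#: Identifier for the vocabulary above; persisted with trained models so a
#: model can refuse inputs featurized under a different scheme.
FEATURE_SPEC = f"molscreen-v1:atom{ATOM_FDIM}:bond{BOND_FDIM}"


@dataclass(frozen=True)
class AtomDescriptor:
    element: str
    degree: int
    formal_charge: int
    aromatic: bool
    hybridization: str


@dataclass(frozen=True)
class BondDescriptor:
    order: str  # single/double/triple/aromatic/other
    conjugated: bool
    in_ring: bool
    begin: int
    end: int


@dataclass
class MolGraph:
    """Chemical-level (undirected) graph of one molecule."""

    atoms: list[AtomDescriptor]
    bonds: list[BondDescriptor]

    def __post_init__(self):
        n = len(self.atoms)
        if n < 1:
            raise ValueError("MolGraph must have at least one atom")
        for b in self.bonds:
            if not (0 <= b.begin < n and 0 <= b.end < n):
                raise ValueError(f"bond endpoints out of range: {b}")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_bonds(self) -> int:
        return len(self.bonds)


@dataclass
class GraphFeatures:
    """The four-block MPNN input for one molecule.

    ``atom_features``  (n_atoms, ATOM_FDIM); ``bond_features``
    (2*n_bonds, BOND_FDIM) — arc 2k is bond k traversed begin->end, arc 2k+1
    its reverse; ``atom_neighbors[v]`` lists the arcs pointing *into* atom v;
    ``bond_neighbors[e]`` lists the arcs feeding arc e's source atom,
    excluding e's own reverse.
    """

    atom_features: np.ndarray
    bond_features: np.ndarray
    atom_neighbors: list[list[int]]
    bond_neighbors: list[list[int]]
    arc_src: np.ndarray  # (2*n_bonds,) source atom of each arc
    arc_dst: np.ndarray  # (2*n_bonds,) destination atom
    arc_rev: np.ndarray  # (2*n_bonds,) index of the reverse arc

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_arcs(self) -> int:
        return self.bond_features.shape[0]


def parse_smiles(smiles: str) -> MolGraph:
    """Parse a SMILES string into a :class:`MolGraph` (heavy atoms only).

    Syntactically or chemically invalid input raises
    :class:`InvalidSmilesError` carrying the offending string.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(smiles, "parse_smiles")
    return mol_to_graph(mol)


def mol_to_graph(mol: Chem.Mol) -> MolGraph:
    atoms = [
        AtomDescriptor(
            element=a.GetSymbol(),
            degree=a.GetDegree(),
            formal_charge=a.GetFormalCharge(),
            aromatic=a.GetIsAromatic(),
            hybridization=str(a.GetHybridization()),
        )
        for a in mol.GetAtoms()
    ]
    order_names = {
        Chem.BondType.SINGLE: "single",
        Chem.BondType.DOUBLE: "double",
        Chem.BondType.TRIPLE: "triple",
        Chem.BondType.AROMATIC: "aromatic",
    }
    bonds = [
        BondDescriptor(
            order=order_names.get(b.GetBondType(), "other"),
            conjugated=b.GetIsConjugated(),
            in_ring=b.IsInRing(),
            begin=b.GetBeginAtomIdx(),
            end=b.GetEndAtomIdx(),
        )
        for b in mol.GetBonds()
    ]
    return MolGraph(atoms=atoms, bonds=bonds)


_seen_other_elements: set[str] = set()


def _atom_row(a: AtomDescriptor) -> np.ndarray:
    row = np.zeros(ATOM_FDIM)
    off = 0
    if a.element in ELEMENTS:
        row[off + ELEMENTS.index(a.element)] = 1.0
    else:
        row[off + len(ELEMENTS)] = 1.0  # "other" slot
        if a.element not in _seen_other_elements:
            _seen_other_elements.add(a.element)
            logger.info("element %r outside vocabulary, using catch-all slot", a.element)
    off += len(ELEMENTS) + 1
    row[off + min(a.degree, MAX_DEGREE)] = 1.0
    off += MAX_DEGREE + 1
    charge = int(np.clip(a.formal_charge, *CHARGE_RANGE))
    row[off + charge - CHARGE_RANGE[0]] = 1.0
    off += 5
    row[off] = float(a.aromatic)
    off += 1
    hyb_names = ("SP", "SP2", "SP3")
    if a.hybridization in hyb_names:
        row[off + hyb_names.index(a.hybridization)] = 1.0
    else:
        row[off + len(hyb_names)] = 1.0
    return row


def _bond_row(b: BondDescriptor) -> np.ndarray:
    row = np.zeros(BOND_FDIM)
    order_names = ("single", "double", "triple", "aromatic")
    if b.order in order_names:
        row[order_names.index(b.order)] = 1.0
    row[4] = float(b.conjugated)
    row[5] = float(b.in_ring)
    return row


def featurize(graph: MolGraph) -> GraphFeatures:
    """Encode a :class:`MolGraph` into the four-block representation."""
    n_atoms = graph.n_atoms
    atom_features = np.array([_atom_row(a) for a in graph.atoms]).reshape(n_atoms, ATOM_FDIM)

    n_arcs = 2 * graph.n_bonds
    bond_features = np.zeros((n_arcs, BOND_FDIM))
    arc_src = np.zeros(n_arcs, dtype=np.int64)
    arc_dst = np.zeros(n_arcs, dtype=np.int64)
    arc_rev = np.zeros(n_arcs, dtype=np.int64)
    atom_neighbors: list[list[int]] = [[] for _ in range(n_atoms)]
    for k, b in enumerate(graph.bonds):
        row = _bond_row(b)
        fwd, bwd = 2 * k, 2 * k + 1
        bond_features[fwd] = row
        bond_features[bwd] = row
        arc_src[fwd], arc_dst[fwd] = b.begin, b.end
        arc_src[bwd], arc_dst[bwd] = b.end, b.begin
        arc_rev[fwd], arc_rev[bwd] = bwd, fwd
        atom_neighbors[b.end].append(fwd)
        atom_neighbors[b.begin].append(bwd)
    bond_neighbors = [
        [k for k in atom_neighbors[arc_src[e]] if k != arc_rev[e]] for e in range(n_arcs)
    ]
    return GraphFeatures(
        atom_features=atom_features,
        bond_features=bond_features,
        atom_neighbors=atom_neighbors,
        bond_neighbors=bond_neighbors,
        arc_src=arc_src,
        arc_dst=arc_dst,
        arc_rev=arc_rev,
    )


def featurize_smiles(smiles: str) -> GraphFeatures:
    return featurize(parse_smiles(smiles))


@dataclass
class PackedBatch:
    """Several molecules' features concatenated for vectorized message passing.

    Atom and arc indices are offset into shared arrays; ``atom_mol`` maps
    each atom row to its molecule so the readout can mean-pool per molecule.
    """

    atom_features: np.ndarray  # (N_atoms, ATOM_FDIM)
    bond_features: np.ndarray  # (N_arcs, BOND_FDIM)
    arc_src: np.ndarray
    arc_dst: np.ndarray
    arc_rev: np.ndarray
    atom_mol: np.ndarray  # (N_atoms,) molecule index
    n_mols: int

    @property
    def n_atoms(self) -> int:
        return self.atom_features.shape[0]

    @property
    def n_arcs(self) -> int:
        return self.bond_features.shape[0]


def pack(features: list[GraphFeatures]) -> PackedBatch:
    """Concatenate per-molecule features into one batch with offset indices."""
    if not features:
        raise ValueError("cannot pack an empty feature list")
    atom_blocks, bond_blocks = [], []
    src, dst, rev, atom_mol = [], [], [], []
    atom_off = arc_off = 0
    for i, f in enumerate(features):
        atom_blocks.append(f.atom_features)
        bond_blocks.append(f.bond_features)
        src.append(f.arc_src + atom_off)
        dst.append(f.arc_dst + atom_off)
        rev.append(f.arc_rev + arc_off)
        atom_mol.append(np.full(f.n_atoms, i, dtype=np.int64))
        atom_off += f.n_atoms
        arc_off += f.n_arcs
    return PackedBatch(
        atom_features=np.concatenate(atom_blocks, axis=0),
        bond_features=(
            np.concatenate(bond_blocks, axis=0)
            if arc_off
            else np.zeros((0, BOND_FDIM))
        ),
        arc_src=np.concatenate(src) if arc_off else np.zeros(0, dtype=np.int64),
        arc_dst=np.concatenate(dst) if arc_off else np.zeros(0, dtype=np.int64),
        arc_rev=np.concatenate(rev) if arc_off else np.zeros(0, dtype=np.int64),
        atom_mol=np.concatenate(atom_mol),
        n_mols=len(features),
    )
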