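"""Molecule parsing, fingerprints, descriptors and corpus file I/O.

Molecules are handled as attributed graphs over heavy atoms: nodes carry
(atomic number, chirality code), edges carry (bond type, bond direction).
Structural fingerprints are 166-bit MACCS keys; similarity between
fingerprints is the Tanimoto coefficient.  All chemistry primitives are
delegated to RDKit; this module fixes the feature vocabularies and the
graph container used by the rest of the package.
"""

from __future__ import annotations

import csv
import logging
import math
import os
import sys
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDConfig, RDLogger
from rdkit.Chem import Crippen, Descriptors, MACCSkeys, QED, rdMolDescriptors

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

# -- feature vocabularies -----------------------------------------------------

#: chirality codes: unspecified / clockwise / counter-clockwise / other
CHIRALITY_CODES = {
    Chem.ChiralType.CHI_UNSPECIFIED: 0,
    Chem.ChiralType.CHI_TETRAHEDRAL_CW: 1,
    Chem.ChiralType.CHI_TETRAHEDRAL_CCW: 2,
}
CHIRALITY_OTHER = 3
N_CHIRALITY = 4

#: bond type codes: single / double / triple / aromatic
BOND_TYPE_CODES = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}
N_BOND_TYPES = 4

#: bond direction codes: none / end-upward / end-downward
BOND_DIR_CODES = {
    Chem.BondDir.NONE: 0,
    Chem.BondDir.ENDUPRIGHT: 1,
    Chem.BondDir.ENDDOWNRIGHT: 2,
}
N_BOND_DIRS = 3

#: atomic-number embedding table size; index MASK_ATOM_CODE is reserved for the
#: mask token used by masked-graph augmentation and lies outside the chemical
#: vocabulary (no element has Z = 119 here).
MAX_ATOMIC_NUM = 118
MASK_ATOM_CODE = 119
N_ATOM_CODES = 120

FINGERPRINT_LENGTH = 166


class SmilesParseError(ValueError):
    """Raised for syntactically or chemically invalid SMILES."""


@dataclass(frozen=True)
class AtomFeature:
    atomic_number: int
    chirality: int

    def __post_init__(self):
        if not (1 <= self.atomic_number <= MAX_ATOMIC_NUM
                or self.atomic_number == MASK_ATOM_CODE):
            raise ValueError(f"atomic number {self.atomic_number} out of range")
        if self.chirality not in range(N_CHIRALITY):
            raise ValueError(f"chirality code {self.chirality} out of vocabulary")


@dataclass(frozen=True)
class BondFeature:
    bond_type: int
    direction: int

    def __post_init__(self):
        if self.bond_type not in range(N_BOND_TYPES):
            raise ValueError(f"bond type code {self.bond_type} out of vocabulary")
        if self.direction not in range(N_BOND_DIRS):
            raise ValueError(f"bond direction code {self.direction} out of vocabulary")


@dataclass
class MolecularGraph:
    """Undirected attributed graph over heavy atoms.

    Edges are stored once with ``u < v``; ``adjacency[v]`` lists the
    neighbours of node ``v`` in ascending index order.
    """

    nodes: list[AtomFeature]
    edges: list[tuple[int, int, BondFeature]]

    adjacency: list[list[int]] = field(init=False, repr=False)

    def __post_init__(self):
        n = len(self.nodes)
        if n < 1:
            raise ValueError("a molecular graph needs at least one atom")
        adj: list[list[int]] = [[] for _ in range(n)]
        seen = set()
        for u, v, _ in self.edges:
            if not (0 <= u < n and 0 <= v < n):
                raise ValueError(f"edge ({u},{v}) references a missing node")
            if u >= v:
                raise ValueError(f"edges must be stored once with u < v, got ({u},{v})")
            if (u, v) in seen:
                raise ValueError(f"duplicate edge ({u},{v})")
            seen.add((u, v))
            adj[u].append(v)
            adj[v].append(u)
        for lst in adj:
            lst.sort()
        self.adjacency = adj

    @property
    def n_atoms(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def edge_pairs(self) -> set[tuple[int, int]]:
        return {(u, v) for u, v, _ in self.edges}

    def degree_multiset(self) -> list[int]:
        return sorted(len(a) for a in self.adjacency)


@dataclass
class Molecule:
    smiles: str  # canonical form
    graph: MolecularGraph
    id: str


class Corpus(list):
    """A list of :class:`Molecule` that remembers how many input rows were skipped."""

    n_skipped: int = 0


# -- parsing ------------------------------------------------------------------

def _mol_to_graph(mol: Chem.Mol) -> MolecularGraph:
    nodes = []
    for atom in mol.GetAtoms():
        code = CHIRALITY_CODES.get(atom.GetChiralTag(), CHIRALITY_OTHER)
        nodes.append(AtomFeature(atom.GetAtomicNum(), code))
    edges = []
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        if u > v:
            u, v = v, u
        btype = BOND_TYPE_CODES.get(bond.GetBondType(), 0)
        bdir = BOND_DIR_CODES.get(bond.GetBondDir(), 0)
        edges.append((u, v, BondFeature(btype, bdir)))
    edges.sort(key=lambda e: (e[0], e[1]))
    return MolecularGraph(nodes, edges)


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    if len(frags) <= 1:
        return mol
    return max(frags, key=lambda m: m.GetNumHeavyAtoms())


def parse_smiles(smiles: str, mol_id: str | None = None,
                 keep_largest_fragment: bool = True) -> Molecule:
    """Parse a SMILES string into a :class:`Molecule` over heavy atoms.

    Multi-fragment inputs (salts, mixtures) are reduced to the largest
    fragment by default.  Raises :class:`SmilesParseError` on invalid input.
    """
    if not smiles or not smiles.strip():
        raise SmilesParseError("empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"invalid SMILES: {smiles!r}")
    if keep_largest_fragment:
        mol = _largest_fragment(mol)
    if mol.GetNumHeavyAtoms() < 1:
        raise SmilesParseError(f"no heavy atoms in {smiles!r}")
    canonical = Chem.MolToSmiles(mol)
    return Molecule(smiles=canonical, graph=_mol_to_graph(mol),
                    id=mol_id if mol_id is not None else canonical)


def to_rdkit(mol: Molecule) -> Chem.Mol:
    return Chem.MolFromSmiles(mol.smiles)


# -- fingerprints -------------------------------------------------------------

def compute_maccs(mol: Molecule | str) -> np.ndarray:
    """166-bit MACCS structural-key fingerprint as a uint8 0/1 vector.

    RDKit emits 167 bits with bit 0 permanently unset; it is dropped so the
    vector length matches the 166 defined keys.
    """
    if isinstance(mol, str):
        mol = parse_smiles(mol)
    rdmol = to_rdkit(mol)
    bv = MACCSkeys.GenMACCSKeys(rdmol)
    arr = np.zeros(167, dtype=np.uint8)
    for bit in bv.GetOnBits():
        arr[bit] = 1
    return arr[1:]


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity |a AND b| / |a OR b| between binary fingerprints.

    Two all-zero vectors are defined to have similarity 1.0.
    """
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    inter = int(np.sum((a != 0) & (b != 0)))
    union = int(np.sum((a != 0) | (b != 0)))
    if union == 0:
        return 1.0
    return inter / union


# -- descriptors --------------------------------------------------------------

DESCRIPTOR_NAMES = ("mol_logp", "mol_wt", "tpsa", "num_rotatable_bonds", "qed", "sa")

_sascorer = None


def _get_sascorer():
    global _sascorer
    if _sascorer is None:
        sa_dir = os.path.join(RDConfig.RDContribDir, "SA_Score")
        if sa_dir not in sys.path:
            sys.path.append(sa_dir)
        import sascorer  # noqa: PLC0415
        _sascorer = sascorer
    return _sascorer


@dataclass(frozen=True)
class DescriptorVector:
    """Physicochemical descriptors: Crippen logP, molecular weight (g/mol),
    topological polar surface area (A^2), rotatable-bond count, quantitative
    estimate of drug-likeness in [0,1], and synthetic accessibility (1-10).

    A descriptor whose computation fails is flagged as NaN rather than
    raising.
    """

    mol_logp: float
    mol_wt: float
    tpsa: float
    num_rotatable_bonds: float
    qed: float
    sa: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in DESCRIPTOR_NAMES], dtype=float)


def compute_descriptors(mol: Molecule | str) -> DescriptorVector:
    if isinstance(mol, str):
        mol = parse_smiles(mol)
    rdmol = to_rdkit(mol)

    def _safe(fn):
        try:
            return float(fn(rdmol))
        except Exception:  # descriptor-specific failure -> flagged missing
            return math.nan

    return DescriptorVector(
        mol_logp=_safe(Crippen.MolLogP),
        mol_wt=_safe(Descriptors.MolWt),
        tpsa=_safe(Descriptors.TPSA),
        num_rotatable_bonds=_safe(rdMolDescriptors.CalcNumRotatableBonds),
        qed=_safe(QED.qed),
        sa=_safe(lambda m: _get_sascorer().calculateScore(m)),
    )


# -- corpus I/O ---------------------------------------------------------------

def read_corpus(path: str, fmt: str | None = None,
                smiles_column: str = "smiles") -> Corpus:
    """Read molecules from a .smi (one SMILES per line, optional id) or .csv file.

    Invalid rows are skipped with a logged warning; the returned
    :class:`Corpus` carries the skip count as ``n_skipped``.  An empty corpus
    after filtering is an error.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if fmt is None:
        fmt = "csv" if path.lower().endswith(".csv") else "smi"
    rows: list[tuple[str, str | None]] = []
    if fmt == "smi":
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                rows.append((parts[0], parts[1] if len(parts) > 1 else None))
    elif fmt == "csv":
        with open(path, newline="") as fh:
            reader = csv.DictReader(fh)
            if reader.fieldnames is None or smiles_column not in reader.fieldnames:
                raise ValueError(f"column {smiles_column!r} not found in {path}")
            id_col = "id" if "id" in reader.fieldnames else None
            for rec in reader:
                rows.append((rec[smiles_column], rec[id_col] if id_col else None))
    else:
        raise ValueError(f"unknown corpus format {fmt!r}")

    corpus = Corpus()
    skipped = 0
    for i, (smi, mol_id) in enumerate(rows):
        try:
            corpus.append(parse_smiles(smi, mol_id=mol_id or f"mol{i:06d}"))
        except SmilesParseError as exc:
            skipped += 1
            logger.warning("skipping row %d of %s: %s", i, path, exc)
    corpus.n_skipped = skipped
    if not corpus:
        raise ValueError(f"empty corpus: no valid molecules in {path}")
    return corpus


def write_corpus(path: str, molecules: Iterable[Molecule]) -> None:
    with open(path, "w") as fh:
        for mol in molecules:
            fh.write(f"{mol.smiles}\t{mol.id}\n")


def write_fingerprints(path: str, molecules: Sequence[Molecule],
                       fingerprints: Sequence[np.ndarray]) -> None:
    """Columnar fingerprint table: id, canonical SMILES, 166-char bitstring."""
    with open(path, "w") as fh:
        fh.write("id\tsmiles\tmaccs\n")
        for mol, fp in zip(molecules, fingerprints, strict=True):
            bits = "".join(str(int(b)) for b in fp)
            fh.write(f"{mol.id}\t{mol.smiles}\t{bits}\n")
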