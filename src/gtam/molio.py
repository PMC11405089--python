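"""Molecular I/O and graph construction.

A molecule enters the library in one or both of two modalities:

* :class:`Graph2D` — the topological graph: atoms as nodes with categorical
  features (element, formal charge, aromaticity), chemical bonds as typed
  edges stored in both directions.
* :class:`Graph3D` — the conformation: Cartesian coordinates in Å with the
  fully connected pairwise distance map (no cutoff).

This module also provides the 32-bin distogram discretization of pairwise
distances over [1.0, 2.4] Å, the 5-class bond labelling (single, double,
triple, aromatic, no-bond) of every atom pair, and Bemis–Murcko scaffold
splitting.  All format parsing and writing stands on RDKit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem
from rdkit.Chem.Scaffolds import MurckoScaffold
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.*")

ELEMENTS = ["H", "C", "N", "O", "F", "P", "S", "Cl", "Br", "I"]
OTHER_ELEMENT = len(ELEMENTS)  # bucket for anything outside the vocabulary
N_ELEMENT_CLASSES = len(ELEMENTS) + 1

BOND_TYPES = {"single": 0, "double": 1, "triple": 2, "aromatic": 3}
BOND_TYPE_NAMES = ["single", "double", "triple", "aromatic", "no-bond"]
NO_BOND = 4
N_BOND_CLASSES = 5

_RDKIT_BOND = {
    Chem.BondType.SINGLE: 0,
    Chem.BondType.DOUBLE: 1,
    Chem.BondType.TRIPLE: 2,
    Chem.BondType.AROMATIC: 3,
}
_BOND_RDKIT = {v: k for k, v in _RDKIT_BOND.items()}


def element_index(symbol: str) -> int:
    try:
        return ELEMENTS.index(symbol)
    except ValueError:
        return OTHER_ELEMENT


# ---------------------------------------------------------------------------
# Graph containers
# ---------------------------------------------------------------------------

@dataclass
class Graph2D:
    """Topological molecular graph with typed atoms and bonds.

    ``edge_index`` has shape (2, 2E): every undirected bond is stored in both
    directions with identical features, so directed per-pair operations are
    expressible downstream.
    """

    element_idx: np.ndarray        # (N,) int in [0, N_ELEMENT_CLASSES)
    formal_charge: np.ndarray      # (N,) int
    is_aromatic_atom: np.ndarray   # (N,) bool
    edge_index: np.ndarray         # (2, 2E) int
    edge_type: np.ndarray          # (2E,) int in [0, 4)

    def __post_init__(self):
        self.element_idx = np.asarray(self.element_idx, dtype=np.intp)
        self.formal_charge = np.asarray(self.formal_charge, dtype=np.intp)
        self.is_aromatic_atom = np.asarray(self.is_aromatic_atom, dtype=bool)
        self.edge_index = np.asarray(self.edge_index, dtype=np.intp).reshape(2, -1)
        self.edge_type = np.asarray(self.edge_type, dtype=np.intp)
        self.validate()

    @property
    def n_atoms(self) -> int:
        return len(self.element_idx)

    @property
    def n_bonds(self) -> int:
        """Number of undirected bonds."""
        return self.edge_index.shape[1] // 2

    def neighbor_map(self) -> list[list[int]]:
        nbrs: list[list[int]] = [[] for _ in range(self.n_atoms)]
        for u, v in self.edge_index.T:
            nbrs[int(u)].append(int(v))
        return [sorted(n) for n in nbrs]

    def bond_type_matrix(self) -> np.ndarray:
        """(N, N) matrix: bond-type index for bonded pairs, NO_BOND elsewhere,
        -1 on the diagonal."""
        m = np.full((self.n_atoms, self.n_atoms), NO_BOND, dtype=np.intp)
        np.fill_diagonal(m, -1)
        m[self.edge_index[0], self.edge_index[1]] = self.edge_type
        return m

    def adjacency(self) -> np.ndarray:
        a = np.zeros((self.n_atoms, self.n_atoms), dtype=bool)
        a[self.edge_index[0], self.edge_index[1]] = True
        return a

    def validate(self) -> None:
        n = self.n_atoms
        if n < 1:
            raise ValueError("Graph2D requires at least one atom")
        if self.edge_index.size:
            if self.edge_index.min() < 0 or self.edge_index.max() >= n:
                raise ValueError("edge_index out of range")
            if np.any(self.edge_index[0] == self.edge_index[1]):
                raise ValueError("self-loops are not allowed")
        if self.edge_index.shape[1] != len(self.edge_type):
            raise ValueError("edge_index / edge_type length mismatch")
        # symmetry: (v,u) present with the same type whenever (u,v) is
        fwd = {(int(u), int(v)): int(t)
               for (u, v), t in zip(self.edge_index.T, self.edge_type)}
        for (u, v), t in fwd.items():
            if fwd.get((v, u)) != t:
                raise ValueError(f"edge ({u},{v}) lacks a symmetric partner")

    def to_rdkit(self, coords: np.ndarray | None = None) -> Chem.Mol:
        mol = Chem.RWMol()
        for i in range(self.n_atoms):
            idx = int(self.element_idx[i])
            symbol = ELEMENTS[idx] if idx < len(ELEMENTS) else "C"
            atom = Chem.Atom(symbol)
            atom.SetFormalCharge(int(self.formal_charge[i]))
            atom.SetIsAromatic(bool(self.is_aromatic_atom[i]))
            atom.SetNoImplicit(False)
            mol.AddAtom(atom)
        seen = set()
        for (u, v), t in zip(self.edge_index.T, self.edge_type):
            key = (min(u, v), max(u, v))
            if key in seen:
                continue
            seen.add(key)
            mol.AddBond(int(u), int(v), _BOND_RDKIT[int(t)])
        m = mol.GetMol()
        Chem.SanitizeMol(m)
        if coords is not None:
            conf = Chem.Conformer(self.n_atoms)
            for i, xyz in enumerate(np.asarray(coords, dtype=float)):
                conf.SetAtomPosition(i, tuple(float(c) for c in xyz))
            m.AddConformer(conf, assignId=True)
        return m

    def to_smiles(self) -> str:
        return Chem.MolToSmiles(self.to_rdkit())


@dataclass
class Graph3D:
    """Conformation: coordinates in Å plus the fully connected distance map."""

    coords: np.ndarray          # (N, 3) float, Å
    atomic_numbers: np.ndarray  # (N,) int >= 1
    _dmap: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=np.float64).reshape(-1, 3)
        self.atomic_numbers = np.asarray(self.atomic_numbers, dtype=np.intp)
        if len(self.coords) < 1:
            raise ValueError("Graph3D requires at least one atom")
        if len(self.coords) != len(self.atomic_numbers):
            raise ValueError("coords / atomic_numbers length mismatch")
        bad = np.where(~np.isfinite(self.coords).all(axis=1))[0]
        if bad.size:
            raise ValueError(f"non-finite coordinates at atom index {int(bad[0])}")
        if np.any(self.atomic_numbers < 1):
            raise ValueError("atomic numbers must be >= 1")

    @property
    def n_atoms(self) -> int:
        return len(self.coords)

    @property
    def distance_map(self) -> np.ndarray:
        if self._dmap is None:
            if self.n_atoms == 1:
                self._dmap = np.zeros((1, 1))
            else:
                self._dmap = squareform(pdist(self.coords))
        return self._dmap


def build_graph3d(coords, atomic_numbers) -> Graph3D:
    """Build the fully connected conformation graph; no distance cutoff."""
    return Graph3D(np.asarray(coords, dtype=np.float64),
                   np.asarray(atomic_numbers))


# ---------------------------------------------------------------------------
# Distogram binning
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BinSpec:
    """Half-open, left-closed distance bins; out-of-range distances clamp
    into the end bins so the labelling is total over all pairs."""

    lo: float = 1.0
    hi: float = 2.4
    n_bins: int = 32

    def __post_init__(self):
        if not self.lo < self.hi:
            raise ValueError("BinSpec requires lo < hi")
        if self.n_bins < 2:
            raise ValueError("BinSpec requires n_bins >= 2")

    @property
    def width(self) -> float:
        return (self.hi - self.lo) / self.n_bins


DEFAULT_BINSPEC = BinSpec()


def bin_distance(d, spec: BinSpec = DEFAULT_BINSPEC):
    """Map distance(s) in Å to bin indices in [0, n_bins).

    Bins are [lo + k*w, lo + (k+1)*w); d < lo clamps to bin 0 and
    d >= hi clamps to the last bin.
    """
    d = np.asarray(d, dtype=np.float64)
    idx = np.floor((d - spec.lo) / spec.width).astype(np.intp)
    idx = np.clip(idx, 0, spec.n_bins - 1)
    return idx if idx.ndim else int(idx)


def bin_one_hot(d, spec: BinSpec = DEFAULT_BINSPEC) -> np.ndarray:
    idx = np.atleast_1d(np.asarray(bin_distance(d, spec)))
    out = np.zeros(idx.shape + (spec.n_bins,))
    np.put_along_axis(out, idx[..., None], 1.0, axis=-1)
    return out


# ---------------------------------------------------------------------------
# Bond labels
# ---------------------------------------------------------------------------

def bond_labels(g2d: Graph2D, g3d: Graph3D | None = None) -> np.ndarray:
    """Per-ordered-pair bond-class labels over the fully connected pair set.

    Returns an (N, N) integer matrix: bonded pairs carry the bond-type index
    from the 2D graph, every other off-diagonal pair carries NO_BOND, and
    the diagonal is -1 (no self pair).
    """
    if g3d is not None and g3d.n_atoms != g2d.n_atoms:
        raise ValueError(
            f"atom count mismatch: Graph2D has {g2d.n_atoms}, "
            f"Graph3D has {g3d.n_atoms}"
        )
    return g2d.bond_type_matrix()


# ---------------------------------------------------------------------------
# RDKit conversion and file reading
# ---------------------------------------------------------------------------

def graph2d_from_mol(mol: Chem.Mol) -> Graph2D:
    element_idx, charge, aromatic = [], [], []
    for atom in mol.GetAtoms():
        element_idx.append(element_index(atom.GetSymbol()))
        charge.append(atom.GetFormalCharge())
        aromatic.append(atom.GetIsAromatic())
    src, dst, etype = [], [], []
    for bond in mol.GetBonds():
        t = _RDKIT_BOND.get(bond.GetBondType())
        if t is None:
            logger.warning("bond type %s mapped to single", bond.GetBondType())
            t = 0
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        src += [u, v]
        dst += [v, u]
        etype += [t, t]
    return Graph2D(
        element_idx=np.array(element_idx, dtype=np.intp),
        formal_charge=np.array(charge, dtype=np.intp),
        is_aromatic_atom=np.array(aromatic, dtype=bool),
        edge_index=np.array([src, dst], dtype=np.intp).reshape(2, -1),
        edge_type=np.array(etype, dtype=np.intp),
    )


def graph3d_from_mol(mol: Chem.Mol, conf_id: int = 0) -> Graph3D:
    conf = mol.GetConformer(conf_id)
    coords = np.array(conf.GetPositions(), dtype=np.float64)
    z = np.array([a.GetAtomicNum() for a in mol.GetAtoms()], dtype=np.intp)
    return build_graph3d(coords, z)


@dataclass
class ParseReport:
    n_read: int = 0
    n_failed: int = 0
    failures: list = field(default_factory=list)  # (record index, message)

    def record_failure(self, index: int, message: str) -> None:
        self.n_failed += 1
        self.failures.append((index, message))
        logger.warning("record %d skipped: %s", index, message)


def _prepare_mol(mol: Chem.Mol, explicit_hydrogens: bool) -> Chem.Mol:
    return Chem.AddHs(mol, addCoords=True) if explicit_hydrogens else Chem.RemoveHs(mol)


def read_molecules(path, fmt: str, explicit_hydrogens: bool = False):
    """Read molecules from ``path`` in the named format.

    Returns ``(samples, report)``.  SDF records with coordinates yield
    paired ``(Graph2D, Graph3D)`` tuples; SMILES yields ``Graph2D`` only;
    XYZ yields ``Graph3D`` only.  Unparseable records are skipped, counted
    and logged; an empty file is an empty list, not an error.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    report = ParseReport()
    samples: list = []

    if fmt == "sdf":
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
        for i, mol in enumerate(supplier):
            report.n_read += 1
            if mol is None:
                report.record_failure(i, "unparseable SDF record")
                continue
            try:
                mol = _prepare_mol(mol, explicit_hydrogens)
                g2d = graph2d_from_mol(mol)
                g3d = graph3d_from_mol(mol) if mol.GetNumConformers() else None
            except Exception as exc:  # noqa: BLE001 - skip contract
                report.record_failure(i, str(exc))
                continue
            samples.append((g2d, g3d) if g3d is not None else g2d)
    elif fmt == "smiles":
        lines = [ln.strip() for ln in path.read_text().splitlines()]
        for i, line in enumerate(ln for ln in lines if ln):
            report.n_read += 1
            smi = line.split("\t")[0].split()[0]
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                report.record_failure(i, f"unparseable SMILES: {smi}")
                continue
            if explicit_hydrogens:
                mol = Chem.AddHs(mol)
            samples.append(graph2d_from_mol(mol))
    elif fmt == "xyz":
        for i, block in enumerate(_split_xyz_blocks(path.read_text())):
            report.n_read += 1
            mol = Chem.MolFromXYZBlock(block)
            if mol is None or mol.GetNumAtoms() == 0:
                report.record_failure(i, "unparseable XYZ block")
                continue
            samples.append(graph3d_from_mol(mol))
    else:
        raise ValueError(f"unknown format {fmt!r}; expected sdf, smiles or xyz")
    return samples, report


def _split_xyz_blocks(text: str) -> list[str]:
    """Split a concatenated XYZ file into per-molecule blocks by the
    leading atom-count line of each frame."""
    lines = text.splitlines()
    blocks, i = [], 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].split()[0])
        except ValueError:
            blocks.append("\n".join(lines[i:]) + "\n")
            break
        blocks.append("\n".join(lines[i:i + n + 2]) + "\n")
        i += n + 2
    return blocks


def write_sdf(samples, path) -> None:
    """Write paired (Graph2D, Graph3D) samples (or bare Graph2D) to SDF V2000."""
    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(True)
    try:
        for sample in samples:
            if isinstance(sample, tuple):
                g2d, g3d = sample
                mol = g2d.to_rdkit(coords=g3d.coords)
            else:
                mol = sample.to_rdkit()
                AllChem.Compute2DCoords(mol)
            writer.write(mol)
    finally:
        writer.close()


# ---------------------------------------------------------------------------
# Scaffold split
# ---------------------------------------------------------------------------

def scaffold_split(molecules, ratios=(0.8, 0.1, 0.1), seed: int = 0):
    """Bemis–Murcko scaffold split into (train, valid, test) index lists.

    Molecules sharing a scaffold never straddle splits.  Scaffold groups are
    sorted by descending size (the seed shuffles ties) and each group is
    assigned to the split with the largest remaining deficit, preferring
    train, then valid, then test on exact ties.
    """
    ratios = np.asarray(ratios, dtype=float)
    if ratios.min() <= 0 or abs(ratios.sum() - 1.0) > 1e-9:
        raise ValueError("ratios must be positive and sum to 1")
    groups: dict[str, list[int]] = {}
    for i, g in enumerate(molecules):
        mol = g[0].to_rdkit() if isinstance(g, tuple) else g.to_rdkit()
        scaffold = MurckoScaffold.MurckoScaffoldSmiles(mol=mol)
        groups.setdefault(scaffold, []).append(i)
    group_list = list(groups.values())
    rng = np.random.default_rng(seed)
    rng.shuffle(group_list)
    group_list.sort(key=len, reverse=True)  # stable: seed breaks ties
    if len(group_list) < 3:
        logger.warning("only %d distinct scaffolds for a 3-way split",
                       len(group_list))
    n = sum(len(g) for g in group_list)
    targets = ratios * n
    splits: list[list[int]] = [[], [], []]
    for group in group_list:
        deficits = [targets[k] - len(splits[k]) for k in range(3)]
        k = int(np.argmax(deficits))  # argmax prefers train on ties
        splits[k].extend(group)
    return tuple(sorted(s) for s in splits)


def save_splits(splits, path) -> None:
    Path(path).write_text(json.dumps([list(map(int, s)) for s in splits]))


def load_splits(path):
    return tuple(list(map(int, s)) for s in json.loads(Path(path).read_text()))
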