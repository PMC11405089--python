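"""Deterministic paired 2D/3D toy molecules for offline testing.

The generator emulates the one statistical regularity the cross-modal edge
objectives rely on: bond type determines bond length.  Each bond type has a
fixed mean length (C–C class defaults: single 1.54 Å, double 1.34 Å, triple
1.20 Å, aromatic 1.39 Å) and realized lengths are the mean plus small
Gaussian jitter, with the jitter constrained so the type classes stay
separable.  Topologies are chemically plausible small graphs — chains,
branched chains and 5/6-rings with substituents — over {C, N, O} with
valences respected, and coordinates are grown with standard internal
geometry (tetrahedral/trigonal angles, near-trans dihedrals, planar rings)
so that non-bonded pairs land beyond the 2.4 Å distogram ceiling wherever
feasible.  A short steric-repulsion relaxation nudges residual clashes
apart; only bonded-pair geometry is guaranteed.

Everything is a pure function of the :class:`FixtureSpec` seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .molio import BOND_TYPES, Graph2D, Graph3D, build_graph3d, element_index

__all__ = [
    "FixtureSpec",
    "make_fixture_set",
    "make_property_labels",
    "harmonic_energy",
    "harmonic_forces",
]

_VALENCE = {"C": 4, "N": 3, "O": 2}
_ATOMIC_NUM = {"C": 6, "N": 7, "O": 8}

DEFAULT_BOND_LENGTHS = {
    "single": 1.54,
    "double": 1.34,
    "triple": 1.20,
    "aromatic": 1.39,
}


@dataclass
class FixtureSpec:
    n_molecules: int = 16
    min_atoms: int = 3
    max_atoms: int = 12
    bond_lengths: dict = field(default_factory=lambda: dict(DEFAULT_BOND_LENGTHS))
    sigma_len: float = 0.01      # Å jitter on realized bond lengths
    seed: int = 0

    def __post_init__(self):
        if self.n_molecules < 1:
            raise ValueError("n_molecules must be >= 1")
        if not 1 <= self.min_atoms <= self.max_atoms:
            raise ValueError("need 1 <= min_atoms <= max_atoms")
        means = sorted(self.bond_lengths.values())
        if means[0] < 1.0 or means[-1] > 2.4:
            raise ValueError("bond-length means must lie within [1.0, 2.4] Å")
        min_gap = min(b - a for a, b in zip(means, means[1:]))
        if 3.0 * self.sigma_len >= min_gap:
            raise ValueError(
                f"sigma_len {self.sigma_len} violates separability: "
                f"3*sigma must be < minimal inter-mean gap {min_gap:.3f} Å"
            )


# ---------------------------------------------------------------------------
# Topology generation
# ---------------------------------------------------------------------------

def _gen_topology(n: int, rng: np.random.Generator):
    """Return (elements, aromatic_flags, bonds) with bonds as
    (u, v, type_name) and valences respected."""
    elements: list[str] = []
    aromatic = np.zeros(n, dtype=bool)
    bonds: list[tuple[int, int, str]] = []
    free: list[int] = []   # remaining valence per atom

    def add_atom(symbol: str) -> int:
        elements.append(symbol)
        free.append(_VALENCE[symbol])
        return len(elements) - 1

    def add_bond(u: int, v: int, kind: str) -> None:
        order = {"single": 1, "double": 2, "triple": 3, "aromatic": 1}[kind]
        bonds.append((u, v, kind))
        free[u] -= order
        free[v] -= order

    use_ring = n >= 5 and rng.random() < 0.5
    ring_size = 0
    if use_ring:
        ring_size = int(rng.choice([5, 6])) if n >= 6 else 5
        aromatic_ring = ring_size == 6 and rng.random() < 0.6
        for _ in range(ring_size):
            add_atom("C")
        kind = "aromatic" if aromatic_ring else "single"
        for i in range(ring_size):
            add_bond(i, (i + 1) % ring_size, kind)
        if aromatic_ring:
            aromatic[:6] = True
            for i in range(6):   # aromatic carbon: one remaining substituent slot
                free[i] = 1
    else:
        add_atom("C")

    # grow the remaining atoms as a tree off any atom with spare valence
    while len(elements) < n:
        candidates = [i for i, f in enumerate(free) if f >= 1]
        parent = int(rng.choice(candidates))
        symbol = str(rng.choice(["C", "N", "O"], p=[0.7, 0.15, 0.15]))
        child = add_atom(symbol)
        kind = "single"
        if (not aromatic[parent] and free[parent] >= 2
                and _VALENCE[symbol] >= 2 and rng.random() < 0.15):
            kind = "double"
        if (kind == "single" and symbol == "C" and elements[parent] == "C"
                and not aromatic[parent] and free[parent] >= 3
                and rng.random() < 0.05):
            kind = "triple"
        add_bond(parent, child, kind)
    return elements, aromatic, bonds, ring_size


# ---------------------------------------------------------------------------
# Coordinate realization
# ---------------------------------------------------------------------------

def _bond_angle(kind_a: str, kind_b: str) -> float:
    if "triple" in (kind_a, kind_b):
        return np.pi                      # linear sp center
    if "double" in (kind_a, kind_b) or "aromatic" in (kind_a, kind_b):
        return np.deg2rad(120.0)
    return np.deg2rad(111.0)              # near-tetrahedral

def _place_nerf(a, b, c, r, theta, phi):
    """Standard internal-coordinate placement: new atom at distance r from c,
    angle theta at c against b, dihedral phi around the b-c axis."""
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-8:                         # collinear chain: pick any normal
        helper = np.array([1.0, 0.0, 0.0])
        if abs(bc[0]) > 0.9:
            helper = np.array([0.0, 1.0, 0.0])
        n = np.cross(helper, bc)
        nn = np.linalg.norm(n)
    n /= nn
    m = np.cross(n, bc)
    d = np.array([
        -r * np.cos(theta),
        r * np.sin(theta) * np.cos(phi),
        r * np.sin(theta) * np.sin(phi),
    ])
    return c + d[0] * bc + d[1] * m + d[2] * n


def _realize_coords(elements, bonds, ring_size, lengths, sigma, rng):
    n = len(elements)
    coords = np.full((n, 3), np.nan)
    nbrs = {i: [] for i in range(n)}
    bond_kind = {}
    for u, v, kind in bonds:
        nbrs[u].append(v)
        nbrs[v].append(u)
        bond_kind[(u, v)] = bond_kind[(v, u)] = kind

    def length(u, v):
        return lengths[bond_kind[(u, v)]] + rng.normal(0.0, sigma)

    placed: list[int] = []
    if ring_size:
        # planar regular polygon; one shared jittered side keeps closure exact
        side = lengths[bond_kind[(0, 1)]] + rng.normal(0.0, sigma)
        radius = side / (2.0 * np.sin(np.pi / ring_size))
        ang = 2.0 * np.pi * np.arange(ring_size) / ring_size
        coords[:ring_size, 0] = radius * np.cos(ang)
        coords[:ring_size, 1] = radius * np.sin(ang)
        coords[:ring_size, 2] = 0.0
        placed = list(range(ring_size))
    else:
        coords[0] = 0.0
        placed = [0]

    # BFS over the bond tree from the placed seed
    queue = [u for u in placed]
    seen = set(placed)
    child_rank: dict[int, int] = {}
    while queue:
        parent = queue.pop(0)
        for child in nbrs[parent]:
            if child in seen:
                continue
            seen.add(child)
            queue.append(child)
            r = length(parent, child)
            placed_nb = [w for w in nbrs[parent] if not np.isnan(coords[w, 0])]
            if not placed_nb:             # first bond of a bare chain seed
                coords[child] = coords[parent] + np.array([r, 0.0, 0.0])
            else:
                grand = placed_nb[0]
                theta = _bond_angle(bond_kind[(parent, child)],
                                    bond_kind[(parent, grand)])
                ggs = [w for w in nbrs[grand]
                       if w != parent and not np.isnan(coords[w, 0])]
                if ggs:
                    anchor = coords[ggs[0]]
                else:
                    anchor = coords[grand] + np.array([0.0, 0.0, 1.0])
                rank = child_rank.get(parent, 0)
                child_rank[parent] = rank + 1
                # near-trans backbone; later children fan out around the axis
                phi = np.deg2rad(180.0 - 120.0 * rank + rng.normal(0.0, 8.0))
                coords[child] = _place_nerf(anchor, coords[grand],
                                            coords[parent], r, theta, phi)
    return _relax(coords, bonds, lengths, bond_kind, rng)


def _relax(coords, bonds, lengths, bond_kind, rng, n_steps: int = 60,
           clash: float = 2.45, step: float = 0.03):
    """Best-effort steric relaxation: push non-bonded pairs beyond the
    distogram ceiling while harmonically restoring bonded lengths."""
    n = len(coords)
    bonded = set()
    for u, v, _ in bonds:
        bonded.add((min(u, v), max(u, v)))
    one_three = set()
    nbrs = {i: set() for i in range(n)}
    for u, v, _ in bonds:
        nbrs[u].add(v)
        nbrs[v].add(u)
    for m in range(n):
        for a in nbrs[m]:
            for b in nbrs[m]:
                if a < b:
                    one_three.add((a, b))
    x = coords.copy()
    for _ in range(n_steps):
        grad = np.zeros_like(x)
        moved = False
        for u in range(n):
            for v in range(u + 1, n):
                d = np.linalg.norm(x[u] - x[v])
                unit = (x[u] - x[v]) / (d + 1e-12)
                if (u, v) in bonded:
                    target = lengths[bond_kind[(u, v)]]
                    grad[u] -= 10.0 * (d - target) * unit
                    grad[v] += 10.0 * (d - target) * unit
                elif (u, v) not in one_three and d < clash:
                    grad[u] += (clash - d) * unit
                    grad[v] -= (clash - d) * unit
                    moved = True
        if not moved:
            break
        x += step * grad
    return x


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def make_fixture_set(spec: FixtureSpec) -> list[tuple[Graph2D, Graph3D]]:
    """Generate ``spec.n_molecules`` paired (Graph2D, Graph3D) samples,
    deterministically from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.n_molecules):
        n = int(rng.integers(spec.min_atoms, spec.max_atoms + 1))
        elements, aromatic, bonds, ring_size = _gen_topology(n, rng)
        coords = _realize_coords(elements, bonds, ring_size,
                                 spec.bond_lengths, spec.sigma_len, rng)
        src, dst, etype = [], [], []
        for u, v, kind in bonds:
            t = BOND_TYPES[kind]
            src += [u, v]
            dst += [v, u]
            etype += [t, t]
        g2d = Graph2D(
            element_idx=np.array([element_index(e) for e in elements]),
            formal_charge=np.zeros(n, dtype=np.intp),
            is_aromatic_atom=aromatic,
            edge_index=np.array([src, dst], dtype=np.intp).reshape(2, -1),
            edge_type=np.array(etype, dtype=np.intp),
        )
        g3d = build_graph3d(coords,
                            [_ATOMIC_NUM[e] for e in elements])
        out.append((g2d, g3d))
    return out


def has_ring(g2d: Graph2D) -> bool:
    return g2d.n_bonds >= g2d.n_atoms    # connected graph: tree has N-1 edges


def bonded_length_sum(g2d: Graph2D, g3d: Graph3D) -> float:
    dmap = g3d.distance_map
    total = 0.0
    seen = set()
    for u, v in g2d.edge_index.T:
        key = (min(u, v), max(u, v))
        if key not in seen:
            seen.add(key)
            total += dmap[u, v]
    return float(total)


def harmonic_energy(g2d: Graph2D, coords: np.ndarray,
                    lengths: dict | None = None, k: float = 1.0) -> float:
    """Toy bond energy E = Σ_bonds k (d_uv − d0_type)² in arbitrary units."""
    lengths = lengths or DEFAULT_BOND_LENGTHS
    names = {v: n for n, v in BOND_TYPES.items()}
    e = 0.0
    seen = set()
    for (u, v), t in zip(g2d.edge_index.T, g2d.edge_type):
        key = (min(u, v), max(u, v))
        if key in seen:
            continue
        seen.add(key)
        d = float(np.linalg.norm(coords[u] - coords[v]))
        e += k * (d - lengths[names[int(t)]]) ** 2
    return e


def harmonic_forces(g2d: Graph2D, coords: np.ndarray,
                    lengths: dict | None = None, k: float = 1.0) -> np.ndarray:
    """Analytic forces F = −∇E of :func:`harmonic_energy`, per atom."""
    lengths = lengths or DEFAULT_BOND_LENGTHS
    names = {v: n for n, v in BOND_TYPES.items()}
    f = np.zeros_like(np.asarray(coords, dtype=float))
    seen = set()
    for (u, v), t in zip(g2d.edge_index.T, g2d.edge_type):
        key = (min(u, v), max(u, v))
        if key in seen:
            continue
        seen.add(key)
        delta = coords[u] - coords[v]
        d = float(np.linalg.norm(delta))
        unit = delta / d
        g = 2.0 * k * (d - lengths[names[int(t)]]) * unit   # dE/dx_u
        f[u] -= g
        f[v] += g
    return f


def make_property_labels(fixtures, task: str, seed: int = 0):
    """Labels for the downstream protocols.

    * ``classification``: ring presence (separable from topology alone)
    * ``regression``: sum of bonded 3D lengths
    * ``forces``: per-atom analytic forces of the harmonic bond-energy toy,
      returned as a list of (energy, forces) tuples
    """
    if task == "classification":
        return pd.DataFrame({
            "label": [int(has_ring(g2d)) for g2d, _ in fixtures]})
    if task == "regression":
        return pd.DataFrame({
            "label": [bonded_length_sum(g2d, g3d) for g2d, g3d in fixtures]})
    if task == "forces":
        return [(harmonic_energy(g2d, g3d.coords),
                 harmonic_forces(g2d, g3d.coords))
                for g2d, g3d in fixtures]
    raise ValueError(f"unknown task {task!r}; expected classification, "
                     "regression or forces")
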