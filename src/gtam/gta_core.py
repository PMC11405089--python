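"""Triangle-aware molecular graph encoders (GTA-2D and GTA-3D).

Both encoders share one update mechanism operating on per-node embeddings
``h`` (N, D_h) and per-ordered-pair embeddings ``z`` (N, N, D_z):

* node-to-edge:   z_uv <- z_uv + Linear(f(h_u) * f(h_v)), f = Linear∘LayerNorm
* triangle multiplicative: z_uv <- z_uv + g(z_uv) ⊙ Linear(LayerNorm(
      Σ_w LN(z_uw) ⊙ LN(z_vw))) over the admissible third vertices w
* triangle attention: per head, a_uvw = softmax_w(q_uv·k_wv / c + b_wu),
      z_uv <- z_uv + g(z_uv) ⊙ Σ_w a_uvw v_uw
* edge-to-node:   h_u <- h_u + MLP(row sum of LN(z)) + MLP(column sum)

where g is a sigmoid gate (a learned linear projection of z_uv), in the
AlphaFold2 triangle-update style.  The third edge enters the attention
logits as a bias, so each edge update is aware of the triangles it closes.

The 2D encoder initializes embeddings with two bond-aware GIN layers
(two-hop topological context); the 3D encoder with one continuous-filter
convolution over radial-basis-expanded interatomic distances, making every
downstream quantity a function of the distance map only and hence invariant
to rigid motions of the conformation.  Empty aggregation sets (an edge that
closes no triangle, an isolated node) leave the embedding unchanged:
every update is residual.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .molio import (
    Graph2D,
    Graph3D,
    N_BOND_CLASSES,
    N_ELEMENT_CLASSES,
    NO_BOND,
    element_index,
)
from .nn import MLP, Embedding, LayerNorm, Linear, Module, softmax

__all__ = [
    "EncoderConfig",
    "EmbeddingState",
    "NodeToEdge",
    "TriangleMultiplicative",
    "TriangleAttention",
    "EdgeToNode",
    "GINInit",
    "CFConvInit",
    "GTAEncoder2D",
    "GTAEncoder3D",
    "rbf_expand",
]

# atomic number -> element vocabulary index (same buckets as molio.ELEMENTS)
_Z_TO_SYMBOL = {1: "H", 6: "C", 7: "N", 8: "O", 9: "F", 15: "P", 16: "S",
                17: "Cl", 35: "Br", 53: "I"}

MAX_ABS_CHARGE = 2  # formal charges clipped to [-2, 2] for the embedding


@dataclass
class EncoderConfig:
    d_h: int = 128
    d_z: int = 128
    n_triangle_blocks: int = 3
    n_heads: int = 4
    d_hidden: int = 128          # hidden width of the 3-layer edge-to-node MLPs
    pooled_dim: int = 256
    n_rbf: int = 32              # radial basis size for the 3D init stage
    rbf_cutoff: float = 5.0      # Å; Gaussian centers span [0, cutoff]
    tensor_product: str = "elementwise"   # "elementwise" or "outer" (node-to-edge)
    outer_rank: int = 16         # projection width used by the outer-product variant
    w_set: str = "intersection"  # admissible third vertices on sparse 2D graphs

    def __post_init__(self):
        for name in ("d_h", "d_z", "n_triangle_blocks", "n_heads", "d_hidden",
                     "pooled_dim", "n_rbf"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.d_z % self.n_heads:
            raise ValueError("d_z must be divisible by n_heads")
        if self.tensor_product not in ("elementwise", "outer"):
            raise ValueError("tensor_product must be 'elementwise' or 'outer'")
        if self.w_set not in ("intersection", "union"):
            raise ValueError("w_set must be 'intersection' or 'union'")


@dataclass
class EmbeddingState:
    """Per-node, per-pair and pooled molecule embeddings for one modality."""

    h: Tensor                 # (N, D_h)
    z: Tensor                 # (N, N, D_z); diagonal entries are unused
    pair_mask: np.ndarray     # (N, N) bool; pairs that drive triangle updates
    pooled: Tensor            # (pooled_dim,)

    @property
    def n_atoms(self) -> int:
        return self.h.shape[0]


def _offdiag(n: int) -> np.ndarray:
    return ~np.eye(n, dtype=bool)


def admissible_w(pair_mask: np.ndarray, w_set: str) -> np.ndarray:
    """(N, N, N) bool: M[u, v, w] marks w as an admissible third vertex for
    the edge (u, v).  Intersection requires both pair embeddings (u,w) and
    (v,w) to be defined; union requires either (missing ones fall back on
    the materialized no-bond embeddings)."""
    n = pair_mask.shape[0]
    pu = pair_mask[:, None, :]   # pair (u, w)
    pv = pair_mask[None, :, :]   # pair (v, w)
    m = (pu | pv) if w_set == "union" else (pu & pv)
    idx = np.arange(n)
    m = m.copy()
    m[idx, :, idx] = False   # w != u
    m[:, idx, idx] = False   # w != v
    return m


class NodeToEdge(Module):
    """z_uv <- z_uv + Linear(f(h_u) ⊗ f(h_v)); ⊗ is elementwise by default
    (commutative, so undirected bonds keep z_uv = z_vu)."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        d_p = cfg.d_z if cfg.tensor_product == "elementwise" else cfg.outer_rank
        self.norm = LayerNorm(cfg.d_h)
        self.proj = Linear(cfg.d_h, d_p, rng)
        d_in = d_p if cfg.tensor_product == "elementwise" else d_p * d_p
        self.out = Linear(d_in, cfg.d_z, rng)
        self.mode = cfg.tensor_product

    def forward(self, h: Tensor, z: Tensor, pair_mask: np.ndarray) -> Tensor:
        n = h.shape[0]
        f = self.proj(self.norm(h))                      # (N, d_p)
        fu = f.reshape(n, 1, -1)
        fv = f.reshape(1, n, -1)
        if self.mode == "elementwise":
            prod = fu * fv                               # (N, N, d_p)
        else:
            prod = (f.reshape(n, 1, -1, 1) * f.reshape(1, n, 1, -1)).reshape(
                n, n, -1)                                # flattened outer product
        upd = self.out(prod)
        return z + upd * pair_mask[:, :, None].astype(float)


class TriangleMultiplicative(Module):
    """Direct update of the third edge from the two adjacent edges of each
    triangle, gated by a sigmoid of the edge being updated."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.norm_in = LayerNorm(cfg.d_z)
        self.norm_sum = LayerNorm(cfg.d_z)
        self.out = Linear(cfg.d_z, cfg.d_z, rng)
        self.gate = Linear(cfg.d_z, cfg.d_z, rng)
        self.w_set = cfg.w_set

    def forward(self, z: Tensor, pair_mask: np.ndarray) -> Tensor:
        n = z.shape[0]
        m3 = admissible_w(pair_mask, self.w_set)
        a = self.norm_in(z) * _offdiag(n)[:, :, None].astype(float)
        prod = a.reshape(n, 1, n, -1) * a.reshape(1, n, n, -1)  # [u,v,w,:]
        s = (prod * m3[:, :, :, None].astype(float)).sum(axis=2)
        nonempty = m3.any(axis=2) & pair_mask
        upd = self.gate(z).sigmoid() * self.out(self.norm_sum(s))
        return z + upd * nonempty[:, :, None].astype(float)


class TriangleAttention(Module):
    """Attention over third vertices w with the (w,u) edge as a logit bias.

    Logits follow the printed index pattern q_uv · k_wv / c + b_wu with
    c = sqrt(per-head key width); one head reproduces the single-head form
    exactly, the multi-head variant splits d_z into n_heads slices.
    """

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.n_heads = cfg.n_heads
        self.d_head = cfg.d_z // cfg.n_heads
        self.q = Linear(cfg.d_z, cfg.d_z, rng)
        self.k = Linear(cfg.d_z, cfg.d_z, rng)
        self.v = Linear(cfg.d_z, cfg.d_z, rng)
        self.b = Linear(cfg.d_z, cfg.n_heads, rng)
        self.gate = Linear(cfg.d_z, cfg.d_z, rng)
        self.w_set = cfg.w_set
        self.last_attention: np.ndarray | None = None  # (N,N,N,H) diagnostics

    def forward(self, z: Tensor, pair_mask: np.ndarray) -> Tensor:
        n, h, dk = z.shape[0], self.n_heads, self.d_head
        m3 = admissible_w(pair_mask, self.w_set)
        q = self.q(z).reshape(n, n, h, dk)
        k = self.k(z).reshape(n, n, h, dk)
        v = self.v(z).reshape(n, n, h, dk)
        b = self.b(z)                                     # (N, N, H), entry (w,u)
        c = float(np.sqrt(dk))
        # logits[u, v, w, head] = q_uv . k_wv / c + b_wu
        qk = (q.reshape(n, n, 1, h, dk) *
              k.transpose(1, 0, 2, 3).reshape(1, n, n, h, dk)).sum(axis=-1) / c
        bias = b.transpose(1, 0, 2).reshape(n, 1, n, h)   # [u, ., w, head] = b[w, u]
        logits = qk + bias
        neg = (~m3)[:, :, :, None].astype(float) * (-1e9)
        attn = softmax(logits + neg, axis=2)
        self.last_attention = attn.data
        out = (attn.reshape(n, n, n, h, 1) *
               v.reshape(n, 1, n, h, dk)).sum(axis=2)   # v_uw broadcast over v
        out = out.reshape(n, n, h * dk)
        nonempty = m3.any(axis=2) & pair_mask
        upd = self.gate(z).sigmoid() * out
        return z + upd * nonempty[:, :, None].astype(float)


class EdgeToNode(Module):
    """h_u <- h_u + MLP(Σ_v LN(z)_vu) + MLP(Σ_v LN(z)_uv): independent
    three-layer MLPs over the row and column aggregations of the pair map."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.norm = LayerNorm(cfg.d_z)
        self.mlp_row = MLP(cfg.d_z, cfg.d_hidden, cfg.d_h, n_layers=3, rng=rng)
        self.mlp_col = MLP(cfg.d_z, cfg.d_hidden, cfg.d_h, n_layers=3, rng=rng)

    def forward(self, h: Tensor, z: Tensor, pair_mask: np.ndarray) -> Tensor:
        pm = pair_mask[:, :, None].astype(float)
        lz = self.norm(z) * pm
        row = lz.sum(axis=0)     # node u aggregates pairs (v, u)
        col = lz.sum(axis=1)     # node u aggregates pairs (u, v)
        has_row = (pair_mask.sum(axis=0) > 0)[:, None].astype(float)
        has_col = (pair_mask.sum(axis=1) > 0)[:, None].astype(float)
        return h + self.mlp_row(row) * has_row + self.mlp_col(col) * has_col


class TriangleBlock(Module):
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.node_to_edge = NodeToEdge(cfg, rng)
        self.tri_mult = TriangleMultiplicative(cfg, rng)
        self.tri_attn = TriangleAttention(cfg, rng)
        self.edge_to_node = EdgeToNode(cfg, rng)

    def forward(self, h: Tensor, z: Tensor, pair_mask: np.ndarray):
        z = self.node_to_edge(h, z, pair_mask)
        z = self.tri_mult(z, pair_mask)
        z = self.tri_attn(z, pair_mask)
        h = self.edge_to_node(h, z, pair_mask)
        return h, z


# ---------------------------------------------------------------------------
# Initialization stages
# ---------------------------------------------------------------------------

class GINInit(Module):
    """Two bond-aware GIN layers: sum aggregation of ReLU(h_v + bond embed)
    with a learned (1 + eps) self weight, MLP update.  Two layers expose
    two-hop topological context before any triangle update runs."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        d = cfg.d_h
        self.elem_emb = Embedding(N_ELEMENT_CLASSES, d, rng)
        self.charge_emb = Embedding(2 * MAX_ABS_CHARGE + 1, d, rng)
        self.arom_emb = Embedding(2, d, rng)
        self.bond_emb = [Embedding(4, d, rng) for _ in range(2)]
        self.eps = [Tensor(np.zeros(()), requires_grad=True) for _ in range(2)]
        self.mlps = [MLP(d, d, d, n_layers=2, rng=rng) for _ in range(2)]
        self.z_emb = Embedding(N_BOND_CLASSES, cfg.d_z, rng)

    def forward(self, g: Graph2D):
        n = g.n_atoms
        charge = np.clip(g.formal_charge, -MAX_ABS_CHARGE, MAX_ABS_CHARGE)
        h = (self.elem_emb(g.element_idx)
             + self.charge_emb(charge + MAX_ABS_CHARGE)
             + self.arom_emb(g.is_aromatic_atom.astype(np.intp)))
        adj = g.adjacency()
        btm = g.bond_type_matrix()
        bonded_types = np.where(adj, np.maximum(btm, 0), 0)
        for layer in range(2):
            e = self.bond_emb[layer](bonded_types)          # (N, N, d_h)
            msg = ((h.reshape(1, n, -1) + e).relu()
                   * adj[:, :, None].astype(float)).sum(axis=1)
            h = self.mlps[layer]((1.0 + self.eps[layer]) * h + msg)
        # pair embeddings for every ordered pair, including the learned
        # no-bond (null) vector on non-bonded pairs
        z_classes = np.where(btm < 0, NO_BOND, btm)
        z = self.z_emb(z_classes) * _offdiag(n)[:, :, None].astype(float)
        return h, z


def rbf_expand(d: Tensor, n_rbf: int, cutoff: float) -> Tensor:
    """Gaussian radial basis over [0, cutoff] Å applied elementwise."""
    centers = np.linspace(0.0, cutoff, n_rbf)
    width = centers[1] - centers[0]
    gamma = 1.0 / (2.0 * width**2)
    shaped = d.reshape(*d.shape, 1)
    return (-(gamma) * (shaped - centers) ** 2).exp()


class CFConvInit(Module):
    """One continuous-filter convolution: h_u <- h_u + Dense(Σ_{v≠u} h_v ⊙
    W(rbf(d_uv))) with a filter MLP over the radial basis; pair embeddings
    are a linear image of the same basis, so everything downstream of this
    stage sees coordinates only through interatomic distances."""

    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.elem_emb = Embedding(N_ELEMENT_CLASSES, cfg.d_h, rng)
        self.filter = MLP(cfg.n_rbf, cfg.d_h, cfg.d_h, n_layers=2, rng=rng)
        self.post = MLP(cfg.d_h, cfg.d_h, cfg.d_h, n_layers=2, rng=rng)
        self.z_proj = Linear(cfg.n_rbf, cfg.d_z, rng)

    def forward(self, atomic_numbers: np.ndarray, dmap: Tensor):
        n = len(atomic_numbers)
        elem = np.array([element_index(_Z_TO_SYMBOL.get(int(z), "?"))
                         for z in atomic_numbers], dtype=np.intp)
        h0 = self.elem_emb(elem)
        rbf = rbf_expand(dmap, self.cfg.n_rbf, self.cfg.rbf_cutoff)  # (N,N,R)
        off = _offdiag(n)[:, :, None].astype(float)
        w = self.filter(rbf) * off
        conv = (h0.reshape(1, n, -1) * w).sum(axis=1)
        h = h0 + self.post(conv)
        z = self.z_proj(rbf) * off
        return h, z


# ---------------------------------------------------------------------------
# Encoders
# ---------------------------------------------------------------------------

class _PooledHead(Module):
    def __init__(self, cfg: EncoderConfig, rng: np.random.Generator):
        self.proj = Linear(cfg.d_h, cfg.pooled_dim, rng)

    def forward(self, h: Tensor) -> Tensor:
        return self.proj(h.mean(axis=0))


class GTAEncoder2D(Module):
    """GIN initialization followed by triangle blocks on the bonded pair set,
    mean-pooled to a molecule-level vector (default width 256)."""

    def __init__(self, config: EncoderConfig | None = None, seed: int = 0):
        self.config = config or EncoderConfig()
        ss = np.random.SeedSequence([seed, 2])
        rngs = [np.random.default_rng(s)
                for s in ss.spawn(self.config.n_triangle_blocks + 2)]
        self.init_stage = GINInit(self.config, rngs[0])
        self.blocks = [TriangleBlock(self.config, rngs[i + 1])
                       for i in range(self.config.n_triangle_blocks)]
        self.pool = _PooledHead(self.config, rngs[-1])

    def forward(self, g: Graph2D) -> EmbeddingState:
        h, z = self.init_stage(g)
        pair_mask = g.adjacency()
        for block in self.blocks:
            h, z = block(h, z, pair_mask)
        return EmbeddingState(h=h, z=z, pair_mask=pair_mask,
                              pooled=self.pool(h))

    def encode_batch(self, graphs) -> list[EmbeddingState]:
        return [self.forward(g) for g in graphs]


class GTAEncoder3D(Module):
    """cfconv initialization followed by triangle blocks on the fully
    connected pair set; rigid-motion invariant by construction."""

    def __init__(self, config: EncoderConfig | None = None, seed: int = 0):
        self.config = config or EncoderConfig()
        ss = np.random.SeedSequence([seed, 3])
        rngs = [np.random.default_rng(s)
                for s in ss.spawn(self.config.n_triangle_blocks + 2)]
        self.init_stage = CFConvInit(self.config, rngs[0])
        self.blocks = [TriangleBlock(self.config, rngs[i + 1])
                       for i in range(self.config.n_triangle_blocks)]
        self.pool = _PooledHead(self.config, rngs[-1])

    def forward(self, g: Graph3D, coords: Tensor | None = None) -> EmbeddingState:
        """Encode a conformation.  Pass ``coords`` (a Tensor leaf over
        ``g.coords``) to differentiate outputs with respect to positions,
        e.g. for force prediction."""
        n = g.n_atoms
        if coords is None:
            dmap = Tensor(g.distance_map)
        else:
            diff = coords.reshape(n, 1, 3) - coords.reshape(1, n, 3)
            sq = (diff * diff).sum(axis=-1)
            dmap = (sq + np.eye(n) + 1e-12).sqrt() * _offdiag(n).astype(float)
        h, z = self.init_stage(g.atomic_numbers, dmap)
        pair_mask = _offdiag(n)
        for block in self.blocks:
            h, z = block(h, z, pair_mask)
        return EmbeddingState(h=h, z=z, pair_mask=pair_mask,
                              pooled=self.pool(h))

    def encode_batch(self, graphs) -> list[EmbeddingState]:
        return [self.forward(g) for g in graphs]
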