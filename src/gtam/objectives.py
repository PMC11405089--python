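"""Contrastive and supervised pretraining objectives.

Four families of terms, combined by :func:`total_loss` into the overall
objective  L = a1*(eta1*L_node + eta2*L_edge) + a2*L_2D->3D + a3*L_3D->2D
(optionally + a4*L_infomax):

* the distogram loss: 2D edge embeddings predict the 32-bin discretized 3D
  distance map by softmax cross-entropy;
* the bond loss: 3D pair embeddings predict the 5-class bond label (single,
  double, triple, aromatic, no-bond) of every atom pair;
* the node contrastive loss: EBM-NCE binary discrimination of matched
  versus in-batch mismatched (noised sample, condition) pairs, with the
  logit read off a scalar head over each score network's invariant pooled
  representation;
* GTAInfomax: symmetric InfoNCE between the pooled 2D and 3D molecule
  embeddings of a batch, paired rows positive, in-batch rows negative.

Labels (distance bins, bond classes, kernel scores) are plain arrays, so no
gradient flows into them; only the encoders and heads learn.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, stack
from .diffusion import (
    SDESchedule,
    VE_DEFAULT,
    VP_DEFAULT,
    perturb_2d,
    perturb_3d,
)
from .molio import BinSpec, DEFAULT_BINSPEC, Graph2D, Graph3D, N_BOND_CLASSES, bond_labels, bin_distance
from .nn import Linear, Module, log_softmax

__all__ = [
    "EdgePredictionHeads",
    "edge_loss_2d",
    "edge_loss_3d",
    "node_contrastive_loss",
    "ebm_nce",
    "gta_infomax_loss",
    "LossWeights",
    "LossBundle",
    "total_loss",
]


class EdgePredictionHeads(Module):
    """Projections of edge embeddings onto the supervision targets, plus the
    scalar discriminator heads used by the node contrastive loss."""

    def __init__(self, d_z2: int, d_z3: int, disc_dim_2d: int, disc_dim_3d: int,
                 n_bins: int = DEFAULT_BINSPEC.n_bins, seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 21]))
        self.distogram = Linear(d_z2, n_bins, rng)
        self.bond = Linear(d_z3, N_BOND_CLASSES, rng)
        self.disc_2d = Linear(disc_dim_2d, 1, rng)   # over ScoreNet3Dto2D reps
        self.disc_3d = Linear(disc_dim_3d, 1, rng)   # over ScoreNet2Dto3D reps


def _cross_entropy(logits: Tensor, labels: np.ndarray, reduction: str) -> Tensor:
    lp = log_softmax(logits, axis=-1)
    picked = lp[np.arange(len(labels)), labels]
    return -picked.mean() if reduction == "mean" else -picked.sum()


def edge_loss_2d(z2d: Tensor, g3d: Graph3D, heads: EdgePredictionHeads,
                 spec: BinSpec = DEFAULT_BINSPEC, pair_set: str = "all",
                 reduction: str = "mean", g2d: Graph2D | None = None) -> Tensor:
    """Distogram cross-entropy: the 2D edge embeddings, projected to
    ``spec.n_bins`` logits, predict the binned 3D distances.

    ``pair_set`` selects all heavy-atom pairs (default; out-of-range
    distances clamp into the end bins so the loss stays total) or bonded
    pairs only, in which case the paired ``g2d`` supplies the adjacency.
    """
    if g3d is None:
        raise ValueError("edge_loss_2d requires the paired conformation")
    if z2d.shape[0] != g3d.n_atoms:
        raise ValueError(
            f"atom count mismatch: embeddings {z2d.shape[0]}, "
            f"conformation {g3d.n_atoms}")
    n = g3d.n_atoms
    if pair_set == "bonded":
        if g2d is None:
            raise ValueError("pair_set='bonded' requires the paired Graph2D")
        mask = g2d.adjacency()
    else:
        mask = ~np.eye(n, dtype=bool)
    uu, vv = np.nonzero(mask)
    labels = bin_distance(g3d.distance_map[uu, vv], spec)
    logits = heads.distogram(z2d[uu, vv])
    return _cross_entropy(logits, np.atleast_1d(labels), reduction)


def edge_loss_3d(z3d: Tensor, g2d: Graph2D, heads: EdgePredictionHeads,
                 reduction: str = "mean") -> Tensor:
    """Bond-class cross-entropy: 3D pair embeddings predict the 2D bond
    labels (with no-bond as the extra class) over all ordered pairs."""
    if g2d is None:
        raise ValueError("edge_loss_3d requires the paired 2D graph")
    if z3d.shape[0] != g2d.n_atoms:
        raise ValueError(
            f"atom count mismatch: embeddings {z3d.shape[0]}, "
            f"graph {g2d.n_atoms}")
    n = g2d.n_atoms
    mask = ~np.eye(n, dtype=bool)
    uu, vv = np.nonzero(mask)
    labels = bond_labels(g2d)[uu, vv]
    logits = heads.bond(z3d[uu, vv])
    return _cross_entropy(logits, labels, reduction)


def _derangement(n: int, rng: np.random.Generator) -> np.ndarray:
    shift = int(rng.integers(1, n))
    return (np.arange(n) + shift) % n


def _mean_condition(h: Tensor, n_atoms: int) -> Tensor:
    """Tile a molecule-level mean condition to ``n_atoms`` atoms, so a
    condition from a differently sized molecule can be paired with any
    noised sample (needed for the mismatched negatives)."""
    return h.mean(axis=0, keepdims=True) + Tensor(np.zeros((n_atoms, 1)))


def node_contrastive_loss(pairs, enc2d, enc3d, score_2d3d, score_3d2d,
                          heads: EdgePredictionHeads,
                          schedule_3d: SDESchedule = VE_DEFAULT,
                          schedule_2d: SDESchedule = VP_DEFAULT,
                          seed=0, states_2d=None, states_3d=None):
    """EBM-NCE node contrastive loss over both modalities.

    For each molecule a noised sample is paired with its own condition
    (positive) and with the condition of another in-batch molecule chosen by
    a seeded derangement (negative); a scalar discriminator head on the
    score network's pooled representation supplies the logit, and each
    modality contributes -1/2 E[log sigma(D_pos)] - 1/2 E[log(1-sigma(D_neg))].
    Returns (L_node_2D, L_node_3D).
    """
    if len(pairs) < 2:
        raise ValueError(
            "node_contrastive_loss needs a batch of >= 2 molecules to draw "
            "mismatched pairs; increase the batch size")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if states_2d is None:
        states_2d = [enc2d(g2d) for g2d, _ in pairs]
    if states_3d is None:
        states_3d = [enc3d(g3d) for _, g3d in pairs]
    perm = _derangement(len(pairs), rng)

    pos_3d, neg_3d, pos_2d, neg_2d = [], [], [], []
    for i, (g2d, g3d) in enumerate(pairs):
        j = int(perm[i])
        # 3D modality: noised conformation, conditioned on a 2D embedding
        t = float(rng.uniform(schedule_3d.t_eps, 1.0))
        ns = perturb_3d(g3d, t, schedule_3d, rng)
        _, rep_pos = score_2d3d(ns.coords_t,
                                _mean_condition(states_2d[i].h, g3d.n_atoms), t)
        _, rep_neg = score_2d3d(ns.coords_t,
                                _mean_condition(states_2d[j].h, g3d.n_atoms), t)
        pos_3d.append(heads.disc_3d(rep_pos))
        neg_3d.append(heads.disc_3d(rep_neg))
        # 2D modality: noised relaxed graph, conditioned on a 3D embedding
        t2 = float(rng.uniform(schedule_2d.t_eps, 1.0))
        ns2 = perturb_2d(g2d, t2, schedule_2d, rng)
        _, _, rep2_pos = score_3d2d(
            ns2.nodes_t, ns2.edges_t,
            _mean_condition(states_3d[i].h, g2d.n_atoms), t2)
        _, _, rep2_neg = score_3d2d(
            ns2.nodes_t, ns2.edges_t,
            _mean_condition(states_3d[j].h, g2d.n_atoms), t2)
        pos_2d.append(heads.disc_2d(rep2_pos))
        neg_2d.append(heads.disc_2d(rep2_neg))

    return (ebm_nce(stack(pos_2d).reshape(-1), stack(neg_2d).reshape(-1)),
            ebm_nce(stack(pos_3d).reshape(-1), stack(neg_3d).reshape(-1)))


def ebm_nce(pos_logits: Tensor, neg_logits: Tensor) -> Tensor:
    """Binary noise-contrastive term -1/2 E[log sigma(pos)]
    - 1/2 E[log(1 - sigma(neg))], written with softplus for stability."""
    return 0.5 * (_softplus(-pos_logits).mean() + _softplus(neg_logits).mean())


def _softplus(x: Tensor) -> Tensor:
    # numerically stable: softplus(x) = max(x, 0) + log1p(exp(-|x|))
    ax = x.relu() + (-x).relu()          # |x|
    return x.relu() + (1.0 + (-ax).exp()).log()


def gta_infomax_loss(pooled_2d: Tensor, pooled_3d: Tensor,
                     temperature: float = 0.1) -> Tensor:
    """Symmetric InfoNCE over cosine similarities of pooled molecule
    embeddings: row i of each input is the same molecule (positive);
    within-batch off-diagonal entries are negatives."""
    if pooled_2d.shape[0] < 2:
        raise ValueError("gta_infomax_loss needs a batch of >= 2 molecules")
    a = _l2_normalize(pooled_2d)
    b = _l2_normalize(pooled_3d)
    sim = (a @ b.transpose()) / temperature
    k = sim.shape[0]
    diag = (np.arange(k), np.arange(k))
    loss_ab = -log_softmax(sim, axis=1)[diag].mean()
    loss_ba = -log_softmax(sim.transpose(), axis=1)[diag].mean()
    return 0.5 * (loss_ab + loss_ba)


def _l2_normalize(x: Tensor) -> Tensor:
    norm = ((x * x).sum(axis=-1, keepdims=True) + 1e-12).sqrt()
    return x / norm


@dataclass
class LossWeights:
    eta1: float = 1.0     # node contrastive weight inside L_contrastive
    eta2: float = 1.0     # edge contrastive weight inside L_contrastive
    alpha1: float = 1.0   # contrastive
    alpha2: float = 1.0   # 2D -> 3D score matching
    alpha3: float = 1.0   # 3D -> 2D score matching
    alpha4: float = 0.0   # GTAInfomax (off unless enabled)

    def __post_init__(self):
        for name in ("eta1", "eta2", "alpha1", "alpha2", "alpha3", "alpha4"):
            if getattr(self, name) < 0:
                raise ValueError(f"loss weight {name} must be non-negative")


@dataclass
class LossBundle:
    """All component losses of one training step plus their weighted total."""

    node_2d: float = 0.0
    node_3d: float = 0.0
    edge_2d: float = 0.0
    edge_3d: float = 0.0
    gen_2d_to_3d: float = 0.0
    gen_3d_to_2d: float = 0.0
    infomax: float = 0.0
    total: float = 0.0

    def as_dict(self) -> dict:
        return {
            "L_node_2D": self.node_2d, "L_node_3D": self.node_3d,
            "L_edge_2D": self.edge_2d, "L_edge_3D": self.edge_3d,
            "L_2D3D": self.gen_2d_to_3d, "L_3D2D": self.gen_3d_to_2d,
            "L_infomax": self.infomax, "L_total": self.total,
        }


def total_loss(node_2d=None, node_3d=None, edge_2d=None, edge_3d=None,
               gen_2d_to_3d=None, gen_3d_to_2d=None, infomax=None,
               weights: LossWeights | None = None):
    """Weighted sum  a1*(eta1*L_node + eta2*L_edge) + a2*L_2D->3D +
    a3*L_3D->2D + a4*L_infomax over whichever components are provided.
    Returns (total Tensor, LossBundle of detached values)."""
    w = weights or LossWeights()
    zero = Tensor(0.0)

    def _or_zero(x):
        return zero if x is None else x

    l_node = _or_zero(node_2d) + _or_zero(node_3d)
    l_edge = _or_zero(edge_2d) + _or_zero(edge_3d)
    contrastive = w.eta1 * l_node + w.eta2 * l_edge
    total = (w.alpha1 * contrastive
             + w.alpha2 * _or_zero(gen_2d_to_3d)
             + w.alpha3 * _or_zero(gen_3d_to_2d)
             + w.alpha4 * _or_zero(infomax))
    bundle = LossBundle(
        node_2d=float(_or_zero(node_2d).data),
        node_3d=float(_or_zero(node_3d).data),
        edge_2d=float(_or_zero(edge_2d).data),
        edge_3d=float(_or_zero(edge_3d).data),
        gen_2d_to_3d=float(_or_zero(gen_2d_to_3d).data),
        gen_3d_to_2d=float(_or_zero(gen_3d_to_2d).data),
        infomax=float(_or_zero(infomax).data),
        total=float(total.data),
    )
    return total, bundle
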