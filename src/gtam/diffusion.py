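"""Forward-SDE perturbation kernels, conditional score networks, and the
denoising score-matching losses for both generation directions.

Two forward SDEs diffuse the two modalities:

* coordinates (2D → 3D direction): a variance-exploding SDE whose Gaussian
  perturbation kernel has mean x0 and std sigma_min * (sigma_max/sigma_min)^t;
* relaxed one-hot node/edge features (3D → 2D direction): a
  variance-preserving SDE with mean coefficient exp(-1/2 ∫0^t beta(s) ds)
  and two independent Brownian motions for the node and edge channels.

Because both kernels are Gaussian, the target score ∇ log p_t at a noised
sample has the closed form -(x_t - mean)/std², which the losses use as the
regression label.  The denoising losses are Monte-Carlo estimates of
Eqs-of-motion-weighted squared score error with the conventional std(t)²
weighting, under which a zero network has expectation equal to the feature
dimensionality — a convenient analytic check.

The 2D→3D score network is built from relative coordinates (rotation
equivariant, translation invariant); the 3D→2D score network is a per-node /
per-pair MLP over noised features and the (rigid-motion-invariant) 3D
condition embeddings.  Both output heads are zero-initialized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, concat
from .gta_core import rbf_expand
from .molio import Graph2D, Graph3D, N_BOND_CLASSES, N_ELEMENT_CLASSES, bond_labels
from .nn import MLP, Linear, Module

__all__ = [
    "SDESchedule",
    "Noised3D",
    "Noised2D",
    "perturb_3d",
    "perturb_2d",
    "relax_graph2d",
    "ScoreNet2Dto3D",
    "ScoreNet3Dto2D",
    "loss_2d_to_3d",
    "loss_3d_to_2d",
]


@dataclass(frozen=True)
class SDESchedule:
    """Closed-form perturbation kernel of a forward SDE.

    kind "ve": mean coefficient 1, std sigma_min*(sigma_max/sigma_min)^t.
    kind "vp": beta(t) = beta_min + t*(beta_max - beta_min); mean coefficient
    exp(-1/2 ∫ beta), std sqrt(1 - mean_coef²).
    """

    kind: str = "ve"
    sigma_min: float = 0.01
    sigma_max: float = 2.0
    beta_min: float = 0.1
    beta_max: float = 9.5
    t_eps: float = 1e-3

    def __post_init__(self):
        if self.kind not in ("ve", "vp"):
            raise ValueError("kind must be 've' or 'vp'")
        if not 0.0 < self.t_eps < 1.0:
            raise ValueError("t_eps must lie in (0, 1)")
        if self.kind == "ve" and not self.sigma_min < self.sigma_max:
            raise ValueError("sigma_min < sigma_max required")
        if self.kind == "vp" and not self.beta_min < self.beta_max:
            raise ValueError("beta_min < beta_max required")

    def mean_coef(self, t: float) -> float:
        if self.kind == "ve":
            return 1.0
        integral = self.beta_min * t + 0.5 * (self.beta_max - self.beta_min) * t**2
        return float(np.exp(-0.5 * integral))

    def std(self, t: float) -> float:
        if self.kind == "ve":
            return float(self.sigma_min * (self.sigma_max / self.sigma_min) ** t)
        return float(np.sqrt(1.0 - self.mean_coef(t) ** 2))

    def check_t(self, t: float) -> None:
        if not self.t_eps <= t <= 1.0:
            raise ValueError(f"t={t} outside [{self.t_eps}, 1]")


VE_DEFAULT = SDESchedule(kind="ve")
VP_DEFAULT = SDESchedule(kind="vp")


# ---------------------------------------------------------------------------
# Perturbation kernels
# ---------------------------------------------------------------------------

@dataclass
class Noised3D:
    coords_t: np.ndarray      # (N, 3), centered
    coords_0: np.ndarray      # (N, 3), centered clean coordinates
    t: float
    score: np.ndarray         # closed-form ∇ log p_t at coords_t


@dataclass
class Noised2D:
    nodes_t: np.ndarray       # (N, n_elements)
    edges_t: np.ndarray       # (N, N, n_bond_classes), diagonal zero
    nodes_0: np.ndarray
    edges_0: np.ndarray
    t: float
    score_nodes: np.ndarray
    score_edges: np.ndarray
    edge_mask: np.ndarray     # (N, N) bool off-diagonal


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def perturb_3d(g3d: Graph3D, t: float, schedule: SDESchedule = VE_DEFAULT,
               seed=0) -> Noised3D:
    """Diffuse centered coordinates with the Gaussian perturbation kernel and
    return the closed-form score at the sample."""
    schedule.check_t(t)
    rng = _rng(seed)
    x0 = g3d.coords - g3d.coords.mean(axis=0, keepdims=True)
    m, s = schedule.mean_coef(t), schedule.std(t)
    eps = rng.standard_normal(x0.shape)
    xt = m * x0 + s * eps
    score = -(xt - m * x0) / s**2
    return Noised3D(coords_t=xt, coords_0=x0, t=t, score=score)


def relax_graph2d(g2d: Graph2D):
    """Continuous relaxation of the discrete 2D features: element one-hots
    per node, 5-class bond-label one-hots per ordered pair (diagonal zero)."""
    n = g2d.n_atoms
    nodes = np.zeros((n, N_ELEMENT_CLASSES))
    nodes[np.arange(n), g2d.element_idx] = 1.0
    labels = bond_labels(g2d)
    mask = ~np.eye(n, dtype=bool)
    edges = np.zeros((n, n, N_BOND_CLASSES))
    uu, vv = np.nonzero(mask)
    edges[uu, vv, labels[uu, vv]] = 1.0
    return nodes, edges, mask


def perturb_2d(g2d: Graph2D, t: float, schedule: SDESchedule = VP_DEFAULT,
               seed=0) -> Noised2D:
    """Diffuse the relaxed node and edge features with independent Brownian
    drivers for the two channels."""
    schedule.check_t(t)
    rng = _rng(seed)
    nodes0, edges0, mask = relax_graph2d(g2d)
    m, s = schedule.mean_coef(t), schedule.std(t)
    eps_nodes = rng.standard_normal(nodes0.shape)        # w^1
    eps_edges = rng.standard_normal(edges0.shape)        # w^2, independent
    eps_edges *= mask[:, :, None]
    nodes_t = m * nodes0 + s * eps_nodes
    edges_t = m * edges0 + s * eps_edges
    return Noised2D(
        nodes_t=nodes_t, edges_t=edges_t, nodes_0=nodes0, edges_0=edges0, t=t,
        score_nodes=-(nodes_t - m * nodes0) / s**2,
        score_edges=-(edges_t - m * edges0) / s**2 * mask[:, :, None],
        edge_mask=mask,
    )


# ---------------------------------------------------------------------------
# Score networks
# ---------------------------------------------------------------------------

def _time_feature(t: float, n: int) -> np.ndarray:
    return np.full((n, 1), float(t))


class ScoreNet2Dto3D(Module):
    """SE(3)-equivariant conditional score over coordinates.

    The score is a sum of pairwise terms w_uv * (x_u - x_v) with invariant
    scalar weights w_uv predicted from the 2D condition embeddings of both
    endpoints, a radial basis over the current interatomic distance, and t.
    Relative coordinates make the output translation invariant; invariant
    weights times relative vectors make it rotation equivariant.  The weight
    head is zero-initialized, so the initial score is identically zero.
    """

    def __init__(self, d_cond: int, d_hidden: int = 64, n_rbf: int = 16,
                 rbf_cutoff: float = 6.0, seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))
        self.n_rbf = n_rbf
        self.rbf_cutoff = rbf_cutoff
        d_in = 2 * d_cond + n_rbf + 1
        self.pair_mlp = MLP(d_in, d_hidden, d_hidden, n_layers=2, rng=rng)
        self.weight_head = Linear(d_hidden, 1, rng, zero_init=True)
        self.d_hidden = d_hidden

    def forward(self, coords_t, h_cond: Tensor, t: float):
        """Returns (score (N,3), invariant pooled representation)."""
        x = coords_t if isinstance(coords_t, Tensor) else Tensor(coords_t)
        n = x.shape[0]
        if h_cond.shape[0] != n:
            raise ValueError(
                f"atom count mismatch: coords have {n}, condition has "
                f"{h_cond.shape[0]}")
        xc = x - x.mean(axis=0, keepdims=True)
        diff = xc.reshape(n, 1, 3) - xc.reshape(1, n, 3)
        off = (~np.eye(n, dtype=bool)).astype(float)
        d = ((diff * diff).sum(axis=-1) + np.eye(n) + 1e-12).sqrt() * off
        rbf = rbf_expand(d, self.n_rbf, self.rbf_cutoff)
        hu = h_cond.reshape(n, 1, -1) + Tensor(np.zeros((n, n, 1)))
        hv = h_cond.reshape(1, n, -1) + Tensor(np.zeros((n, n, 1)))
        tt = Tensor(np.full((n, n, 1), float(t)))
        feats = concat([hu, hv, rbf, tt], axis=-1)
        hidden = self.pair_mlp(feats)                       # (N, N, d_hidden)
        w = self.weight_head(hidden) * off[:, :, None]      # (N, N, 1)
        score = (w * diff).sum(axis=1)
        rep = (hidden * off[:, :, None]).mean(axis=(0, 1))  # invariant pooled
        return score, rep


class ScoreNet3Dto2D(Module):
    """SE(3)-invariant conditional score over relaxed 2D features: per-node
    and per-pair MLPs over the noised features, the 3D condition embeddings
    and t.  Inherits rigid-motion invariance from the condition encoder and
    is permutation equivariant by construction.  Output heads zero-init."""

    def __init__(self, d_cond: int, d_hidden: int = 64, seed: int = 0):
        rng = np.random.default_rng(np.random.SeedSequence([seed, 12]))
        self.node_mlp = MLP(N_ELEMENT_CLASSES + d_cond + 1, d_hidden, d_hidden,
                            n_layers=2, rng=rng)
        self.node_head = Linear(d_hidden, N_ELEMENT_CLASSES, rng, zero_init=True)
        self.edge_mlp = MLP(N_BOND_CLASSES + 2 * d_cond + 1, d_hidden, d_hidden,
                            n_layers=2, rng=rng)
        self.edge_head = Linear(d_hidden, N_BOND_CLASSES, rng, zero_init=True)
        self.d_hidden = d_hidden

    def forward(self, nodes_t, edges_t, h_cond: Tensor, t: float):
        """Returns (node score, edge score, invariant pooled representation)."""
        nt = nodes_t if isinstance(nodes_t, Tensor) else Tensor(nodes_t)
        et = edges_t if isinstance(edges_t, Tensor) else Tensor(edges_t)
        n = nt.shape[0]
        if h_cond.shape[0] != n:
            raise ValueError(
                f"atom count mismatch: features have {n}, condition has "
                f"{h_cond.shape[0]}")
        node_in = concat([nt, h_cond, Tensor(_time_feature(t, n))], axis=-1)
        node_hidden = self.node_mlp(node_in)
        s_nodes = self.node_head(node_hidden)
        off = (~np.eye(n, dtype=bool)).astype(float)[:, :, None]
        hu = h_cond.reshape(n, 1, -1) + Tensor(np.zeros((n, n, 1)))
        hv = h_cond.reshape(1, n, -1) + Tensor(np.zeros((n, n, 1)))
        tt = Tensor(np.full((n, n, 1), float(t)))
        edge_in = concat([et, hu, hv, tt], axis=-1)
        edge_hidden = self.edge_mlp(edge_in)
        s_edges = self.edge_head(edge_hidden) * off
        rep = concat([node_hidden.mean(axis=0),
                      (edge_hidden * off).mean(axis=(0, 1))])
        return s_nodes, s_edges, rep


# ---------------------------------------------------------------------------
# Denoising score-matching losses
# ---------------------------------------------------------------------------

def _sample_t(rng, schedule) -> float:
    return float(rng.uniform(schedule.t_eps, 1.0))


def loss_2d_to_3d(pairs, encoder2d, score_net: ScoreNet2Dto3D,
                  schedule: SDESchedule = VE_DEFAULT, seed=0,
                  weighting: str = "std2", states=None) -> Tensor:
    """Monte-Carlo denoising score matching for coordinate generation
    conditioned on the 2D graph: one uniformly sampled t per molecule,
    squared error against the closed-form kernel score, std(t)² weighted
    by default (set weighting="none" for the unweighted form).  Pass
    ``states`` (precomputed 2D EmbeddingStates) to reuse encoder outputs."""
    rng = _rng(seed)
    total = None
    for i, (g2d, g3d) in enumerate(pairs):
        t = _sample_t(rng, schedule)
        ns = perturb_3d(g3d, t, schedule, rng)
        h = (states[i].h if states is not None else encoder2d(g2d).h)
        pred, _ = score_net(ns.coords_t, h, t)
        res = pred - Tensor(ns.score)
        term = (res * res).sum()
        if weighting == "std2":
            term = term * schedule.std(t) ** 2
        total = term if total is None else total + term
    return total / len(pairs)


def loss_3d_to_2d(pairs, encoder3d, score_net: ScoreNet3Dto2D,
                  schedule: SDESchedule = VP_DEFAULT, seed=0,
                  weighting: str = "std2", states=None) -> Tensor:
    """Mirror of :func:`loss_2d_to_3d` over the relaxed node and edge
    features, conditioned on the 3D conformation."""
    rng = _rng(seed)
    total = None
    for i, (g2d, g3d) in enumerate(pairs):
        t = _sample_t(rng, schedule)
        ns = perturb_2d(g2d, t, schedule, rng)
        h = (states[i].h if states is not None else encoder3d(g3d).h)
        s_nodes, s_edges, _ = score_net(ns.nodes_t, ns.edges_t, h, t)
        rn = s_nodes - Tensor(ns.score_nodes)
        re = s_edges - Tensor(ns.score_edges)
        term = (rn * rn).sum() + (re * re).sum()
        if weighting == "std2":
            term = term * schedule.std(t) ** 2
        total = term if total is None else total + term
    return total / len(pairs)
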