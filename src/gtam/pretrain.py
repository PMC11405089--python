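"""Pretraining orchestration: model bundle, training loop, checkpoints,
JSONL logging, and checkpoint diagnostics.

Every source of randomness is threaded from the single ``seed`` in the run
configuration; with one thread the loop is bit-reproducible, and a resumed
run continues exactly where the checkpoint left off (the generator state is
stored alongside the parameters).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .autodiff import no_grad
from .diffusion import (
    ScoreNet2Dto3D,
    ScoreNet3Dto2D,
    SDESchedule,
    VE_DEFAULT,
    VP_DEFAULT,
    loss_2d_to_3d,
    loss_3d_to_2d,
)
from .gta_core import EncoderConfig, GTAEncoder2D, GTAEncoder3D
from .molio import DEFAULT_BINSPEC, bin_distance, bond_labels
from .nn import Adam, Module
from .objectives import (
    EdgePredictionHeads,
    LossBundle,
    LossWeights,
    edge_loss_2d,
    edge_loss_3d,
    gta_infomax_loss,
    node_contrastive_loss,
    total_loss,
)

__all__ = ["RunConfig", "PretrainModel", "pretrain", "save_checkpoint",
           "load_checkpoint", "evaluate_checkpoint"]


@dataclass
class RunConfig:
    encoder: EncoderConfig = field(default_factory=EncoderConfig)
    schedule_3d: SDESchedule = field(default_factory=lambda: VE_DEFAULT)
    schedule_2d: SDESchedule = field(default_factory=lambda: VP_DEFAULT)
    weights: LossWeights = field(default_factory=LossWeights)
    score_hidden: int = 64
    lr: float = 1e-4
    n_steps: int = 200
    seed: int = 0
    enable_node: bool = True
    enable_edge: bool = True
    enable_gen: bool = True
    enable_infomax: bool = False
    log_path: str | None = None
    checkpoint_path: str | None = None
    checkpoint_every: int = 0     # 0 = only at the end

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "encoder" in d and isinstance(d["encoder"], dict):
            d["encoder"] = EncoderConfig(**d["encoder"])
        for key in ("schedule_3d", "schedule_2d"):
            if key in d and isinstance(d[key], dict):
                d[key] = SDESchedule(**d[key])
        if "weights" in d and isinstance(d["weights"], dict):
            d["weights"] = LossWeights(**d["weights"])
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)


class PretrainModel(Module):
    """Both encoders, both score networks and all prediction heads."""

    def __init__(self, config: RunConfig):
        self.config = config
        enc = config.encoder
        self.enc2d = GTAEncoder2D(enc, seed=config.seed)
        self.enc3d = GTAEncoder3D(enc, seed=config.seed)
        self.score_2d3d = ScoreNet2Dto3D(enc.d_h, d_hidden=config.score_hidden,
                                         seed=config.seed)
        self.score_3d2d = ScoreNet3Dto2D(enc.d_h, d_hidden=config.score_hidden,
                                         seed=config.seed)
        self.heads = EdgePredictionHeads(
            d_z2=enc.d_z, d_z3=enc.d_z,
            disc_dim_2d=2 * config.score_hidden,
            disc_dim_3d=config.score_hidden,
            seed=config.seed,
        )

    def compute_losses(self, pairs, rng: np.random.Generator):
        """One full forward over a batch of paired molecules; returns
        (total Tensor, LossBundle)."""
        cfg = self.config
        states_2d = [self.enc2d(g2d) for g2d, _ in pairs]
        states_3d = [self.enc3d(g3d) for _, g3d in pairs]
        kw = {}
        if cfg.enable_edge:
            e2 = [edge_loss_2d(s.z, g3d, self.heads)
                  for s, (_, g3d) in zip(states_2d, pairs)]
            e3 = [edge_loss_3d(s.z, g2d, self.heads)
                  for s, (g2d, _) in zip(states_3d, pairs)]
            kw["edge_2d"] = sum(e2[1:], e2[0]) / len(e2)
            kw["edge_3d"] = sum(e3[1:], e3[0]) / len(e3)
        if cfg.enable_node:
            n2, n3 = node_contrastive_loss(
                pairs, self.enc2d, self.enc3d, self.score_2d3d,
                self.score_3d2d, self.heads, cfg.schedule_3d, cfg.schedule_2d,
                seed=rng, states_2d=states_2d, states_3d=states_3d)
            kw["node_2d"], kw["node_3d"] = n2, n3
        if cfg.enable_gen:
            kw["gen_2d_to_3d"] = loss_2d_to_3d(
                pairs, self.enc2d, self.score_2d3d, cfg.schedule_3d, seed=rng)
            kw["gen_3d_to_2d"] = loss_3d_to_2d(
                pairs, self.enc3d, self.score_3d2d, cfg.schedule_2d, seed=rng)
        if cfg.enable_infomax:
            from .autodiff import stack
            p2 = stack([s.pooled for s in states_2d])
            p3 = stack([s.pooled for s in states_3d])
            kw["infomax"] = gta_infomax_loss(p2, p3)
        return total_loss(weights=cfg.weights, **kw)


def pretrain(pairs, config: RunConfig, model: PretrainModel | None = None,
             optimizer: Adam | None = None, rng: np.random.Generator | None = None,
             start_step: int = 0):
    """Run the pretraining loop; returns (model, list of LossBundle).

    Every step computes all enabled loss components on the full fixture
    batch, applies one Adam update and logs the bundle.  A NaN in any
    component aborts with the offending component and step named.
    """
    if len(pairs) < 2 and config.enable_node:
        raise ValueError("node contrastive loss needs >= 2 paired molecules")
    model = model or PretrainModel(config)
    optimizer = optimizer or Adam(model.parameters(), lr=config.lr)
    rng = rng or np.random.default_rng(np.random.SeedSequence([config.seed, 41]))
    log_file = open(config.log_path, "a") if config.log_path else None
    history: list[LossBundle] = []
    try:
        for step in range(start_step, config.n_steps):
            total, bundle = model.compute_losses(pairs, rng)
            for name, value in bundle.as_dict().items():
                if not np.isfinite(value):
                    raise RuntimeError(
                        f"non-finite loss component {name} at step {step}")
            optimizer.zero_grad()
            total.backward()
            optimizer.step()
            history.append(bundle)
            if log_file:
                log_file.write(json.dumps({"step": step, **bundle.as_dict()})
                               + "\n")
            if (config.checkpoint_path and config.checkpoint_every
                    and (step + 1) % config.checkpoint_every == 0):
                save_checkpoint(model, config.checkpoint_path, step + 1, rng)
    finally:
        if log_file:
            log_file.close()
    if config.checkpoint_path:
        save_checkpoint(model, config.checkpoint_path, config.n_steps, rng)
    return model, history


# ---------------------------------------------------------------------------
# Checkpoints: npz with the config as embedded JSON -- self-describing
# ---------------------------------------------------------------------------

def save_checkpoint(model: PretrainModel, path, step: int,
                    rng: np.random.Generator | None = None) -> None:
    arrays = {f"param_{i}": a for i, a in enumerate(model.state_arrays())}
    meta = {
        "config": model.config.to_dict(),
        "step": step,
        "rng_state": rng.bit_generator.state if rng else None,
    }
    with open(path, "wb") as fh:
        np.savez(fh, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path):
    """Returns (model, step, rng) rebuilt from a checkpoint file."""
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        arrays = [data[f"param_{i}"]
                  for i in range(sum(1 for k in data.files
                                     if k.startswith("param_")))]
    config = RunConfig.from_dict(meta["config"])
    model = PretrainModel(config)
    model.load_state_arrays(arrays)
    rng = np.random.default_rng()
    if meta.get("rng_state"):
        rng.bit_generator.state = meta["rng_state"]
    return model, int(meta["step"]), rng


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def probe_accuracies(model: PretrainModel, pairs) -> dict:
    """Edge-probe accuracies on held-out molecules: bond-type top-1 from the
    3D pair embeddings, distogram top-1 from the 2D pair embeddings."""
    bond_hits = bond_total = disto_hits = disto_total = 0
    with no_grad():
        for g2d, g3d in pairs:
            n = g2d.n_atoms
            mask = ~np.eye(n, dtype=bool)
            uu, vv = np.nonzero(mask)
            z3 = model.enc3d(g3d).z
            logits = model.heads.bond(z3[uu, vv]).data
            labels = bond_labels(g2d, g3d)[uu, vv]
            bond_hits += int((logits.argmax(axis=-1) == labels).sum())
            bond_total += len(labels)
            z2 = model.enc2d(g2d).z
            dlogits = model.heads.distogram(z2[uu, vv]).data
            dlabels = bin_distance(g3d.distance_map[uu, vv], DEFAULT_BINSPEC)
            disto_hits += int((dlogits.argmax(axis=-1) == dlabels).sum())
            disto_total += len(dlabels)
    return {
        "bond_accuracy": bond_hits / bond_total,
        "distogram_accuracy": disto_hits / disto_total,
    }


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random 3x3 rotation matrix (QR of a Gaussian matrix)."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def invariance_suite(model: PretrainModel, pairs, n_motions: int = 5,
                     seed: int = 0) -> dict:
    """Max relative deviation of the 3D encoder outputs under random rigid
    motions of the input conformations."""
    from .molio import build_graph3d

    rng = np.random.default_rng(seed)
    worst = 0.0
    with no_grad():
        for _, g3d in pairs:
            ref = model.enc3d(g3d)
            for _ in range(n_motions):
                rot = random_rotation(rng)
                shift = rng.normal(0, 5.0, 3)
                moved = build_graph3d(g3d.coords @ rot.T + shift,
                                      g3d.atomic_numbers)
                out = model.enc3d(moved)
                scale = np.abs(ref.pooled.data).max() + 1e-12
                dev = np.abs(out.pooled.data - ref.pooled.data).max() / scale
                hscale = np.abs(ref.h.data).max() + 1e-12
                hdev = np.abs(out.h.data - ref.h.data).max() / hscale
                worst = max(worst, dev, hdev)
    return {"se3_max_rel_dev": worst}


def evaluate_checkpoint(checkpoint_path, pairs) -> dict:
    """Diagnostics report for a checkpoint on a fixture set: SE(3)
    invariance, edge-probe accuracies, and per-component losses."""
    model, step, _ = load_checkpoint(checkpoint_path)
    rng = np.random.default_rng(0)
    report = {"step": step}
    report.update(invariance_suite(model, pairs))
    report.update(probe_accuracies(model, pairs))
    with no_grad():
        _, bundle = model.compute_losses(pairs, rng)
    report["losses"] = bundle.as_dict()
    return report
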