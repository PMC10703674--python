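"""Contrastive training of the 3D embedding encoder.

Each training step draws a batch of positive pairs (two views of the same
segment within 150 um path length, from distinct segments across the
batch), extracts and augments the masked views, and minimizes

    L = NT-Xent(projections; tau) + w_dec * L_decorrelation(embeddings)

with momentum SGD under a linear-warmup + cosine-decay learning-rate
schedule. The NT-Xent temperature defaults to 0.1; the base learning rate
defaults to 0.2 at a reference batch of 512 positive pairs and is scaled
linearly with the actual batch size, so small-batch refinement runs use a
proportionally smaller rate.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .nn import (Encoder, EncoderConfig, SGD, build_encoder, decorrelation,
                 get_state, nt_xent, set_state, warmup_cosine_schedule)
from .nn.losses import decorrelation_loss, nt_xent_loss  # re-export  # noqa: F401
from .pairs import PairPools
from .skeleton import Skeleton
from .synth import SegmentedVolume
from .views import augment, extract_masked_view, views_to_batch


@dataclass(frozen=True)
class LossConfig:
    temperature: float = 0.1
    decorrelation_weight: float = 1.0
    batch_pairs: int = 512
    base_lr: float = 0.2
    reference_batch_pairs: int = 512
    momentum: float = 0.9

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.decorrelation_weight < 0:
            raise ValueError("decorrelation weight must be non-negative")

    @property
    def lr(self) -> float:
        return self.base_lr * self.batch_pairs / self.reference_batch_pairs


@dataclass
class TrainResult:
    encoder: Encoder
    loss_trace: list[dict]
    opt_velocity: list[np.ndarray] | None = None

    @property
    def final_loss(self) -> float:
        return self.loss_trace[-1]["total"]


def _batch_views(volume: SegmentedVolume, skeletons: dict[int, Skeleton],
                 batch, view_size: int, rng: np.random.Generator,
                 augment_mode: str) -> np.ndarray:
    views = []
    for pair in batch:
        sk = skeletons[pair.segment_id]
        for node in (pair.node_a, pair.node_b):
            v = extract_masked_view(volume, sk.coords(node), pair.segment_id,
                                    view_size)
            if augment_mode != "none":
                v = augment(v, seed=int(rng.integers(1 << 31)),
                            mode=augment_mode)
            views.append(v)
    return views_to_batch(views)


def train(pools: PairPools, volume: SegmentedVolume,
          skeletons: dict[int, Skeleton], encoder: Encoder,
          loss_config: LossConfig, steps: int, seed: int = 0,
          lr_schedule=None, start_step: int = 0,
          total_steps: int | None = None,
          opt_velocity: list[np.ndarray] | None = None) -> TrainResult:
    """Run contrastive training; returns the trained encoder and loss trace.

    Deterministic given ``seed`` and the initial encoder state; a run
    restarted from a checkpoint at ``start_step`` with the same seed
    reproduces the continuation of the original loss trace.
    """
    if not pools.segment_ids:
        raise ValueError("empty pair pools")
    cfg = encoder.config
    if lr_schedule is None:
        lr_schedule = warmup_cosine_schedule(
            loss_config.lr, total_steps if total_steps is not None else steps + start_step)
    opt = SGD(encoder.parameters(), lr=loss_config.lr,
              momentum=loss_config.momentum)
    if opt_velocity is not None:
        for vel, saved in zip(opt.velocity, opt_velocity):
            vel[...] = saved
    encoder.set_training(True)
    trace: list[dict] = []
    for local_step in range(steps):
        step = start_step + local_step
        step_rng = np.random.default_rng((seed, step))
        batch = pools.sample_batch(loss_config.batch_pairs,
                                   seed=int(step_rng.integers(1 << 31)))
        x = _batch_views(volume, skeletons, batch, cfg.view_size, step_rng,
                         "contrastive")
        emb, proj = encoder.forward(x)
        l_con, d_proj = nt_xent(proj, loss_config.temperature)
        l_dec, d_emb = decorrelation(emb)
        total = l_con + loss_config.decorrelation_weight * l_dec
        if not np.isfinite(total):
            raise RuntimeError(
                f"training diverged at step {step}: contrastive={l_con}, "
                f"decorrelation={l_dec}")
        encoder.backward(loss_config.decorrelation_weight * d_emb, d_proj)
        opt.lr = lr_schedule(step)
        opt.step()
        trace.append({"step": step, "contrastive": l_con,
                      "decorrelation": l_dec, "total": total,
                      "lr": opt.lr})
    return TrainResult(encoder, trace, opt_velocity=opt.velocity)


def refine(encoder: Encoder, pools: PairPools, volume: SegmentedVolume,
           skeletons: dict[int, Skeleton], steps: int,
           batch_pairs: int = 8, loss_config: LossConfig | None = None,
           seed: int = 0) -> TrainResult:
    """Continue training a pretrained encoder on a new dataset.

    No layers are frozen; the learning rate is the original base rate
    scaled linearly to the (typically much smaller) batch size.
    """
    base = loss_config or LossConfig()
    cfg = LossConfig(temperature=base.temperature,
                     decorrelation_weight=base.decorrelation_weight,
                     batch_pairs=batch_pairs, base_lr=base.base_lr,
                     reference_batch_pairs=base.reference_batch_pairs,
                     momentum=base.momentum)
    return train(pools, volume, skeletons, encoder, cfg, steps, seed=seed)


def embed_views(encoder: Encoder, views: np.ndarray,
                batch_size: int = 16) -> np.ndarray:
    """64-d embeddings for an (N, 1, V, V, V) batch; projection head dropped."""
    if views.ndim != 5 or views.shape[2] != encoder.config.view_size:
        raise ValueError(
            f"expected (N, 1, {encoder.config.view_size}^3) views, "
            f"got {views.shape}")
    return encoder.embed(views, batch_size=batch_size)


# -- checkpoints -----------------------------------------------------------


def save_checkpoint(encoder: Encoder, directory: str | Path,
                    meta: dict | None = None,
                    opt_velocity: list[np.ndarray] | None = None) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    spec = {"encoder_config": encoder.config.to_dict(), "meta": meta or {}}
    (d / "architecture.json").write_text(json.dumps(spec, indent=2))
    state = get_state(encoder.state_container)
    if opt_velocity is not None:
        for i, vel in enumerate(opt_velocity):
            state[f"__opt_velocity__/{i}"] = vel
    np.savez(d / "weights.npz", **state)


def load_checkpoint(directory: str | Path) -> tuple[Encoder, dict]:
    d = Path(directory)
    spec = json.loads((d / "architecture.json").read_text())
    config = EncoderConfig.from_dict(spec["encoder_config"])
    encoder, _ = build_encoder(config)
    with np.load(d / "weights.npz") as npz:
        state = {k: v for k, v in npz.items()
                 if not k.startswith("__opt_velocity__/")}
        set_state(encoder.state_container, state)
    return encoder, spec.get("meta", {})


def load_optimizer_state(directory: str | Path) -> list[np.ndarray] | None:
    """Momentum buffers saved alongside a checkpoint, if any."""
    with np.load(Path(directory) / "weights.npz") as npz:
        keys = sorted((k for k in npz if k.startswith("__opt_velocity__/")),
                      key=lambda k: int(k.rsplit("/", 1)[1]))
        if not keys:
            return None
        return [npz[k] for k in keys]
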