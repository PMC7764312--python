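"""Patch-based cross-entropy training and the two-step pre-train/fine-tune
strategy.

Patches are sampled uniformly per iteration, optionally augmented, and
optimized with AdamW (decoupled weight decay) + AMSGrad. Pre-training uses
learning rate 1e-3; fine-tuning continues from the pre-trained weights at
1e-4. The reference configuration trains 96-cube patches at batch size 4
for 300k iterations; desk presets shrink patch size and iteration count so
the full loop runs on one CPU.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .augment import AugmentConfig, compose
from .io_schema import LabelVolume, Volume3D
from .network import Network, NetworkConfig, Tensor

__all__ = [
    "TrainConfig",
    "Checkpoint",
    "AdamW",
    "sample_patch",
    "cross_entropy_loss",
    "run_stage",
    "two_step_train",
]

PRETRAIN_LR = 1e-3
FINETUNE_LR = 1e-4


@dataclass
class TrainConfig:
    stage: str = "pretrain"  # pretrain | finetune
    learning_rate: float | None = None  # default from stage
    batch_size: int = 4
    iterations: int = 300_000
    patch_size: tuple[int, int, int] = (96, 96, 96)
    weight_decay: float = 1e-2
    checkpoint_every: int = 0  # 0 = only final
    seed: int = 0
    network: NetworkConfig = field(default_factory=NetworkConfig)
    augment: AugmentConfig | None = None
    # fraction of patches centered on a random foreground-structure voxel
    # instead of drawn uniformly (0 = plain random sampling, the default)
    balanced_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.stage not in ("pretrain", "finetune"):
            raise ValueError(f"unknown stage {self.stage!r}")
        if self.learning_rate is None:
            self.learning_rate = PRETRAIN_LR if self.stage == "pretrain" \
                else FINETUNE_LR
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be positive")
        self.patch_size = tuple(int(s) for s in self.patch_size)

    @classmethod
    def desk(cls, stage: str = "pretrain", iterations: int = 2000,
             n_classes: int = 34, **overrides) -> "TrainConfig":
        kwargs = dict(stage=stage, iterations=iterations,
                      patch_size=(32, 32, 32),
                      network=NetworkConfig.desk(n_classes=n_classes))
        kwargs.update(overrides)
        return cls(**kwargs)


@dataclass
class Checkpoint:
    """Network weights + config + training provenance."""

    state: dict[str, np.ndarray]
    network: NetworkConfig
    stage: str = "init"
    iteration: int = 0

    def build(self, seed: int = 0) -> Network:
        net = Network(self.network, seed=seed)
        net.load_state_dict(self.state)
        return net

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        meta = {
            "network": self.network.__dict__,
            "stage": self.stage,
            "iteration": self.iteration,
            "keys": sorted(self.state),
        }
        np.savez_compressed(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **self.state)
        return path if path.suffix == ".npz" else path.with_suffix(
            path.suffix + ".npz")

    @classmethod
    def load(cls, path: str | Path) -> "Checkpoint":
        with np.load(path) as payload:
            meta = json.loads(bytes(payload["__meta__"]).decode())
            state = {k: payload[k] for k in payload.files if k != "__meta__"}
        return cls(state, NetworkConfig.from_dict(meta["network"]),
                   meta["stage"], meta["iteration"])


class AdamW:
    """AdamW with the maximum-of-second-moment (AMSGrad) correction."""

    def __init__(self, params: Sequence[Tensor], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 1e-2):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.v_max = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            np.maximum(self.v_max[i], self.v[i], out=self.v_max[i])
            m_hat = self.m[i] / bc1
            v_hat = self.v_max[i] / bc2
            p.data -= self.lr * (m_hat / (np.sqrt(v_hat) + self.eps)
                                 + self.weight_decay * p.data)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()


def sample_patch(v: Volume3D, lv: LabelVolume,
                 size: Sequence[int], rng: np.random.Generator,
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly random patch crop, image and labels cut identically."""
    size = tuple(int(s) for s in size)
    if v.shape != lv.shape:
        raise ValueError("image and label grids differ")
    for n, s in zip(v.shape, size):
        if n < s:
            raise ValueError(f"volume {v.shape} smaller than patch {size}")
    origin = tuple(int(rng.integers(0, n - s + 1))
                   for n, s in zip(v.shape, size))
    sl = tuple(slice(o, o + s) for o, s in zip(origin, size))
    return v.data[sl].copy(), lv.data[sl].copy()


def sample_patch_centered(v: Volume3D, lv: LabelVolume, size: Sequence[int],
                          center: Sequence[int],
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Patch centered on ``center``, clamped so it stays inside the volume."""
    size = tuple(int(s) for s in size)
    origin = []
    for c, s, n in zip(center, size, v.shape):
        o = int(np.clip(int(c) - s // 2, 0, n - s))
        origin.append(o)
    sl = tuple(slice(o, o + s) for o, s in zip(origin, size))
    return v.data[sl].copy(), lv.data[sl].copy()


class _ForegroundIndex:
    """Per-volume cache of foreground voxel coordinates, by label."""

    def __init__(self, lv: LabelVolume):
        self.by_label = {}
        for label in lv.present_ids():
            if label == 0:
                continue
            self.by_label[label] = np.argwhere(lv.data == label)

    def random_center(self, rng: np.random.Generator) -> np.ndarray | None:
        if not self.by_label:
            return None
        label = list(self.by_label)[int(rng.integers(0, len(self.by_label)))]
        coords = self.by_label[label]
        return coords[int(rng.integers(0, len(coords)))]


def cross_entropy_loss(probs, target: np.ndarray) -> float:
    """Mean over voxels of -log p(target class); probs (N, *S) or (B, N, *S)."""
    p = probs.data if isinstance(probs, Tensor) else np.asarray(probs)
    target = np.asarray(target)
    if p.ndim == target.ndim + 1:
        p = p[None]
        target = target[None]
    n_classes = p.shape[1]
    if target.max() >= n_classes:
        raise ValueError(f"target id {target.max()} >= {n_classes} classes")
    picked = np.take_along_axis(p, target[:, None], axis=1)[:, 0]
    return float(-np.mean(np.log(np.maximum(picked, 1e-30))))


def _loss_trace_to_csv(trace: list[tuple[int, float]], path: Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["iteration", "loss"])
        writer.writerows(trace)


def run_stage(cfg: TrainConfig,
              data: Sequence[tuple[Volume3D, LabelVolume]],
              init: Checkpoint | None = None,
              out_dir: str | Path | None = None,
              ) -> tuple[Checkpoint, list[tuple[int, float]]]:
    """Run one training stage: sample -> augment -> forward -> loss -> step.

    Deterministic given ``cfg.seed``. Returns the final checkpoint and the
    per-iteration loss trace.
    """
    if cfg.stage == "finetune" and init is None:
        raise ValueError("finetune stage requires an initial checkpoint")
    if not data:
        raise ValueError("no training data")
    n_classes = cfg.network.n_classes
    for _, lv in data:
        if lv.schema.n_classes > n_classes:
            raise ValueError(
                f"schema has {lv.schema.n_classes} classes but network "
                f"outputs {n_classes}")
    rng = np.random.default_rng(cfg.seed)
    net = Network(cfg.network, seed=cfg.seed)
    if init is not None:
        net.load_state_dict(init.state)
    opt = AdamW(net.parameters(), lr=cfg.learning_rate,
                weight_decay=cfg.weight_decay)
    augment = compose(cfg.augment, rng) if cfg.augment is not None else None
    fg_index = [_ForegroundIndex(lv) for _, lv in data] \
        if cfg.balanced_fraction > 0 else None
    trace: list[tuple[int, float]] = []
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    net.train()
    for it in range(cfg.iterations):
        imgs = np.empty((cfg.batch_size, 1) + cfg.patch_size, dtype=np.float32)
        tgts = np.empty((cfg.batch_size,) + cfg.patch_size, dtype=np.int64)
        for b in range(cfg.batch_size):
            k = int(rng.integers(0, len(data)))
            vol, lab = data[k]
            center = None
            if fg_index is not None and rng.random() < cfg.balanced_fraction:
                center = fg_index[k].random_center(rng)
            if center is not None:
                img, tgt = sample_patch_centered(vol, lab, cfg.patch_size,
                                                 center)
            else:
                img, tgt = sample_patch(vol, lab, cfg.patch_size, rng)
            if augment is not None:
                pv = Volume3D(img, vol.spacing)
                plv = LabelVolume(tgt, lab.schema, lab.spacing)
                pv, plv = augment(pv, plv)
                img, tgt = pv.data, plv.data
            imgs[b, 0] = img
            tgts[b] = tgt
        logits = net.forward_logits(Tensor(imgs))
        loss = logits.cross_entropy(tgts)
        value = loss.item()
        if not np.isfinite(value):
            raise FloatingPointError(
                f"non-finite loss at iteration {it}: {value} "
                f"(lr={cfg.learning_rate}, stage={cfg.stage})")
        opt.zero_grad()
        loss.backward()
        opt.step()
        trace.append((it, value))
        if (out_dir is not None and cfg.checkpoint_every
                and (it + 1) % cfg.checkpoint_every == 0):
            Checkpoint(net.state_dict(), cfg.network, cfg.stage,
                       it + 1).save(out_dir / f"ckpt_{it + 1:07d}.npz")
    ckpt = Checkpoint(net.state_dict(), cfg.network, cfg.stage, cfg.iterations)
    if init is not None and cfg.iterations == 0:
        ckpt = Checkpoint(init.state, cfg.network, cfg.stage, 0)
    if out_dir is not None:
        ckpt.save(out_dir / "ckpt_final.npz")
        _loss_trace_to_csv(trace, out_dir / "loss_trace.csv")
    return ckpt, trace


def two_step_train(pre_data: Sequence[tuple[Volume3D, LabelVolume]],
                   fine_data: Sequence[tuple[Volume3D, LabelVolume]],
                   pre_cfg: TrainConfig, fine_cfg: TrainConfig,
                   out_dir: str | Path | None = None,
                   ) -> tuple[Checkpoint, list, Checkpoint, list]:
    """Stage 1 trains from scratch on auxiliary labels; stage 2 continues
    from those weights on manually-labeled data. Both checkpoints returned."""
    if pre_cfg.stage != "pretrain" or fine_cfg.stage != "finetune":
        raise ValueError("configs must be (pretrain, finetune)")
    schema_a = pre_data[0][1].schema
    schema_b = fine_data[0][1].schema
    if schema_a.ids != schema_b.ids:
        raise ValueError("pre-training and fine-tuning schemas differ")
    sub = None if out_dir is None else Path(out_dir)
    pre_ckpt, pre_trace = run_stage(
        pre_cfg, pre_data, out_dir=None if sub is None else sub / "pretrain")
    fine_ckpt, fine_trace = run_stage(
        fine_cfg, fine_data, init=pre_ckpt,
        out_dir=None if sub is None else sub / "finetune")
    return pre_ckpt, pre_trace, fine_ckpt, fine_trace
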