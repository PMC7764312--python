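"""The full segmentation network: encoder pyramid, nested dense skip
pathways ending in split-attention blocks, and a 1x1x1 softmax classifier."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from ..io_schema import Volume3D
from .autograd import Tensor, no_grad
from .layers import Conv3d, ConvUnit, Module, ResNeStBlock

__all__ = ["NetworkConfig", "NodeAddress", "Network"]


@dataclass(frozen=True)
class NetworkConfig:
    levels: int = 4
    base_channels: int = 32
    cardinality: int = 2
    radix: int = 2
    reduction: int = 4
    norm_groups: int = 8
    n_classes: int = 34
    conv_units_per_node: int = 2
    eps: float = 1e-5
    in_channels: int = 1

    def __post_init__(self) -> None:
        if self.cardinality < 1 or self.radix < 1:
            raise ValueError("cardinality and radix must be >= 1")
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")
        if self.levels < 2:
            raise ValueError("need at least 2 pyramid levels")
        g = self.cardinality * self.radix
        if self.base_channels % g:
            raise ValueError(f"base channels {self.base_channels} must be "
                             f"divisible by G={g}")

    @property
    def feature_groups(self) -> int:
        """G = K * R."""
        return self.cardinality * self.radix

    def channels_at(self, level: int) -> int:
        return self.base_channels * (2 ** level)

    @classmethod
    def desk(cls, n_classes: int = 34, **overrides) -> "NetworkConfig":
        """Scaled-down preset (3 levels, 8 base channels) for CPU work."""
        kwargs = dict(levels=3, base_channels=8, n_classes=n_classes)
        kwargs.update(overrides)
        return cls(**kwargs)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(asdict(self), indent=1))
        return path

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        return cls(**d)


@dataclass(frozen=True)
class NodeAddress:
    """Position in the skip-pathway lattice: level p, dense index q."""

    p: int
    q: int

    def validate(self, levels: int) -> None:
        if not 0 <= self.p < levels:
            raise ValueError(f"level {self.p} out of range for {levels} levels")
        if not 0 <= self.q <= levels - 1 - self.p:
            raise ValueError(f"dense index {self.q} invalid at level {self.p}")


def node_addresses(levels: int) -> list[NodeAddress]:
    return [NodeAddress(p, q) for p in range(levels)
            for q in range(levels - p)]


class _Upsampler(Module):
    """Trilinear 2x up-sampling followed by a 1x1x1 channel-matching conv."""

    def __init__(self, in_channels: int, out_channels: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv3d(in_channels, out_channels, 1, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.conv(x.upsample2())


class _Node(Module):
    def __init__(self, addr: NodeAddress, cfg: NetworkConfig,
                 rng: np.random.Generator):
        super().__init__()
        self.addr = addr
        width = cfg.channels_at(addr.p)
        if addr.q == 0:
            in_ch = cfg.in_channels if addr.p == 0 else cfg.channels_at(addr.p - 1)
        else:
            in_ch = addr.q * width + width  # q same-level predecessors + upsampled
            self.up = _Upsampler(cfg.channels_at(addr.p + 1), width, rng=rng)
        chain_in = in_ch
        for i in range(cfg.conv_units_per_node):
            setattr(self, f"conv{i}", ConvUnit(chain_in, width, cfg.norm_groups,
                                               eps=cfg.eps, rng=rng))
            chain_in = width
        self.n_units = cfg.conv_units_per_node
        if addr.q > 0:
            self.block = ResNeStBlock(width, width, cfg.cardinality, cfg.radix,
                                      cfg.reduction, cfg.norm_groups, cfg.eps,
                                      rng=rng)

    def forward(self, same_level: list[Tensor], below: Tensor | None) -> Tensor:
        addr = self.addr
        if addr.q == 0:
            if len(same_level) != 1 or below is not None:
                raise ValueError(f"node {addr} takes exactly one input")
            x = same_level[0]
            if addr.p > 0:
                x = x.maxpool2()
        else:
            if below is None or len(same_level) != addr.q:
                raise ValueError(
                    f"node {addr} needs {addr.q} same-level inputs plus one "
                    f"deeper input")
            x = Tensor.concat(same_level + [self.up(below)], axis=1)
        for i in range(self.n_units):
            x = getattr(self, f"conv{i}")(x)
        if addr.q > 0:
            x = self.block(x)
        return x


class Network(Module):
    """Encoder/decoder over ``cfg.levels`` resolutions with dense skip nodes.

    Node (p, 0) is the encoder column (max-pool for p > 0, then conv units);
    node (p, q>0) concatenates all same-level predecessors with the
    up-sampled (p+1, q-1) output, applies the conv-unit chain and a
    split-attention residual block. The classifier consumes node
    (0, levels-1).
    """

    def __init__(self, cfg: NetworkConfig, seed: int = 0):
        super().__init__()
        self.cfg = cfg
        rng = np.random.default_rng(seed)
        self.addresses = node_addresses(cfg.levels)
        for addr in self.addresses:
            setattr(self, f"node_{addr.p}_{addr.q}", _Node(addr, cfg, rng))
        self.classifier_conv = Conv3d(cfg.base_channels, cfg.n_classes, 1, rng=rng)

    def node(self, p: int, q: int) -> _Node:
        return getattr(self, f"node_{p}_{q}")

    def node_forward(self, addr: NodeAddress, same_level: list[Tensor],
                     below: Tensor | None) -> Tensor:
        addr.validate(self.cfg.levels)
        return self.node(addr.p, addr.q)(same_level, below)

    def _check_patch(self, shape: tuple[int, ...]) -> None:
        factor = 2 ** (self.cfg.levels - 1)
        for s in shape:
            if s % factor:
                raise ValueError(
                    f"patch dims {shape} must be divisible by {factor} "
                    f"for {self.cfg.levels} levels")

    def forward_logits(self, x: Tensor) -> Tensor:
        """Logits (B, N, D, H, W) for a batch of patches."""
        self._check_patch(x.shape[2:])
        outputs: dict[tuple[int, int], Tensor] = {}
        levels = self.cfg.levels
        # encoder column first, then dense nodes in diagonal order
        outputs[(0, 0)] = self.node(0, 0)([x], None)
        for p in range(1, levels):
            outputs[(p, 0)] = self.node(p, 0)([outputs[(p - 1, 0)]], None)
        for q in range(1, levels):
            for p in range(0, levels - q):
                same = [outputs[(p, k)] for k in range(q)]
                outputs[(p, q)] = self.node(p, q)(same, outputs[(p + 1, q - 1)])
        return self.classifier_conv(outputs[(0, levels - 1)])

    def classifier(self, features: Tensor) -> Tensor:
        """1x1x1 conv to N channels + per-voxel softmax."""
        return self.classifier_conv(features).softmax(axis=1)

    def forward(self, patch: "Volume3D | np.ndarray | Tensor") -> Tensor:
        """Per-voxel class probabilities (B, N, D, H, W) for one patch."""
        if isinstance(patch, Volume3D):
            arr = patch.data[None, None].astype(np.float32)
            x = Tensor(arr)
        elif isinstance(patch, Tensor):
            x = patch
        else:
            arr = np.asarray(patch, dtype=np.float32)
            if arr.ndim == 3:
                arr = arr[None, None]
            x = Tensor(arr)
        return self.forward_logits(x).softmax(axis=1)

    def predict_probs(self, patch: np.ndarray) -> np.ndarray:
        """Inference helper: (N, D, H, W) probabilities, no graph kept."""
        was_training = self.training
        self.eval()
        try:
            with no_grad():
                out = self.forward(patch)
        finally:
            self.train(was_training)
        return out.data[0]
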