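"""Network building blocks: EvoNorm-S0 convolution units, split-attention
(ResNeSt-style) blocks with radix softmax, and a tiny Module system for
parameter bookkeeping and checkpointing."""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, evonorm_s0_op

__all__ = [
    "Module",
    "Conv3d",
    "EvoNormS0",
    "ConvUnit",
    "BatchNorm3d",
    "SplitAttention",
    "ResNeStBlock",
    "evonorm_s0",
]


class Module:
    """Minimal parameter container with named recursion and state dicts."""

    def __init__(self) -> None:
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield f"{prefix}{name}", p
        for name, m in self._modules.items():
            yield from m.named_parameters(f"{prefix}{name}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield f"{prefix}{name}", b
        for name, m in self._modules.items():
            yield from m.named_buffers(f"{prefix}{name}.")

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({f"buffer.{name}": b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        bufs = dict(self.named_buffers())
        for name, value in state.items():
            if name.startswith("buffer."):
                key = name[len("buffer."):]
                if key not in bufs:
                    raise KeyError(f"unknown buffer {key}")
                bufs[key][...] = value
            else:
                if name not in own:
                    raise KeyError(f"unknown parameter {name}")
                if own[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {name}")
                own[name].data[...] = value

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _kaiming(shape: tuple[int, ...], fan_in: int,
             rng: np.random.Generator) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Conv3d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel: int = 3,
                 pad: int | None = None, bias: bool = True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.pad = (kernel - 1) // 2 if pad is None else pad
        fan_in = in_channels * kernel ** 3
        self.weight = Tensor(_kaiming((out_channels, in_channels, kernel, kernel,
                                       kernel), fan_in, rng), requires_grad=True)
        self.bias = Tensor(np.zeros(out_channels, dtype=np.float32),
                           requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(f"expected {self.in_channels} input channels, "
                             f"got {x.shape[1]}")
        return x.conv3d(self.weight, self.bias, pad=self.pad)


def evonorm_s0(x: Tensor, gamma: Tensor, beta: Tensor, v: Tensor,
               groups: int, eps: float = 1e-5) -> Tensor:
    """y = gamma * x * sigmoid(v*x) / sqrt(Var_group(x) + eps) + beta.

    The variance is taken per sample over each channel group's channels and
    all spatial positions (biased estimator). gamma/beta/v are per-channel.
    """
    return evonorm_s0_op(x, gamma, beta, v, groups, eps)


class EvoNormS0(Module):
    def __init__(self, channels: int, groups: int = 8, eps: float = 1e-5):
        super().__init__()
        self.channels = channels
        self.groups = min(groups, channels)
        while channels % self.groups:
            self.groups -= 1
        self.eps = eps
        shape = (1, channels, 1, 1, 1)
        self.gamma = Tensor(np.ones(shape, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(shape, dtype=np.float32), requires_grad=True)
        self.v = Tensor(np.ones(shape, dtype=np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return evonorm_s0(x, self.gamma, self.beta, self.v, self.groups, self.eps)


class ConvUnit(Module):
    """3x3x3 convolution (stride 1, padding 1) followed by EvoNorm-S0."""

    def __init__(self, in_channels: int, out_channels: int, norm_groups: int = 8,
                 kernel: int = 3, eps: float = 1e-5,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv3d(in_channels, out_channels, kernel, rng=rng)
        self.norm = EvoNormS0(out_channels, norm_groups, eps)

    def forward(self, x: Tensor) -> Tensor:
        return self.norm(self.conv(x))


class BatchNorm3d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        shape = (1, channels, 1, 1, 1)
        self.gamma = Tensor(np.ones(shape, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(shape, dtype=np.float32), requires_grad=True)
        self.register_buffer("running_mean", np.zeros(shape, dtype=np.float32))
        self.register_buffer("running_var", np.ones(shape, dtype=np.float32))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3, 4), keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=(0, 2, 3, 4), keepdims=True)
            self.running_mean *= (1 - self.momentum)
            self.running_mean += self.momentum * mu.data
            self.running_var *= (1 - self.momentum)
            self.running_var += self.momentum * var.data
            return self.gamma * ((x - mu) / (var + self.eps).sqrt()) + self.beta
        mu_t = Tensor(self.running_mean)
        var_t = Tensor(self.running_var)
        return self.gamma * ((x - mu_t) / (var_t + self.eps).sqrt()) + self.beta


class SplitAttention(Module):
    """Split-attention over K cardinal groups with R splits each (G = K*R).

    The input is split channel-wise into G groups; each split goes through a
    3x3x3 conv unit to width C/K. Within a cardinal group the R split maps
    are summed, globally average-pooled, passed through a bottleneck
    (1x1x1 conv, batch norm, relu), and expanded to R*(C/K) logits whose
    per-channel softmax across the R splits weights the split maps. Cardinal
    group outputs are concatenated, restoring C channels.
    """

    def __init__(self, channels: int, cardinality: int = 2, radix: int = 2,
                 reduction: int = 4, norm_groups: int = 8, eps: float = 1e-5,
                 rng: np.random.Generator | None = None):
        super().__init__()
        g = cardinality * radix
        if channels % g:
            raise ValueError(f"channels {channels} not divisible by G={g}")
        self.channels = channels
        self.cardinality = cardinality
        self.radix = radix
        self.split_channels = channels // g      # width of each input split
        self.group_channels = channels // cardinality  # width after split conv
        self.hidden = max(self.group_channels * radix // reduction, 8)
        rng = rng or np.random.default_rng(0)
        for i in range(g):
            setattr(self, f"split_conv{i}",
                    ConvUnit(self.split_channels, self.group_channels,
                             norm_groups, eps=eps, rng=rng))
        for k in range(cardinality):
            setattr(self, f"fc1_{k}", Conv3d(self.group_channels, self.hidden, 1,
                                             rng=rng))
            setattr(self, f"bn_{k}", BatchNorm3d(self.hidden, eps=eps))
            setattr(self, f"fc2_{k}",
                    Conv3d(self.hidden, self.group_channels * radix, 1, rng=rng))

    @property
    def n_feature_groups(self) -> int:
        return self.cardinality * self.radix

    def forward(self, x: Tensor, return_attention: bool = False):
        c, r = self.cardinality, self.radix
        sc = self.split_channels
        outputs = []
        attentions = []
        for k in range(c):
            splits = []
            for j in range(r):
                i = k * r + j
                xs = x[:, i * sc:(i + 1) * sc]
                splits.append(getattr(self, f"split_conv{i}")(xs))
            summed = splits[0]
            for s in splits[1:]:
                summed = summed + s
            pooled = summed.mean(axis=(2, 3, 4), keepdims=True)
            z = getattr(self, f"fc1_{k}")(pooled)
            z = getattr(self, f"bn_{k}")(z).relu()
            logits = getattr(self, f"fc2_{k}")(z)  # (B, gc*r, 1, 1, 1)
            b = logits.shape[0]
            gc = self.group_channels
            logits = logits.reshape(b, r, gc, 1, 1, 1)
            if r > 1:
                attn = logits.softmax(axis=1)
            else:
                attn = logits.sigmoid()
            attentions.append(attn)
            out_k = splits[0] * attn[:, 0]
            for j in range(1, r):
                out_k = out_k + splits[j] * attn[:, j]
            outputs.append(out_k)
        out = Tensor.concat(outputs, axis=1)
        if return_attention:
            return out, attentions
        return out


class ResNeStBlock(Module):
    """Split-attention followed by a 1x1x1 conv and a residual shortcut.

    The shortcut is the identity when input and output widths match,
    otherwise a 1x1x1 projection. Stride is always 1 here.
    """

    def __init__(self, in_channels: int, out_channels: int | None = None,
                 cardinality: int = 2, radix: int = 2, reduction: int = 4,
                 norm_groups: int = 8, eps: float = 1e-5,
                 rng: np.random.Generator | None = None):
        super().__init__()
        out_channels = out_channels or in_channels
        self.attention = SplitAttention(in_channels, cardinality, radix,
                                        reduction, norm_groups, eps, rng=rng)
        self.project = Conv3d(in_channels, out_channels, 1, rng=rng)
        if in_channels != out_channels:
            self.shortcut = Conv3d(in_channels, out_channels, 1, rng=rng)
        else:
            self.shortcut = None
        self.out_channels = out_channels

    def forward(self, x: Tensor) -> Tensor:
        y = self.project(self.attention(x))
        sc = x if self.shortcut is None else self.shortcut(x)
        return y + sc
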