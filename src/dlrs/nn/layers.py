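"""Layer building blocks on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat, conv2d, upsample_nearest


class Module:
    """Base class: recursive parameter discovery and train/eval mode."""

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out: list[tuple[str, Tensor]] = []

        def visit(name: str, val) -> None:
            if isinstance(val, Tensor) and val.requires_grad:
                out.append((name, val))
            elif isinstance(val, Module):
                out.extend(val.named_parameters(prefix=name + "."))
            elif isinstance(val, (list, tuple)):  # nested containers included
                for i, item in enumerate(val):
                    visit(f"{name}.{i}", item)

        for attr, val in vars(self).items():
            visit(f"{prefix}{attr}", val)
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        if set(params) != set(state):
            missing = set(params) ^ set(state)
            raise KeyError(f"state dict keys mismatch: {sorted(missing)}")
        for k, v in state.items():
            params[k].data = np.asarray(v, dtype=np.float64).copy()

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def _he_normal(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


class Conv2d(Module):
    """3x3 (or kxk) convolution with He fan-in initialization."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 k: int = 3, stride: int = 1, pad: int | None = None):
        self.stride = stride
        self.pad = (k // 2) if pad is None else pad
        fan_in = in_ch * k * k
        self.weight = Tensor(_he_normal(rng, (out_ch, in_ch, k, k), fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.weight = Tensor(_he_normal(rng, (in_dim, out_dim), in_dim), requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class SEBlock(Module):
    """Squeeze-and-excitation channel gate.

    Global average pooling summarizes each channel; a two-layer perceptron
    (C -> C/r -> C) with a sigmoid produces per-channel weights that rescale
    the feature map. ``identity=True`` fixes the gate at 1 (the no-SE
    ablation).
    """

    def __init__(self, channels: int, reduction_ratio: int, rng: np.random.Generator):
        hidden = max(channels // reduction_ratio, 1)
        self.fc1 = Linear(channels, hidden, rng)
        self.fc2 = Linear(hidden, channels, rng)
        self.identity = False

    def __call__(self, x: Tensor) -> Tensor:
        if self.identity:
            return x
        squeezed = x.mean(axis=(2, 3))  # (B, C)
        gate = self.fc2(self.fc1(squeezed).relu()).sigmoid()  # (B, C)
        B, C = gate.shape
        return x * gate.reshape(B, C, 1, 1)


def global_avg_pool(x: Tensor) -> Tensor:
    return x.mean(axis=(2, 3))


__all__ = [
    "Module",
    "Conv2d",
    "Linear",
    "SEBlock",
    "Tensor",
    "concat",
    "conv2d",
    "upsample_nearest",
    "global_avg_pool",
]
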