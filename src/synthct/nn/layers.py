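"""Layers for the synthesis networks, built on :mod:`synthct.nn.autodiff`.

Includes the spatially-adaptive normalization (SPADE) block at the heart
of the generator: features are instance-normalized, then re-scaled and
re-shifted per pixel by maps predicted from the (resized) semantic label
stack, so the semantic layout survives every stage of generation.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = ["Module", "Conv2d", "Linear", "SPADE", "instance_norm", "resize_nearest"]


class Module:
    """Tiny parameter container; submodules found by attribute walk."""

    def parameters(self) -> list[Tensor]:
        out: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"parameter count mismatch: {len(arrays)} vs {len(params)}"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = a.astype(np.float32)


class Conv2d(Module):
    """He-initialized convolution: weight sd = gain * sqrt(2 / fan_in)."""

    def __init__(self, cin, cout, k=3, stride=1, padding=None,
                 rng: np.random.Generator | None = None, gain=1.0):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.padding = (k - 1) // 2 if padding is None else padding
        sd = gain * np.sqrt(2.0 / (cin * k * k))
        self.weight = Tensor(
            rng.normal(0.0, sd, size=(cout, cin, k, k)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, self.stride, self.padding)


class Linear(Module):
    def __init__(self, n_in, n_out, rng: np.random.Generator | None = None,
                 gain=1.0):
        rng = rng or np.random.default_rng(0)
        sd = gain * np.sqrt(2.0 / n_in)
        self.weight = Tensor(
            rng.normal(0.0, sd, size=(n_in, n_out)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


def instance_norm(x: Tensor, eps: float = 1e-5) -> Tensor:
    """Parameter-free instance normalization over the spatial axes."""
    m = x.mean(axis=(2, 3), keepdims=True)
    centered = x - m
    v = (centered * centered).mean(axis=(2, 3), keepdims=True)
    return centered * (v + eps).pow(-0.5)


def resize_nearest(seg: np.ndarray, side: int) -> np.ndarray:
    """Nearest-neighbour resize of a (N, C, H, W) stack to side x side."""
    h = seg.shape[2]
    if h == side:
        return seg
    idx = (np.arange(side) * (h / side)).astype(int)
    return seg[:, :, idx][:, :, :, idx]


class SPADE(Module):
    """Spatially-adaptive normalization conditioned on the label stack."""

    def __init__(self, channels, label_channels, hidden=16,
                 rng: np.random.Generator | None = None):
        # spatial context comes from the 3x3 shared conv; the modulation
        # heads are 1x1, which keeps SPADE cheap at full resolution
        self.shared = Conv2d(label_channels, hidden, k=3, rng=rng)
        self.gamma = Conv2d(hidden, channels, k=1, rng=rng)
        self.beta = Conv2d(hidden, channels, k=1, rng=rng)

    def __call__(self, x: Tensor, seg: np.ndarray) -> Tensor:
        seg_t = Tensor(resize_nearest(seg, x.shape[2]))
        h = self.shared(seg_t).relu()
        return instance_norm(x) * (1.0 + self.gamma(h)) + self.beta(h)
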