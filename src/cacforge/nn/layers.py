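"""Layers, parameter containers and checkpointing for the numpy networks."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .core import Tensor, conv2d, conv3d, global_mean_pool


class Module:
    """Base class: tracks parameters of itself and of child modules."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in vars(self).values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_arrays(self) -> list[np.ndarray]:
        return [p.data for p in self.parameters()]

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(f"checkpoint has {len(arrays)} arrays, model expects {len(params)}")
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch: {p.data.shape} vs {a.shape}")
            p.data = a.astype(np.float32)


def _he_init(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    def __init__(self, rng, c_in, c_out, k=3, stride=1, pad=None):
        self.stride = stride
        self.pad = (k // 2) if pad is None else pad
        self.w = Tensor(_he_init(rng, (c_out, c_in, k, k), c_in * k * k), requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)


class Conv3d(Module):
    def __init__(self, rng, c_in, c_out, k=3, pad=None):
        self.pad = (k // 2) if pad is None else pad
        self.w = Tensor(_he_init(rng, (c_out, c_in, k, k, k), c_in * k**3), requires_grad=True)
        self.b = Tensor(np.zeros(c_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.w, self.b, pad=self.pad)


class Dense(Module):
    def __init__(self, rng, n_in, n_out):
        self.w = Tensor(_he_init(rng, (n_in, n_out), n_in), requires_grad=True)
        self.b = Tensor(np.zeros(n_out, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x.matmul(self.w) + self.b


class ResBlock2d(Module):
    """Two 3x3 convolutions with an identity skip (pre-activation style)."""

    def __init__(self, rng, channels):
        self.c1 = Conv2d(rng, channels, channels)
        self.c2 = Conv2d(rng, channels, channels)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.c1(x).relu()
        return x + self.c2(h)


class ResBlock3d(Module):
    def __init__(self, rng, channels):
        self.c1 = Conv3d(rng, channels, channels)
        self.c2 = Conv3d(rng, channels, channels)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.c1(x).relu()
        return x + self.c2(h)


class Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# Checkpoints: one .npz per model with the config embedded as JSON
# ---------------------------------------------------------------------------

def save_checkpoint(path, model: Module, config: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {f"p{i}": a for i, a in enumerate(model.state_arrays())}
    np.savez(path, config=np.frombuffer(json.dumps(config).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path) -> tuple[dict, list[np.ndarray]]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model checkpoint not found: {path}")
    with np.load(path) as data:
        config = json.loads(bytes(data["config"]).decode())
        n = len([k for k in data.files if k.startswith("p")])
        arrays = [data[f"p{i}"] for i in range(n)]
    return config, arrays
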