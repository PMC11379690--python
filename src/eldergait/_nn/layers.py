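"""Neural-network modules built on the autodiff core.

Conventions follow the familiar layer-library style: modules register
parameters and sub-modules automatically on attribute assignment, expose
``state_dict``/``load_state_dict`` with slash-separated names, and switch
between training and evaluation behaviour via ``train()``/``eval()`` (which
only matters for batch normalization here).
"""

from __future__ import annotations

import hashlib
from typing import Iterator

import numpy as np

from .autodiff import Tensor, conv1d, relu, sqrt

__all__ = [
    "Module", "Linear", "Conv1d", "BatchNorm1d", "ReLU", "Sequential",
    "Upsample1d", "param_checksum",
]


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_children", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self._params[name] = value
        elif isinstance(value, Module):
            self._children[name] = value
        object.__setattr__(self, name, value)

    # -- traversal ---------------------------------------------------------
    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Tensor]]:
        for name, p in self._params.items():
            yield prefix + name, p
        for cname, child in self._children.items():
            yield from child.named_parameters(prefix + cname + "/")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def trainable_parameters(self) -> list[Tensor]:
        return [p for p in self.parameters() if p.requires_grad]

    def modules(self) -> Iterator["Module"]:
        yield self
        for child in self._children.values():
            yield from child.modules()

    # -- mode / gradient switches -----------------------------------------
    def train(self):
        for m in self.modules():
            object.__setattr__(m, "training", True)
        return self

    def eval(self):
        for m in self.modules():
            object.__setattr__(m, "training", False)
        return self

    def freeze(self):
        for p in self.parameters():
            p.requires_grad = False
        return self

    def unfreeze(self):
        for p in self.parameters():
            p.requires_grad = True
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # -- (de)serialization -------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, buf in self._buffers().items():
            out[name] = buf.copy()
        return out

    def _buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        bufs = {}
        for attr in getattr(self, "_buffer_names", ()):  # set by BatchNorm1d
            bufs[prefix + attr] = getattr(self, attr)
        for cname, child in self._children.items():
            bufs.update(child._buffers(prefix + cname + "/"))
        return bufs

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True):
        own_params = dict(self.named_parameters())
        own_bufs = self._buffers()
        own = {**own_params, **own_bufs}
        missing = sorted(set(own) - set(state))
        unexpected = sorted(set(state) - set(own))
        mismatched = sorted(
            k for k in set(own) & set(state)
            if tuple(state[k].shape) != tuple(np.shape(own[k]))
        )
        if strict and (missing or unexpected or mismatched):
            raise ValueError(
                "state mismatch: "
                f"missing={missing} unexpected={unexpected} shape_mismatch={mismatched}")
        for k in set(own) & set(state):
            if k in mismatched:
                continue
            if k in own_params:
                own_params[k].data[...] = state[k]
            else:
                self._assign_buffer(k, state[k])
        return {"missing": missing, "unexpected": unexpected, "mismatched": mismatched}

    def _assign_buffer(self, dotted: str, value: np.ndarray):
        parts = dotted.split("/")
        mod: Module = self
        for part in parts[:-1]:
            mod = mod._children[part]
        getattr(mod, parts[-1])[...] = value

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)


def param_checksum(module: Module) -> str:
    """SHA-1 over all parameter bytes, in name order; detects any update."""
    h = hashlib.sha1()
    for name, p in sorted(module.named_parameters()):
        h.update(name.encode())
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()


class Linear(Module):
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        super().__init__()
        scale = np.sqrt(2.0 / in_dim)
        self.weight = Tensor(rng.normal(0.0, scale, (in_dim, out_dim)).astype(np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_dim, np.float32), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv1d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, bias: bool = True):
        super().__init__()
        scale = np.sqrt(2.0 / (in_ch * kernel))
        self.weight = Tensor(rng.normal(0.0, scale,
                                        (out_ch, in_ch, kernel)).astype(np.float32),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(out_ch, np.float32), requires_grad=True) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, stride=self.stride,
                      padding=self.padding)


class BatchNorm1d(Module):
    """Batch normalization over (N, C, L); running stats used in eval mode."""

    _buffer_names = ("running_mean", "running_var")

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones((1, channels, 1), np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros((1, channels, 1), np.float32), requires_grad=True)
        self.running_mean = np.zeros((1, channels, 1), dtype=np.float32)
        self.running_var = np.ones((1, channels, 1), dtype=np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2), keepdims=True)
            m = self.momentum
            self.running_mean[...] = (1 - m) * self.running_mean + m * mu.data
            self.running_var[...] = (1 - m) * self.running_var + m * var.data
        else:
            mu, var = Tensor(self.running_mean), Tensor(self.running_var)
        xhat = (x - mu) / sqrt(var + self.eps)
        return xhat * self.gamma + self.beta


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return relu(x)


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"l{i}", layer)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Upsample1d(Module):
    """Nearest-neighbour upsampling along the last axis (for the U-Net head)."""

    def __init__(self, factor: int = 2):
        super().__init__()
        self.factor = factor

    def forward(self, x: Tensor) -> Tensor:
        from .autodiff import _make  # reuse graph plumbing
        f = self.factor
        out_data = np.repeat(x.data, f, axis=-1)

        def backward():
            if x.requires_grad:
                g = out.grad
                N, C, L = g.shape
                x._accum(g.reshape(N, C, L // f, f).sum(axis=-1))

        out = _make(out_data, (x,), backward)
        return out
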