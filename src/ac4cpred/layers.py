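"""Neural-network building blocks on the autodiff core.

A tiny Module system: modules own parameters (Tensors with gradients),
sub-modules, and a shared training/inference flag. Inference mode freezes
batch-norm statistics and disables dropout, so scoring is deterministic and
batch-size independent.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv1d, embedding_lookup

__all__ = ["Module", "Linear", "Conv1d", "BatchNorm1d", "Dropout", "Embedding"]


class Module:
    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        super().__setattr__(name, value)

    def register(self, name: str, data: np.ndarray) -> Tensor:
        t = Tensor(np.asarray(data, dtype=np.float32), requires_grad=True)
        self._params[name] = t
        return t

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Tensor]]:
        out = [(prefix + n, p) for n, p in self._params.items()]
        for cname, child in self._children.items():
            out.extend(child.named_parameters(prefix + cname + "."))
        return out

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for child in self._children.values():
            child.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self) -> dict[str, np.ndarray]:
        """All learnable parameters plus persistent buffers, by name."""
        state = {n: p.data for n, p in self.named_parameters()}
        for n, b in self.named_buffers():
            state["buffer:" + n] = b
        return state

    def named_buffers(self, prefix: str = "") -> list[tuple[str, np.ndarray]]:
        out = [(prefix + n, b) for n, b in getattr(self, "_buffers", {}).items()]
        for cname, child in self._children.items():
            out.extend(child.named_buffers(prefix + cname + "."))
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = {n: (m, n2) for m, n2, n in self._walk_buffers()}
        for key, arr in state.items():
            if key.startswith("buffer:"):
                name = key[len("buffer:"):]
                mod, local = buffers[name]
                mod._buffers[local] = arr.copy()
            else:
                if params[key].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for parameter {key}")
                params[key].data = arr.astype(np.float32).copy()

    def _walk_buffers(self, prefix: str = ""):
        for n in getattr(self, "_buffers", {}):
            yield self, n, prefix + n
        for cname, child in self._children.items():
            yield from child._walk_buffers(prefix + cname + ".")


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int,
            fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        super().__init__()
        self.w = self.register("w", _glorot(rng, (in_features, out_features),
                                            in_features, out_features))
        self.b = self.register("b", np.zeros(out_features))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    __call__ = forward


class Conv1d(Module):
    """Dilated 1-D convolution, optionally weight-normalised.

    With ``weight_norm=True`` the kernel is re-parameterised as
    w = g * v / ||v|| (norm over each output filter), the stabilisation used
    inside the TCN residual blocks.
    """

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 rng: np.random.Generator, dilation: int = 1,
                 padding: str = "same", weight_norm: bool = False):
        super().__init__()
        self.dilation = int(dilation)
        self.padding = padding
        self.weight_norm = weight_norm
        fan_in = in_channels * kernel_size
        init = _glorot(rng, (out_channels, in_channels, kernel_size),
                       fan_in, out_channels * kernel_size)
        if weight_norm:
            norm = np.sqrt((init ** 2).sum(axis=(1, 2), keepdims=True)) + 1e-12
            self.v = self.register("v", init / norm)
            self.g = self.register("g", norm)
        else:
            self.w = self.register("w", init)
        self.b = self.register("b", np.zeros(out_channels))

    def kernel(self) -> Tensor:
        if not self.weight_norm:
            return self.w
        norm = (self.v * self.v).sum(axis=(1, 2), keepdims=True).pow(0.5)
        return self.v * (self.g / (norm + 1e-12))

    def forward(self, x: Tensor) -> Tensor:
        return conv1d(x, self.kernel(), self.b, dilation=self.dilation,
                      padding=self.padding)

    __call__ = forward


class BatchNorm1d(Module):
    """Per-channel normalisation over (batch, length) with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = self.register("gamma", np.ones(channels))
        self.beta = self.register("beta", np.zeros(channels))
        self._buffers: dict[str, np.ndarray] = {
            "running_mean": np.zeros(channels, dtype=np.float32),
            "running_var": np.ones(channels, dtype=np.float32),
        }

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mu) * (x - mu)).mean(axis=(0, 2), keepdims=True)
            m = self.momentum
            self._buffers["running_mean"] = ((1 - m) * self._buffers["running_mean"]
                                             + m * mu.data.reshape(-1))
            self._buffers["running_var"] = ((1 - m) * self._buffers["running_var"]
                                            + m * var.data.reshape(-1))
        else:
            mu = Tensor(self._buffers["running_mean"].reshape(1, -1, 1))
            var = Tensor(self._buffers["running_var"].reshape(1, -1, 1))
        xhat = (x - mu) * (var + self.eps).pow(-0.5)
        c = self.gamma.data.shape[0]
        return xhat * self.gamma.reshape(1, c, 1) + self.beta.reshape(1, c, 1)

    __call__ = forward


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        super().__init__()
        if not (0.0 <= p < 1.0):
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = (self.rng.random(x.shape) >= self.p).astype(np.float32)
        return x * Tensor(keep / (1.0 - self.p))

    __call__ = forward


class Embedding(Module):
    """Learnable lookup table mapping integer base codes to vectors."""

    def __init__(self, vocab: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = self.register("weight", rng.normal(0.0, 0.1, size=(vocab, dim)))

    def forward(self, codes: np.ndarray) -> Tensor:
        return embedding_lookup(self.weight, codes)

    __call__ = forward
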