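"""Network building blocks on the autodiff engine.

Layout conventions: volumetric activations are NCDHW, token sequences are
(batch, tokens, features).  Parameter initialization draws from a
caller-supplied ``numpy.random.Generator`` so identical seeds build
bit-identical networks.
"""

from __future__ import annotations

import numpy as np

from vmatrl.nn.autodiff import Tensor, conv3d

__all__ = ["Module", "Linear", "Conv3d", "BatchNorm3d", "LayerNorm",
           "MultiheadSelfAttention", "relu", "tanh", "softplus", "softmax"]


def relu(x: Tensor) -> Tensor:
    return x.relu()


def tanh(x: Tensor) -> Tensor:
    return x.tanh()


def softplus(x: Tensor) -> Tensor:
    return x.softplus()


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - Tensor(x.data.max(axis=axis, keepdims=True))
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


class Module:
    """Base class: parameter/buffer registration, train/eval, state dicts."""

    def __init__(self):
        self._params: dict = {}
        self._buffers: dict = {}
        self._children: dict = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        object.__setattr__(self, name, value)

    def register_parameter(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        return t

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        arr = np.asarray(value, dtype=np.float64)
        self._buffers[name] = arr
        return arr

    def parameters(self) -> list:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_modules(self, prefix: str = "") -> list:
        out = [(prefix, self)]
        for name, child in self._children.items():
            out.extend(child.named_modules(f"{prefix}.{name}" if prefix else name))
        return out

    def train(self, mode: bool = True):
        for _, m in self.named_modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self) -> dict:
        out = {}
        for prefix, m in self.named_modules():
            for name, p in m._params.items():
                out[f"{prefix}.{name}" if prefix else name] = p.data.copy()
            for name, b in m._buffers.items():
                out[f"{prefix}.{name}" if prefix else name] = b.copy()
        return out

    def load_state_dict(self, state: dict) -> None:
        for prefix, m in self.named_modules():
            for name in m._params:
                key = f"{prefix}.{name}" if prefix else name
                m._params[name].data = state[key].copy()
            for name in m._buffers:
                key = f"{prefix}.{name}" if prefix else name
                m._buffers[name] = state[key].copy()

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        super().__init__()
        bound = np.sqrt(6.0 / (n_in + n_out))
        self.weight = self.register_parameter(
            "weight", rng.uniform(-bound, bound, size=(n_in, n_out)))
        self.bias = self.register_parameter("bias", np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv3d(Module):
    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 1):
        super().__init__()
        fan_in = c_in * kernel ** 3
        bound = np.sqrt(2.0 / fan_in)
        self.weight = self.register_parameter(
            "weight", rng.normal(0.0, bound, size=(c_out, c_in, kernel, kernel, kernel)))
        self.bias = self.register_parameter("bias", np.zeros(c_out))
        self.stride, self.padding = stride, padding

    def __call__(self, x: Tensor) -> Tensor:
        return conv3d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class BatchNorm3d(Module):
    """Channel normalization with running statistics.

    Normalization always uses the running estimates so a forward pass is a
    deterministic function of one sample; statistics are updated from the
    batch only during training-mode passes (the PPO/BC update passes).  This
    keeps the importance-ratio contract exact between rollout and update.
    """

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = self.register_parameter("gamma", np.ones(channels))
        self.beta = self.register_parameter("beta", np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels))
        self.register_buffer("running_var", np.ones(channels))
        self.momentum, self.eps = momentum, eps

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            axes = (0, 2, 3, 4)
            bm = x.data.mean(axis=axes)
            bv = x.data.var(axis=axes)
            self._buffers["running_mean"] = ((1 - self.momentum) *
                                             self._buffers["running_mean"] + self.momentum * bm)
            self._buffers["running_var"] = ((1 - self.momentum) *
                                            self._buffers["running_var"] + self.momentum * bv)
        shape = (1, -1, 1, 1, 1)
        mean = self._buffers["running_mean"].reshape(shape)
        std = np.sqrt(self._buffers["running_var"].reshape(shape) + self.eps)
        xn = (x - Tensor(mean)) * Tensor(1.0 / std)
        return xn * self.gamma.reshape(1, -1, 1, 1, 1) + self.beta.reshape(1, -1, 1, 1, 1)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = self.register_parameter("gamma", np.ones(dim))
        self.beta = self.register_parameter("beta", np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        xn = (x - mu) / (var + self.eps).sqrt()
        return xn * self.gamma + self.beta


class MultiheadSelfAttention(Module):
    """Standard scaled dot-product self-attention over machine-parameter tokens."""

    def __init__(self, d_model: int, n_heads: int, rng: np.random.Generator):
        super().__init__()
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.n_heads = n_heads
        self.d_head = d_model // n_heads
        self.qkv = Linear(d_model, 3 * d_model, rng)
        self.out = Linear(d_model, d_model, rng)

    def __call__(self, x: Tensor) -> Tensor:
        B, T, D = x.shape
        qkv = self.qkv(x)  # (B, T, 3D)
        qkv = qkv.reshape(B, T, 3, self.n_heads, self.d_head)
        qkv = qkv.transpose(2, 0, 3, 1, 4)  # (3, B, H, T, dh)
        q, k, v = qkv[0], qkv[1], qkv[2]
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.d_head))
        attn = softmax(scores, axis=-1)
        ctx = attn @ v  # (B, H, T, dh)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(B, T, D)
        return self.out(ctx)
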