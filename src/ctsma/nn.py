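"""Neural-network layers and optimization on top of the autodiff engine.

Small, explicit building blocks: linear and convolutional layers with He/
Glorot init, layer normalization, dropout, multi-head self-attention and a
post-norm transformer encoder layer, plus Adam with decoupled L2 weight
decay.  All randomness (init, dropout) flows through a numpy Generator
supplied by the caller, so training runs are reproducible from a seed.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, adaptive_avg_pool, conv_nd

__all__ = [
    "Module", "Linear", "Conv", "LayerNorm", "Dropout", "Sequential", "ReLU",
    "LeakyReLU", "Tanh", "Sigmoid", "MultiHeadSelfAttention",
    "TransformerEncoderLayer", "Adam", "mse_loss", "l1_loss", "cross_entropy",
    "adaptive_avg_pool",
]


class Module:
    """Minimal container: tracks parameters through attributes and lists."""

    training: bool = True

    def parameters(self) -> list[Tensor]:
        params, seen = [], set()

        def collect(obj):
            if isinstance(obj, Tensor) and obj.requires_grad:
                if id(obj) not in seen:
                    seen.add(id(obj))
                    params.append(obj)
            elif isinstance(obj, Module):
                for v in vars(obj).values():
                    collect(v)
            elif isinstance(obj, (list, tuple)):
                for v in obj:
                    collect(v)

        collect(self)
        return params

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for v in vars(self).values():
            for m in (v if isinstance(v, (list, tuple)) else [v]):
                if isinstance(m, Module):
                    m.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, state: list[np.ndarray]) -> None:
        params = self.parameters()
        if len(params) != len(state):
            raise ValueError(f"state has {len(state)} arrays, model has {len(params)}")
        for p, s in zip(params, state):
            p.data = np.asarray(s, dtype=np.float64).reshape(p.shape)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.weight = Tensor(rng.normal(0, scale, (n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class Conv(Module):
    """N-d convolution (channels first); ndim inferred from the kernel."""

    def __init__(self, c_in: int, c_out: int, kernel, rng: np.random.Generator,
                 stride=1, padding=0):
        kernel = (kernel,) * 3 if np.isscalar(kernel) else tuple(kernel)
        fan_in = c_in * int(np.prod(kernel))
        self.weight = Tensor(rng.normal(0, np.sqrt(2.0 / fan_in), (c_out, c_in) + kernel),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride, self.padding = stride, padding

    def forward(self, x: Tensor) -> Tensor:
        return conv_nd(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        return (x - mu) / ((var + self.eps) ** 0.5) * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float, rng: np.random.Generator):
        self.p, self.rng = float(p), rng

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p <= 0:
            return x
        mask = (self.rng.random(x.shape) >= self.p) / (1.0 - self.p)
        return x * Tensor(mask)


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.2):
        self.slope = slope

    def forward(self, x):
        return x.leaky_relu(self.slope)


class Tanh(Module):
    def forward(self, x):
        return x.tanh()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class Sequential(Module):
    def __init__(self, *layers: Module):
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class MultiHeadSelfAttention(Module):
    def __init__(self, dim: int, heads: int, rng: np.random.Generator):
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.dim, self.heads, self.dh = dim, heads, dim // heads
        self.qkv = Linear(dim, 3 * dim, rng)
        self.proj = Linear(dim, dim, rng)

    def forward(self, x: Tensor) -> Tensor:  # x: (B, N, d)
        B, N, d = x.shape
        qkv = self.qkv(x).reshape(B, N, 3, self.heads, self.dh)
        qkv = qkv.transpose(2, 0, 3, 1, 4)  # (3, B, h, N, dh)
        q, k, v = qkv[0], qkv[1], qkv[2]
        att = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(self.dh))
        att = att.softmax(axis=-1)
        out = (att @ v).transpose(0, 2, 1, 3).reshape(B, N, d)
        return self.proj(out)


class TransformerEncoderLayer(Module):
    """Post-norm encoder layer: LN(x + Drop(Attn(x))), LN(x + Drop(FF(x)))."""

    def __init__(self, dim: int, heads: int, ff_dim: int, rng: np.random.Generator,
                 dropout: float = 0.5):
        self.attn = MultiHeadSelfAttention(dim, heads, rng)
        self.ff = Sequential(Linear(dim, ff_dim, rng), ReLU(), Linear(ff_dim, dim, rng))
        self.ln1, self.ln2 = LayerNorm(dim), LayerNorm(dim)
        self.drop1, self.drop2 = Dropout(dropout, rng), Dropout(dropout, rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.ln1(x + self.drop1(self.attn(x)))
        return self.ln2(x + self.drop2(self.ff(x)))


class Adam:
    """Adam with L2 weight decay folded into the gradient."""

    def __init__(self, params: list[Tensor], lr: float, betas=(0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        if lr <= 0:
            raise ValueError("learning rate must be positive")
        self.params = params
        self.lr, self.betas, self.eps, self.wd = lr, betas, eps, weight_decay
        self.m = [np.zeros(p.shape) for p in params]
        self.v = [np.zeros(p.shape) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad + self.wd * p.data
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mh = self.m[i] / (1 - b1 ** self.t)
            vh = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mh / (np.sqrt(vh) + self.eps)


# --- losses ----------------------------------------------------------------

def mse_loss(pred: Tensor, target) -> Tensor:
    target = target if isinstance(target, Tensor) else Tensor(target)
    return ((pred - target) ** 2).mean()


def l1_loss(pred: Tensor, target) -> Tensor:
    target = target if isinstance(target, Tensor) else Tensor(target)
    return (pred - target).abs().mean()


def cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer labels against (B, C) logits."""
    logp = logits.log_softmax(axis=-1)
    picked = logp[np.arange(len(labels)), np.asarray(labels, dtype=int)]
    return -picked.mean()
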