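"""Feed-forward building blocks on the autodiff engine.

Hidden blocks are affine -> batch-norm -> ReLU -> dropout; the output layer
is plain affine.  Batch normalization uses batch statistics during training
and momentum-0.9 running averages at inference.  Dropout is "inverted"
(activations rescaled at train time) so inference needs no correction.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor


def xavier_uniform(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=(fan_in, fan_out))


class Linear:
    def __init__(self, in_dim: int, out_dim: int, rng: np.random.Generator):
        self.W = Tensor(xavier_uniform(rng, in_dim, out_dim), requires_grad=True)
        self.b = Tensor(np.zeros(out_dim), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]

    def weight_matrices(self):
        return [self.W]


class BatchNorm:
    def __init__(self, dim: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(dim), requires_grad=True)
        self.beta = Tensor(np.zeros(dim), requires_grad=True)
        self.running_mean = np.zeros(dim)
        self.running_var = np.ones(dim)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=0, keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=0, keepdims=True)
            xhat = xc / (var + self.eps).sqrt()
            m = self.momentum
            self.running_mean = m * self.running_mean + (1 - m) * mu.data.ravel()
            self.running_var = m * self.running_var + (1 - m) * var.data.ravel()
        else:
            xhat = (x - Tensor(self.running_mean)) / Tensor(
                np.sqrt(self.running_var + self.eps)
            )
        return xhat * self.gamma + self.beta

    def parameters(self):
        return [self.gamma, self.beta]

    def weight_matrices(self):
        return []


class MLP:
    """Hidden stack of (affine, batch-norm, ReLU, dropout) blocks with a
    linear output layer.  An empty hidden list gives a single affine map."""

    def __init__(self, in_dim: int, hidden_sizes, out_dim: int,
                 rng: np.random.Generator, dropout_rate: float = 0.0,
                 batch_norm: bool = True):
        self.in_dim = in_dim
        self.out_dim = out_dim
        self.dropout_rate = float(dropout_rate)
        self.batch_norm = bool(batch_norm)
        self.hidden = []
        prev = in_dim
        for h in hidden_sizes:
            lin = Linear(prev, h, rng)
            bn = BatchNorm(h) if batch_norm else None
            self.hidden.append((lin, bn))
            prev = h
        self.out = Linear(prev, out_dim, rng)

    def __call__(self, x, training: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(x)
        for lin, bn in self.hidden:
            x = lin(x)
            if bn is not None:
                x = bn(x, training)
            x = x.relu()
            if training and self.dropout_rate > 0:
                if rng is None:
                    raise ValueError("training forward with dropout needs an rng")
                keep = 1.0 - self.dropout_rate
                mask = (rng.random(x.shape) < keep) / keep
                x = x * Tensor(mask)
        return self.out(x)

    def parameters(self):
        params = []
        for lin, bn in self.hidden:
            params += lin.parameters()
            if bn is not None:
                params += bn.parameters()
        return params + self.out.parameters()

    def weight_matrices(self):
        """Affine weight matrices only — the ridge penalty's domain."""
        mats = []
        for lin, _ in self.hidden:
            mats += lin.weight_matrices()
        return mats + self.out.weight_matrices()

    # -- flat (de)serialization ----------------------------------------
    def state_arrays(self) -> dict:
        state = {}
        for i, (lin, bn) in enumerate(self.hidden):
            state[f"h{i}_W"] = lin.W.data
            state[f"h{i}_b"] = lin.b.data
            if bn is not None:
                state[f"h{i}_gamma"] = bn.gamma.data
                state[f"h{i}_beta"] = bn.beta.data
                state[f"h{i}_rmean"] = bn.running_mean
                state[f"h{i}_rvar"] = bn.running_var
        state["out_W"] = self.out.W.data
        state["out_b"] = self.out.b.data
        return state

    def load_state_arrays(self, state: dict, prefix: str = ""):
        for i, (lin, bn) in enumerate(self.hidden):
            lin.W.data = np.array(state[f"{prefix}h{i}_W"])
            lin.b.data = np.array(state[f"{prefix}h{i}_b"])
            if bn is not None:
                bn.gamma.data = np.array(state[f"{prefix}h{i}_gamma"])
                bn.beta.data = np.array(state[f"{prefix}h{i}_beta"])
                bn.running_mean = np.array(state[f"{prefix}h{i}_rmean"])
                bn.running_var = np.array(state[f"{prefix}h{i}_rvar"])
        self.out.W.data = np.array(state[f"{prefix}out_W"])
        self.out.b.data = np.array(state[f"{prefix}out_b"])


class Adam:
    """Adam with the conventional defaults (b1=0.9, b2=0.999, eps=1e-8)."""

    def __init__(self, params, lr: float = 1e-4, b1: float = 0.9,
                 b2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.b1, self.b2
        for i, p in enumerate(self.params):
            g = p.grad
            if g is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
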