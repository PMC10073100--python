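"""Dense layers, batch normalization and Adam for the embedding network.

Built on :mod:`deepvis.autodiff`. Layers follow the usual conventions:
Kaiming-style initialization for the dense layers, batch statistics during
training and exponential running statistics at inference for BN.
"""

from __future__ import annotations

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor


class Linear:
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 weight_scale: float = 1.0, dtype=np.float64):
        std = weight_scale * np.sqrt(2.0 / d_in)
        self.W = Tensor(rng.normal(0.0, std, size=(d_in, d_out)).astype(dtype),
                        is_param=True, name=f"W[{d_in}x{d_out}]")
        self.b = Tensor(np.zeros(d_out, dtype=dtype), is_param=True,
                        name=f"b[{d_out}]")

    def __call__(self, x, training: bool):
        return ad.matmul(x, self.W) + self.b

    def parameters(self):
        return [self.W, self.b]

    def state_arrays(self):
        return {"W": self.W.data, "b": self.b.data}

    def load_state(self, state, prefix):
        self.W.data = np.asarray(state[prefix + "W"])
        self.b.data = np.asarray(state[prefix + "b"])


class BatchNorm:
    def __init__(self, d: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float64):
        self.gamma = Tensor(np.ones(d, dtype=dtype), is_param=True,
                            name=f"bn_gamma[{d}]")
        self.beta = Tensor(np.zeros(d, dtype=dtype), is_param=True,
                           name=f"bn_beta[{d}]")
        self.running_mean = np.zeros(d)
        self.running_var = np.ones(d)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x, training: bool):
        if training:
            mu = ad.tmean(x, axis=0, keepdims=True)
            xc = x - mu
            var = ad.tmean(xc * xc, axis=0, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * ad.asarray(mu).ravel()
            self.running_var = (1 - m) * self.running_var + m * ad.asarray(var).ravel()
            xn = xc / ad.sqrt(var + self.eps)
        else:
            xn = (x - self.running_mean) / np.sqrt(self.running_var + self.eps)
        return self.gamma * xn + self.beta

    def parameters(self):
        return [self.gamma, self.beta]

    def state_arrays(self):
        return {"gamma": self.gamma.data, "beta": self.beta.data,
                "rmean": self.running_mean, "rvar": self.running_var}

    def load_state(self, state, prefix):
        self.gamma.data = np.asarray(state[prefix + "gamma"])
        self.beta.data = np.asarray(state[prefix + "beta"])
        self.running_mean = np.asarray(state[prefix + "rmean"])
        self.running_var = np.asarray(state[prefix + "rvar"])


class LeakyReLU:
    def __init__(self, alpha: float = 0.01):
        self.alpha = alpha

    def __call__(self, x, training: bool):
        return ad.leaky_relu(x, self.alpha)

    def parameters(self):
        return []

    def state_arrays(self):
        return {}

    def load_state(self, state, prefix):
        pass


class MLP:
    """Fully connected stack: Linear(+BN+LeakyReLU) per hidden layer,
    linear output layer (no activation, no BN)."""

    def __init__(self, dims: list[int], rng: np.random.Generator,
                 last_layer_scale: float = 1.0, dtype=np.float64):
        self.layers: list = []
        n = len(dims) - 1
        for i in range(n):
            last = i == n - 1
            self.layers.append(Linear(dims[i], dims[i + 1], rng,
                                      weight_scale=last_layer_scale if last else 1.0,
                                      dtype=dtype))
            if not last:
                self.layers.append(BatchNorm(dims[i + 1], dtype=dtype))
                self.layers.append(LeakyReLU())

    def __call__(self, x, training: bool):
        for layer in self.layers:
            x = layer(x, training)
        return x

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    def state_arrays(self, prefix=""):
        out = {}
        for i, layer in enumerate(self.layers):
            for k, v in layer.state_arrays().items():
                out[f"{prefix}l{i}_{k}"] = v
        return out

    def load_state(self, state, prefix=""):
        for i, layer in enumerate(self.layers):
            layer.load_state(state, f"{prefix}l{i}_")


class Adam:
    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
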