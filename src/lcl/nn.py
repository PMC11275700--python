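"""Neural-network building blocks on the numpy autodiff core.

Layers follow the familiar module convention: parameters are named tensors,
``train``/``eval`` toggles batch-norm statistics, and ``state_dict`` exposes
a flat name -> array mapping for checkpointing.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor


class Module:
    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for attr in vars(self).values():
            if isinstance(attr, Tensor) and attr.requires_grad:
                params.append(attr)
            elif isinstance(attr, Module):
                params.extend(attr.parameters())
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, attr in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(attr, Tensor):
                state[key] = attr.data
            elif isinstance(attr, np.ndarray):
                state[key] = attr
            elif isinstance(attr, Module):
                state.update(attr.named_state(prefix=key + "."))
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        state.update(item.named_state(prefix=f"{key}.{i}."))
        return state

    def load_state(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, attr in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(attr, Tensor):
                attr.data = np.array(state[key], dtype=np.float64)
            elif isinstance(attr, np.ndarray):
                setattr(self, name, np.array(state[key]))
            elif isinstance(attr, Module):
                attr.load_state(state, prefix=key + ".")
            elif isinstance(attr, (list, tuple)):
                for i, item in enumerate(attr):
                    if isinstance(item, Module):
                        item.load_state(state, prefix=f"{key}.{i}.")

    def set_training(self, mode: bool) -> None:
        for attr in vars(self).values():
            if isinstance(attr, Module):
                attr.set_training(mode)
            elif isinstance(attr, (list, tuple)):
                for item in attr:
                    if isinstance(item, Module):
                        item.set_training(mode)
        if hasattr(self, "training"):
            self.training = mode

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 stride: int = 1, padding: int = 0, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        fan_in = in_channels * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)  # He init for ReLU stages
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(out_channels, in_channels, kernel, kernel)),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)
        self.stride = stride
        self.padding = padding

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    """Per-channel normalization; batch statistics in training mode, running
    statistics (exponential moving average, momentum 0.1) in inference mode."""

    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.eps = eps
        self.momentum = momentum
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        c = x.shape[1]
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            centered = x - mu
            var = (centered * centered).mean(axis=(0, 2, 3), keepdims=True)
            n = x.data.size / c
            self.running_mean = (
                (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
            )
            self.running_var = (
                (1 - self.momentum) * self.running_var
                + self.momentum * var.data.ravel() * n / max(n - 1, 1)
            )
            xhat = centered / (var + self.eps).sqrt()
        else:
            mu = self.running_mean.reshape(1, c, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, c, 1, 1)
            xhat = (x - Tensor(mu)) / Tensor(sd)
        g = self.gamma.reshape(1, c, 1, 1)
        b = self.beta.reshape(1, c, 1, 1)
        return xhat * g + b


class MaxPool2d(Module):
    def __init__(self, kernel: int, stride: int):
        self.kernel = kernel
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return x.maxpool2d(self.kernel, self.stride)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        scale = np.sqrt(2.0 / in_features)
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(in_features, out_features)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class MLP(Module):
    """Single-hidden-layer perceptron used for projection heads and the
    SimSiam predictor."""

    def __init__(self, in_dim: int, hidden_dim: int, out_dim: int,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.fc1 = Linear(in_dim, hidden_dim, rng=rng)
        self.fc2 = Linear(hidden_dim, out_dim, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).relu())


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999),
                 eps: float = 1e-8, weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def state(self) -> dict[str, np.ndarray]:
        out = {"t": np.array(self.t)}
        for i in range(len(self.params)):
            out[f"m{i}"] = self.m[i]
            out[f"v{i}"] = self.v[i]
        return out

    def load(self, state: dict[str, np.ndarray]) -> None:
        self.t = int(state["t"])
        for i in range(len(self.params)):
            self.m[i] = np.array(state[f"m{i}"])
            self.v[i] = np.array(state[f"v{i}"])
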