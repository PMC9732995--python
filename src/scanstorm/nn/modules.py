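"""Layer modules on top of the autodiff tensor: dense, conv, batchnorm."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d

__all__ = ["Module", "Dense", "Conv2d", "BatchNorm2d", "Sequential", "Activation"]


class Module:
    """Base class: tracks parameters and sub-modules, supports train/eval mode."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for m in self._modules.values():
            out.extend(m.parameters())
        return out

    def named_parameters(self, prefix="") -> dict[str, Tensor]:
        out = {prefix + k: v for k, v in self._params.items()}
        for name, m in self._modules.items():
            out.update(m.named_parameters(prefix + name + "."))
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {k: v.data.copy() for k, v in self.named_parameters().items()}
        for name, buf in self._buffers().items():
            state[name] = buf.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        params = self.named_parameters()
        for k, v in state.items():
            if k in params:
                params[k].data[...] = v
            else:
                self._set_buffer(k, v)

    def _buffers(self, prefix="") -> dict[str, np.ndarray]:
        out = {}
        for name, m in self._modules.items():
            out.update(m._buffers(prefix + name + "."))
        if isinstance(self, BatchNorm2d):
            out[prefix + "running_mean"] = self.running_mean
            out[prefix + "running_var"] = self.running_var
        return out

    def _set_buffer(self, dotted: str, value: np.ndarray):
        obj = self
        parts = dotted.split(".")
        for p in parts[:-1]:
            obj = obj._modules[p]
        setattr(obj, parts[-1], value.copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Dense(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 weight_mean: float = 0.0, weight_std: float | None = None,
                 bias_init: str = "zeros"):
        super().__init__()
        if weight_std is None:
            weight_std = np.sqrt(2.0 / n_in)
        self.w = Tensor(rng.normal(weight_mean, weight_std, (n_in, n_out)),
                        requires_grad=True)
        if bias_init == "truncnorm":
            b = rng.normal(0.0, 0.1, n_out)
            b = np.clip(b, -0.2, 0.2)  # truncated at 2 sigma
        else:
            b = np.zeros(n_out)
        self.b = Tensor(b, requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    def __init__(self, c_in: int, c_out: int, kernel, rng: np.random.Generator,
                 stride=1, padding=0, bias: bool = True):
        super().__init__()
        kh, kw = (kernel, kernel) if np.isscalar(kernel) else kernel
        fan_in = c_in * kh * kw
        self.w = Tensor(rng.normal(0.0, np.sqrt(2.0 / fan_in), (c_out, c_in, kh, kw)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    """Per-channel batch normalization; running statistics used at inference."""

    def __init__(self, c: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = Tensor(np.ones(c), requires_grad=True)
        self.beta = Tensor(np.zeros(c), requires_grad=True)
        self.running_mean = np.zeros(c)
        self.running_var = np.ones(c)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        xn = (x - mu) / ((var + self.eps) ** 0.5)
        g = self.gamma.reshape(1, -1, 1, 1)
        b = self.beta.reshape(1, -1, 1, 1)
        return xn * g + b


class Activation(Module):
    def __init__(self, fn: str):
        super().__init__()
        self.fn = fn

    def forward(self, x: Tensor) -> Tensor:
        return getattr(x, self.fn)()


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)
        self.layers = list(layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
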