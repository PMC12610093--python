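"""Neural-network layers and optimisation built on the autodiff engine.

Layers follow the conventions of mainstream deep-learning frameworks:
fan-in uniform initialisation for affine/convolutional weights, batch
normalisation with running statistics and learnable affine parameters,
inverted dropout, Adam with standard moment defaults, and a step learning
rate schedule.  All randomness flows through an explicit
``numpy.random.Generator`` so runs are reproducible from a single seed.
"""

from __future__ import annotations

import math

import numpy as np

from . import _autograd as ag
from ._autograd import Tensor

#: dtype for newly created parameters and buffers; float32 trains the
#: network at full speed, float64 is used for high-precision checks
_DEFAULT_DTYPE = np.float32


def set_default_dtype(dtype):
    """Set the dtype used for newly created parameters (float32/float64)."""
    global _DEFAULT_DTYPE
    if np.dtype(dtype) not in (np.dtype(np.float32), np.dtype(np.float64)):
        raise ValueError("dtype must be float32 or float64")
    _DEFAULT_DTYPE = np.dtype(dtype).type


def default_dtype():
    return _DEFAULT_DTYPE


class Parameter(Tensor):
    """A tensor that is updated by the optimiser."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=_DEFAULT_DTYPE),
                         requires_grad=True)


class Module:
    """Base class: parameter collection and train/eval mode propagation."""

    def __init__(self):
        self.training = False

    def parameters(self):
        params = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def modules(self):
        mods = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self, mode=True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def num_parameters(self):
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self):
        """Flat name -> array mapping of parameters and buffers."""
        state = {}

        def walk(mod, prefix):
            for name, v in mod.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(v, Parameter):
                    state[key] = v.data.copy()
                elif isinstance(v, Module):
                    walk(v, key + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")
                        elif isinstance(item, Parameter):
                            state[f"{key}.{i}"] = item.data.copy()
                elif isinstance(v, np.ndarray) and name.startswith("running_"):
                    state[key] = v.copy()

        walk(self, "")
        return state

    def load_state_dict(self, state):
        def walk(mod, prefix):
            for name, v in mod.__dict__.items():
                key = f"{prefix}{name}"
                if isinstance(v, Parameter):
                    v.data = np.asarray(state[key],
                                        dtype=v.data.dtype).reshape(v.shape)
                elif isinstance(v, Module):
                    walk(v, key + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")
                        elif isinstance(item, Parameter):
                            item.data = np.asarray(
                                state[f"{key}.{i}"],
                                dtype=item.data.dtype).reshape(item.shape)
                elif isinstance(v, np.ndarray) and name.startswith("running_"):
                    setattr(mod, name, np.asarray(state[key], dtype=v.dtype))

        walk(self, "")


def _fan_in_uniform(rng, shape, fan_in):
    bound = 1.0 / math.sqrt(fan_in)
    return rng.uniform(-bound, bound, size=shape)  # cast by Parameter


class Linear(Module):
    """Affine map on the last axis: y = x W + b."""

    def __init__(self, in_features, out_features, rng, bias=True):
        super().__init__()
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(_fan_in_uniform(rng, (in_features, out_features),
                                                in_features))
        self.bias = Parameter(_fan_in_uniform(rng, (out_features,), in_features)) \
            if bias else None

    def __call__(self, x):
        y = ag.matmul(x, self.weight)
        if self.bias is not None:
            y = ag.add(y, self.bias)
        return y


class Conv2d(Module):
    """Valid 2-D convolution, stride 1, bias disabled (batch-norm follows)."""

    def __init__(self, in_channels, out_channels, kernel, rng):
        super().__init__()
        self.kernel = tuple(kernel)
        fan_in = in_channels * kernel[0] * kernel[1]
        self.weight = Parameter(
            _fan_in_uniform(rng, (out_channels, in_channels, *kernel), fan_in)
        )

    def __call__(self, x):
        kh, kw = self.kernel
        _, _, H, W = x.shape
        if H < kh or W < kw:
            raise ValueError(
                f"Conv2d: input plane ({H}x{W}) smaller than kernel ({kh}x{kw})"
            )
        return ag.conv2d(x, self.weight)


class BatchNorm2d(Module):
    """Per-feature-map normalisation over (batch, height, width)."""

    def __init__(self, num_features, eps=1e-5, momentum=0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.running_mean = np.zeros(num_features, dtype=_DEFAULT_DTYPE)
        self.running_var = np.ones(num_features, dtype=_DEFAULT_DTYPE)

    def __call__(self, x):
        if self.training:
            mu = ag.mean(x, axis=(0, 2, 3), keepdims=True)
            xc = ag.add(x, ag.scale(mu, -1.0))
            var = ag.mean(ag.mul(xc, xc), axis=(0, 2, 3), keepdims=True)
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbiased = var.data.ravel() * n / max(n - 1, 1)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel()
                                 ).astype(self.running_mean.dtype)
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * unbiased
                                ).astype(self.running_var.dtype)
            xhat = ag.mul(xc, _rsqrt(ag.shift(var, self.eps)))
        else:
            dt = x.data.dtype
            mu = self.running_mean.reshape(1, -1, 1, 1).astype(dt)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, -1, 1, 1)
            xhat = ag.mul(ag.add(x, Tensor(-mu)),
                          Tensor((1.0 / sd).astype(dt)))
        g = ag.reshape(self.gamma, (1, -1, 1, 1))
        b = ag.reshape(self.beta, (1, -1, 1, 1))
        return ag.add(ag.mul(xhat, g), b)


def _rsqrt(t):
    out = Tensor(t.data ** -0.5, parents=(t,))

    def backward(g):
        if t.requires_grad:
            t._accumulate(-0.5 * g * t.data ** -1.5)

    out._backward = backward
    return out


class LayerNorm(Module):
    """Normalisation over the last (feature) axis with learnable gain/shift."""

    def __init__(self, num_features, eps=1e-5):
        super().__init__()
        self.eps = eps
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))

    def __call__(self, x):
        mu = ag.mean(x, axis=-1, keepdims=True)
        xc = ag.add(x, ag.scale(mu, -1.0))
        var = ag.mean(ag.mul(xc, xc), axis=-1, keepdims=True)
        xhat = ag.mul(xc, _rsqrt(ag.shift(var, self.eps)))
        return ag.add(ag.mul(xhat, self.gamma), self.beta)


class Dropout(Module):
    def __init__(self, p, rng):
        super().__init__()
        self.p = float(p)
        self.rng = rng

    def __call__(self, x):
        return ag.dropout(x, self.p, self.rng, self.training)


def resample_matrix(n_in, n_out):
    """Area-based (box) resampling matrix R of shape (n_out, n_in).

    Output bin i averages the fractional overlap of the input treated as a
    piecewise-constant signal on [0, n_in).  Row sums are 1 and the output
    mean equals the input mean exactly, for both down- and up-sampling.
    """
    R = np.zeros((n_out, n_in))
    scale = n_in / n_out
    for i in range(n_out):
        lo, hi = i * scale, (i + 1) * scale
        j0, j1 = int(math.floor(lo)), int(math.ceil(hi))
        for j in range(j0, min(j1, n_in)):
            overlap = min(hi, j + 1) - max(lo, j)
            if overlap > 0:
                R[i, j] = overlap / scale
    return R


class Adam:
    """Adam optimiser with standard defaults (β1=0.9, β2=0.999, ε=1e-8)."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def step_lr(base_lr, epoch, step_size, gamma):
    """Learning rate in effect at ``epoch`` (0-based): lr·γ^⌊epoch/step⌋."""
    return base_lr * gamma ** (epoch // step_size)
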