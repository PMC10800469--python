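"""Module/parameter containers over the autograd primitives."""

from __future__ import annotations

import numpy as np

from . import autograd as F
from .autograd import Tensor

__all__ = ["Parameter", "Module", "Sequential", "Conv2d", "ConvTranspose2d",
           "BatchNorm2d", "ReLU", "MaxPool2d", "DeformConv2d", "ConvBNReLU"]


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Base container; discovers parameters/buffers by attribute walk."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def modules(self):
        yield self
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield from v.modules()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        yield from item.modules()

    def named_parameters(self, prefix=""):
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, Parameter):
                yield key, v
            elif isinstance(v, Module):
                yield from v.named_parameters(f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{key}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix=""):
        for name, v in self.__dict__.items():
            key = f"{prefix}{name}"
            if isinstance(v, np.ndarray):
                yield key, v
            elif isinstance(v, Module):
                yield from v.named_buffers(f"{key}.")
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{key}.{i}.")

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self):
        d = {f"param.{k}": p.data for k, p in self.named_parameters()}
        d.update({f"buffer.{k}": b for k, b in self.named_buffers()})
        return d

    def load_state_dict(self, d):
        for k, p in self.named_parameters():
            p.data = np.asarray(d[f"param.{k}"], dtype=np.float32)
        for k, b in self.named_buffers():
            b[...] = d[f"buffer.{k}"]

    def save(self, path):
        np.savez(path, **self.state_dict())

    def load(self, path):
        with np.load(path) as d:
            self.load_state_dict({k: d[k] for k in d.files})


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def _he_init(rng, co, fan_in, shape):
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin, cout, k, stride=1, pad=None, dilation=1, bias=True,
                 rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        if pad is None:
            pad = dilation * (k - 1) // 2
        self.stride, self.pad, self.dilation = stride, pad, dilation
        self.weight = Parameter(_he_init(rng, cout, cin * k * k, (cout, cin, k, k)))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride, self.pad, self.dilation)


class ConvTranspose2d(Module):
    """Kernel-size-equals-stride transposed convolution (block upsampling)."""

    def __init__(self, cin, cout, k=2, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.k = k
        self.weight = Parameter(_he_init(rng, cout, cin, (cin, cout, k, k)))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32))

    def forward(self, x):
        return F.conv_transpose2d(x, self.weight, self.bias, stride=self.k)


class BatchNorm2d(Module):
    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Parameter(np.ones(c, dtype=np.float32))
        self.beta = Parameter(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def forward(self, x):
        return F.batch_norm2d(x, self.gamma, self.beta, self.running_mean,
                              self.running_var, self.training, self.momentum, self.eps)


class ReLU(Module):
    def forward(self, x):
        return F.relu(x)


class MaxPool2d(Module):
    def __init__(self, k=2):
        super().__init__()
        self.k = k

    def forward(self, x):
        return F.max_pool2d(x, self.k)


class DeformConv2d(Module):
    """Deformable 3x3 convolution with its own offset-predicting convolution.

    The offset predictor is a standard convolution with 2*k*k output channels,
    zero-initialized so the layer starts out exactly equal to a standard
    convolution (all offsets zero).
    """

    def __init__(self, cin, cout, k=3, rng=None):
        super().__init__()
        rng = rng if rng is not None else np.random.default_rng(0)
        self.k = k
        self.offset_conv = Conv2d(cin, 2 * k * k, k, rng=rng)
        self.offset_conv.weight.data[...] = 0.0
        self.offset_conv.bias.data[...] = 0.0
        self.weight = Parameter(_he_init(rng, cout, cin * k * k, (cout, cin, k, k)))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32))

    def forward(self, x):
        offsets = self.offset_conv(x)
        return F.deform_conv2d(x, offsets, self.weight, self.bias)


class ConvBNReLU(Module):
    def __init__(self, cin, cout, k=3, stride=1, dilation=1, rng=None):
        super().__init__()
        self.conv = Conv2d(cin, cout, k, stride=stride, dilation=dilation, bias=False,
                           rng=rng)
        self.bn = BatchNorm2d(cout)
        self.act = ReLU()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))
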