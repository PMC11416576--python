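"""Layer primitives mirroring the building blocks of the segmentation nets."""

from __future__ import annotations

import numpy as np

from . import functional as F
from .tensor import Parameter, Tensor

__all__ = ["Module", "Conv2D", "ConvTranspose2D", "Dropout", "MaxPool2D"]


class Module:
    """Base class with parameter discovery and train/eval mode."""

    training: bool = False

    def parameters(self):
        params = []
        seen = set()
        stack = [self]
        while stack:
            obj = stack.pop()
            for value in vars(obj).values():
                if isinstance(value, Parameter):
                    if id(value) not in seen:
                        seen.add(id(value))
                        params.append(value)
                elif isinstance(value, Module):
                    stack.append(value)
                elif isinstance(value, (list, tuple)):
                    stack.extend(v for v in value if isinstance(v, Module))
        return params

    def modules(self):
        mods = [self]
        stack = [self]
        while stack:
            obj = stack.pop()
            for value in vars(obj).values():
                children = []
                if isinstance(value, Module):
                    children = [value]
                elif isinstance(value, (list, tuple)):
                    children = [v for v in value if isinstance(v, Module)]
                for child in children:
                    mods.append(child)
                    stack.append(child)
        return mods

    def train(self):
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        for m in self.modules():
            m.training = False
        return self

    def n_parameters(self) -> int:
        return sum(int(np.prod(p.shape)) for p in self.parameters())

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2D(Module):
    """Stride-1 same-padding convolution with optional built-in activation.

    He-normal initialisation for ReLU layers, Glorot for linear/sigmoid/
    softmax heads.  ``param_count`` follows kh*kw*Cin*F + F.
    """

    def __init__(self, in_channels, out_channels, kernel_size=3,
                 activation="relu", rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        k = kernel_size
        fan_in = k * k * in_channels
        if activation == "relu":
            std = np.sqrt(2.0 / fan_in)
        else:
            std = np.sqrt(1.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, std, size=(k, k, in_channels, out_channels)).astype(dtype)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype))
        self.activation = activation
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = k

    @property
    def param_count(self) -> int:
        k = self.kernel_size
        return k * k * self.in_channels * self.out_channels + self.out_channels

    def forward(self, x):
        out = F.conv2d(x, self.weight, self.bias)
        if self.activation == "relu":
            out = F.relu(out)
        elif self.activation == "sigmoid":
            out = F.sigmoid(out)
        # linear / softmax heads return raw logits; softmax is fused with the
        # loss during training and applied explicitly at inference.
        return out


class ConvTranspose2D(Module):
    """2x2 stride-2 transposed convolution (linear activation)."""

    def __init__(self, in_channels, out_channels, rng=None, dtype=np.float32):
        rng = rng or np.random.default_rng()
        fan_in = in_channels
        std = np.sqrt(1.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, std, size=(2, 2, in_channels, out_channels)).astype(dtype)
        )
        self.bias = Parameter(np.zeros(out_channels, dtype=dtype))
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = 2

    @property
    def param_count(self) -> int:
        return 2 * 2 * self.in_channels * self.out_channels + self.out_channels

    def forward(self, x):
        return F.conv_transpose2d(x, self.weight, self.bias)


class Dropout(Module):
    """Inverted dropout; active only in training mode."""

    def __init__(self, rate: float, rng: np.random.Generator | None = None):
        if not 0.0 <= rate < 1.0:
            raise ValueError("dropout rate must be in [0, 1)")
        self.rate = rate
        self.rng = rng or np.random.default_rng()

    def reseed(self, seed: int):
        self.rng = np.random.default_rng(seed)

    def forward(self, x):
        return F.dropout(x, self.rate, self.rng, self.training)


class MaxPool2D(Module):
    def forward(self, x):
        return F.max_pool2d(x)
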