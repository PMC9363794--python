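"""Layer/module abstractions over the autograd engine.

Modules hold :class:`Parameter` leaves and non-trainable buffers (batch-norm
running statistics), discover children by attribute traversal, and expose
flat ``state_dict``/``load_state_dict`` for checkpointing.  Weight
initialization is He-normal, drawn from the RNG passed at construction time
(every network builder threads one seeded generator through all layers, so
models are reproducible end to end).
"""

from __future__ import annotations

import numpy as np

from . import autograd as F
from .autograd import Parameter, Tensor

__all__ = [
    "Module",
    "Sequential",
    "ModuleList",
    "Conv2d",
    "DepthwiseConv2d",
    "BatchNorm2d",
    "ReLU",
    "ReLU6",
    "Identity",
]


class Module:
    def __init__(self):
        self.training = True

    # -- traversal ---------------------------------------------------------
    def _children(self):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, v in enumerate(value):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, np.ndarray):
                yield prefix + name, value
        for cname, child in self._children():
            yield from child.named_buffers(prefix + cname + ".")

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    # -- mode --------------------------------------------------------------
    def train(self):
        self.training = True
        for _, c in self._children():
            c.train()
        return self

    def eval(self):
        self.training = False
        for _, c in self._children():
            c.eval()
        return self

    # -- checkpointing -----------------------------------------------------
    def state_dict(self) -> dict:
        state = {f"param:{k}": p.data.copy() for k, p in self.named_parameters()}
        state.update({f"buffer:{k}": b.copy() for k, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            kind, name = key.split(":", 1)
            if kind == "param":
                params[name].data[...] = value
            else:
                buffers[name][...] = value

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def __call__(self, x):
        return self.forward(x)


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return F.relu(x)


class ReLU6(Module):
    def forward(self, x):
        return F.relu6(x)


class Sequential(Module):
    def __init__(self, *modules):
        super().__init__()
        self.modules = list(modules)

    def forward(self, x):
        for m in self.modules:
            x = m(x)
        return x


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self.modules = list(modules)

    def __iter__(self):
        return iter(self.modules)

    def __len__(self):
        return len(self.modules)

    def __getitem__(self, i):
        return self.modules[i]

    def append(self, m):
        self.modules.append(m)

    def forward(self, x):  # pragma: no cover - containers are not called
        raise NotImplementedError("ModuleList is a container")


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
        dilation: int = 1,
        bias: bool = True,
    ):
        super().__init__()
        self.stride, self.padding, self.dilation = stride, padding, dilation
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(
            rng.normal(0.0, std, (out_channels, in_channels, kernel_size, kernel_size))
        )
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x):
        return F.conv2d(
            x, self.weight, self.bias, self.stride, self.padding, self.dilation
        )


class DepthwiseConv2d(Module):
    def __init__(
        self,
        channels: int,
        kernel_size: int,
        rng: np.random.Generator,
        stride: int = 1,
        padding: int = 0,
        dilation: int = 1,
        bias: bool = True,
    ):
        super().__init__()
        self.stride, self.padding, self.dilation = stride, padding, dilation
        std = np.sqrt(2.0 / (kernel_size * kernel_size))
        self.weight = Parameter(
            rng.normal(0.0, std, (channels, kernel_size, kernel_size))
        )
        self.bias = Parameter(np.zeros(channels)) if bias else None

    def forward(self, x):
        return F.depthwise_conv2d(
            x, self.weight, self.bias, self.stride, self.padding, self.dilation
        )


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.momentum, self.eps = momentum, eps
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)

    def forward(self, x):
        return F.batch_norm2d(
            x,
            self.gamma,
            self.beta,
            self.running_mean,
            self.running_var,
            self.training,
            self.momentum,
            self.eps,
        )
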