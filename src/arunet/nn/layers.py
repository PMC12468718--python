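"""Trainable layers and attention modules built on the autograd engine.

Layout convention is NCHW throughout.  Convolutions are initialised
He-uniform; batch-norm starts at the identity (gamma=1, beta=0); channel
attention kernels start at zero so that a freshly built gate is exactly the
identity under the residual ``x * (1 + omega)`` form.
"""

from __future__ import annotations

import numpy as np

from ..attention import adaptive_kernel_size
from ..exceptions import ConfigurationError
from . import tensor as T
from .tensor import Parameter, Tensor

__all__ = [
    "Module",
    "ModuleList",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "AcaGate",
    "FcChannelAttention",
    "TripletAttention",
]


class Module:
    """Minimal module base: parameter/buffer registration and state dicts."""

    def __init__(self):
        object.__setattr__(self, "_params", {})
        object.__setattr__(self, "_modules", {})
        object.__setattr__(self, "_buffers", {})
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name, array):
        self._buffers[name] = array
        object.__setattr__(self, name, array)

    # -- traversal ---------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for name, m in self._modules.items():
            yield from m.named_parameters(prefix + name + ".")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for name, m in self._modules.items():
            yield from m.named_buffers(prefix + name + ".")

    def modules(self):
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, flag: bool = True):
        for m in self.modules():
            object.__setattr__(m, "training", flag)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- (de)serialisation -------------------------------------------------
    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({"buffer:" + name: b.copy() for name, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict) -> None:
        for name, p in self.named_parameters():
            p.data = np.array(state[name], dtype=np.float64)
        for name, b in self.named_buffers():
            b[...] = state["buffer:" + name]

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class ModuleList(Module):
    def __init__(self, modules=()):
        super().__init__()
        self._list = []
        for m in modules:
            self.append(m)

    def append(self, module: Module):
        setattr(self, str(len(self._list)), module)
        self._list.append(module)

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


def _he_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape)


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=0, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        fan_in = in_channels * k * k
        self.weight = Parameter(_he_uniform(rng, (out_channels, in_channels, k, k), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x: Tensor) -> Tensor:
        return T.conv2d(x, self.weight, self.bias, stride=self.stride, padding=self.padding)


class ConvTranspose2d(Module):
    """Stride-2, kernel-2 transposed convolution (exact 2x upsampling)."""

    def __init__(self, in_channels, out_channels, bias=True, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        fan_in = in_channels * 4
        self.weight = Parameter(_he_uniform(rng, (in_channels, out_channels, 2, 2), fan_in))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return T.conv_transpose2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(channels))
        self.beta = Parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels))
        self.register_buffer("running_var", np.ones(channels))
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return T.batchnorm2d(x, self.gamma, self.beta, self.running_mean,
                             self.running_var, self.training,
                             momentum=self.momentum, eps=self.eps)


def _apply_channel_gate(x: Tensor, omega: Tensor, gate: str) -> Tensor:
    """Gate an (N,C,H,W) tensor with per-channel weights omega of shape (N,C)."""
    n, c = omega.shape
    omega4 = T.reshape(omega, (n, c, 1, 1))
    if gate == "residual":
        return T.mul(x, T.add(omega4, Tensor(np.ones(1))))
    if gate == "literal":
        return T.mul(x, omega4)
    raise ConfigurationError(f"unknown gate form {gate!r}")


class AcaGate(Module):
    """Adaptive channel attention: 1D conv over the pooled channel vector.

    Kernel length adapts to the channel count; the kernel starts at zero so
    the residual gate form is initially the identity.
    """

    def __init__(self, channels, alpha=1.0, gate="residual", gamma=2.0, beta=1.0):
        super().__init__()
        if gate not in ("residual", "literal"):
            raise ConfigurationError(f"unknown gate form {gate!r}")
        self.channels = channels
        self.kernel_size = adaptive_kernel_size(channels, gamma, beta)
        self.kernel = Parameter(np.zeros(self.kernel_size))
        self.alpha = alpha
        self.gate = gate

    def gate_weights(self, x: Tensor) -> Tensor:
        pooled = T.mean_axes(x, (2, 3))  # (N, C)
        conv = T.channel_conv1d(pooled, self.kernel)
        return T.tanh(T.scale(conv, self.alpha))

    def forward(self, x: Tensor) -> Tensor:
        return _apply_channel_gate(x, self.gate_weights(x), self.gate)


class FcChannelAttention(Module):
    """Squeeze-and-excite channel attention with a reduction-r bottleneck."""

    def __init__(self, channels, reduction=4, alpha=1.0, gate="residual", rng=None):
        super().__init__()
        if gate not in ("residual", "literal"):
            raise ConfigurationError(f"unknown gate form {gate!r}")
        rng = rng or np.random.default_rng(0)
        hidden = max(1, -(-channels // reduction))
        self.ua = Parameter(_he_uniform(rng, (channels, hidden), channels))
        self.ub = Parameter(np.zeros((hidden, channels)))
        self.alpha = alpha
        self.gate = gate

    def forward(self, x: Tensor) -> Tensor:
        pooled = T.mean_axes(x, (2, 3))  # (N, C)
        omega = T.tanh(T.scale(T.matmul(T.matmul(pooled, self.ua), self.ub), self.alpha))
        return _apply_channel_gate(x, omega, self.gate)


class TripletAttention(Module):
    """Dimensional-space triplet attention over an (N,C,H,W) tensor.

    Three branches pool one axis away (max and average stacked as two
    channels), convolve the remaining plane with a k x k kernel, and gate the
    input with the scaled-tanh weights; the literal ``x * omega`` of the
    three branches is averaged with equal 1/3 weights.  Branch order is
    height-channel (pools W), width-channel (pools H), height-width
    (pools C).
    """

    def __init__(self, alpha=1.0, kernel_size=7, rng=None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        pad = kernel_size // 2
        self.conv_hc = Conv2d(2, 1, kernel_size, padding=pad, bias=False, rng=rng)
        self.conv_wc = Conv2d(2, 1, kernel_size, padding=pad, bias=False, rng=rng)
        self.alpha = alpha
        self.conv_hw = Conv2d(2, 1, kernel_size, padding=pad, bias=False, rng=rng)

    def _branch(self, x: Tensor, pool_axis: int, conv: Conv2d):
        """Pool ``pool_axis`` away, stack max/avg, convolve, gate.

        Returns the gated tensor back in (N,C,H,W) layout.
        """
        mx = T.max_axes(x, axis=pool_axis, keepdims=False)
        av = T.mean_axes(x, (pool_axis,), keepdims=False)
        if pool_axis == 3:  # height-channel branch: plane (H, C)
            # pooled maps are (N, C, H) -> (N, H, C)
            mx = T.transpose(mx, (0, 2, 1))
            av = T.transpose(av, (0, 2, 1))
            stack = T.concat([_addchan(mx), _addchan(av)], axis=1)  # (N,2,H,C)
            omega = T.tanh(T.scale(conv(stack), self.alpha))  # (N,1,H,C)
            omega = T.transpose(omega, (0, 3, 2, 1))  # (N,C,H,1)
        elif pool_axis == 2:  # width-channel branch: plane (W, C)
            mx = T.transpose(mx, (0, 2, 1))  # (N, W, C)
            av = T.transpose(av, (0, 2, 1))
            stack = T.concat([_addchan(mx), _addchan(av)], axis=1)  # (N,2,W,C)
            omega = T.tanh(T.scale(conv(stack), self.alpha))  # (N,1,W,C)
            omega = T.transpose(omega, (0, 3, 1, 2))  # (N,C,1,W)
        elif pool_axis == 1:  # height-width branch: plane (H, W)
            stack = T.concat([_addchan(mx), _addchan(av)], axis=1)  # (N,2,H,W)
            omega = T.tanh(T.scale(conv(stack), self.alpha))  # (N,1,H,W)
        else:  # pragma: no cover - internal
            raise ConfigurationError(f"bad pool axis {pool_axis}")
        return T.mul(x, omega)

    def forward(self, x: Tensor) -> Tensor:
        y1 = self._branch(x, 3, self.conv_hc)
        y2 = self._branch(x, 2, self.conv_wc)
        y3 = self._branch(x, 1, self.conv_hw)
        return T.scale(T.add(T.add(y1, y2), y3), 1.0 / 3.0)


def _addchan(t: Tensor) -> Tensor:
    """(N, A, B) -> (N, 1, A, B)."""
    n, a, b = t.shape
    return T.reshape(t, (n, 1, a, b))
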