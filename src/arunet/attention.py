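"""Attention primitives on channels-last feature maps.

These are the reference, framework-free forms of the package's attention
operators, operating on plain ``(H, W, C)`` numpy arrays:

* ``fc_channel_attention`` -- squeeze-and-excite style gate: global average
  pooling followed by a two-matrix bottleneck and a scaled tanh.
* ``aca_gate`` -- adaptive channel attention: a 1D convolution over the
  pooled channel vector whose kernel size grows with log2 of the channel
  count, avoiding the fully connected bottleneck.
* ``dta`` / ``dta_branch`` -- dimensional-space triplet attention: three
  branches each pool one tensor axis away (max and average, stacked as two
  channels), convolve the remaining plane, and gate the input with the
  resulting scaled-tanh weights; branch outputs are averaged with equal 1/3
  weights.

The trainable network layers in :mod:`arunet.nn.layers` implement the same
mathematics on the autograd engine; the two are cross-checked in the test
suite.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import ndimage

from .exceptions import ConfigurationError, ParameterError

__all__ = [
    "global_avg_pool",
    "scaled_tanh",
    "adaptive_kernel_size",
    "aca_gate",
    "fc_channel_attention",
    "dta_branch",
    "dta",
    "DTA_BRANCHES",
]

#: branch tag -> axis of an (H, W, C) map that the branch pools away
DTA_BRANCHES = {"height-channel": 1, "width-channel": 0, "height-width": 2}


def _check_fm(fm: np.ndarray) -> np.ndarray:
    fm = np.asarray(fm, dtype=np.float64)
    if fm.ndim != 3:
        raise ParameterError(f"feature map must be (H, W, C), got shape {fm.shape}")
    if not np.all(np.isfinite(fm)):
        raise ParameterError("feature map contains non-finite entries")
    return fm


def global_avg_pool(fm: np.ndarray) -> np.ndarray:
    """Spatial mean per channel: ``g(z)_c = (1/(H*W)) * sum_ij z_ijc``."""
    return _check_fm(fm).mean(axis=(0, 1))


def scaled_tanh(x: np.ndarray, alpha: float = 1.0) -> np.ndarray:
    """Elementwise ``tanh(alpha * x)``; output strictly inside (-1, 1)."""
    if alpha <= 0:
        raise ParameterError("alpha must be positive")
    return np.tanh(alpha * np.asarray(x, dtype=np.float64))


def adaptive_kernel_size(channels: int, gamma: float = 2.0, beta: float = 1.0) -> int:
    """Channel-adaptive 1D kernel size ``k = odd(floor(|log2(C)/g + b/g|))``.

    An even truncation is bumped up to the next odd integer and the result is
    at least 1, so nearby channels interact through a small odd-length kernel
    that widens logarithmically with the channel count (C=64 -> 3, C=256 -> 5
    at the default gamma=2, beta=1).
    """
    if channels < 1:
        raise ParameterError("channel count must be >= 1")
    if gamma <= 0:
        raise ParameterError("gamma must be positive")
    k = int(abs(math.log2(channels) / gamma + beta / gamma))
    if k % 2 == 0:
        k += 1
    return max(k, 1)


def _apply_channel_gate(fm: np.ndarray, omega: np.ndarray, gate: str) -> np.ndarray:
    if gate == "residual":
        return fm * (1.0 + omega)[None, None, :]
    if gate == "literal":
        return fm * omega[None, None, :]
    raise ConfigurationError(f"unknown gate form {gate!r}")


def aca_gate(
    fm: np.ndarray,
    kernel: np.ndarray,
    alpha: float = 1.0,
    gate: str = "residual",
) -> np.ndarray:
    """Adaptive channel attention gate.

    ``omega = tanh(alpha * C1D_k(gap(fm)))`` where the 1D convolution runs
    over the channel axis with zero padding at the channel ends and kernel
    length ``k = adaptive_kernel_size(C)``.  With ``gate="residual"`` the
    map is scaled by ``1 + omega`` (identity at zero weights); ``"literal"``
    multiplies by ``omega`` directly.
    """
    fm = _check_fm(fm)
    kernel = np.asarray(kernel, dtype=np.float64)
    c = fm.shape[2]
    k = adaptive_kernel_size(c)
    if kernel.shape != (k,):
        raise ConfigurationError(
            f"ACA kernel must have length {k} for C={c}, got shape {kernel.shape}"
        )
    pooled = global_avg_pool(fm)
    # cross-correlation with zero same-padding over the channel axis
    conv = np.convolve(pooled, kernel[::-1], mode="same")
    omega = scaled_tanh(conv, alpha)
    return _apply_channel_gate(fm, omega, gate)


def fc_channel_attention(
    fm: np.ndarray,
    ua: np.ndarray,
    ub: np.ndarray,
    alpha: float = 1.0,
    gate: str = "residual",
) -> np.ndarray:
    """Fully connected channel attention with a reduction bottleneck.

    ``omega = tanh(alpha * (g(z) @ Ua) @ Ub)`` with ``Ua`` of shape
    ``(C, ceil(C/r))`` and ``Ub`` of shape ``(ceil(C/r), C)``; gating as in
    :func:`aca_gate`.
    """
    fm = _check_fm(fm)
    ua = np.asarray(ua, dtype=np.float64)
    ub = np.asarray(ub, dtype=np.float64)
    c = fm.shape[2]
    if ua.ndim != 2 or ua.shape[0] != c or ub.ndim != 2 or ub.shape != (ua.shape[1], c):
        raise ConfigurationError(
            f"weight matrices must be (C, Ch) and (Ch, C) with C={c}; "
            f"got {ua.shape} and {ub.shape}"
        )
    omega = scaled_tanh(global_avg_pool(fm) @ ua @ ub, alpha)
    return _apply_channel_gate(fm, omega, gate)


def dta_branch(
    fm: np.ndarray,
    branch: str,
    kernel: np.ndarray,
    alpha: float = 1.0,
):
    """One branch of the triplet attention.

    The branch's reduced axis is moved to the front; max- and average-pooling
    over it are stacked into a two-channel map over the remaining plane; a
    single 2D convolution (two input channels, one output channel, zero same
    padding) followed by a scaled tanh yields the gate ``omega``, which is
    broadcast back over the reduced axis.

    Returns ``(gated, omega)`` where ``gated`` has the reduced axis leading.
    """
    fm = _check_fm(fm)
    if branch not in DTA_BRANCHES:
        raise ConfigurationError(
            f"unknown DTA branch {branch!r}; expected one of {sorted(DTA_BRANCHES)}"
        )
    kernel = np.asarray(kernel, dtype=np.float64)
    if kernel.ndim != 3 or kernel.shape[0] != 2 or kernel.shape[1] != kernel.shape[2]:
        raise ConfigurationError(
            f"DTA kernel must be (2, k, k), got shape {kernel.shape}"
        )
    axis = DTA_BRANCHES[branch]
    x_hat = np.moveaxis(fm, axis, 0)
    mx = x_hat.max(axis=0)
    av = x_hat.mean(axis=0)
    conv = (
        ndimage.correlate(mx, kernel[0], mode="constant", cval=0.0)
        + ndimage.correlate(av, kernel[1], mode="constant", cval=0.0)
    )
    omega = scaled_tanh(conv, alpha)
    return x_hat * omega[None], omega


def dta(fm: np.ndarray, kernels, alpha: float = 1.0) -> np.ndarray:
    """Full triplet attention: average of the three gated branches.

    ``y = (1/3) * (x1*w1 + x2*w2 + x3*w3)`` with each branch's gated output
    permuted back to ``(H, W, C)``.  ``kernels`` maps branch tags (or is a
    sequence in ``height-channel, width-channel, height-width`` order) to
    ``(2, k, k)`` convolution kernels.
    """
    fm = _check_fm(fm)
    order = ["height-channel", "width-channel", "height-width"]
    if not isinstance(kernels, dict):
        kernels = dict(zip(order, kernels))
    out = np.zeros_like(fm)
    for branch in order:
        gated, _ = dta_branch(fm, branch, kernels[branch], alpha)
        out += np.moveaxis(gated, 0, DTA_BRANCHES[branch])
    return out / 3.0
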