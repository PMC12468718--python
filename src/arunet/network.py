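"""U-shaped segmentation networks with residual and attention blocks.

Four nested architecture variants mirror the ablation ladder:

* ``unet``          -- plain double-conv encoder/decoder stages;
* ``unet_res``      -- residual blocks (two conv blocks plus a projected
  identity shortcut);
* ``unet_res_aca``  -- adds an adaptive channel attention gate after every
  encoder stage, refining channel weights where resolution is low;
* ``arunet``        -- additionally wraps the stem in a context information
  transmission (CIT) block and applies dimensional-space triplet attention
  (DTA) after every decoder stage.

Each variant's parameter set is a strict superset of the previous one, so
parameter counts are strictly nested at fixed width.  Inputs are NCHW with
spatial size divisible by ``2**(depth-1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Optional

import numpy as np

from . import nn
from .exceptions import ConfigurationError
from .nn import tensor as T
from .nn.tensor import Tensor

__all__ = [
    "VARIANTS",
    "ArchitectureConfig",
    "ConvBlock",
    "DoubleConv",
    "ResidualBlock",
    "CitBlock",
    "SegModel",
    "build_model",
    "count_parameters",
    "parameter_counts",
    "conv_output_size",
]

VARIANTS = ("unet", "unet_res", "unet_res_aca", "arunet")


def conv_output_size(size: int, kernel: int, stride: int = 1, padding: int = 0) -> int:
    """Spatial size after a convolution: ``(H - K + 2P) / S + 1`` (must be integral)."""
    num = size - kernel + 2 * padding
    if num % stride != 0 or num < 0:
        raise ConfigurationError(
            f"size {size} incompatible with kernel {kernel}, stride {stride}, padding {padding}"
        )
    return num // stride + 1


@dataclass
class ArchitectureConfig:
    """Plain-text-serialisable description of a network variant."""

    variant: str = "arunet"
    depth: int = 5
    base_width: int = 64
    n_classes: int = 6
    in_channels: int = 1
    alpha: float = 1.0
    aca_gate: str = "residual"
    dta_kernel_size: int = 7
    seed: int = 0

    def validate(self) -> None:
        if self.variant not in VARIANTS:
            raise ConfigurationError(
                f"unknown variant {self.variant!r}; expected one of {VARIANTS}"
            )
        if self.depth < 2:
            raise ConfigurationError("depth must be >= 2")
        if self.base_width < 1 or self.n_classes < 2:
            raise ConfigurationError("base_width >= 1 and n_classes >= 2 required")

    def to_dict(self) -> dict:
        return asdict(self)


class ConvBlock(nn.Module):
    """3x3 convolution -> batch norm -> ReLU; spatial size preserved."""

    def __init__(self, in_channels, out_channels, rng=None):
        super().__init__()
        self.conv = nn.Conv2d(in_channels, out_channels, 3, padding=1, rng=rng)
        self.bn = nn.BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        return T.relu(self.bn(self.conv(x)))


class DoubleConv(nn.Module):
    """Two stacked conv blocks: the classical U-Net stage."""

    def __init__(self, in_channels, out_channels, rng=None):
        super().__init__()
        self.cb1 = ConvBlock(in_channels, out_channels, rng=rng)
        self.cb2 = ConvBlock(out_channels, out_channels, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        return self.cb2(self.cb1(x))


class ResidualBlock(nn.Module):
    """``proj(x) + cb2(cb1(x))`` with a 1x1 projection when channels differ.

    With matching channels and zeroed inner weights this is exactly the
    identity, which residual learning relies on to keep gradients flowing in
    deep stacks.
    """

    def __init__(self, in_channels, out_channels, rng=None):
        super().__init__()
        self.cb1 = ConvBlock(in_channels, out_channels, rng=rng)
        self.cb2 = ConvBlock(out_channels, out_channels, rng=rng)
        if in_channels != out_channels:
            self.proj = nn.Conv2d(in_channels, out_channels, 1, bias=False, rng=rng)
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        shortcut = self.proj(x) if self.proj is not None else x
        return T.add(shortcut, self.cb2(self.cb1(x)))


class CitBlock(nn.Module):
    """Context information transmission stem.

    The primary block produces the full-resolution feature map ``Q1``;
    max-pooling gives ``Q2``; the pooled branch is refined by a scaled tanh,
    an adaptive channel attention gate, and a second scaled tanh, then
    upsampled (nearest-neighbour) back to the full grid as ``Q3``.  The stage
    output is ``R1 = Q1 + Q3`` and the pooled ``Q2`` is forwarded down the
    encoder, so fine detail reaches deeper layers without another
    convolution.
    """

    def __init__(self, primary: nn.Module, channels: int, alpha: float = 1.0,
                 aca_gate: str = "residual"):
        super().__init__()
        self.primary = primary
        self.aca = nn.AcaGate(channels, alpha=alpha, gate=aca_gate)
        self.alpha = alpha

    def forward(self, x: Tensor):
        q1 = self.primary(x)
        q2 = T.maxpool2d(q1)
        z = T.tanh(T.scale(q2, self.alpha))
        q3 = T.upsample_nearest2(T.tanh(T.scale(self.aca(z), self.alpha)))
        r1 = T.add(q1, q3)
        return r1, q2


class _StagePrimary(nn.Module):
    """A variant block followed by an optional channel attention gate."""

    def __init__(self, block, aca=None):
        super().__init__()
        self.block = block
        self.aca = aca

    def forward(self, x: Tensor) -> Tensor:
        f = self.block(x)
        if self.aca is not None:
            f = self.aca(f)
        return f


class _EncoderStage(nn.Module):
    """Encoder stage: either a plain primary or a CIT-wrapped primary."""

    def __init__(self, primary: Optional[_StagePrimary] = None,
                 cit: Optional[CitBlock] = None):
        super().__init__()
        self.primary = primary
        self.cit = cit

    def forward(self, x: Tensor):
        if self.cit is not None:
            return self.cit(x)  # (skip feature R1, pooled Q2)
        return self.primary(x), None


class _DecoderStage(nn.Module):
    """Transposed conv -> concatenate skip -> conv block -> optional DTA."""

    def __init__(self, up, block, dta=None):
        super().__init__()
        self.up = up
        self.block = block
        self.dta = dta

    def forward(self, x: Tensor, skip: Tensor) -> Tensor:
        x = self.up(x)
        x = T.concat([skip, x], axis=1)
        x = self.block(x)
        if self.dta is not None:
            x = self.dta(x)
        return x


class SegModel(nn.Module):
    """An assembled segmentation network (one of the four variants)."""

    def __init__(self, config: ArchitectureConfig):
        super().__init__()
        config.validate()
        self.config = config
        rng = np.random.default_rng(config.seed)
        v = config.variant
        depth, base = config.depth, config.base_width
        widths = [base * 2 ** i for i in range(depth)]
        self.widths = widths
        block_cls = DoubleConv if v == "unet" else ResidualBlock
        with_aca = v in ("unet_res_aca", "arunet")

        enc = nn.ModuleList()
        cin = config.in_channels
        for i, w in enumerate(widths):
            block = block_cls(cin, w, rng=rng)
            aca = nn.AcaGate(w, alpha=config.alpha, gate=config.aca_gate) if with_aca else None
            primary = _StagePrimary(block, aca)
            if v == "arunet" and i == 0:
                cit = CitBlock(primary, w, alpha=config.alpha, aca_gate=config.aca_gate)
                enc.append(_EncoderStage(cit=cit))
            else:
                enc.append(_EncoderStage(primary=primary))
            cin = w
        self.encoder = enc

        dec = nn.ModuleList()
        for i in range(depth - 2, -1, -1):
            up = nn.ConvTranspose2d(widths[i + 1], widths[i], rng=rng)
            block = block_cls(2 * widths[i], widths[i], rng=rng)
            dta = (
                nn.TripletAttention(alpha=config.alpha,
                                    kernel_size=config.dta_kernel_size, rng=rng)
                if v == "arunet" else None
            )
            dec.append(_DecoderStage(up, block, dta))
        self.decoder = dec
        self.head = nn.Conv2d(widths[0], config.n_classes, 1, rng=rng)

    # -- forward -----------------------------------------------------------
    def forward(self, x) -> Tensor:
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float64))
        if x.ndim == 3:
            x = T.reshape(x, (x.shape[0], 1, x.shape[1], x.shape[2]))
        depth = self.config.depth
        mult = 2 ** (depth - 1)
        h, w = x.shape[2], x.shape[3]
        if h % mult or w % mult:
            raise ConfigurationError(
                f"input spatial size {h}x{w} must be a multiple of {mult} "
                f"for depth {depth}"
            )
        skips = []
        for i in range(depth - 1):
            f, pooled = self.encoder[i](x)
            skips.append(f)
            x = pooled if pooled is not None else T.maxpool2d(f)
        x, _ = self.encoder[depth - 1](x)  # bottleneck (never pooled)
        for j, stage in enumerate(self.decoder):
            x = stage(x, skips[depth - 2 - j])
        return self.head(x)

    def predict_proba(self, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Softmax class probabilities, (N, C, H, W); runs in eval mode."""
        was_training = self.training
        self.eval()
        images = np.asarray(images, dtype=np.float64)
        outs = []
        for start in range(0, len(images), batch_size):
            logits = self.forward(images[start:start + batch_size])
            outs.append(T.softmax(logits.data, axis=1))
        if was_training:
            self.train()
        return np.concatenate(outs, axis=0)

    def predict(self, images: np.ndarray, batch_size: int = 8) -> np.ndarray:
        """Argmax class-index masks, (N, H, W)."""
        return self.predict_proba(images, batch_size=batch_size).argmax(axis=1)


def build_model(
    variant: str = "arunet",
    depth: int = 5,
    base_width: int = 64,
    n_classes: int = 6,
    in_channels: int = 1,
    seed: int = 0,
    alpha: float = 1.0,
    aca_gate: str = "residual",
    dta_kernel_size: int = 7,
) -> SegModel:
    """Assemble one of the four nested network variants with seeded init."""
    cfg = ArchitectureConfig(
        variant=variant, depth=depth, base_width=base_width, n_classes=n_classes,
        in_channels=in_channels, alpha=alpha, aca_gate=aca_gate,
        dta_kernel_size=dta_kernel_size, seed=seed,
    )
    return SegModel(cfg)


def count_parameters(model: nn.Module) -> int:
    """Total number of trainable scalars (frozen parameters excluded)."""
    return int(sum(p.data.size for p in model.parameters() if p.requires_grad))


def parameter_counts(model: SegModel) -> dict:
    """Per-block trainable-parameter subtotals, plus the grand total."""
    counts: dict[str, int] = {}
    for name, p in model.named_parameters():
        if not p.requires_grad:
            continue
        block = name.split(".")[0]
        counts[block] = counts.get(block, 0) + p.data.size
    counts["total"] = sum(counts.values())
    return counts


def save_checkpoint(model: SegModel, path) -> None:
    """Write model weights plus the architecture config to a single .npz file."""
    import json

    state = model.state_dict()
    state["__config__"] = np.frombuffer(
        json.dumps(model.config.to_dict()).encode(), dtype=np.uint8
    )
    np.savez(path, **state)


def load_checkpoint(path) -> SegModel:
    """Rebuild a model from :func:`save_checkpoint` output."""
    import json

    with np.load(path) as data:
        cfg = ArchitectureConfig(**json.loads(bytes(data["__config__"].tobytes()).decode()))
        model = SegModel(cfg)
        state = {k: data[k] for k in data.files if k != "__config__"}
    model.load_state_dict(state)
    return model
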