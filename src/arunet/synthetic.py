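"""Seeded brain-phantom generator emulating a folder-per-class MRI dataset.

Phantoms are deliberately simple stand-ins for axial brain MRI slices, not
radiological simulations: an elliptical "head" with smooth random texture, a
class-styled tumor blob (classes differ in eccentricity, boundary
irregularity, lobe count and intensity offset so they are learnably
distinct), a multiplicative low-frequency bias field of the kind coil
inhomogeneity produces, and additive Gaussian noise.  The mask is the exact
generating blob, carrying the class index as pixel value (0 = background;
the Normal class has an empty mask).

Everything is driven by ``numpy`` generators seeded from ``(seed,
class_index, item_index)``, so regeneration is bit-identical.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .exceptions import ParameterError

__all__ = [
    "CLASS_NAMES",
    "PhantomSpec",
    "PhantomExample",
    "generate_phantom",
    "generate_examples",
    "generate_dataset",
]

#: dataset class vocabulary; index doubles as the mask pixel value
#: (Normal maps to 0 = background, consistent with its empty mask)
CLASS_NAMES = ("Normal", "Glioma", "Meningioma", "Neurocytoma", "Other", "Schwannoma")

#: per-tumor-class style: (intensity offset, eccentricity, irregularity, lobes)
_CLASS_STYLES = {
    1: (70.0, 1.0, 0.30, 5),   # Glioma: bright, very irregular
    2: (90.0, 1.0, 0.08, 3),   # Meningioma: brightest, round
    3: (60.0, 1.4, 0.18, 4),   # Neurocytoma: elongated, moderate
    4: (50.0, 1.8, 0.28, 6),   # Other: faint, stretched, lobulated
    5: (80.0, 1.2, 0.12, 2),   # Schwannoma: bright, smooth oval
}


@dataclass
class PhantomSpec:
    """Parameters of the phantom generator.

    ``tumor_radius_range`` is in pixels; when left ``None`` it defaults to
    10-18% of the image size.  ``bias_field_amplitude`` is a fraction of the
    dynamic range; ``noise_sd`` is in 8-bit intensity units.
    """

    image_size: int = 256
    n_classes: int = 6
    tumor_radius_range: Optional[tuple] = None
    tumor_intensity_offset: tuple = (70.0, 90.0, 60.0, 50.0, 80.0)
    bias_field_amplitude: float = 0.3
    noise_sd: float = 5.0
    texture_scale: Optional[float] = None

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.image_size < 16:
            raise ParameterError("image_size must be >= 16")
        if self.tumor_radius_range is None:
            s = self.image_size
            self.tumor_radius_range = (0.10 * s, 0.18 * s)
        if self.tumor_radius_range[1] > 0.45 * self.image_size:
            raise ParameterError("tumor radius must fit inside the image")
        if self.texture_scale is None:
            self.texture_scale = self.image_size / 32.0


@dataclass
class PhantomExample:
    """One phantom image with its ground-truth mask."""

    image: np.ndarray       # (H, W) uint8
    mask: np.ndarray        # (H, W) uint8 class-index map
    class_label: str
    meta: dict = field(default_factory=dict)


def _class_index(class_label: str) -> int:
    try:
        return CLASS_NAMES.index(class_label)
    except ValueError:
        raise ParameterError(
            f"unknown class {class_label!r}; expected one of {CLASS_NAMES}"
        ) from None


def _bias_field(rng: np.random.Generator, size: int, amplitude: float) -> np.ndarray:
    """Multiplicative low-frequency field: a few low-order cosine terms."""
    yy, xx = np.meshgrid(np.arange(size), np.arange(size), indexing="ij")
    n_terms = int(rng.integers(2, 5))
    b = np.zeros((size, size))
    for _ in range(n_terms):
        fy, fx = rng.uniform(0.3, 1.2, size=2)
        py, px = rng.uniform(0, 2 * np.pi, size=2)
        amp = rng.uniform(0.5, 1.0)
        b += amp * np.cos(2 * np.pi * fy * yy / size + py) * np.cos(2 * np.pi * fx * xx / size + px)
    b /= np.abs(b).max()
    return 1.0 + amplitude * b


def generate_phantom(spec: PhantomSpec, class_label: str, seed) -> PhantomExample:
    """Generate one phantom image/mask pair for the given class.

    ``seed`` may be an int or a sequence of ints (numpy seed-spawning
    convention); identical seeds give bit-identical examples.
    """
    cls = _class_index(class_label)
    rng = np.random.default_rng(seed)
    s = spec.image_size
    yy, xx = np.meshgrid(np.arange(s), np.arange(s), indexing="ij")

    # elliptical head with smooth texture
    cy, cx = s / 2 + rng.uniform(-0.02, 0.02, 2) * s
    ay = s * rng.uniform(0.38, 0.42)
    ax = s * rng.uniform(0.33, 0.37)
    head = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    tex = ndimage.gaussian_filter(rng.standard_normal((s, s)), spec.texture_scale)
    tex *= 18.0 / max(tex.std(), 1e-9)
    img = np.where(head, 112.0 + tex, 4.0)

    mask = np.zeros((s, s), dtype=np.uint8)
    meta = {"class_index": cls}
    if cls != 0:
        offset = float(spec.tumor_intensity_offset[cls - 1])
        _, ecc, irr, lobes = _CLASS_STYLES[cls]
        r0 = float(rng.uniform(*spec.tumor_radius_range))
        # tumor centre well inside the head
        theta_c = rng.uniform(0, 2 * np.pi)
        rad_c = rng.uniform(0, 0.45)
        ty = cy + rad_c * ay * np.sin(theta_c)
        tx = cx + rad_c * ax * np.cos(theta_c)
        rot = rng.uniform(0, np.pi)
        u = (yy - ty) * np.cos(rot) + (xx - tx) * np.sin(rot)
        v = -(yy - ty) * np.sin(rot) + (xx - tx) * np.cos(rot)
        rho = np.sqrt((u / r0) ** 2 + (v * ecc / r0) ** 2)
        theta = np.arctan2(v, u)
        p1, p2 = rng.uniform(0, 2 * np.pi, 2)
        boundary = 1.0 + irr * (0.6 * np.sin(lobes * theta + p1)
                                + 0.4 * np.sin((lobes + 2) * theta + p2))
        blob = rho <= boundary
        mask[blob] = cls
        img[blob] += offset + 0.3 * tex[blob]
        meta.update(radius=r0, eccentricity=ecc, irregularity=irr,
                    centre=(float(ty), float(tx)))

    img *= _bias_field(rng, s, spec.bias_field_amplitude)
    if spec.noise_sd > 0:
        img += rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)
    return PhantomExample(image=img, mask=mask, class_label=class_label, meta=meta)


def _item_seed(seed: int, cls: int, i: int):
    return [int(seed) % (2 ** 31), cls, i]


def generate_examples(
    spec: PhantomSpec,
    per_class: int | Sequence[int],
    seed: int,
    classes: Sequence[str] = CLASS_NAMES,
) -> list:
    """Generate ``per_class`` phantoms for each class, in memory."""
    if isinstance(per_class, int):
        per_class = [per_class] * len(classes)
    examples = []
    for label, count in zip(classes, per_class):
        cls = _class_index(label)
        for i in range(count):
            examples.append(generate_phantom(spec, label, _item_seed(seed, cls, i)))
    return examples


def generate_dataset(
    spec: PhantomSpec,
    per_class: int | Sequence[int],
    seed: int,
    out_dir,
    classes: Sequence[str] = CLASS_NAMES,
) -> Path:
    """Write a folder-per-class phantom dataset with sidecar masks.

    Layout: ``<out_dir>/<Class>/<id>.png`` plus ``<id>_mask.png`` and a
    ``manifest.csv`` with columns path, mask_path, class, seed.  Regeneration
    with the same seed is byte-identical.
    """
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(per_class, int):
        per_class = [per_class] * len(classes)
    rows = []
    for label, count in zip(classes, per_class):
        if count < 1:
            raise ParameterError("per-class counts must be >= 1")
        cls = _class_index(label)
        cls_dir = out_dir / label
        cls_dir.mkdir(exist_ok=True)
        for i in range(count):
            ex = generate_phantom(spec, label, _item_seed(seed, cls, i))
            img_path = cls_dir / f"{i:04d}.png"
            mask_path = cls_dir / f"{i:04d}_mask.png"
            iio.imwrite(img_path, ex.image)
            iio.imwrite(mask_path, ex.mask)
            rows.append({
                "path": str(img_path.relative_to(out_dir)),
                "mask_path": str(mask_path.relative_to(out_dir)),
                "class": label,
                "seed": seed,
            })
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=["path", "mask_path", "class", "seed"])
        writer.writeheader()
        writer.writerows(rows)
    return out_dir
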