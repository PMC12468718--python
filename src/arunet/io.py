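"""Dataset readers/writers and experiment configuration.

Datasets follow a folder-per-class layout: ``<root>/<Class>/<id>.png`` (or
``.jpg``) with a sidecar class-index mask ``<id>_mask.png`` for tumor
classes.  Masks store the class index as the pixel value, 0 = background;
classes named "Normal" may omit masks (an all-zero mask is implied).
Coordinates are row-major, origin top-left, 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from .exceptions import DataError
from .preprocess import ClaheParams, KuwaharaParams, NlmParams, to_grayscale
from .synthetic import CLASS_NAMES
from .training import LabeledExample, TrainConfig

__all__ = [
    "DatasetIndex",
    "ExperimentConfig",
    "read_image",
    "write_image",
    "load_dataset",
    "load_examples",
    "resize_image",
    "resize_mask",
]

_IMAGE_SUFFIXES = (".png", ".jpg", ".jpeg")


def read_image(path) -> np.ndarray:
    import imageio.v3 as iio

    return np.asarray(iio.imread(path))


def write_image(path, img: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, np.asarray(img, dtype=np.uint8))


def resize_image(img: np.ndarray, size: int) -> np.ndarray:
    """Bilinear resize of an intensity image to ``size x size``."""
    from PIL import Image

    if img.shape == (size, size):
        return img
    return np.asarray(
        Image.fromarray(img).resize((size, size), resample=Image.BILINEAR)
    )


def resize_mask(mask: np.ndarray, size: int) -> np.ndarray:
    """Nearest-neighbour resize of a class-index mask (no new indices)."""
    from PIL import Image

    if mask.shape == (size, size):
        return mask
    return np.asarray(
        Image.fromarray(mask).resize((size, size), resample=Image.NEAREST)
    )


@dataclass
class DatasetIndex:
    """Catalog of (image path, mask path, class) triples."""

    entries: list  # of (Path, Optional[Path], str)
    class_names: list
    excluded: list = field(default_factory=list)  # validation report

    def __len__(self):
        return len(self.entries)


def load_dataset(root) -> DatasetIndex:
    """Index a folder-per-class dataset.

    Tumor-class images without a sidecar mask are excluded and listed in the
    returned index's ``excluded`` report rather than failing the whole load.
    """
    root = Path(root)
    class_dirs = sorted(d for d in root.iterdir() if d.is_dir())
    if not class_dirs:
        raise DataError(f"no class folders found under {root}")
    names = [d.name for d in class_dirs]
    if set(names) <= set(CLASS_NAMES):
        # canonical vocabulary order (Normal first = background index 0)
        names = [n for n in CLASS_NAMES if n in names]
    entries = []
    excluded = []
    for d in class_dirs:
        maskless_ok = d.name.lower() == "normal"
        for img_path in sorted(d.iterdir()):
            if img_path.suffix.lower() not in _IMAGE_SUFFIXES:
                continue
            if img_path.stem.endswith("_mask"):
                continue
            mask_path = img_path.with_name(img_path.stem + "_mask.png")
            if mask_path.exists():
                entries.append((img_path, mask_path, d.name))
            elif maskless_ok:
                entries.append((img_path, None, d.name))
            else:
                excluded.append((img_path, "missing mask"))
    return DatasetIndex(entries=entries, class_names=names, excluded=excluded)


def load_examples(index: DatasetIndex, size: Optional[int] = None) -> list:
    """Materialise an index into :class:`LabeledExample` objects.

    Images are converted to grayscale and bilinearly rescaled to the network
    input size; masks use nearest-neighbour so no new class indices appear.
    """
    examples = []
    for img_path, mask_path, label in index.entries:
        img = to_grayscale(read_image(img_path))
        mask = (read_image(mask_path) if mask_path is not None
                else np.zeros_like(img))
        if mask.ndim == 3:
            mask = mask[..., 0]
        if size is not None:
            img = resize_image(img, size)
            mask = resize_mask(mask, size)
        examples.append(LabeledExample(image=img, mask=mask, image_class=label))
    return examples


@dataclass
class ExperimentConfig:
    """Round-trippable description of a full experiment run."""

    data_dir: str = ""
    out_dir: str = "runs/exp"
    seed: int = 0
    image_size: int = 64
    variant: str = "arunet"
    depth: int = 3
    base_width: int = 8
    n_classes: int = 6
    alpha: float = 1.0
    preprocess: bool = True
    clahe: ClaheParams = field(default_factory=ClaheParams)
    nlm: NlmParams = field(default_factory=NlmParams)
    kuwahara: KuwaharaParams = field(default_factory=KuwaharaParams)
    train: TrainConfig = field(default_factory=TrainConfig)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        d = dict(d)
        for key, sub in (("clahe", ClaheParams), ("nlm", NlmParams),
                         ("kuwahara", KuwaharaParams), ("train", TrainConfig)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
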