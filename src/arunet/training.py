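"""Training protocol: stratified splits, class weighting, balanced batches,
Adam updates, early stopping on validation loss, checkpoint selection on
validation weighted F1.

The two monitoring criteria are deliberately independent: training stops when
validation loss stalls for ``patience`` epochs, while the retained checkpoint
is the epoch with the highest validation weighted F1.  Everything is driven
by a single integer seed (model initialisation is seeded separately at build
time), so two runs with the same configuration produce bit-identical
histories and checkpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .exceptions import DataError, ParameterError
from .metrics import confusion_counts, metric_suite, weighted_f1
from .network import SegModel
from .nn import Adam
from .nn.tensor import softmax, weighted_softmax_cross_entropy

__all__ = [
    "TrainConfig",
    "LabeledExample",
    "TrainHistory",
    "TrainResult",
    "split_dataset",
    "class_weights",
    "weighted_cce",
    "balanced_batches",
    "train",
]


@dataclass
class TrainConfig:
    """Optimisation and sampling hyperparameters.

    Defaults follow the reference protocol: Adam at learning rate 1e-4,
    mini-batches of 8, at most 40 epochs with early-stopping patience 10,
    inverse-frequency class weighting and class-balanced batch sampling.
    ``max_steps`` optionally caps the total number of optimisation steps
    (used by short smoke-training runs).
    """

    learning_rate: float = 1e-4
    batch_size: int = 8
    max_epochs: int = 40
    patience: int = 10
    seed: int = 0
    class_weighting: str = "inverse_frequency"
    sampler: str = "balanced"
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    max_steps: Optional[int] = None

    def validate(self, n_classes_present: Optional[int] = None) -> None:
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be positive")
        if self.patience < 1 or self.max_epochs < 1 or self.batch_size < 1:
            raise ParameterError("patience, max_epochs and batch_size must be >= 1")
        if self.class_weighting not in ("inverse_frequency", "none"):
            raise ParameterError(f"unknown class_weighting {self.class_weighting!r}")
        if self.sampler not in ("balanced", "uniform"):
            raise ParameterError(f"unknown sampler {self.sampler!r}")
        if (self.sampler == "balanced" and n_classes_present is not None
                and self.batch_size < n_classes_present):
            raise ParameterError(
                "batch_size must be >= number of classes for balanced sampling"
            )


@dataclass
class LabeledExample:
    """An image, its class-index mask, and the image-level dataset class."""

    image: np.ndarray
    mask: np.ndarray
    image_class: str

    def __post_init__(self):
        if np.asarray(self.mask).shape != np.asarray(self.image).shape[:2]:
            raise DataError("mask shape must equal image shape")


# ---------------------------------------------------------------------------
# dataset plumbing
# ---------------------------------------------------------------------------

def split_dataset(
    examples: Sequence,
    ratios: tuple = (0.6, 0.2, 0.2),
    seed: int = 0,
    label_of=lambda ex: ex.image_class,
):
    """Stratified train/validation/test split.

    Within every class the examples are shuffled (seeded) and cut at the
    cumulative ratio boundaries, so each class is represented in every part
    in the requested 6:2:2 proportions.  The three parts are disjoint and
    exhaustive.
    """
    if abs(sum(ratios) - 1.0) > 1e-9 or len(ratios) != 3:
        raise ParameterError("ratios must be three values summing to 1")
    by_class: dict[str, list] = {}
    for ex in examples:
        by_class.setdefault(label_of(ex), []).append(ex)
    rng = np.random.default_rng(seed)
    parts: tuple[list, list, list] = ([], [], [])
    for label in sorted(by_class):
        group = by_class[label]
        if len(group) < 3:
            raise DataError(
                f"class {label!r} has only {len(group)} examples; at least 3 "
                "are needed for a three-way split"
            )
        order = rng.permutation(len(group))
        n = len(group)
        cut1 = int(round(ratios[0] * n))
        cut2 = int(round((ratios[0] + ratios[1]) * n))
        cut1 = min(max(cut1, 1), n - 2)
        cut2 = min(max(cut2, cut1 + 1), n - 1)
        for part, idx in zip(parts, (order[:cut1], order[cut1:cut2], order[cut2:])):
            part.extend(group[i] for i in idx)
    return parts


def class_weights(label_pixel_counts) -> np.ndarray:
    """Inverse-frequency class weights normalised to mean 1.

    ``w_c = C * (1/n_c) / sum_k (1/n_k)``; rarer classes get weights above 1.
    """
    counts = np.asarray(label_pixel_counts, dtype=np.float64)
    if np.any(counts <= 0):
        bad = np.where(counts <= 0)[0]
        raise DataError(
            f"class(es) {bad.tolist()} have zero pixels; drop them before "
            "computing inverse-frequency weights"
        )
    inv = 1.0 / counts
    return len(counts) * inv / inv.sum()


def weighted_cce(
    scores: np.ndarray,
    target_mask: np.ndarray,
    weights: Optional[np.ndarray] = None,
) -> float:
    """Class-weighted categorical cross-entropy, averaged over pixels.

    ``scores`` carries the class axis last (``(..., C)``); raw scores are
    softmax-normalised internally, probabilities are used as given.
    Per pixel the loss is ``-w_t * log(p_t)`` with the true class's weight,
    probabilities clamped at 1e-12.
    """
    scores = np.asarray(scores, dtype=np.float64)
    target = np.asarray(target_mask)
    if scores.shape[:-1] != target.shape:
        raise DataError(
            f"scores shape {scores.shape} incompatible with target {target.shape}"
        )
    sums = scores.sum(axis=-1)
    if not (np.all(scores >= 0) and np.allclose(sums, 1.0, atol=1e-6)):
        scores = np.moveaxis(softmax(np.moveaxis(scores, -1, 1), axis=1), 1, -1)
    pt = np.take_along_axis(scores, target[..., None], axis=-1)[..., 0]
    if weights is None:
        wmap = np.ones_like(pt)
    else:
        wmap = np.asarray(weights, dtype=np.float64)[target]
    return float((-wmap * np.log(np.clip(pt, 1e-12, None))).mean())


def balanced_batches(
    labels: Sequence,
    batch_size: int,
    seed: int,
    n_batches: Optional[int] = None,
) -> Iterable[list]:
    """Class-balanced mini-batch index iterator for one epoch.

    Every batch holds floor(B/C) examples of each class, with the remaining
    ``B mod C`` slots rotating deterministically over the classes, so each
    batch mixes majority and minority classes almost equally.  Per class the
    examples are drawn without replacement from a seeded shuffle; once a
    class is exhausted its queue reshuffles and drawing continues with
    replacement.  The epoch covers the majority class once.
    """
    labels = list(labels)
    classes = sorted(set(labels))
    c = len(classes)
    if batch_size < c:
        raise ParameterError("batch_size must be >= number of classes present")
    rng = np.random.default_rng(seed)
    pools = {k: [i for i, lab in enumerate(labels) if lab == k] for k in classes}
    queues = {k: list(rng.permutation(pools[k])) for k in classes}
    base, extra = divmod(batch_size, c)
    largest = max(len(v) for v in pools.values())
    per_batch_max = base + (1 if extra else 0)
    if n_batches is None:
        n_batches = -(-largest // per_batch_max)

    def draw(k: str) -> int:
        if not queues[k]:
            queues[k] = list(rng.permutation(pools[k]))
        return int(queues[k].pop())

    for b in range(n_batches):
        batch = []
        quota = {k: base for k in classes}
        for j in range(extra):
            quota[classes[(b * extra + j) % c]] += 1
        for k in classes:
            batch.extend(draw(k) for _ in range(quota[k]))
        yield batch


def _uniform_batches(n: int, batch_size: int, seed: int) -> Iterable[list]:
    order = np.random.default_rng(seed).permutation(n)
    for start in range(0, n, batch_size):
        yield [int(i) for i in order[start:start + batch_size]]


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainHistory:
    """Per-epoch records plus the stop reason and best-epoch index."""

    epochs: list = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""

    def append(self, **record):
        self.epochs.append(record)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(self.epochs)

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")


@dataclass
class TrainResult:
    """Best checkpoint (state dict), its epoch, and the full history."""

    best_state: dict
    best_epoch: int
    best_weighted_f1: float
    history: TrainHistory


def _stack_images(examples, idx) -> tuple[np.ndarray, np.ndarray]:
    images = np.stack([examples[i].image for i in idx]).astype(np.float64) / 255.0
    masks = np.stack([np.asarray(examples[i].mask, dtype=np.int64) for i in idx])
    return images, masks


def _evaluate(model: SegModel, examples, weights, n_classes, batch_size=8):
    """Validation loss, pixel accuracy and weighted F1 in eval mode."""
    model.eval()
    total_loss = 0.0
    total_pix = 0
    counts = None
    for start in range(0, len(examples), batch_size):
        idx = range(start, min(start + batch_size, len(examples)))
        images, masks = _stack_images(examples, idx)
        logits = model.forward(images)
        loss = weighted_softmax_cross_entropy(logits, masks, weights)
        npix = masks.size
        total_loss += loss.item() * npix
        total_pix += npix
        batch_counts = confusion_counts(logits.data.argmax(axis=1), masks, n_classes)
        counts = batch_counts if counts is None else counts + batch_counts
    model.train()
    report = metric_suite(counts)
    acc = float((counts.tp.sum()) / counts.n_pixels)
    return total_loss / total_pix, acc, weighted_f1(report)


def train(
    model: SegModel,
    train_examples: Sequence[LabeledExample],
    val_examples: Sequence[LabeledExample],
    cfg: Optional[TrainConfig] = None,
) -> TrainResult:
    """Run the full training protocol and return the best checkpoint.

    Early stopping watches validation loss (stop after ``patience`` epochs
    without strict improvement); the saved checkpoint is the epoch with the
    maximal validation weighted F1.  A non-finite training loss aborts with a
    diagnostic.
    """
    cfg = cfg or TrainConfig()
    labels = [ex.image_class for ex in train_examples]
    classes_present = sorted(set(labels))
    cfg.validate(len(classes_present))
    n_classes = model.config.n_classes

    if cfg.class_weighting == "inverse_frequency":
        # weighting targets the imbalance BETWEEN tumor classes; the
        # background (class 0, shared with tumor-free images) keeps weight 1
        pix = np.zeros(n_classes, dtype=np.int64)
        for ex in train_examples:
            pix += np.bincount(np.asarray(ex.mask).ravel(), minlength=n_classes)
        present = np.where(pix[1:] > 0)[0] + 1
        weights = np.ones(n_classes)
        if len(present) > 0:
            weights[present] = class_weights(pix[present])
    else:
        weights = None

    optimizer = Adam(model.parameters(), lr=cfg.learning_rate,
                     beta1=cfg.beta1, beta2=cfg.beta2, eps=cfg.eps)
    history = TrainHistory()
    best_val_loss = np.inf
    best_wf1 = -np.inf
    best_state: dict = model.state_dict()
    best_epoch = -1
    epochs_since_improve = 0
    step = 0
    stop_reason = "max_epochs"

    model.train()
    for epoch in range(1, cfg.max_epochs + 1):
        if cfg.sampler == "balanced":
            batches = balanced_batches(labels, cfg.batch_size, seed=cfg.seed + epoch)
        else:
            batches = _uniform_batches(len(train_examples), cfg.batch_size,
                                       seed=cfg.seed + epoch)
        epoch_loss = 0.0
        epoch_batches = 0
        hit_step_cap = False
        for batch in batches:
            images, masks = _stack_images(train_examples, batch)
            optimizer.zero_grad()
            logits = model.forward(images)
            loss = weighted_softmax_cross_entropy(logits, masks, weights)
            if not np.isfinite(loss.item()):
                raise RuntimeError(
                    f"training diverged: non-finite loss {loss.item()} at "
                    f"epoch {epoch}, step {step}"
                )
            loss.backward()
            optimizer.step()
            epoch_loss += loss.item()
            epoch_batches += 1
            step += 1
            if cfg.max_steps is not None and step >= cfg.max_steps:
                hit_step_cap = True
                break

        val_loss, val_acc, val_wf1 = _evaluate(model, val_examples, weights, n_classes,
                                               batch_size=cfg.batch_size)
        history.append(
            epoch=epoch,
            train_loss=epoch_loss / max(epoch_batches, 1),
            val_loss=val_loss,
            val_acc=val_acc,
            val_weighted_f1=val_wf1,
        )
        if val_wf1 > best_wf1:
            best_wf1 = val_wf1
            best_state = model.state_dict()
            best_epoch = epoch
        if val_loss < best_val_loss:
            best_val_loss = val_loss
            epochs_since_improve = 0
        else:
            epochs_since_improve += 1
        if hit_step_cap:
            stop_reason = "max_steps"
            break
        if epochs_since_improve >= cfg.patience:
            stop_reason = "early_stopping"
            break

    history.best_epoch = best_epoch
    history.stop_reason = stop_reason
    return TrainResult(best_state=best_state, best_epoch=best_epoch,
                       best_weighted_f1=float(best_wf1), history=history)
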