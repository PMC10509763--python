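"""Patient-level splitting, augmentation, loss and the training protocol.

The dataset is split at the patient level (7:1:2 train/val/test by default)
so that repeated views of one abdomen never leak across subsets.
Augmentation is horizontal flipping plus a random contrast change.  The loss
is the mean binary cross-entropy between the predicted probability map and
the binary ground truth.  Optimization uses Adam (first-moment decay 0.9,
learning rate 1e-3, batch size 8); after every epoch the validation Dice is
computed in inference mode, the best-scoring parameters are kept, and
training stops early when the validation score has not improved for
``early_stop_patience`` epochs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .core import BinaryMask, DataError, ParameterError, ProbMap, ShapeError
from .nets import Param, SegModel, _sigmoid
from . import metrics as _metrics

__all__ = [
    "SplitSpec",
    "TrainConfig",
    "split_patients",
    "augment",
    "bce_loss",
    "Adam",
    "fit",
]

_EPS = 1e-7


@dataclass
class SplitSpec:
    """Patient-level subset assignment."""

    assignment: Dict[str, str]  # patient_id -> "train" | "val" | "test"
    ratio: Tuple[float, float, float] = (7.0, 1.0, 2.0)

    def patients(self, subset: str) -> List[str]:
        return [p for p, s in self.assignment.items() if s == subset]

    def subset_of(self, patient_id: str) -> str:
        return self.assignment[patient_id]


@dataclass
class TrainConfig:
    """Optimization and augmentation hyperparameters."""

    learning_rate: float = 0.001
    beta1: float = 0.9
    batch_size: int = 8
    max_epochs: int = 100
    early_stop_patience: int = 15
    seed: int = 0
    flip_prob: float = 0.5
    contrast_range: Tuple[float, float] = (0.7, 1.3)

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be positive")
        if not (0.0 <= self.flip_prob <= 1.0):
            raise ParameterError("flip_prob must lie in [0, 1]")
        lo, hi = self.contrast_range
        if not lo < hi:
            raise ParameterError("contrast_range must satisfy low < high")


def split_patients(
    patient_ids: Sequence[str],
    ratio: Tuple[float, float, float] = (7.0, 1.0, 2.0),
    seed: int = 0,
) -> SplitSpec:
    """Randomly partition patients into train/val/test at the given ratio.

    Patients are permuted by the seed, then allocated contiguously with
    largest-remainder rounding, so each subset's patient count deviates from
    its exact proportion by at most one.  All images of a patient inherit
    its subset.
    """
    ids = list(dict.fromkeys(patient_ids))  # preserve order, drop duplicates
    if len(ids) < 3:
        raise ParameterError("patient-level split needs at least 3 patients")
    if min(ratio) < 0 or sum(ratio) <= 0:
        raise ParameterError("ratio entries must be non-negative, sum positive")
    n = len(ids)
    exact = np.array(ratio, dtype=float) * n / float(sum(ratio))
    counts = np.floor(exact).astype(int)
    # distribute the remainder by largest fractional part (ties -> earlier subset)
    order = np.argsort(-(exact - counts), kind="stable")
    for k in range(n - counts.sum()):
        counts[order[k]] += 1
    # guarantee non-empty subsets when possible
    for i in range(3):
        if counts[i] == 0:
            j = int(np.argmax(counts))
            counts[j] -= 1
            counts[i] += 1
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(n)]
    names = ("train", "val", "test")
    assignment: Dict[str, str] = {}
    start = 0
    for name, c in zip(names, counts):
        for pid in perm[start : start + c]:
            assignment[pid] = name
        start += c
    return SplitSpec(assignment=assignment, ratio=tuple(float(r) for r in ratio))


def augment(
    image: np.ndarray,
    mask: np.ndarray,
    config: TrainConfig,
    rng: Union[int, np.random.Generator],
) -> Tuple[np.ndarray, np.ndarray]:
    """Horizontal flip (image+mask) and contrast change (image only).

    The contrast gain is drawn uniformly from ``config.contrast_range`` and
    applied around the mid-gray pivot 128, clipped to [0, 255]; the mask is
    never intensity-transformed so it stays binary.  Flipping is an
    involution: applying it twice recovers the original pair.
    """
    if image.shape != mask.shape:
        raise ShapeError("image and mask must share a grid")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    img = image.astype(np.float64)
    msk = mask.copy()
    if rng.random() < config.flip_prob:
        img = img[:, ::-1].copy()
        msk = msk[:, ::-1].copy()
    lo, hi = config.contrast_range
    gain = rng.uniform(lo, hi)
    img = np.clip((img - 128.0) * gain + 128.0, 0.0, 255.0)
    return np.round(img).astype(image.dtype), msk


def bce_loss(
    pred: Union[ProbMap, np.ndarray], gt: Union[BinaryMask, np.ndarray]
) -> float:
    """Mean binary cross-entropy −mean[y·log x + (1−y)·log(1−x)].

    Probabilities are clamped to [eps, 1−eps] with eps = 1e-7 so a perfect
    prediction yields a loss near (not exactly) zero.
    """
    x = pred.values if isinstance(pred, ProbMap) else np.asarray(pred, dtype=np.float64)
    y = gt.values if isinstance(gt, BinaryMask) else np.asarray(gt)
    if x.shape != y.shape:
        raise ShapeError(f"shapes differ: {x.shape} vs {y.shape}")
    x = np.clip(x.astype(np.float64), _EPS, 1.0 - _EPS)
    y = y.astype(np.float64)
    return float(-np.mean(y * np.log(x) + (1.0 - y) * np.log(1.0 - x)))


class Adam:
    """Adaptive-moment optimizer (first-moment decay beta1)."""

    def __init__(
        self,
        params: Sequence[Param],
        lr: float = 0.001,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def _stack_samples(samples: Sequence[Tuple[np.ndarray, np.ndarray]]) -> Tuple[np.ndarray, np.ndarray]:
    xs = np.stack([s[0] for s in samples]).astype(np.float32) / 255.0
    ys = np.stack([s[1] for s in samples]).astype(np.float32)
    return xs[..., None], ys


def _validation_scores(
    model: SegModel, val_items: Sequence[Tuple[np.ndarray, np.ndarray]],
    batch_size: int,
) -> Tuple[float, float]:
    dices, ious = [], []
    for start in range(0, len(val_items), batch_size):
        xb, yb = _stack_samples(val_items[start : start + batch_size])
        probs = _sigmoid(model.forward(xb, train=False))
        for k in range(xb.shape[0]):
            pred = BinaryMask((probs[k] > 0.5).astype(np.uint8))
            gt = BinaryMask(yb[k].astype(np.uint8))
            dices.append(_metrics.dice(pred, gt))
            ious.append(_metrics.miou(pred, gt))
    return float(np.mean(dices)), float(np.mean(ious))


def fit(
    model: SegModel,
    dataset: Sequence[Tuple[str, object]],
    split: SplitSpec,
    config: TrainConfig,
) -> Tuple[dict, List[Dict[str, float]]]:
    """Train a segmentation model with validation-based checkpoint selection.

    Parameters
    ----------
    model
        A built :class:`~rectuseg.nets.SegModel` (modified in place; on return
        it holds the best-validation parameters).
    dataset
        Sequence of ``(patient_id, sample)`` where each sample exposes
        ``image`` (a Frame or uint8 array) and ``mask`` (BinaryMask or array).
    split
        Patient-level subset assignment; train and val must be non-empty.
    config
        Optimization hyperparameters; ``config.seed`` drives shuffling and
        augmentation, making the run deterministic on CPU.

    Returns
    -------
    best : dict
        ``{"arrays": parameters, "epoch": best_epoch, "val_dice": score}``.
    history : list of dict
        Per-epoch ``{"epoch", "train_loss", "val_dice", "val_iou"}`` rows —
        the training-loss and validation-score curves.
    """
    def _pair(sample) -> Tuple[np.ndarray, np.ndarray]:
        img = getattr(sample, "image", sample)
        img = img.pixels if hasattr(img, "pixels") else np.asarray(img)
        msk = getattr(sample, "mask")
        msk = msk.values if hasattr(msk, "values") else np.asarray(msk)
        return img, msk

    subsets: Dict[str, List[Tuple[np.ndarray, np.ndarray]]] = {"train": [], "val": [], "test": []}
    for pid, sample in dataset:
        subsets[split.subset_of(pid)].append(_pair(sample))
    if not subsets["train"] or not subsets["val"]:
        raise DataError("train and val subsets must both be non-empty")

    rng = np.random.default_rng(config.seed)
    opt = Adam(model.parameters(), lr=config.learning_rate, beta1=config.beta1)
    history: List[Dict[str, float]] = []
    best_state: Optional[List[np.ndarray]] = None
    best_dice = -np.inf
    best_epoch = -1
    train_items = subsets["train"]

    for epoch in range(config.max_epochs):
        order = rng.permutation(len(train_items))
        losses = []
        for start in range(0, len(order), config.batch_size):
            batch_idx = order[start : start + config.batch_size]
            batch = []
            for bi in batch_idx:
                img, msk = train_items[bi]
                batch.append(augment(img, msk, config, rng))
            xb, yb = _stack_samples(batch)
            logits = model.forward(xb, train=True)
            probs = _sigmoid(logits)
            losses.append(bce_loss(probs, yb))
            model.zero_grad()
            model.backward((probs - yb) / probs.size)  # d(mean BCE)/d(logit)
            opt.step()
        val_dice, val_iou = _validation_scores(model, subsets["val"], config.batch_size)
        history.append(
            {
                "epoch": float(epoch),
                "train_loss": float(np.mean(losses)),
                "val_dice": val_dice,
                "val_iou": val_iou,
            }
        )
        if val_dice > best_dice:
            best_dice = val_dice
            best_epoch = epoch
            best_state = model.copy_state()
        if epoch - best_epoch >= config.early_stop_patience:
            break

    assert best_state is not None
    model.load_state_arrays(best_state)
    return (
        {"arrays": best_state, "epoch": best_epoch, "val_dice": float(best_dice)},
        history,
    )
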