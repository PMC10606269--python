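"""Training (Adam + dice loss) and segmentation metrics.

The training protocol mirrors common medical-segmentation practice: Adam
minimizing a soft dice loss over the foreground classes (kidney, tumor),
with random right-angle rotation/flip augmentation.  Pure soft-dice
optimization from random initialization is unstable for very small
structures — once the softmax saturates against a class, the dice gradient
vanishes with the class probability and a collapsed tumor channel cannot
recover — so the default objective is the standard compound loss
``dice + cross-entropy`` (loss="dice_ce"), with a short CE-only warmup
before the dice term switches on.  Pure dice (loss="dice") is available.

Defaults are desk-scale (20 epochs, batch 2, 64x64 slices);
``paper_protocol()`` returns the published-style configuration
(100 epochs, batch 12).

Metrics: per-class dice coefficient, precision and recall, and overall
pixel accuracy.  Zero-denominator cases are reported as ``None``
("undefined"), never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import Adam, Model, WeightStore
from .phantoms import SegmentationSample, augment, normalize_intensity


@dataclass
class TrainConfig:
    epochs: int = 20
    batch_size: int = 2
    learning_rate: float = 3e-3
    loss: str = "dice_ce"
    warmup_epochs: int = 5  # CE-only epochs before the dice term engages
    seed: int = 0
    augmentation: bool = True
    smooth: float = 1.0
    foreground_classes: tuple[int, ...] = (1, 2)

    def __post_init__(self) -> None:
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("epochs must be >= 0 and batch_size >= 1")
        if self.loss not in ("dice", "dice_ce"):
            raise ValueError(f"unsupported loss {self.loss!r}")


def paper_protocol(**overrides) -> TrainConfig:
    """The published-style protocol: 100 epochs, batch size 12, dice loss."""
    return TrainConfig(**{"epochs": 100, "batch_size": 12, "loss": "dice",
                          "warmup_epochs": 0, **overrides})


@dataclass
class PredictionMap:
    scores: np.ndarray          # (H, W, n_classes) pre-softmax
    predicted_mask: np.ndarray  # argmax labels; ties -> lowest label


def predict(model: Model, x: np.ndarray) -> PredictionMap:
    """Deterministic forward pass; argmax ties go to the lowest label."""
    squeeze = x.ndim == 2
    if squeeze:
        x = x[None, ..., None]
    elif x.ndim == 3:
        x = x[None]
    scores = model.forward(x)
    scores = scores[0] if squeeze or x.shape[0] == 1 else scores
    return PredictionMap(scores=scores,
                         predicted_mask=scores.argmax(axis=-1))


# ---------------------------------------------------------------------------
# Losses and metrics


def softmax(scores: np.ndarray) -> np.ndarray:
    z = scores - scores.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def dice_loss(probabilities: np.ndarray, target_onehot: np.ndarray,
              smooth: float = 1.0,
              classes: tuple[int, ...] | None = None) -> float:
    """Soft dice loss ``1 - mean_c (2*sum(p*t) + s) / (sum(p) + sum(t) + s)``.

    Averaged over ``classes`` (default: every class present in the one-hot
    target's last axis).  Value lies in [0, 1].
    """
    if probabilities.shape != target_onehot.shape:
        raise ValueError("probability and target shapes must match")
    cls = classes if classes is not None else tuple(range(probabilities.shape[-1]))
    dices = []
    for c in cls:
        p, t = probabilities[..., c], target_onehot[..., c]
        dices.append((2.0 * (p * t).sum() + smooth) / (p.sum() + t.sum() + smooth))
    return float(1.0 - np.mean(dices))


def _dice_loss_grad(probabilities, target_onehot, smooth, classes):
    """d(loss)/d(probabilities); same averaging as :func:`dice_loss`."""
    grad = np.zeros_like(probabilities)
    n = len(classes)
    for c in classes:
        p, t = probabilities[..., c], target_onehot[..., c]
        num = 2.0 * (p * t).sum() + smooth
        den = p.sum() + t.sum() + smooth
        grad[..., c] = -(2.0 * t * den - num) / (den * den) / n
    return grad


def one_hot(mask: np.ndarray, n_classes: int) -> np.ndarray:
    return np.eye(n_classes)[mask]


def dice_coefficient(pred_mask: np.ndarray, target_mask: np.ndarray,
                     label: int) -> float | None:
    """2|A∩B| / (|A| + |B|); ``None`` (undefined) when both sets are empty."""
    a, b = pred_mask == label, target_mask == label
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return None
    return 2.0 * int((a & b).sum()) / denom


def precision_recall(pred_mask: np.ndarray, target_mask: np.ndarray,
                     label: int) -> tuple[float | None, float | None]:
    """(TP/(TP+FP), TP/(TP+FN)); ``None`` on a zero denominator."""
    a, b = pred_mask == label, target_mask == label
    tp = int((a & b).sum())
    fp = int((a & ~b).sum())
    fn = int((~a & b).sum())
    precision = tp / (tp + fp) if tp + fp else None
    recall = tp / (tp + fn) if tp + fn else None
    return precision, recall


def pixel_accuracy(pred_mask: np.ndarray, target_mask: np.ndarray) -> float:
    """Fraction of pixels whose predicted label equals the ground truth."""
    if pred_mask.shape != target_mask.shape:
        raise ValueError("mask shapes must match")
    return float((pred_mask == target_mask).mean())


def evaluate(model: Model, samples: list[SegmentationSample],
             labels: tuple[int, ...] = (1, 2)) -> dict:
    """Mean per-class dice/precision/recall and pixel accuracy over samples."""
    per_label: dict[int, dict[str, list[float]]] = {
        l: {"dice": [], "precision": [], "recall": []} for l in labels}
    accs = []
    for s in samples:
        pm = predict(model, normalize_intensity(s.image))
        accs.append(pixel_accuracy(pm.predicted_mask, s.mask))
        for l in labels:
            d = dice_coefficient(pm.predicted_mask, s.mask, l)
            p, r = precision_recall(pm.predicted_mask, s.mask, l)
            for key, v in (("dice", d), ("precision", p), ("recall", r)):
                if v is not None:
                    per_label[l][key].append(v)
    out: dict = {"pixel_accuracy": float(np.mean(accs))}
    for l in labels:
        for key in ("dice", "precision", "recall"):
            vals = per_label[l][key]
            out[f"{key}_{l}"] = float(np.mean(vals)) if vals else None
    fg = [out[f"dice_{l}"] for l in labels if out[f"dice_{l}"] is not None]
    out["dice_mean"] = float(np.mean(fg)) if fg else None
    return out


# ---------------------------------------------------------------------------
# Training loop


def _as_arrays(samples: list[SegmentationSample], n_classes: int):
    x = np.stack([normalize_intensity(s.image) for s in samples])[..., None]
    y = np.stack([one_hot(s.mask, n_classes) for s in samples])
    return x, y


def train(stage, dataset, config: TrainConfig, mask=None,
          val_dataset=None):
    """Train a ``(spec, weights)`` stage with Adam on the dice loss.

    Fully seeded: batch order and augmentation draws come from
    ``config.seed``.  When a prune ``mask`` is given, gradients are masked
    and pruned weights stay exactly zero throughout.  Returns
    ``(weights, history)``; history has one record per epoch with train
    (and optionally validation) loss and dice.  Raises on a non-finite loss.
    """
    spec, weights = stage
    weights = weights.copy()
    if config.epochs == 0:
        return weights, []
    model = Model(spec, weights)
    opt = Adam(weights, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed)
    n_classes = spec.n_classes
    classes = config.foreground_classes
    history = []
    for epoch in range(config.epochs):
        order = rng.permutation(len(dataset))
        epoch_losses = []
        for start in range(0, len(dataset), config.batch_size):
            batch = [dataset[i] for i in order[start:start + config.batch_size]]
            if config.augmentation:
                batch = [augment(s, int(rng.integers(0, 2 ** 31))) for s in batch]
            x, y = _as_arrays(batch, n_classes)
            scores, tape = model.forward(x, keep_tape=True)
            if not np.isfinite(scores).all():
                raise FloatingPointError(f"diverged (non-finite scores) "
                                         f"at epoch {epoch}")
            probs = softmax(scores)
            loss = dice_loss(probs, y, config.smooth, classes)
            if not np.isfinite(loss):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            dscores = np.zeros_like(probs)
            dice_active = config.loss == "dice" or epoch >= config.warmup_epochs
            if dice_active:
                dprobs = _dice_loss_grad(probs, y, config.smooth, classes)
                # softmax Jacobian-vector product
                dscores += probs * (dprobs
                                    - (dprobs * probs).sum(axis=-1, keepdims=True))
            if config.loss == "dice_ce":
                # cross-entropy through softmax: mean over pixels of (p - t)
                dscores += (probs - y) / np.prod(y.shape[:-1])
            grads, _ = model.backward(tape, dscores)
            opt.step(grads, mask=mask)
            epoch_losses.append(loss)
        record = {"epoch": epoch + 1, "train_loss": float(np.mean(epoch_losses))}
        if val_dataset:
            m = evaluate(model, val_dataset)
            record["val_dice"] = m["dice_mean"]
            record["val_accuracy"] = m["pixel_accuracy"]
        history.append(record)
    return weights, history
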