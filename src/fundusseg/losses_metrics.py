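"""Multi-label Dice loss with analytic gradient, side-output fusion, and
segmentation metrics (pixel accuracy, IoU, Dice, mIoU).

The disc/cup segmentation is posed as a *multi-label* problem: each class k
gets an independent binary target g_(k,i) and predicted probability
p_(k,i), so a pixel may belong to both disc and cup (the cup lies inside
the disc).  The loss is a class-weighted Dice loss

    L_s = 1 - sum_k 2 w_k (sum_i p_(k,i) g_(k,i))
                      / (sum_i p_(k,i)^2 + sum_i g_(k,i)^2),

with sum_k w_k = 1 (w_k = 0.5 each for disc and cup).  For K = 1 this
reduces to the classic soft Dice loss 1 - Dice.  The gradient w.r.t. the
predicted probabilities is available in closed form, which keeps the loss
cheap to back-propagate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DiceLossConfig",
    "SideOutputConfig",
    "MetricsReport",
    "multilabel_dice_loss",
    "multilabel_dice_grad",
    "side_output_loss",
    "pixel_accuracy",
    "iou",
    "dice_coefficient",
    "mean_iou",
]


@dataclass
class DiceLossConfig:
    """Configuration of the multi-label Dice loss.

    ``class_weights`` must sum to 1; ``smoothing_eps`` is added to each
    class denominator so an all-empty class (0/0) stays defined.
    """

    n_classes: int = 2
    class_weights: tuple = (0.5, 0.5)
    smoothing_eps: float = 1e-7

    def __post_init__(self):
        if self.n_classes < 1:
            raise ValueError("n_classes must be >= 1")
        w = np.asarray(self.class_weights, dtype=float)
        if w.size != self.n_classes:
            raise ValueError("class_weights length must equal n_classes")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("class_weights must be non-negative and sum to 1")
        if self.smoothing_eps < 0:
            raise ValueError("smoothing_eps must be non-negative")


@dataclass
class SideOutputConfig:
    """Deep-supervision fusion: M side outputs with weights a_m (0.25 each
    by default, pairing naturally with M = 4 heads)."""

    n_side_outputs: int = 4
    fusion_weights: tuple = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        if self.n_side_outputs < 1:
            raise ValueError("n_side_outputs must be >= 1")
        w = np.asarray(self.fusion_weights, dtype=float)
        if w.size != self.n_side_outputs:
            raise ValueError("fusion_weights length must equal n_side_outputs")
        if np.any(w < 0):
            raise ValueError("fusion_weights must be non-negative")


def _validate_batch(p, g, cfg: DiceLossConfig):
    p = np.asarray(p, dtype=float)
    g = np.asarray(g, dtype=float)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: p {p.shape} vs g {g.shape}")
    if p.ndim != 2 or p.shape[1] != cfg.n_classes:
        raise ValueError("batch must be (n_pixels, n_classes)")
    if p.min() < 0 or p.max() > 1:
        raise ValueError("predicted probabilities must lie in [0, 1]")
    if not np.isin(g, (0.0, 1.0)).all():
        raise ValueError("ground truth must be binary")
    return p, g


def _denominators(p, g, cfg: DiceLossConfig):
    den = (p ** 2).sum(axis=0) + (g ** 2).sum(axis=0) + cfg.smoothing_eps
    if np.any(den == 0):
        raise FloatingPointError(
            "0/0 Dice term: a class is empty in both p and g with smoothing_eps=0"
        )
    return den


def multilabel_dice_loss(p, g, cfg: DiceLossConfig | None = None) -> float:
    """Class-weighted multi-label Dice loss L_s in [0, 1].

    Parameters
    ----------
    p : (n_pixels, n_classes) array of predicted probabilities in [0, 1].
    g : (n_pixels, n_classes) binary ground-truth array.
    """
    cfg = cfg or DiceLossConfig()
    p, g = _validate_batch(p, g, cfg)
    w = np.asarray(cfg.class_weights, dtype=float)
    den = _denominators(p, g, cfg)
    inter = (p * g).sum(axis=0)
    return float(1.0 - (2.0 * w * inter / den).sum())


def multilabel_dice_grad(p, g, cfg: DiceLossConfig | None = None) -> np.ndarray:
    """Closed-form gradient dL_s/dp_(k,i) of :func:`multilabel_dice_loss`.

    For each class k with denominator D_k = sum p^2 + sum g^2:

        dL_s/dp_(k,i) = 2 w_k [ -g_(k,i)/D_k + 2 p_(k,i) (sum_i p g) / D_k^2 ]
    """
    cfg = cfg or DiceLossConfig()
    p, g = _validate_batch(p, g, cfg)
    w = np.asarray(cfg.class_weights, dtype=float)
    den = _denominators(p, g, cfg)
    inter = (p * g).sum(axis=0)
    return 2.0 * w * (-g / den + 2.0 * p * inter / den ** 2)


def side_output_loss(side_losses, cfg: SideOutputConfig | None = None) -> float:
    """Fused deep-supervision objective: sum_m a_m L_s^(m)."""
    cfg = cfg or SideOutputConfig()
    losses = np.asarray(side_losses, dtype=float)
    if losses.ndim != 1 or losses.size != cfg.n_side_outputs:
        raise ValueError(
            f"expected {cfg.n_side_outputs} side losses, got {losses.size}"
        )
    return float((np.asarray(cfg.fusion_weights) * losses).sum())


# -- evaluation metrics ---------------------------------------------------

def _check_same_shape(pred, gt):
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    return pred, gt


def pixel_accuracy(pred, gt) -> float:
    """Fraction of pixels whose predicted class equals the ground truth."""
    pred, gt = _check_same_shape(pred, gt)
    return float((pred == gt).mean())


def iou(pred, gt, class_id=None) -> float:
    """Intersection over union.

    Boolean/binary inputs are compared directly; for integer label masks
    pass ``class_id`` to select one class, or leave ``None`` for the
    micro-averaged IoU over all classes present in either mask.  An empty
    union counts as perfect agreement (1.0).
    """
    pred, gt = _check_same_shape(pred, gt)
    if class_id is not None:
        pred = pred == class_id
        gt = gt == class_id
    if pred.dtype != bool:
        if np.isin(pred, (0, 1)).all() and np.isin(gt, (0, 1)).all():
            pred = pred.astype(bool)
            gt = gt.astype(bool)
        else:  # micro-average over the classes of a label mask
            classes = np.union1d(np.unique(pred), np.unique(gt))
            inter = sum(np.sum((pred == c) & (gt == c)) for c in classes)
            union = sum(np.sum((pred == c) | (gt == c)) for c in classes)
            return 1.0 if union == 0 else float(inter / union)
    inter = np.logical_and(pred, gt).sum()
    union = np.logical_or(pred, gt).sum()
    return 1.0 if union == 0 else float(inter / union)


def dice_coefficient(pred, gt, class_id=None) -> float:
    """Dice/F1 overlap 2|A∩B|/(|A|+|B|); 1.0 when both are empty."""
    pred, gt = _check_same_shape(pred, gt)
    if class_id is not None:
        pred = pred == class_id
        gt = gt == class_id
    pred = pred.astype(bool)
    gt = gt.astype(bool)
    total = pred.sum() + gt.sum()
    if total == 0:
        return 1.0
    return float(2.0 * np.logical_and(pred, gt).sum() / total)


def mean_iou(pred, gt, n_classes: int) -> float:
    """Unweighted mean of per-class IoU over all ``n_classes`` classes.

    A class absent from both masks contributes 1.0 (empty/empty
    convention), which keeps the mean defined on sparse scenes.
    """
    pred, gt = _check_same_shape(pred, gt)
    if pred.max(initial=0) >= n_classes or gt.max(initial=0) >= n_classes:
        raise ValueError("mask contains a class id >= n_classes")
    return float(np.mean([iou(pred, gt, class_id=c) for c in range(n_classes)]))


@dataclass
class MetricsReport:
    """Evaluation summary matching the standard segmentation columns:
    pixel accuracy, micro-averaged IoU, Dice, macro mIoU, and the value of
    the training objective on the evaluation set."""

    pixel_accuracy: float
    iou: float
    dice: float
    mean_iou: float
    model_loss: float
    extras: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "pixel_accuracy": self.pixel_accuracy,
            "iou": self.iou,
            "dice": self.dice,
            "mean_iou": self.mean_iou,
            "model_loss": self.model_loss,
        }
        d.update(self.extras)
        return d

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text
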