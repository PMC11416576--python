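"""Training, cross-validation, patch protocols, prediction post-processing
and evaluation.

The module-level functions are thin wrappers around the estimator layer
(:mod:`fundusseg.estimators`): ``train`` drives :func:`fit_loop` on an
existing network handle, ``kfold_cv`` runs seeded 5-fold cross-validation,
and the patch functions implement the random 48x48-patch training and
stride-5 overlap-averaged prediction protocols.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.model_selection import KFold

from .estimators import _as_float_batch, fit_loop
from .losses_metrics import (
    MetricsReport,
    dice_coefficient,
    iou,
    mean_iou,
    pixel_accuracy,
)
from .polar import PolarGrid, estimate_disc_center, from_polar, to_polar
from .preprocess import ThresholdParams, contour_threshold

__all__ = [
    "TrainConfig",
    "PatchConfig",
    "train",
    "kfold_cv",
    "extract_patches",
    "predict_overlap_average",
    "cover_count_map",
    "fov_mask",
    "prob_to_mask",
    "evaluate",
    "segment_disc_cup",
]


@dataclass(frozen=True)
class TrainConfig:
    """Training protocol: Adam, learning rate 1e-4, batch size 1, 100
    epochs, categorical cross-entropy (6-class model) or multi-label Dice
    (MSU/BU variants), no shuffling within epochs, seed 42, 5 folds."""

    optimizer: str = "adam"
    learning_rate: float = 1e-4
    batch_size: int = 1
    epochs: int = 100
    loss_name: str = "categorical_crossentropy"
    test_fraction: float = 0.2
    seed: int = 42
    shuffle_within_epoch: bool = False
    folds: int = 5

    def __post_init__(self):
        if self.epochs <= 0 or self.batch_size <= 0:
            raise ValueError("epochs and batch_size must be positive")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass(frozen=True)
class PatchConfig:
    """Patch protocol: 48x48 patches, overlap-averaged prediction at
    stride 5, 9500 random patches per image with a 90/10 train/validation
    split, sampling permitted outside the field of view."""

    patch_size: int = 48
    stride: int = 5
    patches_per_image: int = 9500
    val_fraction: float = 0.10
    include_outside_fov: bool = True

    def __post_init__(self):
        if self.patch_size <= 0:
            raise ValueError("patch_size must be positive")
        if self.stride > self.patch_size:
            raise ValueError("stride greater than patch_size leaves gaps")


def train(model, images, masks, cfg: TrainConfig | None = None,
          validation=None):
    """Train an existing network handle per the protocol; returns
    ``(history, model)``."""
    cfg = cfg or TrainConfig()
    history = fit_loop(
        model, images, masks, loss_name=cfg.loss_name, epochs=cfg.epochs,
        learning_rate=cfg.learning_rate, seed=cfg.seed,
        validation=validation, shuffle_within_epoch=cfg.shuffle_within_epoch,
    )
    return history, model


def kfold_cv(model_builder, images, masks, cfg: TrainConfig | None = None):
    """Seeded k-fold cross-validation.

    ``model_builder()`` must return a fresh network handle.  Each sample
    is validated exactly once; returns a list of per-fold
    :class:`MetricsReport` (histories in ``extras``).
    """
    cfg = cfg or TrainConfig()
    images = _as_float_batch(images)
    masks = np.asarray(masks)
    n = len(images)
    if n < cfg.folds:
        raise ValueError(f"{n} samples cannot fill {cfg.folds} folds")
    kf = KFold(n_splits=cfg.folds, shuffle=True, random_state=cfg.seed)
    reports = []
    for fold, (tr, va) in enumerate(kf.split(np.arange(n))):
        model = model_builder()
        history, model = train(model, images[tr], masks[tr], cfg,
                               validation=(images[va], masks[va]))
        report = evaluate(model, images[va], masks[va], cfg)
        report.extras["fold"] = fold
        report.extras["history"] = history
        report.extras["val_indices"] = va.tolist()
        reports.append(report)
    return reports


def extract_patches(image, mask, cfg: PatchConfig | None = None, seed=42):
    """Random patches at uniform valid offsets; deterministic per seed.

    Returns a list of ``(patch, patch_mask, (row, col))`` triples.
    """
    cfg = cfg or PatchConfig()
    image = np.asarray(image)
    mask = np.asarray(mask) if mask is not None else None
    h, w = image.shape[:2]
    ps = cfg.patch_size
    if h < ps or w < ps:
        raise ValueError(f"image {h}x{w} is smaller than the patch size {ps}")
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, h - ps + 1, size=cfg.patches_per_image)
    cols = rng.integers(0, w - ps + 1, size=cfg.patches_per_image)
    out = []
    for r, c in zip(rows, cols):
        patch = image[r : r + ps, c : c + ps]
        patch_mask = mask[r : r + ps, c : c + ps] if mask is not None else None
        out.append((patch, patch_mask, (int(r), int(c))))
    return out


def _window_offsets(extent, patch, stride):
    offs = list(range(0, extent - patch + 1, stride))
    if offs[-1] != extent - patch:  # clamp the final window to the border
        offs.append(extent - patch)
    return offs


def cover_count_map(shape, cfg: PatchConfig) -> np.ndarray:
    """How many sliding windows cover each pixel."""
    h, w = shape
    counts = np.zeros((h, w), dtype=np.int64)
    for r in _window_offsets(h, cfg.patch_size, cfg.stride):
        for c in _window_offsets(w, cfg.patch_size, cfg.stride):
            counts[r : r + cfg.patch_size, c : c + cfg.patch_size] += 1
    return counts


def predict_overlap_average(model, image, cfg: PatchConfig | None = None):
    """Slide patch windows at the configured stride, average per-pixel
    class probabilities over every covering window."""
    cfg = cfg or PatchConfig()
    image = _as_float_batch(image)[0]
    h, w = image.shape[:2]
    ps = cfg.patch_size
    if h < ps or w < ps:
        raise ValueError("image is smaller than the patch size")
    acc = None
    counts = np.zeros((h, w), dtype=np.int64)
    for r in _window_offsets(h, ps, cfg.stride):
        for c in _window_offsets(w, ps, cfg.stride):
            prob = model.predict_proba(image[None, r : r + ps, c : c + ps])[0]
            if acc is None:
                acc = np.zeros((h, w, prob.shape[-1]), dtype=np.float64)
            acc[r : r + ps, c : c + ps] += prob
            counts[r : r + ps, c : c + ps] += 1
    return acc / counts[..., None]


def fov_mask(image, threshold_cfg: ThresholdParams | None = None,
             channel: int = 0) -> np.ndarray:
    """Field-of-view by color thresholding: threshold the chosen channel
    (red by default) at mean + k*sigma and keep the largest connected
    component."""
    threshold_cfg = threshold_cfg or ThresholdParams(k=0.0)
    image = np.asarray(image)
    chan = image[..., channel].astype(float) if image.ndim == 3 else image
    binary = contour_threshold(chan, threshold_cfg)
    if binary.sum() == 0:
        return binary
    labels, n = ndimage.label(binary)
    if n > 1:
        sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
        binary = (labels == (1 + int(sizes.argmax()))).astype(np.uint8)
    return binary


def prob_to_mask(prob, mode="argmax", threshold=0.5):
    """Argmax label mask (ties to the lowest class id) or per-class binary
    stack (multi-label)."""
    prob = np.asarray(prob)
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    if mode == "argmax":
        return prob.argmax(axis=-1)
    if mode == "threshold":
        return (prob >= threshold).astype(np.uint8)
    raise ValueError("mode must be 'argmax' or 'threshold'")


def evaluate(model, images, masks, cfg: TrainConfig | None = None
             ) -> MetricsReport:
    """Aggregate segmentation metrics of a trained model over a set.

    Reports pixel accuracy, micro-averaged IoU, Dice, macro mIoU and the
    training-objective value on the evaluation set.
    """
    cfg = cfg or TrainConfig()
    images = _as_float_batch(images)
    masks = np.asarray(masks)
    if len(images) == 0:
        raise ValueError("empty evaluation set")
    from .losses_metrics import DiceLossConfig, multilabel_dice_loss

    accs, ious, dices, mious, losses = [], [], [], [], []
    for xi, yi in zip(images, masks):
        prob = model.predict_proba(xi[None])[0]
        k = prob.shape[-1]
        if cfg.loss_name == "categorical_crossentropy":
            pred = prob.argmax(axis=-1)
            eps = np.finfo(np.float64).tiny
            onehot = np.eye(k)[yi]
            losses.append(float(-(onehot * np.log(prob + eps)).sum() / yi.size))
            accs.append(pixel_accuracy(pred, yi))
            ious.append(iou(pred, yi))
            dices.append(np.mean([dice_coefficient(pred, yi, class_id=c)
                                  for c in range(k)]))
            mious.append(mean_iou(pred, yi, k))
        else:
            pred = (prob >= 0.5).astype(np.uint8)
            dcfg = DiceLossConfig(n_classes=k,
                                  class_weights=tuple(np.full(k, 1.0 / k)))
            losses.append(multilabel_dice_loss(
                prob.reshape(-1, k).clip(0, 1), yi.reshape(-1, k), dcfg))
            accs.append(pixel_accuracy(pred, yi))
            per_iou = [iou(pred[..., c], yi[..., c]) for c in range(k)]
            ious.append(float(np.mean(per_iou)))
            dices.append(np.mean([dice_coefficient(pred[..., c], yi[..., c])
                                  for c in range(k)]))
            mious.append(float(np.mean(per_iou)))
    return MetricsReport(
        pixel_accuracy=float(np.mean(accs)),
        iou=float(np.mean(ious)),
        dice=float(np.mean(dices)),
        mean_iou=float(np.mean(mious)),
        model_loss=float(np.mean(losses)),
    )


def _largest_component_filled(binary: np.ndarray) -> np.ndarray:
    if binary.sum() == 0:
        return binary.astype(np.uint8)
    labels, n = ndimage.label(binary)
    if n > 1:
        sizes = ndimage.sum_labels(binary, labels, index=np.arange(1, n + 1))
        binary = labels == (1 + int(sizes.argmax()))
    return ndimage.binary_fill_holes(binary).astype(np.uint8)


def segment_disc_cup(image, model, center=None, grid: PolarGrid | None = None,
                     threshold=0.5, cleanup=True):
    """Disc and cup masks via the polar pipeline.

    ROI -> polar transform about the disc center -> multi-label model
    prediction (K = 2) -> inverse polar transform -> per-class 0.5
    threshold -> largest-component + hole-fill cleanup, with the cup
    clipped to the disc.  Returns ``(disc_mask, cup_mask, prob_maps)``.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    if center is None:
        center = estimate_disc_center(image)
    if grid is None:
        r_max = 0.45 * min(h, w)
        size = getattr(model, "input_size", None) or (
            getattr(model, "model_", None) and model.model_.input_size)
        bins, radial = (size[0], size[1]) if size else (400, 400)
        grid = PolarGrid(center=center, radius=r_max, angular_bins=bins,
                         radial_samples=radial)
    x = _as_float_batch(image)[0]
    polar_img = to_polar(x, grid, order=1)
    prob_polar = model.predict_proba(polar_img.data[None])[0]
    prob_maps = np.stack(
        [
            from_polar(
                type(polar_img)(data=prob_polar[..., c], grid=grid),
                (h, w), order=1, fill=0.0,
            )
            for c in range(prob_polar.shape[-1])
        ],
        axis=-1,
    ).clip(0.0, 1.0)
    disc = (prob_maps[..., 0] >= threshold).astype(np.uint8)
    cup = (prob_maps[..., 1] >= threshold).astype(np.uint8)
    if cleanup:
        disc = _largest_component_filled(disc)
        cup = _largest_component_filled(cup)
    cup = (cup & disc).astype(np.uint8)  # the cup cannot exceed the disc
    return disc, cup, prob_maps
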