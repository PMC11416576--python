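"""Preprocessing and ground-truth composition for fundus segmentation.

Covers the standardisation chain applied before training — mean-plus-k-sigma
contour thresholding, polygon filling, alpha compositing, RGBA flattening,
resizing, min-max normalisation — plus the composition of per-structure
binary masks into a single 6-class label raster and the seeded train/test
split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize
from sklearn.model_selection import train_test_split

from .io_rle import ALPHA_ZONE, BETA_ZONE, CUP, DISC, VESSELS

__all__ = [
    "ThresholdParams",
    "ResizeSpec",
    "SplitConfig",
    "contour_threshold",
    "fill_polygon",
    "alpha_composite",
    "rgba_to_rgb",
    "resize",
    "minmax_normalize",
    "compose_ground_truth",
    "split_dataset",
]


@dataclass(frozen=True)
class ThresholdParams:
    """Mean + k * sigma threshold; k typically between 1 and 3."""

    k: float = 2.0

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("k must be non-negative")


@dataclass(frozen=True)
class ResizeSpec:
    """Target size plus interpolation order (0 nearest, 1 linear, 3 cubic),
    border mode and extrapolation fill value."""

    target_size: tuple
    order: int = 1
    mode: str = "edge"
    extrapolated_value: float = 0.0

    def __post_init__(self):
        h, w = self.target_size
        if h <= 0 or w <= 0:
            raise ValueError("target_size must be positive")
        if self.order not in (0, 1, 3):
            raise ValueError("order must be one of 0, 1, 3")


@dataclass(frozen=True)
class SplitConfig:
    test_fraction: float = 0.2
    seed: int = 42

    def __post_init__(self):
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must be in (0, 1)")


def contour_threshold(image: np.ndarray, params: ThresholdParams) -> np.ndarray:
    """Binary mask of pixels strictly above mean + k * population std."""
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise ValueError("cannot threshold an empty raster")
    if image.ndim != 2:
        raise ValueError("contour_threshold expects a 2-D grayscale raster")
    threshold = image.mean() + params.k * image.std()
    return (image > threshold).astype(np.uint8)


def fill_polygon(vertices, shape) -> np.ndarray:
    """Rasterise a polygon: pixels whose centers fall inside (even-odd rule)
    become foreground.

    ``vertices`` are (x, y) points with x = column, y = row; pixel (r, c)
    has its center at (x, y) = (c, r).
    """
    vertices = np.asarray(vertices, dtype=float)
    if vertices.ndim != 2 or vertices.shape[0] < 3 or vertices.shape[1] != 2:
        raise ValueError("a polygon needs at least 3 (x, y) vertices")
    h, w = shape
    ys, xs = np.mgrid[0:h, 0:w]
    px = xs.ravel().astype(float)
    py = ys.ravel().astype(float)
    inside = np.zeros(px.size, dtype=bool)
    # even-odd ray casting: count edge crossings of a ray to the right
    x1 = vertices[:, 0]
    y1 = vertices[:, 1]
    x2 = np.roll(x1, -1)
    y2 = np.roll(y1, -1)
    for ex1, ey1, ex2, ey2 in zip(x1, y1, x2, y2):
        if ey1 == ey2:
            continue  # horizontal edge never crosses a horizontal ray
        cond = (ey1 > py) != (ey2 > py)
        xcross = ex1 + (py - ey1) * (ex2 - ex1) / (ey2 - ey1)
        inside ^= cond & (px < xcross)
    return inside.reshape(h, w).astype(np.uint8)


def alpha_composite(source, destination, alpha) -> np.ndarray:
    """Convex combination source * alpha + destination * (1 - alpha).

    ``alpha`` may be a scalar or a per-pixel map; it must lie in [0, 1].
    """
    source = np.asarray(source, dtype=float)
    destination = np.asarray(destination, dtype=float)
    alpha = np.asarray(alpha, dtype=float)
    if source.shape != destination.shape:
        raise ValueError("source and destination must share a shape")
    if alpha.min() < 0 or alpha.max() > 1:
        raise ValueError("alpha must lie in [0, 1]")
    if alpha.ndim == source.ndim - 1:  # per-pixel alpha for a color raster
        alpha = alpha[..., None]
    return source * alpha + destination * (1.0 - alpha)


def rgba_to_rgb(image: np.ndarray, background=(0, 0, 0)) -> np.ndarray:
    """Flatten an RGBA raster onto a background color:
    RGB = (1 - a) * background + a * color, with a normalised to [0, 1]."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 4:
        raise ValueError("rgba_to_rgb expects an HxWx4 raster")
    color = image[..., :3].astype(float)
    a = image[..., 3].astype(float)
    if np.issubdtype(image.dtype, np.integer):
        a = a / 255.0
    if a.max() > 1.0:
        a = a / 255.0
    bg = np.asarray(background, dtype=float)
    out = (1.0 - a[..., None]) * bg + a[..., None] * color
    if np.issubdtype(image.dtype, np.integer):
        return np.clip(np.rint(out), 0, 255).astype(image.dtype)
    return out


def resize(image: np.ndarray, spec: ResizeSpec) -> np.ndarray:
    """Resample a raster to ``spec.target_size``.

    Integer-typed rasters (label masks) must use order=0 so class ids are
    preserved; resizing one with a higher order raises.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("cannot resize an empty raster")
    if np.issubdtype(image.dtype, np.integer) and spec.order > 0:
        raise TypeError(
            "integer raster (label mask?) resized with order > 0 would "
            "invent class ids; use order=0 or cast to float first"
        )
    target = tuple(spec.target_size) + image.shape[2:]
    out = _sk_resize(
        image,
        target,
        order=spec.order,
        mode=spec.mode,
        cval=spec.extrapolated_value,
        preserve_range=True,
        anti_aliasing=False,
    )
    if np.issubdtype(image.dtype, np.integer):
        return out.astype(image.dtype)
    return out


def minmax_normalize(images) -> np.ndarray:
    """Per-raster min-max scaling to [0, 1]; a constant raster maps to zeros."""
    batch = np.asarray(images, dtype=float)
    if batch.size == 0:
        raise ValueError("empty batch")
    single = batch.ndim <= 2 or (batch.ndim == 3 and batch.shape[-1] in (3, 4))
    rasters = batch[None] if single else batch
    out = np.empty_like(rasters, dtype=float)
    for i, raster in enumerate(rasters):
        lo, hi = raster.min(), raster.max()
        out[i] = 0.0 if hi == lo else (raster - lo) / (hi - lo)
    return out[0] if single else out


def compose_ground_truth(disc, cup, vessels, beta, alpha_z) -> np.ndarray:
    """Merge per-structure binary masks into one 6-class label mask.

    Precedence (highest first): cup > vessels > disc > beta > alpha zone >
    background — the cup sits inside the disc, vessels cross the disc, the
    beta zone hugs the disc boundary and the alpha zone lies outside beta.
    """
    masks = [np.asarray(m).astype(bool) for m in (disc, cup, vessels, beta, alpha_z)]
    shape = masks[0].shape
    if any(m.shape != shape for m in masks):
        raise ValueError("all structure masks must share a shape")
    disc_b, cup_b, vessels_b, beta_b, alpha_b = masks
    out = np.zeros(shape, dtype=np.int64)
    # paint lowest precedence first; later classes overwrite
    out[alpha_b] = ALPHA_ZONE
    out[beta_b] = BETA_ZONE
    out[disc_b] = DISC
    out[vessels_b] = VESSELS
    out[cup_b] = CUP
    return out


def split_dataset(n_items: int, cfg: SplitConfig | None = None):
    """Seeded shuffled train/test split of ``range(n_items)``;
    |test| = round(n * test_fraction)."""
    cfg = cfg or SplitConfig()
    if n_items < 2:
        raise ValueError("need at least 2 items to split")
    n_test = int(round(n_items * cfg.test_fraction))
    n_test = min(max(n_test, 1), n_items - 1)
    train_idx, test_idx = train_test_split(
        np.arange(n_items), test_size=n_test, random_state=cfg.seed, shuffle=True
    )
    return np.sort(train_idx), np.sort(test_idx)
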