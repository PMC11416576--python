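"""Disc-centered polar transformation of fundus images and its inverse.

Resampling an image about the optic-disc center into (angle, radius)
coordinates turns the nested disc/cup geometry into a layered structure,
enlarges the cup through interpolation (balancing the cup-to-background
imbalance), and makes rotations of the image equivalent to cyclic shifts
of the polar rows — a cheap form of data augmentation.

Conventions: image coordinates are (u, v) = (column, row), 0-based, with
pixel-center sampling.  The angle is measured from the +x axis, counter-
clockwise in (x, y), with a default -90 degree rotation applied before
binning.  The circle is divided into 400 angular bins by default.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from .preprocess import ThresholdParams, contour_threshold

__all__ = [
    "PolarGrid",
    "PolarImage",
    "polar_to_cart",
    "cart_to_polar",
    "to_polar",
    "from_polar",
    "estimate_disc_center",
]


@dataclass(frozen=True)
class PolarGrid:
    """Sampling grid: disc center (u0, v0), maximal radius, angular bins,
    radial samples, and the rotation applied to the angular origin."""

    center: tuple
    radius: float
    angular_bins: int = 400
    radial_samples: int = 400
    rotation_deg: float = -90.0

    def __post_init__(self):
        if self.angular_bins < 4:
            raise ValueError("angular_bins must be >= 4")
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if self.radial_samples < 2:
            raise ValueError("radial_samples must be >= 2")


@dataclass(frozen=True)
class PolarImage:
    """Polar raster (angular_bins x radial_samples [x C]) plus the grid
    needed to invert the transformation."""

    data: np.ndarray
    grid: PolarGrid

    def __post_init__(self):
        if self.grid is None:
            raise ValueError("PolarImage requires its sampling grid")
        b, s = self.data.shape[:2]
        if (b, s) != (self.grid.angular_bins, self.grid.radial_samples):
            raise ValueError("polar data shape does not match its grid")


def polar_to_cart(r, theta):
    """x = r cos(theta), y = r sin(theta)."""
    return r * np.cos(theta), r * np.sin(theta)


def cart_to_polar(x, y):
    """r = sqrt(x^2 + y^2), theta = arctan2(y, x) in (-pi, pi]."""
    return np.hypot(x, y), np.arctan2(y, x)


def _sample_channels(image, rows, cols, order, cval):
    coords = np.stack([rows, cols])
    if image.ndim == 2:
        return ndimage.map_coordinates(
            image.astype(float), coords, order=order, mode="constant", cval=cval
        )
    out = [
        ndimage.map_coordinates(
            image[..., c].astype(float), coords, order=order, mode="constant",
            cval=cval,
        )
        for c in range(image.shape[-1])
    ]
    return np.stack(out, axis=-1)


def to_polar(image: np.ndarray, grid: PolarGrid, order: int = 1,
             cval: float = 0.0) -> PolarImage:
    """Resample an image onto the polar grid.

    Row b, column s sample the source at angle
    ``rotation + 2*pi*b/angular_bins`` and radius
    ``radius * s/(radial_samples-1)`` relative to the grid center.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    u0, v0 = grid.center
    if not (0 <= u0 <= w - 1 and 0 <= v0 <= h - 1):
        raise ValueError(f"grid center {grid.center} lies outside the image")
    rot = math.radians(grid.rotation_deg)
    theta = rot + 2.0 * np.pi * np.arange(grid.angular_bins) / grid.angular_bins
    r = grid.radius * np.arange(grid.radial_samples) / (grid.radial_samples - 1)
    tt, rr = np.meshgrid(theta, r, indexing="ij")
    x, y = polar_to_cart(rr, tt)
    data = _sample_channels(image, v0 + y, u0 + x, order, cval)
    if np.issubdtype(image.dtype, np.integer) and order == 0:
        data = np.rint(data).astype(image.dtype)
    return PolarImage(data=data, grid=grid)


def from_polar(polar: PolarImage, out_shape, order: int = 1,
               fill=0.0) -> np.ndarray:
    """Inverse resampling onto Cartesian pixels.

    Pixels farther than the grid radius from the center keep ``fill``
    (scalar, or an image to leave unchanged outside the sampled disk).
    """
    grid = polar.grid
    h, w = out_shape[:2]
    u0, v0 = grid.center
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    r, theta = cart_to_polar(xs - u0, ys - v0)
    rot = math.radians(grid.rotation_deg)
    two_pi = 2.0 * np.pi
    bin_f = ((theta - rot) % two_pi) / two_pi * grid.angular_bins
    s_f = r / grid.radius * (grid.radial_samples - 1)
    # pad the angular axis cyclically so interpolation wraps at 0/2pi
    pad = max(order, 1)
    data = polar.data
    padded = np.concatenate([data, data[:pad]], axis=0)
    sampled = _sample_channels(padded, bin_f, s_f, order, 0.0)
    inside = r <= grid.radius
    if np.isscalar(fill):
        out_chan = sampled.shape[2:] if sampled.ndim == 3 else ()
        out = np.full((h, w) + out_chan, float(fill))
    else:
        out = np.asarray(fill, dtype=float).copy()
    out[inside] = sampled[inside]
    if np.issubdtype(polar.data.dtype, np.integer) and order == 0:
        return np.rint(out).astype(polar.data.dtype)
    return out


def estimate_disc_center(image: np.ndarray, k: float = 2.0) -> tuple:
    """Fallback disc-center detector: centroid of the brightest pixels.

    Thresholds the intensity at mean + k*sigma and returns the centroid
    (u, v) of the surviving pixels; the disc is the brightest large
    structure in a fundus photograph.  Falls back to the image center if
    nothing survives the threshold.
    """
    image = np.asarray(image, dtype=float)
    gray = image.mean(axis=-1) if image.ndim == 3 else image
    mask = contour_threshold(gray, ThresholdParams(k=k))
    if mask.sum() == 0:
        return ((gray.shape[1] - 1) / 2.0, (gray.shape[0] - 1) / 2.0)
    vs, us = np.nonzero(mask)
    return (float(us.mean()), float(vs.mean()))


def rotate_grid(grid: PolarGrid, delta_deg: float) -> PolarGrid:
    """Grid with the angular origin rotated by ``delta_deg``."""
    return replace(grid, rotation_deg=grid.rotation_deg + delta_deg)
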