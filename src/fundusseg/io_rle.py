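"""Image and mask IO, run-length mask codec, and the class/color legend.

Six classes are used throughout: 0 background, 1 optic disc, 2 optic cup,
3 blood vessels, 4 PPA beta zone, 5 PPA alpha zone.  The default color
legend follows the standard named web colors: the alpha zone is yellow,
the beta zone yellow-green, the cup medium sea green, the disc dark blue
and the vessels dark cyan.

Run-length masks use the simplest exactly-invertible dialect: row-major,
0-based start indices, maximal runs, stored as a plain-text sidecar with
an ``H W`` header followed by ``start length class`` lines.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
from PIL import Image

__all__ = [
    "BACKGROUND",
    "DISC",
    "CUP",
    "VESSELS",
    "BETA_ZONE",
    "ALPHA_ZONE",
    "ClassLegend",
    "DEFAULT_LEGEND",
    "RLEMask",
    "read_image",
    "read_mask",
    "write_image",
    "rle_encode",
    "rle_decode",
    "read_rle",
    "write_rle",
    "labels_to_color",
    "color_to_labels",
]

BACKGROUND, DISC, CUP, VESSELS, BETA_ZONE, ALPHA_ZONE = range(6)


class UnmappedPixelError(ValueError):
    """A pixel's color is farther than the tolerance from every legend color."""

    def __init__(self, count, first_location, msg=None):
        self.count = count
        self.first_location = first_location
        super().__init__(
            msg
            or f"{count} pixel(s) match no legend color; first at {first_location}"
        )


@dataclass(frozen=True)
class ClassLegend:
    """Ordered (class_id, class_name, RGB color) entries for classes 0-5."""

    entries: tuple

    def __post_init__(self):
        ids = [e[0] for e in self.entries]
        if sorted(ids) != list(range(len(ids))):
            raise ValueError("class ids must be exactly 0..K-1")
        if ids[0] != 0 or self.entries[0][1] != "background":
            raise ValueError("class 0 must be the background")
        colors = [tuple(e[2]) for e in self.entries]
        if len(set(colors)) != len(colors):
            raise ValueError("legend colors must be pairwise distinct")

    @property
    def n_classes(self) -> int:
        return len(self.entries)

    def colors(self) -> np.ndarray:
        return np.array([e[2] for e in self.entries], dtype=np.int64)

    def color_of(self, class_id: int) -> tuple:
        return tuple(self.entries[class_id][2])

    def name_of(self, class_id: int) -> str:
        return self.entries[class_id][1]


DEFAULT_LEGEND = ClassLegend(
    entries=(
        (BACKGROUND, "background", (0, 0, 0)),
        (DISC, "optic disc", (0, 0, 139)),        # dark blue
        (CUP, "optic cup", (60, 179, 113)),       # medium sea green
        (VESSELS, "blood vessels", (0, 139, 139)),  # dark cyan
        (BETA_ZONE, "PPA beta zone", (154, 205, 50)),  # yellow green
        (ALPHA_ZONE, "PPA alpha zone", (255, 255, 0)),  # yellow
    )
)


@dataclass(frozen=True)
class RLEMask:
    """Run-length encoded label mask: ``runs`` are (start, length, class_id)
    triples in row-major order that tile the mask exactly."""

    shape: tuple
    runs: tuple


# -- raster IO ------------------------------------------------------------

def read_image(path) -> np.ndarray:
    """Read a PNG/TIFF/JPEG image as an HxWx3 (or HxWx4) uint8 array."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    try:
        with Image.open(path) as im:
            arr = np.asarray(im)
    except Exception as exc:  # unreadable or unsupported container
        raise ValueError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 2:  # promote grayscale photographs to 3 channels
        arr = np.stack([arr] * 3, axis=-1)
    return arr


def read_mask(path) -> np.ndarray:
    """Read a single-channel label mask PNG as a 2-D integer array."""
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.ndim != 2:
        raise ValueError(f"mask file {path} is not single-channel")
    return arr.astype(np.int64)


def write_image(image: np.ndarray, path) -> None:
    """Write a raster losslessly (PNG/TIFF for masks and uint8 images).

    2-D integer arrays are written as single-channel masks; HxWx3/4 uint8
    arrays as color images.  Float rasters are rejected: scale them to
    integers explicitly first.
    """
    image = np.asarray(image)
    if image.ndim not in (2, 3):
        raise ValueError("image must be 2-D (mask) or 3-D (color)")
    if image.ndim == 3 and image.shape[-1] not in (3, 4):
        raise ValueError("color images need 3 or 4 channels")
    if not np.issubdtype(image.dtype, np.integer) and image.dtype != np.uint8:
        raise TypeError(
            "refusing to write a float raster to a lossless container; "
            "scale and cast to an integer dtype first"
        )
    ext = os.path.splitext(str(path))[1].lower()
    if image.ndim == 2 and ext in {".jpg", ".jpeg"}:
        raise TypeError("masks must use a lossless container (PNG/TIFF)")
    Image.fromarray(image.astype(np.uint8)).save(path)


# -- run-length codec -----------------------------------------------------

def rle_encode(mask: np.ndarray) -> RLEMask:
    """Encode a 2-D integer mask as maximal row-major runs."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not np.issubdtype(mask.dtype, np.integer):
        raise TypeError("mask must be integer-typed")
    flat = mask.ravel(order="C")
    if flat.size == 0:
        return RLEMask(shape=mask.shape, runs=())
    boundaries = np.flatnonzero(np.diff(flat)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [flat.size]))
    runs = tuple(
        (int(s), int(e - s), int(flat[s])) for s, e in zip(starts, ends)
    )
    return RLEMask(shape=tuple(mask.shape), runs=runs)


def rle_decode(rle: RLEMask, shape=None) -> np.ndarray:
    """Decode runs back to a 2-D mask; runs must tile the raster exactly."""
    shape = tuple(shape) if shape is not None else tuple(rle.shape)
    n = shape[0] * shape[1]
    flat = np.full(n, -1, dtype=np.int64)
    cursor = 0
    for start, length, class_id in sorted(rle.runs, key=lambda r: r[0]):
        if length <= 0:
            raise ValueError(f"non-positive run length at start {start}")
        if start != cursor:
            kind = "overlap" if start < cursor else "gap"
            raise ValueError(f"runs have a {kind} at index {start}")
        if start + length > n:
            raise ValueError("runs exceed the raster size")
        flat[start : start + length] = class_id
        cursor = start + length
    if cursor != n:
        raise ValueError(f"runs leave a gap: covered {cursor} of {n} pixels")
    return flat.reshape(shape)


def write_rle(rle: RLEMask, path) -> None:
    """Write the sidecar text format: 'H W' header then 'start length class'."""
    with open(path, "w") as fh:
        fh.write(f"{rle.shape[0]} {rle.shape[1]}\n")
        for start, length, class_id in rle.runs:
            fh.write(f"{start} {length} {class_id}\n")


def read_rle(path) -> RLEMask:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    h, w = (int(t) for t in lines[0].split())
    runs = tuple(tuple(int(t) for t in ln.split()) for ln in lines[1:])
    return RLEMask(shape=(h, w), runs=runs)


# -- legend codec ---------------------------------------------------------

def labels_to_color(mask: np.ndarray, legend: ClassLegend = DEFAULT_LEGEND) -> np.ndarray:
    """Render a label mask as an HxWx3 uint8 image using the legend colors."""
    mask = np.asarray(mask)
    if mask.ndim != 2:
        raise ValueError("mask must be 2-D")
    if mask.min(initial=0) < 0 or mask.max(initial=0) >= legend.n_classes:
        bad = int(mask.max())
        raise KeyError(f"mask contains class id {bad} not present in legend")
    colors = legend.colors().astype(np.uint8)
    return colors[mask]


def color_to_labels(image: np.ndarray, legend: ClassLegend = DEFAULT_LEGEND,
                    tolerance: int = 0) -> np.ndarray:
    """Map a legend-colored image back to class ids.

    Each pixel is assigned the nearest legend color (Euclidean distance in
    RGB); a pixel farther than ``tolerance`` from every legend color raises
    :class:`UnmappedPixelError` reporting the count and first location.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError("image must be HxWx3")
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    colors = legend.colors()  # (K, 3)
    diff = image[..., None, :].astype(np.int64) - colors  # (H, W, K, 3)
    dist2 = (diff ** 2).sum(axis=-1)
    labels = dist2.argmin(axis=-1)
    min_dist2 = np.take_along_axis(dist2, labels[..., None], axis=-1)[..., 0]
    bad = min_dist2 > tolerance ** 2
    if bad.any():
        count = int(bad.sum())
        first = tuple(int(i) for i in np.argwhere(bad)[0])
        raise UnmappedPixelError(count, first)
    return labels.astype(np.int64)
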