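"""Seeded synthetic fundus phantoms with 6-class ground truth.

The generator emulates the anatomical structure the segmentation method
assumes — a bright elliptical optic disc containing a brighter optic cup,
dark branching vessels emanating from the disc, a pale peripapillary-
atrophy beta annulus hugging the disc boundary with a paler alpha annulus
outside it, all on a dark-red textured background with radial
illumination falloff and Gaussian pixel noise.  It is a structural test
fixture, not a simulator of pathology or camera optics: geometry is
parametric (ellipses and random-walk vessel trees) and appearance is a
flat per-class palette with mild texture and blur.

Everything is driven by ``numpy.random.default_rng`` so a fixed
(config, seed) pair yields byte-identical images and masks across runs
and platforms.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from . import io_rle
from .preprocess import compose_ground_truth

__all__ = ["PhantomConfig", "PhantomSample", "generate_phantom",
           "generate_dataset", "degrade"]


@dataclass(frozen=True)
class PhantomConfig:
    """Geometry and appearance ranges for one phantom.

    Defaults describe a 512x512 fundus-like scene: disc radius 12-16 % of
    the short side, cup-to-disc ratio 0.2-0.7, 2-6 vessels, and beta/alpha
    annulus widths of roughly a quarter of the disc radius.  Pixel-valued
    fields scale with ``image_size`` so the same config generates
    consistent scenes at 64x64 or 512x512.
    """

    image_size: tuple = (512, 512)
    disc_radius_frac: tuple = (0.12, 0.16)   # of min(H, W)
    cdr_range: tuple = (0.2, 0.7)
    vessel_count_range: tuple = (2, 6)
    vessel_width_frac: tuple = (0.006, 0.012)
    beta_width_frac: tuple = (0.03, 0.045)
    alpha_width_frac: tuple = (0.025, 0.04)
    illumination_gradient: float = 0.35
    noise_sigma: float = 6.0                 # on the 0-255 intensity scale
    blur_sigma_frac: float = 0.002
    background_color: tuple = (110, 35, 25)
    palette: dict = field(default_factory=lambda: {
        io_rle.DISC: (225, 160, 90),
        io_rle.CUP: (250, 220, 140),
        io_rle.VESSELS: (70, 15, 15),
        io_rle.BETA_ZONE: (215, 185, 150),
        io_rle.ALPHA_ZONE: (160, 110, 75),
    })
    seed: int = 42

    def __post_init__(self):
        h, w = self.image_size
        if h < 32 or w < 32:
            raise ValueError("image_size must be at least 32x32")
        if not 0 < self.cdr_range[0] <= self.cdr_range[1] < 1:
            raise ValueError("cdr_range must lie inside (0, 1)")
        r_out = self.disc_radius_frac[1] * (1.15 + 0.1)  # ellipse + jitter slack
        total = r_out + self.beta_width_frac[1] + self.alpha_width_frac[1]
        if total >= 0.5:
            raise ValueError(
                "disc radius plus PPA annuli exceed the image half-size"
            )


@dataclass
class PhantomSample:
    image: np.ndarray        # HxWx3 uint8
    mask: np.ndarray         # HxW int labels 0-5
    meta: dict               # center, radii, CDR, seed


def _ellipse_mask(h, w, center, rx, ry, angle):
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    dx = xs - center[0]
    dy = ys - center[1]
    ca, sa = np.cos(angle), np.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _vessel_mask(rng, h, w, center, disc_r, n_vessels, width):
    """Random-walk vessel polylines growing outward from the disc center,
    each with one mid-course branch; rasterised by stamping disks."""
    mask = np.zeros((h, w), dtype=bool)
    length = int(0.9 * min(h, w))
    base_angles = rng.uniform(0, 2 * np.pi) + np.arange(n_vessels) * (
        2 * np.pi / max(n_vessels, 1)
    )
    rad = max(int(round(width / 2)), 1)
    stamp = np.zeros((2 * rad + 1, 2 * rad + 1), dtype=bool)
    sy, sx = np.mgrid[-rad : rad + 1, -rad : rad + 1]
    stamp[sy ** 2 + sx ** 2 <= rad ** 2] = True

    def walk(x, y, angle, steps, allow_branch):
        for step in range(steps):
            angle += rng.normal(0.0, 0.18)
            x += np.cos(angle) * 2.0
            y += np.sin(angle) * 2.0
            xi, yi = int(round(x)), int(round(y))
            if not (0 <= xi < w and 0 <= yi < h):
                return
            y0, y1 = max(yi - rad, 0), min(yi + rad + 1, h)
            x0, x1 = max(xi - rad, 0), min(xi + rad + 1, w)
            mask[y0:y1, x0:x1] |= stamp[
                y0 - (yi - rad) : y1 - (yi - rad),
                x0 - (xi - rad) : x1 - (xi - rad),
            ]
            if allow_branch and step == steps // 3:
                walk(x, y, angle + rng.choice((-1, 1)) * rng.uniform(0.4, 0.9),
                     steps // 2, False)

    for angle in base_angles:
        x0 = center[0] + np.cos(angle) * disc_r * 0.2
        y0 = center[1] + np.sin(angle) * disc_r * 0.2
        walk(x0, y0, angle + rng.normal(0, 0.2), length // 2, True)
    return mask


def generate_phantom(cfg: PhantomConfig | None = None,
                     seed: int | None = None) -> PhantomSample:
    """Deterministically generate one phantom image and its label mask."""
    cfg = cfg or PhantomConfig()
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    h, w = cfg.image_size
    s = min(h, w)

    disc_r = rng.uniform(*cfg.disc_radius_frac) * s
    cdr = rng.uniform(*cfg.cdr_range)
    cup_r = cdr * disc_r
    ecc = rng.uniform(0.85, 1.15)
    tilt = rng.uniform(0, np.pi)
    margin = disc_r * max(ecc, 1.0) + (cfg.beta_width_frac[1]
                                       + cfg.alpha_width_frac[1]) * s + 2
    cx = rng.uniform(margin, w - margin)
    cy = rng.uniform(margin, h - margin)

    disc = _ellipse_mask(h, w, (cx, cy), disc_r * ecc, disc_r / ecc, tilt)
    # cup center jitter bounded so the cup stays inside the disc
    slack = (disc_r * min(ecc, 1.0 / ecc)) - cup_r * max(ecc, 1.0 / ecc)
    jitter = rng.uniform(-0.3, 0.3, size=2) * max(slack, 0.0)
    cup = _ellipse_mask(h, w, (cx + jitter[0], cy + jitter[1]),
                        cup_r * ecc, cup_r / ecc, tilt)
    cup &= disc

    n_vessels = int(rng.integers(cfg.vessel_count_range[0],
                                 cfg.vessel_count_range[1] + 1))
    vessel_w = rng.uniform(*cfg.vessel_width_frac) * s
    vessels = (
        _vessel_mask(rng, h, w, (cx, cy), disc_r, n_vessels, max(vessel_w, 1.5))
        if n_vessels > 0
        else np.zeros((h, w), dtype=bool)
    )

    beta_w = rng.uniform(*cfg.beta_width_frac) * s
    alpha_w = rng.uniform(*cfg.alpha_width_frac) * s
    beta = np.zeros((h, w), dtype=bool)
    alpha = np.zeros((h, w), dtype=bool)
    if beta_w > 0:
        outer_b = _ellipse_mask(h, w, (cx, cy),
                                disc_r * ecc + beta_w, disc_r / ecc + beta_w,
                                tilt)
        beta = outer_b & ~disc
        if alpha_w > 0:
            outer_a = _ellipse_mask(
                h, w, (cx, cy),
                disc_r * ecc + beta_w + alpha_w,
                disc_r / ecc + beta_w + alpha_w, tilt,
            )
            alpha = outer_a & ~outer_b

    mask = compose_ground_truth(disc, cup, vessels, beta, alpha)

    # -- render ----------------------------------------------------------
    ys, xs = np.mgrid[0:h, 0:w].astype(float)
    r_norm = np.hypot(xs - w / 2, ys - h / 2) / (0.75 * s)
    shading = 1.0 - cfg.illumination_gradient * np.clip(r_norm, 0, 1) ** 2
    texture = ndimage.gaussian_filter(rng.normal(0, 1, (h, w)), 0.03 * s)
    tex_span = texture.max() - texture.min()
    if tex_span > 0:
        texture = (texture - texture.min()) / tex_span - 0.5

    colors = np.array(
        [cfg.background_color] + [cfg.palette[c] for c in range(1, 6)],
        dtype=float,
    )
    img = colors[mask]
    # shading and texture belong to the background tissue; the anatomical
    # structures keep their palette colors (noise and blur apply globally)
    bg = mask == 0
    modulation = shading * (1.0 + 0.15 * texture)
    img[bg] *= modulation[bg, None]
    blur = cfg.blur_sigma_frac * s
    if blur > 0:
        img = ndimage.gaussian_filter(img, (blur, blur, 0))
    img += rng.normal(0, cfg.noise_sigma, img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    meta = {
        "seed": int(seed),
        "center": (float(cx), float(cy)),
        "disc_radius": float(disc_r),
        "cup_radius": float(cup_r),
        "cdr": float(cdr),
        "n_vessels": n_vessels,
    }
    return PhantomSample(image=img, mask=mask, meta=meta)


def generate_dataset(n: int, cfg: PhantomConfig | None = None,
                     seed: int = 42, out_dir=None):
    """Generate ``n`` phantoms with per-sample seeds ``seed + i``.

    When ``out_dir`` is given, writes ``images/*.png``, ``masks/*.png``
    plus RLE sidecars, and a ``manifest.csv`` with the per-sample
    geometry.  Returns ``(samples, manifest_rows)``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = cfg or PhantomConfig()
    samples = [generate_phantom(cfg, seed + i) for i in range(n)]
    manifest = []
    for i, sample in enumerate(samples):
        row = {"index": i, **{k: sample.meta[k] for k in
                              ("seed", "disc_radius", "cup_radius", "cdr",
                               "n_vessels")}}
        row["center_x"], row["center_y"] = sample.meta["center"]
        manifest.append(row)
    if out_dir is not None:
        img_dir = os.path.join(out_dir, "images")
        mask_dir = os.path.join(out_dir, "masks")
        os.makedirs(img_dir, exist_ok=True)
        os.makedirs(mask_dir, exist_ok=True)
        for i, sample in enumerate(samples):
            io_rle.write_image(sample.image,
                               os.path.join(img_dir, f"phantom_{i:04d}.png"))
            io_rle.write_image(sample.mask.astype(np.uint8),
                               os.path.join(mask_dir, f"phantom_{i:04d}.png"))
            io_rle.write_rle(io_rle.rle_encode(sample.mask),
                             os.path.join(mask_dir, f"phantom_{i:04d}.rle"))
        with open(os.path.join(out_dir, "manifest.csv"), "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(manifest[0]))
            writer.writeheader()
            writer.writerows(manifest)
    return samples, manifest


def degrade(sample: PhantomSample, blur_sigma: float = 0.0,
            contrast_scale: float = 1.0) -> PhantomSample:
    """Blur and/or rescale contrast of the image; the mask is untouched."""
    if blur_sigma < 0:
        raise ValueError("blur_sigma must be non-negative")
    img = sample.image.astype(float)
    if blur_sigma > 0:
        img = ndimage.gaussian_filter(img, (blur_sigma, blur_sigma, 0))
    if contrast_scale != 1.0:
        mean = img.mean()
        img = mean + contrast_scale * (img - mean)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return PhantomSample(image=img, mask=sample.mask.copy(),
                         meta=dict(sample.meta))
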