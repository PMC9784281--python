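"""Synthetic contrast-enhanced brain phantoms, plus real-slice loading.

A phantom emulates an axial T1 post-contrast slice containing a single
enhancing tumor: an elliptical "brain" of moderate intensity with smooth
low-frequency texture and additive Gaussian noise, and one bright,
quasi-circular lesion placed uniformly over grid blocks (so localization
accuracy is not dominated by lesion-position imbalance).  The lesion mask
is exact — it marks precisely the pixels whose intensity was raised.

Real slices can be pulled from NIfTI volumes with :func:`load_mri_slice`.
Datasets round-trip through 16-bit PNGs plus a CSV manifest.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .env import GridSpec, LesionImage, build_grid, normalize_intensities

__all__ = [
    "PhantomConfig",
    "generate_phantom",
    "generate_dataset",
    "save_dataset",
    "load_dataset",
    "load_mri_slice",
]


@dataclass(frozen=True)
class PhantomConfig:
    """Parameters of the phantom generator.

    Lengths are in pixels; intensities are on the raw (pre-normalization)
    scale where the background tissue mean is ``background_mean``.
    ``None`` ranges are derived from ``image_size`` so that phantoms at
    reduced resolution keep the default geometry proportionally.
    """

    image_size: int = 240
    block_grid: int = 4
    ellipse_semiaxis_range: tuple[float, float] | None = None
    background_mean: float = 0.35
    texture_amplitude: float = 0.12
    noise_sigma: float = 0.05
    lesion_radius_range: tuple[float, float] | None = None
    lesion_contrast: float = 0.45
    boundary_irregularity: float = 0.15
    center_mode: str = "block"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size % self.block_grid != 0:
            raise ValueError("image_size must be divisible by block_grid")
        if self.lesion_contrast <= self.noise_sigma:
            raise ValueError(
                "lesion_contrast must exceed noise_sigma for a visible lesion"
            )
        if self.center_mode not in ("block", "pixel"):
            raise ValueError("center_mode must be 'block' or 'pixel'")

    @property
    def semiaxis_range(self) -> tuple[float, float]:
        if self.ellipse_semiaxis_range is not None:
            return self.ellipse_semiaxis_range
        return (0.46 * self.image_size, 0.495 * self.image_size)

    @property
    def radius_range(self) -> tuple[float, float]:
        if self.lesion_radius_range is not None:
            return self.lesion_radius_range
        scale = self.image_size / 240.0
        return (15.0 * scale, 40.0 * scale)

    @property
    def block_size(self) -> int:
        return self.image_size // self.block_grid


class PhantomConfigError(ValueError):
    """Raised when a phantom cannot be realized under the configuration."""


def _disk_fits(cx: float, cy: float, r: float, center: float,
               a: float, b: float) -> bool:
    # conservative: the bounding circle of the (irregular) lesion must lie
    # inside the ellipse
    dx = abs(cx - center) + r
    dy = abs(cy - center) + r
    return (dx / a) ** 2 + (dy / b) ** 2 <= 1.0


def _sample_center(rng: np.random.Generator, y_range: tuple[float, float],
                   x_range: tuple[float, float], r: float, center: float,
                   a: float, b: float) -> tuple[float, float] | None:
    """Draw a lesion center uniformly from the feasible part of a box.

    Feasible means the bounding circle of radius ``r`` fits inside the
    background ellipse.  For each candidate row the feasible column
    interval is computed in closed form; rows are then weighted by the
    length of that interval intersected with the box.  Returns None when
    the feasible region is empty.
    """
    n = 128
    ys = np.linspace(y_range[0], y_range[1], n, endpoint=False)
    step_y = (y_range[1] - y_range[0]) / n
    dy = np.abs(ys + step_y / 2 - center) + r
    half = np.full(n, -1.0)
    inside = dy < b
    half[inside] = a * np.sqrt(1.0 - (dy[inside] / b) ** 2) - r
    lo = np.maximum(center - half, x_range[0])
    hi = np.minimum(center + half, x_range[1])
    weights = np.where(half > 0, np.maximum(hi - lo, 0.0), 0.0)
    total = weights.sum()
    if total <= 0:
        return None
    i = int(rng.choice(n, p=weights / total))
    cy = ys[i] + rng.uniform(0, step_y)
    dyc = abs(cy - center) + r
    if dyc >= b:
        return None
    halfc = a * np.sqrt(1.0 - (dyc / b) ** 2) - r
    loc, hic = max(center - halfc, x_range[0]), min(center + halfc, x_range[1])
    if hic <= loc:
        return None
    return cy, rng.uniform(loc, hic)


def _lesion_mask(size: int, cy: float, cx: float, r: float,
                 irregularity: float, rng: np.random.Generator) -> np.ndarray:
    """Quasi-circular region: radius modulated by low-order harmonics."""
    coeffs = rng.normal(0.0, 1.0, size=(3, 2))
    yy, xx = np.mgrid[0:size, 0:size]
    dy = yy - cy
    dx = xx - cx
    dist = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    mod = np.zeros_like(theta)
    for k, (ac, bc) in zip((2, 3, 4), coeffs):
        mod += ac * np.cos(k * theta) + bc * np.sin(k * theta)
    mod *= irregularity / math.sqrt(3.0)
    boundary = r * np.clip(1.0 + mod, 0.5, 1.5)
    return dist <= boundary


def generate_phantom(config: PhantomConfig,
                     rng: np.random.Generator | None = None,
                     image_id: str = "phantom") -> LesionImage:
    """Draw one phantom image/mask pair.

    Raises :class:`PhantomConfigError` if no lesion satisfying the
    geometry (inside the brain ellipse, centered in the drawn block) can
    be placed.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    size = config.image_size
    center = (size - 1) / 2.0
    bsize = config.block_size
    r_lo, r_hi = config.radius_range

    # The lesion block is drawn exactly once so its marginal distribution
    # stays uniform over the grid; the ellipse axes, lesion center and
    # radius are rejection-sampled jointly until the lesion fits inside
    # the brain (corner blocks only admit lesions tucked into their inner
    # corner, so they need many more attempts than central blocks).
    if config.center_mode == "block":
        brow = int(rng.integers(config.block_grid))
        bcol = int(rng.integers(config.block_grid))
        y_range = (brow * bsize, (brow + 1) * bsize)
        x_range = (bcol * bsize, (bcol + 1) * bsize)
    else:
        y_range = x_range = (0.0, float(size))

    a = b = None
    mask = None
    for attempt in range(50):
        a = rng.uniform(*config.semiaxis_range)
        b = rng.uniform(*config.semiaxis_range)
        # shrink the radius toward its minimum as attempts accumulate so
        # tight corner blocks remain feasible
        hi = r_hi if attempt < 10 else r_lo
        radius = rng.uniform(r_lo, hi)
        placed = _sample_center(rng, y_range, x_range,
                                radius * (1.0 + config.boundary_irregularity),
                                center, a, b)
        if placed is not None:
            cy, cx = placed
            mask = _lesion_mask(size, cy, cx, radius,
                                config.boundary_irregularity, rng)
            if mask.any():
                break
            mask = None
    if mask is None:
        raise PhantomConfigError(
            f"could not place a lesion of radius >= {r_lo:.1f} px inside the "
            f"background ellipse (semi-axes in {config.semiaxis_range})"
        )

    yy, xx = np.mgrid[0:size, 0:size]
    ellipse = (((yy - center) / b) ** 2 + ((xx - center) / a) ** 2) <= 1.0

    raw = np.zeros((size, size), dtype=np.float64)
    texture = rng.normal(0.0, 1.0, size=(size, size))
    texture = ndimage.gaussian_filter(texture, sigma=size / 12.0)
    tstd = texture.std()
    if tstd > 0:
        texture *= config.texture_amplitude / (3.0 * tstd)
    raw[ellipse] = config.background_mean + texture[ellipse]

    raw[mask] += config.lesion_contrast
    raw += rng.normal(0.0, config.noise_sigma, size=(size, size))
    meta = {"lesion_center": (float(cy), float(cx)), "lesion_radius": float(radius)}
    if config.center_mode == "block":
        meta["lesion_block"] = (brow, bcol)
    return LesionImage(id=image_id,
                       intensities=normalize_intensities(raw),
                       lesion_mask=mask,
                       meta=meta)


def generate_dataset(n: int, config: PhantomConfig, seed: int) -> list[LesionImage]:
    """``n`` phantoms from independent streams spawned off ``seed``."""
    if n < 1:
        raise ValueError("n must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n)
    return [
        generate_phantom(config, np.random.default_rng(s),
                         image_id=f"phantom-{seed}-{i:04d}")
        for i, s in enumerate(streams)
    ]


# -- disk round-trip ----------------------------------------------------------

def save_dataset(images: list[LesionImage], outdir: str | Path,
                 block_size: int | None = None) -> Path:
    """Write 16-bit image PNGs, binary mask PNGs, and a CSV manifest."""
    import imageio.v3 as iio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for img in images:
        stem = img.id
        img_path = outdir / f"{stem}_image.png"
        mask_path = outdir / f"{stem}_mask.png"
        iio.imwrite(img_path, np.round(img.intensities * 65535).astype(np.uint16))
        iio.imwrite(mask_path, (img.lesion_mask * 255).astype(np.uint8))
        entry = {"id": stem, "image": img_path.name, "mask": mask_path.name}
        if block_size is not None:
            grid = build_grid(img, block_size)
            blocks = sorted(
                (r, c)
                for r in range(grid.n_rows)
                for c in range(grid.n_cols)
                if img.lesion_mask[grid.block_slices(r, c)].any()
            )
            entry["lesion_blocks"] = ";".join(f"{r},{c}" for r, c in blocks)
        rows.append(entry)
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def load_dataset(directory: str | Path) -> list[LesionImage]:
    """Read a dataset written by :func:`save_dataset`."""
    import imageio.v3 as iio

    directory = Path(directory)
    manifest = pd.read_csv(directory / "manifest.csv")
    images = []
    for row in manifest.itertuples():
        raster = iio.imread(directory / row.image).astype(np.float32) / 65535.0
        mask = iio.imread(directory / row.mask) > 0
        images.append(LesionImage(id=str(row.id), intensities=raster,
                                  lesion_mask=mask))
    return images


def _crop_pad(arr: np.ndarray, target: int) -> np.ndarray:
    """Center-crop then symmetric zero-pad to a target square size."""
    out = arr
    for axis in (0, 1):
        n = out.shape[axis]
        if n > target:
            start = (n - target) // 2
            out = out.take(range(start, start + target), axis=axis)
        elif n < target:
            before = (target - n) // 2
            after = target - n - before
            pad = [(0, 0), (0, 0)]
            pad[axis] = (before, after)
            out = np.pad(out, pad)
    return out


def load_mri_slice(volume_path: str | Path, mask_path: str | Path,
                   slice_index: int, target_size: int = 240) -> LesionImage:
    """Extract one axial slice + lesion mask from NIfTI volumes.

    The slice is min-max normalized and center-cropped / zero-padded to a
    ``target_size`` square.  A slice whose mask is empty is rejected.
    """
    import nibabel as nib

    vol = np.asanyarray(nib.load(str(volume_path)).dataobj)
    msk = np.asanyarray(nib.load(str(mask_path)).dataobj)
    if vol.shape != msk.shape:
        raise ValueError(f"volume shape {vol.shape} != mask shape {msk.shape}")
    img2d = np.asarray(vol[..., slice_index], dtype=np.float64)
    mask2d = np.asarray(msk[..., slice_index]) > 0
    if not mask2d.any():
        raise ValueError(f"slice {slice_index} has an empty lesion mask")
    img2d = _crop_pad(img2d, target_size)
    mask2d = _crop_pad(mask2d.astype(np.uint8), target_size) > 0
    if not mask2d.any():
        raise ValueError("lesion cropped away while shaping the slice")
    name = f"{Path(volume_path).name}:{slice_index}"
    return LesionImage(id=name, intensities=normalize_intensities(img2d),
                       lesion_mask=mask2d)
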