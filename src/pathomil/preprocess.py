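"""Whole-slide raster preprocessing: tissue masking, patch extraction,
magnification handling and WSI-level augmentation.

A slide is reduced to a bag of fixed-size patches (default 224x224 at 10x):
a saturation-channel Otsu mask separates tissue from the white background,
the slide is resampled to the target magnification, and a regular grid is
tiled, keeping cells whose tissue fraction clears a threshold.  Training-time
augmentation samples one transform per slide (rotation, flips, colour jitter,
each included with probability 0.5) and applies it identically to every patch
of that slide.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import imageio.v3 as iio
import tifffile
from scipy import ndimage
from skimage import color, filters, morphology, transform

logger = logging.getLogger(__name__)


class PreprocessError(ValueError):
    pass


class ResolutionError(PreprocessError):
    """Requested magnification cannot be reached from the available levels."""


@dataclass
class SlideRaster:
    """A slide as one or more raster levels.

    ``levels`` holds the pyramid (level 0 first); ``downsamples`` the factor
    of each level relative to level 0 (strictly increasing, starting at 1).
    ``base_magnification`` is the nominal objective power of level 0.
    """

    levels: list[np.ndarray]
    base_magnification: float
    downsamples: list[float] = field(default_factory=lambda: [1.0])
    slide_id: str = ""

    def __post_init__(self):
        if not self.levels:
            raise PreprocessError("slide has no raster levels")
        if self.base_magnification <= 0:
            raise PreprocessError("base_magnification must be positive")
        if len(self.downsamples) != len(self.levels):
            raise PreprocessError("one downsample factor per level required")
        if self.downsamples[0] != 1 or any(
            b <= a for a, b in zip(self.downsamples, self.downsamples[1:])
        ):
            raise PreprocessError("downsamples must be strictly increasing from 1")
        for lv in self.levels:
            if lv.ndim != 3 or lv.shape[2] != 3:
                raise PreprocessError("levels must be HxWx3 color rasters")

    @property
    def pixels(self) -> np.ndarray:
        return self.levels[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.levels[0].shape[:2]

    def level_magnification(self, level: int) -> float:
        return self.base_magnification / self.downsamples[level]


DEFAULT_ASSUMED_MAGNIFICATION = 20.0


def read_slide(path, assumed_magnification: float | None = None, slide_id: str | None = None) -> SlideRaster:
    """Read a PNG/TIFF slide; pyramidal TIFF series become pyramid levels.

    Magnification is taken from the TIFF ImageDescription tag
    (``magnification=<x>``) when present; otherwise ``assumed_magnification``
    (default 20x) is used and logged prominently.
    """
    path = Path(path)
    slide_id = slide_id or path.stem
    mag = None
    if path.suffix.lower() in {".tif", ".tiff"}:
        with tifffile.TiffFile(path) as tf:
            series = tf.series[0]
            levels = [lvl.asarray() for lvl in series.levels]
            desc = tf.pages[0].description or ""
            for part in desc.replace(";", " ").split():
                if part.startswith("magnification="):
                    mag = float(part.split("=", 1)[1])
    else:
        levels = [iio.imread(path)]
    levels = [np.ascontiguousarray(lv[..., :3]) for lv in levels]
    h0 = levels[0].shape[0]
    downsamples = [h0 / lv.shape[0] for lv in levels]
    if mag is None:
        mag = assumed_magnification or DEFAULT_ASSUMED_MAGNIFICATION
        logger.warning(
            "slide %s has no magnification metadata; assuming base %gx", slide_id, mag
        )
    return SlideRaster(levels=levels, base_magnification=mag, downsamples=downsamples, slide_id=slide_id)


@dataclass
class TissueMask:
    mask: np.ndarray  # binary H'xW'
    downsample: float = 1.0


@dataclass
class PatchRecord:
    """One retained patch: top-left corner at the extraction magnification."""

    slide_id: str
    x: int
    y: int
    magnification: float
    tissue_fraction: float
    patch_size: int = 224


@dataclass
class PreprocessConfig:
    patch_size: int = 224
    target_magnification: float = 10.0
    tissue_threshold: float = 0.5
    stride: int | None = None  # None -> patch_size (non-overlapping)
    allow_upscale: bool = False

    def __post_init__(self):
        if self.patch_size < 1:
            raise PreprocessError("patch_size must be >= 1")
        if not 0 < self.tissue_threshold <= 1:
            raise PreprocessError("tissue_threshold must be in (0, 1]")
        if self.stride is not None and self.stride < 1:
            raise PreprocessError("stride must be >= 1")

    @property
    def effective_stride(self) -> int:
        return self.patch_size if self.stride is None else self.stride


def compute_tissue_mask(slide: SlideRaster | np.ndarray, level: int = 0) -> TissueMask:
    """Otsu threshold on the HSV saturation channel, then morphological
    opening, closing (disk radius 2) and hole filling.  Deterministic.

    Degenerate single-colour rasters yield an empty (unsaturated colour) or
    full (saturated colour) mask rather than raising.
    """
    if isinstance(slide, SlideRaster):
        raster = slide.levels[level]
        downsample = slide.downsamples[level]
    else:
        raster, downsample = slide, 1.0
    rgb = raster.astype(np.float64) / 255.0 if raster.dtype != np.float64 else raster
    sat = color.rgb2hsv(rgb)[..., 1]
    if sat.max() - sat.min() < 1e-9:
        mask = sat > 0.1
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            thr = filters.threshold_otsu(sat)
        mask = sat > thr
    selem = morphology.disk(2)
    mask = morphology.opening(mask, selem)
    mask = morphology.closing(mask, selem)
    mask = ndimage.binary_fill_holes(mask)
    return TissueMask(mask=mask, downsample=downsample)


def resolve_level(
    slide: SlideRaster, target_magnification: float, allow_upscale: bool = False
) -> tuple[int, float]:
    """Pick the pyramid level with the smallest magnification >= target and
    the rescale factor (<= 1) that reaches the target exactly."""
    if target_magnification <= 0:
        raise PreprocessError("target magnification must be positive")
    candidates = [
        (slide.level_magnification(i), i) for i in range(len(slide.levels))
    ]
    feasible = [(m, i) for m, i in candidates if m >= target_magnification - 1e-9]
    if not feasible:
        if allow_upscale:
            mag, level = max(candidates)
            return level, target_magnification / mag
        raise ResolutionError(
            f"slide {slide.slide_id!r}: no level at or above {target_magnification}x "
            f"(available: {[m for m, _ in candidates]}) and upscaling is disabled"
        )
    mag, level = min(feasible)
    return level, target_magnification / mag


def _rescale(raster: np.ndarray, factor: float) -> np.ndarray:
    if abs(factor - 1.0) < 1e-9:
        return raster
    out = transform.rescale(
        raster.astype(np.float64) / 255.0,
        factor,
        channel_axis=-1 if raster.ndim == 3 else None,
        anti_aliasing=factor < 1,
        order=1,
    )
    return (np.clip(out, 0, 1) * 255).astype(np.uint8)


def extract_patches(
    slide: SlideRaster,
    mask: TissueMask | None = None,
    config: PreprocessConfig | None = None,
) -> tuple[list[PatchRecord], np.ndarray]:
    """Tile the slide at the target magnification on a regular grid.

    Partial border cells are dropped; a cell is retained iff its tissue
    fraction >= the threshold.  Returns row-major patch records plus the
    stacked pixel tiles (p, patch, patch, 3) uint8.
    """
    config = config or PreprocessConfig()
    if mask is None:
        mask = compute_tissue_mask(slide)
    level, factor = resolve_level(slide, config.target_magnification, config.allow_upscale)
    raster = _rescale(slide.levels[level], factor)
    h, w = raster.shape[:2]
    ps, stride = config.patch_size, config.effective_stride
    if h < ps or w < ps:
        warnings.warn(
            f"slide {slide.slide_id!r} smaller than one {ps}px patch at "
            f"{config.target_magnification}x; no patches extracted",
            stacklevel=2,
        )
        return [], np.empty((0, ps, ps, 3), dtype=np.uint8)

    # tissue fraction per cell, evaluated on the mask resampled to this grid
    mfull = transform.resize(
        mask.mask.astype(np.float64), (h, w), order=0, anti_aliasing=False
    )
    integral = np.pad(mfull, ((1, 0), (1, 0))).cumsum(0).cumsum(1)

    records: list[PatchRecord] = []
    tiles: list[np.ndarray] = []
    for y in range(0, h - ps + 1, stride):
        for x in range(0, w - ps + 1, stride):
            total = (
                integral[y + ps, x + ps]
                - integral[y, x + ps]
                - integral[y + ps, x]
                + integral[y, x]
            )
            fraction = float(total) / (ps * ps)
            if fraction >= config.tissue_threshold:
                records.append(
                    PatchRecord(
                        slide_id=slide.slide_id,
                        x=x,
                        y=y,
                        magnification=config.target_magnification,
                        tissue_fraction=fraction,
                        patch_size=ps,
                    )
                )
                tiles.append(raster[y : y + ps, x : x + ps])
    tiles_arr = (
        np.stack(tiles) if tiles else np.empty((0, ps, ps, 3), dtype=np.uint8)
    )
    return records, tiles_arr


# ---------------------------------------------------------------------------
# WSI-level augmentation


#: colour-jitter bounds on the 8-bit scale: hue, saturation, value
COLOR_JITTER_BOUNDS = (20, 30, 20)


def sample_wsi_transform(rng: np.random.Generator) -> dict:
    """Sample one slide-level transform: rotation, horizontal flip, vertical
    flip and colour jitter, each independently included with probability 0.5."""
    desc: dict = {"rotation": 0, "hflip": False, "vflip": False, "color": None}
    if rng.random() < 0.5:
        desc["rotation"] = int(rng.choice([90, 180, 270]))
    if rng.random() < 0.5:
        desc["hflip"] = True
    if rng.random() < 0.5:
        desc["vflip"] = True
    if rng.random() < 0.5:
        bh, bs, bv = COLOR_JITTER_BOUNDS
        desc["color"] = (
            float(rng.uniform(-bh, bh)),
            float(rng.uniform(-bs, bs)),
            float(rng.uniform(-bv, bv)),
        )
    return desc


def apply_transform(tiles: np.ndarray, desc: dict) -> np.ndarray:
    """Apply one sampled transform identically to every tile (p, h, w, 3)."""
    out = tiles
    k = desc.get("rotation", 0) // 90
    if k:
        out = np.rot90(out, k=k, axes=(1, 2))
    if desc.get("hflip"):
        out = out[:, :, ::-1]
    if desc.get("vflip"):
        out = out[:, ::-1]
    jitter = desc.get("color")
    if jitter is not None:
        out = _hsv_jitter(out, *jitter)
    return np.ascontiguousarray(out)


def _hsv_jitter(tiles: np.ndarray, dh: float, ds: float, dv: float) -> np.ndarray:
    """Shift hue/saturation/value by 8-bit-scale offsets (float32 round-trip)."""
    x = tiles.astype(np.float32) / 255.0
    mx = x.max(axis=-1)
    mn = x.min(axis=-1)
    diff = mx - mn
    safe = np.where(diff > 0, diff, 1.0)
    r, g, b = x[..., 0], x[..., 1], x[..., 2]
    h = np.where(
        mx == r, (g - b) / safe % 6.0, np.where(mx == g, (b - r) / safe + 2.0, (r - g) / safe + 4.0)
    )
    h = np.where(diff > 0, h / 6.0, 0.0)
    s = np.where(mx > 0, diff / np.where(mx > 0, mx, 1.0), 0.0)
    v = mx
    h = (h + np.float32(dh / 255.0)) % 1.0
    s = np.clip(s + np.float32(ds / 255.0), 0.0, 1.0)
    v = np.clip(v + np.float32(dv / 255.0), 0.0, 1.0)
    h6 = h * 6.0
    vs = v * s
    out = np.empty_like(x)
    for channel, n in ((0, 5.0), (1, 3.0), (2, 1.0)):
        k = (n + h6) % 6.0
        out[..., channel] = v - vs * np.clip(np.minimum(k, 4.0 - k), 0.0, 1.0)
    return (np.clip(out, 0, 1) * 255).astype(np.uint8)


def wsi_augment(
    tiles: np.ndarray, seed: int | np.random.Generator
) -> tuple[np.ndarray, dict]:
    """Augment a slide's tiles with one shared transform; fully seeded.

    Returns the transformed tiles and the transform descriptor (identical for
    every tile of the bag by construction).
    """
    if len(tiles) == 0:
        raise PreprocessError("cannot augment an empty tile list")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    desc = sample_wsi_transform(rng)
    return apply_transform(tiles, desc), desc


def patch_manifest(records: list[PatchRecord]) -> "pd.DataFrame":
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "slide_id": r.slide_id,
                "x": r.x,
                "y": r.y,
                "magnification": r.magnification,
                "tissue_fraction": r.tissue_fraction,
            }
            for r in records
        ],
        columns=["slide_id", "x", "y", "magnification", "tissue_fraction"],
    )
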