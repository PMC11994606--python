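"""Tissue detection and non-overlapping 256x256 patch tiling.

Tissue is found by Otsu thresholding the greyscale slide: stained tissue
is darker than glass, so the mask keeps pixels below the threshold (an
inverted scan would silently fail — the polarity is fixed here on
purpose).  Patches are cropped on the 256-aligned grid over tissue;
coordinates are 0-based, top-left origin, half-open windows, and every
other module (bagging, heatmap reconstruction) relies on that convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.morphology import closing, footprint_rectangle

DEFAULT_PATCH_SIZE = 256
DEFAULT_KEEP_THRESHOLD = 0.5


@dataclass
class Patch:
    """One 256x256 tile cropped from a slide at level-0 coordinates."""

    slide_id: str
    x: int
    y: int
    tissue_fraction: float
    pixels: np.ndarray = field(repr=False)
    tumor_prob: float | None = None


def detect_tissue(image: np.ndarray, closing_size: int = 5) -> np.ndarray:
    """Binary tissue mask via Otsu on luminance; tissue is darker than glass.

    A small morphological closing fills nuclear holes.  A
    constant-intensity image leaves Otsu undefined; that returns an
    all-empty mask with a warning instead of raising.
    """
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim == 3:
        gray = image[..., :3].astype(float) @ np.array([0.2126, 0.7152, 0.0722])
    else:
        gray = image.astype(float)
    if np.ptp(gray) < 1e-9:
        warnings.warn("constant-intensity image: Otsu undefined, returning empty mask")
        return np.zeros(gray.shape, dtype=bool)
    t = threshold_otsu(gray)
    mask = gray < t
    if closing_size > 1:
        mask = closing(mask, footprint_rectangle((closing_size, closing_size)))
    return mask


def tile_slide(
    image: np.ndarray,
    mask: np.ndarray,
    slide_id: str = "slide",
    patch_size: int = DEFAULT_PATCH_SIZE,
    keep_threshold: float = DEFAULT_KEEP_THRESHOLD,
) -> list[Patch]:
    """Crop the aligned non-overlapping grid, keeping tissue-rich patches.

    A patch is retained iff the mean mask value inside its window is at
    least ``keep_threshold``.  Right/bottom remainders narrower than
    ``patch_size`` are discarded.
    """
    if patch_size <= 0:
        raise ValueError(f"patch_size must be positive, got {patch_size}")
    image = np.asarray(image)
    mask = np.asarray(mask)
    if image.shape[:2] != mask.shape[:2]:
        raise ValueError(
            f"image extent {image.shape[:2]} != mask extent {mask.shape[:2]}"
        )
    h, w = mask.shape[:2]
    patches = []
    for y in range(0, h - patch_size + 1, patch_size):
        for x in range(0, w - patch_size + 1, patch_size):
            frac = float(mask[y:y + patch_size, x:x + patch_size].mean())
            if frac >= keep_threshold:
                patches.append(
                    Patch(
                        slide_id=slide_id,
                        x=x,
                        y=y,
                        tissue_fraction=frac,
                        pixels=image[y:y + patch_size, x:x + patch_size],
                    )
                )
    return patches


def patch_index(patches: list[Patch], patch_size: int = DEFAULT_PATCH_SIZE) -> pd.DataFrame:
    """Tabular patch index (slide_id, x, y, width, height, tissue_fraction, tumor_prob)."""
    return pd.DataFrame(
        {
            "slide_id": [p.slide_id for p in patches],
            "x": [p.x for p in patches],
            "y": [p.y for p in patches],
            "width": patch_size,
            "height": patch_size,
            "tissue_fraction": [p.tissue_fraction for p in patches],
            "tumor_prob": [p.tumor_prob for p in patches],
        }
    )
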