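"""Per-patch TPS heatmap reconstruction and overlay rendering.

Every tumor patch inherits the predictions of the inference bags it was
sampled into; its heatmap value is the average of those bag predictions
(the recalculation count is the patch's multiplicity across bags).  The
count-weighted mean of patch values therefore equals the mean of the bag
predictions exactly — a conservation identity the tests enforce.  By
default heatmap bagging uses 100 patches per bag to keep maps local; the
200-patch inference default is reachable through the MIL config.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mil import Bag, MILModel, build_bags_infer, center_crop, predict_bags

DEFAULT_HEATMAP_BAG_SIZE = 100
DEFAULT_CMAP = "inferno"
DEFAULT_ALPHA = 0.55


@dataclass
class HeatmapGrid:
    """Per-patch prediction map over one slide.

    Grid cells without a tumor patch are simply absent from ``xs``/``ys``
    (never encoded as zero — zero is a valid TPS).
    """

    slide_id: str
    xs: np.ndarray            # top-left x of each tumor patch
    ys: np.ndarray
    values: np.ndarray        # mean bag prediction per patch, in [0,1]
    counts: np.ndarray        # recalculation frequency, >= 1
    extent: tuple             # (height, width) of the slide raster
    patch_size: int = 256

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"x": self.xs, "y": self.ys, "value": self.values, "count": self.counts}
        ).to_csv(path, index=False)


def aggregate_patch_values(
    bags: list[Bag], bag_predictions: np.ndarray, n_patches: int
) -> tuple[np.ndarray, np.ndarray]:
    """Average each patch's bag predictions; returns (values, counts)."""
    sums = np.zeros(n_patches)
    counts = np.zeros(n_patches, dtype=int)
    for bag, pred in zip(bags, bag_predictions):
        np.add.at(sums, bag.patch_refs, pred)
        np.add.at(counts, bag.patch_refs, 1)
        # multiplicity inside one bag counts once per occurrence
    covered = counts > 0
    values = np.full(n_patches, np.nan)
    values[covered] = sums[covered] / counts[covered]
    return values, counts


def build_heatmap(
    model: MILModel,
    tumor_patches,
    extent: tuple,
    slide_id: str = "slide",
    n_bags: int | None = None,
    bag_size: int = DEFAULT_HEATMAP_BAG_SIZE,
    seed: int = 0,
) -> HeatmapGrid:
    """Bag the slide's tumor patches, predict each bag, average per patch.

    ``tumor_patches`` are tiled+classified patches (with pixels and grid
    coordinates); ``extent`` is the slide's (height, width).
    """
    if len(tumor_patches) == 0:
        warnings.warn(f"slide {slide_id}: no tumor patches, empty heatmap")
        empty = np.empty(0)
        return HeatmapGrid(slide_id, empty.astype(int), empty.astype(int),
                           empty, empty.astype(int), extent)
    n = len(tumor_patches)
    cfg = model.config
    pixels = np.stack([p.pixels for p in tumor_patches])
    feats = model.extract_features(center_crop(pixels, cfg.crop_size))
    bags, counts = build_bags_infer(
        range(n), n_bags=n_bags or cfg.n_bags_infer, bag_size=bag_size, seed=seed
    )
    preds = predict_bags(model, feats, bags)
    values, counts = aggregate_patch_values(bags, preds, n)
    return HeatmapGrid(
        slide_id=slide_id,
        xs=np.array([p.x for p in tumor_patches]),
        ys=np.array([p.y for p in tumor_patches]),
        values=values,
        counts=counts,
        extent=extent,
    )


def render_overlay(
    grid: HeatmapGrid,
    image: np.ndarray,
    threshold: float = 0.0,
    cmap: str = DEFAULT_CMAP,
    alpha: float = DEFAULT_ALPHA,
) -> np.ndarray:
    """Blend a colormapped overlay of patches with value >= threshold.

    ``threshold=0`` shows every tumor patch; raising it progressively
    hides low-expression regions (coverage is monotone in the threshold).
    """
    import matplotlib

    image = np.asarray(image)
    if image.shape[:2] != tuple(grid.extent):
        raise ValueError(
            f"image extent {image.shape[:2]} does not match grid extent {grid.extent}"
        )
    out = image.astype(float).copy()
    colormap = matplotlib.colormaps[cmap]
    ps = grid.patch_size
    for x, y, v in zip(grid.xs, grid.ys, grid.values):
        if np.isnan(v) or v < threshold:
            continue
        color = np.array(colormap(float(v))[:3]) * 255.0
        out[y:y + ps, x:x + ps] = (
            (1 - alpha) * out[y:y + ps, x:x + ps] + alpha * color
        )
    return np.clip(out, 0, 255).astype(np.uint8)


def heatmap_metadata(
    grid: HeatmapGrid, threshold: float, n_bags: int, bag_size: int,
    cmap: str = DEFAULT_CMAP, alpha: float = DEFAULT_ALPHA, model_hash: str = "",
) -> dict:
    """Sidecar metadata so a render is reproducible."""
    return {
        "slide_id": grid.slide_id,
        "threshold": threshold,
        "n_bags": n_bags,
        "bag_size": bag_size,
        "cmap": cmap,
        "alpha": alpha,
        "model_hash": model_hash,
        "n_patches": int(len(grid.xs)),
    }
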