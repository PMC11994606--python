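"""Synthetic IHC slide generator with exact, by-construction ground truth.

Renders caricature PD-L1 immunohistochemistry slides: white glass
background, eosin-pink tissue blobs, tumor cells as large ellipses with
hematoxylin-blue nuclei (PD-L1-positive ones carry a brown membranous
ring), and smaller distractor immune cells, a configurable fraction of
which are also brown-stained.  Because every cell is placed
parametrically, the slide-level TPS, per-cell positivity and per-patch
tumor labels are known exactly, which makes the whole scoring pipeline
testable without any real whole-slide images.

Not photorealistic by design: no stain gradients, no nuclear texture, no
out-of-focus regions.  The point is exact truth, not realism.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

PATCH_SIZE = 256
#: a 256x256 patch is labelled "tumor" iff at least this many tumor-cell
#: centroids fall inside it
DEFAULT_MIN_TUMOR_CELLS_PER_PATCH = 5

# Render palette (RGB, uint8). Chosen to mimic H-DAB appearance: glass is
# near-white, eosin counterstained tissue pink, hematoxylin nuclei
# blue-violet, DAB-positive membranes brown.
GLASS = np.array([250, 250, 250], dtype=float)
TISSUE = np.array([231, 183, 205], dtype=float)
TUMOR_NUCLEUS = np.array([72, 70, 160], dtype=float)
IMMUNE_NUCLEUS = np.array([52, 55, 135], dtype=float)
DAB_BROWN = np.array([150, 95, 40], dtype=float)

#: realized TPS must land within this many percentage points of the target
TPS_TOLERANCE_POINTS = 2.0


class GeometryError(ValueError):
    """Requested cell count cannot be placed in the generated tissue."""


@dataclass(frozen=True)
class SlideSpec:
    """Parameters of one synthetic slide.

    ``immune_cell_density`` is in cells per tissue pixel (e.g. 2e-4 puts
    ~100 immune cells on 500k tissue pixels). ``stain_noise_sd`` is the
    SD of additive Gaussian intensity noise on the 0–255 scale.
    """

    slide_id: str = "slide"
    width_px: int = 1024
    height_px: int = 1024
    n_tissue_blobs: int = 6
    tumor_area_fraction: float = 0.6
    n_tumor_cells: int = 400
    target_tps: float = 0.5
    immune_cell_density: float = 2.0e-4
    immune_positive_fraction: float = 0.3
    stain_noise_sd: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_tumor_cells < 100:
            raise ValueError(
                f"n_tumor_cells must be >= 100 (slide validity rule), got {self.n_tumor_cells}"
            )
        for name in ("target_tps", "tumor_area_fraction", "immune_positive_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.width_px < 512 or self.height_px < 512:
            raise ValueError("slide must be at least 512x512 pixels")
        if self.n_tissue_blobs < 1:
            raise ValueError("need at least one tissue blob")


@dataclass
class SlideTruth:
    """Exact ground truth emitted alongside a rendered slide.

    ``tumor_centroids`` rows are (x, y, ring_radius, is_positive);
    ``immune_centroids`` rows are (x, y, radius, is_stained).
    ``patch_labels`` is keyed ``"x_y"`` on the 256-aligned grid and only
    contains patches with at least one tumor centroid or tissue.
    """

    slide_id: str
    true_tps_percent: float
    n_positive_tumor_cells: int
    n_tumor_cells: int
    patch_labels: dict = field(repr=False)
    tissue_mask: np.ndarray = field(repr=False)
    tumor_mask: np.ndarray = field(repr=False)
    tumor_centroids: np.ndarray = field(repr=False)
    immune_centroids: np.ndarray = field(repr=False)

    def to_json(self, path) -> None:
        payload = {
            "slide_id": self.slide_id,
            "true_tps_percent": self.true_tps_percent,
            "n_positive_tumor_cells": self.n_positive_tumor_cells,
            "n_tumor_cells": self.n_tumor_cells,
            "patch_labels": self.patch_labels,
            "tumor_centroids": np.asarray(self.tumor_centroids).tolist(),
            "immune_centroids": np.asarray(self.immune_centroids).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)


def _ellipse_mask(h, w, cy, cx, ry, rx, theta) -> np.ndarray:
    """Boolean mask of a rotated ellipse, evaluated on the full grid."""
    yy, xx = np.mgrid[0:h, 0:w]
    y = yy - cy
    x = xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = x * ct + y * st
    v = -x * st + y * ct
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _stamp_ellipse(canvas, cy, cx, ry, rx, theta, color):
    """Paint a small rotated ellipse; bounding-box local evaluation."""
    h, w = canvas.shape[:2]
    r = int(math.ceil(max(ry, rx))) + 1
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    y = yy - cy
    x = xx - cx
    ct, st = math.cos(theta), math.sin(theta)
    u = x * ct + y * st
    v = -x * st + y * ct
    inside = (u / rx) ** 2 + (v / ry) ** 2 <= 1.0
    canvas[y0:y1, x0:x1][inside] = color


def _stamp_ring(canvas, cy, cx, r_in, r_out, color):
    """Paint a circular annulus (membranous staining)."""
    h, w = canvas.shape[:2]
    r = int(math.ceil(r_out)) + 1
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    ring = (d2 >= r_in**2) & (d2 <= r_out**2)
    canvas[y0:y1, x0:x1][ring] = color


def _draw_positive_count(rng, n_cells: int, target_tps: float) -> int:
    """Binomial draw of the positive-cell count, clamped so the realized
    TPS stays within +/-2 points of the target."""
    if target_tps <= 0.0:
        return 0
    if target_tps >= 1.0:
        return n_cells
    n_pos = int(rng.binomial(n_cells, target_tps))
    lo = max(0, int(math.ceil(n_cells * (target_tps - TPS_TOLERANCE_POINTS / 100.0))))
    hi = min(n_cells, int(math.floor(n_cells * (target_tps + TPS_TOLERANCE_POINTS / 100.0))))
    if lo > hi:  # grid too coarse for the band; use nearest representable
        return int(round(n_cells * target_tps))
    return int(np.clip(n_pos, lo, hi))


def generate_slide(
    spec: SlideSpec,
    min_tumor_cells_per_patch: int = DEFAULT_MIN_TUMOR_CELLS_PER_PATCH,
) -> tuple[np.ndarray, SlideTruth]:
    """Render one synthetic slide and its exact truth.

    Returns ``(image, truth)`` where image is an (H, W, 3) uint8 RGB
    raster.  Identical spec (including seed) gives a bit-identical image.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px

    # --- tissue: union of random ellipses -------------------------------
    tissue = np.zeros((h, w), dtype=bool)
    blob_masks = []
    for _ in range(spec.n_tissue_blobs):
        cy = rng.uniform(0.2 * h, 0.8 * h)
        cx = rng.uniform(0.2 * w, 0.8 * w)
        ry = rng.uniform(0.12, 0.30) * h
        rx = rng.uniform(0.12, 0.30) * w
        theta = rng.uniform(0, math.pi)
        m = _ellipse_mask(h, w, cy, cx, ry, rx, theta)
        blob_masks.append(m)
        tissue |= m

    # --- tumor region: greedy subset of blobs near the area target ------
    order = rng.permutation(len(blob_masks))
    tissue_area = int(tissue.sum())
    target_area = spec.tumor_area_fraction * tissue_area
    tumor = np.zeros_like(tissue)
    area = 0
    for bi in order:
        cand = tumor | blob_masks[bi]
        cand_area = int(cand.sum())
        # add a blob only while it brings the area closer to the target
        if abs(cand_area - target_area) < abs(area - target_area):
            tumor, area = cand, cand_area
    if not tumor.any():
        tumor = blob_masks[order[0]].copy()

    tumor_px = np.flatnonzero(tumor)
    if tumor_px.size < spec.n_tumor_cells * 16:
        raise GeometryError(
            f"tumor region of {tumor_px.size} px cannot hold "
            f"{spec.n_tumor_cells} cells (~16 px each)"
        )

    # --- cell placement -------------------------------------------------
    flat = rng.choice(tumor_px, size=spec.n_tumor_cells, replace=False)
    tum_y, tum_x = np.unravel_index(flat, (h, w))
    n_pos = _draw_positive_count(rng, spec.n_tumor_cells, spec.target_tps)
    pos_idx = rng.choice(spec.n_tumor_cells, size=n_pos, replace=False)
    is_pos = np.zeros(spec.n_tumor_cells, dtype=bool)
    is_pos[pos_idx] = True

    n_immune = int(round(spec.immune_cell_density * tissue_area))
    tissue_px = np.flatnonzero(tissue)
    if n_immune > 0:
        flat_i = rng.choice(tissue_px, size=min(n_immune, tissue_px.size), replace=False)
        imm_y, imm_x = np.unravel_index(flat_i, (h, w))
        n_immune = flat_i.size
    else:
        imm_y = imm_x = np.empty(0, dtype=int)
    imm_stained = rng.random(n_immune) < spec.immune_positive_fraction

    # --- render ---------------------------------------------------------
    img = np.empty((h, w, 3), dtype=float)
    img[:] = GLASS
    img[tissue] = TISSUE + rng.normal(0, 4, size=3)

    imm_r = rng.uniform(2.0, 3.0, size=n_immune)
    for i in range(n_immune):
        color = DAB_BROWN if imm_stained[i] else IMMUNE_NUCLEUS
        _stamp_ellipse(img, imm_y[i], imm_x[i], imm_r[i], imm_r[i] * rng.uniform(0.8, 1.0),
                       rng.uniform(0, math.pi), color)

    nuc_ry = rng.uniform(4.5, 6.5, size=spec.n_tumor_cells)
    nuc_rx = nuc_ry * rng.uniform(0.7, 1.0, size=spec.n_tumor_cells)
    nuc_th = rng.uniform(0, math.pi, size=spec.n_tumor_cells)
    ring_r = np.ceil(nuc_ry) + 1.0  # membrane sits just outside the nucleus
    for i in range(spec.n_tumor_cells):
        _stamp_ellipse(img, tum_y[i], tum_x[i], nuc_ry[i], nuc_rx[i], nuc_th[i],
                       TUMOR_NUCLEUS)
    # rings last so positive membranes are never overpainted by nuclei
    for i in np.flatnonzero(is_pos):
        _stamp_ring(img, tum_y[i], tum_x[i], ring_r[i], ring_r[i] + 2.0, DAB_BROWN)

    if spec.stain_noise_sd > 0:
        img += rng.normal(0, spec.stain_noise_sd, size=img.shape)
    img = np.clip(img, 0, 255).astype(np.uint8)

    # --- truth ----------------------------------------------------------
    patch_labels = {}
    for py in range(0, h - PATCH_SIZE + 1, PATCH_SIZE):
        for px in range(0, w - PATCH_SIZE + 1, PATCH_SIZE):
            inside = (
                (tum_x >= px) & (tum_x < px + PATCH_SIZE)
                & (tum_y >= py) & (tum_y < py + PATCH_SIZE)
            )
            patch_labels[f"{px}_{py}"] = bool(inside.sum() >= min_tumor_cells_per_patch)

    truth = SlideTruth(
        slide_id=spec.slide_id,
        true_tps_percent=100.0 * n_pos / spec.n_tumor_cells,
        n_positive_tumor_cells=n_pos,
        n_tumor_cells=spec.n_tumor_cells,
        patch_labels=patch_labels,
        tissue_mask=tissue,
        tumor_mask=tumor,
        tumor_centroids=np.column_stack([tum_x, tum_y, ring_r, is_pos.astype(int)]),
        immune_centroids=(
            np.column_stack([imm_x, imm_y, imm_r, imm_stained.astype(int)])
            if n_immune else np.empty((0, 4))
        ),
    )
    return img, truth


def save_image(img: np.ndarray, path) -> None:
    """Write a rendered slide as PNG or single-level tiled TIFF by suffix."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(path, img, tile=(256, 256))
    else:
        Image.fromarray(img).save(path)


def load_image(path) -> np.ndarray:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(path))
    return np.asarray(Image.open(path).convert("RGB"))


def generate_patch_dataset(
    n_per_class: int,
    seed: int = 0,
    base_spec: SlideSpec | None = None,
    tissue_threshold: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Balanced labelled 256x256 patch set for classifier benchmarks.

    Renders slides (targets cycling over a mid-range TPS grid) and
    collects tissue-rich patches by their truth labels until both
    classes hold ``n_per_class`` patches.  The default spec shrinks the
    tumor area fraction to 0.35 so non-tumor tissue patches are not
    rare.  Returns ``(pixels, labels)`` with pixels (N, 256, 256, 3).
    """
    if base_spec is None:
        base_spec = SlideSpec(tumor_area_fraction=0.35)
    targets = [0.0, 0.1, 0.3, 0.5, 0.7, 0.9]
    tumor, non = [], []
    i = 0
    while (len(tumor) < n_per_class or len(non) < n_per_class) and i < 400:
        spec = replace(
            base_spec,
            slide_id=f"P{i:03d}",
            target_tps=targets[i % len(targets)],
            seed=int(np.random.default_rng([seed, 977, i]).integers(2**31)),
        )
        img, truth = generate_slide(spec)
        for key, lab in truth.patch_labels.items():
            x, y = map(int, key.split("_"))
            win = truth.tissue_mask[y:y + PATCH_SIZE, x:x + PATCH_SIZE]
            if win.mean() < tissue_threshold:
                continue
            bucket = tumor if lab else non
            if len(bucket) < n_per_class:
                bucket.append(img[y:y + PATCH_SIZE, x:x + PATCH_SIZE])
        i += 1
    if len(tumor) < n_per_class or len(non) < n_per_class:
        raise GeometryError(
            f"could not collect {n_per_class} patches per class "
            f"(got {len(tumor)} tumor / {len(non)} non-tumor)"
        )
    pixels = np.stack(tumor + non)
    labels = np.concatenate([np.ones(n_per_class, bool), np.zeros(n_per_class, bool)])
    return pixels, labels


def default_tps_grid() -> list[float]:
    """Target TPS fractions spanning the 12-label range 0–0.9 plus 1.0."""
    return [0.0, 0.01, 0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]


def generate_cohort(
    n_slides: int,
    tps_grid: list[float] | None = None,
    base_spec: SlideSpec | None = None,
    seed: int = 0,
    out_dir=None,
    cohort: str = "synthetic",
    image_format: str = "png",
) -> tuple[pd.DataFrame, list[SlideTruth]]:
    """Generate a cohort of slides with slide-level train/val/test splits.

    Targets cycle through ``tps_grid``; splits are assigned at the slide
    level 3/1/1 (train/val/test) by a seeded shuffle, so no slide leaks
    across splits.  When ``out_dir`` is given, images, per-slide truth
    JSON sidecars and a manifest CSV are written there; otherwise images
    stay in memory (manifest image_path is empty).

    Returns ``(manifest, truths)``.  The manifest carries an extra
    in-memory-only column ``tps_target`` for audit.
    """
    if n_slides < 1:
        raise ValueError(f"n_slides must be >= 1, got {n_slides}")
    if tps_grid is None:
        tps_grid = default_tps_grid()
    if base_spec is None:
        base_spec = SlideSpec()

    rng = np.random.default_rng(seed)
    # slide-level 3/1/1 split
    order = rng.permutation(n_slides)
    split = np.empty(n_slides, dtype=object)
    n_train = int(round(n_slides * 3 / 5))
    n_val = int(round(n_slides * 1 / 5))
    split[order[:n_train]] = "train"
    split[order[n_train:n_train + n_val]] = "val"
    split[order[n_train + n_val:]] = "test"

    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        (out_dir / "images").mkdir(parents=True, exist_ok=True)
        (out_dir / "truth").mkdir(parents=True, exist_ok=True)

    rows, truths, images = [], [], []
    for i in range(n_slides):
        target = tps_grid[i % len(tps_grid)]
        spec = replace(
            base_spec,
            slide_id=f"S{i:03d}",
            target_tps=float(target),
            seed=int(np.random.default_rng([seed, i]).integers(2**31)),
        )
        img, truth = generate_slide(spec)
        truths.append(truth)
        images.append(img)
        image_path = ""
        if out_dir is not None:
            ext = ".tiff" if image_format == "tiff" else ".png"
            # relative to the manifest so the cohort directory is portable
            image_path = f"images/{spec.slide_id}{ext}"
            save_image(img, out_dir / image_path)
            truth.to_json(out_dir / "truth" / f"{spec.slide_id}.json")
        rows.append(
            {
                "slide_id": spec.slide_id,
                "image_path": image_path,
                "tps_truth_percent": truth.true_tps_percent,
                "cohort": cohort,
                "split": split[i],
                "tps_target": target,
            }
        )

    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        manifest.drop(columns=["tps_target"]).to_csv(out_dir / "manifest.csv", index=False)
    manifest.attrs["images"] = images
    return manifest, truths
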