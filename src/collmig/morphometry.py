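"""Fixed-image morphometry: puncta (focal adhesion / pERM) quantification,
cell spreading area, and nuclear/cytoplasmic intensity ratio.

The puncta pipeline follows the enhancement chain used for stained puncta:
background removal (rolling ball), local contrast enhancement (CLAHE), an
exponential remap that suppresses residual background relative to bright
structures, an automatic percentile contrast stretch, Otsu binarization
inside the cell mask, and 8-connected component labelling with a strict
area filter (area > 0.5 um^2 by default). Segmentation of the cells
themselves is an input (label mask), never computed here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.exposure import equalize_adapthist, rescale_intensity
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.restoration import rolling_ball

__all__ = [
    "LabeledRegions",
    "NCRatio",
    "fa_perm_pipeline",
    "nuclear_cytoplasmic_ratio",
    "spreading_area",
]


@dataclass
class LabeledRegions:
    """Puncta surviving the area filter, with per-cell tallies."""

    label_image: np.ndarray
    regions: pd.DataFrame  # region_id, cell_id, area_um2
    per_cell: pd.DataFrame  # cell_id, n_regions, total_area_um2
    area_threshold_um2: float


@dataclass(frozen=True)
class NCRatio:
    nuclear_mean: float
    cytoplasmic_mean: float

    @property
    def ratio(self) -> float:
        return self.nuclear_mean / self.cytoplasmic_mean


def _enhance(img: np.ndarray, ball_radius: int, clahe_kernel: int,
             clahe_clip: float, stretch_pct: float) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    lo, hi = img.min(), img.max()
    if hi <= lo:
        return np.zeros_like(img)
    img = (img - lo) / (hi - lo)  # affine-normalize; makes the chain scale-robust
    img = img - rolling_ball(img, radius=ball_radius)
    img = np.clip(img, 0.0, None)
    if img.max() > 0:
        img = img / img.max()
    img = equalize_adapthist(img, kernel_size=clahe_kernel, clip_limit=clahe_clip)
    img = (np.exp(img) - 1.0) / (np.e - 1.0)
    p_lo, p_hi = np.percentile(img, [stretch_pct, 100.0 - stretch_pct])
    if p_hi > p_lo:
        img = rescale_intensity(img, in_range=(p_lo, p_hi), out_range=(0.0, 1.0))
    return img


def fa_perm_pipeline(
    image: np.ndarray,
    cell_mask: np.ndarray,
    pixel_size: float,
    area_threshold_um2: float = 0.5,
    ball_radius: int = 50,
    clahe_kernel: int = 64,
    clahe_clip: float = 0.01,
    stretch_pct: float = 0.1,
    max_foreground_fraction: float = 0.25,
) -> LabeledRegions:
    """Count and measure bright puncta per cell.

    ``cell_mask`` is either a binary mask (treated as one cell, id 1) or an
    integer label image; each surviving punctum is assigned to the cell
    label at its centroid (falling back to the majority label under the
    punctum). Only regions with area strictly greater than
    ``area_threshold_um2`` are counted. No surviving region is a valid
    zero count, but an empty cell mask is an error.
    """
    if image.shape != cell_mask.shape:
        raise ValueError("image and cell mask must have the same shape")
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    cells = np.asarray(cell_mask)
    if cells.dtype == bool:
        cells = cells.astype(int)
    if not np.any(cells > 0):
        raise ValueError("cell mask is empty")
    enhanced = _enhance(image, ball_radius, clahe_kernel, clahe_clip, stretch_pct)
    inside = cells > 0
    vals = enhanced[inside]
    if np.ptp(vals) <= 0:
        binary = np.zeros_like(inside)
    else:
        binary = (enhanced > threshold_otsu(vals)) & inside
        # puncta are sparse bright objects; when Otsu labels a large share
        # of the cell as foreground it is splitting background noise on a
        # punctum-free image, not detecting structures
        if binary.sum() > max_foreground_fraction * inside.sum():
            binary = np.zeros_like(inside)
    lab = label(binary, connectivity=2)
    out_label = np.zeros_like(lab)
    rows = []
    next_id = 0
    for rp in regionprops(lab):
        area_um2 = rp.area * pixel_size**2
        if area_um2 <= area_threshold_um2:
            continue
        next_id += 1
        cy, cx = (int(round(c)) for c in rp.centroid)
        cell_id = int(cells[cy, cx])
        if cell_id == 0:
            region_cells = cells[tuple(rp.coords.T)]
            region_cells = region_cells[region_cells > 0]
            cell_id = int(np.bincount(region_cells).argmax()) if len(region_cells) else 0
        out_label[lab == rp.label] = next_id
        rows.append({"region_id": next_id, "cell_id": cell_id, "area_um2": area_um2})
    regions = pd.DataFrame(rows, columns=["region_id", "cell_id", "area_um2"])
    cell_ids = sorted(int(c) for c in np.unique(cells) if c > 0)
    per_cell = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "n_regions": [
                int((regions["cell_id"] == c).sum()) if len(regions) else 0
                for c in cell_ids
            ],
            "total_area_um2": [
                float(regions.loc[regions["cell_id"] == c, "area_um2"].sum())
                if len(regions)
                else 0.0
                for c in cell_ids
            ],
        }
    )
    return LabeledRegions(
        label_image=out_label,
        regions=regions,
        per_cell=per_cell,
        area_threshold_um2=area_threshold_um2,
    )


def nuclear_cytoplasmic_ratio(
    image: np.ndarray, nuclear_mask: np.ndarray, cell_mask: np.ndarray
) -> NCRatio:
    """Mean signal inside the nucleus divided by the mean in the cytoplasm
    (cell minus nucleus). The nuclear mask must lie inside the cell mask
    and the cytoplasm must be nonempty."""
    nuc = np.asarray(nuclear_mask, dtype=bool)
    cell = np.asarray(cell_mask, dtype=bool)
    if image.shape != nuc.shape or image.shape != cell.shape:
        raise ValueError("image and masks must share a shape")
    if np.any(nuc & ~cell):
        raise ValueError("nuclear mask must lie within the cell mask")
    cyto = cell & ~nuc
    if not nuc.any() or not cyto.any():
        raise ValueError("empty nucleus or cytoplasm")
    img = np.asarray(image, dtype=float)
    return NCRatio(
        nuclear_mean=float(img[nuc].mean()),
        cytoplasmic_mean=float(img[cyto].mean()),
    )


def spreading_area(cell_mask: np.ndarray, pixel_size: float) -> float:
    """Cell footprint area in um^2 (pixel count times pixel area)."""
    if pixel_size <= 0:
        raise ValueError("pixel_size must be positive")
    return float(np.asarray(cell_mask, dtype=bool).sum()) * pixel_size**2
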