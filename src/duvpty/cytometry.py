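"""Label-free cell segmentation and per-cell morphometric features.

Segmentation is Otsu thresholding on a smoothed cell-signal image (an
absorption amplitude or a total-mass map), with touching cells split by a
marker-controlled watershed; nucleus masks come from the nucleic-acid
channel (or, absent one, the high-absorption core) inside each cell.  The
features are the standard cytometric trio used to separate mononuclear from
polymorphonuclear leukocytes: cell area, nuclear-to-cytoplasmic area ratio,
and the isoperimetric nuclear roundness 4πA/P².
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
import tifffile
from scipy import ndimage
from skimage import filters, measure, morphology, segmentation

from .errors import ValidationError

__all__ = ["CellRecord", "segment_cells", "cell_features", "write_features_csv"]


@dataclass(frozen=True)
class CellRecord:
    """Morphometrics of one segmented cell (areas in µm²)."""

    cell_id: int
    area: float
    nuclear_area: float
    nc_ratio: float
    nuclear_roundness: float
    centroid: tuple[float, float]
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise ValidationError("cell area must be positive")


def segment_cells(
    cell_signal: np.ndarray,
    nucleus_signal: np.ndarray | None = None,
    smooth_sigma: float = 2.0,
    min_area_px: int = 64,
    nucleus_quantile: float = 0.75,
):
    """Segment cells and nuclei; returns ``(cell_labels, nucleus_labels)``.

    An empty image (no foreground after thresholding) returns two all-zero
    label maps rather than raising.  Touching cells are split by a watershed
    seeded from the nucleus components; without a nucleus channel the seeds
    come from the brightest ``nucleus_quantile`` core of each cell.
    Deterministic for fixed inputs.
    """
    img = np.asarray(cell_signal, dtype=float)
    if img.ndim != 2 or min(img.shape) < 64:
        raise ValidationError("cell_signal must be 2-D and at least 64 px per side")
    smooth = ndimage.gaussian_filter(img, smooth_sigma)
    if smooth.max() <= smooth.min():
        return np.zeros(img.shape, np.int32), np.zeros(img.shape, np.int32)
    # log compression before Otsu: nuclei can be an order of magnitude
    # brighter than cytoplasm, and thresholding the raw signal would split
    # nucleus-vs-rest instead of foreground-vs-background
    lo = smooth.min()
    compressed = np.log1p((smooth - lo) / (0.02 * (smooth.max() - lo)))
    thresh = filters.threshold_otsu(compressed)
    mask = compressed > thresh
    mask = ndimage.binary_fill_holes(mask)
    mask = morphology.remove_small_objects(mask, max_size=min_area_px - 1)
    if not mask.any():
        return np.zeros(img.shape, np.int32), np.zeros(img.shape, np.int32)

    if nucleus_signal is not None:
        nuc_img = ndimage.gaussian_filter(np.asarray(nucleus_signal, float), smooth_sigma)
        if nuc_img[mask].max() > nuc_img[mask].min():
            nthr = filters.threshold_otsu(nuc_img[mask])
            nuc_mask = (nuc_img > nthr) & mask
        else:
            nuc_mask = np.zeros_like(mask)
    else:
        core = np.quantile(smooth[mask], nucleus_quantile)
        nuc_mask = (smooth > core) & mask
    nuc_mask = morphology.remove_small_objects(nuc_mask, max_size=max(min_area_px // 8, 4) - 1)

    # close thin waists (e.g. between nuclear lobes) so one nucleus yields
    # one watershed marker instead of splitting its cell
    marker_mask = ndimage.binary_closing(nuc_mask, structure=morphology.disk(3))
    markers, n_markers = ndimage.label(marker_mask)
    if n_markers == 0:
        cell_labels, _ = ndimage.label(mask)
        return cell_labels.astype(np.int32), np.zeros(img.shape, np.int32)
    distance = ndimage.distance_transform_edt(mask)
    cell_labels = segmentation.watershed(-distance, markers=markers, mask=mask)
    counts = np.bincount(cell_labels.ravel())
    too_small = np.nonzero(counts < min_area_px)[0]
    if too_small.size:
        cell_labels[np.isin(cell_labels, too_small[too_small > 0])] = 0
    nucleus_labels = np.where(nuc_mask, cell_labels, 0)
    return cell_labels.astype(np.int32), nucleus_labels.astype(np.int32)


def cell_features(
    cell_labels: np.ndarray,
    nucleus_labels: np.ndarray,
    pixel_size: float,
) -> list[CellRecord]:
    """Per-cell area, nuclear area, N/C ratio, and nuclear roundness.

    Roundness is 4πA/P² with the perimeter from the boundary contour
    (clipped to 1 against rasterisation overshoot); a cell without nucleus
    pixels, or with nucleus pixels outside the cell, is flagged.  An empty
    label map yields an empty list.
    """
    if pixel_size <= 0:
        raise ValidationError("pixel_size must be positive")
    cell_labels = np.asarray(cell_labels)
    nucleus_labels = np.asarray(nucleus_labels)
    if cell_labels.shape != nucleus_labels.shape:
        raise ValidationError("label maps must share one shape")
    records: list[CellRecord] = []
    px_area = pixel_size**2
    for prop in measure.regionprops(cell_labels):
        cid = prop.label
        cell_mask = cell_labels == cid
        nuc_mask = nucleus_labels == cid
        nuc_in = nuc_mask & cell_mask
        flagged = bool(np.any(nuc_mask & ~cell_mask)) or not nuc_in.any()
        area = prop.area * px_area
        if not nuc_in.any():
            records.append(
                CellRecord(cid, area, 0.0, 0.0, 0.0, tuple(prop.centroid), True)
            )
            continue
        nprop = measure.regionprops(nuc_in.astype(np.uint8))[0]
        n_area_px = nprop.area
        perimeter = nprop.perimeter
        roundness = (
            min(4.0 * np.pi * n_area_px / perimeter**2, 1.0) if perimeter > 0 else 1.0
        )
        records.append(
            CellRecord(
                cell_id=cid,
                area=area,
                nuclear_area=n_area_px * px_area,
                nc_ratio=min(n_area_px / prop.area, 1.0),
                nuclear_roundness=roundness,
                centroid=tuple(prop.centroid),
                flagged=flagged,
            )
        )
    return records


def write_features_csv(path, records: list[CellRecord]) -> None:
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(
            ["cell_id", "area_um2", "nuclear_area_um2", "nc_ratio",
             "nuclear_roundness", "centroid_y", "centroid_x", "flagged"]
        )
        for r in records:
            w.writerow(
                [r.cell_id, f"{r.area:.4f}", f"{r.nuclear_area:.4f}",
                 f"{r.nc_ratio:.5f}", f"{r.nuclear_roundness:.5f}",
                 f"{r.centroid[0]:.2f}", f"{r.centroid[1]:.2f}", int(r.flagged)]
            )


def export_labels_tiff(path, labels: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(labels).astype(np.uint16))
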