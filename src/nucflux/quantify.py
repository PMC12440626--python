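"""Per-cell compartment measurements from images and label masks.

The quantification rules follow the standard nucleocytoplasmic-ratio
workflow: concentrations are background-subtracted integrated signal per
area, and the cytoplasm is obtained by subtraction — cytoplasmic integrated
intensity (area) is the whole-cell value minus the nuclear value, so the
decompositions ``I_cell = I_nuc + I_cyt`` and ``A_cell = A_nuc + A_cyt``
hold exactly. Autofluorescence is not corrected, mirroring the measurement
convention this pipeline reproduces (both compartment concentrations are
therefore slightly overestimated on real data).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

log = logging.getLogger(__name__)

__all__ = [
    "CellMeasurement", "estimate_background", "measure_cell",
    "topk_mean", "two_roi_cytoplasm", "nc_ratio",
    "normalize_to_reference", "minmax_normalize",
]


@dataclass
class CellMeasurement:
    """One cell's compartment areas, intensities and concentrations in one
    frame. Areas in px², intensities in background-subtracted a.u.,
    concentrations in a.u./px²."""

    cell_id: int
    t_min: float
    area_cell: float
    area_nuc: float
    i_cell: float
    i_nuc: float
    background: float
    clamped: bool = False

    @property
    def area_cyt(self) -> float:
        return self.area_cell - self.area_nuc

    @property
    def i_cyt(self) -> float:
        return self.i_cell - self.i_nuc

    @property
    def c_cell(self) -> float:
        return self.i_cell / self.area_cell if self.area_cell > 0 else math.nan

    @property
    def c_nuc(self) -> float:
        return self.i_nuc / self.area_nuc if self.area_nuc > 0 else math.nan

    @property
    def c_cyt(self) -> float:
        if self.area_cyt <= 0:
            return math.nan
        return (self.i_cell - self.i_nuc) / (self.area_cell - self.area_nuc)


def estimate_background(image: np.ndarray, cell_labels: np.ndarray,
                        n_rois: int = 8, roi_px: int = 15,
                        margin_px: int = 5) -> float:
    """Mean intensity over off-cell ROIs, one value per frame.

    ROIs are square patches auto-placed on a grid wherever they are fully
    outside the cell masks (dilated by ``margin_px``); the mean of the ROI
    means is returned, emulating manually drawn background regions.
    """
    image = np.asarray(image, dtype=float)
    off = np.asarray(cell_labels) == 0
    if margin_px > 0:
        off = ndimage.binary_erosion(off, iterations=margin_px)
    if not off.any():
        raise ValueError("no background pixels available")
    h, w = image.shape
    means = []
    step_r = max(h // int(np.ceil(np.sqrt(4 * n_rois))), roi_px)
    for r0 in range(0, h - roi_px + 1, step_r):
        for c0 in range(0, w - roi_px + 1, step_r):
            patch_off = off[r0:r0 + roi_px, c0:c0 + roi_px]
            if patch_off.all():
                means.append(image[r0:r0 + roi_px, c0:c0 + roi_px].mean())
            if len(means) >= n_rois:
                break
        if len(means) >= n_rois:
            break
    if not means:
        # fall back to all background pixels
        return float(image[off].mean())
    return float(np.mean(means))


def measure_cell(image: np.ndarray, cell_mask: np.ndarray,
                 nucleus_mask: np.ndarray, background: float,
                 cell_id: int = 0, t_min: float = 0.0) -> CellMeasurement:
    """Integrated intensities and areas for one cell and its nucleus.

    ``background`` is subtracted per pixel before integration; negative
    background-corrected integrals are clamped at 0 and flagged. The
    nucleus mask may hold two objects (post-anaphase) — they are summed.
    """
    if background < 0:
        raise ValueError("background must be >= 0")
    image = np.asarray(image, dtype=float)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool) & cell_mask
    a_cell = float(cell_mask.sum())
    a_nuc = float(nucleus_mask.sum())
    i_cell = float(image[cell_mask].sum()) - background * a_cell
    i_nuc = float(image[nucleus_mask].sum()) - background * a_nuc
    clamped = False
    if i_cell < 0:
        i_cell, clamped = 0.0, True
    if i_nuc < 0:
        i_nuc, clamped = 0.0, True
    if i_nuc > i_cell:
        i_nuc = i_cell
    if clamped:
        log.info("cell %d t=%.2f: negative corrected integral clamped at 0",
                 cell_id, t_min)
    m = CellMeasurement(cell_id=cell_id, t_min=t_min, area_cell=a_cell,
                        area_nuc=a_nuc, i_cell=i_cell, i_nuc=i_nuc,
                        background=background, clamped=clamped)
    if m.area_cyt <= 0:
        log.info("cell %d t=%.2f: zero cytoplasmic area, c_cyt undefined",
                 cell_id, t_min)
    return m


def topk_mean(image: np.ndarray, mask: np.ndarray, k: int = 40) -> float:
    """Mean of the ``k`` brightest in-mask pixels (default 40)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    vals = np.asarray(image, dtype=float)[np.asarray(mask, dtype=bool)]
    if vals.size < k:
        raise ValueError(f"mask holds {vals.size} pixels, fewer than k={k}")
    top = np.partition(vals, vals.size - k)[vals.size - k:]
    return float(top.mean())


def two_roi_cytoplasm(image: np.ndarray, cell_mask: np.ndarray,
                      nucleus_mask: np.ndarray, roi_radius_px: int = 4,
                      gap_px: int = 2) -> float:
    """Mean over two discs flanking the nucleus along the cell long axis.

    Emulates two manually placed cytoplasmic regions on either side of the
    nucleus. If a disc collides with the nucleus or leaves the cell it is
    pushed outward once; failing that, an error is raised.
    """
    image = np.asarray(image, dtype=float)
    cell_mask = np.asarray(cell_mask, dtype=bool)
    nucleus_mask = np.asarray(nucleus_mask, dtype=bool)
    if not nucleus_mask.any():
        raise ValueError("empty nucleus mask")
    # long axis from the cell mask's second moments
    rr, cc = np.nonzero(cell_mask)
    cr, ccol = rr.mean(), cc.mean()
    cov = np.cov(np.vstack([rr - cr, cc - ccol]))
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    nrr, ncc = np.nonzero(nucleus_mask)
    ncenter = np.array([nrr.mean(), ncc.mean()])
    r_nuc = math.sqrt(nucleus_mask.sum() / math.pi)

    def roi_mask(center):
        g0, g1 = np.ogrid[0:image.shape[0], 0:image.shape[1]]
        return ((g0 - center[0]) ** 2 + (g1 - center[1]) ** 2
                <= roi_radius_px ** 2)

    vals = []
    for sign in (-1.0, 1.0):
        placed = False
        for attempt in range(2):
            offset = r_nuc + gap_px + roi_radius_px + attempt * roi_radius_px
            center = ncenter + sign * offset * axis
            m = roi_mask(center)
            if m.any() and (m <= cell_mask).all() and not (m & nucleus_mask).any():
                vals.append(image[m])
                placed = True
                break
        if not placed:
            raise ValueError("could not place cytoplasmic ROI inside the cell "
                             "clear of the nucleus")
    return float(np.concatenate(vals).mean())


def nc_ratio(meas: CellMeasurement) -> float:
    """Nucleocytoplasmic concentration ratio; NaN when c_cyt <= 0."""
    c_cyt = meas.c_cyt
    if not (c_cyt > 0):
        return math.nan
    return meas.c_nuc / c_cyt


def normalize_to_reference(ratios: np.ndarray,
                           reference: np.ndarray) -> np.ndarray:
    """Divide ratios by the mean ratio of a wild-type reference group."""
    reference = np.asarray(reference, dtype=float)
    reference = reference[np.isfinite(reference)]
    if reference.size == 0:
        raise ValueError("reference group is empty")
    return np.asarray(ratios, dtype=float) / reference.mean()


def minmax_normalize(values: np.ndarray) -> np.ndarray:
    """Scale a trace to [0, 1] over its own window (min -> 0, max -> 1)."""
    values = np.asarray(values, dtype=float)
    lo = np.nanmin(values)
    hi = np.nanmax(values)
    if not hi > lo:
        raise ValueError("constant trace: min-max normalization is degenerate")
    return (values - lo) / (hi - lo)
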