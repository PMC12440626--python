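"""Space-time kymographs along the cell long axis.

Each column is one frame's axial intensity profile: the cell is rotated to
its mask's principal axis and, for every position along that axis, the
maximum (default; keeps SPB foci visible) or mean intensity across the
short axis inside the mask becomes one row. Columns can be subsampled
(figures in this field often show every fourth or sixth image).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = ["Kymograph", "build_kymograph", "axial_profile"]


@dataclass
class Kymograph:
    """Rows = axial position (µm), columns = (subsampled) frames."""

    image: np.ndarray
    times_min: np.ndarray
    positions_um: np.ndarray
    channel: str
    subsample: int
    cell_id: int

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.image, index=self.positions_um,
                          columns=self.times_min)
        df.index.name = "position_um"
        df.columns.name = "t_min"
        return df


def axial_profile(image: np.ndarray, mask: np.ndarray, n_bins: int,
                  mode: str = "max") -> np.ndarray:
    """Project in-mask intensities onto the mask's principal axis.

    Pixel coordinates are rotated so the long axis is vertical, binned into
    ``n_bins`` axial positions centred on the mask centroid, and reduced by
    max or mean. Bins without pixels are NaN.
    """
    if mode not in ("max", "mean"):
        raise ValueError("mode must be 'max' or 'mean'")
    mask = np.asarray(mask, dtype=bool)
    rr, cc = np.nonzero(mask)
    if rr.size == 0:
        return np.full(n_bins, np.nan)
    vals = np.asarray(image, dtype=float)[rr, cc]
    cr, ccol = rr.mean(), cc.mean()
    cov = np.cov(np.vstack([rr - cr, cc - ccol]))
    evals, evecs = np.linalg.eigh(cov)
    axis = evecs[:, np.argmax(evals)]
    if axis[0] < 0 or (axis[0] == 0 and axis[1] < 0):
        axis = -axis  # stable sign
    along = (rr - cr) * axis[0] + (cc - ccol) * axis[1]
    half = n_bins / 2.0
    idx = np.clip(np.floor(along + half).astype(int), 0, n_bins - 1)
    if mode == "max":
        out = np.full(n_bins, -np.inf)
        np.maximum.at(out, idx, vals)
        out[~np.isfinite(out)] = np.nan
    else:
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins)
        np.add.at(sums, idx, vals)
        np.add.at(counts, idx, 1)
        with np.errstate(invalid="ignore"):
            out = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    return out


def build_kymograph(movie, cell_track_labels: np.ndarray, cell_id: int,
                    channel: str = "reporter", subsample: int = 1,
                    mode: str = "max") -> Kymograph:
    """Build one cell's kymograph from a rendered or loaded movie.

    ``cell_track_labels`` is the (T, H, W) stack of track-stable cell ids;
    frames where the cell is untracked yield blank (NaN) columns, logged.
    """
    if subsample < 1:
        raise ValueError("subsample must be >= 1")
    stack = movie.channels[channel]
    frame_idx = np.arange(0, movie.n_frames, subsample)
    px = movie.optics.pixel_size_um
    # row extent covers the maximal cell length over the window
    max_len_px = 0
    for k in frame_idx:
        m = cell_track_labels[k] == cell_id
        if m.any():
            rr, cc = np.nonzero(m)
            ext = math.hypot(rr.max() - rr.min(), cc.max() - cc.min())
            max_len_px = max(max_len_px, int(math.ceil(ext)) + 1)
    if max_len_px == 0:
        raise ValueError(f"cell {cell_id} never tracked in the window")
    img = np.full((max_len_px, frame_idx.size), np.nan)
    for j, k in enumerate(frame_idx):
        m = cell_track_labels[k] == cell_id
        if not m.any():
            log.info("cell %d untracked at frame %d: blank column", cell_id, k)
            continue
        img[:, j] = axial_profile(stack[k], m, max_len_px, mode=mode)
    positions = (np.arange(max_len_px) - max_len_px / 2.0) * px
    return Kymograph(image=img, times_min=movie.times_min[frame_idx],
                     positions_um=positions, channel=channel,
                     subsample=subsample, cell_id=cell_id)
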