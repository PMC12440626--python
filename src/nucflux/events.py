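"""Mitotic event detection and event-aligned ensemble pooling.

Anaphase (nuclear separation) is the frame at which a cell's nucleus count
goes from one to two and stays two; SPB separation is the first frame with
two persistent foci in the focus channel; Plo1 onset is the first sustained
excursion of the top-k brightest-pixel trace above its early baseline.
Traces are aligned by shifting each cell's timestamps so the anchor event
is 0 and pooling on the shared acquisition grid without interpolation
(event times are frame-quantized). Nuclear separation and sister-chromatid
separation are treated as the same anchor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.feature import peak_local_max

from .loess import loess_smooth

log = logging.getLogger(__name__)

__all__ = [
    "detect_anaphase", "detect_spb_separation", "detect_plo1_onset",
    "align_and_pool", "AlignedEnsemble", "build_event_table",
]


def detect_anaphase(times: np.ndarray, n_nuclei: np.ndarray,
                    persist: int = 2) -> float | None:
    """First time a cell's nucleus count rises from 1 to >=2 and stays
    there for ``persist`` frames; None when no such transition occurs."""
    times = np.asarray(times, dtype=float)
    n = np.asarray(n_nuclei)
    if times.shape != n.shape:
        raise ValueError("times and n_nuclei must match")
    seen_one = False
    for i in range(len(n)):
        if n[i] <= 1:
            seen_one = seen_one or n[i] == 1
            continue
        if not seen_one:
            continue
        if all(n[j] >= 2 for j in range(i, min(i + persist, len(n)))) \
                and i + persist <= len(n):
            return float(times[i])
    return None


def _frame_foci(image, cell_mask, mad_factor, min_distance_px):
    vals = image[cell_mask]
    med = np.median(vals)
    mad = np.median(np.abs(vals - med))
    thr = med + mad_factor * mad
    masked = np.where(cell_mask, image, -np.inf)
    peaks = peak_local_max(masked, min_distance=max(int(min_distance_px), 1),
                           threshold_abs=thr, exclude_border=False)
    if len(peaks) == 0:
        return []
    heights = image[peaks[:, 0], peaks[:, 1]]
    order = np.argsort(heights)[::-1][:2]
    return [tuple(peaks[i]) for i in order]


def detect_spb_separation(focus_stack: np.ndarray, cell_masks: np.ndarray,
                          times: np.ndarray, mad_factor: float = 6.0,
                          min_distance_px: float = 3.0,
                          persist: int = 2) -> float | None:
    """First frame with two foci farther apart than ``min_distance_px``
    persisting for ``persist`` frames.

    Foci are local maxima above median + ``mad_factor``·MAD of the in-cell
    pixels; at most the two brightest are kept per frame.
    """
    times = np.asarray(times, dtype=float)
    separated = np.zeros(len(times), dtype=bool)
    for k in range(len(times)):
        mask = np.asarray(cell_masks[k], dtype=bool)
        if not mask.any():
            continue
        foci = _frame_foci(np.asarray(focus_stack[k], dtype=float), mask,
                           mad_factor, min_distance_px)
        if len(foci) == 2:
            (r1, c1), (r2, c2) = foci
            d = math.hypot(r1 - r2, c1 - c2)
            separated[k] = d > min_distance_px
    for k in range(len(times) - persist + 1):
        if separated[k:k + persist].all():
            return float(times[k])
    return None


def detect_plo1_onset(times: np.ndarray, topk_trace: np.ndarray,
                      sd_factor: float = 4.0, persist: int = 3,
                      smooth_points: int = 5) -> float | None:
    """Onset of SPB enrichment from a top-k brightest-pixel trace.

    Baseline mean and SD come from the earliest quartile of the raw trace;
    the loess-smoothed trace must exceed baseline mean + ``sd_factor``·SD
    and stay above for ``persist`` frames. Returns None when the trace
    never does. Smoothing uses a short ``smooth_points`` local window: a
    wide smoother would bleed a sharp onset backwards in time by half its
    support, biasing the detected time early.
    """
    times = np.asarray(times, dtype=float)
    y = np.asarray(topk_trace, dtype=float)
    if times.shape != y.shape or y.size < 8:
        raise ValueError("need matched trace of at least 8 points")
    n_base = max(y.size // 4, 3)
    base = y[:n_base]
    thr = base.mean() + sd_factor * base.std(ddof=1)
    span = min(max(smooth_points, 5) / y.size, 1.0)
    smooth = loess_smooth(times, y, span=span)
    above = smooth > thr
    for k in range(len(y) - persist + 1):
        if above[k:k + persist].all():
            return float(times[k])
    return None


@dataclass
class AlignedEnsemble:
    """Traces re-indexed to a shared event time 0.

    ``values`` is (n_cells, n_grid) with NaN where a cell has no frame;
    mean/SD are reported only where at least two cells contribute.
    """

    grid_min: np.ndarray
    values: np.ndarray
    cell_ids: list[int]

    @property
    def n(self) -> np.ndarray:
        return np.sum(np.isfinite(self.values), axis=0)

    @property
    def mean(self) -> np.ndarray:
        out = np.full(self.grid_min.shape, np.nan)
        ok = self.n >= 1
        with np.errstate(invalid="ignore"):
            out[ok] = np.nanmean(self.values[:, ok], axis=0)
        return out

    @property
    def sd(self) -> np.ndarray:
        """Sample SD where >= 2 cells contribute; 0 where exactly one does
        (a single trace is its own ensemble), NaN where none does."""
        out = np.full(self.grid_min.shape, np.nan)
        one = self.n == 1
        out[one] = 0.0
        ok = self.n >= 2
        with np.errstate(invalid="ignore"):
            out[ok] = np.nanstd(self.values[:, ok], axis=0, ddof=1)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"t_rel_min": self.grid_min, "mean": self.mean,
                             "sd": self.sd, "n": self.n})


def align_and_pool(traces: list[tuple[np.ndarray, np.ndarray]],
                   anchors: list[float],
                   cell_ids: list[int] | None = None) -> AlignedEnsemble:
    """Shift each (times, values) trace so its anchor event is time 0 and
    pool on the shared acquisition grid.

    All traces must share one frame interval (no interpolation across
    cells); relative times are snapped to that grid. Cells lacking an
    anchor must be excluded by the caller.
    """
    if not traces:
        raise ValueError("no traces to pool")
    if len(anchors) != len(traces):
        raise ValueError("one anchor per trace required")
    if cell_ids is None:
        cell_ids = list(range(len(traces)))
    dts = []
    for times, _ in traces:
        d = np.diff(np.asarray(times, dtype=float))
        if d.size:
            dts.append(np.median(d))
    dt = dts[0]
    if any(abs(x - dt) > 1e-6 for x in dts):
        raise ValueError(f"mixed frame intervals in one pool: {sorted(set(dts))}")

    rel_idx = []
    for (times, values), anchor in zip(traces, anchors):
        if anchor is None or not np.isfinite(anchor):
            raise ValueError("every pooled cell needs a finite anchor time")
        idx = np.round((np.asarray(times, dtype=float) - anchor) / dt).astype(int)
        rel_idx.append(idx)
    lo = min(int(i.min()) for i in rel_idx)
    hi = max(int(i.max()) for i in rel_idx)
    grid = np.arange(lo, hi + 1) * dt
    mat = np.full((len(traces), grid.size), np.nan)
    for row, ((times, values), idx) in enumerate(zip(traces, rel_idx)):
        mat[row, idx - lo] = np.asarray(values, dtype=float)
    return AlignedEnsemble(grid_min=grid, values=mat, cell_ids=list(cell_ids))


def build_event_table(cell_ids, anaphase, spb_separation=None,
                      plo1_onset=None, division=None) -> pd.DataFrame:
    """Tidy per-cell event table; missing events are NaN."""
    n = len(cell_ids)

    def col(v):
        if v is None:
            return [np.nan] * n
        return [np.nan if x is None else float(x) for x in v]

    df = pd.DataFrame({
        "cell_id": list(cell_ids),
        "anaphase_time": col(anaphase),
        "spb_separation_time": col(spb_separation),
        "plo1_onset_time": col(plo1_onset),
        "division_time": col(division),
    })
    bad = df.dropna(subset=["anaphase_time", "spb_separation_time"])
    viol = bad[bad.spb_separation_time >= bad.anaphase_time]
    for cid in viol.cell_id:
        log.warning("cell %s: SPB separation not before anaphase", cid)
    return df
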