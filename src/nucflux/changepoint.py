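"""Change-point estimation of export onset/stop from single-cell traces.

The switch-like transitions in nuclear reporter concentration are
formalized as a continuous piecewise-linear model

    y(t) = b0 + b1*t + sum_k  g_k * max(t - tau_k, 0) + eps,

fitted by exhaustive search over breakpoint locations on the frame grid
with ordinary least squares for each candidate; the global RSS minimizer is
returned, ties broken toward earlier breakpoints. For an exporting trace
fitted with two breakpoints over the pre-anaphase window, the first
breakpoint is the export onset and the second the export stop, and the
middle segment must have the lowest slope (nuclear signal falls during
export).

Transition sharpness is quantified separately: a logistic blend of the two
adjoining line segments is fitted locally around a breakpoint and the
10-90% width of the blend weight reported, operationalizing "the transition
happens within about a minute".
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .loess import loess_smooth

log = logging.getLogger(__name__)

__all__ = [
    "PiecewiseLinearModel", "PiecewiseLinearResults",
    "fit_piecewise_linear", "estimate_export_window", "ExportWindow",
    "transition_width",
]

_LN81 = 2.0 * math.log(9.0)


class PiecewiseLinearModel:
    """Continuous piecewise-linear model for a single-cell trace.

    Parameters
    ----------
    times, values : 1-D arrays, strictly increasing times.
    n_breakpoints : number of slope changes to fit (1-3).
    """

    def __init__(self, times, values, n_breakpoints: int = 2):
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise ValueError("times and values must be matched 1-D arrays")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if n_breakpoints not in (1, 2, 3):
            raise ValueError("n_breakpoints must be 1, 2 or 3")
        n_min = 4 + 2 * n_breakpoints
        if self.times.size < n_min:
            raise ValueError(f"need at least {n_min} points for "
                             f"{n_breakpoints} breakpoints")
        if np.ptp(self.values) == 0:
            raise ValueError("constant trace: breakpoints are unidentifiable")
        self.n_breakpoints = n_breakpoints

    @staticmethod
    def design(times: np.ndarray, breakpoints) -> np.ndarray:
        cols = [np.ones_like(times), times]
        for b in breakpoints:
            cols.append(np.maximum(times - b, 0.0))
        return np.column_stack(cols)

    def _rss(self, breakpoints) -> tuple[float, np.ndarray]:
        X = self.design(self.times, breakpoints)
        g = X.T @ X
        try:
            beta = np.linalg.solve(g, X.T @ self.values)
        except np.linalg.LinAlgError:
            beta, *_ = np.linalg.lstsq(X, self.values, rcond=None)
        resid = self.values - X @ beta
        return float(resid @ resid), beta

    def fit(self, min_segment_points: int = 2) -> "PiecewiseLinearResults":
        """Exhaustive search over breakpoint tuples on the frame grid."""
        n = self.times.size
        k = self.n_breakpoints
        m = max(min_segment_points, 2)
        candidates = range(m, n - m + 1)
        best = None
        for combo in itertools.combinations(candidates, k):
            if any(b - a < m for a, b in zip(combo, combo[1:])):
                continue
            bps = self.times[list(combo)]
            rss, beta = self._rss(bps)
            if best is None or rss < best[0] - 1e-12:
                best = (rss, beta, bps)
        if best is None:
            raise ValueError("no admissible breakpoint placement")
        rss, beta, bps = best
        return PiecewiseLinearResults(model=self, breakpoints=np.asarray(bps),
                                      params=beta, rss=rss)


@dataclass
class PiecewiseLinearResults:
    """Fitted breakpoints, segment slopes and diagnostics."""

    model: PiecewiseLinearModel = field(repr=False)
    breakpoints: np.ndarray
    params: np.ndarray
    rss: float

    @property
    def slopes(self) -> np.ndarray:
        """Slope of each of the k+1 segments, left to right."""
        return self.params[1] + np.concatenate([[0.0],
                                                np.cumsum(self.params[2:])])

    @property
    def fittedvalues(self) -> np.ndarray:
        X = PiecewiseLinearModel.design(self.model.times, self.breakpoints)
        return X @ self.params

    @property
    def df_resid(self) -> int:
        return self.model.times.size - len(self.params) - len(self.breakpoints)

    def predict(self, times) -> np.ndarray:
        X = PiecewiseLinearModel.design(np.asarray(times, dtype=float),
                                        self.breakpoints)
        return X @ self.params

    def summary(self) -> str:
        lines = ["Continuous piecewise-linear fit",
                 f"  points:          {self.model.times.size}",
                 f"  breakpoints:     "
                 + ", ".join(f"{b:.3f} min" for b in self.breakpoints),
                 f"  segment slopes:  "
                 + ", ".join(f"{s:.4g}" for s in self.slopes) + " a.u./min",
                 f"  RSS:             {self.rss:.6g}",
                 f"  resid df:        {self.df_resid}"]
        return "\n".join(lines)


def fit_piecewise_linear(times, values, n_breakpoints: int = 2,
                         min_segment_points: int = 2) -> PiecewiseLinearResults:
    """Convenience wrapper: build the model and fit it."""
    return PiecewiseLinearModel(times, values, n_breakpoints).fit(
        min_segment_points)


@dataclass
class ExportWindow:
    """Export onset/stop of one cell, as positive minutes before anaphase."""

    cell_id: int
    onset_before_anaphase_min: float | None
    stop_before_anaphase_min: float | None
    flagged: bool
    fit: PiecewiseLinearResults | None = field(repr=False, default=None)

    @property
    def window_min(self) -> float | None:
        if self.flagged:
            return None
        return self.onset_before_anaphase_min - self.stop_before_anaphase_min


def estimate_export_window(times, values, anaphase_time: float,
                           window_min: float = 25.0, smooth: bool = True,
                           span: float = 0.3, cell_id: int = 0,
                           min_segment_points: int = 2) -> ExportWindow:
    """Two-breakpoint fit of a nuclear-concentration trace before anaphase.

    Only the window ``[anaphase - window_min, anaphase]`` enters the fit,
    which excludes the post-anaphase degradation phase. The trace is
    loess-smoothed by default before fitting (raw fitting via
    ``smooth=False``). Cells whose fit violates the export shape (middle
    segment not the steepest decline) are flagged.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    sel = (times >= anaphase_time - window_min - 1e-9) & \
          (times <= anaphase_time + 1e-9) & np.isfinite(values)
    t = times[sel]
    y = values[sel]
    if t.size < 8:
        raise ValueError("trace does not cover the pre-anaphase window")
    if smooth:
        y = loess_smooth(t, y, span=span)
    try:
        res = fit_piecewise_linear(t, y, n_breakpoints=2,
                                   min_segment_points=min_segment_points)
    except ValueError as exc:
        log.warning("cell %s: export-window fit failed (%s)", cell_id, exc)
        return ExportWindow(cell_id, None, None, True, None)
    s1, s2, s3 = res.slopes
    ok = s2 < s1 and s2 < s3 and s2 < 0
    if not ok:
        log.info("cell %s flagged: middle segment not a decline "
                 "(slopes %.3g, %.3g, %.3g)", cell_id, s1, s2, s3)
        return ExportWindow(cell_id, None, None, True, res)
    onset = anaphase_time - res.breakpoints[0]
    stop = anaphase_time - res.breakpoints[1]
    return ExportWindow(cell_id, float(onset), float(stop), False, res)


def transition_width(times, values, breakpoint: float,
                     halfwindow_min: float = 3.0) -> float | None:
    """10-90% width (min) of the logistic blend joining the two line
    segments adjoining a breakpoint.

    The local model blends the *slopes* of the two segments with a logistic
    weight s centred at t0 — equivalently y is a softplus-smoothed corner,

        y(t) = y0 + b_left (t - t0) + (b_right - b_left) tau softplus((t-t0)/tau),

    so s is exactly the slope-mixing weight and the reported width (the
    time for s to go 0.1 -> 0.9, = 2 ln 9 tau) measures how fast the slope
    switches — the quantity the sharp-transition claim is about. Fitted to
    the raw trace within ``±halfwindow_min`` of the breakpoint; returns
    None when no start converges.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    sel = np.abs(times - breakpoint) <= halfwindow_min + 1e-9
    t = times[sel]
    y = values[sel]
    if t.size < 8:
        raise ValueError("need at least 8 points within the local window")

    def blend(tt, y0, b_left, b_right, t0, tau):
        x = (tt - t0) / tau
        return (y0 + b_left * (tt - t0)
                + (b_right - b_left) * tau * np.logaddexp(0.0, x))

    left = t < breakpoint
    right = ~left
    b_l = (np.polyfit(t[left], y[left], 1)[0] if left.sum() >= 2 else 0.0)
    b_r = (np.polyfit(t[right], y[right], 1)[0] if right.sum() >= 2 else 0.0)
    y0 = float(np.interp(breakpoint, t, y))
    dt = float(np.median(np.diff(t)))
    lo = [-np.inf, -np.inf, -np.inf, breakpoint - 1.0, 1e-4]
    hi = [np.inf, np.inf, np.inf, breakpoint + 1.0, 5.0]
    # multi-start over initial widths: the SSE surface has local minima in
    # tau (a sharp corner can shadow a wide blend and vice versa)
    best = None
    for w0 in (dt / 2, 0.5, 1.0, 2.0, 4.0):
        p0 = [y0, b_l, b_r, breakpoint, w0 / _LN81]
        try:
            popt, _ = curve_fit(blend, t, y, p0=p0, bounds=(lo, hi),
                                maxfev=20000)
        except (RuntimeError, ValueError):
            continue
        sse = float(np.sum((blend(t, *popt) - y) ** 2))
        if best is None or sse < best[0]:
            best = (sse, popt)
    if best is None:
        log.warning("transition-width fit did not converge")
        return None
    return float(_LN81 * best[1][4])
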