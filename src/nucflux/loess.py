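"""Locally weighted polynomial regression (loess) with tricube weights.

Matches the R ``loess`` convention used for trace smoothing in this
pipeline: degree-2 local fits over the ``span`` fraction of nearest points,
tricube distance weights, evaluated at the observed abscissae. Default span
0.3. When a window holds too few distinct points for a quadratic fit the
local degree is reduced to 1 with a warning.
"""

from __future__ import annotations

import logging

import numpy as np

log = logging.getLogger(__name__)

__all__ = ["loess_smooth"]


def _local_fit(x, y, w, x0, degree):
    # centred design for conditioning
    xc = x - x0
    cols = [np.ones_like(xc)]
    for d in range(1, degree + 1):
        cols.append(xc ** d)
    X = np.column_stack(cols)
    sw = np.sqrt(w)
    beta, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
    return beta[0]


def loess_smooth(t: np.ndarray, y: np.ndarray, span: float = 0.3,
                 degree: int = 2) -> np.ndarray:
    """Smooth ``y(t)`` by local weighted polynomial regression.

    Parameters
    ----------
    t, y : 1-D arrays of equal length (``t`` strictly increasing).
    span : fraction of points in each local window, in (0, 1].
    degree : local polynomial degree (2 by default).
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("t and y must be 1-D arrays of equal length")
    n = t.size
    if n < 5:
        raise ValueError("need at least 5 points")
    if not 0 < span <= 1:
        raise ValueError("span must lie in (0, 1]")
    q = max(int(np.ceil(span * n)), degree + 2)
    q = min(q, n)
    out = np.empty(n)
    for i in range(n):
        d = np.abs(t - t[i])
        order = np.argsort(d, kind="stable")
        idx = order[:q]
        dmax = d[idx].max()
        if dmax == 0:
            out[i] = y[idx].mean()
            continue
        w = (1.0 - (d[idx] / dmax) ** 3) ** 3
        w = np.clip(w, 0.0, None)
        pos = w > 0
        deg = degree
        if pos.sum() < degree + 1:
            deg = 1
            log.warning("loess window at t=%g too small for degree %d; "
                        "reduced to linear", t[i], degree)
        out[i] = _local_fit(t[idx][pos], y[idx][pos], w[pos], t[i], deg)
    return out
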