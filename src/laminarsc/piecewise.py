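"""Two-segment ("hinge point") piecewise linear regression.

The hinge point of a waveform is the time at which its rate of change
deviates from the current trend.  It is located by an exhaustive search
over candidate breakpoints: at each candidate a broken-stick model — two
lines constrained to meet at the breakpoint — is fit by least squares, and
the breakpoint minimizing the total sum of squared residuals is returned.
Ties resolve to the earliest breakpoint.  An unconstrained variant (two
independent lines sharing only the breakpoint sample) is available via
``continuous=False``; the continuous form is the default because a hinge is
a connected joint and the unconstrained fit degenerates on windows whose
structure is weak (any split of a flat stretch fits equally well).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PiecewiseFit", "two_piecewise_fit"]

MIN_SEGMENT_POINTS = 3


@dataclass
class PiecewiseFit:
    breakpoint: float
    left_slope: float
    left_intercept: float
    right_slope: float
    right_intercept: float
    sse: float
    continuous: bool = True


def _line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)


def _segment_sse(sx, sy, sxx, sxy, syy, n):
    """SSE of the least-squares line through a segment, from raw sums."""
    with np.errstate(invalid="ignore", divide="ignore"):
        sxx_c = sxx - sx * sx / n
        sxy_c = sxy - sx * sy / n
        syy_c = syy - sy * sy / n
        sse = syy_c - np.where(
            sxx_c > 0, sxy_c**2 / np.where(sxx_c > 0, sxx_c, 1.0), 0.0
        )
    return np.maximum(sse, 0.0)


def _independent_sse(x, y, ks):
    n = x.size
    cx = np.concatenate([[0.0], np.cumsum(x)])
    cy = np.concatenate([[0.0], np.cumsum(y)])
    cxx = np.concatenate([[0.0], np.cumsum(x * x)])
    cxy = np.concatenate([[0.0], np.cumsum(x * y)])
    cyy = np.concatenate([[0.0], np.cumsum(y * y)])
    nl = (ks + 1).astype(float)
    sse_l = _segment_sse(cx[ks + 1], cy[ks + 1], cxx[ks + 1], cxy[ks + 1],
                         cyy[ks + 1], nl)
    nr = (n - ks).astype(float)
    sse_r = _segment_sse(cx[n] - cx[ks], cy[n] - cy[ks], cxx[n] - cxx[ks],
                         cxy[n] - cxy[ks], cyy[n] - cyy[ks], nr)
    return sse_l + sse_r


def _continuous_sse(x, y, ks):
    """Batch SSE of the broken-stick model y = a + b x + c (x - x_k)+."""
    n = x.size
    # suffix sums over the strict right side (v = x - x_k positive there)
    def suffix(arr):
        c = np.concatenate([np.cumsum(arr[::-1])[::-1], [0.0]])
        return c
    sx_r = suffix(x)[ks + 1]
    sxx_r = suffix(x * x)[ks + 1]
    sy_r = suffix(y)[ks + 1]
    sxy_r = suffix(x * y)[ks + 1]
    n_r = (n - ks - 1).astype(float)
    xk = x[ks]

    sv = sx_r - n_r * xk
    svv = sxx_r - 2 * xk * sx_r + n_r * xk**2
    suv = sxx_r - xk * sx_r
    svy = sxy_r - xk * sy_r

    su = x.sum()
    suu = (x * x).sum()
    sy = y.sum()
    suy = (x * y).sum()
    syy = (y * y).sum()

    K = ks.size
    A = np.empty((K, 3, 3))
    A[:, 0, 0] = n
    A[:, 0, 1] = A[:, 1, 0] = su
    A[:, 0, 2] = A[:, 2, 0] = sv
    A[:, 1, 1] = suu
    A[:, 1, 2] = A[:, 2, 1] = suv
    A[:, 2, 2] = svv
    r = np.empty((K, 3))
    r[:, 0] = sy
    r[:, 1] = suy
    r[:, 2] = svy
    beta = np.linalg.solve(A, r[..., None])[..., 0]
    sse = syy - np.einsum("ki,ki->k", beta, r)
    return np.maximum(sse, 0.0), beta


def two_piecewise_fit(
    x: np.ndarray,
    y: np.ndarray,
    search_range: tuple[float, float] | None = None,
    *,
    min_points: int = MIN_SEGMENT_POINTS,
    continuous: bool = True,
) -> PiecewiseFit:
    """Exhaustive breakpoint search minimizing the summed residuals.

    Parameters
    ----------
    x, y
        Sample coordinates; ``x`` must be strictly increasing.
    search_range
        Optional ``(lo, hi)`` restriction on candidate breakpoints (x units).
    min_points
        Minimum samples per segment (the breakpoint sample counts for both).
    continuous
        Constrain the two lines to meet at the breakpoint (default); set
        False for two fully independent segment fits.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size:
        raise ValueError("x and y must have equal length")
    if n < 2 * min_points - 1:
        raise ValueError(
            f"need at least {2 * min_points - 1} points for two segments of "
            f"{min_points} points sharing the breakpoint"
        )

    ks = np.arange(min_points - 1, n - min_points + 1)
    if search_range is not None:
        lo, hi = search_range
        ks = ks[(x[ks] >= lo) & (x[ks] <= hi)]
        if ks.size == 0:
            raise ValueError("no admissible breakpoints in search_range")

    if continuous:
        total, betas = _continuous_sse(x, y, ks)
    else:
        total = _independent_sse(x, y, ks)

    best = total.min()
    pos = int(np.flatnonzero(total <= best + 1e-9 * max(1.0, abs(best)))[0])
    k = int(ks[pos])

    if continuous:
        a, b, c = betas[pos]
        fit = PiecewiseFit(
            breakpoint=float(x[k]),
            left_slope=float(b),
            left_intercept=float(a),
            right_slope=float(b + c),
            right_intercept=float(a - c * x[k]),
            sse=float(total[pos]),
            continuous=True,
        )
    else:
        ls, li = _line(x[: k + 1], y[: k + 1])
        rs, ri = _line(x[k:], y[k:])
        fit = PiecewiseFit(
            breakpoint=float(x[k]), left_slope=ls, left_intercept=li,
            right_slope=rs, right_intercept=ri, sse=float(total[pos]),
            continuous=False,
        )
    return fit
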