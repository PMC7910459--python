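"""Local polynomial regression (LOESS) with tricube weights.

Classic Cleveland-style local regression: for each evaluation point the
nearest ``ceil(span * n)`` observations are weighted by the tricube kernel
of their scaled distance and a degree-1 or degree-2 weighted polynomial is
fitted; optional bisquare robustifying iterations down-weight outliers.

The fit is evaluated on a grid of points spanning the data (every point for
small inputs, quantile-spaced for large ones) and queried by linear
interpolation, with linear extension beyond the fitted range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["LoessFit", "fit_population_loess", "LoessError"]


class LoessError(ValueError):
    pass


@dataclass
class LoessFit:
    """Evaluable fitted curve: linear interpolation between grid points,
    linear extension beyond [x_min, x_max]."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    span: float
    degree: int
    method: str  # "loess" | "ols"

    def __call__(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        gx, gy = self.grid_x, self.grid_y
        y = np.interp(x, gx, gy)
        if len(gx) >= 2:
            lo_slope = (gy[1] - gy[0]) / (gx[1] - gx[0])
            hi_slope = (gy[-1] - gy[-2]) / (gx[-1] - gx[-2])
            below = x < gx[0]
            above = x > gx[-1]
            y = np.where(below, gy[0] + (x - gx[0]) * lo_slope, y)
            y = np.where(above, gy[-1] + (x - gx[-1]) * hi_slope, y)
        return y


def _tricube(u: np.ndarray) -> np.ndarray:
    w = np.clip(1.0 - np.abs(u) ** 3, 0.0, None)
    return w ** 3


def _local_fit(x, y, w_robust, x0, q, degree):
    """Weighted polynomial fit of the q nearest points, evaluated at x0."""
    d = np.abs(x - x0)
    idx = np.argpartition(d, q - 1)[:q]
    xi, yi, di = x[idx], y[idx], d[idx]
    dmax = di.max()
    if dmax == 0:
        # all selected points coincide with x0
        return np.average(yi, weights=w_robust[idx]) \
            if w_robust[idx].sum() > 0 else yi.mean()
    w = _tricube(di / dmax) * w_robust[idx]
    if w.sum() <= 0:
        w = _tricube(di / dmax)
    xc = xi - x0  # center for conditioning; intercept is the fit at x0
    X = np.vander(xc, degree + 1, increasing=True)
    WX = X * w[:, None]
    beta, *_ = np.linalg.lstsq(WX.T @ X, WX.T @ yi, rcond=None)
    return beta[0]


def _loess_grid(x, y, span, degree, robust_iters, max_grid):
    n = len(x)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    q = max(int(np.ceil(span * n)), degree + 1)
    q = min(q, n)

    if n <= max_grid:
        grid = np.unique(xs)
    else:
        qs = np.linspace(0, 1, max_grid)
        grid = np.unique(np.quantile(xs, qs))

    w_robust = np.ones(n)
    fitted_grid = np.empty_like(grid)
    for it in range(robust_iters + 1):
        for i, g in enumerate(grid):
            fitted_grid[i] = _local_fit(xs, ys, w_robust, g, q, degree)
        if it == robust_iters:
            break
        fit_at_data = np.interp(xs, grid, fitted_grid)
        resid = ys - fit_at_data
        s = np.median(np.abs(resid))
        if s <= 0:
            break
        u = resid / (6.0 * s)
        w_robust = np.clip(1.0 - u ** 2, 0.0, None) ** 2
        if w_robust.sum() == 0:
            w_robust = np.ones(n)
            break
    return grid, fitted_grid


def fit_population_loess(expected, observed, span: float = 0.75,
                         degree: int = 2, robust_iters: int = 3,
                         max_grid: int = 200,
                         min_points: int = 30) -> LoessFit:
    """Model observed vs expected log2FC for one comparison's population.

    With fewer than ``min_points`` observations a plain least-squares line
    is fitted instead (with a warning); identical x throughout is a
    degenerate design and raises.
    """
    x = np.asarray(expected, dtype=float)
    y = np.asarray(observed, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise LoessError("expected and observed must be equal-length 1-D")
    if not (0 < span <= 1):
        raise LoessError("span must lie in (0, 1]")
    if degree not in (1, 2):
        raise LoessError("degree must be 1 or 2")
    if np.ptp(x) == 0:
        raise LoessError("degenerate design: all expected values identical")

    if len(x) < min_points:
        warnings.warn(
            f"only {len(x)} points; falling back to a least-squares line",
            stacklevel=2)
        slope, intercept = np.polyfit(x, y, 1)
        gx = np.array([x.min(), x.max()])
        return LoessFit(gx, intercept + slope * gx, span, degree, "ols")

    grid, fitted = _loess_grid(x, y, span, degree, robust_iters, max_grid)
    if len(grid) == 1:  # cannot happen with ptp>0, but keep interp safe
        grid = np.array([grid[0], grid[0] + 1e-9])
        fitted = np.array([fitted[0], fitted[0]])
    return LoessFit(grid, fitted, span, degree, "loess")
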