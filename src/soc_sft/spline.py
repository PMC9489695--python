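"""Equal-area (mass-preserving) smoothing spline over soil depth.

Soil laboratories report one value per sampled depth interval (a layer mean),
not a continuous function of depth.  To compare profiles sampled on different
layer schemes, a smooth function f(z) is fitted whose *mean over each observed
layer* reproduces the reported layer value, and that function is then averaged
over a set of standard depth intervals.

The fit solves the discretized variational problem

    minimize  sum_i  d_i * (y_i - mean(f over layer i))^2  +  lam * int f'(z)^2 dz

over piecewise-constant f on a fine depth grid, where d_i is the thickness of
layer i and lam controls smoothness.  Weighting the fidelity term by thickness
makes the optimum conserve the total observed mass exactly: the stationarity
condition along a constant shift of f is sum_i d_i (y_i - fbar_i) = 0.

The solution is linear in the layer values, so the whole fit is a single
matrix applied to y; that matrix depends only on the layer boundaries and is
cached, which makes harmonizing thousands of identically-structured profiles
cheap.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

__all__ = ["DepthSpline", "DEFAULT_LAMBDA", "DEFAULT_RESOLUTION"]

DEFAULT_LAMBDA = 0.1
DEFAULT_RESOLUTION = 0.01  # grid cell height, m


@lru_cache(maxsize=256)
def _solve_operator(
    bounds: tuple[tuple[float, float], ...], lam: float, resolution: float
) -> tuple[np.ndarray, float, float]:
    """Matrix M with f_grid = M @ y, plus the grid span (z0, z1)."""
    tops = np.array([b[0] for b in bounds])
    bots = np.array([b[1] for b in bounds])
    z0, z1 = float(tops.min()), float(bots.max())
    n_cells = max(int(round((z1 - z0) / resolution)), 2)
    h = (z1 - z0) / n_cells
    edges = z0 + h * np.arange(n_cells + 1)

    # averaging operator: row i = fraction of layer i inside each grid cell
    A = np.zeros((len(bounds), n_cells))
    for i, (t, b) in enumerate(zip(tops, bots)):
        overlap = np.minimum(edges[1:], b) - np.maximum(edges[:-1], t)
        A[i] = np.clip(overlap, 0.0, None) / (b - t)

    thick = (bots - tops) / np.mean(bots - tops)  # relative fidelity weights
    W = A.T * thick  # A^T diag(d)
    # first-difference penalty lam * int f'^2 dz with depth z in cm (the depth
    # scale on which lam is conventionally quoted); h is in m, hence the /100.
    D = np.diff(np.eye(n_cells), axis=0)
    P = (lam / (100.0 * h)) * (D.T @ D)
    M = np.linalg.solve(W @ A + P, W)
    return M, z0, z1


class DepthSpline:
    """Mass-preserving spline fitted to one profile's layer means.

    Parameters
    ----------
    boundaries : sequence of (top, bottom) in m, positive downward, sorted,
        non-overlapping.
    values : layer means (one per boundary pair), e.g. SOC content in g/kg.
    lam : smoothing parameter (>0), quoted on the centimetre depth scale as is
        conventional for this spline family; small values track the layer
        means closely, large values flatten the profile.
    resolution : depth-grid cell height in m.
    """

    def __init__(self, boundaries, values, lam=DEFAULT_LAMBDA, resolution=DEFAULT_RESOLUTION):
        boundaries = [(float(t), float(b)) for t, b in boundaries]
        values = np.asarray(values, dtype=float)
        if len(boundaries) != len(values) or len(values) == 0:
            raise ValueError("need one value per layer and at least one layer")
        if lam <= 0:
            raise ValueError("lam must be positive")
        for t, b in boundaries:
            if not 0 <= t < b:
                raise ValueError(f"bad layer bounds ({t}, {b})")
        if np.any(~np.isfinite(values)):
            raise ValueError("layer values must be finite")
        self.boundaries = boundaries
        self.values = values
        M, z0, z1 = _solve_operator(tuple(boundaries), float(lam), float(resolution))
        self.grid = M @ values
        self.z0, self.z1 = z0, z1
        self._h = (z1 - z0) / len(self.grid)

    def mean(self, top: float, bottom: float) -> float:
        """Mean of the fitted function over [top, bottom] ∩ observed span.

        Returns NaN when the interval does not overlap the observed span; no
        extrapolation above the shallowest or below the deepest observed depth.
        """
        lo, hi = max(top, self.z0), min(bottom, self.z1)
        if hi - lo <= 1e-12:
            return float("nan")
        edges = self.z0 + self._h * np.arange(len(self.grid) + 1)
        overlap = np.clip(np.minimum(edges[1:], hi) - np.maximum(edges[:-1], lo), 0.0, None)
        return float(np.dot(overlap, self.grid) / overlap.sum())

    def covers(self, top: float, bottom: float, slack: float = 1e-9) -> bool:
        """Whether the observed span fully contains [top, bottom]."""
        return self.z0 <= top + slack and self.z1 >= bottom - slack

    def layer_means(self) -> np.ndarray:
        """Fitted means over the original observed layers."""
        return np.array([self.mean(t, b) for t, b in self.boundaries])
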