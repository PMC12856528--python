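"""Turnpoint detection and cohort-level 2D kernel-density clustering of extrema.

Turnpoints are the interior local maxima and minima of a (smoothed,
inverted) depth profile, found as strict sign changes of the first
differences; plateaus collapse to a single extremum at the run midpoint,
ties rounding medially.  Pooled across a cohort, the extrema form clusters
in (position, depth) space which are summarized with a product-Gaussian
kernel density estimate on a 100 x 100 grid spanning the outermost extrema,
per-axis bandwidths by the normal-reference rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profiles import DepthProfile

__all__ = [
    "Extremum",
    "DensityGrid",
    "DensitySummary",
    "find_turnpoints",
    "kde2d_extrema",
    "density_summary",
    "nrd_bandwidth",
]


@dataclass(frozen=True)
class Extremum:
    position: int
    depth: float
    kind: str  # "maximum" | "minimum"
    is_global_minimum: bool = False


def find_turnpoints(profile: DepthProfile) -> list[Extremum]:
    """Extract all interior local maxima and minima of a profile.

    A point is a turnpoint when its nearest unequal neighbours on both sides
    lie on the same side of it (both below for a maximum, both above for a
    minimum).  Runs of equal values count once, at the run midpoint with
    half-positions rounded toward the medial end.  Maxima and minima
    alternate by construction; the deepest minimum is flagged as the global
    minimum (ties broken medially).
    """
    if not profile.smoothed:
        raise ValueError("find_turnpoints expects a smoothed profile")
    return _turnpoints_of(profile.depths)


def _turnpoints_of(y: np.ndarray) -> list[Extremum]:
    y = np.asarray(y, dtype=float)
    n = y.size
    if n < 3:
        raise ValueError("need at least 3 points to define a turnpoint")
    # collapse plateaus: indices of run starts, runs of equal consecutive values
    starts = np.flatnonzero(np.concatenate(([True], np.diff(y) != 0.0)))
    vals = y[starts]
    ends = np.concatenate((starts[1:] - 1, [n - 1]))
    out: list[Extremum] = []
    for j in range(1, len(vals) - 1):
        left, right = vals[j - 1], vals[j + 1]
        if vals[j] > left and vals[j] > right:
            kind = "maximum"
        elif vals[j] < left and vals[j] < right:
            kind = "minimum"
        else:
            continue
        # run midpoint, half-positions rounded medially
        pos = int((starts[j] + ends[j]) // 2)
        out.append(Extremum(position=pos, depth=float(vals[j]), kind=kind))
    minima = [e for e in out if e.kind == "minimum"]
    if minima:
        gmin = min(minima, key=lambda e: (e.depth, e.position))
        out = [
            Extremum(e.position, e.depth, e.kind, is_global_minimum=(e is gmin))
            for e in out
        ]
    return out


def nrd_bandwidth(v: np.ndarray) -> float:
    """Normal-reference bandwidth 4 * 1.06 * min(sd, IQR/1.34) * n^(-1/5).

    This is the full-width convention of the classic 2D KDE implementation,
    which the estimator divides by 4 to obtain the Gaussian kernel sd.
    """
    v = np.asarray(v, dtype=float)
    sd = float(np.std(v, ddof=1))
    q1, q3 = np.percentile(v, [25.0, 75.0])
    spread = min(sd, (q3 - q1) / 1.34)
    if spread <= 0:
        raise ValueError("zero spread on an axis; KDE bandwidth undefined")
    return 4.0 * 1.06 * spread * v.size ** (-0.2)


@dataclass
class DensityGrid:
    """100 x 100 KDE of pooled extrema in (position, depth) space."""

    x: np.ndarray  # grid positions, length grid_n
    y: np.ndarray  # grid depths, length grid_n
    density: np.ndarray  # (grid_n, grid_n), indexed [ix, iy]
    bandwidths: tuple[float, float]  # Gaussian kernel sds (position, depth)
    n_points: int

    @property
    def cell_area(self) -> float:
        return float((self.x[1] - self.x[0]) * (self.y[1] - self.y[0]))

    def total_mass(self) -> float:
        return float(self.density.sum() * self.cell_area)


def kde2d_extrema(
    positions: np.ndarray,
    depths: np.ndarray,
    grid_n: int = 100,
    h: tuple[float, float] | None = None,
) -> DensityGrid:
    """Product-Gaussian KDE of extrema on a square grid spanning the data.

    Grid bounds are the outermost extrema values (closed interval).  ``h``
    overrides the per-axis bandwidths in the conventional full-width sense
    (the Gaussian kernel sd is ``h/4``); by default the normal-reference
    rule supplies them.  Requires at least two points and nonzero spread on
    both axes.
    """
    px = np.asarray(positions, dtype=float)
    py = np.asarray(depths, dtype=float)
    if px.size != py.size or px.size < 2:
        raise ValueError("need >= 2 pooled extrema")
    if np.ptp(px) == 0 or np.ptp(py) == 0:
        raise ValueError("zero spread on an axis; cannot estimate a 2D density")
    if h is not None:
        if h[0] <= 0 or h[1] <= 0:
            raise ValueError("bandwidths must be positive")
        hx, hy = h[0] / 4.0, h[1] / 4.0
    else:
        hx = nrd_bandwidth(px) / 4.0
        hy = nrd_bandwidth(py) / 4.0
    gx = np.linspace(px.min(), px.max(), grid_n)
    gy = np.linspace(py.min(), py.max(), grid_n)
    zx = _gauss(gx[:, None], px[None, :], hx)
    zy = _gauss(gy[:, None], py[None, :], hy)
    dens = zx @ zy.T / px.size
    return DensityGrid(x=gx, y=gy, density=dens, bandwidths=(hx, hy), n_points=px.size)


def _gauss(g: np.ndarray, p: np.ndarray, h: float) -> np.ndarray:
    return np.exp(-0.5 * ((g - p) / h) ** 2) / (h * np.sqrt(2.0 * np.pi))


@dataclass(frozen=True)
class DensitySummary:
    peak_position: float
    peak_depth: float
    peak_density: float
    level: float
    position_range: tuple[float, float] | None  # None when level exceeds the peak
    depth_range: tuple[float, float] | None


def density_summary(grid: DensityGrid, level: float) -> DensitySummary:
    """Peak cell and the bounding box of all cells with density >= level."""
    if level < 0:
        raise ValueError("level must be >= 0")
    flat = int(np.argmax(grid.density))
    ix, iy = np.unravel_index(flat, grid.density.shape)
    mask = grid.density >= level
    if mask.any():
        xs = grid.x[mask.any(axis=1)]
        ys = grid.y[mask.any(axis=0)]
        pos_range = (float(xs.min()), float(xs.max()))
        depth_range = (float(ys.min()), float(ys.max()))
    else:
        pos_range = depth_range = None
    return DensitySummary(
        peak_position=float(grid.x[ix]),
        peak_depth=float(grid.y[iy]),
        peak_density=float(grid.density[ix, iy]),
        level=float(level),
        position_range=pos_range,
        depth_range=depth_range,
    )
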