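"""2D event-density estimation and highest-density-region contours.

The gate geometry is derived from contour lines of the event density on the
(fluorescence, back-scatter) plane. Density is a smoothed 2D histogram
normalised to unit mass; a "contour at mass alpha" is the boundary of the
highest-density region (HDR): the density threshold t is chosen so the cells
with density >= t hold a fraction alpha of total event mass, and the
iso-contours at t are traced with marching squares. This percent-of-mass
semantics is the convention of cytometry contour plots; a percent-of-peak
mode (threshold at a fraction of the density maximum) is available as an
alternative.

Contours that would run off the grid are closed along the boundary (the grid
is padded with a zero-density ring before tracing, so every traced ring is
closed). Holes in an HDR (annular regions) are not modelled: each ring's
enclosed mass is computed independently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path as MplPath
from scipy.ndimage import gaussian_filter
from skimage import measure

from .errors import (
    DegenerateDataError,
    InsufficientEventsError,
    NoContourError,
    ValidationError,
)
from .event_io import AxisMapping, EventTable

#: Gating is refused below this many events — the density estimate (and hence
#: the gate) is unreliable on sparser profiles.
MIN_EVENTS = 100

DEFAULT_GRID_SIZE = 256
DEFAULT_BANDWIDTH = 2.0  # grid cells
MASS_TOLERANCE = 1e-4


@dataclass(frozen=True)
class DensityGrid:
    """Normalised event mass on a rectangular (fluorescence, back-scatter) grid.

    ``mass[i, j]`` is the probability mass of the cell between ``x_edges[i:i+2]``
    and ``y_edges[j:j+2]``; the matrix sums to 1.
    """

    x_edges: np.ndarray
    y_edges: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        if self.mass.shape != (len(self.x_edges) - 1, len(self.y_edges) - 1):
            raise ValidationError("mass shape does not match bin edges")
        if np.any(np.diff(self.x_edges) <= 0) or np.any(np.diff(self.y_edges) <= 0):
            raise ValidationError("bin edges must be strictly increasing")
        if abs(float(self.mass.sum()) - 1.0) > 1e-9:
            raise ValidationError(f"grid mass sums to {self.mass.sum()}, expected 1")
        if np.any(self.mass < 0):
            raise ValidationError("grid mass must be non-negative")

    @property
    def x_centers(self) -> np.ndarray:
        return 0.5 * (self.x_edges[:-1] + self.x_edges[1:])

    @property
    def y_centers(self) -> np.ndarray:
        return 0.5 * (self.y_edges[:-1] + self.y_edges[1:])

    @property
    def cell_size(self) -> tuple[float, float]:
        return (
            float(self.x_edges[1] - self.x_edges[0]),
            float(self.y_edges[1] - self.y_edges[0]),
        )


@dataclass(frozen=True)
class ContourPolygon:
    """One closed iso-contour ring with its enclosed event mass."""

    level_mass: float
    vertices: np.ndarray  # (k, 2) open ring: last vertex connects to first
    enclosed_mass: float

    @property
    def area(self) -> float:
        x, y = self.vertices[:, 0], self.vertices[:, 1]
        return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))

    def bsc_extent(self) -> tuple[float, float]:
        return float(self.vertices[:, 1].min()), float(self.vertices[:, 1].max())

    def fluo_extent(self) -> tuple[float, float]:
        return float(self.vertices[:, 0].min()), float(self.vertices[:, 0].max())


def estimate_density(
    table: EventTable,
    axis: AxisMapping,
    grid_size: int = DEFAULT_GRID_SIZE,
    smoothing_bandwidth: float = DEFAULT_BANDWIDTH,
) -> DensityGrid:
    """Smoothed 2D histogram of the gating axes, normalised to unit mass.

    The grid spans each axis's [min, max] padded by 5% of the span on both
    sides; smoothing is an isotropic Gaussian filter with sigma given in grid
    cells.
    """
    if table.n_events < MIN_EVENTS:
        raise InsufficientEventsError(
            f"{table.sample_id!r}: {table.n_events} events < {MIN_EVENTS} required for gating"
        )
    ix, iy = axis.indices(table)
    x, y = table.values[:, ix], table.values[:, iy]
    edges = []
    for arr, name in ((x, axis.fluorescence_channel), (y, axis.backscatter_channel)):
        lo, hi = float(arr.min()), float(arr.max())
        span = hi - lo
        if span <= 0:
            raise DegenerateDataError(
                f"{table.sample_id!r}: channel {name!r} has zero variance"
            )
        edges.append(np.linspace(lo - 0.05 * span, hi + 0.05 * span, grid_size + 1))
    counts, _, _ = np.histogram2d(x, y, bins=edges)
    if smoothing_bandwidth > 0:
        counts = gaussian_filter(counts, sigma=smoothing_bandwidth, mode="constant")
    return DensityGrid(edges[0], edges[1], counts / counts.sum())


def hdr_threshold(
    grid: DensityGrid, alpha: float, tolerance: float = MASS_TOLERANCE
) -> float:
    """Largest density threshold whose superlevel set holds mass >= alpha.

    Bisection on t: mass_above(t) is a non-increasing step function, so the
    bracket [lo, hi] with mass_above(lo) >= alpha > mass_above(hi) collapses
    onto the step; iteration stops early once within ``tolerance`` of alpha.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    mass = grid.mass

    def mass_above(t: float) -> float:
        return float(mass[mass >= t].sum())

    lo, hi = 0.0, float(mass.max())
    for _ in range(100):
        if abs(mass_above(lo) - alpha) <= tolerance or hi - lo < 1e-18:
            break
        mid = 0.5 * (lo + hi)
        if mass_above(mid) >= alpha:
            lo = mid
        else:
            hi = mid
    return lo


def contour_at_mass(
    grid: DensityGrid,
    alpha: float,
    mode: str = "mass",
    tolerance: float = MASS_TOLERANCE,
) -> list[ContourPolygon]:
    """Closed contour polygons enclosing a fraction ``alpha`` of event mass.

    ``mode="mass"`` (default) uses the HDR threshold; ``mode="peak"`` places
    the iso-level at ``(1 - alpha)`` of the density maximum instead (so larger
    alpha still means a larger region). Polygons are returned largest enclosed
    mass first.
    """
    if not 0.0 < alpha < 1.0:
        raise ValidationError(f"alpha must be in (0, 1), got {alpha}")
    if mode == "mass":
        level = hdr_threshold(grid, alpha, tolerance)
    elif mode == "peak":
        level = (1.0 - alpha) * float(grid.mass.max())
    else:
        raise ValidationError(f"unknown contour mode {mode!r} (use 'mass' or 'peak')")
    if level <= 0:
        level = float(grid.mass[grid.mass > 0].min()) / 2.0

    # Zero-density pad ring: contours touching the data boundary close along it.
    padded = np.pad(grid.mass, 1, mode="constant")
    xc, yc = grid.x_centers, grid.y_centers
    dx, dy = grid.cell_size
    polygons = []
    for contour in measure.find_contours(padded, level, fully_connected="high"):
        ring = contour[:-1] if np.allclose(contour[0], contour[-1]) else contour
        if len(ring) < 3:
            continue
        verts = np.column_stack(
            [xc[0] + (ring[:, 0] - 1.0) * dx, yc[0] + (ring[:, 1] - 1.0) * dy]
        )
        poly = ContourPolygon(
            level_mass=alpha,
            vertices=verts,
            enclosed_mass=_grid_mass_inside(grid, verts),
        )
        if poly.area > 0:
            polygons.append(poly)
    polygons.sort(key=lambda p: (p.enclosed_mass, p.area), reverse=True)
    return polygons


def _grid_mass_inside(grid: DensityGrid, ring: np.ndarray) -> float:
    """Event mass of grid cells whose centers fall inside the ring."""
    xc, yc = np.meshgrid(grid.x_centers, grid.y_centers, indexing="ij")
    pts = np.column_stack([xc.ravel(), yc.ravel()])
    path = MplPath(np.vstack([ring, ring[:1]]), closed=True)
    inside = path.contains_points(pts).reshape(grid.mass.shape)
    return float(grid.mass[inside].sum())


def main_component(polygons: list[ContourPolygon]) -> ContourPolygon:
    """The contour of the main population: largest enclosed mass, ties by area."""
    if not polygons:
        raise NoContourError("no contour polygons to choose from")
    return max(polygons, key=lambda p: (p.enclosed_mass, p.area))
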