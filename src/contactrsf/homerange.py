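"""Kernel-density home ranges, isopleths and dyadic overlap.

Density is evaluated on the shared analysis grid with a separable Gaussian
kernel and per-coordinate reference (Silverman) bandwidths.  Isopleths are
mass-ranked: the level-q region is the smallest set of highest-density
cells whose cumulative probability mass reaches q.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely

from contactrsf.errors import DegenerateInputError, InsufficientDataError, InvalidArgumentError
from contactrsf.landscape import Grid

_MIN_POINTS_REFERENCE = 30


@dataclass
class HomeRange:
    """KDE utilization surface with mass-ranked isopleth regions."""

    animal_id: str
    grid: Grid
    density: np.ndarray  # per m^2, sums to 1 over cells x cell area
    masks: dict[float, np.ndarray]  # level -> boolean cell mask
    masses: dict[float, float]  # level -> actual enclosed probability mass
    bandwidth: tuple[float, float]
    window: tuple | None = None
    _polygons: dict[float, shapely.Geometry] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if (self.density < 0).any():
            raise InvalidArgumentError("density must be non-negative")
        total = float(self.density.sum()) * self.grid.cell_area
        if not (0.999 <= total <= 1.001):
            raise InvalidArgumentError(f"density mass {total} not ~1")
        levels = sorted(self.masks)
        for lo, hi in zip(levels, levels[1:]):
            if (self.masks[lo] & ~self.masks[hi]).any():
                raise InvalidArgumentError("isopleth masks must be nested")

    @property
    def levels(self) -> list[float]:
        return sorted(self.masks)

    def area(self, level: float) -> float:
        """Area (m^2) of the level's isopleth region."""
        return float(self.masks[self._key(level)].sum()) * self.grid.cell_area

    def mass(self, level: float) -> float:
        return self.masses[self._key(level)]

    def polygon(self, level: float) -> shapely.Geometry:
        """Isopleth region as a (multi)polygon of unioned grid cells."""
        key = self._key(level)
        if key not in self._polygons:
            self._polygons[key] = mask_to_polygon(self.masks[key], self.grid)
        return self._polygons[key]

    def polygon_geojson(self, level: float) -> str:
        return shapely.to_geojson(self.polygon(level))

    def contains(self, x, y, level: float) -> np.ndarray:
        """Whether points fall in cells belonging to the level region."""
        key = self._key(level)
        row, col = self.grid.cell_of(x, y)
        ok = (
            (row >= 0) & (row < self.grid.n_rows) & (col >= 0) & (col < self.grid.n_cols)
        )
        out = np.zeros(np.shape(row), dtype=bool)
        out[ok] = self.masks[key][row[ok], col[ok]]
        return out

    def _key(self, level: float) -> float:
        for k in self.masks:
            if abs(k - level) < 1e-9:
                return k
        raise InvalidArgumentError(f"level {level} not computed for this range")


def mask_to_polygon(mask: np.ndarray, grid: Grid) -> shapely.Geometry:
    rows, cols = np.nonzero(mask)
    if len(rows) == 0:
        return shapely.Polygon()
    cs = grid.cell_size
    x0 = grid.x0 + cols * cs
    y1 = grid.y_top - rows * cs
    boxes = shapely.box(x0, y1 - cs, x0 + cs, y1)
    return shapely.union_all(boxes)


def reference_bandwidth(pts: np.ndarray) -> tuple[float, float]:
    """Per-coordinate Silverman bandwidth ``sd * n^(-1/6)`` (2-D rule)."""
    n = len(pts)
    sx = float(np.std(pts[:, 0]))
    sy = float(np.std(pts[:, 1]))
    f = n ** (-1.0 / 6.0)
    return sx * f, sy * f


def kde_homerange(
    points,
    grid: Grid,
    isopleth_levels=(0.50, 0.95),
    bandwidth="reference",
    animal_id: str = "",
    window=None,
) -> HomeRange:
    """Gaussian-kernel utilization distribution on the analysis grid.

    ``bandwidth`` may be ``"reference"`` (requires >= 30 points) or an
    explicit ``(hx, hy)`` pair in meters.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise InvalidArgumentError("points must be an (n, 2) array")
    n = len(pts)
    if bandwidth == "reference":
        if n < _MIN_POINTS_REFERENCE:
            raise InsufficientDataError(
                f"reference bandwidth needs >= {_MIN_POINTS_REFERENCE} points, got {n}"
            )
        hx, hy = reference_bandwidth(pts)
    else:
        hx, hy = bandwidth
    if hx <= 0 or hy <= 0:
        raise DegenerateInputError("zero bandwidth (all points identical?)")

    xs = grid.x0 + (np.arange(grid.n_cols) + 0.5) * grid.cell_size
    ys = grid.y_top - (np.arange(grid.n_rows) + 0.5) * grid.cell_size
    kx = np.exp(-0.5 * ((xs[None, :] - pts[:, 0:1]) / hx) ** 2)
    ky = np.exp(-0.5 * ((ys[None, :] - pts[:, 1:2]) / hy) ** 2)
    density = ky.T @ kx  # (n_rows, n_cols)
    total = density.sum() * grid.cell_area
    if total <= 0:
        raise DegenerateInputError("no density mass on the grid")
    density /= total

    order = np.argsort(density, axis=None)[::-1]
    cum = np.cumsum(density.flat[order]) * grid.cell_area
    masks: dict[float, np.ndarray] = {}
    masses: dict[float, float] = {}
    for level in sorted(set(float(l) for l in isopleth_levels)):
        if not 0 < level < 1:
            raise InvalidArgumentError(f"isopleth level {level} outside (0, 1)")
        n_cells = int(np.searchsorted(cum, level) + 1)
        n_cells = min(n_cells, len(order))
        mask = np.zeros(density.size, dtype=bool)
        mask[order[:n_cells]] = True
        masks[level] = mask.reshape(density.shape)
        masses[level] = float(cum[n_cells - 1])
    return HomeRange(
        animal_id=animal_id,
        grid=grid,
        density=density,
        masks=masks,
        masses=masses,
        bandwidth=(hx, hy),
        window=window,
    )


def overlap_region(hr_a: HomeRange, hr_b: HomeRange, level: float = 0.95) -> shapely.Geometry:
    """Geometric intersection of the two level polygons (possibly empty)."""
    ga, gb = hr_a.grid, hr_b.grid
    if (ga.cell_size, ga.x0, ga.y_top) != (gb.cell_size, gb.x0, gb.y_top):
        raise InvalidArgumentError("home ranges computed on incompatible grids")
    return hr_a.polygon(level).intersection(hr_b.polygon(level))


def overlap_index(hr_a: HomeRange, hr_b: HomeRange, level: float = 0.50) -> float:
    """area(A∩B) / min(area A, area B) on the shared cell grid, in [0, 1]."""
    ka, kb = hr_a._key(level), hr_b._key(level)
    inter = float((hr_a.masks[ka] & hr_b.masks[kb]).sum())
    amin = min(hr_a.masks[ka].sum(), hr_b.masks[kb].sum())
    return inter / amin if amin else 0.0
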