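"""Gridded landscape covariate stacks.

A stack holds static layers (one 2-D array each) and dynamic daily layers
(one 2-D array per calendar day) on a shared regular grid in projected
meters.  Rasters are exchanged as ESRI ASCII grids plus a JSON manifest,
which keeps every artifact plain text.
"""

from __future__ import annotations

import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from contactrsf.errors import InvalidArgumentError, MissingDataError

BINARY_LAYERS = frozenset(
    {"wetland", "water", "road", "fence_or_trail", "ditch", "food"}
)


@dataclass(frozen=True)
class Grid:
    """Regular analysis grid, origin at the top-left corner.

    Cells are row-major; cell ``(r, c)`` covers the half-open box
    ``x in [x0 + c*cs, x0 + (c+1)*cs)`` and ``y in (ytop - (r+1)*cs, ytop - r*cs]``
    so that right and bottom edges belong to the neighbouring cell.
    """

    n_rows: int
    n_cols: int
    cell_size: float
    x0: float
    y_top: float

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1 or self.cell_size <= 0:
            raise InvalidArgumentError("grid dimensions and cell size must be positive")

    @property
    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the gridded area."""
        return (
            self.x0,
            self.y_top - self.n_rows * self.cell_size,
            self.x0 + self.n_cols * self.cell_size,
            self.y_top,
        )

    @property
    def cell_area(self) -> float:
        return self.cell_size * self.cell_size

    def cell_of(self, x, y):
        """Row/column indices of the cells containing the points."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.x0) / self.cell_size).astype(np.int64)
        row = np.floor((self.y_top - y) / self.cell_size).astype(np.int64)
        # top edge of the grid belongs to row 0
        row = np.where(np.asarray(y) == self.y_top, 0, row)
        return row, col

    def contains(self, x, y):
        row, col = self.cell_of(x, y)
        return (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)

    def cell_center(self, row, col):
        row = np.asarray(row)
        col = np.asarray(col)
        x = self.x0 + (col + 0.5) * self.cell_size
        y = self.y_top - (row + 0.5) * self.cell_size
        return x, y

    def centers(self):
        """Meshgrid of cell-center coordinates, shape (n_rows, n_cols)."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.x0 + (cols + 0.5) * self.cell_size
        y = self.y_top - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)


def _as_date(d) -> dt.date:
    if isinstance(d, dt.datetime):
        return d.date()
    if isinstance(d, dt.date):
        return d
    return pd.Timestamp(d).date()


@dataclass
class EnvStack:
    """Static plus dynamic daily covariate layers on one grid."""

    grid: Grid
    static: dict[str, np.ndarray] = field(default_factory=dict)
    dynamic: dict[str, dict[dt.date, np.ndarray]] = field(default_factory=dict)

    def __post_init__(self):
        self.validate()

    # -- invariants -------------------------------------------------------

    def validate(self) -> None:
        shape = (self.grid.n_rows, self.grid.n_cols)
        for name, arr in self.static.items():
            if arr.shape != shape:
                raise InvalidArgumentError(
                    f"static layer {name!r} shape {arr.shape} != grid {shape}"
                )
            self._check_binary(name, arr)
        expected_days = None
        for name, per_day in self.dynamic.items():
            days = sorted(per_day)
            if expected_days is None:
                expected_days = days
            elif days != expected_days:
                raise InvalidArgumentError(
                    f"dynamic layer {name!r} covers different days than others"
                )
            for day, arr in per_day.items():
                if arr.shape != shape:
                    raise InvalidArgumentError(
                        f"dynamic layer {name!r}@{day} shape {arr.shape} != grid {shape}"
                    )
                self._check_binary(name, arr)
        if expected_days:
            first, last = expected_days[0], expected_days[-1]
            n = (last - first).days + 1
            if len(expected_days) != n:
                raise InvalidArgumentError(
                    "dynamic layers must cover every calendar day of the window"
                )

    @staticmethod
    def _check_binary(name: str, arr: np.ndarray) -> None:
        if name in BINARY_LAYERS and not np.isin(arr, (0, 1)).all():
            raise InvalidArgumentError(f"binary layer {name!r} has values outside {{0,1}}")

    # -- introspection ----------------------------------------------------

    @property
    def layer_names(self) -> list[str]:
        return list(self.static) + list(self.dynamic)

    @property
    def days(self) -> list[dt.date]:
        for per_day in self.dynamic.values():
            return sorted(per_day)
        return []

    def layer(self, name: str, date=None) -> np.ndarray:
        if name in self.static:
            return self.static[name]
        if name in self.dynamic:
            day = _as_date(date)
            per_day = self.dynamic[name]
            if day not in per_day:
                raise MissingDataError(f"layer {name!r} has no raster for {day}")
            return per_day[day]
        raise MissingDataError(f"unknown layer {name!r}")

    # -- extraction -------------------------------------------------------

    def extract(self, x, y, dates, layers: Iterable[str] | None = None) -> pd.DataFrame:
        """Sample layers at the cells containing the points.

        ``dates`` supplies, per point, the calendar day used for dynamic
        layers; static layers ignore it.
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        days = np.array([_as_date(d) for d in np.atleast_1d(dates)])
        if not (len(x) == len(y) == len(days)):
            raise InvalidArgumentError("x, y and dates must have equal length")
        row, col = self.grid.cell_of(x, y)
        inside = (row >= 0) & (row < self.grid.n_rows) & (col >= 0) & (col < self.grid.n_cols)
        if not inside.all():
            bad = np.flatnonzero(~inside)[:5]
            raise InvalidArgumentError(f"points outside grid at indices {bad.tolist()}")
        names = list(layers) if layers is not None else self.layer_names
        out: dict[str, np.ndarray] = {}
        for name in names:
            if name in self.static:
                out[name] = self.static[name][row, col]
            elif name in self.dynamic:
                per_day = self.dynamic[name]
                vals = np.empty(len(x))
                for day in np.unique(days):
                    if day not in per_day:
                        raise MissingDataError(f"layer {name!r} has no raster for {day}")
                    sel = days == day
                    vals[sel] = per_day[day][row[sel], col[sel]]
                out[name] = vals
            else:
                raise MissingDataError(f"unknown layer {name!r}")
        return pd.DataFrame(out)

    # -- serialization ----------------------------------------------------

    def write_dir(self, path) -> Path:
        """Write one ASCII grid per layer-day plus a JSON manifest."""
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        manifest = {
            "grid": {
                "n_rows": self.grid.n_rows,
                "n_cols": self.grid.n_cols,
                "cell_size": self.grid.cell_size,
                "x0": self.grid.x0,
                "y_top": self.grid.y_top,
            },
            "static": {},
            "dynamic": {},
        }
        for name, arr in sorted(self.static.items()):
            fname = f"{name}.asc"
            write_ascii_grid(path / fname, arr, self.grid)
            manifest["static"][name] = fname
        for name, per_day in sorted(self.dynamic.items()):
            manifest["dynamic"][name] = {}
            for day, arr in sorted(per_day.items()):
                fname = f"{name}_{day.isoformat()}.asc"
                write_ascii_grid(path / fname, arr, self.grid)
                manifest["dynamic"][name][day.isoformat()] = fname
        with open(path / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True)
        return path / "manifest.json"

    @classmethod
    def read_dir(cls, manifest_path) -> "EnvStack":
        manifest_path = Path(manifest_path)
        if manifest_path.is_dir():
            manifest_path = manifest_path / "manifest.json"
        base = manifest_path.parent
        with open(manifest_path) as fh:
            manifest = json.load(fh)
        g = manifest["grid"]
        grid = Grid(g["n_rows"], g["n_cols"], g["cell_size"], g["x0"], g["y_top"])
        static = {
            name: read_ascii_grid(base / fname)[0]
            for name, fname in manifest["static"].items()
        }
        dynamic = {
            name: {
                dt.date.fromisoformat(day): read_ascii_grid(base / fname)[0]
                for day, fname in per_day.items()
            }
            for name, per_day in manifest["dynamic"].items()
        }
        return cls(grid=grid, static=static, dynamic=dynamic)


def write_ascii_grid(path, arr: np.ndarray, grid: Grid) -> None:
    xmin, ymin, _, _ = grid.extent
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.n_cols}\n")
        fh.write(f"nrows {grid.n_rows}\n")
        fh.write(f"xllcorner {xmin!r}\n")
        fh.write(f"yllcorner {ymin!r}\n")
        fh.write(f"cellsize {grid.cell_size!r}\n")
        fh.write("NODATA_value -9999\n")
        for row in arr:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")


def read_ascii_grid(path) -> tuple[np.ndarray, Grid]:
    header: dict[str, float] = {}
    rows = []
    with open(path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) == 2 and parts[0].lower() in {
                "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value",
            }:
                header[parts[0].lower()] = float(parts[1])
            else:
                rows.append([float(v) for v in parts])
    arr = np.array(rows)
    n_rows, n_cols = int(header["nrows"]), int(header["ncols"])
    if arr.shape != (n_rows, n_cols):
        raise InvalidArgumentError(f"grid body shape {arr.shape} mismatches header")
    grid = Grid(
        n_rows=n_rows,
        n_cols=n_cols,
        cell_size=header["cellsize"],
        x0=header["xllcorner"],
        y_top=header["yllcorner"] + n_rows * header["cellsize"],
    )
    return arr, grid
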