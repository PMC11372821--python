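"""Grid and raster primitives shared by every pipeline stage.

All layers live on a regular WGS84 geographic grid registered by cell
edges, with row 0 at the northern edge and half-open cells: a point on an
interior cell boundary belongs to the higher-index (east / south) cell.
Cell areas are computed on the sphere (R = 6371 km), which matters over a
50-degree-wide tropical window where cell area varies by a few percent.

Rasters are stored as single-band ESRI ASCII grids (plain text) with an
optional JSON sidecar carrying the layer name and units.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np

EARTH_RADIUS_KM = 6371.0
#: 5 arc-minute working resolution, degrees
DEFAULT_RESOLUTION = 5.0 / 60.0


class GridError(ValueError):
    """Raised for malformed grids or grid mismatches."""


class OutOfExtentError(GridError):
    """Raised when a point falls outside the grid extent."""


@dataclass(frozen=True)
class GridSpec:
    """Regular geographic grid: extent in degrees plus a cell size.

    The extent must be an integral number of cells in each direction.
    """

    lon_min: float
    lon_max: float
    lat_min: float
    lat_max: float
    resolution: float = DEFAULT_RESOLUTION

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise GridError("resolution must be positive")
        for span, axis in (
            (self.lon_max - self.lon_min, "longitude"),
            (self.lat_max - self.lat_min, "latitude"),
        ):
            if span <= 0:
                raise GridError(f"{axis} extent must be positive")
            n = span / self.resolution
            if abs(n - round(n)) > 1e-9 * max(1.0, n):
                raise GridError(
                    f"{axis} span {span} is not an integral number of cells "
                    f"at resolution {self.resolution}"
                )

    @property
    def n_rows(self) -> int:
        return int(round((self.lat_max - self.lat_min) / self.resolution))

    @property
    def n_cols(self) -> int:
        return int(round((self.lon_max - self.lon_min) / self.resolution))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def lon_centers(self) -> np.ndarray:
        return self.lon_min + (np.arange(self.n_cols) + 0.5) * self.resolution

    def lat_centers(self) -> np.ndarray:
        """Cell-center latitudes ordered north to south (row order)."""
        return self.lat_max - (np.arange(self.n_rows) + 0.5) * self.resolution

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """(lon, lat) of a cell center."""
        if not (0 <= row < self.n_rows and 0 <= col < self.n_cols):
            raise IndexError(f"cell ({row}, {col}) outside grid {self.shape}")
        lon = self.lon_min + (col + 0.5) * self.resolution
        lat = self.lat_max - (row + 0.5) * self.resolution
        return lon, lat

    def contains(self, lon: float, lat: float) -> bool:
        return (
            self.lon_min <= lon <= self.lon_max
            and self.lat_min <= lat <= self.lat_max
        )


def cell_area(grid: GridSpec, row: int) -> float:
    """Area in km² of any cell in the given row (spherical cap band).

    A = R² · Δλ · (sin φ_top − sin φ_bottom) with cell-edge latitudes.
    Constant along a row; decreases away from the equator.
    """
    if not 0 <= row < grid.n_rows:
        raise IndexError(f"row {row} outside grid with {grid.n_rows} rows")
    lat_top = grid.lat_max - row * grid.resolution
    lat_bot = lat_top - grid.resolution
    dlam = math.radians(grid.resolution)
    return (
        EARTH_RADIUS_KM**2
        * dlam
        * (math.sin(math.radians(lat_top)) - math.sin(math.radians(lat_bot)))
    )


def cell_area_grid(grid: GridSpec) -> np.ndarray:
    """(n_rows, n_cols) array of cell areas in km²."""
    per_row = np.array([cell_area(grid, r) for r in range(grid.n_rows)])
    return np.broadcast_to(per_row[:, None], grid.shape).copy()


def point_to_cell(grid: GridSpec, lon: float, lat: float) -> tuple[int, int]:
    """Map a point to its (row, col).

    Cells are half-open [edge, edge + res): a point on an interior boundary
    goes to the higher-index cell.  The far east / south extent edges are
    folded into the last cell so the closed extent is fully covered.
    """
    if not grid.contains(lon, lat):
        raise OutOfExtentError(
            f"point ({lon}, {lat}) outside extent "
            f"[{grid.lon_min}, {grid.lon_max}] x [{grid.lat_min}, {grid.lat_max}]"
        )
    col = int(_snap_floor((lon - grid.lon_min) / grid.resolution))
    row = int(_snap_floor((grid.lat_max - lat) / grid.resolution))
    col = min(col, grid.n_cols - 1)
    row = min(row, grid.n_rows - 1)
    return row, col


def _snap_floor(q):
    """floor() that snaps quotients within 1e-9 of an integer, so points
    meant to sit exactly on a cell edge obey the half-open rule despite
    floating-point representation."""
    return np.floor(np.where(np.abs(q - np.round(q)) < 1e-9, np.round(q), q))


def points_to_cells(
    grid: GridSpec, lon: np.ndarray, lat: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized point_to_cell. Raises on the first out-of-extent point."""
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)
    inside = (
        (lon >= grid.lon_min)
        & (lon <= grid.lon_max)
        & (lat >= grid.lat_min)
        & (lat <= grid.lat_max)
    )
    if not inside.all():
        i = int(np.flatnonzero(~inside)[0])
        raise OutOfExtentError(f"point ({lon[i]}, {lat[i]}) outside grid extent")
    col = _snap_floor((lon - grid.lon_min) / grid.resolution).astype(int)
    row = _snap_floor((grid.lat_max - lat) / grid.resolution).astype(int)
    return np.minimum(row, grid.n_rows - 1), np.minimum(col, grid.n_cols - 1)


@dataclass
class Layer:
    """One named raster band on a grid with a sea/land validity mask."""

    grid: GridSpec
    values: np.ndarray
    mask: np.ndarray
    name: str
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.grid.shape or self.mask.shape != self.grid.shape:
            raise GridError(
                f"layer '{self.name}': array shape {self.values.shape} does not "
                f"match grid shape {self.grid.shape}"
            )

    def masked_values(self) -> np.ndarray:
        """Values on valid cells, NaN elsewhere."""
        out = np.full(self.grid.shape, np.nan)
        out[self.mask] = self.values[self.mask]
        return out

    def copy(self, **changes) -> "Layer":
        base = Layer(
            grid=self.grid,
            values=self.values.copy(),
            mask=self.mask.copy(),
            name=self.name,
            units=self.units,
        )
        for k, v in changes.items():
            setattr(base, k, v)
        return base


@dataclass
class PredictorStack:
    """Ordered set of layers sharing one grid and one mask."""

    layers: list[Layer]
    scenario_tag: str = "current"

    def __post_init__(self) -> None:
        if not self.layers:
            raise GridError("stack must contain at least one layer")
        g0 = self.layers[0].grid
        m0 = self.layers[0].mask
        names = set()
        for lyr in self.layers:
            if lyr.grid != g0:
                raise GridError(f"layer '{lyr.name}' on a different grid")
            if not np.array_equal(lyr.mask, m0):
                raise GridError(f"layer '{lyr.name}' has a different mask")
            if lyr.name in names:
                raise GridError(f"duplicate layer name '{lyr.name}'")
            names.add(lyr.name)

    @property
    def grid(self) -> GridSpec:
        return self.layers[0].grid

    @property
    def mask(self) -> np.ndarray:
        return self.layers[0].mask

    @property
    def names(self) -> list[str]:
        return [lyr.name for lyr in self.layers]

    def __getitem__(self, name: str) -> Layer:
        for lyr in self.layers:
            if lyr.name == name:
                return lyr
        raise KeyError(f"stack has no layer '{name}'")

    def __contains__(self, name: str) -> bool:
        return name in self.names

    def __iter__(self) -> Iterator[Layer]:
        return iter(self.layers)

    def with_tag(self, tag: str) -> "PredictorStack":
        return PredictorStack(layers=[l.copy() for l in self.layers], scenario_tag=tag)


# ---------------------------------------------------------------------------
# ASCII-grid raster I/O

_NODATA = -99999.0


def write_raster(layer: Layer, path: str | Path) -> None:
    """Write a layer as an ESRI ASCII grid plus a JSON metadata sidecar.

    Valid-cell values round-trip bit-exactly (written with repr precision).
    """
    path = Path(path)
    g = layer.grid
    vals = np.where(layer.mask, layer.values, _NODATA)
    with open(path, "w") as fh:
        fh.write(f"ncols {g.n_cols}\n")
        fh.write(f"nrows {g.n_rows}\n")
        fh.write(f"xllcorner {g.lon_min!r}\n")
        fh.write(f"yllcorner {g.lat_min!r}\n")
        fh.write(f"cellsize {g.resolution!r}\n")
        fh.write(f"NODATA_value {_NODATA!r}\n")
        for row in vals:
            fh.write(" ".join(repr(float(v)) for v in row))
            fh.write("\n")
    meta = {"name": layer.name, "units": layer.units}
    Path(str(path) + ".json").write_text(json.dumps(meta))


def read_raster(path: str | Path, expect_grid: GridSpec | None = None) -> Layer:
    """Read an ESRI ASCII grid written by :func:`write_raster`.

    If ``expect_grid`` is given, a mismatching geotransform raises GridError.
    """
    path = Path(path)
    header: dict[str, float] = {}
    with open(path) as fh:
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh, dtype=float)
    n_rows = int(header["nrows"])
    n_cols = int(header["ncols"])
    res = header["cellsize"]
    grid = GridSpec(
        lon_min=header["xllcorner"],
        lon_max=header["xllcorner"] + n_cols * res,
        lat_min=header["yllcorner"],
        lat_max=header["yllcorner"] + n_rows * res,
        resolution=res,
    )
    if expect_grid is not None and grid != expect_grid:
        raise GridError(f"raster {path} grid does not match expected grid")
    data = data.reshape(n_rows, n_cols)
    mask = data != header["nodata_value"]
    values = np.where(mask, data, np.nan)
    name, units = path.stem, ""
    sidecar = Path(str(path) + ".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        name = meta.get("name", name)
        units = meta.get("units", units)
    return Layer(grid=grid, values=values, mask=mask, name=name, units=units)


def write_stack(stack: PredictorStack, directory: str | Path) -> list[Path]:
    """Write every layer of a stack into a directory, one .asc per layer.

    Files are prefixed with the layer's position so order survives a round
    trip through the filesystem.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, lyr in enumerate(stack.layers):
        p = directory / f"{i:02d}_{lyr.name}.asc"
        write_raster(lyr, p)
        paths.append(p)
    (directory / "scenario.json").write_text(
        json.dumps({"scenario_tag": stack.scenario_tag})
    )
    return paths


def read_stack(directory: str | Path) -> PredictorStack:
    directory = Path(directory)
    paths = sorted(directory.glob("*.asc"))
    if not paths:
        raise GridError(f"no .asc rasters found in {directory}")
    layers = [read_raster(p) for p in paths]
    tag = "current"
    scen = directory / "scenario.json"
    if scen.exists():
        tag = json.loads(scen.read_text()).get("scenario_tag", tag)
    return PredictorStack(layers=layers, scenario_tag=tag)
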