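"""Synthetic inputs with the statistical structure the analysis assumes.

Emulates the study setting for the giant clam *Tridacna maxima*: a
90-140° E, 11° S-15° N tropical window at 5 arc-minute resolution, nine
environmental predictor layers (four of them "dynamic", i.e. perturbed
under future climate scenarios), two populations whose realized niches
differ in temperature and salinity optima on either side of a boundary
line, presence records sampled proportionally to true suitability, and
rectangular marine protected areas covering a configurable share of sea.

Everything is deterministic given a seed, so the full pipeline is testable
end to end with a known ground truth.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import LineString, Point, Polygon, box
from shapely.ops import split as shapely_split

from .grid import GridSpec, Layer, PredictorStack, cell_area_grid

#: canonical names of the nine predictor layers (units in LAYER_UNITS)
LAYER_NAMES = [
    "current_velocity",
    "salinity",
    "temperature_mean",
    "temperature_range",
    "depth",
    "distance_to_shore",
    "dissolved_oxygen",
    "light_at_bottom",
    "phytoplankton",
]

LAYER_UNITS = {
    "current_velocity": "m s-1",
    "salinity": "PSS",
    "temperature_mean": "degC",
    "temperature_range": "degC",
    "depth": "m",
    "distance_to_shore": "km",
    "dissolved_oxygen": "mol m-3",
    "light_at_bottom": "",
    "phytoplankton": "umol m-3",
}

#: the four layers that change under future climate scenarios; the other
#: five are held fixed in every scenario.
DYNAMIC_LAYERS = [
    "current_velocity",
    "salinity",
    "temperature_mean",
    "temperature_range",
]

#: plausible (low, high) value ranges the smoothed fields are mapped onto
_LAYER_RANGES = {
    "current_velocity": (0.02, 1.2),
    "salinity": (31.0, 35.5),
    "temperature_mean": (20.0, 31.0),
    "temperature_range": (1.0, 8.0),
    "dissolved_oxygen": (0.15, 0.25),
    "light_at_bottom": (0.0, 60.0),
    "phytoplankton": (0.5, 8.0),
}

#: study window used throughout: 90-140 E, 11 S - 15 N at 5 arc-minutes
STUDY_GRID = GridSpec(lon_min=90.0, lon_max=140.0, lat_min=-11.0, lat_max=15.0)


class ScenarioError(ValueError):
    """A scenario delta touched a non-dynamic layer."""


@dataclass(frozen=True)
class NicheFunction:
    """Product of independent Gaussian suitability terms.

    suitability(x) = max_suitability * prod_v exp(-((x_v - mu_v)^2) / (2 s_v^2))
    over the variables named in ``optima``; unnamed variables do not
    constrain the niche.  Values lie in [0, max_suitability] with the
    maximum attained exactly at the optimum vector.
    """

    optima: dict[str, float]
    tolerances: dict[str, float]
    max_suitability: float = 1.0

    def __post_init__(self) -> None:
        if set(self.optima) != set(self.tolerances):
            raise ValueError("optima and tolerances must name the same variables")
        if any(t <= 0 for t in self.tolerances.values()):
            raise ValueError("tolerances must be positive")
        if not 0 < self.max_suitability <= 1:
            raise ValueError("max_suitability must lie in (0, 1]")

    def __call__(self, env: dict[str, np.ndarray] | pd.DataFrame) -> np.ndarray:
        keys = self.optima.keys()
        first = env[next(iter(keys))]
        out = np.full(np.shape(first), self.max_suitability, dtype=float)
        for v in keys:
            z = (np.asarray(env[v], dtype=float) - self.optima[v]) / self.tolerances[v]
            out = out * np.exp(-0.5 * z * z)
        return out


@dataclass(frozen=True)
class PopulationNiches:
    """Two population niches joined at a meridional boundary.

    West of ``boundary_lon`` the EIOS niche applies, east of it the WPI
    niche; the two typically differ in their temperature and salinity
    optima.  Callable like a :class:`NicheFunction` on an environment
    frame that carries a ``lon`` column.
    """

    west: NicheFunction
    east: NicheFunction
    boundary_lon: float

    def __call__(self, env: pd.DataFrame) -> np.ndarray:
        lon = np.asarray(env["lon"], dtype=float)
        return np.where(lon < self.boundary_lon, self.west(env), self.east(env))


@dataclass(frozen=True)
class ScenarioDelta:
    """Per-layer perturbation applied only to the four dynamic layers."""

    offsets: dict[str, float] = field(default_factory=dict)
    factors: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = (set(self.offsets) | set(self.factors)) - set(DYNAMIC_LAYERS)
        if bad:
            raise ScenarioError(
                f"scenario delta names non-dynamic layer(s): {sorted(bad)}"
            )


#: illustrative (period, RCP) presets: sea-surface warming grows toward the
#: pessimistic end-of-century pathway, with small salinity freshening and a
#: widening seasonal temperature range.
SCENARIO_PRESETS: dict[tuple[str, str], ScenarioDelta] = {
    ("2050s", "RCP2.6"): ScenarioDelta(
        offsets={"temperature_mean": 0.6, "salinity": -0.1, "temperature_range": 0.1}
    ),
    ("2100s", "RCP2.6"): ScenarioDelta(
        offsets={"temperature_mean": 0.9, "salinity": -0.15, "temperature_range": 0.15}
    ),
    ("2050s", "RCP8.5"): ScenarioDelta(
        offsets={"temperature_mean": 1.4, "salinity": -0.25, "temperature_range": 0.3},
        factors={"current_velocity": 1.03},
    ),
    ("2100s", "RCP8.5"): ScenarioDelta(
        offsets={"temperature_mean": 2.8, "salinity": -0.5, "temperature_range": 0.6},
        factors={"current_velocity": 1.06},
    ),
}


def _smooth_field(
    rng: np.random.Generator, shape: tuple[int, int], autocorr_cells: float
) -> np.ndarray:
    """Standardized spatially autocorrelated Gaussian field."""
    noise = rng.standard_normal(shape)
    if autocorr_cells > 0:
        noise = ndimage.gaussian_filter(noise, sigma=autocorr_cells, mode="reflect")
    noise = noise - noise.mean()
    sd = noise.std()
    return noise / sd if sd > 0 else noise


def _affine_to_range(field_: np.ndarray, low: float, high: float) -> np.ndarray:
    lo, hi = field_.min(), field_.max()
    if hi == lo:
        return np.full_like(field_, 0.5 * (low + high))
    return low + (field_ - lo) * (high - low) / (hi - lo)


def simulate_predictors(
    grid: GridSpec = STUDY_GRID,
    seed: int = 0,
    autocorr_cells: float = 6.0,
    sea_fraction: float = 0.8,
) -> PredictorStack:
    """Generate the nine-layer predictor stack on a shared sea mask.

    Land/sea comes from the sign of a synthetic depth field (depth > 0 is
    sea, thresholded so roughly ``sea_fraction`` of cells are sea).
    Temperature carries a latitudinal gradient (warmer near the equator) on
    top of the autocorrelated noise; distance to shore is the true distance
    transform from the synthetic coastline.  Deterministic given ``seed``.
    """
    if autocorr_cells < 0:
        raise ValueError("autocorr_cells must be >= 0")
    if not 0 < sea_fraction < 1:
        raise ValueError("sea_fraction must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    shape = grid.shape

    # depth field defines the mask: shift so the sea fraction is as requested
    raw_depth = _smooth_field(rng, shape, autocorr_cells)
    thresh = np.quantile(raw_depth, 1.0 - sea_fraction)
    sea = raw_depth > thresh
    depth_vals = np.where(sea, _affine_to_range(raw_depth - thresh, 1.0, 4000.0), np.nan)

    lat = np.broadcast_to(grid.lat_centers()[:, None], shape)

    layers: list[Layer] = []
    for name in LAYER_NAMES:
        if name == "depth":
            vals = depth_vals
        elif name == "distance_to_shore":
            # distance (cells) from nearest land cell; ~9.2 km per cell
            if sea.all():
                dist = _affine_to_range(_smooth_field(rng, shape, autocorr_cells), 0, 300)
            else:
                dist = ndimage.distance_transform_edt(sea) * 9.2
            vals = np.where(sea, dist, np.nan)
        else:
            f = _smooth_field(rng, shape, autocorr_cells)
            if name == "temperature_mean":
                # equator-peaked gradient dominates, noise modulates
                grad = -np.abs(lat) / max(abs(grid.lat_min), abs(grid.lat_max), 1.0)
                f = 1.5 * (grad - grad.mean()) / max(grad.std(), 1e-12) + f
            lo, hi = _LAYER_RANGES[name]
            vals = np.where(sea, _affine_to_range(f, lo, hi), np.nan)
        layers.append(
            Layer(grid=grid, values=vals, mask=sea.copy(), name=name,
                  units=LAYER_UNITS[name])
        )
    return PredictorStack(layers=layers, scenario_tag="current")


def apply_scenario(
    stack: PredictorStack, delta: ScenarioDelta, tag: str
) -> PredictorStack:
    """Perturb the dynamic layers; static layers pass through bit-identically."""
    layers = []
    for lyr in stack.layers:
        if lyr.name in delta.offsets or lyr.name in delta.factors:
            vals = lyr.values * delta.factors.get(lyr.name, 1.0) + delta.offsets.get(
                lyr.name, 0.0
            )
            layers.append(lyr.copy(values=np.where(lyr.mask, vals, np.nan)))
        else:
            layers.append(lyr.copy())
    return PredictorStack(layers=layers, scenario_tag=tag)


def scenario_stacks(stack: PredictorStack) -> dict[str, PredictorStack]:
    """The four preset future stacks keyed '2050s_RCP2.6' etc."""
    out = {}
    for (period, rcp), delta in SCENARIO_PRESETS.items():
        tag = f"{period}_{rcp}"
        out[tag] = apply_scenario(stack, delta, tag)
    return out


# ---------------------------------------------------------------------------
# boundary geometry and occurrence sampling

def default_boundary(grid: GridSpec = STUDY_GRID, lon: float | None = None) -> LineString:
    """A meridional boundary line splitting the window into west and east.

    Stands in for the Indonesian Throughflow / Makassar Strait line that
    separates the EIOS (west) and WPI (east) populations.  The canonical
    119° E meridian is used when it crosses the grid; otherwise the grid's
    own midline (so reduced test windows still split in two).
    """
    if lon is None:
        lon = 119.0
        if not grid.lon_min < lon < grid.lon_max:
            lon = 0.5 * (grid.lon_min + grid.lon_max)
    return LineString([(lon, grid.lat_min - 1.0), (lon, grid.lat_max + 1.0)])


def split_extent(grid: GridSpec, boundary: LineString) -> tuple[Polygon, Polygon]:
    """(west, east) polygons of the extent cut by the boundary line."""
    extent = box(grid.lon_min, grid.lat_min, grid.lon_max, grid.lat_max)
    pieces = list(shapely_split(extent, boundary).geoms)
    if len(pieces) != 2:
        raise ValueError("boundary must split the extent into exactly two regions")
    pieces.sort(key=lambda p: p.representative_point().x)
    return pieces[0], pieces[1]


def stack_env_frame(stack: PredictorStack) -> pd.DataFrame:
    """Environment of every sea cell: columns = layers plus row/col/lon/lat."""
    rows, cols = np.nonzero(stack.mask)
    g = stack.grid
    data = {
        "row": rows,
        "col": cols,
        "lon": g.lon_min + (cols + 0.5) * g.resolution,
        "lat": g.lat_max - (rows + 0.5) * g.resolution,
    }
    for lyr in stack.layers:
        data[lyr.name] = lyr.values[rows, cols]
    return pd.DataFrame(data)


def true_suitability(stack: PredictorStack, niche: NicheFunction) -> Layer:
    """The generating niche evaluated on every sea cell (the 'truth' map)."""
    env = stack_env_frame(stack)
    suit = niche(env)
    vals = np.full(stack.grid.shape, np.nan)
    vals[env["row"].to_numpy(), env["col"].to_numpy()] = suit
    return Layer(grid=stack.grid, values=vals, mask=stack.mask.copy(),
                 name="true_suitability")


def sample_occurrences(
    stack: PredictorStack,
    niche: NicheFunction,
    n: int,
    seed: int = 0,
    boundary: LineString | None = None,
    jitter: bool = True,
) -> pd.DataFrame:
    """Draw presence points from sea cells with probability ∝ suitability.

    Returns a table (id, lon, lat, population, response=1).  The population
    label is the side of the boundary (EIOS west, WPI east).  Points are
    placed inside their cell (center plus a small uniform jitter) so the
    downstream cleaning and thinning steps have realistic work to do.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if boundary is None:
        boundary = default_boundary(stack.grid)
    rng = np.random.default_rng(seed)
    env = stack_env_frame(stack)
    w = np.asarray(niche(env), dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("niche assigns zero suitability to every sea cell")
    idx = rng.choice(len(env), size=n, replace=True, p=w / total)
    g = stack.grid
    lon = env["lon"].to_numpy()[idx]
    lat = env["lat"].to_numpy()[idx]
    if jitter:
        lon = lon + rng.uniform(-0.49, 0.49, size=n) * g.resolution
        lat = lat + rng.uniform(-0.49, 0.49, size=n) * g.resolution
    west, _ = split_extent(g, boundary)
    pop = np.where(
        [west.covers(Point(x, y)) for x, y in zip(lon, lat)], "EIOS", "WPI"
    )
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "lon": lon,
            "lat": lat,
            "population": pop,
            "response": 1,
        }
    )


# ---------------------------------------------------------------------------
# synthetic marine protected areas

def simulate_mpas(
    grid: GridSpec,
    sea_mask: np.ndarray,
    coverage_target: float,
    n_polygons: int = 25,
    seed: int = 0,
) -> list[Polygon]:
    """Axis-aligned rectangular MPAs covering ≈ ``coverage_target`` of sea area.

    Rectangles are centered on random sea cells and accumulated greedily
    until the realized (cell-area-weighted) sea coverage reaches the
    target or the polygon budget runs out; placement is independent of any
    suitability signal.  Emits a warning when the target is unreachable.
    """
    if not 0 < coverage_target < 1:
        raise ValueError("coverage_target must lie in (0, 1)")
    if n_polygons == 0:
        return []
    rng = np.random.default_rng(seed)
    areas = cell_area_grid(grid)
    sea_area = areas[sea_mask].sum()
    target_area = coverage_target * sea_area

    rows, cols = np.nonzero(sea_mask)
    lon_c = grid.lon_min + (cols + 0.5) * grid.resolution
    lat_c = grid.lat_max - (rows + 0.5) * grid.resolution
    sea_cell_areas = areas[rows, cols]

    covered = np.zeros(len(rows), dtype=bool)
    polys: list[Polygon] = []
    mean_cell = sea_cell_areas.mean()
    realized = 0.0
    while len(polys) < n_polygons and realized < 0.97 * target_area:
        # size the next rectangle to the remaining deficit, inflated for the
        # share expected to land on land or on already-covered sea
        polys_left = n_polygons - len(polys)
        cells_needed = 1.4 * (target_area - realized) / mean_cell / polys_left
        side = math.sqrt(max(cells_needed, 1.0)) * grid.resolution
        i = rng.integers(len(rows))
        aspect = rng.uniform(0.6, 1.6)
        w, h = side * aspect, side / aspect
        x0, x1 = lon_c[i] - w / 2, lon_c[i] + w / 2
        y0, y1 = lat_c[i] - h / 2, lat_c[i] + h / 2
        polys.append(box(x0, y0, x1, y1))
        inside = (lon_c >= x0) & (lon_c <= x1) & (lat_c >= y0) & (lat_c <= y1)
        covered |= inside
        realized = sea_cell_areas[covered].sum()
    if abs(realized - target_area) > 0.2 * target_area:
        warnings.warn(
            f"realized MPA sea coverage {realized / sea_area:.3f} misses target "
            f"{coverage_target:.3f} with n_polygons={n_polygons}; best effort kept"
        )
    return polys
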