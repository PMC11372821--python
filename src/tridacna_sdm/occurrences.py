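"""Occurrence cleaning, grid thinning, population assignment and
pseudo-absence generation.

The workflow turns raw point records into the balanced presence /
pseudo-absence table the distribution models consume: drop incomplete,
duplicated, out-of-extent and non-marine records; keep at most one
presence per 5 arc-minute cell; label each record EIOS (west of the
boundary) or WPI (east); and draw one pseudo-absence per presence from
sea cells outside both the occupied cells and the presences'
environmental envelope.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

from .grid import GridSpec, PredictorStack, points_to_cells
from .simulate import split_extent

log = logging.getLogger(__name__)

REQUIRED_COLUMNS = ["id", "lon", "lat"]


class EmptyDataError(ValueError):
    """All records were removed by cleaning."""


def _check_columns(occ: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in occ.columns]
    if missing:
        raise KeyError(f"occurrence table missing column(s) {missing}")


def clean_records(raw: pd.DataFrame, stack: PredictorStack) -> pd.DataFrame:
    """Remove incomplete, duplicate, out-of-extent and non-marine records.

    Exact-coordinate duplicates collapse to their first row; input order is
    preserved otherwise.  Raises :class:`EmptyDataError` when nothing
    survives.
    """
    _check_columns(raw)
    occ = raw.copy()
    occ = occ[occ["lon"].notna() & occ["lat"].notna()]
    occ = occ.drop_duplicates(subset=["lon", "lat"], keep="first")
    g = stack.grid
    inside = (
        (occ["lon"] >= g.lon_min)
        & (occ["lon"] <= g.lon_max)
        & (occ["lat"] >= g.lat_min)
        & (occ["lat"] <= g.lat_max)
    )
    n_out = int((~inside).sum())
    occ = occ[inside]
    if len(occ):
        r, c = points_to_cells(g, occ["lon"].to_numpy(), occ["lat"].to_numpy())
        at_sea = stack.mask[r, c]
        n_land = int((~at_sea).sum())
        occ = occ[at_sea]
    else:
        n_land = 0
    log.info(
        "clean_records: %d -> %d rows (%d out of extent, %d non-marine)",
        len(raw), len(occ), n_out, n_land,
    )
    if occ.empty:
        raise EmptyDataError("no occurrence records survived cleaning")
    return occ.reset_index(drop=True)


def thin_to_grid(occ: pd.DataFrame, grid: GridSpec) -> pd.DataFrame:
    """Keep at most one record per grid cell (first in input order wins).

    Idempotent: thinning a thinned table is a no-op.
    """
    _check_columns(occ)
    if occ.empty:
        return occ.copy()
    r, c = points_to_cells(grid, occ["lon"].to_numpy(), occ["lat"].to_numpy())
    cell = r.astype(np.int64) * grid.n_cols + c
    keep = ~pd.Series(cell).duplicated(keep="first").to_numpy()
    out = occ[keep].reset_index(drop=True)
    log.info("thin_to_grid: %d -> %d records", len(occ), len(out))
    return out


def assign_population(
    occ: pd.DataFrame, boundary: LineString, grid: GridSpec
) -> pd.DataFrame:
    """Label every record EIOS (west of the boundary) or WPI (east).

    A point exactly on the boundary is assigned to the western (EIOS) side
    by convention; such ties are logged.
    """
    _check_columns(occ)
    west, _ = split_extent(grid, boundary)
    labels = []
    for lon, lat in zip(occ["lon"], occ["lat"]):
        p = Point(lon, lat)
        if boundary.distance(p) == 0.0:
            log.info("record at (%s, %s) lies on the boundary; assigned EIOS", lon, lat)
            labels.append("EIOS")
        else:
            labels.append("EIOS" if west.covers(p) else "WPI")
    out = occ.copy()
    out["population"] = labels
    return out


def presence_envelope(env: pd.DataFrame) -> pd.DataFrame:
    """Per-variable [min, max] across presence records."""
    return pd.DataFrame({"min": env.min(axis=0), "max": env.max(axis=0)})


def generate_pseudo_absences(
    presences: pd.DataFrame,
    stack: PredictorStack,
    seed: int = 0,
    strategy: str = "envelope",
) -> pd.DataFrame:
    """Draw one pseudo-absence per presence from eligible sea cells.

    Eligible cells contain no presence and, under the default "envelope"
    strategy, fall outside the presences' per-variable [min, max]
    environmental envelope — i.e. conditions where the species was not
    observed.  Cells are drawn uniformly without replacement; absences sit
    at cell centers with response 0.  If the envelope rule leaves too few
    cells it is relaxed to "cells_only" with a warning; if even that
    fails, an error is raised.
    """
    if strategy not in ("envelope", "cells_only"):
        raise ValueError(f"unknown pseudo-absence strategy '{strategy}'")
    _check_columns(presences)
    if presences.empty:
        raise EmptyDataError("no presences to balance against")
    n = len(presences)
    g = stack.grid
    pr, pc = points_to_cells(g, presences["lon"].to_numpy(), presences["lat"].to_numpy())
    presence_cells = np.zeros(g.shape, dtype=bool)
    presence_cells[pr, pc] = True

    rows, cols = np.nonzero(stack.mask & ~presence_cells)
    if strategy == "envelope":
        env_vals = np.column_stack([lyr.values[pr, pc] for lyr in stack.layers])
        lo = env_vals.min(axis=0)
        hi = env_vals.max(axis=0)
        cand = np.column_stack([lyr.values[rows, cols] for lyr in stack.layers])
        outside = ((cand < lo) | (cand > hi)).any(axis=1)
        if outside.sum() < n:
            warnings.warn(
                "too few cells outside the presence envelope "
                f"({int(outside.sum())} < {n}); relaxing to cells_only"
            )
        else:
            rows, cols = rows[outside], cols[outside]
    if len(rows) < n:
        raise EmptyDataError(
            f"only {len(rows)} eligible cells for {n} pseudo-absences"
        )
    rng = np.random.default_rng(seed)
    pick = rng.choice(len(rows), size=n, replace=False)
    lon = g.lon_min + (cols[pick] + 0.5) * g.resolution
    lat = g.lat_max - (rows[pick] + 0.5) * g.resolution
    start = int(presences["id"].max()) + 1 if len(presences) else 0
    out = pd.DataFrame(
        {
            "id": np.arange(start, start + n),
            "lon": lon,
            "lat": lat,
            "population": "unassigned",
            "response": 0,
        }
    )
    return out


def build_response_table(
    presences: pd.DataFrame, absences: pd.DataFrame
) -> pd.DataFrame:
    """Concatenate presences (response 1) and pseudo-absences (response 0)."""
    pres = presences.copy()
    if "response" not in pres:
        pres["response"] = 1
    return pd.concat([pres, absences], ignore_index=True)
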