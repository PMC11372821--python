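"""Marine-protected-area gap analysis.

Overlay the binary suitable-habitat map with MPA polygons rasterized by
cell centers, report protected area (km²) and percent protection per
scenario, and classify the projected loss class into Priority
Conservation Areas (PCA: suitable now, unsuitable later, outside any MPA)
and Conservation Areas Pending Optimization (POCA: same trajectory but
already inside an MPA).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, mapping, shape
from shapely.validation import make_valid

from .grid import GridSpec, cell_area_grid
from .projection import BinaryMap


class GapAnalysisError(ValueError):
    pass


def load_mpas_geojson(path: str | Path) -> list[Polygon]:
    """Read MPA polygons from a GeoJSON FeatureCollection."""
    gj = json.loads(Path(path).read_text())
    polys = []
    for feat in gj.get("features", []):
        geom = shape(feat["geometry"])
        if geom.geom_type == "MultiPolygon":
            polys.extend(geom.geoms)
        else:
            polys.append(geom)
    return polys


def write_mpas_geojson(polys: list[Polygon], path: str | Path) -> None:
    features = [
        {"type": "Feature", "properties": {"id": i}, "geometry": mapping(p)}
        for i, p in enumerate(polys)
    ]
    Path(path).write_text(
        json.dumps({"type": "FeatureCollection", "features": features})
    )


def rasterize_mpas(polys: list[Polygon], grid: GridSpec) -> np.ndarray:
    """Boolean grid: True where the cell center lies in (or on the boundary
    of) at least one polygon.  Invalid polygons are repaired first."""
    out = np.zeros(grid.shape, dtype=bool)
    if not polys:
        return out
    repaired = []
    for i, p in enumerate(polys):
        if not p.is_valid:
            p = make_valid(p)
            if not p.is_valid:
                raise GapAnalysisError(f"polygon {i} could not be repaired")
        repaired.append(p)
    union = shapely.union_all(repaired)
    lon = grid.lon_centers()
    lat = grid.lat_centers()
    lon2, lat2 = np.meshgrid(lon, lat)
    hits = shapely.intersects_xy(union, lon2.ravel(), lat2.ravel())
    return hits.reshape(grid.shape)


def protection_percent(predicted_km2: float, protected_km2: float) -> float:
    """Percent of the predicted range that is protected."""
    if predicted_km2 <= 0:
        raise GapAnalysisError("zero predicted area; percent protected undefined")
    if not 0 <= protected_km2 <= predicted_km2:
        raise GapAnalysisError("protected area must lie in [0, predicted area]")
    return 100.0 * protected_km2 / predicted_km2


@dataclass
class GapReportRow:
    scenario: str
    predicted_km2: float
    protected_km2: float
    percent_protected: float


def protection_stats(
    binary: BinaryMap, mpa_mask: np.ndarray, scenario: str | None = None
) -> GapReportRow:
    """Cell-area-weighted protected area and percent protection."""
    lyr = binary.layer
    if mpa_mask.shape != lyr.grid.shape:
        raise GapAnalysisError("MPA mask shape does not match the map grid")
    areas = cell_area_grid(lyr.grid)
    suitable = binary.suitable()
    predicted = float(areas[suitable].sum())
    protected = float(areas[suitable & mpa_mask].sum())
    return GapReportRow(
        scenario=scenario or binary.scenario_tag,
        predicted_km2=predicted,
        protected_km2=protected,
        percent_protected=protection_percent(predicted, protected),
    )


def gap_report_frame(rows: list[GapReportRow]) -> pd.DataFrame:
    """CSV-ready table (scenario, predicted km², protected km², percent)."""
    return pd.DataFrame(
        [
            {
                "scenario": r.scenario,
                "predicted_km2": round(r.predicted_km2, 2),
                "protected_km2": round(r.protected_km2, 2),
                "percent_protected": round(r.percent_protected, 2),
            }
            for r in rows
        ]
    )


def classify_conservation(
    current: BinaryMap, future: BinaryMap, mpa_mask: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(PCA, POCA) boolean masks partitioning the projected loss class.

    PCA  = suitable now, unsuitable in the future, outside every MPA;
    POCA = suitable now, unsuitable in the future, inside an MPA.
    The two are disjoint and their union is exactly the loss category.
    """
    if current.layer.grid != future.layer.grid:
        raise GapAnalysisError("current/future maps on different grids")
    if mpa_mask.shape != current.layer.grid.shape:
        raise GapAnalysisError("MPA mask shape does not match the map grid")
    loss = current.suitable() & ~future.suitable()
    pca = loss & ~mpa_mask
    poca = loss & mpa_mask
    return pca, poca
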