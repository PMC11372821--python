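"""Map-space projection: continuous suitability maps, maxTSS binarization,
change categories and cell-area-weighted range change.

The ensemble is evaluated on every sea cell of a predictor stack; the
continuous map is thresholded at the maxTSS threshold derived from the
full-data training predictions (one threshold per model, reused across
scenarios).  Current/future binary pairs classify each cell as loss,
stable, gain or unsuitable, and range change is the percent change of
cell-area-weighted suitable area.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble import EnsembleModel
from .grid import GridSpec, Layer, PredictorStack, cell_area_grid
from .simulate import stack_env_frame

#: change-map category codes
UNSUITABLE, LOSS, STABLE, GAIN = 0, 1, 2, 3
CHANGE_LEGEND = {UNSUITABLE: "unsuitable", LOSS: "loss", STABLE: "stable", GAIN: "gain"}


class ProjectionError(ValueError):
    pass


@dataclass
class SuitabilityMap:
    layer: Layer
    model_id: str
    scenario_tag: str


@dataclass
class BinaryMap:
    layer: Layer
    threshold: float
    model_id: str = ""
    scenario_tag: str = ""

    def suitable(self) -> np.ndarray:
        """Boolean suitable-cell array (False off-mask)."""
        return self.layer.mask & (self.layer.values == 1.0)


@dataclass
class ChangeMap:
    layer: Layer  # values are CHANGE_LEGEND codes on valid cells


def predict_map(
    ensemble: EnsembleModel, stack: PredictorStack, model_id: str = "ensemble"
) -> SuitabilityMap:
    """Ensemble suitability on every sea cell; masked cells stay masked."""
    missing = [c for c in ensemble.members[0].columns if c not in stack]
    if missing:
        raise ProjectionError(f"stack is missing layer(s) {missing}")
    env = stack_env_frame(stack)
    pred = ensemble.predict(env)
    vals = np.full(stack.grid.shape, np.nan)
    vals[env["row"].to_numpy(), env["col"].to_numpy()] = pred
    layer = Layer(
        grid=stack.grid, values=vals, mask=stack.mask.copy(),
        name=f"suitability_{model_id}_{stack.scenario_tag}",
    )
    return SuitabilityMap(layer=layer, model_id=model_id,
                          scenario_tag=stack.scenario_tag)


def binarize(smap: SuitabilityMap, tau: float) -> BinaryMap:
    """Threshold at tau (clamped to [0, 1]); suitability >= tau counts as
    presence."""
    tau = float(np.clip(tau, 0.0, 1.0))
    lyr = smap.layer
    vals = np.where(lyr.mask, (lyr.values >= tau).astype(float), np.nan)
    layer = Layer(
        grid=lyr.grid, values=vals, mask=lyr.mask.copy(),
        name=lyr.name.replace("suitability", "binary"),
    )
    return BinaryMap(layer=layer, threshold=tau, model_id=smap.model_id,
                     scenario_tag=smap.scenario_tag)


def _check_same_grid(a: Layer, b: Layer) -> None:
    if a.grid != b.grid or not np.array_equal(a.mask, b.mask):
        raise ProjectionError("maps are on different grids or masks")


def change_map(current: BinaryMap, future: BinaryMap) -> ChangeMap:
    """Per-cell change category from the (current, future) binary pair:
    (1,0) loss, (1,1) stable, (0,1) gain, (0,0) unsuitable."""
    _check_same_grid(current.layer, future.layer)
    cur = current.suitable()
    fut = future.suitable()
    codes = np.full(current.layer.grid.shape, float(UNSUITABLE))
    codes[cur & ~fut] = LOSS
    codes[cur & fut] = STABLE
    codes[~cur & fut] = GAIN
    vals = np.where(current.layer.mask, codes, np.nan)
    layer = Layer(
        grid=current.layer.grid, values=vals, mask=current.layer.mask.copy(),
        name=f"change_{current.model_id}_{future.scenario_tag}",
    )
    return ChangeMap(layer=layer)


def suitable_area_km2(binary: BinaryMap) -> float:
    """Cell-area-weighted suitable area in km²."""
    areas = cell_area_grid(binary.layer.grid)
    return float(areas[binary.suitable()].sum())


def range_change(current: BinaryMap, future: BinaryMap) -> float:
    """Percent change in suitable area, 100 x (A_future - A_current) / A_current,
    cell-area-weighted; negative means contraction."""
    _check_same_grid(current.layer, future.layer)
    a_cur = suitable_area_km2(current)
    if a_cur <= 0:
        raise ProjectionError("current suitable area is zero; range change undefined")
    a_fut = suitable_area_km2(future)
    return 100.0 * (a_fut - a_cur) / a_cur


def change_areas_km2(cmap: ChangeMap) -> dict[str, float]:
    """km² per change category; loss + stable equals the current suitable
    area and stable + gain the future one."""
    areas = cell_area_grid(cmap.layer.grid)
    out = {}
    for code, name in CHANGE_LEGEND.items():
        sel = cmap.layer.mask & (cmap.layer.values == code)
        out[name] = float(areas[sel].sum())
    return out


def restrict_to_region(binary: BinaryMap, region_mask: np.ndarray) -> BinaryMap:
    """Zero out suitability outside a boolean region (population reporting)."""
    lyr = binary.layer
    vals = np.where(lyr.mask & region_mask, lyr.values, np.where(lyr.mask, 0.0, np.nan))
    layer = Layer(grid=lyr.grid, values=vals, mask=lyr.mask.copy(),
                  name=lyr.name + "_region")
    return BinaryMap(layer=layer, threshold=binary.threshold,
                     model_id=binary.model_id, scenario_tag=binary.scenario_tag)
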