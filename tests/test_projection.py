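import numpy as np
import pandas as pd
import pytest

from tridacna_sdm.ensemble import EnsembleModel, LearnerSpec
from tridacna_sdm.grid import GridSpec, Layer, cell_area_grid
from tridacna_sdm.projection import (
    GAIN,
    LOSS,
    STABLE,
    UNSUITABLE,
    BinaryMap,
    ProjectionError,
    SuitabilityMap,
    binarize,
    change_areas_km2,
    change_map,
    predict_map,
    range_change,
    suitable_area_km2,
)
from tridacna_sdm.simulate import (
    NicheFunction,
    ScenarioDelta,
    apply_scenario,
    scenario_stacks,
    true_suitability,
)


class ConstMember:
    def __init__(self, value, columns):
        self.value = value
        self.columns = columns
        self.spec = LearnerSpec("GLM")

    def predict(self, env):
        return np.full(len(env), self.value)


def binary_from_bools(grid, suitable, mask=None):
    mask = np.ones(grid.shape, bool) if mask is None else mask
    vals = np.where(mask, suitable.astype(float), np.nan)
    return BinaryMap(layer=Layer(grid, vals, mask, "bin"), threshold=0.5)


def binarize_truth(stack, niche, tau=0.5):
    truth = true_suitability(stack, niche)
    smap = SuitabilityMap(layer=truth, model_id="truth",
                          scenario_tag=stack.scenario_tag)
    return binarize(smap, tau)


@pytest.fixture(scope="module")
def equal_area_grid():
    """A single-row grid straddling the equator: every cell has the same area."""
    return GridSpec(0.0, 1000 * (5 / 60), -2.5 / 60, 2.5 / 60)


class TestPredictMap:
    def test_constant_ensemble_constant_map(self, small_stack):
        ens = EnsembleModel(members=[ConstMember(0.42, small_stack.names)],
                            weights=[1.0], tss_min=0.7, auc_min=0.8,
                            weighting="equal")
        smap = predict_map(ens, small_stack)
        vals = smap.layer.values[small_stack.mask]
        assert np.allclose(vals, 0.42)
        assert np.isnan(smap.layer.values[~small_stack.mask]).all()

    def test_zero_delta_scenario_identical_map(self, small_stack):
        ens = EnsembleModel(members=[ConstMember(0.3, small_stack.names)],
                            weights=[1.0], tss_min=0.7, auc_min=0.8,
                            weighting="equal")
        null_future = apply_scenario(small_stack, ScenarioDelta(), "null")
        a = predict_map(ens, small_stack)
        b = predict_map(ens, null_future)
        assert np.array_equal(a.layer.values, b.layer.values, equal_nan=True)

    def test_missing_layer_named(self, small_stack):
        ens = EnsembleModel(
            members=[ConstMember(0.3, small_stack.names + ["mystery_var"])],
            weights=[1.0], tss_min=0.7, auc_min=0.8, weighting="equal")
        with pytest.raises(ProjectionError, match="mystery_var"):
            predict_map(ens, small_stack)


class TestBinarize:
    def _smap(self, grid, values):
        mask = np.ones(grid.shape, bool)
        return SuitabilityMap(Layer(grid, values, mask, "s"), "m", "current")

    def test_zero_threshold_all_suitable(self, rng):
        g = GridSpec(0, 1, 0, 1)
        smap = self._smap(g, rng.random(g.shape))
        assert binarize(smap, 0.0).suitable().all()

    def test_threshold_above_one_clamped(self, rng):
        g = GridSpec(0, 1, 0, 1)
        vals = rng.random(g.shape)
        vals[0, 0] = 1.0
        bmap = binarize(self._smap(g, vals), 1.5)
        assert bmap.threshold == 1.0
        assert bmap.suitable().sum() == (vals >= 1.0).sum()

    def test_count_matches_brute_force(self, rng):
        g = GridSpec(0, 2, 0, 2)
        vals = rng.random(g.shape)
        bmap = binarize(self._smap(g, vals), 0.6)
        brute = sum(vals[r, c] >= 0.6
                    for r in range(g.n_rows) for c in range(g.n_cols))
        assert bmap.suitable().sum() == brute


class TestChangeMap:
    def test_all_loss(self, equal_area_grid):
        g = equal_area_grid
        cur = binary_from_bools(g, np.ones(g.shape, bool))
        fut = binary_from_bools(g, np.zeros(g.shape, bool))
        cmap = change_map(cur, fut)
        assert (cmap.layer.values == LOSS).all()

    def test_identical_maps_only_stable_or_unsuitable(self, equal_area_grid, rng):
        g = equal_area_grid
        suit = rng.random(g.shape) > 0.5
        cmap = change_map(binary_from_bools(g, suit), binary_from_bools(g, suit))
        assert set(np.unique(cmap.layer.values)) <= {STABLE, UNSUITABLE}

    def test_random_pair_matches_tabulation(self, equal_area_grid, rng):
        g = equal_area_grid
        cur = rng.random(g.shape) > 0.4
        fut = rng.random(g.shape) > 0.6
        cmap = change_map(binary_from_bools(g, cur), binary_from_bools(g, fut))
        codes = cmap.layer.values
        assert (codes == LOSS).sum() == (cur & ~fut).sum()
        assert (codes == STABLE).sum() == (cur & fut).sum()
        assert (codes == GAIN).sum() == (~cur & fut).sum()
        assert (codes == UNSUITABLE).sum() == (~cur & ~fut).sum()

    def test_grid_mismatch(self, equal_area_grid, small_grid):
        a = binary_from_bools(equal_area_grid,
                              np.ones(equal_area_grid.shape, bool))
        b = binary_from_bools(small_grid, np.ones(small_grid.shape, bool))
        with pytest.raises(ProjectionError):
            change_map(a, b)


class TestRangeChange:
    def test_500_to_400_equal_area_cells(self, equal_area_grid):
        g = equal_area_grid
        cur = np.zeros(g.shape, bool)
        fut = np.zeros(g.shape, bool)
        cur[0, :500] = True
        fut[0, :400] = True
        rc = range_change(binary_from_bools(g, cur), binary_from_bools(g, fut))
        assert rc == pytest.approx(-20.0, abs=1e-9)

    def test_identical_zero(self, equal_area_grid, rng):
        g = equal_area_grid
        suit = rng.random(g.shape) > 0.5
        a, b = binary_from_bools(g, suit), binary_from_bools(g, suit)
        assert range_change(a, b) == 0.0

    def test_doubling_is_plus_hundred(self, equal_area_grid):
        g = equal_area_grid
        cur = np.zeros(g.shape, bool)
        fut = np.zeros(g.shape, bool)
        cur[0, :300] = True
        fut[0, :600] = True
        rc = range_change(binary_from_bools(g, cur), binary_from_bools(g, fut))
        assert rc == pytest.approx(100.0, abs=1e-9)

    def test_zero_current_area_undefined(self, equal_area_grid):
        g = equal_area_grid
        none = binary_from_bools(g, np.zeros(g.shape, bool))
        some = binary_from_bools(g, np.ones(g.shape, bool))
        with pytest.raises(ProjectionError):
            range_change(none, some)

    def test_warming_scenarios_monotone_on_synthetic_truth(self, small_stack):
        """On the generating truth, the scenario sequence 2050s RCP2.6 →
        2100s RCP8.5 loses suitable area monotonically, and strong warming
        pushes temperatures past the optimum so area strictly shrinks."""
        niche = NicheFunction(optima={"temperature_mean": 27.4,
                                      "salinity": 33.2},
                              tolerances={"temperature_mean": 1.2,
                                          "salinity": 1.0})
        cur = binarize_truth(small_stack, niche)
        order = ["2050s_RCP2.6", "2100s_RCP2.6", "2050s_RCP8.5", "2100s_RCP8.5"]
        futures = scenario_stacks(small_stack)
        changes = [range_change(cur, binarize_truth(futures[t], niche))
                   for t in order]
        assert all(a > b for a, b in zip(changes, changes[1:]))
        assert changes[-1] < 0

    def test_conservation_identities_and_consistency(self, small_grid, rng):
        """loss + stable = current area; stable + gain = future area; the
        range change from change-map areas equals the direct computation."""
        for seed in range(5):
            r = np.random.default_rng(seed)
            mask = r.random(small_grid.shape) > 0.2
            cur_b = mask & (r.random(small_grid.shape) > 0.4)
            fut_b = mask & (r.random(small_grid.shape) > 0.5)
            cur = binary_from_bools(small_grid, cur_b, mask)
            fut = binary_from_bools(small_grid, fut_b, mask)
            areas = change_areas_km2(change_map(cur, fut))
            a_cur = suitable_area_km2(cur)
            a_fut = suitable_area_km2(fut)
            assert areas["loss"] + areas["stable"] == pytest.approx(a_cur, rel=1e-12)
            assert areas["stable"] + areas["gain"] == pytest.approx(a_fut, rel=1e-12)
            if a_cur > 0:
                via_change = 100.0 * (a_fut - a_cur) / a_cur
                assert range_change(cur, fut) == pytest.approx(via_change, abs=1e-9)
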