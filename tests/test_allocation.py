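import numpy as np
import pandas as pd
import pytest

import ecoscape as es
from conftest import make_lulc


def toy_drivers(grid, rng):
    return es.DriverStack(
        grid=grid,
        layers={
            "elevation": rng.random(grid.shape) * 200,
            "noise": rng.random(grid.shape),
        },
    )


class TestExpansionSampling:
    def test_no_change_no_positives(self, landscape):
        t1 = landscape["t1"]
        s = None
        with pytest.warns(UserWarning, match="no expansion cells"):
            s = es.extract_expansion_samples(
                t1, t1.copy(), landscape["drivers"], target_class=1
            )
        assert s.X.shape[0] == 0

    def test_positive_count_by_construction(self):
        rng = np.random.default_rng(0)
        codes = np.full((10, 10), 2, dtype=np.int64)
        m1 = make_lulc(codes)
        m2 = m1.copy()
        m2.codes[0, 0] = m2.codes[3, 4] = m2.codes[9, 9] = 1
        drivers = toy_drivers(m1.grid, rng)
        s = es.extract_expansion_samples(m1, m2, drivers, 1, seed=7)
        assert int(s.y.sum()) == 3
        assert s.X.shape == (6, 2)  # 3 positives + 1:1 background

    def test_seed_reproducibility(self, landscape):
        args = (landscape["t1"], landscape["t2"], landscape["drivers"], 1)
        a = es.extract_expansion_samples(*args, seed=3)
        b = es.extract_expansion_samples(*args, seed=3)
        np.testing.assert_array_equal(a.X, b.X)
        np.testing.assert_array_equal(a.y, b.y)


class TestDevelopmentProbability:
    def make_separable(self):
        """Expansion happens iff elevation < 100, noise-free."""
        rng = np.random.default_rng(1)
        grid = es.GridSpec(40, 40, 30.0)
        elevation = rng.random(grid.shape) * 200
        drivers = es.DriverStack(
            grid=grid,
            layers={"elevation": elevation, "constant": np.zeros(grid.shape)},
        )
        m1 = make_lulc(np.full(grid.shape, 2), cell_size=30.0)
        m2 = m1.copy()
        m2.codes[elevation < 100] = 1
        return m1, m2, drivers, elevation

    def test_separable_rule_learned(self):
        m1, m2, drivers, elevation = self.make_separable()
        s = es.extract_expansion_samples(m1, m2, drivers, 1, seed=0)
        dp = es.fit_development_probability(s, drivers, seed=0)
        low, high = elevation < 80, elevation > 120  # away from the boundary
        assert np.nanmean(dp.surface[low]) > 0.9
        assert np.nanmean(dp.surface[high]) < 0.1
        assert dp.importances.idxmax() == "elevation"

    def test_constant_driver_uninformative(self):
        m1, m2, drivers, _ = self.make_separable()
        s = es.extract_expansion_samples(m1, m2, drivers, 1, seed=0)
        dp = es.fit_development_probability(s, drivers, seed=0)
        assert dp.importances["constant"] == pytest.approx(0.0, abs=1e-6)
        assert dp.importances.sum() == pytest.approx(1.0)

    def test_seed_reproducibility(self):
        m1, m2, drivers, _ = self.make_separable()
        s = es.extract_expansion_samples(m1, m2, drivers, 1, seed=0)
        a = es.fit_development_probability(s, drivers, seed=5)
        b = es.fit_development_probability(s, drivers, seed=5)
        np.testing.assert_array_equal(a.surface, b.surface)

    def test_single_label_rejected(self):
        m1, m2, drivers, _ = self.make_separable()
        s = es.extract_expansion_samples(m1, m2, drivers, 1, seed=0)
        s.y[:] = 1
        with pytest.raises(ValueError, match="both positive and background"):
            es.fit_development_probability(s, drivers)


class TestNeighborhoodEffect:
    def test_uniform_map_is_one(self):
        m = make_lulc(np.full((7, 7), 2))
        np.testing.assert_allclose(es.neighborhood_effect(m, 2, radius=1), 1.0)

    def test_single_cell_interior_hand_count(self):
        codes = np.full((7, 7), 2, dtype=np.int64)
        codes[3, 3] = 1
        m = make_lulc(codes)
        eff = es.neighborhood_effect(m, 1, radius=1)
        assert eff[3, 4] == pytest.approx(1 / 9)
        assert eff[3, 3] == pytest.approx(1 / 9)
        assert eff[0, 0] == 0.0

    def test_truncated_edge_window(self):
        codes = np.full((5, 5), 2, dtype=np.int64)
        codes[0, 0] = 1
        m = make_lulc(codes)
        eff = es.neighborhood_effect(m, 1, radius=1)
        assert eff[0, 0] == pytest.approx(1 / 4)  # corner window has 4 cells

    def test_bounded(self, landscape):
        eff = es.neighborhood_effect(landscape["t1"], 2, radius=2)
        assert eff.min() >= 0.0 and eff.max() <= 1.0


def uniform_probs(grid, classes, value=1.0):
    return {
        c: es.DevelopmentProbability(
            c, np.full(grid.shape, value), pd.Series({"x": 1.0})
        )
        for c in classes
    }


class TestAllocate:
    def forest_map(self, n=20):
        codes = np.full((n, n), 2, dtype=np.int64)
        codes[:3, :] = 1  # a farmland band to seed the neighbourhood
        return make_lulc(codes, cell_size=1000.0)

    def test_demand_equals_current_is_identity(self):
        m = self.forest_map()
        demand = pd.Series(m.class_areas_km2())
        res = es.allocate(m, demand, uniform_probs(m.grid, [1, 2]))
        assert res.converged
        np.testing.assert_array_equal(res.lulc.codes, m.codes)

    def test_moves_exact_cell_count(self):
        m = self.forest_map()
        areas = m.class_areas_km2()
        demand = pd.Series(areas) + pd.Series({1: 10.0, 2: -10.0}).reindex(
            areas.keys(), fill_value=0.0
        )
        res = es.allocate(m, demand, uniform_probs(m.grid, [1]))
        assert res.converged
        assert res.lulc.class_counts()[1] == m.class_counts()[1] + 10
        assert res.lulc.class_counts()[2] == m.class_counts()[2] - 10

    def test_mask_blocks_all_conversions(self):
        m = self.forest_map()
        areas = m.class_areas_km2()
        demand = pd.Series(areas) + pd.Series({1: 10.0, 2: -10.0}).reindex(
            areas.keys(), fill_value=0.0
        )
        cfg = es.AllocationConfig(
            restricted_mask=np.ones(m.grid.shape, dtype=bool), max_iterations=30
        )
        with pytest.warns(UserWarning, match="did not meet demand"):
            res = es.allocate(m, demand, uniform_probs(m.grid, [1]), cfg)
        assert res.infeasible
        np.testing.assert_array_equal(res.lulc.codes, m.codes)
        assert res.residuals.abs().max() == pytest.approx(10.0)

    def test_determinism_under_seed(self, landscape):
        t2 = landscape["t2"]
        areas = pd.Series(t2.class_areas_km2())
        shift = areas[2] * 0.02
        demand = areas.add(
            pd.Series({1: shift, 2: -shift}), fill_value=0.0
        )
        rng = np.random.default_rng(2)
        probs = {
            1: es.DevelopmentProbability(
                1, rng.random(t2.grid.shape), pd.Series({"x": 1.0})
            )
        }
        cfg = es.AllocationConfig(rng_seed=9)
        a = es.allocate(t2, demand, probs, cfg)
        b = es.allocate(t2, demand, probs, cfg)
        np.testing.assert_array_equal(a.lulc.codes, b.lulc.codes)
        assert a.n_iterations == b.n_iterations

    def test_prefers_high_probability_cells(self, landscape):
        t2 = landscape["t2"]
        areas = pd.Series(t2.class_areas_km2())
        shift = areas[2] * 0.05
        demand = areas.add(pd.Series({1: shift, 2: -shift}), fill_value=0.0)
        rng = np.random.default_rng(4)
        surface = rng.random(t2.grid.shape)
        probs = {1: es.DevelopmentProbability(1, surface, pd.Series({"x": 1.0}))}
        res = es.allocate(t2, demand, probs, es.AllocationConfig(rng_seed=0))
        converted = (t2.codes != res.lulc.codes) & (res.lulc.codes == 1)
        assert converted.any()
        assert surface[converted].mean() > surface[t2.codes == 2].mean()

    def test_conservation_of_cells(self, landscape):
        t2 = landscape["t2"]
        areas = pd.Series(t2.class_areas_km2())
        shift = areas[2] * 0.02
        demand = areas.add(pd.Series({1: shift, 2: -shift}), fill_value=0.0)
        res = es.allocate(t2, demand, uniform_probs(t2.grid, [1]))
        assert res.lulc.n_valid == t2.n_valid
        assert sum(res.lulc.class_counts().values()) == sum(
            t2.class_counts().values()
        )

    def test_demand_exceeding_map_raises(self):
        m = self.forest_map()
        demand = pd.Series(m.class_areas_km2()) * 2
        with pytest.raises(ValueError, match="demand exceeds"):
            es.allocate(m, demand, uniform_probs(m.grid, [1]))
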