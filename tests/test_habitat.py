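import itertools

import numpy as np
import pytest

import ecoscape as es
from ecoscape.habitat import EXP_DECAY_RATE
from conftest import make_lulc, random_lulc

FARM = es.ThreatSpec("farmland", 1, d_max=1.0, weight=0.4, decay="linear")
CONS = es.ThreatSpec("construction", 6, d_max=10.0, weight=1.0, decay="exponential")


def brute_force_degradation(lulc, threats, sens, beta=1.0):
    """All-pairs reference: per threat, influence = decay of nearest source."""
    cell_km = lulc.grid.cell_size / 1000.0
    w_total = sum(t.weight for t in threats)
    D = np.full(lulc.grid.shape, np.nan)
    rows, cols = np.indices(lulc.grid.shape)
    for x in zip(*np.nonzero(lulc.valid_mask)):
        total = 0.0
        for t in threats:
            src = np.argwhere(lulc.codes == t.source_class)
            if len(src) == 0:
                continue
            d_min = min(
                np.hypot(x[0] - y[0], x[1] - y[1]) * cell_km for y in src
            )
            if t.decay == "linear":
                i = max(0.0, 1.0 - d_min / t.d_max)
            else:
                i = np.exp(-EXP_DECAY_RATE * d_min / t.d_max)
            if d_min > t.d_max:
                i = 0.0
            total += (t.weight / w_total) * i * sens.sensitivity[
                int(lulc.codes[x])
            ][t.name]
        D[x] = min(max(total * beta, 0.0), 1.0)
    return D


class TestDecayWeight:
    def test_zero_distance_is_one(self):
        assert es.decay_weight(0.0, FARM) == pytest.approx(1.0)
        assert es.decay_weight(0.0, CONS) == pytest.approx(1.0)

    def test_linear_vanishes_at_dmax(self):
        assert es.decay_weight(FARM.d_max, FARM) == pytest.approx(0.0)
        assert es.decay_weight(0.5, FARM) == pytest.approx(0.5)

    def test_exponential_closed_form(self):
        # independent evaluation of exp(-2.99 d / d_max)
        for d in (1.0, 5.0, 10.0):
            assert es.decay_weight(d, CONS) == pytest.approx(
                np.exp(-2.99 * d / 10.0)
            )
        assert es.decay_weight(CONS.d_max, CONS) == pytest.approx(
            np.exp(-2.99), rel=1e-12
        )

    def test_clamped_beyond_dmax(self):
        assert es.decay_weight(1.01, FARM) == 0.0
        assert es.decay_weight(10.5, CONS) == 0.0

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            es.decay_weight(-0.1, FARM)


class TestThreatPresence:
    def test_no_sources(self):
        m = make_lulc(np.full((4, 4), 2))
        assert es.threat_presence(m, FARM).sum() == 0

    def test_counts_match_histogram(self):
        rng = np.random.default_rng(5)
        m = random_lulc(rng)
        for t in (FARM, CONS):
            assert es.threat_presence(m, t).sum() == m.class_counts().get(
                t.source_class, 0
            )


class TestDegradation:
    def test_no_sources_means_zero(self):
        m = make_lulc(np.full((6, 6), 2))
        D = es.compute_degradation(m)
        assert np.all(D == 0.0)

    def test_weight_normalisation_invariance(self):
        rng = np.random.default_rng(7)
        m = random_lulc(rng, p_nodata=0.0)
        doubled = [
            es.ThreatSpec(t.name, t.source_class, t.d_max, 2 * t.weight, t.decay)
            for t in (FARM, CONS)
        ]
        np.testing.assert_allclose(
            es.compute_degradation(m, [FARM, CONS]),
            es.compute_degradation(m, doubled),
            atol=1e-12,
        )

    def test_single_pair_hand_value(self):
        # construction at (0,0), forest at (0,5): 5 km apart on 1 km cells
        codes = np.zeros((1, 6), dtype=np.int64)
        codes[0, 0] = 6
        codes[0, 5] = 2
        m = make_lulc(codes, cell_size=1000.0)
        D = es.compute_degradation(m, [CONS])
        expected = 1.0 * np.exp(-2.99 * 5.0 / 10.0) * 1.0 * 0.5  # ω̂·i·β·S(forest)
        assert D[0, 5] == pytest.approx(expected, abs=1e-12)
        assert D[0, 0] == pytest.approx(0.0)  # construction insensitive to itself

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = random_lulc(rng, shape=(15, 15), cell_size=1000.0)
        sens = es.default_sensitivity()
        D = es.compute_degradation(m, [FARM, CONS], sens)
        ref = brute_force_degradation(m, [FARM, CONS], sens)
        np.testing.assert_allclose(D, ref, atol=1e-9, equal_nan=True)

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(9)
        m = random_lulc(rng, p_nodata=0.0)
        mirrored = make_lulc(m.codes[:, ::-1], cell_size=m.grid.cell_size)
        np.testing.assert_allclose(
            es.compute_degradation(m)[:, ::-1],
            es.compute_degradation(mirrored),
            atol=1e-12,
        )

    def test_mean_aggregation_bounded_by_nearest(self):
        rng = np.random.default_rng(13)
        m = random_lulc(rng, p_nodata=0.0, cell_size=200.0)
        near = es.compute_degradation(m, config=es.HabitatConfig(aggregation="nearest"))
        mean = es.compute_degradation(m, config=es.HabitatConfig(aggregation="mean"))
        assert np.all(mean <= near + 1e-9)

    def test_missing_sensitivity_entry_raises(self):
        m = make_lulc([[1, 2]])
        sens = es.SensitivityTable(
            suitability={1: 0.3, 2: 1.0}, sensitivity={1: {}, 2: {}}
        )
        with pytest.raises(KeyError):
            es.compute_degradation(m, [FARM], sens)


class TestQuality:
    def test_pristine_forest_scores_one(self):
        m = make_lulc(np.full((3, 3), 2))
        D = es.compute_degradation(m)
        Q = es.compute_quality(m, D)
        assert np.all(Q == pytest.approx(1.0))

    def test_construction_scores_zero_regardless_of_degradation(self):
        codes = np.full((3, 3), 6, dtype=np.int64)
        m = make_lulc(codes)
        Q = es.compute_quality(m, np.full((3, 3), 0.8))
        assert np.all(Q == 0.0)

    def test_half_saturation_symmetry(self):
        m = make_lulc(np.full((2, 2), 4))  # grass, H = 0.7
        k = 0.37
        Q = es.compute_quality(m, np.full((2, 2), k), config=es.HabitatConfig(k=k))
        assert np.all(Q == pytest.approx(0.7 / 2))

    def test_quality_bounded_by_suitability(self):
        rng = np.random.default_rng(3)
        m = random_lulc(rng)
        D = es.compute_degradation(m)
        Q = es.compute_quality(m, D)
        H = es.default_sensitivity().suitability
        for c, h in H.items():
            sel = m.codes == c
            if sel.any():
                assert np.nanmax(Q[sel]) <= h + 1e-12

    def test_monotonicity_adding_threat_source(self):
        # turning a forest cell into construction never raises Q anywhere
        rng = np.random.default_rng(21)
        for _ in range(3):
            m = random_lulc(rng, shape=(12, 12), cell_size=500.0, p_nodata=0.0)
            forest_cells = np.argwhere(m.codes == 2)
            if len(forest_cells) == 0:
                continue
            r, c = forest_cells[rng.integers(len(forest_cells))]
            worse = m.copy()
            worse.codes[r, c] = 6
            q0 = es.compute_quality(m, es.compute_degradation(m))
            q1 = es.compute_quality(worse, es.compute_degradation(worse))
            other = np.ones(m.grid.shape, dtype=bool)
            other[r, c] = False
            assert np.all(q1[other] <= q0[other] + 1e-12)


class TestClassification:
    @pytest.mark.parametrize(
        "q,grade",
        [(0.99, 4), (1.0, 4), (0.984, 4), (0.698, 3), (0.5, 2), (0.298, 2), (0.0, 1)],
    )
    def test_grade_boundaries(self, q, grade):
        assert es.classify_quality(np.array([[q]]))[0, 0] == grade

    def test_nan_maps_to_zero(self):
        g = es.classify_quality(np.array([[np.nan, 0.5]]))
        assert g[0, 0] == 0 and g[0, 1] == 2


class TestJenksBreaks:
    def test_two_cluster_sample(self):
        breaks = es.jenks_breaks([0.1, 0.11, 0.9, 0.91], 2)
        assert len(breaks) == 1
        assert 0.11 <= breaks[0] < 0.9

    @pytest.mark.parametrize("seed", range(3))
    def test_optimal_against_exhaustive_partitions(self, seed):
        rng = np.random.default_rng(seed)
        x = np.sort(rng.random(10))
        k = 3

        def ssd(seg):
            return float(np.sum((seg - seg.mean()) ** 2))

        best = np.inf
        for cut1, cut2 in itertools.combinations(range(1, len(x)), 2):
            cost = ssd(x[:cut1]) + ssd(x[cut1:cut2]) + ssd(x[cut2:])
            best = min(best, cost)
        breaks = es.jenks_breaks(x, k)
        # reconstruct classes from the returned upper-inclusive cut points
        labels = np.searchsorted(breaks, x, side="left")
        got = sum(ssd(x[labels == c]) for c in np.unique(labels))
        assert got == pytest.approx(best, abs=1e-12)

    def test_each_distinct_value_its_own_class(self):
        breaks = es.jenks_breaks([1.0, 2.0, 3.0], 3)
        assert breaks == [1.0, 2.0]

    def test_degenerate_sample_warns(self):
        with pytest.warns(UserWarning, match="all values equal"):
            assert es.jenks_breaks([0.5] * 6, 3) == [0.5]


class TestGradeSummary:
    def test_uniform_excellent(self):
        grid = es.GridSpec(2, 2, 1000.0)
        q = np.ones((2, 2))
        g = es.classify_quality(q)
        df = es.grade_summary(g, q, np.zeros((2, 2)), grid)
        assert df.loc[4, "proportion"] == pytest.approx(1.0)
        assert df.attrs["mean_quality"] == pytest.approx(1.0)

    def test_four_cell_hand_average(self):
        grid = es.GridSpec(2, 2, 1000.0)
        q = np.array([[1.0, 0.9], [0.5, 0.1]])
        d = np.array([[0.0, 0.1], [0.4, 0.9]])
        g = es.classify_quality(q)
        df = es.grade_summary(g, q, d, grid)
        assert df.attrs["mean_quality"] == pytest.approx(0.625)
        assert df.attrs["mean_degradation"] == pytest.approx(0.35)
        assert df["area"].sum() == pytest.approx(4.0)
        assert df.loc[4, "area"] == pytest.approx(1.0)  # only Q=1.0 is >= 0.984
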