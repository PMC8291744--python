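"""The four classification methods and their shuffle machinery."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import placecell as pc
from placecell import detect as d


class TestTimeShiftShuffle:
    def test_value_multiset_preserved(self):
        x = np.random.default_rng(0).normal(size=500)
        y = pc.time_shift_shuffle(x, seed=1)
        np.testing.assert_array_equal(np.sort(x), np.sort(y))
        assert not np.array_equal(x, y)

    def test_minimum_shift_frames(self):
        # ceil(5 s * 7.51 Hz) = 38 frames, and the identity shift (T) is
        # outside the draw range
        assert d._min_shift_frames(7.51, 5.0) == 38
        shifts = d._draw_shifts(np.random.default_rng(0), 2000, 500, 38)
        assert shifts.min() >= 38 and shifts.max() <= 500 - 38

    def test_trace_too_short(self):
        with pytest.raises(pc.ParameterError):
            pc.time_shift_shuffle(np.zeros(40), frame_rate=7.51)


class TestChunkShuffle:
    @given(st.integers(1, 60), st.integers(0, 10))
    def test_multiset_preserved(self, chunk_frames, seed):
        x = np.random.default_rng(3).normal(size=173)
        y = pc.chunk_shuffle(x, chunk_s=chunk_frames / 7.51, seed=seed)
        np.testing.assert_array_equal(np.sort(x), np.sort(y))

    def test_single_chunk_is_identity(self):
        x = np.arange(50.0)
        y = pc.chunk_shuffle(x, chunk_s=100.0, seed=0)
        np.testing.assert_array_equal(x, y)

    def test_all_orders_reachable(self):
        x = np.arange(8.0)
        orders = {tuple(pc.chunk_shuffle(x, chunk_s=2 / 7.51, seed=s))
                  for s in range(200)}
        assert len(orders) == 24  # 4 chunks of 2 frames -> 4! orders

    def test_bad_chunk(self):
        with pytest.raises(pc.ParameterError):
            pc.chunk_shuffle(np.zeros(10), chunk_s=0)


class TestSpatialInformation:
    def test_uniform_map_is_zero(self):
        assert pc.spatial_information([2.0, 2.0, 2.0]) == 0.0

    def test_single_bin_closed_form(self):
        v, n = 2.0, 4
        np.testing.assert_allclose(pc.spatial_information([0, 0, v, 0]),
                                   v * np.log2(n))

    def test_direct_evaluation(self):
        np.testing.assert_allclose(pc.spatial_information([2.0, 1.0, 1.0]),
                                   2 * np.log2(1.5) + 2 * np.log2(0.75),
                                   atol=1e-10)
        # == 0.3399 to 4 decimals
        assert round(pc.spatial_information([2.0, 1.0, 1.0]), 4) == 0.3399

    def test_zero_mean_map(self):
        assert pc.spatial_information([0.0, 0.0]) == 0.0
        assert pc.spatial_information([-1.0, -2.0]) == 0.0

    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=30))
    def test_nonnegative_and_permutation_invariant(self, vals):
        si = pc.spatial_information(vals)
        assert si >= 0
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(vals))
        np.testing.assert_allclose(
            pc.spatial_information(np.asarray(vals)[perm]), si, atol=1e-9)


class TestNearestRank:
    def test_ranks(self):
        v = np.arange(1, 101)
        assert d.nearest_rank(v, 95) == 95
        assert d.nearest_rank(v, 99) == 99
        assert d.nearest_rank(np.arange(1, 6), 50) == 3


class TestPeakMethod:
    def test_constant_cell_never_classified(self, loco, mask):
        dff = np.full((1, loco.n_frames), 0.7)
        r = pc.peak_method(dff, loco.position, mask, n_shuffles=50, seed=0)
        assert not r.labels[0]

    def test_default_place_cell_detected(self, loco, mask, small_population):
        r = pc.peak_method(small_population.dff, loco.position, mask,
                           n_shuffles=200, seed=1)
        assert r.labels[:5].all()  # the 5 true place cells

    def test_decision_invariant_to_constant_offset(self, loco, mask,
                                                   small_population):
        dff = small_population.dff
        a = pc.peak_method(dff, loco.position, mask, n_shuffles=100, seed=2)
        b = pc.peak_method(dff + 3.0, loco.position, mask, n_shuffles=100,
                           seed=2)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_allclose(b.statistic - a.statistic, 3.0)


class TestInformationMethod:
    def test_constant_cell_never_classified(self, loco, mask):
        dff = np.full((1, loco.n_frames), 0.7)
        r = pc.information_method(dff, loco.position, mask, n_shuffles=50,
                                  seed=0)
        assert not r.labels[0] and r.statistic[0] == 0.0

    def test_default_place_cell_detected(self, loco, mask, small_population):
        r = pc.information_method(small_population.dff, loco.position, mask,
                                  n_shuffles=200, seed=3)
        assert r.labels[:5].all()


class TestStabilityMethod:
    def test_identical_halves_give_r_one(self, loco, mask, small_population):
        r = pc.stability_method(small_population.dff, loco.position, mask,
                                seed=4)
        assert r.labels[:5].all()
        assert (r.statistic[:5] > 0.9).all()

    def test_statistic_scale_invariant(self, loco, mask, small_population):
        dff = small_population.dff.copy()
        a = pc.stability_method(dff, loco.position, mask, seed=5)
        dff[0] = 2.5 * dff[0] + 0.3  # positive affine rescale of one cell
        b = pc.stability_method(dff, loco.position, mask, seed=5)
        np.testing.assert_allclose(a.statistic[0], b.statistic[0], atol=1e-9)
        assert a.labels[0] == b.labels[0]

    def test_relocating_field_not_classified(self, loco, mask):
        # a cell active at 50 cm in the first half and 150 cm in the second
        half = loco.n_frames // 2
        centre = np.where(np.arange(loco.n_frames) < half, 50.0, 150.0)
        dff = 1.3 * np.exp(-((loco.position - centre) ** 2) / (2 * 12.5**2))
        pop = np.vstack([dff, np.random.default_rng(0).normal(
            0, 0.065, (10, loco.n_frames))])
        r = pc.stability_method(pop, loco.position, mask, seed=6)
        assert r.statistic[0] < 0.5 and not r.labels[0]

    def test_needs_two_cells(self, loco, mask):
        with pytest.raises(pc.ParameterError):
            pc.stability_method(np.zeros((1, loco.n_frames)), loco.position,
                                mask)


class TestTransientDetection:
    def test_pure_noise_nearly_empty(self):
        x = np.random.default_rng(0).normal(0, 0.05, 3000)
        tm = pc.detect_significant_transients(x)
        assert tm.mask.mean() < 0.1

    def test_single_excursion_single_run(self):
        x = np.random.default_rng(1).normal(0, 0.05, 2000)
        x[700:720] += 10 * 0.05 * 10  # one huge transient
        tm = pc.detect_significant_transients(x)
        edges = np.diff(np.concatenate([[0], tm.mask.astype(int), [0]]))
        assert (edges == 1).sum() == 1
        assert tm.mask[700:720].all()

    def test_window_longer_than_session(self):
        x = np.random.default_rng(2).normal(0, 0.05, 50)
        tm = pc.detect_significant_transients(x, window_s=100.0)
        assert np.allclose(tm.baseline, tm.baseline[0])


class TestCombinationPreprocess:
    def test_none_is_identity(self):
        x = np.random.default_rng(0).normal(size=500)
        pre = pc.combination_preprocess(x, "none")
        np.testing.assert_array_equal(pre.trace, x)

    def test_subtract_zeroes_outside_transients(self):
        x = np.random.default_rng(1).normal(0, 0.05, 1000)
        x[200:210] += 2.0
        pre = pc.combination_preprocess(x, "subtract")
        assert (pre.trace[~pre.transient_mask] == 0).all()
        assert pre.trace[200:210].max() > 1.0

    def test_divide_with_negative_baseline_raises(self):
        x = np.random.default_rng(2).normal(-0.5, 0.05, 1000)
        with pytest.raises(pc.ParameterError, match="baseline"):
            pc.combination_preprocess(x, "divide")

    def test_unknown_mode(self):
        with pytest.raises(pc.ParameterError):
            pc.combination_preprocess(np.zeros(100), "weird")


class TestCombinationCriteria:
    def _classify(self, values, **kw):
        params = pc.CombinationParams()
        n_bins = len(values)
        defaults = dict(baseline=0.0, mean_fluor=0.1,
                        transients_by_bin=np.ones((10, n_bins), bool),
                        n_traversals=10, bin_width=5.0, params=params)
        defaults.update(kw)
        return d._classify_map(np.asarray(values, float),
                               defaults["baseline"], defaults["mean_fluor"],
                               defaults["transients_by_bin"],
                               defaults["n_traversals"],
                               defaults["bin_width"], defaults["params"])

    def _field_map(self, in_value, out_value, width_bins=6, n_bins=40):
        v = np.full(n_bins, out_value)
        v[10:10 + width_bins] = in_value
        return v

    def test_inout_ratio_threshold_is_four(self):
        assert not self._classify(self._field_map(3.9, 1.0))
        assert self._classify(self._field_map(4.0, 1.0))

    def test_field_width_bounds(self):
        # run extent is measured between the first and last bin centres
        # (unbiased for the threshold-crossing span): 4 bins span 15 cm,
        # below the 20 cm minimum; 5 bins span exactly 20 cm
        assert not self._classify(self._field_map(4.0, 1.0, width_bins=4))
        assert self._classify(self._field_map(4.0, 1.0, width_bins=5))
        # 25 bins span 120 cm, no longer < 120 cm
        assert not self._classify(self._field_map(4.0, 0.0, width_bins=25))
        assert self._classify(self._field_map(4.0, 0.0, width_bins=24))

    def test_traversal_fraction_threshold(self):
        tbb = np.zeros((10, 40), bool)
        tbb[0] = True  # transients on 1 of 10 traversals only
        assert not self._classify(self._field_map(4.0, 0.0),
                                  transients_by_bin=tbb)
        tbb[1] = True  # 2 of 10 = 20% passes
        assert self._classify(self._field_map(4.0, 0.0),
                              transients_by_bin=tbb)

    def test_min_bin_fraction_of_mean(self):
        assert not self._classify(self._field_map(4.0, 0.0),
                                  mean_fluor=1000.0)


@pytest.fixture(scope="module")
def params():
    return pc.CombinationParams(n_shuffles=100)


class TestCombinationMethod:
    def test_narrow_field_rejected(self, loco, mask, params):
        # 20 cm wide model fields are never detected
        pop = pc.PopulationSpec(n_place=4, n_nonplace=8)
        fl = pc.build_population(pop, loco, seed=0,
                                 template=pc.PlaceFieldSpec(sigma=5.0))
        r = pc.combination_method(fl.dff, loco.position, mask,
                                  loco.traversal_id, params, seed=1)
        assert not r.labels[:4].any()

    def test_wide_field_accepted(self, loco, mask, params):
        # 100 cm wide fields at full reliability are detected
        pop = pc.PopulationSpec(n_place=4, n_nonplace=8)
        fl = pc.build_population(pop, loco, seed=0,
                                 template=pc.PlaceFieldSpec(sigma=25.0))
        r = pc.combination_method(fl.dff, loco.position, mask,
                                  loco.traversal_id, params, seed=2)
        assert r.labels[:4].sum() >= 3

    def test_noise_cells_rejected(self, loco, mask, params):
        pop = pc.PopulationSpec(n_place=0, n_nonplace=10)
        fl = pc.build_population(pop, loco, seed=3)
        r = pc.combination_method(fl.dff, loco.position, mask,
                                  loco.traversal_id, params, seed=4)
        assert not r.labels.any()


class TestDetectAll:
    def test_runs_all_methods_and_tabulates(self, loco, small_population):
        res = pc.detect_all(
            small_population.dff, loco.position, loco.velocity,
            traversal_id=loco.traversal_id,
            n_shuffles={"peak": 50, "information": 50, "stability": 50,
                        "combination": 50}, seed=0)
        assert set(res) == set(pc.ALL_METHODS)
        frame = pc.results_frame(res)
        assert len(frame) == 4 * small_population.n_cells
        assert set(frame.columns) >= {"cell", "method", "label",
                                      "statistic", "percentile"}

    def test_deterministic_under_seed(self, loco, small_population):
        kw = dict(traversal_id=loco.traversal_id,
                  n_shuffles={"peak": 30, "information": 30,
                              "stability": 30, "combination": 30})
        a = pc.detect_all(small_population.dff, loco.position, loco.velocity,
                          seed=42, **kw)
        b = pc.detect_all(small_population.dff, loco.position, loco.velocity,
                          seed=42, **kw)
        for m in a:
            np.testing.assert_array_equal(a[m].labels, b[m].labels)
            np.testing.assert_array_equal(a[m].statistic, b[m].statistic)
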