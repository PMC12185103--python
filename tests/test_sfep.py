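import numpy as np
import pytest

from placeframes.geometry import PositionSeries, SectorSpec
from placeframes.sfep import (
    FrameDistributions,
    PreferenceMap,
    SfepError,
    WindowGrid,
    delta_ipos_ensemble,
    estimate_distributions,
    make_windows,
    near_far_summary,
    preference_map,
    runs_test,
    spike_counts,
)
from placeframes.simulate import SimConfig, simulate_trajectory
from placeframes.units import SpikeTrain


@pytest.fixture(scope="module")
def session_windows():
    series = simulate_trajectory(SimConfig(duration=600.0, seed=0))
    return make_windows(series), series


class TestDiscretize:
    def test_window_count_600s(self, session_windows):
        windows, _ = session_windows
        assert windows.n_windows == 4511   # floor(600 / 0.133)

    def test_silent_cell_all_zero(self, session_windows):
        windows, _ = session_windows
        c = spike_counts(SpikeTrain("u", np.array([])), windows)
        assert c.shape == (4511,) and not c.any()

    def test_one_spike_per_window(self, session_windows):
        windows, _ = session_windows
        times = windows.edges[:-1] + 0.05
        c = spike_counts(SpikeTrain("u", times), windows)
        assert np.all(c == 1)


class TestDistributionsAndIpos:
    def two_location_toy(self):
        """Equal occupancy of bins A=0 and B=1; i=1 only at A, i=0 at B."""
        counts = np.array([1] * 50 + [0] * 50)
        bins = np.array([0] * 50 + [1] * 50)
        return estimate_distributions(counts, bins, "room", n_bins_total=2,
                                      min_samples=10)

    def brute_force_ipos(self, counts, bins, i, x):
        """Independent oracle: enumerate the joint histogram directly."""
        joint = {}
        for ci, bi in zip(counts, bins):
            joint[(ci, bi)] = joint.get((ci, bi), 0) + 1
        total = sum(joint.values())
        p_marg = sum(v for (ci, _), v in joint.items() if ci == i) / total
        col = sum(v for (_, bi), v in joint.items() if bi == x)
        p_cond = joint.get((i, x), 0) / col
        if p_cond == 0:
            return 0.0
        return abs(p_cond * np.log2(p_cond / p_marg))

    def test_toy_histogram(self):
        d = self.two_location_toy()
        assert d.p_cond[1, 0] == pytest.approx(1.0)
        assert d.p_marg[1] == pytest.approx(0.5)

    def test_ipos_matches_brute_force(self):
        counts = np.array([1] * 50 + [0] * 50)
        bins = np.array([0] * 50 + [1] * 50)
        d = self.two_location_toy()
        # informative query: p_cond=1, p_marg=0.5 -> 1 * log2(2) = 1 bit
        assert d.ipos(1, 0)[0] == pytest.approx(1.0)
        for i, x in [(1, 0), (0, 0), (1, 1), (0, 1)]:
            expect = self.brute_force_ipos(counts, bins, i, x)
            if (i, x) == (1, 1):  # p_cond = 0 at that location
                assert d.ipos(i, x)[0] == pytest.approx(0.0)
            else:
                assert d.ipos(i, x)[0] == pytest.approx(expect)

    def test_zero_when_conditional_equals_marginal(self):
        counts = np.tile([0, 1], 50)
        bins = np.repeat([0, 1], 50)
        d = estimate_distributions(counts, bins, "room", 2, min_samples=10)
        assert d.ipos(0, 0)[0] == pytest.approx(0.0)
        assert d.ipos(1, 1)[0] == pytest.approx(0.0)

    def test_direct_formula(self):
        # p_cond = 0.5, p_marg = 0.25 -> |0.5 * log2 2| = 0.5
        d = FrameDistributions("room", 2, 1,
                              p_cond=np.array([[0.5], [0.5]]),
                              p_marg=np.array([0.75, 0.25]),
                              bin_counts=np.array([100]),
                              valid_bins=np.array([True]))
        assert d.ipos(1, 0)[0] == pytest.approx(0.5)

    def test_conditionals_normalize(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(1.0, 5000)
        bins = rng.integers(0, 4, 5000)
        d = estimate_distributions(counts, bins, "room", 4, min_samples=10)
        sums = np.nansum(d.p_cond, axis=0)
        assert np.allclose(sums[d.valid_bins], 1.0)
        assert d.p_marg.sum() == pytest.approx(1.0)

    def test_unobserved_level_query_is_error(self):
        # levels 0 and 2 occur, level 1 never does: its marginal is zero
        counts = np.array([0] * 50 + [2] * 50)
        bins = np.array([0] * 50 + [1] * 50)
        d = estimate_distributions(counts, bins, "room", 2, min_samples=10)
        with pytest.raises(SfepError):
            d.ipos(1, 0)

    def test_sparse_bin_is_nan(self):
        counts = np.array([1] * 50 + [0] * 50 + [1])
        bins = np.array([0] * 50 + [1] * 50 + [2])   # bin 2 has one sample
        d = estimate_distributions(counts, bins, "room", 3, min_samples=10)
        assert np.isnan(d.ipos(1, 2)[0])


class TestRunsTest:
    def test_alternating_closed_form(self):
        x = np.tile([1.0, -1.0], 10)    # 20 runs, n1 = n2 = 10
        assert runs_test(x, threshold=0.0) == pytest.approx(4.135, abs=0.001)

    def test_block_series_symmetric(self):
        x = np.concatenate([np.ones(10), -np.ones(10)])
        assert runs_test(x, threshold=0.0) == pytest.approx(-4.135, abs=0.001)

    def test_threshold_defaults_to_mean_and_drops_ties(self):
        x = np.array([2.0, 0.0, 2.0, 0.0, 1.0, 2.0, 0.0, 2.0, 0.0])
        # mean = 1.0; the value equal to the mean is dropped
        z = runs_test(x)
        assert np.isfinite(z)

    def test_one_sided_series_error(self):
        with pytest.raises(SfepError):
            runs_test(np.ones(10), threshold=0.0)


class TestEnsemble:
    def test_constant_positive_delta(self):
        pref = delta_ipos_ensemble([np.full(200, 0.2)])
        assert pref.sfep_room == 1.0

    def test_exact_cancellation_flagged(self):
        a = np.full(100, 0.3)
        with pytest.raises(SfepError, match="tied"):
            delta_ipos_ensemble([a, -a])

    def test_cell_order_invariance(self):
        rng = np.random.default_rng(7)
        cells = [rng.normal(0, 1, 500) for _ in range(6)]
        p1 = delta_ipos_ensemble(cells)
        p2 = delta_ipos_ensemble(cells[::-1])
        assert p1.sfep_room == p2.sfep_room
        assert p1.runs_z == p2.runs_z
        assert np.allclose(p1.delta_i, p2.delta_i)

    def test_zero_cells_error(self):
        with pytest.raises(SfepError):
            delta_ipos_ensemble([])


def _uniform_windows(n_grid=4, n=4000, seed=0):
    rng = np.random.default_rng(seed)
    R = 41.0
    xy = rng.uniform(-18.0, 18.0, (n, 2))  # central bins only; corners unvisited
    w = 2 * R / n_grid
    ix = ((xy[:, 0] + R) / w).astype(int)
    iy = ((xy[:, 1] + R) / w).astype(int)
    bins = ix * n_grid + iy
    return WindowGrid(edges=np.arange(n + 1) * 0.133,
                      t_center=(np.arange(n) + 0.5) * 0.133,
                      room_bin=bins, arena_bin=bins, room_xy=xy,
                      n_grid=n_grid, arena_radius=R)


class TestPreferenceMap:
    def test_all_room_ensemble_is_one(self):
        windows = _uniform_windows()
        pref = delta_ipos_ensemble([np.full(windows.n_windows, 0.1)])
        pmap = preference_map(pref, windows)
        assert np.allclose(pmap.prob[np.isfinite(pmap.prob)], 1.0)

    def test_unvisited_bins_masked(self):
        windows = _uniform_windows()
        # samples confined to the centre square: corner bins unvisited
        pref = delta_ipos_ensemble([np.full(windows.n_windows, 0.1)])
        pmap = preference_map(pref, windows)
        assert np.isnan(pmap.grid()[0, 0])

    def test_near_far_uniform_value(self):
        windows = _uniform_windows()
        n_bins = windows.n_grid ** 2
        pmap = PreferenceMap(np.full(n_bins, 0.6), np.full(n_bins, 50.0),
                             windows.n_grid, windows.arena_radius)
        near = SectorSpec(0.0, 180.0, "room")
        far = SectorSpec(180.0, 180.0, "room")
        p_near, p_far = near_far_summary(pmap, windows, near, far)
        assert p_near == pytest.approx(0.6) and p_far == pytest.approx(0.6)

    def test_empty_far_sector_error(self):
        windows = _uniform_windows()
        pmap = PreferenceMap(np.full(16, 0.5), np.full(16, 50.0), 4, 41.0)
        with pytest.raises(SfepError):
            near_far_summary(pmap, windows, SectorSpec(0, 360, "room"),
                             SectorSpec(180, 0, "room"))
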