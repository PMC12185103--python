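import numpy as np
import pytest

from placeframes.geometry import PositionSeries, SectorSpec, in_sector
from placeframes.overdispersion import rate_map
from placeframes.simulate import (
    CellSpec,
    GainProcess,
    SimConfig,
    StateProcess,
    gain_series,
    latent_state,
    simulate_ensemble,
    simulate_session,
    simulate_trajectory,
)


def test_one_revolution_per_minute():
    cfg = SimConfig(duration=61.0, rotation_rpm=1.0, seed=0)
    s = simulate_trajectory(cfg)
    i60 = int(round(60.0 * cfg.fs))
    assert s.theta[i60] == pytest.approx(360.0)


def test_signed_rotation():
    cfg = SimConfig(duration=61.0, rotation_rpm=-1.0, seed=0)
    s = simulate_trajectory(cfg)
    assert s.theta[-1] < -350.0


def test_zero_noise_walker_never_moves():
    cfg = SimConfig(duration=10.0, ou_sigma=0.0, seed=1)
    s = simulate_trajectory(cfg)
    assert np.all(s.x == s.x[0]) and np.all(s.y == s.y[0])


@pytest.mark.parametrize("seed", [0, 7, 99])
def test_trajectory_confined_to_disk(seed):
    cfg = SimConfig(duration=200.0, seed=seed)
    s = simulate_trajectory(cfg)
    assert np.all(np.hypot(s.x, s.y) <= cfg.arena_radius + 1e-9)


def test_fixed_seed_bit_identical():
    cfg = SimConfig(duration=60.0, seed=5)
    cells = [CellSpec("room", (0.0, 0.0))]
    a = simulate_session(cfg, cells, StateProcess("dwell"))
    b = simulate_session(cfg, cells, StateProcess("dwell"))
    assert np.array_equal(a.series.x, b.series.x)
    assert np.array_equal(a.state, b.state)
    assert np.array_equal(a.trains[0].spike_times, b.trains[0].spike_times)


def test_avoidance_depresses_zone_occupancy():
    zone = SectorSpec(0.0, 60.0, "room")
    base = simulate_trajectory(SimConfig(duration=600.0, seed=11))
    avoid = simulate_trajectory(SimConfig(duration=600.0, seed=11,
                                          avoidance_gain=4.0, avoidance_zone=zone))
    f0 = in_sector(base.x, base.y, zone).mean()
    f1 = in_sector(avoid.x, avoid.y, zone).mean()
    assert f1 < f0


class TestLatentState:
    def test_none_is_constant_room(self):
        s = simulate_trajectory(SimConfig(duration=5.0, seed=0))
        assert np.all(latent_state(s, StateProcess("none"), 0) == 1)

    def test_dwell_mean_recovered(self):
        s = simulate_trajectory(SimConfig(duration=2000.0, seed=3))
        st = latent_state(s, StateProcess("dwell", mean_dwell=2.0), 4)
        # dwell lengths from run-length encoding
        change = np.flatnonzero(np.diff(st)) + 1
        bounds = np.concatenate([[0], change, [st.size]])
        dwells = np.diff(bounds) / s.fs
        assert np.mean(dwells[1:-1]) == pytest.approx(2.0, rel=0.10)

    def test_proximity_conditional_frequencies(self):
        zone = SectorSpec(0.0, 60.0, "room")
        s = simulate_trajectory(SimConfig(duration=2000.0, seed=5))
        sp = StateProcess("proximity", mean_dwell=1.0, p_room_near=0.9,
                          p_room_far=0.1, zone=zone)
        st = latent_state(s, sp, 6)
        near_half = SectorSpec(0.0, 180.0, "room")
        near = in_sector(s.x, s.y, near_half)
        # renewal positions move during a dwell, so allow modest blur on
        # top of the +/-0.05 sampling band
        assert st[near].mean() == pytest.approx(0.9, abs=0.1)
        assert st[~near].mean() == pytest.approx(0.1, abs=0.1)

    def test_dwell_room_fraction(self):
        s = simulate_trajectory(SimConfig(duration=2000.0, seed=3))
        for p in (0.3, 0.7):
            st = latent_state(s, StateProcess("dwell", p_room=p), 9)
            assert st.mean() == pytest.approx(p, abs=0.05)


class TestEnsembleSpiking:
    def _clamped(self, duration=10.0):
        n = int(30 * duration)
        t = np.arange(n) / 30.0
        return PositionSeries(t, np.full(n, 10.0), np.zeros(n), np.zeros(n))

    def test_poisson_count_at_field_center(self):
        series = self._clamped(10.0)
        cell = CellSpec("room", (10.0, 0.0), peak_rate=10.0, baseline_rate=0.0)
        (train,) = simulate_ensemble(series, [cell], rng=0)
        assert abs(train.n_spikes - 100) <= 3 * np.sqrt(100)

    def test_opposite_state_and_zero_baseline_silences(self):
        series = self._clamped(10.0)
        cell = CellSpec("room", (10.0, 0.0), peak_rate=10.0, baseline_rate=0.0)
        state = np.zeros(len(series), dtype=np.int8)  # arena state, room cell
        (train,) = simulate_ensemble(series, [cell], state=state, rng=0)
        assert train.n_spikes == 0

    def test_spike_times_within_session(self):
        series = simulate_trajectory(SimConfig(duration=30.0, seed=2))
        (train,) = simulate_ensemble(series, [CellSpec("arena", (0.0, 0.0))], rng=1)
        assert train.spike_times.min() >= series.t[0]
        assert train.spike_times.max() <= series.t[-1] + 1 / series.fs


def test_gain_series_blocks():
    series = simulate_trajectory(SimConfig(duration=60.0, seed=0))
    g = gain_series(series, GainProcess(gains=(0.5, 1.5), pass_length=5.0), 7)
    block = int(5.0 * series.fs)
    for b in range(len(series) // block):
        seg = g[b * block:(b + 1) * block]
        assert np.all(seg == seg[0])
    assert set(np.unique(g)) <= {0.5, 1.5}


def test_rate_map_recovers_generative_field():
    """Empirical map peak lies within one field sigma of the true centre."""
    cfg = SimConfig(duration=1200.0, seed=8)
    series = simulate_trajectory(cfg)
    cell = CellSpec("room", (10.0, -5.0), sigma=9.0, peak_rate=15.0,
                    baseline_rate=0.5)
    (train,) = simulate_ensemble(series, [cell], rng=3)
    rm = rate_map(train, series, "room")
    idx = np.unravel_index(np.nanargmax(rm.rate), rm.rate.shape)
    px = (rm.x_edges[idx[0]] + rm.x_edges[idx[0] + 1]) / 2
    py = (rm.y_edges[idx[1]] + rm.y_edges[idx[1] + 1]) / 2
    assert np.hypot(px - 10.0, py + 5.0) < cell.sigma


def test_config_validation():
    with pytest.raises(ValueError):
        SimConfig(duration=-1.0)
    with pytest.raises(ValueError):
        StateProcess("proximity")  # zone required
    with pytest.raises(ValueError):
        GainProcess(gains=(1.0, -0.5))
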