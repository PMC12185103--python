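"""Spatial-frame momentary positional information and ensemble preference.

For each 133 ms window the activity level i of a cell (its spike count)
and the current location x are combined into the momentary positional
information

    I_pos = | p(i|x) * log2( p(i|x) / p(i) ) |

computed separately with x expressed in the stationary room frame and in
the rotating arena frame; both conditional and marginal activity
distributions are empirical, estimated from the same session. The
per-window difference dI = I_pos(room) - I_pos(arena) is positive when
the cell's activity is momentarily more informative about the room
location. Averaging dI over the simultaneously recorded cells gives the
ensemble preference time series; the fraction of windows with a positive
ensemble dI is the spatial frame ensemble preference (SFEP), and a runs
test on the series (dichotomized at its mean) checks that the room/arena
alternation is slower than chance. The probability of room preference
per room-frame location forms a preference map, summarised over the
near/far halves of the arena.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import PositionSeries, SectorSpec, in_sector
from .units import SpikeTrain

DT_S = 0.133          # window length
N_GRID = 16           # spatial bins per axis, each frame
MIN_BIN_SAMPLES = 10  # windows required per spatial bin for p(i|x)
CAP_QUANTILE = 0.99   # activity levels above this quantile pool into a top bin


class SfepError(ValueError):
    pass


@dataclass
class WindowGrid:
    """Shared discretization of a session into Δt windows.

    Each window carries its centre time and the spatial bin (flattened
    index on an N_GRID x N_GRID grid over the arena square) of the
    window-centre tracker sample, in both frames.
    """

    edges: np.ndarray        # window edges, length n_windows + 1
    t_center: np.ndarray
    room_bin: np.ndarray     # int, flattened grid index
    arena_bin: np.ndarray
    room_xy: np.ndarray      # (n, 2) window-centre coordinates, room frame
    n_grid: int
    arena_radius: float

    @property
    def n_windows(self) -> int:
        return int(self.t_center.size)

    def bin_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) centre coordinates of every flattened grid bin."""
        R = self.arena_radius
        w = 2 * R / self.n_grid
        c = -R + w * (np.arange(self.n_grid) + 0.5)
        ix, iy = np.divmod(np.arange(self.n_grid**2), self.n_grid)
        return c[ix], c[iy]


def make_windows(series: PositionSeries, dt: float = DT_S,
                 n_grid: int = N_GRID) -> WindowGrid:
    """Divide the session into consecutive Δt windows.

    The number of windows is floor(duration / dt); the window position
    is taken from the tracker sample nearest the window centre (not an
    average), separately in each frame.
    """
    n_win = int(np.floor(series.duration / dt))
    if n_win == 0:
        raise SfepError("session shorter than one window")
    t0 = series.t[0]
    edges = t0 + dt * np.arange(n_win + 1)
    t_center = edges[:-1] + dt / 2.0
    idx = np.clip(np.round((t_center - t0) * series.fs).astype(int), 0, len(series) - 1)

    R = series.arena_radius
    w = 2 * R / n_grid

    def flat_bins(x, y):
        ix = np.clip(((x + R) / w).astype(int), 0, n_grid - 1)
        iy = np.clip(((y + R) / w).astype(int), 0, n_grid - 1)
        return ix * n_grid + iy

    xa, ya = series.arena_xy()
    room_xy = np.column_stack([series.x[idx], series.y[idx]])
    return WindowGrid(
        edges=edges, t_center=t_center,
        room_bin=flat_bins(series.x[idx], series.y[idx]),
        arena_bin=flat_bins(xa[idx], ya[idx]),
        room_xy=room_xy, n_grid=n_grid, arena_radius=R,
    )


def spike_counts(train: SpikeTrain, windows: WindowGrid) -> np.ndarray:
    """Spike count i per window."""
    counts, _ = np.histogram(train.spike_times, bins=windows.edges)
    return counts


@dataclass
class FrameDistributions:
    """Empirical p(i, x), p(i|x) and p(i) for one frame of one cell.

    Activity levels are spike counts per window, with counts above the
    session's 99th percentile pooled into the top level. Spatial bins
    visited fewer than ``min_samples`` windows are invalid: windows that
    fall in them are excluded from this frame's information series.
    """

    frame: str
    n_levels: int
    cap: int
    p_cond: np.ndarray           # (n_levels, n_bins); NaN columns = invalid bin
    p_marg: np.ndarray           # (n_levels,)
    bin_counts: np.ndarray       # windows per bin (all windows)
    valid_bins: np.ndarray       # bool per bin

    def ipos(self, i, bins) -> np.ndarray:
        """I_pos for window(s) with activity level(s) i at spatial bin(s).

        NaN where the bin is invalid; levels are capped like the fitted
        distributions. Querying a level never observed in the session is
        an error (its marginal probability is zero).
        """
        i = np.minimum(np.atleast_1d(np.asarray(i, dtype=int)), self.cap)
        bins = np.atleast_1d(np.asarray(bins, dtype=int))
        pm = self.p_marg[i]
        pc = self.p_cond[i, bins]
        out = np.full(i.shape, np.nan)
        valid = np.isfinite(pc)  # invalid spatial bins stay NaN (excluded)
        if np.any(pm[valid] == 0):
            raise SfepError("queried an activity level with zero marginal probability")
        pcv, pmv = pc[valid], pm[valid]
        vals = np.zeros(pcv.shape)
        nz = pcv > 0
        vals[nz] = np.abs(pcv[nz] * np.log2(pcv[nz] / pmv[nz]))
        out[valid] = vals
        return out


def estimate_distributions(counts: np.ndarray, bins: np.ndarray, frame: str,
                           n_bins_total: int, min_samples: int = MIN_BIN_SAMPLES,
                           cap_quantile: float = CAP_QUANTILE) -> FrameDistributions:
    """Empirical joint histogram of (activity level, spatial bin).

    Conditionals are normalized per valid bin; the marginal is computed
    over the windows that fall in valid bins, so the joint, conditional
    and marginal tables describe the same window population.
    """
    counts = np.asarray(counts, dtype=int)
    bins = np.asarray(bins, dtype=int)
    if counts.size == 0:
        raise SfepError("no windows")
    cap = max(1, int(np.ceil(np.quantile(counts, cap_quantile))))
    lev = np.minimum(counts, cap)
    n_levels = cap + 1

    bin_counts = np.bincount(bins, minlength=n_bins_total)
    valid = bin_counts >= min_samples

    use = valid[bins]
    joint = np.zeros((n_levels, n_bins_total))
    np.add.at(joint, (lev[use], bins[use]), 1.0)
    total = joint.sum()
    if total == 0:
        raise SfepError("no windows fall in valid spatial bins")
    p_marg = joint.sum(axis=1) / total
    col = joint.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_cond = joint / col
    p_cond[:, ~valid] = np.nan
    return FrameDistributions(frame, n_levels, cap, p_cond, p_marg, bin_counts, valid)


def ipos_series(counts: np.ndarray, bins: np.ndarray,
                dist: FrameDistributions) -> np.ndarray:
    """Per-window I_pos; NaN for windows in invalid spatial bins."""
    return dist.ipos(counts, bins)


def delta_ipos_cell(train: SpikeTrain, windows: WindowGrid,
                    min_samples: int = MIN_BIN_SAMPLES,
                    cap_quantile: float = CAP_QUANTILE) -> np.ndarray:
    """dI = I_pos(room) - I_pos(arena) per window for one cell."""
    c = spike_counts(train, windows)
    n_bins = windows.n_grid**2
    d_room = estimate_distributions(c, windows.room_bin, "room", n_bins,
                                    min_samples, cap_quantile)
    d_arena = estimate_distributions(c, windows.arena_bin, "arena", n_bins,
                                     min_samples, cap_quantile)
    return (ipos_series(c, windows.room_bin, d_room)
            - ipos_series(c, windows.arena_bin, d_arena))


def runs_test(x: np.ndarray, threshold: float | None = None) -> float:
    """Wald–Wolfowitz runs-test z for serial non-randomness.

    The series is dichotomized above/below ``threshold`` (default: its
    mean); values equal to the threshold are dropped. With n1 and n2
    values on the two sides and R observed runs,
    mu_R = 2 n1 n2 / (n1 + n2) + 1 and
    var_R = 2 n1 n2 (2 n1 n2 - n1 - n2) / ((n1+n2)^2 (n1+n2-1)).
    Negative z means fewer runs than chance (slow alternation).
    """
    x = np.asarray(x, dtype=float)
    x = x[np.isfinite(x)]
    if threshold is None:
        threshold = float(np.mean(x))
    x = x[x != threshold]
    above = x > threshold
    n1 = int(above.sum())
    n2 = int(above.size - n1)
    if n1 < 2 or n2 < 2:
        raise SfepError("runs test needs at least two values on each side")
    R = 1 + int(np.count_nonzero(np.diff(above)))
    n = n1 + n2
    mu = 2.0 * n1 * n2 / n + 1.0
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1.0))
    return float((R - mu) / np.sqrt(var))


@dataclass
class EnsemblePreference:
    """Ensemble dI series and its summaries."""

    delta_i: np.ndarray       # per-window ensemble mean dI (NaN where undefined)
    sfep_room: float          # fraction of non-tied windows with dI > 0
    runs_z: float
    n_cells: int
    n_windows_used: int
    n_ties: int
    per_cell: list[np.ndarray] = field(default_factory=list, repr=False)

    @property
    def sfep_arena(self) -> float:
        return 1.0 - self.sfep_room


def delta_ipos_ensemble(per_cell_delta: list[np.ndarray]) -> EnsemblePreference:
    """Average per-cell dI series into the ensemble preference.

    Windows where no cell has a defined dI are excluded; exact ties
    (ensemble dI == 0, common only in degenerate inputs) are excluded
    from the SFEP proportion and the runs test.
    """
    if len(per_cell_delta) == 0:
        raise SfepError("ensemble requires at least one cell")
    M = np.vstack(per_cell_delta)
    valid = np.isfinite(M)
    n_valid = valid.sum(axis=0)
    sums = np.where(valid, M, 0.0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        ens = np.where(n_valid > 0, sums / n_valid, np.nan)
    finite = np.isfinite(ens)
    nonzero = finite & (ens != 0.0)
    n_ties = int(finite.sum() - nonzero.sum())
    if nonzero.sum() == 0:
        raise SfepError("ensemble dI is tied (exactly zero) in every window")
    sfep_room = float(np.mean(ens[nonzero] > 0))
    # The ensemble alternates between frames on a seconds timescale, far
    # slower than the window length, so the dichotomized series is clumped
    # and the classical runs z is negative. Report the sign flipped so that
    # positive runs_z means slower-than-chance alternation, matching how
    # the significance of representational switching is quoted.
    try:
        z = -runs_test(ens[nonzero])
    except SfepError:
        z = float("nan")  # degenerate series (one-sided): test undefined
    return EnsemblePreference(ens, sfep_room, z, len(per_cell_delta),
                              int(nonzero.sum()), n_ties, per_cell=per_cell_delta)


def ensemble_preference(trains: list[SpikeTrain], series: PositionSeries,
                        dt: float = DT_S, n_grid: int = N_GRID,
                        min_samples: int = MIN_BIN_SAMPLES) -> tuple[EnsemblePreference, WindowGrid]:
    """End-to-end SFEP for an ensemble of (pyramidal) cells."""
    windows = make_windows(series, dt=dt, n_grid=n_grid)
    per_cell = [delta_ipos_cell(tr, windows, min_samples=min_samples) for tr in trains]
    return delta_ipos_ensemble(per_cell), windows


@dataclass
class PreferenceMap:
    """P(room-preferring ensemble dI) per room-frame spatial bin."""

    prob: np.ndarray          # flattened grid; NaN where masked
    counts: np.ndarray        # non-tied windows per bin
    n_grid: int
    arena_radius: float

    def grid(self) -> np.ndarray:
        return self.prob.reshape(self.n_grid, self.n_grid)


def preference_map(pref: EnsemblePreference, windows: WindowGrid,
                   min_samples: int = MIN_BIN_SAMPLES) -> PreferenceMap:
    """Fraction of room-preferring windows per room-frame location."""
    ens = pref.delta_i
    use = np.isfinite(ens) & (ens != 0.0)
    bins = windows.room_bin[use]
    room = ens[use] > 0
    n_bins = windows.n_grid**2
    counts = np.bincount(bins, minlength=n_bins).astype(float)
    hits = np.bincount(bins[room], minlength=n_bins).astype(float)
    with np.errstate(invalid="ignore"):
        prob = hits / counts
    prob[counts < min_samples] = np.nan
    return PreferenceMap(prob, counts, windows.n_grid, windows.arena_radius)


def near_far_summary(pmap: PreferenceMap, windows: WindowGrid,
                     near: SectorSpec, far: SectorSpec) -> tuple[float, float]:
    """Occupancy-weighted mean room preference over the two partitions."""
    if near.width_deg == 0.0 or far.width_deg == 0.0:
        raise SfepError("near/far summary requires two non-empty sectors")
    cx, cy = windows.bin_centers()
    ok = np.isfinite(pmap.prob) & ((cx != 0) | (cy != 0))
    vals = {}
    for name, sector in (("near", near), ("far", far)):
        m = ok & in_sector(cx, cy, sector)
        w = pmap.counts[m]
        if w.sum() == 0:
            raise SfepError(f"no mapped bins in the {name} sector")
        vals[name] = float(np.average(pmap.prob[m], weights=w))
    return vals["near"], vals["far"]


def sfep_bias_test(sfep_values: np.ndarray, null: float = 0.5
                   ) -> tuple[float, float]:
    """One-sample t-test of per-recording SFEP proportions against 0.5."""
    res = stats.ttest_1samp(np.asarray(sfep_values, dtype=float), null)
    return float(res.statistic), float(res.pvalue)
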