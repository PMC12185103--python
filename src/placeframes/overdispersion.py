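"""Place-cell overdispersion: standardized episode firing deviations.

The spike and position time series is divided into consecutive 5 s
episodes. For each episode the expected count under an inhomogeneous
Poisson model (exp) is accumulated from the cell's rate map along the
trajectory, and the deviation of the observed count is standardized,
z = (obs - exp) / sqrt(exp). Episodes with exp = 0 are undefined, and
only episodes where exp exceeds the cell's mean firing (mean rate times
the episode length, in counts) are retained — these are passes through
the central region of the firing field. The variance of the retained z
values quantifies overdispersion: variance 1 is the Poisson expectation,
larger values indicate extra-positional modulation. Variances are
compared between conditions with an F-test on their ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter

from .geometry import PositionSeries
from .units import SpikeTrain

EPISODE_LEN_S = 5.0
BIN_CM = 2.5
SMOOTHING_SIGMA_BINS = 1.0
MIN_OCCUPANCY_S = 0.5


@dataclass
class RateMap:
    """Binned, smoothed firing-rate map in one spatial frame.

    ``rate`` is NaN wherever occupancy falls below the minimum; queries
    that land in a masked bin report NaN rather than zero so that
    episodes touching unsampled space can be dropped, not biased.
    """

    frame: str
    x_edges: np.ndarray
    y_edges: np.ndarray
    rate: np.ndarray          # spikes/s, NaN where masked
    occupancy: np.ndarray     # seconds per bin (unsmoothed)

    def rate_at(self, x, y) -> np.ndarray:
        """Rate at coordinates (cm); NaN for masked or out-of-grid bins."""
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        ix = np.searchsorted(self.x_edges, x, side="right") - 1
        iy = np.searchsorted(self.y_edges, y, side="right") - 1
        out = np.full(x.shape, np.nan)
        ok = (ix >= 0) & (ix < self.rate.shape[0]) & (iy >= 0) & (iy < self.rate.shape[1])
        out[ok] = self.rate[ix[ok], iy[ok]]
        return out

    def spatial_information(self) -> float:
        """Skaggs information rate, bits/spike, over unmasked bins."""
        occ = np.where(np.isfinite(self.rate), self.occupancy, 0.0)
        if occ.sum() == 0:
            return 0.0
        p = occ / occ.sum()
        r = np.where(np.isfinite(self.rate), self.rate, 0.0)
        rbar = float((p * r).sum())
        if rbar == 0:
            return 0.0
        with np.errstate(divide="ignore", invalid="ignore"):
            term = p * (r / rbar) * np.log2(r / rbar)
        return float(np.nansum(term[r > 0]))


def spike_positions(train: SpikeTrain, series: PositionSeries, frame: str
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Frame coordinates at each spike time (nearest tracker sample)."""
    fs = series.fs
    idx = np.clip(np.round((train.spike_times - series.t[0]) * fs).astype(int),
                  0, len(series) - 1)
    x, y = series.xy_in_frame(frame)
    return x[idx], y[idx]


def rate_map(train: SpikeTrain, series: PositionSeries, frame: str = "room",
             bin_cm: float = BIN_CM, smoothing_sigma: float = SMOOTHING_SIGMA_BINS,
             min_occupancy: float = MIN_OCCUPANCY_S) -> RateMap:
    """Adaptive ratio-of-smoothed-histograms rate map.

    Spike and occupancy histograms are smoothed with the same Gaussian
    kernel before dividing; bins whose raw occupancy is below
    ``min_occupancy`` seconds are masked.
    """
    R = series.arena_radius
    n_bins = int(np.ceil(2 * R / bin_cm))
    edges = -R + bin_cm * np.arange(n_bins + 1)
    x, y = series.xy_in_frame(frame)
    dt = 1.0 / series.fs
    occ, _, _ = np.histogram2d(x, y, bins=(edges, edges))
    occ *= dt
    if occ.sum() == 0:
        raise ValueError("zero total occupancy")
    sx, sy = spike_positions(train, series, frame)
    spk, _, _ = np.histogram2d(sx, sy, bins=(edges, edges))
    if smoothing_sigma > 0:
        spk_s = gaussian_filter(spk, smoothing_sigma, mode="constant")
        occ_s = gaussian_filter(occ, smoothing_sigma, mode="constant")
    else:
        spk_s, occ_s = spk, occ
    with np.errstate(divide="ignore", invalid="ignore"):
        rate = spk_s / occ_s
    rate[occ < min_occupancy] = np.nan
    return RateMap(frame, edges, edges, rate, occ)


def pick_frame(train: SpikeTrain, series: PositionSeries, **map_kwargs) -> str:
    """Frame ('room' or 'arena') in which the cell's map carries more
    spatial information — the default expectation frame on the rotating
    arena, where a cell's reference frame is not known a priori."""
    info = {f: rate_map(train, series, f, **map_kwargs).spatial_information()
            for f in ("room", "arena")}
    return "room" if info["room"] >= info["arena"] else "arena"


def expected_count(x: np.ndarray, y: np.ndarray, ratemap, dt: float) -> float:
    """Expected spike count along a sample path: sum of rate(bin) * dt.

    ``ratemap`` may be a binned :class:`RateMap` or any object with a
    ``rate_at(x, y)`` method (e.g. a generative tuning curve). Returns
    NaN if any sample falls in a masked bin.
    """
    r = np.asarray(ratemap.rate_at(x, y), dtype=float)
    if np.any(~np.isfinite(r)):
        return float("nan")
    return float(r.sum() * dt)


def episode_zs(train: SpikeTrain, series: PositionSeries, ratemap,
               episode_len: float = EPISODE_LEN_S,
               frame: str | None = None) -> pd.DataFrame:
    """Standardized deviation z per retained 5 s episode.

    Retention: exp > 0, exp greater than the cell's session-mean count
    per episode (mean rate x episode length), and no episode sample in a
    masked map bin. Dropped episodes remain in the table with
    ``retained=False`` so the filters are auditable.
    """
    frame = frame or getattr(ratemap, "frame", "room")
    fs = series.fs
    dt = 1.0 / fs
    n_per = int(round(episode_len * fs))
    n_ep = len(series) // n_per
    if n_ep == 0:
        raise ValueError("session shorter than one episode")
    x, y = series.xy_in_frame(frame)
    t0 = series.t[0]
    mean_count = train.n_spikes / series.duration * episode_len

    rows = []
    for e in range(n_ep):
        sl = slice(e * n_per, (e + 1) * n_per)
        t_start = float(series.t[sl.start] - t0)
        exp = expected_count(x[sl], y[sl], ratemap, dt)
        lo, hi = series.t[sl.start], series.t[sl.start] + episode_len
        obs = int(np.searchsorted(train.spike_times, hi) -
                  np.searchsorted(train.spike_times, lo))
        if not np.isfinite(exp):
            rows.append((e, t_start, obs, np.nan, np.nan, False, "masked bin"))
            continue
        if exp <= 0:
            rows.append((e, t_start, obs, exp, np.nan, False, "exp = 0"))
            continue
        z = (obs - exp) / np.sqrt(exp)
        if exp <= mean_count:
            rows.append((e, t_start, obs, exp, z, False, "exp <= mean firing"))
        else:
            rows.append((e, t_start, obs, exp, z, True, ""))
    return pd.DataFrame(rows, columns=["episode", "t_start", "obs", "exp",
                                       "z", "retained", "drop_reason"])


def overdispersion_variance(zs: np.ndarray) -> tuple[float, int]:
    """Sample variance (ddof=1) of z values and the episode count."""
    zs = np.asarray(zs, dtype=float)
    zs = zs[np.isfinite(zs)]
    n = zs.size
    if n < 2:
        raise ValueError("need at least two z values")
    return float(np.var(zs, ddof=1)), n


def variance_ratio_test(zs_a: np.ndarray, zs_b: np.ndarray
                        ) -> tuple[float, int, int, float]:
    """F-test of the ratio of overdispersion variances.

    Returns (F, df_a, df_b, two-sided p) with F = var_a / var_b and
    degrees of freedom (n_a - 1, n_b - 1).
    """
    va, na = overdispersion_variance(zs_a)
    vb, nb = overdispersion_variance(zs_b)
    if vb == 0:
        raise ValueError("zero variance in the denominator sample")
    F = va / vb
    dfa, dfb = na - 1, nb - 1
    p = 2.0 * min(stats.f.cdf(F, dfa, dfb), stats.f.sf(F, dfa, dfb))
    return F, dfa, dfb, min(p, 1.0)


def cell_overdispersion(train: SpikeTrain, series: PositionSeries,
                        frame: str = "auto", episode_len: float = EPISODE_LEN_S,
                        **map_kwargs) -> dict:
    """Map estimation plus episode scoring for one cell (plug-in map)."""
    if frame == "auto":
        frame = pick_frame(train, series, **map_kwargs)
    rm = rate_map(train, series, frame, **map_kwargs)
    table = episode_zs(train, series, rm, episode_len=episode_len, frame=frame)
    retained = table.loc[table.retained, "z"].to_numpy()
    var, n = (overdispersion_variance(retained) if retained.size >= 2
              else (float("nan"), int(retained.size)))
    return {"frame": frame, "episodes": table, "var_z": var, "n_retained": n,
            "retention_fraction": float(table.retained.mean())}
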