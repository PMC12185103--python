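"""Synthetic rotating-arena sessions.

Generates position, latent spatial-frame state, per-pass gain and spike
data with the statistical structure the downstream analyses assume:

* an Ornstein–Uhlenbeck velocity random walk confined to the arena disk,
  optionally repelled from a stationary room-frame sector (avoidance);
* place cells with Gaussian spatial tuning referenced to either the room
  or the rotating arena frame;
* an ensemble-level latent state that alternates between the two frames
  on a seconds timescale, optionally conditioned on proximity to the
  shock zone;
* multiplicative per-pass gain modulation, the generative source of
  overdispersion;
* Poisson spike counts per sample bin, with spike times jittered
  uniformly within the bin, so the generator is an exact inhomogeneous
  Poisson oracle at the bin level.

The real experiment provides no generative model; everything here is an
explicit stand-in whose parameters are recorded in the session manifest.
A single master seed spawns independent substreams for the trajectory,
the state, the gain process and each cell, so components are
individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .geometry import (
    ARENA_RADIUS_CM,
    PositionSeries,
    SectorSpec,
    in_sector,
    polar_angle_deg,
    room_to_arena,
)
from .units import SpikeTrain

ROOM, ARENA = 1, 0


@dataclass
class SimConfig:
    """Apparatus and locomotion parameters.

    ``rotation_rpm`` is signed; the apparatus rotates at 1 rpm and its
    direction is not constrained, so both signs are exercised in tests.
    ``ou_tau``/``ou_sigma`` set the velocity relaxation time (s) and the
    stationary per-component speed scale (cm/s) of the random walk;
    the defaults give a mean running speed of ~10 cm/s, typical of a
    foraging rat. ``avoidance_gain`` scales a tangential repulsion from
    ``avoidance_zone`` (room frame), depressing occupancy inside it.
    """

    arena_radius: float = ARENA_RADIUS_CM
    rotation_rpm: float = 1.0
    fs: float = 30.0
    duration: float = 600.0
    ou_tau: float = 1.0
    ou_sigma: float = 8.0
    avoidance_gain: float = 0.0
    avoidance_zone: SectorSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0 or self.duration <= 0 or self.arena_radius <= 0:
            raise ValueError("fs, duration and arena_radius must be positive")
        if self.ou_tau <= 0 or self.ou_sigma < 0:
            raise ValueError("ou_tau must be positive and ou_sigma non-negative")


@dataclass
class CellSpec:
    """Gaussian place-field tuning referenced to one spatial frame."""

    frame: str
    center: tuple[float, float]
    sigma: float = 9.0
    peak_rate: float = 20.0
    baseline_rate: float = 3.0
    unit_id: str | None = None
    waveform_us: float = 320.0

    def __post_init__(self) -> None:
        if self.frame not in ("room", "arena"):
            raise ValueError(f"frame must be 'room' or 'arena', got {self.frame!r}")
        if not (self.peak_rate >= self.baseline_rate >= 0):
            raise ValueError("require peak_rate >= baseline_rate >= 0")
        if self.sigma <= 0:
            raise ValueError("field_sigma must be positive")

    def rate_at(self, x, y) -> np.ndarray:
        """Generative firing rate (spikes/s) at frame coordinates (x, y)."""
        d2 = (np.asarray(x) - self.center[0]) ** 2 + (np.asarray(y) - self.center[1]) ** 2
        return self.baseline_rate + (self.peak_rate - self.baseline_rate) * np.exp(
            -d2 / (2.0 * self.sigma**2)
        )


@dataclass
class StateProcess:
    """Latent ensemble frame state (room=1 / arena=0).

    ``none``      : permanently room.
    ``dwell``     : strict alternation with exponential dwells; the room
                    and arena mean dwells are 2*mean_dwell*p_room and
                    2*mean_dwell*(1-p_room), so the long-run room-state
                    fraction is p_room and the overall mean dwell equals
                    mean_dwell when p_room = 0.5.
    ``proximity`` : exponential dwell renewals; at each renewal the state
                    is room with probability p_room_near if the current
                    position lies in the near (shock-zone) half of the
                    room frame, else p_room_far.
    """

    mode: str = "none"
    mean_dwell: float = 5.0
    p_room: float = 0.5
    p_room_near: float = 0.9
    p_room_far: float = 0.1
    zone: SectorSpec | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("none", "dwell", "proximity"):
            raise ValueError(f"unknown state mode {self.mode!r}")
        for p in (self.p_room, self.p_room_near, self.p_room_far):
            if not (0.0 <= p <= 1.0):
                raise ValueError("state probabilities must lie in [0, 1]")
        if self.mean_dwell <= 0:
            raise ValueError("mean_dwell must be positive")
        if self.mode == "proximity" and self.zone is None:
            raise ValueError("proximity mode requires a zone")


@dataclass
class GainProcess:
    """Piecewise-constant multiplicative gain, resampled every pass.

    A 'pass' is a fixed-length block (default 5 s, the overdispersion
    episode length); within each block one gain multiplier is drawn from
    ``gains`` with probabilities ``probs`` and applied to every cell's
    rate. ``gains=(1,)`` recovers a pure inhomogeneous Poisson ensemble.
    """

    gains: tuple[float, ...] = (1.0,)
    probs: tuple[float, ...] | None = None
    pass_length: float = 5.0

    def __post_init__(self) -> None:
        if any(g < 0 for g in self.gains):
            raise ValueError("gains must be non-negative")
        if self.probs is None:
            self.probs = tuple([1.0 / len(self.gains)] * len(self.gains))
        if len(self.probs) != len(self.gains):
            raise ValueError("gains and probs must have equal length")
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError("probs must sum to 1")
        if self.pass_length <= 0:
            raise ValueError("pass_length must be positive")


def _substreams(seed: int) -> dict[str, np.random.SeedSequence]:
    root = np.random.SeedSequence(seed)
    names = ("trajectory", "state", "gain", "cells")
    return dict(zip(names, root.spawn(len(names))))


def simulate_trajectory(cfg: SimConfig, rng: np.random.Generator | None = None) -> PositionSeries:
    """OU-velocity random walk on the arena disk.

    The velocity follows an exact Ornstein–Uhlenbeck update per sample;
    hitting the wall produces a specular bounce of both position and
    velocity. theta(t) = 6 * rotation_rpm * t degrees, unwrapped. With
    ``avoidance_gain > 0`` a tangential acceleration pushes the walker
    away from the centre line of the (stationary, room-frame) avoidance
    zone, depressing occupancy inside it.
    """
    if rng is None:
        rng = np.random.default_rng(_substreams(cfg.seed)["trajectory"])
    dt = 1.0 / cfg.fs
    n = int(round(cfg.duration * cfg.fs))
    t = np.arange(n) * dt
    theta = 6.0 * cfg.rotation_rpm * t

    a = np.exp(-dt / cfg.ou_tau)
    b = cfg.ou_sigma * np.sqrt(1.0 - a * a)
    noise = rng.standard_normal((n, 2))

    zone = cfg.avoidance_zone
    half_width = zone.width_deg / 2.0 if zone is not None else 0.0
    sigma_ang = half_width + 15.0  # angular reach of the repulsion, degrees

    pos = np.empty((n, 2))
    p = np.zeros(2)
    v = cfg.ou_sigma * rng.standard_normal(2)
    R = cfg.arena_radius
    for i in range(n):
        v = a * v + b * noise[i]
        if cfg.avoidance_gain > 0.0 and zone is not None:
            r = np.hypot(p[0], p[1])
            if r > 1.0:
                ang = np.degrees(np.arctan2(p[1], p[0]))
                d = (ang - zone.center_deg + 180.0) % 360.0 - 180.0
                f = cfg.avoidance_gain * np.exp(-0.5 * (d / sigma_ang) ** 2)
                s = 1.0 if d >= 0 else -1.0
                # unit tangent (counterclockwise), pushed away from the zone centre line
                v += (f * s * dt) * np.array([-p[1] / r, p[0] / r])
        p = p + v * dt
        r = np.hypot(p[0], p[1])
        if r > R:
            nhat = p / r
            p = p - 2.0 * (r - R) * nhat
            v = v - 2.0 * (v @ nhat) * nhat
        pos[i] = p
    return PositionSeries(t, pos[:, 0], pos[:, 1], theta)


def latent_state(
    series: PositionSeries,
    sp: StateProcess,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Per-sample latent frame state (room=1 / arena=0)."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = len(series)
    if sp.mode == "none":
        return np.ones(n, dtype=np.int8)

    dt = float(series.t[1] - series.t[0])
    duration = n * dt
    state = np.empty(n, dtype=np.int8)

    if sp.mode == "dwell":
        mean = {ROOM: 2.0 * sp.mean_dwell * sp.p_room,
                ARENA: 2.0 * sp.mean_dwell * (1.0 - sp.p_room)}
        cur = ROOM if rng.random() < sp.p_room else ARENA
        if mean[cur] == 0.0:  # degenerate fraction: the other frame only
            cur = ARENA if cur == ROOM else ROOM
        t_now, i = 0.0, 0
        while i < n:
            dwell = rng.exponential(mean[cur]) if mean[cur] > 0 else duration
            j = min(n, int(np.ceil((t_now + dwell) / dt)))
            state[i:max(j, i + 1)] = cur
            i = max(j, i + 1)
            t_now = i * dt
            cur = ARENA if cur == ROOM else ROOM
        return state

    # proximity mode
    near_half = SectorSpec(sp.zone.center_deg, 180.0, "room")
    t_now, i = 0.0, 0
    while i < n:
        x, y = series.x[i], series.y[i]
        if x == 0.0 and y == 0.0:
            near = True
        else:
            near = bool(in_sector(x, y, near_half))
        p = sp.p_room_near if near else sp.p_room_far
        cur = ROOM if rng.random() < p else ARENA
        dwell = rng.exponential(sp.mean_dwell)
        j = min(n, int(np.ceil((t_now + dwell) / dt)))
        state[i:max(j, i + 1)] = cur
        i = max(j, i + 1)
        t_now = i * dt
    return state


def gain_series(
    series: PositionSeries,
    gp: GainProcess,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Per-sample gain multiplier, constant within each pass block."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = len(series)
    dt = float(series.t[1] - series.t[0])
    block = max(1, int(round(gp.pass_length / dt)))
    n_blocks = int(np.ceil(n / block))
    g = rng.choice(np.asarray(gp.gains, dtype=float), size=n_blocks, p=np.asarray(gp.probs))
    return np.repeat(g, block)[:n]


def simulate_ensemble(
    series: PositionSeries,
    cells: Sequence[CellSpec],
    state: np.ndarray | None = None,
    gain: np.ndarray | None = None,
    rng: np.random.Generator | int | None = None,
) -> list[SpikeTrain]:
    """Draw Poisson spike trains for an ensemble of place cells.

    Per sample, each cell's rate is its Gaussian tuning evaluated in its
    own frame, suppressed to the baseline rate whenever the latent state
    disagrees with that frame, then multiplied by the current gain.
    ``state=None`` disables the suppression entirely (every cell
    expresses its tuning at all times, whatever its frame). Spike counts
    are Poisson per 1/fs bin; spike times are jittered uniformly within
    the bin.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = len(series)
    dt = float(series.t[1] - series.t[0])
    if gain is None:
        gain = np.ones(n)
    state = None if state is None else np.asarray(state)
    gain = np.asarray(gain, dtype=float)
    xa, ya = series.arena_xy()

    cell_rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(
        entropy=int(rng.integers(0, 2**63))).spawn(len(cells))]

    trains: list[SpikeTrain] = []
    for k, (cell, crng) in enumerate(zip(cells, cell_rngs)):
        if cell.frame == "room":
            tuned = cell.rate_at(series.x, series.y)
            agrees = np.ones(n, dtype=bool) if state is None else state == ROOM
        else:
            tuned = cell.rate_at(xa, ya)
            agrees = np.ones(n, dtype=bool) if state is None else state == ARENA
        rate = np.where(agrees, tuned, cell.baseline_rate) * gain
        counts = crng.poisson(rate * dt)
        starts = np.repeat(series.t, counts)
        times = np.sort(starts + crng.uniform(0.0, dt, size=starts.size))
        uid = cell.unit_id if cell.unit_id is not None else f"sim{k:03d}"
        trains.append(SpikeTrain(uid, times, waveform_us=cell.waveform_us,
                                 region="hippocampus"))
    return trains


@dataclass
class SimulatedSession:
    """A complete synthetic session plus its generative manifest."""

    series: PositionSeries
    state: np.ndarray
    gain: np.ndarray
    trains: list[SpikeTrain]
    cells: list[CellSpec]
    manifest: dict = field(default_factory=dict)


def simulate_session(
    cfg: SimConfig,
    cells: Sequence[CellSpec] = (),
    state_process: StateProcess | None = None,
    gain_process: GainProcess | None = None,
) -> SimulatedSession:
    """Run trajectory, state, gain and spiking from one master seed."""
    sp = state_process or StateProcess()
    gp = gain_process or GainProcess()
    streams = _substreams(cfg.seed)
    series = simulate_trajectory(cfg, np.random.default_rng(streams["trajectory"]))
    state = latent_state(series, sp, np.random.default_rng(streams["state"]))
    gain = gain_series(series, gp, np.random.default_rng(streams["gain"]))
    trains = simulate_ensemble(series, cells, state, gain,
                               np.random.default_rng(streams["cells"]))
    manifest = {
        "generator": "placeframes.simulate (synthetic stand-in, not a biophysical model)",
        "config": asdict(cfg),
        "state_process": asdict(sp),
        "gain_process": asdict(gp),
        "cells": [asdict(c) for c in cells],
    }
    return SimulatedSession(series, state, gain, list(trains), list(cells), manifest)


def place_cell_grid(
    n_cells: int,
    frame: str,
    arena_radius: float = ARENA_RADIUS_CM,
    sigma: float = 9.0,
    peak_rate: float = 20.0,
    baseline_rate: float = 3.0,
    rng: np.random.Generator | int | None = None,
) -> list[CellSpec]:
    """Cells with field centres spread quasi-uniformly over the disk.

    Centres follow a sunflower (golden-angle) layout so small ensembles
    still tile the arena; jitter comes from ``rng`` if given.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    idx = np.arange(n_cells) + 0.5
    r = 0.85 * arena_radius * np.sqrt(idx / n_cells)
    ang = idx * golden
    cx = r * np.cos(ang) + rng.normal(0, 1.0, n_cells)
    cy = r * np.sin(ang) + rng.normal(0, 1.0, n_cells)
    return [
        CellSpec(frame=frame, center=(float(cx[i]), float(cy[i])), sigma=sigma,
                 peak_rate=peak_rate, baseline_rate=baseline_rate,
                 unit_id=f"{frame}{i:03d}")
        for i in range(n_cells)
    ]
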