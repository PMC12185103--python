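"""Canonical synthetic study conditions.

Each factory fixes one simulated 'experiment' whose generative
parameters are known, so the corresponding analysis stage can be
validated as a parameter-recovery or calibration problem:

* :func:`positional_only` — place cells with no state switching and
  unit gain: an exact inhomogeneous Poisson ensemble whose episode
  z-scores must be unit-variance (the overdispersion null).
* :func:`gain_modulated` — the same ensemble with per-pass gain
  multipliers, the generative source of overdispersion.
* :func:`dwell_switching` — a two-frame ensemble whose latent state
  alternates with a set long-run room fraction; SFEP must recover that
  fraction.
* :func:`proximity_switching` — state switching conditioned on
  proximity to the shock zone, with avoidance shaping occupancy; the
  preference map must recover the near/far gradient.

Tuning strengths follow CA1 place-field phenomenology: field sigma
9 cm on the 41 cm-radius arena, in-field peaks of 20-30 spikes/s over a
3 spikes/s out-of-field baseline, and frame switching on a seconds
timescale. Durations are chosen so the empirical activity distributions
underlying I_pos are well estimated.
"""

from __future__ import annotations

import numpy as np

from .geometry import SectorSpec
from .simulate import (
    CellSpec,
    GainProcess,
    SimConfig,
    SimulatedSession,
    StateProcess,
    place_cell_grid,
    simulate_ensemble,
    simulate_session,
    simulate_trajectory,
)

SHOCK_ZONE = SectorSpec(0.0, 60.0, "room")


def positional_only(seed: int = 0, duration: float = 3000.0, n_cells: int = 30,
                    peak_rate: float = 20.0, baseline_rate: float = 3.0,
                    ) -> tuple[SimulatedSession, list[CellSpec]]:
    """Room-frame ensemble, no state switching, gain = 1.

    Spiking is exactly inhomogeneous Poisson around the generative
    Gaussian tuning, so episode z-scores standardized against the
    generative maps have mean 0 and variance 1.
    """
    cfg = SimConfig(duration=duration, seed=seed)
    cells = place_cell_grid(n_cells, "room", sigma=10.0, peak_rate=peak_rate,
                            baseline_rate=baseline_rate, rng=3)
    sess = simulate_session(cfg, cells, StateProcess("none"), GainProcess())
    return sess, cells


def gain_modulated(spread: float, seed: int = 0, duration: float = 1500.0,
                   n_cells: int = 12) -> tuple[SimulatedSession, list[CellSpec]]:
    """Per-pass gains {1-spread, 1+spread}, equiprobable, 5 s passes.

    spread = 0 recovers the positional-only ensemble; var(z) grows with
    the spread as 1 + E[exp]*spread^2 when passes align with episodes.
    """
    if not (0.0 <= spread < 1.0):
        raise ValueError("spread must lie in [0, 1)")
    cfg = SimConfig(duration=duration, seed=seed)
    cells = place_cell_grid(n_cells, "room", sigma=10.0, peak_rate=20.0,
                            baseline_rate=3.0, rng=3)
    gp = (GainProcess(gains=(1.0 - spread, 1.0 + spread)) if spread > 0
          else GainProcess())
    sess = simulate_session(cfg, cells, StateProcess("none"), gp)
    return sess, cells


def two_frame_cells(n_per_frame: int = 20, peak_rate: float = 20.0) -> list[CellSpec]:
    """Strongly tuned ensembles tiling both frames."""
    return (place_cell_grid(n_per_frame, "room", peak_rate=peak_rate, rng=21)
            + place_cell_grid(n_per_frame, "arena", peak_rate=peak_rate, rng=22))


def dwell_switching(p_room: float, seed: int = 0, duration: float = 2000.0,
                    mean_dwell: float = 5.0, n_per_frame: int = 20
                    ) -> SimulatedSession:
    """Alternating-renewal state with long-run room fraction ``p_room``."""
    cfg = SimConfig(duration=duration, seed=seed)
    sp = StateProcess("dwell", mean_dwell=mean_dwell, p_room=p_room)
    return simulate_session(cfg, two_frame_cells(n_per_frame), sp)


def pure_frame_ensemble(frame: str, seed: int = 0, duration: float = 1200.0,
                        n_cells: int = 20):
    """Single-frame ensemble with suppression disabled (always tuned)."""
    cfg = SimConfig(duration=duration, seed=seed)
    series = simulate_trajectory(cfg)
    cells = place_cell_grid(n_cells, frame, rng=31 if frame == "room" else 32)
    trains = simulate_ensemble(series, cells, state=None,
                               rng=np.random.default_rng(seed + 1000))
    return series, trains


def proximity_switching(seed: int = 0, duration: float = 4000.0,
                        p_room_near: float = 0.9, p_room_far: float = 0.1,
                        mean_dwell: float = 2.0, n_per_frame: int = 30,
                        avoidance_gain: float = 4.0) -> SimulatedSession:
    """Shock-zone-conditioned switching with avoidance-shaped occupancy.

    The walker avoids the 60-degree room-frame zone (occupancy inside it
    drops several-fold), and at each state renewal the ensemble prefers
    the room frame with probability ``p_room_near`` in the half of the
    arena containing the zone, ``p_room_far`` opposite. The faster
    2 s dwell keeps the state spatially coherent with the position at
    which it was drawn.
    """
    cfg = SimConfig(duration=duration, seed=seed, avoidance_gain=avoidance_gain,
                    avoidance_zone=SHOCK_ZONE)
    sp = StateProcess("proximity", mean_dwell=mean_dwell,
                      p_room_near=p_room_near, p_room_far=p_room_far,
                      zone=SHOCK_ZONE)
    return simulate_session(cfg, two_frame_cells(n_per_frame, peak_rate=30.0), sp)
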