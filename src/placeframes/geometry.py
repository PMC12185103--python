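"""Spatial-frame geometry for the rotating-arena place avoidance task.

The task dissociates two coordinate systems: the stationary *room* frame
(where the shock zone is defined) and the *arena* frame that rotates with
the platform. Positions are tracked in the room frame together with the
accumulated arena rotation angle; the arena-frame position is obtained by
a time-varying rigid rotation. Angular sectors (the 60-degree shock zone,
the near/far halves used to summarise ensemble frame preference) are
defined here as well.

Conventions: angles in degrees, counterclockwise positive, 0 at the +x
axis. The rotation angle ``theta`` accumulates without wrapping so the
number of revolutions stays recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Arena radius in cm (82 cm diameter platform).
ARENA_RADIUS_CM = 41.0

#: Slack allowed on the radius check when validating tracked positions, cm.
TRACKING_TOLERANCE_CM = 2.0

VALID_FRAMES = ("room", "arena")


class GeometryError(ValueError):
    """Raised for invalid geometric input (origin angle, bad sector, ...)."""


@dataclass(frozen=True)
class SectorSpec:
    """An angular sector of the arena in one spatial frame.

    Membership is half-open on the leading (counterclockwise) edge:
    a point belongs to the sector iff its polar angle lies in
    ``[center - width/2, center + width/2)`` after reduction modulo 360.
    ``width == 0`` denotes an empty sector (membership always false).
    """

    center_deg: float
    width_deg: float
    frame: str = "room"

    def __post_init__(self) -> None:
        if not (0.0 <= self.width_deg <= 360.0):
            raise GeometryError(f"sector width must be in [0, 360], got {self.width_deg}")
        if self.frame not in VALID_FRAMES:
            raise GeometryError(f"frame must be one of {VALID_FRAMES}, got {self.frame!r}")
        if not np.isfinite(self.center_deg):
            raise GeometryError("sector center must be finite")

    def shifted(self, delta_deg: float) -> "SectorSpec":
        """Sector rotated by ``delta_deg`` (e.g. the 180-degree conflict zone)."""
        return SectorSpec((self.center_deg + delta_deg) % 360.0, self.width_deg, self.frame)


@dataclass
class PositionSeries:
    """Tracked positions on a uniform time grid.

    ``x``/``y`` are room-frame coordinates in cm with the origin at the
    arena centre; ``theta`` is the accumulated arena rotation angle in
    degrees. Sampling is nominally 30 Hz.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    arena_radius: float = ARENA_RADIUS_CM
    validate: bool = field(default=True, repr=False)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if not (self.t.shape == self.x.shape == self.y.shape == self.theta.shape):
            raise GeometryError("t, x, y, theta must have identical shapes")
        if self.validate:
            self._validate()

    def _validate(self) -> None:
        if self.t.size == 0:
            raise GeometryError("empty position series")
        for name, a in (("t", self.t), ("x", self.x), ("y", self.y), ("theta", self.theta)):
            if not np.all(np.isfinite(a)):
                bad = int(np.flatnonzero(~np.isfinite(a))[0])
                raise GeometryError(f"non-finite {name} at row {bad}")
        if self.t.size > 1:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                bad = int(np.flatnonzero(dt <= 0)[0]) + 1
                raise GeometryError(f"timestamps not strictly increasing at row {bad}")
            if np.max(np.abs(dt - dt[0])) > 1e-4:
                raise GeometryError("time grid is not uniform")
        r = np.hypot(self.x, self.y)
        limit = self.arena_radius + TRACKING_TOLERANCE_CM
        if np.any(r > limit):
            bad = int(np.flatnonzero(r > limit)[0])
            raise GeometryError(
                f"position at row {bad} lies {r[bad]:.1f} cm from centre, "
                f"outside the arena (limit {limit:.1f} cm)"
            )

    def __len__(self) -> int:
        return int(self.t.size)

    @property
    def fs(self) -> float:
        """Sampling rate in Hz."""
        if len(self) < 2:
            raise GeometryError("sampling rate undefined for a single sample")
        return 1.0 / float(self.t[1] - self.t[0])

    @property
    def duration(self) -> float:
        """Session length in seconds (span plus one sample period)."""
        if len(self) < 2:
            return 0.0
        return float(self.t[-1] - self.t[0]) + 1.0 / self.fs

    def arena_xy(self) -> tuple[np.ndarray, np.ndarray]:
        """Positions transformed into the rotating arena frame."""
        return room_to_arena(self.x, self.y, self.theta)

    def xy_in_frame(self, frame: str) -> tuple[np.ndarray, np.ndarray]:
        if frame == "room":
            return self.x, self.y
        if frame == "arena":
            return self.arena_xy()
        raise GeometryError(f"unknown frame {frame!r}")

    def window(self, t_start: float, t_stop: float) -> "PositionSeries":
        """Sub-series with ``t_start <= t < t_stop`` (times relative to session start)."""
        rel = self.t - self.t[0]
        m = (rel >= t_start) & (rel < t_stop)
        if not np.any(m):
            raise GeometryError(f"window [{t_start}, {t_stop}) contains no samples")
        return PositionSeries(
            self.t[m], self.x[m], self.y[m], self.theta[m],
            arena_radius=self.arena_radius, validate=False,
        )


def room_to_arena(x, y, theta_deg):
    """Rotate room-frame coordinates into the arena frame.

    The arena frame is rotated by ``theta`` relative to the room, so a
    room-frame point maps to the arena frame through a rotation by
    ``-theta`` about the origin. Radius is preserved exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y)) and np.all(np.isfinite(theta_deg))):
        raise GeometryError("non-finite input to room_to_arena")
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    c, s = np.cos(th), np.sin(th)
    # rotation by -theta
    return x * c + y * s, -x * s + y * c


def arena_to_room(x, y, theta_deg):
    """Inverse of :func:`room_to_arena` (rotation by ``+theta``)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y)) and np.all(np.isfinite(theta_deg))):
        raise GeometryError("non-finite input to arena_to_room")
    th = np.deg2rad(np.asarray(theta_deg, dtype=float))
    c, s = np.cos(th), np.sin(th)
    return x * c - y * s, x * s + y * c


def polar_angle_deg(x, y):
    """Polar angle of (x, y) in degrees in [0, 360); the origin is an error."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    at_origin = (x == 0) & (y == 0)
    if np.any(at_origin):
        raise GeometryError("polar angle undefined at the origin")
    return np.degrees(np.arctan2(y, x)) % 360.0


def in_sector(x, y, sector: SectorSpec) -> np.ndarray:
    """Membership of point(s) in a sector; half-open on the leading edge.

    The caller is responsible for supplying coordinates already expressed
    in ``sector.frame``.
    """
    if sector.width_deg == 0.0:
        return np.zeros(np.broadcast(np.asarray(x), np.asarray(y)).shape, dtype=bool)
    ang = polar_angle_deg(x, y)
    lo = sector.center_deg - sector.width_deg / 2.0
    return np.asarray((ang - lo) % 360.0 < sector.width_deg)


def angular_occupancy(series: PositionSeries, bin_deg: float = 1.0) -> np.ndarray:
    """Sample counts per angular bin of the room-frame polar angle."""
    ang = polar_angle_deg(series.x, series.y)
    n_bins = int(round(360.0 / bin_deg))
    counts, _ = np.histogram(ang, bins=n_bins, range=(0.0, 360.0))
    return counts


def _window_occupancy(counts: np.ndarray, center: int, width: int) -> int:
    """Occupancy of a width-degree window centred on integer degree `center`.

    Uses 1-degree bins; the window covers bins [center - width//2,
    center + width//2) modulo 360, matching the half-open sector rule.
    """
    idx = (np.arange(center - width // 2, center + width // 2)) % 360
    return int(counts[idx].sum())


def near_far_partition(
    series: PositionSeries,
    seed_width: float = 20.0,
    coverage: float = 0.5,
) -> tuple[SectorSpec, SectorSpec]:
    """Split the room frame into a 'near' and a 'far' sector.

    The near sector is the largest room-frame sector that surrounds the
    least-visited ``seed_width``-degree sector and contains at least a
    ``coverage`` fraction of the recording time; the far sector is its
    complement. During avoidance the least-visited sector sits inside the
    shock zone, so "near" means near the shock zone.

    The seed centre is scanned on a 1-degree grid (ties broken by the
    smallest angle) and the sector is grown symmetrically in 1-degree
    steps on both edges until the coverage threshold is met.
    """
    if len(series) == 0:
        raise GeometryError("empty position series")
    if not (0.0 < coverage <= 1.0):
        raise GeometryError("coverage must be in (0, 1]")
    counts = angular_occupancy(series, bin_deg=1.0)
    total = counts.sum()
    w0 = int(round(seed_width))
    occ = np.array([_window_occupancy(counts, c, w0) for c in range(360)])
    center = int(np.argmin(occ))  # argmin takes the smallest index on ties

    width = w0
    while width < 360 and _window_occupancy(counts, center, width) < coverage * total:
        width += 2  # one degree on each edge
    width = min(width, 360)

    near = SectorSpec(float(center), float(width), "room")
    far = SectorSpec(float((center + 180) % 360), float(360 - width), "room")
    return near, far
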