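"""Track smoothing and kinematic derivation.

Positions are smoothed with a centered 3-point running mean (configurable
odd window) to suppress high-frequency GPS jitter, then differenced forward
in time to obtain per-interval ground-velocity components, ground speed,
heading, turn rate and vertical rate.  Forward differences (not central)
are used throughout so maneuver boundaries align with fix indices.

Distances use the haversine formula on a mean-radius sphere
(R = 6,371,008.8 m); at the step lengths of a 1 Hz soaring track the
difference from full ellipsoid geodesics is far below GPS noise.  Local
east/north displacements use an equirectangular projection about each
step's midpoint latitude.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import DataError
from .track_io import GpsFix, Track

__all__ = [
    "EARTH_RADIUS_M",
    "KinematicSeries",
    "PathStats",
    "smooth_positions",
    "haversine_m",
    "geodesic_distance",
    "derive_kinematics",
    "path_statistics",
    "wrap_angle",
]

EARTH_RADIUS_M = 6_371_008.8

#: ground speeds below this (m/s) are treated as stationary: the heading is
#: held from the previous interval and the turn rate is zero, so GPS jitter
#: at rest cannot masquerade as turning flight.
STILLNESS_FLOOR_MS = 0.5


def wrap_angle(deg):
    """Wrap angle differences into (-180, 180] degrees."""
    return -((-np.asarray(deg, dtype=float) + 180.0) % 360.0 - 180.0)


def haversine_m(lat1, lon1, lat2, lon2, radius: float = EARTH_RADIUS_M):
    """Great-circle distance in meters between WGS84 points (vectorized)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dp = p2 - p1
    dl = np.radians(np.asarray(lon2, dtype=float) - np.asarray(lon1, dtype=float))
    a = np.sin(dp / 2.0) ** 2 + np.cos(p1) * np.cos(p2) * np.sin(dl / 2.0) ** 2
    return 2.0 * radius * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


def geodesic_distance(a: GpsFix, b: GpsFix) -> float:
    """Horizontal great-circle distance between two fixes, meters.

    Altitude is ignored; the result is symmetric, non-negative and zero iff
    the coordinates coincide.
    """
    return float(haversine_m(a.lat, a.lon, b.lat, b.lon))


def smooth_positions(track: Track, window: int = 3) -> Track:
    """Centered running mean of lat/lon/altitude, applied per gap-free block.

    The first and last ``(window - 1) // 2`` fixes of each block keep their
    raw values; times are never changed.  Blocks shorter than the window are
    returned unsmoothed with a warning.  Linear sequences are fixed points on
    the interior, so smoothing is idempotent there.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("smoothing window must be odd and >= 1")
    if window == 1:
        return track
    half = window // 2
    cols = {name: track.df[name].to_numpy(dtype=float).copy()
            for name in ("lat", "lon", "alt_asl", "alt_agl")}
    kernel = np.ones(window) / window
    for start, end in track.blocks():
        n = end - start
        if n < window:
            if n > 1:
                warnings.warn(f"block [{start}:{end}) shorter than window {window}; left unsmoothed",
                              stacklevel=2)
            continue
        for name, arr in cols.items():
            seg = arr[start:end]
            if np.all(np.isnan(seg)):
                continue
            sm = np.convolve(seg, kernel, mode="valid")
            arr[start + half:end - half] = sm
    return track.with_columns(**cols)


@dataclass
class KinematicSeries:
    """Per-interval kinematics of a track.

    All arrays have length ``n_fixes - 1``; entry ``i`` describes the
    interval from fix ``i`` to fix ``i + 1``.  Intervals spanning a sampling
    gap have ``valid = False`` and NaN kinematics.  Fix-level time and
    altitude arrays (length ``n_fixes``) ride along so segmenters can compute
    durations and altitude changes without the original track.
    """

    dt: np.ndarray
    ve: np.ndarray            # east ground-velocity component, m/s
    vn: np.ndarray            # north ground-velocity component, m/s
    ground_speed: np.ndarray  # m/s, = hypot(ve, vn)
    heading: np.ndarray       # deg clockwise from true north, [0, 360)
    turn_rate: np.ndarray     # deg/s, signed; positive = clockwise
    vertical_rate: np.ndarray  # m/s from ASL differences
    valid: np.ndarray         # bool; False for gap-spanning intervals
    fix_times: np.ndarray     # length n_fixes
    fix_alt_asl: np.ndarray   # length n_fixes
    fix_alt_agl: np.ndarray   # length n_fixes
    fix_lat: np.ndarray
    fix_lon: np.ndarray

    @property
    def n_intervals(self) -> int:
        return len(self.dt)

    @property
    def n_fixes(self) -> int:
        return len(self.fix_times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t0": self.fix_times[:-1], "dt": self.dt, "ve": self.ve, "vn": self.vn,
            "ground_speed": self.ground_speed, "heading": self.heading,
            "turn_rate": self.turn_rate, "vertical_rate": self.vertical_rate,
            "valid": self.valid,
        })


def derive_kinematics(track: Track, stillness_floor: float = STILLNESS_FLOOR_MS) -> KinematicSeries:
    """Forward-difference kinematics of a (smoothed) track.

    East/north displacements come from an equirectangular projection about
    each step's midpoint latitude; vertical rate uses ASL differences so
    terrain slope never masquerades as climb.  Below ``stillness_floor``
    ground speed the heading is carried from the previous interval.
    """
    t = track.times
    n = len(t)
    if n < 2:
        raise DataError("need at least two fixes to derive kinematics")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise DataError("non-positive dt encountered")
    lat, lon = track.lat, track.lon
    latmid = np.radians((lat[:-1] + lat[1:]) / 2.0)
    de = EARTH_RADIUS_M * np.cos(latmid) * np.radians(np.diff(lon))
    dn = EARTH_RADIUS_M * np.radians(np.diff(lat))
    ve = de / dt
    vn = dn / dt
    gs = np.hypot(ve, vn)
    heading = np.degrees(np.arctan2(ve, vn)) % 360.0
    vz = np.diff(track.alt_asl) / dt

    valid = np.zeros(n - 1, dtype=bool)
    turn = np.zeros(n - 1)
    for start, end in track.blocks():
        if end - start < 2:
            continue
        sl = slice(start, end - 1)  # intervals inside the block
        valid[sl] = True
        # hold heading through stationary intervals (forward fill per block)
        still = gs[sl] < stillness_floor
        h = heading[sl].copy()
        idx = np.arange(len(h))
        moving = ~still
        if moving.any():
            fill = np.maximum.accumulate(np.where(moving, idx, -1))
            first = int(np.argmax(moving))
            fill[fill < 0] = first  # leading still intervals take first real heading
            h = h[fill]
        heading[sl] = h
        tr = np.zeros(len(h))
        if len(h) > 1:
            tr[1:] = wrap_angle(np.diff(h)) / dt[sl][1:]
        tr[still] = 0.0
        turn[sl] = tr
    for arr in (ve, vn, gs, heading, turn, vz):
        arr[~valid] = np.nan

    return KinematicSeries(dt=dt, ve=ve, vn=vn, ground_speed=gs, heading=heading,
                           turn_rate=turn, vertical_rate=vz, valid=valid,
                           fix_times=t, fix_alt_asl=track.alt_asl,
                           fix_alt_agl=track.alt_agl, fix_lat=lat, fix_lon=lon)


@dataclass(frozen=True)
class PathStats:
    """Whole-track distance statistics.

    ``path_distance`` sums consecutive great-circle steps; ``direct_distance``
    is first fix to last fix; ``average_speed = path_distance / duration``
    where duration is total elapsed time including gaps.
    """

    path_distance: float
    direct_distance: float
    duration: float
    average_speed: float


def path_statistics(track: Track) -> PathStats:
    """Path distance, direct (migration) distance, duration and mean speed."""
    if len(track) < 2:
        warnings.warn("path_statistics of a <2-fix track is degenerate", stacklevel=2)
        return PathStats(0.0, 0.0, 0.0, 0.0)
    lat, lon = track.lat, track.lon
    steps = haversine_m(lat[:-1], lon[:-1], lat[1:], lon[1:])
    path = float(np.sum(steps))
    direct = float(haversine_m(lat[0], lon[0], lat[-1], lon[-1]))
    duration = float(track.times[-1] - track.times[0])
    return PathStats(path, direct, duration, path / duration if duration > 0 else 0.0)
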