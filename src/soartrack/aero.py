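"""Airspeed, wind, sink-rate and shear estimation from circling flight.

The central identity: a bird's ground velocity is the vector sum of its air
velocity (magnitude = true airspeed, TAS) and the ambient wind at flight
level.  Over one closed circle flown at constant airspeed the air-velocity
contribution integrates to zero, so the **time-weighted vector mean of the
ground velocity over a full turn is exactly the ambient wind**, and the mean
magnitude of (ground velocity − wind) is the TAS.  This estimator is exact
for uniform circling and needs no model fit.

Two scalar diagnostics of the ground-speed trace are also reported: its
mean and its half-range ("sinusoid" mean/amplitude).  For wind weaker than
the airspeed these tend to TAS and wind speed respectively; they let the
classical read-the-sine-wave analysis be compared against the vector
estimator on the same circle.

Forward-differenced positions measure chord speed, which understates arc
speed by sin(x)/x with x = |turn rate| * dt / 2; per-interval speeds are
corrected by x/sin(x) before averaging, which is exact for uniform turning.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._errors import ContractError
from .kinematics import KinematicSeries
from .maneuvers import ManeuverSegment

__all__ = [
    "AeroConfig",
    "WindEstimate",
    "estimate_tas_and_wind",
    "banked_sink_rate",
    "ambient_vertical_velocity",
    "bulk_wind_shear",
    "tailwind_component",
]


@dataclass(frozen=True)
class AeroConfig:
    """Aerodynamic constants for a large soaring raptor.

    base_sink_rate: still-air sink at best glide speed, wings level (m/s,
    negative; a conservative value for a golden eagle). bank_angle: assumed
    bank while circling (deg); banking reduces the vertical lift component
    by cos(bank), steepening sink to base/cos(bank) (~10% at 25 deg).
    lift_drag_ratio: best-glide L/D, ~15 for large birds.
    """

    base_sink_rate: float = -0.75
    bank_angle: float = 25.0
    lift_drag_ratio: float = 15.0

    def __post_init__(self) -> None:
        if self.base_sink_rate >= 0:
            raise ContractError("base_sink_rate must be negative")
        if not (0.0 <= self.bank_angle < 90.0):
            raise ContractError("bank_angle must be in [0, 90)")
        if self.lift_drag_ratio <= 0:
            raise ContractError("lift_drag_ratio must be positive")


@dataclass(frozen=True)
class WindEstimate:
    """Ambient wind and true airspeed inferred from one circling segment."""

    wind_east: float
    wind_north: float
    wind_speed: float
    wind_direction_from: float  # deg, meteorological (direction wind blows FROM)
    tas: float
    sinusoid_mean: float        # mean ground speed over the circle
    sinusoid_amplitude: float   # half-range of ground speed over the circle
    circle_id: int = -1
    mean_alt_asl: float = float("nan")
    mean_alt_agl: float = float("nan")


def _nanmean_or_nan(values: np.ndarray) -> float:
    finite = values[np.isfinite(values)]
    return float(finite.mean()) if finite.size else float("nan")


def _chord_correction(turn_rate_deg_s: np.ndarray, dt: np.ndarray) -> np.ndarray:
    x = np.abs(np.radians(turn_rate_deg_s)) * dt / 2.0
    x = np.clip(x, 0.0, 1.4)  # guard: beyond ~160 deg/step the correction is meaningless
    out = np.ones_like(x)
    nz = x > 1e-9
    out[nz] = x[nz] / np.sin(x[nz])
    return out


def estimate_tas_and_wind(kin: KinematicSeries, circle: ManeuverSegment,
                          full_turn_min: float = 350.0, circle_id: int = -1) -> WindEstimate:
    """Wind vector and TAS from one closed circle.

    Requires the segment to accumulate at least ``full_turn_min`` degrees of
    turn (the air-velocity cancellation argument needs a closed turn);
    otherwise raises :class:`ContractError`.
    """
    a, b = circle.start, circle.end
    sl = slice(a, b)
    ok = kin.valid[sl]
    if not ok.all():
        raise ContractError("circle segment spans a sampling gap")
    cum = float(np.abs(np.sum(np.radians(kin.turn_rate[sl]) * kin.dt[sl]))) * 180.0 / math.pi
    if np.isfinite(circle.cum_turn):
        cum = abs(circle.cum_turn)
    if cum < full_turn_min:
        raise ContractError(f"accumulated turn {cum:.1f} deg < {full_turn_min} deg; not a closed circle")
    w = kin.dt[sl]
    wsum = float(np.sum(w))
    ve, vn = kin.ve[sl], kin.vn[sl]
    corr = _chord_correction(kin.turn_rate[sl], w)
    # Vector mean of ground velocity = wind + tas * (mean unit air-velocity).
    # Over an exactly closed turn the second term vanishes; a circle closing
    # at, say, 350 deg leaves a small uncancelled arc, so solve the coupled
    # system by fixed-point iteration (converges geometrically for W < TAS).
    we = float(np.sum(ve * w) / wsum)
    wn = float(np.sum(vn * w) / wsum)
    tas = float("nan")
    for _ in range(8):
        ae, an = ve - we, vn - wn
        mag = np.hypot(ae, an)
        mag = np.where(mag > 1e-12, mag, 1e-12)
        tas = float(np.sum(mag * corr * w) / wsum)
        ue = float(np.sum(ae / mag * w) / wsum)
        un = float(np.sum(an / mag * w) / wsum)
        we_new = float(np.sum(ve * w) / wsum) - tas * ue
        wn_new = float(np.sum(vn * w) / wsum) - tas * un
        if abs(we_new - we) < 1e-10 and abs(wn_new - wn) < 1e-10:
            we, wn = we_new, wn_new
            break
        we, wn = we_new, wn_new
    ae, an = ve - we, vn - wn
    air_speed = np.hypot(ae, an) * corr
    tas = float(np.sum(air_speed * w) / wsum)
    gs = kin.ground_speed[sl] * corr
    mean_gs = float(np.sum(gs * w) / np.sum(w))
    amp = float((np.max(gs) - np.min(gs)) / 2.0)
    return WindEstimate(
        wind_east=we, wind_north=wn, wind_speed=float(np.hypot(we, wn)),
        wind_direction_from=float(np.degrees(np.arctan2(-we, -wn)) % 360.0),
        tas=tas, sinusoid_mean=mean_gs, sinusoid_amplitude=amp, circle_id=circle_id,
        mean_alt_asl=_nanmean_or_nan(kin.fix_alt_asl[a:b + 1]),
        mean_alt_agl=_nanmean_or_nan(kin.fix_alt_agl[a:b + 1]))


def banked_sink_rate(cfg: AeroConfig) -> float:
    """Still-air sink rate while circling at the configured bank angle.

    Banking tilts the lift vector, so the vertical lift component drops by
    cos(bank) and the equilibrium sink steepens to base / cos(bank).
    """
    if not (0.0 <= cfg.bank_angle < 90.0):
        raise ContractError("bank angle must be in [0, 90)")
    return cfg.base_sink_rate / math.cos(math.radians(cfg.bank_angle))


def ambient_vertical_velocity(observed_climb: float, sink: float) -> float:
    """Vertical air motion implied by an observed climb and a still-air sink.

    A bird sinking at ``sink`` (< 0) through air moving vertically at ``w``
    climbs at ``w + sink``; hence ``w = observed_climb - sink``.
    """
    if sink >= 0:
        raise ContractError("sink rate must be negative")
    return observed_climb - sink


def bulk_wind_shear(speed_low: float, z_low: float, speed_high: float, z_high: float) -> float:
    """Bulk vertical shear of horizontal wind speed, (m/s)/m = 1/s."""
    if z_high <= z_low:
        raise ContractError("z_high must exceed z_low")
    return (speed_high - speed_low) / (z_high - z_low)


def tailwind_component(wind_east: float, wind_north: float, course_deg: float) -> float:
    """Projection of the wind vector onto a course (deg clockwise from north).

    Positive = tailwind along the course, negative = headwind.
    """
    c = math.radians(course_deg)
    return wind_east * math.sin(c) + wind_north * math.cos(c)
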