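"""Synthetic soaring-flight generator with ground-truth labels.

A rule-based flight agent (constant true airspeed, fixed circling period,
assumed bank angle and still-air sink) moves through a parametric field of
atmospheric gravity-wave vertical velocity over flat synthetic terrain,
with a horizontal wind that strengthens and veers with height.  The agent

* **glides** on the migration heading, sinking at the wings-level rate plus
  whatever the air is doing;
* switches to **climb** (circling at 360/period deg/s, direction occasionally
  reversing between consecutive circles) after sustained banked-flight lift,
  and circles until the ceiling is reached or the lift is lost, always
  finishing the circle in progress so every climb is a whole number of
  circles;
* **meanders** (a run-and-tumble heading search that homes in on rising air)
  when it sinks below the working floor without lift.

The wave field is a stationary monochromatic wave with a Gaussian vertical
envelope; the default scenario sums a main wave layer near 2 km ASL with a
weaker low-level terrain-induced wave, mirroring the two lift regimes such
flights exploit (an elevated wave train plus near-surface wave lift for
climb-out).  Every fix records its generating maneuver label, the true
vertical air velocity and the true wind vector, so classifier and estimator
recovery can be scored exactly.  All randomness flows through a single seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._errors import ContractError
from .kinematics import EARTH_RADIUS_M
from .track_io import Track

__all__ = [
    "WaveField",
    "FlightPolicy",
    "SyntheticTrack",
    "wave_vertical_velocity",
    "default_wave_fields",
    "simulate_flight",
    "add_gps_noise",
    "uniform_circling_track",
    "label_recovery",
]

#: epoch seconds of 2016-03-24 15:57:46 UTC, the default simulated start time
DEFAULT_START_TIME = 1458835066.0


@dataclass(frozen=True)
class WaveField:
    """One monochromatic gravity-wave layer.

    Vertical velocity at local coordinates (x east, y north, z ASL):

        w = A * sin(2 pi d / wavelength + phase) * exp(-(z - z0)^2 / (2 sz^2))

    where d is the projection of (x, y) onto the wave-normal azimuth.
    """

    amplitude: float = 2.0            # A, m/s
    wavelength: float = 10_000.0      # m
    wave_normal_azimuth: float = 20.0  # deg clockwise from north
    z0: float = 2000.0                # layer center, m ASL
    sigma_z: float = 400.0            # vertical envelope scale, m
    phase: float = 0.0                # radians

    def __post_init__(self) -> None:
        if self.amplitude < 0 or self.wavelength <= 0 or self.sigma_z <= 0:
            raise ContractError("WaveField requires A >= 0, wavelength > 0, sigma_z > 0")


def wave_vertical_velocity(x, y, z, fld: WaveField):
    """Vertical air velocity (m/s) of one wave layer at local (x, y, z)."""
    az = math.radians(fld.wave_normal_azimuth)
    d = np.asarray(x, dtype=float) * math.sin(az) + np.asarray(y, dtype=float) * math.cos(az)
    envelope = np.exp(-((np.asarray(z, dtype=float) - fld.z0) ** 2) / (2.0 * fld.sigma_z ** 2))
    return fld.amplitude * np.sin(2.0 * math.pi * d / fld.wavelength + fld.phase) * envelope


def default_wave_fields() -> tuple[WaveField, ...]:
    """Default scenario: main elevated wave, low-level wave, short secondary wave.

    All components share phase 0 so the flight starts at a node entering the
    rising half-wavelength and the first climb can harvest the full lift
    band before the first trough crossing.  The amplitudes are set so the
    combined crest amplitude is ~3.3 m/s through the 600-2000 m AGL working
    band, which (i) puts peak climb rates after the banked sink of
    ~-0.82 m/s in the observed 1-3 m/s range and (ii) makes the climb/glide
    sawtooth self-sustaining: the bird drifts through the lift
    half-wavelength at wind speed but crosses the sinking half at glide
    ground speed, so lift must overcome sink by roughly the ratio of those
    speeds.  The lower layer stands in for terrain-induced wave lift below
    the main elevated wave train.  The secondary shorter wave rides on the
    dominant ~10 km train: where the two interfere constructively, crests
    strengthen and climb/glide cycles occur more often than the dominant
    wavelength alone would give, and in long-wave troughs it opens patches
    of weaker sink, moderating mean glide descent rates.
    """
    main = WaveField(amplitude=3.2, wavelength=10_000.0, wave_normal_azimuth=20.0,
                     z0=2000.0, sigma_z=400.0, phase=0.0)
    low = WaveField(amplitude=3.0, wavelength=10_000.0, wave_normal_azimuth=20.0,
                    z0=1100.0, sigma_z=350.0, phase=0.0)
    short = WaveField(amplitude=1.5, wavelength=4_500.0, wave_normal_azimuth=20.0,
                      z0=1600.0, sigma_z=600.0, phase=0.0)
    return (main, low, short)


@dataclass(frozen=True)
class FlightPolicy:
    """Behavioral and aerodynamic parameters of the simulated bird."""

    tas: float = 11.4                  # m/s, airspeed while circling (min sink)
    #: airspeed on inter-lift glides; soaring birds may speed up between
    #: climbs (speed-to-fly).  Default matches the circling airspeed.
    glide_tas: float = 11.4
    circle_period: float = 22.0        # s per full circle
    bank: float = 25.0                 # deg while circling
    base_sink: float = -0.75           # m/s wings-level still-air sink
    migration_heading: float = 20.0    # deg
    ceiling_agl: float = 2000.0        # m; stop climbing here
    floor_agl: float = 600.0           # m; search below here
    #: piecewise-linear wind profile: (z ASL m, speed m/s, bearing TOWARD deg);
    #: speed strengthens and direction veers with height.
    wind_profile: tuple[tuple[float, float, float], ...] = (
        (500.0, 4.5, 35.0), (2500.0, 11.5, 10.0))
    meander_turn_sigma: float = 20.0   # deg/s heading noise while searching
    flip_prob: float = 0.12            # P(reverse circling direction) per circle
    #: lift selectivity (hysteresis): a gliding bird starts circling only
    #: where the banked climb rate would reach climb_entry_margin (strong
    #: cores -> fast climbs and a glide-heavy time budget, as observed), and
    #: keeps circling until it falls below climb_exit_margin.  A bird
    #: searching below the floor takes any positive lift.
    climb_entry_margin: float = 0.9    # m/s
    climb_exit_margin: float = 0.2     # m/s
    #: extra turn (deg) carried past closure before a direction reversal is
    #: applied: a bird rolling from one circling direction to the other
    #: overshoots its entry heading while reversing bank.  This also keeps
    #: the pre-reversal circle's smoothed heading trace closing cleanly.
    flip_overshoot: float = 30.0
    #: each glide leg holds a heading drawn uniformly within this many
    #: degrees of the migration heading: route-scale wandering (following
    #: lift lines and terrain) that makes the flown path longer than the
    #: direct distance, as real migration tracks are.
    glide_tack: float = 45.0
    lift_confirm_s: float = 5.0        # sustained lift needed to start climbing
    terrain_elevation: float = 500.0   # m ASL, flat synthetic terrain
    start_agl: float = 800.0
    origin_lat: float = 38.8
    origin_lon: float = -79.0
    start_time: float = DEFAULT_START_TIME
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tas <= 0 or self.circle_period <= 0:
            raise ContractError("tas and circle_period must be positive")
        if self.ceiling_agl <= self.floor_agl:
            raise ContractError("ceiling_agl must exceed floor_agl")
        if not (0.0 <= self.bank < 90.0):
            raise ContractError("bank must be in [0, 90)")

    def wind_at(self, z_asl: float) -> tuple[float, float]:
        """(east, north) wind components at a height, linear in speed and bearing."""
        prof = self.wind_profile
        zs = [p[0] for p in prof]
        if z_asl <= zs[0]:
            sp, br = prof[0][1], prof[0][2]
        elif z_asl >= zs[-1]:
            sp, br = prof[-1][1], prof[-1][2]
        else:
            k = int(np.searchsorted(zs, z_asl)) - 1
            z1, s1, b1 = prof[k]
            z2, s2, b2 = prof[k + 1]
            f = (z_asl - z1) / (z2 - z1)
            sp = s1 + f * (s2 - s1)
            db = ((b2 - b1 + 180.0) % 360.0) - 180.0  # shortest-path bearing lerp
            br = b1 + f * db
        brr = math.radians(br)
        return sp * math.sin(brr), sp * math.cos(brr)


@dataclass
class SyntheticTrack:
    """A simulated track plus its per-fix ground truth."""

    track: Track
    labels: np.ndarray       # per fix: circle_cw / circle_ccw / glide / meander
    w_air: np.ndarray        # true vertical air velocity at each fix, m/s
    wind_east: np.ndarray
    wind_north: np.ndarray
    terrain_elevation: float
    policy: FlightPolicy
    fields: tuple[WaveField, ...]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "time": self.track.times, "label": self.labels, "w_air": self.w_air,
            "wind_east": self.wind_east, "wind_north": self.wind_north,
        })


def _to_geodetic(x: np.ndarray, y: np.ndarray, lat0: float, lon0: float):
    lat = lat0 + np.degrees(y / EARTH_RADIUS_M)
    lon = lon0 + np.degrees(x / (EARTH_RADIUS_M * math.cos(math.radians(lat0))))
    return lat, lon


def simulate_flight(policy: FlightPolicy | None = None,
                    fields: WaveField | Sequence[WaveField] | None = None,
                    duration: float = 7600.0, dt: float = 1.0,
                    seed: int | None = None) -> SyntheticTrack:
    """Integrate the flight policy through the wave field.

    Reproducible: identical (policy, fields, duration, dt, seed) give
    bit-identical tracks.  ``seed`` overrides ``policy.seed`` when given.
    """
    policy = policy or FlightPolicy()
    if fields is None:
        fields = default_wave_fields()
    elif isinstance(fields, WaveField):
        fields = (fields,)
    fields = tuple(fields)
    rng = np.random.default_rng(policy.seed if seed is None else seed)
    n = int(round(duration / dt))
    if n < 1:
        raise ContractError("duration must cover at least one step")

    sink_banked = policy.base_sink / math.cos(math.radians(policy.bank))
    turn_step = 360.0 / policy.circle_period * dt

    x = np.empty(n + 1)
    y = np.empty(n + 1)
    z = np.empty(n + 1)
    labels = np.empty(n + 1, dtype=object)
    w_rec = np.empty(n + 1)
    we_rec = np.empty(n + 1)
    wn_rec = np.empty(n + 1)

    x[0], y[0] = 0.0, 0.0
    z[0] = policy.terrain_elevation + policy.start_agl
    heading = policy.migration_heading
    mode = "glide"
    turn_dir = 1
    turn_accum = 0.0
    lift_streak = 0.0
    entry_streak = 0.0
    w_prev = None
    meander_bias = 6.0
    flip_pending = False
    exit_pending = False
    glide_heading = policy.migration_heading

    for k in range(n + 1):
        w = float(sum(wave_vertical_velocity(x[k], y[k], z[k], f) for f in fields))
        we, wn = policy.wind_at(z[k])
        z_agl = z[k] - policy.terrain_elevation

        lift_streak = lift_streak + dt if (w + sink_banked) > 0.0 else 0.0
        entry_streak = entry_streak + dt if (w + sink_banked) >= policy.climb_entry_margin else 0.0

        if mode == "glide":
            if entry_streak >= policy.lift_confirm_s and z_agl < policy.ceiling_agl:
                mode = "climb"
                turn_dir = 1 if rng.random() < 0.5 else -1
                turn_accum = 0.0
            elif z_agl < policy.floor_agl and lift_streak == 0.0:
                mode = "meander"
        elif mode == "meander":
            if lift_streak >= policy.lift_confirm_s and z_agl < policy.ceiling_agl:
                mode = "climb"
                turn_dir = 1 if rng.random() < 0.5 else -1
                turn_accum = 0.0
            elif z_agl >= policy.floor_agl:
                mode = "glide"
                glide_heading = policy.migration_heading + rng.uniform(-policy.glide_tack,
                                                                       policy.glide_tack)
                heading = glide_heading
        elif mode == "climb":
            # direction reversals and glide exits are committed at circle
            # closure but applied after a short roll-out arc (flip_overshoot
            # degrees of extra turn), as a banked bird rolling level or over
            # would fly; this also keeps the final circle's smoothed heading
            # trace closing cleanly.
            if flip_pending and turn_accum >= policy.flip_overshoot:
                turn_dir = -turn_dir
                turn_accum = 0.0  # the reversed circle starts here
                flip_pending = False
            elif exit_pending and turn_accum >= policy.flip_overshoot:
                exit_pending = False
                mode = "glide"
                glide_heading = policy.migration_heading + rng.uniform(
                    -policy.glide_tack, policy.glide_tack)
                heading = glide_heading
            elif not (flip_pending or exit_pending) and turn_accum >= 360.0 - 1e-9:
                turn_accum -= 360.0
                if z_agl >= policy.ceiling_agl or (w + sink_banked) <= policy.climb_exit_margin:
                    exit_pending = True
                elif rng.random() < policy.flip_prob:
                    flip_pending = True

        if mode == "climb":
            labels[k] = "circle_cw" if turn_dir > 0 else "circle_ccw"
        else:
            labels[k] = mode
        w_rec[k], we_rec[k], wn_rec[k] = w, we, wn

        if k == n:
            break

        airspeed = policy.glide_tas if mode == "glide" else policy.tas
        if mode == "climb":
            heading = (heading + turn_dir * turn_step) % 360.0
            turn_accum += turn_step
            vz = w + sink_banked
        elif mode == "meander":
            # run-and-tumble lift search: curve gently while the air improves
            # (heading-variable enough never to look like a glide), reorient
            # sharply and pick a new curvature when it worsens
            if w_prev is not None and w < w_prev:
                heading = (heading + rng.uniform(60.0, 300.0)) % 360.0
                meander_bias = rng.uniform(1.5, 4.0) * (1 if rng.random() < 0.5 else -1)
            else:
                heading = (heading + meander_bias * dt + rng.normal(0.0, 3.0) * dt) % 360.0
            vz = w + policy.base_sink
        else:
            heading = glide_heading
            vz = w + policy.base_sink

        h = math.radians(heading)
        x[k + 1] = x[k] + (airspeed * math.sin(h) + we) * dt
        y[k + 1] = y[k] + (airspeed * math.cos(h) + wn) * dt
        z[k + 1] = z[k] + vz * dt
        w_prev = w

    lat, lon = _to_geodetic(x, y, policy.origin_lat, policy.origin_lon)
    times = policy.start_time + dt * np.arange(n + 1)
    df = pd.DataFrame({"time": times, "lat": lat, "lon": lon, "alt_asl": z,
                       "alt_agl": z - policy.terrain_elevation})
    track = Track(df, track_id="synthetic", nominal_dt=dt)
    return SyntheticTrack(track=track, labels=np.asarray(labels, dtype=object),
                          w_air=w_rec, wind_east=we_rec, wind_north=wn_rec,
                          terrain_elevation=policy.terrain_elevation,
                          policy=policy, fields=fields)


def add_gps_noise(st: SyntheticTrack, sigma_h: float = 1.0, sigma_v: float = 11.0,
                  seed: int | None = None) -> SyntheticTrack:
    """Gaussian GPS noise per fix; labels and truth fields untouched.

    Defaults interpret the receiver's published accuracies (<2 m horizontal,
    <22.5 m vertical) as ~2-sigma bounds.  Reproducible from ``seed``.
    """
    if sigma_h < 0 or sigma_v < 0:
        raise ContractError("noise sigmas must be non-negative")
    rng = np.random.default_rng(seed)
    n = len(st.track)
    lat = st.track.lat.copy()
    lon = st.track.lon.copy()
    de = rng.normal(0.0, sigma_h, n) if sigma_h else np.zeros(n)
    dn = rng.normal(0.0, sigma_h, n) if sigma_h else np.zeros(n)
    dz = rng.normal(0.0, sigma_v, n) if sigma_v else np.zeros(n)
    lat2 = lat + np.degrees(dn / EARTH_RADIUS_M)
    lon2 = lon + np.degrees(de / (EARTH_RADIUS_M * np.cos(np.radians(lat))))
    df = pd.DataFrame({"time": st.track.times, "lat": lat2, "lon": lon2,
                       "alt_asl": st.track.alt_asl + dz,
                       "alt_agl": st.track.alt_agl + dz})
    track = Track(df, st.track.id, st.track.nominal_dt)
    return SyntheticTrack(track=track, labels=st.labels.copy(), w_air=st.w_air.copy(),
                          wind_east=st.wind_east.copy(), wind_north=st.wind_north.copy(),
                          terrain_elevation=st.terrain_elevation, policy=st.policy,
                          fields=st.fields)


def uniform_circling_track(tas: float, period: float, wind_east: float, wind_north: float,
                           n_circles: int = 2, dt: float = 1.0, clockwise: bool = True,
                           alt0: float = 1950.0, climb_rate: float = 0.0,
                           origin: tuple[float, float] = (38.8, -79.0),
                           start_time: float = 0.0) -> Track:
    """Exact closed-form track of uniform circling in a uniform wind.

    The air velocity rotates at 360/period deg/s with magnitude ``tas``;
    positions are the exact integral of (air velocity + wind), so the track
    has no integration error — ideal as a wind/TAS estimator oracle.
    """
    if tas <= 0 or period <= 0 or n_circles < 1:
        raise ContractError("tas, period and n_circles must be positive")
    omega = 2.0 * math.pi / period * (1.0 if clockwise else -1.0)
    t = dt * np.arange(int(round(n_circles * period / dt)) + 1)
    theta0 = 0.0
    theta = theta0 + omega * t
    # integral of tas*sin(theta(t)) and tas*cos(theta(t))
    xs = wind_east * t - (tas / omega) * (np.cos(theta) - np.cos(theta0))
    ys = wind_north * t + (tas / omega) * (np.sin(theta) - np.sin(theta0))
    zs = alt0 + climb_rate * t
    lat, lon = _to_geodetic(xs, ys, origin[0], origin[1])
    df = pd.DataFrame({"time": start_time + t, "lat": lat, "lon": lon, "alt_asl": zs})
    return Track(df, track_id="uniform_circle", nominal_dt=dt)


def label_recovery(truth: SyntheticTrack, segments) -> float:
    """Fraction of fixes whose classified label matches the generating label.

    The generator does not pre-judge glide climb sign, so truth ``glide``
    matches either ``glide_up`` or ``glide_down``; circle labels must match
    in direction; ``unclassified`` never matches.
    """
    n = len(truth.track)
    pred = np.full(n, "unclassified", dtype=object)
    for seg in segments:
        pred[seg.start:seg.end] = seg.label
        pred[seg.end - 1 if seg.end >= n else seg.end] = seg.label
    hits = 0
    for tl, pl in zip(truth.labels, pred):
        if tl == "glide":
            hits += pl in ("glide_up", "glide_down")
        else:
            hits += pl == tl
    return hits / n
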