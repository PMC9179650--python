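"""Shared fixtures: simulated scenarios are expensive enough to build once."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

import soartrack as st
from soartrack.kinematics import EARTH_RADIUS_M

ORIGIN = (38.8, -79.0)


def track_from_xy(x, y, z, dt: float = 1.0, origin=ORIGIN, t0: float = 0.0) -> st.Track:
    """Build a Track from local east/north/up meters about an origin."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    z = np.asarray(z, float)
    lat = origin[0] + np.degrees(y / EARTH_RADIUS_M)
    lon = origin[1] + np.degrees(x / (EARTH_RADIUS_M * math.cos(math.radians(origin[0]))))
    df = pd.DataFrame({"time": t0 + dt * np.arange(len(x)), "lat": lat, "lon": lon,
                       "alt_asl": z})
    return st.Track(df, track_id="local", nominal_dt=dt)


def turning_track(turn_rates_deg_s, speed: float = 12.0, heading0: float = 0.0,
                  vz=0.0, dt: float = 1.0, alt0: float = 1500.0) -> st.Track:
    """Integrate a heading profile into a Track (constant ground speed)."""
    turn = np.asarray(turn_rates_deg_s, float)
    n = len(turn)
    heading = heading0 + np.concatenate([[0.0], np.cumsum(turn[:-1] * dt)])
    vx = speed * np.sin(np.radians(heading))
    vy = speed * np.cos(np.radians(heading))
    x = np.concatenate([[0.0], np.cumsum(vx * dt)])
    y = np.concatenate([[0.0], np.cumsum(vy * dt)])
    vzs = np.broadcast_to(np.asarray(vz, float), (n,))
    z = alt0 + np.concatenate([[0.0], np.cumsum(vzs * dt)])
    return track_from_xy(x, y, z, dt=dt)


@pytest.fixture(scope="session")
def sim_clean() -> st.SyntheticTrack:
    """Default scenario, seed 1, no GPS noise."""
    return st.simulate_flight(seed=1)


@pytest.fixture(scope="session")
def sim_noisy(sim_clean) -> st.SyntheticTrack:
    """Default scenario with default GPS noise."""
    return st.add_gps_noise(sim_clean, seed=101)


@pytest.fixture(scope="session")
def kin_clean(sim_clean) -> st.KinematicSeries:
    return st.derive_kinematics(st.smooth_positions(sim_clean.track))


@pytest.fixture(scope="session")
def segs_clean(kin_clean):
    return st.classify_track(kin_clean)


@pytest.fixture(scope="session")
def kin_noisy(sim_noisy) -> st.KinematicSeries:
    return st.derive_kinematics(st.smooth_positions(sim_noisy.track))


@pytest.fixture(scope="session")
def segs_noisy(kin_noisy):
    return st.classify_track(kin_noisy)


@pytest.fixture(scope="session")
def fitted_noisy(sim_noisy) -> st.SoaringFlightResults:
    return st.SoaringFlightModel(sim_noisy.track, migration_heading=20.0).fit()
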