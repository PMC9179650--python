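"""Maneuver segmentation: circles, glides, meanders.

The classifier partitions a kinematic track into the three soaring maneuver
classes seen in migrating raptors:

* **circling** — near-circular flight closing a full turn and returning to
  the starting heading within a tolerance; labeled clockwise (``circle_cw``)
  or counterclockwise (``circle_ccw``) by the sign of the accumulated turn;
* **gliding** — straight flight whose heading stays within a tolerance over
  every sliding test window; split into ``glide_up`` / ``glide_down`` by
  whether the mean climb rate exceeds the still-air sink-rate offset;
* **meandering** — the residual class: heading-variable flight that never
  closes a circle, interpreted as searching for lift.

Circle detection is a deterministic greedy left-to-right scan over the
signed turn rate: from an anchor interval, turn is accumulated until it
first lands in the closure band ``[full_turn_min, 360 + heading_return_tol]``
with the heading back within ``heading_return_tol`` of the anchor heading and
the duration inside the configured circle-duration window.  Both the
accumulated-turn and the heading-return conditions are required, so an
S-shaped meander can never close a circle.  The scan is O(n · max_duration).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._errors import ContractError
from .kinematics import KinematicSeries, wrap_angle, STILLNESS_FLOOR_MS

__all__ = [
    "ClassifierConfig",
    "ManeuverSegment",
    "ManeuverSummary",
    "CircleCluster",
    "detect_circles",
    "detect_glides",
    "classify_track",
    "cluster_circles",
    "summarize_maneuvers",
    "CIRCLE_LABELS",
    "GLIDE_LABELS",
    "ALL_LABELS",
]

CIRCLE_LABELS = ("circle_cw", "circle_ccw")
GLIDE_LABELS = ("glide_up", "glide_down")
ALL_LABELS = ("circle_ccw", "circle_cw", "meander", "glide_up", "glide_down", "unclassified")


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the maneuver classifier.

    Defaults follow the field conventions for soaring raptors: a circle must
    return to its starting heading within +-10 deg of azimuth; a glide's
    heading may not change more than 10 deg in any 20 s window; upward glides
    are those climbing faster than 0.75 m/s (offsetting the assumed still-air
    sink rate); circle clusters need >= 3 consecutive circles.
    """

    heading_return_tol: float = 10.0   # deg
    full_turn_min: float = 350.0       # deg of accumulated turn to close
    glide_heading_tol: float = 10.0    # deg range allowed per window
    glide_window: float = 20.0         # s
    up_glide_threshold: float = 0.75   # m/s, strict inequality
    min_circle_duration: float = 8.0   # s; rejects GPS-jitter loops
    max_circle_duration: float = 60.0  # s; keeps one circle per segment
    min_cluster_size: int = 3
    #: transient overshoot of |cumulative turn| beyond 360 deg tolerated
    #: before a scan aborts.  A circle drifting in wind W at airspeed T has a
    #: ground-heading wobble of up to +-asin(W/T) about the uniform air-frame
    #: rotation (+-45 deg at W/T = 0.7, ~120 deg peak-to-peak near W/T = 0.9),
    #: which cancels at true closure; the closure band itself stays
    #: [full_turn_min, 360 + heading_return_tol], and direction changes are
    #: caught by turn_reversal_tol, so this can be generous.
    cum_overshoot_tol: float = 160.0
    #: abort the scan when the cumulative turn retreats this far from its
    #: running extreme: the bird reversed direction, so no single circle can
    #: close.  Must exceed the peak-to-peak ground-heading wobble (~120 deg
    #: at W/T near 0.9) or drifting circles are aborted spuriously.
    turn_reversal_tol: float = 135.0
    #: abort when |cumulative turn| is still below this many degrees a
    #: quarter of max_circle_duration into the scan: sustained circling turns
    #: from the start, so a straight prefix cannot be glued onto a circle.
    turn_stall_deg: float = 60.0

    def __post_init__(self) -> None:
        positive = ("heading_return_tol", "full_turn_min", "glide_heading_tol",
                    "glide_window", "up_glide_threshold", "min_circle_duration",
                    "max_circle_duration", "min_cluster_size")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ContractError(f"ClassifierConfig.{name} must be positive")
        if self.full_turn_min > 360.0:
            raise ContractError("full_turn_min must be <= 360")
        if self.max_circle_duration < self.min_circle_duration:
            raise ContractError("max_circle_duration < min_circle_duration")


@dataclass
class ManeuverSegment:
    """A labeled, half-open span of track intervals.

    ``start``/``end`` are fix indices; the segment owns intervals
    ``start .. end - 1`` and therefore spans fixes ``start .. end``
    inclusive.  ``duration = time(end) - time(start)`` and
    ``mean_climb_rate = altitude_change / duration``.
    """

    label: str
    start: int
    end: int
    start_time: float
    end_time: float
    duration: float
    altitude_change: float
    mean_ground_speed: float
    mean_climb_rate: float
    cum_turn: float = float("nan")   # deg, circles only
    diameter: float = float("nan")   # m, diagnostic only (2 x mean centroid distance)

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ContractError(f"segment end {self.end} <= start {self.start}")


def _make_segment(kin: KinematicSeries, label: str, a: int, b: int,
                  cum_turn: float = float("nan")) -> ManeuverSegment:
    """Segment over interval range [a, b) (fixes a..b)."""
    t0, t1 = float(kin.fix_times[a]), float(kin.fix_times[b])
    dur = t1 - t0
    dalt = float(kin.fix_alt_asl[b] - kin.fix_alt_asl[a])
    w = kin.dt[a:b]
    gs = kin.ground_speed[a:b]
    ok = np.isfinite(gs)
    mean_gs = float(np.sum(gs[ok] * w[ok]) / np.sum(w[ok])) if ok.any() else float("nan")
    diameter = float("nan")
    if label in CIRCLE_LABELS:
        lat = kin.fix_lat[a:b + 1]
        lon = kin.fix_lon[a:b + 1]
        latc, lonc = lat.mean(), lon.mean()
        r = 6_371_008.8
        dx = r * np.cos(np.radians(latc)) * np.radians(lon - lonc)
        dy = r * np.radians(lat - latc)
        diameter = float(2.0 * np.mean(np.hypot(dx, dy)))
    return ManeuverSegment(label=label, start=a, end=b, start_time=t0, end_time=t1,
                           duration=dur, altitude_change=dalt, mean_ground_speed=mean_gs,
                           mean_climb_rate=dalt / dur if dur > 0 else 0.0,
                           cum_turn=cum_turn, diameter=diameter)


def _blocks_of(kin: KinematicSeries) -> list[tuple[int, int]]:
    """Maximal runs of valid intervals, as half-open interval-index ranges."""
    v = kin.valid
    if not v.any():
        return []
    edges = np.flatnonzero(np.diff(v.astype(int)))
    bounds = [0, *(edges + 1), len(v)]
    return [(bounds[k], bounds[k + 1]) for k in range(len(bounds) - 1) if v[bounds[k]]]


# ---------------------------------------------------------------------------
# circles


def detect_circles(kin: KinematicSeries, cfg: ClassifierConfig | None = None) -> list[ManeuverSegment]:
    """Greedy scan for closed circles; returns non-overlapping segments."""
    cfg = cfg or ClassifierConfig()
    t = kin.fix_times
    h = kin.heading
    segments: list[ManeuverSegment] = []
    for bs, be in _blocks_of(kin):
        a = bs
        while a < be:
            if not np.isfinite(h[a]) or kin.ground_speed[a] < STILLNESS_FLOOR_MS:
                a += 1
                continue
            cum = 0.0
            cmax = cmin = 0.0
            closed = False
            j = a + 1
            while j < be:
                if t[j + 1] - t[a] > cfg.max_circle_duration:
                    break
                cum += wrap_angle(h[j] - h[j - 1])
                cmax = max(cmax, cum)
                cmin = min(cmin, cum)
                if abs(cum) > 360.0 + cfg.cum_overshoot_tol:
                    break
                if (cmax - cum > cfg.turn_reversal_tol and cmax > 45.0) or \
                        (cum - cmin > cfg.turn_reversal_tol and cmin < -45.0):
                    break  # direction reversal: this anchor cannot close a circle
                if (t[j + 1] - t[a] >= cfg.max_circle_duration / 4.0
                        and abs(cum) < cfg.turn_stall_deg):
                    break  # not turning: straight prefix, give up early
                if (cfg.full_turn_min <= abs(cum) <= 360.0 + cfg.heading_return_tol
                        and abs(wrap_angle(h[j] - h[a])) <= cfg.heading_return_tol
                        and t[j + 1] - t[a] >= cfg.min_circle_duration):
                    label = "circle_cw" if cum > 0 else "circle_ccw"
                    segments.append(_make_segment(kin, label, a, j + 1, cum_turn=cum))
                    a = j + 1
                    closed = True
                    break
                j += 1
            if not closed:
                a += 1
    return segments


# ---------------------------------------------------------------------------
# glides


def _glide_mask(kin: KinematicSeries, free: np.ndarray, cfg: ClassifierConfig) -> np.ndarray:
    """Mark intervals covered by some passing straight-flight window.

    A window starting at interval ``i`` spans intervals until elapsed time
    reaches ``glide_window``; it passes if the unwrapped-heading range over
    it is <= ``glide_heading_tol`` and no interval is stationary.  Only
    windows fully inside a free run are evaluated, so a run shorter than the
    window can never be a glide.
    """
    t = kin.fix_times
    covered = np.zeros(kin.n_intervals, dtype=bool)
    edges = np.flatnonzero(np.diff(free.astype(int)))
    bounds = [0, *(edges + 1), len(free)]
    for k in range(len(bounds) - 1):
        s, e = bounds[k], bounds[k + 1]
        if not free[s]:
            continue
        h = kin.heading[s:e]
        if np.any(~np.isfinite(h)):
            continue
        u = np.concatenate([[h[0]], h[0] + np.cumsum(wrap_angle(np.diff(h)))])
        still = kin.ground_speed[s:e] < STILLNESS_FLOOR_MS
        j = s
        for i in range(s, e):
            if t[e] - t[i] < cfg.glide_window - 1e-9:
                break  # remaining windows would be truncated
            j = max(j, i + 1)
            while j < e and t[j + 1] - t[i] < cfg.glide_window - 1e-9:
                j += 1
            ui = u[i - s:j - s + 1]
            if still[i - s:j - s + 1].any():
                continue
            if ui.max() - ui.min() <= cfg.glide_heading_tol:
                covered[i:j + 1] = True
    return covered


def detect_glides(kin: KinematicSeries, occupied: np.ndarray,
                  cfg: ClassifierConfig | None = None) -> list[ManeuverSegment]:
    """Straight-flight segments outside ``occupied`` (circle) intervals.

    Each maximal straight run becomes one segment, labeled ``glide_up`` if
    its mean climb rate strictly exceeds ``up_glide_threshold`` (the climb
    needed to offset the assumed still-air sink), else ``glide_down``.
    """
    cfg = cfg or ClassifierConfig()
    free = kin.valid & ~np.asarray(occupied, dtype=bool)
    covered = _glide_mask(kin, free, cfg)
    segments: list[ManeuverSegment] = []
    edges = np.flatnonzero(np.diff(covered.astype(int)))
    bounds = [0, *(edges + 1), len(covered)]
    for k in range(len(bounds) - 1):
        s, e = bounds[k], bounds[k + 1]
        if not covered[s]:
            continue
        seg = _make_segment(kin, "glide_down", s, e)
        if seg.mean_climb_rate > cfg.up_glide_threshold:
            seg.label = "glide_up"
        segments.append(seg)
    return segments


# ---------------------------------------------------------------------------
# full classification


def classify_track(kin: KinematicSeries, cfg: ClassifierConfig | None = None) -> list[ManeuverSegment]:
    """Exhaustive, sorted, non-overlapping partition of all intervals.

    Precedence: circles, then glides on the remainder, then the residual.
    Residual spans become ``meander`` when they represent moving flight of at
    least 3 fixes; stationary or very short residues — and intervals inside
    sampling gaps — are ``unclassified``.
    """
    cfg = cfg or ClassifierConfig()
    n = kin.n_intervals
    circles = detect_circles(kin, cfg)
    occupied = np.zeros(n, dtype=bool)
    for seg in circles:
        occupied[seg.start:seg.end] = True
    glides = detect_glides(kin, occupied, cfg)
    for seg in glides:
        occupied[seg.start:seg.end] = True

    residual: list[ManeuverSegment] = []
    free = ~occupied
    edges = np.flatnonzero(np.diff(free.astype(int)))
    bounds = [0, *(edges + 1), len(free)]
    for k in range(len(bounds) - 1):
        s, e = bounds[k], bounds[k + 1]
        if not free[s]:
            continue
        # split the residual run at gap boundaries so labels never span gaps
        sub = s
        while sub < e:
            v = bool(kin.valid[sub])
            sube = sub
            while sube < e and bool(kin.valid[sube]) == v:
                sube += 1
            seg = _make_segment(kin, "unclassified", sub, sube)
            if v and (sube - sub) >= 2 and np.isfinite(seg.mean_ground_speed) \
                    and seg.mean_ground_speed >= STILLNESS_FLOOR_MS:
                seg.label = "meander"
            residual.append(seg)
            sub = sube

    segments = sorted(circles + glides + residual, key=lambda s: s.start)
    # partition sanity: exhaustive and non-overlapping
    cursor = 0
    for seg in segments:
        if seg.start != cursor:
            raise AssertionError(f"partition hole/overlap at fix {cursor} vs {seg.start}")
        cursor = seg.end
    if segments and cursor != n:
        raise AssertionError("partition does not reach the final interval")
    return segments


# ---------------------------------------------------------------------------
# clusters and summaries


@dataclass(frozen=True)
class CircleCluster:
    """A run of >= min_cluster_size consecutive circles used to gain height."""

    segments: tuple
    start: int
    end: int
    start_time: float
    end_time: float
    n_circles: int
    total_gain: float  # m, net over the cluster
    duration: float    # s


def cluster_circles(segments: Sequence[ManeuverSegment],
                    cfg: ClassifierConfig | None = None) -> list[CircleCluster]:
    """Maximal runs of consecutive circle segments with no intervening label."""
    cfg = cfg or ClassifierConfig()
    clusters: list[CircleCluster] = []
    run: list[ManeuverSegment] = []

    def flush() -> None:
        if len(run) >= cfg.min_cluster_size:
            clusters.append(CircleCluster(
                segments=tuple(run), start=run[0].start, end=run[-1].end,
                start_time=run[0].start_time, end_time=run[-1].end_time,
                n_circles=len(run),
                total_gain=float(sum(s.altitude_change for s in run)),
                duration=run[-1].end_time - run[0].start_time))
        run.clear()

    for seg in segments:
        if seg.label in CIRCLE_LABELS:
            run.append(seg)
        else:
            flush()
    flush()
    return clusters


@dataclass
class ManeuverSummary:
    """Per-label maneuver statistics in the layout of a flight-summary table.

    ``table`` has one column per label and the statistic rows: segment count,
    mean duration, mean altitude change, mean climb/descent rate, mean ground
    speed, total time (min), percent of classified time, and net altitude
    change.  Percentages use classified time only (unclassified spans are
    excluded from the denominator and reported separately).
    """

    table: pd.DataFrame
    classified_time_s: float
    unclassified_time_s: float
    total_time_s: float

    ROWS = ["n_segments", "mean_duration_s", "mean_altitude_change_m",
            "mean_climb_rate_ms", "mean_ground_speed_ms", "total_time_min",
            "percent_classified_time", "net_altitude_change_m"]

    def stat(self, label: str, row: str) -> float:
        return float(self.table.loc[row, label])

    # convenience accessors used by the energy budget
    @property
    def time_circling_s(self) -> float:
        return 60.0 * (self.stat("circle_cw", "total_time_min")
                       + self.stat("circle_ccw", "total_time_min"))

    @property
    def time_glide_down_s(self) -> float:
        return 60.0 * self.stat("glide_down", "total_time_min")

    @property
    def mean_glide_down_speed(self) -> float:
        return self.stat("glide_down", "mean_ground_speed_ms")

    @property
    def circling_height_gain_m(self) -> float:
        """Total positive altitude gain over circle segments."""
        return self._positive_circle_gain

    _positive_circle_gain: float = 0.0


def summarize_maneuvers(segments: Sequence[ManeuverSegment]) -> ManeuverSummary:
    """Per-label statistics of a classified partition (all-zero if empty)."""
    cols = {}
    for label in ALL_LABELS:
        if label == "unclassified":
            continue
        group = [s for s in segments if s.label == label]
        n = len(group)
        if n:
            durs = np.array([s.duration for s in group])
            dalt = np.array([s.altitude_change for s in group])
            rates = np.array([s.mean_climb_rate for s in group])
            gss = np.array([s.mean_ground_speed for s in group])
            gss = gss[np.isfinite(gss)]
            cols[label] = {
                "n_segments": n,
                "mean_duration_s": durs.mean(),
                "mean_altitude_change_m": dalt.mean(),
                "mean_climb_rate_ms": rates.mean(),
                "mean_ground_speed_ms": gss.mean() if gss.size else float("nan"),
                "total_time_min": durs.sum() / 60.0,
                "net_altitude_change_m": dalt.sum(),
            }
        else:
            cols[label] = {r: 0.0 for r in ManeuverSummary.ROWS if r != "percent_classified_time"}
    classified = sum(c["total_time_min"] for c in cols.values()) * 60.0
    unclassified = sum(s.duration for s in segments if s.label == "unclassified")
    for label, c in cols.items():
        c["percent_classified_time"] = (100.0 * c["total_time_min"] * 60.0 / classified
                                        if classified > 0 else 0.0)
    table = pd.DataFrame(cols).reindex(ManeuverSummary.ROWS)[list(cols)]
    summary = ManeuverSummary(table=table, classified_time_s=classified,
                              unclassified_time_s=float(unclassified),
                              total_time_s=float(classified + unclassified))
    summary._positive_circle_gain = float(sum(
        s.altitude_change for s in segments
        if s.label in CIRCLE_LABELS and s.altitude_change > 0))
    return summary
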