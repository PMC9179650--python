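"""Statsmodels-style entry point: a model over one GPS track, fitted once.

``SoaringFlightModel`` holds the data (track, optional terrain) and the
analysis configuration; ``fit()`` runs the full pipeline — AGL conversion,
smoothing, kinematics, maneuver classification, circle clustering, per-circle
wind/TAS estimation, the maneuver summary and the climb/glide energy
budget — and returns a ``SoaringFlightResults`` carrying every intermediate
product plus a ``summary()`` report.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._errors import ContractError
from . import track_io
from .track_io import ColumnMap, TerrainGrid, Track
from .kinematics import (KinematicSeries, PathStats, derive_kinematics,
                         path_statistics, smooth_positions)
from .maneuvers import (CIRCLE_LABELS, CircleCluster, ClassifierConfig,
                        ManeuverSegment, ManeuverSummary, classify_track,
                        cluster_circles, summarize_maneuvers)
from .aero import AeroConfig, WindEstimate, estimate_tas_and_wind, tailwind_component
from .energy_budget import EnergyBudget, budget_from_summary, compute_energy_budget

__all__ = ["SoaringFlightModel", "SoaringFlightResults"]


class SoaringFlightModel:
    """Soaring-flight analysis of one 1 Hz GPS track.

    Parameters
    ----------
    track : Track
        Raw fixes (use :meth:`from_csv` / :meth:`from_dataframe` to build).
    terrain : TerrainGrid, optional
        If given, AGL heights are derived before analysis.
    classifier, aero : threshold and aerodynamic configuration.
    migration_heading : deg; course onto which circle-derived winds are
        projected to obtain the budget tailwind.
    tailwind : m/s, optional; overrides the circle-derived tailwind (e.g. a
        reported flight-level value).
    direct_distance : m, optional; overrides the track's first-to-last-fix
        geodesic distance in the sufficiency comparison.
    smooth_window : odd int; running-mean width applied before differencing.
    """

    def __init__(self, track: Track, terrain: TerrainGrid | None = None,
                 classifier: ClassifierConfig | None = None,
                 aero: AeroConfig | None = None,
                 migration_heading: float = 20.0,
                 tailwind: float | None = None,
                 direct_distance: float | None = None,
                 smooth_window: int = 3):
        if len(track) < 2:
            raise ContractError("track must contain at least two fixes")
        self.track = track
        self.terrain = terrain
        self.classifier = classifier or ClassifierConfig()
        self.aero = aero or AeroConfig()
        self.migration_heading = float(migration_heading)
        self.tailwind = tailwind
        self.direct_distance = direct_distance
        self.smooth_window = int(smooth_window)

    @classmethod
    def from_csv(cls, path, terrain_path=None, dialect: ColumnMap | None = None, **kwargs):
        track = track_io.read_track(path, dialect=dialect)
        terrain = TerrainGrid.read(terrain_path) if terrain_path else None
        return cls(track, terrain=terrain, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, track_id: str = "track", **kwargs):
        return cls(Track(df, track_id=track_id), **kwargs)

    def fit(self) -> "SoaringFlightResults":
        track = self.track
        if self.terrain is not None:
            track = track_io.compute_agl(track, self.terrain)
        smoothed = smooth_positions(track, self.smooth_window)
        kin = derive_kinematics(smoothed)
        stats = path_statistics(track)
        segments = classify_track(kin, self.classifier)
        clusters = cluster_circles(segments, self.classifier)
        winds: list[WindEstimate] = []
        cluster_circle_ids = {id(s) for c in clusters for s in c.segments}
        for i, seg in enumerate(segments):
            if seg.label in CIRCLE_LABELS:
                try:
                    est = estimate_tas_and_wind(kin, seg, self.classifier.full_turn_min,
                                                circle_id=i)
                except ContractError:
                    continue
                winds.append(est)
        if self.tailwind is not None:
            tailwind = float(self.tailwind)
            tailwind_source = "explicit"
        elif winds:
            # Tailwind at the established flight level, as such budgets use
            # (the wind printed for the migration altitude, not an average
            # over the whole climb): duration-weighted mean wind vector over
            # circles in the upper quarter of the circling-altitude range,
            # projected once onto the migration course.
            alts = np.array([w.mean_alt_asl for w in winds])
            cut = alts.max() - (alts.max() - alts.min()) / 4.0
            top = [w for w in winds if w.mean_alt_asl >= cut]
            wts = np.array([segments[w.circle_id].duration for w in top])
            we = float(np.average([w.wind_east for w in top], weights=wts))
            wn = float(np.average([w.wind_north for w in top], weights=wts))
            tailwind = max(tailwind_component(we, wn, self.migration_heading), 0.0)
            tailwind_source = "circle-derived (flight-level mean vector on course)"
        else:
            tailwind = 0.0
            tailwind_source = "none available"
        direct = self.direct_distance if self.direct_distance is not None else stats.direct_distance
        summary = summarize_maneuvers(segments)
        # Tc is the total time spent circling: the spans of the primary
        # circling sequences (first circle entry to last circle exit, which
        # credits tailwind drift through the partial turns between closed
        # circles of a cluster) plus any circles flown outside a sequence.
        if clusters:
            in_cluster = {id(s) for c in clusters for s in c.segments}
            tc = float(sum(c.duration for c in clusters))
            tc += float(sum(s.duration for s in segments
                            if s.label in CIRCLE_LABELS and id(s) not in in_cluster))
            h_gain = float(sum(max(s.altitude_change, 0.0) for s in segments
                               if s.label in CIRCLE_LABELS and s.altitude_change > 0))
            budget = compute_energy_budget(
                tailwind=tailwind, time_circling_s=tc,
                time_gliding_s=summary.time_glide_down_s,
                mean_glide_ground_speed=summary.mean_glide_down_speed,
                direct_distance_m=direct, height_gain_m=h_gain,
                cfg=self.aero, source="clusters+summary")
        else:
            budget = budget_from_summary(summary, tailwind, direct, self.aero)
        return SoaringFlightResults(
            model=self, track=track, smoothed=smoothed, kinematics=kin,
            path_stats=stats, segments=segments, clusters=clusters,
            wind_estimates=winds, maneuver_summary=summary, budget=budget,
            tailwind_source=tailwind_source)


@dataclass
class SoaringFlightResults:
    """Everything the fitted pipeline produced."""

    model: SoaringFlightModel
    track: Track
    smoothed: Track
    kinematics: KinematicSeries
    path_stats: PathStats
    segments: list[ManeuverSegment]
    clusters: list[CircleCluster]
    wind_estimates: list[WindEstimate]
    maneuver_summary: ManeuverSummary
    budget: EnergyBudget
    tailwind_source: str = "circle-derived"

    def segments_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "start_fix": s.start, "end_fix": s.end, "start_time": s.start_time,
            "end_time": s.end_time, "label": s.label, "duration_s": s.duration,
            "altitude_change_m": s.altitude_change,
            "mean_ground_speed_ms": s.mean_ground_speed,
            "mean_climb_rate_ms": s.mean_climb_rate,
        } for s in self.segments])

    def winds_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "circle_id": w.circle_id, "wind_east_ms": w.wind_east,
            "wind_north_ms": w.wind_north, "wind_speed_ms": w.wind_speed,
            "wind_direction_from_deg": w.wind_direction_from, "tas_ms": w.tas,
            "sinusoid_mean_ms": w.sinusoid_mean,
            "sinusoid_amplitude_ms": w.sinusoid_amplitude,
            "mean_alt_asl_m": w.mean_alt_asl, "mean_alt_agl_m": w.mean_alt_agl,
        } for w in self.wind_estimates])

    def summary(self) -> str:
        from .report import render_report
        return render_report(self.maneuver_summary, self.budget,
                             winds=self.wind_estimates, path_stats=self.path_stats,
                             clusters=self.clusters, tailwind_source=self.tailwind_source)
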