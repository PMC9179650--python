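"""Maneuver classification: circles, glides, meanders, clusters, summaries."""

import numpy as np
import pytest

import soartrack as st
from soartrack import ContractError
from soartrack.kinematics import wrap_angle
from soartrack.maneuvers import CIRCLE_LABELS, ManeuverSegment

from conftest import turning_track


def classify(track, cfg=None):
    return st.classify_track(st.derive_kinematics(track), cfg)


def make_segment(label, a, b, duration, dalt, gs=15.0, t0=None):
    t0 = float(a) if t0 is None else t0
    return ManeuverSegment(label=label, start=a, end=b, start_time=t0,
                           end_time=t0 + duration, duration=duration,
                           altitude_change=dalt, mean_ground_speed=gs,
                           mean_climb_rate=dalt / duration)


class TestDetectCircles:
    def test_constant_heading_yields_no_circles(self):
        kin = st.derive_kinematics(turning_track(np.zeros(60)))
        assert st.detect_circles(kin) == []

    def test_uniform_turn_closes_one_circle_per_period(self):
        # 360/22 deg/s for exactly one period
        kin = st.derive_kinematics(turning_track(np.full(23, 360.0 / 22.0)))
        segs = st.detect_circles(kin)
        assert len(segs) == 1
        assert segs[0].label == "circle_cw"
        assert segs[0].duration == pytest.approx(22.0, abs=1.5)

    def test_opposite_turns_give_cw_then_ccw(self):
        rate = 360.0 / 22.0
        turn = np.concatenate([np.full(22, rate), np.full(26, -rate)])
        kin = st.derive_kinematics(turning_track(turn))
        segs = st.detect_circles(kin)
        assert [s.label for s in segs] == ["circle_cw", "circle_ccw"]

    def test_s_shaped_meander_never_closes(self):
        # half turn one way, half turn back: large heading activity, no closure
        rate = 360.0 / 22.0
        turn = np.tile(np.concatenate([np.full(8, rate), np.full(8, -rate)]), 5)
        kin = st.derive_kinematics(turning_track(turn))
        assert st.detect_circles(kin) == []

    def test_closure_soundness_on_simulated_track(self, kin_clean, segs_clean):
        """Every emitted circle accumulates >= 350 deg and returns to its
        anchor heading within +-10 deg -- checked on the output itself."""
        h = kin_clean.heading
        circles = [s for s in segs_clean if s.label in CIRCLE_LABELS]
        assert circles, "simulated flight must contain circles"
        for s in circles:
            cum = np.sum(wrap_angle(np.diff(h[s.start:s.end])))
            assert abs(cum) >= 350.0 - 1e-6
            assert abs(wrap_angle(h[s.end - 1] - h[s.start])) <= 10.0 + 1e-6
            assert abs(s.cum_turn) >= 350.0

    def test_widening_return_tolerance_never_loses_circles(self, kin_clean):
        narrow = st.ClassifierConfig(heading_return_tol=10.0)
        wide = st.ClassifierConfig(heading_return_tol=15.0)
        n_narrow = len(st.detect_circles(kin_clean, narrow))
        n_wide = len(st.detect_circles(kin_clean, wide))
        assert n_wide >= n_narrow


class TestDetectGlides:
    def _straight(self, vz, n=60):
        return st.derive_kinematics(turning_track(np.zeros(n), vz=vz))

    def test_straight_descending_run_is_glide_down(self):
        kin = self._straight(-1.0)
        segs = st.detect_glides(kin, np.zeros(kin.n_intervals, bool))
        assert [s.label for s in segs] == ["glide_down"]

    def test_straight_climbing_run_is_glide_up(self):
        kin = self._straight(+1.0)
        segs = st.detect_glides(kin, np.zeros(kin.n_intervals, bool))
        assert [s.label for s in segs] == ["glide_up"]

    def test_climb_at_exact_threshold_stays_glide_down(self):
        # "greater than" 0.75 m/s is strict
        kin = self._straight(+0.75)
        segs = st.detect_glides(kin, np.zeros(kin.n_intervals, bool))
        assert [s.label for s in segs] == ["glide_down"]

    def test_run_shorter_than_window_is_not_a_glide(self):
        kin = self._straight(-1.0, n=15)  # < 20 s window
        assert st.detect_glides(kin, np.zeros(kin.n_intervals, bool)) == []

    def test_occupied_intervals_are_excluded(self):
        kin = self._straight(-1.0)
        occupied = np.ones(kin.n_intervals, bool)
        assert st.detect_glides(kin, occupied) == []


class TestClassifyTrack:
    def test_partition_is_sorted_nonoverlapping_exhaustive(self, kin_clean, segs_clean):
        cursor = 0
        for seg in segs_clean:
            assert seg.start == cursor
            assert seg.end > seg.start
            cursor = seg.end
        assert cursor == kin_clean.n_intervals

    def test_circle_then_glide_concatenation(self):
        rate = 360.0 / 22.0
        turn = np.concatenate([np.full(22, rate), np.zeros(40)])
        segs = classify(turning_track(turn, vz=-1.0))
        labels = [s.label for s in segs]
        assert labels[0] == "circle_cw"
        assert "glide_down" in labels
        assert len(segs) <= 3  # circle, (possible sliver), glide

    def test_all_stationary_track_is_single_unclassified(self):
        track = turning_track(np.zeros(50), speed=0.05)
        segs = classify(track)
        assert [s.label for s in segs] == ["unclassified"]

    def test_determinism(self, kin_clean, segs_clean):
        again = st.classify_track(kin_clean)
        assert [(s.label, s.start, s.end) for s in again] == \
               [(s.label, s.start, s.end) for s in segs_clean]

    def test_maneuvers_never_span_sampling_gaps(self):
        # two straight blocks separated by a 50 s dropout
        import pandas as pd
        t1 = turning_track(np.zeros(40), vz=-1.0)
        df = t1.df.copy()
        df2 = df.copy()
        df2["time"] = df["time"] + 90.0  # 50 s gap after the 40 s block
        both = pd.concat([df, df2], ignore_index=True)
        segs = classify(st.Track(both, nominal_dt=1.0))
        gap_interval = len(df) - 1
        for s in segs:
            if s.start <= gap_interval < s.end:
                assert s.label == "unclassified"


class TestClusterCircles:
    def test_two_consecutive_circles_do_not_cluster(self):
        segs = [make_segment("circle_cw", 0, 22, 22.0, 35.0),
                make_segment("circle_cw", 22, 44, 22.0, 35.0, t0=22.0)]
        assert st.cluster_circles(segs) == []

    def test_twenty_nine_consecutive_circles_form_one_cluster(self):
        segs = [make_segment("circle_ccw", 22 * i, 22 * (i + 1), 22.0, 35.0,
                             t0=22.0 * i) for i in range(29)]
        clusters = st.cluster_circles(segs)
        assert len(clusters) == 1
        assert clusters[0].n_circles == 29
        assert clusters[0].total_gain == pytest.approx(29 * 35.0)

    def test_glide_splits_runs_into_separate_clusters(self):
        labels = ["circle_cw"] * 3 + ["glide_down"] + ["circle_ccw"] * 4
        segs = []
        pos = 0
        for i, lab in enumerate(labels):
            dur = 22.0 if lab.startswith("circle") else 120.0
            segs.append(make_segment(lab, pos, pos + int(dur), dur,
                                     35.0 if lab.startswith("circle") else -120.0,
                                     t0=float(pos)))
            pos += int(dur)
        clusters = st.cluster_circles(segs)
        assert [c.n_circles for c in clusters] == [3, 4]

    def test_simulated_flight_has_many_clusters(self, segs_clean):
        clusters = st.cluster_circles(segs_clean)
        assert len(clusters) >= 10
        assert all(c.n_circles >= 3 for c in clusters)


class TestSummarizeManeuvers:
    def test_counterclockwise_net_gain_from_counts_and_means(self):
        segs = [make_segment("circle_ccw", 25 * i, 25 * i + 23, 23.2, 38.7,
                             t0=25.0 * i) for i in range(44)]
        summary = st.summarize_maneuvers(segs)
        assert summary.stat("circle_ccw", "net_altitude_change_m") == \
            pytest.approx(1702.8, abs=0.1)
        assert summary.stat("circle_ccw", "total_time_min") == \
            pytest.approx(17.0, abs=0.05)

    def test_empty_input_gives_all_zero_summary(self):
        summary = st.summarize_maneuvers([])
        assert summary.table.to_numpy().sum() == 0.0
        assert summary.total_time_s == 0.0

    def test_single_glide_descent_rate(self):
        segs = [make_segment("glide_down", 0, 200, 200.0, -200.0, gs=19.1)]
        summary = st.summarize_maneuvers(segs)
        assert summary.stat("glide_down", "mean_climb_rate_ms") == \
            pytest.approx(-1.0)

    def test_percentages_use_classified_time_only(self):
        segs = [make_segment("glide_down", 0, 100, 100.0, -100.0),
                make_segment("unclassified", 100, 200, 300.0, 0.0, t0=100.0)]
        summary = st.summarize_maneuvers(segs)
        assert summary.stat("glide_down", "percent_classified_time") == \
            pytest.approx(100.0)
        assert summary.unclassified_time_s == pytest.approx(300.0)

    def test_totals_partition_the_track_duration(self, segs_clean, sim_clean):
        summary = st.summarize_maneuvers(segs_clean)
        duration = sim_clean.track.times[-1] - sim_clean.track.times[0]
        assert summary.total_time_s == pytest.approx(duration, abs=1.0)


def test_classifier_config_validation():
    with pytest.raises(ContractError):
        st.ClassifierConfig(glide_window=-1.0)
    with pytest.raises(ContractError):
        st.ClassifierConfig(full_turn_min=400.0)
    with pytest.raises(ContractError):
        st.ClassifierConfig(max_circle_duration=5.0, min_circle_duration=8.0)
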