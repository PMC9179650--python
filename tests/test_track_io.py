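"""Track and terrain I/O: parsing, AGL conversion, segment round-trips."""

import textwrap

import numpy as np
import pandas as pd
import pytest

import soartrack as st
from soartrack import ConfigurationError, ContractError, CoverageError, DataError
from soartrack.maneuvers import ManeuverSegment

TRACK_CSV = textwrap.dedent("""\
    timestamp,lat,lon,alt_asl_m
    2016-03-24T15:57:46.000Z,38.7000000,-79.0000000,1950.00
    2016-03-24T15:57:47.000Z,38.7001000,-79.0000500,1951.25
    2016-03-24T15:57:48.000Z,38.7002000,-79.0001000,1952.50
    """)


class TestReadTrack:
    def test_well_formed_file_round_trips(self, tmp_path):
        p = tmp_path / "t.csv"
        p.write_text(TRACK_CSV)
        track = st.read_track(p)
        assert len(track) == 3
        assert track.times[0] == pytest.approx(1458835066.0)
        out = tmp_path / "o.csv"
        st.write_track(track, out)
        back = st.read_track(out)
        assert np.allclose(back.times, track.times, atol=1.0)
        assert np.allclose(back.lat, track.lat, atol=1e-7)
        assert np.allclose(back.lon, track.lon, atol=1e-7)
        assert np.allclose(back.alt_asl, track.alt_asl, atol=0.01)

    def test_duplicate_timestamp_keeps_first_with_warning(self, tmp_path):
        rows = TRACK_CSV + "2016-03-24T15:57:48.000Z,38.9,-79.1,2000.0\n"
        p = tmp_path / "dup.csv"
        p.write_text(rows)
        with pytest.warns(UserWarning, match="duplicate"):
            track = st.read_track(p)
        assert len(track) == 3
        assert track.lat[-1] == pytest.approx(38.7002)  # first row won

    def test_missing_column_is_configuration_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("timestamp,lat,alt_asl_m\n2016-03-24T15:57:46Z,38.7,1950\n")
        with pytest.raises(ConfigurationError, match="lon"):
            st.read_track(p)

    def test_non_monotone_time_is_data_error(self, tmp_path):
        rows = TRACK_CSV + "2016-03-24T15:57:40.000Z,38.7,-79.0,1950.0\n"
        p = tmp_path / "mono.csv"
        p.write_text(rows)
        with pytest.raises(DataError):
            st.read_track(p)

    def test_movebank_style_column_map(self, tmp_path):
        p = tmp_path / "mb.csv"
        p.write_text("ts,location-lat,location-long,height\n100.0,38.7,-79.0,1950\n"
                     "101.0,38.7001,-79.0001,1951\n")
        cm = st.ColumnMap(time="ts", lat="location-lat", lon="location-long",
                         alt_asl="height")
        track = st.read_track(p, dialect=cm)
        assert len(track) == 2 and track.times[0] == 100.0


class TestTrackInvariants:
    def test_latitude_bounds_enforced(self):
        df = pd.DataFrame({"time": [0.0, 1.0], "lat": [91.0, 91.0],
                           "lon": [0.0, 0.0], "alt_asl": [0.0, 0.0]})
        with pytest.raises(DataError):
            st.Track(df)

    def test_gap_splits_into_blocks(self):
        df = pd.DataFrame({"time": [0, 1, 2, 10, 11.0], "lat": [38.0] * 5,
                           "lon": [-79.0] * 5, "alt_asl": [0.0] * 5})
        track = st.Track(df, nominal_dt=1.0)
        assert track.blocks() == [(0, 3), (3, 5)]
        assert track.n_gaps() == 1


class TestComputeAgl:
    def test_flight_over_terrain_gives_height_above_ground(self):
        # 1950 m ASL over 490 m terrain -> 1460 m AGL
        terrain = st.TerrainGrid.flat(490.0, lat0=38.0, lon0=-80.0)
        df = pd.DataFrame({"time": [0.0, 1.0], "lat": [38.7, 38.7001],
                           "lon": [-79.0, -79.0001], "alt_asl": [1950.0, 1950.0]})
        out = st.compute_agl(st.Track(df), terrain)
        assert out.alt_agl == pytest.approx([1460.0, 1460.0])
        assert out.alt_asl == pytest.approx([1950.0, 1950.0])  # ASL untouched

    def test_zero_terrain_means_agl_equals_asl(self):
        terrain = st.TerrainGrid.flat(0.0, lat0=38.0, lon0=-80.0)
        df = pd.DataFrame({"time": [0.0, 1.0], "lat": [38.5, 38.5],
                           "lon": [-79.5, -79.4], "alt_asl": [1000.0, 1200.0]})
        out = st.compute_agl(st.Track(df), terrain)
        assert np.allclose(out.alt_agl, out.alt_asl)

    def test_bilinear_center_of_cell(self):
        grid = st.TerrainGrid(lat0=38.0, lon0=-80.0, dlat=0.1, dlon=0.1,
                              elevations=np.array([[0.0, 0.0], [100.0, 100.0]]))
        assert grid.sample(38.05, -79.95) == pytest.approx(50.0)
        assert grid.sample(38.0, -80.0) == pytest.approx(0.0)
        # nearest-neighbor mode snaps
        assert grid.sample(38.04, -79.95, method="nearest") == pytest.approx(0.0)

    def test_idempotent_and_order_independent(self):
        terrain = st.TerrainGrid.flat(100.0, lat0=38.0, lon0=-80.0)
        df = pd.DataFrame({"time": [0.0, 1.0], "lat": [38.5, 38.6],
                           "lon": [-79.5, -79.4], "alt_asl": [900.0, 950.0]})
        once = st.compute_agl(st.Track(df), terrain)
        twice = st.compute_agl(once, terrain)
        assert np.allclose(once.alt_agl, twice.alt_agl)
        rev = st.compute_agl(st.Track(df.iloc[::-1].reset_index(drop=True)
                                      .assign(time=[0.0, 1.0])), terrain)
        assert np.allclose(sorted(rev.alt_agl), sorted(once.alt_agl))

    def test_fix_outside_grid_raises_coverage_error(self):
        terrain = st.TerrainGrid.flat(0.0, lat0=38.0, lon0=-80.0, shape=(5, 5))
        df = pd.DataFrame({"time": [0.0], "lat": [45.0], "lon": [-79.0],
                           "alt_asl": [1000.0]})
        with pytest.raises(CoverageError, match="45"):
            st.compute_agl(st.Track(df), terrain)


class TestTerrainFormats:
    def test_esri_ascii_round_trip(self, tmp_path):
        asc = textwrap.dedent("""\
            ncols 3
            nrows 2
            xllcorner -80.0
            yllcorner 38.0
            cellsize 0.5
            NODATA_value -9999
            10 20 30
            40 50 60
            """)
        p = tmp_path / "g.asc"
        p.write_text(asc)
        grid = st.TerrainGrid.read(p)
        # .asc top row is the NORTH row
        assert grid.elevations[0].tolist() == [40.0, 50.0, 60.0]
        assert grid.elevations[1].tolist() == [10.0, 20.0, 30.0]
        assert grid.lat0 == pytest.approx(38.25)  # sw cell center

    def test_csv_grid_round_trip(self, tmp_path):
        grid = st.TerrainGrid(38.0, -80.0, 0.1, 0.1,
                              np.arange(12.0).reshape(3, 4))
        p = tmp_path / "g.csv"
        grid.to_csv_grid(p)
        back = st.TerrainGrid.read(p)
        assert np.allclose(back.elevations, grid.elevations)
        assert back.dlat == pytest.approx(0.1)


class TestSegmentIO:
    @staticmethod
    def _seg(label, a, b, t0, t1, dalt=10.0, gs=12.0):
        dur = t1 - t0
        return ManeuverSegment(label=label, start=a, end=b, start_time=t0,
                               end_time=t1, duration=dur, altitude_change=dalt,
                               mean_ground_speed=gs, mean_climb_rate=dalt / dur)

    def test_round_trip(self, tmp_path):
        segs = [self._seg("circle_cw", 0, 22, 0.0, 22.0),
                self._seg("glide_down", 22, 300, 22.0, 300.0, dalt=-250.0, gs=19.1)]
        p = tmp_path / "segs.csv"
        st.write_segments(segs, p)
        back = st.read_segments(p)
        assert [(s.label, s.start, s.end) for s in back] == \
               [(s.label, s.start, s.end) for s in segs]
        assert back[1].mean_ground_speed == pytest.approx(19.1, abs=1e-3)

    def test_empty_list_writes_header_only(self, tmp_path):
        p = tmp_path / "empty.csv"
        st.write_segments([], p)
        assert p.read_text().strip().startswith("start_fix,")
        assert st.read_segments(p) == []

    def test_overlapping_segments_rejected(self, tmp_path):
        segs = [self._seg("circle_cw", 0, 22, 0.0, 22.0),
                self._seg("glide_down", 10, 40, 10.0, 40.0)]
        with pytest.raises(ContractError, match="overlap"):
            st.write_segments(segs, tmp_path / "x.csv")
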