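"""GPS track and terrain I/O.

A :class:`Track` is an ordered sequence of geodetic fixes (time, lat, lon,
altitude ASL, optionally altitude AGL) backed by a pandas DataFrame.  A
:class:`TerrainGrid` is a regular lat/lon elevation raster used to convert
ASL altitudes to heights above ground.  Readers cover a plain CSV track
dialect (Movebank-style exports via a configurable column map) and two
terrain formats: ESRI ASCII grid (.asc) and a small CSV grid dialect.

Conventions: WGS84 coordinates, headings degrees clockwise from true north
in [0, 360), altitudes in meters, times in seconds since the Unix epoch
(UTC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, ContractError, CoverageError, DataError

__all__ = [
    "GpsFix",
    "Track",
    "TerrainGrid",
    "ColumnMap",
    "read_track",
    "write_track",
    "compute_agl",
    "write_segments",
    "read_segments",
]


class GpsFix(NamedTuple):
    """A single GPS fix: epoch seconds (UTC), WGS84 degrees, meters."""

    time: float
    lat: float
    lon: float
    alt_asl: float
    alt_agl: float = float("nan")


@dataclass(frozen=True)
class ColumnMap:
    """Column names of a delimited track file.

    Defaults match the package's own dialect; override for Movebank-style
    exports (e.g. ``ColumnMap(lat="location-lat", lon="location-long")``).
    """

    time: str = "timestamp"
    lat: str = "lat"
    lon: str = "lon"
    alt_asl: str = "alt_asl_m"
    alt_agl: str = "alt_agl_m"  # optional in the file
    delimiter: str = ","


class Track:
    """An ordered 1 Hz (nominally) GPS track for one animal.

    Parameters
    ----------
    df : DataFrame with columns ``time`` (float epoch s), ``lat``, ``lon``,
        ``alt_asl`` and optionally ``alt_agl``. Times must be strictly
        increasing.
    track_id : free-text identifier.
    nominal_dt : nominal sampling interval in seconds. Sampling gaps larger
        than ``3 * nominal_dt`` split the track into analysis blocks;
        maneuvers never span a gap and gaps are never interpolated.
    """

    GAP_FACTOR = 3.0

    def __init__(self, df: pd.DataFrame, track_id: str = "track", nominal_dt: float = 1.0):
        required = ["time", "lat", "lon", "alt_asl"]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ConfigurationError(f"Track frame missing columns: {missing}")
        df = df.reset_index(drop=True).copy()
        if "alt_agl" not in df.columns:
            df["alt_agl"] = np.nan
        t = df["time"].to_numpy(dtype=float)
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            bad = int(np.argmin(np.diff(t) > 0))
            raise DataError(f"times not strictly increasing at row {bad + 1} (t={t[bad + 1]!r})")
        lat = df["lat"].to_numpy(dtype=float)
        lon = df["lon"].to_numpy(dtype=float)
        if np.any(np.abs(lat) > 90.0):
            raise DataError("latitude outside [-90, 90]")
        if np.any((lon < -180.0) | (lon >= 180.0)):
            raise DataError("longitude outside [-180, 180)")
        if not np.all(np.isfinite(df["alt_asl"].to_numpy(dtype=float))):
            raise DataError("non-finite alt_asl")
        self._df = df[["time", "lat", "lon", "alt_asl", "alt_agl"]]
        self.id = track_id
        self.nominal_dt = float(nominal_dt)

    # -- basic accessors -------------------------------------------------
    def __len__(self) -> int:
        return len(self._df)

    @property
    def df(self) -> pd.DataFrame:
        return self._df

    @property
    def times(self) -> np.ndarray:
        return self._df["time"].to_numpy(dtype=float)

    @property
    def lat(self) -> np.ndarray:
        return self._df["lat"].to_numpy(dtype=float)

    @property
    def lon(self) -> np.ndarray:
        return self._df["lon"].to_numpy(dtype=float)

    @property
    def alt_asl(self) -> np.ndarray:
        return self._df["alt_asl"].to_numpy(dtype=float)

    @property
    def alt_agl(self) -> np.ndarray:
        return self._df["alt_agl"].to_numpy(dtype=float)

    def fix(self, i: int) -> GpsFix:
        r = self._df.iloc[i]
        return GpsFix(float(r.time), float(r.lat), float(r.lon), float(r.alt_asl), float(r.alt_agl))

    def with_columns(self, **cols: np.ndarray) -> "Track":
        df = self._df.copy()
        for name, values in cols.items():
            df[name] = values
        return Track(df, self.id, self.nominal_dt)

    # -- gap handling ----------------------------------------------------
    def gap_threshold(self) -> float:
        return self.GAP_FACTOR * self.nominal_dt

    def blocks(self) -> list[tuple[int, int]]:
        """Half-open fix-index ranges free of sampling gaps."""
        t = self.times
        if len(t) < 2:
            return [(0, len(t))] if len(t) else []
        gap_after = np.flatnonzero(np.diff(t) > self.gap_threshold())
        bounds = [0, *(gap_after + 1), len(t)]
        return [(bounds[k], bounds[k + 1]) for k in range(len(bounds) - 1)]

    def n_gaps(self) -> int:
        return len(self.blocks()) - 1 if len(self) else 0


# ---------------------------------------------------------------------------
# terrain


@dataclass
class TerrainGrid:
    """Regular lat/lon elevation raster (meters ASL).

    ``elevations[i, j]`` is the cell whose center is at
    ``(lat0 + i * dlat, lon0 + j * dlon)``; row index increases northward.
    """

    lat0: float
    lon0: float
    dlat: float
    dlon: float
    elevations: np.ndarray

    def __post_init__(self) -> None:
        self.elevations = np.asarray(self.elevations, dtype=float)
        if self.elevations.ndim != 2:
            raise ConfigurationError("terrain elevations must be a 2-D array")
        if self.dlat <= 0 or self.dlon <= 0:
            raise ConfigurationError("terrain cell size must be positive")

    @classmethod
    def flat(cls, elevation: float, lat0: float = 38.0, lon0: float = -80.0,
             dlat: float = 0.05, dlon: float = 0.05, shape: tuple[int, int] = (40, 40)) -> "TerrainGrid":
        """Uniform-elevation grid, handy for synthetic scenarios."""
        return cls(lat0, lon0, dlat, dlon, np.full(shape, float(elevation)))

    def sample(self, lat, lon, method: str = "bilinear"):
        """Terrain elevation at (lat, lon); bilinear or nearest.

        Raises :class:`CoverageError` if any query falls outside the grid.
        """
        lat = np.asarray(lat, dtype=float)
        lon = np.asarray(lon, dtype=float)
        fi = (lat - self.lat0) / self.dlat
        fj = (lon - self.lon0) / self.dlon
        ni, nj = self.elevations.shape
        bad = (fi < 0) | (fi > ni - 1) | (fj < 0) | (fj > nj - 1)
        if np.any(bad):
            k = int(np.argmax(np.atleast_1d(bad)))
            blat = float(np.atleast_1d(lat)[k])
            blon = float(np.atleast_1d(lon)[k])
            raise CoverageError(f"fix ({blat:.6f}, {blon:.6f}) outside terrain grid")
        if method == "nearest":
            return self.elevations[np.round(fi).astype(int), np.round(fj).astype(int)]
        if method != "bilinear":
            raise ConfigurationError(f"unknown terrain interpolation {method!r}")
        i0 = np.clip(np.floor(fi).astype(int), 0, ni - 2) if ni > 1 else np.zeros_like(fi, dtype=int)
        j0 = np.clip(np.floor(fj).astype(int), 0, nj - 2) if nj > 1 else np.zeros_like(fj, dtype=int)
        wi = fi - i0
        wj = fj - j0
        e = self.elevations
        if ni == 1:
            wi = np.zeros_like(wi)
        if nj == 1:
            wj = np.zeros_like(wj)
        i1 = np.minimum(i0 + 1, ni - 1)
        j1 = np.minimum(j0 + 1, nj - 1)
        z = ((1 - wi) * (1 - wj) * e[i0, j0] + (1 - wi) * wj * e[i0, j1]
             + wi * (1 - wj) * e[i1, j0] + wi * wj * e[i1, j1])
        return z

    # -- file formats ----------------------------------------------------
    @classmethod
    def from_ascii(cls, path: str | Path) -> "TerrainGrid":
        """Read an ESRI ASCII grid (.asc). Cell registration: ll corner."""
        header: dict[str, float] = {}
        rows: list[list[float]] = []
        with open(path) as fh:
            for line in fh:
                parts = line.split()
                if not parts:
                    continue
                if len(parts) == 2 and parts[0].lower() in {
                        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"}:
                    header[parts[0].lower()] = float(parts[1])
                else:
                    rows.append([float(x) for x in parts])
        try:
            ncols = int(header["ncols"])
            nrows = int(header["nrows"])
            cell = header["cellsize"]
            xll = header["xllcorner"]
            yll = header["yllcorner"]
        except KeyError as exc:
            raise ConfigurationError(f"ESRI ASCII grid missing header key {exc}") from exc
        data = np.array(rows, dtype=float)
        if data.shape != (nrows, ncols):
            data = data.reshape(nrows, ncols)
        data = data[::-1]  # .asc rows run north->south; store south->north
        if "nodata_value" in header:
            data = np.where(data == header["nodata_value"], np.nan, data)
        # ll corner -> center of the south-west cell
        return cls(yll + cell / 2.0, xll + cell / 2.0, cell, cell, data)

    @classmethod
    def from_csv_grid(cls, path: str | Path) -> "TerrainGrid":
        """Read the package's CSV grid dialect.

        Three header lines (``origin,<lat>,<lon>``, ``cellsize,<dlat>,<dlon>``,
        ``shape,<nrows>,<ncols>``) followed by ``nrows`` comma-separated rows
        of elevations ordered south to north.
        """
        with open(path) as fh:
            lines = [ln.strip() for ln in fh if ln.strip()]
        try:
            o = lines[0].split(",")
            c = lines[1].split(",")
            s = lines[2].split(",")
            assert o[0] == "origin" and c[0] == "cellsize" and s[0] == "shape"
            lat0, lon0 = float(o[1]), float(o[2])
            dlat, dlon = float(c[1]), float(c[2])
            nrows, ncols = int(s[1]), int(s[2])
        except (IndexError, ValueError, AssertionError) as exc:
            raise ConfigurationError(f"bad CSV grid header in {path}") from exc
        data = np.array([[float(x) for x in ln.split(",")] for ln in lines[3:3 + nrows]])
        if data.shape != (nrows, ncols):
            raise ConfigurationError(f"CSV grid body shape {data.shape} != header {(nrows, ncols)}")
        return cls(lat0, lon0, dlat, dlon, data)

    def to_csv_grid(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write(f"origin,{self.lat0:.7f},{self.lon0:.7f}\n")
            fh.write(f"cellsize,{self.dlat:.7f},{self.dlon:.7f}\n")
            ni, nj = self.elevations.shape
            fh.write(f"shape,{ni},{nj}\n")
            for row in self.elevations:
                fh.write(",".join(f"{v:.2f}" for v in row) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "TerrainGrid":
        path = Path(path)
        if path.suffix.lower() == ".asc":
            return cls.from_ascii(path)
        return cls.from_csv_grid(path)


# ---------------------------------------------------------------------------
# track reading / writing


def _parse_times(col: pd.Series) -> np.ndarray:
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)
    ts = pd.to_datetime(col, utc=True, format="ISO8601")
    return ts.astype("int64").to_numpy() / 1e9


def read_track(path: str | Path, dialect: ColumnMap | None = None,
               track_id: str | None = None, nominal_dt: float = 1.0) -> Track:
    """Read a delimited track file into a :class:`Track`.

    Duplicate timestamps keep the first row (with a warning); non-monotone
    times after deduplication raise :class:`DataError`.
    """
    dialect = dialect or ColumnMap()
    raw = pd.read_csv(path, sep=dialect.delimiter)
    for req in (dialect.time, dialect.lat, dialect.lon, dialect.alt_asl):
        if req not in raw.columns:
            raise ConfigurationError(f"{path}: missing required column {req!r}")
    df = pd.DataFrame({
        "time": _parse_times(raw[dialect.time]),
        "lat": raw[dialect.lat].to_numpy(dtype=float),
        "lon": raw[dialect.lon].to_numpy(dtype=float),
        "alt_asl": raw[dialect.alt_asl].to_numpy(dtype=float),
    })
    if dialect.alt_agl in raw.columns:
        df["alt_agl"] = raw[dialect.alt_agl].to_numpy(dtype=float)
    dup = df["time"].duplicated(keep="first")
    if dup.any():
        warnings.warn(f"{path}: dropped {int(dup.sum())} duplicate-timestamp rows (kept first)",
                      stacklevel=2)
        df = df[~dup].reset_index(drop=True)
    t = df["time"].to_numpy()
    if len(t) > 1:
        nonmono = np.flatnonzero(np.diff(t) <= 0)
        if nonmono.size:
            raise DataError(f"{path}: time not increasing at data row {int(nonmono[0]) + 1}")
    track = Track(df, track_id or Path(path).stem, nominal_dt)
    return track


def write_track(track: Track, path: str | Path, iso_times: bool = True) -> None:
    """Write a track in the package CSV dialect (round-trips with read_track)."""
    df = track.df
    with open(path, "w") as fh:
        cols = ["timestamp", "lat", "lon", "alt_asl_m"]
        has_agl = bool(np.any(np.isfinite(df["alt_agl"].to_numpy())))
        if has_agl:
            cols.append("alt_agl_m")
        fh.write(",".join(cols) + "\n")
        for row in df.itertuples(index=False):
            if iso_times:
                ts = pd.Timestamp(row.time, unit="s", tz="UTC").strftime("%Y-%m-%dT%H:%M:%S.%f")[:-3] + "Z"
            else:
                ts = f"{row.time:.3f}"
            line = f"{ts},{row.lat:.7f},{row.lon:.7f},{row.alt_asl:.2f}"
            if has_agl:
                line += f",{row.alt_agl:.2f}"
            fh.write(line + "\n")


def compute_agl(track: Track, terrain: TerrainGrid, method: str = "bilinear") -> Track:
    """Attach ``alt_agl = alt_asl - terrain`` to every fix.

    Idempotent and order-independent; ``alt_asl`` is never modified.
    Raises :class:`CoverageError` if any fix is off-grid.
    """
    ground = terrain.sample(track.lat, track.lon, method=method)
    return track.with_columns(alt_agl=track.alt_asl - np.asarray(ground, dtype=float))


# ---------------------------------------------------------------------------
# segment table I/O (the classifier's output format)

SEGMENT_COLUMNS = ["start_fix", "end_fix", "start_time", "end_time", "label",
                   "duration_s", "altitude_change_m", "mean_ground_speed_ms",
                   "mean_climb_rate_ms"]


def write_segments(segments: Sequence, path: str | Path) -> None:
    """Write classified maneuver segments as CSV (round-trips via read_segments).

    Segments must be sorted by start index and non-overlapping.
    """
    prev_end = None
    prev_start = None
    for seg in segments:
        if prev_start is not None and seg.start < prev_start:
            raise ContractError("segments not sorted by start index")
        if prev_end is not None and seg.start < prev_end:
            raise ContractError(f"overlapping segments at fix {seg.start}")
        prev_start, prev_end = seg.start, seg.end
    with open(path, "w") as fh:
        fh.write(",".join(SEGMENT_COLUMNS) + "\n")
        for seg in segments:
            fh.write(f"{seg.start},{seg.end},{seg.start_time:.3f},{seg.end_time:.3f},"
                     f"{seg.label},{seg.duration:.3f},{seg.altitude_change:.3f},"
                     f"{seg.mean_ground_speed:.4f},{seg.mean_climb_rate:.4f}\n")


def read_segments(path: str | Path) -> list:
    """Read a segment CSV written by :func:`write_segments`."""
    from .maneuvers import ManeuverSegment  # local import to avoid a cycle

    df = pd.read_csv(path)
    missing = [c for c in SEGMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path}: segment file missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        out.append(ManeuverSegment(
            label=str(row.label), start=int(row.start_fix), end=int(row.end_fix),
            start_time=float(row.start_time), end_time=float(row.end_time),
            duration=float(row.duration_s), altitude_change=float(row.altitude_change_m),
            mean_ground_speed=float(row.mean_ground_speed_ms),
            mean_climb_rate=float(row.mean_climb_rate_ms)))
    return out
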