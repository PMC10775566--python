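"""Track ingestion, filtering, regularization and step/turn computation.

Tracks are ordered, timestamped 2D locations in planar projected coordinates
(kilometres).  Times are stored as float days; when the source CSV carries
ISO-8601 timestamps an epoch is kept so days can be mapped back to dates.
The end product of this module is a :class:`StepSeries` — aligned step
lengths ``r_t`` (km) and turning angles ``phi_t`` (radians, signed, in
``(-pi, pi]``) with validity masks — which is what the change-point
likelihood consumes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Track",
    "StepSeries",
    "read_track_csv",
    "filter_dop",
    "rarefy_daily",
    "subset_dates",
    "check_gaps",
    "split_at_southernmost",
    "compute_steps",
]


@dataclass
class Track:
    """An ordered sequence of timestamped planar locations for one animal.

    Parameters
    ----------
    id : str
        Animal / deployment identifier.
    times : ndarray of float
        Location times in days, strictly increasing.
    x, y : ndarray of float
        Planar easting / northing in km (or dimensionless spatial units for
        simulated paths).
    hdop, vdop : ndarray of float or None
        Optional horizontal / vertical dilution-of-precision values; NaN
        where not recorded.
    dt_nominal : float
        Nominal sampling interval in days.
    epoch : pandas.Timestamp or None
        Calendar time corresponding to ``times == 0``; present when the
        track was read from dated records.
    """

    id: str
    times: np.ndarray
    x: np.ndarray
    y: np.ndarray
    hdop: np.ndarray | None = None
    vdop: np.ndarray | None = None
    dt_nominal: float = 1.0
    epoch: pd.Timestamp | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.hdop is not None:
            self.hdop = np.asarray(self.hdop, dtype=float)
        if self.vdop is not None:
            self.vdop = np.asarray(self.vdop, dtype=float)
        if not (len(self.times) == len(self.x) == len(self.y)):
            raise ValueError("times, x and y must have equal length")
        if np.any(~np.isfinite(self.x)) or np.any(~np.isfinite(self.y)):
            raise ValueError("coordinates must be finite")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    def take(self, idx: np.ndarray) -> "Track":
        """Return a copy restricted to the given location indices."""
        idx = np.asarray(idx)
        return replace(
            self,
            times=self.times[idx],
            x=self.x[idx],
            y=self.y[idx],
            hdop=None if self.hdop is None else self.hdop[idx],
            vdop=None if self.vdop is None else self.vdop[idx],
        )

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame({"id": self.id, "time": self.times, "x": self.x, "y": self.y})
        if self.hdop is not None:
            df["hdop"] = self.hdop
        if self.vdop is not None:
            df["vdop"] = self.vdop
        return df


@dataclass
class StepSeries:
    """Aligned step lengths and turning angles with validity masks.

    ``r[i]`` is the length of the step *arriving* at ``times[i]``;
    ``phi[i]`` is the turn between that step's heading and the previous
    step's heading.  ``valid_phi[i]`` implies ``valid_r[i]`` and
    ``valid_r[i-1]`` (three consecutive on-interval fixes are needed for a
    turning angle).
    """

    times: np.ndarray
    r: np.ndarray
    phi: np.ndarray
    valid_r: np.ndarray
    valid_phi: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.r = np.asarray(self.r, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)
        self.valid_r = np.asarray(self.valid_r, dtype=bool)
        self.valid_phi = np.asarray(self.valid_phi, dtype=bool)
        n = len(self.times)
        if not all(len(a) == n for a in (self.r, self.phi, self.valid_r, self.valid_phi)):
            raise ValueError("all StepSeries fields must have equal length")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_valid_r(self) -> int:
        return int(self.valid_r.sum())

    @property
    def n_valid_phi(self) -> int:
        return int(self.valid_phi.sum())

    def shifted(self, delta: float) -> "StepSeries":
        """The same series with all times translated by ``delta``."""
        return StepSeries(self.times + delta, self.r, self.phi, self.valid_r, self.valid_phi)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "r": self.r,
                "phi": self.phi,
                "valid_r": self.valid_r,
                "valid_phi": self.valid_phi,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "StepSeries":
        return cls(
            df["time"].to_numpy(float),
            df["r"].to_numpy(float),
            df["phi"].to_numpy(float),
            df["valid_r"].to_numpy(bool),
            df["valid_phi"].to_numpy(bool),
        )

    @classmethod
    def read_csv(cls, path) -> "StepSeries":
        return cls.from_dataframe(pd.read_csv(path))


_DEFAULT_COLUMNS = {
    "id": "id",
    "timestamp": "timestamp",
    "x": "x",
    "y": "y",
    "hdop": "hdop",
    "vdop": "vdop",
}


def _parse_times(raw: pd.Series, path) -> tuple[np.ndarray, pd.Timestamp | None]:
    """Parse timestamps to float days, returning (days, epoch)."""
    if pd.api.types.is_numeric_dtype(raw):
        return raw.to_numpy(dtype=float), None
    parsed = pd.to_datetime(raw, errors="coerce", format="mixed")
    bad = parsed.isna() & raw.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValueError(f"{path}: unparseable timestamp at row {row}: {raw.iloc[row]!r}")
    epoch = parsed.min().normalize()
    days = (parsed - epoch) / pd.Timedelta(days=1)
    return days.to_numpy(dtype=float), epoch


def read_track_csv(
    path,
    column_map: dict[str, str] | None = None,
    dt_nominal: float = 1.0,
) -> list[Track]:
    """Read one :class:`Track` per animal id from a CSV file.

    Parameters
    ----------
    path : path-like
        CSV with at least id / timestamp / x / y columns.
    column_map : dict, optional
        Maps the logical names ``id, timestamp, x, y, hdop, vdop`` to the
        file's column names.  Defaults to the identical names.
    dt_nominal : float
        Nominal sampling interval in days, attached to each track.

    Returns
    -------
    list of Track
        Sorted by time within each track; rows with duplicate timestamps are
        collapsed to the first occurrence (logged).
    """
    cols = dict(_DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path)
    for key in ("id", "timestamp", "x", "y"):
        if cols[key] not in df.columns:
            raise ValueError(f"{path}: missing required column {cols[key]!r}")

    tracks = []
    for track_id, sub in df.groupby(cols["id"], sort=False):
        times, epoch = _parse_times(sub[cols["timestamp"]], path)
        order = np.argsort(times, kind="stable")
        times = times[order]
        sub = sub.iloc[order]
        keep = np.concatenate([[True], np.diff(times) > 0])
        n_dup = int((~keep).sum())
        if n_dup:
            logger.warning("track %s: dropped %d duplicate-timestamp rows", track_id, n_dup)
        sub = sub.iloc[keep]
        times = times[keep]

        def _opt(key):
            c = cols[key]
            return sub[c].to_numpy(dtype=float) if c in sub.columns else None

        tracks.append(
            Track(
                id=str(track_id),
                times=times,
                x=sub[cols["x"]].to_numpy(dtype=float),
                y=sub[cols["y"]].to_numpy(dtype=float),
                hdop=_opt("hdop"),
                vdop=_opt("vdop"),
                dt_nominal=dt_nominal,
                epoch=epoch,
            )
        )
    return tracks


def filter_dop(track: Track, max_dop: float = 5.0) -> Track:
    """Drop locations whose horizontal *or* vertical DOP exceeds ``max_dop``.

    Locations without DOP fields (or with NaN DOP) are retained.
    """
    bad = np.zeros(len(track), dtype=bool)
    for dop in (track.hdop, track.vdop):
        if dop is not None:
            with np.errstate(invalid="ignore"):
                bad |= np.nan_to_num(dop, nan=-np.inf) > max_dop
    return track.take(np.flatnonzero(~bad))


def rarefy_daily(track: Track) -> Track:
    """Thin a track to at most one location per calendar day.

    The retained fix is the one nearest 12:00 of its day (ties go to the
    earlier fix); ``dt_nominal`` is set to 1 day.
    """
    if len(track) == 0:
        raise ValueError("cannot rarefy an empty track")
    day = np.floor(track.times).astype(int)
    dist_noon = np.abs(track.times - (day + 0.5))
    keep = []
    for d in np.unique(day):
        idx = np.flatnonzero(day == d)
        dist = dist_noon[idx]
        # earlier fix wins ties (up to float noise in the noon distance)
        keep.append(idx[np.flatnonzero(dist <= dist.min() + 1e-9)[0]])
    out = track.take(np.asarray(sorted(keep)))
    out.dt_nominal = 1.0
    return out


def subset_dates(track: Track, start: float, end: float) -> Track:
    """Retain locations with ``start <= time <= end`` (float days).

    Emits a warning and returns an empty track when nothing survives.
    """
    if start > end:
        raise ValueError("start must not exceed end")
    mask = (track.times >= start) & (track.times <= end)
    if not mask.any():
        warnings.warn(f"track {track.id}: no locations in [{start}, {end}]", stacklevel=2)
    return track.take(np.flatnonzero(mask))


@dataclass
class GapReport:
    """Spatial / temporal gap violations for one track."""

    track_id: str
    spatial: pd.DataFrame  # columns: index, time_prev, time, displacement_km
    temporal: pd.DataFrame  # columns: index, time_prev, time, interval_days
    passed: bool

    def to_dataframe(self) -> pd.DataFrame:
        s = self.spatial.assign(kind="spatial", value=self.spatial.get("displacement_km"))
        t = self.temporal.assign(kind="temporal", value=self.temporal.get("interval_days"))
        cols = ["kind", "index", "time_prev", "time", "value"]
        return pd.concat([s, t], ignore_index=True)[cols] if len(s) + len(t) else pd.DataFrame(columns=cols)


def check_gaps(track: Track, max_spatial_gap: float, max_temporal_gap: float) -> GapReport:
    """Report consecutive-fix displacements / intervals above the thresholds.

    Used as an exclusion filter: a track with any violation fails and is
    dropped whole, mirroring the removal of entire migration paths with
    > 400 km jumps (hawks) / > 150 km (caribou) or 14-day holes.
    """
    disp = np.hypot(np.diff(track.x), np.diff(track.y))
    gaps = np.diff(track.times)
    si = np.flatnonzero(disp > max_spatial_gap)
    ti = np.flatnonzero(gaps > max_temporal_gap)
    spatial = pd.DataFrame(
        {
            "index": si + 1,
            "time_prev": track.times[si],
            "time": track.times[si + 1],
            "displacement_km": disp[si],
        }
    )
    temporal = pd.DataFrame(
        {
            "index": ti + 1,
            "time_prev": track.times[ti],
            "time": track.times[ti + 1],
            "interval_days": gaps[ti],
        }
    )
    return GapReport(track.id, spatial, temporal, passed=len(si) == 0 and len(ti) == 0)


def split_at_southernmost(track: Track) -> tuple[Track, Track]:
    """Split an annual-cycle track at its southernmost (minimum-y) location.

    Returns ``(fall, spring)``: fall runs up to and including the
    southernmost fix, spring from that fix onward.  Ties on y break to the
    earliest fix.  A track whose minimum is at the very first fix is
    degenerate (e.g. constant y) and triggers a warning.
    """
    if len(track) < 3:
        raise ValueError("need at least 3 locations to split a track")
    imin = int(np.argmin(track.y))  # argmin returns the first (earliest) min
    if imin == 0:
        warnings.warn(
            f"track {track.id}: southernmost location is the first fix; degenerate split",
            stacklevel=2,
        )
    fall = track.take(np.arange(0, imin + 1))
    spring = track.take(np.arange(imin, len(track)))
    return fall, spring


def compute_steps(track: Track, tolerance: float = 0.01, normalize_by_interval: bool = False) -> StepSeries:
    """Compute the step-length / turning-angle series for a regular track.

    A step arriving at ``z_t`` is valid when its duration lies within
    ``(1 +/- tolerance) * dt_nominal``; steps spanning missing fixes are
    masked out of the likelihood rather than rescaled (set
    ``normalize_by_interval=True`` to divide step lengths by the elapsed
    interval in units of ``dt_nominal`` instead, which also marks them
    valid).  A turning angle at ``z_t`` needs the two preceding steps to be
    valid and contiguous, and is undefined after a zero-length step (no
    heading).
    """
    n = len(track)
    if n < 2:
        raise ValueError("need at least 2 locations for a step")
    dt = track.dt_nominal
    dx = np.diff(track.x)
    dy = np.diff(track.y)
    dur = np.diff(track.times)
    r_raw = np.hypot(dx, dy)
    on_interval = np.abs(dur - dt) <= tolerance * dt

    times = track.times[1:]
    if normalize_by_interval:
        r = r_raw / (dur / dt)
        valid_r = np.ones(n - 1, dtype=bool)
    else:
        r = np.where(on_interval, r_raw, np.nan)
        valid_r = on_interval.copy()

    heading = np.arctan2(dy, dx)
    has_heading = r_raw > 0
    phi = np.full(n - 1, np.nan)
    valid_phi = np.zeros(n - 1, dtype=bool)
    if n >= 3:
        turn = heading[1:] - heading[:-1]
        # wrap into (-pi, pi]
        turn = -np.mod(-turn + np.pi, 2 * np.pi) + np.pi
        contiguous = valid_r[1:] & valid_r[:-1] & has_heading[:-1] & has_heading[1:]
        phi[1:] = np.where(contiguous, turn, np.nan)
        valid_phi[1:] = contiguous
    return StepSeries(times, r, phi, valid_r, valid_phi)
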