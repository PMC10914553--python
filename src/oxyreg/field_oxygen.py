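"""In-situ dissolved-oxygen logger summarization.

Field loggers record DO (mg O2 L-1) and temperature at a nominal 60 s cadence
at the interior thicket and exterior open branches of a colony.  This module
reads and validates those series, computes range/threshold statistics and
cumulative time-at-DO histograms, interior-vs-exterior deltas on the
overlapping deployment window, and nearest-neighbour alignment with tide and
sunrise/sunset tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, MetadataError, ParameterError

POSITIONS = ("interior", "exterior")

NOMINAL_CADENCE_S = 60.0
CADENCE_TOL = 0.10
GAP_THRESHOLD_S = 300.0

_FIELD_ALIASES = {
    "time": ("datetime", "timestamp", "time", "Date Time", "DateTime"),
    "do": ("do_mgL", "do", "DO (mg/L)", "oxygen_mgL", "DO"),
    "temperature": ("temp_C", "temperature", "temp", "Temp (C)"),
}


@dataclass
class FieldSeries:
    """One logger deployment at a labelled colony position."""

    timestamps: pd.DatetimeIndex
    do_mgL: np.ndarray
    temperature: np.ndarray
    position: str
    colony_id: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.timestamps = pd.DatetimeIndex(self.timestamps)
        self.do_mgL = np.asarray(self.do_mgL, dtype=float)
        self.temperature = np.asarray(self.temperature, dtype=float)
        if self.position not in POSITIONS:
            raise MetadataError(
                f"position must be one of {POSITIONS}, got {self.position!r}")
        if len(self.timestamps) == 0:
            raise DataError(f"{self.colony_id}/{self.position}: empty series")
        if len(self.timestamps) != self.do_mgL.size:
            raise DataError("time/DO length mismatch")
        if not self.timestamps.is_monotonic_increasing or self.timestamps.has_duplicates:
            raise DataError(f"{self.colony_id}/{self.position}: timestamps not increasing")
        if np.any(self.do_mgL < 0) or np.any(self.do_mgL > 20):
            raise DataError(f"{self.colony_id}/{self.position}: DO outside [0, 20] mg/L")

    @property
    def n(self) -> int:
        return int(self.do_mgL.size)

    @property
    def span(self) -> pd.Timedelta:
        return self.timestamps[-1] - self.timestamps[0]

    def sample_weights_s(self) -> np.ndarray:
        """Per-sample weight = its inter-sample interval (last reuses the final gap)."""
        d = np.diff(self.timestamps.view("int64")) / 1e9
        if d.size == 0:
            return np.array([NOMINAL_CADENCE_S])
        return np.append(d, d[-1])


@dataclass
class FieldSummary:
    do_min: float
    do_max: float
    do_mean: float
    do_range: float
    fraction_below: dict[float, float]
    n: int
    span_hours: float


def _resolve(columns, key, dialect):
    if dialect and key in dialect:
        if dialect[key] not in columns:
            raise DataError(f"configured column {dialect[key]!r} not in file")
        return dialect[key]
    for alias in _FIELD_ALIASES[key]:
        if alias in columns:
            return alias
    return None


def read_logger_csv(path, position: str, colony_id: str,
                    dialect: Mapping[str, str] | None = None) -> FieldSeries:
    """Read an in-situ logger CSV into a validated :class:`FieldSeries`.

    Cadence outside 60 s +/- 10% and gaps longer than 5 minutes are recorded
    in ``meta`` rather than raised.
    """
    if position not in POSITIONS:
        raise MetadataError(f"unknown position label {position!r}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"{path}: empty file") from exc
    if df.empty:
        raise DataError(f"{path}: no data rows")
    cols = list(df.columns)
    tcol = _resolve(cols, "time", dialect)
    dcol = _resolve(cols, "do", dialect)
    if tcol is None or dcol is None:
        raise DataError(f"{path}: need datetime and DO columns, have {cols}")
    tempcol = _resolve(cols, "temperature", dialect)

    ts = pd.to_datetime(df[tcol])
    do = pd.to_numeric(df[dcol], errors="coerce")
    keep = do.notna()
    ts, do = ts[keep], do[keep]
    if ts.empty:
        raise DataError(f"{path}: no usable rows")
    temp = (pd.to_numeric(df[tempcol], errors="coerce")[keep].to_numpy()
            if tempcol else np.full(len(ts), np.nan))

    meta: dict = {}
    diffs = ts.diff().dt.total_seconds().dropna()
    if not diffs.empty:
        med = float(diffs.median())
        if abs(med - NOMINAL_CADENCE_S) > CADENCE_TOL * NOMINAL_CADENCE_S:
            meta["cadence_warning"] = f"median cadence {med:g} s (nominal 60 s)"
        gaps = diffs[diffs > GAP_THRESHOLD_S]
        if not gaps.empty:
            meta["gaps"] = [
                (str(ts.iloc[i - 1]), str(ts.iloc[i]))
                for i in np.nonzero(diffs.to_numpy() > GAP_THRESHOLD_S)[0] + 1
            ]
    return FieldSeries(timestamps=pd.DatetimeIndex(ts), do_mgL=do.to_numpy(),
                       temperature=temp, position=position,
                       colony_id=colony_id, meta=meta)


def summarize_series(series: FieldSeries,
                     thresholds: Sequence[float] = (2.0, 5.0)) -> FieldSummary:
    """Extremes, mean, range and interval-weighted time fraction below each threshold."""
    if series.n < 100:
        raise ParameterError(f"need >= 100 samples, got {series.n}")
    w = series.sample_weights_s()
    total = w.sum()
    fraction_below = {
        float(thr): float(w[series.do_mgL < thr].sum() / total)
        for thr in thresholds
    }
    do = series.do_mgL
    return FieldSummary(
        do_min=float(do.min()), do_max=float(do.max()),
        do_mean=float(np.average(do, weights=w)),
        do_range=float(do.max() - do.min()),
        fraction_below=fraction_below, n=series.n,
        span_hours=float(series.span.total_seconds() / 3600.0),
    )


@dataclass
class TimeHistogram:
    bin_left: np.ndarray
    bin_right: np.ndarray
    fraction: np.ndarray


def cumulative_time_histogram(series: FieldSeries, bin_width: float = 0.5,
                              origin: float | None = None) -> TimeHistogram:
    """Time-at-DO histogram over half-open bins [lo, lo + width).

    ``origin`` anchors the bin edges (default: edges on integer multiples of
    the width; pass e.g. origin=0.5 with width 1.0 for bins centred on
    integers).  Fractions are interval-weighted and sum to 1.
    """
    if bin_width <= 0:
        raise ParameterError("bin_width must be > 0")
    do = series.do_mgL
    w = series.sample_weights_s()
    if origin is None:
        origin = 0.0
    lo_edge = origin + np.floor((do.min() - origin) / bin_width) * bin_width
    hi_edge = origin + (np.floor((do.max() - origin) / bin_width) + 1) * bin_width
    edges = np.arange(lo_edge, hi_edge + bin_width / 2, bin_width)
    idx = np.floor((do - lo_edge) / bin_width).astype(int)
    idx = np.clip(idx, 0, edges.size - 2)
    frac = np.bincount(idx, weights=w, minlength=edges.size - 1) / w.sum()
    return TimeHistogram(bin_left=edges[:-1], bin_right=edges[1:], fraction=frac)


def _overlap_mask(series: FieldSeries, start, end) -> np.ndarray:
    return (series.timestamps >= start) & (series.timestamps <= end)


def interior_exterior_delta(interior: FieldSeries,
                            exterior: FieldSeries) -> dict[str, float]:
    """Exterior-minus-interior DO deltas on the overlapping deployment window.

    Returns ``delta_mean`` and ``delta_range`` (mg L-1) and ``pct_diff`` =
    100 * delta_mean / exterior mean.
    """
    if interior.colony_id != exterior.colony_id:
        raise DataError(
            f"colony mismatch: {interior.colony_id!r} vs {exterior.colony_id!r}")
    start = max(interior.timestamps[0], exterior.timestamps[0])
    end = min(interior.timestamps[-1], exterior.timestamps[-1])
    if start >= end:
        raise DataError("deployments do not overlap in time")
    m_int = _overlap_mask(interior, start, end)
    m_ext = _overlap_mask(exterior, start, end)
    di = interior.do_mgL[m_int]
    de = exterior.do_mgL[m_ext]
    delta_mean = float(de.mean() - di.mean())
    delta_range = float((de.max() - de.min()) - (di.max() - di.min()))
    return {
        "delta_mean": delta_mean,
        "delta_range": delta_range,
        "pct_diff": 100.0 * delta_mean / float(de.mean()),
    }


def align_with_tides(series: FieldSeries, tides: pd.DataFrame,
                     sun: pd.DataFrame,
                     tolerance: pd.Timedelta = pd.Timedelta(minutes=30)) -> pd.DataFrame:
    """Join per-sample tide height and a day/night flag onto a field series.

    ``tides`` needs columns (datetime, height_m); ``sun`` needs (date,
    sunrise, sunset).  Tide heights come from a nearest-neighbour join with a
    30-minute tolerance; day means sunrise <= t < sunset.  Any sample the
    tables do not cover raises a :class:`DataError` naming the uncovered span.
    """
    tides = tides.copy()
    tides["datetime"] = pd.to_datetime(tides["datetime"])
    tides = tides.sort_values("datetime")

    samples = pd.DataFrame({
        "datetime": series.timestamps,
        "do_mgL": series.do_mgL,
        "temperature": series.temperature,
    })
    joined = pd.merge_asof(samples, tides[["datetime", "height_m"]],
                           on="datetime", direction="nearest",
                           tolerance=tolerance)
    missing = joined["height_m"].isna()
    if missing.any():
        bad = joined.loc[missing, "datetime"]
        raise DataError(
            f"tide table does not cover {bad.iloc[0]} .. {bad.iloc[-1]} "
            f"({int(missing.sum())} samples)")

    sun = sun.copy()
    sun["date"] = pd.to_datetime(sun["date"]).dt.date
    sun_map = {
        row["date"]: (pd.Timestamp(f"{row['date']} {row['sunrise']}"),
                      pd.Timestamp(f"{row['date']} {row['sunset']}"))
        for _, row in sun.iterrows()
    }
    dates = joined["datetime"].dt.date
    uncovered = sorted(set(dates) - set(sun_map))
    if uncovered:
        raise DataError(f"sun table missing dates: {uncovered[0]} .. {uncovered[-1]}")
    rise = dates.map(lambda d: sun_map[d][0])
    sset = dates.map(lambda d: sun_map[d][1])
    joined["is_day"] = (joined["datetime"] >= rise) & (joined["datetime"] < sset)
    joined["position"] = series.position
    joined["colony_id"] = series.colony_id
    return joined
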