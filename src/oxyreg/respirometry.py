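"""Closed-chamber respirometry: drawdown traces, O2 solubility and rate extraction.

A sealed chamber containing one coral fragment is logged at a nominal 60 s
cadence while the fragment draws oxygen down from ~100% air saturation towards
anoxia.  This module turns such traces into blank- and volume-corrected oxygen
consumption rates (VO2, mg O2 h-1) as a function of ambient pO2, and into the
normalized hypoxia-response curves consumed by :mod:`oxyreg.hrc_models`.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, DomainError, FormatError, ParameterError

logger = logging.getLogger(__name__)

DEFAULT_TEMPERATURE_C = 27.0
DEFAULT_SALINITY_PPT = 35.0
DEFAULT_PRESSURE_MBAR = 1013.0

#: column-name aliases tried when no explicit dialect mapping is given
_DEFAULT_ALIASES = {
    "time": ("time_s", "time", "Time (s)", "Time", "seconds", "t_s"),
    "o2": ("airsat_pct", "airsat", "o2_airsat", "O2 (%air sat)", "oxygen", "% air sat"),
    "temperature": ("temp_C", "temperature", "temp", "Temp (C)", "Sample Temp. (°C)"),
}

#: air-saturation values are clamped to this range before any rate work
AIRSAT_CLAMP = (0.0, 120.0)


@dataclass
class DrawdownTrace:
    """One sealed-chamber O2 time series plus the chamber geometry.

    ``timestamps`` are seconds since the start of the record, strictly
    increasing.  ``airsat`` is % air saturation; small sensor excursions in
    [-2, 120] are tolerated here and clamped to [0, 120] downstream.
    """

    chamber_id: str
    timestamps: np.ndarray
    airsat: np.ndarray
    temperature: np.ndarray | float = DEFAULT_TEMPERATURE_C
    chamber_volume: float = 400.0  # mL
    displacement_volume: float = 0.0  # mL
    is_blank: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.airsat = np.asarray(self.airsat, dtype=float)
        if self.timestamps.size == 0:
            raise DataError(f"trace {self.chamber_id!r}: empty series")
        if self.timestamps.shape != self.airsat.shape:
            raise DataError(f"trace {self.chamber_id!r}: time/O2 length mismatch")
        dt = np.diff(self.timestamps)
        bad = np.nonzero(dt <= 0)[0]
        if bad.size:
            i = int(bad[0]) + 1
            raise DataError(
                f"trace {self.chamber_id!r}: timestamps not strictly increasing "
                f"at row {i} (t={self.timestamps[i]:g})"
            )
        if np.any(self.airsat < -2.0) or np.any(self.airsat > 120.0):
            raise DataError(
                f"trace {self.chamber_id!r}: air saturation outside [-2, 120]"
            )
        if np.isscalar(self.temperature) or np.ndim(self.temperature) == 0:
            self.temperature = np.full_like(self.airsat, float(self.temperature))
        else:
            self.temperature = np.asarray(self.temperature, dtype=float)
            if self.temperature.shape != self.airsat.shape:
                raise DataError(f"trace {self.chamber_id!r}: temperature length mismatch")
        if not self.displacement_volume < self.chamber_volume:
            raise DataError(
                f"trace {self.chamber_id!r}: displacement volume "
                f"{self.displacement_volume} mL must be < chamber volume "
                f"{self.chamber_volume} mL"
            )
        if self.is_blank and self.displacement_volume != 0:
            raise DataError(
                f"trace {self.chamber_id!r}: blank trace must have zero displacement"
            )

    @property
    def n(self) -> int:
        return int(self.timestamps.size)

    @property
    def v_net_L(self) -> float:
        """Effective water volume in litres (chamber minus displacement)."""
        return (self.chamber_volume - self.displacement_volume) / 1000.0

    def clamped_airsat(self) -> np.ndarray:
        return np.clip(self.airsat, *AIRSAT_CLAMP)


@dataclass
class RateSeries:
    """Windowed O2 consumption rates for one trace.

    ``points`` columns: pO2_mid (% air sat), vo2 (mg O2 h-1) and the window
    span in seconds.
    """

    pO2_mid: np.ndarray
    vo2: np.ndarray
    window_spans: np.ndarray  # shape (n, 2), seconds
    v_net_L: float
    source_id: str

    def __post_init__(self):
        self.pO2_mid = np.asarray(self.pO2_mid, dtype=float)
        self.vo2 = np.asarray(self.vo2, dtype=float)
        self.window_spans = np.asarray(self.window_spans, dtype=float)
        if not np.all(np.isfinite(self.vo2)):
            raise DataError(f"rates {self.source_id!r}: non-finite VO2")
        if np.any(self.window_spans[:, 1] <= self.window_spans[:, 0]):
            raise DataError(f"rates {self.source_id!r}: degenerate window")

    @property
    def n(self) -> int:
        return int(self.vo2.size)


@dataclass
class HRCurve:
    """Normalized hypoxia response curve: x = pO2 fraction, y = relative VO2."""

    x: np.ndarray
    y: np.ndarray
    y_ref: float
    x_range: tuple[float, float]
    source_id: str = ""

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if np.any(self.x < 0) or np.any(self.x > 1.2):
            raise DataError(f"curve {self.source_id!r}: x outside [0, 1.2]")
        if not np.all(np.isfinite(self.y)):
            raise DataError(f"curve {self.source_id!r}: non-finite y")
        if not self.y_ref > 0:
            raise DataError(f"curve {self.source_id!r}: y_ref must be > 0")

    @property
    def n(self) -> int:
        return int(self.x.size)


# ---------------------------------------------------------------------------
# O2 solubility (Benson-Krause atmospheric-equilibrium relation)
# ---------------------------------------------------------------------------

def o2_solubility(temperature: float, salinity: float = 0.0,
                  pressure: float = DEFAULT_PRESSURE_MBAR) -> float:
    """Equilibrium O2 concentration (mg L-1) at 100% air saturation.

    Benson-Krause fit with the standard salinity term, plus the full
    barometric correction (water-vapour pressure and the second virial
    theta term).  Strictly decreasing in temperature and in salinity.

    Parameters
    ----------
    temperature : deg C, in [0, 40]
    salinity : practical salinity (ppt), in [0, 40]
    pressure : total barometric pressure (mbar), in [800, 1100]
    """
    if not (0.0 <= temperature <= 40.0):
        raise DomainError(f"temperature {temperature} degC outside [0, 40]")
    if not (0.0 <= salinity <= 40.0):
        raise DomainError(f"salinity {salinity} ppt outside [0, 40]")
    if not (800.0 <= pressure <= 1100.0):
        raise DomainError(f"pressure {pressure} mbar outside [800, 1100]")

    t = float(temperature)
    T = t + 273.15
    ln_c = (-139.34411
            + 1.575701e5 / T
            - 6.642308e7 / T ** 2
            + 1.243800e10 / T ** 3
            - 8.621949e11 / T ** 4)
    ln_c -= salinity * (1.7674e-2 - 1.0754e1 / T + 2.1407e3 / T ** 2)
    c_star = math.exp(ln_c)  # mg/L at 1 atm moist air

    p_atm = pressure / 1013.25
    # saturated water-vapour pressure (atm) and theta correction
    ln_u = 11.8571 - 3840.70 / T - 216961.0 / T ** 2
    u = math.exp(ln_u)
    theta = 0.000975 - 1.426e-5 * t + 6.436e-8 * t ** 2
    factor = (p_atm * (1.0 - u / p_atm) * (1.0 - theta * p_atm)
              / ((1.0 - u) * (1.0 - theta)))
    return c_star * factor


def airsat_to_mgL(airsat, temperature, salinity=DEFAULT_SALINITY_PPT,
                  pressure=DEFAULT_PRESSURE_MBAR):
    """Convert % air saturation to dissolved O2 (mg L-1)."""
    c_sat = o2_solubility(temperature, salinity, pressure)
    return np.asarray(airsat, dtype=float) / 100.0 * c_sat


def mgL_to_airsat(do_mgL, temperature, salinity=DEFAULT_SALINITY_PPT,
                  pressure=DEFAULT_PRESSURE_MBAR):
    """Convert dissolved O2 (mg L-1) to % air saturation."""
    c_sat = o2_solubility(temperature, salinity, pressure)
    return np.asarray(do_mgL, dtype=float) / c_sat * 100.0


# ---------------------------------------------------------------------------
# File reading
# ---------------------------------------------------------------------------

def _resolve_column(columns: Sequence[str], key: str,
                    dialect: Mapping[str, str] | None) -> str | None:
    if dialect and key in dialect:
        name = dialect[key]
        if name not in columns:
            raise FormatError(f"configured column {name!r} for {key!r} not in file")
        return name
    for alias in _DEFAULT_ALIASES[key]:
        if alias in columns:
            return alias
    return None


def read_firesting_csv(path, meta: Mapping | None = None,
                       dialect: Mapping[str, str] | None = None) -> DrawdownTrace:
    """Read a chamber-logger CSV into a validated :class:`DrawdownTrace`.

    ``meta`` supplies chamber metadata (``chamber_id``, ``chamber_volume``,
    ``displacement_volume``, ``is_blank`` plus any labels); ``dialect`` maps
    the logical keys ``time``/``o2``/``temperature`` to column names when the
    defaults do not apply.  Rows with NaN or sentinel (< -10) O2 readings are
    dropped with a logged count.
    """
    meta = dict(meta or {})
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"{path}: empty file") from exc

    cols = list(df.columns)
    tcol = _resolve_column(cols, "time", dialect)
    ocol = _resolve_column(cols, "o2", dialect)
    if tcol is None:
        raise FormatError(f"{path}: no time column among {cols}")
    if ocol is None:
        raise FormatError(f"{path}: no O2 column among {cols}")
    tempcol = _resolve_column(cols, "temperature", dialect)

    time_raw = df[tcol]
    try:
        t = time_raw.astype(float).to_numpy()
    except (TypeError, ValueError):
        dt_idx = pd.to_datetime(time_raw)
        t = (dt_idx - dt_idx.iloc[0]).dt.total_seconds().to_numpy()

    o2 = pd.to_numeric(df[ocol], errors="coerce").to_numpy(dtype=float)
    keep = np.isfinite(o2) & (o2 > -10.0) & np.isfinite(t)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: dropped %d rows with missing/sentinel O2", path, n_dropped)
    t, o2 = t[keep], o2[keep]
    if t.size == 0:
        raise DataError(f"{path}: no usable rows after cleaning")

    dup = np.nonzero(np.diff(t) <= 0)[0]
    if dup.size:
        i = int(dup[0]) + 1
        raise DataError(f"{path}: non-increasing timestamp at data row {i} (t={t[i]:g})")

    if tempcol is not None:
        temp = pd.to_numeric(df[tempcol], errors="coerce").to_numpy(dtype=float)[keep]
        temp = np.where(np.isfinite(temp), temp,
                        meta.get("temperature", DEFAULT_TEMPERATURE_C))
    else:
        temp = float(meta.get("temperature", DEFAULT_TEMPERATURE_C))

    trace_meta = {k: v for k, v in meta.items()
                  if k not in {"chamber_id", "chamber_volume",
                               "displacement_volume", "is_blank", "temperature"}}
    trace_meta["n_dropped_rows"] = n_dropped
    return DrawdownTrace(
        chamber_id=str(meta.get("chamber_id", str(path))),
        timestamps=t - t[0],
        airsat=o2,
        temperature=temp,
        chamber_volume=float(meta.get("chamber_volume", 400.0)),
        displacement_volume=float(meta.get("displacement_volume", 0.0)),
        is_blank=bool(meta.get("is_blank", False)),
        meta=trace_meta,
    )


# ---------------------------------------------------------------------------
# Rate extraction
# ---------------------------------------------------------------------------

def _trim_zero_tail(t: np.ndarray, a: np.ndarray, temp: np.ndarray):
    """Drop the post-anoxia flatline: keep at most one trailing exact-zero sample."""
    nz = np.nonzero(a > 0)[0]
    if nz.size == 0:
        raise DataError("trace is all-zero after clamping")
    end = min(int(nz[-1]) + 2, a.size)  # keep first zero after the last positive
    return t[:end], a[:end], temp[:end]


def _window_rates(trace: DrawdownTrace, window: float, step: float,
                  salinity: float, pressure: float):
    """Per sliding window: (mean pO2, volumetric rate mg L-1 h-1, span)."""
    t, a, temp = _trim_zero_tail(trace.timestamps, trace.clamped_airsat(),
                                 trace.temperature)
    if window > t[-1] - t[0]:
        raise ParameterError(
            f"window {window} s longer than trace span {t[-1] - t[0]:g} s")
    med_dt = float(np.median(np.diff(t)))
    if window / med_dt + 1 < 5:
        raise ParameterError(
            f"window {window} s holds fewer than 5 samples at cadence {med_dt:g} s")

    mids, rates, spans = [], [], []
    t0 = t[0]
    while t0 + window <= t[-1] + 1e-9:
        sel = (t >= t0 - 1e-9) & (t <= t0 + window + 1e-9)
        if sel.sum() >= 5:
            tw = t[sel]
            aw = a[sel]
            c_sat = o2_solubility(float(np.mean(temp[sel])), salinity, pressure)
            conc = aw / 100.0 * c_sat
            hours = (tw - tw[0]) / 3600.0
            slope = np.polyfit(hours, conc, 1)[0]  # mg L-1 h-1
            mids.append(float(np.mean(aw)))
            rates.append(-float(slope))
            spans.append((t0, t0 + window))
        t0 += step
    if not mids:
        raise DataError("no usable rate windows")
    return np.array(mids), np.array(rates), np.array(spans)


def compute_vo2_curve(trace: DrawdownTrace, blank: DrawdownTrace | None,
                      window: float = 600.0, step: float = 300.0,
                      salinity: float = DEFAULT_SALINITY_PPT,
                      pressure: float = DEFAULT_PRESSURE_MBAR) -> RateSeries:
    """Windowed, blank-corrected O2 consumption rates against ambient pO2.

    Per sliding window the trace is converted from % air saturation to
    mg O2 L-1 at the window's temperature, a least-squares slope gives the
    volumetric depletion rate, and the blank's volumetric rate — interpolated
    to the same pO2, since control and coral chambers traverse pO2 at
    different speeds — is subtracted before scaling by the net water volume.
    """
    if blank is not None and blank.displacement_volume != 0:
        raise DataError("blank trace must have zero displacement volume")

    mids, rates, spans = _window_rates(trace, window, step, salinity, pressure)

    if blank is not None:
        bmids, brates, _ = _window_rates(blank, window, step, salinity, pressure)
        order = np.argsort(bmids)
        blank_at = np.interp(mids, bmids[order], brates[order])
    else:
        blank_at = np.zeros_like(mids)

    vo2 = (rates - blank_at) * trace.v_net_L
    return RateSeries(pO2_mid=mids, vo2=vo2, window_spans=spans,
                      v_net_L=trace.v_net_L, source_id=trace.chamber_id)


@dataclass
class DrawdownDuration:
    """Time between two air-saturation threshold crossings."""

    hours: float
    censored: bool = False
    min_airsat: float | None = None


def _first_crossing_below(t: np.ndarray, a: np.ndarray, thr: float) -> float | None:
    """Time of the first downward crossing of ``thr`` (linear interpolation)."""
    below = np.nonzero(a <= thr)[0]
    if below.size == 0:
        return None
    i = int(below[0])
    if i == 0:
        return float(t[0])
    a0, a1 = a[i - 1], a[i]
    if a0 == a1:
        return float(t[i])
    frac = (a0 - thr) / (a0 - a1)
    return float(t[i - 1] + frac * (t[i] - t[i - 1]))


def drawdown_duration(trace: DrawdownTrace, start: float = 100.0,
                      end: float = 0.0) -> DrawdownDuration:
    """Hours between the first crossings below ``start`` and below ``end``.

    If the trace never reaches ``end`` a censored duration is returned
    (time from the ``start`` crossing to the end of the record) together
    with the minimum pO2 attained.
    """
    if end >= start:
        raise ParameterError(f"end threshold {end} must be below start {start}")
    t = trace.timestamps
    a = trace.clamped_airsat()
    t_start = _first_crossing_below(t, a, start)
    if t_start is None:
        raise DataError(
            f"trace {trace.chamber_id!r} never drops below start threshold {start}%")
    t_end = _first_crossing_below(t, a, end)
    if t_end is None or t_end < t_start:
        return DrawdownDuration(hours=float(t[-1] - t_start) / 3600.0,
                                censored=True, min_airsat=float(a.min()))
    return DrawdownDuration(hours=(t_end - t_start) / 3600.0,
                            censored=False, min_airsat=float(a.min()))


def normalize_curve(rates: RateSeries, top_decile: float = 0.9) -> HRCurve:
    """Normalize a rate series to dimensionless HRC axes.

    x = pO2/100; y = vo2 / y_ref where y_ref is the mean VO2 over the highest
    decile of observed x (a single-point reference would be too noisy).
    """
    if rates.n < 10:
        raise ParameterError(f"need >= 10 rate points, got {rates.n}")
    span = rates.pO2_mid.max() - rates.pO2_mid.min()
    if span < 50.0:
        raise ParameterError(
            f"rate points span only {span:.1f} %air-sat; need >= 50")
    x = rates.pO2_mid / 100.0
    cut = np.quantile(x, top_decile)
    y_ref = float(np.mean(rates.vo2[x >= cut]))
    if y_ref <= 0:
        raise DataError(
            f"{rates.source_id!r}: non-respiring trace (y_ref {y_ref:g} <= 0)")
    order = np.argsort(x)
    return HRCurve(x=x[order], y=rates.vo2[order] / y_ref, y_ref=y_ref,
                   x_range=(float(x.min()), float(x.max())),
                   source_id=rates.source_id)
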