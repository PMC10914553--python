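"""Synthetic drawdown traces and field logger series with known ground truth.

Every generator is deterministic given its seed, so pipeline stages can be
tested end to end without any external data.  Chamber drawdowns integrate

    dC/dt = -[ VO2(pO2)/v_net + blank_rate ]

with RK4 at the logging cadence, where VO2(pO2) = basal_rate * g(pO2/100)
and g encodes the kinetics: g(x) = x for an oxyconformer, the
endpoint-normalized Michaelis-Menten form (1+K)x/(K+x) for a regulator
(so basal_rate is always the rate at full saturation), or a supplied
origin-constrained polynomial.  Sensor noise is added in % air saturation
(the optode's measurement domain), not concentration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .respirometry import DrawdownTrace, o2_solubility
from .field_oxygen import FieldSeries

CONFORMER = "conformer"
MM = "mm"
POLY = "poly"

MAX_DURATION_H = 12.0


@dataclass
class RegulatorModel:
    """Ground-truth kinetics for a simulated organism."""

    kind: str
    basal_rate: float = 0.35  # mg O2 h-1 at 100% air saturation
    K: float | None = None  # mm only, fraction of air saturation
    coefficients: Sequence[float] | None = None  # poly only, a1..ad

    def __post_init__(self):
        if self.kind not in (CONFORMER, MM, POLY):
            raise ParameterError(f"unknown model kind {self.kind!r}")
        if not self.basal_rate > 0:
            raise ParameterError("basal_rate must be > 0")
        if self.kind == MM and not (self.K is not None and 0 < self.K < 1):
            raise ParameterError("mm model requires K in (0, 1)")
        if self.kind == POLY and not self.coefficients:
            raise ParameterError("poly model requires coefficients")

    def g(self, x):
        """Relative VO2 at pO2 fraction x (g(1) = 1 for conformer and mm)."""
        x = np.asarray(x, dtype=float)
        if self.kind == CONFORMER:
            return x
        if self.kind == MM:
            return (1.0 + self.K) * x / (self.K + x)
        a = np.concatenate([[0.0], np.asarray(self.coefficients, dtype=float)])
        return np.polynomial.polynomial.polyval(x, a)

    def vo2(self, airsat):
        """Absolute consumption rate (mg O2 h-1) at % air saturation."""
        return self.basal_rate * self.g(np.asarray(airsat, dtype=float) / 100.0)


@dataclass
class SimulationConfig:
    chamber_volume: float = 400.0  # mL
    displacement_volume: float = 50.0  # mL
    temperature: float = 27.0  # degC
    salinity: float = 35.0  # ppt
    pressure: float = 1013.0  # mbar
    start_airsat: float = 100.0  # %
    dt: float = 60.0  # s
    noise_sd: float = 0.0  # % air saturation
    blank_noise_sd: float | None = None  # None -> same as noise_sd
    blank_rate: float = 0.0  # mg L-1 h-1, microbial background
    seed: int | None = None

    def __post_init__(self):
        if self.dt <= 0:
            raise ParameterError("dt must be > 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.noise_sd > 0 and self.seed is None:
            raise ParameterError("seed is mandatory for stochastic simulation")

    @property
    def v_net_L(self) -> float:
        return (self.chamber_volume - self.displacement_volume) / 1000.0


def _rk4(f, c, dt_h):
    k1 = f(c)
    k2 = f(c + 0.5 * dt_h * k1)
    k3 = f(c + 0.5 * dt_h * k2)
    k4 = f(c + dt_h * k3)
    return c + dt_h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)


def simulate_drawdown(model: RegulatorModel,
                      config: SimulationConfig,
                      chamber_id: str = "sim",
                      ) -> tuple[DrawdownTrace, DrawdownTrace]:
    """Simulate one sealed-chamber drawdown plus its paired seawater blank.

    Integration stops when the chamber reaches 0% air saturation or after
    12 h.  Returns (trace, blank); the blank integrates only ``blank_rate``
    in a coral-free chamber of the same volume.
    """
    xs = np.linspace(0.01, 1.0, 200)
    if np.any(model.g(xs) < 0):
        raise ParameterError("model yields negative VO2 on (0, 1]")

    c_sat = o2_solubility(config.temperature, config.salinity, config.pressure)
    v_net = config.v_net_L
    dt_h = config.dt / 3600.0
    n_max = int(np.floor(MAX_DURATION_H / dt_h)) + 1

    def dcdt(c):
        x = max(c / c_sat, 0.0)
        return -(model.basal_rate * float(model.g(x)) / v_net
                 + config.blank_rate)

    c = config.start_airsat / 100.0 * c_sat
    conc = [c]
    for _ in range(n_max - 1):
        c = _rk4(dcdt, c, dt_h)
        if c <= c_sat * 1e-6:  # incubation terminated on reaching anoxia
            conc.append(0.0)
            break
        conc.append(c)
    conc = np.asarray(conc)
    t = np.arange(conc.size) * config.dt
    airsat = conc / c_sat * 100.0

    # blank: linear depletion at blank_rate only, same clock
    blank_conc = np.maximum(
        config.start_airsat / 100.0 * c_sat
        - config.blank_rate * np.arange(n_max) * dt_h, 0.0)
    blank_t = np.arange(n_max) * config.dt
    blank_airsat = blank_conc / c_sat * 100.0

    blank_sd = (config.noise_sd if config.blank_noise_sd is None
                else config.blank_noise_sd)
    if config.noise_sd > 0 or blank_sd > 0:
        rng = np.random.default_rng(config.seed)
        airsat = airsat + rng.normal(0.0, config.noise_sd, airsat.size)
        blank_airsat = blank_airsat + rng.normal(0.0, blank_sd,
                                                 blank_airsat.size)
    airsat = np.clip(airsat, -2.0, 120.0)
    blank_airsat = np.clip(blank_airsat, -2.0, 120.0)

    trace = DrawdownTrace(
        chamber_id=chamber_id, timestamps=t, airsat=airsat,
        temperature=config.temperature,
        chamber_volume=config.chamber_volume,
        displacement_volume=config.displacement_volume,
        is_blank=False,
        meta={"ground_truth": model, "c_sat": c_sat},
    )
    blank = DrawdownTrace(
        chamber_id=f"{chamber_id}-blank", timestamps=blank_t,
        airsat=blank_airsat, temperature=config.temperature,
        chamber_volume=config.chamber_volume, displacement_volume=0.0,
        is_blank=True, meta={"blank_rate": config.blank_rate},
    )
    return trace, blank


@dataclass
class ExperimentFixture:
    """Replicated two-group respirometry experiment with known parameters."""

    sample_sheet: pd.DataFrame
    traces: dict[str, DrawdownTrace]
    blanks: dict[str, DrawdownTrace]
    ground_truth: pd.DataFrame


def make_experiment_fixture(n_per_group: int = 6,
                            group_K: tuple[float, float] = (0.10, 0.20),
                            group_basal: tuple[float, float] = (0.35, 0.35),
                            noise_sd: float = 0.3,
                            seed: int = 0,
                            group_labels: tuple[str, str] = ("interior", "exterior"),
                            config: SimulationConfig | None = None,
                            ) -> ExperimentFixture:
    """Generate a two-group set of MM drawdown traces with per-fragment jitter.

    Mirrors the 6-vs-6 designs: each group gets ``n_per_group`` fragments
    with group-specific ground-truth K and basal rate (plus small lognormal
    jitter on the basal rate), one shared noise-free blank per group (a raw
    noisy blank leaks a near-constant rate offset into every corrected curve,
    which an origin-constrained model family misreads as regulation).
    """
    if n_per_group < 2:
        raise ParameterError("n_per_group must be >= 2")
    base = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    rows, truth_rows = [], []
    traces: dict[str, DrawdownTrace] = {}
    blanks: dict[str, DrawdownTrace] = {}

    for gi, label in enumerate(group_labels):
        k_true, basal_true = group_K[gi], group_basal[gi]
        for rep in range(n_per_group):
            cid = f"{label}-{rep + 1}"
            basal = basal_true * float(np.exp(rng.normal(0.0, 0.05)))
            model = RegulatorModel(kind=MM, basal_rate=basal, K=k_true)
            cfg = SimulationConfig(
                chamber_volume=base.chamber_volume,
                displacement_volume=base.displacement_volume,
                temperature=base.temperature, salinity=base.salinity,
                pressure=base.pressure, start_airsat=base.start_airsat,
                dt=base.dt, noise_sd=noise_sd, blank_noise_sd=0.0,
                blank_rate=base.blank_rate,
                seed=int(rng.integers(0, 2 ** 31)) if noise_sd > 0 else None,
            )
            trace, blank = simulate_drawdown(model, cfg, chamber_id=cid)
            traces[cid] = trace
            if label not in blanks:
                blanks[label] = blank
            rows.append({"chamber_id": cid, "group": label,
                         "chamber_volume": cfg.chamber_volume,
                         "displacement_volume": cfg.displacement_volume,
                         "blank_id": f"{label}-blank"})
            truth_rows.append({"chamber_id": cid, "group": label,
                               "K": k_true, "basal_rate": basal})
    return ExperimentFixture(
        sample_sheet=pd.DataFrame(rows),
        traces=traces,
        blanks={f"{label}-blank": b for label, b in blanks.items()},
        ground_truth=pd.DataFrame(truth_rows),
    )


def simulate_field_series(mean_do: float = 7.0,
                          diel_amplitude: float = 1.5,
                          tidal_amplitude: float = 0.4,
                          interior_pct_offset: float = 10.0,
                          noise_sd: float = 0.05,
                          days: int = 3,
                          seed: int = 0,
                          colony_id: str = "colony-1",
                          start: str = "2022-02-05",
                          ) -> tuple[FieldSeries, FieldSeries]:
    """Paired interior/exterior diel-cycling DO series at 60-s cadence.

    Exterior = mean + 24-h sinusoid (peak mid-afternoon) + 12.42-h tidal
    sinusoid + noise; interior = the noiseless exterior scaled by
    (1 - offset/100) plus independent noise.  Returns (interior, exterior).
    """
    if days < 1:
        raise ParameterError("days must be >= 1")
    rng = np.random.default_rng(seed)
    n = int(days * 24 * 60)
    t0 = pd.Timestamp(start)
    ts = pd.DatetimeIndex(t0 + pd.to_timedelta(np.arange(n), unit="min"))
    hours = np.arange(n) / 60.0
    hour_of_day = (ts - ts.normalize()).total_seconds().to_numpy() / 3600.0

    clean_ext = (mean_do
                 + diel_amplitude * np.cos(2 * np.pi * (hour_of_day - 15.0) / 24.0)
                 + tidal_amplitude * np.sin(2 * np.pi * hours / 12.42))
    ext = clean_ext + (rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0)
    inte = (clean_ext * (1.0 - interior_pct_offset / 100.0)
            + (rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0))
    temp = 29.0 + 0.6 * np.cos(2 * np.pi * (hour_of_day - 15.0) / 24.0)

    interior = FieldSeries(timestamps=ts, do_mgL=np.clip(inte, 0.0, 20.0),
                           temperature=temp, position="interior",
                           colony_id=colony_id,
                           meta={"interior_pct_offset": interior_pct_offset})
    exterior = FieldSeries(timestamps=ts, do_mgL=np.clip(ext, 0.0, 20.0),
                           temperature=temp, position="exterior",
                           colony_id=colony_id, meta={})
    return interior, exterior
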