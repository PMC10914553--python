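"""Shared fixtures: hand-built traces and simulated experiment material."""

import numpy as np
import pytest

from oxyreg.hrc_models import FitResult, ModelSpec, LINEAR, MICHAELIS_MENTEN
from oxyreg.respirometry import DrawdownTrace, HRCurve, RateSeries
from oxyreg.synthetic_data import RegulatorModel, SimulationConfig, simulate_drawdown


def make_linear_trace(duration_h=4.0, dt=60.0, start=100.0, end=0.0,
                      temperature=27.0, chamber_volume=400.0,
                      displacement_volume=50.0, chamber_id="lin"):
    """Trace whose air saturation declines exactly linearly in time."""
    n = int(duration_h * 3600 / dt) + 1
    t = np.arange(n) * dt
    airsat = start + (end - start) * t / t[-1]
    return DrawdownTrace(chamber_id=chamber_id, timestamps=t, airsat=airsat,
                         temperature=temperature,
                         chamber_volume=chamber_volume,
                         displacement_volume=displacement_volume)


def make_constant_blank(duration_h=4.0, dt=60.0, level=100.0,
                        temperature=27.0, chamber_volume=400.0):
    n = int(duration_h * 3600 / dt) + 1
    t = np.arange(n) * dt
    return DrawdownTrace(chamber_id="blank", timestamps=t,
                         airsat=np.full(n, level), temperature=temperature,
                         chamber_volume=chamber_volume,
                         displacement_volume=0.0, is_blank=True)


def mm_fit(vmax=1.0, k=0.25, x_range=(0.02, 0.98)):
    """Hand-built Michaelis-Menten FitResult with exact analytic f and f'."""
    return FitResult(
        spec=ModelSpec(MICHAELIS_MENTEN),
        params=np.array([vmax, k]), rss=0.0, aic=-np.inf, n=0, p_free=2,
        x_range=x_range,
        _f=lambda t, v=vmax, kk=k: v * np.asarray(t, float) / (kk + np.asarray(t, float)),
        _fprime=lambda t, v=vmax, kk=k: v * kk / (kk + np.asarray(t, float)) ** 2,
    )


def linear_fit(m=1.0, x_range=(0.02, 0.98)):
    return FitResult(
        spec=ModelSpec(LINEAR), params=np.array([m]), rss=0.0, aic=-np.inf,
        n=0, p_free=1, x_range=x_range,
        _f=lambda t, mm=m: mm * np.asarray(t, float),
        _fprime=lambda t, mm=m: np.full_like(np.asarray(t, float), mm),
    )


class FunctionFit:
    """Ad-hoc fit object from callables, for oracle-style rho checks."""

    def __init__(self, f, fprime, x_range=(0.02, 0.98)):
        self._f, self._fprime = f, fprime
        self.x_range = x_range

    def f(self, x):
        return self._f(np.asarray(x, dtype=float))

    def fprime(self, x):
        return self._fprime(np.asarray(x, dtype=float))


def make_curve_from_function(func, n=80, x_lo=0.02, x_hi=0.98, source_id="fn"):
    """HRCurve sampled noiselessly from y = func(x)."""
    x = np.linspace(x_lo, x_hi, n)
    y = func(x)
    return HRCurve(x=x, y=y, y_ref=1.0, x_range=(x_lo, x_hi),
                   source_id=source_id)


def make_rates(pO2, vo2, v_net=0.35, source_id="rates"):
    pO2 = np.asarray(pO2, dtype=float)
    spans = np.column_stack([np.arange(pO2.size) * 300.0,
                             np.arange(pO2.size) * 300.0 + 600.0])
    return RateSeries(pO2_mid=pO2, vo2=np.asarray(vo2, dtype=float),
                      window_spans=spans, v_net_L=v_net, source_id=source_id)


@pytest.fixture
def linear_trace():
    return make_linear_trace()


@pytest.fixture
def constant_blank():
    return make_constant_blank()


@pytest.fixture(scope="session")
def mm_sim_noiseless():
    """One noiseless MM drawdown (K = 0.15) plus its blank; shared (read-only)."""
    model = RegulatorModel(kind="mm", basal_rate=0.35, K=0.15)
    cfg = SimulationConfig(noise_sd=0.0)
    return simulate_drawdown(model, cfg, chamber_id="mm-015")
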