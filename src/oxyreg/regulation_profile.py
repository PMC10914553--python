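"""Regulation function and oxyregulation statistics.

The local regulation index of a fitted HRC model f is

    rho(x) = f(x)/x - f'(x)

which is identically zero for strict oxyconformity (f(x) = m*x) and positive
wherever respiration is held above the conformity chord.  From rho evaluated
over a pO2 window we extract:

* ``t_pos`` — the integral of the positive part of rho (total positive
  regulation, relative units); ``t_neg`` is the analogous diagnostic for the
  negative part;
* ``p_cmax`` / ``p_cmin`` — the pO2 (% air saturation) at which rho is
  maximal / minimal, i.e. where regulation effort peaks / vanishes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import ParameterError, SingularityError

#: default low-pO2 floor for the evaluation window; avoids the f/x
#: singularity and mirrors the <2% air-sat termination of the drawdowns
DEFAULT_FLOOR = 0.02
DEFAULT_GRID_N = 1000

TPOS_INTEGRAL = "integral"
TPOS_RANGE_MEAN = "range_mean"

_CONST_TOL = 1e-12


@dataclass
class RegulationProfile:
    grid_x: np.ndarray
    rho: np.ndarray
    t_pos: float
    t_neg: float
    p_cmax: float | None  # % air saturation; None when rho is constant
    p_cmin: float | None
    x_window: tuple[float, float]
    source_id: str = ""


def rho(fit, x):
    """Evaluate rho(x) = f(x)/x - f'(x) analytically.

    ``fit`` is anything exposing ``f`` and ``fprime`` (e.g. a
    :class:`~oxyreg.hrc_models.FitResult`).  At x = 0 the limit is used,
    which is 0 for any origin-constrained model; a model with f(0) != 0 is
    singular there.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if np.any(x < 0) or np.any(x > 1.2):
        raise ParameterError("x outside [0, 1.2]")
    out = np.empty_like(x)
    zero = x == 0.0
    if np.any(zero):
        f0 = float(np.atleast_1d(fit.f(0.0))[0])
        if abs(f0) > 1e-12:
            raise SingularityError(f"rho undefined at x=0: f(0) = {f0:g} != 0")
        out[zero] = 0.0
    nz = ~zero
    if np.any(nz):
        xs = x[nz]
        out[nz] = np.atleast_1d(fit.f(xs)) / xs - np.atleast_1d(fit.fprime(xs))
    return float(out[0]) if scalar else out


def _refine(fit, grid, i, sign):
    """Sharpen a grid arg-extremum of rho by bounded scalar optimization."""
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid.size - 1)]
    if hi <= lo:
        return float(grid[i])
    res = minimize_scalar(lambda t: -sign * rho(fit, float(t)),
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    return float(res.x) if res.success else float(grid[i])


def profile(fit, x_window: tuple[float, float] | None = None,
            grid_n: int = DEFAULT_GRID_N, floor: float = DEFAULT_FLOOR,
            tpos_mode: str = TPOS_INTEGRAL,
            source_id: str = "") -> RegulationProfile:
    """Regulation profile of a fitted model over a pO2 window.

    The default window is [max(floor, observed x_min), min(1, observed
    x_max)].  t_pos/t_neg are trapezoidal integrals of the positive/negative
    parts of rho; with ``tpos_mode='range_mean'`` they are divided by the
    window width.  p_cmax/p_cmin are grid arg-extrema refined by bounded
    scalar optimization; ties for the minimum resolve to the larger x, and a
    constant rho (within 1e-12) leaves both undefined (None).
    """
    if grid_n < 200:
        raise ParameterError(f"grid_n must be >= 200, got {grid_n}")
    if tpos_mode not in (TPOS_INTEGRAL, TPOS_RANGE_MEAN):
        raise ParameterError(f"unknown tpos_mode {tpos_mode!r}")
    x_obs = getattr(fit, "x_range", (floor, 1.0))
    if x_window is None:
        x_window = (max(floor, x_obs[0]), min(1.0, x_obs[1]))
    x_lo, x_hi = float(x_window[0]), float(x_window[1])
    if x_lo >= x_hi:
        raise ParameterError(f"empty window [{x_lo}, {x_hi}]")

    grid = np.linspace(x_lo, x_hi, grid_n)
    r = rho(fit, grid)

    t_pos = float(np.trapezoid(np.clip(r, 0.0, None), grid))
    t_neg = float(np.trapezoid(np.clip(r, None, 0.0), grid))
    if tpos_mode == TPOS_RANGE_MEAN:
        t_pos /= (x_hi - x_lo)
        t_neg /= (x_hi - x_lo)

    if float(r.max() - r.min()) < _CONST_TOL:
        p_cmax = p_cmin = None
    else:
        i_max = int(np.argmax(r))
        # last occurrence of the minimum: report the larger x on ties
        i_min = r.size - 1 - int(np.argmin(r[::-1]))
        p_cmax = 100.0 * _refine(fit, grid, i_max, sign=+1)
        p_cmin = 100.0 * _refine(fit, grid, i_min, sign=-1)

    return RegulationProfile(grid_x=grid, rho=r, t_pos=t_pos, t_neg=t_neg,
                             p_cmax=p_cmax, p_cmin=p_cmin,
                             x_window=(x_lo, x_hi), source_id=source_id)


STATS = ("t_pos", "p_cmax", "p_cmin")


@dataclass
class StatSummary:
    mean: float | None
    se: float | None
    n: int
    n_undefined: int


def replicate_summary(profiles: Sequence[RegulationProfile]) -> dict[str, StatSummary]:
    """Mean and standard error (sd/sqrt(n)) per statistic across replicates.

    Undefined entries (constant-rho profiles) are excluded with a recorded
    count; a statistic undefined in every replicate yields a None summary
    with a warning.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ParameterError(f"need >= 2 profiles, got {len(profiles)}")
    out = {}
    for stat in STATS:
        vals = [getattr(p, stat) for p in profiles]
        defined = np.array([v for v in vals if v is not None], dtype=float)
        n_undef = len(vals) - defined.size
        if defined.size == 0:
            warnings.warn(f"{stat}: undefined in all replicates", stacklevel=2)
            out[stat] = StatSummary(None, None, 0, n_undef)
            continue
        mean = float(defined.mean())
        se = float(defined.std(ddof=1) / np.sqrt(defined.size)) \
            if defined.size > 1 else 0.0
        out[stat] = StatSummary(mean, se, int(defined.size), n_undef)
    return out
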