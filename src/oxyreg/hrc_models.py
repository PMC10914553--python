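"""Hypoxia-response-curve model family and AIC-based selection.

Three model kinds are fitted to normalized HRC data (x = pO2 fraction,
y = relative VO2), all constrained through the origin:

* ``linear`` — y = m*x, the strict-oxyconformity line (1 free parameter);
* ``constrained_poly`` — y = sum_{j=1..d} a_j x^j, no intercept (d free
  parameters), solved in a scaled Legendre basis for conditioning and
  reported as raw power coefficients;
* ``michaelis_menten`` — y = Vmax*x/(K+x), 2 free parameters, nonlinear
  least squares.

Fits are ranked by a Gaussian-likelihood AIC in which the residual variance
counts as a parameter (convention configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
from numpy.polynomial import Legendre, Polynomial
from scipy.optimize import curve_fit

from .errors import FitError, ParameterError
from .respirometry import HRCurve

LINEAR = "linear"
CONSTRAINED_POLY = "constrained_poly"
MICHAELIS_MENTEN = "michaelis_menten"

_KIND_ORDER = {LINEAR: 0, MICHAELIS_MENTEN: 1, CONSTRAINED_POLY: 2}

#: default candidate set: conformity line, MM, even-degree polynomials
DEFAULT_DEGREES = (2, 4, 6, 8, 10, 12)

AIC_GAUSSIAN_PLUS_SIGMA = "gaussian_plus_sigma"
AIC_GAUSSIAN_FIXED_SIGMA = "gaussian_fixed_sigma"


@dataclass(frozen=True)
class ModelSpec:
    kind: str
    degree: int | None = None

    def __post_init__(self):
        if self.kind not in _KIND_ORDER:
            raise ParameterError(f"unknown model kind {self.kind!r}")
        if self.kind == CONSTRAINED_POLY:
            if self.degree is None or not (2 <= self.degree <= 12):
                raise ParameterError(
                    f"constrained_poly needs degree in [2, 12], got {self.degree}")
        elif self.degree is not None:
            raise ParameterError(f"degree is only valid for constrained_poly")

    @property
    def p_free(self) -> int:
        if self.kind == LINEAR:
            return 1
        if self.kind == MICHAELIS_MENTEN:
            return 2
        return int(self.degree)

    @property
    def label(self) -> str:
        if self.kind == CONSTRAINED_POLY:
            return f"poly:{self.degree}"
        return {LINEAR: "linear", MICHAELIS_MENTEN: "mm"}[self.kind]


def default_candidates(degrees: Sequence[int] = DEFAULT_DEGREES) -> list[ModelSpec]:
    specs = [ModelSpec(LINEAR), ModelSpec(MICHAELIS_MENTEN)]
    specs += [ModelSpec(CONSTRAINED_POLY, d) for d in degrees]
    return specs


@dataclass
class FitResult:
    """A fitted HRC model exposing analytic f(x) and f'(x)."""

    spec: ModelSpec
    params: np.ndarray
    rss: float
    aic: float
    n: int
    p_free: int
    x_range: tuple[float, float]
    _f: Callable = field(repr=False, default=None)
    _fprime: Callable = field(repr=False, default=None)

    def f(self, x):
        return self._f(np.asarray(x, dtype=float))

    def fprime(self, x):
        return self._fprime(np.asarray(x, dtype=float))


def aic_value(n: int, rss: float, p_free: int,
              convention: str = AIC_GAUSSIAN_PLUS_SIGMA) -> float:
    """Gaussian-likelihood AIC.

    ``gaussian_plus_sigma`` counts the residual variance as an extra
    parameter: AIC = n*ln(2*pi*rss/n) + n + 2*(p_free + 1); the
    ``gaussian_fixed_sigma`` variant drops the +1.  A perfect interpolation
    (rss = 0) returns -inf with a warning.
    """
    if rss < 0:
        raise ParameterError("rss must be >= 0")
    if rss == 0.0:
        warnings.warn("rss = 0: perfect interpolation, AIC is -inf", stacklevel=2)
        return -np.inf
    k = p_free + 1 if convention == AIC_GAUSSIAN_PLUS_SIGMA else p_free
    if convention not in (AIC_GAUSSIAN_PLUS_SIGMA, AIC_GAUSSIAN_FIXED_SIGMA):
        raise ParameterError(f"unknown AIC convention {convention!r}")
    return float(n * np.log(2.0 * np.pi * rss / n) + n + 2.0 * k)


def aic(fit: FitResult, convention: str = AIC_GAUSSIAN_PLUS_SIGMA) -> float:
    return aic_value(fit.n, fit.rss, fit.p_free, convention)


def _fit_linear(x, y):
    m = float(np.dot(x, y) / np.dot(x, x))
    resid = y - m * x
    return np.array([m]), float(np.dot(resid, resid)), \
        (lambda t, m=m: m * t), (lambda t, m=m: np.full_like(t, m, dtype=float))


def _fit_constrained_poly(x, y, degree):
    # basis psi_k(x) = x * L_k(u(x)), u affine onto [-1, 1]: spans
    # {x, ..., x^degree} with no constant term and stays well-conditioned
    # up to degree 12.
    lo, hi = float(x.min()), float(x.max())
    design = np.empty((x.size, degree))
    basis_polys = []
    for k in range(degree):
        coef = np.zeros(k + 1)
        coef[k] = 1.0
        leg = Legendre(coef, domain=[lo, hi])
        pk = leg.convert(kind=Polynomial)  # power series in raw x
        psi = Polynomial(np.concatenate([[0.0], pk.coef]))  # multiply by x
        basis_polys.append(psi)
        design[:, k] = psi(x)
    sol, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    if rank < degree:
        raise FitError(f"rank-deficient design for degree {degree} "
                       f"(rank {rank})", {"degree": degree, "rank": int(rank)})
    poly = Polynomial([0.0])
    for c, psi in zip(sol, basis_polys):
        poly = poly + c * psi
    coefs = np.zeros(degree + 1)
    coefs[:poly.coef.size] = poly.coef
    coefs[0] = 0.0  # exact origin constraint
    poly = Polynomial(coefs)
    dpoly = poly.deriv()
    resid = y - design @ sol
    return coefs[1:], float(np.dot(resid, resid)), \
        (lambda t, p=poly: p(t)), (lambda t, d=dpoly: d(t))


def _mm(x, vmax, k):
    return vmax * x / (k + x)


def _fit_mm(x, y):
    vmax0 = float(np.max(y))
    if vmax0 <= 0:
        raise FitError("cannot fit Michaelis-Menten: all y <= 0")
    half = np.nonzero(y >= vmax0 / 2.0)[0]
    k0 = float(x[half[0]]) if half.size else float(np.median(x))
    k0 = min(max(k0, 1.01e-4), 9.9)
    last_err = None
    for mult in (1.0, 0.1, 10.0, 1.0):
        start = (min(vmax0, 9.9), min(max(k0 * mult, 1.01e-4), 9.9))
        try:
            popt, _ = curve_fit(_mm, x, y, p0=start,
                                bounds=([1e-12, 1e-4], [10.0, 10.0]),
                                maxfev=20000, xtol=1e-12, ftol=1e-12)
            vmax, k = float(popt[0]), float(popt[1])
            resid = y - _mm(x, vmax, k)
            rss = float(np.dot(resid, resid))
            return np.array([vmax, k]), rss, \
                (lambda t, v=vmax, kk=k: v * t / (kk + t)), \
                (lambda t, v=vmax, kk=k: v * kk / (kk + t) ** 2)
        except (RuntimeError, ValueError) as exc:  # pragma: no cover - rare
            last_err = exc
    raise FitError(f"Michaelis-Menten fit failed to converge: {last_err}",
                   {"starts_tried": 4, "k0": k0})


def fit_model(curve: HRCurve, spec: ModelSpec,
              aic_convention: str = AIC_GAUSSIAN_PLUS_SIGMA) -> FitResult:
    """Least-squares fit of one model spec to a normalized curve."""
    x, y = curve.x, curve.y
    n = x.size
    if spec.kind == CONSTRAINED_POLY and n <= spec.degree + 2:
        raise ParameterError(
            f"need n > degree + 2 points for degree {spec.degree}, got {n}")
    if spec.kind == LINEAR:
        params, rss, f, fp = _fit_linear(x, y)
    elif spec.kind == CONSTRAINED_POLY:
        params, rss, f, fp = _fit_constrained_poly(x, y, spec.degree)
    else:
        params, rss, f, fp = _fit_mm(x, y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a = aic_value(n, rss, spec.p_free, aic_convention)
    return FitResult(spec=spec, params=params, rss=rss, aic=a, n=n,
                     p_free=spec.p_free,
                     x_range=(float(x.min()), float(x.max())),
                     _f=f, _fprime=fp)


@dataclass
class SelectionResult:
    """AIC ranking plus the candidates that failed to fit."""

    ranked: list[FitResult]
    failures: list[tuple[ModelSpec, str]]

    @property
    def best(self) -> FitResult:
        return self.ranked[0]


def select_best(curve: HRCurve, candidates: Iterable[ModelSpec],
                aic_convention: str = AIC_GAUSSIAN_PLUS_SIGMA) -> SelectionResult:
    """Fit all candidates and rank ascending by AIC.

    Ties break towards fewer free parameters, then by kind order
    (linear < MM < poly).  Failed candidates are reported with reasons but
    never ranked.
    """
    candidates = list(candidates)
    if not candidates:
        raise ParameterError("empty candidate list")
    fits, failures = [], []
    for spec in candidates:
        try:
            fits.append(fit_model(curve, spec, aic_convention))
        except (FitError, ParameterError) as exc:
            failures.append((spec, str(exc)))
    if not fits:
        raise FitError("all candidate models failed",
                       {spec.label: msg for spec, msg in failures})
    fits.sort(key=lambda r: (r.aic, r.p_free, _KIND_ORDER[r.spec.kind]))
    return SelectionResult(ranked=fits, failures=failures)
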