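"""Group comparisons: two-sample t-tests, Pearson correlation, assumption checks.

The default t method is the pooled-variance independent-samples test
(df = n_a + n_b - 2); Welch and a paired variant are available by flag.
Shapiro-Wilk and Levene (median-centred) checks are advisory only and never
gate the t-test.  No multiple-testing correction is applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .errors import DataError, ParameterError

POOLED = "pooled"
WELCH = "welch"
PAIRED = "paired"


@dataclass
class GroupComparison:
    statistic: str  # "t" or "r"
    value: float
    df: float
    p: float
    estimate_a: tuple[float, float] | None = None  # (mean, se)
    estimate_b: tuple[float, float] | None = None
    n_a: int = 0
    n_b: int = 0
    extra: dict = field(default_factory=dict)


def _as_sample(v, name, min_n):
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise ParameterError(f"{name} must be 1-D")
    if not np.all(np.isfinite(arr)):
        raise ParameterError(f"{name} contains non-finite values")
    if arr.size < min_n:
        raise ParameterError(f"{name} needs >= {min_n} values, got {arr.size}")
    return arr


def _mean_se(a):
    se = float(a.std(ddof=1) / math.sqrt(a.size)) if a.size > 1 else 0.0
    return (float(a.mean()), se)


def two_sample_t(a, b, method: str = POOLED) -> GroupComparison:
    """Two-sample t-test.

    ``pooled``: t = (mean_a - mean_b)/sqrt(s_p^2 (1/n_a + 1/n_b)) with
    df = n_a + n_b - 2.  ``welch``: Welch-Satterthwaite df.  ``paired``:
    one-sample t on the differences (equal n required, df = n - 1).
    Zero variance with equal means gives t = 0, p = 1; with unequal means an
    infinite-t sentinel with p = 0.
    """
    a = _as_sample(a, "a", 2)
    b = _as_sample(b, "b", 2)
    na, nb = a.size, b.size
    if method == PAIRED:
        if na != nb:
            raise ParameterError(f"paired test needs equal n, got {na} vs {nb}")
        d = a - b
        df = na - 1
        sd = d.std(ddof=1)
        if sd == 0.0:
            t = 0.0 if d.mean() == 0 else math.copysign(math.inf, d.mean())
        else:
            t = float(d.mean() / (sd / math.sqrt(na)))
    elif method == POOLED:
        df = na + nb - 2
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / df
        num = a.mean() - b.mean()
        if sp2 == 0.0:
            t = 0.0 if num == 0 else math.copysign(math.inf, num)
        else:
            t = float(num / math.sqrt(sp2 * (1.0 / na + 1.0 / nb)))
    elif method == WELCH:
        va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
        num = a.mean() - b.mean()
        if va + vb == 0.0:
            t = 0.0 if num == 0 else math.copysign(math.inf, num)
            df = na + nb - 2
        else:
            t = float(num / math.sqrt(va + vb))
            df = (va + vb) ** 2 / (va ** 2 / (na - 1) + vb ** 2 / (nb - 1))
    else:
        raise ParameterError(f"unknown t-test method {method!r}")

    if math.isinf(t):
        p = 0.0
    elif t == 0.0:
        p = 1.0
    else:
        p = float(2.0 * sps.t.sf(abs(t), df))
    return GroupComparison(statistic="t", value=t, df=float(df), p=p,
                           estimate_a=_mean_se(a), estimate_b=_mean_se(b),
                           n_a=na, n_b=nb, extra={"method": method})


def pearson(x, y) -> GroupComparison:
    """Pearson correlation with R^2 and a two-sided p at df = n - 2."""
    x = _as_sample(x, "x", 3)
    y = _as_sample(y, "y", 3)
    if x.size != y.size:
        raise ParameterError(f"paired samples differ in length: {x.size} vs {y.size}")
    if x.std() == 0.0 or y.std() == 0.0:
        raise DataError("correlation undefined: zero variance in x or y")
    res = sps.pearsonr(x, y)
    r = float(res.statistic)
    return GroupComparison(statistic="r", value=r, df=float(x.size - 2),
                           p=float(res.pvalue), n_a=x.size, n_b=y.size,
                           extra={"r2": r * r})


def assumption_checks(a, b) -> dict:
    """Advisory Shapiro-Wilk (per group) and median-centred Levene checks.

    Groups with n < 3 or zero variance get a flag instead of a W statistic.
    """
    out: dict = {}
    for name, grp in (("a", np.asarray(a, dtype=float)),
                      ("b", np.asarray(b, dtype=float))):
        if grp.size < 3:
            out[f"shapiro_{name}"] = {"skipped": "n < 3"}
        elif grp.std() == 0.0:
            out[f"shapiro_{name}"] = {"skipped": "constant group"}
        else:
            w, p = sps.shapiro(grp)
            out[f"shapiro_{name}"] = {"w": float(w), "p": float(p)}
    try:
        f, p = sps.levene(np.asarray(a, float), np.asarray(b, float),
                          center="median")
        out["levene"] = {"f": float(f), "p": float(p)}
    except ValueError as exc:
        out["levene"] = {"skipped": str(exc)}
    return out
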