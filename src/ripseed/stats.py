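"""Unequal-variance t-tests and correlation measures.

The statistical kernel is deliberately small: Welch's t-test (the
"Student's t-test assuming unequal variance" used for every group
comparison downstream), a paired t-test, and Pearson/Spearman correlation.
Statistics and degrees of freedom are computed from their closed forms
here; only the t-distribution CDF is taken from scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as _sps

from .errors import InsufficientDataError, RipseedError

TWO_SIDED = "two_sided"
A_GREATER = "a_greater"
B_GREATER = "b_greater"
_ALTERNATIVES = (TWO_SIDED, A_GREATER, B_GREATER)


@dataclass(frozen=True)
class GroupComparison:
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    t: float
    df: float
    p: float
    alternative: str
    degenerate: bool = False


def _clean(x, label) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    arr = arr[np.isfinite(arr)]
    if arr.size < 2:
        raise InsufficientDataError(
            f"group {label!r} has {arr.size} finite values; need >= 2"
        )
    return arr


def _p_from_t(t: float, df: float, alternative: str) -> float:
    if alternative == TWO_SIDED:
        return 2.0 * _sps.t.sf(abs(t), df)
    if alternative == A_GREATER:
        return float(_sps.t.sf(t, df))
    if alternative == B_GREATER:
        return float(_sps.t.cdf(t, df))
    raise RipseedError(f"unknown alternative {alternative!r}")


def _degenerate_p(t: float, alternative: str) -> float:
    # limit of the t-CDF as |t| -> inf (or the t=0 point mass)
    if t == 0.0:
        return 1.0 if alternative == TWO_SIDED else 0.5
    if alternative == TWO_SIDED:
        return 0.0
    if alternative == A_GREATER:
        return 0.0 if t > 0 else 1.0
    return 0.0 if t < 0 else 1.0


def welch_t_test(a, b, alternative: str = TWO_SIDED) -> GroupComparison:
    """Welch's unequal-variance t-test.

    t = (mean_a - mean_b) / sqrt(s2_a/n_a + s2_b/n_b) with
    Welch-Satterthwaite degrees of freedom.  Zero pooled variance is
    handled deterministically: t = 0 (equal means) or +/-inf, flagged
    ``degenerate``, with p the corresponding limit.
    """
    if alternative not in _ALTERNATIVES:
        raise RipseedError(f"unknown alternative {alternative!r}")
    xa, xb = _clean(a, "a"), _clean(b, "b")
    na, nb = xa.size, xb.size
    ma, mb = float(xa.mean()), float(xb.mean())
    va, vb = float(xa.var(ddof=1)), float(xb.var(ddof=1))
    sa, sb = va / na, vb / nb
    if sa + sb == 0.0:
        t = 0.0 if ma == mb else math.copysign(math.inf, ma - mb)
        return GroupComparison(
            na, nb, ma, mb, t, float("nan"),
            _degenerate_p(t, alternative), alternative, degenerate=True,
        )
    t = (ma - mb) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (na - 1) + sb**2 / (nb - 1))
    return GroupComparison(na, nb, ma, mb, t, df, _p_from_t(t, df, alternative),
                           alternative)


def paired_t_test(a, b, alternative: str = TWO_SIDED) -> GroupComparison:
    """Paired t-test on per-pair differences a_i - b_i."""
    if alternative not in _ALTERNATIVES:
        raise RipseedError(f"unknown alternative {alternative!r}")
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.shape != xb.shape:
        raise RipseedError("paired samples must have equal length")
    keep = np.isfinite(xa) & np.isfinite(xb)
    xa, xb = xa[keep], xb[keep]
    n = xa.size
    if n < 2:
        raise InsufficientDataError(f"{n} finite pairs; need >= 2")
    d = xa - xb
    sd = float(d.std(ddof=1))
    md = float(d.mean())
    if sd == 0.0:
        t = 0.0 if md == 0.0 else math.copysign(math.inf, md)
        return GroupComparison(
            n, n, float(xa.mean()), float(xb.mean()), t, float("nan"),
            _degenerate_p(t, alternative), alternative, degenerate=True,
        )
    t = md / (sd / math.sqrt(n))
    df = n - 1
    return GroupComparison(n, n, float(xa.mean()), float(xb.mean()), t, df,
                           _p_from_t(t, df, alternative), alternative)


def pearson_correlation(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise RipseedError("x and y must be 1-D of equal length")
    if xa.size < 2:
        raise InsufficientDataError("need >= 2 observations")
    dx = xa - xa.mean()
    dy = ya - ya.mean()
    sx = float(np.sqrt((dx * dx).sum()))
    sy = float(np.sqrt((dy * dy).sum()))
    if sx == 0.0 or sy == 0.0:
        raise RipseedError("correlation undefined: an argument has zero variance")
    r = float((dx * dy).sum() / (sx * sy))
    return max(-1.0, min(1.0, r))


def spearman_correlation(x, y) -> float:
    """Spearman rank correlation: Pearson on average-ranked data."""
    rx = _sps.rankdata(np.asarray(x, dtype=float), method="average")
    ry = _sps.rankdata(np.asarray(y, dtype=float), method="average")
    return pearson_correlation(rx, ry)
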