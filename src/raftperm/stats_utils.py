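"""Correlation analysis with Fisher z-transform confidence intervals.

The Fisher transform ``z = atanh(r)`` maps a correlation coefficient to an
approximately normal variable with standard error ``1/sqrt(n - 3)``; intervals
are built on the z scale and mapped back with ``tanh``.  Spearman intervals
use the same plain transform by default; the variance-inflated variants
(1.03 or 1.06 over ``sqrt(n - 3)``) can be requested explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

__all__ = ["CorrelationResult", "correlation_with_ci", "ci_from_r_n"]

#: multiplicative standard-error inflation options for rank correlations
_SE_INFLATION = {"none": 1.0, "fieller": 1.06, "bonett": 1.03}


@dataclass(frozen=True)
class CorrelationResult:
    """A correlation coefficient with its Fisher confidence interval."""

    r: float
    method: str
    n: int
    ci_low: float
    ci_high: float
    level: float
    p_value: float
    degenerate: bool = False  # |r| == 1: CI undefined, bounds set to r


def _fisher_interval(r: float, n: int, level: float, inflation: float = 1.0):
    z = np.arctanh(r)
    se = inflation / np.sqrt(n - 3)
    zcrit = _st.norm.ppf(0.5 + level / 2.0)
    return float(np.tanh(z - zcrit * se)), float(np.tanh(z + zcrit * se))


def ci_from_r_n(
    r: float,
    n: int,
    level: float = 0.95,
    se_inflation: str = "none",
) -> tuple[float, float]:
    """Fisher z-transform confidence interval from a published ``(r, n)`` pair.

    Parameters
    ----------
    r
        Correlation coefficient, ``|r| < 1``.
    n
        Number of paired observations, at least 4.
    level
        Two-sided confidence level in ``[0, 1)``.
    se_inflation
        ``"none"`` (default), ``"bonett"`` (1.03) or ``"fieller"`` (1.06)
        standard-error inflation for rank correlations.

    Returns
    -------
    (ci_low, ci_high)
        Interval bounds, each in ``(-1, 1)``.
    """
    if not np.isfinite(r) or abs(r) >= 1:
        raise ValueError(f"|r| must be < 1 for a Fisher interval, got r={r}")
    if n < 4:
        raise ValueError(f"Fisher interval needs n >= 4, got n={n}")
    if not 0 <= level < 1:
        raise ValueError(f"confidence level must be in [0, 1), got {level}")
    return _fisher_interval(r, n, level, _SE_INFLATION[se_inflation])


def correlation_with_ci(
    x,
    y,
    method: str = "pearson",
    level: float = 0.95,
    se_inflation: str = "none",
) -> CorrelationResult:
    """Correlation of two sequences with a Fisher z-transform interval.

    Spearman uses mid-ranks for ties.  A perfectly linear (or, for Spearman,
    perfectly monotone) relationship yields ``|r| = 1``; the interval is then
    degenerate and the result is flagged instead of raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    n = x.size
    if n < 4:
        raise ValueError(f"need at least 4 pairs, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant sequence")

    if method == "pearson":
        r, p = _st.pearsonr(x, y)
    elif method == "spearman":
        res = _st.spearmanr(x, y)
        r, p = res.statistic, res.pvalue
    else:
        raise ValueError(f"unknown method {method!r}")

    r = float(r)
    if abs(r) >= 1.0 - 1e-15:
        r = float(np.sign(r))
        return CorrelationResult(
            r=r, method=method, n=n, ci_low=r, ci_high=r, level=level,
            p_value=float(p), degenerate=True,
        )
    lo, hi = _fisher_interval(r, n, level, _SE_INFLATION[se_inflation])
    return CorrelationResult(
        r=r, method=method, n=n, ci_low=lo, ci_high=hi, level=level,
        p_value=float(p),
    )
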