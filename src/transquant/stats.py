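"""One-tailed t-test conventions shared by the assay modules.

Three conventions are used throughout the figure-level summaries:

* Welch's unequal-variance t test when the two arms have unequal numbers of
  repeats (or unequal variances cannot be excluded),
* a paired Student's t test when repeats come in matched pairs,
* a ratio paired t test for values expressed relative to a control that was
  set to 1: values are log-transformed and tested against 0.

Every test is one-tailed and the direction must be given explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "TestResult",
    "DegenerateVarianceError",
    "welch_one_tailed",
    "paired_t_one_tailed",
    "ratio_paired_t_one_tailed",
]

_DIRECTIONS = ("less", "greater")


class DegenerateVarianceError(ValueError):
    """Raised when a t statistic is undefined because the variance is zero."""


@dataclass(frozen=True)
class TestResult:
    """Outcome of a one-tailed t test."""

    test: str
    statistic: float
    df: float
    pvalue: float
    n: int
    direction: str

    def __post_init__(self) -> None:
        if not (0.0 < self.pvalue <= 1.0):
            raise ValueError(f"p-value outside (0, 1]: {self.pvalue}")


def _check_direction(direction: str) -> str:
    if direction not in _DIRECTIONS:
        raise ValueError(f"direction must be one of {_DIRECTIONS}, got {direction!r}")
    return direction


def _one_tailed_p(t: float, df: float, direction: str) -> float:
    # p = P(T <= t) for "less", P(T >= t) for "greater"
    if direction == "less":
        return float(sps.t.cdf(t, df))
    return float(sps.t.sf(t, df))


def welch_one_tailed(a, b, direction: str) -> TestResult:
    """Welch's unequal-variance t test of mean(a) vs mean(b), one-tailed.

    ``direction="less"`` tests the alternative mean(a) < mean(b).
    """
    _check_direction(direction)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each sample needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        raise DegenerateVarianceError("both samples have zero variance")
    na, nb = a.size, b.size
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / np.sqrt(se2)
    # Welch-Satterthwaite degrees of freedom
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = _one_tailed_p(t, df, direction)
    return TestResult("welch_one_tailed", float(t), float(df), p, na + nb, direction)


def paired_t_one_tailed(x, y, direction: str) -> TestResult:
    """Paired Student's t test on matched repeats, one-tailed.

    ``direction="less"`` tests the alternative mean(x - y) < 0.
    """
    _check_direction(direction)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("need at least 2 pairs")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0.0:
        raise DegenerateVarianceError("paired differences have zero variance")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = _one_tailed_p(t, df, direction)
    return TestResult("paired_t_one_tailed", float(t), float(df), p, n, direction)


def ratio_paired_t_one_tailed(values, direction: str) -> TestResult:
    """Ratio paired t test on values expressed relative to a control of 1.

    The values are log-transformed (natural log; the base cancels in the
    statistic) and tested against 0 with a one-sample t test.
    ``direction="less"`` tests the alternative that the geometric mean of the
    relative values is below 1.
    """
    _check_direction(direction)
    v = np.asarray(values, dtype=float)
    if np.any(v <= 0):
        raise ValueError("relative values must be positive")
    if v.size < 2:
        raise ValueError("need at least 2 values")
    logs = np.log(v)
    sd = logs.std(ddof=1)
    if sd == 0.0:
        raise DegenerateVarianceError("log-ratios have zero variance")
    n = logs.size
    t = logs.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = _one_tailed_p(t, df, direction)
    return TestResult("ratio_paired_t_one_tailed", float(t), float(df), p, n, direction)
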