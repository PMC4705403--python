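"""SMCV contrast statistics: effect sizes, c+-probabilities, and one-sided p-values.

For groups with means Ybar_i, variances s_i and a zero-sum contrast c_1..c_t, the
standardized mean of the contrast variable (SMCV) is estimated by the
method-of-moments form

    lambda_hat = sum(c_i * Ybar_i) / sqrt(sum(c_i**2 * s_i)).

Under a normal model of the contrast variable the c+-probability — the probability
that the contrast variable is positive — is Phi(lambda_hat); it equals 0.5 when
there is no effect. The test of the one-sided null "SMCV <= 0" uses the sampling
distribution of lambda_hat: its standard error is sqrt(sum(c_i**2 s_i / n_i)) over
the same denominator, so

    p = Phi(-lambda_hat / se(lambda_hat)).

For groups of size 1 this reduces to the asymptotic relation p = 1 - c+, which is
also exposed directly as :func:`smcv_pvalue`. p-values below 0.050 (strict) are
flagged significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "ContrastSpec",
    "GroupSummary",
    "ContrastResult",
    "smcv_estimate",
    "cplus_probability",
    "smcv_pvalue",
    "contrast_test",
    "summary_from_values",
    "SIGNIFICANCE_LEVEL",
]

#: Strict upper boundary for calling a one-sided p-value significant.
SIGNIFICANCE_LEVEL = 0.050


@dataclass(frozen=True)
class ContrastSpec:
    """Zero-sum contrast coefficients over t >= 2 groups."""

    coefficients: tuple[float, ...]

    def __post_init__(self):
        coefs = tuple(float(c) for c in self.coefficients)
        if len(coefs) < 2:
            raise ValueError("a contrast needs at least 2 groups")
        if abs(sum(coefs)) > 1e-12:
            raise ValueError(f"contrast coefficients must sum to 0, got sum={sum(coefs)!r}")
        if all(c == 0 for c in coefs):
            raise ValueError("contrast coefficients cannot all be zero")
        object.__setattr__(self, "coefficients", coefs)

    @property
    def t(self) -> int:
        return len(self.coefficients)


@dataclass(frozen=True)
class GroupSummary:
    """Mean, variance and size of one group (e.g. scaled combination ratios)."""

    mean: float
    variance: float
    n: int

    def __post_init__(self):
        if self.variance < 0:
            raise ValueError("variance must be non-negative")
        if self.n < 1:
            raise ValueError("group size must be >= 1")


@dataclass(frozen=True)
class ContrastResult:
    """SMCV estimate with its c+-probability and one-sided p-value."""

    smcv: float
    cplus: float
    p_value: float
    significant: bool


def summary_from_values(values) -> GroupSummary:
    """Group summary (mean, unbiased variance, n) from raw values."""
    v = np.asarray(values, dtype=float)
    if v.size < 1:
        raise ValueError("empty group")
    var = float(np.var(v, ddof=1)) if v.size > 1 else 0.0
    return GroupSummary(mean=float(np.mean(v)), variance=var, n=int(v.size))


def smcv_estimate(
    groups: list[GroupSummary], contrast: ContrastSpec, sd_form: bool = False
) -> float:
    """Method-of-moments SMCV estimate of a contrast across groups.

    ``sd_form=True`` reads the per-group dispersion as a standard deviation
    instead of a variance (denominator sqrt(sum(c_i^2 s_i^2))) for sensitivity
    analysis; the default treats it as a variance.
    """
    if len(groups) != contrast.t:
        raise ValueError(
            f"contrast has {contrast.t} coefficients but {len(groups)} groups were given"
        )
    c = np.asarray(contrast.coefficients)
    means = np.array([g.mean for g in groups])
    s = np.array([g.variance for g in groups])
    denom_sq = float(np.sum(c**2 * (s**2 if sd_form else s)))
    if denom_sq <= 0:
        raise ValueError("zero contrast-variance denominator (all group variances zero?)")
    return float(np.sum(c * means) / math.sqrt(denom_sq))


def cplus_probability(smcv: float) -> float:
    """c+-probability Phi(smcv): probability the contrast variable is positive."""
    if not np.isfinite(smcv):
        raise ValueError("SMCV must be finite")
    return float(norm.cdf(smcv))


def smcv_pvalue(cplus: float) -> float:
    """One-sided p-value from a c+-probability via p = 1 - c+.

    This is the asymptotic (unit group size) form of the test of the null
    "SMCV <= 0"; :func:`contrast_test` applies the finite-sample version.
    """
    if not (0.0 <= cplus <= 1.0):
        raise ValueError(f"c+-probability must lie in [0, 1], got {cplus}")
    return 1.0 - cplus


def is_significant(p_value: float) -> bool:
    """Strict threshold: significant iff p < 0.050."""
    return p_value < SIGNIFICANCE_LEVEL


def contrast_test(
    groups: list[GroupSummary], contrast: ContrastSpec, sd_form: bool = False
) -> ContrastResult:
    """SMCV estimate, c+-probability and calibrated one-sided p-value.

    The p-value tests the null "SMCV <= 0" against "SMCV > 0" using the normal
    approximation to the sampling distribution of the estimate:
    ``p = Phi(-lambda_hat / se)`` with
    ``se^2 = sum(c_i^2 s_i / n_i) / sum(c_i^2 s_i)``. With all n_i = 1 this
    coincides with ``1 - cplus``.
    """
    lam = smcv_estimate(groups, contrast, sd_form=sd_form)
    c = np.asarray(contrast.coefficients)
    s = np.array([g.variance for g in groups])
    n = np.array([g.n for g in groups], dtype=float)
    disp = s**2 if sd_form else s
    denom_sq = float(np.sum(c**2 * disp))
    se = math.sqrt(float(np.sum(c**2 * disp / n)) / denom_sq)
    p = float(norm.sf(lam / se))
    return ContrastResult(
        smcv=lam, cplus=cplus_probability(lam), p_value=p, significant=is_significant(p)
    )
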