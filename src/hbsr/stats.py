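"""Case-control statistics: complete-case prevalences, pooled two-proportion
z-tests with Bonferroni correction, crude and adjusted odds ratios from an
in-house IRLS logistic fit, and the two-sample t-test on mean scores.

Conventions follow the study design this package models: two-sided tests
throughout, Wald 95% intervals on the log-odds scale, complete-case rows
per analysis, and percentage cells rounded half-up to one decimal as they
would be printed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

Z975 = 1.959963984540054  # two-sided 95% normal quantile


class SeparationError(RuntimeError):
    """Perfect separation: the logistic MLE does not exist."""


class ConvergenceError(RuntimeError):
    pass


# --- prevalence ---------------------------------------------------------------

def round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class PrevalenceCell:
    """count / complete-case denominator, with the printed-style percentage."""

    count: int
    denominator: int
    pct: float

    def __str__(self) -> str:
        return f"{self.count} ({self.pct:.1f})"


def prevalence_cell(count: int, denominator: int) -> PrevalenceCell:
    """Build an ``n (%)`` cell; the denominator counts respondents in the
    stratum with a non-missing answer for the variable."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not 0 <= count <= denominator:
        raise ValueError(f"count {count} outside 0..{denominator}")
    return PrevalenceCell(count, denominator, round_half_up(100.0 * count / denominator))


# --- hypothesis tests ---------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    statistic: float
    p: float
    method: str
    p_adjusted: Optional[float] = None

    def with_adjustment(self, m: int) -> "TestResult":
        return TestResult(self.statistic, self.p, self.method, bonferroni([self.p], m)[0])


def two_proportion_z(x1: int, n1: int, x2: int, n2: int) -> TestResult:
    """Two-sided pooled two-proportion z-test (normal approximation, no
    continuity correction); the statistic carries the sign of p1 - p2.

    A degenerate pooled proportion (0 or 1) yields statistic 0, p = 1.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    if pooled <= 0.0 or pooled >= 1.0:
        return TestResult(0.0, 1.0, "two-proportion pooled z")
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (p1 - p2) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return TestResult(z, min(p, 1.0), "two-proportion pooled z")


def bonferroni(pvals: Sequence[float], m: Optional[int] = None) -> list[float]:
    """Bonferroni adjustment: min(1, m*p); m defaults to the family size
    len(pvals)."""
    if m is None:
        m = len(pvals)
    if m < 1:
        raise ValueError("family size m must be >= 1")
    for p in pvals:
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"p-value {p} outside [0, 1]")
    return [min(1.0, m * p) for p in pvals]


# --- odds ratios --------------------------------------------------------------

@dataclass(frozen=True)
class ContingencyTable2x2:
    """Exposure x outcome counts: a=exposed case, b=exposed control,
    c=unexposed case, d=unexposed control."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cell counts must be non-negative")


@dataclass(frozen=True)
class ORResult:
    term: str
    or_estimate: float
    ci_low: float
    ci_high: float
    covariates: tuple[str, ...]
    n_used: int


def crude_or(t: ContingencyTable2x2, haldane: bool = False) -> ORResult:
    """Unadjusted odds ratio (ad/bc) with the Wald 95% interval.

    Zero cells raise unless ``haldane`` adds the +0.5 continuity correction
    to every cell.
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    if min(a, b, c, d) == 0:
        if not haldane:
            raise ValueError("zero cell; enable the Haldane-Anscombe correction")
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo, hi = math.exp(math.log(orr) - Z975 * se), math.exp(math.log(orr) + Z975 * se)
    return ORResult("exposure", orr, lo, hi, (), t.a + t.b + t.c + t.d)


# --- logistic regression (IRLS) -----------------------------------------------

@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic regression fit."""

    names: tuple[str, ...]
    params: np.ndarray
    bse: np.ndarray
    n_used: int
    deviance: float
    n_iter: int

    def odds_ratios(self, covariates: Sequence[str] = ()) -> list[ORResult]:
        """Per-term odds ratios with Wald 95% CIs, intercept excluded."""
        out = []
        for name, beta, se in zip(self.names, self.params, self.bse):
            if name == "intercept":
                continue
            out.append(
                ORResult(
                    name,
                    math.exp(beta),
                    math.exp(beta - Z975 * se),
                    math.exp(beta + Z975 * se),
                    tuple(covariates),
                    self.n_used,
                )
            )
        return out


def fit_logistic(
    outcome: np.ndarray,
    design: np.ndarray,
    names: Optional[Sequence[str]] = None,
    add_intercept: bool = True,
    max_iter: int = 50,
    score_tol: float = 1e-8,
    dev_tol: float = 1e-10,
) -> LogisticFit:
    """Fit a binary logistic model by iteratively reweighted least squares.

    Rows with any non-finite value are dropped (complete case) and the
    remaining sample size reported.  Convergence requires the largest score
    component below ``score_tol`` or a relative deviance change below
    ``dev_tol`` within ``max_iter`` Newton steps.  Diverging coefficients
    (|beta| > 30 on standardized-scale data is a symptom of perfect
    separation) raise :class:`SeparationError`.
    """
    y = np.asarray(outcome, dtype=float).ravel()
    X = np.asarray(design, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if names is None:
        names = [f"x{i}" for i in range(X.shape[1])]
    names = list(names)
    if add_intercept:
        X = np.column_stack([np.ones(len(X)), X])
        names = ["intercept"] + names

    keep = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    y, X = y[keep], X[keep]
    n = len(y)
    if n == 0:
        raise ValueError("no complete-case rows")
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if y.min() == y.max():
        raise ValueError("outcome is constant; model not identifiable")

    beta = np.zeros(X.shape[1])
    dev_old = np.inf
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30.0, 30.0)
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        score = X.T @ (y - mu)
        info = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(
                "singular information matrix (separation or collinearity)"
            ) from exc
        beta = beta + step
        if np.max(np.abs(beta)) > 30.0:
            raise SeparationError("diverging coefficients: perfect separation")
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = y * np.log(mu) + (1 - y) * np.log1p(-mu)
        dev = -2.0 * np.nansum(ll)
        if np.max(np.abs(score)) < score_tol:
            break
        if np.isfinite(dev_old) and abs(dev - dev_old) <= dev_tol * (abs(dev_old) + 1e-12):
            break
        dev_old = dev
    else:
        raise ConvergenceError(f"IRLS did not converge in {max_iter} iterations")

    eta = np.clip(X @ beta, -30.0, 30.0)
    mu = 1.0 / (1.0 + np.exp(-eta))
    w = mu * (1.0 - mu)
    info = (X * w[:, None]).T @ X
    cov = np.linalg.inv(info)
    with np.errstate(divide="ignore", invalid="ignore"):
        ll = y * np.log(mu) + (1 - y) * np.log1p(-mu)
    dev = -2.0 * np.nansum(ll)
    return LogisticFit(tuple(names), beta, np.sqrt(np.diag(cov)), n, dev, it)


# --- mean score comparison ----------------------------------------------------

@dataclass(frozen=True)
class MeanScoreComparison:
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    ci1: tuple[float, float]
    ci2: tuple[float, float]
    t: float
    p: float
    n1: int
    n2: int
    method: str


def mean_score_ttest(
    scores1: Sequence[float], scores2: Sequence[float], welch: bool = True
) -> MeanScoreComparison:
    """Two-sided t-test on group means (Welch by default, Student optional)
    with normal-approximation 95% CIs for each group mean."""
    a = np.asarray(scores1, dtype=float)
    b = np.asarray(scores2, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two complete scores")
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    if not math.isfinite(t):  # both groups constant: 0/0
        if np.isclose(a.mean(), b.mean()):
            t, p = 0.0, 1.0
        else:
            t = math.copysign(math.inf, a.mean() - b.mean())
            p = 0.0
    m1, m2 = a.mean(), b.mean()
    s1, s2 = a.std(ddof=1), b.std(ddof=1)
    ci1 = (m1 - Z975 * s1 / math.sqrt(len(a)), m1 + Z975 * s1 / math.sqrt(len(a)))
    ci2 = (m2 - Z975 * s2 / math.sqrt(len(b)), m2 + Z975 * s2 / math.sqrt(len(b)))
    method = "Welch t-test" if welch else "Student t-test"
    return MeanScoreComparison(m1, m2, s1, s2, ci1, ci2, float(t), float(p), len(a), len(b), method)
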