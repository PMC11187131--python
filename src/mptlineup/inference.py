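"""Chi-square tail probabilities and sensitivity (minimum detectable
effect size w) for likelihood-ratio tests of parameter equality."""

from __future__ import annotations

from dataclasses import dataclass

from scipy.optimize import brentq
from scipy.stats import chi2, ncx2


def chi2_p(value: float, df: int) -> float:
    """Upper-tail probability P(chi2_df > value)."""
    if value < 0:
        raise ValueError("chi-square statistic must be nonnegative")
    if df < 1:
        raise ValueError("df must be at least 1")
    return float(chi2.sf(value, df))


@dataclass(frozen=True)
class SensitivitySpec:
    """Design description for a sensitivity analysis of a chi-square test.

    ``n_responses`` is the total number of observations entering the test
    (participants times responses per participant).
    """

    alpha: float
    beta: float
    df: int
    n_responses: int

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1 and 0 < self.beta < 1):
            raise ValueError("alpha and beta must lie in (0, 1)")
        if self.n_responses <= 0:
            raise ValueError("n_responses must be positive")
        if self.df < 1:
            raise ValueError("df must be at least 1")


@dataclass(frozen=True)
class SensitivityResult:
    w: float
    noncentrality: float
    spec: SensitivitySpec


def required_noncentrality(alpha: float, beta: float, df: int) -> float:
    """Noncentrality lambda at which a chi-square test with level alpha
    attains power 1 - beta: solves  P(chi2_{df,lam} > q_{1-alpha}) = 1-beta.
    The survival function is increasing in lambda, so a bracketed
    root-find applies."""
    crit = chi2.ppf(1.0 - alpha, df)
    target = 1.0 - beta

    def f(lam: float) -> float:
        return ncx2.sf(crit, df, lam) - target

    lo, hi = 1e-6, 100.0
    while f(hi) < 0:
        hi *= 2.0
        if hi > 1e8:
            raise RuntimeError(
                f"noncentrality root-find failed: no sign change in "
                f"[{lo:g}, {hi:g}]"
            )
    return float(brentq(f, lo, hi, xtol=1e-10))


def sensitivity_w(spec: SensitivitySpec) -> SensitivityResult:
    """Minimum detectable chi-square effect size w = sqrt(lambda / N)."""
    lam = required_noncentrality(spec.alpha, spec.beta, spec.df)
    return SensitivityResult(
        w=float((lam / spec.n_responses) ** 0.5), noncentrality=lam, spec=spec
    )
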