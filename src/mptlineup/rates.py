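"""Observable identification rates, Wald confidence intervals, and pooled
two-proportion z-tests.

The unit of analysis is the individual lineup response (each participant
contributes two responses per lineup type); within-participant dependence
is ignored, which is the convention the published z values follow.
"""

from __future__ import annotations

from dataclasses import dataclass

from statsmodels.stats.proportion import proportion_confint, proportions_ztest


@dataclass(frozen=True)
class RateEstimate:
    count: int
    total: int
    rate: float
    ci_lower: float
    ci_upper: float
    level: float


@dataclass(frozen=True)
class ProportionTestResult:
    z: float
    p: float
    rate1: RateEstimate
    rate2: RateEstimate
    degenerate: bool = False


def rate(count: int, total: int, level: float = 0.95, method: str = "wald") -> RateEstimate:
    """Proportion with a confidence interval clamped to [0, 1].

    ``method`` is "wald" (default; rate +- z*sqrt(rate(1-rate)/total)) or
    "wilson".
    """
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= count <= total:
        raise ValueError("count must lie in [0, total]")
    sm_method = {"wald": "normal", "wilson": "wilson"}[method]
    lo, hi = proportion_confint(count, total, alpha=1.0 - level, method=sm_method)
    return RateEstimate(
        count=count,
        total=total,
        rate=count / total,
        ci_lower=max(float(lo), 0.0),
        ci_upper=min(float(hi), 1.0),
        level=level,
    )


def two_proportion_z(
    count1: int, total1: int, count2: int, total2: int, level: float = 0.95
) -> ProportionTestResult:
    """Pooled two-proportion z-test, two-sided, no continuity correction.

    z = (p1 - p2) / sqrt(phat (1 - phat) (1/n1 + 1/n2)) with
    phat = (count1 + count2) / (total1 + total2); the sign of z follows
    p1 - p2.
    """
    r1 = rate(count1, total1, level)
    r2 = rate(count2, total2, level)
    pooled = (count1 + count2) / (total1 + total2)
    if pooled in (0.0, 1.0):
        return ProportionTestResult(
            z=0.0, p=1.0, rate1=r1, rate2=r2, degenerate=True
        )
    z, p = proportions_ztest(
        [count1, count2], [total1, total2], alternative="two-sided"
    )
    return ProportionTestResult(z=float(z), p=float(p), rate1=r1, rate2=r2)
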