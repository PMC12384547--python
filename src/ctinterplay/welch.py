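"""Welch two-sample t-tests between scan protocols.

Each motion condition yields one sample of absolute alignment errors per
protocol; a two-sided Welch (unequal-variance) t-test compares the two
protocols' means.  Tests can be run either from raw samples or directly from
the (mean, SD, n) summaries — the two routes are definitionally equivalent.

t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2); degrees of freedom follow the
Welch–Satterthwaite approximation.  No multiple-testing correction is
applied: p-values are per comparison at the chosen alpha.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as _st

from .exceptions import InsufficientDataError
from .margins import ConditionSummary

__all__ = [
    "WelchResult",
    "welch_from_summary",
    "welch_from_samples",
    "protocol_comparisons",
    "significance_pattern",
]


@dataclass(frozen=True)
class WelchResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def welch_from_summary(
    mean1: float, sd1: float, n1: int,
    mean2: float, sd2: float, n2: int,
    alpha: float = 0.05,
) -> WelchResult:
    """Two-sided Welch t-test from group summary statistics.

    Degenerate cases: both SDs zero with equal means gives t=0, p=1; both
    SDs zero with unequal means gives p=0 with a warning (the test statistic
    is unbounded).
    """
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError("Welch test requires n >= 2 per group")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    se2 = v1 + v2
    if se2 == 0.0:
        df = float(n1 + n2 - 2)
        if mean1 == mean2:
            return WelchResult(0.0, df, 1.0, alpha)
        warnings.warn(
            "degenerate Welch test: zero variance in both groups with "
            "unequal means; p set to 0",
            RuntimeWarning,
            stacklevel=2,
        )
        t = math.inf if mean1 > mean2 else -math.inf
        return WelchResult(t, df, 0.0, alpha)
    t = (mean1 - mean2) / math.sqrt(se2)
    df = se2**2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = 2.0 * float(_st.t.sf(abs(t), df))
    return WelchResult(t, df, p, alpha)


def welch_from_samples(xs, ys, alpha: float = 0.05) -> WelchResult:
    """Two-sided Welch t-test from raw samples (summary-equivalent)."""
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    if xs.size < 2 or ys.size < 2:
        raise InsufficientDataError("Welch test requires n >= 2 per group")
    return welch_from_summary(
        float(xs.mean()), float(xs.std(ddof=1)), xs.size,
        float(ys.mean()), float(ys.std(ddof=1)), ys.size,
        alpha=alpha,
    )


def _paired_conditions(
    summaries: list[ConditionSummary],
    group1: str = "standard",
    group2: str = "slow",
) -> dict[tuple[float, float], tuple[ConditionSummary, ConditionSummary]]:
    by_key: dict[tuple, ConditionSummary] = {
        (s.protocol, s.rate_bpm, s.amplitude_mm): s for s in summaries
    }
    conditions = sorted({(s.rate_bpm, s.amplitude_mm) for s in summaries})
    pairs = {}
    for rate, amp in conditions:
        a = by_key.get((group1, rate, amp))
        b = by_key.get((group2, rate, amp))
        if a is None or b is None:
            missing = group1 if a is None else group2
            raise InsufficientDataError(
                f"condition ({rate} BPM, {amp} mm) lacks a {missing!r} summary"
            )
        pairs[(rate, amp)] = (a, b)
    return pairs


def protocol_comparisons(
    summaries: list[ConditionSummary],
    alpha: float = 0.05,
    group1: str = "standard",
    group2: str = "slow",
) -> dict[tuple[float, float], WelchResult]:
    """Per-condition Welch comparison of two protocols' summaries.

    Keys are (rate_bpm, amplitude_mm).
    """
    return {
        cond: welch_from_summary(
            a.sigma_sys_mm, a.sigma_rand_mm, a.n,
            b.sigma_sys_mm, b.sigma_rand_mm, b.n,
            alpha=alpha,
        )
        for cond, (a, b) in _paired_conditions(summaries, group1, group2).items()
    }


def significance_pattern(
    summaries: list[ConditionSummary], alpha: float = 0.05
) -> set[tuple[float, float]]:
    """Conditions (rate_bpm, amplitude_mm) where the protocols differ at alpha."""
    return {
        cond
        for cond, res in protocol_comparisons(summaries, alpha=alpha).items()
        if res.significant
    }
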