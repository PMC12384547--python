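"""PTV margin estimation from systematic and random alignment uncertainty.

Alignment errors from repeated guidance scans of one motion condition are
summarised into a systematic component Sigma (the mean absolute longitudinal
error, i.e. the reproducible offset from the mean target position) and a
random component sigma (the scan-to-scan sample SD).  Two margin recipes are
provided:

* ``eq1_margin`` — 2.5 * sqrt(b^2 + Sigma^2) + 0.7 * sigma - offset, where
  b (default 2 mm) is a patient/system systematic baseline added in
  quadrature (it covers couch and image resolution) and the offset default
  is 3 mm.
* ``van_herk_margin`` — the linear 2.5 * Sigma + 0.7 * sigma - offset form
  without the quadrature baseline (the classic population-margin recipe with
  an optional offset).

Reported margins are rounded half-up to 0.1 mm; the unrounded value is kept
on the result object.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .acquisition import AlignmentRecord
from .exceptions import AggregationError, InsufficientDataError

__all__ = [
    "ConditionSummary",
    "MarginParameters",
    "MarginResult",
    "summarize_condition",
    "summarize_by_condition",
    "eq1_margin",
    "van_herk_margin",
    "margin_table",
    "protocol_maxima",
    "round_margin",
]


@dataclass(frozen=True)
class ConditionSummary:
    """(Sigma, sigma, n) for one protocol x amplitude x rate cell."""

    protocol: str
    amplitude_mm: float
    rate_bpm: float
    n: int
    sigma_sys_mm: float  # Sigma: mean absolute longitudinal error
    sigma_rand_mm: float  # sigma: sample SD (n-1 denominator)

    def __post_init__(self) -> None:
        if self.n < 2:
            raise InsufficientDataError("a condition summary requires n >= 2")
        if self.sigma_sys_mm < 0 or self.sigma_rand_mm < 0:
            raise ValueError("uncertainty components must be non-negative")

    @property
    def condition(self) -> tuple[float, float]:
        return (self.rate_bpm, self.amplitude_mm)


@dataclass(frozen=True)
class MarginParameters:
    """Coefficients of the margin recipe; defaults as used clinically."""

    systematic_multiplier: float = 2.5
    random_multiplier: float = 0.7
    baseline_systematic_mm: float = 2.0  # patient/system term, in quadrature
    offset_mm: float = 3.0

    def __post_init__(self) -> None:
        for attr in ("systematic_multiplier", "random_multiplier",
                     "baseline_systematic_mm", "offset_mm"):
            if getattr(self, attr) < 0:
                raise ValueError(f"{attr} must be non-negative")


@dataclass(frozen=True)
class MarginResult:
    protocol: str
    amplitude_mm: float
    rate_bpm: float
    margin_mm_exact: float

    @property
    def margin_mm(self) -> float:
        """Margin rounded half-up to 0.1 mm for reporting."""
        return round_margin(self.margin_mm_exact)


def round_margin(x: float) -> float:
    """Round half-up to 0.1 mm (report convention)."""
    return math.floor(x * 10.0 + 0.5) / 10.0


def summarize_condition(
    records: list[AlignmentRecord], mode: str = "absolute"
) -> ConditionSummary:
    """Sigma / sigma summary of one condition's alignment records.

    In the default ``absolute`` mode Sigma is the mean of |signed error| and
    sigma the sample SD of the same absolute series; ``signed`` mode uses
    the signed errors instead (sensitivity analysis).
    """
    if mode not in ("absolute", "signed"):
        raise ValueError(f"mode must be 'absolute' or 'signed', got {mode!r}")
    if len(records) < 2:
        raise InsufficientDataError("need at least 2 records for a defined SD")
    keys = {(r.protocol, r.amplitude_mm, r.rate_bpm) for r in records}
    if len(keys) != 1:
        raise AggregationError(f"records span multiple conditions: {sorted(keys)}")
    errs = np.array([r.signed_error_mm for r in records])
    series = np.abs(errs) if mode == "absolute" else errs
    protocol, amp, rate = next(iter(keys))
    return ConditionSummary(
        protocol=protocol,
        amplitude_mm=amp,
        rate_bpm=rate,
        n=len(records),
        sigma_sys_mm=float(series.mean()),
        sigma_rand_mm=float(series.std(ddof=1)),
    )


def summarize_by_condition(
    records: list[AlignmentRecord], mode: str = "absolute"
) -> list[ConditionSummary]:
    """Group records by (protocol, amplitude, rate) and summarise each cell."""
    groups: dict[tuple, list[AlignmentRecord]] = {}
    for r in records:
        groups.setdefault((r.protocol, r.amplitude_mm, r.rate_bpm), []).append(r)
    return [summarize_condition(g, mode=mode) for g in groups.values()]


def eq1_margin(
    sigma_sys_mm: float,
    sigma_rand_mm: float,
    params: MarginParameters = MarginParameters(),
) -> float:
    """Quadrature-baseline PTV margin (mm), unrounded.

    ``2.5 * sqrt(b^2 + Sigma^2) + 0.7 * sigma - 3`` at the defaults.
    """
    if sigma_sys_mm < 0 or sigma_rand_mm < 0:
        raise ValueError("uncertainty inputs must be non-negative")
    return (
        params.systematic_multiplier
        * math.sqrt(params.baseline_systematic_mm**2 + sigma_sys_mm**2)
        + params.random_multiplier * sigma_rand_mm
        - params.offset_mm
    )


def van_herk_margin(
    sigma_sys_mm: float, sigma_rand_mm: float, offset_mm: float = 3.0
) -> float:
    """Linear population-margin recipe: 2.5 * Sigma + 0.7 * sigma - offset."""
    if sigma_sys_mm < 0 or sigma_rand_mm < 0:
        raise ValueError("uncertainty inputs must be non-negative")
    return 2.5 * sigma_sys_mm + 0.7 * sigma_rand_mm - offset_mm


def margin_table(
    summaries: list[ConditionSummary],
    params: MarginParameters = MarginParameters(),
) -> list[MarginResult]:
    """Apply the quadrature margin recipe to each condition cell."""
    return [
        MarginResult(
            protocol=s.protocol,
            amplitude_mm=s.amplitude_mm,
            rate_bpm=s.rate_bpm,
            margin_mm_exact=eq1_margin(s.sigma_sys_mm, s.sigma_rand_mm, params),
        )
        for s in summaries
    ]


def protocol_maxima(results: list[MarginResult]) -> dict[str, float]:
    """Largest reported (rounded) margin per protocol."""
    out: dict[str, float] = {}
    for r in results:
        out[r.protocol] = max(out.get(r.protocol, -math.inf), r.margin_mm)
    return out
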