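"""Clinical image-guidance decision procedures.

Two procedures used at the treatment unit are encoded here:

* **Modality selection** — given a lesion's motion amplitude and breathing
  rate, choose CT-on-rail (CTOR) or an MR-Linac for soft-tissue guidance.
  CTOR is chosen when motion is 5 mm or less, or when it is under 10 mm and
  the breathing rate is 20 breaths/min or greater; otherwise the MR-Linac.

* **Bone-vs-tumour stability and re-imaging** — at each guidance session the
  couch shift from bone (vertebral) registration is compared with the shift
  from soft-tissue (tumour) registration.  The target is deemed stable when
  the two alignments differ by less than 5 mm in every cardinal direction.
  An unstable first image triggers a second; the session proceeds after the
  second image only if it is stable AND its longitudinal alignment is
  consistent (within 5 mm) with the first; otherwise a third image is taken,
  and a stable third image proceeds while anything else escalates to the
  physician.  At most three images are taken.  The longitudinal value used
  for treatment is the most recent image's for CBCT and the mean over all
  images for CTOR.

All lengths are millimetres internally; helpers accept cm where noted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .exceptions import InsufficientDataError, ProtocolViolationError

__all__ = [
    "ShiftTriplet",
    "GuidanceDecision",
    "ImagingSessionState",
    "DriftSummary",
    "select_guidance",
    "is_stable",
    "imaging_decision",
    "cohort_drift_summary",
]

CTOR = "CTOR"
MR_LINAC = "MR_Linac"
CBCT = "CBCT"


@dataclass(frozen=True)
class ShiftTriplet:
    """Couch shifts (mm) for one alignment in the three cardinal directions."""

    lateral_mm: float
    longitudinal_mm: float
    vertical_mm: float

    def __sub__(self, other: "ShiftTriplet") -> "ShiftTriplet":
        return ShiftTriplet(
            self.lateral_mm - other.lateral_mm,
            self.longitudinal_mm - other.longitudinal_mm,
            self.vertical_mm - other.vertical_mm,
        )

    def max_abs_mm(self) -> float:
        return max(
            abs(self.lateral_mm), abs(self.longitudinal_mm), abs(self.vertical_mm)
        )


@dataclass(frozen=True)
class GuidanceDecision:
    amplitude_mm: float
    rate_bpm: float
    modality: str  # CTOR or MR_Linac
    rule: str


@dataclass(frozen=True)
class ImagingSessionState:
    modality: str  # CBCT or CTOR
    differences: tuple[ShiftTriplet, ...]
    decision: str  # proceed | acquire_again | escalate
    final_longitudinal_mm: float | None


def select_guidance(amplitude_mm: float, rate_bpm: float) -> GuidanceDecision:
    """Choose the image-guidance modality from motion amplitude and rate."""
    if amplitude_mm < 0 or rate_bpm <= 0:
        raise ValueError("amplitude must be >= 0 and rate > 0")
    if amplitude_mm <= 5.0:
        modality, rule = CTOR, "amplitude <= 5 mm"
    elif amplitude_mm < 10.0 and rate_bpm >= 20.0:
        modality, rule = CTOR, "amplitude < 10 mm and rate >= 20 BPM"
    else:
        modality, rule = MR_LINAC, "amplitude/rate outside CTOR envelope"
    return GuidanceDecision(amplitude_mm, rate_bpm, modality, rule)


def is_stable(
    bone: ShiftTriplet, gtv: ShiftTriplet, threshold_mm: float = 5.0
) -> bool:
    """True when bone and tumour alignments differ by < threshold on every axis."""
    return (bone - gtv).max_abs_mm() < threshold_mm


def _diff_stable(d: ShiftTriplet, threshold_mm: float) -> bool:
    return d.max_abs_mm() < threshold_mm


def imaging_decision(
    diffs: Sequence[ShiftTriplet],
    modality: str,
    threshold_mm: float = 5.0,
) -> ImagingSessionState:
    """Replay the stability/re-imaging procedure over 1-3 acquired images.

    ``diffs`` are the per-image bone-minus-tumour difference triplets in
    acquisition order.  The decision after the last provided image is
    returned; acquiring an image after the procedure has already allowed
    treatment, or a fourth image, is a protocol violation.
    """
    if modality not in (CBCT, CTOR):
        raise ValueError(f"modality must be {CBCT!r} or {CTOR!r}")
    diffs = tuple(diffs)
    if not diffs:
        raise ProtocolViolationError("at least one image is required")
    if len(diffs) > 3:
        raise ProtocolViolationError("the procedure allows at most three images")

    def _state(decision: str) -> ImagingSessionState:
        final = None
        if decision == "proceed":
            longs = [d.longitudinal_mm for d in diffs]
            final = longs[-1] if modality == CBCT else float(np.mean(longs))
        return ImagingSessionState(modality, diffs, decision, final)

    # image 1
    if _diff_stable(diffs[0], threshold_mm):
        if len(diffs) > 1:
            raise ProtocolViolationError(
                "images acquired after the first image already allowed treatment"
            )
        return _state("proceed")
    if len(diffs) == 1:
        return _state("acquire_again")

    # image 2: must itself be stable and longitudinally consistent with image 1
    consistent = (
        _diff_stable(diffs[1], threshold_mm)
        and abs(diffs[1].longitudinal_mm - diffs[0].longitudinal_mm) < threshold_mm
    )
    if consistent:
        if len(diffs) > 2:
            raise ProtocolViolationError(
                "a third image was acquired after the second allowed treatment"
            )
        return _state("proceed")
    if len(diffs) == 2:
        return _state("acquire_again")

    # image 3: last chance
    if _diff_stable(diffs[2], threshold_mm):
        return _state("proceed")
    return _state("escalate")


@dataclass(frozen=True)
class DriftSummary:
    """Cohort summary of longitudinal bone-minus-tumour differences."""

    mean_mm: float
    sd_mm: float
    min_mm: float
    max_mm: float
    n: int

    @property
    def as_cm(self) -> tuple[float, float, float, float]:
        return (self.mean_mm / 10, self.sd_mm / 10, self.min_mm / 10, self.max_mm / 10)


def cohort_drift_summary(records) -> DriftSummary:
    """Mean/SD/min/max of longitudinal bone-minus-tumour drift over fractions.

    ``records`` are per-fraction patient records exposing
    ``longitudinal_difference_mm`` (see the synthetic cohort generator) or
    raw floats in mm.
    """
    vals = np.array(
        [
            getattr(r, "longitudinal_difference_mm", r if np.isscalar(r) else None)
            for r in records
        ],
        dtype=float,
    )
    if vals.size < 2:
        raise InsufficientDataError("drift summary requires at least 2 records")
    return DriftSummary(
        mean_mm=float(vals.mean()),
        sd_mm=float(vals.std(ddof=1)),
        min_mm=float(vals.min()),
        max_mm=float(vals.max()),
        n=int(vals.size),
    )
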