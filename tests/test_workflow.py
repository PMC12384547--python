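"""Clinical guidance-selection and stability/re-imaging procedures."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ctinterplay import (
    CohortModel,
    ShiftTriplet,
    cohort_drift_summary,
    generate_cohort,
    imaging_decision,
    is_stable,
    select_guidance,
)
from ctinterplay.exceptions import InsufficientDataError, ProtocolViolationError


def T(lat=0.0, long=0.0, vert=0.0):
    return ShiftTriplet(lat, long, vert)


class TestSelectGuidance:
    @pytest.mark.parametrize(
        "amplitude, rate, modality",
        [
            (4.0, 12.0, "CTOR"),      # small motion: CTOR regardless of rate
            (8.0, 22.0, "CTOR"),      # <10 mm at fast breathing: CTOR
            (12.0, 25.0, "MR_Linac"),
            (8.0, 15.0, "MR_Linac"),  # <10 mm but breathing too slow
            (5.0, 6.0, "CTOR"),       # 5 mm is inclusive
            (5.0, 40.0, "CTOR"),
            (10.0, 20.0, "MR_Linac"),  # 10 mm is exclusive
            (9.99, 20.0, "CTOR"),      # 20 BPM is inclusive
            (9.99, 19.99, "MR_Linac"),
        ],
    )
    def test_boundary_truth_table(self, amplitude, rate, modality):
        assert select_guidance(amplitude, rate).modality == modality

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            select_guidance(-1.0, 12.0)
        with pytest.raises(ValueError):
            select_guidance(5.0, 0.0)


class TestIsStable:
    def test_strict_threshold(self):
        assert is_stable(T(), T(long=4.9))
        assert not is_stable(T(), T(long=5.0))
        assert is_stable(T(1, 2, 3), T(1, 2, 3))

    @given(
        vals=st.tuples(*[st.floats(-20, 20) for _ in range(6)]),
        offset=st.tuples(*[st.floats(-20, 20) for _ in range(3)]),
    )
    def test_symmetric_and_translation_invariant(self, vals, offset):
        bone, gtv = T(*vals[:3]), T(*vals[3:])
        shift = T(*offset)
        assert is_stable(bone, gtv) == is_stable(gtv, bone)
        assert is_stable(bone, gtv) == is_stable(
            T(*(v + o for v, o in zip(vals[:3], offset))),
            T(*(v + o for v, o in zip(vals[3:], offset))),
        )


class TestImagingDecision:
    def test_stable_first_image_proceeds_cbct(self):
        state = imaging_decision([T(long=2.0)], "CBCT")
        assert state.decision == "proceed"
        assert state.final_longitudinal_mm == 2.0

    def test_unstable_first_image_requires_second(self):
        state = imaging_decision([T(long=6.0)], "CBCT")
        assert state.decision == "acquire_again"
        assert state.final_longitudinal_mm is None

    def test_second_image_consistent_ctor_averages(self):
        state = imaging_decision([T(long=6.0), T(long=3.0)], "CTOR")
        assert state.decision == "proceed"
        assert state.final_longitudinal_mm == pytest.approx(4.5)

    def test_second_image_consistent_cbct_uses_most_recent(self):
        state = imaging_decision([T(long=6.0), T(long=3.0)], "CBCT")
        assert state.decision == "proceed"
        assert state.final_longitudinal_mm == 3.0

    def test_inconsistent_second_image_requires_third(self):
        # image 2 is itself stable but disagrees with image 1 by >= 5 mm
        state = imaging_decision([T(long=9.0), T(long=3.0)], "CBCT")
        assert state.decision == "acquire_again"

    def test_stable_third_image_proceeds(self):
        state = imaging_decision([T(long=9.0), T(long=3.0), T(long=2.0)], "CTOR")
        assert state.decision == "proceed"
        assert state.final_longitudinal_mm == pytest.approx((9 + 3 + 2) / 3)

    def test_exhausted_procedure_escalates_without_value(self):
        state = imaging_decision([T(long=9.0), T(long=3.0), T(long=7.0)], "CBCT")
        assert state.decision == "escalate"
        assert state.final_longitudinal_mm is None

    def test_fourth_image_is_a_protocol_violation(self):
        with pytest.raises(ProtocolViolationError):
            imaging_decision([T(long=9.0)] * 4, "CBCT")

    def test_empty_sequence_is_a_protocol_violation(self):
        with pytest.raises(ProtocolViolationError):
            imaging_decision([], "CBCT")

    def test_imaging_after_approval_is_a_protocol_violation(self):
        with pytest.raises(ProtocolViolationError):
            imaging_decision([T(long=1.0), T(long=2.0)], "CBCT")

    def test_ctor_average_is_order_insensitive(self):
        a = imaging_decision([T(long=9.0), T(long=3.0), T(long=2.0)], "CTOR")
        b = imaging_decision([T(long=9.0), T(long=2.0), T(long=3.0)], "CTOR")
        assert a.final_longitudinal_mm == b.final_longitudinal_mm


class TestCohortDriftSummary:
    def test_hand_computed_summary(self):
        s = cohort_drift_summary([-1.0, -3.0])
        assert s.mean_mm == pytest.approx(-2.0)
        assert s.sd_mm == pytest.approx(np.sqrt(2.0))
        assert (s.min_mm, s.max_mm) == (-3.0, -1.0)

    def test_all_zero(self):
        s = cohort_drift_summary([0.0, 0.0, 0.0])
        assert (s.mean_mm, s.sd_mm, s.min_mm, s.max_mm) == (0, 0, 0, 0)

    def test_single_record_raises(self):
        with pytest.raises(InsufficientDataError):
            cohort_drift_summary([1.0])

    def test_cm_conversion(self):
        s = cohort_drift_summary([-1.0, -3.0])
        assert s.as_cm[0] == pytest.approx(-0.2)

    def test_recovers_generator_parameters(self):
        model = CohortModel(n_patients=75, fractions_per_patient=4, seed=9)
        s = cohort_drift_summary(generate_cohort(model))
        assert s.n == 300
        assert s.mean_mm == pytest.approx(-1.9, abs=0.3)
        assert s.sd_mm == pytest.approx(1.7, abs=0.3)
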