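"""Behaviour of the revised 0-8 grading cascade: worked examples, boundary
conventions at every threshold, mutual exclusivity of the rule regions,
restricted monotonicity in sensory velocity, and totality/determinism over
randomised records."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from ctsgrade import (
    Digit,
    GradingThresholds,
    MotorMeasurement,
    MotorSite,
    NCSRecord,
    RevisedGrade,
    SensoryMeasurement,
    Sex,
    Status,
    TreatmentBand,
    classify_revised,
    treatment_band,
)
from ctsgrade.ncs_model import Hand
from ctsgrade.revised_grader import GRADING_REASON_MESSAGES

from _builders import ABSENT, make_record


class TestWorkedExamples:
    """One record per grade, using mid-band values."""

    def test_grade_0_normal_study(self):
        g = classify_revised(make_record(d3=(55.0, 12.0), apb=(3.5, 8.0, 55.0)))
        assert g.value == 0

    def test_grade_1_early_double_peak(self):
        g = classify_revised(make_record(
            d3=(47.0, 9.0), d4=(46.0, 8.0, 0.8), apb=(4.0, 7.0, 54.0)))
        assert g.value == 1

    def test_grade_2_mild_sensory(self):
        g = classify_revised(make_record(d3=(42.0, 8.0), apb=(4.0, 7.0, 55.0)))
        assert g.value == 2

    def test_grade_3_mild_sensory_motor(self):
        g = classify_revised(make_record(d3=(42.0, 8.0), apb=(4.8, 7.0, 55.0)))
        assert g.value == 3

    def test_grade_4_moderate_sensory(self):
        g = classify_revised(make_record(d3=(34.0, 6.0), apb=(4.0, 6.0, 52.0)))
        assert g.value == 4

    def test_grade_5_moderate_sensory_motor(self):
        g = classify_revised(make_record(d3=(34.0, 6.0), apb=(5.2, 6.0, 52.0)))
        assert g.value == 5

    def test_grade_6_severe_measured_pattern(self):
        g = classify_revised(make_record(
            d3=(25.0, 2.0), d2=(28.0, 2.0), apb=(5.8, 4.0, 48.0)))
        assert g.value == 6

    def test_grade_6_severe_absent_pattern(self):
        g = classify_revised(make_record(d3=ABSENT, d2=ABSENT, apb=(5.8, 4.0, 48.0)))
        assert g.value == 6

    def test_grade_7_lumbrical_prolonged_low(self):
        g = classify_revised(make_record(
            d2=ABSENT, d3=ABSENT, apb=ABSENT,
            lum_med=(5.0, 0.8), lum_uln=(3.1, 3.5)))
        assert g.value == 7

    def test_grade_8_complete(self):
        g = classify_revised(make_record(
            d2=ABSENT, d3=ABSENT, apb=ABSENT,
            lum_med=ABSENT, lum_uln=(3.1, 3.5)))
        assert g.value == 8

    def test_missing_lumbricals_are_indeterminate(self):
        g = classify_revised(make_record(d2=ABSENT, d3=ABSENT, apb=ABSENT))
        assert g.is_indeterminate
        assert "lumbricals_missing" in g.reasons


class TestBoundaryWitnesses:
    """Every threshold pinned to its documented convention; comparisons are
    exact, so ties land deterministically."""

    @pytest.mark.parametrize(
        "record_kwargs, expected_value, expected_reason",
        [
            # SCV 50 belongs to the early band, 50.1 to normal
            (dict(d3=(50.0, 9.0), d4=(48.0, 8.0, 0.8)), 1, "double_peak_positive"),
            (dict(d3=(50.1, 9.0)), 0, "scv_normal"),
            # SCV 45 is early, 44.9 is mild
            (dict(d3=(45.0, 9.0), d4=(45.0, 8.0, 0.8)), 1, "scv_early_band"),
            (dict(d3=(44.9, 9.0)), 2, "scv_mild_band"),
            # SCV 40 is mild, 39.9 is moderate
            (dict(d3=(40.0, 9.0)), 2, "scv_mild_band"),
            (dict(d3=(39.9, 9.0)), 4, "scv_moderate_band"),
            # DML exactly 4.2 is normal; 4.3 is abnormal
            (dict(d3=(42.0, 9.0), apb=(4.2, 8.0, 55.0)), 2, "motor_normal"),
            (dict(d3=(42.0, 9.0), apb=(4.3, 8.0, 55.0)), 3, "dml_prolonged"),
            # sensory amplitude exactly 5 is normal
            (dict(d3=(42.0, 5.0)), 2, "sensory_amp_normal"),
            # motor amplitude exactly 5 / MCV exactly 50 are normal
            (dict(d3=(55.0, 9.0), apb=(3.5, 5.0, 50.0)), 0, "motor_normal"),
            # interpeak exactly 0.5 is not a positive early finding
            (dict(d3=(47.0, 9.0), d4=(46.0, 8.0, 0.5)), 0, "early_criteria_not_met"),
            (dict(d3=(47.0, 9.0), d4=(46.0, 8.0, 0.6)), 1, "double_peak_positive"),
            # early band without a digit IV study is graded normal with a warning
            (dict(d3=(47.0, 9.0)), 0, "early_criteria_not_met"),
            # severe pattern: both digits under 3 uV with SCV under 30
            (dict(d3=(29.9, 2.9), d2=(28.0, 2.9), apb=(4.3, 8.0, 55.0)), 6,
             "severe_sensory_pattern"),
        ],
    )
    def test_threshold_convention(self, record_kwargs, expected_value, expected_reason):
        g = classify_revised(make_record(**record_kwargs))
        assert g.value == expected_value
        assert expected_reason in g.reasons

    @pytest.mark.parametrize(
        "record_kwargs, expected_reason",
        [
            # sensory amplitude 4.9 falls in the scale's undefined gap
            (dict(d3=(42.0, 4.9)), "amplitude_gap"),
            # amplitude exactly 3 misses the severe cut (< 3)
            (dict(d3=(25.0, 3.0), d2=(28.0, 3.0), apb=(5.0, 8.0, 55.0)), "amplitude_gap"),
            # SCV exactly 30 misses the severe cut (< 30)
            (dict(d3=(30.0, 2.0), d2=(28.0, 2.0), apb=(5.0, 8.0, 55.0)), "amplitude_gap"),
            # abnormal motor with fully normal sensory is not CTS-gradable
            (dict(d3=(55.0, 9.0), apb=(3.5, 4.9, 55.0)), "isolated_motor_abnormality"),
            (dict(d3=(55.0, 9.0), apb=(3.5, 8.0, 49.9)), "isolated_motor_abnormality"),
            (dict(d3=(55.0, 9.0), apb=(5.0, 8.0, 55.0)), "isolated_motor_abnormality"),
            # severe sensory loss with a normal DML matches no printed grade
            (dict(d3=ABSENT, d2=ABSENT, apb=(3.5, 8.0, 55.0)), "severe_sensory_normal_motor"),
        ],
    )
    def test_refusals_at_boundaries(self, record_kwargs, expected_reason):
        g = classify_revised(make_record(**record_kwargs))
        assert g.is_indeterminate
        assert expected_reason in g.reasons

    def test_lumbrical_prolongation_cut(self):
        # median latency exactly ulnar + 0.4 ms counts as prolonged
        at_cut = make_record(d2=ABSENT, d3=ABSENT, apb=ABSENT,
                             lum_med=(3.5, 1.0), lum_uln=(3.1, 3.5))
        below = make_record(d2=ABSENT, d3=ABSENT, apb=ABSENT,
                            lum_med=(3.4, 1.0), lum_uln=(3.1, 3.5))
        assert classify_revised(at_cut).value == 7
        assert classify_revised(below).is_indeterminate
        assert "lumbrical_pattern_atypical" in classify_revised(below).reasons


def _region_oracle(scv, samp, dml, mamp, mcv, interpeak):
    """Independent restatement of the measurable-pathway grade regions
    (digit III measured): returns the grade or None for the gaps."""
    motor_normal = dml <= 4.2 and mamp >= 5 and mcv >= 50
    dml_only = dml > 4.2 and mamp >= 5 and mcv >= 50
    if samp < 5:
        return None
    if scv < 40:
        return 4 if motor_normal else (5 if dml_only else None)
    if scv < 45:
        return 2 if motor_normal else (3 if dml_only else None)
    if scv <= 50:
        early = interpeak is not None and interpeak > 0.5
        if early:
            return 1 if (dml <= 4.2 and mamp >= 5) else None
        return 0 if motor_normal else None
    return 0 if motor_normal else None


class TestMutualExclusivity:
    SCV = [29.9, 30.0, 39.9, 40.0, 44.9, 45.0, 47.0, 50.0, 50.1, 55.0]
    SAMP = [4.9, 5.0, 8.0]
    DML = [4.1, 4.2, 4.3, 5.5]
    MAMP = [4.9, 5.0, 8.0]
    MCV = [49.9, 50.0, 55.0]
    INTERPEAK = [None, 0.5, 0.6]

    def test_exactly_one_scv_band_contains_each_value(self):
        for scv in self.SCV:
            bands = [scv > 50, 45 <= scv <= 50, 40 <= scv < 45, scv < 40]
            assert sum(bands) == 1, scv

    def test_grid_agrees_with_independent_region_oracle(self):
        """Threshold-adjacent grid: the cascade's answer equals the region
        oracle's, so no two rule regions can claim the same record."""
        for scv, samp, dml, mamp, mcv, ip in itertools.product(
            self.SCV, self.SAMP, self.DML, self.MAMP, self.MCV, self.INTERPEAK
        ):
            d4 = None if ip is None else (46.0, 8.0, ip)
            record = make_record(d3=(scv, samp), d4=d4, apb=(dml, mamp, mcv))
            got = classify_revised(record)
            expected = _region_oracle(scv, samp, dml, mamp, mcv, ip)
            assert got.value == expected, (scv, samp, dml, mamp, mcv, ip, got)
            if expected is None:
                assert got.reasons


class TestMonotonicity:
    def test_scv_descent_is_grade_nondecreasing(self):
        """Holding amplitudes and motor normal (digit IV interpeak 0.8 ms),
        velocity 55 -> 47 -> 42 -> 35 walks grades 0 -> 1 -> 2 -> 4."""
        grades = []
        for scv in (55.0, 47.0, 42.0, 35.0):
            d4 = (46.0, 8.0, 0.8) if 45 <= scv <= 50 else None
            grades.append(classify_revised(
                make_record(d3=(scv, 9.0), d4=d4, apb=(3.5, 8.0, 55.0))).value)
        assert grades == [0, 1, 2, 4]
        assert grades == sorted(grades)

    def test_prolonged_dml_shifts_sensory_grades_to_sensory_motor(self):
        for scv, expected in ((42.0, 3), (35.0, 5)):
            g = classify_revised(make_record(d3=(scv, 9.0), apb=(5.0, 8.0, 55.0)))
            assert g.value == expected


class TestTreatmentBand:
    @pytest.mark.parametrize(
        "value, band",
        [
            (0, TreatmentBand.NONE),
            (1, TreatmentBand.PHYSIOTHERAPY),
            (2, TreatmentBand.PHYSIOTHERAPY),
            (3, TreatmentBand.CONSERVATIVE_OR_STEROID),
            (4, TreatmentBand.CONSERVATIVE_OR_STEROID),
            (5, TreatmentBand.SURGICAL),
            (6, TreatmentBand.SURGICAL),
            (7, TreatmentBand.SURGICAL),
            (8, TreatmentBand.SURGEON_JUDGEMENT),
        ],
    )
    def test_bands(self, value, band):
        assert treatment_band(RevisedGrade(value=value)) is band

    def test_indeterminate_has_no_band(self):
        with pytest.raises(ValueError):
            treatment_band(RevisedGrade(value=None, reasons=("amplitude_gap",)))


class TestThresholds:
    def test_default_cut_points(self):
        t = GradingThresholds()
        assert (t.scv_normal_min, t.scv_early_min, t.scv_mild_min, t.scv_severe_max) == (50, 45, 40, 30)
        assert (t.dml_normal_max, t.interpeak_early_min) == (4.2, 0.5)

    def test_band_ordering_is_enforced(self):
        with pytest.raises(ValueError):
            GradingThresholds(scv_mild_min=46.0)  # would cross the early cut
        with pytest.raises(ValueError):
            GradingThresholds(dml_normal_max=-1.0)

    def test_configurable_lumbrical_cut(self):
        record = make_record(d2=ABSENT, d3=ABSENT, apb=ABSENT,
                             lum_med=(3.4, 1.0), lum_uln=(3.1, 3.5))
        loose = GradingThresholds(lumbrical_latency_diff_min=0.3)
        assert classify_revised(record, loose).value == 7
        assert classify_revised(record).is_indeterminate


def _sensory_strategy(draw, digit):
    status = draw(st.sampled_from(list(Status)))
    if status is not Status.MEASURED:
        return SensoryMeasurement(digit=digit, status=status)
    kwargs = dict(
        conduction_velocity=draw(st.floats(5, 80).map(lambda x: round(x, 1))),
        amplitude=draw(st.floats(0, 30).map(lambda x: round(x, 1))),
    )
    if digit is Digit.IV and draw(st.booleans()):
        kwargs["interpeak_latency"] = draw(st.floats(0, 3).map(lambda x: round(x, 1)))
    return SensoryMeasurement(digit=digit, status=Status.MEASURED, **kwargs)


def _motor_strategy(draw, site):
    status = draw(st.sampled_from(list(Status)))
    if status is not Status.MEASURED:
        return MotorMeasurement(site=site, status=status)
    kwargs = dict(
        distal_latency=draw(st.floats(1, 12).map(lambda x: round(x, 1))),
        amplitude=draw(st.floats(0, 20).map(lambda x: round(x, 1))),
    )
    if site is MotorSite.APB:
        kwargs["conduction_velocity"] = draw(st.floats(10, 80).map(lambda x: round(x, 1)))
    return MotorMeasurement(site=site, status=Status.MEASURED, **kwargs)


@st.composite
def ncs_records(draw):
    return NCSRecord(
        patient_id="H0001",
        hand=Hand.LEFT,
        age=draw(st.floats(18, 98)),
        sex=Sex.UNKNOWN,
        symptomatic=draw(st.booleans()),
        sensory={d: _sensory_strategy(draw, d) for d in Digit},
        motor_apb=_motor_strategy(draw, MotorSite.APB),
        lumbrical_median=_motor_strategy(draw, MotorSite.MEDIAN_2ND_LUMBRICAL),
        lumbrical_ulnar=_motor_strategy(draw, MotorSite.ULNAR_2ND_LUMBRICAL),
    )


class TestTotalityAndDeterminism:
    @given(record=ncs_records())
    @settings(max_examples=400)
    def test_every_record_gets_exactly_one_outcome(self, record):
        g = classify_revised(record)
        assert isinstance(g, RevisedGrade)
        if g.value is None:
            assert g.reasons, "Indeterminate must carry a diagnostic reason"
        else:
            assert 0 <= g.value <= 8
        for reason in g.reasons:
            assert reason in GRADING_REASON_MESSAGES

    @given(record=ncs_records())
    @settings(max_examples=150)
    def test_classification_is_pure(self, record):
        assert classify_revised(record) == classify_revised(record)
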