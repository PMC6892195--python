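"""The revised nine-grade (0-8) CTS nerve-conduction severity cascade.

The scale splits severity by which median-nerve fascicles are measurably
involved: a purely sensory slowing (conduction velocity bands 45-50, 40-44.9,
< 40 m/s), sensory plus distal motor slowing (DML > 4.2 ms), near-loss of the
standard responses with preserved 2nd-lumbrical recordings, and finally
complete absence of every median response with the ulnar 2nd-lumbrical intact
as the technical control. Rules are evaluated most-severe-first; a record
matching none of the printed criteria is refused as Indeterminate rather
than forced into a nearby grade.

Boundary conventions (all configurable via :class:`GradingThresholds`):

* Normal sensory velocity is strictly above 50 m/s; the early band [45, 50]
  is inclusive at both ends; the mild band is [40, 45); moderate is < 40.
* Abnormal distal motor latency means DML strictly greater than 4.2 ms —
  exactly 4.2 is normal, keeping the normal and sensory-motor bands disjoint.
* Amplitude normality is >= 5 (μV sensory, mV motor); the severe sensory
  cut is < 3 μV. A measured sensory amplitude below 5 μV that does not meet
  the severe pattern falls in a gap the scale does not define and comes back
  Indeterminate (``amplitude_gap``).
* "Prolonged" median 2nd-lumbrical latency at grade 7 is quantified as
  median >= ulnar + 0.4 ms (no published figure exists; the default is an
  explicit, documented choice) and "low amplitude" as strictly below ulnar.

Comparisons are exact — no epsilon. Clinical readings carry at most one
decimal, so ties land deliberately on the conventions above.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

from .ncs_model import Digit, NCSRecord, RevisedGrade, Status

__all__ = [
    "GradingThresholds",
    "DEFAULT_THRESHOLDS",
    "TreatmentBand",
    "classify_revised",
    "treatment_band",
    "GRADING_REASON_MESSAGES",
]


@dataclass(frozen=True)
class GradingThresholds:
    """Cut points of the revised scale, defaulted to its published values.

    Units: velocities m/s, latencies ms, sensory amplitudes μV, motor
    amplitudes mV. The four SCV cuts induce the contiguous bands
    (scv_mild_min, scv_early_min, scv_normal_min partition (0, inf)), so band
    overlap is impossible by construction.
    """

    scv_normal_min: float = 50.0   # Normal requires SCV strictly above this
    scv_early_min: float = 45.0    # Early band is [scv_early_min, scv_normal_min]
    scv_mild_min: float = 40.0     # Mild band is [scv_mild_min, scv_early_min)
    scv_severe_max: float = 30.0   # severe pattern requires measured SCV below this
    sensory_amp_normal_min: float = 5.0
    sensory_amp_severe_max: float = 3.0
    dml_normal_max: float = 4.2    # DML strictly greater than this is abnormal
    motor_amp_normal_min: float = 5.0
    mcv_normal_min: float = 50.0
    interpeak_early_min: float = 0.5   # digit IV double peak strictly above this
    lumbrical_latency_diff_min: float = 0.4  # median minus ulnar lumbrical latency

    def __post_init__(self) -> None:
        if not (0 < self.scv_severe_max < self.scv_mild_min
                < self.scv_early_min < self.scv_normal_min):
            raise ValueError("SCV cut points must satisfy 0 < severe < mild < early < normal")
        for name in ("sensory_amp_normal_min", "sensory_amp_severe_max",
                     "dml_normal_max", "motor_amp_normal_min", "mcv_normal_min",
                     "interpeak_early_min", "lumbrical_latency_diff_min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.sensory_amp_severe_max > self.sensory_amp_normal_min:
            raise ValueError("severe sensory amplitude cut cannot exceed the normal minimum")


DEFAULT_THRESHOLDS = GradingThresholds()


#: One-line renderings for every grading reason code (fired criteria,
#: advisories and Indeterminate diagnostics alike).
GRADING_REASON_MESSAGES: dict[str, str] = {
    # fired criteria
    "scv_normal": "digit III sensory conduction velocity above the normal cut",
    "scv_early_band": "digit III sensory conduction velocity in the early (45-50 m/s) band",
    "scv_mild_band": "digit III sensory conduction velocity in the mild (40-44.9 m/s) band",
    "scv_moderate_band": "digit III sensory conduction velocity below 40 m/s",
    "double_peak_positive": "digit IV double-peak interpeak latency above 0.5 ms",
    "sensory_amp_normal": "sensory amplitude at or above the 5 uV normal minimum",
    "severe_sensory_pattern": "digits II and III absent, or both below 3 uV with digit III velocity below 30 m/s",
    "sensory_absent": "no recordable median sensory response from digits II and III",
    "motor_normal": "distal motor latency, motor amplitude and motor conduction velocity all normal",
    "dml_prolonged": "distal motor latency above the 4.2 ms normal maximum",
    "apb_absent": "no recordable motor response from abductor pollicis brevis",
    "median_lumbrical_prolonged_low": "median 2nd-lumbrical response prolonged and lower-amplitude than the ulnar 2nd-lumbrical",
    "median_lumbrical_absent": "no recordable median 2nd-lumbrical response",
    "ulnar_lumbrical_present": "ulnar 2nd-lumbrical response recordable (technical control intact)",
    # advisories on a determinate grade
    "early_criteria_not_met": "velocity in the 45-50 m/s band without a positive digit IV double peak; no positive early finding, graded Normal",
    # Indeterminate diagnostics
    "digit_III_missing": "digit III was not tested, so no sensory rule can be evaluated",
    "digit_II_missing": "digit III is absent but digit II was not tested; the absent-response rules need both",
    "sensory_pattern_unclassifiable": "the digit II/III status combination matches no printed sensory pattern",
    "amplitude_gap": "measured sensory amplitude below 5 uV outside the severe pattern; the scale defines no grade here",
    "isolated_motor_abnormality": "abnormal motor values with fully normal sensory findings; the scale requires sensory involvement",
    "motor_values_out_of_band": "motor amplitude or conduction velocity abnormal in a pattern no printed grade covers",
    "severe_sensory_normal_motor": "severe sensory loss with a normal distal motor latency; the scale defines no grade here",
    "apb_missing": "the APB motor study needed by every reachable rule is missing",
    "lumbricals_missing": "all standard responses absent but 2nd-lumbrical recordings are missing; cannot separate extremely-severe from complete loss",
    "lumbrical_pattern_atypical": "2nd-lumbrical responses present but not in the prolonged/low-amplitude median pattern",
}


class TreatmentBand(str, Enum):
    NONE = "none"
    PHYSIOTHERAPY = "physiotherapy"
    CONSERVATIVE_OR_STEROID = "conservative_or_steroid"
    SURGICAL = "surgical"
    SURGEON_JUDGEMENT = "surgeon_judgement"


def _grade(value: int, *reasons: str) -> RevisedGrade:
    return RevisedGrade(value=value, reasons=tuple(reasons))


def _indeterminate(*reasons: str) -> RevisedGrade:
    return RevisedGrade(value=None, reasons=tuple(reasons))


def classify_revised(
    record: NCSRecord, thresholds: Optional[GradingThresholds] = None
) -> RevisedGrade:
    """Grade one hand on the revised 0-8 scale.

    Pure and total: a structurally valid record always yields exactly one
    determinate grade or an Indeterminate result whose reasons say which
    measurement was missing or which printed pattern the record fell between.
    Protocol warnings from :func:`~ctsgrade.ncs_model.validate_record` do not
    block grading.
    """
    t = thresholds or DEFAULT_THRESHOLDS
    d2 = record.sensory[Digit.II]
    d3 = record.sensory[Digit.III]
    d4 = record.sensory[Digit.IV]
    apb = record.motor_apb

    if d3.status is Status.NOT_TESTED:
        return _indeterminate("digit_III_missing")

    # ---- absent-response pathway (grades 6-8) ------------------------------
    sensory_absent = d3.status is Status.ABSENT and d2.status is Status.ABSENT

    if sensory_absent and apb.status is Status.ABSENT:
        lm, lu = record.lumbrical_median, record.lumbrical_ulnar
        if lm.status is Status.ABSENT and lu.status is Status.MEASURED:
            return _grade(
                8, "sensory_absent", "apb_absent",
                "median_lumbrical_absent", "ulnar_lumbrical_present",
            )
        if lm.status is Status.MEASURED and lu.status is Status.MEASURED:
            prolonged = (
                lm.distal_latency is not None
                and lu.distal_latency is not None
                and lm.distal_latency >= lu.distal_latency + t.lumbrical_latency_diff_min
            )
            low_amplitude = (
                lm.amplitude is not None
                and lu.amplitude is not None
                and lm.amplitude < lu.amplitude
            )
            if prolonged and low_amplitude:
                return _grade(
                    7, "sensory_absent", "apb_absent", "median_lumbrical_prolonged_low",
                )
            return _indeterminate("lumbrical_pattern_atypical")
        return _indeterminate("lumbricals_missing")

    if d3.status is Status.ABSENT and not sensory_absent:
        # digit III gone but digit II not confirming the pattern
        if d2.status is Status.NOT_TESTED:
            return _indeterminate("digit_II_missing")
        return _indeterminate("sensory_pattern_unclassifiable")

    # ---- grade 6: severe sensory pattern with prolonged DML ----------------
    severe_measured = (
        d3.status is Status.MEASURED
        and d2.status is Status.MEASURED
        and d3.amplitude < t.sensory_amp_severe_max
        and d2.amplitude < t.sensory_amp_severe_max
        and d3.conduction_velocity < t.scv_severe_max
    )
    if sensory_absent or severe_measured:
        if apb.status is Status.MEASURED:
            if apb.distal_latency > t.dml_normal_max:
                # MCV slow or normal and low motor amplitude are both permitted
                return _grade(6, "severe_sensory_pattern", "dml_prolonged")
            return _indeterminate("severe_sensory_normal_motor")
        return _indeterminate("apb_missing")

    # ---- graded (measurable) pathway, digit III measured from here ---------
    scv = d3.conduction_velocity
    if d3.amplitude < t.sensory_amp_normal_min:
        return _indeterminate("amplitude_gap")

    if apb.status is not Status.MEASURED:
        return _indeterminate("apb_missing")
    dml_ok = apb.distal_latency <= t.dml_normal_max
    motor_rest_ok = (
        apb.amplitude >= t.motor_amp_normal_min
        and apb.conduction_velocity is not None
        and apb.conduction_velocity >= t.mcv_normal_min
    )
    motor_normal = dml_ok and motor_rest_ok

    if scv < t.scv_mild_min:  # moderate band, SCV < 40
        if motor_normal:
            return _grade(4, "scv_moderate_band", "sensory_amp_normal", "motor_normal")
        if not dml_ok and motor_rest_ok:
            return _grade(5, "scv_moderate_band", "sensory_amp_normal", "dml_prolonged")
        return _indeterminate("motor_values_out_of_band")

    if scv < t.scv_early_min:  # mild band, [40, 45)
        if motor_normal:
            return _grade(2, "scv_mild_band", "sensory_amp_normal", "motor_normal")
        if not dml_ok and motor_rest_ok:
            return _grade(3, "scv_mild_band", "sensory_amp_normal", "dml_prolonged")
        return _indeterminate("motor_values_out_of_band")

    if scv <= t.scv_normal_min:  # early band, [45, 50]
        early_positive = (
            d4.status is Status.MEASURED
            and d4.interpeak_latency is not None
            and d4.interpeak_latency > t.interpeak_early_min
        )
        if early_positive:
            if dml_ok and apb.amplitude >= t.motor_amp_normal_min:
                return _grade(1, "scv_early_band", "double_peak_positive", "sensory_amp_normal")
            return _indeterminate("motor_values_out_of_band")
        # no positive early finding: treated as normal sensory
        if motor_normal:
            return _grade(0, "scv_early_band", "early_criteria_not_met", "motor_normal")
        return _indeterminate("isolated_motor_abnormality")

    # SCV strictly above the normal cut
    if motor_normal:
        return _grade(0, "scv_normal", "sensory_amp_normal", "motor_normal")
    return _indeterminate("isolated_motor_abnormality")


_TREATMENT_BANDS: dict[int, TreatmentBand] = {
    0: TreatmentBand.NONE,
    1: TreatmentBand.PHYSIOTHERAPY,
    2: TreatmentBand.PHYSIOTHERAPY,
    3: TreatmentBand.CONSERVATIVE_OR_STEROID,
    4: TreatmentBand.CONSERVATIVE_OR_STEROID,
    5: TreatmentBand.SURGICAL,
    6: TreatmentBand.SURGICAL,
    7: TreatmentBand.SURGICAL,
    8: TreatmentBand.SURGEON_JUDGEMENT,
}


def treatment_band(grade: RevisedGrade) -> TreatmentBand:
    """Advisory treatment band for a determinate grade.

    Grades 1-2 suggest physiotherapy, 3-4 conservative or steroid
    intervention, 5-7 surgical decompression; grade 8 is left to the
    surgeon's judgement on the individual case; grade 0 needs none. The
    output is advisory only — it never replaces clinical decision-making,
    and any rendering of it should say so.
    """
    if grade.is_indeterminate:
        raise ValueError("treatment band is undefined for an Indeterminate grade")
    return _TREATMENT_BANDS[grade.value]
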