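"""The Bland comparator scale (grades 0-6) and its correspondence to the
revised 0-8 scale.

The Bland scale grades CTS severity mainly on the distal motor latency
(DML): mild disease is sensory slowing (SCV < 40 m/s) with DML < 4.5 ms,
moderately-severe and severe occupy the 4.5-6.5 ms DML band (split on
whether the sensory response survives), very severe is DML > 6.5 ms and
extremely severe is a motor amplitude below 0.2 mV. Grade 1 in the original
scale rests on comparative tests (inching, palm/wrist ratios, ring-finger
double peak); only the ring-finger double peak is representable in this
package's record schema, so grade 1 is operationalised as a positive digit-IV
interpeak with otherwise-normal standard studies — a documented narrowing.

Precedence is most-severe-first; in particular a hand with both DML > 6.5 ms
and motor amplitude < 0.2 mV takes grade 6 (amplitude is the grade-6
discriminator). A record matching no positive rule is grade 0.
"""

from __future__ import annotations

from typing import Optional

from .ncs_model import BlandGrade, Digit, NCSRecord, RevisedGrade, Status

__all__ = [
    "classify_bland",
    "map_grades",
    "revised_to_bland",
    "BLAND_TO_REVISED",
    "MNAP_EXTREMELY_SEVERE_MAX",
    "DML_MODERATE_MIN",
    "DML_VERY_SEVERE_MIN",
    "SCV_MILD_MAX",
    "INTERPEAK_MIN",
]

MNAP_EXTREMELY_SEVERE_MAX = 0.2  # mV, grade 6 cut
DML_MODERATE_MIN = 4.5           # ms, grades 3/4 occupy the open band (4.5, 6.5)
DML_VERY_SEVERE_MIN = 6.5        # ms, grade 5 is strictly above
SCV_MILD_MAX = 40.0              # m/s, grade 2 requires SCV below this
INTERPEAK_MIN = 0.5              # ms, ring-finger double peak for grade 1


#: Static correspondence between the Bland scale and the revised scale: the
#: revised scale splits Bland's mild (2) and moderate (3) categories into
#: sensory vs sensory-motor pairs and appends the lumbrical-resolved grades.
BLAND_TO_REVISED: dict[int, frozenset[int]] = {
    0: frozenset({0}),
    1: frozenset({1}),
    2: frozenset({2, 3}),
    3: frozenset({4, 5}),
    4: frozenset({6}),
    5: frozenset({7}),
    6: frozenset({8}),
}

_REVISED_TO_BLAND: dict[int, int] = {
    h: b for b, hs in BLAND_TO_REVISED.items() for h in hs
}


def classify_bland(record: NCSRecord) -> BlandGrade:
    """Grade one hand on the Bland 0-6 scale.

    Pure and total up to Indeterminate: every rule above grade 1 needs the
    APB motor study, so a record without it cannot be graded. Grade 0 is the
    explicit fallthrough for records matching no positive rule (which
    includes the measure-zero DML == 6.5 ms boundary, excluded from both the
    open moderate band and the > 6.5 ms rule as transcribed).
    """
    apb = record.motor_apb
    d3 = record.sensory[Digit.III]
    d4 = record.sensory[Digit.IV]

    if apb.status is Status.NOT_TESTED:
        return BlandGrade(value=None, reasons=("apb_missing",))
    if apb.status is Status.ABSENT:
        # the scale's severe end is defined on measured amplitude/latency
        return BlandGrade(value=None, reasons=("apb_absent_ungradable",))

    if apb.amplitude < MNAP_EXTREMELY_SEVERE_MAX:
        return BlandGrade(value=6)
    dml = apb.distal_latency
    if dml > DML_VERY_SEVERE_MIN:
        return BlandGrade(value=5)
    if DML_MODERATE_MIN < dml < DML_VERY_SEVERE_MIN:
        if d3.status is Status.ABSENT:
            return BlandGrade(value=4)
        if d3.status is Status.MEASURED:
            return BlandGrade(value=3)
        return BlandGrade(value=None, reasons=("digit_III_missing",))

    if (
        d3.status is Status.MEASURED
        and d3.conduction_velocity < SCV_MILD_MAX
        and dml <= DML_MODERATE_MIN
    ):
        return BlandGrade(value=2)

    if (
        d3.status is Status.MEASURED
        and d4.status is Status.MEASURED
        and d4.interpeak_latency is not None
        and d4.interpeak_latency > INTERPEAK_MIN
    ):
        return BlandGrade(value=1)

    return BlandGrade(value=0)


def map_grades(bland: BlandGrade | int) -> frozenset[int]:
    """The set of revised-scale grades a Bland grade corresponds to."""
    value = bland.value if isinstance(bland, BlandGrade) else int(bland)
    if value is None:
        raise ValueError("no correspondence for an Indeterminate Bland grade")
    try:
        return BLAND_TO_REVISED[value]
    except KeyError:
        raise ValueError(f"Bland grade must be 0-6, got {value}") from None


def revised_to_bland(revised: RevisedGrade | int) -> int:
    """The Bland grade a revised-scale grade corresponds to (total on 0-8)."""
    value = revised.value if isinstance(revised, RevisedGrade) else int(revised)
    if value is None:
        raise ValueError("no correspondence for an Indeterminate grade")
    try:
        return _REVISED_TO_BLAND[value]
    except KeyError:
        raise ValueError(f"revised grade must be 0-8, got {value}") from None
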