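"""Domain types for nerve conduction study (NCS) records.

A record holds one hand's median-nerve workup: orthodromic sensory studies
from digits II/III/IV (conduction velocity in m/s, peak-to-peak amplitude in
μV, plus the ring-finger "double peak" interpeak latency for digit IV), the
median motor study recorded at abductor pollicis brevis (distal motor latency
in ms, base-to-peak amplitude in mV, forearm conduction velocity in m/s), and
the second-lumbrical recordings from median and ulnar wrist stimulation used
to separate extremely-severe from complete median dysfunction.

Every measurement carries a three-valued status: ``measured`` (values
present), ``absent`` (the nerve was stimulated and no response could be
recorded — a clinical finding in its own right) and ``not_tested`` (the site
was skipped, usually because the conditional testing protocol did not call
for it). Collapsing ``absent`` and ``not_tested`` into a single null would
make a complete median lesion indistinguishable from missing data, so the
distinction is enforced structurally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional

__all__ = [
    "Digit",
    "Status",
    "Hand",
    "Sex",
    "MotorSite",
    "SensoryMeasurement",
    "MotorMeasurement",
    "NCSRecord",
    "RevisedGrade",
    "BlandGrade",
    "MeasurementError",
    "REVISED_LABELS",
    "BLAND_LABELS",
    "VIOLATION_MESSAGES",
    "validate_record",
]


class MeasurementError(ValueError):
    """A structurally invalid measurement or record (hard rejection)."""


class Digit(str, Enum):
    II = "II"
    III = "III"
    IV = "IV"


class Status(str, Enum):
    MEASURED = "measured"
    ABSENT = "absent"
    NOT_TESTED = "not_tested"


class Hand(str, Enum):
    LEFT = "left"
    RIGHT = "right"


class Sex(str, Enum):
    F = "F"
    M = "M"
    UNKNOWN = "unknown"


class MotorSite(str, Enum):
    APB = "apb"
    MEDIAN_2ND_LUMBRICAL = "median_2nd_lumbrical"
    ULNAR_2ND_LUMBRICAL = "ulnar_2nd_lumbrical"
    FDI = "fdi"


#: Sites that carry latency + amplitude only (no forearm segment, hence no CV).
_LUMBRICAL_SITES = frozenset(
    {MotorSite.MEDIAN_2ND_LUMBRICAL, MotorSite.ULNAR_2ND_LUMBRICAL}
)


@dataclass(frozen=True)
class SensoryMeasurement:
    """One digit's antidromic/orthodromic sensory study.

    ``conduction_velocity`` (m/s) and ``amplitude`` (μV, peak to peak) are
    present iff ``status`` is measured. ``interpeak_latency`` (ms) is the
    ring-finger double-peak interval and is only meaningful on digit IV.
    """

    digit: Digit
    status: Status
    conduction_velocity: Optional[float] = None
    amplitude: Optional[float] = None
    interpeak_latency: Optional[float] = None

    def __post_init__(self) -> None:
        if self.status is Status.MEASURED:
            if self.conduction_velocity is None or self.conduction_velocity <= 0:
                raise MeasurementError(
                    f"digit {self.digit.value}: measured sensory response requires "
                    f"conduction velocity > 0, got {self.conduction_velocity}"
                )
            if self.amplitude is None or self.amplitude < 0:
                raise MeasurementError(
                    f"digit {self.digit.value}: measured sensory response requires "
                    f"amplitude >= 0, got {self.amplitude}"
                )
        else:
            for name in ("conduction_velocity", "amplitude", "interpeak_latency"):
                if getattr(self, name) is not None:
                    raise MeasurementError(
                        f"digit {self.digit.value}: {name} set on a "
                        f"{self.status.value} response"
                    )
        if self.interpeak_latency is not None and self.digit is not Digit.IV:
            raise MeasurementError(
                f"interpeak latency is a digit IV quantity, set on digit "
                f"{self.digit.value}"
            )
        if self.interpeak_latency is not None and self.interpeak_latency < 0:
            raise MeasurementError("interpeak latency must be >= 0")


@dataclass(frozen=True)
class MotorMeasurement:
    """One motor recording site.

    ``distal_latency`` in ms, ``amplitude`` in mV (base to peak);
    ``conduction_velocity`` (m/s, forearm segment) only exists for the
    APB/FDI sites — lumbrical recordings carry latency + amplitude only.
    """

    site: MotorSite
    status: Status
    distal_latency: Optional[float] = None
    amplitude: Optional[float] = None
    conduction_velocity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.status is Status.MEASURED:
            if self.distal_latency is None or self.distal_latency <= 0:
                raise MeasurementError(
                    f"{self.site.value}: measured motor response requires distal "
                    f"latency > 0, got {self.distal_latency}"
                )
            if self.amplitude is None or self.amplitude < 0:
                raise MeasurementError(
                    f"{self.site.value}: measured motor response requires "
                    f"amplitude >= 0, got {self.amplitude}"
                )
        else:
            for name in ("distal_latency", "amplitude", "conduction_velocity"):
                if getattr(self, name) is not None:
                    raise MeasurementError(
                        f"{self.site.value}: {name} set on a {self.status.value} response"
                    )
        if self.conduction_velocity is not None and self.site in _LUMBRICAL_SITES:
            raise MeasurementError(
                f"{self.site.value}: lumbrical recordings have no conduction velocity"
            )
        if self.conduction_velocity is not None and self.conduction_velocity <= 0:
            raise MeasurementError("motor conduction velocity must be > 0")


def _not_tested_sensory(digit: Digit) -> SensoryMeasurement:
    return SensoryMeasurement(digit=digit, status=Status.NOT_TESTED)


@dataclass(frozen=True)
class NCSRecord:
    """One hand's full nerve conduction study.

    Missing digits in ``sensory`` are normalised to explicit ``not_tested``
    measurements so downstream rules never see an absent key. Ulnar digit-V
    sensory and FDI motor context recordings may be attached but play no role
    in any grading rule.
    """

    patient_id: str
    hand: Hand
    age: float
    sex: Sex
    symptomatic: bool
    sensory: Mapping[Digit, SensoryMeasurement]
    motor_apb: MotorMeasurement
    lumbrical_median: MotorMeasurement
    lumbrical_ulnar: MotorMeasurement
    sensory_ulnar_d5: Optional[SensoryMeasurement] = None
    motor_fdi: Optional[MotorMeasurement] = None

    def __post_init__(self) -> None:
        if self.age < 0:
            raise MeasurementError(f"age must be non-negative, got {self.age}")
        full = {d: _not_tested_sensory(d) for d in Digit}
        for digit, m in dict(self.sensory).items():
            digit = Digit(digit)
            if m.digit is not digit:
                raise MeasurementError(
                    f"sensory map key {digit.value} holds a measurement for "
                    f"digit {m.digit.value}"
                )
            full[digit] = m
        object.__setattr__(self, "sensory", full)
        if self.motor_apb.site is not MotorSite.APB:
            raise MeasurementError("motor_apb must record from the APB site")
        if self.lumbrical_median.site is not MotorSite.MEDIAN_2ND_LUMBRICAL:
            raise MeasurementError("lumbrical_median must record from median_2nd_lumbrical")
        if self.lumbrical_ulnar.site is not MotorSite.ULNAR_2ND_LUMBRICAL:
            raise MeasurementError("lumbrical_ulnar must record from ulnar_2nd_lumbrical")


# --- grade value objects -----------------------------------------------------

REVISED_LABELS: dict[int, str] = {
    0: "Normal",
    1: "Early",
    2: "Mild Sensory",
    3: "Mild Sensory-Motor",
    4: "Moderate Sensory",
    5: "Moderate Sensory-Motor",
    6: "Severe Sensory-Motor",
    7: "Extremely Severe Sensory-Motor",
    8: "Complete",
}

BLAND_LABELS: dict[int, str] = {
    0: "Normal",
    1: "Very mild",
    2: "Mild",
    3: "Moderately severe",
    4: "Severe",
    5: "Very severe",
    6: "Extremely severe",
}

INDETERMINATE_LABEL = "Indeterminate"


@dataclass(frozen=True)
class RevisedGrade:
    """Ordinal severity grade 0–8 on the revised scale, or Indeterminate.

    ``value`` is None for Indeterminate, in which case ``reasons`` must name
    at least one diagnostic code. For determinate grades ``reasons`` lists
    the criteria that fired (plus any advisory codes such as
    ``early_criteria_not_met``).
    """

    value: Optional[int]
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.value is not None and self.value not in REVISED_LABELS:
            raise ValueError(f"revised grade must be 0-8, got {self.value}")
        if self.value is None and not self.reasons:
            raise ValueError("Indeterminate grade requires at least one reason code")
        object.__setattr__(self, "reasons", tuple(self.reasons))

    @property
    def label(self) -> str:
        return INDETERMINATE_LABEL if self.value is None else REVISED_LABELS[self.value]

    @property
    def is_indeterminate(self) -> bool:
        return self.value is None


@dataclass(frozen=True)
class BlandGrade:
    """Ordinal grade 0–6 on the Bland comparator scale, or Indeterminate."""

    value: Optional[int]
    reasons: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.value is not None and self.value not in BLAND_LABELS:
            raise ValueError(f"Bland grade must be 0-6, got {self.value}")
        if self.value is None and not self.reasons:
            raise ValueError("Indeterminate grade requires at least one reason code")
        object.__setattr__(self, "reasons", tuple(self.reasons))

    @property
    def label(self) -> str:
        return INDETERMINATE_LABEL if self.value is None else BLAND_LABELS[self.value]

    @property
    def is_indeterminate(self) -> bool:
        return self.value is None


# --- protocol validity -------------------------------------------------------

#: One-line human renderings for every protocol violation code.
VIOLATION_MESSAGES: dict[str, str] = {
    "digit_III_missing": "digit III was not tested; it is the primary sensory site and must be attempted on every hand",
    "digit_II_unnecessary": "digit II was tested although digit III responded with amplitude >= 3 uV (protocol stimulates digit II only for low or absent digit III responses)",
    "digit_IV_unnecessary": "digit IV was tested although digit III conduction velocity is outside 45-50 m/s (protocol reserves digit IV for that band)",
    "lumbricals_required": "digits II/III and APB are all absent but 2nd-lumbrical recordings were not obtained; they are required to separate extremely-severe from complete loss",
    "age_below_18": "patient age is below 18 years (outside the scale's inclusion range); grading proceeds, interpret with care",
}


def validate_record(record: NCSRecord) -> list[str]:
    """Check a structurally valid record against the conditional-testing protocol.

    Returns the list of violation codes (keys of :data:`VIOLATION_MESSAGES`),
    empty iff the record is fully protocol-conformant. Violations are
    warnings: grading still proceeds on the data present. The function is
    pure — it inspects the record and never mutates it.
    """
    codes: list[str] = []
    d2 = record.sensory[Digit.II]
    d3 = record.sensory[Digit.III]
    d4 = record.sensory[Digit.IV]

    if d3.status is Status.NOT_TESTED:
        codes.append("digit_III_missing")

    if (
        d3.status is Status.MEASURED
        and d3.amplitude is not None
        and d3.amplitude >= 3.0
        and d2.status is not Status.NOT_TESTED
    ):
        codes.append("digit_II_unnecessary")

    d4_allowed = (
        d3.status is Status.MEASURED
        and d3.conduction_velocity is not None
        and 45.0 <= d3.conduction_velocity <= 50.0
    )
    if d4.status is not Status.NOT_TESTED and not d4_allowed:
        codes.append("digit_IV_unnecessary")

    all_absent = (
        d2.status is Status.ABSENT
        and d3.status is Status.ABSENT
        and record.motor_apb.status is Status.ABSENT
    )
    lumbricals_obtained = (
        record.lumbrical_median.status is not Status.NOT_TESTED
        and record.lumbrical_ulnar.status is not Status.NOT_TESTED
    )
    if all_absent and not lumbricals_obtained:
        codes.append("lumbricals_required")

    if record.age < 18:
        codes.append("age_below_18")

    return codes
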