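"""Record builders shared across the test modules.

``make_record`` takes per-site shorthand: a tuple of measured values,
the string "absent", or None for not tested.

* d2 / d3: (scv, amp)
* d4: (scv, amp, interpeak) — interpeak may be None
* apb: (dml, amp, mcv)
* lum_med / lum_uln: (latency, amp)
"""

from __future__ import annotations

from ctsgrade import (
    Digit,
    Hand,
    MotorMeasurement,
    MotorSite,
    NCSRecord,
    SensoryMeasurement,
    Sex,
    Status,
)

ABSENT = "absent"


def _sensory(digit: Digit, spec):
    if spec is None:
        return SensoryMeasurement(digit=digit, status=Status.NOT_TESTED)
    if spec == ABSENT:
        return SensoryMeasurement(digit=digit, status=Status.ABSENT)
    if digit is Digit.IV:
        scv, amp, interpeak = spec
        return SensoryMeasurement(
            digit=digit, status=Status.MEASURED,
            conduction_velocity=scv, amplitude=amp, interpeak_latency=interpeak,
        )
    scv, amp = spec
    return SensoryMeasurement(
        digit=digit, status=Status.MEASURED, conduction_velocity=scv, amplitude=amp
    )


def _motor(site: MotorSite, spec):
    if spec is None:
        return MotorMeasurement(site=site, status=Status.NOT_TESTED)
    if spec == ABSENT:
        return MotorMeasurement(site=site, status=Status.ABSENT)
    if site is MotorSite.APB:
        dml, amp, mcv = spec
        return MotorMeasurement(
            site=site, status=Status.MEASURED,
            distal_latency=dml, amplitude=amp, conduction_velocity=mcv,
        )
    lat, amp = spec
    return MotorMeasurement(
        site=site, status=Status.MEASURED, distal_latency=lat, amplitude=amp
    )


def make_record(
    *,
    d2=None,
    d3=(55.0, 12.0),
    d4=None,
    apb=(3.5, 8.0, 55.0),
    lum_med=None,
    lum_uln=None,
    age=50.0,
    sex=Sex.F,
    hand=Hand.LEFT,
    symptomatic=True,
    patient_id="T0001",
) -> NCSRecord:
    return NCSRecord(
        patient_id=patient_id,
        hand=hand,
        age=age,
        sex=sex,
        symptomatic=symptomatic,
        sensory={
            Digit.II: _sensory(Digit.II, d2),
            Digit.III: _sensory(Digit.III, d3),
            Digit.IV: _sensory(Digit.IV, d4),
        },
        motor_apb=_motor(MotorSite.APB, apb),
        lumbrical_median=_motor(MotorSite.MEDIAN_2ND_LUMBRICAL, lum_med),
        lumbrical_ulnar=_motor(MotorSite.ULNAR_2ND_LUMBRICAL, lum_uln),
    )
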