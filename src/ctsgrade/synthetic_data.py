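"""Seeded generator of synthetic NCS records with known true grades.

Each hand is drawn by first sampling a target grade from a configurable
grade mix, then sampling measurement values uniformly from the *interior* of
that grade's defining region — at least one jitter-scale away from every
decision threshold — so that the grading cascade recovers the target grade
exactly by construction. Boundary behaviour is deliberately not exercised
here; it is pinned by hand-written witness tests against the grader.

The conditional-testing protocol is honoured: digit IV is populated only
when the drawn digit III velocity lies in the 45-50 m/s band, digit II only
when the digit III response is below 3 μV or absent, and the 2nd-lumbrical
recordings only on the absent-response pathway (grades 7-8; the severe
grade 6 keeps a recordable APB, so lumbricals stay untested).

Values are rounded to one decimal, matching the precision of real clinical
readings; the default jitter scales exceed the rounding step so rounding
never crosses a threshold.

Demographics default to the study cohort's shape: ages 19-98 with median
about 56 (clipped normal) and a 687:436 female:male ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .cohort_stats import load_reference
from .ncs_model import (
    Digit,
    Hand,
    MotorMeasurement,
    MotorSite,
    NCSRecord,
    REVISED_LABELS,
    SensoryMeasurement,
    Sex,
    Status,
)
from .revised_grader import DEFAULT_THRESHOLDS, GradingThresholds

__all__ = ["GeneratorConfig", "SyntheticHand", "generate", "generate_paper_mix"]


def _uniform_mix() -> dict[int, float]:
    return {g: 1.0 / 9.0 for g in range(9)}


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration for the synthetic cohort generator.

    ``grade_mix`` maps grade 0-8 to sampling probability (must sum to 1);
    the jitter fields are the minimum distances kept from every grading
    threshold, in the measurement's own unit (m/s, ms, μV, mV).
    """

    n_hands: int
    grade_mix: Mapping[int, float] = field(default_factory=_uniform_mix)
    seed: int = 0
    scv_jitter: float = 0.5
    latency_jitter: float = 0.2
    sensory_amp_jitter: float = 0.5
    motor_amp_jitter: float = 0.5
    age_min: float = 19.0
    age_max: float = 98.0
    age_center: float = 56.0
    age_spread: float = 15.0
    female_fraction: float = 687 / 1123

    def __post_init__(self) -> None:
        if self.n_hands < 0:
            raise ValueError("n_hands must be non-negative")
        bad_keys = [k for k in self.grade_mix if not (isinstance(k, int) and 0 <= k <= 8)]
        if bad_keys:
            raise ValueError(
                f"grade_mix keys must be integer grades 0-8 (no Indeterminate mass); got {bad_keys}"
            )
        total = float(sum(self.grade_mix.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"grade_mix probabilities must sum to 1, got {total}")
        if any(p < 0 for p in self.grade_mix.values()):
            raise ValueError("grade_mix probabilities must be non-negative")
        for name in ("scv_jitter", "latency_jitter", "sensory_amp_jitter", "motor_amp_jitter"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.female_fraction <= 1:
            raise ValueError("female_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class SyntheticHand:
    """A generated record together with the grade it was sampled to have."""

    record: NCSRecord
    true_grade: int


def _r1(x: float) -> float:
    """One-decimal rounding, the precision of real machine readouts."""
    return round(float(x), 1)


def _u(rng: np.random.Generator, lo: float, hi: float) -> float:
    return _r1(rng.uniform(lo, hi))


def _not_tested(digit: Digit) -> SensoryMeasurement:
    return SensoryMeasurement(digit=digit, status=Status.NOT_TESTED)


def _absent(digit: Digit) -> SensoryMeasurement:
    return SensoryMeasurement(digit=digit, status=Status.ABSENT)


def _motor(site: MotorSite, status: Status, **kw) -> MotorMeasurement:
    return MotorMeasurement(site=site, status=status, **kw)


def _normal_apb(rng, t: GradingThresholds, cfg: GeneratorConfig) -> MotorMeasurement:
    return _motor(
        MotorSite.APB,
        Status.MEASURED,
        distal_latency=_u(rng, 2.5, t.dml_normal_max - cfg.latency_jitter),
        amplitude=_u(rng, t.motor_amp_normal_min + cfg.motor_amp_jitter, 15.0),
        conduction_velocity=_u(rng, t.mcv_normal_min + cfg.scv_jitter, 65.0),
    )


def _prolonged_dml_apb(rng, t, cfg) -> MotorMeasurement:
    return _motor(
        MotorSite.APB,
        Status.MEASURED,
        distal_latency=_u(rng, t.dml_normal_max + cfg.latency_jitter, 6.5),
        amplitude=_u(rng, t.motor_amp_normal_min + cfg.motor_amp_jitter, 15.0),
        conduction_velocity=_u(rng, t.mcv_normal_min + cfg.scv_jitter, 65.0),
    )


def _normal_sensory_amp(rng, t, cfg) -> float:
    return _u(rng, t.sensory_amp_normal_min + cfg.sensory_amp_jitter, 25.0)


def _sample_measurements(
    rng: np.random.Generator, grade: int, cfg: GeneratorConfig, t: GradingThresholds
) -> dict:
    """Sensory map, APB and lumbrical measurements for one target grade."""
    sensory: dict[Digit, SensoryMeasurement] = {
        Digit.II: _not_tested(Digit.II),
        Digit.IV: _not_tested(Digit.IV),
    }
    lum_med = _motor(MotorSite.MEDIAN_2ND_LUMBRICAL, Status.NOT_TESTED)
    lum_uln = _motor(MotorSite.ULNAR_2ND_LUMBRICAL, Status.NOT_TESTED)

    if grade == 0:
        sensory[Digit.III] = SensoryMeasurement(
            Digit.III, Status.MEASURED,
            conduction_velocity=_u(rng, t.scv_normal_min + cfg.scv_jitter, 65.0),
            amplitude=_normal_sensory_amp(rng, t, cfg),
        )
        apb = _normal_apb(rng, t, cfg)
    elif grade == 1:
        sensory[Digit.III] = SensoryMeasurement(
            Digit.III, Status.MEASURED,
            conduction_velocity=_u(
                rng, t.scv_early_min + cfg.scv_jitter, t.scv_normal_min - cfg.scv_jitter
            ),
            amplitude=_normal_sensory_amp(rng, t, cfg),
        )
        sensory[Digit.IV] = SensoryMeasurement(
            Digit.IV, Status.MEASURED,
            conduction_velocity=_u(rng, 40.0, 55.0),
            amplitude=_u(rng, 5.0, 20.0),
            interpeak_latency=_u(
                rng, t.interpeak_early_min + cfg.latency_jitter, 1.5
            ),
        )
        apb = _normal_apb(rng, t, cfg)
    elif grade in (2, 3):
        sensory[Digit.III] = SensoryMeasurement(
            Digit.III, Status.MEASURED,
            conduction_velocity=_u(
                rng, t.scv_mild_min + cfg.scv_jitter, t.scv_early_min - cfg.scv_jitter
            ),
            amplitude=_normal_sensory_amp(rng, t, cfg),
        )
        apb = _normal_apb(rng, t, cfg) if grade == 2 else _prolonged_dml_apb(rng, t, cfg)
    elif grade in (4, 5):
        sensory[Digit.III] = SensoryMeasurement(
            Digit.III, Status.MEASURED,
            conduction_velocity=_u(rng, 22.0, t.scv_mild_min - cfg.scv_jitter),
            amplitude=_normal_sensory_amp(rng, t, cfg),
        )
        apb = _normal_apb(rng, t, cfg) if grade == 4 else _prolonged_dml_apb(rng, t, cfg)
    elif grade == 6:
        if rng.random() < 0.5:  # measured but tiny sensory responses
            sensory[Digit.III] = SensoryMeasurement(
                Digit.III, Status.MEASURED,
                conduction_velocity=_u(rng, 18.0, t.scv_severe_max - cfg.scv_jitter),
                amplitude=_u(rng, 0.5, t.sensory_amp_severe_max - cfg.sensory_amp_jitter),
            )
            sensory[Digit.II] = SensoryMeasurement(
                Digit.II, Status.MEASURED,
                conduction_velocity=_u(rng, 18.0, 35.0),
                amplitude=_u(rng, 0.5, t.sensory_amp_severe_max - cfg.sensory_amp_jitter),
            )
        else:  # both digits lost outright
            sensory[Digit.III] = _absent(Digit.III)
            sensory[Digit.II] = _absent(Digit.II)
        apb = _motor(
            MotorSite.APB, Status.MEASURED,
            distal_latency=_u(rng, t.dml_normal_max + cfg.latency_jitter, 7.5),
            amplitude=_u(rng, 1.5, 8.0),
            conduction_velocity=_u(rng, 38.0, 58.0),
        )
    elif grade in (7, 8):
        sensory[Digit.III] = _absent(Digit.III)
        sensory[Digit.II] = _absent(Digit.II)
        apb = _motor(MotorSite.APB, Status.ABSENT)
        uln_lat = _u(rng, 2.8, 3.6)
        uln_amp = _u(rng, 2.0, 5.0)
        lum_uln = _motor(
            MotorSite.ULNAR_2ND_LUMBRICAL, Status.MEASURED,
            distal_latency=uln_lat, amplitude=uln_amp,
        )
        if grade == 7:
            lum_med = _motor(
                MotorSite.MEDIAN_2ND_LUMBRICAL, Status.MEASURED,
                distal_latency=_r1(
                    uln_lat
                    + rng.uniform(
                        t.lumbrical_latency_diff_min + cfg.latency_jitter, 2.0
                    )
                ),
                amplitude=_r1(uln_amp * rng.uniform(0.2, 0.7)),
            )
        else:
            lum_med = _motor(MotorSite.MEDIAN_2ND_LUMBRICAL, Status.ABSENT)
    else:  # pragma: no cover - guarded by config validation
        raise ValueError(f"no sampling region for grade {grade}")

    return {
        "sensory": sensory,
        "motor_apb": apb,
        "lumbrical_median": lum_med,
        "lumbrical_ulnar": lum_uln,
    }


def _sample_age(rng: np.random.Generator, cfg: GeneratorConfig) -> float:
    age = rng.normal(cfg.age_center, cfg.age_spread)
    return float(np.clip(round(age), cfg.age_min, cfg.age_max))


def _sample_hand_record(
    rng: np.random.Generator,
    index: int,
    grade: int,
    cfg: GeneratorConfig,
    t: GradingThresholds,
) -> SyntheticHand:
    # two hands per synthetic patient, mirroring bilateral testing
    patient_id = f"S{index // 2:05d}"
    hand = Hand.LEFT if index % 2 == 0 else Hand.RIGHT
    sex = Sex.F if rng.random() < cfg.female_fraction else Sex.M
    symptomatic = bool(grade > 0 or rng.random() < 0.25)
    record = NCSRecord(
        patient_id=patient_id,
        hand=hand,
        age=_sample_age(rng, cfg),
        sex=sex,
        symptomatic=symptomatic,
        **_sample_measurements(rng, grade, cfg, t),
    )
    return SyntheticHand(record=record, true_grade=grade)


def generate(
    config: GeneratorConfig, thresholds: Optional[GradingThresholds] = None
) -> list[SyntheticHand]:
    """Generate ``config.n_hands`` records; deterministic for a fixed seed."""
    t = thresholds or DEFAULT_THRESHOLDS
    rng = np.random.default_rng(config.seed)
    grades = sorted(config.grade_mix)
    probs = np.array([config.grade_mix[g] for g in grades], dtype=float)
    probs = probs / probs.sum()  # re-normalise away float dust
    drawn = rng.choice(grades, size=config.n_hands, p=probs)
    return [
        _sample_hand_record(rng, i, int(g), config, t) for i, g in enumerate(drawn)
    ]


def generate_paper_mix(seed: int = 0) -> list[SyntheticHand]:
    """A 2246-hand cohort whose true grades match the published per-grade
    counts exactly (counts deterministic; ordering and values seed-dependent)."""
    reference = load_reference("revised")
    label_to_value = {label: value for value, label in REVISED_LABELS.items()}
    counts = {label_to_value[cat]: n for cat, n in reference.counts.items()}
    n_hands = sum(counts.values())
    config = GeneratorConfig(n_hands=n_hands, seed=seed)
    rng = np.random.default_rng(seed)
    grades = np.repeat(
        [g for g in sorted(counts)], [counts[g] for g in sorted(counts)]
    )
    rng.shuffle(grades)
    return [
        _sample_hand_record(rng, i, int(g), config, DEFAULT_THRESHOLDS)
        for i, g in enumerate(grades)
    ]
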