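"""Cohort aggregation: per-grade counts, integer percentages and the
three-scale comparison table, plus the published reference counts.

Percentages are integer round-half-up of ``100 * count / total`` — the
convention pinned by the published Padua cells 123/600 = 20.5 → 21 and
81/600 = 13.5 → 14 (bankers' rounding would print 20 for the first).
Computation is exact integer arithmetic, never floating point.

The reference counts ship as a packaged CSV fixture
(``data/published_counts.csv``). The Bland cohort's printed total (8501)
disagrees with the sum of its printed category counts (8141); the printed
total is kept and used as the percentage denominator, since every printed
Bland percentage reproduces under 8501 and several fail under 8141.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Optional, Union

import pandas as pd

from .ncs_model import REVISED_LABELS, RevisedGrade

__all__ = [
    "Exclusions",
    "CohortSummary",
    "ReferenceTable",
    "percent",
    "summarize",
    "comparison_table",
    "load_reference",
    "PUBLISHED_TOTALS",
    "PUBLISHED_EXCLUSIONS",
]

#: Printed cohort totals used as percentage denominators.
PUBLISHED_TOTALS: dict[str, int] = {"padua": 600, "bland": 8501, "revised": 2246}


@dataclass(frozen=True)
class Exclusions:
    """Patient-level accounting from referral to final cohort."""

    initial_patients: int
    declined: int
    protocol_breach: int

    @property
    def final_patients(self) -> int:
        return self.initial_patients - self.declined - self.protocol_breach


#: Published accounting: 1132 referred, 2 declined, 7 protocol breaches -> 1123.
PUBLISHED_EXCLUSIONS = Exclusions(initial_patients=1132, declined=2, protocol_breach=7)


@dataclass(frozen=True)
class ReferenceTable:
    """Published per-category counts for one grading scheme.

    ``published_total`` is the total as printed, which for the Bland cohort
    differs from ``sum(counts.values())``; it is the denominator used for
    the scheme's percentages.
    """

    scheme: str
    counts: Mapping[str, int]   # category label -> count, in printed order
    published_total: int

    def percentages(self) -> dict[str, int]:
        return {cat: percent(n, self.published_total) for cat, n in self.counts.items()}


def percent(count: int, total: int) -> int:
    """Integer percentage, round-half-up, in [0, 100].

    Requires ``0 <= count <= total`` and ``total > 0``. Pure integer
    arithmetic: round-half-up(100 c / t) = floor((200 c + t) / 2 t).
    """
    count, total = int(count), int(total)
    if total <= 0:
        raise ValueError(f"total must be positive, got {total}")
    if not 0 <= count <= total:
        raise ValueError(f"count must lie in [0, {total}], got {count}")
    return (200 * count + total) // (2 * total)


@dataclass(frozen=True)
class CohortSummary:
    """Per-grade counts and integer percentages for one graded cohort.

    ``counts`` covers the nine determinate grade labels in grade order;
    Indeterminate results are accounted separately and never folded into the
    nine labels. ``percentages`` is empty when the cohort is empty.
    """

    counts: Mapping[str, int]
    total_hands: int
    percentages: Mapping[str, int]
    indeterminate: int = 0
    exclusions: Optional[Exclusions] = None

    def __post_init__(self) -> None:
        if self.total_hands != sum(self.counts.values()):
            raise ValueError("total_hands must equal the sum of per-grade counts")


GradeLike = Union[RevisedGrade, int, None]


def _grade_value(g: GradeLike) -> Optional[int]:
    if g is None or isinstance(g, int):
        return g
    return g.value


def summarize(
    grades: Iterable[GradeLike], exclusions: Optional[Exclusions] = None
) -> CohortSummary:
    """Aggregate graded hands into a :class:`CohortSummary`.

    Accepts :class:`RevisedGrade` objects, plain integers 0-8, or None for
    Indeterminate. An empty input yields a zero-total summary with an empty
    percentage map.
    """
    by_value = {v: 0 for v in range(9)}
    indeterminate = 0
    for g in grades:
        v = _grade_value(g)
        if v is None:
            indeterminate += 1
        else:
            by_value[v] += 1
    counts = {REVISED_LABELS[v]: by_value[v] for v in range(9)}
    total = sum(counts.values())
    percentages = (
        {label: percent(n, total) for label, n in counts.items()} if total else {}
    )
    return CohortSummary(
        counts=counts,
        total_hands=total,
        percentages=percentages,
        indeterminate=indeterminate,
        exclusions=exclusions,
    )


def load_reference(scheme: str) -> ReferenceTable:
    """Load the published counts for ``padua``, ``bland`` or ``revised``."""
    scheme = scheme.lower()
    if scheme not in PUBLISHED_TOTALS:
        raise ValueError(f"unknown scheme {scheme!r}; expected one of {sorted(PUBLISHED_TOTALS)}")
    with resources.files("ctsgrade.data").joinpath("published_counts.csv").open() as fh:
        frame = pd.read_csv(fh, comment="#")
    rows = frame[frame["scheme"] == scheme].sort_values("order")
    counts = dict(zip(rows["category"], rows["count"].astype(int)))
    return ReferenceTable(
        scheme=scheme, counts=counts, published_total=PUBLISHED_TOTALS[scheme]
    )


# Row alignment of the published three-scale comparison: the revised scale
# splits the mild and moderate categories in two and appends Complete, so
# Padua/Bland cells are blank on the second row of each split pair.
_COMPARISON_ROWS: list[tuple[Optional[str], Optional[str], str]] = [
    ("Normal", "Normal", "Normal"),
    ("Minimal", "Very mild", "Early"),
    ("Mild", "Mild sensory-motor", "Mild Sensory"),
    (None, None, "Mild Sensory-Motor"),
    ("Moderate", "Moderately severe", "Moderate Sensory"),
    (None, None, "Moderate Sensory-Motor"),
    ("Severe", "Severe", "Severe Sensory-Motor"),
    ("Extremely severe", "Very severe", "Extremely Severe Sensory-Motor"),
    (None, "Extremely severe", "Complete"),
]


def comparison_table(summary: CohortSummary) -> pd.DataFrame:
    """Three-scheme comparison: published Padua and Bland columns next to the
    input cohort's revised-scale counts and percentages.

    Reference percentages use each scheme's printed total as denominator.
    Cells on rows where a scheme has no corresponding category hold pandas
    NA. An empty summary yields zero counts and NA percentages in the
    revised columns.
    """
    padua = load_reference("padua")
    bland = load_reference("bland")
    rows = []
    for p_cat, b_cat, r_cat in _COMPARISON_ROWS:
        row: dict[str, object] = {
            "padua_category": p_cat,
            "padua_count": padua.counts[p_cat] if p_cat else pd.NA,
            "padua_pct": percent(padua.counts[p_cat], padua.published_total) if p_cat else pd.NA,
            "bland_category": b_cat,
            "bland_count": bland.counts[b_cat] if b_cat else pd.NA,
            "bland_pct": percent(bland.counts[b_cat], bland.published_total) if b_cat else pd.NA,
            "revised_category": r_cat,
            "revised_count": summary.counts.get(r_cat, 0),
            "revised_pct": (
                summary.percentages.get(r_cat, pd.NA) if summary.total_hands else pd.NA
            ),
        }
        rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs["totals"] = {
        "padua": padua.published_total,
        "bland": bland.published_total,
        "revised": summary.total_hands,
    }
    return table
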