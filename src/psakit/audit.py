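"""Post-treatment outcome auditing.

A treatment is counted biochemically successful when the follow-up PSA at a
scheduled month falls below the modality's threshold: 0.2 ng/mL after
surgery, 2 ng/mL after radiotherapy (strict "less than"; boundary values
fail).  A second, modality-agnostic criterion counts success whenever the
follow-up PSA is lower than the recorded pre-treatment PSA.

:func:`audit_cohort` tabulates success fractions per (modality, criterion,
month) the way follow-up audits are usually reported — cells of the form
``successes/total (percent)``, where the denominator counts only patients
with an evaluable measurement near that month, so missed visits shrink the
denominator rather than being imputed.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import pandas as pd

from .errors import DomainError
from .records import Modality, PatientRecord, PSAMeasurement, TreatmentEvent
from .units import DAYS_PER_MONTH

__all__ = [
    "Outcome",
    "Criterion",
    "OutcomeCriteria",
    "AuditCell",
    "AuditTable",
    "assess_success",
    "audit_cohort",
    "summarize_counts",
    "MATCH_WINDOW_DAYS",
]

#: a follow-up measurement counts for month *m* when it lies within this
#: many days of the nominal date (treatment date + m months)
MATCH_WINDOW_DAYS: int = 45


class Outcome(str, Enum):
    SUCCESS = "success"
    FAILURE = "failure"
    NOT_EVALUABLE = "not_evaluable"


class Criterion(str, Enum):
    THRESHOLD = "threshold"  # PSA below the modality threshold
    BELOW_PRETREATMENT = "below_pretreatment"  # PSA below the pre-treatment value


@dataclass(frozen=True)
class OutcomeCriteria:
    """Modality-specific biochemical success thresholds in ng/mL."""

    surgery_threshold: float = 0.2
    radiotherapy_threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.surgery_threshold <= 0 or self.radiotherapy_threshold <= 0:
            raise DomainError("outcome thresholds must be positive")

    def threshold_for(self, modality: Modality) -> float:
        if modality is Modality.SURGERY:
            return self.surgery_threshold
        if modality is Modality.RADIOTHERAPY:
            return self.radiotherapy_threshold
        raise DomainError(
            f"no biochemical success threshold is defined for modality {modality.value!r}"
        )


@dataclass(frozen=True)
class AuditCell:
    successes: int
    total: int

    def __post_init__(self) -> None:
        if not 0 <= self.successes <= self.total:
            raise ValueError(f"invalid cell counts {self.successes}/{self.total}")

    @property
    def percent(self) -> int:
        return summarize_counts(self.successes, self.total)

    def __str__(self) -> str:
        return f"{self.successes}/{self.total}({self.percent}%)"


@dataclass
class AuditTable:
    """Success fractions keyed by (modality, criterion) row and month column."""

    months: tuple[int, ...]
    rows: dict[tuple[Modality, Criterion], dict[int, AuditCell]] = field(default_factory=dict)

    def cell(self, modality: Modality, criterion: Criterion, month: int) -> Optional[AuditCell]:
        return self.rows.get((modality, criterion), {}).get(month)

    def to_frame(self) -> pd.DataFrame:
        """Human-readable frame with ``successes/total(percent%)`` cells."""
        data = {}
        for (modality, criterion), cells in self.rows.items():
            data[(modality.value, criterion.value)] = {
                m: (str(c) if (c := cells.get(m)) else "") for m in self.months
            }
        frame = pd.DataFrame(data).T
        frame.index.names = ["treatment", "criterion"]
        frame.columns.name = "month"
        return frame


def summarize_counts(successes: int, total: int) -> int:
    """Percent of successes, rounded to the nearest integer half away from zero."""
    if total <= 0:
        raise DomainError("cannot summarize a cell with zero evaluable patients")
    if not 0 <= successes <= total:
        raise DomainError(f"invalid counts: {successes}/{total}")
    return math.floor(100.0 * successes / total + 0.5)


def _measurement_near(
    record: PatientRecord, event: TreatmentEvent, month: int
) -> Optional[PSAMeasurement]:
    """The post-treatment measurement nearest the nominal follow-up date.

    Only measurements strictly after the treatment date are candidates (a
    pre-treatment draw can fall inside the month-1 window); must lie within
    ``MATCH_WINDOW_DAYS`` of nominal.  Ties go to the earlier measurement.
    """
    nominal = event.date + _dt.timedelta(days=round(month * DAYS_PER_MONTH))
    best: Optional[PSAMeasurement] = None
    best_dist = MATCH_WINDOW_DAYS + 1
    for m in record.psa_series.measurements:
        if m.date <= event.date:
            continue
        dist = abs((m.date - nominal).days)
        if dist < best_dist:
            best, best_dist = m, dist
    return best


def assess_success(
    record: PatientRecord,
    event: TreatmentEvent,
    month: int,
    criteria: OutcomeCriteria = OutcomeCriteria(),
    criterion: Criterion = Criterion.THRESHOLD,
) -> Outcome:
    """Assess one treatment at one follow-up month.

    Threshold criterion: success iff the matched PSA is strictly below the
    modality threshold (raises :class:`DomainError` for modalities without
    one).  Below-pretreatment criterion: success iff strictly below the
    recorded pre-treatment PSA; ``not_evaluable`` when that value (or any
    measurement in the matching window) is missing.
    """
    if month <= 0:
        raise DomainError(f"follow-up month must be positive, got {month}")
    if event not in record.treatments:
        raise DomainError("treatment event does not belong to this record")
    if criterion is Criterion.THRESHOLD:
        threshold = criteria.threshold_for(event.modality)  # may raise DomainError
    m = _measurement_near(record, event, month)
    if m is None:
        return Outcome.NOT_EVALUABLE
    if criterion is Criterion.THRESHOLD:
        return Outcome.SUCCESS if m.psa < threshold else Outcome.FAILURE
    if event.pre_treatment_psa is None:
        return Outcome.NOT_EVALUABLE
    return Outcome.SUCCESS if m.psa < event.pre_treatment_psa else Outcome.FAILURE


def audit_cohort(
    cohort: list[PatientRecord],
    months: list[int] = [1, 3, 6, 9, 12],
    criteria: OutcomeCriteria = OutcomeCriteria(),
) -> AuditTable:
    """Tabulate success fractions over a cohort.

    For each modality with a threshold (surgery, radiotherapy), each
    criterion and each month: total counts treatments with an evaluable
    follow-up, successes those assessed successful.  Months with no
    evaluable patient yield no cell.
    """
    if not months:
        raise DomainError("months schedule must be non-empty")
    table = AuditTable(months=tuple(months))
    for modality in (Modality.SURGERY, Modality.RADIOTHERAPY):
        for criterion in Criterion:
            cells: dict[int, AuditCell] = {}
            for month in months:
                successes = total = 0
                for record in cohort:
                    for event in record.treatments:
                        if event.modality is not modality:
                            continue
                        outcome = assess_success(record, event, month, criteria, criterion)
                        if outcome is Outcome.NOT_EVALUABLE:
                            continue
                        total += 1
                        successes += outcome is Outcome.SUCCESS
                if total:
                    cells[month] = AuditCell(successes=successes, total=total)
            table.rows[(modality, criterion)] = cells
    return table
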