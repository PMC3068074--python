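"""Clinical record domain types and parsers.

The central objects are longitudinal PSA series plus the three pretreatment
variables that drive risk assessment: TNM clinical stage, Gleason score and
(optionally) prostate volume.  Types are pydantic models so every invariant
(non-negative PSA, sorted unique measurement dates, grades within 1-5,
sums within 2-10) is enforced at construction time rather than discovered
downstream.
"""

from __future__ import annotations

import datetime as _dt
import re
from enum import Enum
from typing import Optional

from pydantic import BaseModel, Field, field_validator, model_validator

from .errors import ParseError

__all__ = [
    "TCategory",
    "NCategory",
    "MCategory",
    "Modality",
    "PSAMeasurement",
    "PSASeries",
    "ClinicalStage",
    "GleasonScore",
    "TreatmentEvent",
    "PatientRecord",
    "parse_tnm",
    "parse_gleason",
    "parse_date",
]


class TCategory(str, Enum):
    """Primary-tumour substage (AJCC/UICC TNM, prostate)."""

    T1a = "T1a"
    T1b = "T1b"
    T1c = "T1c"
    T2a = "T2a"
    T2b = "T2b"
    T2c = "T2c"
    T3a = "T3a"
    T3b = "T3b"
    T4 = "T4"


class NCategory(str, Enum):
    N0 = "N0"
    N1 = "N1"
    NX = "NX"  # nodal status not assessed


class MCategory(str, Enum):
    M0 = "M0"
    M1 = "M1"
    MX = "MX"  # metastasis status not assessed


class Modality(str, Enum):
    SURGERY = "surgery"
    RADIOTHERAPY = "radiotherapy"
    HORMONAL = "hormonal"
    CHEMOTHERAPY = "chemotherapy"
    WATCHFUL_WAITING = "watchful_waiting"


class PSAMeasurement(BaseModel):
    """One dated serum PSA draw, in ng/mL."""

    model_config = {"frozen": True}

    date: _dt.date
    psa: float = Field(ge=0.0)


class PSASeries(BaseModel):
    """Ordered PSA history for one patient.

    Measurements are kept sorted ascending by date; two draws on the same
    calendar date are rejected (duplicates must be resolved upstream, not
    silently averaged).
    """

    patient_id: str = Field(min_length=1)
    measurements: list[PSAMeasurement] = Field(default_factory=list)

    @model_validator(mode="after")
    def _sorted_unique(self) -> "PSASeries":
        ms = sorted(self.measurements, key=lambda m: m.date)
        for a, b in zip(ms, ms[1:]):
            if a.date == b.date:
                raise ValueError(
                    f"patient {self.patient_id!r}: duplicate PSA measurement date {a.date}"
                )
        # assignment inside a validator bypasses re-validation
        object.__setattr__(self, "measurements", ms)
        return self

    def __len__(self) -> int:
        return len(self.measurements)

    def dates(self) -> list[_dt.date]:
        return [m.date for m in self.measurements]

    def values(self) -> list[float]:
        return [m.psa for m in self.measurements]

    def between(self, start: _dt.date | None = None, end: _dt.date | None = None) -> list[PSAMeasurement]:
        """Measurements with start <= date <= end (either bound optional)."""
        return [
            m
            for m in self.measurements
            if (start is None or m.date >= start) and (end is None or m.date <= end)
        ]


class ClinicalStage(BaseModel):
    """Parsed TNM triple.  NX/MX record that a component was not assessed."""

    model_config = {"frozen": True}

    t_category: TCategory
    n_category: NCategory = NCategory.NX
    m_category: MCategory = MCategory.MX

    def __str__(self) -> str:
        return f"{self.t_category.value}{self.n_category.value}{self.m_category.value}"


class GleasonScore(BaseModel):
    """Gleason grading: two pattern grades 1-5 whose sum lies in 2-10.

    Records sometimes carry only a sum or a sum range ("5-6"); then the
    patterns are absent and ``sum_set`` holds every plausible sum.
    """

    model_config = {"frozen": True}

    primary: Optional[int] = Field(default=None, ge=1, le=5)
    secondary: Optional[int] = Field(default=None, ge=1, le=5)
    sum_set: frozenset[int]

    @field_validator("sum_set")
    @classmethod
    def _sums_in_range(cls, v: frozenset[int]) -> frozenset[int]:
        if not v:
            raise ValueError("sum_set must be non-empty")
        bad = [s for s in v if not 2 <= s <= 10]
        if bad:
            raise ValueError(f"Gleason sums must lie in 2..10, got {sorted(bad)}")
        return v

    @model_validator(mode="after")
    def _patterns_consistent(self) -> "GleasonScore":
        if (self.primary is None) != (self.secondary is None):
            raise ValueError("primary and secondary patterns must both be present or both absent")
        if self.primary is not None and self.sum_set != {self.primary + self.secondary}:
            raise ValueError("sum_set must equal {primary + secondary} when patterns are known")
        return self

    @property
    def max_sum(self) -> int:
        """Worst-case sum; range scores match grade criteria through this."""
        return max(self.sum_set)

    @property
    def min_sum(self) -> int:
        return min(self.sum_set)

    def __str__(self) -> str:
        if self.primary is not None:
            return f"{self.primary}+{self.secondary}"
        if len(self.sum_set) == 1:
            return str(next(iter(self.sum_set)))
        return f"{self.min_sum}-{self.max_sum}"


class TreatmentEvent(BaseModel):
    """A dated treatment with optional pre-treatment PSA reference value."""

    model_config = {"frozen": True}

    modality: Modality
    date: _dt.date
    pre_treatment_psa: Optional[float] = Field(default=None, ge=0.0)


class PatientRecord(BaseModel):
    """Everything known about one patient: PSA history, staging, treatments."""

    patient_id: str = Field(min_length=1)
    psa_series: PSASeries
    stage: Optional[ClinicalStage] = None
    gleason: Optional[GleasonScore] = None
    prostate_volume_ml: Optional[float] = Field(default=None, gt=0.0)
    life_expectancy_years: Optional[float] = Field(default=None, gt=0.0)
    treatments: list[TreatmentEvent] = Field(default_factory=list)

    @model_validator(mode="after")
    def _consistent(self) -> "PatientRecord":
        if self.psa_series.patient_id != self.patient_id:
            raise ValueError("psa_series.patient_id must match patient_id")
        object.__setattr__(
            self, "treatments", sorted(self.treatments, key=lambda t: t.date)
        )
        return self


# --- parsers ---------------------------------------------------------------

_TNM_RE = re.compile(
    r"^(?P<t>T(?:1[abc]|2[abc]|3[ab]|4))(?:(?P<n>N[01X]))?(?:(?P<m>M[01X]))?$",
    re.IGNORECASE,
)


def parse_tnm(text: str) -> ClinicalStage:
    """Parse a TNM stage string such as ``"T2cN0M0"`` or bare ``"T1c"``.

    Missing N/M components parse as NX/MX (not assessed) rather than being
    assumed negative.  Raises :class:`ParseError` naming the offending token
    for anything outside the T1a..T4 / N0,N1,NX / M0,M1,MX grid.
    """
    if not text or not text.strip():
        raise ParseError("empty TNM stage string")
    s = text.strip()
    m = _TNM_RE.match(s)
    if m is None:
        # identify the offending token for the error message
        tm = re.match(r"^(T[0-9][a-z]?)", s, re.IGNORECASE)
        bad = tm.group(1) if tm and tm.group(1).upper() not in {
            t.value.upper() for t in TCategory
        } else s
        raise ParseError(f"malformed TNM stage {text!r}: unrecognised token {bad!r}")
    t = TCategory(m.group("t")[0].upper() + m.group("t")[1:].lower())
    n = NCategory(m.group("n").upper()) if m.group("n") else NCategory.NX
    mm = MCategory(m.group("m").upper()) if m.group("m") else MCategory.MX
    return ClinicalStage(t_category=t, n_category=n, m_category=mm)


_GLEASON_PATTERNS = re.compile(r"^\s*(\d+)\s*\+\s*(\d+)\s*$")
_GLEASON_RANGE = re.compile(r"^\s*(\d+)\s*-\s*(\d+)\s*$")
_GLEASON_SUM = re.compile(r"^\s*(\d+)\s*$")


def parse_gleason(text: str) -> GleasonScore:
    """Parse a Gleason score given as ``"a+b"``, a bare sum, or a range ``"a-b"``.

    ``"4+3"`` yields primary 4 / secondary 3 / sum {7}; ``"5-6"`` yields the
    sum set {5, 6} with patterns absent.  Pattern grades must lie in 1..5 and
    sums in 2..10.
    """
    if not text or not text.strip():
        raise ParseError("empty Gleason score string")
    if m := _GLEASON_PATTERNS.match(text):
        a, b = int(m.group(1)), int(m.group(2))
        if not (1 <= a <= 5 and 1 <= b <= 5):
            raise ParseError(f"Gleason pattern grades must lie in 1..5: {text!r}")
        return GleasonScore(primary=a, secondary=b, sum_set=frozenset({a + b}))
    if m := _GLEASON_RANGE.match(text):
        lo, hi = int(m.group(1)), int(m.group(2))
        if lo > hi:
            raise ParseError(f"Gleason range bounds out of order: {text!r}")
        if not (2 <= lo and hi <= 10):
            raise ParseError(f"Gleason sums must lie in 2..10: {text!r}")
        return GleasonScore(sum_set=frozenset(range(lo, hi + 1)))
    if m := _GLEASON_SUM.match(text):
        s = int(m.group(1))
        if not 2 <= s <= 10:
            raise ParseError(f"Gleason sum must lie in 2..10: {text!r}")
        return GleasonScore(sum_set=frozenset({s}))
    raise ParseError(f"unrecognised Gleason score format: {text!r}")


def parse_date(text: str) -> _dt.date:
    """Parse an ISO-8601 (YYYY-MM-DD) calendar date."""
    try:
        return _dt.date.fromisoformat(text.strip())
    except ValueError as e:
        raise ParseError(f"invalid ISO date {text!r}: {e}") from None
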