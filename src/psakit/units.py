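"""Calendar-time conventions shared across the package.

Elapsed time between two calendar dates is always computed in whole days
and then converted with fixed factors (Julian year of 365.25 days, mean
month of 30.44 days).  Every module that turns dates into numeric time —
kinetics regressions, the outcome audit's follow-up windows, the cohort
simulator — uses these same constants, so estimates are mutually
consistent to machine precision.
"""

from __future__ import annotations

import datetime as _dt
from enum import Enum

DAYS_PER_YEAR: float = 365.25
DAYS_PER_MONTH: float = 30.44


class TimeUnit(str, Enum):
    """Unit in which elapsed time (and hence PSAV/PSADT) is expressed."""

    DAYS = "days"
    MONTHS = "months"
    YEARS = "years"

    @property
    def days(self) -> float:
        return _FACTORS[self]


_FACTORS = {
    TimeUnit.DAYS: 1.0,
    TimeUnit.MONTHS: DAYS_PER_MONTH,
    TimeUnit.YEARS: DAYS_PER_YEAR,
}


def elapsed(start: _dt.date, end: _dt.date, unit: TimeUnit = TimeUnit.YEARS) -> float:
    """Elapsed time from *start* to *end* in *unit* (negative if end < start)."""
    return (end - start).days / unit.days
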