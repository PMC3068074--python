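"""Pretreatment PSA kinetics: velocity (PSAV), doubling time (PSADT), density (PSAD).

Two estimation algorithms are provided for both PSAV and PSADT, mirroring
how the quantities are used clinically:

* **regression** — ordinary least squares over all measurements in a
  selected window.  PSAV is the slope of the linear model
  ``PSA(t) = initial_PSA + PSAV * t``; PSADT comes from the log-linear
  model ``ln PSA(t) = a + b t`` as ``ln(2) / b``.
* **two-marker** — closed forms from two chosen measurements: the secant
  slope for PSAV, and ``(t2 - t1) * ln 2 / ln(P2/P1)`` for PSADT.

With exactly two points the two algorithms coincide.  A non-increasing PSA
has no doubling time; PSADT is then reported as *undefined* (``None``), not
as a negative number.

Time is measured from the first selected measurement, so "initial PSA" is
the regression intercept at the window start.  Default units follow the
clinical cut-offs: PSAV in ng/mL/year (flagging thresholds 0.75 and
2 ng/mL/yr), PSADT in months.
"""

from __future__ import annotations

import datetime as _dt
import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DomainError
from .records import PSAMeasurement, PSASeries
from .units import TimeUnit

__all__ = [
    "VELOCITY_CUTOFF_DEFAULT",
    "VELOCITY_CUTOFF_ALTERNATE",
    "KineticsMethod",
    "KineticsWindow",
    "KineticsResult",
    "psav_regression",
    "psav_two_marker",
    "psadt_regression",
    "psadt_two_marker",
    "psad",
    "flag_velocity",
    "kinetics_report",
]

#: PSA velocity above 0.75 ng/mL/yr is a significant indicator of prostate
#: cancer; 2 ng/mL/yr is the stricter alternative cut-off in use.
VELOCITY_CUTOFF_DEFAULT: float = 0.75
VELOCITY_CUTOFF_ALTERNATE: float = 2.0


class KineticsMethod(str, Enum):
    REGRESSION = "regression"
    TWO_MARKER = "two_marker"


@dataclass(frozen=True)
class KineticsWindow:
    """A selected, chronologically ordered slice of a PSA series.

    ``t_origin`` is the date of the first selected measurement; elapsed
    times handed to the estimators are measured from it in ``time_unit``.
    """

    measurements: tuple[PSAMeasurement, ...]
    time_unit: TimeUnit = TimeUnit.YEARS

    def __post_init__(self) -> None:
        if len(self.measurements) < 2:
            raise DomainError("kinetics window needs at least 2 measurements")
        dates = [m.date for m in self.measurements]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise DomainError("kinetics window dates must be strictly increasing")

    @classmethod
    def from_series(
        cls,
        series: PSASeries,
        start: _dt.date | None = None,
        end: _dt.date | None = None,
        time_unit: TimeUnit = TimeUnit.YEARS,
    ) -> "KineticsWindow":
        return cls(tuple(series.between(start, end)), time_unit)

    @property
    def t_origin(self) -> _dt.date:
        return self.measurements[0].date

    def times(self) -> np.ndarray:
        """Elapsed time of each measurement from ``t_origin``, in ``time_unit``."""
        origin = self.t_origin
        return np.array([(m.date - origin).days for m in self.measurements]) / self.time_unit.days

    def psa_values(self) -> np.ndarray:
        return np.array([m.psa for m in self.measurements], dtype=float)


@dataclass(frozen=True)
class KineticsResult:
    """Fitted kinetics for one window.

    ``psadt`` is ``None`` both when it was not requested and when it is
    undefined (non-increasing PSA); ``initial_psa`` is the model value at
    the window origin.
    """

    initial_psa: float
    psav: float
    psadt: Optional[float]
    n_points: int
    method: KineticsMethod
    time_unit: TimeUnit


def _ols(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if len(t) == 2:
        # exact secant; avoids any numerical daylight between the two
        # algorithms on two-point windows
        slope = (y[1] - y[0]) / (t[1] - t[0])
        return slope, y[0] - slope * t[0]
    fit = stats.linregress(t, y)
    return float(fit.slope), float(fit.intercept)


def psav_regression(window: KineticsWindow) -> KineticsResult:
    """PSA velocity by OLS of PSA against elapsed time.

    Slope is the velocity (ng/mL per window time unit) and the intercept is
    the initial PSA at the window origin.
    """
    t, y = window.times(), window.psa_values()
    slope, intercept = _ols(t, y)
    return KineticsResult(
        initial_psa=intercept,
        psav=slope,
        psadt=None,
        n_points=len(window.measurements),
        method=KineticsMethod.REGRESSION,
        time_unit=window.time_unit,
    )


def psav_two_marker(p1: float, t1: float, p2: float, t2: float) -> float:
    """Secant PSA velocity from two markers: ``(p2 - p1) / (t2 - t1)``."""
    if t2 <= t1:
        raise DomainError(f"marker times out of order: t2={t2} <= t1={t1}")
    return (p2 - p1) / (t2 - t1)


def psadt_regression(window: KineticsWindow) -> Optional[float]:
    """PSA doubling time from the log-linear fit ``ln PSA = a + b t``.

    Returns ``ln(2)/b`` in the window's time unit, or ``None`` when the
    fitted slope is non-positive (PSA not rising — no doubling time).
    All PSA values in the window must be strictly positive.
    """
    y = window.psa_values()
    if np.any(y <= 0):
        raise DomainError("PSADT requires strictly positive PSA values (log undefined)")
    slope, _ = _ols(window.times(), np.log(y))
    if slope <= 0:
        return None
    return math.log(2.0) / slope


def psadt_two_marker(p1: float, t1: float, p2: float, t2: float) -> Optional[float]:
    """Doubling time interpolated from two markers.

    ``(t2 - t1) * ln 2 / ln(p2 / p1)``; ``None`` when ``p2 <= p1`` (not
    rising).  PSA values must be strictly positive.
    """
    if p1 <= 0 or p2 <= 0:
        raise DomainError("PSADT requires strictly positive PSA values")
    if t2 <= t1:
        raise DomainError(f"marker times out of order: t2={t2} <= t1={t1}")
    if p2 <= p1:
        return None
    return (t2 - t1) * math.log(2.0) / math.log(p2 / p1)


def psad(psa: float, prostate_volume_ml: float | None) -> float:
    """PSA density: serum PSA divided by prostate volume (ng/mL per mL)."""
    if prostate_volume_ml is None or prostate_volume_ml <= 0:
        raise DomainError(f"PSAD requires a positive prostate volume, got {prostate_volume_ml!r}")
    if psa < 0:
        raise DomainError(f"PSA must be non-negative, got {psa}")
    return psa / prostate_volume_ml


def flag_velocity(psav: float, cutoff: float = VELOCITY_CUTOFF_DEFAULT) -> bool:
    """True iff the velocity strictly exceeds the cut-off ("in excess of")."""
    if cutoff <= 0:
        raise DomainError(f"velocity cut-off must be positive, got {cutoff}")
    return psav > cutoff


def kinetics_report(
    window: KineticsWindow,
    method: KineticsMethod = KineticsMethod.REGRESSION,
    markers: Sequence[int] | None = None,
    psadt_unit: TimeUnit = TimeUnit.MONTHS,
) -> dict:
    """One-row summary combining PSAV, PSADT and velocity flags.

    ``markers`` selects the two measurement indices for the two-marker
    method (default: first and last).  PSAV is reported per the window's
    time unit, PSADT per ``psadt_unit``.
    """
    t, y = window.times(), window.psa_values()
    if method is KineticsMethod.REGRESSION:
        res = psav_regression(window)
        psav, initial = res.psav, res.initial_psa
        dt = psadt_regression(window) if np.all(y > 0) else None
    else:
        i, j = (0, len(y) - 1) if markers is None else tuple(markers)
        if not (0 <= i < j < len(y)):
            raise DomainError(f"invalid marker indices ({i}, {j}) for {len(y)} measurements")
        psav = psav_two_marker(y[i], t[i], y[j], t[j])
        initial = y[i]
        dt = psadt_two_marker(y[i], t[i], y[j], t[j]) if (y[i] > 0 and y[j] > 0) else None
    if dt is not None:
        dt = dt * window.time_unit.days / psadt_unit.days
    psav_per_year = psav * TimeUnit.YEARS.days / window.time_unit.days
    return {
        "initial_psa": initial,
        "psav": psav,
        "psav_unit": f"ng/mL/{window.time_unit.value[:-1]}",
        "psadt": dt,
        "psadt_unit": psadt_unit.value,
        "n_points": len(y),
        "method": method.value,
        "flag_0.75": flag_velocity(psav_per_year, VELOCITY_CUTOFF_DEFAULT),
        "flag_2.0": flag_velocity(psav_per_year, VELOCITY_CUTOFF_ALTERNATE),
    }
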