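"""Pretreatment risk stratification and pathologic-stage lookup.

Implements the three-tier (low / intermediate / high) risk classification
for clinically localized prostate cancer from clinical stage, serum PSA and
Gleason score, with the associated 5-year PSA-failure risk bands and
5/10-year PSA-failure-free survival percentages:

======  =====================================================  ==========  ======  ======
Tier    Criteria                                               5-yr fail   5-yr    10-yr
======  =====================================================  ==========  ======  ======
low     (T1c or T2a) and PSA <= 10 and Gleason <= 6            < 25 %      85 %    83 %
inter.  T2b, or Gleason = 7, or 10 < PSA <= 20                 25-50 %     60 %    46 %
high    T2c, or PSA > 20, or Gleason >= 8                      > 50 %      30 %    29 %
======  =====================================================  ==========  ======  ======

The OR-criteria overlap; tiers are checked high → intermediate → low so the
worse tier governs.  Gleason scores given as a sum range ("5-6") match grade
criteria through their maximum element (worst-case reading).  Stages outside
T1c..T2c with no PSA/Gleason trigger return ``unclassified`` rather than
raising — the classifier never invents coverage the criteria do not have.

The criteria live in a delimited table shipped with the package
(``data/risk_criteria.csv``) so institutions can substitute their own; a
row matches when all its non-empty constraints hold and a tier matches when
any of its rows do.  A pluggable Partin-style lookup maps (stage, PSA range,
Gleason range) to pathologic-stage probabilities; the shipped table is a
synthetic placeholder with the published tables' structure and must be
replaced with a published edition for clinical interpretation.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Optional

from .errors import CoverageError, DomainError, LoadError
from .records import ClinicalStage, GleasonScore, TCategory

__all__ = [
    "RiskGroup",
    "RiskProfile",
    "RiskCriteriaTable",
    "PartinTable",
    "load_risk_criteria",
    "default_risk_criteria",
    "stratify",
    "risk_profile",
    "load_partin_table",
    "default_partin_table",
    "partin_lookup",
]


class RiskGroup(str, Enum):
    LOW = "low"
    INTERMEDIATE = "intermediate"
    HIGH = "high"
    UNCLASSIFIED = "unclassified"


#: tier severity used by the precedence rule and the monotonicity contract
_TIER_ORDER = [RiskGroup.HIGH, RiskGroup.INTERMEDIATE, RiskGroup.LOW]


@dataclass(frozen=True)
class RiskProfile:
    """A tier's outcome row: 5-yr PSA-failure band and survival percentages.

    Band ends are ``-inf``/``+inf`` for the open-ended low and high tiers.
    """

    group: RiskGroup
    failure_5yr_band: tuple[float, float]  # (% lower, % upper)
    survival_5yr: float  # %
    survival_10yr: float  # %

    def __post_init__(self) -> None:
        lo, hi = self.failure_5yr_band
        if lo >= hi:
            raise ValueError(f"degenerate failure band {self.failure_5yr_band}")
        for s in (self.survival_5yr, self.survival_10yr):
            if not 0 <= s <= 100:
                raise ValueError(f"survival percentage out of [0,100]: {s}")


@dataclass(frozen=True)
class _CriteriaRow:
    group: RiskGroup
    t_stages: frozenset[TCategory]  # empty = no stage constraint
    psa_min: Optional[float]  # exclusive lower bound (PSA > psa_min)
    psa_max: Optional[float]  # inclusive upper bound (PSA <= psa_max)
    gleason_min: Optional[int]  # inclusive, matched against max_sum
    gleason_max: Optional[int]  # inclusive, matched against max_sum
    profile: RiskProfile

    def matches(self, stage: ClinicalStage, psa: float, gleason: GleasonScore) -> bool:
        if self.t_stages and stage.t_category not in self.t_stages:
            return False
        if self.psa_min is not None and not psa > self.psa_min:
            return False
        if self.psa_max is not None and not psa <= self.psa_max:
            return False
        g = gleason.max_sum
        if self.gleason_min is not None and g < self.gleason_min:
            return False
        if self.gleason_max is not None and g > self.gleason_max:
            return False
        return True


@dataclass(frozen=True)
class RiskCriteriaTable:
    rows: tuple[_CriteriaRow, ...]

    def profile(self, group: RiskGroup) -> RiskProfile:
        for row in self.rows:
            if row.group is group:
                return row.profile
        raise DomainError(f"no profile for risk group {group.value!r}")


def _cell(row: dict[str, str], key: str) -> str:
    return (row.get(key) or "").strip()


def load_risk_criteria(path: str | Path) -> RiskCriteriaTable:
    """Load a risk-criteria table.

    Columns: ``group,t_stages,psa_min,psa_max,gleason_min,gleason_max,
    failure_lo,failure_hi,surv5,surv10``; ``t_stages`` is ``|``-separated;
    empty cells mean "no constraint" (or an open band end).
    """
    p = Path(path)
    rows: list[_CriteriaRow] = []
    with p.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for i, row in enumerate(reader, start=2):
            try:
                group = RiskGroup(_cell(row, "group"))
                stages = frozenset(
                    TCategory(s) for s in _cell(row, "t_stages").split("|") if s
                )
                psa_min = float(_cell(row, "psa_min")) if _cell(row, "psa_min") else None
                psa_max = float(_cell(row, "psa_max")) if _cell(row, "psa_max") else None
                g_min = int(_cell(row, "gleason_min")) if _cell(row, "gleason_min") else None
                g_max = int(_cell(row, "gleason_max")) if _cell(row, "gleason_max") else None
                lo = float(_cell(row, "failure_lo")) if _cell(row, "failure_lo") else -math.inf
                hi = float(_cell(row, "failure_hi")) if _cell(row, "failure_hi") else math.inf
                profile = RiskProfile(
                    group=group,
                    failure_5yr_band=(lo, hi),
                    survival_5yr=float(_cell(row, "surv5")),
                    survival_10yr=float(_cell(row, "surv10")),
                )
            except (ValueError, KeyError) as e:
                raise LoadError(f"bad risk-criteria row: {e}", source=str(p), line=i) from None
            rows.append(
                _CriteriaRow(
                    group=group,
                    t_stages=stages,
                    psa_min=psa_min,
                    psa_max=psa_max,
                    gleason_min=g_min,
                    gleason_max=g_max,
                    profile=profile,
                )
            )
    if not rows:
        raise LoadError("risk-criteria table is empty", source=str(p))
    return RiskCriteriaTable(rows=tuple(rows))


_DEFAULT_CRITERIA: RiskCriteriaTable | None = None


def default_risk_criteria() -> RiskCriteriaTable:
    """The packaged three-tier criteria table (loaded once, cached)."""
    global _DEFAULT_CRITERIA
    if _DEFAULT_CRITERIA is None:
        with resources.as_file(
            resources.files("psakit.data").joinpath("risk_criteria.csv")
        ) as p:
            _DEFAULT_CRITERIA = load_risk_criteria(p)
    return _DEFAULT_CRITERIA


def stratify(
    stage: ClinicalStage,
    psa: float,
    gleason: GleasonScore,
    criteria: RiskCriteriaTable | None = None,
) -> RiskGroup:
    """Assign the risk tier for (clinical stage, PSA ng/mL, Gleason score).

    Tiers are evaluated high, then intermediate, then low; the first tier
    with a matching criteria row wins, so a patient matching several
    overlapping OR-criteria lands in the worst tier.  Returns
    ``RiskGroup.UNCLASSIFIED`` when no row matches (e.g. stage T3 with
    unremarkable PSA and Gleason).
    """
    if psa < 0:
        raise DomainError(f"PSA must be non-negative, got {psa}")
    table = criteria if criteria is not None else default_risk_criteria()
    for tier in _TIER_ORDER:
        for row in table.rows:
            if row.group is tier and row.matches(stage, psa, gleason):
                return tier
    return RiskGroup.UNCLASSIFIED


def risk_profile(group: RiskGroup, criteria: RiskCriteriaTable | None = None) -> RiskProfile:
    """The outcome row (failure band, 5/10-yr survival) for a risk tier."""
    if group is RiskGroup.UNCLASSIFIED:
        raise DomainError("no risk profile is defined for the unclassified group")
    table = criteria if criteria is not None else default_risk_criteria()
    return table.profile(group)


# --- Partin-style pathologic-stage lookup ----------------------------------


@dataclass(frozen=True)
class _PartinCell:
    t_category: TCategory
    psa_lo: float  # inclusive
    psa_hi: float  # exclusive (inf allowed)
    gleason_lo: int  # inclusive
    gleason_hi: int  # inclusive
    probabilities: dict[str, float]  # outcome name -> %

    def covers(self, t: TCategory, psa: float, gleason_sum: int) -> bool:
        return (
            t is self.t_category
            and self.psa_lo <= psa < self.psa_hi
            and self.gleason_lo <= gleason_sum <= self.gleason_hi
        )


@dataclass(frozen=True)
class PartinTable:
    """Lookup from (T category, PSA range, Gleason range) to pathologic-stage
    probabilities in percent.  PSA ranges are lower-closed, upper-open so any
    published edition's bin edges can be transcribed unambiguously."""

    outcomes: tuple[str, ...]
    cells: tuple[_PartinCell, ...]


_PARTIN_KEY_COLS = ["t_category", "psa_min", "psa_max", "gleason_min", "gleason_max"]


def load_partin_table(path: str | Path) -> PartinTable:
    """Load a Partin-style table.

    Key columns ``t_category,psa_min,psa_max,gleason_min,gleason_max``
    (empty ``psa_max`` = unbounded); every remaining column is a
    pathologic-stage outcome with probabilities in percent.
    """
    p = Path(path)
    cells: list[_PartinCell] = []
    with p.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or reader.fieldnames[: len(_PARTIN_KEY_COLS)] != _PARTIN_KEY_COLS:
            raise LoadError(
                f"expected leading columns {_PARTIN_KEY_COLS}, got {reader.fieldnames}",
                source=str(p),
                line=1,
            )
        outcome_cols = tuple(reader.fieldnames[len(_PARTIN_KEY_COLS) :])
        if not outcome_cols:
            raise LoadError("no outcome probability columns", source=str(p), line=1)
        for i, row in enumerate(reader, start=2):
            try:
                probs = {c: float(_cell(row, c)) for c in outcome_cols}
                if any(not 0 <= v <= 100 for v in probs.values()):
                    raise ValueError("probability outside [0,100]")
                cells.append(
                    _PartinCell(
                        t_category=TCategory(_cell(row, "t_category")),
                        psa_lo=float(_cell(row, "psa_min")),
                        psa_hi=float(_cell(row, "psa_max")) if _cell(row, "psa_max") else math.inf,
                        gleason_lo=int(_cell(row, "gleason_min")),
                        gleason_hi=int(_cell(row, "gleason_max")),
                        probabilities=probs,
                    )
                )
            except ValueError as e:
                raise LoadError(f"bad table row: {e}", source=str(p), line=i) from None
    # overlapping cells would make the lookup ambiguous
    for i, a in enumerate(cells):
        for b in cells[i + 1 :]:
            if (
                a.t_category is b.t_category
                and a.psa_lo < b.psa_hi
                and b.psa_lo < a.psa_hi
                and a.gleason_lo <= b.gleason_hi
                and b.gleason_lo <= a.gleason_hi
            ):
                raise LoadError(
                    f"overlapping cells for {a.t_category.value} "
                    f"(PSA [{a.psa_lo},{a.psa_hi}) vs [{b.psa_lo},{b.psa_hi}))",
                    source=str(p),
                )
    return PartinTable(outcomes=outcome_cols, cells=tuple(cells))


_DEFAULT_PARTIN: PartinTable | None = None


def default_partin_table() -> PartinTable:
    """The packaged SYNTHETIC placeholder table (structure only, not
    published probabilities); cached after first load."""
    global _DEFAULT_PARTIN
    if _DEFAULT_PARTIN is None:
        with resources.as_file(
            resources.files("psakit.data").joinpath("partin_table_synthetic.csv")
        ) as p:
            _DEFAULT_PARTIN = load_partin_table(p)
    return _DEFAULT_PARTIN


def partin_lookup(
    table: PartinTable,
    stage: ClinicalStage,
    psa: float,
    gleason: GleasonScore,
) -> dict[str, float]:
    """Return the matching cell's pathologic-stage probability vector verbatim.

    Gleason sum ranges are matched through their maximum element, consistent
    with :func:`stratify`.  Raises :class:`CoverageError` when no cell covers
    the query.
    """
    g = gleason.max_sum
    for cell in table.cells:
        if cell.covers(stage.t_category, psa, g):
            return dict(cell.probabilities)
    raise CoverageError(
        f"({stage.t_category.value}, PSA {psa} ng/mL, Gleason {g}) is not covered by the table"
    )
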