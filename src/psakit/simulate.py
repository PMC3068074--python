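"""Synthetic longitudinal PSA cohorts with known ground truth.

The generator emulates the course of a treated prostate-cancer patient:

* **pre-treatment** — exponential PSA growth ``P(t) = P0 · 2^(t / PSADT)``
  with a patient-specific doubling time, sampled at scheduled visits;
* **treatment** — a single surgery or radiotherapy event after which PSA
  drops to a modality-specific nadir (0.05 ng/mL post-surgery, 1.0 ng/mL
  post-radiotherapy);
* **recurrence** — with some probability, exponential regrowth from the
  nadir resumes after a random delay, at the patient's own doubling time;
* **noise** — multiplicative log-normal measurement error (PSA is positive
  and assay error scales with level); follow-up visits may be missed.

Measurement dates are whole calendar days; PSA values are computed from the
true elapsed days with the same days-per-month constant the kinetics module
uses, so the estimators' round trip on noiseless data is exact to machine
precision.  Every patient's true doubling time, treatment, recurrence
status and per-visit outcome are recorded in a ground-truth sidecar, so
tests never peek into simulator internals.

The same seed always reproduces the cohort byte-for-byte.
"""

from __future__ import annotations

import csv
import datetime as _dt
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from pydantic import BaseModel, Field, model_validator

from .audit import Criterion, Outcome, OutcomeCriteria
from .cohort_io import write_cohort
from .records import (
    ClinicalStage,
    GleasonScore,
    MCategory,
    Modality,
    NCategory,
    PatientRecord,
    PSAMeasurement,
    PSASeries,
    TCategory,
    TreatmentEvent,
)
from .units import DAYS_PER_MONTH

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "simulate_trajectory",
    "simulate_cohort",
    "simulate_to_dir",
    "truth_tally",
    "TRUTH_FILE",
]

TRUTH_FILE = "truth.csv"

# staging is sampled independently of the PSA trajectory, spanning the
# stratifier's T1c..T2c domain
_T_CATEGORIES = (TCategory.T1c, TCategory.T2a, TCategory.T2b, TCategory.T2c)
_T_WEIGHTS = (0.35, 0.25, 0.20, 0.20)
_GLEASON_GRADES = (3, 4, 5)
_GLEASON_WEIGHTS = (0.5, 0.35, 0.15)


class SimulationParams(BaseModel):
    """Cohort-level simulation settings.

    Defaults emulate a ~95-patient pilot cohort with a 61/34 surgery/
    radiotherapy split tracked for 12 months after treatment, preceded by
    four years of PSA surveillance every four months.
    """

    model_config = {"frozen": True}

    n_patients: int = Field(default=95, ge=0)
    baseline_psa_range: tuple[float, float] = (2.0, 15.0)  # ng/mL at first visit
    true_psadt_range: tuple[float, float] = (12.0, 48.0)  # months
    surgery_fraction: float = Field(default=61 / 95, ge=0.0, le=1.0)
    post_surgery_nadir: float = Field(default=0.05, gt=0.0)
    post_radio_nadir: float = Field(default=1.0, gt=0.0)
    recurrence_prob: float = Field(default=0.15, ge=0.0, le=1.0)
    recurrence_delay_range: tuple[float, float] = (3.0, 9.0)  # months after treatment
    noise_cv: float = Field(default=0.1, ge=0.0)  # sd of log measurement error
    pre_visit_months: tuple[float, ...] = tuple(float(m) for m in range(0, 49, 4))
    visit_schedule: tuple[int, ...] = (1, 3, 6, 9, 12)  # months after treatment
    dropout_prob_per_visit: float = Field(default=0.2, ge=0.0, le=1.0)
    treatment_lag_days: int = Field(default=7, ge=1)
    start_date: _dt.date = _dt.date(2008, 1, 6)
    seed: int = 0

    @model_validator(mode="after")
    def _ranges_ok(self) -> "SimulationParams":
        for name in ("baseline_psa_range", "true_psadt_range", "recurrence_delay_range"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must satisfy 0 < lo <= hi, got ({lo}, {hi})")
        if len(self.pre_visit_months) < 2:
            raise ValueError("need at least 2 pre-treatment visits")
        return self


@dataclass(frozen=True)
class GroundTruth:
    """The simulator's bookkeeping for one patient."""

    patient_id: str
    true_psadt_months: float
    modality: Modality
    recurred: bool
    recurrence_month: Optional[float]  # months after treatment, None if no recurrence
    #: month -> outcome under the modality-threshold criterion
    threshold_outcome_by_month: dict[int, Outcome]
    #: month -> outcome under the below-pretreatment criterion
    below_pre_outcome_by_month: dict[int, Outcome]


def _month_to_days(m: float) -> int:
    return round(m * DAYS_PER_MONTH)


def simulate_trajectory(
    params: SimulationParams, patient_index: int, rng: np.random.Generator
) -> tuple[PatientRecord, GroundTruth]:
    """Simulate one patient from the given random stream."""
    pid = f"SIM{patient_index + 1:04d}"
    p0 = rng.uniform(*params.baseline_psa_range)
    psadt = rng.uniform(*params.true_psadt_range)
    modality = Modality.SURGERY if rng.random() < params.surgery_fraction else Modality.RADIOTHERAPY
    nadir = params.post_surgery_nadir if modality is Modality.SURGERY else params.post_radio_nadir
    recurred = rng.random() < params.recurrence_prob
    rec_delay = rng.uniform(*params.recurrence_delay_range) if recurred else None

    def noise() -> float:
        return float(np.exp(rng.normal(0.0, params.noise_cv))) if params.noise_cv > 0 else 1.0

    measurements: list[PSAMeasurement] = []
    for m in params.pre_visit_months:
        d = params.start_date + _dt.timedelta(days=_month_to_days(m))
        t_months = (d - params.start_date).days / DAYS_PER_MONTH
        value = p0 * 2.0 ** (t_months / psadt) * noise()
        measurements.append(PSAMeasurement(date=d, psa=value))

    treat_date = measurements[-1].date + _dt.timedelta(days=params.treatment_lag_days)
    pre_psa = measurements[-1].psa
    event = TreatmentEvent(modality=modality, date=treat_date, pre_treatment_psa=pre_psa)

    threshold = OutcomeCriteria().threshold_for(modality)
    threshold_outcomes: dict[int, Outcome] = {}
    below_pre_outcomes: dict[int, Outcome] = {}
    for month in params.visit_schedule:
        if rng.random() < params.dropout_prob_per_visit:
            threshold_outcomes[month] = Outcome.NOT_EVALUABLE
            below_pre_outcomes[month] = Outcome.NOT_EVALUABLE
            continue
        d = treat_date + _dt.timedelta(days=_month_to_days(month))
        t_months = (d - treat_date).days / DAYS_PER_MONTH
        level = nadir
        if rec_delay is not None and t_months > rec_delay:
            level = nadir * 2.0 ** ((t_months - rec_delay) / psadt)
        value = level * noise()
        measurements.append(PSAMeasurement(date=d, psa=value))
        threshold_outcomes[month] = Outcome.SUCCESS if value < threshold else Outcome.FAILURE
        below_pre_outcomes[month] = Outcome.SUCCESS if value < pre_psa else Outcome.FAILURE

    primary = int(rng.choice(_GLEASON_GRADES, p=_GLEASON_WEIGHTS))
    secondary = int(rng.choice(_GLEASON_GRADES, p=_GLEASON_WEIGHTS))
    record = PatientRecord(
        patient_id=pid,
        psa_series=PSASeries(patient_id=pid, measurements=measurements),
        stage=ClinicalStage(
            t_category=_T_CATEGORIES[int(rng.choice(len(_T_CATEGORIES), p=_T_WEIGHTS))],
            n_category=NCategory.N0,
            m_category=MCategory.M0,
        ),
        gleason=GleasonScore(
            primary=primary, secondary=secondary, sum_set=frozenset({primary + secondary})
        ),
        prostate_volume_ml=float(rng.uniform(20.0, 60.0)),
        life_expectancy_years=float(rng.uniform(8.0, 20.0)),
        treatments=[event],
    )
    truth = GroundTruth(
        patient_id=pid,
        true_psadt_months=psadt,
        modality=modality,
        recurred=recurred,
        recurrence_month=rec_delay,
        threshold_outcome_by_month=threshold_outcomes,
        below_pre_outcome_by_month=below_pre_outcomes,
    )
    return record, truth


def simulate_cohort(params: SimulationParams) -> tuple[list[PatientRecord], list[GroundTruth]]:
    """Simulate a full cohort in memory.

    Each patient draws from an independent child stream of the cohort seed,
    so the cohort is reproducible as a whole and per patient.
    """
    streams = np.random.SeedSequence(params.seed).spawn(params.n_patients)
    records: list[PatientRecord] = []
    truths: list[GroundTruth] = []
    for i, ss in enumerate(streams):
        rec, truth = simulate_trajectory(params, i, np.random.default_rng(ss))
        records.append(rec)
        truths.append(truth)
    return records, truths


def simulate_to_dir(params: SimulationParams, out_dir: str | Path) -> dict[str, Path]:
    """Simulate a cohort and write it in the standard cohort file layout.

    Emits ``psa.csv``/``staging.csv``/``treatments.csv`` plus a
    ``truth.csv`` ground-truth sidecar (one row per patient with the true
    doubling time, modality, recurrence and per-month outcomes).  Identical
    parameters (including seed) produce byte-identical files.
    """
    records, truths = simulate_cohort(params)
    paths = write_cohort(records, out_dir)
    truth_path = Path(out_dir) / TRUTH_FILE
    months = list(params.visit_schedule)
    with truth_path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["patient_id", "true_psadt_months", "modality", "recurred", "recurrence_month"]
            + [f"threshold_outcome_m{m}" for m in months]
            + [f"below_pre_outcome_m{m}" for m in months]
        )
        for t in truths:
            w.writerow(
                [
                    t.patient_id,
                    repr(t.true_psadt_months),
                    t.modality.value,
                    str(t.recurred).lower(),
                    "" if t.recurrence_month is None else repr(t.recurrence_month),
                ]
                + [t.threshold_outcome_by_month[m].value for m in months]
                + [t.below_pre_outcome_by_month[m].value for m in months]
            )
    paths[TRUTH_FILE] = truth_path
    return paths


def truth_tally(
    truths: list[GroundTruth], criterion: Criterion = Criterion.THRESHOLD
) -> dict[tuple[Modality, int], tuple[int, int]]:
    """(modality, month) -> (successes, evaluable) from the ground truth."""
    tally: dict[tuple[Modality, int], tuple[int, int]] = {}
    for t in truths:
        by_month = (
            t.threshold_outcome_by_month
            if criterion is Criterion.THRESHOLD
            else t.below_pre_outcome_by_month
        )
        for month, outcome in by_month.items():
            if outcome is Outcome.NOT_EVALUABLE:
                continue
            s, n = tally.get((t.modality, month), (0, 0))
            tally[(t.modality, month)] = (s + (outcome is Outcome.SUCCESS), n + 1)
    return tally
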