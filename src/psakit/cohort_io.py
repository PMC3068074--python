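"""Delimited-file readers and writers for patient cohorts.

Three comma-delimited UTF-8 files with mandatory headers describe a cohort,
joined on ``patient_id``:

* ``psa.csv`` — ``patient_id,date,psa_ng_ml``; one row per PSA draw.
* ``staging.csv`` — ``patient_id,tnm,gleason,prostate_volume_ml,life_expectancy_years``;
  at most one row per patient, empty cell = absent.
* ``treatments.csv`` — ``patient_id,modality,date,pre_treatment_psa_ng_ml``.

Reading after writing reproduces the cohort field-for-field.  Format
violations raise :class:`~psakit.errors.LoadError` carrying file and line.
"""

from __future__ import annotations

import csv
import datetime as _dt
from pathlib import Path
from typing import Iterable

from pydantic import ValidationError

from .errors import LoadError, ParseError
from .records import (
    Modality,
    PatientRecord,
    PSAMeasurement,
    PSASeries,
    parse_date,
    parse_gleason,
    parse_tnm,
)

__all__ = ["read_cohort", "write_cohort", "PSA_FILE", "STAGING_FILE", "TREATMENTS_FILE"]

PSA_FILE = "psa.csv"
STAGING_FILE = "staging.csv"
TREATMENTS_FILE = "treatments.csv"

_PSA_COLS = ["patient_id", "date", "psa_ng_ml"]
_STAGING_COLS = ["patient_id", "tnm", "gleason", "prostate_volume_ml", "life_expectancy_years"]
_TREATMENT_COLS = ["patient_id", "modality", "date", "pre_treatment_psa_ng_ml"]


def _rows(path: Path, expected_cols: list[str]) -> Iterable[tuple[int, dict[str, str]]]:
    if not path.exists():
        raise LoadError("file not found", source=str(path))
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise LoadError("missing header row", source=str(path))
        if list(reader.fieldnames) != expected_cols:
            raise LoadError(
                f"unexpected columns {reader.fieldnames}, expected {expected_cols}",
                source=str(path),
                line=1,
            )
        for row in reader:
            yield reader.line_num, row


def _opt_float(cell: str | None, path: Path, line: int, what: str) -> float | None:
    if cell is None or cell.strip() == "":
        return None
    try:
        return float(cell)
    except ValueError:
        raise LoadError(f"unparseable {what} {cell!r}", source=str(path), line=line) from None


def read_cohort(
    psa_file: str | Path,
    staging_file: str | Path | None = None,
    treatment_file: str | Path | None = None,
) -> list[PatientRecord]:
    """Read a cohort from its delimited files, joined by patient id.

    ``staging_file`` and ``treatment_file`` may be omitted (e.g. a
    PSA-only cohort).  Returns one :class:`PatientRecord` per distinct
    patient id, in first-appearance order of the PSA file; patients that
    occur only in the staging or treatment file get an empty PSA series.
    """
    psa_path = Path(psa_file)
    series: dict[str, list[PSAMeasurement]] = {}
    seen_dates: dict[str, set[_dt.date]] = {}
    order: list[str] = []

    for line, row in _rows(psa_path, _PSA_COLS):
        pid = (row["patient_id"] or "").strip()
        if not pid:
            raise LoadError("empty patient_id", source=str(psa_path), line=line)
        try:
            d = parse_date(row["date"])
        except ParseError as e:
            raise LoadError(str(e), source=str(psa_path), line=line) from None
        try:
            psa = float(row["psa_ng_ml"])
        except (TypeError, ValueError):
            raise LoadError(
                f"unparseable PSA value {row['psa_ng_ml']!r}", source=str(psa_path), line=line
            ) from None
        if pid not in series:
            series[pid] = []
            seen_dates[pid] = set()
            order.append(pid)
        if d in seen_dates[pid]:
            raise LoadError(
                f"duplicate PSA row for patient {pid!r} on {d}", source=str(psa_path), line=line
            )
        seen_dates[pid].add(d)
        series[pid].append(PSAMeasurement(date=d, psa=psa))

    staging: dict[str, dict] = {}
    if staging_file is not None:
        st_path = Path(staging_file)
        for line, row in _rows(st_path, _STAGING_COLS):
            pid = (row["patient_id"] or "").strip()
            if not pid:
                raise LoadError("empty patient_id", source=str(st_path), line=line)
            if pid in staging:
                raise LoadError(f"duplicate staging row for patient {pid!r}", source=str(st_path), line=line)
            try:
                stage = parse_tnm(row["tnm"]) if (row["tnm"] or "").strip() else None
                gleason = parse_gleason(row["gleason"]) if (row["gleason"] or "").strip() else None
            except ParseError as e:
                raise LoadError(str(e), source=str(st_path), line=line) from None
            staging[pid] = {
                "stage": stage,
                "gleason": gleason,
                "prostate_volume_ml": _opt_float(row["prostate_volume_ml"], st_path, line, "prostate volume"),
                "life_expectancy_years": _opt_float(
                    row["life_expectancy_years"], st_path, line, "life expectancy"
                ),
            }
            if pid not in series:
                series[pid] = []
                order.append(pid)

    treatments: dict[str, list] = {}
    if treatment_file is not None:
        tr_path = Path(treatment_file)
        from .records import TreatmentEvent  # local to avoid re-export confusion

        for line, row in _rows(tr_path, _TREATMENT_COLS):
            pid = (row["patient_id"] or "").strip()
            if not pid:
                raise LoadError("empty patient_id", source=str(tr_path), line=line)
            mod_txt = (row["modality"] or "").strip()
            try:
                modality = Modality(mod_txt)
            except ValueError:
                raise LoadError(f"unknown treatment modality {mod_txt!r}", source=str(tr_path), line=line) from None
            try:
                d = parse_date(row["date"])
            except ParseError as e:
                raise LoadError(str(e), source=str(tr_path), line=line) from None
            ev = TreatmentEvent(
                modality=modality,
                date=d,
                pre_treatment_psa=_opt_float(
                    row["pre_treatment_psa_ng_ml"], tr_path, line, "pre-treatment PSA"
                ),
            )
            treatments.setdefault(pid, []).append(ev)
            if pid not in series:
                series[pid] = []
                order.append(pid)

    records: list[PatientRecord] = []
    for pid in order:
        st = staging.get(pid, {})
        try:
            records.append(
                PatientRecord(
                    patient_id=pid,
                    psa_series=PSASeries(patient_id=pid, measurements=series[pid]),
                    stage=st.get("stage"),
                    gleason=st.get("gleason"),
                    prostate_volume_ml=st.get("prostate_volume_ml"),
                    life_expectancy_years=st.get("life_expectancy_years"),
                    treatments=treatments.get(pid, []),
                )
            )
        except ValidationError as e:
            raise LoadError(f"invalid record for patient {pid!r}: {e}", source=str(psa_path)) from None
    return records


def _fmt(x: float | None) -> str:
    # repr round-trips float64 exactly, keeping read∘write the identity
    return "" if x is None else repr(float(x))


def write_cohort(cohort: list[PatientRecord], out_dir: str | Path) -> dict[str, Path]:
    """Write a cohort to ``psa.csv``/``staging.csv``/``treatments.csv``.

    Returns a mapping of logical file name to the path written.  The files
    round-trip through :func:`read_cohort` field-for-field.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / name for name in (PSA_FILE, STAGING_FILE, TREATMENTS_FILE)}

    with paths[PSA_FILE].open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_PSA_COLS)
        for rec in cohort:
            for m in rec.psa_series.measurements:
                w.writerow([rec.patient_id, m.date.isoformat(), _fmt(m.psa)])

    with paths[STAGING_FILE].open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_STAGING_COLS)
        for rec in cohort:
            w.writerow(
                [
                    rec.patient_id,
                    str(rec.stage) if rec.stage else "",
                    str(rec.gleason) if rec.gleason else "",
                    _fmt(rec.prostate_volume_ml),
                    _fmt(rec.life_expectancy_years),
                ]
            )

    with paths[TREATMENTS_FILE].open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(_TREATMENT_COLS)
        for rec in cohort:
            for ev in rec.treatments:
                w.writerow(
                    [rec.patient_id, ev.modality.value, ev.date.isoformat(), _fmt(ev.pre_treatment_psa)]
                )

    return paths
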