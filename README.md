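# psakit

Desk-scale decision-support toolkit for prostate-cancer treatment planning:
PSA kinetics, pretreatment risk stratification, treatment-guideline
evaluation, post-treatment outcome auditing, and a synthetic-cohort
simulator, with both a Python API and a `psakit` command-line interface.

It is aimed at clinical researchers and biostatisticians who want the
analytic core of a prostate-cancer decision-support workflow — the
computations a clinician would see at a clinic visit — as a reproducible,
scriptable library that runs on plain CSV exports instead of a hospital
information system.

## What it computes

**PSA kinetics.** Serum prostate-specific antigen (PSA, ng/mL) tracked over
time carries most of the diagnostic signal. For a selected measurement
window the package estimates:

* *PSA velocity* (PSAV, ng/mL/yr) from the linear model
  `P(t) = initial_PSA + PSAV · t`, fitted by ordinary least squares, or as
  the secant slope between two chosen markers. Velocities in excess of
  0.75 ng/mL/yr (or the stricter 2 ng/mL/yr cut-off) are flagged.
* *PSA doubling time* (PSADT, months) from the log-linear model
  `ln P(t) = a + b·t` as `ln 2 / b`, or from two markers as
  `(t₂ − t₁)·ln 2 / ln(P₂/P₁)`. A non-rising PSA has no doubling time and
  is reported as undefined.
* *PSA density* (PSAD): PSA divided by prostate volume (ng/mL per mL).

**Risk stratification.** The three-tier pretreatment classification for
clinically localized disease from TNM stage, PSA and Gleason score:

| Tier | Criteria | 5-yr failure risk | 5-yr survival | 10-yr survival |
|---|---|---|---|---|
| low | (T1c or T2a) and PSA ≤ 10 and Gleason ≤ 6 | < 25 % | 85 % | 83 % |
| intermediate | T2b, or Gleason 7, or 10 < PSA ≤ 20 | 25–50 % | 60 % | 46 % |
| high | T2c, or PSA > 20, or Gleason ≥ 8 | > 50 % | 30 % | 29 % |

Overlapping OR-criteria are resolved worst-tier-first. A pluggable
Partin-style lookup additionally maps (stage, PSA range, Gleason range) to
pathologic-stage probabilities; the shipped table is a clearly-labelled
synthetic placeholder — drop in a published edition for real use.

**Guideline evaluation.** Treatment guidelines are directed acyclic graphs
whose nodes carry predicates over clinical facts. Given a patient's facts
the engine highlights every step reachable through satisfied predicates,
with three-valued logic for missing facts (unknown never highlights).

**Outcome audit.** A treatment counts as a biochemical success when
follow-up PSA falls below 0.2 ng/mL after surgery or 2 ng/mL after
radiotherapy (strict inequality), or — under the second criterion — below
the pre-treatment PSA. `audit_cohort` tabulates `successes/total(percent%)`
per modality and follow-up month.

**Simulation.** Synthetic cohorts with exponential PSA growth at known
doubling times, treatment-induced decline to a modality nadir, optional
recurrence, log-normal measurement noise and missed visits, plus a
ground-truth sidecar, so every estimator can be validated end to end.

## Worked example

The pretreatment profile of a patient staged T1c with PSA 32.4 ng/mL and a
Gleason score recorded as the range 5–6:

```sh
$ psakit stratify --tnm T1c --psa 32.4 --gleason 5-6
tnm,psa_ng_ml,gleason,risk_group,failure_5yr_band_pct,survival_5yr_pct,survival_10yr_pct
T1cNXMX,32.4,5-6,high,>50,30.0,29.0
```

The PSA alone (> 20 ng/mL) places the patient in the high-risk tier despite
the favourable stage and grade: the 5-year PSA-failure risk exceeds 50 %,
with 30 % and 29 % PSA-failure-free survival at 5 and 10 years.

A high-risk patient's facts highlight the applicable therapeutic path in
the packaged demo guideline (PSA 82.35 ng/mL, stage T2cN0M0, Gleason 4+3,
15-year life expectancy, 38 % lymph-node involvement, asymptomatic):

```sh
$ psakit guideline --psa 82.35 --tnm T2cN0M0 --gleason 4+3 \
    --life-expectancy 15 --lymph-node-pct 38 --asymptomatic
[decision] Pretreatment evaluation (PSA, clinical stage, Gleason score)
  -> [decision] High-risk disease: T2c or PSA > 20 or Gleason >= 8
  -> [therapy] Radiation therapy
  -> [therapy] Androgen-deprivation (hormonal) therapy
  -> [terminal] PSA follow-up schedule
```

End to end on synthetic data:

```sh
$ psakit simulate --n 95 --seed 1 --out-dir cohort/
$ psakit kinetics --cohort-dir cohort/ --patient SIM0001 --to 2012-01-02
patient_id,initial_psa,psav,psav_unit,psadt,psadt_unit,n_points,method,flag_0.75,flag_2.0,psad
SIM0001,5.4878045138730585,12.79398152100635,ng/mL/year,17.229958253195786,months,12,regression,True,True,1.756918809256275
$ psakit audit --cohort-dir cohort/
treatment,criterion,1,3,6,9,12
surgery,threshold,40/40(100%),48/48(100%),43/43(100%),42/42(100%),48/48(100%)
surgery,below_pretreatment,40/40(100%),48/48(100%),43/43(100%),42/42(100%),48/48(100%)
radiotherapy,threshold,26/26(100%),33/33(100%),32/32(100%),31/31(100%),30/30(100%)
radiotherapy,below_pretreatment,26/26(100%),33/33(100%),32/32(100%),31/31(100%),30/30(100%)
```

(The kinetics row reads: over this patient's pre-treatment window the PSA
rose 12.8 ng/mL/yr — flagged at both cut-offs — doubling every ~17 months,
with a PSA density of 1.76 ng/mL per mL. The all-success audit reflects the
simulator's simplified treatment model; see `docs/methods.md`.)

`psakit report --cohort-dir cohort/ --patient SIM0001` chains kinetics,
stratification and the guideline path into one clinic-visit summary.

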