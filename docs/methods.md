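# Methods

This note documents the models, conventions and design decisions behind
psakit, and what its synthetic-data validation does and does not establish.

## Time and units

Measurement dates are ISO-8601 calendar dates. Elapsed time between dates
is always computed in whole days and converted with fixed factors — a
Julian year of 365.25 days and a mean month of 30.44 days — shared by every
module (`psakit.units`), so the kinetics estimators, the audit's follow-up
windows and the simulator are mutually consistent to machine precision.
Defaults follow the units of the clinical cut-offs: PSA velocity in
ng/mL/yr (flagging thresholds 0.75 and 2 ng/mL/yr), doubling time in
months; both are configurable per call.

## PSA kinetics

PSAV is the slope of the OLS fit of PSA against elapsed time from the
first selected measurement; "initial PSA" is the intercept at that window
origin, i.e. the model value at the window start, not the raw first
measurement. PSADT comes from the OLS fit of ln PSA against time as
`ln 2 / slope`. The alternative two-marker algorithm uses the secant slope
and the closed-form interpolation `(t₂ − t₁)·ln 2 / ln(P₂/P₁)`; on
two-point windows the regression path evaluates the same closed forms, so
the two algorithms agree identically there.

Conventions chosen where usage in the field varies:

* A non-positive fitted log-slope (PSA not rising) yields an **undefined**
  doubling time, reported as such rather than as a negative number —
  negative doubling times have no clinical meaning. Requesting PSADT on a
  window containing non-positive PSA values is a domain error; values are
  never silently dropped from the log fit, since silent exclusion would
  undermine auditability.
* Velocity flagging is strict ("in excess of"): a velocity exactly at the
  cut-off is not flagged.
* PSA density is the plain quotient PSA / prostate volume and requires a
  positive volume.

## Risk stratification

The three-tier classification (low / intermediate / high) is stored as a
delimited criteria table shipped with the package, not hard-coded: each
row is a conjunction of optional constraints (allowed T substages, an
exclusive PSA lower bound, an inclusive PSA upper bound, inclusive Gleason
bounds) and a tier matches when any of its rows match. The shipped table
transcribes the published tier definitions and their outcome columns
(5-year PSA-failure band; 5- and 10-year PSA-failure-free survival).

Decisions taken where the published criteria are silent:

* **Precedence.** The OR-criteria overlap (e.g. T2b with PSA 25 matches
  both intermediate and high). Tiers are evaluated high → intermediate →
  low, so the worse tier governs.
* **Boundaries.** PSA comparisons follow the printed inequalities exactly:
  low requires ≤ 10, intermediate > 10 and ≤ 20, high > 20; so PSA 10 is
  low-compatible and PSA 20 intermediate-compatible.
* **Gleason ranges.** A score recorded as a sum range ("5-6") matches
  grade criteria through its maximum element — the worst-case reading.
* **Coverage.** Stages outside T1c–T2c whose PSA/Gleason trigger no tier
  return `unclassified` rather than raising or guessing; the classifier
  never invents coverage the criteria do not define.

These choices make the classifier total and monotone over the covered
domain: raising PSA or Gleason sum never lowers the tier (verified
exhaustively in the test suite over stages T1c–T2c, sums 2–10 and a PSA
grid 0–40 by 0.1).

A bare TNM string ("T1c") parses with N and M as NX/MX — absence of
evidence is recorded, not assumed negative.

### Partin-style lookup

The pathologic-stage lookup maps (T category, PSA range, Gleason range) to
a probability vector. PSA ranges are lower-closed, upper-open so published
bin edges transcribe unambiguously, and overlapping cells are rejected at
load time. The packaged `partin_table_synthetic.csv` is **synthetic**: it
reproduces the structure (axes, bins, monotone trends, rows summing to
100 %) but its probabilities are generated placeholders; users must load a
published edition for clinical interpretation.

## Guideline engine

Guideline content is data, not code: graphs are authored in a YAML schema
(node ids, labels, kinds, predicates; edges; a declared fact schema; one
entry node). Published flowcharts are not reproduced; the packaged graph is
a simplified illustrative flow. Validation at load time covers duplicate
ids, dangling edges, acyclicity (the offending cycle is listed) and
predicates referencing undeclared facts.

The predicate language supports comparisons (`<, <=, >, >=, ==, !=`,
chained), membership over literal collections, and `and/or/not`. It is
parsed with Python's `ast` module against a strict whitelist and
interpreted by the package — never executed as Python — so graph files
cannot run arbitrary code.

Missing facts evaluate under Kleene three-valued logic: `True or unknown`
is true, `True and unknown` is unknown, `False and unknown` is false. A
node is highlighted iff it is reachable from the entry through highlighted
nodes via satisfied edge predicates and its own predicate is true; unknown
stops highlighting but the node is recorded as unmet. Consequences:
evaluation is deterministic, the highlighted region is always connected to
the entry, and adding facts can only extend the highlight while existing
predicate outcomes are unchanged (all three are property-tested, the
connectivity invariant on randomly generated DAGs).

## Outcome audit

Success criteria: follow-up PSA strictly below 0.2 ng/mL after surgery or
2 ng/mL after radiotherapy (threshold criterion; other modalities have no
threshold and raise a domain error), or strictly below the recorded
pre-treatment PSA (second criterion, any modality). Boundary values fail.

Matching a follow-up month to a measurement is not specified by the
criteria themselves; the package's rule is: the nominal date is the
treatment date plus the month converted at 30.44 days/month; the nearest
measurement **strictly after the treatment date** within ±45 days of
nominal is used (ties go to the earlier one); otherwise the patient is not
evaluable at that month and drops out of the denominator. This reproduces
audit tables whose denominators vary by month as visits are missed. The
strictly-after restriction matters: the last pre-treatment draw can
otherwise fall inside the month-1 window.

Cell percentages are rounded to the nearest integer, halves away from
zero — the convention consistent with published `successes/total(percent)`
cells such as 19/24 → 79 %.

## Synthetic cohorts

The simulator emulates a treated-cohort natural history sufficient to
validate the estimators and the audit, with known ground truth:

* Pre-treatment PSA grows exponentially, `P(t) = P0 · 2^(t/PSADT)`, with a
  patient-specific doubling time.
* A single treatment (surgery or radiotherapy) drops PSA to a
  modality-specific nadir.
* With some probability, exponential regrowth from the nadir resumes after
  a uniform random delay, at the patient's own doubling time.
* Measurements carry multiplicative log-normal noise (PSA is positive and
  assay error scales with level) and follow-up visits are missed
  independently with a fixed probability.

Defaults, chosen once as a realistic surveillance-then-treatment scenario:
baseline PSA uniform on 2–15 ng/mL; true PSADT uniform on 12–48 months
(typical of untreated localized disease); pre-treatment visits every 4
months over 4 years (13 points — enough span that a 10 % noise level still
identifies slopes as shallow as a 48-month doubling time); treatment 7 days
after the last surveillance visit; follow-up at months 1, 3, 6, 9, 12 with
20 % missed-visit probability (pre-treatment visits are kept complete so
kinetics validation is not confounded with missingness); nadirs 0.05 ng/mL
(surgery) and 1.0 ng/mL (radiotherapy); 15 % recurrence with a 3–9 month
delay; a 61/95 surgery fraction and a default cohort size of 95, matching a
~95-patient pilot-scale cohort.

Two numerical details:

* Visit dates are whole calendar days, so a nominal "12-month" visit lands
  on day 365, not day 365.28. PSA values are computed from the **true
  elapsed days** using the same days-per-month constant as the kinetics
  module; hence noiseless estimator round trips recover the generating
  PSADT to machine precision, while nominally round values like
  {2, 4, 8} ng/mL at 0/12/24 months hold to ~0.3 %.
* Each patient draws from an independent child stream of the cohort seed
  (`numpy` `SeedSequence.spawn`), making output files byte-identical across
  reruns and individual patients reproducible.

Ground truth (true PSADT, modality, recurrence, per-month outcomes under
both criteria) is written to a separate `truth.csv` sidecar so validation
code never reads simulator internals.

**What the simulator does not model** — and what passing tests therefore do
not show about real data: no slow post-radiotherapy PSA decline (PSA drops
to the nadir instantly, so simulated early-month success rates are far
higher than clinically observed ones); constant nadirs without
inter-patient variability; staging and Gleason sampled independently of the
PSA trajectory; no benign PSA fluctuation, assay changes, or
treatment-modality selection by risk. It validates the *estimators and
bookkeeping*, not prostate-cancer epidemiology.

## Validation problem sizes

The test suite exercises: exhaustive grids for parsing (all 25 Gleason
pattern pairs; the full 9×3×3 TNM grid) and stratifier monotonicity
(4 stages × 9 sums × 401 PSA values); exact-exponential recovery over a
(P0, PSADT) grid; simulated cohorts of 50–200 patients for estimator
recovery (median relative PSADT error < 1e-6 noiseless, < 10 % at 10 %
noise) and cell-for-cell audit/ground-truth equality; and
property-based tests (seeded, derandomized) for round-trip IO, time-shift
and scale invariances, and guideline-trace connectivity on random DAGs.

## Known limitations

* The stratifier covers the published criteria's domain only; T3/T4
  management is representable in records but not classified.
* The packaged Partin table is a synthetic placeholder (above).
* The packaged guideline graph is demonstration content; no fidelity to
  any published guideline is claimed.
* The audit's ±45-day matching rule is this package's operationalization
  of "PSA at month m"; audits with different visit-matching conventions
  will differ at the margins.
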