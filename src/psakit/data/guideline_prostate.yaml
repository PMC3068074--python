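# Simplified prostate-cancer treatment decision graph shipped as a DEMO
# fixture.  The branching (risk tier -> therapy options, gated on life
# expectancy and nodal involvement) follows common clinical practice, but
# this file is illustrative in-repo content, not a transcription of any
# published guideline; author your own graph in the same schema for real use.
entry: evaluation
facts:
  psa: number                        # serum PSA, ng/mL
  t_category: category               # TNM primary-tumour substage
  gleason_sum: number
  life_expectancy_years: number
  lymph_node_involvement_pct: number
  symptomatic: boolean
nodes:
  - id: evaluation
    label: Pretreatment evaluation (PSA, clinical stage, Gleason score)
    kind: decision
    predicate: true
  - id: low_risk
    label: "Low-risk disease: T1c/T2a, PSA <= 10, Gleason <= 6"
    kind: decision
    predicate: t_category in ("T1c", "T2a") and psa <= 10 and gleason_sum <= 6
  - id: intermediate_risk
    label: "Intermediate-risk disease: T2b or Gleason 7 or 10 < PSA <= 20"
    kind: decision
    predicate: >
      not (t_category == "T2c" or psa > 20 or gleason_sum >= 8)
      and (t_category == "T2b" or gleason_sum == 7 or psa > 10)
  - id: high_risk
    label: "High-risk disease: T2c or PSA > 20 or Gleason >= 8"
    kind: decision
    predicate: t_category == "T2c" or psa > 20 or gleason_sum >= 8
  - id: watchful_waiting
    label: Watchful waiting (limited life expectancy)
    kind: therapy
    predicate: life_expectancy_years < 10
  - id: surgery
    label: Radical prostatectomy
    kind: therapy
    predicate: life_expectancy_years >= 10
  - id: radiotherapy
    label: Radiation therapy
    kind: therapy
    predicate: true
  - id: hormonal
    label: Androgen-deprivation (hormonal) therapy
    kind: therapy
    predicate: lymph_node_involvement_pct > 20 or symptomatic
  - id: followup
    label: PSA follow-up schedule
    kind: terminal
    predicate: true
edges:
  - {from: evaluation, to: low_risk}
  - {from: evaluation, to: intermediate_risk}
  - {from: evaluation, to: high_risk}
  - {from: low_risk, to: watchful_waiting}
  - {from: low_risk, to: surgery}
  - {from: intermediate_risk, to: surgery}
  - {from: intermediate_risk, to: radiotherapy}
  - {from: high_risk, to: radiotherapy}
  - {from: high_risk, to: hormonal}
  - {from: watchful_waiting, to: followup}
  - {from: surgery, to: followup}
  - {from: radiotherapy, to: followup}
  - {from: hormonal, to: followup}
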