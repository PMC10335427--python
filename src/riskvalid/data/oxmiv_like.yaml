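# Synthetic 16-item violence-risk model (15 binary items + age).
# Coefficient signs follow the risk directions observed in first-episode
# psychosis cohorts (male sex, younger age, antisocial history, substance
# misuse and socioeconomic adversity increase risk); the magnitudes are
# synthetic defaults, NOT published OxMIV weights.  Age is centred at the
# cohort mean of 25 years; its declared range (14-65) is the service age
# band and is used for risk bands when age is unknown.
label: oxmiv_like
# constant solved once at large n so the default model's mean predicted risk
# over the default cohort is the 11% target prevalence
constant: -3.61
predictors:
  - name: male
    kind: binary
    coefficient: 0.90
  - name: age
    kind: continuous
    coefficient: -0.045
    center: 25
    minimum: 14
    maximum: 65
  - name: previous_violent_crime
    kind: binary
    coefficient: 1.20
  - name: previous_drug_misuse
    kind: binary
    coefficient: 0.80
  - name: previous_alcohol_misuse
    kind: binary
    coefficient: 0.30
  - name: previous_self_harm
    kind: binary
    coefficient: 0.20
  - name: lower_secondary_education
    kind: binary
    coefficient: 0.60
  - name: parent_drug_alcohol_misuse
    kind: binary
    coefficient: 0.40
  - name: parent_violent_crime
    kind: binary
    coefficient: 0.70
  - name: sibling_violent_crime
    kind: binary
    coefficient: 0.60
  - name: current_inpatient
    kind: binary
    coefficient: -0.40
  - name: antipsychotic_treatment
    kind: binary
    coefficient: -0.10
  - name: antidepressant_treatment
    kind: binary
    coefficient: -0.20
  - name: dependence_treatment
    kind: binary
    coefficient: 0.30
  - name: low_income
    kind: binary
    coefficient: 0.80
  - name: benefit_recipient
    kind: binary
    coefficient: 0.30
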