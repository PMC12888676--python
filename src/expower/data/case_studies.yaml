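# Published cohort analyses used as worked design examples.  Each numeric
# field carries a source note tracing it to the cohort publication (or the
# repeated-measures study its variance components come from).
sol_bpa:
  label: "Bisphenols and fetal growth (pregnancy cohort, Sol et al. 2021)"
  n_actual: 1379
  m_actual: 2
  icc_design: 0.2
  sigma2_between: 0.21
  sigma2_within: 0.72
  sigma2_outcome: 1.0
  beta_design: 0.25
  effects_reported:
    - effect: 0.18
      note: "slope for BPS on fetal head circumference SD score per IQR of ln-exposure, m=2"
    - effect: -0.12
      note: "slope for BPA per IQR of ln-exposure, m=3"
  citation: >-
    Sol et al. 2021 (Environment International): 1,379 pregnancies; fetal
    growth z-scores (variance 1 by construction); urinary bisphenol
    ln-variance components sigma2_B=0.21, sigma2_W=0.72 from a
    repeated-measures biomonitoring study of urinary BPA.
guo_mothers:
  label: "Maternal urinary triclosan and child motor function (Guo et al. 2020)"
  n_actual: 377
  m_actual: 1
  icc_design: 0.6
  icc: 0.6
  sigma2_between: 0.019
  sigma2_outcome: 6.0
  beta_design: 0.25
  effects_reported:
    - effect: 0.25
      note: "slope for maternal triclosan on motor function per ln-unit"
  citation: >-
    Guo et al. 2020: 377 mother-child pairs, single delivery-day spot urine
    (m=1); ICC for pregnancy triclosan fixed at 0.6 (best case); total
    ln-variance 0.019 treated as between-person (best case), within-person
    variance derived from the ICC; outcome variance 6.
guo_boys:
  label: "Child urinary triclosan and social development, boys (Guo et al. 2020)"
  n_actual: 184
  m_actual: 1
  icc_design: 0.4
  icc: 0.4
  sigma2_between: 0.0095
  sigma2_outcome: 6.0
  beta_design: -0.37
  effects_reported:
    - effect: -0.37
      note: "slope for triclosan at age 3 on social development per ln-unit, boys"
  citation: >-
    Guo et al. 2020: 184 boys, single spot urine at age 3 (m=1); ICC for
    children fixed at 0.4 (best case); total ln-variance 0.0095 treated as
    between-person, within-person variance derived from the ICC; outcome
    variance 6.
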