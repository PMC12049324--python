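# Packaged base-case parameter set.
# Scalars live here; tabular parameters are referenced as CSV files in the
# same directory.  Any field may be overridden by a user manifest; absent
# fields fall back to these values.
#
# The bundled life table (synthetic_life_table.csv) is SYNTHETIC — a
# Gompertz-Makeham schedule with remaining life expectancy at 60 of ~25.8
# years.  Replace the tables.life_table entry with a national life table
# for calibration runs.
starting_age: 60
max_age: 100
cycle_length_years: 1
discount_rate: 0.02
cohort_scale: 1000
female_fraction: 0.467

conventions:
  cv_rate_basis: per10y          # reference CV risk is a 10-year risk
  treatment_scope: initial       # treatment/adjustment persist while the
                                 # patient remains in the initial state
                                 # (alternatives: first_cycle, lifetime)
  half_cycle: false
  mortality_rrr_on: total        # RRR scales the whole effective hazard ratio
  hr_composition: rate           # q = 1 - (1-q_bg)^HR
  sah_cost_category: event_stroke_ich

starting_egfr_props:
  G1: 0.285
  G2: 0.642
  G3a: 0.066
  G3b: 0.004
  G4: 0.002
  G5: 0.001
starting_acr_props:
  A1: 0.830
  A2: 0.160
  A3: 0.011

treatment_effects:
  ACEI_ARB:
    rrr_progression: 0.21
    rrr_mortality: 0.1
    annual_drug_cost_categories: [drug_acei_arb]
  ACEI_ARB_PLUS_SGLT2I:
    rrr_progression: 0.35
    rrr_mortality: 0.1
    annual_drug_cost_categories: [drug_acei_arb, drug_sglt2i]

tables:
  transitions: transitions.csv
  adjustment_factors: adjustment_factors.csv
  mortality_hr: mortality_hr.csv
  cv: cv.csv
  costs: costs.csv
  resource_use: resource_use.csv
  utilities: utilities.csv
  reclassification: reclassification.csv
  life_table: synthetic_life_table.csv
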