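# uacr-cea

Cost-effectiveness model of urine albumin-to-creatinine ratio (UACR)
testing for chronic kidney disease (CKD) in a non-diabetic population,
compared against urine protein-creatinine ratio (UPCR) testing and
against no urine testing, from a Japanese healthcare-system perspective.

Intended users are health economists and nephrology researchers who want
a transparent, scriptable reimplementation of a decision-tree +
Markov-cohort screening model: every parameter is a diffable CSV/YAML
input, every modelling convention is an explicit flag, and the whole
pipeline is importable from Python.

## The model

**Decision tree.** All arms receive regular eGFR testing, so the eGFR
stage (G1–G5) is always observed; the arms differ only in how albuminuria
(A1–A3) is classified. UACR is the diagnostic gold standard. UPCR
under-detects: re-test data give only marginal class proportions, so the
joint distribution is reconstructed under *nested detection* — a UPCR
test never classifies a patient more severely than truth, per-class
sensitivity is the ratio of marginal counts (unstratified:
s(A2) = 75/198 ≈ 0.38, s(A3) = 13/13 = 1), and a missed case is
classified one level lower. No urine testing manages everyone as A1.
Patients with an observed (G, diagnosed-A) pair in G1–G4 × A2–A3 receive
ACEi/ARB therapy (relative risk reduction 0.21 on progression, 0.10 on
mortality); a combination scenario adds SGLT2i (RRR 0.35) for the
higher-risk diagnosed groups.

**Markov cohort.** Six states: the four KDIGO-heatmap prognosis bands
(low / moderate / high / very-high risk), ESKD (dialysis) and death;
annual cycles from age 60 to 100. While a patient remains in their
starting state, transitions use KDIGO-cell-specific inputs — base
state-to-state probabilities scaled by per-cell adjustment factors, and
mortality from an age-indexed life table composed with per-cell hazard
ratios on the rate scale, `q = 1 − (1 − q_bg)^HR`; after leaving it,
dynamics switch to occupancy-weighted state averages identical across
arms. Treatment multiplies worsening-direction transition probabilities
by (1 − RRR) and lapses when the patient leaves the starting state (a
flag enables first-cycle-only or lifetime treatment). Cardiovascular
events are costed side events (reference 10-year risk 0.109 for the
low-risk state, state hazard ratios up to 12 for ESKD) with no effect on
state membership or survival.

**Outcomes.** Annual state costs combine fee-schedule unit costs with
clinician resource-use counts; incident events add one-time costs
(vascular-access surgery at dialysis initiation, mix-weighted acute CV
care). QALYs weight person-time by state utilities (0.940 low-risk to
0.789 ESKD). Costs and QALYs are discounted at 2%/year, end-of-cycle.
Each arm pair is reported as Δcost, ΔQALY and the incremental
cost-effectiveness ratio ICER = Δcost/ΔQALY (¥ per QALY gained), with
dominance labels when the ratio is uninformative, judged against the
¥5,000,000/QALY willingness-to-pay threshold.

The package ships the full published parameter set as its defaults. The
bundled life table is **synthetic** (Gompertz–Makeham, remaining life
expectancy at 60 ≈ 25.8 y); point `tables.life_table` at a national life
table CSV for calibration-grade runs.

## Worked example

```python
from uacr_cea import load_config, run_base_case

cfg = load_config()                 # packaged defaults
res = run_base_case(cfg)
c = res.comparisons["UACR_vs_NONE"]
print(f"ΔQALY={c.delta_qaly:.2f}  Δcost=¥{c.delta_cost:,.0f}  "
      f"ICER=¥{c.icer:,.0f}/QALY")
```

prints

```
ΔQALY=14.33  Δcost=¥8,015,776  ICER=¥559,299/QALY
```

i.e. per 1000 people screened over a lifetime, UACR testing (vs no urine
testing) gains 14.3 QALYs and prevents 0.77 dialysis initiations for an
extra ¥8.0M — about ¥0.56M per QALY, well under the ¥5M threshold. The
`examples/` scripts walk through the base case, risk-state and dipstick
subgroups, the SGLT2i treatment scenario, the one-way sensitivity
tornado, and the synthetic input generators; a thin CLI (`uacr-cea run`,
`uacr-cea dsa`, `uacr-cea dump-defaults`, `uacr-cea synth`) wraps the
same calls for shell use.

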