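# Methods

## Model structure

The analysis couples a one-shot decision tree (how a testing strategy
classifies albuminuria and what treatment that triggers) to a six-state
annual-cycle Markov cohort model (how CKD then progresses). States are
the four prognosis bands of the KDIGO eGFR × albuminuria heatmap — low,
moderate, high, very-high risk — plus ESKD (dialysis-requiring kidney
failure; all G5 cells) and death. Death is absorbing; ESKD never returns
to a CKD band. The cohort starts at age 60 and runs 40 one-year cycles
(to age 100), with 2%/year discounting of costs and health outcomes and
results scaled to a 1000-person cohort.

### Starting distribution

Published cohort data give only the eGFR marginal (G1 28.5%, G2 64.2%,
G3a 6.6%, G3b 0.4%, G4 0.2%, G5 0.1%) and the albuminuria marginal
(A1 83%, A2 16%, A3 1.1%). Each marginal is renormalised exactly to 1
(the printed values carry rounding; the albuminuria column sums to
100.1%) and the joint 18-cell occupancy is taken as their product, i.e.
eGFR and albuminuria are assumed independent at baseline. A
`joint_starting_cells` override accepts a full cross-tabulation when one
is available.

### Test classification (decision tree)

UACR is treated as the gold standard, so its diagnosed class equals the
true class. The no-testing arm manages every patient as A1. For UPCR
only marginal class counts are published, so the joint
(true, diagnosed) table is reconstructed under *nested detection*:

* a UPCR test never assigns a more severe class than the truth;
* a true class-k patient is detected at level k with sensitivity s_k,
  otherwise classified one level lower;
* working top-down, s(A3) = UPCR ~A3 count / true A3 count; severe cases
  missed at A3 fall into the ~A2 column, and the remainder of that
  column over the true A2 count gives s(A2).

With the unstratified re-test counts this yields s(A2) = 75/198 ≈ 0.379
and s(A3) = 1.0; the reconstruction reproduces every published marginal
exactly (tested against a brute-force joint-table enumeration), including
the dipstick-positive stratum where s(A3) = 10/13 and three demoted
severe cases sit in the ~A2 column. Dipstick strata are treated as
alternative cohorts: the stratum's UACR row becomes the starting
albuminuria distribution and its own re-test rows drive detection.

Treatment eligibility keys on the *diagnosed* albuminuria class and the
*true* G stage (eGFR is measured in every arm): ACEi/ARB for G1–G4 ×
diagnosed A2–A3; in the combination scenario SGLT2i is added for G3a–G4
× diagnosed A2 and G1–G4 × diagnosed A3. Misclassified patients are
treated per the observed result.

### Transition dynamics

Each cycle composes, in a fixed order:

1. **adjustment** — worsening-direction base probabilities × the
   starting cell's adjustment factor (cell-resolved phase only);
2. **treatment** — worsening-direction probabilities × (1 − RRR_prog)
   for treated patients;
3. **mortality thinning** — all living entries × (1 − q_death);
4. **residual** — remaining mass stays in state; each row sums to 1
   exactly.

"Worsening direction" means any move to a strictly higher band or to
ESKD; improvement probabilities (e.g. moderate→low 0.337) are never
scaled by treatment or adjustment. Overflow (adjusted outgoing mass > 1)
raises an error rather than being clamped.

Mortality composes an age-indexed background probability q_bg(age) with
a hazard ratio on the rate scale, q = 1 − (1 − q_bg)^HR, which stays in
[0, 1) even at HR 12; a multiplicative alternative is a flag. Treatment
scales the whole effective HR by (1 − RRR_mort) by default
(`mortality_rrr_on: excess` scales only the excess over 1).

**Two-phase residence convention.** While a patient remains in their
starting state, transitions stay cell-resolved: the cell's adjustment
factor, the cell's mortality HR and the patient's own treatment flag
apply. On leaving it (or from the start, for later-cycle entrants) the
patient joins state-average dynamics — per-state HRs are
occupancy-weighted means of the cell HRs with weights from the starting
distribution (ESKD: the G5 row weighted by the albuminuria marginal),
no adjustment factors, no treatment. This is the default
`treatment_scope: initial`. The choice was genuinely open; the two
alternatives are kept as flags because they bracket the plausible
designs: `first_cycle` (cell-specific inputs for a single cycle) roughly
halves-to-thirds the treatment effect, while `lifetime` (treatment
follows the patient) triples it and flips the base-case incremental cost
negative. Drug costs always accrue over exactly the person-time the
treatment effect applies (cost/effect symmetry).

### Cardiovascular events

CV events generate acute-care costs only — no state change, mortality or
utility decrement. The published low-risk "incidence rate" of 0.109 is
read as a **10-year risk** and converted to an annual probability
q₁ = 1 − (1 − 0.109)^0.1 ≈ 0.0115, then state hazard ratios (1.00, 1.52,
2.04, 3.69, 12.00) apply on the rate scale. Read at face value as an
annual rate, the ESKD hazard ratio of 12 would push the implied
probability far above any observable event frequency, and the resulting
event totals (~0.33 events/person-lifetime) match the scale of the
published per-1000 event counts; `cv_rate_basis: annual` restores the
literal reading. Event costs are the mix-weighted mean of the published
acute costs (MI 9%, ischaemic stroke 63%, intracerebral haemorrhage 15%,
subarachnoid haemorrhage 6%, other 7%); subarachnoid haemorrhage has no
published cost and is costed at the intracerebral rate (configurable).

### Costs, utilities, discounting

Annual state costs = Σ(resource-use count × unit cost) over GP and
nephrologist consultations, tests, prescriptions and other costs, plus
the arm's urine test at the state's annual frequency (UACR ¥1,730,
UPCR ¥810; 1/2/4/4/4 tests per year by state), eGFR tests, drug costs
while treated (ACEi/ARB ¥4,015/yr; +SGLT2i ¥96,725/yr) and, in ESKD,
annual dialysis (¥5,456,714.14; consultations assumed bundled into it,
since no ESKD consultation counts are published). Per-state test and
prescription cost lines are read as annual amounts, not per-visit
multipliers. Incident events add one-time costs: vascular-access surgery
(¥1,579,488) per dialysis initiation and the mix-weighted CV cost
(¥3,085,744) per event.

Accrual uses start-of-cycle occupancy discounted end-of-cycle
(cycle t at 1/(1+r)^(t+1)); `half_cycle: true` switches to the mid-cycle
average. No half-cycle correction is applied by default, matching common
spreadsheet cohort-model practice. Clinical event counts (dialysis
initiations, CV events) are reported undiscounted. A
`weighted_state_utilities` operator rebuilds per-state utilities from
user-supplied eGFR-level values; the packaged defaults use the published
final state utilities directly.

### Incremental analysis

ICER = Δcost/ΔQALY for each arm pair. Dominance labels follow the
reporting convention of the staged-subgroup tables: Δcost > 0 with
ΔQALY ≤ 0 (including exactly 0) is "dominated"; Δcost < 0 with
ΔQALY ≥ 0 (not both 0) is "dominant". One-way DSA re-runs the full
analysis at low/high bounds for a standard driver set (progression and
mortality RRRs, discount rate, dialysis and drug costs, utilities capped
at 1, CV reference risk; ±20% default) and orders results by ICER spread;
a dominance flip at either bound sorts as maximal sensitivity.

## Synthetic inputs

**Life table.** No national life table is redistributed. The bundled
table is Gompertz–Makeham, q(x) = 1 − exp(−(A + B·e^(cx))) with
A = 2×10⁻⁴ (age-independent background), B = 3.6×10⁻⁶, c = 0.117
(≈5.9-year hazard doubling), chosen to give q(60) ≈ 0.0042 and remaining
life expectancy at 60 of 25.8 years, typical of a modern low-mortality
population. It is smooth and strictly monotone — it has no cohort
effects, accident hump, sex split or old-age deceleration — so absolute
survival-dependent quantities (life years, lifetime costs, ICER levels)
shift when a real national table is substituted, while the structural
and directional results do not depend on it.

**Re-test cohorts.** The generator draws n patients' true classes
multinomially, observes them perfectly under UACR, and applies the
nested-detection mechanism (per-class sensitivity, one-level demotion of
misses) for UPCR, optionally splitting true classes across dipstick
strata. Because it emits exactly the table dialect the configuration
reader consumes, the classification module's sensitivity reconstruction
can be validated end to end: 200-replicate recovery checks show the
estimator is unbiased within Monte-Carlo error and its SD shrinks as
1/√n. What the generator does not emulate: correlation between eGFR and
albuminuria, real dipstick operating characteristics, or
regression-to-the-mean in repeat testing.

## Verification

The test suite (seconds on one CPU) checks, among others: row-
stochasticity of every constructed transition row (±1e-12); occupancy
conservation (±1e-9) and monotone death; exact geometric-series life
years in a single-state reduction; bit-level arm equivalence when both
RRRs are zero; the pairwise identity Δ(UACR−none) − Δ(UPCR−none) =
Δ(UACR−UPCR); agreement of the deterministic trace with a
200,000-individual microsimulation of the same per-cycle probabilities
within 3 Monte-Carlo standard errors on life years, ESKD entries and CV
events; and a spreadsheet-style straight-line recomputation of the
discounted totals (1e-6 relative). Problem sizes (40 cycles, 200k
simulated individuals, 200-replicate recovery runs) were chosen as
comfortably sufficient for these tolerances.

## Known limitations

* The bundled life table is synthetic; headline ICER *levels* are only
  calibration-grade with a real national life table supplied via
  `tables.life_table`.
* Treatment persistence (the dominant driver of absolute effect size) is
  a convention, not a published fact; all three readings are implemented
  and flagged, and the default is the initial-residence reading.
* No probabilistic sensitivity analysis, budget impact, CV mortality or
  disutility, treatment adherence decay, or societal costs.
* Aggregation weights collapsing cell-level hazard ratios to state level
  use the starting distribution throughout; a cohort that drifts far
  from its starting mix over 40 years would strain this.
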