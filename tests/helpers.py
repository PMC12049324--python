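"""Independent oracles shared across test modules.

The microsimulation draws individual patients through the same per-cycle
probabilities the cohort engine uses, but by sampling counts rather than
propagating expected mass — so agreement checks the deterministic
expectation propagation against a stochastic realisation of the same
process.  Batching gives an honest Monte-Carlo standard error for the
comparison tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from uacr_cea.classification import (
    detection_profile,
    diagnosed_cell_distribution,
    treatment_assignment,
)
from uacr_cea.config import ModelConfig, starting_distribution
from uacr_cea.markov import (
    _state_hr_weights,
    cv_annual_probability,
    death_probability,
    progression_row,
    state_mortality_hr,
)
from uacr_cea.states import (
    ALL_STATES,
    DipstickStratum,
    LIVING_STATES,
    RiskState,
    STATE_INDEX,
    Scenario,
    TestStrategy,
    Treatment,
    kdigo_risk_map,
)

_TR_SCEN = {
    Treatment.ACEI_ARB: Scenario.ACEI_ARB,
    Treatment.ACEI_ARB_PLUS_SGLT2I: Scenario.ACEI_ARB_PLUS_SGLT2I,
}


@dataclass
class MicrosimResult:
    """Per-person means and Monte-Carlo SEs over batches."""

    ly: float
    eskd_entries: float
    cv_events: float
    se_ly: float
    se_eskd: float
    se_cv: float
    n: int


def _row_probs(row: dict[RiskState, float]) -> np.ndarray:
    return np.array([row.get(s, 0.0) for s in ALL_STATES])


def _simulate_batch(
    cfg: ModelConfig,
    arm: TestStrategy,
    scenario: Scenario,
    n: int,
    rng: np.random.Generator,
) -> tuple[float, float, float]:
    """One batch of n sampled individuals; returns per-person (LY, ESKD, CV)."""
    conv = cfg.conventions
    assert conv.treatment_scope == "initial"
    T = cfg.horizon
    sd = starting_distribution(cfg.starting_egfr_props, cfg.starting_acr_props)
    diag = detection_profile(
        cfg.reclassification, arm, DipstickStratum.UNSTRATIFIED
    )
    joint = diagnosed_cell_distribution(sd.cells, diag)
    keys = list(joint)
    counts = rng.multinomial(n, np.array([joint[k] for k in keys]))

    groups: dict[tuple, int] = {}
    for (cell, d), c in zip(keys, counts):
        tr = treatment_assignment(cell, d, scenario)
        groups[(cell, tr)] = groups.get((cell, tr), 0) + int(c)

    state_hrs = {
        s: state_mortality_hr(s, _state_hr_weights(sd.cells, s), cfg.mortality_hr)
        for s in LIVING_STATES
    }
    q_cv = {
        s: cv_annual_probability(s, cfg.cv, rate_basis=conv.cv_rate_basis)
        for s in LIVING_STATES
    }

    pool = np.zeros(len(ALL_STATES), dtype=np.int64)
    ly = eskd = cv = 0
    for t in range(T):
        age = cfg.starting_age + t
        living_counts = {s: int(pool[STATE_INDEX[s]]) for s in LIVING_STATES}
        for (cell, tr), c in groups.items():
            living_counts[kdigo_risk_map(cell)] += c
        ly += sum(living_counts.values())
        for s, c in living_counts.items():
            if c:
                cv += int(rng.binomial(c, q_cv[s]))

        new_groups: dict[tuple, int] = {}
        for (cell, tr), c in groups.items():
            if c == 0:
                continue
            s = kdigo_risk_map(cell)
            treated = tr is not Treatment.NONE
            eff = cfg.treatment_effects[_TR_SCEN[tr]] if treated else None
            q = death_probability(
                age, cfg.mortality_hr[cell], cfg.life_table,
                treated, eff.rrr_mortality if treated else 0.0,
                rrr_on=conv.mortality_rrr_on,
            )
            factor = (
                cfg.adjustment_factors[cell]
                if s is not RiskState.ESKD else 1.0
            )
            row = progression_row(
                s, cfg.transitions, factor, treated,
                eff.rrr_progression if treated else 0.0, q,
            )
            draw = rng.multinomial(c, _row_probs(row))
            for si, cnt in zip(ALL_STATES, draw):
                if cnt == 0:
                    continue
                if si is s:
                    new_groups[(cell, tr)] = (
                        new_groups.get((cell, tr), 0) + int(cnt)
                    )
                else:
                    pool[STATE_INDEX[si]] += cnt
                    if si is RiskState.ESKD and s is not RiskState.ESKD:
                        eskd += int(cnt)

        new_pool = np.zeros_like(pool)
        new_pool[STATE_INDEX[RiskState.DEATH]] = pool[STATE_INDEX[RiskState.DEATH]]
        for s in LIVING_STATES:
            c = int(pool[STATE_INDEX[s]])
            if c == 0:
                continue
            q = death_probability(
                age, state_hrs[s], cfg.life_table,
                rrr_on=conv.mortality_rrr_on,
            )
            row = progression_row(s, cfg.transitions, 1.0, False, 0.0, q)
            draw = rng.multinomial(c, _row_probs(row))
            for si, cnt in zip(ALL_STATES, draw):
                new_pool[STATE_INDEX[si]] += cnt
                if (
                    cnt
                    and si is RiskState.ESKD
                    and s is not RiskState.ESKD
                ):
                    eskd += int(cnt)
        pool = new_pool
        groups = new_groups
    return ly / n, eskd / n, cv / n


def microsim(
    cfg: ModelConfig,
    arm: TestStrategy,
    scenario: Scenario = Scenario.ACEI_ARB,
    n: int = 200_000,
    seed: int = 20240,
    batches: int = 10,
) -> MicrosimResult:
    rng = np.random.default_rng(seed)
    per = n // batches
    vals = np.array(
        [_simulate_batch(cfg, arm, scenario, per, rng) for _ in range(batches)]
    )
    mean = vals.mean(axis=0)
    se = vals.std(axis=0, ddof=1) / np.sqrt(batches)
    return MicrosimResult(
        ly=mean[0], eskd_entries=mean[1], cv_events=mean[2],
        se_ly=se[0], se_eskd=se[1], se_cv=se[2], n=per * batches,
    )


def straight_line_accumulate(trace, cfg: ModelConfig) -> dict[str, float]:
    """Spreadsheet-style recomputation of discounted totals from raw inputs.

    Costs are rebuilt directly from the cost/resource tables rather than
    through the outcomes module's helpers.
    """
    C = cfg.costs
    urine = {"UACR": C["test_uacr"], "UPCR": C["test_upcr"], "NONE": 0.0}[
        trace.arm.value
    ]
    per_state_cost = {}
    for s in (RiskState.LOW, RiskState.MODERATE, RiskState.HIGH,
              RiskState.VERY_HIGH):
        n = s.value
        per_state_cost[s] = (
            cfg.resource_use[(s, "gp_appointments")] * C["gp_consultation"]
            + C[f"gp_tests_{n}"] + C[f"gp_prescription_{n}"]
            + cfg.resource_use[(s, "nephrologist_appointments")]
            * C["nephrologist_consultation"]
            + C[f"nephrologist_tests_{n}"] + C[f"nephrologist_prescription_{n}"]
            + C[f"other_nephrologist_{n}"]
            + cfg.resource_use[(s, "egfr_tests")] * C["test_egfr"]
            + cfg.resource_use[(s, "urine_tests")] * urine
        )
    per_state_cost[RiskState.ESKD] = (
        C["dialysis_annual"]
        + cfg.resource_use[(RiskState.ESKD, "egfr_tests")] * C["test_egfr"]
        + cfg.resource_use[(RiskState.ESKD, "urine_tests")] * urine
    )
    mix_cost = (
        cfg.cv.mix["mi"] * C["event_mi"]
        + cfg.cv.mix["stroke_ischemic"] * C["event_stroke_ischemic"]
        + (cfg.cv.mix["stroke_ich"] + cfg.cv.mix["stroke_sah"])
        * C["event_stroke_ich"]
        + cfg.cv.mix["other_cv"] * C["event_other_cv"]
    )
    drug_cost = {
        Treatment.ACEI_ARB: C["drug_acei_arb"],
        Treatment.ACEI_ARB_PLUS_SGLT2I: C["drug_acei_arb"] + C["drug_sglt2i"],
    }
    r = cfg.discount_rate
    cost = qaly = ly = 0.0
    for t in range(trace.horizon):
        d = (1 + r) ** -(t + 1)
        c = q = l = 0.0
        for s in LIVING_STATES:
            occ = trace.occupancy[t, STATE_INDEX[s]]
            c += occ * per_state_cost[s]
            q += occ * cfg.utilities[s]
            l += occ
        for tr, arr in trace.treated_living.items():
            c += arr[t] * drug_cost[tr]
        c += trace.eskd_inflow[t] * C["event_vascular_access"]
        c += trace.cv_events[t] * mix_cost
        cost += d * c
        qaly += d * q
        ly += d * l
    k = cfg.cohort_scale
    return {"cost": cost * k, "qaly": qaly * k, "ly": ly * k}
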