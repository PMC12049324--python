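"""Costing, utilities and discounting of a cohort trace.

Annual per-state costs combine clinician-suggested resource-use counts
with unit costs from the national fee schedule; one-time costs attach to
incident events (vascular-access surgery at dialysis initiation, acute
cardiovascular care at the published event mix).  Health benefit is
state-utility-weighted person-time.  Costs and benefits discount at the
end-of-cycle convention; clinical event counts are reported undiscounted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .config import ModelConfig
from .markov import CohortTrace
from .states import (
    CKD_STATES,
    GStage,
    LIVING_STATES,
    RiskState,
    STATE_INDEX,
    Scenario,
    TestStrategy,
    Treatment,
)

_URINE_COST_CATEGORY = {
    TestStrategy.UACR: "test_uacr",
    TestStrategy.UPCR: "test_upcr",
    TestStrategy.NONE: None,
}

_TREATMENT_SCENARIO = {
    Treatment.ACEI_ARB: Scenario.ACEI_ARB,
    Treatment.ACEI_ARB_PLUS_SGLT2I: Scenario.ACEI_ARB_PLUS_SGLT2I,
}


def discount_factor(cycle: int, rate: float) -> float:
    """1/(1+rate)^cycle; cycle-1 accrual is discounted one full year."""
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    return (1.0 + rate) ** (-cycle)


def _cost(cfg: ModelConfig, category: str) -> float:
    try:
        return cfg.costs[category]
    except KeyError:
        raise KeyError(f"unknown cost category {category!r}") from None


def _use(cfg: ModelConfig, state: RiskState, category: str) -> float:
    return cfg.resource_use.get((state, category), 0.0)


def annual_drug_cost(cfg: ModelConfig, treatment: Treatment) -> float:
    """Annual drug cost for an active treatment level."""
    if treatment is Treatment.NONE:
        return 0.0
    eff = cfg.treatment_effects[_TREATMENT_SCENARIO[treatment]]
    return sum(_cost(cfg, c) for c in eff.annual_drug_cost_categories)


def annual_state_cost(
    state: RiskState,
    arm: TestStrategy,
    cfg: ModelConfig,
    treatment: Treatment = Treatment.NONE,
) -> float:
    """Yen per person-year in ``state`` under testing arm ``arm``.

    CKD states accrue GP/nephrologist consultations, tests, prescriptions
    and other costs at the state's annual counts; ESKD accrues the annual
    dialysis cost plus its monitoring tests.  Testing arms add their urine
    test at the state's annual frequency; drug cost is added only when an
    active ``treatment`` is passed.
    """
    if state is RiskState.DEATH:
        raise ValueError("DEATH accrues no costs")
    total = 0.0
    if state in CKD_STATES:
        st = state.value
        total += _use(cfg, state, "gp_appointments") * _cost(cfg, "gp_consultation")
        total += _cost(cfg, f"gp_tests_{st}")
        total += _cost(cfg, f"gp_prescription_{st}")
        total += _use(cfg, state, "nephrologist_appointments") * _cost(
            cfg, "nephrologist_consultation"
        )
        total += _cost(cfg, f"nephrologist_tests_{st}")
        total += _cost(cfg, f"nephrologist_prescription_{st}")
        total += _cost(cfg, f"other_nephrologist_{st}")
    else:  # ESKD: consultations bundled into the dialysis cost
        total += _cost(cfg, "dialysis_annual")
    total += _use(cfg, state, "egfr_tests") * _cost(cfg, "test_egfr")
    urine = _URINE_COST_CATEGORY[arm]
    if urine is not None:
        total += _use(cfg, state, "urine_tests") * _cost(cfg, urine)
    total += annual_drug_cost(cfg, treatment)
    return total


def cv_event_unit_cost(cfg: ModelConfig) -> float:
    """Mix-weighted acute-care cost of one cardiovascular event.

    Subarachnoid haemorrhage has no published cost of its own and is
    costed at the configured proxy category (intracerebral haemorrhage by
    default).
    """
    category = {
        "mi": "event_mi",
        "stroke_ischemic": "event_stroke_ischemic",
        "stroke_ich": "event_stroke_ich",
        "stroke_sah": cfg.conventions.sah_cost_category,
        "other_cv": "event_other_cv",
    }
    return sum(
        share * _cost(cfg, category[kind]) for kind, share in cfg.cv.mix.items()
    )


def event_cost(
    incident_eskd: float,
    cv_events_by_type: Mapping[str, float],
    cfg: ModelConfig,
) -> float:
    """One-time costs for a cycle's incident events."""
    category = {
        "mi": "event_mi",
        "stroke_ischemic": "event_stroke_ischemic",
        "stroke_ich": "event_stroke_ich",
        "stroke_sah": cfg.conventions.sah_cost_category,
        "other_cv": "event_other_cv",
    }
    total = incident_eskd * _cost(cfg, "event_vascular_access")
    for kind, n in cv_events_by_type.items():
        total += n * _cost(cfg, category[kind])
    return total


@dataclass(frozen=True)
class OutcomeSummary:
    """One arm's totals, scaled to the configured cohort size (1000 default)."""

    arm: TestStrategy
    scenario: Scenario
    cost: float                 # discounted yen
    ly: float                   # discounted life years
    qaly: float                 # discounted QALYs
    dialysis_initiations: float  # cumulative incident ESKD entries, undiscounted
    cv_events: float            # cumulative expected CV events, undiscounted
    cost_undiscounted: float
    ly_undiscounted: float
    qaly_undiscounted: float

    def as_dict(self) -> dict[str, float]:
        return {
            "arm": self.arm.value,
            "scenario": self.scenario.value,
            "cost": self.cost,
            "ly": self.ly,
            "qaly": self.qaly,
            "dialysis_initiations": self.dialysis_initiations,
            "cv_events": self.cv_events,
            "cost_undiscounted": self.cost_undiscounted,
            "ly_undiscounted": self.ly_undiscounted,
            "qaly_undiscounted": self.qaly_undiscounted,
        }


def accumulate(trace: CohortTrace, cfg: ModelConfig) -> OutcomeSummary:
    """Attach costs and utilities to a trace and aggregate over the horizon.

    Cycle t's accrual uses start-of-cycle occupancy (or the half-cycle
    average when configured) and is discounted by 1/(1+r)^(t+1).
    """
    arm = trace.arm
    rate = cfg.discount_rate
    half = cfg.conventions.half_cycle
    state_cost = {s: annual_state_cost(s, arm, cfg) for s in LIVING_STATES}
    util = {s: cfg.utilities[s] for s in LIVING_STATES}
    unit_cv = cv_event_unit_cost(cfg)
    vasc = _cost(cfg, "event_vascular_access")
    drug = {tr: annual_drug_cost(cfg, tr) for tr in trace.treated_living}

    cost_d = cost_u = ly_d = ly_u = qaly_d = qaly_u = 0.0
    dial = cv = 0.0
    T = trace.horizon
    for t in range(T):
        occ = trace.occupancy[t]
        if half:
            occ = 0.5 * (trace.occupancy[t] + trace.occupancy[t + 1])
        c = sum(occ[STATE_INDEX[s]] * state_cost[s] for s in LIVING_STATES)
        c += sum(trace.treated_living[tr][t] * drug[tr] for tr in drug)
        c += trace.eskd_inflow[t] * vasc + trace.cv_events[t] * unit_cv
        q = sum(occ[STATE_INDEX[s]] * util[s] for s in LIVING_STATES)
        ly = sum(occ[STATE_INDEX[s]] for s in LIVING_STATES)
        d = discount_factor(t + 1, rate)
        cost_d += d * c
        cost_u += c
        qaly_d += d * q
        qaly_u += q
        ly_d += d * ly
        ly_u += ly
        dial += trace.eskd_inflow[t]
        cv += trace.cv_events[t]

    k = cfg.cohort_scale
    return OutcomeSummary(
        arm=arm,
        scenario=trace.scenario,
        cost=cost_d * k,
        ly=ly_d * k,
        qaly=qaly_d * k,
        dialysis_initiations=dial * k,
        cv_events=cv * k,
        cost_undiscounted=cost_u * k,
        ly_undiscounted=ly_u * k,
        qaly_undiscounted=qaly_u * k,
    )


def weighted_state_utilities(
    utility_by_egfr: Mapping[GStage, float],
    egfr_props_by_state: Mapping[RiskState, Mapping[GStage, float]],
) -> dict[RiskState, float]:
    """Per-state utilities as eGFR-category utilities weighted by occupancy.

    The packaged defaults already carry final per-state utilities; this
    operator lets users rebuild them from their own eGFR-level values.
    """
    out: dict[RiskState, float] = {}
    for state, props in egfr_props_by_state.items():
        tot = sum(props.values())
        if tot <= 0:
            raise ValueError(f"empty eGFR proportions for state {state.value}")
        for g, u in utility_by_egfr.items():
            if not (0.0 < u <= 1.0):
                raise ValueError(f"utility for {g.value} outside (0,1]")
        out[state] = (
            sum(utility_by_egfr[g] * p for g, p in props.items()) / tot
        )
    return out
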