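"""Six-state Markov cohort engine.

States are the four KDIGO prognosis bands, ESKD and death.  Each annual
cycle composes, in a fixed order: (1) progression-risk adjustment for the
starting KDIGO cell (first transition only), (2) the treatment relative
risk reduction on worsening transitions, (3) thinning of all living
transitions by the age- and state-specific death probability, and (4) the
residual mass remaining in state.  Death probabilities combine an
age-indexed background life table with CKD mortality hazard ratios on the
rate scale, q = 1 - (1 - q_bg)^HR, which keeps probabilities in [0, 1)
even at the large ESKD hazard ratios.

Two-phase dynamics: while a patient remains in their starting health
state, transitions use KDIGO-cell-specific inputs (adjustment factor,
cell hazard ratio, diagnosis-dependent treatment); once they leave it,
dynamics switch to state-average inputs that are identical across testing
arms.  Arm differences therefore flow entirely through what happens
during initial-state residence — testing informs treatment at diagnosis
and that treatment lapses when the patient transitions onward.
``first_cycle`` (cell-specific inputs for one cycle only) and
``lifetime`` (treatment follows the patient) scopes are available as
convention flags.

Cardiovascular events are side events: they generate acute-care costs but
do not alter state membership, mortality or utility.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .classification import (
    DiagnosisDistribution,
    detection_profile,
    diagnosed_cell_distribution,
    treatment_assignment,
)
from .config import CvModel, ModelConfig, TransitionTable, starting_distribution
from .states import (
    ALL_STATES,
    AStage,
    DipstickStratum,
    KdigoCell,
    LIVING_STATES,
    RiskState,
    STATE_INDEX,
    Scenario,
    TestStrategy,
    Treatment,
    cells_of_state,
    is_worsening,
    kdigo_risk_map,
)

_N = len(ALL_STATES)
_DEATH = STATE_INDEX[RiskState.DEATH]
_ESKD = STATE_INDEX[RiskState.ESKD]

_TREATMENT_SCENARIO = {
    Treatment.ACEI_ARB: Scenario.ACEI_ARB,
    Treatment.ACEI_ARB_PLUS_SGLT2I: Scenario.ACEI_ARB_PLUS_SGLT2I,
}


def state_mortality_hr(
    state: RiskState,
    cell_weights: Mapping[KdigoCell, float],
    hr_table: Mapping[KdigoCell, float],
) -> float:
    """Occupancy-weighted mean mortality hazard ratio for a state.

    ``cell_weights`` need not be normalised; they are renormalised over the
    state's own KDIGO cells (for ESKD, the G5 row weighted by the
    albuminuria distribution).
    """
    cells = cells_of_state(state)
    if not cells:
        raise ValueError(f"state {state.value} has no KDIGO cells")
    w = np.array([max(cell_weights.get(c, 0.0), 0.0) for c in cells])
    tot = w.sum()
    if tot <= 0.0:
        raise ValueError(f"empty cell weight vector for state {state.value}")
    hrs = np.array([hr_table[c] for c in cells])
    return float(np.dot(w, hrs) / tot)


def death_probability(
    age: int,
    hr: float,
    life_table: Mapping[int, float],
    treated: bool = False,
    rrr_mort: float = 0.0,
    rrr_on: str = "total",
    composition: str = "rate",
) -> float:
    """Annual death probability at ``age`` under hazard ratio ``hr``.

    Treatment scales the effective hazard ratio by (1 - rrr_mort) — either
    the whole ratio (``total``) or only its excess over 1 (``excess``).
    """
    if hr <= 0:
        raise ValueError("hazard ratio must be > 0")
    q_bg = life_table.get(age)
    if q_bg is None:
        raise ValueError(f"age {age} outside life table")
    hr_eff = hr
    if treated and rrr_mort > 0.0:
        if rrr_on == "excess":
            hr_eff = 1.0 + (hr - 1.0) * (1.0 - rrr_mort)
        else:
            hr_eff = hr * (1.0 - rrr_mort)
    if composition == "multiplicative":
        q = q_bg * hr_eff
    else:
        q = 1.0 - (1.0 - q_bg) ** hr_eff
    return min(max(q, 0.0), 1.0 - 1e-15)


def cv_annual_probability(
    state: RiskState,
    cv: CvModel,
    rate_basis: str = "per10y",
    composition: str = "rate",
) -> float:
    """Annual probability of a cardiovascular event in a living state.

    The reference risk (reported for the low-risk state) is converted to an
    annual probability (from a 10-year risk under the default basis), then
    the state's hazard ratio is applied on the rate scale.
    """
    if state is RiskState.DEATH:
        raise ValueError("CV events are defined for living states only")
    ref = cv.reference_risk
    q1 = 1.0 - (1.0 - ref) ** 0.1 if rate_basis == "per10y" else ref
    hr = cv.hr[state]
    if composition == "multiplicative":
        return min(q1 * hr, 1.0 - 1e-15)
    return 1.0 - (1.0 - q1) ** hr


def progression_row(
    state: RiskState,
    base: TransitionTable,
    adjustment_factor: float,
    treated: bool,
    rrr_prog: float,
    death_prob: float,
) -> dict[RiskState, float]:
    """One row of the per-cycle transition matrix; sums to exactly 1.

    Composition order: adjustment -> treatment RRR (worsening-direction
    moves only) -> mortality thinning of all living entries -> residual
    mass stays in state.
    """
    if not (0.0 <= death_prob < 1.0):
        raise ValueError("death probability must lie in [0, 1)")
    if state is RiskState.DEATH:
        return {RiskState.DEATH: 1.0}
    moves: dict[RiskState, float] = {}
    for to, p in base.row(state).items():
        if p == 0.0:
            continue
        if is_worsening(state, to):
            p = p * adjustment_factor
            if treated:
                p = p * (1.0 - rrr_prog)
        moves[to] = p
    mass = sum(moves.values())
    if mass > 1.0:
        raise ValueError(
            f"adjustment overflow: outgoing mass {mass:.4f} > 1 "
            f"for state {state.value} (factor {adjustment_factor})"
        )
    surv = 1.0 - death_prob
    row = {to: p * surv for to, p in moves.items()}
    row[state] = row.get(state, 0.0) + surv * (1.0 - mass)
    row[RiskState.DEATH] = death_prob
    return row


@dataclass
class CohortTrace:
    """Per-cycle record of one arm's cohort (per-person mass, not scaled).

    ``occupancy`` has one row per cycle boundary t = 0..T; incident arrays
    have one entry per cycle (the year from t to t+1).  ``treated_living``
    records the living mass carrying each active treatment at each cycle
    start, which is what drug costs accrue on.
    """

    ages: np.ndarray                    # (T+1,)
    occupancy: np.ndarray               # (T+1, 6), ALL_STATES order
    treated_living: dict[Treatment, np.ndarray]  # each (T,)
    eskd_inflow: np.ndarray             # (T,)
    cv_events: np.ndarray               # (T,)
    deaths: np.ndarray                  # (T,)
    arm: TestStrategy
    scenario: Scenario

    @property
    def horizon(self) -> int:
        return len(self.eskd_inflow)

    def occupancy_at(self, t: int) -> dict[RiskState, float]:
        return {s: float(self.occupancy[t, STATE_INDEX[s]]) for s in ALL_STATES}

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for t in range(self.occupancy.shape[0]):
            row = {"cycle": t, "age": int(self.ages[t])}
            row.update(
                {s.value: float(self.occupancy[t, i]) for s, i in STATE_INDEX.items()}
            )
            if t < self.horizon:
                row["eskd_inflow"] = float(self.eskd_inflow[t])
                row["cv_events"] = float(self.cv_events[t])
                row["deaths"] = float(self.deaths[t])
            rows.append(row)
        return pd.DataFrame(rows)


def _state_hr_weights(
    cells: Mapping[KdigoCell, float], state: RiskState
) -> dict[KdigoCell, float]:
    w = {c: cells.get(c, 0.0) for c in cells_of_state(state)}
    if sum(w.values()) <= 0.0:
        w = {c: 1.0 for c in cells_of_state(state)}  # degenerate: uniform
    return w


def _state_matrix(
    cfg: ModelConfig,
    age: int,
    state_hrs: Mapping[RiskState, float],
    treated: bool,
    rrr_prog: float,
    rrr_mort: float,
) -> np.ndarray:
    """State-level transition matrix for one cycle (rows = ALL_STATES)."""
    conv = cfg.conventions
    M = np.zeros((_N, _N))
    for s in LIVING_STATES:
        q = death_probability(
            age, state_hrs[s], cfg.life_table, treated, rrr_mort,
            rrr_on=conv.mortality_rrr_on, composition=conv.hr_composition,
        )
        row = progression_row(
            s, cfg.transitions, 1.0, treated, rrr_prog, q
        )
        for to, p in row.items():
            M[STATE_INDEX[s], STATE_INDEX[to]] = p
    M[_DEATH, _DEATH] = 1.0
    return M


def run_cohort(
    cfg: ModelConfig,
    arm: TestStrategy,
    scenario: Scenario = Scenario.ACEI_ARB,
    stratum: DipstickStratum = DipstickStratum.UNSTRATIFIED,
    subgroup_state: RiskState | None = None,
    diag: DiagnosisDistribution | None = None,
) -> CohortTrace:
    """Run one testing arm's cohort over the full horizon.

    ``stratum`` conditions the starting albuminuria distribution on a prior
    dipstick result (and uses that stratum's re-test data); ``subgroup_state``
    restricts the starting cohort to one risk state.  ``diag`` overrides the
    detection profile (mainly for testing).
    """
    T = cfg.horizon
    if T < 1:
        raise ValueError("horizon must be at least one cycle")
    conv = cfg.conventions

    acr_props = cfg.starting_acr_props
    joint = cfg.joint_starting_cells
    if stratum is not DipstickStratum.UNSTRATIFIED:
        m = cfg.reclassification.marginal(stratum, TestStrategy.UACR)
        acr_props = dict(m.proportions)
        joint = None
    sd = starting_distribution(cfg.starting_egfr_props, acr_props, joint=joint)
    cells = dict(sd.cells)

    if subgroup_state is not None:
        keep = {
            c: m for c, m in cells.items()
            if kdigo_risk_map(c) is subgroup_state and m > 0.0
        }
        tot = sum(keep.values())
        if tot <= 0.0:
            raise ValueError(
                f"empty subgroup: no starting mass in {subgroup_state.value}"
            )
        start_cells = {c: m / tot for c, m in keep.items()}
    else:
        start_cells = cells

    if diag is None:
        diag = detection_profile(cfg.reclassification, arm, stratum)
    joint_mass = diagnosed_cell_distribution(start_cells, diag)

    # mass per (cell, treatment level); diagnosis only matters via treatment
    groups: dict[tuple[KdigoCell, Treatment], float] = {}
    for (cell, d), mass in joint_mass.items():
        tr = treatment_assignment(cell, d, scenario)
        key = (cell, tr)
        groups[key] = groups.get(key, 0.0) + mass

    # state-average HRs (weights from the full starting distribution of the
    # analysed cohort, before any subgroup restriction)
    state_hrs = {
        s: state_mortality_hr(s, _state_hr_weights(cells, s), cfg.mortality_hr)
        for s in LIVING_STATES
    }
    q_cv = {
        s: cv_annual_probability(
            s, cfg.cv, rate_basis=conv.cv_rate_basis,
            composition=conv.hr_composition,
        )
        for s in LIVING_STATES
    }

    ages = np.arange(cfg.starting_age, cfg.starting_age + T + 1)
    occupancy = np.zeros((T + 1, _N))
    eskd_inflow = np.zeros(T)
    cv_events = np.zeros(T)
    deaths = np.zeros(T)
    active = (Treatment.ACEI_ARB, Treatment.ACEI_ARB_PLUS_SGLT2I)
    treated_living = {tr: np.zeros(T) for tr in active}

    scope = conv.treatment_scope
    lifetime = scope == "lifetime"
    # cell-resolved cohorts still in their starting state (phase one)
    initial: dict[tuple[KdigoCell, Treatment], float] = dict(groups)
    # state-average pools (phase two); per treatment level only under
    # lifetime scope — otherwise everyone who has left is untreated
    pools: dict[Treatment, np.ndarray] = {tr: np.zeros(_N) for tr in Treatment}

    for t in range(T):
        occ_t = np.array(sum(pools.values()))
        for (cell, tr), m in initial.items():
            occ_t[STATE_INDEX[kdigo_risk_map(cell)]] += m
        occupancy[t] = occ_t
        cv_events[t] = float(
            sum(occ_t[STATE_INDEX[s]] * q_cv[s] for s in LIVING_STATES)
        )
        for tr in active:
            treated_living[tr][t] = sum(
                m for (c, g), m in initial.items() if g is tr
            )
            if lifetime:
                treated_living[tr][t] += float(pools[tr][:_DEATH].sum())

        age = int(ages[t])

        # ---- phase one: cohorts resident in their starting cell
        new_initial: dict[tuple[KdigoCell, Treatment], float] = {}
        for (cell, tr), m in initial.items():
            if m == 0.0:
                continue
            s = kdigo_risk_map(cell)
            treated = tr is not Treatment.NONE
            eff = (
                cfg.treatment_effects[_TREATMENT_SCENARIO[tr]] if treated else None
            )
            q = death_probability(
                age, cfg.mortality_hr[cell], cfg.life_table,
                treated, eff.rrr_mortality if treated else 0.0,
                rrr_on=conv.mortality_rrr_on, composition=conv.hr_composition,
            )
            factor = (
                cfg.adjustment_factors[cell]
                if s is not RiskState.ESKD
                else 1.0
            )
            row = progression_row(
                s, cfg.transitions, factor, treated,
                eff.rrr_progression if treated else 0.0, q,
            )
            dest_pool = pools[tr] if lifetime else pools[Treatment.NONE]
            for to, p in row.items():
                flow = m * p
                if flow == 0.0:
                    continue
                if to is RiskState.DEATH:
                    deaths[t] += flow
                    dest_pool[_DEATH] += flow
                elif to is s and scope == "initial":
                    key = (cell, tr)
                    new_initial[key] = new_initial.get(key, 0.0) + flow
                else:
                    dest_pool[STATE_INDEX[to]] += flow
                    if to is RiskState.ESKD and s is not RiskState.ESKD:
                        eskd_inflow[t] += flow

        # ---- phase two: state-average pools
        for tr, v in pools.items():
            if not v[:_DEATH].any():
                continue
            pool_treated = lifetime and tr is not Treatment.NONE
            eff = (
                cfg.treatment_effects[_TREATMENT_SCENARIO[tr]]
                if pool_treated
                else None
            )
            M = _state_matrix(
                cfg, age, state_hrs, pool_treated,
                eff.rrr_progression if pool_treated else 0.0,
                eff.rrr_mortality if pool_treated else 0.0,
            )
            living = v[:_DEATH]
            eskd_inflow[t] += float(
                np.dot(
                    np.delete(living, _ESKD),
                    np.delete(M[:_DEATH, _ESKD], _ESKD),
                )
            )
            deaths[t] += float(np.dot(living, M[:_DEATH, _DEATH]))
            pools[tr] = v @ M
        initial = new_initial

    occ_T = np.array(sum(pools.values()))
    for (cell, tr), m in initial.items():
        occ_T[STATE_INDEX[kdigo_risk_map(cell)]] += m
    occupancy[T] = occ_T

    return CohortTrace(
        ages=ages,
        occupancy=occupancy,
        treated_living=treated_living,
        eskd_inflow=eskd_inflow,
        cv_events=cv_events,
        deaths=deaths,
        arm=arm,
        scenario=scenario,
    )
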