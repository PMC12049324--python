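"""Markov engine: transition construction, mortality, CV risk, cohort runs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from uacr_cea.config import TransitionTable
from uacr_cea.markov import (
    cv_annual_probability,
    death_probability,
    progression_row,
    run_cohort,
    state_mortality_hr,
)
from uacr_cea.states import (
    ALL_CELLS,
    AStage,
    GStage,
    KdigoCell,
    LIVING_STATES,
    RiskState,
    STATE_INDEX,
    Scenario,
    TestStrategy,
)

G4A1 = KdigoCell(GStage.G4, AStage.A1)
G4A2 = KdigoCell(GStage.G4, AStage.A2)
G1A2 = KdigoCell(GStage.G1, AStage.A2)


class TestStateMortalityHr:
    def test_single_cell_weight(self, cfg):
        hr = state_mortality_hr(
            RiskState.MODERATE, {G1A2: 1.0}, cfg.mortality_hr
        )
        assert hr == pytest.approx(1.880)

    def test_equal_weights_mean(self, cfg):
        hr = state_mortality_hr(
            RiskState.VERY_HIGH, {G4A1: 0.5, G4A2: 0.5}, cfg.mortality_hr
        )
        assert hr == pytest.approx((4.710 + 4.410) / 2)

    def test_empty_weights_rejected(self, cfg):
        with pytest.raises(ValueError, match="empty"):
            state_mortality_hr(RiskState.LOW, {}, cfg.mortality_hr)

    def test_eskd_uses_g5_rows_weighted_by_albuminuria(self, cfg):
        w = {
            KdigoCell(GStage.G5, a): cfg.starting_acr_props[a] for a in AStage
        }
        hr = state_mortality_hr(RiskState.ESKD, w, cfg.mortality_hr)
        z = sum(cfg.starting_acr_props.values())
        expected = (0.830 * 4.850 + 0.160 * 12.000 + 0.011 * 8.690) / z
        assert hr == pytest.approx(expected, rel=1e-12)


class TestDeathProbability:
    def test_unit_hazard_is_identity(self):
        lt = {70: 0.0123}
        assert death_probability(70, 1.0, lt) == pytest.approx(0.0123)

    def test_rate_scale_closed_form(self):
        assert death_probability(70, 2.0, {70: 0.01}) == pytest.approx(
            1 - 0.99**2, abs=1e-15
        )

    def test_against_daily_hazard_discretisation(self):
        """Composing the HR on the hazard scale day by day gives the same
        annual probability as the closed form."""
        q_bg, hr = 0.017, 3.4
        daily_h = -math.log(1 - q_bg) / 365.0
        surv = (math.exp(-daily_h * hr)) ** 365
        assert death_probability(80, hr, {80: q_bg}) == pytest.approx(
            1 - surv, rel=1e-10
        )

    def test_treatment_reduces_mortality(self):
        lt = {65: 0.02}
        q_untr = death_probability(65, 2.5, lt)
        q_tr = death_probability(65, 2.5, lt, treated=True, rrr_mort=0.1)
        assert q_tr < q_untr
        q_excess = death_probability(
            65, 2.5, lt, treated=True, rrr_mort=0.1, rrr_on="excess"
        )
        assert q_tr < q_excess < q_untr

    def test_age_outside_table_rejected(self):
        with pytest.raises(ValueError, match="life table"):
            death_probability(101, 1.0, {60: 0.01})


class TestCvAnnualProbability:
    def test_reference_state_closed_form(self, cfg):
        q = cv_annual_probability(RiskState.LOW, cfg.cv)
        assert q == pytest.approx(1 - (1 - 0.109) ** 0.1, abs=1e-12)

    def test_annual_basis_identity(self, cfg):
        q = cv_annual_probability(RiskState.LOW, cfg.cv, rate_basis="annual")
        assert q == pytest.approx(0.109)

    def test_strictly_monotone_in_hazard_ratio(self, cfg):
        qs = [
            cv_annual_probability(s, cfg.cv)
            for s in (RiskState.LOW, RiskState.MODERATE, RiskState.HIGH,
                      RiskState.VERY_HIGH, RiskState.ESKD)
        ]
        assert all(a < b for a, b in zip(qs, qs[1:]))


class TestProgressionRow:
    def test_published_low_row(self, cfg):
        row = progression_row(RiskState.LOW, cfg.transitions, 1.0, False, 0.0, 0.0)
        assert row[RiskState.MODERATE] == pytest.approx(0.085)
        assert row[RiskState.HIGH] == pytest.approx(0.002)
        assert row[RiskState.LOW] == pytest.approx(0.913)
        assert row[RiskState.DEATH] == 0.0

    def test_treatment_scales_worsening_only(self, cfg):
        row = progression_row(
            RiskState.MODERATE, cfg.transitions, 1.0, True, 0.21, 0.0
        )
        assert row[RiskState.HIGH] == pytest.approx(0.067 * 0.79)
        # improvement back to LOW is untouched by the RRR
        assert row[RiskState.LOW] == pytest.approx(0.337)

    def test_null_treatment_is_identity(self, cfg):
        a = progression_row(RiskState.HIGH, cfg.transitions, 1.0, True, 0.0, 0.01)
        b = progression_row(RiskState.HIGH, cfg.transitions, 1.0, False, 0.0, 0.01)
        assert a == b

    def test_adjustment_overflow_rejected(self, cfg):
        with pytest.raises(ValueError, match="overflow"):
            progression_row(RiskState.LOW, cfg.transitions, 20.0, False, 0.0, 0.0)

    @settings(derandomize=True, max_examples=200)
    @given(
        state=st.sampled_from(LIVING_STATES),
        factor=st.floats(0.1, 2.0),
        treated=st.booleans(),
        rrr=st.floats(0.0, 0.99),
        q=st.floats(0.0, 0.999),
    )
    def test_rows_are_stochastic(self, state, factor, treated, rrr, q):
        base = TransitionTable(
            base={
                (RiskState.LOW, RiskState.MODERATE): 0.085,
                (RiskState.LOW, RiskState.HIGH): 0.002,
                (RiskState.MODERATE, RiskState.LOW): 0.337,
                (RiskState.MODERATE, RiskState.HIGH): 0.067,
                (RiskState.HIGH, RiskState.LOW): 0.067,
                (RiskState.HIGH, RiskState.MODERATE): 0.267,
                (RiskState.HIGH, RiskState.VERY_HIGH): 0.067,
                (RiskState.VERY_HIGH, RiskState.MODERATE): 0.010,
                (RiskState.VERY_HIGH, RiskState.HIGH): 0.040,
                (RiskState.VERY_HIGH, RiskState.ESKD): 0.100,
            }
        )
        row = progression_row(state, base, factor, treated, rrr, q)
        assert abs(sum(row.values()) - 1.0) <= 1e-12
        assert all(0.0 <= p <= 1.0 for p in row.values())


def _flat_config(cfg, q=0.0, horizon=40):
    """All mass in LOW, no inter-state transitions, flat mortality q, HR 1."""
    lt = {age: max(q, 1e-300) if q > 0 else 1e-12
          for age in range(cfg.starting_age, cfg.max_age)}
    return cfg.with_override(
        starting_egfr_props={GStage.G1: 1.0},
        starting_acr_props={AStage.A1: 1.0},
        transitions=TransitionTable(base={}),
        mortality_hr={c: 1.0 for c in ALL_CELLS},
        adjustment_factors={c: 1.0 for c in ALL_CELLS},
        life_table=lt,
        max_age=cfg.starting_age + horizon,
    )


class TestRunCohort:
    def test_conservation_and_death_monotone(self, cfg):
        for arm in TestStrategy:
            trace = run_cohort(cfg, arm)
            sums = trace.occupancy.sum(axis=1)
            assert np.all(np.abs(sums - 1.0) < 1e-9)
            dead = trace.occupancy[:, STATE_INDEX[RiskState.DEATH]]
            assert np.all(np.diff(dead) >= -1e-15)
            assert np.all(trace.eskd_inflow >= 0)
            assert np.all(trace.cv_events >= 0)

    def test_immortal_static_cohort(self, cfg):
        trace = run_cohort(_flat_config(cfg), TestStrategy.NONE)
        low = trace.occupancy[:, STATE_INDEX[RiskState.LOW]]
        assert np.all(np.abs(low - 1.0) < 1e-9)

    def test_two_state_geometric_life_years(self, cfg):
        """Single living state with constant q: undiscounted LY is the
        geometric partial sum sum_t (1-q)^t."""
        q = 0.05
        trace = run_cohort(_flat_config(cfg, q=q), TestStrategy.NONE)
        ly = sum(
            trace.occupancy[t, : STATE_INDEX[RiskState.DEATH]].sum()
            for t in range(trace.horizon)
        )
        expected = sum((1 - q) ** t for t in range(trace.horizon))
        assert ly == pytest.approx(expected, abs=1e-12)

    def test_null_treatment_traces_identical_across_arms(self, cfg):
        effects = {
            s: e.model_copy(update={"rrr_progression": 0.0, "rrr_mortality": 0.0})
            for s, e in cfg.treatment_effects.items()
        }
        null = cfg.with_override(treatment_effects=effects)
        traces = {arm: run_cohort(null, arm) for arm in TestStrategy}
        base = traces[TestStrategy.NONE]
        # UACR groups the cohort exactly as the no-testing arm does, so the
        # traces are bit-identical; UPCR splits cohorts between identical
        # dynamics, which only reorders float sums (tolerance ~1 ulp).
        t = traces[TestStrategy.UACR]
        assert np.array_equal(t.occupancy, base.occupancy)
        assert np.array_equal(t.eskd_inflow, base.eskd_inflow)
        t = traces[TestStrategy.UPCR]
        assert np.allclose(t.occupancy, base.occupancy, rtol=0, atol=1e-13)
        assert np.allclose(t.eskd_inflow, base.eskd_inflow, rtol=0, atol=1e-13)
        assert np.allclose(t.cv_events, base.cv_events, rtol=0, atol=1e-13)
        assert np.allclose(t.deaths, base.deaths, rtol=0, atol=1e-13)

    def test_stronger_treatment_fewer_eskd_more_ly(self, cfg):
        def totals(rrr):
            effects = {
                s: e.model_copy(update={"rrr_progression": rrr})
                for s, e in cfg.treatment_effects.items()
            }
            t = run_cohort(cfg.with_override(treatment_effects=effects),
                           TestStrategy.UACR)
            ly = sum(
                t.occupancy[i, : STATE_INDEX[RiskState.DEATH]].sum()
                for i in range(t.horizon)
            )
            return t.eskd_inflow.sum(), ly

        eskd = []
        lys = []
        for rrr in (0.0, 0.21, 0.5):
            e, l = totals(rrr)
            eskd.append(e)
            lys.append(l)
        assert eskd[0] >= eskd[1] >= eskd[2]
        assert lys[0] <= lys[1] <= lys[2]

    def test_agrees_with_microsimulation(self, cfg):
        """Stochastic individual-level realisation of the same per-cycle
        probabilities matches the deterministic trace within 3 MC SEs."""
        from helpers import microsim

        trace = run_cohort(cfg, TestStrategy.UACR)
        ly = sum(
            trace.occupancy[t, : STATE_INDEX[RiskState.DEATH]].sum()
            for t in range(trace.horizon)
        )
        sim = microsim(cfg, TestStrategy.UACR, n=60_000, seed=11)
        assert abs(sim.ly - ly) <= 3 * sim.se_ly
        assert abs(sim.eskd_entries - trace.eskd_inflow.sum()) <= 3 * sim.se_eskd
        assert abs(sim.cv_events - trace.cv_events.sum()) <= 3 * sim.se_cv

    def test_trace_frame_export(self, cfg):
        df = run_cohort(cfg, TestStrategy.NONE).to_frame()
        assert {"cycle", "age", "LOW", "DEATH", "eskd_inflow"} <= set(df.columns)
        assert len(df) == cfg.horizon + 1
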