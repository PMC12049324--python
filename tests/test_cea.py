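"""Incremental analysis, subgroups, scenarios, DSA, CLI plumbing."""

import json

import pytest

from uacr_cea.cea import (
    DOMINANT,
    DOMINATED,
    IDENTICAL,
    DsaSpec,
    default_dsa_specs,
    incremental,
    one_way_dsa,
    run_analysis,
    run_base_case,
    run_scenario,
    run_subgroup,
    set_parameter,
)
from uacr_cea.outcomes import OutcomeSummary
from uacr_cea.states import (
    DipstickStratum,
    RiskState,
    Scenario,
    TestStrategy,
)


def _summary(cost, qaly, arm=TestStrategy.UACR, **kw):
    defaults = dict(
        scenario=Scenario.ACEI_ARB, ly=qaly, dialysis_initiations=0.0,
        cv_events=0.0, cost_undiscounted=cost, ly_undiscounted=qaly,
        qaly_undiscounted=qaly,
    )
    defaults.update(kw)
    return OutcomeSummary(arm=arm, cost=cost, qaly=qaly, **defaults)


class TestIncremental:
    def test_icer_quadrant(self):
        r = incremental(_summary(2e6, 1.0), _summary(1e6, 0.5, TestStrategy.NONE))
        assert r.label == "ICER"
        assert r.icer == pytest.approx(2e6)
        assert r.cost_effective(5e6)

    def test_dominated_with_zero_qaly_gain(self):
        r = incremental(_summary(2e6, 1.0), _summary(1e6, 1.0, TestStrategy.NONE))
        assert r.label == DOMINATED
        assert r.icer is None
        assert not r.cost_effective()

    def test_dominant(self):
        r = incremental(_summary(1e6, 1.5), _summary(2e6, 1.0, TestStrategy.NONE))
        assert r.label == DOMINANT
        assert r.cost_effective()

    def test_identical(self):
        a = _summary(1e6, 1.0)
        r = incremental(a, _summary(1e6, 1.0, TestStrategy.NONE))
        assert r.label == IDENTICAL

    def test_antisymmetry(self, cfg):
        res = run_base_case(cfg)
        a = res.summaries[TestStrategy.UACR]
        b = res.summaries[TestStrategy.NONE]
        fwd, rev = incremental(a, b), incremental(b, a)
        assert fwd.delta_cost == pytest.approx(-rev.delta_cost)
        assert fwd.delta_qaly == pytest.approx(-rev.delta_qaly)
        assert fwd.delta_ly == pytest.approx(-rev.delta_ly)
        assert fwd.delta_dialysis == pytest.approx(-rev.delta_dialysis)
        assert fwd.delta_cv_events == pytest.approx(-rev.delta_cv_events)


class TestBaseCase:
    def test_qaly_ordering_by_detection(self, cfg):
        res = run_base_case(cfg)
        q = {arm: s.qaly for arm, s in res.summaries.items()}
        assert q[TestStrategy.UACR] > q[TestStrategy.UPCR] > q[TestStrategy.NONE]

    def test_pairwise_consistency(self, cfg):
        """Shared no-testing baseline: (UACR-NONE) - (UPCR-NONE) = UACR-UPCR."""
        res = run_base_case(cfg)
        c = res.comparisons
        assert (
            c["UACR_vs_NONE"].delta_cost - c["UPCR_vs_NONE"].delta_cost
        ) == pytest.approx(c["UACR_vs_UPCR"].delta_cost, abs=1e-9)
        assert (
            c["UACR_vs_NONE"].delta_qaly - c["UPCR_vs_NONE"].delta_qaly
        ) == pytest.approx(c["UACR_vs_UPCR"].delta_qaly, abs=1e-9)

    def test_deterministic_json(self, cfg):
        a = json.dumps(run_base_case(cfg).as_dict(), sort_keys=True)
        b = json.dumps(run_base_case(cfg).as_dict(), sort_keys=True)
        assert a == b

    def test_null_rrr_makes_clinical_deltas_vanish(self, cfg):
        effects = {
            s: e.model_copy(update={"rrr_progression": 0.0, "rrr_mortality": 0.0})
            for s, e in cfg.treatment_effects.items()
        }
        res = run_base_case(cfg.with_override(treatment_effects=effects))
        for c in res.comparisons.values():
            assert abs(c.delta_qaly) < 1e-9
            assert abs(c.delta_ly) < 1e-9
            assert abs(c.delta_dialysis) < 1e-9
            assert abs(c.delta_cv_events) < 1e-9


class TestScenario:
    def test_combo_uses_stronger_effect_and_improves_icer(self, cfg):
        base = run_scenario(cfg, Scenario.ACEI_ARB)
        combo = run_scenario(cfg, Scenario.ACEI_ARB_PLUS_SGLT2I)
        cb = base.comparisons["UACR_vs_UPCR"]
        cc = combo.comparisons["UACR_vs_UPCR"]
        assert cc.delta_qaly > cb.delta_qaly
        if cb.icer is not None and cc.icer is not None:
            assert cc.icer < cb.icer

    def test_free_sglt2i_lowers_combo_cost(self, cfg):
        combo = run_scenario(cfg, Scenario.ACEI_ARB_PLUS_SGLT2I)
        free = run_scenario(
            set_parameter(cfg, "costs.drug_sglt2i", 0.0),
            Scenario.ACEI_ARB_PLUS_SGLT2I,
        )
        assert (
            free.comparisons["UACR_vs_NONE"].delta_cost
            < combo.comparisons["UACR_vs_NONE"].delta_cost
        )


class TestSubgroups:
    def test_low_risk_no_benefit_positive_cost(self, cfg):
        """Low-risk (A1) patients are never treated, so testing adds cost
        without QALYs and is dominated."""
        res = run_subgroup(cfg, RiskState.LOW)
        c = res.comparisons["UACR_vs_NONE"]
        assert c.delta_qaly == pytest.approx(0.0, abs=1e-9)
        assert c.delta_cost > 0
        assert c.label == DOMINATED

    @pytest.mark.parametrize("state", [RiskState.HIGH, RiskState.VERY_HIGH])
    def test_high_risk_subgroups_save_money(self, cfg, state):
        res = run_subgroup(cfg, state)
        assert res.comparisons["UACR_vs_NONE"].delta_cost < 0

    def test_dipstick_stratum_uses_stratified_detection(self, cfg):
        res = run_subgroup(cfg, DipstickStratum.DIPSTICK_NEGATIVE)
        c = res.comparisons["UACR_vs_NONE"]
        # negative-dipstick cohort: 10.8% true A2, no A3; finite positive gain
        assert c.delta_qaly > 0

    def test_empty_subgroup_rejected(self, cfg):
        from uacr_cea.markov import run_cohort
        from uacr_cea.states import GStage, AStage

        only_low = cfg.with_override(
            starting_egfr_props={GStage.G1: 1.0},
            starting_acr_props={AStage.A1: 1.0},
        )
        with pytest.raises(ValueError, match="subgroup"):
            run_cohort(only_low, TestStrategy.UACR,
                       subgroup_state=RiskState.HIGH)


class TestDsa:
    def test_empty_specs_empty_list(self, cfg):
        assert one_way_dsa(cfg, []) == []

    def test_discount_rate_bounds_well_formed(self, cfg):
        recs = one_way_dsa(cfg, [DsaSpec("discount_rate", 0.0, 0.04)])
        assert len(recs) == 1
        r = recs[0]
        assert r.parameter == "discount_rate"
        assert {r.label_low, r.label_high} <= {"ICER", DOMINANT, DOMINATED}

    def test_rrr_monotone_qaly_gain(self, cfg):
        gains = []
        for rrr in (0.05, 0.21, 0.4):
            varied = set_parameter(
                cfg, "treatment_effects.ACEI_ARB.rrr_progression", rrr
            )
            gains.append(
                run_analysis(varied).comparisons["UACR_vs_NONE"].delta_qaly
            )
        assert gains[0] < gains[1] < gains[2]

    def test_default_driver_set_runs_sorted(self, cfg):
        specs = default_dsa_specs(cfg)[:3]
        recs = one_way_dsa(cfg, specs)
        spreads = [r.spread for r in recs]
        assert spreads == sorted(spreads, reverse=True)

    def test_unknown_path_named_in_error(self, cfg):
        with pytest.raises(KeyError, match="no_such_parameter"):
            set_parameter(cfg, "no_such_parameter", 1.0)


class TestCli:
    def test_run_and_synth_commands(self, tmp_path):
        from click.testing import CliRunner

        from uacr_cea.cli import main

        runner = CliRunner()
        out = tmp_path / "res.json"
        r = runner.invoke(main, ["run", "--out", str(out)])
        assert r.exit_code == 0, r.output
        payload = json.loads(out.read_text())
        assert "comparisons" in payload

        lt = tmp_path / "lt.csv"
        r = runner.invoke(main, ["synth", "life-table", "--out", str(lt)])
        assert r.exit_code == 0
        assert lt.exists()

    def test_dump_defaults_round_trips(self, tmp_path, cfg):
        from click.testing import CliRunner

        from uacr_cea import load_config
        from uacr_cea.cli import main

        runner = CliRunner()
        r = runner.invoke(main, ["dump-defaults", "--out", str(tmp_path / "d")])
        assert r.exit_code == 0
        assert load_config(tmp_path / "d" / "model.yaml") == cfg
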