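"""Incremental cost-effectiveness analysis: base case, subgroups,
scenarios and one-way deterministic sensitivity analysis.

The primary outputs are pairwise comparisons of the three testing arms —
UACR vs no urine testing, UPCR vs no urine testing, UACR vs UPCR — each
reported as incremental cost, incremental QALYs and their ratio (the
ICER), or a dominance label when the ratio is not informative.  ICERs are
judged against the Japanese HTA willingness-to-pay threshold of
5,000,000 yen per QALY.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

from .config import ModelConfig, TreatmentEffect, validate_config
from .markov import run_cohort
from .outcomes import OutcomeSummary, accumulate
from .states import (
    AStage,
    DipstickStratum,
    GStage,
    KdigoCell,
    RiskState,
    Scenario,
    TestStrategy,
)

WTP_THRESHOLD_YEN = 5_000_000.0

DOMINANT = "DOMINANT"
DOMINATED = "DOMINATED"
IDENTICAL = "IDENTICAL"

_EPS = 1e-9


@dataclass(frozen=True)
class IncrementalResult:
    """Pairwise incremental outcomes (arm a minus arm b, per cohort)."""

    arm_a: TestStrategy
    arm_b: TestStrategy
    delta_cost: float
    delta_qaly: float
    delta_ly: float
    delta_dialysis: float
    delta_cv_events: float
    icer: float | None
    label: str  # DOMINANT / DOMINATED / IDENTICAL / "ICER"

    def cost_effective(self, wtp: float = WTP_THRESHOLD_YEN) -> bool:
        """Cost-effective iff dominant or ICER below the threshold."""
        if self.label == DOMINANT:
            return True
        if self.label in (DOMINATED, IDENTICAL):
            return False
        return self.icer is not None and self.icer < wtp

    def as_dict(self) -> dict:
        return {
            "comparison": f"{self.arm_a.value}_vs_{self.arm_b.value}",
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "delta_ly": self.delta_ly,
            "delta_dialysis": self.delta_dialysis,
            "delta_cv_events": self.delta_cv_events,
            "icer": self.icer,
            "label": self.label,
        }


def incremental(a: OutcomeSummary, b: OutcomeSummary) -> IncrementalResult:
    """Compare two arms run under an otherwise identical configuration.

    Dominance follows the reporting convention of CKD staging subgroup
    tables: a strategy that costs more without gaining QALYs is labelled
    dominated even when the QALY difference is exactly zero.
    """
    dc = a.cost - b.cost
    dq = a.qaly - b.qaly
    if abs(dc) <= _EPS and abs(dq) <= _EPS:
        label, icer = IDENTICAL, None
    elif dc < 0 and dq >= 0:
        label, icer = DOMINANT, None
    elif dc > 0 and dq <= 0:
        label, icer = DOMINATED, None
    else:
        label, icer = "ICER", dc / dq
    return IncrementalResult(
        arm_a=a.arm,
        arm_b=b.arm,
        delta_cost=dc,
        delta_qaly=dq,
        delta_ly=a.ly - b.ly,
        delta_dialysis=a.dialysis_initiations - b.dialysis_initiations,
        delta_cv_events=a.cv_events - b.cv_events,
        icer=icer,
        label=label,
    )


@dataclass
class AnalysisResult:
    """Per-arm summaries plus the three pairwise comparisons."""

    summaries: dict[TestStrategy, OutcomeSummary]
    comparisons: dict[str, IncrementalResult]
    scenario: Scenario
    stratum: DipstickStratum = DipstickStratum.UNSTRATIFIED
    subgroup_state: RiskState | None = None

    def as_dict(self) -> dict:
        return {
            "scenario": self.scenario.value,
            "stratum": self.stratum.value,
            "subgroup_state": (
                self.subgroup_state.value if self.subgroup_state else None
            ),
            "arms": {
                arm.value: s.as_dict() for arm, s in self.summaries.items()
            },
            "comparisons": {
                k: r.as_dict() for k, r in self.comparisons.items()
            },
        }


_PAIRS = (
    (TestStrategy.UACR, TestStrategy.NONE),
    (TestStrategy.UPCR, TestStrategy.NONE),
    (TestStrategy.UACR, TestStrategy.UPCR),
)


def run_analysis(
    cfg: ModelConfig,
    scenario: Scenario = Scenario.ACEI_ARB,
    stratum: DipstickStratum = DipstickStratum.UNSTRATIFIED,
    subgroup_state: RiskState | None = None,
) -> AnalysisResult:
    """Run all three arms and form the pairwise comparisons."""
    report = validate_config(cfg)
    if report.hard_errors:
        raise ValueError("invalid configuration: " + "; ".join(report.hard_errors))
    summaries = {
        arm: accumulate(
            run_cohort(
                cfg, arm, scenario, stratum=stratum, subgroup_state=subgroup_state
            ),
            cfg,
        )
        for arm in TestStrategy
    }
    comparisons = {
        f"{a.value}_vs_{b.value}": incremental(summaries[a], summaries[b])
        for a, b in _PAIRS
    }
    return AnalysisResult(
        summaries=summaries,
        comparisons=comparisons,
        scenario=scenario,
        stratum=stratum,
        subgroup_state=subgroup_state,
    )


def run_base_case(cfg: ModelConfig) -> AnalysisResult:
    """Base case: unstratified cohort, ACEi/ARB treatment paradigm."""
    return run_analysis(cfg, Scenario.ACEI_ARB)


def run_scenario(cfg: ModelConfig, scenario: Scenario) -> AnalysisResult:
    """Same pipeline under an alternative treatment paradigm."""
    return run_analysis(cfg, scenario)


def run_subgroup(
    cfg: ModelConfig,
    selector: RiskState | DipstickStratum,
    scenario: Scenario = Scenario.ACEI_ARB,
) -> AnalysisResult:
    """Subgroup analysis by starting risk state or prior dipstick result."""
    if isinstance(selector, RiskState):
        return run_analysis(cfg, scenario, subgroup_state=selector)
    return run_analysis(cfg, scenario, stratum=selector)


# ---------------------------------------------------------------------------
# Parameter paths and one-way DSA


def set_parameter(cfg: ModelConfig, path: str, value: float) -> ModelConfig:
    """Return a copy of ``cfg`` with the dotted parameter ``path`` replaced.

    Supported roots: scalar run settings (e.g. ``discount_rate``),
    ``costs.<category>``, ``utilities.<STATE>``, ``cv.reference_risk``,
    ``cv.hr.<STATE>``, ``mortality_hr.<CELL>``, ``adjustment_factors.<CELL>``
    and ``treatment_effects.<SCENARIO>.<field>``.
    """
    parts = path.split(".")
    root = parts[0]
    try:
        if len(parts) == 1:
            if root not in (
                "discount_rate", "starting_age", "max_age", "cohort_scale",
                "female_fraction",
            ):
                raise KeyError(root)
            return replace(cfg, **{root: type(getattr(cfg, root))(value)})
        if root == "costs":
            costs = dict(cfg.costs)
            if parts[1] not in costs:
                raise KeyError(parts[1])
            costs[parts[1]] = float(value)
            return replace(cfg, costs=costs)
        if root == "utilities":
            utils = dict(cfg.utilities)
            utils[RiskState(parts[1])] = float(value)
            return replace(cfg, utilities=utils)
        if root == "cv":
            if parts[1] == "reference_risk" or parts[1] == "reference_10yr_risk":
                return replace(
                    cfg, cv=replace(cfg.cv, reference_risk=float(value))
                )
            if parts[1] == "hr":
                hr = dict(cfg.cv.hr)
                hr[RiskState(parts[2])] = float(value)
                return replace(cfg, cv=replace(cfg.cv, hr=hr))
            raise KeyError(parts[1])
        if root == "mortality_hr":
            table = dict(cfg.mortality_hr)
            table[KdigoCell.parse(parts[1])] = float(value)
            return replace(cfg, mortality_hr=table)
        if root == "adjustment_factors":
            table = dict(cfg.adjustment_factors)
            table[KdigoCell.parse(parts[1])] = float(value)
            return replace(cfg, adjustment_factors=table)
        if root == "treatment_effects":
            scen = Scenario(parts[1])
            effects = dict(cfg.treatment_effects)
            effects[scen] = effects[scen].model_copy(
                update={parts[2]: float(value)}
            )
            return replace(cfg, treatment_effects=effects)
    except (KeyError, ValueError) as exc:
        raise KeyError(f"unknown parameter path {path!r}: {exc}") from None
    raise KeyError(f"unknown parameter path {path!r}")


def get_parameter(cfg: ModelConfig, path: str) -> float:
    parts = path.split(".")
    root = parts[0]
    if len(parts) == 1:
        return float(getattr(cfg, root))
    if root == "costs":
        return cfg.costs[parts[1]]
    if root == "utilities":
        return cfg.utilities[RiskState(parts[1])]
    if root == "cv":
        if parts[1] in ("reference_risk", "reference_10yr_risk"):
            return cfg.cv.reference_risk
        return cfg.cv.hr[RiskState(parts[2])]
    if root == "mortality_hr":
        return cfg.mortality_hr[KdigoCell.parse(parts[1])]
    if root == "adjustment_factors":
        return cfg.adjustment_factors[KdigoCell.parse(parts[1])]
    if root == "treatment_effects":
        return float(getattr(cfg.treatment_effects[Scenario(parts[1])], parts[2]))
    raise KeyError(f"unknown parameter path {path!r}")


@dataclass(frozen=True)
class DsaSpec:
    """One parameter to vary: dotted path plus low/high input values."""

    path: str
    low: float
    high: float


@dataclass(frozen=True)
class DsaRecord:
    """One-way DSA result for one parameter (tornado bar)."""

    parameter: str
    low: float
    high: float
    icer_low: float | None
    icer_high: float | None
    label_low: str
    label_high: str

    @property
    def spread(self) -> float:
        if self.icer_low is None or self.icer_high is None:
            return math.inf  # a dominance flip is maximal sensitivity
        return abs(self.icer_high - self.icer_low)


def default_dsa_specs(cfg: ModelConfig, rel: float = 0.20) -> list[DsaSpec]:
    """The standard driver set at +/-20% (utilities capped at 1)."""
    paths = [
        "treatment_effects.ACEI_ARB.rrr_progression",
        "treatment_effects.ACEI_ARB.rrr_mortality",
        "discount_rate",
        "costs.dialysis_annual",
        "costs.drug_acei_arb",
        "costs.drug_sglt2i",
        "cv.reference_risk",
    ] + [f"utilities.{s.value}" for s in cfg.utilities]
    specs = []
    for p in paths:
        v = get_parameter(cfg, p)
        low, high = v * (1 - rel), v * (1 + rel)
        if p.startswith("utilities."):
            high = min(high, 1.0)
        specs.append(DsaSpec(path=p, low=low, high=high))
    return specs


def one_way_dsa(
    cfg: ModelConfig,
    param_specs: Sequence[DsaSpec] | None = None,
    comparison: str = "UACR_vs_NONE",
    scenario: Scenario = Scenario.ACEI_ARB,
) -> list[DsaRecord]:
    """Re-run the analysis at each parameter's bounds; tornado-ordered output."""
    if param_specs is None:
        param_specs = default_dsa_specs(cfg)
    records = []
    for spec in param_specs:
        results = {}
        for bound, value in (("low", spec.low), ("high", spec.high)):
            varied = set_parameter(cfg, spec.path, value)
            res = run_analysis(varied, scenario)
            results[bound] = res.comparisons[comparison]
        records.append(
            DsaRecord(
                parameter=spec.path,
                low=spec.low,
                high=spec.high,
                icer_low=results["low"].icer,
                icer_high=results["high"].icer,
                label_low=results["low"].label,
                label_high=results["high"].label,
            )
        )
    records.sort(key=lambda r: r.spread, reverse=True)
    return records
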