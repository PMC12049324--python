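"""Model configuration: typed parameter set, readers/writers, validation.

A configuration is one YAML manifest plus a set of CSV tables (kept
tabular so they stay diffable against their published sources).  The
package ships a complete base-case parameter set; a user manifest may
override any scalar or point any table at a replacement CSV, and absent
fields fall back to the packaged defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Mapping

import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

try:  # Python >= 3.9
    from importlib.resources import files as _pkg_files
except ImportError:  # pragma: no cover
    _pkg_files = None

from .classification import ReclassificationTable
from .states import (
    ALL_CELLS,
    AStage,
    CKD_STATES,
    GStage,
    KdigoCell,
    LIVING_STATES,
    RiskState,
    Scenario,
    kdigo_risk_map,
)

DEFAULTS_DIR = Path(str(_pkg_files("uacr_cea") / "defaults"))


class ConfigError(ValueError):
    """Raised for missing or malformed configuration inputs."""


class Conventions(BaseModel):
    """Modelling-convention flags for points the source model left open."""

    model_config = ConfigDict(extra="forbid")

    cv_rate_basis: Literal["per10y", "annual"] = "per10y"
    treatment_scope: Literal["initial", "first_cycle", "lifetime"] = "initial"
    half_cycle: bool = False
    mortality_rrr_on: Literal["total", "excess"] = "total"
    hr_composition: Literal["rate", "multiplicative"] = "rate"
    sah_cost_category: str = "event_stroke_ich"


class TreatmentEffect(BaseModel):
    """Relative risk reductions and drug costs for one treatment paradigm."""

    model_config = ConfigDict(extra="forbid")

    rrr_progression: float = Field(ge=0.0, lt=1.0)
    rrr_mortality: float = Field(ge=0.0, lt=1.0)
    annual_drug_cost_categories: tuple[str, ...] = ()


@dataclass(frozen=True)
class TransitionTable:
    """Base annual inter-state probabilities (before mortality/treatment)."""

    base: Mapping[tuple[RiskState, RiskState], float]

    def prob(self, frm: RiskState, to: RiskState) -> float:
        return self.base.get((frm, to), 0.0)

    def row(self, frm: RiskState) -> dict[RiskState, float]:
        return {
            to: self.base[(f, to)]
            for (f, to) in self.base
            if f == frm
        }


@dataclass(frozen=True)
class CvModel:
    """Cardiovascular side-event inputs: reference risk, HRs, event mix."""

    reference_risk: float
    hr: Mapping[RiskState, float]
    mix: Mapping[str, float]  # keys mi, stroke_ischemic, stroke_ich, stroke_sah, other_cv


@dataclass
class ModelConfig:
    """The full validated parameter set for one analysis."""

    starting_age: int
    max_age: int
    cycle_length_years: int
    discount_rate: float
    cohort_scale: float
    female_fraction: float
    conventions: Conventions
    starting_egfr_props: dict[GStage, float]
    starting_acr_props: dict[AStage, float]
    treatment_effects: dict[Scenario, TreatmentEffect]
    transitions: TransitionTable
    adjustment_factors: dict[KdigoCell, float]
    mortality_hr: dict[KdigoCell, float]
    cv: CvModel
    costs: dict[str, float]
    resource_use: dict[tuple[RiskState, str], float]
    utilities: dict[RiskState, float]
    reclassification: ReclassificationTable
    life_table: dict[int, float]
    #: Optional explicit joint starting occupancy over KDIGO cells; when
    #: set it replaces the independent-marginals reconstruction.
    joint_starting_cells: dict[KdigoCell, float] | None = None

    @property
    def horizon(self) -> int:
        return self.max_age - self.starting_age

    def with_override(self, **kwargs) -> "ModelConfig":
        return replace(self, **kwargs)


# ---------------------------------------------------------------------------
# CSV readers


def _read_csv(path: Path, table: str) -> pd.DataFrame:
    if not path.exists():
        raise ConfigError(f"config incomplete: missing table {table!r} at {path}")
    try:
        return pd.read_csv(path)
    except Exception as exc:  # malformed file
        raise ConfigError(f"could not parse table {table!r} at {path}: {exc}") from exc


def _number(df_row, col: str, table: str, idx: int) -> float:
    raw = df_row[col]
    try:
        val = float(raw)
        if math.isnan(val):
            raise ValueError
        return val
    except (TypeError, ValueError):
        raise ConfigError(
            f"table {table!r}, row {idx}, column {col!r}: "
            f"not a number: {raw!r}"
        ) from None


def _load_transitions(path: Path) -> TransitionTable:
    df = _read_csv(path, "transitions")
    base = {}
    for i, row in df.iterrows():
        frm = RiskState(row["from_state"])
        to = RiskState(row["to_state"])
        base[(frm, to)] = _number(row, "probability", "transitions", i)
    return TransitionTable(base=base)


def _load_cell_table(path: Path, table: str, col: str) -> dict[KdigoCell, float]:
    df = _read_csv(path, table)
    out = {}
    for i, row in df.iterrows():
        cell = KdigoCell(GStage(row["g"]), AStage(row["a"]))
        out[cell] = _number(row, col, table, i)
    return out


def _load_cv(path: Path) -> CvModel:
    df = _read_csv(path, "cv")
    kv = {}
    for i, row in df.iterrows():
        kv[str(row["parameter"])] = _number(row, "value", "cv", i)
    try:
        return CvModel(
            reference_risk=kv["reference_10yr_risk"],
            hr={s: kv[f"hr_{s.value}"] for s in LIVING_STATES},
            mix={
                k.removeprefix("mix_"): v
                for k, v in kv.items()
                if k.startswith("mix_")
            },
        )
    except KeyError as exc:
        raise ConfigError(f"config incomplete: cv table missing {exc}") from None


def _load_costs(path: Path) -> dict[str, float]:
    df = _read_csv(path, "costs")
    return {
        str(row["category"]): _number(row, "yen", "costs", i)
        for i, row in df.iterrows()
    }


def _load_resource_use(path: Path) -> dict[tuple[RiskState, str], float]:
    df = _read_csv(path, "resource_use")
    return {
        (RiskState(row["state"]), str(row["category"])): _number(
            row, "annual_count", "resource_use", i
        )
        for i, row in df.iterrows()
    }


def _load_utilities(path: Path) -> dict[RiskState, float]:
    df = _read_csv(path, "utilities")
    return {
        RiskState(row["state"]): _number(row, "utility", "utilities", i)
        for i, row in df.iterrows()
    }


def _load_life_table(path: Path) -> dict[int, float]:
    df = _read_csv(path, "life_table")
    out = {}
    for i, row in df.iterrows():
        out[int(row["age"])] = _number(row, "qx", "life_table", i)
    return out


def _load_reclassification(path: Path) -> ReclassificationTable:
    df = _read_csv(path, "reclassification")
    return ReclassificationTable.from_frame(df)


# ---------------------------------------------------------------------------
# Manifest loading


def _deep_update(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_update(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | Path | None = None) -> ModelConfig:
    """Load a configuration, overlaying a user manifest on packaged defaults.

    ``path`` is a YAML manifest; relative table paths in it resolve against
    the manifest's directory.  ``None`` (or an empty manifest) returns the
    packaged base case.
    """
    default_manifest = yaml.safe_load((DEFAULTS_DIR / "model.yaml").read_text())
    manifest = dict(default_manifest)
    table_dirs = {t: DEFAULTS_DIR for t in default_manifest["tables"]}

    if path is not None:
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config manifest not found: {path}")
        user = yaml.safe_load(path.read_text()) or {}
        if not isinstance(user, Mapping):
            raise ConfigError(f"manifest {path} is not a mapping")
        for t in (user.get("tables") or {}):
            table_dirs[t] = path.parent
        manifest = _deep_update(manifest, user)

    def tpath(name: str) -> Path:
        ref = manifest["tables"][name]
        p = Path(ref)
        return p if p.is_absolute() else table_dirs.get(name, DEFAULTS_DIR) / p

    try:
        conventions = Conventions(**(manifest.get("conventions") or {}))
        effects = {
            Scenario(k): TreatmentEffect(**v)
            for k, v in manifest["treatment_effects"].items()
        }
        egfr = {GStage(k): float(v) for k, v in manifest["starting_egfr_props"].items()}
        acr = {AStage(k): float(v) for k, v in manifest["starting_acr_props"].items()}
    except (KeyError, ValueError, TypeError) as exc:
        raise ConfigError(f"invalid manifest field: {exc}") from exc

    joint = manifest.get("joint_starting_cells")
    joint_cells = (
        {KdigoCell.parse(k): float(v) for k, v in joint.items()} if joint else None
    )

    cfg = ModelConfig(
        starting_age=int(manifest["starting_age"]),
        max_age=int(manifest["max_age"]),
        cycle_length_years=int(manifest["cycle_length_years"]),
        discount_rate=float(manifest["discount_rate"]),
        cohort_scale=float(manifest["cohort_scale"]),
        female_fraction=float(manifest["female_fraction"]),
        conventions=conventions,
        starting_egfr_props=egfr,
        starting_acr_props=acr,
        treatment_effects=effects,
        transitions=_load_transitions(tpath("transitions")),
        adjustment_factors=_load_cell_table(
            tpath("adjustment_factors"), "adjustment_factors", "factor"
        ),
        mortality_hr=_load_cell_table(tpath("mortality_hr"), "mortality_hr", "hr"),
        cv=_load_cv(tpath("cv")),
        costs=_load_costs(tpath("costs")),
        resource_use=_load_resource_use(tpath("resource_use")),
        utilities=_load_utilities(tpath("utilities")),
        reclassification=_load_reclassification(tpath("reclassification")),
        life_table=_load_life_table(tpath("life_table")),
        joint_starting_cells=joint_cells,
    )
    report = validate_config(cfg)
    if report.hard_errors:
        raise ConfigError("; ".join(report.hard_errors))
    return cfg


def write_config(cfg: ModelConfig, outdir: str | Path) -> Path:
    """Write a configuration as model.yaml + CSV tables; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {"from_state": f.value, "to_state": t.value, "probability": p}
            for (f, t), p in cfg.transitions.base.items()
        ]
    ).to_csv(outdir / "transitions.csv", index=False)
    pd.DataFrame(
        [{"g": c.g.value, "a": c.a.value, "factor": v}
         for c, v in cfg.adjustment_factors.items()]
    ).to_csv(outdir / "adjustment_factors.csv", index=False)
    pd.DataFrame(
        [{"g": c.g.value, "a": c.a.value, "hr": v}
         for c, v in cfg.mortality_hr.items()]
    ).to_csv(outdir / "mortality_hr.csv", index=False)
    cv_rows = [{"parameter": "reference_10yr_risk", "value": cfg.cv.reference_risk}]
    cv_rows += [
        {"parameter": f"hr_{s.value}", "value": cfg.cv.hr[s]} for s in LIVING_STATES
    ]
    cv_rows += [{"parameter": f"mix_{k}", "value": v} for k, v in cfg.cv.mix.items()]
    pd.DataFrame(cv_rows).to_csv(outdir / "cv.csv", index=False)
    pd.DataFrame(
        [{"category": k, "yen": v} for k, v in cfg.costs.items()]
    ).to_csv(outdir / "costs.csv", index=False)
    pd.DataFrame(
        [
            {"state": s.value, "category": c, "annual_count": v}
            for (s, c), v in cfg.resource_use.items()
        ]
    ).to_csv(outdir / "resource_use.csv", index=False)
    pd.DataFrame(
        [{"state": s.value, "utility": u} for s, u in cfg.utilities.items()]
    ).to_csv(outdir / "utilities.csv", index=False)
    cfg.reclassification.to_frame().to_csv(
        outdir / "reclassification.csv", index=False
    )
    pd.DataFrame(
        sorted(cfg.life_table.items()), columns=["age", "qx"]
    ).to_csv(outdir / "life_table.csv", index=False)

    manifest = {
        "starting_age": cfg.starting_age,
        "max_age": cfg.max_age,
        "cycle_length_years": cfg.cycle_length_years,
        "discount_rate": cfg.discount_rate,
        "cohort_scale": cfg.cohort_scale,
        "female_fraction": cfg.female_fraction,
        "conventions": cfg.conventions.model_dump(),
        "starting_egfr_props": {g.value: v for g, v in cfg.starting_egfr_props.items()},
        "starting_acr_props": {a.value: v for a, v in cfg.starting_acr_props.items()},
        "treatment_effects": {
            s.value: {
                "rrr_progression": e.rrr_progression,
                "rrr_mortality": e.rrr_mortality,
                "annual_drug_cost_categories": list(e.annual_drug_cost_categories),
            }
            for s, e in cfg.treatment_effects.items()
        },
        "tables": {
            "transitions": "transitions.csv",
            "adjustment_factors": "adjustment_factors.csv",
            "mortality_hr": "mortality_hr.csv",
            "cv": "cv.csv",
            "costs": "costs.csv",
            "resource_use": "resource_use.csv",
            "utilities": "utilities.csv",
            "reclassification": "reclassification.csv",
            "life_table": "life_table.csv",
        },
    }
    if cfg.joint_starting_cells is not None:
        manifest["joint_starting_cells"] = {
            str(c): v for c, v in cfg.joint_starting_cells.items()
        }
    out = outdir / "model.yaml"
    out.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return out


# ---------------------------------------------------------------------------
# Validation


@dataclass
class ValidationReport:
    """All invariant violations found in a configuration."""

    problems: list[str] = field(default_factory=list)
    #: subset of problems severe enough to refuse to run
    hard_errors: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.problems

    def _add(self, msg: str, hard: bool = False) -> None:
        self.problems.append(msg)
        if hard:
            self.hard_errors.append(msg)


def validate_config(cfg: ModelConfig) -> ValidationReport:
    """Check every structural invariant; an empty report means a clean config."""
    r = ValidationReport()

    if cfg.max_age <= cfg.starting_age:
        r._add("max_age must exceed starting_age", hard=True)
    if cfg.discount_rate < 0:
        r._add("discount rate must be >= 0")

    # transitions: probabilities in [0,1]; living rows sum < 1; ESKD emits none
    for (f, t), p in cfg.transitions.base.items():
        if not (0.0 <= p <= 1.0):
            r._add(f"transition {f.value}->{t.value} = {p} outside [0,1]", hard=True)
    for s in LIVING_STATES:
        tot = sum(cfg.transitions.row(s).values())
        if tot >= 1.0:
            r._add(
                f"transition row {s.value} sums to {tot} >= 1 "
                "(no residual remain probability)", hard=True,
            )
    for t in CKD_STATES:
        if cfg.transitions.prob(RiskState.ESKD, t) != 0.0:
            r._add(f"ESKD->{t.value} transition must be 0")

    for cell in ALL_CELLS:
        if kdigo_risk_map(cell) is not RiskState.ESKD:
            fac = cfg.adjustment_factors.get(cell)
            if fac is None:
                r._add(f"missing adjustment factor for {cell}", hard=True)
            elif fac <= 0:
                r._add(f"adjustment factor for {cell} must be > 0")
        hr = cfg.mortality_hr.get(cell)
        if hr is None:
            r._add(f"missing mortality hazard ratio for {cell}", hard=True)
        elif hr <= 0:
            r._add(f"mortality hazard ratio for {cell} must be > 0")

    for age in range(cfg.starting_age, cfg.max_age):
        q = cfg.life_table.get(age)
        if q is None:
            r._add(f"life table missing age {age}", hard=True)
        elif not (0.0 < q < 1.0):
            r._add(f"life table q({age}) = {q} outside (0,1)")

    mixsum = sum(cfg.cv.mix.values())
    if abs(mixsum - 1.0) > 0.005:
        r._add(f"CV event mix sums to {mixsum:.4f}, not 1 +/- 0.005")
    for s, hr in cfg.cv.hr.items():
        if hr <= 0:
            r._add(f"CV hazard ratio for {s.value} must be > 0")
    if not (0.0 < cfg.cv.reference_risk < 1.0):
        r._add("CV reference risk must lie in (0,1)")

    for cat, yen in cfg.costs.items():
        if yen < 0:
            r._add(f"cost {cat!r} is negative")

    for s in LIVING_STATES:
        u = cfg.utilities.get(s)
        if u is None:
            r._add(f"missing utility for {s.value}", hard=True)
        elif not (0.0 < u <= 1.0):
            r._add(f"utility for {s.value} = {u} outside (0,1]")

    for name, props in (
        ("eGFR", cfg.starting_egfr_props),
        ("albuminuria", cfg.starting_acr_props),
    ):
        if any(v < 0 for v in props.values()):
            r._add(f"negative starting {name} proportion", hard=True)
        tot = sum(props.values())
        if abs(tot - 1.0) > 0.01:
            r._add(f"starting {name} marginals sum to {tot:.4f}, not 1 +/- 0.01")

    r.problems.extend(cfg.reclassification.validate())
    return r


# ---------------------------------------------------------------------------
# Starting distribution


@dataclass(frozen=True)
class StartingDistribution:
    """Cycle-0 occupancy over KDIGO cells and over risk states."""

    cells: dict[KdigoCell, float]
    states: dict[RiskState, float]


def starting_distribution(
    egfr_props: Mapping[GStage, float],
    acr_props: Mapping[AStage, float],
    joint: Mapping[KdigoCell, float] | None = None,
) -> StartingDistribution:
    """Joint cell occupancy from marginals (independence) or an explicit joint.

    Published cohort tables typically report only the eGFR and albuminuria
    marginals; the joint occupancy is reconstructed as their product after
    renormalising each marginal exactly to 1 (printed values carry rounding).
    An explicit joint table overrides the independence reconstruction.
    """
    if joint is not None:
        tot = sum(joint.values())
        if tot <= 0 or any(v < 0 for v in joint.values()):
            raise ValueError("joint starting distribution must be non-negative")
        cells = {c: joint.get(c, 0.0) / tot for c in ALL_CELLS}
    else:
        for name, props in (("eGFR", egfr_props), ("albuminuria", acr_props)):
            if any(v < 0 for v in props.values()):
                raise ValueError(f"negative {name} starting proportion")
            tot = sum(props.values())
            if abs(tot - 1.0) > 0.01:
                raise ValueError(
                    f"{name} starting marginals sum to {tot:.4f}, not 1 +/- 0.01"
                )
        zg = sum(egfr_props.values())
        za = sum(acr_props.values())
        cells = {
            KdigoCell(g, a): (egfr_props.get(g, 0.0) / zg)
            * (acr_props.get(a, 0.0) / za)
            for g in GStage
            for a in AStage
        }
    states = {s: 0.0 for s in LIVING_STATES}
    for c, m in cells.items():
        states[kdigo_risk_map(c)] += m
    return StartingDistribution(cells=cells, states=states)
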