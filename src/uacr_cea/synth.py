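"""Synthetic model inputs: a parametric life table and re-test counts.

The model needs an age-indexed background-mortality table and a re-test
classification table.  Real national life tables are not bundled; instead
a Gompertz–Makeham generator produces a smooth, monotone annual-mortality
schedule whose default parameters give a remaining life expectancy at age
60 of about 26 years, in the range of a modern low-mortality population.
The re-test generator draws cohorts with the same nested-detection
structure the classification module assumes, so reconstruction of the
generating sensitivities can be checked end to end.

Both generators are deterministic given their spec (the life table has no
randomness at all) and emit objects/frames in the exact dialects the
configuration reader consumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .classification import ClassMarginal, ReclassificationTable, upcr_sensitivities
from .states import AStage, DipstickStratum, TestStrategy

_A_ORDER = (AStage.A1, AStage.A2, AStage.A3)


@dataclass(frozen=True)
class LifeTableSpec:
    """Gompertz–Makeham annual mortality: h(x) = makeham + level * exp(slope * x).

    ``q(x) = 1 - exp(-h(x))`` per integer age x.  Defaults give a remaining
    life expectancy at 60 of ~26 years.
    """

    makeham: float = 2.0e-4
    gompertz_level: float = 3.6e-6
    gompertz_slope: float = 0.117
    age_min: int = 40
    age_max: int = 100  # inclusive
    model: str = "GOMPERTZ_MAKEHAM"

    def hazard(self, age: float) -> float:
        return self.makeham + self.gompertz_level * math.exp(
            self.gompertz_slope * age
        )


def synth_life_table(spec: LifeTableSpec = LifeTableSpec()) -> pd.DataFrame:
    """Generate an (age, qx) life table frame from a Gompertz–Makeham spec."""
    if spec.model != "GOMPERTZ_MAKEHAM":
        raise ValueError(f"unknown life-table model {spec.model!r}")
    if spec.makeham < 0 or spec.gompertz_level <= 0 or spec.gompertz_slope <= 0:
        raise ValueError("Gompertz–Makeham parameters out of range")
    ages = np.arange(spec.age_min, spec.age_max + 1)
    qx = 1.0 - np.exp(-np.array([spec.hazard(float(a)) for a in ages]))
    if np.any(qx >= 1.0) or np.any(qx <= 0.0):
        raise ValueError("life-table parameters produce q outside (0, 1)")
    if np.any(np.diff(qx) <= 0):
        raise ValueError("generated q(age) is not strictly increasing")
    return pd.DataFrame({"age": ages, "qx": qx})


def life_expectancy(table: pd.DataFrame, age: int) -> float:
    """Discrete remaining life expectancy at ``age`` from an (age, qx) table.

    Counts a full year per year survived into; everyone alive at the end of
    the table dies in the following year (truncation).
    """
    sub = table[table["age"] >= age].sort_values("age")
    if sub.empty or int(sub["age"].iloc[0]) != age:
        raise ValueError(f"age {age} not covered by life table")
    surv = 1.0
    total = 0.0
    for q in sub["qx"]:
        total += surv
        surv *= 1.0 - float(q)
    return total


@dataclass(frozen=True)
class RetestSpec:
    """Data-generating spec for a synthetic re-test classification cohort.

    ``n`` patients draw a true albuminuria class from ``true_dist``; UACR
    observes truth; UPCR detects a true class-k positive with probability
    ``sensitivity[k]`` and classifies misses one level lower.  Optional
    ``dipstick_probs`` maps each true class to a distribution over dipstick
    strata, producing per-stratum tables alongside the unstratified one.
    """

    n: int = 1238
    true_dist: Mapping[AStage, float] = field(
        default_factory=lambda: {
            AStage.A1: 0.830, AStage.A2: 0.160, AStage.A3: 0.011,
        }
    )
    sensitivity: Mapping[AStage, float] = field(
        default_factory=lambda: {AStage.A2: 75 / 198, AStage.A3: 1.0}
    )
    dipstick_probs: Mapping[AStage, Mapping[DipstickStratum, float]] | None = None
    seed: int = 0


def _upcr_counts(
    rng: np.random.Generator, true_counts: dict[AStage, int],
    sens: Mapping[AStage, float],
) -> dict[AStage, int]:
    d3 = int(rng.binomial(true_counts[AStage.A3], sens[AStage.A3]))
    d2 = int(rng.binomial(true_counts[AStage.A2], sens[AStage.A2]))
    return {
        AStage.A3: d3,
        AStage.A2: d2 + (true_counts[AStage.A3] - d3),
        AStage.A1: true_counts[AStage.A1] + (true_counts[AStage.A2] - d2),
    }


def _marginal(counts: dict[AStage, int]) -> ClassMarginal:
    n = sum(counts.values())
    props = {a: (counts[a] / n if n else 0.0) for a in _A_ORDER}
    return ClassMarginal(
        counts={a: float(counts[a]) for a in _A_ORDER}, proportions=props
    )


def synth_retest_counts(spec: RetestSpec) -> ReclassificationTable:
    """Draw one synthetic re-test cohort and lay it out like real re-test data."""
    rng = np.random.default_rng(spec.seed)
    p = np.array([spec.true_dist.get(a, 0.0) for a in _A_ORDER], dtype=float)
    p = p / p.sum()
    true_n = rng.multinomial(spec.n, p)
    true_counts = {a: int(c) for a, c in zip(_A_ORDER, true_n)}

    marginals: dict[tuple[DipstickStratum, TestStrategy], ClassMarginal] = {}
    marginals[(DipstickStratum.UNSTRATIFIED, TestStrategy.UACR)] = _marginal(
        true_counts
    )
    marginals[(DipstickStratum.UNSTRATIFIED, TestStrategy.UPCR)] = _marginal(
        _upcr_counts(rng, true_counts, spec.sensitivity)
    )

    if spec.dipstick_probs is not None:
        strata = [
            DipstickStratum.DIPSTICK_NEGATIVE,
            DipstickStratum.DIPSTICK_TRACE,
            DipstickStratum.DIPSTICK_POSITIVE,
        ]
        per_stratum: dict[DipstickStratum, dict[AStage, int]] = {
            s: {a: 0 for a in _A_ORDER} for s in strata
        }
        for a in _A_ORDER:
            probs = np.array(
                [spec.dipstick_probs[a].get(s, 0.0) for s in strata], dtype=float
            )
            probs = probs / probs.sum()
            split = rng.multinomial(true_counts[a], probs)
            for s, c in zip(strata, split):
                per_stratum[s][a] = int(c)
        for s in strata:
            marginals[(s, TestStrategy.UACR)] = _marginal(per_stratum[s])
            marginals[(s, TestStrategy.UPCR)] = _marginal(
                _upcr_counts(rng, per_stratum[s], spec.sensitivity)
            )
    return ReclassificationTable(marginals=marginals)


@dataclass(frozen=True)
class RecoveryReport:
    """Monte-Carlo check that sensitivity reconstruction is unbiased."""

    n_reps: int
    true_sensitivity: dict[AStage, float]
    mean_estimate: dict[AStage, float]
    bias: dict[AStage, float]
    mc_se: dict[AStage, float]
    within_mc_error: bool


def parameter_recovery_check(
    n_reps: int, spec: RetestSpec, z: float = 4.0
) -> RecoveryReport:
    """Regenerate ``n_reps`` cohorts and re-estimate the UPCR sensitivities.

    Estimates come from the classification module's nested reconstruction
    applied to each synthetic table; the report records mean estimate, bias
    against the generating value and the Monte-Carlo standard error of the
    mean.  ``within_mc_error`` is True when |bias| <= z * SE for every class.
    """
    if n_reps < 100:
        raise ValueError("n_reps must be >= 100 for a stable check")
    ests: dict[AStage, list[float]] = {AStage.A2: [], AStage.A3: []}
    for rep in range(n_reps):
        rep_spec = RetestSpec(
            n=spec.n, true_dist=spec.true_dist, sensitivity=spec.sensitivity,
            dipstick_probs=None, seed=spec.seed + rep,
        )
        table = synth_retest_counts(rep_spec)
        sens = upcr_sensitivities(table)
        for a in (AStage.A2, AStage.A3):
            ests[a].append(sens[a])

    mean = {a: float(np.mean(v)) for a, v in ests.items()}
    se = {
        a: float(np.std(v, ddof=1) / math.sqrt(n_reps)) for a, v in ests.items()
    }
    true = {a: float(spec.sensitivity[a]) for a in (AStage.A2, AStage.A3)}
    bias = {a: mean[a] - true[a] for a in mean}
    ok = all(abs(bias[a]) <= max(z * se[a], 1e-12) for a in mean)
    return RecoveryReport(
        n_reps=n_reps, true_sensitivity=true, mean_estimate=mean,
        bias=bias, mc_se=se, within_mc_error=ok,
    )
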