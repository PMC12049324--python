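"""Decision-tree test classification: who gets diagnosed with what.

All arms receive regular eGFR testing, so the kidney-function (G) stage is
always observed.  The arms differ only in how kidney damage (albuminuria)
is classified:

* **UACR** is treated as the diagnostic gold standard — the diagnosed
  albuminuria class equals the true class.
* **UPCR** under-detects.  The re-test data give only marginal class
  proportions per test, so the joint distribution is reconstructed under a
  *nested detection* assumption: every patient a UPCR test flags at class
  k is a true class-k patient (no over-diagnosis), and a missed class-k
  patient is classified one level lower.  Per-class sensitivity then
  follows from the ratio of marginal counts.
* **No urine testing** identifies nobody: every patient is managed as if
  normoalbuminuric (A1).

Treatment eligibility is keyed on the *diagnosed* albuminuria class and
the *true* G stage (eGFR is measured in every arm).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .states import (
    AStage,
    DipstickStratum,
    GStage,
    KdigoCell,
    Scenario,
    TestStrategy,
    Treatment,
)

_A_ORDER = (AStage.A1, AStage.A2, AStage.A3)


@dataclass(frozen=True)
class ClassMarginal:
    """Marginal albuminuria-class distribution of one test in one stratum."""

    counts: Mapping[AStage, float]
    proportions: Mapping[AStage, float]

    @property
    def n(self) -> float:
        return sum(self.counts.values())


@dataclass
class ReclassificationTable:
    """Per-stratum, per-strategy marginal classification of a cohort.

    Holds, for each dipstick stratum present and each of the UACR / UPCR
    strategies, the count and proportion of the cohort assigned to each
    albuminuria class.  UACR rows double as the stratum's true class
    distribution (gold standard).
    """

    marginals: dict[tuple[DipstickStratum, TestStrategy], ClassMarginal]

    def marginal(
        self, stratum: DipstickStratum, strategy: TestStrategy
    ) -> ClassMarginal:
        try:
            return self.marginals[(stratum, strategy)]
        except KeyError:
            raise KeyError(
                f"no re-test data for stratum={stratum.value} "
                f"strategy={strategy.value}"
            ) from None

    def strata(self) -> tuple[DipstickStratum, ...]:
        return tuple(dict.fromkeys(s for s, _ in self.marginals))

    def validate(self) -> list[str]:
        """Invariant check: proportions sum to 1 within printed rounding."""
        problems = []
        for (stratum, strategy), m in self.marginals.items():
            tot = sum(m.proportions.values())
            if abs(tot - 1.0) > 0.005:
                problems.append(
                    f"reclassification {stratum.value}/{strategy.value}: "
                    f"proportions sum to {tot:.4f}, not 1 +/- 0.005"
                )
            if any(v < 0 for v in m.counts.values()):
                problems.append(
                    f"reclassification {stratum.value}/{strategy.value}: "
                    "negative count"
                )
        return problems

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReclassificationTable":
        """Build from the CSV dialect (stratum,strategy,class,proportion,count)."""
        marginals: dict[tuple[DipstickStratum, TestStrategy], ClassMarginal] = {}
        for (stratum, strategy), grp in df.groupby(
            ["stratum", "strategy"], sort=False
        ):
            counts = {}
            props = {}
            for _, row in grp.iterrows():
                a = AStage(row["class"])
                counts[a] = float(row["count"])
                props[a] = float(row["proportion"])
            for a in _A_ORDER:
                counts.setdefault(a, 0.0)
                props.setdefault(a, 0.0)
            marginals[(DipstickStratum(stratum), TestStrategy(strategy))] = (
                ClassMarginal(counts=counts, proportions=props)
            )
        return cls(marginals=marginals)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (stratum, strategy), m in self.marginals.items():
            for a in _A_ORDER:
                rows.append(
                    {
                        "stratum": stratum.value,
                        "strategy": strategy.value,
                        "class": a.value,
                        "proportion": m.proportions[a],
                        "count": m.counts[a],
                    }
                )
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class DiagnosisDistribution:
    """P(diagnosed class | true albuminuria class) for one strategy/stratum."""

    probs: Mapping[AStage, Mapping[AStage, float]]

    def p(self, true: AStage, diagnosed: AStage) -> float:
        return self.probs[true].get(diagnosed, 0.0)

    def validate(self) -> None:
        for true, row in self.probs.items():
            tot = sum(row.values())
            if abs(tot - 1.0) > 1e-12:
                raise ValueError(
                    f"diagnosis row for true {true.value} sums to {tot!r}"
                )


_IDENTITY = DiagnosisDistribution(
    probs={a: {a: 1.0} for a in _A_ORDER}
)
_ALL_TO_A1 = DiagnosisDistribution(
    probs={a: {AStage.A1: 1.0} for a in _A_ORDER}
)


def upcr_sensitivities(
    reclass: ReclassificationTable,
    stratum: DipstickStratum = DipstickStratum.UNSTRATIFIED,
) -> dict[AStage, float]:
    """Per-class UPCR detection sensitivity under nested detection.

    Working top-down from the most severe class: the UPCR marginal count at
    A3 must come from true (UACR) A3 patients, giving the A3 sensitivity;
    missed A3 patients land in the ~A2 column, and the remainder of that
    column over the true A2 count gives the A2 sensitivity.  A1 is the
    fall-through class (sensitivity is not defined there; a true A1 patient
    is always classified ~A1).
    """
    ua = reclass.marginal(stratum, TestStrategy.UACR).counts
    up = reclass.marginal(stratum, TestStrategy.UPCR).counts

    if up[AStage.A3] > ua[AStage.A3] + 1e-9:
        raise ValueError(
            f"UPCR ~A3 count {up[AStage.A3]} exceeds true A3 count "
            f"{ua[AStage.A3]} in stratum {stratum.value}: violates nesting"
        )
    if ua[AStage.A3] > 0:
        s3 = up[AStage.A3] / ua[AStage.A3]
    else:
        s3 = 1.0
    demoted_to_a2 = ua[AStage.A3] - up[AStage.A3]

    native_a2 = up[AStage.A2] - demoted_to_a2
    if native_a2 < -1e-9 or native_a2 > ua[AStage.A2] + 1e-9:
        raise ValueError(
            f"UPCR ~A2 count {up[AStage.A2]} inconsistent with nested "
            f"detection in stratum {stratum.value} "
            f"(true A2 {ua[AStage.A2]}, demoted from A3 {demoted_to_a2})"
        )
    s2 = native_a2 / ua[AStage.A2] if ua[AStage.A2] > 0 else 1.0
    return {AStage.A2: min(max(s2, 0.0), 1.0), AStage.A3: min(max(s3, 0.0), 1.0)}


def detection_profile(
    reclass: ReclassificationTable,
    strategy: TestStrategy,
    stratum: DipstickStratum = DipstickStratum.UNSTRATIFIED,
) -> DiagnosisDistribution:
    """Diagnosed-class distribution conditional on true class.

    UACR is the gold standard (identity); no-testing sends everyone to
    A1-like management; UPCR detects class-k patients with the nested
    sensitivity and demotes misses one level.
    """
    if strategy is TestStrategy.UACR:
        return _IDENTITY
    if strategy is TestStrategy.NONE:
        return _ALL_TO_A1
    sens = upcr_sensitivities(reclass, stratum)
    s2, s3 = sens[AStage.A2], sens[AStage.A3]
    return DiagnosisDistribution(
        probs={
            AStage.A1: {AStage.A1: 1.0},
            AStage.A2: {AStage.A2: s2, AStage.A1: 1.0 - s2},
            AStage.A3: {AStage.A3: s3, AStage.A2: 1.0 - s3},
        }
    )


def diagnosed_cell_distribution(
    starting_cells: Mapping[KdigoCell, float],
    diag: DiagnosisDistribution,
) -> dict[tuple[KdigoCell, AStage], float]:
    """Joint mass over (true KDIGO cell, diagnosed albuminuria class).

    The true G stage is carried through unchanged (eGFR is tested in every
    arm); the diagnosed class attaches to the true A class independently
    of G.
    """
    joint: dict[tuple[KdigoCell, AStage], float] = {}
    for cell, mass in starting_cells.items():
        if mass == 0.0:
            continue
        for diagnosed, p in diag.probs[cell.a].items():
            if p == 0.0:
                continue
            key = (cell, diagnosed)
            joint[key] = joint.get(key, 0.0) + mass * p
    return joint


_G_ELIGIBLE = frozenset({GStage.G1, GStage.G2, GStage.G3a, GStage.G3b, GStage.G4})
_G_SGLT2I_A2 = frozenset({GStage.G3a, GStage.G3b, GStage.G4})


def treatment_assignment(
    true_cell: KdigoCell, diagnosed_class: AStage, scenario: Scenario
) -> Treatment:
    """Therapy assigned from the observed (G, diagnosed-A) pair.

    ACEi/ARB for G1–G4 with a diagnosed A2/A3 result; in the combination
    scenario, SGLT2i is added for G3a–G4 with diagnosed A2, or G1–G4 with
    diagnosed A3.
    """
    g = true_cell.g
    if g not in _G_ELIGIBLE or diagnosed_class is AStage.A1:
        return Treatment.NONE
    if scenario is Scenario.ACEI_ARB_PLUS_SGLT2I:
        if diagnosed_class is AStage.A3 or (
            diagnosed_class is AStage.A2 and g in _G_SGLT2I_A2
        ):
            return Treatment.ACEI_ARB_PLUS_SGLT2I
    return Treatment.ACEI_ARB


def treated_fraction(
    starting_cells: Mapping[KdigoCell, float],
    diag: DiagnosisDistribution,
    scenario: Scenario = Scenario.ACEI_ARB,
) -> float:
    """Fraction of the cohort assigned any active treatment."""
    joint = diagnosed_cell_distribution(starting_cells, diag)
    return sum(
        mass
        for (cell, d), mass in joint.items()
        if treatment_assignment(cell, d, scenario) is not Treatment.NONE
    )
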