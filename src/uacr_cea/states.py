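"""KDIGO staging primitives: eGFR stages, albuminuria classes, risk states.

Chronic kidney disease severity is staged on a two-dimensional grid: six
eGFR (kidney function) stages G1..G5 crossed with three albuminuria
(kidney damage) classes A1..A3.  The KDIGO "heatmap" assigns each of the
18 (G, A) cells a prognosis band — low, moderate, high or very high risk
of progression — and G5 is kidney failure (here, the dialysis-requiring
ESKD state).  The Markov model runs on the prognosis bands plus ESKD and
death; per-cell inputs (transition adjustment factors, mortality hazard
ratios) are keyed on the grid itself.
"""

from __future__ import annotations

import enum
from typing import NamedTuple


class GStage(str, enum.Enum):
    """eGFR stage (declining kidney function)."""

    G1 = "G1"
    G2 = "G2"
    G3a = "G3a"
    G3b = "G3b"
    G4 = "G4"
    G5 = "G5"


class AStage(str, enum.Enum):
    """Albuminuria class: normo- (A1), micro- (A2), macroalbuminuria (A3)."""

    A1 = "A1"
    A2 = "A2"
    A3 = "A3"


class KdigoCell(NamedTuple):
    """One cell of the 18-cell KDIGO grid."""

    g: GStage
    a: AStage

    def __str__(self) -> str:  # e.g. "G3aA2"
        return f"{self.g.value}{self.a.value}"

    @classmethod
    def parse(cls, label: str) -> "KdigoCell":
        for g in GStage:
            for a in AStage:
                if label == f"{g.value}{a.value}":
                    return cls(g, a)
        raise ValueError(f"not a KDIGO cell label: {label!r}")


ALL_CELLS: tuple[KdigoCell, ...] = tuple(
    KdigoCell(g, a) for g in GStage for a in AStage
)


class RiskState(str, enum.Enum):
    """Markov health state: four KDIGO prognosis bands, ESKD, death."""

    LOW = "LOW"
    MODERATE = "MODERATE"
    HIGH = "HIGH"
    VERY_HIGH = "VERY_HIGH"
    ESKD = "ESKD"
    DEATH = "DEATH"


#: The five living states, in worsening order (used for "worsening
#: direction" logic: any move to a later entry in this tuple, or to ESKD,
#: counts as progression).
LIVING_STATES: tuple[RiskState, ...] = (
    RiskState.LOW,
    RiskState.MODERATE,
    RiskState.HIGH,
    RiskState.VERY_HIGH,
    RiskState.ESKD,
)

CKD_STATES: tuple[RiskState, ...] = LIVING_STATES[:4]

ALL_STATES: tuple[RiskState, ...] = LIVING_STATES + (RiskState.DEATH,)

STATE_INDEX: dict[RiskState, int] = {s: i for i, s in enumerate(ALL_STATES)}

_SEVERITY: dict[RiskState, int] = {s: i for i, s in enumerate(LIVING_STATES)}

# Standard KDIGO 2012 prognosis bands.  Rows are G stages, columns A1..A3.
_HEATMAP: dict[GStage, tuple[RiskState, RiskState, RiskState]] = {
    GStage.G1: (RiskState.LOW, RiskState.MODERATE, RiskState.HIGH),
    GStage.G2: (RiskState.LOW, RiskState.MODERATE, RiskState.HIGH),
    GStage.G3a: (RiskState.MODERATE, RiskState.HIGH, RiskState.VERY_HIGH),
    GStage.G3b: (RiskState.HIGH, RiskState.VERY_HIGH, RiskState.VERY_HIGH),
    GStage.G4: (RiskState.VERY_HIGH, RiskState.VERY_HIGH, RiskState.VERY_HIGH),
    GStage.G5: (RiskState.ESKD, RiskState.ESKD, RiskState.ESKD),
}


def kdigo_risk_map(cell: KdigoCell) -> RiskState:
    """Map a KDIGO (G, A) cell to its prognosis band (G5 -> ESKD)."""
    return _HEATMAP[cell.g][list(AStage).index(cell.a)]


def cells_of_state(state: RiskState) -> tuple[KdigoCell, ...]:
    """All grid cells whose prognosis band is ``state`` (empty for DEATH)."""
    return tuple(c for c in ALL_CELLS if kdigo_risk_map(c) == state)


def is_worsening(frm: RiskState, to: RiskState) -> bool:
    """True if the ``frm -> to`` move is toward higher risk or ESKD.

    Improvement moves (e.g. MODERATE -> LOW) and remaining are not
    worsening; DEATH is handled separately from progression.
    """
    if frm == RiskState.DEATH or to == RiskState.DEATH:
        return False
    return _SEVERITY[to] > _SEVERITY[frm]


class TestStrategy(str, enum.Enum):
    """Urine testing arm: UACR, UPCR, or eGFR-only (no urine test)."""

    UACR = "UACR"
    UPCR = "UPCR"
    NONE = "NONE"


class DipstickStratum(str, enum.Enum):
    """Prior dipstick result defining a sub-cohort (or no stratification)."""

    UNSTRATIFIED = "UNSTRATIFIED"
    DIPSTICK_NEGATIVE = "DIPSTICK_NEGATIVE"
    DIPSTICK_TRACE = "DIPSTICK_TRACE"
    DIPSTICK_POSITIVE = "DIPSTICK_POSITIVE"


class Treatment(str, enum.Enum):
    """Assigned therapy following diagnosis."""

    NONE = "NONE"
    ACEI_ARB = "ACEI_ARB"
    ACEI_ARB_PLUS_SGLT2I = "ACEI_ARB_PLUS_SGLT2I"


class Scenario(str, enum.Enum):
    """Treatment paradigm: current standard of care or combination therapy."""

    ACEI_ARB = "ACEI_ARB"
    ACEI_ARB_PLUS_SGLT2I = "ACEI_ARB_PLUS_SGLT2I"
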