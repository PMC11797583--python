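"""OGTT-based classification of glucose-regulation disorders.

A 75 g oral glucose tolerance test yields a fasting plasma glucose (FPG) and
a 2-hour post-load glucose (2h-PG).  The pair is classified into five
mutually exclusive states using the 2012-Cuba / ALAD / ADA thresholds:

================  ==========================  ==========================
state             fasting glucose (mmol/L)    2-hour glucose (mmol/L)
================  ==========================  ==========================
normal            < 5.6                       < 7.8
AFG               5.6 ≤ FPG < 7.0             < 7.8
AGT               < 5.6                       7.8 ≤ 2h < 11.1
AFG + AGT         5.6 ≤ FPG < 7.0             7.8 ≤ 2h < 11.1
DM2               ≥ 7.0  — or —               ≥ 11.1
================  ==========================  ==========================

"Prediabetes" covers AFG, AGT and the mixed state; "dysglycemia" covers any
non-normal state (prediabetes or previously undiagnosed type 2 diabetes).
Values exactly on a threshold belong to the higher category (the defining
inequalities at lower bounds are all "≥").  The canonical unit is mmol/L;
mg/dL inputs convert with divisor 18.0.
"""
from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from typing import Mapping

import numpy as np

__all__ = [
    "GlycemicState",
    "GlycemicStatus",
    "GlucoseThresholds",
    "DEFAULT_THRESHOLDS",
    "classify_ogtt",
    "classify_ogtt_array",
    "mgdl_to_mmol",
    "prediabetes_flag",
    "outcome_rates",
]

MGDL_PER_MMOL = 18.0


class GlycemicState(str, enum.Enum):
    __str__ = str.__str__  # numpy/pandas see the plain code, not the repr

    NORMAL = "normal"
    AFG = "AFG"  # altered fasting glucose
    AGT = "AGT"  # altered glucose tolerance
    AFG_AGT = "AFG_AGT"  # mixed / double prediabetes
    DM2 = "DM2"  # previously undiagnosed type 2 diabetes


#: Severity order used by the generator's proportional-odds outcome link and
#: by monotonicity checks (AFG and AGT are exchangeable single disturbances).
STATE_ORDER: tuple[GlycemicState, ...] = (
    GlycemicState.NORMAL,
    GlycemicState.AFG,
    GlycemicState.AGT,
    GlycemicState.AFG_AGT,
    GlycemicState.DM2,
)

PREDIABETES_STATES = frozenset(
    {GlycemicState.AFG, GlycemicState.AGT, GlycemicState.AFG_AGT}
)


@dataclass(frozen=True)
class GlycemicStatus:
    state: GlycemicState
    dysglycemic: bool

    def __post_init__(self) -> None:
        if self.dysglycemic != (self.state is not GlycemicState.NORMAL):
            raise ValueError("dysglycemic flag inconsistent with state")


@dataclass(frozen=True)
class GlucoseThresholds:
    """Diagnostic cut-offs in mmol/L; overridable via JSON config."""

    fpg_lower: float = 5.6
    fpg_dm: float = 7.0
    g2h_lower: float = 7.8
    g2h_dm: float = 11.1

    def __post_init__(self) -> None:
        if not (0 < self.fpg_lower < self.fpg_dm):
            raise ValueError("require 0 < fpg_lower < fpg_dm")
        if not (0 < self.g2h_lower < self.g2h_dm):
            raise ValueError("require 0 < g2h_lower < g2h_dm")

    @classmethod
    def from_json(cls, s: str) -> "GlucoseThresholds":
        return cls(**json.loads(s))

    def to_json(self) -> str:
        return json.dumps(
            {
                "fpg_lower": self.fpg_lower,
                "fpg_dm": self.fpg_dm,
                "g2h_lower": self.g2h_lower,
                "g2h_dm": self.g2h_dm,
            }
        )


DEFAULT_THRESHOLDS = GlucoseThresholds()


def classify_ogtt(
    fpg: float, g2h: float, thresholds: GlucoseThresholds = DEFAULT_THRESHOLDS
) -> GlycemicStatus:
    """Classify one OGTT pair (mmol/L) into the five-state partition.

    Both measurements are required — there is no single-measure fallback,
    mirroring the study design in which every participant completed the OGTT.
    """
    if fpg is None or g2h is None:
        raise ValueError("both fasting and 2-hour glucose are required to classify an OGTT")
    for name, v in (("fpg", fpg), ("g2h", g2h)):
        if not (0 < v < 50):
            raise ValueError(f"{name} must lie in (0, 50) mmol/L, got {v}")
    t = thresholds
    if fpg >= t.fpg_dm or g2h >= t.g2h_dm:
        state = GlycemicState.DM2
    elif fpg >= t.fpg_lower and g2h >= t.g2h_lower:
        state = GlycemicState.AFG_AGT
    elif fpg >= t.fpg_lower:
        state = GlycemicState.AFG
    elif g2h >= t.g2h_lower:
        state = GlycemicState.AGT
    else:
        state = GlycemicState.NORMAL
    return GlycemicStatus(state=state, dysglycemic=state is not GlycemicState.NORMAL)


def classify_ogtt_array(
    fpg: np.ndarray,
    g2h: np.ndarray,
    thresholds: GlucoseThresholds = DEFAULT_THRESHOLDS,
) -> np.ndarray:
    """Vectorised :func:`classify_ogtt`; returns an object array of states."""
    fpg = np.asarray(fpg, dtype=float)
    g2h = np.asarray(g2h, dtype=float)
    if fpg.shape != g2h.shape:
        raise ValueError("fpg and g2h must have identical shapes")
    if np.isnan(fpg).any() or np.isnan(g2h).any():
        raise ValueError("both fasting and 2-hour glucose are required to classify an OGTT")
    if ((fpg <= 0) | (fpg >= 50) | (g2h <= 0) | (g2h >= 50)).any():
        raise ValueError("glucose values must lie in (0, 50) mmol/L")
    t = thresholds
    afg = (fpg >= t.fpg_lower) & (fpg < t.fpg_dm)
    agt = (g2h >= t.g2h_lower) & (g2h < t.g2h_dm)
    dm = (fpg >= t.fpg_dm) | (g2h >= t.g2h_dm)
    codes = np.select([dm, afg & agt, afg, agt], [4, 3, 1, 2], default=0)
    lut = np.array(
        [
            GlycemicState.NORMAL,
            GlycemicState.AFG,
            GlycemicState.AGT,
            GlycemicState.AFG_AGT,
            GlycemicState.DM2,
        ],
        dtype=object,
    )
    return lut[codes]


def mgdl_to_mmol(value: float) -> float:
    """Convert plasma glucose from mg/dL to mmol/L (divisor 18.0)."""
    arr = np.asarray(value, dtype=float)
    if (arr <= 0).any():
        raise ValueError(f"glucose in mg/dL must be positive, got {value}")
    out = arr / MGDL_PER_MMOL
    return float(out) if np.isscalar(value) or arr.ndim == 0 else out


def prediabetes_flag(status: GlycemicStatus) -> bool:
    """True iff the state is one of the prediabetes forms (AFG, AGT or both).

    Diabetes is deliberately excluded: prediabetes and undiagnosed DM2 are
    the two disjoint components of dysglycemia.
    """
    return status.state in PREDIABETES_STATES


def outcome_rates(counts: Mapping[GlycemicState, int]) -> dict[str, float]:
    """Cohort-level outcome fractions from per-state counts.

    Returns ``dysglycemia`` (any non-normal state), ``prediabetes``
    (AFG + AGT + mixed) and ``dm2`` as fractions of the total.
    """
    counts = {GlycemicState(k): int(v) for k, v in counts.items()}
    if any(v < 0 for v in counts.values()):
        raise ValueError("state counts must be non-negative")
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no records counted")
    pre = sum(counts.get(s, 0) for s in PREDIABETES_STATES)
    dm2 = counts.get(GlycemicState.DM2, 0)
    return {
        "n": total,
        "dysglycemia": (pre + dm2) / total,
        "prediabetes": pre / total,
        "dm2": dm2 / total,
    }
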