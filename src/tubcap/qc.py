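"""Acceptance criteria for sucrose-solution measurements.

A measurement is analyzable only when the tubular system is thoroughly
washed with the low-conductivity solution; incomplete exchange shows up in
the resistance combinations and in the balance of the two exponential
components.  The acceptance rules (all strict inequalities) are:

    R_2 > 20 MOhm,  R_1/R_2 > 0.08,  R_a_suc − R_a_Tyr > 3 MOhm,
    J_1/J_2 > 0.16,  tau_1/tau_2 < 10,

with tau_1 the longer time constant and R_a_suc/R_a_Tyr the access
resistances in sucrose and Tyrode solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .biexp import BiexpParams
from .extract import ExtractionResult

__all__ = ["QCResult", "DEFAULT_THRESHOLDS", "evaluate_criteria"]

DEFAULT_THRESHOLDS = {
    "r2_min": 20.0,        # MOhm, R_2 must exceed
    "r1_r2_ratio": 0.08,   # R_1/R_2 must exceed
    "ra_shift": 3.0,       # MOhm, R_a_suc - R_a_Tyr must exceed
    "amp_ratio": 0.16,     # J_1/J_2 must exceed
    "tau_ratio": 10.0,     # tau_1/tau_2 must stay below
}


@dataclass
class QCResult:
    """Outcome of the five acceptance criteria.

    Each flag is True (passed), False (failed) or None (not evaluable —
    only ``ra_shift`` when no Tyrode reference is available).  ``passed``
    is the conjunction of the evaluable flags; ``conditional`` marks a
    verdict reached without the Tyrode access-resistance criterion.
    """

    flags: dict = field(default_factory=dict)
    values: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    passed: bool = False
    conditional: bool = False
    R_a_suc: float | None = None
    R_a_Tyr: float | None = None

    def to_dict(self) -> dict:
        return {
            "flags": dict(self.flags),
            "values": dict(self.values),
            "thresholds": dict(self.thresholds),
            "passed": self.passed,
            "conditional": self.conditional,
            "R_a_suc": self.R_a_suc,
            "R_a_Tyr": self.R_a_Tyr,
        }


def evaluate_criteria(
    result: ExtractionResult,
    p: BiexpParams,
    R_a_Tyr: float | None = None,
    thresholds: dict | None = None,
) -> QCResult:
    """Evaluate the five acceptance criteria on an extraction result.

    All inequalities are strict, exactly as stated.  When ``R_a_Tyr`` is
    missing the access-resistance-shift criterion is marked indeterminate
    and excluded from the conjunction (conditional pass).
    """
    thr = dict(DEFAULT_THRESHOLDS)
    if thresholds:
        thr.update(thresholds)
    if result.combined is None:
        raise ValueError("extraction result lacks combined resistances")

    R_1, R_2 = result.combined.R_1, result.combined.R_2
    values = {
        "r2_min": R_2,
        "r1_r2_ratio": R_1 / R_2,
        "ra_shift": result.R_a - R_a_Tyr if R_a_Tyr is not None else None,
        "amp_ratio": p.J_1 / p.J_2,
        "tau_ratio": p.tau_1 / p.tau_2,
    }
    flags = {
        "r2_min": values["r2_min"] > thr["r2_min"],
        "r1_r2_ratio": values["r1_r2_ratio"] > thr["r1_r2_ratio"],
        "ra_shift": (
            values["ra_shift"] > thr["ra_shift"]
            if values["ra_shift"] is not None else None
        ),
        "amp_ratio": values["amp_ratio"] > thr["amp_ratio"],
        "tau_ratio": values["tau_ratio"] < thr["tau_ratio"],
    }
    evaluable = [v for v in flags.values() if v is not None]
    return QCResult(
        flags=flags,
        values=values,
        thresholds=thr,
        passed=all(evaluable),
        conditional=flags["ra_shift"] is None,
        R_a_suc=result.R_a,
        R_a_Tyr=R_a_Tyr,
    )
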