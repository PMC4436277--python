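"""Incremental cost-effectiveness calculus.

ICER = (cost_comparator - cost_reference) / (QALY_comparator - QALY_reference),
defined only when both deltas share a sign and the QALY delta is nonzero.
A comparator that is no more costly and no less effective (one strictly)
*dominates* the reference; the converse is *dominated*; equal on both axes is
*equivalent*.  A willingness-to-pay threshold (default $50,000/QALY) turns an
ICER or dominance label into a cost-effectiveness verdict.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .engine import ArmResult
from .params import Treatment

__all__ = [
    "DOMINANT",
    "DOMINATED",
    "EQUIVALENT",
    "Verdict",
    "CEAComparison",
    "icer",
    "decide",
    "compare",
    "round_to_100",
]

# Dominance labels returned by icer() in place of a number.
DOMINANT = "dominant"
DOMINATED = "dominated"
EQUIVALENT = "equivalent"


class Verdict(str, enum.Enum):
    COST_EFFECTIVE = "cost_effective"
    NOT_COST_EFFECTIVE = "not_cost_effective"


def icer(
    ref_cost: float, ref_qaly: float, comp_cost: float, comp_qaly: float
) -> float | str:
    """ICER of comparator vs reference, or a dominance label.

    Returns ``DOMINANT`` when the comparator is cheaper-or-equal and
    better-or-equal (one strictly), ``DOMINATED`` for the converse,
    ``EQUIVALENT`` when both deltas are exactly zero, and otherwise the
    numeric quotient delta_cost / delta_qaly (full precision; see
    :func:`round_to_100` for reporting).
    """
    dc = comp_cost - ref_cost
    dq = comp_qaly - ref_qaly
    if dc == 0.0 and dq == 0.0:
        return EQUIVALENT
    if dc <= 0.0 and dq >= 0.0:
        return DOMINANT
    if dc >= 0.0 and dq <= 0.0:
        return DOMINATED
    return dc / dq


def decide(icer_or_label: float | str, threshold: float) -> Verdict:
    """Cost-effectiveness verdict at a willingness-to-pay threshold.

    Dominant (and equivalent) comparators are cost-effective; dominated ones
    are not.  For a numeric ICER this function assumes the north-east
    quadrant (more costly, more effective): cost-effective iff
    ICER <= threshold, with exact equality counting as cost-effective.
    The south-west quadrant (cheaper and less effective, where the verdict
    flips to ICER >= threshold) is handled by :func:`compare`, which knows
    the sign of the deltas.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if icer_or_label in (DOMINANT, EQUIVALENT):
        return Verdict.COST_EFFECTIVE
    if icer_or_label == DOMINATED:
        return Verdict.NOT_COST_EFFECTIVE
    value = float(icer_or_label)
    return Verdict.COST_EFFECTIVE if value <= threshold else Verdict.NOT_COST_EFFECTIVE


@dataclass(frozen=True)
class CEAComparison:
    """One comparator-vs-reference incremental comparison."""

    reference: Treatment
    comparator: Treatment
    delta_cost: float
    delta_qaly: float
    icer: float | str  # numeric or dominance label
    verdict: Verdict
    threshold: float

    @property
    def icer_rounded_100(self) -> float | str:
        return round_to_100(self.icer)


def compare(
    ref: ArmResult, comp: ArmResult, threshold: float = 50_000.0
) -> CEAComparison:
    """Build a :class:`CEAComparison` from two arm results.

    The south-west quadrant (comparator cheaper and less effective) is
    cost-effective iff the ICER is at least the threshold.
    """
    label = icer(ref.mean_cost, ref.mean_qaly, comp.mean_cost, comp.mean_qaly)
    dc = comp.mean_cost - ref.mean_cost
    dq = comp.mean_qaly - ref.mean_qaly
    if isinstance(label, str):
        verdict = decide(label, threshold)
    elif dq < 0.0:  # south-west: cheaper and worse
        verdict = (
            Verdict.COST_EFFECTIVE if label >= threshold else Verdict.NOT_COST_EFFECTIVE
        )
    else:
        verdict = decide(label, threshold)
    return CEAComparison(
        reference=ref.arm,
        comparator=comp.arm,
        delta_cost=dc,
        delta_qaly=dq,
        icer=label,
        verdict=verdict,
        threshold=threshold,
    )


def round_to_100(icer_or_label: float | str) -> float | str:
    """Round a numeric ICER to the nearest $100 (labels pass through)."""
    if isinstance(icer_or_label, str):
        return icer_or_label
    return round(icer_or_label / 100.0) * 100.0
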