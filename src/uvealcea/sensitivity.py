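"""One-way (tornado) sensitivity analysis over all 21 model parameters.

Each registry entry carries a low and a high value; for each extreme the
parameter is set in every arm it touches (transition-probability extremes are
shared across arms, so the same low/high applies whichever arm is being
varied; shared costs and utilities move all arms together), all three arms
are re-run with the deterministic cohort engine, and both comparators' ICERs
against enucleation are recomputed.  A parameter is flagged *sensitive* when
the optimal strategy at the willingness-to-pay threshold changes, or any
dominance relation against the reference appears, at either extreme.

The registry follows the published grid structure: 9 transition
probabilities (3 per arm), 7 costs (3 treatment costs, the local-recurrence
cost varied separately for enucleation versus plaque + proton jointly, and
2 end-of-life costs), and 5 utilities (3 post-treatment, shared
local-recurrence and metastasis utilities) - 21 parameters, 84 grid cells.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, replace
from typing import Callable

import pandas as pd

from . import cea
from .engine import run_arm
from .lifetable import LifeTable
from .params import (
    ModelConfig,
    ParameterBundle,
    RangedParameter,
    Treatment,
)

__all__ = ["SAParameter", "SACell", "SAGrid", "default_registry", "one_way_sa",
           "tornado_ordering"]

_E = Treatment.ENUCLEATION
_B = Treatment.PLAQUE_BRACHYTHERAPY
_P = Treatment.PROTON_BEAM_THERAPY
_COMPARATORS = (_B, _P)

# Display labels for grid exports, mirroring the published table wording.
_LABEL_DOMINATES = "Dominates"
_LABEL_DOMINATED = "Dominated"


@dataclass(frozen=True)
class SAParameter:
    """One registry entry: identifier, range, and how to apply it."""

    identifier: str
    low: float
    high: float
    affected_arms: tuple[Treatment, ...]
    _apply: Callable[[ParameterBundle, float], ParameterBundle]

    def apply(self, bundle: ParameterBundle, value: float) -> ParameterBundle:
        """Return a copy of ``bundle`` with this parameter set to ``value``."""
        return self._apply(bundle, value)


@dataclass(frozen=True)
class SACell:
    """One grid cell: a comparator's ICER (or label) at one extreme."""

    parameter: str
    extreme: str  # "low" | "high"
    comparator: Treatment
    icer: float | str  # numeric, "Dominates", "Dominated", or "error: ..."


@dataclass(frozen=True)
class SAGrid:
    """Complete one-way grid plus per-parameter sensitivity flags."""

    cells: dict[tuple[str, str, Treatment], float | str]
    sensitive: dict[str, bool]
    base_icers: dict[Treatment, float | str]
    parameters: tuple[SAParameter, ...]

    @property
    def sensitive_parameters(self) -> tuple[str, ...]:
        return tuple(p.identifier for p in self.parameters if self.sensitive[p.identifier])

    @property
    def insensitive_parameters(self) -> tuple[str, ...]:
        return tuple(
            p.identifier for p in self.parameters if not self.sensitive[p.identifier]
        )

    def dominance_count(self, comparator: Treatment, label: str) -> int:
        """Number of grid cells where ``comparator`` carries ``label``."""
        return sum(
            1
            for (_, _, c), v in self.cells.items()
            if c is comparator and v == label
        )

    def to_frame(self) -> pd.DataFrame:
        """Wide table shaped like the published grid: one row per parameter."""
        rows = []
        for p in self.parameters:
            rows.append(
                {
                    "parameter": p.identifier,
                    "low_plaque": self.cells[(p.identifier, "low", _B)],
                    "low_proton": self.cells[(p.identifier, "low", _P)],
                    "high_plaque": self.cells[(p.identifier, "high", _B)],
                    "high_proton": self.cells[(p.identifier, "high", _P)],
                    "sensitive": self.sensitive[p.identifier],
                }
            )
        return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Registry construction
# --------------------------------------------------------------------------

def _replace_in(mapping: dict, arm: Treatment, **field_updates) -> dict:
    new = dict(mapping)
    new[arm] = replace(mapping[arm], **field_updates)
    return new


def _set_transition(arm: Treatment, field: str):
    def apply(b: ParameterBundle, v: float) -> ParameterBundle:
        old: RangedParameter = getattr(b.transitions[arm], field)
        new = RangedParameter(v, min(v, old.low), max(v, old.high))
        return dataclasses.replace(
            b, transitions=_replace_in(b.transitions, arm, **{field: new})
        )

    return apply


def _set_cost(arms: tuple[Treatment, ...], field: str):
    def apply(b: ParameterBundle, v: float) -> ParameterBundle:
        costs = dict(b.costs)
        for arm in arms:
            old: RangedParameter = getattr(costs[arm], field)
            new = RangedParameter(v, min(v, old.low), max(v, old.high))
            costs = _replace_in(costs, arm, **{field: new})
        return dataclasses.replace(b, costs=costs)

    return apply


def _set_utility(arms: tuple[Treatment, ...], field: str):
    def apply(b: ParameterBundle, v: float) -> ParameterBundle:
        utils = dict(b.utilities)
        for arm in arms:
            old: RangedParameter = getattr(utils[arm], field)
            new = RangedParameter(v, min(v, old.low), max(v, old.high))
            utils = _replace_in(utils, arm, **{field: new})
        return dataclasses.replace(b, utilities=utils)

    return apply


def default_registry(bundle: ParameterBundle) -> tuple[SAParameter, ...]:
    """The 21-parameter registry with the published low/high values.

    Probability lows/highs are treatment-agnostic (shared across arms);
    cost and post-treatment-utility ranges are the per-arm tabulated
    Min/Max; shared utilities and end-of-life costs carry their own ranges.
    """
    ALL = (_E, _B, _P)
    entries: list[SAParameter] = []
    shared_prob = {
        "p_post_to_lr": (0.001, 0.030),
        "p_post_to_met": (0.001, 0.083),
        "p_lr_to_met": (0.001, 0.202),
    }
    prob_names = {
        "p_post_to_lr": "lr_probability",
        "p_post_to_met": "met_probability",
        "p_lr_to_met": "met_probability_from_lr",
    }
    for field, (lo, hi) in shared_prob.items():
        for arm in ALL:
            entries.append(
                SAParameter(
                    f"{prob_names[field]}.{arm.value}",
                    lo,
                    hi,
                    (arm,),
                    _set_transition(arm, field),
                )
            )
    eol_other = bundle.costs[_E].eol_other_cost
    eol_disease = bundle.costs[_E].eol_disease_cost
    entries.append(
        SAParameter(
            "eol_cost.other", eol_other.low, eol_other.high, ALL,
            _set_cost(ALL, "eol_other_cost"),
        )
    )
    entries.append(
        SAParameter(
            "eol_cost.disease", eol_disease.low, eol_disease.high, ALL,
            _set_cost(ALL, "eol_disease_cost"),
        )
    )
    for arm in ALL:
        tc = bundle.costs[arm].treatment_cost
        entries.append(
            SAParameter(
                f"treatment_cost.{arm.value}", tc.low, tc.high, (arm,),
                _set_cost((arm,), "treatment_cost"),
            )
        )
    lrc = bundle.costs[_E].local_recurrence_cost
    entries.append(
        SAParameter(
            "lr_cost.enucleation", lrc.low, lrc.high, (_E,),
            _set_cost((_E,), "local_recurrence_cost"),
        )
    )
    entries.append(
        SAParameter(
            "lr_cost.plaque_proton", lrc.low, lrc.high, (_B, _P),
            _set_cost((_B, _P), "local_recurrence_cost"),
        )
    )
    for arm in ALL:
        up = bundle.utilities[arm].u_post_treatment
        entries.append(
            SAParameter(
                f"utility.post_treatment.{arm.value}", up.low, up.high, (arm,),
                _set_utility((arm,), "u_post_treatment"),
            )
        )
    ulr = bundle.utilities[_E].u_local_recurrence
    umet = bundle.utilities[_E].u_metastasis
    entries.append(
        SAParameter(
            "utility.local_recurrence", ulr.low, ulr.high, ALL,
            _set_utility(ALL, "u_local_recurrence"),
        )
    )
    entries.append(
        SAParameter(
            "utility.metastasis", umet.low, umet.high, ALL,
            _set_utility(ALL, "u_metastasis"),
        )
    )
    assert len(entries) == 21
    return tuple(entries)


# --------------------------------------------------------------------------
# Grid evaluation
# --------------------------------------------------------------------------

def _grid_label(comparison: cea.CEAComparison) -> float | str:
    if comparison.icer == cea.DOMINANT:
        return _LABEL_DOMINATES
    if comparison.icer == cea.DOMINATED:
        return _LABEL_DOMINATED
    if comparison.icer == cea.EQUIVALENT:
        return cea.EQUIVALENT
    return float(comparison.icer)


def _evaluate(
    bundle: ParameterBundle, life: LifeTable, config: ModelConfig
) -> dict[Treatment, cea.CEAComparison]:
    """Run all three arms (cohort engine) and compare each comparator."""
    results = {arm: run_arm(arm, bundle, life, config) for arm in Treatment}
    return {
        c: cea.compare(results[_E], results[c], config.wtp_threshold)
        for c in _COMPARATORS
    }


def _optimal_strategy(
    comparisons: dict[Treatment, cea.CEAComparison]
) -> Treatment:
    """Strategy adopted at the threshold: the reference unless a comparator
    is cost-effective; among cost-effective comparators, the one with the
    larger QALY gain."""
    winners = [
        c
        for c, cmp_ in comparisons.items()
        if cmp_.verdict is cea.Verdict.COST_EFFECTIVE
    ]
    if not winners:
        return _E
    return max(winners, key=lambda c: comparisons[c].delta_qaly)


def one_way_sa(
    bundle: ParameterBundle,
    life: LifeTable,
    config: ModelConfig | None = None,
    registry: tuple[SAParameter, ...] | None = None,
) -> SAGrid:
    """Evaluate the full one-way grid with the cohort engine.

    Every perturbation re-runs all three arms (a shared parameter moves the
    reference arm too).  A perturbed configuration that fails to run is
    recorded as an ``"error: ..."`` cell rather than raising.
    """
    config = config or bundle.config
    registry = registry if registry is not None else default_registry(bundle)
    base = _evaluate(bundle, life, config)
    base_optimal = _optimal_strategy(base)
    base_dominance = {
        c: base[c].icer if isinstance(base[c].icer, str) else None
        for c in _COMPARATORS
    }

    cells: dict[tuple[str, str, Treatment], float | str] = {}
    sensitive: dict[str, bool] = {}
    for p in registry:
        flag = False
        for extreme, value in (("low", p.low), ("high", p.high)):
            try:
                perturbed = p.apply(bundle, value)
                comparisons = _evaluate(perturbed, life, config)
            except Exception as exc:
                for c in _COMPARATORS:
                    cells[(p.identifier, extreme, c)] = f"error: {exc}"
                flag = True
                continue
            for c in _COMPARATORS:
                cells[(p.identifier, extreme, c)] = _grid_label(comparisons[c])
            dominance = {
                c: comparisons[c].icer if isinstance(comparisons[c].icer, str) else None
                for c in _COMPARATORS
            }
            if (
                _optimal_strategy(comparisons) != base_optimal
                or dominance != base_dominance
            ):
                flag = True
        sensitive[p.identifier] = flag
    base_icers = {c: _grid_label(base[c]) for c in _COMPARATORS}
    return SAGrid(cells=cells, sensitive=sensitive, base_icers=base_icers,
                  parameters=tuple(registry))


def tornado_ordering(grid: SAGrid) -> list[str]:
    """Parameters ranked by decreasing ICER swing across their range.

    The swing is the largest, over the two comparators, absolute difference
    between the high- and low-extreme ICERs.  Dominance labels are mapped to
    signed infinities (Dominates -> -inf, Dominated -> +inf), so any
    parameter whose extremes straddle a dominance change ranks ahead of all
    purely numeric swings.  Ties preserve registry order.
    """

    def as_number(v: float | str) -> float:
        if v == _LABEL_DOMINATES:
            return -math.inf
        if v == _LABEL_DOMINATED:
            return math.inf
        if isinstance(v, str):  # equivalent / error cells carry no swing
            return math.nan
        return float(v)

    def swing(identifier: str) -> float:
        widths = []
        for c in _COMPARATORS:
            lo = as_number(grid.cells[(identifier, "low", c)])
            hi = as_number(grid.cells[(identifier, "high", c)])
            if math.isnan(lo) or math.isnan(hi):
                continue
            w = abs(hi - lo)
            widths.append(0.0 if math.isnan(w) else w)  # inf - inf -> nan -> 0
        return max(widths, default=0.0)

    ids = [p.identifier for p in grid.parameters]
    return sorted(ids, key=lambda i: -swing(i))
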