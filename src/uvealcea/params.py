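"""Model parameters for the intraocular-melanoma cost-utility model.

Holds the treatment-arm transition probabilities, one-time state-entry costs
(2011 USD) and health-state utilities, each with a base-case value and a
plausible (low, high) range used by the one-way sensitivity analysis, plus
the derivation utilities used to build them: sample-size-weighted pooling of
study estimates, relative-risk scaling of an annual probability, and the
Medicare spending-per-beneficiary cost-range construction.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, asdict, replace
from importlib import resources
from typing import Iterable, Sequence

import yaml

__all__ = [
    "Treatment",
    "RangedParameter",
    "TransitionProbabilitySet",
    "CostSet",
    "UtilitySet",
    "ModelConfig",
    "ParameterBundle",
    "Violation",
    "pooled_weighted_mean",
    "apply_relative_risk",
    "scale_cost_range",
    "default_parameters",
    "validate_parameters",
    "load_bundle",
    "save_bundle",
]


class Treatment(str, enum.Enum):
    """The three treatment strategies compared by the model.

    Enucleation (surgical removal of the eye) is the designated reference
    comparator for all incremental cost-effectiveness ratios.
    """

    ENUCLEATION = "enucleation"
    PLAQUE_BRACHYTHERAPY = "plaque_brachytherapy"
    PROTON_BEAM_THERAPY = "proton_beam_therapy"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Reference comparator for ICERs.
REFERENCE: Treatment = Treatment.ENUCLEATION


@dataclass(frozen=True)
class RangedParameter:
    """A base-case value with its (low, high) sensitivity-analysis range."""

    base: float
    low: float
    high: float

    def __post_init__(self) -> None:
        if not (self.low <= self.base <= self.high):
            raise ValueError(
                f"range must satisfy low <= base <= high, got "
                f"({self.low}, {self.base}, {self.high})"
            )

    def at(self, extreme: str) -> float:
        """Return the value at ``'low'``, ``'base'`` or ``'high'``."""
        try:
            return {"low": self.low, "base": self.base, "high": self.high}[extreme]
        except KeyError:
            raise ValueError(f"unknown extreme {extreme!r}") from None


@dataclass(frozen=True)
class TransitionProbabilitySet:
    """Annual transition probabilities for one treatment arm.

    The three event probabilities are: post-treatment to local recurrence,
    post-treatment to metastasis, and local recurrence to metastasis.
    The probability of remaining in post-treatment or local recurrence is the
    residual (1 minus the outgoing event probabilities and the age-specific
    other-cause death probability), so it is not stored.
    """

    p_post_to_lr: RangedParameter
    p_post_to_met: RangedParameter
    p_lr_to_met: RangedParameter


@dataclass(frozen=True)
class CostSet:
    """One-time state-entry costs for one treatment arm, 2011 USD.

    Each cost is paid once, on entry into the state: the treatment cost at
    model entry, the local-recurrence cost on entering local recurrence
    (salvage treatment), and an end-of-life cost on dying of disease or of
    other causes.  End-of-life costs are shared across arms at base case.
    """

    treatment_cost: RangedParameter
    local_recurrence_cost: RangedParameter
    eol_disease_cost: RangedParameter
    eol_other_cost: RangedParameter


@dataclass(frozen=True)
class UtilitySet:
    """Health-state utility weights (0 = death, 1 = perfect health)."""

    u_post_treatment: RangedParameter
    u_local_recurrence: RangedParameter
    u_metastasis: RangedParameter


class EventTiming(str, enum.Enum):
    """When, within a yearly cycle, entry events are discounted.

    ``mid_cycle`` places transitions halfway through the cycle (the
    half-cycle assumption), so an entry during cycle t carries the factor
    (1+r)^-(t+0.5).  ``cycle_start`` and ``cycle_end`` use t and t+1.
    """

    MID_CYCLE = "mid_cycle"
    CYCLE_START = "cycle_start"
    CYCLE_END = "cycle_end"


@dataclass(frozen=True)
class ModelConfig:
    """Run-level settings for the Markov engines."""

    start_age: int = 59
    horizon: int = 5
    cycle_length: float = 1.0  # years; fixed at 1 in this model
    discount_rate: float = 0.03
    wtp_threshold: float = 50_000.0
    cohort_size: int = 10_000
    n_replications: int = 1_000
    rng_seed: int = 0
    engine: str = "cohort"  # "cohort" | "microsim"
    half_cycle: bool = True
    cost_timing: EventTiming = EventTiming.MID_CYCLE
    interval_method: str = "percentile"  # "percentile" | "normal"

    def __post_init__(self) -> None:
        if self.horizon < 1:
            raise ValueError("horizon must be >= 1")
        if not 0.0 <= self.discount_rate < 1.0:
            raise ValueError("discount_rate must be in [0, 1)")
        if self.cohort_size < 1 or self.n_replications < 1:
            raise ValueError("cohort_size and n_replications must be >= 1")
        if self.engine not in ("cohort", "microsim"):
            raise ValueError(f"unknown engine {self.engine!r}")


@dataclass(frozen=True)
class ParameterBundle:
    """Full model parameterization: one entry of each set per treatment arm."""

    transitions: dict[Treatment, TransitionProbabilitySet]
    costs: dict[Treatment, CostSet]
    utilities: dict[Treatment, UtilitySet]
    config: ModelConfig = field(default_factory=ModelConfig)
    metadata: dict = field(default_factory=dict)

    def arms(self) -> tuple[Treatment, ...]:
        return tuple(Treatment)


# --------------------------------------------------------------------------
# Derivation utilities
# --------------------------------------------------------------------------

def pooled_weighted_mean(values: Sequence[float], weights: Sequence[float]) -> float:
    """Sample-size-weighted mean used to pool per-study probability estimates.

    Returns sum(w_i * v_i) / sum(w_i).  Weights must be strictly positive.
    """
    values = list(values)
    weights = list(weights)
    if not values or len(values) != len(weights):
        raise ValueError("values and weights must be non-empty and equal length")
    if any(w <= 0 for w in weights):
        raise ValueError("weights must be strictly positive")
    return sum(w * v for v, w in zip(values, weights)) / sum(weights)


def apply_relative_risk(p: float, rr: float) -> float:
    """Scale an annual probability by a relative risk on the probability scale.

    Used to derive the local-recurrence-to-metastasis probability from the
    post-treatment-to-metastasis probability (RR = 1.5 in the default
    parameterization; note the bundled base-case values are the published
    pooled estimates, not re-derived through this helper).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be a probability, got {p}")
    if rr <= 0:
        raise ValueError(f"relative risk must be positive, got {rr}")
    out = rr * p
    if out > 1.0:
        raise ValueError(f"rr * p = {out} exceeds 1")
    return out


def scale_cost_range(
    base_cost: float, low_factor: float = 0.70, high_factor: float = 1.54
) -> tuple[int, int]:
    """Build a cost sensitivity range from regional Medicare spending variation.

    Base-case costs are scaled by the low (0.70) and high (1.54) ratios of
    Medicare spending per beneficiary; returns whole-dollar (low, high).
    """
    if base_cost < 0:
        raise ValueError("base_cost must be nonnegative")
    return round(base_cost * low_factor), round(base_cost * high_factor)


# --------------------------------------------------------------------------
# Default (base-case) parameter bundle
# --------------------------------------------------------------------------

def default_parameters() -> ParameterBundle:
    """Literature-based base-case parameter bundle with sensitivity ranges.

    Probabilities are annual; costs are 2011 USD; utilities are preference
    weights.  The plaque-brachytherapy treatment cost is the sum of its
    hospital (16,444) and physician (1,778) components, 18,222; the
    inflation-adjusted printed total (19,108) is kept in ``metadata`` and is
    the basis of that arm's sensitivity range.
    """
    E, B, P = (
        Treatment.ENUCLEATION,
        Treatment.PLAQUE_BRACHYTHERAPY,
        Treatment.PROTON_BEAM_THERAPY,
    )
    rp = RangedParameter

    transitions = {
        E: TransitionProbabilitySet(
            p_post_to_lr=rp(0.002, 0.001, 0.030),
            p_post_to_met=rp(0.047, 0.001, 0.083),
            p_lr_to_met=rp(0.074, 0.001, 0.202),
        ),
        B: TransitionProbabilitySet(
            p_post_to_lr=rp(0.021, 0.001, 0.030),
            p_post_to_met=rp(0.029, 0.001, 0.083),
            p_lr_to_met=rp(0.045, 0.001, 0.202),
        ),
        P: TransitionProbabilitySet(
            p_post_to_lr=rp(0.009, 0.001, 0.030),
            p_post_to_met=rp(0.039, 0.001, 0.083),
            p_lr_to_met=rp(0.061, 0.001, 0.202),
        ),
    }

    lr_cost = rp(8_678, 6_075, 13_364)
    eol_disease = rp(76_645, 53_652, 118_035)
    eol_other = rp(42_787, 29_952, 65_894)
    costs = {
        E: CostSet(rp(8_678, 6_075, 13_364), lr_cost, eol_disease, eol_other),
        B: CostSet(rp(18_222, 13_376, 29_426), lr_cost, eol_disease, eol_other),
        P: CostSet(rp(12_438, 8_707, 19_155), lr_cost, eol_disease, eol_other),
    }

    u_lr = rp(0.52, 0.47, 0.57)
    u_met = rp(0.23, 0.18, 0.28)
    utilities = {
        E: UtilitySet(rp(0.71, 0.66, 0.76), u_lr, u_met),
        B: UtilitySet(rp(0.71, 0.66, 0.76), u_lr, u_met),
        P: UtilitySet(rp(0.706, 0.656, 0.756), u_lr, u_met),
    }

    metadata = {
        "currency": "2011 USD",
        "plaque_brachytherapy_cost_components": {
            "hospital": 16_444,
            "physician": 1_778,
            "printed_total": 19_108,
        },
        "lr_to_met_relative_risk": 1.5,
    }
    return ParameterBundle(transitions, costs, utilities, ModelConfig(), metadata)


# --------------------------------------------------------------------------
# Validation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Violation:
    """One structured validation failure."""

    location: str
    message: str

    def __str__(self) -> str:
        return f"{self.location}: {self.message}"


def _check_ranged(
    out: list[Violation], loc: str, p: RangedParameter, kind: str
) -> None:
    if not (p.low <= p.base <= p.high):
        out.append(Violation(loc, f"low <= base <= high violated: {p}"))
    vals = (p.low, p.base, p.high)
    if kind == "probability" and not all(0.0 <= v <= 1.0 for v in vals):
        out.append(Violation(loc, f"probability outside [0, 1]: {p}"))
    if kind in ("cost", "utility") and any(v < 0 for v in vals):
        out.append(Violation(loc, f"negative {kind}: {p}"))
    if kind == "utility" and not all(v <= 1.0 for v in vals):
        out.append(Violation(loc, f"utility above 1: {p}"))


def validate_parameters(bundle: ParameterBundle, life_table) -> list[Violation]:
    """Check every parameter invariant; return a (possibly empty) violation list.

    Never raises.  Beyond per-parameter range checks, verifies that for every
    cycle in the horizon the outgoing probabilities from each alive state
    (event probabilities plus the age-specific other-cause death probability)
    sum to at most 1, so the residual stay probability is nonnegative.
    """
    out: list[Violation] = []
    cfg = bundle.config
    for arm in Treatment:
        tp = bundle.transitions[arm]
        for name in ("p_post_to_lr", "p_post_to_met", "p_lr_to_met"):
            _check_ranged(out, f"{arm.value}.{name}", getattr(tp, name), "probability")
        cs = bundle.costs[arm]
        for name in (
            "treatment_cost",
            "local_recurrence_cost",
            "eol_disease_cost",
            "eol_other_cost",
        ):
            _check_ranged(out, f"{arm.value}.{name}", getattr(cs, name), "cost")
        us = bundle.utilities[arm]
        for name in ("u_post_treatment", "u_local_recurrence", "u_metastasis"):
            _check_ranged(out, f"{arm.value}.{name}", getattr(us, name), "utility")
        if not (
            us.u_post_treatment.base
            >= us.u_local_recurrence.base
            >= us.u_metastasis.base
        ):
            out.append(
                Violation(
                    f"{arm.value}.utilities",
                    "base utilities must satisfy u_post >= u_lr >= u_met",
                )
            )
        # residual stay probabilities must be nonnegative at every age
        for t in range(cfg.horizon):
            try:
                q = life_table.annual_death_probability(cfg.start_age + t)
            except Exception as exc:  # out-of-range life table
                out.append(Violation("life_table", f"lookup failed at cycle {t}: {exc}"))
                break
            if tp.p_post_to_lr.base + tp.p_post_to_met.base + q > 1.0:
                out.append(
                    Violation(
                        f"{arm.value}.post_treatment",
                        f"outgoing probabilities exceed 1 at age {cfg.start_age + t}",
                    )
                )
            if tp.p_lr_to_met.base + q > 1.0:
                out.append(
                    Violation(
                        f"{arm.value}.local_recurrence",
                        f"outgoing probabilities exceed 1 at age {cfg.start_age + t}",
                    )
                )
    return out


# --------------------------------------------------------------------------
# Serialization (YAML bundle files)
# --------------------------------------------------------------------------

def _ranged_to_list(p: RangedParameter) -> list[float]:
    return [p.base, p.low, p.high]


def bundle_to_dict(bundle: ParameterBundle) -> dict:
    """Plain-dict form of a bundle, suitable for YAML/JSON round-trips."""
    d: dict = {"transitions": {}, "costs": {}, "utilities": {}}
    for arm in Treatment:
        tp, cs, us = (
            bundle.transitions[arm],
            bundle.costs[arm],
            bundle.utilities[arm],
        )
        d["transitions"][arm.value] = {
            k: _ranged_to_list(getattr(tp, k))
            for k in ("p_post_to_lr", "p_post_to_met", "p_lr_to_met")
        }
        d["costs"][arm.value] = {
            k: _ranged_to_list(getattr(cs, k))
            for k in (
                "treatment_cost",
                "local_recurrence_cost",
                "eol_disease_cost",
                "eol_other_cost",
            )
        }
        d["utilities"][arm.value] = {
            k: _ranged_to_list(getattr(us, k))
            for k in ("u_post_treatment", "u_local_recurrence", "u_metastasis")
        }
    cfg = asdict(bundle.config)
    cfg["cost_timing"] = bundle.config.cost_timing.value
    d["config"] = cfg
    d["metadata"] = dict(bundle.metadata)
    return d


def bundle_from_dict(d: dict) -> ParameterBundle:
    """Inverse of :func:`bundle_to_dict`."""
    def rp(x: Iterable[float]) -> RangedParameter:
        base, low, high = x
        return RangedParameter(float(base), float(low), float(high))

    transitions, costs, utilities = {}, {}, {}
    for arm in Treatment:
        t = d["transitions"][arm.value]
        transitions[arm] = TransitionProbabilitySet(
            rp(t["p_post_to_lr"]), rp(t["p_post_to_met"]), rp(t["p_lr_to_met"])
        )
        c = d["costs"][arm.value]
        costs[arm] = CostSet(
            rp(c["treatment_cost"]),
            rp(c["local_recurrence_cost"]),
            rp(c["eol_disease_cost"]),
            rp(c["eol_other_cost"]),
        )
        u = d["utilities"][arm.value]
        utilities[arm] = UtilitySet(
            rp(u["u_post_treatment"]),
            rp(u["u_local_recurrence"]),
            rp(u["u_metastasis"]),
        )
    cfg_d = dict(d.get("config", {}))
    if "cost_timing" in cfg_d:
        cfg_d["cost_timing"] = EventTiming(cfg_d["cost_timing"])
    config = ModelConfig(**cfg_d)
    return ParameterBundle(transitions, costs, utilities, config, dict(d.get("metadata", {})))


def save_bundle(bundle: ParameterBundle, path) -> None:
    """Write a bundle to a YAML file."""
    with open(path, "w") as fh:
        yaml.safe_dump(bundle_to_dict(bundle), fh, sort_keys=False)


def load_bundle(path) -> ParameterBundle:
    """Read a bundle from a YAML file written by :func:`save_bundle`."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ValueError(f"{path}: not a parameter bundle document")
    return bundle_from_dict(d)


def default_bundle_path():
    """Path to the bundled YAML copy of :func:`default_parameters`."""
    return resources.files("uvealcea.data") / "default_parameters.yaml"


def with_config(bundle: ParameterBundle, **overrides) -> ParameterBundle:
    """Return a copy of ``bundle`` with config fields replaced."""
    return replace(bundle, config=replace(bundle.config, **overrides))
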