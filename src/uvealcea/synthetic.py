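"""Synthetic parameter bundles and life tables for testing.

Emulates the statistical structure of the model's parameter tables so every
stage of the pipeline (validation, both engines, CEA, sensitivity analysis)
can be exercised without any external input: probabilities are drawn
uniformly within their tabulated sensitivity ranges, costs log-uniformly
within theirs, utilities uniformly with the ordering u_post >= u_lr >= u_met
enforced, and the background-mortality table follows a Gompertz curve
q(age) = min(1, b * exp(c * (age - age0))).  Draws are rejection-sampled
until the bundle passes :func:`uvealcea.params.validate_parameters` against
the generated life table, so generated inputs are valid by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .lifetable import LifeTable
from .params import (
    CostSet,
    ModelConfig,
    ParameterBundle,
    RangedParameter,
    Treatment,
    TransitionProbabilitySet,
    UtilitySet,
    default_parameters,
    validate_parameters,
)

__all__ = ["GeneratorSpec", "generate_bundle", "generate_life_table"]


class GenerationError(RuntimeError):
    """Rejection sampling failed to find a valid bundle."""


@dataclass(frozen=True)
class GeneratorSpec:
    """Ranges and mortality-shape settings for the generators.

    ``prob_ranges`` maps the three transition fields to (low, high) sampling
    intervals (defaults: the shared tabulated sensitivity ranges);
    ``cost_ranges`` and ``utility_ranges`` likewise.  ``life_b`` is baseline
    adult annual mortality at ``life_age0`` and ``life_c`` the exponential
    age slope of the Gompertz curve.  ``degenerate=True`` collapses every
    range to the base-case point (useful as a point-mass oracle).
    """

    seed: int = 0
    prob_ranges: dict = field(
        default_factory=lambda: {
            "p_post_to_lr": (0.001, 0.030),
            "p_post_to_met": (0.001, 0.083),
            "p_lr_to_met": (0.001, 0.202),
        }
    )
    cost_ranges: dict = field(
        default_factory=lambda: {
            "treatment_cost": (6_075.0, 29_426.0),
            "local_recurrence_cost": (6_075.0, 13_364.0),
            "eol_disease_cost": (53_652.0, 118_035.0),
            "eol_other_cost": (29_952.0, 65_894.0),
        }
    )
    utility_ranges: dict = field(
        default_factory=lambda: {
            "u_post_treatment": (0.656, 0.76),
            "u_local_recurrence": (0.47, 0.57),
            "u_metastasis": (0.18, 0.28),
        }
    )
    life_b: float = 0.009
    life_c: float = 0.09
    life_age0: int = 59
    degenerate: bool = False
    max_attempts: int = 1000


def generate_life_table(spec: GeneratorSpec, ages: range) -> LifeTable:
    """Gompertz-shaped synthetic mortality over ``ages``.

    q(age) = min(1, b * exp(c * (age - age0))); deterministic given the spec
    (the randomness of the generators lives in the bundle draw).
    """
    ages_t = tuple(ages)
    qx = tuple(
        min(1.0, spec.life_b * float(np.exp(spec.life_c * (a - spec.life_age0))))
        for a in ages_t
    )
    return LifeTable(ages_t, qx)


def _draw_sorted(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    return np.sort(rng.uniform(lo, hi, size=n))


def generate_bundle(spec: GeneratorSpec) -> ParameterBundle:
    """Draw a random, valid parameter bundle; reproducible per seed.

    Ordering constraints are enforced by construction: within each arm
    p_lr_to_met >= p_post_to_met (recurrent disease progresses at least as
    fast) and u_post >= u_lr >= u_met.  The draw is repeated (fresh
    sub-stream each attempt) until validation against the generated life
    table passes; exceeding ``spec.max_attempts`` raises
    :class:`GenerationError`.
    """
    if spec.degenerate:
        base = default_parameters()
        return replace(base, config=replace(base.config, rng_seed=spec.seed))

    life = generate_life_table(
        spec, range(spec.life_age0, spec.life_age0 + ModelConfig().horizon)
    )
    root = np.random.SeedSequence(spec.seed)
    for attempt, ss in enumerate(root.spawn(spec.max_attempts)):
        rng = np.random.default_rng(ss)
        bundle = _draw_bundle(rng, spec)
        if not validate_parameters(bundle, life):
            return bundle
    raise GenerationError(
        f"no valid bundle after {spec.max_attempts} attempts (seed {spec.seed})"
    )


def _draw_bundle(rng: np.random.Generator, spec: GeneratorSpec) -> ParameterBundle:
    transitions: dict[Treatment, TransitionProbabilitySet] = {}
    costs: dict[Treatment, CostSet] = {}
    utilities: dict[Treatment, UtilitySet] = {}

    def rp(v: float, lo: float, hi: float) -> RangedParameter:
        return RangedParameter(v, min(v, lo), max(v, hi))

    for arm in Treatment:
        p_lr = rng.uniform(*spec.prob_ranges["p_post_to_lr"])
        # order the metastasis pair so LR-origin progression is the faster
        pm_lo = min(spec.prob_ranges["p_post_to_met"][0], spec.prob_ranges["p_lr_to_met"][0])
        pm_hi = max(spec.prob_ranges["p_post_to_met"][1], spec.prob_ranges["p_lr_to_met"][1])
        p_met, p_lrmet = _draw_sorted(rng, pm_lo, pm_hi, 2)
        p_met = float(np.clip(p_met, *spec.prob_ranges["p_post_to_met"]))
        p_lrmet = float(np.clip(p_lrmet, *spec.prob_ranges["p_lr_to_met"]))
        p_lrmet = max(p_lrmet, p_met)
        transitions[arm] = TransitionProbabilitySet(
            rp(p_lr, *spec.prob_ranges["p_post_to_lr"]),
            rp(p_met, *spec.prob_ranges["p_post_to_met"]),
            rp(p_lrmet, *spec.prob_ranges["p_lr_to_met"]),
        )

        def log_uniform(lo: float, hi: float) -> float:
            return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

        cr = spec.cost_ranges
        costs[arm] = CostSet(
            rp(log_uniform(*cr["treatment_cost"]), *cr["treatment_cost"]),
            rp(log_uniform(*cr["local_recurrence_cost"]), *cr["local_recurrence_cost"]),
            rp(log_uniform(*cr["eol_disease_cost"]), *cr["eol_disease_cost"]),
            rp(log_uniform(*cr["eol_other_cost"]), *cr["eol_other_cost"]),
        )

        ur = spec.utility_ranges
        u_met = rng.uniform(*ur["u_metastasis"])
        u_lr = rng.uniform(max(ur["u_local_recurrence"][0], u_met), ur["u_local_recurrence"][1])
        u_post = rng.uniform(max(ur["u_post_treatment"][0], u_lr), ur["u_post_treatment"][1])
        utilities[arm] = UtilitySet(
            rp(u_post, *ur["u_post_treatment"]),
            rp(u_lr, *ur["u_local_recurrence"]),
            rp(u_met, *ur["u_metastasis"]),
        )

    config = replace(ModelConfig(), start_age=spec.life_age0, rng_seed=spec.seed)
    return ParameterBundle(
        transitions, costs, utilities, config, {"generator": "synthetic"}
    )
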