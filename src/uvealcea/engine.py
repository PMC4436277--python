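"""Five-state Markov engine for the melanoma treatment model.

States: post-treatment, local recurrence, metastasis, death from disease,
death from other causes.  All patients start in post-treatment; local
recurrence cannot revert to post-treatment; metastasis lasts exactly one
yearly cycle and then transitions to death from disease; both death states
are absorbing.  Background (other-cause) mortality applies in the
post-treatment and local-recurrence states at the age-specific life-table
probability; the age tracked is start_age + cycle index.

Two solvers share the same parameterization and accrual rules:

* :func:`run_cohort` - the deterministic expected-value recursion
  (occupancy row vector times the cycle transition matrix), which is the
  exact expectation of the stochastic process;
* :func:`run_microsim` - seeded patient-level Monte-Carlo replications,
  giving the same point estimates up to sampling error plus 95% uncertainty
  intervals across replications.

Rewards follow the half-cycle convention: transitions are assumed to occur
halfway through a cycle, so cycle-t state membership is valued as the mean
of the start- and end-of-cycle occupancy, and both membership rewards and
one-time entry costs in cycle t are discounted at the mid-cycle time,
(1+r)^-(t+0.5).  The treatment cost is paid by everyone at model entry,
undiscounted.  Entry costs are paid once per state (re-entry is impossible
by construction).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .lifetable import LifeTable
from .params import (
    CostSet,
    EventTiming,
    ModelConfig,
    ParameterBundle,
    TransitionProbabilitySet,
    Treatment,
    UtilitySet,
)

__all__ = [
    "HealthState",
    "ALIVE_STATES",
    "CohortTrace",
    "ArmResult",
    "transition_row",
    "transition_matrix",
    "run_cohort",
    "accrue_costs",
    "accrue_qalys",
    "summarize",
    "run_arm",
    "run_microsim",
]


class HealthState(enum.IntEnum):
    POST_TREATMENT = 0
    LOCAL_RECURRENCE = 1
    METASTASIS = 2
    DEATH_DISEASE = 3
    DEATH_OTHER = 4


#: States in which a patient is alive (accrue utility and time).
ALIVE_STATES = (
    HealthState.POST_TREATMENT,
    HealthState.LOCAL_RECURRENCE,
    HealthState.METASTASIS,
)

_N = len(HealthState)


class InvalidConfigurationError(ValueError):
    """A transition row's residual stay probability would be negative."""


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy and state-entry mass per cycle for one arm.

    ``occupancy[t, s]`` is the cohort fraction in state ``s`` at the start of
    cycle ``t`` (t = 0..H); ``entries[t, s]`` is the fraction entering ``s``
    during cycle ``t`` (entries[0] is all zeros; the initial post-treatment
    mass is starting occupancy, not an entry).
    """

    occupancy: np.ndarray  # (H+1, 5)
    entries: np.ndarray  # (H+1, 5)

    @property
    def horizon(self) -> int:
        return self.occupancy.shape[0] - 1


@dataclass(frozen=True)
class Interval:
    low: float
    high: float


@dataclass(frozen=True)
class ArmResult:
    """Summary outcomes for one treatment arm.

    Costs are discounted 2011 USD per patient; QALYs are discounted
    quality-adjusted life-years per patient; ``ending_state_dist`` is the
    state distribution at the end of the horizon; ``ever_lr``/``ever_met``
    are the fractions ever entering local recurrence / metastasis;
    ``time_in_state`` holds undiscounted half-cycle-corrected mean years per
    alive state.  ``intervals`` (95%) are present for microsimulation
    results only, keyed like the scalar fields.
    """

    arm: Treatment
    mean_cost: float
    mean_qaly: float
    ending_state_dist: np.ndarray  # (5,)
    ever_lr: float
    ever_met: float
    time_in_state: dict[HealthState, float]
    total_time: float
    intervals: dict[str, Interval] = field(default_factory=dict)


# --------------------------------------------------------------------------
# Transition structure
# --------------------------------------------------------------------------

def transition_row(
    state: HealthState,
    cycle: int,
    tp: TransitionProbabilitySet,
    life: LifeTable,
    config: ModelConfig,
) -> np.ndarray:
    """Probability vector over the five states for one origin state and cycle.

    From post-treatment: local recurrence, metastasis and other-cause death
    compete simultaneously; the stay probability is the residual.  From local
    recurrence: metastasis and other-cause death compete.  Metastasis moves
    to death-from-disease with probability 1 after its single cycle.  Death
    states are absorbing.  A negative residual raises
    :class:`InvalidConfigurationError`.
    """
    row = np.zeros(_N)
    if state in (HealthState.DEATH_DISEASE, HealthState.DEATH_OTHER):
        row[state] = 1.0
        return row
    if state is HealthState.METASTASIS:
        row[HealthState.DEATH_DISEASE] = 1.0
        return row
    q = life.annual_death_probability(config.start_age + cycle)
    if state is HealthState.POST_TREATMENT:
        events = tp.p_post_to_lr.base + tp.p_post_to_met.base + q
        if events > 1.0:
            raise InvalidConfigurationError(
                f"post-treatment outgoing probabilities sum to {events:.4f} > 1 "
                f"at cycle {cycle}"
            )
        row[HealthState.LOCAL_RECURRENCE] = tp.p_post_to_lr.base
        row[HealthState.METASTASIS] = tp.p_post_to_met.base
        row[HealthState.DEATH_OTHER] = q
        row[HealthState.POST_TREATMENT] = 1.0 - events
        return row
    # local recurrence
    events = tp.p_lr_to_met.base + q
    if events > 1.0:
        raise InvalidConfigurationError(
            f"local-recurrence outgoing probabilities sum to {events:.4f} > 1 "
            f"at cycle {cycle}"
        )
    row[HealthState.METASTASIS] = tp.p_lr_to_met.base
    row[HealthState.DEATH_OTHER] = q
    row[HealthState.LOCAL_RECURRENCE] = 1.0 - events
    return row


def transition_matrix(
    cycle: int, tp: TransitionProbabilitySet, life: LifeTable, config: ModelConfig
) -> np.ndarray:
    """Full 5x5 row-stochastic matrix for one cycle."""
    return np.vstack(
        [transition_row(s, cycle, tp, life, config) for s in HealthState]
    )


# --------------------------------------------------------------------------
# Cohort (expected-value) solver
# --------------------------------------------------------------------------

def run_cohort(
    arm: Treatment,
    bundle: ParameterBundle,
    life: LifeTable,
    config: ModelConfig | None = None,
) -> CohortTrace:
    """Deterministic expected-value recursion for one arm.

    occupancy[t+1] = occupancy[t] @ P(t); entries[t+1, s] is the off-diagonal
    inflow into s during cycle t.
    """
    config = config or bundle.config
    tp = bundle.transitions[arm]
    H = config.horizon
    occ = np.zeros((H + 1, _N))
    ent = np.zeros((H + 1, _N))
    occ[0, HealthState.POST_TREATMENT] = 1.0
    for t in range(H):
        P = transition_matrix(t, tp, life, config)
        occ[t + 1] = occ[t] @ P
        flow = occ[t][:, None] * P  # mass moving from row state to col state
        ent[t + 1] = flow.sum(axis=0) - np.diag(flow)
    return CohortTrace(occupancy=occ, entries=ent)


# --------------------------------------------------------------------------
# Reward accrual
# --------------------------------------------------------------------------

def _event_discounts(config: ModelConfig) -> np.ndarray:
    """Discount factor for an entry event during cycle t (t = 0..H-1)."""
    r = config.discount_rate
    t = np.arange(config.horizon, dtype=float)
    offset = {
        EventTiming.MID_CYCLE: 0.5,
        EventTiming.CYCLE_START: 0.0,
        EventTiming.CYCLE_END: 1.0,
    }[config.cost_timing]
    return (1.0 + r) ** -(t + offset)


def accrue_costs(
    trace: CohortTrace, costs: CostSet, config: ModelConfig
) -> float:
    """Expected discounted cost per patient for one arm.

    The treatment cost applies to the whole cohort at model entry
    (undiscounted).  The local-recurrence cost applies to entries into local
    recurrence, and the end-of-life costs to entries into the two death
    states; each entry during cycle t is discounted at the mid-cycle time
    (or per ``config.cost_timing``).  Metastasis itself carries no entry
    cost: its terminal-care cost is attached to death from disease.
    """
    d = _event_discounts(config)
    ent = trace.entries[1:]  # entries during cycle t land at index t+1
    total = costs.treatment_cost.base
    total += float(
        (d * ent[:, HealthState.LOCAL_RECURRENCE]).sum()
        * costs.local_recurrence_cost.base
        + (d * ent[:, HealthState.DEATH_DISEASE]).sum() * costs.eol_disease_cost.base
        + (d * ent[:, HealthState.DEATH_OTHER]).sum() * costs.eol_other_cost.base
    )
    return total


def _membership(trace: CohortTrace, config: ModelConfig) -> np.ndarray:
    """(H, 5) per-cycle state membership, half-cycle corrected if enabled."""
    occ = trace.occupancy
    if config.half_cycle:
        return (occ[:-1] + occ[1:]) / 2.0
    return occ[:-1]


def accrue_qalys(
    trace: CohortTrace,
    utilities: UtilitySet,
    config: ModelConfig,
) -> float:
    """Expected discounted QALYs per patient for one arm.

    Cycle-t accrual is the utility-weighted mean of start- and end-of-cycle
    occupancy over the alive states (the half-cycle/trapezoid correction),
    discounted at the mid-cycle time (1+r)^-(t+0.5); with
    ``half_cycle=False`` start-of-cycle occupancy and (1+r)^-t are used.
    """
    u = np.zeros(_N)
    u[HealthState.POST_TREATMENT] = utilities.u_post_treatment.base
    u[HealthState.LOCAL_RECURRENCE] = utilities.u_local_recurrence.base
    u[HealthState.METASTASIS] = utilities.u_metastasis.base
    r = config.discount_rate
    t = np.arange(config.horizon, dtype=float)
    offset = 0.5 if config.half_cycle else 0.0
    disc = (1.0 + r) ** -(t + offset)
    per_cycle = _membership(trace, config) @ u
    return float((per_cycle * disc).sum()) * config.cycle_length


def summarize(
    trace: CohortTrace,
    arm: Treatment,
    bundle: ParameterBundle,
    config: ModelConfig | None = None,
) -> ArmResult:
    """Full :class:`ArmResult` for a cohort trace.

    Ever-recurrence and ever-metastasis are cumulative entry mass; time in
    state is the undiscounted half-cycle-corrected occupancy sum per alive
    state; total time is their sum (expected life-years lived within the
    horizon).
    """
    config = config or bundle.config
    cost = accrue_costs(trace, bundle.costs[arm], config)
    qaly = accrue_qalys(trace, bundle.utilities[arm], config)
    membership = _membership(trace, config)
    time_in_state = {
        s: float(membership[:, s].sum()) * config.cycle_length for s in ALIVE_STATES
    }
    return ArmResult(
        arm=arm,
        mean_cost=cost,
        mean_qaly=qaly,
        ending_state_dist=trace.occupancy[-1].copy(),
        ever_lr=float(trace.entries[:, HealthState.LOCAL_RECURRENCE].sum()),
        ever_met=float(trace.entries[:, HealthState.METASTASIS].sum()),
        time_in_state=time_in_state,
        total_time=float(sum(time_in_state.values())),
    )


def run_arm(
    arm: Treatment,
    bundle: ParameterBundle,
    life: LifeTable,
    config: ModelConfig | None = None,
) -> ArmResult:
    """Cohort-engine convenience: trace, accrual and summary in one call."""
    config = config or bundle.config
    return summarize(run_cohort(arm, bundle, life, config), arm, bundle, config)


# --------------------------------------------------------------------------
# Microsimulation solver
# --------------------------------------------------------------------------

def _simulate_replication(
    rng: np.random.Generator,
    cum_rows: list[np.ndarray],
    H: int,
    n: int,
) -> CohortTrace:
    """One replication of n patients; returns a fraction-scale trace."""
    occ_counts = np.zeros((H + 1, _N), dtype=np.int64)
    ent_counts = np.zeros((H + 1, _N), dtype=np.int64)
    state = np.zeros(n, dtype=np.int64)  # all start post-treatment
    occ_counts[0, HealthState.POST_TREATMENT] = n
    for t in range(H):
        cum = cum_rows[t]  # (5, 5) row-wise cumulative probabilities
        u = rng.random(n)
        new_state = (u[:, None] > cum[state]).sum(axis=1)
        moved = new_state != state
        np.add.at(ent_counts[t + 1], new_state[moved], 1)
        state = new_state
        np.add.at(occ_counts[t + 1], state, 1)
    return CohortTrace(occupancy=occ_counts / n, entries=ent_counts / n)


def run_microsim(
    arm: Treatment,
    bundle: ParameterBundle,
    life: LifeTable,
    config: ModelConfig | None = None,
) -> ArmResult:
    """Patient-level Monte-Carlo estimate of the arm outcomes.

    Simulates ``config.cohort_size`` trajectories per replication,
    ``config.n_replications`` times.  Point estimates are means of the
    per-replication cohort means; 95% intervals are the 2.5/97.5 percentiles
    of the across-replication distribution (or a normal approximation with
    ``interval_method='normal'``).  Replication streams are spawned from the
    root seed, so results are reproducible and independent of execution
    order.
    """
    config = config or bundle.config
    tp = bundle.transitions[arm]
    H = config.horizon
    cum_rows = [
        np.cumsum(transition_matrix(t, tp, life, config), axis=1) for t in range(H)
    ]
    # guard against float round-off leaving the last cumulative < 1
    for c in cum_rows:
        c[:, -1] = 1.0

    seeds = np.random.SeedSequence(config.rng_seed).spawn(config.n_replications)
    reps: dict[str, list] = {k: [] for k in (
        "cost", "qaly", "end", "ever_lr", "ever_met", "time", "total_time")}
    for ss in seeds:
        trace = _simulate_replication(
            np.random.default_rng(ss), cum_rows, H, config.cohort_size
        )
        res = summarize(trace, arm, bundle, config)
        reps["cost"].append(res.mean_cost)
        reps["qaly"].append(res.mean_qaly)
        reps["end"].append(res.ending_state_dist)
        reps["ever_lr"].append(res.ever_lr)
        reps["ever_met"].append(res.ever_met)
        reps["time"].append([res.time_in_state[s] for s in ALIVE_STATES])
        reps["total_time"].append(res.total_time)

    def ci(x: np.ndarray) -> Interval:
        x = np.asarray(x, dtype=float)
        if config.interval_method == "normal":
            m, se = x.mean(axis=0), x.std(axis=0, ddof=1) / np.sqrt(len(x))
            return Interval(float(m - 1.96 * se), float(m + 1.96 * se))
        lo, hi = np.percentile(x, [2.5, 97.5], axis=0)
        return Interval(float(lo), float(hi))

    end = np.vstack(reps["end"])
    times = np.asarray(reps["time"])
    intervals: dict[str, Interval] = {
        "mean_cost": ci(reps["cost"]),
        "mean_qaly": ci(reps["qaly"]),
        "ever_lr": ci(reps["ever_lr"]),
        "ever_met": ci(reps["ever_met"]),
        "total_time": ci(reps["total_time"]),
    }
    for s in HealthState:
        intervals[f"ending_{s.name.lower()}"] = ci(end[:, s])
    for i, s in enumerate(ALIVE_STATES):
        intervals[f"time_{s.name.lower()}"] = ci(times[:, i])

    return ArmResult(
        arm=arm,
        mean_cost=float(np.mean(reps["cost"])),
        mean_qaly=float(np.mean(reps["qaly"])),
        ending_state_dist=end.mean(axis=0),
        ever_lr=float(np.mean(reps["ever_lr"])),
        ever_met=float(np.mean(reps["ever_met"])),
        time_in_state={s: float(times[:, i].mean()) for i, s in enumerate(ALIVE_STATES)},
        total_time=float(np.mean(reps["total_time"])),
        intervals=intervals,
    )
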