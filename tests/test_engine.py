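"""Markov engine: transition structure, cohort recursion, accrual, microsim."""

import dataclasses

import numpy as np
import pytest

from uvealcea.engine import (
    ALIVE_STATES,
    HealthState,
    InvalidConfigurationError,
    accrue_costs,
    accrue_qalys,
    run_arm,
    run_cohort,
    run_microsim,
    summarize,
    transition_matrix,
    transition_row,
)
from uvealcea.lifetable import LifeTable
from uvealcea.params import (
    ModelConfig,
    RangedParameter,
    Treatment,
    with_config,
)

E = Treatment.ENUCLEATION
S = HealthState


def set_probs(bundle, arm, p_lr=None, p_met=None, p_lrmet=None):
    """Copy of ``bundle`` with some of one arm's event probabilities replaced."""
    tp = bundle.transitions[arm]
    fields = {}
    for name, v in (
        ("p_post_to_lr", p_lr),
        ("p_post_to_met", p_met),
        ("p_lr_to_met", p_lrmet),
    ):
        if v is not None:
            fields[name] = RangedParameter(v, min(v, 0.0), max(v, 1.0))
    new_tp = dataclasses.replace(tp, **fields)
    return dataclasses.replace(
        bundle, transitions={**bundle.transitions, arm: new_tp}
    )


class TestTransitionRow:
    def test_post_treatment_residual(self, bundle, flat_life):
        row = transition_row(S.POST_TREATMENT, 0, bundle.transitions[E], flat_life,
                             bundle.config)
        assert row[S.POST_TREATMENT] == pytest.approx(0.942)
        assert row[S.LOCAL_RECURRENCE] == 0.002
        assert row[S.METASTASIS] == 0.047
        assert row[S.DEATH_DISEASE] == 0.0
        assert row[S.DEATH_OTHER] == 0.009
        assert row.sum() == pytest.approx(1.0, abs=1e-15)

    def test_metastasis_is_one_year_terminal(self, bundle, flat_life):
        row = transition_row(S.METASTASIS, 3, bundle.transitions[E], flat_life,
                             bundle.config)
        assert list(row) == [0, 0, 0, 1, 0]

    @pytest.mark.parametrize("state", [S.DEATH_DISEASE, S.DEATH_OTHER])
    def test_death_states_absorbing(self, state, bundle, flat_life):
        row = transition_row(state, 1, bundle.transitions[E], flat_life, bundle.config)
        assert row[state] == 1.0
        assert row.sum() == 1.0

    def test_negative_residual_rejected(self, bundle):
        heavy = LifeTable(tuple(range(59, 70)), (0.95,) * 11)
        b = set_probs(bundle, E, p_lr=0.1, p_met=0.1)
        with pytest.raises(InvalidConfigurationError):
            transition_row(S.POST_TREATMENT, 0, b.transitions[E], heavy, b.config)

    def test_matrix_rows_stochastic(self, bundle, life):
        for t in range(5):
            P = transition_matrix(t, bundle.transitions[E], life, bundle.config)
            assert np.allclose(P.sum(axis=1), 1.0, atol=1e-15)
            assert (P >= 0).all()


class TestRunCohort:
    def test_identity_dynamics(self, bundle, zero_life):
        b = set_probs(bundle, E, p_lr=0.0, p_met=0.0, p_lrmet=0.0)
        trace = run_cohort(E, b, zero_life)
        expected = np.zeros(5)
        expected[S.POST_TREATMENT] = 1.0
        for t in range(6):
            assert np.allclose(trace.occupancy[t], expected)
        assert trace.entries.sum() == 0.0

    def test_forced_chain_through_metastasis(self, bundle, zero_life):
        b = set_probs(bundle, E, p_lr=0.0, p_met=1.0)
        b = with_config(b, horizon=3)
        trace = run_cohort(E, b, zero_life)
        assert trace.occupancy[1][S.METASTASIS] == 1.0
        assert trace.occupancy[2][S.DEATH_DISEASE] == 1.0
        assert trace.occupancy[3][S.DEATH_DISEASE] == 1.0

    def test_occupancy_conserved_and_absorption_monotone(self, bundle, life):
        for arm in Treatment:
            trace = run_cohort(arm, bundle, life)
            assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)
            for s in (S.DEATH_DISEASE, S.DEATH_OTHER):
                deaths = trace.occupancy[:, s]
                assert (np.diff(deaths) >= -1e-15).all()

    def test_no_reentry_into_post_treatment(self, bundle, life):
        for arm in Treatment:
            trace = run_cohort(arm, bundle, life)
            assert (trace.entries[:, S.POST_TREATMENT] == 0).all()


class TestAccrual:
    def test_cost_is_treatment_cost_without_events(self, bundle, zero_life):
        b = set_probs(bundle, E, p_lr=0.0, p_met=0.0, p_lrmet=0.0)
        trace = run_cohort(E, b, zero_life)
        assert accrue_costs(trace, b.costs[E], b.config) == pytest.approx(
            b.costs[E].treatment_cost.base
        )

    def test_forced_chain_cost_without_discounting(self, bundle, zero_life):
        b = set_probs(bundle, E, p_lr=0.0, p_met=1.0)
        b = with_config(b, horizon=2, discount_rate=0.0)
        trace = run_cohort(E, b, zero_life)
        cs = b.costs[E]
        assert accrue_costs(trace, cs, b.config) == pytest.approx(
            cs.treatment_cost.base + cs.eol_disease_cost.base
        )

    def test_constant_occupancy_qalys_exact(self, bundle, zero_life):
        b = set_probs(bundle, E, p_lr=0.0, p_met=0.0, p_lrmet=0.0)
        b = with_config(b, discount_rate=0.0)
        trace = run_cohort(E, b, zero_life)
        u = b.utilities[E].u_post_treatment.base
        assert accrue_qalys(trace, b.utilities[E], b.config) == pytest.approx(5 * u)

    def test_zero_utilities_zero_qalys(self, bundle, life):
        zero_u = dataclasses.replace(
            bundle.utilities[E],
            u_post_treatment=RangedParameter(0, 0, 0),
            u_local_recurrence=RangedParameter(0, 0, 0),
            u_metastasis=RangedParameter(0, 0, 0),
        )
        trace = run_cohort(E, bundle, life)
        assert accrue_qalys(trace, zero_u, bundle.config) == 0.0

    def test_zero_discount_limit(self, bundle, life):
        """At r=0 the discounted accruals equal plain undiscounted sums."""
        b0 = with_config(bundle, discount_rate=0.0)
        for arm in Treatment:
            trace = run_cohort(arm, b0, life)
            ent = trace.entries[1:]
            cs = b0.costs[arm]
            undiscounted = (
                cs.treatment_cost.base
                + ent[:, S.LOCAL_RECURRENCE].sum() * cs.local_recurrence_cost.base
                + ent[:, S.DEATH_DISEASE].sum() * cs.eol_disease_cost.base
                + ent[:, S.DEATH_OTHER].sum() * cs.eol_other_cost.base
            )
            assert accrue_costs(trace, cs, b0.config) == pytest.approx(undiscounted)

    def test_discounting_reduces_qalys(self, bundle, life):
        q_disc = run_arm(E, bundle, life).mean_qaly
        q_undisc = run_arm(E, with_config(bundle, discount_rate=0.0), life).mean_qaly
        assert q_disc < q_undisc

    def test_raising_metastasis_probability_lowers_qalys(self, bundle, life):
        base = run_arm(E, bundle, life).mean_qaly
        worse = set_probs(bundle, E, p_met=0.08)
        assert run_arm(E, worse, life).mean_qaly < base


class TestSummarize:
    def test_forced_chain_ever_met_is_one(self, bundle, zero_life):
        b = set_probs(bundle, E, p_lr=0.0, p_met=1.0)
        trace = run_cohort(E, b, zero_life)
        res = summarize(trace, E, b)
        assert res.ever_met == pytest.approx(1.0)

    def test_structural_identity_ever_met(self, bundle, life):
        """Metastasis lasts one cycle and disease death occurs only via
        metastasis, so ever_met == ending metastasis + ending disease-death."""
        for arm in Treatment:
            res = run_arm(arm, bundle, life)
            assert res.ever_met == pytest.approx(
                res.ending_state_dist[S.METASTASIS]
                + res.ending_state_dist[S.DEATH_DISEASE],
                abs=1e-12,
            )

    def test_result_invariants(self, bundle, life):
        for arm in Treatment:
            res = run_arm(arm, bundle, life)
            assert res.ending_state_dist.sum() == pytest.approx(1.0, abs=1e-12)
            assert res.ever_met >= res.ending_state_dist[S.METASTASIS]
            assert res.total_time == pytest.approx(
                sum(res.time_in_state[s] for s in ALIVE_STATES)
            )
            assert 0.0 <= res.mean_qaly <= bundle.config.horizon


class TestMicrosim:
    SMALL = dict(cohort_size=2_000, n_replications=40, rng_seed=7)

    def test_same_seed_reproduces(self, bundle, life):
        b = with_config(bundle, **self.SMALL)
        r1 = run_microsim(E, b, life)
        r2 = run_microsim(E, b, life)
        assert r1.mean_cost == r2.mean_cost
        assert r1.mean_qaly == r2.mean_qaly
        assert np.array_equal(r1.ending_state_dist, r2.ending_state_dist)
        assert r1.intervals["mean_cost"] == r2.intervals["mean_cost"]

    def test_different_seed_differs(self, bundle, life):
        b1 = with_config(bundle, **self.SMALL)
        b2 = with_config(bundle, **{**self.SMALL, "rng_seed": 8})
        assert run_microsim(E, b1, life).mean_cost != run_microsim(E, b2, life).mean_cost

    def test_counts_conserved(self, bundle, life):
        b = with_config(bundle, cohort_size=500, n_replications=3, rng_seed=1)
        r = run_microsim(E, b, life)
        assert r.ending_state_dist.sum() == pytest.approx(1.0, abs=1e-12)

    def test_agrees_with_cohort_expectation(self, bundle, life):
        """The cohort solver is the exact expectation of the microsimulation:
        point estimates agree within 3 across-replication standard errors."""
        b = with_config(bundle, cohort_size=4_000, n_replications=50, rng_seed=11)
        for arm in Treatment:
            micro = run_microsim(arm, b, life)
            exact = run_arm(arm, b, life)
            for field in ("mean_cost", "mean_qaly"):
                iv = micro.intervals[field]
                # the percentile interval spans ~3.92 SD of the replication
                # distribution; the SE of the overall mean divides by sqrt(R)
                se_mean = (iv.high - iv.low) / 3.92 / np.sqrt(b.config.n_replications)
                assert abs(getattr(micro, field) - getattr(exact, field)) <= max(
                    3 * se_mean, 1e-9
                )
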