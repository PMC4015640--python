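"""Exact stationary solver: Boolean rules, transition matrices, pi, profiles."""

import numpy as np
import pytest

from ribolattice import LatticeConfig, enumerate_states
from ribolattice.lattice import allowed_events, apply_event, build_events
from ribolattice.pbn import (
    CachedSolver,
    build_event_matrix,
    build_transition_matrix,
    boolean_event_rule,
    average_occurrence_probability,
    rank_states,
    rate_sensitivity,
    solve,
    stationary_distribution,
    steady_state_profiles,
)
from ribolattice.regulation import PrematureStopSpec

from conftest import TOY_ME, TOY_PI, ctmc_stationary


def _cfg(n, r, alpha=1.0, beta=1.0, gamma=1.0):
    return LatticeConfig(n, r, alpha, beta, gamma)


class TestBooleanRules:
    @pytest.mark.parametrize("n,r", [(4, 1), (6, 2), (8, 3)])
    def test_rules_equal_predicate_plus_shift_semantics(self, n, r):
        """The logic-formula event functions coincide with the reference
        predicate-then-apply semantics on every reachable state (the module's
        core correctness argument)."""
        cfg = _cfg(n, r)
        for e in build_events(cfg):
            rule = boolean_event_rule(e, cfg)
            for s in enumerate_states(cfg):
                assert rule(s) == apply_event(s, e, cfg)

    @pytest.mark.parametrize("n,r,j", [(6, 2, 3), (8, 3, 4), (5, 1, 3)])
    def test_dissociation_rule_matches_semantics(self, n, r, j):
        cfg = _cfg(n, r)
        stop = PrematureStopSpec(position=j, mu=0.3)
        events = build_events(cfg, stop)
        dis = [e for e in events if e.kind == "dissociation"][0]
        rule = boolean_event_rule(dis, cfg)
        for s in enumerate_states(cfg):
            assert rule(s) == apply_event(s, dis, cfg)

    def test_entry_rule_identity_branch(self):
        cfg = _cfg(3, 2)
        entry = build_events(cfg)[0]
        rule = boolean_event_rule(entry, cfg)
        assert rule((0, 0, 0)) == (1, 1, 0)
        assert rule((1, 1, 0)) == (1, 1, 0)   # first r codons keep unchanged


class TestEventMatrices:
    def test_toy_exit_matrix_columns(self, toy_config):
        states = enumerate_states(toy_config)
        exit_ = build_events(toy_config)[-1]
        M = build_event_matrix(exit_, states, toy_config).toarray()
        i = {s: k for k, s in enumerate(states)}
        col = M[:, i[(1, 1)]]
        assert col[i[(1, 0)]] == 1 and col.sum() == 1
        for s in [(1, 0), (0, 0)]:
            assert M[i[s], i[s]] == 1  # identity where exit disallowed

    def test_toy_entry_matrix_column(self, toy_config):
        states = enumerate_states(toy_config)
        entry = build_events(toy_config)[0]
        M = build_event_matrix(entry, states, toy_config).toarray()
        i = {s: k for k, s in enumerate(states)}
        assert M[i[(1, 1)], i[(0, 1)]] == 1

    def test_single_state_space_gives_identity(self):
        # a disallowed event restricted to a closed 1-state space is identity
        cfg = _cfg(1, 1)
        states = [(0,)]
        exit_ = build_events(cfg)[-1]
        M = build_event_matrix(exit_, states, cfg).toarray()
        assert np.array_equal(M, [[1.0]])

    @pytest.mark.parametrize("n,r", [(4, 2), (6, 3), (5, 1)])
    def test_event_matrices_are_column_stochastic_01(self, n, r):
        cfg = _cfg(n, r, alpha=0.3, beta=0.7, gamma=1.3)
        states = enumerate_states(cfg)
        for e in build_events(cfg):
            M = build_event_matrix(e, states, cfg)
            assert np.all(M.sum(axis=0) == 1)
            assert set(np.unique(M.toarray())) <= {0.0, 1.0}


class TestTransitionMatrix:
    def test_toy_matrix_matches_printed_values(self, toy_config):
        M = build_transition_matrix(toy_config)
        assert np.allclose(M.matrix.toarray(), TOY_ME, atol=1e-12)
        # self-transition of the fully occupied state is 0.8000
        assert M.matrix.toarray()[0, 0] == pytest.approx(0.8, abs=1e-12)
        assert M.probabilities == pytest.approx((0.3, 0.5, 0.2))

    def test_uniform_single_codon_toggle(self):
        M = build_transition_matrix(_cfg(1, 1))
        assert np.allclose(M.matrix.toarray(), [[0.5, 0.5], [0.5, 0.5]])

    @pytest.mark.parametrize("n,r", [(5, 2), (7, 3), (6, 1)])
    def test_columns_sum_to_one(self, n, r):
        rng = np.random.default_rng(7)
        cfg = _cfg(n, r, alpha=rng.uniform(0.1, 2), beta=rng.uniform(0.1, 2),
                   gamma=rng.uniform(0.1, 2, size=n - r))
        M = build_transition_matrix(cfg)
        assert np.allclose(np.asarray(M.matrix.sum(axis=0)).ravel(), 1.0)

    def test_uniformization_identity(self):
        # M_E == I + Q / sum(gamma) with Q the raw-rate generator
        cfg = _cfg(5, 2, alpha=0.4, beta=0.9, gamma=[1.2, 0.5, 2.0])
        M = build_transition_matrix(cfg)
        states = list(M.states)
        total = sum(e.rate for e in M.events)
        index = {s: k for k, s in enumerate(states)}
        Q = np.zeros((len(states),) * 2)
        for s in states:
            j = index[s]
            for e in allowed_events(s, cfg):
                t = apply_event(s, e, cfg)
                Q[index[t], j] += e.rate
                Q[j, j] -= e.rate
        assert np.allclose(M.matrix.toarray(), np.eye(len(states)) + Q / total)


class TestStationary:
    def test_toy_stationary_exact(self, toy_config):
        sol = solve(toy_config)
        assert np.allclose(sol.pi, list(TOY_PI.values()), atol=1e-12)
        assert np.allclose(sol.rho, [0.6, 0.6], atol=1e-12)
        assert sol.c == pytest.approx(0.24, abs=1e-12)

    def test_symmetric_toggle(self):
        pi = stationary_distribution(build_transition_matrix(_cfg(1, 1)))
        assert np.allclose(pi, [0.5, 0.5], atol=1e-14)

    def test_power_iteration_agrees_with_linear_solve(self, toy_config):
        M = build_transition_matrix(toy_config)
        pi_lin = stationary_distribution(M, method="linear")
        pi_pow = stationary_distribution(M, method="power", tol=1e-14)
        assert np.allclose(pi_lin, pi_pow, atol=1e-10)

    def test_matches_ctmc_oracle_on_random_instances(self):
        """Uniformized discrete chain and raw-rate continuous chain share
        their stationary law on every small lattice."""
        rng = np.random.default_rng(42)
        for n in range(2, 7):
            for r in range(1, min(3, n) + 1):
                cfg = _cfg(n, r, alpha=rng.uniform(0.2, 2.0),
                           beta=rng.uniform(0.2, 2.0),
                           gamma=rng.uniform(0.2, 2.0, size=n - r))
                M = build_transition_matrix(cfg)
                pi = stationary_distribution(M)
                pi_ctmc = ctmc_stationary(cfg, list(M.states))
                assert np.allclose(pi, pi_ctmc, atol=1e-10), (n, r)

    def test_matches_ctmc_oracle_with_premature_stop(self):
        cfg = _cfg(6, 2, alpha=0.8, beta=0.3, gamma=1.0)
        stop = PrematureStopSpec(position=3, mu=0.4)
        M = build_transition_matrix(cfg, stop)
        pi = stationary_distribution(M)
        pi_ctmc = ctmc_stationary(cfg, list(M.states), stop=stop)
        assert np.allclose(pi, pi_ctmc, atol=1e-10)

    def test_alpha_zero_concentrates_on_empty_state(self):
        cfg = _cfg(4, 2, alpha=0.0)
        sol = solve(cfg)
        assert sol.c == pytest.approx(0.0, abs=1e-14)
        assert sol.pi[list(sol.states).index((0, 0, 0, 0))] == pytest.approx(1.0)

    def test_figure_scale_instance(self):
        cfg = _cfg(50, 12, alpha=1.0, beta=1.0, gamma=1.0)
        sol = solve(cfg)
        assert len(sol.states) == 1113
        assert sol.pi.sum() == pytest.approx(1.0, abs=1e-10)
        assert 0.0 <= sol.c <= 1.0  # bounded by the minimum event rate
        M = build_transition_matrix(cfg)
        resid = np.max(np.abs(M.matrix @ sol.pi - sol.pi))
        assert resid < 1e-10


class TestProfiles:
    def test_flux_balance_every_event(self, toy_config):
        # psi_bar_i * gamma_i is equal across all events and equals c
        sol = solve(toy_config)
        for e in build_events(toy_config):
            psi = average_occurrence_probability(sol, e)
            assert psi * e.rate == pytest.approx(sol.c, abs=1e-12)

    def test_flux_balance_random_instance(self):
        cfg = _cfg(6, 2, alpha=0.35, beta=1.4, gamma=[0.8, 1.1, 0.6, 2.0])
        sol = solve(cfg)
        fluxes = [average_occurrence_probability(sol, e) * e.rate
                  for e in build_events(cfg)]
        assert np.allclose(fluxes, sol.c, atol=1e-11)
        assert 0.0 <= sol.c <= min(e.rate for e in build_events(cfg))

    def test_degenerate_pi_gives_zero_profiles(self, toy_config):
        states = enumerate_states(toy_config)
        pi = np.zeros(len(states))
        pi[states.index((0, 0))] = 1.0
        sol = steady_state_profiles(pi, states, toy_config)
        assert np.all(sol.rho == 0) and sol.c == 0

    def test_rank_states_toy(self, toy_config):
        top, bottom = rank_states(solve(toy_config), k=1)
        assert top == [((1, 1), pytest.approx(0.36, abs=1e-12))]
        assert bottom == [((0, 0), pytest.approx(0.16, abs=1e-12))]

    def test_rank_states_clips_and_breaks_ties_canonically(self):
        sol = solve(_cfg(1, 1))  # pi = [0.5, 0.5]
        top, bottom = rank_states(sol, k=5)
        assert [s for s, _ in top] == [(1,), (0,)]
        assert [s for s, _ in bottom] == [(1,), (0,)]


class TestSensitivity:
    def test_dc_dbeta_matches_fine_grid_slope(self, toy_config):
        exit_ = build_events(toy_config)[-1]
        sens = rate_sensitivity(toy_config, "c", exit_, delta=1e-5)
        d = 1e-7
        hi = solve(LatticeConfig(2, 1, 0.6, 0.4 + d, 1.0)).c
        lo = solve(LatticeConfig(2, 1, 0.6, 0.4 - d, 1.0)).c
        assert sens == pytest.approx((hi - lo) / (2 * d), rel=1e-5)

    def test_normalization_insensitive(self, toy_config):
        # sum(pi) stays 1, so the sensitivity of any pi_j sums to ~0
        entry = build_events(toy_config)[0]
        total = sum(rate_sensitivity(toy_config, f"pi_{j}", entry, 1e-6)
                    for j in range(1, 5))
        assert total == pytest.approx(0.0, abs=1e-6)

    def test_dc_dalpha_nonnegative(self):
        for cfg in [_cfg(2, 1, 0.6, 0.4), _cfg(6, 2, 0.5, 0.8)]:
            entry = build_events(cfg)[0]
            assert rate_sensitivity(cfg, "c", entry, 1e-5) >= -1e-9

    def test_delta_making_rate_nonpositive_errors(self, toy_config):
        from ribolattice.lattice import ConfigurationError
        exit_ = build_events(toy_config)[-1]
        with pytest.raises(ConfigurationError):
            rate_sensitivity(toy_config, "c", exit_, delta=0.5)


def test_cached_solver_matches_fresh_solve():
    cfg = _cfg(8, 2, alpha=0.5, beta=0.9, gamma=1.0)
    cached = CachedSolver(cfg)
    for alpha in (0.2, 0.7, 1.5):
        full = solve(LatticeConfig(8, 2, alpha, 0.9, 1.0))
        fast = cached.solve_alpha(alpha)
        assert np.allclose(full.pi, fast.pi, atol=1e-12)
        assert full.c == pytest.approx(fast.c, abs=1e-12)
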