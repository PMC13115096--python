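"""Contagion mechanics: confidence, intimacy, transitions, trajectories."""

import numpy as np
import pytest

from dihypernet import (
    ContagionConfig,
    DirectedHypergraph,
    EdgeKind,
    GrowthConfig,
    Mode,
    grow_directed_social,
    classical_sir,
    classical_seir,
    initialize,
    intimacy,
    run,
    run_ensemble,
    step,
)
from dihypernet.contagion import (
    ClassicalRates,
    NodeAttributes,
    dropout_prob,
    recovery_prob,
    sample_confidence,
    threshold_met,
    transmission_prob,
    S, E, I, R,
)
from dihypernet.fixtures import ScriptedRng
from dihypernet.generators import ConfigError
from dihypernet.hypergraph import HypergraphError

from oracles import brute_in_neighbors, brute_step, brute_xi, random_hypergraph, threshold_closure


class TestConfidence:
    def test_zero_w_gives_zero_confidence(self, rng):
        w, C = sample_confidence(5, coi=0.0, sigma_coi=0.0, rng=rng)
        assert np.allclose(C, 0.0)

    def test_log2_w_gives_half_confidence(self):
        assert 1.0 - np.exp(-np.log(2)) == pytest.approx(0.5)
        w, C = sample_confidence(3, coi=np.log(2), sigma_coi=0.0,
                                 rng=np.random.default_rng(0))
        assert np.allclose(C, 0.5)

    def test_degenerate_sigma_closed_form(self, rng):
        w, C = sample_confidence(10, coi=0.2, sigma_coi=0.0, rng=rng)
        assert np.allclose(C, 1.0 - np.exp(-0.2))

    def test_truncation_keeps_confidence_in_unit_interval(self, rng):
        w, C = sample_confidence(5000, coi=0.05, sigma_coi=0.5, rng=rng)
        assert (w >= 0).all()
        assert ((C >= 0) & (C < 1)).all()


class TestIntimacy:
    def test_alpha_zero_gives_unit_omega(self, small_social):
        table = intimacy(small_social, alpha=0.0)
        assert np.allclose(table.omega, 1.0)

    def test_homogeneous_pairs_give_unit_omega(self, star_network):
        # all pairs have zero common in-neighbors -> omega = 1 everywhere
        table = intimacy(star_network, alpha=1.0)
        assert np.allclose(table.omega, 1.0)

    def test_omega_mean_is_exactly_one(self, small_social):
        table = intimacy(small_social, alpha=1.0)
        raised = (table.n_common + 1.0) ** table.alpha
        assert raised.mean() / table.normalizer == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_on_random_graphs(self, rng):
        checked = 0
        for _ in range(60):
            H = random_hypergraph(rng, max_nodes=7)
            expected = brute_xi(H, alpha=1.3)
            table = intimacy(H, alpha=1.3)
            for (j, i), xi in expected.items():
                assert transmission_prob(j, i, table) == pytest.approx(xi)
                checked += 1
        assert checked > 100

    def test_no_adjacent_pairs_raises(self):
        with pytest.raises(HypergraphError):
            intimacy(DirectedHypergraph(3), alpha=1.0)

    def test_lookup_rejects_non_adjacent_pair(self, star_network):
        table = intimacy(star_network, alpha=1.0)
        with pytest.raises(HypergraphError):
            transmission_prob(1, 2, table)

    def test_transmission_prob_caps_at_one(self):
        # receiver-side heterogeneity: pairs sharing a common in-neighbor
        # get omega > 1 and must be capped
        H = DirectedHypergraph(5)
        H.add_edge(EdgeKind.ONE_WAY, {1, 2}, {0})      # 1,2 follow 0
        H.add_edge(EdgeKind.ONE_WAY, {1}, {2})          # 1 follows 2
        table = intimacy(H, alpha=2.0)
        assert table.omega.max() > 1.0
        # pair (2 -> 1) shares influence source 0: omega = 2, capped to 1
        assert transmission_prob(2, 1, table) == 1.0
        # pairs with no common source keep omega < 1 uncapped
        assert transmission_prob(0, 1, table) == pytest.approx(0.5)


class TestTransitionProbabilities:
    def test_dropout_is_confidence(self):
        assert dropout_prob(0.0) == 0.0
        assert dropout_prob(0.3) == pytest.approx(0.3)
        assert dropout_prob(1 - np.exp(-np.log(2))) == pytest.approx(0.5)

    @pytest.mark.parametrize("t,lam,expected", [
        (0, 0.5, 0.0),
        (3, 0.0, 0.0),
        (2, 0.5, 1.0 - np.exp(-1.0)),
    ])
    def test_recovery_closed_form(self, t, lam, expected):
        assert recovery_prob(t, lam) == pytest.approx(expected)

    def test_negative_lambda_rejected(self):
        with pytest.raises(ConfigError):
            recovery_prob(1, -0.1)

    def test_threshold_rule(self, star_network):
        attrs = NodeAttributes(
            w=np.zeros(5), C=np.full(5, 0.5), K=np.array([0, 1, 1, 1, 1])
        )
        states = np.array([I, E, S, S, S], dtype=np.int8)
        sets = star_network.in_neighbor_sets()
        assert threshold_met(1, states, attrs, sets)      # m=1 >= 0.5*1
        attrs_zero = NodeAttributes(w=np.zeros(5), C=np.zeros(5),
                                    K=np.array([0, 1, 1, 1, 1]))
        assert threshold_met(1, states, attrs_zero, sets)  # theta=0
        # the hub has no in-neighbors: never activates
        assert not threshold_met(0, states, attrs_zero, sets)

    def test_threshold_fraction_of_k(self):
        H = DirectedHypergraph(5)
        H.add_edge(EdgeKind.ONE_WAY, {4}, {0, 1, 2, 3})   # K(4) = 4
        attrs = NodeAttributes(w=np.zeros(5), C=np.full(5, 0.5),
                               K=np.array([0, 0, 0, 0, 4]))
        sets = H.in_neighbor_sets()
        states = np.array([I, S, S, S, E], dtype=np.int8)
        assert not threshold_met(4, states, attrs, sets)   # m=1 < 2
        states = np.array([I, I, S, S, E], dtype=np.int8)
        assert threshold_met(4, states, attrs, sets)       # m=2 >= 2


class TestInitialize:
    def test_rho_one_infects_everyone(self, star_network, rng):
        st = initialize(star_network, ContagionConfig(rho0=1.0), rng=rng)
        assert (st.states == I).all()

    def test_infected_count_rounds(self, rng):
        H = DirectedHypergraph(100)
        H.add_edge(EdgeKind.ONE_WAY, {1}, {0})
        st = initialize(H, ContagionConfig(rho0=0.05, xi=1.0), rng=rng)
        assert (st.states == I).sum() == 5

    def test_scripted_seed_set(self, star_network, rng):
        st = initialize(star_network, ContagionConfig(), rng=rng, seeds=[0])
        assert st.states[0] == I and (st.states[1:] == S).all()


class TestStep:
    def test_star_all_probabilities_one(self, star_network):
        cfg = ContagionConfig(xi=1.0, eta=0.0, gamma=0.0, lam=0.0)
        st = initialize(star_network, cfg, rng=np.random.default_rng(0), seeds=[0])
        step(st)
        assert (st.states[1:] == E).all() and st.states[0] == I

    def test_no_infected_sources_leaves_s_untouched(self, star_network, rng):
        cfg = ContagionConfig(xi=1.0, eta=0.0, gamma=0.0)
        st = initialize(star_network, cfg, rng=rng, seeds=[1])
        st.states[1] = R   # no I nodes anywhere
        step(st)
        assert (st.states == np.array([S, R, S, S, S])).all()

    def test_oracle_equivalence_on_scripted_draws(self, rng):
        """step() must match a literal rule-by-rule oracle, draw for
        draw, across random small hypergraphs, states and modes."""
        cases = 0
        while cases < 1000:
            H = random_hypergraph(rng, max_nodes=6)
            n = H.n_nodes
            states = rng.integers(0, 4, size=n).astype(np.int8)
            C = rng.random(n)
            fixed = rng.random() < 0.5
            kw = dict(mode="fixed_rate" if fixed else "threshold", C=C)
            cfg = ContagionConfig(alpha=1.3, lam=0.3)
            if fixed:
                cfg.mode = Mode.FIXED_RATE
                cfg.beta, cfg.eta, cfg.gamma = rng.random(3)
                kw.update(beta=cfg.beta, eta=cfg.eta, gamma=cfg.gamma)
            draws = rng.random(4 * n + 100).tolist()
            t = int(rng.integers(0, 5))

            expected = brute_step(states, H, draws, t, alpha=1.3, lam=0.3, **kw)

            sim = initialize(H, cfg, rng=np.random.default_rng(0), seeds=[0],
                             attrs=NodeAttributes(w=-np.log1p(-C), C=C, K=None))
            sim.states = states.copy()
            sim.t = t
            sim.rng = ScriptedRng(uniforms=draws)
            step(sim)
            np.testing.assert_array_equal(sim.states, expected)
            cases += 1


class TestTrajectories:
    def test_conservation_and_monotonicity(self, small_social):
        tr = run(small_social, ContagionConfig(seed=3), rng=np.random.default_rng(3))
        sums = tr.densities.sum(axis=1)
        assert np.allclose(sums, 1.0, atol=1e-12)
        assert (np.diff(tr.r) >= -1e-15).all()
        assert (np.diff(tr.s) <= 1e-15).all()

    def test_r_absorbing_per_node(self, small_social):
        tr = run(small_social, ContagionConfig(seed=8),
                 rng=np.random.default_rng(8), record_states=True)
        hist = tr.states_history
        was_r = hist[:-1] == R
        assert (hist[1:][was_r] == R).all()

    def test_rho_one_leaves_no_s_or_e(self, small_social):
        tr = run(small_social, ContagionConfig(rho0=1.0, seed=1),
                 rng=np.random.default_rng(1))
        assert (tr.s == 0).all() and (tr.e == 0).all()
        assert tr.i[-1] == 0.0

    def test_large_lambda_extinguishes_spreaders_fast(self, small_social):
        # gamma(t) ~ 1 for t >= 1, so infectious nodes vanish within a
        # few steps; the exposed pool then drains through eta and the
        # run absorbs well before the horizon
        tr = run(small_social, ContagionConfig(lam=5.0, seed=2),
                 rng=np.random.default_rng(2))
        assert (tr.i[5:] < 0.01).all()
        assert tr.absorbed and tr.n_steps < 100

    def test_all_runs_absorb_with_positive_lambda(self):
        for s in range(100):
            H = grow_directed_social(GrowthConfig(N=120, seed=s))
            tr = run(H, ContagionConfig(lam=0.1, max_steps=500),
                     rng=np.random.default_rng(s))
            assert tr.absorbed and tr.n_steps < 500

    def test_pure_threshold_limit_matches_closure(self, rng):
        """With xi=1, eta=0, gamma=0 the absorbed infected set equals the
        monotone closure of the in-neighbor threshold rule, and each node
        activates no earlier than its closure round."""
        for _ in range(300):
            H = random_hypergraph(rng, max_nodes=5)
            n = H.n_nodes
            theta = rng.random(n)
            seeds = [int(v) for v in
                     rng.choice(n, size=int(rng.integers(1, n + 1)), replace=False)]
            expected, rounds = threshold_closure(H, set(seeds), theta)

            cfg = ContagionConfig(xi=1.0, eta=0.0, gamma=0.0, lam=0.0,
                                  max_steps=4 * n + 4)
            attrs = NodeAttributes(w=-np.log1p(-np.minimum(theta, 1 - 1e-12)),
                                   C=theta, K=None)
            tr = run(H, cfg, rng=np.random.default_rng(0), seeds=seeds,
                     attrs=attrs, record_states=True)
            final = tr.states_history[-1]
            got = {int(v) for v in np.flatnonzero(final == I)}
            assert got == expected
            for v, rnd in rounds.items():
                first_i = int(np.argmax(tr.states_history[:, v] == I))
                assert first_i >= rnd

    def test_ensemble_reproducible_and_padded(self):
        cfg = ContagionConfig(seed=7, max_steps=60)
        a = run_ensemble(GrowthConfig(N=200), cfg, n_reps=5)
        b = run_ensemble(GrowthConfig(N=200), cfg, n_reps=5)
        np.testing.assert_array_equal(a.mean, b.mean)
        assert (a.std >= 0).all()
        assert a.mean.sum(axis=1) == pytest.approx(1.0, abs=1e-12)


class TestClassicalBaselines:
    def test_zero_infection_prob_dies_immediately(self, small_social, rng):
        tr = classical_sir(small_social, ClassicalRates(infection=0.0, recovery=0.5),
                           rng=rng)
        assert tr.s[0] == tr.s[-1]
        assert tr.absorbed

    def test_complete_graph_saturates_in_one_step(self):
        H = DirectedHypergraph(6)
        for u in range(6):
            for v in range(u + 1, 6):
                H.add_edge(EdgeKind.MUTUAL, {u}, {v})
        tr = classical_sir(H, ClassicalRates(infection=1.0, recovery=0.0),
                           rho0=1 / 6, max_steps=3, rng=np.random.default_rng(0))
        assert tr.densities[1, I] == pytest.approx(1.0)

    def test_seir_latency_delays_peak(self, small_social):
        rates = ClassicalRates()
        peaks_sir, peaks_seir = [], []
        for s in range(15):
            peaks_sir.append(classical_sir(small_social, rates,
                             rng=np.random.default_rng(s)).i.argmax())
            peaks_seir.append(classical_seir(small_social, rates,
                              rng=np.random.default_rng(1000 + s)).i.argmax())
        assert np.mean(peaks_sir) <= np.mean(peaks_seir)
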