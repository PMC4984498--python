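"""Mk2 likelihood, fitting, MCMC and marginal reconstruction."""

import itertools

import numpy as np
import pytest
from scipy import linalg, stats

from sdmevol import mk2, treeio
from sdmevol import synthetic_data as syn
from sdmevol.mk2 import Mk2Model, fit_mk2, lrt, marginal_asr_mk2, mk2_loglik, mk2_mcmc

from conftest import random_binary_tree


def enumeration_loglik(tree, tip_state, model):
    """Independent oracle: sum the joint probability over all internal-node
    state assignments (exponential in the number of internal nodes)."""
    P = np.empty((tree.n_nodes, 2, 2))
    for v in range(tree.n_nodes):
        Q = np.array([[-model.q01, model.q01], [model.q10, -model.q10]])
        P[v] = linalg.expm(Q * tree.lengths[v])
    internals = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
    D = np.zeros(2)  # root partial per root state
    for assign in itertools.product([0, 1], repeat=len(internals)):
        amap = dict(zip(internals, assign))
        p = 1.0
        for v in range(tree.n_nodes):
            par = tree.parent[v]
            if par < 0:
                continue
            sv = amap[v] if v in amap else tip_state[v]
            p *= P[v, amap[par], sv]
        D[amap[tree.root]] += p
    if model.root_prior == "flat":
        w = np.array([0.5, 0.5])
    elif model.root_prior == "obs-weighted":
        w = D / D.sum()
    elif model.root_prior.startswith("fixed:"):
        w = np.eye(2)[int(model.root_prior[-1])]
    else:
        s = model.q01 + model.q10
        w = np.array([model.q10 / s, model.q01 / s])
    return np.log(w @ D)


class TestLoglik:
    def test_zero_rates_monomorphic_fixed_root(self, yule100):
        states = np.ones(yule100.n_tips, dtype=np.int8)
        ll = mk2_loglik(yule100, states, Mk2Model(0.0, 0.0, "fixed:1"))
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_cherry_against_matrix_exponential(self):
        tree = treeio.read_newick("(A:1,B:1);")
        q = 0.5
        P = linalg.expm(np.array([[-q, q], [q, -q]]) * 1.0)
        expected = np.log(0.5 * P[0, 0] ** 2 + 0.5 * P[1, 0] ** 2)
        ll = mk2_loglik(tree, np.zeros(2, dtype=np.int8), Mk2Model(q, q, "flat"))
        assert ll == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("prior", ["flat", "obs-weighted", "stationary", "fixed:1"])
    def test_pruning_equals_enumeration(self, prior):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(3, 7))
            tree = random_binary_tree(rng, n)
            model = Mk2Model(rng.uniform(0.01, 2.0), rng.uniform(0.01, 2.0), prior)
            states = rng.integers(0, 2, n).astype(np.int8)
            ll = mk2_loglik(tree, states, model)
            assert ll == pytest.approx(enumeration_loglik(tree, states, model), abs=1e-10)

    def test_pattern_probabilities_conserve(self):
        rng = np.random.default_rng(5)
        tree = random_binary_tree(rng, 6)
        model = Mk2Model(0.7, 0.2, "fixed:1")
        total = sum(
            np.exp(mk2_loglik(tree, np.array(pat, dtype=np.int8), model))
            for pat in itertools.product([0, 1], repeat=6)
        )
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_polytomy_resolution_invariance(self):
        a = treeio.read_newick("((A:1,B:1):0,C:1);")
        b = treeio.read_newick("(A:1,(B:1,C:1):0);")
        model = Mk2Model(0.4, 0.9, "flat")
        s = {"A": 0, "B": 1, "C": 1}
        lla = mk2_loglik(a, treeio.TipStateTable.from_dict(s).states_for(a), model)
        llb = mk2_loglik(b, treeio.TipStateTable.from_dict(s).states_for(b), model)
        assert lla == pytest.approx(llb, abs=1e-12)

    def test_unknown_states_rejected(self, tree3):
        tab = treeio.TipStateTable(["A", "B", "C"], [0, 1, treeio.UNKNOWN])
        with pytest.raises(ValueError):
            mk2_loglik(tree3, tab, Mk2Model(0.1, 0.1))


class TestFit:
    def test_free_fit_at_least_as_good_as_constrained(self, yule100):
        states, _ = syn.simulate_binary_character(
            yule100, syn.CharSimParams(0.02, 0.06, 1, seed=3)
        )
        _, ll_eq = fit_mk2(yule100, states, constrain_equal=True)
        _, ll_free = fit_mk2(yule100, states)
        assert ll_free >= ll_eq - 1e-8

    def test_monomorphic_data_drives_rate_to_bound(self, yule100):
        states = np.ones(yule100.n_tips, dtype=np.int8)
        with pytest.warns(UserWarning):
            model, _ = fit_mk2(yule100, states, root_prior="fixed:1")
        assert model.q10 <= 1e-6  # no 1->0 transitions observed

    def test_recovery_on_large_tree(self):
        tree = syn.simulate_bd_tree(syn.BDParams(0.1, 0.0, 1000, seed=21))
        states, _ = syn.simulate_binary_character(
            tree, syn.CharSimParams(0.1, 0.05, 1, seed=22)
        )
        model, _ = fit_mk2(tree, states)
        assert model.q01 == pytest.approx(0.1, rel=0.5)
        assert model.q10 == pytest.approx(0.05, rel=0.5)


class TestLRT:
    def test_zero_difference_gives_p_one(self):
        comp = lrt(-10.0, -10.0, df=1)
        assert comp.p_value == pytest.approx(1.0)

    def test_critical_value_df1(self):
        comp = lrt(0.0, 3.841 / 2, df=1)
        assert comp.p_value == pytest.approx(0.05, abs=5e-4)

    def test_small_stat_df2(self):
        comp = lrt(0.0, 0.05, df=2)
        assert comp.p_value == pytest.approx(stats.chi2.sf(0.1, 2), abs=1e-12)
        assert comp.p_value == pytest.approx(0.951, abs=1e-3)

    def test_optimizer_failure_detected(self):
        with pytest.raises(ValueError, match="optimizer"):
            lrt(-5.0, -6.0, df=1)


class TestMCMC:
    def test_reproducible(self, yule100):
        states, _ = syn.simulate_binary_character(
            yule100, syn.CharSimParams(0.02, 0.02, 1, seed=4)
        )
        a = mk2_mcmc(yule100, states, n_steps=200, seed=42)
        b = mk2_mcmc(yule100, states, n_steps=200, seed=42)
        assert np.array_equal(a.q01, b.q01) and np.array_equal(a.q10, b.q10)
        assert len(a) == 150  # 25% burn-in discarded

    def test_uninformative_data_returns_prior(self):
        # 2 identical tips on a short cherry: likelihood nearly flat in q,
        # so the posterior mean should be near the exponential prior mean.
        tree = treeio.read_newick("(A:0.01,B:0.01);")
        states = np.ones(2, dtype=np.int8)
        trace = mk2_mcmc(tree, states, prior_mean=0.1, n_steps=4000, seed=0,
                         root_prior="fixed:1")
        assert np.mean(trace.q01) == pytest.approx(0.1, rel=0.35)
        assert np.mean(trace.q10) == pytest.approx(0.1, rel=0.35)

    def test_credible_interval_coverage(self):
        """95% equal-tailed intervals cover the generating rates in most
        replicate datasets (scaled-down coverage simulation)."""
        q01, q10 = 0.03, 0.06
        hits = 0
        n_data = 24
        for s in range(n_data):
            tree = syn.simulate_bd_tree(syn.BDParams(0.1, 0.0, 100, seed=1000 + s))
            states, _ = syn.simulate_binary_character(
                tree, syn.CharSimParams(q01, q10, 1, seed=2000 + s)
            )
            trace = mk2_mcmc(tree, states, n_steps=600, seed=s)
            lo1, hi1 = np.quantile(trace.q01, [0.025, 0.975])
            lo2, hi2 = np.quantile(trace.q10, [0.025, 0.975])
            hits += (lo1 <= q01 <= hi1) and (lo2 <= q10 <= hi2)
        assert hits / n_data >= 0.8

    def test_pp_rules(self):
        base = dict(loglik=np.zeros(4), prior_mean=0.1, n_steps=4, burn_in=0.0)
        hi = mk2.MCMCTrace(q01=np.full(4, 0.1), q10=np.full(4, 0.2), **base)
        res = mk2.posterior_prob_asymmetry(hi)
        assert res.pp == 1.0 and res.significant
        mid = mk2.MCMCTrace(q01=np.array([0.1, 0.2, 0.1, 0.2]),
                            q10=np.array([0.2, 0.1, 0.2, 0.1]), **base)
        res = mk2.posterior_prob_asymmetry(mid)
        assert res.pp == 0.5 and not res.significant
        # 0.97 is inside the two-sided significance band
        q10 = np.concatenate([np.full(97, 0.2), np.full(3, 0.01)])
        trace = mk2.MCMCTrace(q01=np.full(100, 0.1), q10=q10,
                              loglik=np.zeros(100), prior_mean=0.1,
                              n_steps=100, burn_in=0.0)
        res = mk2.posterior_prob_asymmetry(trace)
        assert res.pp == pytest.approx(0.97) and not res.significant

    def test_empty_trace_rejected(self):
        trace = mk2.MCMCTrace(np.array([]), np.array([]), np.array([]), 0.1, 0, 0.0)
        with pytest.raises(ValueError):
            mk2.posterior_prob_asymmetry(trace)


class TestMarginalASR:
    def test_zero_rates_propagate_tip_state(self, yule100):
        states = np.ones(yule100.n_tips, dtype=np.int8)
        rec = marginal_asr_mk2(yule100, states, Mk2Model(0.0, 0.0, "fixed:1"))
        assert np.allclose(rec.internal_probs()[:, 1], 1.0)

    def test_rows_sum_to_one(self, yule100):
        states, _ = syn.simulate_binary_character(
            yule100, syn.CharSimParams(0.05, 0.02, 1, seed=6)
        )
        rec = marginal_asr_mk2(yule100, states, Mk2Model(0.05, 0.02))
        assert np.allclose(rec.probs.sum(axis=1), 1.0, atol=1e-10)

    def test_symmetric_cherry_root_is_even(self):
        tree = treeio.read_newick("(A:1,B:1);")
        rec = marginal_asr_mk2(tree, np.array([0, 1], dtype=np.int8),
                               Mk2Model(0.5, 0.5, "flat"))
        assert np.allclose(rec.root_probs, [0.5, 0.5], atol=1e-12)

    def test_matches_exhaustive_enumeration(self):
        """Marginals from the two-pass algorithm equal brute-force sums over
        all joint internal-state assignments."""
        rng = np.random.default_rng(23)
        for _ in range(10):
            n = int(rng.integers(3, 6))
            tree = random_binary_tree(rng, n)
            model = Mk2Model(rng.uniform(0.05, 1.0), rng.uniform(0.05, 1.0), "flat")
            states = rng.integers(0, 2, n).astype(np.int8)
            rec = marginal_asr_mk2(tree, states, model)
            # oracle: per-node marginal via enumeration
            P = np.array([
                linalg.expm(np.array([[-model.q01, model.q01],
                                      [model.q10, -model.q10]]) * t)
                for t in tree.lengths
            ])
            internals = [v for v in range(tree.n_nodes) if not tree.is_tip(v)]
            marg = np.zeros((tree.n_nodes, 2))
            for assign in itertools.product([0, 1], repeat=len(internals)):
                amap = dict(zip(internals, assign))
                p = 0.5
                for v in range(tree.n_nodes):
                    par = tree.parent[v]
                    if par < 0:
                        continue
                    sv = amap[v] if v in amap else states[v]
                    p *= P[v, amap[par], sv]
                for v in internals:
                    marg[v, amap[v]] += p
            marg = marg[internals]
            marg /= marg.sum(axis=1, keepdims=True)
            assert np.allclose(rec.probs[internals], marg, atol=1e-10)
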