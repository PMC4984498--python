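"""BiSSE likelihood, constrained fits, and marginal reconstruction."""

import numpy as np
import pytest

from sdmevol import bisse, mk2, treeio
from sdmevol import synthetic_data as syn
from sdmevol._core import bisse_prune
from sdmevol.bisse import BisseModel, bisse_loglik, fit_yule, yule_loglik

from conftest import random_binary_tree


def simulate_bisse_tree(la0, la1, mu, q01, q10, n_tips, root_state, rng):
    """Minimal forward simulator with state-dependent speciation (test oracle
    for the power of the diversification test; extinction shared)."""
    while True:
        parent = [-1]
        start = [0.0]
        state = [root_state]
        children = [[]]
        alive = []
        t = 0.0
        for _ in range(2):
            parent.append(0); start.append(0.0); state.append(root_state)
            children.append([]); children[0].append(len(parent) - 1)
            alive.append(len(parent) - 1)
        end = {}
        failed = False
        while len(alive) < n_tips:
            lam = np.array([la0 if state[v] == 0 else la1 for v in alive])
            qr = np.array([q01 if state[v] == 0 else q10 for v in alive])
            rates = lam + mu + qr
            tot = rates.sum()
            t += rng.exponential(1.0 / tot)
            i = rng.choice(len(alive), p=rates / tot)
            v = alive[i]
            u = rng.random() * rates[i]
            if u < lam[i]:
                end[v] = t
                alive[i] = alive[-1]; alive.pop()
                for _ in range(2):
                    parent.append(v); start.append(t); state.append(state[v])
                    children.append([]); children[v].append(len(parent) - 1)
                    alive.append(len(parent) - 1)
            elif u < lam[i] + mu:
                end[v] = t
                alive[i] = alive[-1]; alive.pop()
                if not alive:
                    failed = True
                    break
            else:
                state[v] = 1 - state[v]
        if failed:
            continue
        t_end = t + rng.exponential(1.0 / len(alive))
        for v in alive:
            end[v] = t_end
        end[0] = 0.0
        alive_set = set(alive)
        b = treeio._Builder()
        tip_states = []

        def convert(v):
            if not children[v]:
                if v not in alive_set:
                    return None
                tip_states.append(state[v])
                return ("tip", b.add_tip(f"t{len(tip_states)}", end[v] - start[v]))
            kids = [k for k in (convert(c) for c in children[v]) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                kind, bid = kids[0]
                if kind == "tip":
                    b.tip_lengths[bid] += end[v] - start[v]
                else:
                    ch, ln = b.internals[-bid - 1]
                    b.internals[-bid - 1] = (ch, ln + end[v] - start[v])
                return kids[0]
            return ("internal", b.add_internal([bid for _k, bid in kids], end[v] - start[v]))

        res = convert(0)
        if res is None or res[0] != "internal":
            continue
        ch, _ln = b.internals[-res[1] - 1]
        b.internals[-res[1] - 1] = (ch, 0.0)
        return b.build(res[1]), np.array(tip_states, dtype=np.int8)


class TestLoglik:
    @pytest.mark.parametrize("cond", [True, False])
    def test_matches_yule_closed_form(self, yule100, cond):
        states = np.ones(yule100.n_tips, dtype=np.int8)
        m = BisseModel(0.1, 0.1, 0, 0, 0, 0, condition_on_survival=cond)
        assert bisse_loglik(yule100, states, m) == pytest.approx(
            yule_loglik(yule100, 0.1, cond), abs=1e-8
        )

    def test_full_sampling_boundary_condition(self, yule100):
        """With f = 1 and mu = 0 lineages cannot vanish: E stays 0."""
        states = np.ones(yule100.n_tips, dtype=np.int8)
        m = BisseModel(0.1, 0.1, 0, 0, 0.02, 0.02)
        E0, E1, _D0, _D1, _ls = bisse_prune(
            yule100.postorder, yule100.child1, yule100.child2, yule100.lengths,
            yule100.n_tips, states, 0.1, 0.1, 0.0, 0.0, 0.02, 0.02, 1.0, 1.0,
            0.01 / m.rate_scale(),
        )
        assert np.all(E0 == 0) and np.all(E1 == 0)

    def test_extinction_probabilities_bounded(self, yule100):
        states = np.ones(yule100.n_tips, dtype=np.int8)
        m = BisseModel(0.2, 0.3, 0.1, 0.05, 0.02, 0.02, f0=0.4, f1=0.4)
        E0, E1, D0, D1, _ls = bisse_prune(
            yule100.postorder, yule100.child1, yule100.child2, yule100.lengths,
            yule100.n_tips, states, 0.2, 0.3, 0.1, 0.05, 0.02, 0.02, 0.4, 0.4,
            0.01 / m.rate_scale(),
        )
        for arr in (E0, E1):
            assert np.all((arr >= 0) & (arr <= 1))
        assert np.all(D0 >= 0) and np.all(D1 >= 0)

    def test_factorizes_into_tree_and_character_at_zero_extinction(self):
        """With state-independent lambda, mu = 0 and f = 1 the joint
        likelihood is exactly (pure-birth tree) x (Mk2 character)."""
        rng = np.random.default_rng(31)
        for s in range(3):
            tree = syn.simulate_bd_tree(syn.BDParams(0.1, 0, 20, seed=40 + s))
            states, _ = syn.simulate_binary_character(
                tree, syn.CharSimParams(0.05, 0.1, 1, seed=50 + s)
            )
            ts = states.states_for(tree)
            m = BisseModel(0.1, 0.1, 0, 0, 0.05, 0.1,
                           condition_on_survival=False, root_prior="flat")
            lhs = bisse_loglik(tree, ts, m)
            rhs = yule_loglik(tree, 0.1, False) + mk2.mk2_loglik(
                tree, ts, mk2.Mk2Model(0.05, 0.1, "flat")
            )
            assert lhs == pytest.approx(rhs, abs=1e-7)

    def test_label_swap_symmetry(self, yule100):
        states, _ = syn.simulate_binary_character(
            yule100, syn.CharSimParams(0.05, 0.02, 1, seed=8)
        )
        ts = states.states_for(yule100)
        m = BisseModel(0.12, 0.08, 0.01, 0.03, 0.05, 0.02, f0=0.8, f1=0.6)
        m_swapped = BisseModel(0.08, 0.12, 0.03, 0.01, 0.02, 0.05, f0=0.6, f1=0.8)
        assert bisse_loglik(yule100, ts, m) == pytest.approx(
            bisse_loglik(yule100, (1 - ts).astype(np.int8), m_swapped), abs=1e-7
        )

    def test_invalid_sampling_fraction_rejected(self):
        with pytest.raises(ValueError):
            BisseModel(0.1, 0.1, 0, 0, 0.1, 0.1, f0=0.0)


class TestYuleFit:
    def test_recovers_generating_rate(self):
        lams = [fit_yule(syn.simulate_bd_tree(syn.BDParams(0.1, 0, 200, seed=s)))[0]
                for s in range(20)]
        assert np.mean(lams) == pytest.approx(0.1, abs=0.01)

    def test_mle_maximizes_closed_form(self, yule100):
        lam, ll = fit_yule(yule100)
        for other in (lam * 0.9, lam * 1.1):
            assert yule_loglik(yule100, other) < ll


class TestTransitionTest:
    def test_rates_match_mk2_when_diversification_is_neutral(self):
        tree = syn.simulate_bd_tree(syn.BDParams(0.1, 0, 200, seed=60))
        states, _ = syn.simulate_binary_character(
            tree, syn.CharSimParams(0.02, 0.05, 1, seed=61)
        )
        m_bisse, comp = bisse.fit_bisse_transition_test(tree, states)
        m_mk2, _ = mk2.fit_mk2(tree, states)
        assert m_bisse.q01 == pytest.approx(m_mk2.q01, rel=0.05)
        assert m_bisse.q10 == pytest.approx(m_mk2.q10, rel=0.05)
        assert comp.loglik_alt >= comp.loglik_null

    def test_detects_strong_asymmetry(self, lizard_fixture):
        fx = lizard_fixture
        keep = [s for s, x in zip(fx.states.species, fx.states.state) if x != treeio.UNKNOWN]
        tree = treeio.prune_to_taxa(fx.tree, keep)
        _m, comp = bisse.fit_bisse_transition_test(tree, fx.states)
        assert comp.p_value < 0.05
        assert _m.q10 > _m.q01


class TestDiversificationTest:
    def test_dll_non_negative(self, yule100):
        states, _ = syn.simulate_binary_character(
            yule100, syn.CharSimParams(0.02, 0.02, 1, seed=70)
        )
        comp = bisse.fit_bisse_diversification_test(yule100, states)
        assert comp.statistic >= 0

    def test_power_against_state_dependent_speciation(self):
        """A 2x speciation-rate ratio is detected in most replicates."""
        rng = np.random.default_rng(123)
        rejections = 0
        n_rep = 5
        for _ in range(n_rep):
            tree, ts = simulate_bisse_tree(
                0.2, 0.1, 0.0, 0.03, 0.03, 250, root_state=1, rng=rng
            )
            if min((ts == 0).sum(), (ts == 1).sum()) < 10:
                continue
            comp = bisse.fit_bisse_diversification_test(tree, ts)
            rejections += comp.p_value < 0.05
        assert rejections >= (n_rep + 1) // 2


class TestMarginalASR:
    def test_monomorphic_neutral_reconstruction(self, yule100):
        states = np.ones(yule100.n_tips, dtype=np.int8)
        m = BisseModel(0.1, 0.1, 0, 0, 0.0, 0.0, root_prior="fixed:1")
        rec = bisse.marginal_asr_bisse(yule100, states, m)
        assert np.allclose(rec.probs[yule100.n_tips :, 1], 1.0)

    def test_rows_sum_to_one(self, yule100):
        states, _ = syn.simulate_binary_character(
            yule100, syn.CharSimParams(0.05, 0.02, 1, seed=80)
        )
        m = BisseModel(0.1, 0.1, 0.01, 0.01, 0.05, 0.02)
        rec = bisse.marginal_asr_bisse(yule100, states, m)
        assert np.allclose(rec.probs.sum(axis=1), 1.0, atol=1e-8)

    def test_converges_to_mk2_marginals(self, yule100):
        """With equal lambda, mu -> 0 and f = 1, BiSSE marginals reduce to
        the pure character-model reconstruction."""
        states, _ = syn.simulate_binary_character(
            yule100, syn.CharSimParams(0.03, 0.06, 1, seed=81)
        )
        ts = states.states_for(yule100)
        rec_mk2 = mk2.marginal_asr_mk2(yule100, ts, mk2.Mk2Model(0.03, 0.06, "flat"))
        m = BisseModel(0.1, 0.1, 1e-9, 1e-9, 0.03, 0.06,
                       condition_on_survival=False, root_prior="flat")
        rec_b = bisse.marginal_asr_bisse(yule100, ts, m)
        assert np.abs(rec_b.probs - rec_mk2.probs).max() < 1e-4
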