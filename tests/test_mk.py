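"""Mk1 likelihood, rate estimation, marginal reconstruction, decision rule."""

import math

import numpy as np
import pytest
from scipy.linalg import expm

from _oracles import exhaustive_log_likelihood, exhaustive_marginals
from conftest import random_matrix, random_tree
from habitevol.io import CharacterMatrix, parse_newick
from habitevol.mk import (
    AsrResult,
    MkModel,
    apply_decision_rule,
    estimate_rate,
    marginal_reconstruction,
    mk_transition_matrix,
    tree_log_likelihood,
)
from habitevol.simulate import simulate_mk_character, simulate_yule_tree


class TestTransitionMatrix:
    def test_zero_rate_is_identity(self):
        P = mk_transition_matrix(MkModel(4, 0.0), 3.7)
        assert np.allclose(P, np.eye(4))

    def test_stationary_limit(self):
        P = mk_transition_matrix(MkModel(4, 1.0), 1e6)
        assert np.allclose(P, 0.25, atol=1e-9)

    @pytest.mark.parametrize("k,r,t", [(2, 1.0, 1.0), (3, 0.4, 2.5), (6, 0.07, 10.0)])
    def test_matches_matrix_exponential(self, k, r, t):
        model = MkModel(k, r)
        assert np.allclose(
            mk_transition_matrix(model, t), expm(model.q_matrix() * t), atol=1e-12
        )

    def test_k2_closed_form_value(self):
        P = mk_transition_matrix(MkModel(2, 1.0), 1.0)
        assert P[0, 1] == pytest.approx(0.5 * (1 - math.exp(-2)), abs=1e-9)
        assert np.allclose(P.sum(axis=1), 1.0)

    def test_negative_branch_rejected(self):
        with pytest.raises(ValueError):
            mk_transition_matrix(MkModel(2, 1.0), -0.1)


class TestTreeLogLikelihood:
    def test_two_tip_closed_form(self):
        # different states on a symmetric cherry: L = P_11(1) * P_12(1)
        t = parse_newick("(A:1,B:1);")
        m = CharacterMatrix.from_dict({"A": 2, "B": 3})
        lnl = tree_log_likelihood(t, m, MkModel(2, 1.0))
        assert lnl == pytest.approx(math.log(0.25 * (1 - math.exp(-4))), abs=1e-9)
        assert lnl == pytest.approx(-1.4047798, abs=1e-6)

    def test_all_missing_gives_zero(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        m = CharacterMatrix({"A": 0, "B": 0, "C": 0})
        assert tree_log_likelihood(t, m, MkModel(3, 0.7)) == pytest.approx(0.0, abs=1e-12)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            MkModel(1, 0.5)

    @pytest.mark.parametrize("k", [2, 3, 6])
    def test_pruning_matches_enumeration(self, rng, k):
        for _ in range(8):
            tree = random_tree(rng, int(rng.integers(3, 7)))
            matrix = random_matrix(rng, tree, k, missing_prob=0.15)
            model = MkModel(len(matrix.state_space), float(rng.uniform(0.05, 2.0)))
            got = tree_log_likelihood(tree, matrix, model)
            want = exhaustive_log_likelihood(tree, matrix, model)
            assert got == pytest.approx(want, abs=1e-8)

    def test_invariant_under_child_order(self, rng):
        tree = parse_newick("((A:1,B:2):0.5,(C:1,D:1):2);")
        swapped = parse_newick("((D:1,C:1):2,(B:2,A:1):0.5);")
        m = CharacterMatrix.from_dict({"A": 1, "B": 2, "C": 2, "D": 3})
        model = MkModel(3, 0.6)
        assert tree_log_likelihood(tree, m, model) == pytest.approx(
            tree_log_likelihood(swapped, m, model), abs=1e-12
        )

    def test_saturation_limit(self):
        # r -> inf: every observed tip contributes 1/k independently
        t = parse_newick("((A:1,B:1):1,(C:1,D:1):1);")
        m = CharacterMatrix.from_dict({"A": 1, "B": 2, "C": 3, "D": 1})
        lnl = tree_log_likelihood(t, m, MkModel(3, 1e5))
        assert lnl == pytest.approx(4 * math.log(1 / 3), abs=1e-6)

    def test_low_rate_penalises_variable_tips(self):
        t = parse_newick("(A:1,B:1);")
        m = CharacterMatrix.from_dict({"A": 2, "B": 3})
        lnls = [tree_log_likelihood(t, m, MkModel(2, r)) for r in (0.1, 0.01, 0.001)]
        assert lnls[0] > lnls[1] > lnls[2]  # -> -inf as r -> 0


class TestEstimateRate:
    def test_invariant_character_at_lower_bound(self):
        t = parse_newick("((A:1,B:1):1,C:2);")
        m = CharacterMatrix.from_dict({"A": 2, "B": 2, "C": 2})
        with pytest.warns(UserWarning, match="invariant"):
            model = estimate_rate(t, m)
        assert model.rate == pytest.approx(1e-8)

    def test_local_optimality(self, rng):
        tree = random_tree(rng, 16)
        hist = simulate_mk_character(tree, k=3, rate=0.3, root_state=1, seed=rng)
        from habitevol.simulate import character_matrix_from_history

        m = character_matrix_from_history(hist)
        if m.k < 2:
            pytest.skip("degenerate draw")
        model = estimate_rate(tree, m)
        best = tree_log_likelihood(tree, m, model)
        for factor in (0.5, 2.0):
            other = MkModel(model.k, model.rate * factor)
            assert best >= tree_log_likelihood(tree, m, other) - 1e-9

    def test_simulation_recovery_median(self):
        # 50 replicate characters on 128-tip Yule trees, true r = 0.5
        estimates = []
        for seed in range(50):
            rng = np.random.default_rng(10_000 + seed)
            tree = simulate_yule_tree(128, seed=rng)
            hist = simulate_mk_character(tree, k=4, rate=0.5, seed=rng)
            from habitevol.simulate import character_matrix_from_history

            m = character_matrix_from_history(hist)
            if m.k < 2:
                continue
            estimates.append(estimate_rate(tree, m).rate)
        med = float(np.median(estimates))
        assert 0.35 <= med <= 0.70


class TestMarginalReconstruction:
    def test_symmetric_cherry_is_even(self):
        t = parse_newick("(A:1,B:1);")
        m = CharacterMatrix.from_dict({"A": 2, "B": 3})
        asr = marginal_reconstruction(t, m, MkModel(2, 1.0))
        root_label = t.labels[t.root]
        assert np.allclose(asr.marginals[root_label], [0.5, 0.5], atol=1e-12)

    def test_matches_exhaustive_on_five_tips(self, rng):
        for _ in range(5):
            tree = random_tree(rng, 5)
            matrix = random_matrix(rng, tree, 3, missing_prob=0.1)
            model = MkModel(matrix.k, float(rng.uniform(0.1, 1.5)))
            asr = marginal_reconstruction(tree, matrix, model)
            want = exhaustive_marginals(tree, matrix, model)
            for label, expected in want.items():
                assert np.allclose(asr.marginals[label], expected, atol=1e-8), label

    def test_probabilities_sum_to_one(self, rng):
        tree = random_tree(rng, 20)
        matrix = random_matrix(rng, tree, 6, missing_prob=0.1)
        asr = marginal_reconstruction(tree, matrix, MkModel(matrix.k, 0.2))
        for p in asr.marginals.values():
            assert p.sum() == pytest.approx(1.0, abs=1e-9)
            assert np.all((p >= 0) & (p <= 1))

    def test_near_invariant_limit(self, rng):
        tree = random_tree(rng, 10)
        entries = {lab: 4 for lab in tree.tip_names}
        entries[sorted(tree.tip_names)[0]] = 5  # keep k = 2
        m = CharacterMatrix(entries)
        asr = marginal_reconstruction(tree, m, MkModel(2, 0.01))
        state4 = asr.state_space.index(4)
        changed = sorted(tree.tip_names)[0]
        for v in tree.internal_indices:
            lab = tree.labels[v]
            if tree.is_tip(v) or lab == changed:
                continue
            # nodes not adjacent to the lone divergent tip are confidently 4
            if changed not in {
                tree.labels[c] for c in tree.children[v]
            }:
                assert asr.marginals[lab][state4] > 0.99


class TestDecisionRule:
    def _asr(self, lm):
        return AsrResult(
            model=MkModel(2, 1.0),
            state_space=[2, 3],
            log_likelihood=0.0,
            marginals={"n": np.exp(lm) / np.exp(lm).sum()},
            log_marginals={"n": np.asarray(lm)},
        )

    def test_clear_rejection(self):
        sets = apply_decision_rule(self._asr([-10.0, -12.5]), 2.0)
        assert sets["n"] == frozenset({2})

    def test_small_difference_ambiguous(self):
        sets = apply_decision_rule(self._asr([-10.0, -11.0]), 2.0)
        assert sets["n"] == frozenset({2, 3})

    def test_boundary_difference_stays_ambiguous(self):
        # rejection requires a difference strictly greater than the threshold
        sets = apply_decision_rule(self._asr([-10.0, -12.0]), 2.0)
        assert sets["n"] == frozenset({2, 3})
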