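"""Pruning likelihood and relatedness-score tests against exhaustive oracles."""

import math

import numpy as np
import pytest

from conftest import exhaustive_column_likelihood, fig5_tree, make_fragments
from sigma2 import evo_model as em
from sigma2.tree_likelihood import (
    ColumnScorer,
    MissingLeafError,
    PhyloTree,
    TreeError,
    TreeNode,
    build_transitions,
    column_likelihood,
    column_score,
    fragment_pair_score,
    star_tree,
)


def perfect_fixation_transitions(tree, m):
    return build_transitions(tree, lambda n: em.perfect_fixation_transition(n.q, m))


class TestColumnLikelihood:
    def test_star_tree_delta_transitions(self):
        prior = np.array([0.1, 0.2, 0.3, 0.4])
        tree = star_tree(["a", "b", "c"], q=1.0, prior=prior)
        trans = perfect_fixation_transitions(tree, np.full(4, 0.25))
        for k, nuc in enumerate("ACGT"):
            obs = {"a": nuc, "b": nuc, "c": nuc}
            assert column_likelihood(tree, obs, trans) == pytest.approx(prior[k])

    def test_star_tree_zero_conservation_factorises(self, rng):
        m = rng.dirichlet(np.ones(4))
        tree = star_tree(["a", "b", "c"], q=0.5, prior=m)
        trans = build_transitions(tree, lambda n: em.perfect_fixation_transition(0.0, m))
        obs = {"a": "A", "b": "T", "c": "C"}
        expect = m[0] * m[3] * m[1]
        assert column_likelihood(tree, obs, trans) == pytest.approx(expect, rel=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_exhaustive_enumeration(self, seed):
        gen = np.random.default_rng(seed)
        qs = gen.uniform(0.2, 0.95, size=8)
        prior = gen.dirichlet(np.ones(4))
        tree = fig5_tree(*qs, prior=prior)
        m = gen.dirichlet(np.ones(4))
        if seed % 2:
            trans = perfect_fixation_transitions(tree, m)
        else:
            P = gen.random((4, 4))
            np.fill_diagonal(P, 0)
            P = P / P.sum(axis=0)
            trans = build_transitions(tree, lambda n: em.matrix_transition(n.q, P))
        obs = dict(zip(["L1", "L2", "L3", "L4", "L5"], "ATCCA"))
        got = column_likelihood(tree, obs, trans)
        want = exhaustive_column_likelihood(tree, obs, trans)
        assert got == pytest.approx(want, abs=1e-10)

    def test_n_marginalises(self, rng):
        tree = fig5_tree(*rng.uniform(0.3, 0.9, 8))
        m = rng.dirichlet(np.ones(4))
        trans = perfect_fixation_transitions(tree, m)
        obs_n = {"L1": "A", "L2": "N", "L3": "C"}
        total = sum(
            column_likelihood(tree, {"L1": "A", "L2": x, "L3": "C"}, trans)
            for x in "ACGT"
        )
        assert column_likelihood(tree, obs_n, trans) == pytest.approx(total, rel=1e-10)

    def test_child_order_invariance(self, rng):
        tree = fig5_tree(*rng.uniform(0.3, 0.9, 8))
        m = rng.dirichlet(np.ones(4))
        trans = perfect_fixation_transitions(tree, m)
        obs = {"L1": "A", "L2": "T", "L3": "C", "L4": "C", "L5": "A"}
        before = column_likelihood(tree, obs, trans)
        for node in tree.nodes():
            node.children.reverse()
        assert column_likelihood(tree, obs, trans) == pytest.approx(before, rel=1e-12)

    def test_errors(self, rng):
        tree = star_tree(["a", "b"], 0.5)
        trans = perfect_fixation_transitions(tree, np.full(4, 0.25))
        with pytest.raises(TreeError):
            column_likelihood(tree, {}, trans)
        with pytest.raises(MissingLeafError):
            column_likelihood(tree, {"zz": "A"}, trans)
        with pytest.raises(TreeError):
            column_likelihood(tree, {"a": "A"}, {})


class TestRestrict:
    def test_restrict_to_all_leaves_preserves_likelihood(self, rng):
        tree = fig5_tree(*rng.uniform(0.3, 0.9, 8))
        m = rng.dirichlet(np.ones(4))
        sub = tree.restrict(["L1", "L2", "L3", "L4", "L5"])
        obs = {"L1": "A", "L2": "T", "L3": "C", "L4": "G", "L5": "A"}
        v1 = column_likelihood(tree, obs, perfect_fixation_transitions(tree, m))
        v2 = column_likelihood(sub, obs, perfect_fixation_transitions(sub, m))
        assert v1 == pytest.approx(v2, rel=1e-10)

    def test_cherry_restriction_matches_marginalisation(self, rng):
        """Restricting to {L3, L4} composes q_b*q_c*q_d into the root path."""
        qs = rng.uniform(0.3, 0.9, 8)
        m = rng.dirichlet(np.ones(4))
        tree = fig5_tree(*qs)
        sub = tree.restrict(["L3", "L4"])
        assert sorted(sub.leaves()) == ["L3", "L4"]
        obs = {"L3": "C", "L4": "G"}
        full = column_likelihood(tree, obs, perfect_fixation_transitions(tree, m))
        restricted = column_likelihood(sub, obs, perfect_fixation_transitions(sub, m))
        assert restricted == pytest.approx(full, rel=1e-10)

    def test_single_leaf_closed_form(self, rng):
        qs = rng.uniform(0.3, 0.9, 8)
        prior = rng.dirichlet(np.ones(4))
        m = rng.dirichlet(np.ones(4))
        tree = fig5_tree(*qs, prior=prior)
        sub = tree.restrict(["L4"])
        # single branch below the root with the composed proximity
        branch = sub.root.children[0]
        assert branch.is_leaf and branch.name == "L4"
        T = em.perfect_fixation_transition(branch.q, m)
        expect = sum(prior[b] * T[em.NUC_INDEX["G"], b] for b in range(4))
        got = column_likelihood(sub, {"L4": "G"}, perfect_fixation_transitions(sub, m))
        assert got == pytest.approx(expect, rel=1e-12)

    def test_missing_leaf_error(self):
        tree = star_tree(["a", "b"], 0.5)
        with pytest.raises(MissingLeafError):
            tree.restrict(["zz"])
        with pytest.raises(MissingLeafError):
            tree.restrict([])


class TestColumnScore:
    def _pair_setup(self, q_join, q_leaf=0.9, m=None):
        if m is None:
            m = np.full(4, 0.25)
        a = TreeNode("a", q_leaf)
        b = TreeNode("b", q_leaf)
        x = TreeNode(None, q_join, [a])
        y = TreeNode(None, q_join, [b])
        treeAB = PhyloTree(TreeNode(None, None, [x, y]), m)
        treeA = treeAB.restrict(["a"])
        treeB = treeAB.restrict(["b"])
        mk = lambda t: perfect_fixation_transitions(t, m)
        return treeAB, treeA, treeB, mk(treeAB), mk(treeA), mk(treeB)

    def test_identity_scores_positive(self):
        args = self._pair_setup(0.9)
        s = column_score(*args[:3], {"a": "A"}, {"b": "A"}, *args[3:])
        assert s > 0

    def test_decoupling_limit(self):
        args = self._pair_setup(1e-6)
        s = column_score(*args[:3], {"a": "A"}, {"b": "A"}, *args[3:])
        assert abs(s) < 1e-4

    def test_two_leaf_closed_form(self):
        """Scalar oracle from the perfect-fixation transition probabilities."""
        m = np.array([0.1, 0.2, 0.3, 0.4])
        q_join, q_leaf = 0.7, 0.8
        args = self._pair_setup(q_join, q_leaf, m)
        s = column_score(*args[:3], {"a": "A"}, {"b": "A"}, *args[3:])
        T_path = em.perfect_fixation_transition(q_leaf * q_join, m)
        joint = sum(m[b] * T_path[0, b] ** 2 for b in range(4))
        single = sum(m[b] * T_path[0, b] for b in range(4))
        assert s == pytest.approx(math.log(joint) - 2 * math.log(single), rel=1e-10)

    def test_all_n_column_scores_zero(self):
        args = self._pair_setup(0.9)
        assert column_score(*args[:3], {"a": "N"}, {"b": "A"}, *args[3:]) == 0.0

    def test_empty_side_errors(self):
        args = self._pair_setup(0.9)
        with pytest.raises(TreeError):
            column_score(*args[:3], {}, {"b": "A"}, *args[3:])


class TestScorerEngine:
    def test_score_matrix_matches_scalar_scores(self):
        """Vectorised table engine vs scalar pruning, uniform background."""
        model = em.FunctionalModel.uniform_model()
        tree = star_tree(["x", "y"], 0.6, prior=model.marginal)
        scorer = ColumnScorer(tree, model)
        state, (fx, fy) = make_fragments({"x": "ACGTNAC", "y": "TTACGCA"})
        M = scorer.score_matrix(fx, fy)
        treeAB = tree
        treeA = tree.restrict(["x"])
        treeB = tree.restrict(["y"])
        tAB = scorer.transitions_for(treeAB)
        tA = scorer.transitions_for(treeA)
        tB = scorer.transitions_for(treeB)
        for i, ca in enumerate("ACGTNAC"):
            for j, cb in enumerate("TTACGCA"):
                want = column_score(
                    treeAB, treeA, treeB, {"x": ca}, {"y": cb}, tAB, tA, tB
                )
                assert M[i, j] == pytest.approx(want, abs=1e-10)

    def test_fragment_pair_score_additivity(self):
        model = em.FunctionalModel.uniform_model()
        tree = star_tree(["x", "y"], 0.6)
        scorer = ColumnScorer(tree, model)
        state, (fx, fy) = make_fragments(
            {"x": "ACGTACGTAC", "y": "ACGAACGTTC"}
        )
        total = fragment_pair_score(fx, fy, 0, 0, 10, scorer)
        partial = fragment_pair_score(fx, fy, 0, 0, 4, scorer) + fragment_pair_score(
            fx, fy, 4, 4, 6, scorer
        )
        assert total == pytest.approx(partial, rel=1e-12)
        M = scorer.score_matrix(fx, fy)
        assert fragment_pair_score(fx, fy, 2, 2, 1, scorer) == pytest.approx(M[2, 2])

    def test_fragment_pair_score_bounds(self):
        model = em.FunctionalModel.uniform_model()
        tree = star_tree(["x", "y"], 0.6)
        scorer = ColumnScorer(tree, model)
        state, (fx, fy) = make_fragments({"x": "ACGT", "y": "ACGT"})
        with pytest.raises(IndexError):
            fragment_pair_score(fx, fy, 2, 0, 4, scorer)

    def test_multi_row_table_matches_scalar(self, rng):
        """3-vs-2 row fragments: grid pruning vs scalar pruning per column."""
        model = em.default_background()
        tree = fig5_tree(*rng.uniform(0.4, 0.9, 8), prior=model.marginal)
        tree.root.children  # leaves L1..L5
        recs = {
            "L1": "ACGTAC",
            "L2": "ACGTCC",
            "L3": "AAGTAC",
            "L4": "ACGTAG",
            "L5": "TCGTAC",
        }
        state, frags = make_fragments(recs)
        scorer = ColumnScorer(tree, model, em.default_inverse_mutation())
        byname = {f.row_names[0]: f for f in frags}
        # fuse L1+L2 and L3+L4+L5 style pairing via direct fragments
        fa = byname["L1"]
        fb = byname["L3"]
        M = scorer.score_matrix(fa, fb)
        assert M.shape == (6, 6)
        assert np.all(np.isfinite(M))
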