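"""Fragment fusion, consistency labels, assembly, and the full aligner."""

import numpy as np
import pytest

from sigma2 import evo_model as em
from sigma2 import synthetic_data as sd
from sigma2.local_align import LocalAlignmentCandidate
from sigma2.progressive import (
    AlignmentError,
    ConsistencyError,
    assemble,
    bootstrap_tree,
    eligible_pairs,
    init_state,
    matches_per_base,
    pairwise_proximities,
    run_alignment,
)
from sigma2.tree_likelihood import star_tree


def cand(state, fa, fb, sa, sb, m, p=1e-6):
    a, b = (fa, fb) if fa.id < fb.id else (fb, fa)
    sa, sb = (sa, sb) if fa.id < fb.id else (sb, sa)
    return LocalAlignmentCandidate(a.id, b.id, sa, sb, m, 10.0, p, np.log(p))


def frag_on(state, sid, k=0):
    """k-th fragment (left to right) on sequence sid."""
    return state.fragments[state.order[sid][k]]


class TestStateBasics:
    def test_init_one_fragment_per_sequence(self):
        state = init_state({"a": "ACGT", "b": "ACGTT", "c": "AC"})
        assert len(state.fragments) == 3
        assert all(f.labels[f.row_names[0]] == (0,) for f in state.fragments.values())

    def test_init_length_one_sequences(self):
        state = init_state({"a": "A", "b": "C"})
        assert len(state.fragments) == 2
        assert all(f.length == 1 for f in state.fragments.values())

    def test_duplicate_ids_rejected(self):
        with pytest.raises(AlignmentError):
            init_state([("a", "ACGT"), ("a", "ACGT")])

    def test_empty_input_rejected(self):
        with pytest.raises(AlignmentError):
            init_state({"a": "ACGT"})
        with pytest.raises(AlignmentError):
            init_state({"a": "", "b": "ACGT"})

    def test_initially_all_pairs_eligible(self):
        state = init_state({"a": "ACGT" * 3, "b": "ACGT" * 3, "c": "ACGT" * 3})
        assert len(eligible_pairs(state)) == 3


class TestFusion:
    def test_full_length_fusion_collapses_to_one_fragment(self):
        state = init_state({"a": "ACGTACGT", "b": "ACGTACGT"})
        fa, fb = (state.fragments[i] for i in sorted(state.fragments))
        state.fuse(cand(state, fa, fb, 0, 0, 8))
        assert len(state.fragments) == 1
        frag = next(iter(state.fragments.values()))
        assert frag.leafset == {"a", "b"} and frag.length == 8

    def test_interior_fusion_makes_five_fragments(self):
        state = init_state({"a": "ACGTACGTACGT", "b": "TTACGTACGTTT"})
        fa, fb = (state.fragments[i] for i in sorted(state.fragments))
        state.fuse(cand(state, fa, fb, 4, 2, 5))
        assert len(state.fragments) == 5
        state.check_labels()

    def test_two_interior_fusions_give_nine_fragments(self):
        """Worked 3-sequence trace: 3 -> 6 -> 9 fragments."""
        state = init_state(
            {"s1": "A" * 30, "s2": "C" * 30, "s3": "G" * 30}
        )
        f1, f2, f3 = (state.fragments[i] for i in sorted(state.fragments))
        state.fuse(cand(state, f1, f2, 10, 12, 6))
        assert len(state.fragments) == 6
        state.check_labels()
        # second fusion: s3 with the right flank of s1
        s1_right = frag_on(state, "s1", 2)
        s3 = frag_on(state, "s3", 0)
        state.fuse(cand(state, s3, s1_right, 5, 3, 4))
        assert len(state.fragments) == 9
        state.check_labels()

    def test_label_augmentation_scheme(self):
        state = init_state({"a": "ACGTACGTACGT", "b": "TTACGTACGTTT"})
        fa, fb = (state.fragments[i] for i in sorted(state.fragments))
        state.fuse(cand(state, fa, fb, 4, 2, 5))
        assert frag_on(state, "a", 0).labels["a"] == (0, 1)
        assert frag_on(state, "a", 1).labels["a"] == (0, 2)
        assert frag_on(state, "a", 2).labels["a"] == (0, 3)
        assert frag_on(state, "b", 1).labels["b"] == (0, 2)

    def test_fused_away_fragment_rejected(self):
        state = init_state({"a": "ACGTACGT", "b": "ACGTACGT"})
        fa, fb = (state.fragments[i] for i in sorted(state.fragments))
        c = cand(state, fa, fb, 0, 0, 8)
        state.fuse(c)
        with pytest.raises(ConsistencyError):
            state.fuse(c)

    def test_shared_sequence_not_eligible(self):
        state = init_state({"a": "ACGTACGTACGT", "b": "TTACGTACGTTT"})
        fa, fb = (state.fragments[i] for i in sorted(state.fragments))
        state.fuse(cand(state, fa, fb, 4, 2, 5))
        left_a = frag_on(state, "a", 0)
        fused = frag_on(state, "a", 1)
        assert not state.eligible(left_a, fused)


class TestCrossingConsistency:
    def _fig6_like_state(self):
        """Fusion 1 pairs seq1/seq2 interiors; fusion 2 pairs seq2's right
        flank with seq3's interior.  Like-labelled flank pairs stay
        compatible, crossing pairs do not."""
        state = init_state({"s1": "A" * 40, "s2": "C" * 40, "s3": "G" * 40})
        f1, f2, f3 = (state.fragments[i] for i in sorted(state.fragments))
        state.fuse(cand(state, f1, f2, 10, 10, 8))
        s2_right = frag_on(state, "s2", 2)
        s3 = frag_on(state, "s3", 0)
        state.fuse(cand(state, s3, s2_right, 10, 5, 6))
        state.check_labels()
        return state

    def test_like_labelled_flanks_are_eligible(self):
        state = self._fig6_like_state()
        s1_right = frag_on(state, "s1", 2)
        s3_right = frag_on(state, "s3", 2)
        assert s1_right.labels["s1"] == (0, 3)
        assert s3_right.labels["s3"] == (0, 3)
        assert state.eligible(s1_right, s3_right)

    def test_crossing_pairs_are_excluded(self):
        state = self._fig6_like_state()
        s1_left = frag_on(state, "s1", 0)
        s3_right = frag_on(state, "s3", 2)
        # s1-left precedes the s1/s2 fusion, which precedes the s2/s3 fusion,
        # which precedes s3-right: aligning them would cross
        assert not state.eligible(s1_left, s3_right)
        assert (s1_left, s3_right) not in eligible_pairs(state)
        fused_12 = frag_on(state, "s1", 1)
        assert not state.eligible(fused_12, s3_right)

    def test_crossing_fusion_raises(self):
        state = self._fig6_like_state()
        s1_left = frag_on(state, "s1", 0)
        s3_right = frag_on(state, "s3", 2)
        with pytest.raises(ConsistencyError):
            state.fuse(cand(state, s1_left, s3_right, 0, 0, 4))


class TestAssembly:
    def test_matches_per_base_half_paired(self):
        """2 sequences of length 10 with 5 columns paired -> 0.5."""
        state = init_state({"a": "ACGTACGTAC", "b": "ACGTACGTAC"})
        fa, fb = (state.fragments[i] for i in sorted(state.fragments))
        state.fuse(cand(state, fa, fb, 0, 0, 5))
        aln = assemble(state)
        assert matches_per_base(aln) == pytest.approx(0.5)

    def test_matches_per_base_unaligned_is_zero(self):
        state = init_state({"a": "ACGT", "b": "ACGT"})
        assert matches_per_base(assemble(state)) == 0.0

    def test_ungapping_reproduces_inputs(self):
        recs = {"a": "ACGTACGTACGT", "b": "TTACGTACGTTT", "c": "ACGTTTTTACGT"}
        state = init_state(recs)
        f1, f2, f3 = (state.fragments[i] for i in sorted(state.fragments))
        state.fuse(cand(state, f1, f2, 2, 4, 6))
        aln = assemble(state)
        for sid, seq in recs.items():
            assert aln.ungapped(sid) == seq

    def test_assembly_deterministic_and_round_trips(self):
        recs = {"a": "ACGTACGTACGT", "b": "TTACGTACGTTT"}
        state = init_state(recs)
        fa, fb = (state.fragments[i] for i in sorted(state.fragments))
        state.fuse(cand(state, fa, fb, 4, 2, 5))
        a1 = assemble(state)
        a2 = assemble(state)
        assert a1.rows == a2.rows and a1.columns == a2.columns


def _no_crossings(aln):
    for x in range(len(aln.seq_ids)):
        for y in range(x + 1, len(aln.seq_ids)):
            a, b = aln.seq_ids[x], aln.seq_ids[y]
            pairs = [
                (col[a], col[b]) for col in aln.columns if a in col and b in col
            ]
            pairs.sort()
            if any(p2 <= q2 for (_, q2), (_, p2) in zip(pairs, pairs[1:])):
                return False
    return True


class TestRunAlignment:
    def test_identical_pair_aligns_fully(self):
        gen = np.random.default_rng(0)
        seq = "".join(gen.choice(list("ACGT"), 100))
        aln = run_alignment({"a": seq, "b": seq}, seed=1)
        assert aln.rows["a"] == seq and aln.rows["b"] == seq
        assert aln.n_columns == 100  # gapless, no gap columns
        assert matches_per_base(aln) == pytest.approx(1.0)

    def test_synthetic_run_invariants(self):
        synth = sd.make_benchmark(0.8, n_desc=3, n_sets=1, anc_len=250, seed=5)[0]
        aln, state = run_alignment(synth.records(), seed=3, return_state=True)
        state.check_labels()
        assert _no_crossings(aln)
        for sid, seq in synth.records().items():
            assert aln.ungapped(sid) == seq

    def test_deterministic_given_seed(self):
        synth = sd.make_benchmark(0.8, n_desc=3, n_sets=1, anc_len=200, seed=9)[0]
        a1 = run_alignment(synth.records(), seed=4)
        a2 = run_alignment(synth.records(), seed=4)
        assert a1.rows == a2.rows

    def test_tree_must_cover_sequences(self):
        with pytest.raises(AlignmentError):
            run_alignment(
                {"a": "ACGT" * 10, "b": "ACGT" * 10},
                tree=star_tree(["a", "zz"], 0.5),
                seed=0,
            )


class TestBootstrap:
    def test_star_default_proximity(self):
        tree = star_tree(["a", "b", "c"])
        assert all(c.q == 0.33 for c in tree.root.children)

    def test_identical_pair_gives_high_proximity(self):
        gen = np.random.default_rng(2)
        seq = "".join(gen.choice(list("ACGT"), 200))
        tree = bootstrap_tree({"a": seq, "b": seq}, seed=1)
        qs = [c.q for c in tree.root.children]
        assert all(q > 0.95 for q in qs)

    def test_pairwise_proximity_floor_for_unaligned(self):
        model = em.FunctionalModel.uniform_model()
        from sigma2.progressive import GlobalAlignment

        aln = GlobalAlignment(
            ["a", "b"],
            {"a": "ACGT----", "b": "----ACGT"},
            [{"a": k} for k in range(4)] + [{"b": k} for k in range(4)],
        )
        q = pairwise_proximities(aln, model)
        assert q[("a", "b")] == 0.05

    def test_expected_identity_inversion_consistency(self):
        from sigma2.progressive import _invert_identity, expected_identity

        model = em.default_background()
        Q = em.default_inverse_mutation()
        for q in (0.2, 0.5, 0.8):
            ident = expected_identity(q, model, Q)
            assert _invert_identity(ident, model, Q, 0.05) == pytest.approx(
                q, abs=1e-6
            )
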