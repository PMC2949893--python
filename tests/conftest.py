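import numpy as np
import pytest

from sigma2 import init_state
from sigma2.tree_likelihood import PhyloTree, TreeNode


def make_fragments(records):
    """Alignment state plus its initial fragments in id order."""
    state = init_state(records)
    frags = sorted(state.fragments.values(), key=lambda f: f.id)
    return state, frags


def random_mutation_matrix(rng):
    P = rng.random((4, 4))
    np.fill_diagonal(P, 0.0)
    return P / P.sum(axis=0)


def fig5_tree(q1, q2, q3, q4, q5, qb, qc, qd, prior=None):
    """Five-leaf caterpillar: root -> (leaf1, b); b -> (leaf2, c);
    c -> (leaf5, d); d -> (leaf3, leaf4)."""
    d = TreeNode(None, qd, [TreeNode("L3", q3), TreeNode("L4", q4)])
    c = TreeNode(None, qc, [TreeNode("L5", q5), d])
    b = TreeNode(None, qb, [TreeNode("L2", q2), c])
    root = TreeNode(None, None, [TreeNode("L1", q1), b])
    return PhyloTree(root, prior)


def exhaustive_column_likelihood(tree, obs, transitions):
    """Sum over every assignment of states to internal nodes (oracle)."""
    internal = [n for n in tree.nodes() if not n.is_leaf and n is not tree.root]
    leaves = [n for n in tree.nodes() if n.is_leaf]
    codes = {}
    for name, v in obs.items():
        codes[name] = "ACGTN".index(v) if isinstance(v, str) else int(v)

    def branch_prob(node, state, parent_state):
        return transitions[id(node)][state, parent_state]

    total = 0.0
    n_int = len(internal)
    for root_state in range(4):
        for assign in np.ndindex(*(4,) * n_int):
            states = {id(tree.root): root_state}
            for node, st in zip(internal, assign):
                states[id(node)] = st
            prob = tree.prior[root_state]
            for node in internal:
                parent = _parent_of(tree, node)
                prob *= branch_prob(node, states[id(node)], states[id(parent)])
            for leaf in leaves:
                parent = _parent_of(tree, leaf)
                code = codes.get(leaf.name, 4)
                if code == 4:
                    continue  # N marginalises to 1
                prob *= branch_prob(leaf, code, states[id(parent)])
            total += prob
    return total


def _parent_of(tree, node):
    for cand in tree.nodes():
        if node in cand.children:
            return cand
    raise AssertionError("node has no parent")


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
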