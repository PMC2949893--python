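"""Phylogenetic column likelihoods and relatedness scores.

A column of aligned nucleotides is scored by Felsenstein pruning on a rooted
tree whose branches carry *proximities* ``q`` (probability of no substitution
along the branch; multiplicative along paths).  The relatedness score of a
paired column from two fragments A and B is the log-likelihood ratio

    s = log L(obsA u obsB | treeAB) - log[ L(obsA | treeA) * L(obsB | treeB) ]

where ``treeA``/``treeB``/``treeAB`` are restrictions of one global tree to
the sequences present in each fragment (and their union).  A gapless local
alignment of length ``m`` scores ``S = sum_i s_i`` over its columns.

:class:`ColumnScorer` is the production engine: it evaluates the pruning
recursion simultaneously for every distinct (nucleotide, left-context) column
state of two fragments, yielding the full pairwise score matrix required by
the local-alignment dynamic programme at a cost that depends on the number of
distinct column states, not on fragment length.
"""

from __future__ import annotations

import math
from typing import Dict, Iterable, Mapping

import numpy as np

from .evo_model import (
    N_CODE,
    NO_CONTEXT,
    NUC_INDEX,
    FunctionalModel,
    effective_mutation_matrix,
    matrix_transition,
    perfect_fixation_transition,
)

__all__ = [
    "TreeError",
    "MissingLeafError",
    "TreeNode",
    "PhyloTree",
    "star_tree",
    "build_transitions",
    "column_likelihood",
    "column_score",
    "fragment_pair_score",
    "ColumnScorer",
]


class TreeError(ValueError):
    pass


class MissingLeafError(TreeError):
    pass


class TreeNode:
    """Node of a rooted proximity tree.

    ``q`` is the proximity of the branch to the parent (``None`` at the root).
    Leaves carry the identifier of an input sequence in ``name``.
    """

    __slots__ = ("name", "q", "children")

    def __init__(self, name=None, q=None, children=()):
        self.name = name
        self.q = q
        self.children = list(children)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def copy(self) -> "TreeNode":
        return TreeNode(self.name, self.q, [c.copy() for c in self.children])


class PhyloTree:
    """Rooted tree with branch proximities and a root nucleotide prior."""

    def __init__(self, root: TreeNode, prior=None):
        self.root = root
        if prior is None:
            prior = np.full(4, 0.25)
        prior = np.asarray(prior, dtype=float)
        if prior.shape != (4,) or abs(prior.sum() - 1.0) > 1e-9 or np.any(prior < 0):
            raise TreeError("root prior must be a probability 4-vector")
        self.prior = prior
        leaves = self.leaves()
        if len(leaves) != len(set(leaves)):
            raise TreeError("leaf identifiers must be distinct")
        for node in self.nodes():
            if node is not self.root:
                if node.q is None or not 0.0 < node.q <= 1.0:
                    raise TreeError(
                        f"branch proximity must lie in (0, 1], got {node.q}"
                    )

    def nodes(self) -> Iterable[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(node.children)

    def leaves(self) -> list:
        return [n.name for n in self.nodes() if n.is_leaf]

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.root.copy(), self.prior.copy())

    def restrict(self, leaves) -> "PhyloTree":
        """Minimal subtree spanning ``leaves``.

        Unary internal nodes are contracted by multiplying proximities along
        the contracted path; the root (and its prior) is preserved, so a
        restriction to a single leaf is one branch below the original root
        carrying the composed proximity of the whole path.
        """
        wanted = set(leaves)
        if not wanted:
            raise MissingLeafError("cannot restrict to an empty leaf set")
        missing = wanted - set(self.leaves())
        if missing:
            raise MissingLeafError(f"unknown leaves: {sorted(missing)}")

        def prune(node: TreeNode):
            if node.is_leaf:
                if node.name in wanted:
                    return TreeNode(node.name, node.q)
                return None
            kept = [k for k in (prune(c) for c in node.children) if k is not None]
            if not kept:
                return None
            if len(kept) == 1:
                # contract the unary node into its single child: proximities
                # compose multiplicatively along the path
                child = kept[0]
                child.q = child.q * node.q if node.q is not None else child.q
                if node.q is None:
                    # node was the root; keep the root identity below
                    return TreeNode(None, None, [child])
                return child
            return TreeNode(node.name, node.q, kept)

        new_root = prune(self.root)
        if new_root.q is not None:  # root was contracted away; re-wrap
            new_root = TreeNode(None, None, [new_root])
        return PhyloTree(new_root, self.prior.copy())


def star_tree(names, q: float = 0.33, prior=None) -> PhyloTree:
    """Star phylogeny: every sequence hangs off the root at proximity ``q``."""
    root = TreeNode(children=[TreeNode(name, q) for name in names])
    return PhyloTree(root, prior)


def build_transitions(tree: PhyloTree, factory) -> Dict[int, np.ndarray]:
    """Map every non-root branch to a transition matrix via ``factory(node)``.

    The mapping is keyed by node identity (``id(node)``), matching what
    :func:`column_likelihood` expects.
    """
    return {id(n): np.asarray(factory(n)) for n in tree.nodes() if n is not tree.root}


def _obs_code(value) -> int:
    if isinstance(value, str):
        if value == "N":
            return N_CODE
        try:
            return NUC_INDEX[value]
        except KeyError:
            raise TreeError(f"invalid observation {value!r}") from None
    return int(value)


def column_likelihood(tree: PhyloTree, obs: Mapping, transitions: Mapping) -> float:
    """Likelihood of one column of observations by post-order pruning.

    ``obs`` maps leaf identifiers to nucleotides (letters or codes; ``N``
    marginalises over the four states).  Leaves absent from ``obs`` are also
    marginalised.  ``transitions`` maps ``id(node)`` to the 4x4 branch matrix
    (see :func:`build_transitions`).
    """
    if not obs:
        raise TreeError("column observation is empty")
    leaf_set = set(tree.leaves())
    unknown = set(obs) - leaf_set
    if unknown:
        raise MissingLeafError(f"observations for unknown leaves: {sorted(unknown)}")
    codes = {k: _obs_code(v) for k, v in obs.items()}

    def up(node: TreeNode) -> np.ndarray:
        """Message to the parent: P(data below | parent state beta)."""
        try:
            T = transitions[id(node)]
        except KeyError:
            raise TreeError(f"no transition matrix supplied for branch above "
                            f"{node.name or 'internal node'}") from None
        if node.is_leaf:
            code = codes.get(node.name, N_CODE)
            if code == N_CODE:
                return np.ones(4)
            return T[code, :]
        below = np.ones(4)
        for child in node.children:
            below = below * up(child)
        return T.T @ below

    below_root = np.ones(4)
    for child in tree.root.children:
        below_root = below_root * up(child)
    return float(tree.prior @ below_root)


def column_score(
    treeAB: PhyloTree,
    treeA: PhyloTree,
    treeB: PhyloTree,
    obsA: Mapping,
    obsB: Mapping,
    transAB: Mapping,
    transA: Mapping,
    transB: Mapping,
) -> float:
    """Log-likelihood ratio that two column halves share a common ancestry.

    Natural log.  A column half consisting entirely of N observations carries
    no evidence and scores exactly 0.
    """
    if not obsA or not obsB:
        raise TreeError("both column halves must contain at least one observation")
    if all(_obs_code(v) == N_CODE for v in obsA.values()) or all(
        _obs_code(v) == N_CODE for v in obsB.values()
    ):
        return 0.0
    joint = column_likelihood(treeAB, {**obsA, **obsB}, transAB)
    la = column_likelihood(treeA, obsA, transA)
    lb = column_likelihood(treeB, obsB, transB)
    return math.log(joint) - math.log(la) - math.log(lb)


def fragment_pair_score(fragA, fragB, startA: int, startB: int, m: int, scorer) -> float:
    """Total score ``S`` of a gapless pairing: sum of column scores."""
    if m < 1:
        raise ValueError("alignment length m must be >= 1")
    if startA < 0 or startB < 0 or startA + m > fragA.length or startB + m > fragB.length:
        raise IndexError("pairing offsets out of fragment bounds")
    S = scorer.score_matrix(fragA, fragB)
    idx = np.arange(m)
    return float(S[startA + idx, startB + idx].sum())


# ---------------------------------------------------------------------------
# Vectorised scoring engine
# ---------------------------------------------------------------------------


class ColumnScorer:
    """Column relatedness scores for fragment pairs under one global tree.

    Parameters
    ----------
    tree : PhyloTree
        Global phylogeny over all input sequences.
    model : FunctionalModel
        Background functional model.  Leaf branches use the transition matrix
        of the leaf's own left-neighbour context; internal branches (whose
        "sequence" is unobserved) use the unconditioned marginal.
    inverse_mutation : (4, 4) array, optional
        Inverse mutation matrix ``Q``.  When given, branch transitions are the
        matrix model ``q**(I - P')`` with the fixation-corrected ``P'`` per
        context; when ``None`` the perfect-fixation transitions are used.
    prior : (4,) array, optional
        Root nucleotide prior; defaults to the model marginal.
    """

    def __init__(self, tree: PhyloTree, model: FunctionalModel | None = None,
                 inverse_mutation=None, prior=None):
        if model is None:
            model = FunctionalModel.uniform_model()
        self.tree = tree
        self.model = model
        self.prior = np.asarray(prior if prior is not None else model.marginal,
                                dtype=float)
        if inverse_mutation is None:
            self._pprime = None
        else:
            self._pprime = [
                effective_mutation_matrix(inverse_mutation, model.probs(c))
                for c in range(5)
            ]
        self._trans_cache: dict = {}
        self._leaf_stack_cache: dict = {}
        self._rtree_cache: dict = {}
        self._table_cache: dict = {}

    # -- transition matrices -------------------------------------------------

    def transition(self, q: float, context: int = NO_CONTEXT) -> np.ndarray:
        key = (q, context)
        T = self._trans_cache.get(key)
        if T is None:
            if self._pprime is None:
                T = perfect_fixation_transition(q, self.model.probs(context))
            else:
                T = matrix_transition(q, self._pprime[context])
            self._trans_cache[key] = T
        return T

    def _leaf_stack(self, q: float) -> np.ndarray:
        """Array ``stack[ctx, obs, beta] = T_ctx[obs, beta]`` with N -> 1."""
        stack = self._leaf_stack_cache.get(q)
        if stack is None:
            stack = np.empty((5, 5, 4))
            for ctx in range(5):
                stack[ctx, :4, :] = self.transition(q, ctx)
                stack[ctx, 4, :] = 1.0  # N marginalises to 1 (columns sum to 1)
            self._leaf_stack_cache[q] = stack
        return stack

    def restricted(self, leaves: frozenset) -> PhyloTree:
        tree = self._rtree_cache.get(leaves)
        if tree is None:
            tree = self.tree.restrict(leaves)
            self._rtree_cache[leaves] = tree
        return tree

    def transitions_for(self, tree: PhyloTree) -> Dict[int, np.ndarray]:
        """Branch transition matrices for a (restricted) tree.

        Leaf-branch matrices here use the no-context model; they are intended
        for the scalar :func:`column_likelihood` API.  The table engine below
        applies per-column contexts instead.
        """
        return build_transitions(tree, lambda n: self.transition(n.q, NO_CONTEXT))

    # -- table engine --------------------------------------------------------

    @staticmethod
    def _unique_states(frag):
        """Distinct (obs, context) column states of a fragment.

        Returns ``(states, inverse)`` where ``states`` has shape
        ``(n_rows, D)`` with entries ``obs*5 + ctx`` and
        ``inverse[col]`` indexes the state of each column.
        """
        codes = frag.obs.astype(np.int16) * 5 + frag.ctx
        states, inverse = np.unique(codes, axis=1, return_inverse=True)
        return states, inverse.ravel()

    def _grid_likelihood(self, tree: PhyloTree, leaf_arrays, shape) -> np.ndarray:
        """Pruning likelihood evaluated over a grid of column states.

        ``leaf_arrays`` maps leaf name -> (obs_vec, ctx_vec, axis); the
        resulting array has the given broadcast ``shape``.
        """

        def up(node: TreeNode) -> np.ndarray:
            if node.is_leaf:
                obs, ctx, axis = leaf_arrays[node.name]
                stack = self._leaf_stack(node.q)
                msg = stack[ctx, obs, :].T  # (4, D)
                full = [1] * len(shape)
                full[axis] = msg.shape[1]
                return msg.reshape(4, *full)
            below = None
            for child in node.children:
                contrib = up(child)
                below = contrib if below is None else below * contrib
            T = self.transition(node.q, NO_CONTEXT)
            return np.einsum("ab,a...->b...", T, below)

        below_root = None
        for child in tree.root.children:
            contrib = up(child)
            below_root = contrib if below_root is None else below_root * contrib
        return np.einsum("b,b...->...", self.prior, below_root)

    def _single_log_likelihoods(self, frag, states) -> np.ndarray:
        tree = self.restricted(frag.leafset)
        obs = (states // 5).astype(np.intp)
        ctx = (states % 5).astype(np.intp)
        arrays = {
            name: (obs[r], ctx[r], 0) for r, name in enumerate(frag.row_names)
        }
        like = self._grid_likelihood(tree, arrays, (states.shape[1],))
        return np.log(np.maximum(like, 1e-300))

    def score_table(self, fragA, fragB):
        """Score table over distinct column-state pairs.

        Returns ``(table, invA, invB)`` with ``table[a, b]`` the column score
        for state ``a`` of fragment A against state ``b`` of fragment B, and
        ``inv*`` mapping columns to states.  Columns whose observations are
        entirely N on either side score exactly 0.
        """
        # cache by object identity; holding the fragments alive guarantees
        # their id()s cannot be recycled while the entry exists
        key = (id(fragA), id(fragB))
        cached = self._table_cache.get(key)
        if cached is not None and cached[0] is fragA and cached[1] is fragB:
            return cached[2]
        statesA, invA = self._unique_states(fragA)
        statesB, invB = self._unique_states(fragB)
        logA = self._single_log_likelihoods(fragA, statesA)
        logB = self._single_log_likelihoods(fragB, statesB)

        treeAB = self.restricted(fragA.leafset | fragB.leafset)
        obsA = (statesA // 5).astype(np.intp)
        ctxA = (statesA % 5).astype(np.intp)
        obsB = (statesB // 5).astype(np.intp)
        ctxB = (statesB % 5).astype(np.intp)
        arrays = {}
        for r, name in enumerate(fragA.row_names):
            arrays[name] = (obsA[r], ctxA[r], 0)
        for r, name in enumerate(fragB.row_names):
            arrays[name] = (obsB[r], ctxB[r], 1)
        joint = self._grid_likelihood(
            treeAB, arrays, (statesA.shape[1], statesB.shape[1])
        )
        # columns that are impossible under the joint model (e.g. a mismatch
        # across a proximity-1 branch) get a floor instead of -inf
        table = (
            np.log(np.maximum(joint, 1e-300)) - logA[:, None] - logB[None, :]
        )

        all_n_A = np.all(obsA == N_CODE, axis=0)
        all_n_B = np.all(obsB == N_CODE, axis=0)
        table[all_n_A, :] = 0.0
        table[:, all_n_B] = 0.0
        result = (table, invA, invB)
        if len(self._table_cache) > 128:
            self._table_cache.pop(next(iter(self._table_cache)))
        self._table_cache[key] = (fragA, fragB, result)
        return result

    def score_matrix(self, fragA, fragB) -> np.ndarray:
        """Full ``(len(A), len(B))`` matrix of per-column relatedness scores."""
        table, invA, invB = self.score_table(fragA, fragB)
        return table[np.ix_(invA, invB)]
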