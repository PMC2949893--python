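"""Progressive multiple alignment by fusing gapless sequence fragments.

The alignment state is a partition of every input sequence into *fragments*:
gapless blocks of rows from one or more sequences.  Initially each sequence
is one fragment.  Significant gapless local alignments between fragment
pairs are executed in increasing order of corrected p-value; executing one
*fuses* the paired blocks into a single fragment and splits the unpaired
flanks off as new fragments (up to five fragments replace the two, with
zero-length flanks dropped).  The process repeats until no remaining pair
admits an alignment below the p-value threshold, and the surviving fragments
are assembled into a global alignment.

Consistency: a fusion is allowed only between fragments with disjoint
sequence sets whose alignment cannot cross an earlier fusion.  The partial
order of fragments (left-to-right along every sequence) is tracked
explicitly, and each fragment row additionally carries an *order label* — a
dotted numeric string extended on every fusion (left flank ``.1``, fused
block ``.2``, right flank ``.3``) whose numeric (lexicographic) value
strictly increases left to right along any sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from heapq import heappop, heappush
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np

from .evo_model import (
    FunctionalModel,
    context_codes,
    default_background,
    default_inverse_mutation,
    encode_sequence,
)
from .local_align import (
    LocalAlignmentCandidate,
    accept,
    accept_strict,
    best_local_alignment,
)
from .significance import estimate_null_stats
from .tree_likelihood import ColumnScorer, PhyloTree, TreeNode, star_tree

__all__ = [
    "AlignmentError",
    "ConsistencyError",
    "Fragment",
    "AlignmentState",
    "GlobalAlignment",
    "init_state",
    "eligible_pairs",
    "fuse",
    "assemble",
    "run_alignment",
    "bootstrap_tree",
    "pairwise_proximities",
    "matches_per_base",
]

logger = logging.getLogger("sigma2")

#: sentinel selecting the package's built-in inverse mutation matrix
DEFAULT = "default"


class AlignmentError(ValueError):
    pass


class ConsistencyError(AlignmentError):
    pass


def label_str(label: Tuple[int, ...]) -> str:
    return ".".join(str(x) for x in label)


class Fragment:
    """A gapless block of rows from one or more input sequences."""

    __slots__ = ("id", "rows", "length", "labels", "obs", "ctx", "leafset")

    def __init__(self, fid, rows, length, labels, obs, ctx):
        self.id = fid
        self.rows = tuple(rows)  # ((seq_id, start_in_sequence), ...)
        self.length = length
        self.labels = dict(labels)  # seq_id -> tuple label
        self.obs = obs  # (n_rows, length) int8 codes 0..4
        self.ctx = ctx  # (n_rows, length) int8 left-context codes
        self.leafset = frozenset(sid for sid, _ in rows)

    @property
    def row_names(self) -> List[str]:
        return [sid for sid, _ in self.rows]

    def row_start(self, sid) -> int:
        for s, start in self.rows:
            if s == sid:
                return start
        raise KeyError(sid)

    def __repr__(self):
        rows = ",".join(
            f"{sid}[{start}:{start + self.length}]#{label_str(self.labels[sid])}"
            for sid, start in self.rows
        )
        return f"Fragment({self.id}: {rows})"


class AlignmentState:
    """Partition of the input sequences into fragments, with ordering."""

    def __init__(self, records: Mapping[str, str]):
        if len(records) < 2:
            raise AlignmentError("need at least two sequences")
        self.seq_ids = list(records)
        self.seq_index = {sid: k for k, sid in enumerate(self.seq_ids)}
        self.sequences = dict(records)
        self.enc: Dict[str, tuple] = {}
        self.fragments: Dict[int, Fragment] = {}
        self.order: Dict[str, List[int]] = {}
        self.fusion_log: list = []
        self._next_id = 0
        for sid, seq in records.items():
            if not seq:
                raise AlignmentError(f"sequence {sid!r} is empty")
            obs = encode_sequence(seq)
            ctx = context_codes(obs)
            self.enc[sid] = (obs, ctx)
            frag = Fragment(
                self._take_id(),
                ((sid, 0),),
                len(seq),
                {sid: (0,)},
                obs[None, :],
                ctx[None, :],
            )
            self.fragments[frag.id] = frag
            self.order[sid] = [frag.id]
        self._recompute_reach()

    def _take_id(self) -> int:
        fid = self._next_id
        self._next_id += 1
        return fid

    # -- ordering / consistency ---------------------------------------------

    def _recompute_reach(self):
        fids = list(self.fragments)
        bit = {fid: 1 << k for k, fid in enumerate(fids)}
        succs = {fid: set() for fid in fids}
        for lst in self.order.values():
            for a, b in zip(lst, lst[1:]):
                succs[a].add(b)
        preds = {fid: [] for fid in fids}
        for a, ss in succs.items():
            for b in ss:
                preds[b].append(a)
        remaining = {f: len(succs[f]) for f in fids}
        stack = [f for f in fids if remaining[f] == 0]
        reach: Dict[int, int] = {}
        done = 0
        while stack:
            f = stack.pop()
            mask = 0
            for b in succs[f]:
                mask |= bit[b] | reach[b]
            reach[f] = mask
            done += 1
            for a in preds[f]:
                remaining[a] -= 1
                if remaining[a] == 0:
                    stack.append(a)
        if done != len(fids):  # pragma: no cover - guarded by eligibility
            raise ConsistencyError("fragment order contains a cycle")
        self._reach = reach
        self._bit = bit

    def eligible(self, fragA: Fragment, fragB: Fragment) -> bool:
        """Disjoint sequence sets and no ordering path between the fragments."""
        if fragA.id == fragB.id or fragA.leafset & fragB.leafset:
            return False
        if fragA.id not in self.fragments or fragB.id not in self.fragments:
            return False
        if self._reach[fragA.id] & self._bit[fragB.id]:
            return False
        if self._reach[fragB.id] & self._bit[fragA.id]:
            return False
        return True

    def check_labels(self):
        """Assert the label invariant: strictly increasing along every sequence."""
        for sid, lst in self.order.items():
            labels = [self.fragments[f].labels[sid] for f in lst]
            for a, b in zip(labels, labels[1:]):
                if not a < b:
                    raise ConsistencyError(
                        f"label order violated on {sid}: "
                        f"{label_str(a)} !< {label_str(b)}"
                    )

    # -- fragment surgery ----------------------------------------------------

    def _sub_fragment(self, frag: Fragment, lo: int, hi: int, suffix: int):
        if hi <= lo:
            return None
        rows = tuple((sid, start + lo) for sid, start in frag.rows)
        labels = {sid: frag.labels[sid] + (suffix,) for sid, _ in frag.rows}
        sub = Fragment(
            self._take_id(),
            rows,
            hi - lo,
            labels,
            frag.obs[:, lo:hi].copy(),
            frag.ctx[:, lo:hi].copy(),
        )
        return sub

    def fuse(self, candidate: LocalAlignmentCandidate) -> List[Fragment]:
        """Execute an accepted local alignment; returns the new fragments."""
        try:
            A = self.fragments[candidate.frag_a]
            B = self.fragments[candidate.frag_b]
        except KeyError:
            raise ConsistencyError("candidate refers to a fused-away fragment")
        if not self.eligible(A, B):
            raise ConsistencyError("candidate pair is not eligible")
        m = candidate.m
        sa, sb = candidate.start_a, candidate.start_b
        if not (0 <= sa and sa + m <= A.length and 0 <= sb and sb + m <= B.length):
            raise AlignmentError("candidate offsets out of range")

        leftA = self._sub_fragment(A, 0, sa, 1)
        rightA = self._sub_fragment(A, sa + m, A.length, 3)
        leftB = self._sub_fragment(B, 0, sb, 1)
        rightB = self._sub_fragment(B, sb + m, B.length, 3)

        rows = [(sid, start + sa) for sid, start in A.rows]
        rows += [(sid, start + sb) for sid, start in B.rows]
        rows.sort(key=lambda r: self.seq_index[r[0]])
        labels = {sid: A.labels[sid] + (2,) for sid, _ in A.rows}
        labels.update({sid: B.labels[sid] + (2,) for sid, _ in B.rows})
        obs = np.vstack(
            [self.enc[sid][0][start : start + m] for sid, start in rows]
        )
        ctx = np.vstack(
            [self.enc[sid][1][start : start + m] for sid, start in rows]
        )
        fused = Fragment(self._take_id(), rows, m, labels, obs, ctx)

        new = [f for f in (leftA, fused, rightA, leftB, rightB) if f is not None]
        del self.fragments[A.id], self.fragments[B.id]
        for f in new:
            self.fragments[f.id] = f
        for parent, left, right in ((A, leftA, rightA), (B, leftB, rightB)):
            repl = [f.id for f in (left, fused, right) if f is not None]
            for sid, _ in parent.rows:
                lst = self.order[sid]
                k = lst.index(parent.id)
                self.order[sid][k : k + 1] = repl
        self._recompute_reach()
        self.fusion_log.append(
            {
                "frag_a": A.id,
                "frag_b": B.id,
                "fused": fused.id,
                "m": m,
                "score": candidate.score,
                "pvalue": candidate.pvalue,
            }
        )
        # dedupe the fused id in case a flank list already holds it (never
        # happens: leafsets are disjoint, so repl insertion points differ)
        return new


def init_state(sequences) -> AlignmentState:
    """One fragment per input sequence, each labelled ``0``."""
    return AlignmentState(_as_records(sequences))


def _as_records(sequences) -> Dict[str, str]:
    if isinstance(sequences, Mapping):
        return dict(sequences)
    records = {}
    for item in sequences:
        if hasattr(item, "id") and hasattr(item, "residues"):
            sid, seq = item.id, item.residues
        else:
            sid, seq = item
        if sid in records:
            raise AlignmentError(f"duplicate sequence id {sid!r}")
        records[sid] = seq
    return records


def eligible_pairs(state: AlignmentState) -> List[Tuple[Fragment, Fragment]]:
    """All unordered fragment pairs that may be aligned in the current state."""
    frags = sorted(state.fragments.values(), key=lambda f: f.id)
    out = []
    for a in range(len(frags)):
        for b in range(a + 1, len(frags)):
            if state.eligible(frags[a], frags[b]):
                out.append((frags[a], frags[b]))
    return out


def fuse(state: AlignmentState, candidate: LocalAlignmentCandidate) -> AlignmentState:
    """Module-level wrapper over :meth:`AlignmentState.fuse` (mutates state)."""
    state.fuse(candidate)
    return state


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


@dataclass
class GlobalAlignment:
    """Gapped rows over {A,C,G,T,N,-} plus a column-to-position map."""

    seq_ids: List[str]
    rows: Dict[str, str]
    columns: List[Dict[str, int]] = field(repr=False)

    def ungapped(self, sid: str) -> str:
        return self.rows[sid].replace("-", "")

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def aligned_pairs(self) -> set:
        """All aligned residue pairs as ``(sid1, pos1, sid2, pos2)`` tuples.

        Pairs are normalised so that ``(sid1, pos1) < (sid2, pos2)``.
        """
        pairs = set()
        for col in self.columns:
            items = sorted(col.items())
            for a in range(len(items)):
                for b in range(a + 1, len(items)):
                    pairs.add((*items[a], *items[b]))
        return pairs


def assemble(state: AlignmentState) -> GlobalAlignment:
    """Topologically order the fragments into a global alignment.

    Fragments that are unordered relative to each other are laid out in
    sequence-id order (ties broken by start offset), so the output is
    deterministic.
    """
    succs = {fid: [] for fid in state.fragments}
    indeg = {fid: 0 for fid in state.fragments}
    for lst in state.order.values():
        for a, b in zip(lst, lst[1:]):
            succs[a].append(b)
            indeg[b] += 1

    def sort_key(fid):
        frag = state.fragments[fid]
        return min((state.seq_index[sid], start) for sid, start in frag.rows)

    ready = [(sort_key(f), f) for f in state.fragments if indeg[f] == 0]
    ready.sort()
    heap = list(ready)
    import heapq as _heapq

    _heapq.heapify(heap)
    parts: Dict[str, List[str]] = {sid: [] for sid in state.seq_ids}
    columns: List[Dict[str, int]] = []
    seen = 0
    while heap:
        _, fid = _heapq.heappop(heap)
        frag = state.fragments[fid]
        seen += 1
        present = dict(frag.rows)
        for sid in state.seq_ids:
            if sid in present:
                start = present[sid]
                parts[sid].append(state.sequences[sid][start : start + frag.length])
            else:
                parts[sid].append("-" * frag.length)
        for k in range(frag.length):
            columns.append({sid: start + k for sid, start in frag.rows})
        for b in succs[fid]:
            indeg[b] -= 1
            if indeg[b] == 0:
                _heapq.heappush(heap, (sort_key(b), b))
    if seen != len(state.fragments):  # pragma: no cover
        raise ConsistencyError("fragment order contains a cycle")
    rows = {sid: "".join(parts[sid]) for sid in state.seq_ids}
    return GlobalAlignment(list(state.seq_ids), rows, columns)


def matches_per_base(alignment: GlobalAlignment) -> float:
    """Mean number of aligned partners per nucleotide.

    For each nucleotide, the nucleotides (not gaps) sharing its column are
    counted; the sum over all nucleotides is divided by the total nucleotide
    count.  N is not a nucleotide observation: it neither counts as a partner
    nor contributes to the denominator.  The ceiling is ``n - 1`` for ``n``
    fully aligned equal-length sequences.
    """
    total = 0
    matches = 0
    for sid in alignment.seq_ids:
        total += sum(1 for ch in alignment.rows[sid] if ch in "ACGT")
    for k in range(alignment.n_columns):
        count = sum(
            1 for sid in alignment.seq_ids if alignment.rows[sid][k] in "ACGT"
        )
        matches += count * (count - 1)
    return matches / total if total else 0.0


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------


def run_alignment(
    sequences,
    tree: Optional[PhyloTree] = None,
    model: Optional[FunctionalModel] = None,
    inverse_mutation=DEFAULT,
    threshold: float = 0.002,
    min_len: int = 4,
    null_samples: int = 1000,
    seed: int = 0,
    star_q: float = 0.33,
    return_state: bool = False,
    lr_gate: bool = True,
):
    """Full progressive alignment.

    When ``tree`` is omitted, a two-pass bootstrap is used: a preliminary
    alignment under a star phylogeny (proximity ``star_q`` per branch)
    estimates pairwise proximities, a neighbour-joining tree is built from
    them, and the final alignment runs on that tree.

    ``inverse_mutation`` selects the branch model: a 4x4 inverse mutation
    matrix (the package default when left at ``"default"``), or ``None`` for
    the perfect-fixation transitions.

    ``lr_gate`` additionally requires every executed fusion to pass the
    likelihood-ratio tail bound (see
    :class:`~sigma2.local_align.LocalAlignmentCandidate`); the preliminary
    bootstrap pass runs without it, since its only product is the pairwise
    proximity estimates.
    """
    records = _as_records(sequences)
    if model is None:
        model = default_background()
    if isinstance(inverse_mutation, str) and inverse_mutation == DEFAULT:
        inverse_mutation = default_inverse_mutation()
    if tree is None:
        tree = bootstrap_tree(
            records,
            model=model,
            inverse_mutation=inverse_mutation,
            star_q=star_q,
            threshold=threshold,
            min_len=min_len,
            null_samples=null_samples,
            seed=seed,
        )
    missing = set(records) - set(tree.leaves())
    if missing:
        raise AlignmentError(f"tree lacks leaves for sequences: {sorted(missing)}")

    scorer = ColumnScorer(tree, model, inverse_mutation)
    state = AlignmentState(records)
    log_threshold = float(np.log(threshold))
    heap: list = []
    counter = 0
    seen_pairs = set()

    def consider(f: Fragment, g: Fragment):
        nonlocal counter
        key = (min(f.id, g.id), max(f.id, g.id))
        if key in seen_pairs:
            return
        seen_pairs.add(key)
        if f.length < min_len or g.length < min_len:
            return
        if not state.eligible(f, g):
            return
        a, b = (f, g) if f.id < g.id else (g, f)
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(a.id, b.id))
        )
        stats = estimate_null_stats(a, b, scorer, n=null_samples, rng=rng)
        cand = best_local_alignment(a, b, scorer, stats, min_len=min_len)
        if cand is None:
            return
        ok = accept_strict(cand, threshold) if lr_gate else accept(cand, threshold)
        if ok:
            counter += 1
            heappush(
                heap,
                (cand.log_pvalue, -cand.m, cand.start_a, cand.start_b, counter, cand),
            )

    frags = sorted(state.fragments.values(), key=lambda f: f.id)
    for x in range(len(frags)):
        for y in range(x + 1, len(frags)):
            consider(frags[x], frags[y])

    while heap:
        _, _, _, _, _, cand = heappop(heap)
        if cand.frag_a not in state.fragments or cand.frag_b not in state.fragments:
            continue
        A = state.fragments[cand.frag_a]
        B = state.fragments[cand.frag_b]
        if not state.eligible(A, B):
            continue
        new = state.fuse(cand)
        logger.info(
            "fused %d+%d -> %s  m=%d S=%.3f P=%.3g",
            cand.frag_a,
            cand.frag_b,
            [f.id for f in new],
            cand.m,
            cand.score,
            cand.pvalue,
        )
        new_ids = {f.id for f in new}
        others = [f for f in state.fragments.values() if f.id not in new_ids]
        for f in new:
            for g in others:
                consider(f, g)
        new_list = sorted(new, key=lambda f: f.id)
        for x in range(len(new_list)):
            for y in range(x + 1, len(new_list)):
                consider(new_list[x], new_list[y])

    alignment = assemble(state)
    if return_state:
        return alignment, state
    return alignment


# ---------------------------------------------------------------------------
# Tree bootstrap
# ---------------------------------------------------------------------------


def expected_identity(q: float, model: FunctionalModel, inverse_mutation=None) -> float:
    """Expected identity of two sequences joined at path proximity ``q``.

    Under perfect fixation this is ``q + (1-q)*c`` with chance identity
    ``c = sum(p**2)``; under the matrix model it is
    ``sum_a p_a * T(a|a; q)`` (assuming approximate reversibility), which is
    lower because a back-mutation needs at least two events.
    """
    if inverse_mutation is None:
        c = float(np.sum(model.marginal**2))
        return q + (1.0 - q) * c
    from .evo_model import effective_mutation_matrix, matrix_transition

    P = effective_mutation_matrix(inverse_mutation, model.marginal)
    T = matrix_transition(q, P)
    return float(model.marginal @ np.diag(T))


#: estimated proximities are capped below 1: a branch at exactly 1 makes any
#: mismatch impossible (zero likelihood), which degenerates the scores
_PROXIMITY_CAP = 0.99


def _invert_identity(ident: float, model, inverse_mutation, floor: float) -> float:
    """Path proximity whose expected identity matches ``ident`` (bisection)."""
    lo, hi = 1e-6, 1.0
    if ident <= expected_identity(lo, model, inverse_mutation):
        return floor
    if ident >= 1.0:
        return _PROXIMITY_CAP
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if expected_identity(mid, model, inverse_mutation) < ident:
            lo = mid
        else:
            hi = mid
    return max(floor, min(_PROXIMITY_CAP, 0.5 * (lo + hi)))


def pairwise_proximities(
    alignment: GlobalAlignment,
    model: FunctionalModel,
    inverse_mutation=None,
    floor: float = 0.05,
) -> Dict[Tuple[str, str], float]:
    """Pairwise proximity estimates from an alignment.

    The fraction of identical nucleotides among columns where both sequences
    have a base is mapped to a path proximity by inverting the evolutionary
    model's own identity curve (see :func:`expected_identity`).  Estimates
    are clamped to ``[floor, 1]``; a pair with no aligned columns gets the
    floor value.
    """
    out = {}
    ids = alignment.seq_ids
    rows = {sid: alignment.rows[sid] for sid in ids}
    for x in range(len(ids)):
        for y in range(x + 1, len(ids)):
            a, b = ids[x], ids[y]
            n = ident = 0
            for ca, cb in zip(rows[a], rows[b]):
                if ca in "ACGT" and cb in "ACGT":
                    n += 1
                    if ca == cb:
                        ident += 1
            if n == 0:
                logger.warning(
                    "no aligned columns for pair (%s, %s); using floor proximity",
                    a,
                    b,
                )
                q = floor
            else:
                q = _invert_identity(ident / n, model, inverse_mutation, floor)
            out[(a, b)] = float(min(1.0, max(floor, q)))
    return out


def bootstrap_tree(
    sequences,
    model: Optional[FunctionalModel] = None,
    inverse_mutation=DEFAULT,
    star_q: float = 0.33,
    threshold: float = 0.002,
    min_len: int = 4,
    null_samples: int = 1000,
    seed: int = 0,
    floor: float = 0.05,
    prelim_threshold: float = 0.2,
) -> PhyloTree:
    """Two-pass tree estimate: star-phylogeny alignment, then neighbour joining.

    The preliminary alignment runs under a star tree with proximity
    ``star_q`` on every branch; pairwise proximities are estimated from it,
    converted to distances ``d = -ln q``, and a neighbour-joining tree is
    built; its branch lengths are mapped back to proximities ``q = e**-d``.
    The pass is run once (iterating it changes little).

    The preliminary pass is run at a permissive p-value threshold (0.2, the
    loosest setting the aligner exposes) and without the likelihood-ratio
    gate: under the deliberately weak star model, genuinely homologous
    blocks often cannot reach stringent significance, and the only product
    of this pass is the proximity estimates — its false fusions merely
    perturb ``q̂``, and the final pass re-tests everything under the
    estimated tree at the real threshold.
    """
    records = _as_records(sequences)
    if model is None:
        model = default_background()
    if isinstance(inverse_mutation, str) and inverse_mutation == DEFAULT:
        inverse_mutation = default_inverse_mutation()
    names = list(records)
    star = star_tree(names, q=star_q, prior=model.marginal)
    prelim = run_alignment(
        records,
        tree=star,
        model=model,
        inverse_mutation=inverse_mutation,
        threshold=max(threshold, prelim_threshold),
        min_len=min_len,
        null_samples=null_samples,
        seed=seed,
        lr_gate=False,
    )
    qhat = pairwise_proximities(prelim, model, inverse_mutation, floor=floor)
    if len(names) == 2:
        d = -np.log(qhat[(names[0], names[1])])
        q = float(np.exp(-d / 2.0))
        q = min(_PROXIMITY_CAP, max(floor, q))
        root = TreeNode(children=[TreeNode(names[0], q), TreeNode(names[1], q)])
        return PhyloTree(root, model.marginal)

    from skbio import DistanceMatrix
    from skbio.tree import nj

    D = np.zeros((len(names), len(names)))
    for (a, b), q in qhat.items():
        ia, ib = names.index(a), names.index(b)
        D[ia, ib] = D[ib, ia] = -np.log(q)
    sk = nj(DistanceMatrix(D, ids=names))

    def convert(node) -> TreeNode:
        length = node.length if node.length is not None else 0.0
        q = float(np.exp(-max(0.0, length)))
        q = min(_PROXIMITY_CAP, max(floor, q))
        return TreeNode(
            node.name if node.is_tip() else None,
            q,
            [convert(c) for c in node.children],
        )

    children = [convert(c) for c in sk.children]
    return PhyloTree(TreeNode(children=children), model.marginal)
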