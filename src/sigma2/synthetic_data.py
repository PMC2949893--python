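"""Synthetic evolution benchmark: sequence sets with a known true alignment.

Each benchmark set evolves one ancestral sequence into several descendants
along a star history: every descendant independently substitutes each
position according to the branch transition matrix at proximity ``q``, then
suffers insertions and deletions of 1-200 bp stretches at a small
per-position rate.  Because the ancestry of every surviving base is tracked,
the *reference alignment* — the set of descendant base pairs that share an
ancestral position — is known exactly, and predicted alignments can be
scored by

    sensitivity = N_correct / N_ref
    error rate  = N_incorrect / N_ref
    precision   = N_correct / (N_correct + N_incorrect)

A *shuffled* construction recombines sequences across loci so that no two
sequences in a group are orthologous, giving a specificity control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .evo_model import (
    NO_CONTEXT,
    FunctionalModel,
    default_background,
    default_inverse_mutation,
    decode_sequence,
    effective_mutation_matrix,
    encode_sequence,
    matrix_transition,
    perfect_fixation_transition,
)

__all__ = [
    "SyntheticSet",
    "EvaluationReport",
    "generate_ancestor",
    "evolve_descendant",
    "apply_indels",
    "make_benchmark",
    "make_shuffled",
    "reference_pairs",
    "evaluate",
    "Q_GRID",
]

#: the benchmark proximity grid: 0.10 to 0.80 in steps of 0.05
Q_GRID = [round(0.10 + 0.05 * k, 2) for k in range(15)]


@dataclass
class SyntheticSet:
    """One benchmark set: ancestor, descendants, and the true pair set."""

    ancestor: str
    descendants: Dict[str, str]
    ancestries: Dict[str, np.ndarray]
    reference: set
    params: dict

    def records(self) -> Dict[str, str]:
        return dict(self.descendants)


@dataclass
class EvaluationReport:
    sensitivity: float
    error_rate: float
    precision: float
    n_ref: int
    n_correct: int
    n_incorrect: int
    empty_prediction: bool = False


def _transition_stack(q: float, model: FunctionalModel, inverse_mutation):
    """Per-context branch transition matrices (context 0..3 = A..T, 4 = none)."""
    stack = np.empty((5, 4, 4))
    for ctx in range(5):
        if inverse_mutation is None:
            stack[ctx] = perfect_fixation_transition(q, model.probs(ctx))
        else:
            P = effective_mutation_matrix(inverse_mutation, model.probs(ctx))
            stack[ctx] = matrix_transition(q, P)
    return stack


def _sample_categorical(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Draw one category per row of a (n, 4) probability array."""
    u = rng.random(probs.shape[0])
    cum = np.cumsum(probs, axis=1)
    return np.minimum((u[:, None] > cum).sum(axis=1), 3)


def generate_ancestor(
    length: int, background: Optional[FunctionalModel] = None, rng=None
) -> str:
    """Markov ancestor: first base from the marginal, then left-conditioned."""
    if length < 1:
        raise ValueError("ancestor length must be >= 1")
    if background is None:
        background = default_background()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    out = np.empty(length, dtype=np.int8)
    cum = np.cumsum(background._probs, axis=1)  # (5, 4): contexts + marginal
    ctx = NO_CONTEXT
    u = rng.random(length)
    for i in range(length):
        ctx = min(int(np.searchsorted(cum[ctx], u[i], side="right")), 3)
        out[i] = ctx
    return decode_sequence(out)


def evolve_descendant(
    ancestor: str,
    q: float,
    model: Optional[FunctionalModel] = None,
    inverse_mutation="default",
    rng=None,
) -> Tuple[str, np.ndarray]:
    """Substitute each ancestral position independently at proximity ``q``.

    Position ``i`` is drawn from column ``beta`` of the branch transition
    matrix, where ``beta`` is the ancestral base and the matrix uses the
    ancestor's left-neighbour context.  Returns the descendant sequence and
    its ancestry map (identity before indels).
    """
    if not 0.0 < q <= 1.0:
        raise ValueError(f"proximity q must lie in (0, 1], got {q}")
    if model is None:
        model = default_background()
    if isinstance(inverse_mutation, str) and inverse_mutation == "default":
        inverse_mutation = default_inverse_mutation()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    anc = encode_sequence(ancestor)
    if np.any(anc > 3):
        raise ValueError("ancestor must be unambiguous A/C/G/T")
    ctx = np.empty_like(anc)
    ctx[0] = NO_CONTEXT
    ctx[1:] = anc[:-1]
    stack = _transition_stack(q, model, inverse_mutation)
    # probs[i, alpha] = T_ctx[i][alpha, anc[i]]
    probs = stack[ctx, :, anc].reshape(len(anc), 4)
    codes = _sample_categorical(probs, rng)
    ancestry = np.arange(len(anc))
    return decode_sequence(codes), ancestry


def apply_indels(
    seq: str,
    ancestry: np.ndarray,
    event_prob: float = 0.02,
    len_range: Tuple[int, int] = (1, 200),
    background: Optional[FunctionalModel] = None,
    rng=None,
) -> Tuple[str, np.ndarray, int]:
    """Insertions and deletions of short stretches at a per-position rate.

    Every position of the input sequence independently hosts an event with
    probability ``event_prob`` (so the expected event count is exactly
    ``event_prob * len(seq)``); an event is an insertion or a deletion with
    equal probability and a length uniform on ``len_range`` (deletions are
    truncated at the sequence end).  Events are applied from the rightmost
    position leftwards, so every scheduled event acts at its own coordinate
    regardless of earlier length changes.  Inserted bases are drawn from the
    background and map to no ancestral position.

    Returns ``(sequence, ancestry, n_events)``.
    """
    if not 0.0 <= event_prob <= 1.0:
        raise ValueError("event probability must lie in [0, 1]")
    lo, hi = len_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid indel length range {len_range}")
    if background is None:
        background = default_background()
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    positions = np.nonzero(rng.random(len(seq)) < event_prob)[0]
    n_events = len(positions)
    if n_events == 0:
        return seq, ancestry, 0
    is_insertion = rng.random(n_events) < 0.5
    lengths = rng.integers(lo, hi + 1, size=n_events)
    chars = list(seq)
    anc = list(ancestry)
    for pos, ins, ln in zip(positions[::-1], is_insertion[::-1], lengths[::-1]):
        pos = int(pos)
        ln = int(ln)
        if ins:
            inserted = generate_ancestor(ln, background, rng)
            chars[pos:pos] = list(inserted)
            anc[pos:pos] = [-1] * ln
        else:
            del chars[pos : pos + ln]
            del anc[pos : pos + ln]
    return "".join(chars), np.asarray(anc, dtype=int), n_events


def reference_pairs(ancestries: Dict[str, np.ndarray]) -> set:
    """Homologous base pairs implied by shared ancestral positions.

    Pairs are normalised as ``(sid1, pos1, sid2, pos2)`` with
    ``(sid1, pos1) < (sid2, pos2)``; the set is closed under the
    shared-ancestor relation by construction.
    """
    names = sorted(ancestries)
    maps = {}
    for name in names:
        anc = ancestries[name]
        keep = anc >= 0
        maps[name] = dict(zip(anc[keep].tolist(), np.nonzero(keep)[0].tolist()))
    pairs = set()
    for x in range(len(names)):
        for y in range(x + 1, len(names)):
            a, b = names[x], names[y]
            ma, mb = maps[a], maps[b]
            for anc_pos, pa in ma.items():
                pb = mb.get(anc_pos)
                if pb is not None:
                    if (a, pa) < (b, pb):
                        pairs.add((a, pa, b, pb))
                    else:
                        pairs.add((b, pb, a, pa))
    return pairs


def make_benchmark(
    q: float,
    n_desc: int = 5,
    n_sets: int = 100,
    anc_len: int = 500,
    event_prob: float = 0.02,
    len_range: Tuple[int, int] = (1, 200),
    model: Optional[FunctionalModel] = None,
    inverse_mutation="default",
    seed: int = 0,
) -> List[SyntheticSet]:
    """Generate ``n_sets`` independent sets of ``n_desc`` descendants at ``q``."""
    if not 0.0 < q <= 1.0:
        raise ValueError(f"proximity q must lie in (0, 1], got {q}")
    if n_desc < 1 or n_sets < 1 or anc_len < 1:
        raise ValueError("counts must be >= 1")
    if model is None:
        model = default_background()
    if isinstance(inverse_mutation, str) and inverse_mutation == "default":
        inverse_mutation = default_inverse_mutation()
    rng = np.random.default_rng(seed)
    sets = []
    for _ in range(n_sets):
        ancestor = generate_ancestor(anc_len, model, rng)
        descendants = {}
        ancestries = {}
        for k in range(n_desc):
            name = f"d{k}"
            desc, anc_map = evolve_descendant(
                ancestor, q, model, inverse_mutation, rng
            )
            desc, anc_map, _ = apply_indels(
                desc, anc_map, event_prob, len_range, model, rng
            )
            if len(desc) == 0:  # indels deleted everything; keep one base
                desc, anc_map = ancestor[:1], np.array([0])
            descendants[name] = desc
            ancestries[name] = anc_map
        sets.append(
            SyntheticSet(
                ancestor=ancestor,
                descendants=descendants,
                ancestries=ancestries,
                reference=reference_pairs(ancestries),
                params={
                    "q": q,
                    "event_prob": event_prob,
                    "len_range": len_range,
                    "seed": seed,
                },
            )
        )
    return sets


def make_shuffled(groups: Sequence[Sequence[str]], offset: int = 100):
    """Recombine per-locus groups so no output group holds two orthologues.

    ``groups[n][k]`` is the sequence of species ``k`` at locus ``n``.  Output
    group ``n`` receives, for species ``k``, the sequence of species ``k``
    from locus ``(n + k*offset) mod N``.  If the nominal offset would place
    two sequences of one input locus in the same output group, the smallest
    valid offset is used instead; with fewer loci than species no valid
    offset exists.
    """
    n_loci = len(groups)
    if n_loci < 2:
        raise ValueError("need at least two loci to shuffle")
    n_species = len(groups[0])
    if any(len(g) != n_species for g in groups):
        raise ValueError("every locus must provide the same species count")

    def valid(o):
        return len({(k * o) % n_loci for k in range(n_species)}) == n_species

    if not valid(offset):
        for o in range(1, n_loci):
            if valid(o):
                offset = o
                break
        else:
            raise ValueError(
                f"no shuffle offset can separate {n_species} species "
                f"across {n_loci} loci"
            )
    return [
        [groups[(n + k * offset) % n_loci][k] for k in range(n_species)]
        for n in range(n_loci)
    ]


def evaluate(reference: set, predicted: set) -> EvaluationReport:
    """Score a predicted pair set against the reference pair set."""
    n_ref = len(reference)
    if n_ref == 0:
        raise ValueError("reference pair set is empty; metrics are undefined")
    n_correct = len(reference & predicted)
    n_incorrect = len(predicted - reference)
    n_pred = n_correct + n_incorrect
    return EvaluationReport(
        sensitivity=n_correct / n_ref,
        error_rate=n_incorrect / n_ref,
        precision=(n_correct / n_pred) if n_pred else 0.0,
        n_ref=n_ref,
        n_correct=n_correct,
        n_incorrect=n_incorrect,
        empty_prediction=(n_pred == 0),
    )
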