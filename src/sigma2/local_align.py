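"""Best gapless local alignment between two fragments.

Every gapless pairing of two fragments lies on one diagonal of the
``L1 x L2`` comparison matrix of per-column relatedness scores.  The search
centres the scores on the null mean and looks for the segment whose corrected
p-value ``P`` is minimal.  Minimal ``P`` is essentially maximal
``z = C / sqrt(m)`` where ``C`` is the centred segment score — an objective
that is not prefix-decomposable, so a plain maximal-segment recurrence does
not optimise it directly.  The search therefore works on candidate segments:

* when the shorter fragment has at most ``EXACT_LIMIT`` columns, *every*
  segment on every diagonal is enumerated, so the result is exact;
* otherwise one candidate per diagonal is generated by a maximal-segment
  (reset-at-0) recurrence on the centred scores.

Exact corrected p-values are evaluated only on candidates, preserving the
``O(L1*L2)`` character of the scan.  The restraint in the large-fragment
regime is deliberate: the multiplicity correction of the p-value counts the
placements of one alignment length, so mining the exact minimum over every
(start, start, length) triple of two long fragments would optimise over far
more hypotheses than the correction accounts for, and chance segments of
near-zero drift would reach the threshold.  One maximal segment per diagonal
keeps the candidate count at the scale the correction assumes; secondary
excursions on a diagonal are recovered after a fusion, when the flanking
fragments are re-searched.  Coordinates are 0-based, half-open.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .significance import NullScoreStats, _pvalue_arrays

__all__ = ["LocalAlignmentCandidate", "best_local_alignment", "accept"]

#: below this shorter-fragment length the segment search is fully exhaustive
EXACT_LIMIT = 32
#: a large-fragment candidate is split where its running raw score falls
#: this many nats below the running maximum (posterior odds e**-X that the
#: dip is part of the same homologous block)
X_DROP = 10.0


@dataclass(frozen=True)
class LocalAlignmentCandidate:
    """A proposed gapless pairing of two fragments.

    ``pvalue`` is the CLT-based corrected p-value used for ranking and
    acceptance; ``lr_pvalue`` is a rigorous companion bound on the same tail
    obtained from the Markov inequality on the likelihood ratio
    (``Pr[S >= s] <= e**-s`` for any log-likelihood-ratio score), with the
    same placement-multiplicity correction.  The Gaussian tail is accurate
    for strong, concentrated alignments but underestimates the probability
    of long near-zero-drift chance excursions; the likelihood-ratio bound is
    exact there, so the aligner requires both to pass the threshold.
    """

    frag_a: int
    frag_b: int
    start_a: int
    start_b: int
    m: int
    score: float
    pvalue: float
    log_pvalue: float
    lr_pvalue: float = 0.0


def accept(candidate: LocalAlignmentCandidate, threshold: float) -> bool:
    """True iff the candidate's p-value passes the (inclusive) threshold."""
    return candidate.pvalue <= threshold


def accept_strict(candidate: LocalAlignmentCandidate, threshold: float) -> bool:
    """Inclusive threshold on both the CLT p-value and the LR tail bound."""
    return candidate.pvalue <= threshold and candidate.lr_pvalue <= threshold


def _diagonal_prefix(X: np.ndarray):
    """Stack the diagonals of ``X`` into rows of prefix sums.

    Returns ``(c, n, off_i, off_j)`` where row ``r`` of ``c`` holds the
    prefix sums of diagonal ``r`` (length ``n[r]``; padded positions repeat
    the final value) and ``(off_i[r], off_j[r])`` is the diagonal's origin.
    """
    L1, L2 = X.shape
    R = L1 + L2 - 1
    nmax = min(L1, L2)
    r = np.arange(R)
    off_i = np.maximum(0, (L1 - 1) - r)
    off_j = np.maximum(0, r - (L1 - 1))
    n = np.minimum(L1 - off_i, L2 - off_j)
    t = np.arange(nmax)
    valid = t[None, :] < n[:, None]
    flat = np.where(valid, (off_i[:, None] + t) * L2 + (off_j[:, None] + t), 0)
    D = X.ravel()[flat] * valid
    c = np.zeros((R, nmax + 1))
    np.cumsum(D, axis=1, out=c[:, 1:])
    return c, n, off_i, off_j


def _exact_rows(c, n, rows, min_len, cap=2048, chunk=64):
    """All positive segments on the given diagonal rows (batched).

    Rows holding more than ``cap`` qualifying segments each are truncated to
    the ``cap`` best by ``z = C/sqrt(m)``.
    """
    rows = np.asarray(list(rows), dtype=np.intp)
    if rows.size == 0:
        return []
    width = c.shape[1]
    idx = np.arange(width)
    m_grid = idx[None, :] - idx[:, None]  # m[s, e]
    chunk = max(1, min(chunk, (1 << 22) // (width * width)))
    outs = []
    for lo in range(0, rows.size, chunk):
        sel = rows[lo : lo + chunk]
        cc = c[sel]
        diff = cc[:, None, :] - cc[:, :, None]  # diff[r, s, e] = c[e] - c[s]
        mask = (
            (m_grid[None, :, :] >= min_len)
            & (diff > 0)
            & (idx[None, None, :] <= n[sel][:, None, None])
        )
        r_idx, s_idx, e_idx = np.nonzero(mask)
        if r_idx.size == 0:
            continue
        C = diff[r_idx, s_idx, e_idx]
        if r_idx.size > cap * sel.size:
            m = (e_idx - s_idx).astype(float)
            top = np.argpartition(-C / np.sqrt(m), cap * sel.size)[: cap * sel.size]
            r_idx, s_idx, e_idx, C = r_idx[top], s_idx[top], e_idx[top], C[top]
        outs.append((sel[r_idx], s_idx, e_idx, C))
    return outs


def _kadane_rows(c, n, min_len):
    """Best-scoring (max C) segment per diagonal, plus a refinement bound.

    Returns ``(part, bound)``: the per-diagonal maximal-segment candidates
    (start = first occurrence of the running prefix minimum, end = position
    of the maximal gain), and per-diagonal upper bounds on the achievable
    ``z = C/sqrt(m)`` over segments of length >= ``min_len``
    (``bound = C_max / sqrt(min_len)``).
    """
    R, width = c.shape
    idx = np.arange(width)
    vt = idx[None, :] <= n[:, None]
    cmask = np.where(vt, c, np.inf)
    rm = np.minimum.accumulate(cmask, axis=1)
    rm_prev = np.concatenate([np.full((R, 1), np.inf), rm[:, :-1]], axis=1)
    strict = cmask < rm_prev
    pam = np.maximum.accumulate(np.where(strict, idx[None, :], -1), axis=1)
    with np.errstate(invalid="ignore"):
        gain = np.where(vt, c - rm_prev, -np.inf)  # best C for segments ending here
    e_r = np.argmax(gain, axis=1)
    rows = np.arange(R)
    C_r = gain[rows, e_r]
    ok = np.isfinite(C_r) & (C_r > 0)
    s_r = pam[rows, np.maximum(e_r - 1, 0)]
    m_r = e_r - s_r
    keep = ok & (s_r >= 0) & (m_r >= min_len)
    part = (rows[keep], s_r[keep], e_r[keep], C_r[keep])
    bound = np.where(ok, C_r, -np.inf) / np.sqrt(min_len)
    return part, bound


def _collect_candidates(X: np.ndarray, mean: float, min_len: int):
    """Candidate segments ``(i, j, m, C)``; ``C`` is the centred segment score.

    Small fragment pairs are enumerated exhaustively on centred scores
    (exact minimal-P search).  Large pairs take one maximal segment per
    diagonal from a reset-at-0 recurrence on the *raw* scores: raw
    log-likelihood-ratio scores drift negative outside genuine homology, so
    the maximal segment ends crisply at the homology boundary instead of
    wandering into flanking sequence the way a zero-drift centred walk does.
    """
    L1, L2 = X.shape
    if min(L1, L2) <= EXACT_LIMIT:
        c, n, off_i, off_j = _diagonal_prefix(X - mean)
        parts = _exact_rows(c, n, range(len(n)), min_len)
        centred = True
    else:
        c, n, off_i, off_j = _diagonal_prefix(X)
        part, _ = _kadane_rows(c, n, min_len)
        parts = [part]
        centred = False
    parts = [p for p in parts if p[0].size]
    if not parts:
        return None
    r = np.concatenate([p[0] for p in parts]).astype(np.intp)
    s = np.concatenate([p[1] for p in parts]).astype(np.intp)
    e = np.concatenate([p[2] for p in parts]).astype(np.intp)
    C = np.concatenate([p[3] for p in parts])
    m = e - s
    if r.size > 65536:
        # evaluating exact p-values on every family candidate is wasteful;
        # z ranks them almost identically, so keep a generous head
        top = np.argpartition(-C / np.sqrt(m), 65536)[:65536]
        r, s, e, C, m = r[top], s[top], e[top], C[top], m[top]
    i = off_i[r] + s
    j = off_j[r] + s
    if not centred:
        C = C - m * mean
    return i, j, m, C


def _xdrop_pieces(x: np.ndarray, x_drop: float):
    """Split a raw-score run at dips deeper than ``x_drop`` nats.

    Returns ``(start, end)`` pairs (half-open, relative to ``x``); each piece
    runs from a dip bottom to its own running maximum, so pieces are
    themselves maximal segments.
    """
    pieces = []
    start = 0
    cum = 0.0
    runmax = 0.0
    argmax = 0
    for k, v in enumerate(x):
        cum += v
        if cum > runmax:
            runmax = cum
            argmax = k + 1
        elif runmax - cum > x_drop:
            if argmax > start:
                pieces.append((start, argmax))
            start = k + 1
            cum = 0.0
            runmax = 0.0
            argmax = k + 1
    if argmax > start:
        pieces.append((start, argmax))
    return pieces


def best_local_alignment(
    fragA,
    fragB,
    scorer,
    stats: NullScoreStats,
    min_len: int = 4,
    x_drop: float = X_DROP,
) -> LocalAlignmentCandidate | None:
    """Lowest corrected-p-value gapless pairing of two fragments.

    Ties on the p-value are broken towards longer alignments, then smaller
    ``start_a``, then smaller ``start_b``.  Returns ``None`` when no segment
    of at least ``min_len`` columns beats the null mean.
    """
    if fragA.length < 1 or fragB.length < 1:
        raise ValueError("fragments must be non-empty")
    if fragA.length < min_len or fragB.length < min_len:
        return None
    X = scorer.score_matrix(fragA, fragB)
    found = _collect_candidates(X, stats.mean, min_len)
    if found is None:
        return None
    i, j, m, C = found
    P, logP, S = _pvalue_arrays(C, m, stats.sd, stats.mean, fragA.length, fragB.length)
    order = np.lexsort((j, i, -m, logP))
    k = order[0]
    ik, jk, mk = int(i[k]), int(j[k]), int(m[k])
    if min(fragA.length, fragB.length) > EXACT_LIMIT and mk > min_len:
        # Trim the winner to its own minimal-P core.  The maximal raw-score
        # segment can carry weakly-positive non-homologous "riders" at its
        # edges, or bridge two blocks across a shallow dip; splitting at
        # deep dips (X-drop) and re-minimising P over sub-segments keeps
        # only the part the significance machinery itself supports.  Pieces
        # dropped here are re-found after the core has fused.
        run = X[ik + np.arange(mk), jk + np.arange(mk)]
        sub = []
        for a, b in _xdrop_pieces(run, x_drop):
            if b - a < min_len:
                continue
            cr = np.concatenate([[0.0], np.cumsum(run[a:b])])
            w = cr.size
            diff = cr[None, :] - cr[:, None]
            s_idx, e_idx = np.nonzero(
                (np.arange(w)[None, :] - np.arange(w)[:, None]) >= min_len
            )
            mm = e_idx - s_idx
            CC = diff[s_idx, e_idx] - mm * stats.mean
            keep = CC > 0
            if np.any(keep):
                sub.append((a + s_idx[keep], mm[keep], CC[keep]))
        if not sub:
            return None
        off = np.concatenate([p[0] for p in sub])
        mm = np.concatenate([p[1] for p in sub])
        CC = np.concatenate([p[2] for p in sub])
        P, logP, S = _pvalue_arrays(
            CC, mm, stats.sd, stats.mean, fragA.length, fragB.length
        )
        kk = int(np.lexsort((off, -mm, logP))[0])
        ik, jk, mk = ik + int(off[kk]), jk + int(off[kk]), int(mm[kk])
        P, logP, S = P[kk : kk + 1], logP[kk : kk + 1], S[kk : kk + 1]
        k = 0
    # Markov bound on the likelihood ratio.  The multiplicity here is the
    # size of the whole search space (every placement of every length scans
    # O(L1*L2) cells), not the placement count of one length: the bound must
    # cover the segment the scan chose, whatever its length.
    trials = float(fragA.length) * float(fragB.length)
    log_p_lr = min(0.0, -float(S[k]))
    if log_p_lr > -1e-12:
        lr_p = 1.0
    elif log_p_lr > -30:
        lr_p = float(min(1.0, -np.expm1(trials * np.log1p(-np.exp(log_p_lr)))))
    else:
        lr_p = float(min(1.0, trials * np.exp(log_p_lr)))
    return LocalAlignmentCandidate(
        frag_a=fragA.id,
        frag_b=fragB.id,
        start_a=ik,
        start_b=jk,
        m=mk,
        score=float(S[k]),
        pvalue=float(P[k]),
        log_pvalue=float(logP[k]),
        lr_pvalue=lr_p,
    )
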