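"""Null-score statistics and p-values for gapless local alignments.

The null hypothesis is that two fragments are unrelated.  Its per-column
score distribution is characterised empirically: the mean and standard
deviation of the column score over random position pairs drawn from the two
fragments.  By the central limit theorem an alignment of length ``m`` then
has a Gaussian null score, giving the single-alignment tail probability

    p' = 1/2 * erfc( (S - m*sbar) / (sigma * sqrt(2*m)) )

(``sigma`` is the per-column standard deviation, so the ``m``-column standard
deviation is ``sigma*sqrt(m)``).  Correcting for the number of ways a length-m
gapless alignment can be placed in fragments of lengths ``L1``, ``L2``:

    P = 1 - (1 - p')**((L1 - m + 1) * (L2 - m + 1))

``P`` grows with the fragment lengths, which is the progressive aligner's
contextual-significance effect: a short alignment rejected between two long
fragments can become significant once flanking alignments have shrunk the
fragments around it.

Upper tail orientation: large ``S`` means improbably *high* relatedness, so
small ``P`` is significant.  For extreme scores the tail is evaluated through
the scaled complementary error function so that ranking never ties at zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erfc, erfcx

__all__ = [
    "NullScoreStats",
    "estimate_null_stats",
    "single_alignment_pvalue",
    "single_alignment_log_pvalue",
    "corrected_pvalue",
]

_LOG_HALF = float(np.log(0.5))
_ERFCX_SWITCH = 6.0


@dataclass(frozen=True)
class NullScoreStats:
    """Empirical null distribution of the per-column score."""

    mean: float
    sd: float
    n_samples: int
    seed: object = None

    def __post_init__(self):
        if self.sd < 0:
            raise ValueError("standard deviation must be >= 0")
        if self.n_samples < 2:
            raise ValueError("need at least 2 null samples")


def estimate_null_stats(fragA, fragB, scorer, n: int = 1000, rng=None) -> NullScoreStats:
    """Sample ``n`` random position pairs and summarise their column scores.

    Deterministic for a given seed.  With single-column fragments the mean is
    the one possible score and the deviation is 0.
    """
    if n < 2:
        raise ValueError("need at least 2 null samples")
    if fragA.length < 1 or fragB.length < 1:
        raise ValueError("fragments must be non-empty")
    seed = rng if not isinstance(rng, np.random.Generator) else None
    gen = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    table, invA, invB = scorer.score_table(fragA, fragB)
    i = gen.integers(0, fragA.length, size=n)
    j = gen.integers(0, fragB.length, size=n)
    vals = table[invA[i], invB[j]]
    return NullScoreStats(
        mean=float(vals.mean()),
        sd=float(vals.std(ddof=1)),
        n_samples=n,
        seed=seed,
    )


def single_alignment_pvalue(S: float, m: int, stats: NullScoreStats) -> float:
    """Upper-tail probability that unrelated fragments score >= ``S`` at length m."""
    if m < 1:
        raise ValueError("alignment length m must be >= 1")
    if stats.sd == 0.0:
        return 0.0 if S > m * stats.mean else 1.0
    x = (S - m * stats.mean) / (stats.sd * np.sqrt(2.0 * m))
    return float(min(1.0, max(0.0, 0.5 * erfc(x))))


def single_alignment_log_pvalue(S: float, m: int, stats: NullScoreStats) -> float:
    """Natural log of :func:`single_alignment_pvalue`, safe against underflow."""
    if m < 1:
        raise ValueError("alignment length m must be >= 1")
    if stats.sd == 0.0:
        return -np.inf if S > m * stats.mean else 0.0
    x = (S - m * stats.mean) / (stats.sd * np.sqrt(2.0 * m))
    if x > _ERFCX_SWITCH:
        return _LOG_HALF + float(np.log(erfcx(x))) - x * x
    return float(np.log(min(1.0, 0.5 * erfc(x))))


def corrected_pvalue(p_single: float, m: int, L1: int, L2: int) -> float:
    """Probability that *some* length-m alignment scores as well by chance.

    ``P = 1 - (1 - p')**((L1-m+1)(L2-m+1))``; reduces to
    ``p' * (L1-m+1)(L2-m+1)`` for small ``p'``.
    """
    if m < 1:
        raise ValueError("alignment length m must be >= 1")
    if m > L1 or m > L2:
        raise ValueError(f"alignment length {m} exceeds a fragment length")
    if not 0.0 <= p_single <= 1.0:
        raise ValueError("p' must lie in [0, 1]")
    trials = float(L1 - m + 1) * float(L2 - m + 1)
    if p_single >= 1.0:
        return 1.0
    return float(min(1.0, -np.expm1(trials * np.log1p(-p_single))))


def _pvalue_arrays(C, m, sd, mean, L1, L2):
    """Vectorised (P, logP, S) for candidate segments.

    ``C`` are centred segment scores (``S - m*mean``).  Internal helper shared
    with the local-alignment search; natural logs.
    """
    C = np.asarray(C, dtype=float)
    m = np.asarray(m, dtype=float)
    S = C + m * mean
    trials = (L1 - m + 1.0) * (L2 - m + 1.0)
    log_trials = np.log(trials)
    if sd == 0.0:
        p1 = np.where(C > 0, 0.0, 1.0)
        logp1 = np.where(C > 0, -np.inf, 0.0)
    else:
        x = C / (sd * np.sqrt(2.0 * m))
        p1 = 0.5 * erfc(x)
        logp1 = np.where(
            x > _ERFCX_SWITCH,
            _LOG_HALF + np.log(erfcx(np.maximum(x, 0.0))) - x * x,
            np.log(np.maximum(p1, 1e-320)),
        )
    tiny = p1 < 1e-12
    with np.errstate(divide="ignore", over="ignore"):
        P_big = -np.expm1(trials * np.log1p(-np.where(tiny, 0.0, p1)))
        logP = np.where(
            tiny,
            logp1 + log_trials,
            np.log(np.maximum(P_big, 1e-320)),
        )
        logP = np.minimum(logP, 0.0)
        P = np.where(tiny, np.exp(logP), np.minimum(P_big, 1.0))
    return P, logP, S
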