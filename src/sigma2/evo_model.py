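"""Nucleotide substitution model with separate mutation and fixation.

The model distinguishes three ingredients:

* a *functional model* ``M`` — the equilibrium probabilities of the four
  nucleotides at a locus, optionally conditioned on the left neighbour
  (a first-order, dinucleotide background);
* a *mutation matrix* ``P`` — the probability that nucleotide ``beta``
  mutates to ``alpha`` given that a mutation occurs (zero diagonal,
  column-stochastic);
* the *proximity* ``q`` of a branch — the probability that a site is
  unmutated across the branch, ``q = exp(-mu*t)``.

Two branch transition matrices are provided.  Under *perfect fixation*
a mutated site is redrawn from ``M``::

    T(alpha|beta; q, M) = q*delta(alpha,beta) + (1-q)*M[alpha]

Under the matrix model the transition probability sums a Poisson number
of mutations, which collapses to a matrix power of the proximity::

    T = q**(I - P) = expm(ln(q) * (I - P))

Fixation is folded into the matrix model through an *effective* mutation
matrix ``P'`` obtained by Bayesian inversion of an inverse mutation matrix
``Q`` (``Q[beta, alpha]`` = probability the ancestor was ``beta`` given the
descendant is ``alpha``) against the functional model::

    P'[alpha, beta] = Q[beta, alpha] * M[alpha] / sum_a Q[beta, a] * M[a]

Nucleotide order is A, C, G, T everywhere in this package.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

__all__ = [
    "NUCLEOTIDES",
    "NUC_INDEX",
    "N_CODE",
    "NO_CONTEXT",
    "ModelError",
    "FunctionalModel",
    "perfect_fixation_transition",
    "matrix_transition",
    "effective_mutation_matrix",
    "estimate_inverse_mutation_matrix",
    "uniform_inverse_mutation",
    "default_background",
    "default_inverse_mutation",
    "encode_sequence",
    "decode_sequence",
    "context_codes",
]

NUCLEOTIDES = "ACGT"
NUC_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}
#: observation code for the ambiguity character N (treated as missing data)
N_CODE = 4
#: left-neighbour context code used at a sequence start (no left neighbour)
NO_CONTEXT = 4

_COLSUM_TOL = 1e-8


class ModelError(ValueError):
    """Invalid model parameter (non-stochastic matrix, bad proximity, ...)."""


def _check_distribution(m, name="m"):
    m = np.asarray(m, dtype=float)
    if m.shape != (4,):
        raise ModelError(f"{name} must be a 4-vector, got shape {m.shape}")
    if np.any(m < -1e-12) or abs(m.sum() - 1.0) > 1e-9:
        raise ModelError(f"{name} is not a probability distribution: {m}")
    m = np.clip(m, 0.0, None)
    return m / m.sum()


def _check_mutation_matrix(P, name="P"):
    P = np.asarray(P, dtype=float)
    if P.shape != (4, 4):
        raise ModelError(f"{name} must be 4x4, got shape {P.shape}")
    if np.any(np.abs(np.diag(P)) > 1e-12):
        raise ModelError(f"{name} must have a zero diagonal")
    if np.any(P < -1e-12) or np.any(np.abs(P.sum(axis=0) - 1.0) > _COLSUM_TOL):
        raise ModelError(f"{name} must be column-stochastic with entries >= 0")
    return P


class FunctionalModel:
    """Equilibrium nucleotide probabilities, optionally left-neighbour conditioned.

    Parameters
    ----------
    marginal : array-like of shape (4,)
        Unconditioned probabilities of A, C, G, T.  Used at sequence starts
        and wherever no context is available (including after an N).
    conditional : array-like of shape (4, 4), optional
        ``conditional[x, y]`` = probability of nucleotide ``y`` given left
        neighbour ``x``.  When omitted, the marginal is used in every context
        (a mononucleotide background).
    """

    def __init__(self, marginal, conditional=None):
        marginal = _check_distribution(marginal, "marginal")
        probs = np.empty((5, 4))
        probs[NO_CONTEXT] = marginal
        if conditional is None:
            probs[:4] = marginal
        else:
            conditional = np.asarray(conditional, dtype=float)
            if conditional.shape != (4, 4):
                raise ModelError("conditional must be 4x4 (rows = left neighbour)")
            for x in range(4):
                probs[x] = _check_distribution(conditional[x], f"conditional[{x}]")
        self._probs = probs
        self.uniform = bool(np.allclose(probs, 0.25, atol=1e-12))

    @classmethod
    def uniform_model(cls) -> "FunctionalModel":
        return cls(np.full(4, 0.25))

    @classmethod
    def from_dinucleotide_freqs(cls, joint) -> "FunctionalModel":
        """Build from joint dinucleotide frequencies ``joint[x, y]`` (left, right)."""
        joint = np.asarray(joint, dtype=float)
        if joint.shape != (4, 4) or np.any(joint < 0) or joint.sum() <= 0:
            raise ModelError("joint dinucleotide frequencies must be 4x4, >= 0")
        joint = joint / joint.sum()
        left = joint.sum(axis=1)
        if np.any(left <= 0):
            raise ModelError("every left-neighbour marginal must be positive")
        conditional = joint / left[:, None]
        # marginal over the second position of the dinucleotide
        marginal = joint.sum(axis=0)
        return cls(marginal, conditional)

    def probs(self, context: int = NO_CONTEXT) -> np.ndarray:
        """4-vector of nucleotide probabilities given a left-neighbour code."""
        return self._probs[context]

    @property
    def marginal(self) -> np.ndarray:
        return self._probs[NO_CONTEXT]

    def __eq__(self, other):
        return isinstance(other, FunctionalModel) and np.array_equal(
            self._probs, other._probs
        )

    def __repr__(self):
        tag = "uniform" if self.uniform else "dinucleotide"
        return f"FunctionalModel({tag}, marginal={np.round(self.marginal, 4)})"


def perfect_fixation_transition(q: float, m) -> np.ndarray:
    """Branch transition matrix under perfect fixation.

    ``T[alpha, beta] = q*delta + (1-q)*m[alpha]``: with probability ``q`` the
    site is unmutated; otherwise its distribution is the functional model.
    """
    if not 0.0 <= q <= 1.0:
        raise ModelError(f"proximity q must lie in [0, 1], got {q}")
    m = _check_distribution(m)
    return q * np.eye(4) + (1.0 - q) * np.outer(m, np.ones(4))


def matrix_transition(q: float, P) -> np.ndarray:
    """Branch transition matrix ``q**(I - P)`` for mutation matrix ``P``.

    Equivalent to summing ``P**k`` over a Poisson-distributed number of
    mutations ``k`` with mean ``-ln(q)``.
    """
    if not 0.0 < q <= 1.0:
        raise ModelError(f"proximity q must lie in (0, 1], got {q}")
    P = _check_mutation_matrix(P)
    if q == 1.0:
        return np.eye(4)
    T = expm(np.log(q) * (np.eye(4) - P))
    T = np.clip(T, 0.0, None)
    colsums = T.sum(axis=0)
    if np.any(np.abs(colsums - 1.0) > _COLSUM_TOL):
        raise ModelError("transition matrix drifted from column-stochasticity")
    return T / colsums


def effective_mutation_matrix(Q, m) -> np.ndarray:
    """Fixation-corrected mutation matrix ``P'`` from Bayesian inversion.

    ``Q[beta, alpha]`` is the probability that the ancestor was ``beta``
    given descendant ``alpha``; ``m`` is the functional model.  Columns of
    the result sum to 1 and the diagonal is zero.
    """
    Q = _check_mutation_matrix(Q, "Q")
    m = _check_distribution(m)
    denom = Q @ m  # denom[beta] = sum_a Q[beta, a] * m[a]
    if np.any(denom <= 0):
        raise ModelError("degenerate model: a column of P' has zero mass")
    P = (Q.T * m[:, None]) / denom[None, :]
    return P


def estimate_inverse_mutation_matrix(pair_counts) -> np.ndarray:
    """Estimate ``Q[beta, alpha]`` from (ancestor-proxy, descendant) pair counts.

    Off-diagonal counts in each descendant column are normalised to 1; the
    diagonal is zero by definition (a mutation never preserves the base).
    """
    C = np.asarray(pair_counts, dtype=float)
    if C.shape != (4, 4) or np.any(C < 0):
        raise ModelError("pair_counts must be a non-negative 4x4 matrix")
    C = C.copy()
    np.fill_diagonal(C, 0.0)
    colsums = C.sum(axis=0)
    if np.any(colsums <= 0):
        raise ModelError("degenerate counts: a descendant column has no "
                         "off-diagonal observations")
    return C / colsums


def uniform_inverse_mutation() -> np.ndarray:
    """Inverse mutation matrix with all off-diagonal entries equal (1/3)."""
    Q = np.full((4, 4), 1.0 / 3.0)
    np.fill_diagonal(Q, 0.0)
    return Q


# ---------------------------------------------------------------------------
# Built-in defaults.
#
# These are synthetic illustrative parameter values, not estimates from any
# genome: the background is patterned on AT-rich fungal intergenic sequence
# (AA enrichment, CG depletion) and the inverse mutation matrix favours
# transitions over transversions 3:1.  Supply measured files through the
# loaders in :mod:`sigma2.io_formats` for real analyses.
# ---------------------------------------------------------------------------

_DEFAULT_CONDITIONAL = np.array(
    [
        # next:  A     C     G     T        left neighbour
        [0.36, 0.17, 0.17, 0.30],  # A
        [0.32, 0.20, 0.14, 0.34],  # C  (CG depleted)
        [0.30, 0.20, 0.20, 0.30],  # G
        [0.26, 0.19, 0.21, 0.34],  # T
    ]
)

_DEFAULT_Q = np.array(
    [
        # desc:  A     C     G     T       ancestor
        [0.0, 0.2, 0.6, 0.2],  # A
        [0.2, 0.0, 0.2, 0.6],  # C
        [0.6, 0.2, 0.0, 0.2],  # G
        [0.2, 0.6, 0.2, 0.0],  # T
    ]
)


def default_background() -> FunctionalModel:
    """Default dinucleotide background (synthetic AT-rich values).

    The marginal is the stationary distribution of the left-neighbour
    conditional chain, so the background is internally consistent.
    """
    # stationary distribution of the row-stochastic conditional
    w, v = np.linalg.eig(_DEFAULT_CONDITIONAL.T)
    k = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, k])
    if pi.sum() < 0:  # eigenvectors are defined up to sign
        pi = -pi
    pi = np.clip(pi, 0.0, None)
    pi = pi / pi.sum()
    return FunctionalModel(pi, _DEFAULT_CONDITIONAL)


def default_inverse_mutation() -> np.ndarray:
    """Default inverse mutation matrix (synthetic transition-biased values)."""
    return _DEFAULT_Q.copy()


# ---------------------------------------------------------------------------
# Sequence encoding helpers shared across the package.
# ---------------------------------------------------------------------------

_ENCODE = np.full(256, -1, dtype=np.int8)
for _c, _i in NUC_INDEX.items():
    _ENCODE[ord(_c)] = _i
_ENCODE[ord("N")] = N_CODE


def encode_sequence(seq: str) -> np.ndarray:
    """Encode A/C/G/T/N into int8 codes 0..4."""
    codes = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if np.any(codes < 0):
        bad = sorted(set(seq) - set("ACGTN"))
        raise ModelError(f"sequence contains unsupported characters: {bad}")
    return codes


def decode_sequence(codes) -> str:
    return "".join("ACGTN"[c] for c in codes)


def context_codes(obs: np.ndarray) -> np.ndarray:
    """Left-neighbour context codes for an encoded sequence.

    Position 0 has no context; a left neighbour of N also yields no context
    (the unconditioned marginal is used there).
    """
    ctx = np.empty_like(obs)
    ctx[0] = NO_CONTEXT
    ctx[1:] = obs[:-1]
    ctx[ctx == N_CODE] = NO_CONTEXT
    return ctx
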