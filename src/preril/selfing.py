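"""16-state Markov chain for repeated self-fertilization.

Each selfing generation maps the phased-genotype frequency vector
``G`` (16 entries) through a column-stochastic transition matrix ``P``
whose column k is ``vec(h_k^T h_k)`` — the offspring distribution of a
selfed individual of genotype k, obtained by pairing two independent
gametes drawn from row k of the emission table.  The recombination
fraction after t transitions is ``W^T P^t G1`` where ``G1`` puts mass
1/2 on the two phase orderings of the F1 double heterozygote.

As t grows the value climbs from theta to the selfing asymptote
``2*theta / (1 + 2*theta)`` (the classical fully-inbred-line limit).
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

from .core import (
    ThetaTrajectory,
    build_emission_table,
    build_recombinant_weights,
    validate_theta,
    vec_column_major,
)

__all__ = [
    "build_selfing_transition",
    "initial_state_selfing",
    "selfing_theta_sequence",
    "selfing_theta_converged",
    "selfing_asymptote",
    "marginal_heterozygosity",
    "selfing_state_sequence",
]

#: |delta theta| threshold declaring the trajectory converged.
CONVERGENCE_TOL = 1e-10
#: Iteration cap for convergence detection.
CONVERGENCE_MAX_ITER = 500


def build_selfing_transition(theta, *, exact: bool = False) -> np.ndarray:
    """16x16 column-stochastic selfing transition matrix at theta.

    Column k is ``vec(h_k^T h_k)``: the phased-genotype distribution of
    one selfed offspring of genotype k (two independent gametes from the
    same parent).
    """
    H = build_emission_table(theta, exact=exact)
    P = np.empty((16, 16), dtype=H.dtype)
    for k in range(16):
        hk = H[k]
        P[:, k] = vec_column_major(np.outer(hk, hk))
    return P


def initial_state_selfing(*, exact: bool = False) -> np.ndarray:
    """F1 state: mass 1/2 on genotypes 4 (AB/ab) and 13 (ab/AB)."""
    if exact:
        G = np.full(16, Fraction(0), dtype=object)
        G[3] = G[12] = Fraction(1, 2)
    else:
        G = np.zeros(16)
        G[3] = G[12] = 0.5
    return G


def selfing_state_sequence(theta, t_max: int, *, exact: bool = False):
    """Yield ``(t, G_t)`` for t = 0..t_max, where ``G_0`` is the F1 state.

    Iterated matrix-vector products; the state stays an exact
    probability vector up to floating rounding.
    """
    if t_max < 0:
        raise ValueError(f"t_max must be >= 0, got {t_max}")
    P = build_selfing_transition(theta, exact=exact)
    G = initial_state_selfing(exact=exact)
    yield 0, G
    for t in range(1, t_max + 1):
        G = P @ G
        yield t, G


def selfing_theta_sequence(theta, t_max: int, *, exact: bool = False) -> ThetaTrajectory:
    """Recombination-fraction trajectory under selfing.

    ``values[t] = W^T P^t G1`` for t = 0..t_max, with ``values[0] =
    theta``.  At theta = 0.05 four transitions give 0.08923, the worked
    generation-adjusted value consumed by the QTL-prior pipeline.
    """
    validate_theta(theta)
    W = build_recombinant_weights(theta, exact=exact)
    values = [W @ G for _, G in selfing_state_sequence(theta, t_max, exact=exact)]
    return ThetaTrajectory(values=np.array(values, dtype=object if exact else float),
                           scheme="self", theta0=theta)


def selfing_theta_converged(theta, *, tol: float = CONVERGENCE_TOL,
                            max_iter: int = CONVERGENCE_MAX_ITER) -> tuple[float, int]:
    """Iterate until |delta theta| < tol; return (theta_limit, t_used)."""
    validate_theta(theta)
    W = build_recombinant_weights(theta)
    P = build_selfing_transition(theta)
    G = initial_state_selfing()
    prev = W @ G
    for t in range(1, max_iter + 1):
        G = P @ G
        cur = W @ G
        if abs(cur - prev) < tol:
            return float(cur), t
        prev = cur
    return float(prev), max_iter


def selfing_asymptote(theta):
    """Closed-form selfing limit ``2*theta / (1 + 2*theta)``."""
    validate_theta(theta)
    return 2 * theta / (1 + 2 * theta)


def marginal_heterozygosity(G: np.ndarray, locus: str = "A"):
    """Probability of heterozygosity at one locus under state vector G.

    Sums the probabilities of the phased genotypes whose two gametes
    carry different alleles at the chosen locus.  Halves every selfing
    generation: ``(1/2)**(t-1)`` at generation F_t.
    """
    G = np.asarray(G)
    if G.shape != (16,):
        raise ValueError(f"expected a 16-state vector, got shape {G.shape}")
    if locus not in ("A", "B"):
        raise ValueError(f"locus must be 'A' or 'B', got {locus!r}")
    # gamete alleles at (A, B): AB=(1,1), Ab=(1,0), aB=(0,1), ab=(0,0)
    allele = [1, 1, 0, 0] if locus == "A" else [1, 0, 1, 0]
    het = sum(G[i * 4 + j] for i in range(4) for j in range(4)
              if allele[i] != allele[j])
    return het
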