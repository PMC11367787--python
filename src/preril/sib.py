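"""256-state Markov chain for repeated brother-sister mating.

The state is an ordered sib pair: sib 1 of phased genotype i nested
with sib 2 of genotype j, at 1-based position ``k = (i - 1) * 16 + j``.
Given the parental pair (i, j), a single offspring's genotype
distribution is ``u = vec(h_j^T h_i)`` (one gamete from each parent),
and two sibs are conditionally independent given their parents, so
column k of the 256x256 transition matrix is the Kronecker square
``u (x) u``.

The working states are deliberately the full ordered, fully phased
pairs — no pooling into the historical 10 unphased or 22 composite
classes — because the matrix is generated by code, not by hand.

The recombination fraction after t transitions is ``V^T P^t G1`` with
``V[k(i,j)] = (W[i] + W[j]) / 2`` and ``G1`` uniform on the four phase
orderings of an F1 x F1 pair.  Its limit is ``4*theta / (1+6*theta)``;
the 8-way (eight-founder) analogue ``7*theta / (1+6*theta)`` is
provided as a convenience.
"""

from __future__ import annotations

import numpy as np

from .core import (
    ThetaTrajectory,
    build_emission_table,
    build_recombinant_weights,
    validate_theta,
    vec_column_major,
)

__all__ = [
    "sib_pair_index",
    "sib_pair_unindex",
    "build_sib_transition",
    "initial_state_sib",
    "sib_weights",
    "sib_theta_sequence",
    "sib_theta_converged",
    "sib_state_sequence",
    "sib_asymptote",
    "eight_way_sib_asymptote",
    "sib_marginal_state",
]

CONVERGENCE_TOL = 1e-10
CONVERGENCE_MAX_ITER = 500


def sib_pair_index(i: int, j: int) -> int:
    """1-based ordered-pair index ``k = (i - 1) * 16 + j``."""
    if not (1 <= i <= 16 and 1 <= j <= 16):
        raise ValueError(f"genotype indices must be in 1..16, got ({i}, {j})")
    return (i - 1) * 16 + j


def sib_pair_unindex(k: int) -> tuple[int, int]:
    """Inverse of :func:`sib_pair_index`."""
    if not 1 <= k <= 256:
        raise ValueError(f"sib-pair index must be in 1..256, got {k}")
    i, j = divmod(k - 1, 16)
    return i + 1, j + 1


def build_sib_transition(theta, *, swap_parent_convention: bool = False) -> np.ndarray:
    """256x256 column-stochastic sib-mating transition matrix at theta.

    Column ``k(i, j)`` is ``u (x) u`` with ``u = vec(h_j^T h_i)``.
    ``swap_parent_convention`` builds ``u = vec(h_i^T h_j)`` instead;
    because the initial state and the weights are symmetric in the two
    parents, trajectories are invariant to this choice (asserted in the
    test suite).
    """
    H = build_emission_table(theta)
    P = np.empty((256, 256))
    for i in range(16):
        for j in range(16):
            hi, hj = H[i], H[j]
            M = np.outer(hi, hj) if swap_parent_convention else np.outer(hj, hi)
            u = vec_column_major(M)
            P[:, i * 16 + j] = np.kron(u, u)
    return P


def initial_state_sib() -> np.ndarray:
    """F1 x F1 pair state: mass 1/4 on pair indices 52, 61, 196, 205.

    These are the four orderings of the two phase variants (genotypes 4
    and 13) of the F1 double heterozygote: k(4,4)=52, k(4,13)=61,
    k(13,4)=196, k(13,13)=205.
    """
    G = np.zeros(256)
    for i, j in ((4, 4), (4, 13), (13, 4), (13, 13)):
        G[sib_pair_index(i, j) - 1] = 0.25
    return G


def sib_weights(theta) -> np.ndarray:
    """256-vector V averaging the two sibs' recombinant weights.

    ``V = (W (x) J + J (x) W) / 2`` with J the 16-vector of ones, i.e.
    ``V[k(i,j)] = (W[i] + W[j]) / 2``.
    """
    W = build_recombinant_weights(theta)
    J = np.ones(16)
    return 0.5 * (np.kron(W, J) + np.kron(J, W))


def sib_state_sequence(theta, t_max: int):
    """Yield ``(t, G_t)`` for t = 0..t_max from the F1 x F1 pair state."""
    if t_max < 0:
        raise ValueError(f"t_max must be >= 0, got {t_max}")
    P = build_sib_transition(theta)
    G = initial_state_sib()
    yield 0, G
    for t in range(1, t_max + 1):
        G = P @ G
        yield t, G


def sib_theta_sequence(theta, t_max: int) -> ThetaTrajectory:
    """Recombination-fraction trajectory under brother-sister mating.

    ``values[t] = V^T P^t G1``; ``values[0] = theta``.  The first two
    values coincide with the selfing chain (all schemes agree through
    one transition), after which sib mating converges more slowly
    toward ``4*theta / (1 + 6*theta)``.
    """
    validate_theta(theta)
    V = sib_weights(theta)
    values = [float(V @ G) for _, G in sib_state_sequence(theta, t_max)]
    return ThetaTrajectory(values=np.array(values), scheme="sib", theta0=theta)


def sib_theta_converged(theta, *, tol: float = CONVERGENCE_TOL,
                        max_iter: int = CONVERGENCE_MAX_ITER) -> tuple[float, int]:
    """Iterate until |delta theta| < tol; return (theta_limit, t_used)."""
    validate_theta(theta)
    V = sib_weights(theta)
    P = build_sib_transition(theta)
    G = initial_state_sib()
    prev = V @ G
    for t in range(1, max_iter + 1):
        G = P @ G
        cur = V @ G
        if abs(cur - prev) < tol:
            return float(cur), t
        prev = cur
    return float(prev), max_iter


def sib_asymptote(theta):
    """Closed-form sib-mating limit ``4*theta / (1 + 6*theta)``."""
    validate_theta(theta)
    return 4 * theta / (1 + 6 * theta)


def eight_way_sib_asymptote(theta):
    """Eight-founder sib-line limit ``7*theta / (1 + 6*theta)``.

    The fully-inbred-line asymptote for lines founded from an 8-way
    cross and maintained by sib mating; always >= the 2-way limit.
    """
    validate_theta(theta)
    return 7 * theta / (1 + 6 * theta)


def sib_marginal_state(G: np.ndarray, sib: int = 1) -> np.ndarray:
    """16-state marginal genotype distribution of one sib of the pair."""
    G = np.asarray(G).reshape(16, 16)
    if sib == 1:
        return G.sum(axis=1)
    if sib == 2:
        return G.sum(axis=0)
    raise ValueError(f"sib must be 1 or 2, got {sib}")
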