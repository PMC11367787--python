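"""Gametic-frequency recurrence for advanced intercross lines (AIL).

Under random mating it suffices to track the four gamete frequencies
``(p, q, s, t) = (Pr(AB), Pr(Ab), Pr(aB), Pr(ab))``.  Random union of
gametes makes the next generation's genotype frequencies the Kronecker
square of the gamete vector, and applying the emission table H yields
the next gamete vector:

    G_{t+1} = (G_t (x) G_t) H

The recurrence is nonlinear in G (no matrix-power shortcut).  The
recombination fraction is simply ``q + s``, which increases toward 1/2
as linkage disequilibrium ``D = p*t - q*s`` decays by a factor
``(1 - theta)`` per generation.  Starting from the F1-derived gamete
pool the closed form is

    theta_t = (1/2) * [1 - (1 - 2*theta) * (1 - theta)**(t - 2)]

with the convention t = 2 at the F2 generation; the iterative API
counts steps after F2, i.e. t = steps + 2.
"""

from __future__ import annotations

import numpy as np

from .core import build_emission_table, validate_theta, ThetaTrajectory

__all__ = [
    "initial_gametes",
    "random_mating_step",
    "random_theta",
    "random_closed_form",
    "random_theta_sequence",
]


def initial_gametes(theta) -> np.ndarray:
    """F1 gamete pool: ``((1-theta)/2, theta/2, theta/2, (1-theta)/2)``.

    This is the gamete output of the F1 double heterozygote, i.e. the
    pool that forms the F2 generation.
    """
    validate_theta(theta)
    return np.array([(1 - theta) / 2, theta / 2, theta / 2, (1 - theta) / 2])


def random_mating_step(G: np.ndarray, H: np.ndarray) -> np.ndarray:
    """One random-mating generation: ``G_next = (G (x) G) H``.

    The 16-element Kronecker square is ordered to match the phased-
    genotype ordering (element ``(a-1)*4 + b`` is ``G[a] * G[b]``), so
    H applies row-wise.  The caller is responsible for building H at
    the same theta that produced G's provenance.

    The result is renormalized to sum exactly 1: the quadratic map
    squares any rounding deviation of the input's sum each generation,
    so without renormalization an O(1e-16) float error compounds to
    O(1e-3) within 50 generations.  The true sum is identically 1, so
    the renormalization is exact.
    """
    G = np.asarray(G, dtype=float)
    if G.shape != (4,):
        raise ValueError(f"expected 4 gamete frequencies, got shape {G.shape}")
    nxt = np.kron(G, G) @ np.asarray(H, dtype=float)
    return nxt / nxt.sum()


def random_theta(G: np.ndarray) -> float:
    """Recombination fraction of a gamete pool: ``q + s``."""
    G = np.asarray(G, dtype=float)
    if G.shape != (4,):
        raise ValueError(f"expected 4 gamete frequencies, got shape {G.shape}")
    return float(G[1] + G[2])


def random_closed_form(theta, t: int) -> float:
    """Closed-form AIL recombination fraction at generation t (t=2 is F2).

    ``(1/2) * [1 - (1 - 2*theta) * (1 - theta)**(t - 2)]``; equals theta
    at t = 2 and approaches 1/2 geometrically for theta in (0, 0.5).
    """
    validate_theta(theta)
    if t < 2:
        raise ValueError(f"generation label t must be >= 2, got {t}")
    return 0.5 * (1 - (1 - 2 * theta) * (1 - theta) ** (t - 2))


def random_theta_sequence(theta, t_max: int) -> ThetaTrajectory:
    """Iterated recurrence: ``values[k]`` after k steps from the F2 pool.

    ``values[0] = theta`` (the F2 value); ``values[k]`` corresponds to
    generation label ``t = k + 2`` of :func:`random_closed_form`, which
    it matches to machine precision.
    """
    validate_theta(theta)
    if t_max < 0:
        raise ValueError(f"t_max must be >= 0, got {t_max}")
    H = build_emission_table(theta)
    G = initial_gametes(theta)
    values = [random_theta(G)]
    for _ in range(t_max):
        G = random_mating_step(G, H)
        values.append(random_theta(G))
    return ThetaTrajectory(values=np.array(values), scheme="random", theta0=theta)
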