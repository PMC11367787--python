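"""Shared state space for two-locus phased genotypes.

Two biallelic loci (A/a and B/b) admit four gametes and, with gametic
origin tracked, 16 fully phased genotypes.  Everything in this package —
the selfing chain, the sib-mating chain, random mating, and the QTL
priors — is assembled from one object: the 16x4 gamete-emission table
``H`` whose row k gives the probabilities that phased genotype k
transmits each of the four gametes, as a function of the recombination
fraction theta.

Conventions (fixed; all downstream indexing depends on them):

* gamete order: ``AB, Ab, aB, ab`` (indices 1..4);
* phased genotype ``first/second`` has 1-based index
  ``(first - 1) * 4 + second``, so genotype 4 is AB/ab and genotype 13
  is ab/AB (the two phase orderings of the F1 double heterozygote);
* ``vec`` is column-major (stacks matrix columns top to bottom).

Public functions report 1-based genotype/gamete indices; ndarray storage
is 0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Sequence

import numpy as np

__all__ = [
    "GAMETES",
    "GENOTYPES",
    "ThetaTrajectory",
    "validate_theta",
    "genotype_index",
    "genotype_unindex",
    "genotype_label",
    "build_emission_table",
    "build_recombinant_weights",
    "vec_column_major",
    "linkage_ratio",
    "theta_from_linkage_ratio",
]

#: Gamete labels in their fixed order (1-based indices 1..4).
GAMETES: tuple[str, ...] = ("AB", "Ab", "aB", "ab")

# (allele at locus A, allele at locus B) for each gamete; 1 = upper-case
# parental allele, 0 = lower-case.
_GAMETE_ALLELES: tuple[tuple[int, int], ...] = ((1, 1), (1, 0), (0, 1), (0, 0))

#: Phased-genotype labels "first/second" in index order 1..16.
GENOTYPES: tuple[str, ...] = tuple(
    f"{GAMETES[i]}/{GAMETES[j]}" for i in range(4) for j in range(4)
)


class ThetaDomainError(ValueError):
    """Recombination fraction outside its domain [0, 0.5]."""


def validate_theta(theta: float, *, name: str = "theta") -> float:
    """Check ``0 <= theta <= 0.5`` and return theta unchanged.

    Accepts :class:`fractions.Fraction` for the exact-rational mode.
    """
    if not (0 <= theta <= Fraction(1, 2)):
        raise ThetaDomainError(
            f"{name} must lie in [0, 0.5], got {theta!r}"
        )
    return theta


def genotype_index(first: int, second: int) -> int:
    """1-based phased-genotype index ``(first - 1) * 4 + second``.

    ``first`` and ``second`` are 1-based gamete indices (1=AB .. 4=ab).
    """
    if not (1 <= first <= 4 and 1 <= second <= 4):
        raise ValueError(f"gamete indices must be in 1..4, got ({first}, {second})")
    return (first - 1) * 4 + second


def genotype_unindex(index: int) -> tuple[int, int]:
    """Inverse of :func:`genotype_index`; returns 1-based gamete pair."""
    if not 1 <= index <= 16:
        raise ValueError(f"genotype index must be in 1..16, got {index}")
    first, second = divmod(index - 1, 4)
    return first + 1, second + 1


def genotype_label(index: int) -> str:
    """Human-readable label (e.g. ``'AB/ab'``) for a 1-based genotype index."""
    return GENOTYPES[index - 1]


def _zero_one(theta):
    """(0, 1) in the arithmetic matching theta's type."""
    if isinstance(theta, Fraction):
        return Fraction(0), Fraction(1)
    return 0.0, 1.0


def build_emission_table(theta, *, exact: bool = False) -> np.ndarray:
    """Gamete-emission table H: 16x4, rows = phased genotypes, cols = gametes.

    Row k gives the transmission probabilities of the four gametes from
    genotype k.  A gamete draws its locus-A allele from either parental
    chromosome with probability 1/2 and keeps the locus-B allele of the
    same chromosome with probability ``1 - theta`` (switching with
    probability ``theta``).  Double heterozygotes therefore emit
    recombinant gametes with probability theta (coupling, AB/ab) or
    ``1 - theta`` (repulsion, Ab/aB); all other rows are theta-free.

    With ``exact=True`` (theta a :class:`~fractions.Fraction`) the table
    is built in exact rational arithmetic (object dtype).
    """
    validate_theta(theta)
    if exact:
        theta = Fraction(theta)
    zero, one = _zero_one(theta)
    half = one / 2
    H = np.empty((16, 4), dtype=object if exact else float)
    for row in range(16):
        u, v = _GAMETE_ALLELES[row // 4], _GAMETE_ALLELES[row % 4]
        for col, (x, y) in enumerate(_GAMETE_ALLELES):
            p = zero
            for own, other in ((u, v), (v, u)):
                if own[0] == x:
                    p = p + half * (
                        (one - theta) * (one if own[1] == y else zero)
                        + theta * (one if other[1] == y else zero)
                    )
            H[row, col] = p
    return H


def build_recombinant_weights(theta, *, exact: bool = False) -> np.ndarray:
    """Recombinant-gamete weights W: 16-vector, ``W[k] = Pr(Ab) + Pr(aB)``.

    Column sums 2+3 of the emission table: the probability that genotype
    k transmits a recombinant gamete.  Used to read the recombination
    fraction off a genotype-frequency vector.
    """
    H = build_emission_table(theta, exact=exact)
    return H[:, 1] + H[:, 2]


def vec_column_major(M: np.ndarray) -> np.ndarray:
    """Stack the columns of a 4x4 matrix into a 16-vector (column-major).

    Element ``(col - 1) * 4 + row`` of the result is ``M[row, col]``
    (1-based).  This is the vectorization used to turn a gamete-pair
    probability matrix into an offspring phased-genotype distribution.
    """
    M = np.asarray(M)
    if M.shape != (4, 4):
        raise ValueError(f"expected a 4x4 matrix, got shape {M.shape}")
    return M.flatten(order="F")


def linkage_ratio(theta) -> float:
    """Classical linkage ratio ``r = (1 - theta) / theta``.

    The historical parameter of the early two-locus literature: the
    weight of each parental gamete relative to each recombinant one.
    Undefined at theta = 0 (complete linkage).
    """
    validate_theta(theta)
    if theta == 0:
        raise ThetaDomainError("linkage ratio is infinite at theta = 0")
    return (1 - theta) / theta


def theta_from_linkage_ratio(r) -> float:
    """Inverse map ``theta = 1 / (1 + r)``; round-trips with linkage_ratio."""
    if r < 1:
        raise ValueError(f"linkage ratio must be >= 1, got {r!r}")
    return 1 / (1 + r)


@dataclass(frozen=True)
class ThetaTrajectory:
    """Recombination fractions indexed by number of transition applications.

    ``values[t]`` is the recombination fraction after ``t`` applications
    of the scheme's transition operator, with ``values[0] = theta0``.
    The mapping from t to F-generation labels is a documentation matter
    (see docs/methods.md); the trajectory itself is keyed by t only.
    """

    values: np.ndarray
    scheme: str
    theta0: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values))

    def __len__(self) -> int:
        return len(self.values)

    def __getitem__(self, t):
        return self.values[t]

    @property
    def final(self) -> float:
        return float(self.values[-1])
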