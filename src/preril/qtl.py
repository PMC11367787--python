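"""Generation-adjusted QTL-genotype priors for interval mapping.

Interval mapping weights genotype-specific likelihoods by the
conditional probability of the unobserved QTL genotype given the two
flanking marker genotypes.  The F2 formulas survive in later selfing
generations provided their three ingredients are generation-adjusted:

1. the flanking recombination fractions theta_AB and theta_AQ are
   mapped through the inbreeding chain (selfing or sib mating);
2. theta_QB is then recomputed from the adjusted pair via the
   no-interference composition (Q inside the A-B interval);
3. the QTL-genotype prior reflects the reduced heterozygosity,
   e.g. (0.4375, 0.125, 0.4375) at F4 instead of (0.25, 0.5, 0.25).

Genotype codes are 1/2/3 = parent-1 homozygote / heterozygote /
parent-2 homozygote throughout.  All intermediate thetas are carried at
full floating precision; rounding is presentation-only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import validate_theta
from .selfing import selfing_theta_sequence, marginal_heterozygosity
from .sib import sib_theta_sequence, sib_state_sequence, sib_marginal_state

__all__ = [
    "ThreeLocusThetas",
    "interval_theta",
    "genotype_priors_selfing",
    "marker_given_qtl",
    "qtl_posterior",
    "preril_qtl_inputs",
    "write_posterior_table",
]

#: Tolerance for the no-interference composition invariant.
_COMPOSITION_TOL = 1e-12


@dataclass(frozen=True)
class ThreeLocusThetas:
    """Pairwise recombination fractions for loci ordered A - Q - B.

    Construction asserts the no-interference composition
    ``theta_AB = theta_AQ + theta_QB - 2 * theta_AQ * theta_QB``.
    """

    theta_aq: float
    theta_qb: float
    theta_ab: float

    def __post_init__(self) -> None:
        for name in ("theta_aq", "theta_qb", "theta_ab"):
            validate_theta(getattr(self, name), name=name)
        composed = self.theta_aq + self.theta_qb - 2 * self.theta_aq * self.theta_qb
        if abs(composed - self.theta_ab) > _COMPOSITION_TOL:
            raise ValueError(
                "thetas violate the no-interference composition: "
                f"theta_aq + theta_qb - 2*theta_aq*theta_qb = {composed!r} "
                f"!= theta_ab = {self.theta_ab!r}"
            )


def interval_theta(theta_ab: float, theta_aq: float) -> float:
    """theta_QB from theta_AB and theta_AQ for loci ordered A - Q - B.

    ``(theta_AB - theta_AQ) / (1 - 2 * theta_AQ)``, the inverse of the
    no-interference composition.  Returned at full precision: e.g.
    (0.05, 0.01) gives 0.04/0.98 = 0.040816..., of which the customary
    printed form is 0.0408.
    """
    validate_theta(theta_ab, name="theta_ab")
    validate_theta(theta_aq, name="theta_aq")
    if theta_aq > theta_ab:
        raise ValueError(
            f"theta_aq ({theta_aq!r}) must not exceed theta_ab ({theta_ab!r}); "
            "Q lies inside the A-B interval"
        )
    return (theta_ab - theta_aq) / (1 - 2 * theta_aq)


def genotype_priors_selfing(t_generation: int) -> np.ndarray:
    """Single-locus genotype prior at selfing generation F_t.

    Heterozygote mass ``h = (1/2)**(t-1)``; the two homozygotes share
    the rest equally.  F2 gives (0.25, 0.5, 0.25); F4 gives
    (0.4375, 0.125, 0.4375); fully inbred lines approach (0.5, 0, 0.5).
    The integer-ratio form is ``2**(t-1) - 1 : 2 : 2**(t-1) - 1``.
    """
    if t_generation < 2:
        raise ValueError(f"generation label must be >= 2 (F2), got {t_generation}")
    h = 0.5 ** (t_generation - 1)
    return np.array([(1 - h) / 2, h, (1 - h) / 2])


def _priors_from_heterozygosity(h: float) -> np.ndarray:
    return np.array([(1 - h) / 2, h, (1 - h) / 2])


def marker_given_qtl(theta: float) -> np.ndarray:
    """3x3 matrix T with ``T[k, i] = Pr(marker = i | QTL = k)``.

    Rows index the QTL genotype 1/2/3, columns the marker genotype; each
    row sums to 1.  Identity at theta = 0; all rows (1/4, 1/2, 1/4) at
    theta = 0.5.
    """
    validate_theta(theta)
    t, u = theta, 1 - theta
    return np.array([
        [u * u, 2 * t * u, t * t],
        [t * u, u * u + t * t, t * u],
        [t * t, 2 * t * u, u * u],
    ])


def qtl_posterior(priors_q: np.ndarray, theta_aq: float, theta_qb: float) -> pd.DataFrame:
    """9x3 table of ``Pr(Q = k | A = i, B = j)`` for all marker pairs.

    Bayes combination ``Pr(Q=k) * Pr(A=i|Q=k) * Pr(B=j|Q=k)`` normalized
    over k, assuming conditional independence of the two flanking
    markers given the QTL genotype (no interference, loci ordered
    A - Q - B).  The same formula serves F2 and later generations when
    fed generation-adjusted thetas and priors.

    Returns a DataFrame with columns ``A, B, QQ, Qq, qq``; rows ordered
    (A=1,B=1), (A=1,B=2), ..., (A=3,B=3).
    """
    priors_q = np.asarray(priors_q, dtype=float)
    if priors_q.shape != (3,):
        raise ValueError(f"expected 3 QTL-genotype priors, got shape {priors_q.shape}")
    T_aq = marker_given_qtl(theta_aq)
    T_qb = marker_given_qtl(theta_qb)
    rows = []
    for i in range(3):
        for j in range(3):
            joint = priors_q * T_aq[:, i] * T_qb[:, j]
            denom = joint.sum()
            if denom <= 0:
                raise ZeroDivisionError(
                    f"zero marginal probability for marker pair (A={i + 1}, B={j + 1}); "
                    "degenerate theta/prior combination"
                )
            post = joint / denom
            rows.append((i + 1, j + 1, *post))
    return pd.DataFrame(rows, columns=["A", "B", "QQ", "Qq", "qq"])


def preril_qtl_inputs(theta_ab: float, theta_aq: float, scheme: str,
                      t_applications: int,
                      round_chain: int | None = None) -> tuple[ThreeLocusThetas, np.ndarray]:
    """Generation-adjusted thetas and priors for a partially inbred line.

    theta_AB and theta_AQ are each mapped through the chosen chain
    (``scheme`` 'self' or 'sib') for ``t_applications`` transitions;
    theta_QB is then derived from the *adjusted* pair via
    :func:`interval_theta` — not by adjusting theta_QB directly, which
    would disagree because the chain map does not commute with the
    interval composition.  The matching prior uses the heterozygosity
    of the population whose recombination fractions these are: under
    selfing ``(1/2)**(t-1)``, under sib mating the chain's marginal
    heterozygosity.  ``t_applications = 0`` returns the inputs
    unchanged with F2 priors.

    ``round_chain`` rounds the chain-adjusted theta_AB and theta_AQ to
    that many decimals before theta_QB is derived.  The default (None)
    carries full precision; ``round_chain=5`` reproduces the customary
    worked F4 presentation, whose posterior table was computed from the
    5-decimal chain values 0.08923 / 0.01905 rather than the unrounded
    ones (the two differ in the 5th decimal of the posteriors).
    """
    validate_theta(theta_ab, name="theta_ab")
    validate_theta(theta_aq, name="theta_aq")
    if t_applications < 0:
        raise ValueError(f"t_applications must be >= 0, got {t_applications}")
    if scheme not in ("self", "sib"):
        raise ValueError(f"scheme must be 'self' or 'sib', got {scheme!r}")

    if t_applications == 0:
        adj_ab, adj_aq = theta_ab, theta_aq
        priors = genotype_priors_selfing(2)
    else:
        seq = selfing_theta_sequence if scheme == "self" else sib_theta_sequence
        adj_ab = float(seq(theta_ab, t_applications).values[-1])
        adj_aq = float(seq(theta_aq, t_applications).values[-1])
        if round_chain is not None:
            adj_ab = round(adj_ab, round_chain)
            adj_aq = round(adj_aq, round_chain)
        g_label = max(t_applications, 2)
        if scheme == "self":
            priors = genotype_priors_selfing(g_label)
        else:
            # heterozygosity of the population paired with theta at
            # t applications is that of the state after t - 1 steps
            *_, (_, G) = sib_state_sequence(theta_ab, g_label - 1)
            h = float(marginal_heterozygosity(sib_marginal_state(G)))
            priors = _priors_from_heterozygosity(h)
    adj_qb = interval_theta(adj_ab, adj_aq)
    return ThreeLocusThetas(theta_aq=adj_aq, theta_qb=adj_qb, theta_ab=adj_ab), priors


def write_posterior_table(table: pd.DataFrame, path) -> None:
    """Write a posterior table as CSV with header ``A,B,QQ,Qq,qq``."""
    table.to_csv(path, index=False)
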