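"""Correlation-based recombination-fraction estimator and segregation checks.

For a marker pair with genotypes numerically coded 0/1/2, the Pearson
correlation r of the two columns estimates ``1 - 2*theta`` in an F2
population, giving

    theta_hat = (1 - r) / 2,   s_r = sqrt((1 - r^2) / (n - 2)),
    s_theta = s_r / 2,         95% CI: theta_hat +/- 1.96 * s_theta.

This is the moment estimator used in place of EM likelihood
maximization; it is exact at F2 and for fully inbred lines, with a
transient downward attenuation in intermediate generations (see
docs/methods.md).  Estimates above 0.5 (negative r) are reported as
computed, with a warning, rather than clamped.

Segregation checks: under single-seed descent the expected single-locus
genotype ratio at generation F_t is ``2**(t-1) - 1 : 2 : 2**(t-1) - 1``
(1:2:1 at F2, 3:2:3 at F3, 7:2:7 at F4), tested by a Pearson
goodness-of-fit chi-square with 2 degrees of freedom.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ThetaEstimate",
    "read_genotype_matrix",
    "estimate_theta",
    "estimate_all_pairs",
    "expected_segregation_ratio",
    "segregation_chi_square",
]

#: Fixed normal quantile of the 95% confidence interval.
Z_95 = 1.96


class CoSegregationError(ValueError):
    """Marker column with zero variance: the pair co-segregates."""


@dataclass(frozen=True)
class ThetaEstimate:
    """Point estimate, standard errors and 95% CI for one marker pair."""

    marker_i: str
    marker_j: str
    r: float
    theta_hat: float
    s_r: float
    s_theta: float
    ci_low: float
    ci_high: float
    n: int


def read_genotype_matrix(path) -> pd.DataFrame:
    """Read a genotype CSV (header = marker names, one row per individual).

    Validates that every entry is an integer code in {0, 1, 2}.
    """
    df = pd.read_csv(path)
    values = df.to_numpy()
    if not np.isin(values, (0, 1, 2)).all():
        bad = np.unique(values[~np.isin(values, (0, 1, 2))])
        raise ValueError(f"genotype codes must be 0/1/2; found {bad.tolist()}")
    return df.astype(np.int64)


def estimate_theta(geno: pd.DataFrame, marker_i: str, marker_j: str) -> ThetaEstimate:
    """Estimate the recombination fraction between two coded marker columns."""
    for m in (marker_i, marker_j):
        if m not in geno.columns:
            raise KeyError(f"marker {m!r} not present in genotype matrix")
    x = geno[marker_i].to_numpy(dtype=float)
    y = geno[marker_j].to_numpy(dtype=float)
    n = len(x)
    if n < 3:
        raise ValueError(f"need n >= 3 individuals for a standard error, got {n}")
    if x.std() == 0 or y.std() == 0:
        raise CoSegregationError(
            f"co-segregating pair ({marker_i}, {marker_j}): a marker has zero variance"
        )
    r = float(np.corrcoef(x, y)[0, 1])
    s_r = float(np.sqrt((1 - r ** 2) / (n - 2)))
    theta_hat = 0.5 * (1 - r)
    s_theta = 0.5 * s_r
    if theta_hat > 0.5:
        warnings.warn(
            f"estimated theta {theta_hat:.4f} exceeds 0.5 for pair "
            f"({marker_i}, {marker_j}); negative correlation reported unclamped",
            stacklevel=2,
        )
    return ThetaEstimate(
        marker_i=marker_i, marker_j=marker_j, r=r, theta_hat=theta_hat,
        s_r=s_r, s_theta=s_theta,
        ci_low=theta_hat - Z_95 * s_theta, ci_high=theta_hat + Z_95 * s_theta,
        n=n,
    )


def estimate_all_pairs(geno: pd.DataFrame, *, skip_cosegregating: bool = True) -> pd.DataFrame:
    """Estimates for every marker pair; co-segregating pairs are skipped.

    Columns: marker_i, marker_j, r, theta, se, ci_low, ci_high, n.
    """
    cols = list(geno.columns)
    rows = []
    for a in range(len(cols)):
        for b in range(a + 1, len(cols)):
            try:
                e = estimate_theta(geno, cols[a], cols[b])
            except CoSegregationError:
                if skip_cosegregating:
                    continue
                raise
            rows.append((e.marker_i, e.marker_j, e.r, e.theta_hat, e.s_theta,
                         e.ci_low, e.ci_high, e.n))
    return pd.DataFrame(rows, columns=["marker_i", "marker_j", "r", "theta",
                                       "se", "ci_low", "ci_high", "n"])


def expected_segregation_ratio(t_generation: int) -> tuple[int, int, int]:
    """Integer genotype ratio at selfing generation F_t.

    ``(2**(t-1) - 1, 2, 2**(t-1) - 1)``: 1:2:1 at F2, 3:2:3 at F3,
    7:2:7 at F4.  Consistent with a heterozygote prior of
    ``(1/2)**(t-1)``.
    """
    if t_generation < 2:
        raise ValueError(f"generation label must be >= 2 (F2), got {t_generation}")
    side = 2 ** (t_generation - 1) - 1
    return (side, 2, side)


def segregation_chi_square(counts, t_generation: int) -> tuple[float, int]:
    """Pearson goodness-of-fit of observed genotype counts to the F_t ratio.

    ``counts`` are the observed (homozygote-1, heterozygote,
    homozygote-2) counts.  Returns ``(statistic, dof)`` with dof = 2.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.shape != (3,):
        raise ValueError(f"expected 3 genotype counts, got shape {counts.shape}")
    if (counts < 0).any():
        raise ValueError("genotype counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("total genotype count is zero")
    ratio = np.asarray(expected_segregation_ratio(t_generation), dtype=float)
    expected = total * ratio / ratio.sum()
    statistic = float(stats.chisquare(counts, expected).statistic)
    return statistic, 2
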