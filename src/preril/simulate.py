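"""Gamete-level Monte Carlo simulator for selfed and sib-mated lines.

Haplotypes carry one binary allele per locus; the F1 founder is coded
11 (paternal haplotype) / 00 (maternal haplotype).  A gamete is drawn
in two steps: a fair Bernoulli picks the chromosome contributing the
first locus, and a Poisson crossover count with mean mu (the Haldane
map distance, ``mu = -ln(1 - 2*theta) / 2`` Morgans) decides whether
the second locus switches chromosome — it switches iff the count is
odd, which makes the single-meiosis recombination probability exactly
``(1 - exp(-2*mu)) / 2 = theta``.  A faster mode drawing the
recombination indicator directly as Bernoulli(theta) is provided; the
two are distributionally identical for two loci.

The recombinant fraction reported per generation is the proportion of
carried haplotypes equal to 10 or 01 *relative to the founders* —
the state-based quantity the chain weights W measure — not a count of
cumulative crossover events (a later-generation 11 or 00 haplotype may
descend from two recombinations and is deliberately not counted).

Generation indexing matches the chains: the fraction at index t tracks
``theta_sequence(theta, ...).values[t]``, with index 0 the F2
generation (haplotypes = F1 gametes).

This module doubles as the package's synthetic-data generator: the
defaults mirror the validation protocol (theta = 0.1, 20 replicates,
500 or 10,000 individuals/pairs, 10 selfing or 20 sib generations).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core import validate_theta

__all__ = [
    "SimulationConfig",
    "haldane_distance",
    "haldane_inverse",
    "simulate_gamete",
    "simulate_selfing_run",
    "simulate_sib_run",
    "simulate_selfing_population",
    "simulate_sib_population",
    "genotype_codes",
    "export_genotype_matrix",
    "write_run_metadata",
]


def haldane_distance(theta: float) -> float:
    """Haldane map distance ``mu = -ln(1 - 2*theta) / 2`` in Morgans.

    Assumes no crossover interference.  Diverges as theta -> 0.5.
    """
    validate_theta(theta)
    if theta == 0.5:
        raise ValueError("map distance is infinite at theta = 0.5")
    return -0.5 * np.log(1 - 2 * theta)


def haldane_inverse(mu: float) -> float:
    """Recombination fraction ``theta = (1 - exp(-2*mu)) / 2``."""
    if mu < 0:
        raise ValueError(f"map distance must be >= 0, got {mu}")
    return 0.5 * (1 - np.exp(-2 * mu))


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulation run.

    ``n`` counts individuals under selfing and mating pairs under sib
    mating.  ``mu`` is derived from theta via the Haldane map function
    and recorded for provenance.  ``crossover_model`` is 'poisson'
    (Poisson crossover-count parity) or 'bernoulli' (direct
    recombination flag); the two agree in distribution.
    """

    theta: float
    scheme: str  # 'self' | 'sib'
    n: int
    t_max: int
    replicates: int = 1
    seed: int = 0
    crossover_model: str = "poisson"
    mu: float = field(init=False)

    def __post_init__(self) -> None:
        validate_theta(self.theta)
        if self.scheme not in ("self", "sib"):
            raise ValueError(f"scheme must be 'self' or 'sib', got {self.scheme!r}")
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        if self.t_max < 0 or self.replicates < 1:
            raise ValueError("t_max must be >= 0 and replicates >= 1")
        if self.crossover_model not in ("poisson", "bernoulli"):
            raise ValueError(f"unknown crossover model {self.crossover_model!r}")
        object.__setattr__(self, "mu", haldane_distance(self.theta))


def simulate_gamete(parents: np.ndarray, mu: float, rng: np.random.Generator,
                    crossover_model: str = "poisson") -> np.ndarray:
    """One gamete per parent, vectorized over parents.

    ``parents`` has shape (n, 2, 2): individual x haplotype x locus.
    A fair Bernoulli draw picks the chromosome for the first locus; the
    second locus switches chromosome iff a Poisson(mu) crossover count
    is odd (or, in 'bernoulli' mode, with probability
    ``haldane_inverse(mu)`` directly).  Returns shape (n, 2).
    """
    parents = np.asarray(parents)
    n = parents.shape[0]
    first = rng.integers(0, 2, size=n)
    if crossover_model == "poisson":
        recomb = rng.poisson(mu, size=n) % 2 == 1
    elif crossover_model == "bernoulli":
        recomb = rng.random(n) < haldane_inverse(mu)
    else:
        raise ValueError(f"unknown crossover model {crossover_model!r}")
    second = np.where(recomb, 1 - first, first)
    idx = np.arange(n)
    gam = np.empty((n, 2), dtype=np.int8)
    gam[:, 0] = parents[idx, first, 0]
    gam[:, 1] = parents[idx, second, 1]
    return gam


def _founders(n: int) -> np.ndarray:
    """n F1 individuals, haplotypes 11 (paternal) / 00 (maternal)."""
    hap = np.zeros((n, 2, 2), dtype=np.int8)
    hap[:, 0, :] = 1
    return hap


def _recombinant_fraction(pop: np.ndarray) -> float:
    """Proportion of carried haplotypes equal to 10 or 01."""
    return float((pop[:, :, 0] != pop[:, :, 1]).mean())


def simulate_selfing_run(theta: float, n: int, t_max: int, rng: np.random.Generator,
                         crossover_model: str = "poisson",
                         keep_generations: tuple[int, ...] = ()):
    """Single-seed-descent run: n independent F1-founded selfed lines.

    Each generation every line is replaced by one selfed offspring (two
    gametes from the same parent).  Returns ``(fractions, kept)`` where
    ``fractions[t]`` (t = 0..t_max) is the carried recombinant-haplotype
    fraction at generation t (t = 0 is F2) and ``kept`` maps each
    requested generation index to its (n, 2, 2) haplotype array.
    """
    validate_theta(theta)
    mu = haldane_distance(theta)
    pop = _founders(n)
    fractions = np.empty(t_max + 1)
    kept: dict[int, np.ndarray] = {}
    for t in range(t_max + 1):
        g1 = simulate_gamete(pop, mu, rng, crossover_model)
        g2 = simulate_gamete(pop, mu, rng, crossover_model)
        pop = np.stack([g1, g2], axis=1)
        fractions[t] = _recombinant_fraction(pop)
        if t in keep_generations:
            kept[t] = pop.copy()
    return fractions, kept


def simulate_sib_run(theta: float, n_pairs: int, t_max: int, rng: np.random.Generator,
                     crossover_model: str = "poisson",
                     keep_generations: tuple[int, ...] = ()):
    """Brother-sister-mating run: n independent F1 x F1 founded pairs.

    Each next-generation pair is formed as two offspring of the current
    pair; the fraction at index t is computed over all 4 * n_pairs
    carried haplotypes (t = 0 is the F2 sib generation).  Returns
    ``(fractions, kept)`` with ``kept[t]`` of shape (2 * n_pairs, 2, 2).
    """
    validate_theta(theta)
    mu = haldane_distance(theta)
    sib1 = _founders(n_pairs)
    sib2 = _founders(n_pairs)
    fractions = np.empty(t_max + 1)
    kept: dict[int, np.ndarray] = {}
    for t in range(t_max + 1):
        offspring = []
        for _ in range(2):
            g1 = simulate_gamete(sib1, mu, rng, crossover_model)
            g2 = simulate_gamete(sib2, mu, rng, crossover_model)
            offspring.append(np.stack([g1, g2], axis=1))
        sib1, sib2 = offspring
        both = np.concatenate([sib1, sib2], axis=0)
        fractions[t] = _recombinant_fraction(both)
        if t in keep_generations:
            kept[t] = both.copy()
    return fractions, kept


def _replicate_frame(cfg: SimulationConfig, run) -> pd.DataFrame:
    """Per-replicate, per-generation summary with deterministic sub-seeds."""
    master = np.random.SeedSequence(cfg.seed)
    records = []
    n_hap = 2 * cfg.n if cfg.scheme == "self" else 4 * cfg.n
    for rep, child in enumerate(master.spawn(cfg.replicates), start=1):
        rng = np.random.default_rng(child)
        fractions, _ = run(cfg.theta, cfg.n, cfg.t_max, rng, cfg.crossover_model)
        for t, f in enumerate(fractions):
            records.append((rep, t, f, n_hap))
    return pd.DataFrame(records,
                        columns=["replicate", "generation", "recomb_fraction",
                                 "n_haplotypes"])


def simulate_selfing_population(cfg: SimulationConfig) -> pd.DataFrame:
    """Replicated single-seed-descent summary (long format).

    Columns: replicate, generation, recomb_fraction, n_haplotypes.
    Deterministic for a fixed config: replicate streams are spawned
    from the master seed.
    """
    if cfg.scheme != "self":
        raise ValueError(f"config scheme must be 'self', got {cfg.scheme!r}")
    return _replicate_frame(cfg, simulate_selfing_run)


def simulate_sib_population(cfg: SimulationConfig) -> pd.DataFrame:
    """Replicated brother-sister-mating summary (long format)."""
    if cfg.scheme != "sib":
        raise ValueError(f"config scheme must be 'sib', got {cfg.scheme!r}")
    return _replicate_frame(cfg, simulate_sib_run)


def genotype_codes(pop: np.ndarray) -> np.ndarray:
    """0/1/2 genotype codes (count of founder-paternal alleles) per locus.

    ``pop`` has shape (n, 2, m): individual x haplotype x locus.
    """
    pop = np.asarray(pop)
    return pop.sum(axis=1, dtype=np.int64)


def export_genotype_matrix(pop: np.ndarray, path,
                           marker_names: tuple[str, ...] | None = None) -> pd.DataFrame:
    """Write a population's 0/1/2 genotype matrix as CSV; returns the frame."""
    codes = genotype_codes(pop)
    if marker_names is None:
        marker_names = tuple(f"M{i + 1}" for i in range(codes.shape[1]))
    df = pd.DataFrame(codes, columns=list(marker_names))
    try:
        df.to_csv(path, index=False)
    except OSError as exc:
        raise OSError(f"failed to write genotype matrix to {path}: {exc}") from exc
    return df


def write_run_metadata(cfg: SimulationConfig, path, **extra) -> None:
    """JSON sidecar recording every run parameter (theta, mu, seed, ...)."""
    meta = asdict(cfg)
    meta.update(extra)
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
        fh.write("\n")
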