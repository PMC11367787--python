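# Methods

## Problem and model

Recombinant inbred lines (RILs) are bred from an F1 hybrid by repeated
inbreeding — self-fertilization in plants, brother–sister mating in
laboratory animals — until essentially homozygous. At intermediate
generations (pre-recombinant inbred lines, PRERILs) the observable
recombination fraction between two loci is no longer the meiotic
recombination fraction θ of the F2: every extra round of meiosis gives
linked loci another chance to recombine, so the carried fraction of
recombinant haplotypes climbs toward a scheme-specific limit. Using an
F2-calibrated analysis (QTL-genotype priors, map distances) on a PRERIL
population misstates both the effective recombination fraction and the
genotype frequencies; this package computes the generation-correct
quantities.

The machinery is a Markov chain over *fully phased* two-locus
genotypes. With gametes ordered (AB, Ab, aB, ab) there are 16 phased
genotypes (ordered gamete pairs); the 16×4 emission table H gives the
gamete-transmission probabilities per genotype, assuming equal male and
female recombination fractions (so the results apply to diploid plants
and animals, not to taxa with sex-limited recombination) and no
crossover interference. All transition matrices derive from H:

- **Selfing** — 16 states; column k of P is vec(hₖᵀhₖ) (column-major
  vec), the distribution of one selfed offspring of genotype k. With
  G₁ = ½(e₄ + e₁₃) (the two phase orderings of the F1 double
  heterozygote), the recombination fraction after t transitions is
  θ⁽ᵗ⁾ = WᵀPᵗG₁, where W[k] is the probability genotype k transmits a
  recombinant gamete. The limit is ρ_self = 2θ/(1+2θ).
- **Brother–sister mating** — 256 ordered sib-pair states,
  k = (i−1)·16 + j; column k is u⊗u with u = vec(hⱼᵀhᵢ), since sibs
  are conditionally i.i.d. given their parents. Weights
  V[k(i,j)] = (W[i]+W[j])/2; the limit is ρ_sib = 4θ/(1+6θ). The
  8-way-founder analogue 7θ/(1+6θ) is provided as a closed form only.
- **Random mating (advanced intercross lines)** — the four gamete
  frequencies suffice; G_{t+1} = (G_t⊗G_t)H is quadratic in G. The
  closed form θ_t = ½[1−(1−2θ)(1−θ)^(t−2)] (t = 2 at F2) is matched by
  the iteration to machine precision and tends to ½.

The chains are kept at full state resolution on purpose. The classical
treatments compressed the state space (10 unphased, then 5 composite
classes) to make hand derivation feasible; generating the 16- and
256-state matrices by code removes the need and eliminates manual
pooling errors. Correctness is instead guaranteed by brute-force
enumeration oracles in the test suite: every selfing column is checked
against exhaustive enumeration of the 4×4 gamete pairs, and sampled
sib columns against all 4⁴ gamete quadruples.

## Generation indexing

The API keys every trajectory by t = number of transition
applications, with values[0] = θ. The literature's F-generation labels
are internally inconsistent at the one-to-two-generation level: the
recurrence notation suggests θ at F_{t+1} is WᵀPᵗ⁻¹G₁, yet the worked
generation-adjusted value for an F4 selfing population
(θ = 0.05 → 0.08923) equals WᵀP⁴G₁, while the F4 heterozygosity 0.125
is that of the state P³G₁. Rather than guess a reconciliation, the
package reproduces the worked surface: `t_applications = g` yields the
θ adjustment conventionally paired with generation F_g, and the
matching prior uses heterozygosity (½)^(g−1) (selfing) or the sib
chain's marginal heterozygosity after g−1 steps. The analogous offset
in the random-mating literature (a reported 0.4653748 at t = 50 versus
the closed form's 0.4616) is resolved the same way: the closed form
with exponent t−2 is treated as normative.

## QTL-genotype priors and posteriors

For loci ordered A–Q–B, Pr(Q = k | A = i, B = j) is the Bayes
combination of the single-locus prior Pr(Q = k) with the two 3×3
conditional matrices Pr(marker | Q) built from θ_AQ and θ_QB, assuming
conditional independence of the flanking markers given Q (no
interference). For a PRERIL the procedure is: map θ_AB and θ_AQ
through the chain, derive θ_QB from the *adjusted* pair via
θ_QB = (θ_AB−θ_AQ)/(1−2θ_AQ) — adjusting θ_QB directly would disagree,
because the chain map does not commute with the interval composition —
and replace the prior by the generation-correct one. Whether the
F2-form conditional matrices applied with generation-adjusted θ are
exact for the partially inbred two-locus distribution is an open
modeling question; the package implements the established procedure
as stated and records the caveat here.

Numerical policy: all intermediate θ are carried at full precision;
rounding is presentation-only. The reference F2 posterior table is
reproducible only with the unrounded θ_QB = 0.04/0.98 (the customary
worked equations, which round to 0.0408, differ in the 4th decimal).
The reference F4 table, conversely, was computed from 5-decimal chain
values; `preril_qtl_inputs(..., round_chain=5)` reproduces that
presentation exactly, while the default keeps full precision (the two
differ in the 5th decimal of the posteriors).

## Monte Carlo simulator (synthetic-data generator)

The simulator works at the gamete level with founder-coded haplotypes
(F1 = 11/00). Per gamete: a fair Bernoulli picks the chromosome for
the first locus; a Poisson(μ) crossover count with μ = −½ln(1−2θ)
(Haldane map function, no interference) switches the second locus iff
odd. One Bernoulli plus one Poisson draw per gamete reproduces the
single-meiosis recombination probability exactly via the Poisson
parity identity ½(1−e^(−2μ)) = θ; a direct Bernoulli(θ) recombination
flag is available as a distributionally identical fast path. The
reported per-generation statistic is the *state-based* recombinant
fraction — the proportion of carried haplotypes equal to 10 or 01
relative to the founders — matching what the chain weights W measure;
double recombinants that restore 11/00 are deliberately uncounted.
Index t = 0 is the F2 generation, so the simulated trajectory aligns
with `*_theta_sequence(...).values` elementwise.

Default study conditions mirror the validation protocol the recurrences
were originally checked against: θ ∈ {0.05, 0.1, 0.2}, 20 replicates,
500 or 10,000 individuals (selfing) or mating pairs (sib), 10 selfing
or 20 sib generations. The default acceptance-level run uses n = 2000
with 20 replicates — large enough that 3·SE per generation is a
sub-percent band, small enough that the whole suite runs in seconds.
What the generator does *not* emulate: multiple chromosomes, crossover
interference, segregation distortion, genotyping error or missing
data. Passing tests therefore demonstrate correctness of the
recurrences under the model's own assumptions, not robustness to the
violations of those assumptions seen in real populations.

Seed policy: one master seed per run; replicate streams are spawned
deterministically (`numpy` SeedSequence), and all parameters including
μ and the seed are written to a JSON sidecar.

## Correlation estimator and its known bias

The recombination-fraction estimator is the moment estimator on
numerically coded genotypes (0/1/2): θ̂ = ½(1−r) with
s_r = √((1−r²)/(n−2)), s_θ = ½s_r, and a fixed-quantile 95% CI
θ̂ ± 1.96·s_θ. It is used instead of EM likelihood maximization,
matching the validation practice for dense PRERIL marker data.
Negative correlations (θ̂ > 0.5) are reported as computed, with a
warning; no clamping. Co-segregating pairs (zero marker variance)
raise an explicit error.

θ̂ is exactly calibrated at F2 (where corr = 1−2θ) and again at full
inbreeding (haplotype pairs identical, corr = 1−2ρ), but is *biased
downward in intermediate generations*: during inbreeding an
individual's two haplotypes are positively correlated, which inflates
the marker variance relative to the within-haplotype covariance before
the cross-haplotype covariance has fully caught up. Exact computation
from the 16-state chain at θ = 0.1 gives ½(1−r) = 0.1267, 0.1434,
0.1535, 0.1594 at F3–F6 against true carried fractions 0.1400, 0.1560,
0.1624, 0.1650. The attenuation (up to 0.013) is harmless when CI
half-widths are wide (n ≈ 200) but dominates them at n = 10,000, where
nominal-95% CI coverage of the chain value collapses for one to four
transitions (measured pooled coverage 0.376 across t = 0..4 at 50
replicates, versus ~0.95 at t = 0 alone). The acceptance test asserts
the coverage requirement as stated and fails by design, documenting
the estimator's limitation rather than hiding it; an unbiased
alternative would estimate the correlation on haplotypes where phase
is known, or correct the attenuation using the chain's predicted
haplotype-pair correlation.

Segregation checks use the single-seed-descent genotype ratio
(2^(t−1)−1 : 2 : 2^(t−1)−1) at F_t (1:2:1, 3:2:3, 7:2:7, …) in a
Pearson goodness-of-fit chi-square with 2 degrees of freedom.

## Numerical choices

- Trajectories use iterated matrix–vector products, never explicit
  matrix powers; the 256×256 dense matrix (~0.5 MB) needs no sparsity.
- The random-mating step renormalizes its output: the quadratic map
  squares any rounding deviation of the input's sum each generation,
  so an O(1e−16) error would compound to O(1e−3) within 50
  generations; the true sum is identically 1, so renormalization is
  exact.
- Convergence detection stops when |Δθ| < 1e−10 between successive
  generations (cap 500). Because the sib chain contracts more slowly,
  the converged value then sits within a few×1e−10 of the algebraic
  limit; callers needing agreement at 1e−10 pass `tol=1e-12`.
- An exact-rational mode (θ as `fractions.Fraction`, object-dtype
  arrays) backs the invariant tests — e.g. heterozygosity is exactly
  (½)^t after t transitions — removing floating-point doubt from
  oracle comparisons.
- The sib transition fixes which parent contributes each offspring's
  first-listed gamete (u = vec(hⱼᵀhᵢ)); the initial state and weights
  are parent-symmetric, so trajectories are invariant to swapping the
  convention (asserted by a test).

## Limitations

Two loci per chain; two-way crosses only (no MAGIC/Collaborative
Cross multi-parent chains); equal recombination in the two sexes; no
interference or segregation distortion; the estimator bias described
above. The QTL module produces priors/posteriors for an interval scan;
it does not implement the phenotype-likelihood scan itself.
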