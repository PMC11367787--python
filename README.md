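# preril

Two-locus recombination-fraction recurrences for **pre-recombinant
inbred lines** (PRERILs): populations part-way through the inbreeding
that turns an F1 hybrid into recombinant inbred lines (RILs).

Every extra round of meiosis gives linked loci another chance to
recombine, so the recombination fraction observable in generation t is
not the F2 meiotic fraction θ but a larger value that climbs toward a
scheme-specific limit — 2θ/(1+2θ) under self-fertilization, 4θ/(1+6θ)
under brother–sister mating, ½ under random mating (advanced intercross
lines). QTL mapping or map construction that uses F2-calibrated
quantities on a PRERIL population is therefore miscalibrated. This
package computes the generation-correct quantities for geneticists
working with partially inbred plant or animal populations.

## What it computes

- **Selfing chain** — a 16-state Markov chain over fully phased
  two-locus genotypes. Column k of the transition matrix is
  vec(hₖᵀhₖ), built from the 16×4 gamete-emission table H;
  θ⁽ᵗ⁾ = WᵀPᵗG₁ with W the recombinant-gamete weights and G₁ the F1
  state.
- **Sib-mating chain** — the 256-state chain over ordered sib pairs,
  column k(i,j) = vec(hⱼᵀhᵢ)⊗vec(hⱼᵀhᵢ), weights
  V[k(i,j)] = (W[i]+W[j])/2.
- **Random mating (AIL)** — the gametic recurrence
  G_{t+1} = (G_t⊗G_t)H and the closed form
  θ_t = ½[1−(1−2θ)(1−θ)^(t−2)].
- **QTL priors/posteriors** — Pr(Q = k | A = i, B = j) for flanking
  markers, with the recombination fractions and genotype priors
  adjusted to the population's generation and mating scheme.
- **Monte Carlo simulator** — gamete-level simulation of single-seed
  descent and sib-mated designs (Haldane map function, Poisson
  crossover parity); doubles as the synthetic-data generator.
- **Estimator** — the correlation-based estimator θ̂ = ½(1−r) on 0/1/2
  genotype codes with standard errors and 95% CIs, plus
  generation-specific segregation chi-square checks (1:2:1, 3:2:3,
  7:2:7, …).

See `docs/methods.md` for the model, its assumptions, and known
limitations (including a documented transient bias of the correlation
estimator in partially inbred generations).

## Worked example

An F4 selfing population descended from an F1 with meiotic θ = 0.05
between flanking markers A and B and θ = 0.01 between A and a putative
QTL Q:

```python
>>> import preril as pr
>>> tr = pr.selfing_theta_sequence(0.05, 10)
>>> [round(float(v), 5) for v in tr.values]
[0.05, 0.0725, 0.08263, 0.08718, 0.08923, 0.09015, 0.09057, 0.09076,
 0.09084, 0.09088, 0.0909]
>>> pr.selfing_asymptote(0.05)
0.09090909090909091
```

The effective A–B fraction has grown from 0.05 to 0.08923 by four
transitions and is within 2e-3 of the RIL limit 1/11 by generation 10.
The generation-adjusted QTL table:

```python
>>> thetas, priors = pr.preril_qtl_inputs(0.05, 0.01, "self", 4)
>>> (round(thetas.theta_ab, 5), round(thetas.theta_aq, 5), round(thetas.theta_qb, 5))
(0.08923, 0.01905, 0.07296)
>>> priors
array([0.4375, 0.125 , 0.4375])
>>> pr.qtl_posterior(priors, thetas.theta_aq, thetas.theta_qb).round(6)
   A  B        QQ        Qq        qq
0  1  1  0.999561  0.000437  0.000002
1  1  2  0.965386  0.034249  0.000364
...
```

Row (A=1, B=2) says: an individual homozygous for the parent-1 allele
at A and heterozygous at B carries QQ with probability 0.9654 — versus
0.8078 in an F2 — because three extra selfing generations have pushed
the priors toward homozygosity (0.4375, 0.125, 0.4375). Using F2
posteriors here would overweight heterozygous QTL genotypes.

The same computations are available from the shell:

```sh
preril trajectory --scheme self --theta 0.05 --generations 10 --out traj.csv
preril qtl --theta-ab 0.05 --theta-aq 0.01 --scheme self --generation 4 --out qtl.csv
preril simulate --scheme sib --theta 0.1 --n 500 --generations 20 --reps 20 --seed 1 --out sim/
preril estimate --genotypes geno.csv --pair M1,M2
```

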