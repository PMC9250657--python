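# hexahwe

Hardy-Weinberg analysis for autohexaploid populations: the gamete
transmission model with double reduction, the random-mating recursion to
asymptotic equilibrium, EM estimators, chi-square and likelihood-ratio
tests (including variants for dosage-ambiguous markers), and a seeded
Monte-Carlo study engine.

## The problem

Diploid populations reach Hardy-Weinberg equilibrium (HWE) after a single
round of random mating, and the HWE test is a standard tool for studying
natural variation and flagging genotyping errors.  Hexaploids (six
homologous chromosome copies — chrysanthemum, sweetpotato, kiwifruit)
behave differently: a biallelic locus has seven genotypes (dosage
*d* ∈ {0,…,6} of allele A) and four triploid gametes, meiosis is
polysomic with *double reduction* (two sister chromatids entering the
same gamete, at rate α ≤ 3/11), and genotype frequencies only *approach*
an asymptotic HWE (aHWE) over roughly 8–9 generations of random mating.

`hexahwe` is for population geneticists and breeders who have per-locus
genotype (dosage) counts from hexaploid samples and want to test aHWE
and double reduction, estimate gamete frequencies and α, or simulate the
behaviour of these procedures.

## The model in brief

Meiosis is a 7×4 transmission matrix **T**(α): row *d* is the gamete
dosage distribution of a parent with dosage *d*, each entry linear in α;
rows sum to 1 and conserve half the parental dosage.  Random mating maps
a genotype distribution **P** to offspring

> **M** = **P**·**T**(α)  (pooled gametes),  **P**′ = **M** ∗ **M**  (self-convolution),

which conserves allele frequency and converges to aHWE (binomial(6, p)
when α = 0).  On this map the package builds:

* the **recursive aHWE test** — χ² of observed frequencies against the
  distribution after 8 rounds of the recursion (df 6);
* the **gamete-based aHWE test** — χ² against the aHWE distribution
  implied by EM-fitted gamete frequencies (df 5);
* the **double-reduction test** — goodness-of-fit of the fitted α = 0
  transmission model (df 5), plus a likelihood-ratio variant for
  collapsed markers;
* the **parental-aHWE LR test** — free parental frequencies vs.
  equilibrium (gamete-product) parental frequencies (df 1);
* **collapsed-marker tests** for platforms that cannot separate the five
  heterozygote classes (allele-based χ² against (p⁶, 1−p⁶−q⁶, q⁶), and a
  recursive variant with uniform heterozygote expansion; df 2).

See `docs/methods.md` for assumptions, estimator details, numerical
conventions and known limitations — including which published quantities
this implementation deliberately does not reproduce, and why.

## Worked example

A sample of N = 120 hexaploid individuals with genotype counts
(29, 21, 17, 10, 10, 10, 23) for (6A, 5A1a, …, 6a):

```python
>>> import hexahwe as hx
>>> counts = hx.GenotypeCounts([29, 21, 17, 10, 10, 10, 23])
>>> res = hx.recursive_ahwe_test(counts, alpha=0.0, generations=8)
>>> round(res.statistic, 3), res.df
(6.661, 6)
>>> res = hx.gamete_based_ahwe_test(counts, seed=1)
>>> round(res.statistic, 3)
6.68
>>> em = hx.em_gamete_frequencies(counts)
>>> [round(g, 3) for g in em.gametes.freq]   # AAA, AAa, Aaa, aaa
[0.422, 0.16, 0.112, 0.307]
>>> lr = hx.parental_ahwe_lr_test(counts, seed=1)
>>> round(lr.statistic, 2), round(lr.p_value, 5)
(16.39, 5e-05)
```

The recursive statistic (6.661, frequency scale) measures how far the
observed frequencies sit from the aHWE state they would reach after 8
generations of random mating; the gamete-based statistic (6.68) asks the
same question of the EM-fitted equilibrium model, and the two agree.  The
LR test rejects parental equilibrium (p ≈ 5e-5): this sample is too
homozygote-rich to be one round of mating away from a gamete-product
population.

For a dosage-ambiguous marker with class frequencies
(0.4000, 0.4875, 0.1125) for (6A, any-heterozygote, 6a):

```python
>>> snp = hx.CollapsedCounts([0.4000, 0.4875, 0.1125])
>>> res = hx.allele_based_ahwe_test_collapsed(snp)
>>> round(res.statistic, 2), round(res.p_value, 4)
(7.7, 0.0213)
>>> [round(e, 4) for e in res.expected]
[0.0712, 0.9268, 0.002]
```

The allele frequency p = 0.4 + 0.4875/2 = 0.64375 gives expected
homozygote frequencies p⁶ = 0.0712 and q⁶ = 0.0020; the marker deviates
from aHWE at the 5% level.

Command-line equivalents:

```sh
hexahwe fixtures --outdir data
hexahwe test --input data/worked_example.tsv --mode recursive
hexahwe test --input data/chrysanthemum_ahwe.tsv --format three_class --mode allele
hexahwe trajectory --init 0.1,0.05,0.2,0.25,0.13,0.1,0.17 --alpha 0 --generations 12
hexahwe simulate --config study.yaml --out study.tsv
```

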