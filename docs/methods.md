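# Methods

## The model

A biallelic locus in an autohexaploid has seven genotypes, indexed by the
dosage `d` of allele A (6A, 5A1a, ..., 6a), and four triploid gametes
(AAA, AAa, Aaa, aaa).  Meiosis under polysomic inheritance is described by
a 7x4 transmission matrix `T(α)` whose row `d` gives the gamete
distribution produced by a parent of dosage `d`.  Every entry is linear in
the double-reduction rate `α` (the probability that two sister chromatids
of one chromosome end up in the same gamete); under random chromatid
segregation `α` is bounded by 3/11 in hexaploids, and the package treats
the bound as the closed interval `[0, 3/11]` so that boundary values are
evaluable and estimates can be clipped to it.  Two exact identities hold
for every row and every `α`: the entries sum to 1, and the mean gamete
dosage equals half the parental dosage (allele frequencies are conserved
by meiosis).

Random mating (panmixia) maps a parental genotype distribution `P` to the
offspring distribution in two steps: the *pooled gamete distribution*
`M = P·T(α)`, and the self-convolution `P' = M * M` (offspring dosage is
the sum of two independent gamete dosages).  This convolution is
algebraically identical to summing the 28 parental mating types with
their per-type offspring kernels; the package implements the convolution
(exact by construction, immune to transcription errors in printed tables)
and the test suite checks it against the explicit mating-type summation
and against published per-mating-type polynomials.

Iterating the map drives any starting distribution toward asymptotic
Hardy-Weinberg equilibrium (aHWE).  Hexaploids never reach exact
equilibrium in one round; with the reference starting distribution
(0.1, 0.05, 0.2, 0.25, 0.13, 0.1, 0.17) the per-class change falls below
1e-3 by generations 8-9 at every admissible `α`.  Without double
reduction the stationary distribution is binomial(6, p) over dosage,
where p is the (conserved) allele frequency; with `α > 0` the stationary
distribution shifts toward homozygotes.

## Estimators

All estimators are EM algorithms for multinomial mixtures; each M-step is
exact, so the observed-data log-likelihood is non-decreasing within a run
(asserted at every iteration and reported on the result object).
Initialization is one moment-based start (gamete frequencies binomial in
the observed mean dosage; parental start = smoothed observed offspring
frequencies) plus seeded random simplex draws; the best final likelihood
wins.  Convergence is declared when the absolute log-likelihood change
falls below `tol` (default 1e-9, `max_iter` 10 000).  Inside Monte-Carlo
studies the per-replicate fits use one start and `tol` 1e-7 to keep
study runtimes in seconds-to-minutes; the acceptance script notes the
replicate sizes used.

* **Gamete frequencies under equilibrium.**  Class probabilities are the
  self-convolution `Q = G * G`; the heterozygote classes 4A2a, 3A3a and
  2A4a are two-component mixtures over gamete-pair origins.  The E-step
  usage of gamete `g` from class `j` is `2 N_j G_g G_{j-g} / Q_j`, and
  the M-step divides by the 2N gamete slots.
* **Parental genotype frequencies at fixed α.**  Offspring probabilities
  are one round of random mating from the parental distribution.  The
  posterior factorizes through the pooled gamete distribution: gametes
  are attributed to classes as above, then to parental genotypes with
  weights `P_d T(α)_{d,g}`.  Because the offspring distribution depends
  on the parent only through the pooled `M`, the parental solution is
  identified only up to the fiber of the pooling map; the fitted
  offspring distribution is the meaningful output.
* **Joint gamete frequencies and α.**  The parental population is
  constrained to equilibrium (genotypes are products of parental gamete
  frequencies); each parent decomposes further into its two founding
  gametes, giving 4N gamete slots per sample.  α has no closed-form
  update and is refreshed by bounded Brent maximization of the actual
  log-likelihood after blocks of 25 EM sweeps (an ECM scheme, still
  monotone).  Boundary estimates (α near 0 or 3/11) are flagged.
* **Collapsed markers.**  When platforms cannot separate the five
  heterozygote classes, the allele frequency is estimated either by the
  midpoint-dosage rule `p = f(6A) + f(het)/2` (default: it reproduces
  published expected frequencies for such markers) or by the trinomial
  MLE against `(p^6, 1-p^6-q^6, q^6)`.  The midpoint rule implicitly
  assigns the pooled heterozygotes dosage 3 and is therefore biased
  toward 0.5 for unbalanced markers; the MLE mode is exact under the
  allele model.

## Tests

* **Recursive aHWE test** (seven classes): the observed frequencies seed
  the recursion; the distribution after `generations` rounds (default 8)
  is the expected aHWE distribution; chi-square with df 6.
* **Gamete-based aHWE test**: expected aHWE frequencies are obtained by
  projecting the EM-fitted product distribution through the same
  8-round horizon (the product of a non-binomial gamete pool is not yet
  stationary, so the projection is what makes the expectation an
  equilibrium); `generations=0` compares against the raw product.  df
  defaults to 5 (between 7-1-1 and 7-1; configurable).
* **Double-reduction test** (seven classes): goodness-of-fit of the
  fitted `α = 0` transmission model, df 5 by default.
* **Parental-aHWE LR test**: free parental frequencies (+α) against
  equilibrium-constrained parental frequencies (+α), referred to
  chi-square with 1 df and floored at zero.
* **Collapsed variants**: allele-based chi-square against
  `(p^6, 1-p^6-q^6, q^6)` (df 2); recursive test with the heterozygote
  mass expanded uniformly over dosages 1-5 before iterating (df 2; the
  uniform expansion conserves the midpoint allele frequency, so the
  binomial population is exactly stationary only for balanced markers);
  and an LR test of `α = 0` against free `α` with a binomial(6, p)
  parent (df 1).  Frequency-only inputs carry no sample size; a
  `pseudo_n` restores count weighting when the family size is known.

**Scale convention.**  Chi-square sums are computed on frequencies by
default and multiplied by N under `scale="counts"`.  Published hexaploid
worked-example and collapsed-marker statistics are reproduced on the
frequency scale, so that is the default for single-locus reporting; the
count scale is the one with the usual chi-square calibration and is used
inside the Monte-Carlo studies, where rejection rates matter.  Zero
expected frequencies follow the 0/∞ convention (zero observed
contributes nothing; positive observed gives an infinite statistic);
tiny but positive expected frequencies are deliberately not floored or
merged, since collapsed-marker statistics in the hundreds depend on
them.

## Monte-Carlo engine

One study cell is a (α, N) pair.  The parental truth is either an
arbitrary seven-class distribution or the product distribution of given
gamete frequencies; exactly one round of random mating separates the
parental truth from the multinomial offspring sample (parents are used
as exact frequencies by default; `sample_parents` draws a finite
parental generation first).  A master `SeedSequence` spawns one
substream per cell and per replicate, so identical configurations are
bit-identical and any cell can be reproduced in isolation.  Replicate
counts default to 1000 and are configurable; EM failures within
replicates are counted and reported, never fatal.

## Reproducibility of the published numbers

The deterministic seven-class and collapsed-marker statistics reproduce
published values on the frequency scale: the recursive worked-example
statistic is 6.66 at the 8-round horizon (6.602 at 7 rounds — published
generation indexing counts the observed sample as generation 1), the
gamete-based statistic is 6.68 (6.649 at 7 rounds), and the SNP-4
collapsed statistics are 7.635 (recursive) and 7.696 (allele-based)
with expected class-6A frequencies 0.0714 and 0.0712.

Two published quantities are *not* reproducible from converged
maximum-likelihood fits, and this package does not attempt to imitate
them:

* The worked-example double-reduction statistic (published 5.922).  The
  likelihood of the `α = 0` parental model depends on the parent only
  through the pooled gamete distribution, and the best pooled
  distribution fits the worked example almost perfectly (statistic
  0.301 on the frequency scale).  The global optimum was verified from
  200 random EM starts and by an over-parameterized mating-type mixture
  fit.
* The simulated power of the double-reduction and parental-aHWE tests.
  Offspring of one round of random mating always have distribution
  `M * M`; every transmission row at `α > 0` lies in the convex hull of
  the `α = 0` rows, so any pooled gamete distribution reachable with
  double reduction is also reachable without it (with a free parent),
  and numerically the equilibrium-parent family covers the study truths
  as well (likelihood gaps < 3e-5 per observation at N = 100 000).
  Neither double reduction nor parental disequilibrium is therefore
  asymptotically identifiable from a single offspring generation under
  these designs: converged fits give rejection rates near or below the
  nominal level in all cells (observed ~0.003-0.03), rather than the
  published powers (0.667-0.855 and ~0.70-0.90).  What *is*
  reproducible is the calibration side: false-positive rates stay below
  0.08, and the joint EM's mean double-reduction estimate at truth
  α = 1/7, N = 100 is ~0.13, matching the published 0.127 ± 0.139 —
  the constrained estimator tracks α even though hypothesis tests built
  on the same one-generation design carry no power.

## Known limitations

* Single biallelic locus, ploidy fixed at six; no selection, drift,
  mutation, migration, selfing or sex-specific transmission.
* The recursion horizon (8 rounds) and the stability threshold (1e-3
  per-class change) are conventions; no published convergence tolerance
  exists for the "8-9 generations" statement.
* Frequency-scale chi-squares do not have the usual chi-square
  calibration; they are reported because the field's published marker
  tables use them.  p-values on frequency-only inputs should be read as
  descriptive unless a pseudo sample size is supplied.
* The synthetic studies emulate multinomial sampling from exact model
  distributions; real marker data add dosage-calling error, which is
  out of scope here.
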