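"""Gamete transmission and the random-mating recursion for autohexaploids.

An autohexaploid carries six homologous chromosome copies, so a biallelic
locus (alleles ``A``/``a``) has seven genotypes distinguished by A-dosage
(6A, 5A1a, ..., 6a) and four triploid gametes (AAA, AAa, Aaa, aaa).
Meiosis follows polysomic inheritance with double reduction: with rate
``alpha`` two sister chromatids of one chromosome migrate into the same
gamete.  Under random chromatid segregation ``alpha`` is bounded by 3/11
in hexaploids.

All genotype arrays in this package are ordered by *descending* A-dosage
(6A first, 6a last); gamete arrays likewise (AAA first, aaa last).

The central objects are the per-genotype gamete distributions (linear
polynomials in ``alpha``) and the one-generation random-mating map: the
offspring genotype distribution is the self-convolution of the pooled
gamete distribution.  Iterating that map drives any starting population
toward asymptotic Hardy-Weinberg equilibrium (aHWE), which hexaploids
approach (but never exactly reach) after roughly 8-9 generations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ALPHA_MAX",
    "GENOTYPE_LABELS",
    "GAMETE_LABELS",
    "GENOTYPE_DOSAGES",
    "GAMETE_DOSAGES",
    "GenotypeDistribution",
    "GameteDistribution",
    "Trajectory",
    "EquilibriumResult",
    "validate_alpha",
    "transmission_matrix",
    "gamete_distribution",
    "pool_gametes",
    "next_generation",
    "iterate_generations",
    "equilibrium_distribution",
    "zygote_freqs_from_gametes",
    "reduced_zygote_freqs_alpha0",
    "binomial_genotype_distribution",
]

#: Upper bound of the double-reduction rate in hexaploids under random
#: chromatid segregation.  Treated as a closed interval so the boundary
#: is evaluable.
ALPHA_MAX = 3.0 / 11.0

GENOTYPE_LABELS = ("6A", "5A1a", "4A2a", "3A3a", "2A4a", "1A5a", "6a")
GAMETE_LABELS = ("AAA", "AAa", "Aaa", "aaa")

#: A-dosage carried by each genotype class, in array order.
GENOTYPE_DOSAGES = np.arange(6, -1, -1)
#: A-dosage carried by each gamete class, in array order.
GAMETE_DOSAGES = np.arange(3, -1, -1)

# Gamete distributions per parental genotype, as T(alpha) = _T0 + alpha*_T1.
# Rows: parental dosage 6..0 (descending); columns: gamete dosage 3..0.
_T0 = np.array(
    [
        [1.0, 0.0, 0.0, 0.0],
        [1 / 2, 1 / 2, 0.0, 0.0],
        [1 / 5, 3 / 5, 1 / 5, 0.0],
        [1 / 20, 9 / 20, 9 / 20, 1 / 20],
        [0.0, 1 / 5, 3 / 5, 1 / 5],
        [0.0, 0.0, 1 / 2, 1 / 2],
        [0.0, 0.0, 0.0, 1.0],
    ]
)
_T1 = np.array(
    [
        [0.0, 0.0, 0.0, 0.0],
        [1 / 6, -1 / 3, 1 / 6, 0.0],
        [1 / 5, -1 / 3, 1 / 15, 1 / 15],
        [3 / 20, -3 / 20, -3 / 20, 3 / 20],
        [1 / 15, 1 / 15, -1 / 3, 1 / 5],
        [0.0, 1 / 6, -1 / 3, 1 / 6],
        [0.0, 0.0, 0.0, 0.0],
    ]
)

_SUM_TOL = 1e-9


def validate_alpha(alpha: float) -> float:
    """Validate a double-reduction rate, returning it as a float.

    Raises ``ValueError`` outside the closed interval [0, 3/11].
    """
    alpha = float(alpha)
    if not (0.0 <= alpha <= ALPHA_MAX + 1e-15):
        raise ValueError(
            f"double-reduction rate must lie in [0, 3/11]; got {alpha!r}"
        )
    return min(alpha, ALPHA_MAX)


def _as_simplex(values, size: int, what: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float).reshape(-1)
    if arr.size != size:
        raise ValueError(f"{what} needs {size} frequencies; got {arr.size}")
    if np.any(arr < -1e-12):
        raise ValueError(f"{what} frequencies must be non-negative: {arr}")
    total = arr.sum()
    if abs(total - 1.0) > _SUM_TOL:
        raise ValueError(f"{what} frequencies must sum to 1; sum={total!r}")
    return np.clip(arr, 0.0, None) / arr.clip(0.0, None).sum()


@dataclass(frozen=True)
class GenotypeDistribution:
    """Frequencies of the seven hexaploid genotypes, dosage 6 down to 0."""

    freq: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "freq", _as_simplex(self.freq, 7, "genotype distribution")
        )

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.freq, dtype=dtype)

    def __getitem__(self, item):
        return self.freq[item]

    @property
    def mean_dosage(self) -> float:
        return float(self.freq @ GENOTYPE_DOSAGES)

    @property
    def allele_freq(self) -> float:
        """Frequency of allele A (mean dosage / ploidy)."""
        return self.mean_dosage / 6.0

    def swap_alleles(self) -> "GenotypeDistribution":
        """Relabel A <-> a (reverse the dosage axis)."""
        return GenotypeDistribution(self.freq[::-1].copy())

    def collapse(self) -> np.ndarray:
        """Collapse to the three dosage-ambiguous classes (6A, any het, 6a)."""
        f = self.freq
        return np.array([f[0], f[1:6].sum(), f[6]])


@dataclass(frozen=True)
class GameteDistribution:
    """Frequencies of the four triploid gametes, dosage 3 down to 0."""

    freq: np.ndarray

    def __post_init__(self):
        object.__setattr__(
            self, "freq", _as_simplex(self.freq, 4, "gamete distribution")
        )

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.freq, dtype=dtype)

    def __getitem__(self, item):
        return self.freq[item]

    @property
    def mean_dosage(self) -> float:
        return float(self.freq @ GAMETE_DOSAGES)

    def swap_alleles(self) -> "GameteDistribution":
        return GameteDistribution(self.freq[::-1].copy())


def transmission_matrix(alpha: float) -> np.ndarray:
    """7x4 matrix of gamete frequencies per parental genotype.

    Row d (descending dosage) gives the distribution of gamete dosage
    (descending) produced by a parent of that genotype at double-reduction
    rate ``alpha``.
    """
    alpha = validate_alpha(alpha)
    return _T0 + alpha * _T1


def gamete_distribution(dosage: int, alpha: float) -> GameteDistribution:
    """Gamete distribution produced by a single parental genotype.

    ``dosage`` is the parent's A-dosage (0..6).
    """
    dosage = int(dosage)
    if not 0 <= dosage <= 6:
        raise ValueError(f"parental dosage must be in 0..6; got {dosage}")
    row = transmission_matrix(alpha)[6 - dosage]
    return GameteDistribution(row)


def pool_gametes(pop, alpha: float) -> GameteDistribution:
    """Population gamete pool: frequency-weighted mixture of per-genotype
    gamete distributions.  Conserves allele frequency: the pooled mean
    gamete dosage is exactly half the population mean parental dosage."""
    freq = np.asarray(GenotypeDistribution(np.asarray(pop, dtype=float)))
    return GameteDistribution(freq @ transmission_matrix(alpha))


def next_generation(pop, alpha: float) -> GenotypeDistribution:
    """One generation of random mating.

    Offspring genotype frequencies are the self-convolution of the pooled
    gamete distribution, which is algebraically identical to summing the
    28 parental mating types weighted by their frequencies.
    """
    g = np.asarray(pool_gametes(pop, alpha))
    return GenotypeDistribution(np.convolve(g, g))


@dataclass(frozen=True)
class Trajectory:
    """Genotype distributions along successive generations of random mating."""

    alpha: float
    distributions: tuple
    #: generation index of each element, starting at 0.

    def __len__(self) -> int:
        return len(self.distributions)

    def __getitem__(self, t: int) -> GenotypeDistribution:
        return self.distributions[t]

    def __iter__(self):
        return iter(self.distributions)

    @property
    def generations(self) -> int:
        return len(self.distributions) - 1

    def to_frame(self) -> pd.DataFrame:
        rows = [np.asarray(d) for d in self.distributions]
        df = pd.DataFrame(rows, columns=[f"f_{g}" for g in GENOTYPE_LABELS])
        df.insert(0, "generation", np.arange(len(rows)))
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.12g")


def iterate_generations(init, alpha: float, generations: int) -> Trajectory:
    """Iterate the random-mating recursion for a fixed number of generations."""
    generations = int(generations)
    if generations < 0:
        raise ValueError("generations must be >= 0")
    dist = GenotypeDistribution(np.asarray(init, dtype=float))
    out = [dist]
    for _ in range(generations):
        dist = next_generation(dist, alpha)
        out.append(dist)
    return Trajectory(alpha=validate_alpha(alpha), distributions=tuple(out))


@dataclass(frozen=True)
class EquilibriumResult:
    distribution: GenotypeDistribution
    generations: int
    converged: bool


def equilibrium_distribution(
    init,
    alpha: float,
    tol: float = 1e-9,
    max_generations: int = 200,
) -> EquilibriumResult:
    """Iterate random mating until the per-class change drops below ``tol``.

    Returns the near-equilibrium (aHWE) distribution, the number of
    generations used and a convergence flag; warns on non-convergence.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    dist = GenotypeDistribution(np.asarray(init, dtype=float))
    for t in range(1, int(max_generations) + 1):
        new = next_generation(dist, alpha)
        if np.max(np.abs(np.asarray(new) - np.asarray(dist))) < tol:
            return EquilibriumResult(new, t, True)
        dist = new
    warnings.warn(
        f"random-mating recursion did not converge to tol={tol} "
        f"within {max_generations} generations",
        stacklevel=2,
    )
    return EquilibriumResult(dist, int(max_generations), False)


def zygote_freqs_from_gametes(gam) -> GenotypeDistribution:
    """Equilibrium zygote frequencies as products of gamete frequencies.

    Q_6A = P_AAA^2, Q_5A1a = 2 P_AAA P_AAa, ... : exactly the
    self-convolution of the gamete distribution.
    """
    g = np.asarray(GameteDistribution(np.asarray(gam, dtype=float)))
    return GenotypeDistribution(np.convolve(g, g))


def reduced_zygote_freqs_alpha0(parent) -> GenotypeDistribution:
    """Offspring zygote frequencies after one round of random mating with no
    double reduction (alpha = 0)."""
    return next_generation(parent, 0.0)


def binomial_genotype_distribution(p: float) -> GenotypeDistribution:
    """Binomial(6, p) over A-dosage, in descending-dosage order.

    This is the stationary genotype distribution of random mating at
    alpha = 0 for allele frequency ``p``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("allele frequency must lie in [0, 1]")
    d = GENOTYPE_DOSAGES
    from scipy.special import comb

    freq = comb(6, d) * p ** d * (1 - p) ** (6 - d)
    return GenotypeDistribution(freq)
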