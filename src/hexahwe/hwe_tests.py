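"""Tests of asymptotic Hardy-Weinberg equilibrium (aHWE) and double
reduction at a single biallelic marker in an autohexaploid population.

Seven-class (dosage-resolved) tests
-----------------------------------
* :func:`recursive_ahwe_test` -- chi-square of the observed genotype
  frequencies against the distribution reached after several rounds of
  the random-mating recursion seeded with the observed population.
* :func:`gamete_based_ahwe_test` -- chi-square against the aHWE
  distribution implied by EM-fitted gamete frequencies.
* :func:`double_reduction_test` -- chi-square of the observed
  frequencies against the best-fitting no-double-reduction model (free
  parental genotype frequencies, one round of random mating).
* :func:`parental_ahwe_lr_test` -- likelihood ratio of a free parental
  population against a parental population constrained to equilibrium
  (gamete-product) frequencies.

Three-class (dosage-ambiguous) tests, for platforms that cannot
distinguish the five heterozygote classes:
:func:`allele_based_ahwe_test_collapsed`,
:func:`recursive_ahwe_test_collapsed`,
:func:`double_reduction_test_collapsed`.

Scale convention
----------------
Chi-square statistics are computed on observed/expected *frequencies* by
default (``scale="frequencies"``); ``scale="counts"`` multiplies by the
sample size N.  The frequency scale is the one under which this module
reproduces published hexaploid worked examples; the count scale is the
textbook goodness-of-fit scale, and the one to use when p-values are to
carry their usual calibration.  The scale used is recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.stats import chi2

from .estimation import (
    EMResult,
    _as_collapsed,
    _as_counts,
    _loglik,
    em_gamete_frequencies,
    em_joint_gamete_alpha,
    em_parental_genotypes_alpha0,
    em_parental_genotypes_alpha_free,
    estimate_allele_freq_collapsed,
)
from .transmission import (
    ALPHA_MAX,
    binomial_genotype_distribution,
    iterate_generations,
    next_generation,
    zygote_freqs_from_gametes,
)

__all__ = [
    "TestResult",
    "recursive_ahwe_test",
    "gamete_based_ahwe_test",
    "double_reduction_test",
    "parental_ahwe_lr_test",
    "allele_based_ahwe_test_collapsed",
    "recursive_ahwe_test_collapsed",
    "double_reduction_test_collapsed",
]


@dataclass(frozen=True)
class TestResult:
    """A test statistic with its reference distribution and ingredients."""

    statistic: float
    df: int
    p_value: float
    observed: np.ndarray
    expected: np.ndarray
    method: str
    scale: str
    n: float
    em: Optional[EMResult] = None
    degenerate: bool = False

    @property
    def significant_05(self) -> bool:
        return self.p_value < 0.05

    def to_dict(self) -> dict:
        out = {
            "method": self.method,
            "statistic": float(self.statistic),
            "df": int(self.df),
            "p_value": float(self.p_value),
            "n": float(self.n),
            "scale": self.scale,
            "observed": np.asarray(self.observed).tolist(),
            "expected": np.asarray(self.expected).tolist(),
            "degenerate": self.degenerate,
        }
        if self.em is not None:
            out["em"] = self.em.to_dict()
        return out


def _chi_square_stat(obs_freq, exp_freq, n, scale):
    """Goodness-of-fit sum with the zero-expected convention: classes with
    zero expected and zero observed contribute nothing; zero expected with
    positive observed yields an infinite statistic."""
    obs_freq = np.asarray(obs_freq, float)
    exp_freq = np.asarray(exp_freq, float)
    live = exp_freq > 0
    if np.any(~live & (obs_freq > 0)):
        return np.inf
    s = float(np.sum((obs_freq[live] - exp_freq[live]) ** 2 / exp_freq[live]))
    if scale == "counts":
        s *= n
    elif scale != "frequencies":
        raise ValueError(f"scale must be 'counts' or 'frequencies': {scale!r}")
    return s


def _result(stat, df, obs, exp, method, scale, n, em=None, degenerate=False):
    p = float(chi2.sf(stat, df)) if np.isfinite(stat) else 0.0
    return TestResult(
        statistic=float(stat),
        df=int(df),
        p_value=p,
        observed=np.asarray(obs, float),
        expected=np.asarray(exp, float),
        method=method,
        scale=scale,
        n=float(n),
        em=em,
        degenerate=degenerate,
    )


def recursive_ahwe_test(
    counts,
    alpha: float = 0.0,
    generations: int = 8,
    scale: str = "frequencies",
    df: int = 6,
) -> TestResult:
    """Recursive aHWE test.

    The observed genotype frequencies seed the random-mating recursion;
    after ``generations`` rounds (8 by default, where the trajectory has
    stabilized) the endpoint serves as the expected aHWE distribution
    and the chi-square sum is computed against the observation.
    """
    counts = _as_counts(counts)
    obs = counts.frequencies
    traj = iterate_generations(obs, alpha, generations)
    exp = np.asarray(traj[generations])
    stat = _chi_square_stat(obs, exp, counts.total, scale)
    return _result(stat, df, obs, exp, "recursive_ahwe", scale, counts.total)


def gamete_based_ahwe_test(
    counts,
    df: int = 5,
    generations: int = 8,
    scale: str = "frequencies",
    **em_kwargs,
) -> TestResult:
    """Gamete-based aHWE test.

    Gamete frequencies are EM-fitted under the equilibrium (product)
    model; their product zygote distribution is projected through
    ``generations`` rounds of random mating (the product of a
    non-binomial gamete pool is not yet stationary) and the endpoint is
    the expected aHWE distribution.  ``generations=0`` compares against
    the product distribution itself.
    """
    counts = _as_counts(counts)
    obs = counts.frequencies
    em = em_gamete_frequencies(counts, **em_kwargs)
    start = zygote_freqs_from_gametes(em.gametes)
    exp = np.asarray(iterate_generations(start, 0.0, generations)[generations])
    stat = _chi_square_stat(obs, exp, counts.total, scale)
    return _result(stat, df, obs, exp, "gamete_based_ahwe", scale, counts.total, em)


def double_reduction_test(
    counts,
    df: int = 5,
    scale: str = "frequencies",
    **em_kwargs,
) -> TestResult:
    """Goodness-of-fit test of the no-double-reduction transmission model.

    Parental genotype frequencies are EM-fitted under ``alpha = 0``; the
    expected offspring distribution is one round of random mating from
    the fitted parent.  Lack of fit is evidence for double reduction.
    """
    counts = _as_counts(counts)
    obs = counts.frequencies
    em = em_parental_genotypes_alpha0(counts, **em_kwargs)
    exp = np.asarray(next_generation(em.parental, 0.0))
    stat = _chi_square_stat(obs, exp, counts.total, scale)
    return _result(stat, df, obs, exp, "double_reduction", scale, counts.total, em)


def parental_ahwe_lr_test(counts, **em_kwargs) -> TestResult:
    """Likelihood-ratio test of parental aHWE.

    Alternative: free parental genotype frequencies (double-reduction
    rate estimated).  Null: parental frequencies constrained to products
    of parental gamete frequencies (rate estimated).  LR is referred to a
    chi-square with one degree of freedom, and floored at zero (nested
    models; small negative values can arise from optimizer tolerance).
    """
    counts = _as_counts(counts)
    obs = counts.frequencies
    em1 = em_parental_genotypes_alpha_free(counts, **em_kwargs)
    em0 = em_joint_gamete_alpha(counts, **em_kwargs)
    lr = max(0.0, -2.0 * (em0.log_likelihood - em1.log_likelihood))
    exp = np.asarray(next_generation(em0.parental, em0.alpha))
    return _result(lr, 1, obs, exp, "parental_ahwe_lr", "likelihood", counts.total, em1)


def allele_based_ahwe_test_collapsed(
    collapsed, p_mode: str = "midpoint", df: int = 2
) -> TestResult:
    """Allele-based aHWE test for dosage-ambiguous (three-class) markers.

    Gametes are assumed random combinations of three alleles, so the
    expected class frequencies are (p^6, 1-p^6-q^6, q^6).  Computed on
    the frequency scale (no N factor), matching how such markers are
    usually reported as frequency triples.
    """
    collapsed = _as_collapsed(collapsed)
    obs = collapsed.frequencies
    p = estimate_allele_freq_collapsed(collapsed, mode=p_mode)
    q = 1.0 - p
    exp = np.array([p**6, 1.0 - p**6 - q**6, q**6])
    degenerate = p <= 0.0 or p >= 1.0
    stat = _chi_square_stat(obs, exp, collapsed.total, "frequencies")
    return _result(
        stat, df, obs, exp, "allele_based_ahwe_collapsed", "frequencies",
        collapsed.total, degenerate=degenerate,
    )


def _expand_collapsed_uniform(obs3: np.ndarray) -> np.ndarray:
    """Spread the pooled heterozygote mass uniformly over dosage 1-5."""
    out = np.empty(7)
    out[0] = obs3[0]
    out[1:6] = obs3[1] / 5.0
    out[6] = obs3[2]
    return out


def recursive_ahwe_test_collapsed(
    collapsed, generations: int = 8, alpha: float = 0.0, df: int = 2
) -> TestResult:
    """Recursive aHWE test for three-class markers.

    The unobserved heterozygote dosages are expanded uniformly over
    classes 1-5 (conserving the midpoint allele frequency); the
    recursion runs ``generations`` rounds and its endpoint is collapsed
    back to three classes for the chi-square sum (frequency scale).
    """
    collapsed = _as_collapsed(collapsed)
    obs = collapsed.frequencies
    init = _expand_collapsed_uniform(obs)
    traj = iterate_generations(init, alpha, generations)
    exp = traj[generations].collapse()
    stat = _chi_square_stat(obs, exp, collapsed.total, "frequencies")
    return _result(
        stat, df, obs, exp, "recursive_ahwe_collapsed", "frequencies",
        collapsed.total,
    )


def double_reduction_test_collapsed(
    collapsed, pseudo_n: Optional[float] = None
) -> TestResult:
    """Likelihood-ratio test of double reduction for three-class markers.

    The parental population is modelled as binomial(6, p) over dosage
    (the stationary no-double-reduction population); offspring class
    probabilities are one round of random mating at rate ``alpha``,
    collapsed to the three observable classes.  The LR compares the
    (p, alpha) fit against the alpha = 0 fit, with one degree of freedom.

    Frequency triples carry no sample size; ``pseudo_n`` sets the weight
    given to them (default: the stored total, i.e. 1 for frequencies).
    """
    collapsed = _as_collapsed(collapsed)
    obs = collapsed.frequencies
    n = float(pseudo_n) if pseudo_n is not None else collapsed.total
    c = obs * n
    if obs[0] + obs[1] == 0 or obs[1] + obs[2] == 0:
        # monomorphic: no information about alpha
        exp = obs.copy()
        return _result(
            0.0, 1, obs, exp, "double_reduction_collapsed", "likelihood", n,
            degenerate=True,
        )

    def nll(params):
        p, a = params
        if not (1e-9 < p < 1 - 1e-9 and 0.0 <= a <= ALPHA_MAX):
            return np.inf
        parent = binomial_genotype_distribution(p)
        off = next_generation(parent, a).collapse()
        return -_loglik(c, off)

    def fit(fixed_alpha):
        best = None
        for p0 in (0.2, 0.35, 0.5, 0.65, 0.8):
            if fixed_alpha is None:
                for a0 in (0.01, 0.1, 0.25):
                    r = minimize(
                        nll, x0=[p0, a0], method="Nelder-Mead",
                        options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 4000},
                    )
                    if best is None or r.fun < best.fun:
                        best = r
            else:
                r = minimize_scalar(
                    lambda p: nll([p, fixed_alpha]),
                    bounds=(1e-9, 1 - 1e-9), method="bounded",
                    options={"xatol": 1e-12},
                )
                if best is None or r.fun < best.fun:
                    best = r
        return best

    r1 = fit(None)
    r0 = fit(0.0)
    lr = max(0.0, 2.0 * (r0.fun - r1.fun))
    p1, a1 = r1.x
    exp = next_generation(binomial_genotype_distribution(p1), a1).collapse()
    return _result(lr, 1, obs, exp, "double_reduction_collapsed", "likelihood", n)
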