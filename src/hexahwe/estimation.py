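"""Maximum-likelihood estimation for hexaploid genotype-count data.

Three EM-type estimators operate on the seven observed genotype classes:

* :func:`em_gamete_frequencies` -- gamete frequencies of the pool that
  produced the sample, assuming the sample is at equilibrium (genotype
  frequencies are products of gamete frequencies).  The heterozygote
  classes 4A2a, 3A3a and 2A4a are two-component mixtures over their
  gamete-pair origins; the E-step splits them by posterior weight.
* :func:`em_parental_genotypes` -- the seven parental genotype
  frequencies one generation back, given the transmission model at a
  fixed double-reduction rate (``alpha = 0`` for the double-reduction
  test).  The latent variables are the gamete pair that formed each
  offspring and the parental genotype that produced each gamete.
* :func:`em_joint_gamete_alpha` -- parental *gamete* frequencies plus the
  double-reduction rate ``alpha``, with the parental population assumed
  at equilibrium (genotypes are products of the parental gametes).  The
  ``alpha`` update is a bounded one-dimensional maximization nested in
  the EM sweep (an ECM step), since ``alpha`` has no closed-form update.

All EM updates are exact multinomial-mixture steps, so the observed-data
log-likelihood is non-decreasing along every run; this is asserted and
surfaced through :attr:`EMResult.monotone`.

For dosage-ambiguous markers (three observable classes) the allele
frequency is estimated by :func:`estimate_allele_freq_collapsed`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import minimize_scalar

from .transmission import (
    ALPHA_MAX,
    GameteDistribution,
    GenotypeDistribution,
    next_generation,
    transmission_matrix,
    validate_alpha,
    zygote_freqs_from_gametes,
)

__all__ = [
    "GenotypeCounts",
    "CollapsedCounts",
    "EMResult",
    "em_gamete_frequencies",
    "em_parental_genotypes",
    "em_parental_genotypes_alpha0",
    "em_parental_genotypes_alpha_free",
    "em_joint_gamete_alpha",
    "estimate_allele_freq_collapsed",
]

_TINY = 1e-300


@dataclass(frozen=True)
class GenotypeCounts:
    """Observed counts of the seven genotype classes (dosage 6 down to 0)."""

    counts: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.counts, dtype=float).reshape(-1)
        if arr.size != 7:
            raise ValueError(f"need 7 genotype counts; got {arr.size}")
        if np.any(arr < 0):
            raise ValueError(f"counts must be non-negative: {arr}")
        if arr.sum() <= 0:
            raise ValueError("counts must not be all zero")
        object.__setattr__(self, "counts", arr)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.counts, dtype=dtype)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    @classmethod
    def from_frequencies(cls, freqs, n: float) -> "GenotypeCounts":
        """Rescale a frequency vector to pseudo-counts of total ``n``."""
        freqs = np.asarray(freqs, dtype=float)
        return cls(freqs / freqs.sum() * float(n))

    def swap_alleles(self) -> "GenotypeCounts":
        return GenotypeCounts(self.counts[::-1].copy())


@dataclass(frozen=True)
class CollapsedCounts:
    """Counts (or frequencies) of the three dosage-ambiguous classes:
    homozygote 6A, any heterozygote, homozygote 6a.

    Frequency triples (summing to ~1) are accepted as-is; ``total`` then
    equals 1 and tests on them run on the frequency scale.
    """

    counts: np.ndarray

    def __post_init__(self):
        arr = np.asarray(self.counts, dtype=float).reshape(-1)
        if arr.size != 3:
            raise ValueError(f"need 3 collapsed counts; got {arr.size}")
        if np.any(arr < 0):
            raise ValueError(f"counts must be non-negative: {arr}")
        if arr.sum() <= 0:
            raise ValueError("counts must not be all zero")
        object.__setattr__(self, "counts", arr)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.counts, dtype=dtype)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def frequencies(self) -> np.ndarray:
        return self.counts / self.counts.sum()

    def swap_alleles(self) -> "CollapsedCounts":
        return CollapsedCounts(self.counts[::-1].copy())


@dataclass(frozen=True)
class EMResult:
    """Outcome of one maximum-likelihood fit (best over restarts)."""

    log_likelihood: float
    iterations: int
    converged: bool
    n_restarts_used: int
    gametes: Optional[GameteDistribution] = None
    parental: Optional[GenotypeDistribution] = None
    alpha: Optional[float] = None
    allele_freq: Optional[float] = None
    monotone: bool = True
    alpha_at_boundary: bool = False

    def expected_offspring(self) -> GenotypeDistribution:
        """Model-implied genotype distribution for the observed sample."""
        if self.parental is not None and self.alpha is not None:
            return next_generation(self.parental, self.alpha)
        if self.parental is not None:
            return next_generation(self.parental, 0.0)
        if self.gametes is not None:
            return zygote_freqs_from_gametes(self.gametes)
        raise ValueError("EMResult holds no distribution estimates")

    def to_dict(self) -> dict:
        out = {
            "log_likelihood": self.log_likelihood,
            "iterations": self.iterations,
            "converged": self.converged,
            "n_restarts_used": self.n_restarts_used,
            "monotone": self.monotone,
        }
        if self.gametes is not None:
            out["gametes"] = np.asarray(self.gametes).tolist()
        if self.parental is not None:
            out["parental"] = np.asarray(self.parental).tolist()
        if self.alpha is not None:
            out["alpha"] = float(self.alpha)
            out["alpha_at_boundary"] = self.alpha_at_boundary
        if self.allele_freq is not None:
            out["allele_freq"] = float(self.allele_freq)
        return out


def _loglik(counts: np.ndarray, probs: np.ndarray) -> float:
    return float(np.sum(counts * np.log(np.maximum(probs, _TINY))))


def _moment_gamete_start(counts: np.ndarray) -> np.ndarray:
    # binomial(3, p-hat) over gamete dosage, descending
    p = (counts / counts.sum()) @ np.arange(6, -1, -1) / 6.0
    p = min(max(p, 1e-3), 1 - 1e-3)
    q = 1 - p
    return np.array([p**3, 3 * p**2 * q, 3 * p * q**2, q**3])


def _starts(counts, moment, k, rng, dim):
    yield moment
    for _ in range(max(0, k - 1)):
        yield rng.dirichlet(np.ones(dim))


def em_gamete_frequencies(
    counts: GenotypeCounts,
    tol: float = 1e-9,
    max_iter: int = 10000,
    n_restarts: int = 3,
    seed: int = 0,
) -> EMResult:
    """Gamete-frequency MLE under the equilibrium (gamete-product) model.

    Maximizes ``sum_j N_j log Q_j`` where ``Q`` is the self-convolution
    of the gamete distribution.  The M-step sets each gamete frequency
    to its expected usage over the 2N gamete slots.
    """
    counts = _as_counts(counts)
    c = counts.counts
    n2 = 2.0 * counts.total
    rng = np.random.default_rng(seed)
    best = None
    for start in _starts(c, _moment_gamete_start(c), n_restarts, rng, 4):
        g = np.asarray(start, dtype=float).copy()
        ll_prev = -np.inf
        monotone = True
        converged = False
        for it in range(1, max_iter + 1):
            q = np.convolve(g, g)
            ll = _loglik(c, q)
            if ll < ll_prev - 1e-8:
                monotone = False
            if abs(ll - ll_prev) < tol:
                converged = True
                break
            ll_prev = ll
            w = np.where(q > 0, c / np.maximum(q, _TINY), 0.0)
            g = 2.0 * g * np.correlate(w, g, mode="valid") / n2
        cand = EMResult(
            log_likelihood=ll,
            iterations=it,
            converged=converged,
            n_restarts_used=n_restarts,
            gametes=GameteDistribution(g),
            monotone=monotone,
        )
        if best is None or cand.log_likelihood > best.log_likelihood:
            best = cand
    return best


def em_parental_genotypes(
    counts: GenotypeCounts,
    alpha: float = 0.0,
    tol: float = 1e-9,
    max_iter: int = 10000,
    n_restarts: int = 3,
    seed: int = 0,
) -> EMResult:
    """Parental genotype-frequency MLE under the transmission model at a
    fixed double-reduction rate.

    The offspring class probabilities are one round of random mating from
    the parental distribution; the E-step attributes each offspring's two
    gametes to parental genotypes by posterior weight and the M-step sets
    each parental frequency to its share of the 2N parental slots.
    """
    counts = _as_counts(counts)
    alpha = validate_alpha(alpha)
    c = counts.counts
    n2 = 2.0 * counts.total
    t_mat = transmission_matrix(alpha)
    rng = np.random.default_rng(seed)
    obs = counts.frequencies
    moment = (obs + 0.01) / (obs + 0.01).sum()  # smoothed offspring freqs
    best = None
    for start in _starts(c, moment, n_restarts, rng, 7):
        p = np.asarray(start, dtype=float).copy()
        ll_prev = -np.inf
        monotone = True
        converged = False
        for it in range(1, max_iter + 1):
            g = p @ t_mat
            r = np.convolve(g, g)
            ll = _loglik(c, r)
            if ll < ll_prev - 1e-8:
                monotone = False
            if abs(ll - ll_prev) < tol:
                converged = True
                break
            ll_prev = ll
            w = np.where(r > 0, c / np.maximum(r, _TINY), 0.0)
            m = 2.0 * g * np.correlate(w, g, mode="valid")  # gamete usage
            ratio = np.where(g > 0, m / np.maximum(g, _TINY), 0.0)
            p = p * (t_mat @ ratio) / n2
        cand = EMResult(
            log_likelihood=ll,
            iterations=it,
            converged=converged,
            n_restarts_used=n_restarts,
            parental=GenotypeDistribution(p),
            alpha=alpha,
            monotone=monotone,
        )
        if best is None or cand.log_likelihood > best.log_likelihood:
            best = cand
    return best


def em_parental_genotypes_alpha0(counts, **kwargs) -> EMResult:
    """Parental genotype-frequency MLE assuming no double reduction."""
    return em_parental_genotypes(counts, alpha=0.0, **kwargs)


def _brent_alpha(obj, xatol: float = 1e-8):
    res = minimize_scalar(
        obj, bounds=(0.0, ALPHA_MAX), method="bounded", options={"xatol": xatol}
    )
    return float(res.x), -float(res.fun)


def em_parental_genotypes_alpha_free(
    counts: GenotypeCounts,
    tol: float = 1e-9,
    max_iter: int = 10000,
    n_restarts: int = 2,
    seed: int = 0,
    inner_iter: int = 25,
) -> EMResult:
    """MLE of parental genotype frequencies and the double-reduction rate.

    Alternates blocks of parental EM sweeps at fixed ``alpha`` with a
    bounded Brent maximization of the log-likelihood over ``alpha``
    (an expectation/conditional-maximization scheme; both half-steps
    are non-decreasing in the observed-data likelihood).
    """
    counts = _as_counts(counts)
    c = counts.counts
    n2 = 2.0 * counts.total
    rng = np.random.default_rng(seed)
    obs = counts.frequencies
    moment = (obs + 0.01) / (obs + 0.01).sum()

    def ll_of(p, a):
        g = p @ transmission_matrix(a)
        return _loglik(c, np.convolve(g, g))

    best = None
    for start in _starts(c, moment, n_restarts, rng, 7):
        p = np.asarray(start, dtype=float).copy()
        alpha = 0.05
        ll_prev = -np.inf
        monotone = True
        converged = False
        total_it = 0
        for _ in range(max(1, max_iter // inner_iter)):
            t_mat = transmission_matrix(alpha)
            for _ in range(inner_iter):
                total_it += 1
                g = p @ t_mat
                r = np.convolve(g, g)
                w = np.where(r > 0, c / np.maximum(r, _TINY), 0.0)
                m = 2.0 * g * np.correlate(w, g, mode="valid")
                ratio = np.where(g > 0, m / np.maximum(g, _TINY), 0.0)
                p = p * (t_mat @ ratio) / n2
            alpha, ll = _brent_alpha(lambda a: -ll_of(p, a))
            if ll < ll_prev - 1e-8:
                monotone = False
            if abs(ll - ll_prev) < tol:
                converged = True
                break
            ll_prev = ll
        cand = EMResult(
            log_likelihood=ll,
            iterations=total_it,
            converged=converged,
            n_restarts_used=n_restarts,
            parental=GenotypeDistribution(p),
            alpha=alpha,
            monotone=monotone,
            alpha_at_boundary=alpha < 1e-6 or alpha > ALPHA_MAX - 1e-6,
        )
        if best is None or cand.log_likelihood > best.log_likelihood:
            best = cand
    return best


def em_joint_gamete_alpha(
    counts: GenotypeCounts,
    tol: float = 1e-9,
    max_iter: int = 10000,
    n_restarts: int = 2,
    seed: int = 0,
    fix_alpha: Optional[float] = None,
    inner_iter: int = 25,
) -> EMResult:
    """Joint MLE of parental gamete frequencies and ``alpha``.

    The parental population is constrained to equilibrium: its genotype
    frequencies are products of the parental gamete frequencies.  The
    observed sample is one round of random mating (at rate ``alpha``)
    from that parent.  ``fix_alpha`` pins the rate instead of estimating
    it (``fix_alpha=0`` gives the no-double-reduction equilibrium model).
    """
    counts = _as_counts(counts)
    c = counts.counts
    n4 = 4.0 * counts.total
    rng = np.random.default_rng(seed)

    def ll_of(g, a):
        parent = np.convolve(g, g)
        pooled = parent @ transmission_matrix(a)
        return _loglik(c, np.convolve(pooled, pooled))

    best = None
    for start in _starts(c, _moment_gamete_start(c), n_restarts, rng, 4):
        g = np.asarray(start, dtype=float).copy()
        alpha = 0.05 if fix_alpha is None else validate_alpha(fix_alpha)
        ll_prev = -np.inf
        monotone = True
        converged = False
        total_it = 0
        for _ in range(max(1, max_iter // inner_iter)):
            t_mat = transmission_matrix(alpha)
            for _ in range(inner_iter):
                total_it += 1
                parent = np.convolve(g, g)
                pooled = parent @ t_mat
                off = np.convolve(pooled, pooled)
                w = np.where(off > 0, c / np.maximum(off, _TINY), 0.0)
                # transmitted-gamete usage, then parental-slot usage
                m = 2.0 * pooled * np.correlate(w, pooled, mode="valid")
                ratio = np.where(pooled > 0, m / np.maximum(pooled, _TINY), 0.0)
                u = parent * (t_mat @ ratio)
                # founding-gamete usage of each parent (product-form mixture)
                v = np.where(parent > 0, u / np.maximum(parent, _TINY), 0.0)
                g = 2.0 * g * np.correlate(v, g, mode="valid") / n4
            if fix_alpha is None:
                alpha, ll = _brent_alpha(lambda a: -ll_of(g, a))
            else:
                ll = ll_of(g, alpha)
            if ll < ll_prev - 1e-8:
                monotone = False
            if abs(ll - ll_prev) < tol:
                converged = True
                break
            ll_prev = ll
        cand = EMResult(
            log_likelihood=ll,
            iterations=total_it,
            converged=converged,
            n_restarts_used=n_restarts,
            gametes=GameteDistribution(g),
            parental=zygote_freqs_from_gametes(g),
            alpha=alpha,
            monotone=monotone,
            alpha_at_boundary=(fix_alpha is None)
            and (alpha < 1e-6 or alpha > ALPHA_MAX - 1e-6),
        )
        if best is None or cand.log_likelihood > best.log_likelihood:
            best = cand
    return best


def estimate_allele_freq_collapsed(
    collapsed: CollapsedCounts, mode: str = "midpoint"
) -> float:
    """Allele-A frequency from the three dosage-ambiguous classes.

    ``midpoint`` assigns the pooled heterozygote class its average dosage
    (3 of 6): ``p = f(6A) + f(het)/2``.  ``mle`` maximizes the trinomial
    likelihood against expected class frequencies (p^6, 1-p^6-q^6, q^6).
    """
    collapsed = _as_collapsed(collapsed)
    f = collapsed.frequencies
    if mode == "midpoint":
        return float(f[0] + f[1] / 2.0)
    if mode == "mle":
        c = collapsed.counts

        def nll(p):
            q = 1.0 - p
            e = np.array([p**6, 1.0 - p**6 - q**6, q**6])
            return -_loglik(c, e)

        res = minimize_scalar(
            nll, bounds=(1e-9, 1 - 1e-9), method="bounded",
            options={"xatol": 1e-10},
        )
        return float(res.x)
    raise ValueError(f"unknown allele-frequency mode: {mode!r}")


def _as_counts(counts) -> GenotypeCounts:
    if isinstance(counts, GenotypeCounts):
        return counts
    return GenotypeCounts(np.asarray(counts, dtype=float))


def _as_collapsed(collapsed) -> CollapsedCounts:
    if isinstance(collapsed, CollapsedCounts):
        return collapsed
    return CollapsedCounts(np.asarray(collapsed, dtype=float))
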