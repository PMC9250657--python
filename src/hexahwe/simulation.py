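"""Seeded Monte-Carlo engine for power, calibration and estimator studies.

A study cell is a (double-reduction rate, sample size) pair.  For each
cell the engine draws multinomial offspring samples from one round of
random mating applied to the configured parental truth, runs the
configured tests and/or the joint gamete+alpha estimator on every
replicate, and tabulates rejection proportions and estimator means/SDs.

Randomness is fully reproducible: a single master seed spawns one
independent substream per (cell, replicate), so any cell can be rerun in
isolation and identical configurations give bit-identical results.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .estimation import CollapsedCounts, GenotypeCounts, em_joint_gamete_alpha
from . import hwe_tests
from .transmission import (
    GenotypeDistribution,
    next_generation,
    validate_alpha,
    zygote_freqs_from_gametes,
)

__all__ = [
    "SimulationConfig",
    "StudyResult",
    "sample_offspring_counts",
    "run_power_study",
    "run_estimator_study",
    "collapse_counts",
]

#: EM settings used inside replicate loops; lighter than the single-locus
#: defaults because thousands of fits are run per study.
_STUDY_EM = {"n_restarts": 1, "tol": 1e-7, "max_iter": 4000}


def collapse_counts(counts) -> CollapsedCounts:
    """Pool the five heterozygote classes into one (dosage-ambiguous view)."""
    counts = counts if isinstance(counts, GenotypeCounts) else GenotypeCounts(counts)
    c = counts.counts
    return CollapsedCounts(np.array([c[0], c[1:6].sum(), c[6]]))


def sample_offspring_counts(parent, alpha: float, n: int, seed) -> GenotypeCounts:
    """Multinomial offspring sample after one round of random mating.

    ``seed`` may be an integer, a ``SeedSequence`` or a ``Generator``.
    """
    n = int(n)
    if n < 1:
        raise ValueError("sample size must be >= 1")
    rng = np.random.default_rng(seed)
    off = np.asarray(next_generation(parent, alpha))
    return GenotypeCounts(rng.multinomial(n, off))


@dataclass(frozen=True)
class SimulationConfig:
    """Truth specification and study layout.

    Exactly one of ``parent`` (seven genotype frequencies, possibly out
    of equilibrium) or ``gametes`` (four gamete frequencies; the parent
    is their product distribution, i.e. at equilibrium) defines the
    parental truth.
    """

    alpha: float = 0.0
    n_list: tuple = (100, 200, 400)
    replicates: int = 1000
    level: float = 0.05
    seed: int = 0
    tests: tuple = ("double_reduction",)
    parent: Optional[tuple] = None
    gametes: Optional[tuple] = None
    sample_parents: bool = False
    em_settings: dict = field(default_factory=lambda: dict(_STUDY_EM))

    def __post_init__(self):
        if (self.parent is None) == (self.gametes is None):
            raise ValueError("specify exactly one of parent= or gametes=")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must lie in (0, 1)")
        validate_alpha(self.alpha)
        object.__setattr__(self, "n_list", tuple(int(n) for n in self.n_list))
        object.__setattr__(self, "tests", tuple(self.tests))

    @property
    def parent_distribution(self) -> GenotypeDistribution:
        if self.parent is not None:
            return GenotypeDistribution(np.asarray(self.parent, float))
        return zygote_freqs_from_gametes(np.asarray(self.gametes, float))

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {
            "alpha", "n_list", "replicates", "level", "seed", "tests",
            "parent", "gametes", "sample_parents", "em_settings",
        }
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown simulation config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("n_list", "tests", "parent", "gametes"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class StudyResult:
    """Per-cell study summaries with full provenance (config and seed)."""

    table: pd.DataFrame
    config: SimulationConfig

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")

    def to_dict(self) -> dict:
        cfg = {
            "alpha": self.config.alpha,
            "n_list": list(self.config.n_list),
            "replicates": self.config.replicates,
            "level": self.config.level,
            "seed": self.config.seed,
            "tests": list(self.config.tests),
            "parent": None if self.config.parent is None else list(self.config.parent),
            "gametes": None if self.config.gametes is None else list(self.config.gametes),
        }
        return {"config": cfg, "cells": self.table.to_dict(orient="records")}


_TEST_RUNNERS: dict = {}


def _register(name: str):
    def deco(fn):
        _TEST_RUNNERS[name] = fn
        return fn
    return deco


@_register("double_reduction")
def _run_dr(counts, em_settings, em_seed):
    # count-scale statistic so the chi-square reference carries its
    # nominal calibration in repeated sampling
    return hwe_tests.double_reduction_test(
        counts, scale="counts", seed=em_seed, **em_settings
    )


@_register("parental_ahwe_lr")
def _run_lr(counts, em_settings, em_seed):
    return hwe_tests.parental_ahwe_lr_test(counts, seed=em_seed, **em_settings)


@_register("recursive")
def _run_recursive(counts, em_settings, em_seed):
    return hwe_tests.recursive_ahwe_test(counts, scale="counts")


@_register("gamete_based")
def _run_gamete(counts, em_settings, em_seed):
    return hwe_tests.gamete_based_ahwe_test(
        counts, scale="counts", seed=em_seed, **em_settings
    )


def _sample_truth(config, rng, n):
    parent = np.asarray(config.parent_distribution)
    if config.sample_parents:
        # finite parental generation: resample parental frequencies
        parent = rng.multinomial(n, parent) / n
    off = np.asarray(next_generation(parent, config.alpha))
    return rng.multinomial(n, off)


def run_power_study(config: SimulationConfig) -> StudyResult:
    """Rejection proportion of each configured test in every (alpha, N) cell."""
    rows = []
    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(len(config.n_list))
    for n, cell_ss in zip(config.n_list, streams):
        rep_ss = cell_ss.spawn(config.replicates)
        rejections = {t: 0 for t in config.tests}
        failures = {t: 0 for t in config.tests}
        for ss in rep_ss:
            rng = np.random.default_rng(ss)
            em_seed = int(rng.integers(2**31))
            counts = GenotypeCounts(_sample_truth(config, rng, n))
            for t in config.tests:
                try:
                    res = _TEST_RUNNERS[t](counts, config.em_settings, em_seed)
                except Exception:
                    failures[t] += 1
                    continue
                if res.em is not None and not res.em.converged:
                    failures[t] += 1
                if res.p_value < config.level:
                    rejections[t] += 1
        for t in config.tests:
            rows.append(
                {
                    "test": t,
                    "alpha": config.alpha,
                    "n": n,
                    "replicates": config.replicates,
                    "rejection": rejections[t] / config.replicates,
                    "em_failures": failures[t],
                    "level": config.level,
                    "seed": config.seed,
                }
            )
    return StudyResult(pd.DataFrame(rows), config)


def run_estimator_study(config: SimulationConfig) -> StudyResult:
    """Mean and SD of the joint gamete-frequency + alpha estimates per cell."""
    rows = []
    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(len(config.n_list))
    labels = ["P_AAA", "P_AAa", "P_Aaa", "P_aaa"]
    for n, cell_ss in zip(config.n_list, streams):
        rep_ss = cell_ss.spawn(config.replicates)
        estimates = np.empty((config.replicates, 5))
        failures = 0
        for i, ss in enumerate(rep_ss):
            rng = np.random.default_rng(ss)
            em_seed = int(rng.integers(2**31))
            counts = GenotypeCounts(_sample_truth(config, rng, n))
            em = em_joint_gamete_alpha(counts, seed=em_seed, **config.em_settings)
            if not em.converged:
                failures += 1
            estimates[i, :4] = np.asarray(em.gametes)
            estimates[i, 4] = em.alpha
        row = {
            "alpha": config.alpha,
            "n": n,
            "replicates": config.replicates,
            "em_failures": failures,
            "seed": config.seed,
        }
        for j, lab in enumerate(labels):
            row[f"mean_{lab}"] = estimates[:, j].mean()
            row[f"sd_{lab}"] = estimates[:, j].std(ddof=1)
        row["mean_alpha_hat"] = estimates[:, 4].mean()
        row["sd_alpha_hat"] = estimates[:, 4].std(ddof=1)
        rows.append(row)
    return StudyResult(pd.DataFrame(rows), config)
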