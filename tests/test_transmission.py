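"""Transmission model and random-mating recursion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hexahwe as hx
from hexahwe.transmission import ALPHA_MAX, GENOTYPE_DOSAGES

from conftest import random_simplex


def simplex7(rng):
    return random_simplex(rng, 7)


alphas = st.floats(min_value=0.0, max_value=ALPHA_MAX, allow_nan=False)
simplex_raw = st.lists(
    st.floats(min_value=1e-3, max_value=1.0), min_size=7, max_size=7
)


# ---------------------------------------------------------------- gametes
class TestGameteDistribution:
    @pytest.mark.parametrize("alpha", [0.0, 1e-6, 1 / 7, 1 / 5, ALPHA_MAX])
    def test_homozygotes_produce_single_gamete(self, alpha):
        assert np.allclose(hx.gamete_distribution(6, alpha), [1, 0, 0, 0])
        assert np.allclose(hx.gamete_distribution(0, alpha), [0, 0, 0, 1])

    def test_printed_rows(self):
        # balanced heterozygote without double reduction
        assert np.allclose(
            hx.gamete_distribution(3, 0.0), [1 / 20, 9 / 20, 9 / 20, 1 / 20]
        )
        # 5A1a at the upper bound alpha = 3/11
        assert np.allclose(
            hx.gamete_distribution(5, 3 / 11),
            [1 / 2 + 1 / 22, 1 / 2 - 1 / 11, 1 / 22, 0],
        )

    def test_rows_sum_to_one_and_halve_dosage(self, rng):
        # identity in alpha: check at 50 random rates
        for alpha in rng.uniform(0, ALPHA_MAX, size=50):
            t = hx.transmission_matrix(alpha)
            assert np.allclose(t.sum(axis=1), 1.0, atol=1e-14)
            mean = t @ np.arange(3, -1, -1)
            assert np.allclose(mean, GENOTYPE_DOSAGES / 2.0, atol=1e-14)
            assert np.all(t >= -1e-15)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            hx.gamete_distribution(7, 0.0)
        with pytest.raises(ValueError):
            hx.gamete_distribution(-1, 0.0)
        with pytest.raises(ValueError):
            hx.gamete_distribution(3, 0.3)
        with pytest.raises(ValueError):
            hx.gamete_distribution(3, -0.01)


class TestPoolGametes:
    def test_monomorphic_and_homozygote_mixtures(self):
        assert np.allclose(
            hx.pool_gametes([1, 0, 0, 0, 0, 0, 0], 0.17), [1, 0, 0, 0]
        )
        pooled = hx.pool_gametes([0.5, 0, 0, 0, 0, 0, 0.5], 0.21)
        assert np.allclose(pooled, [0.5, 0, 0, 0.5])

    def test_allele_frequency_conserved(self):
        pop = hx.GenotypeDistribution([0.1, 0.05, 0.2, 0.25, 0.13, 0.1, 0.17])
        pooled = hx.pool_gametes(pop, 1 / 7)
        assert pooled.mean_dosage == pytest.approx(pop.mean_dosage / 2, abs=1e-14)


# ------------------------------------------------------- one generation
def mating_type_offspring(pop, alpha):
    """Independent oracle: explicit summation over all ordered parental
    mating types, each contributing the convolution of its two gamete rows."""
    pop = np.asarray(pop, float)
    t = hx.transmission_matrix(alpha)
    out = np.zeros(7)
    for i in range(7):
        for j in range(7):
            out += pop[i] * pop[j] * np.convolve(t[i], t[j])
    return out


class TestNextGeneration:
    def test_matches_mating_type_summation(self, rng):
        for _ in range(100):
            pop = simplex7(rng)
            alpha = rng.uniform(0, ALPHA_MAX)
            conv = np.asarray(hx.next_generation(pop, alpha))
            assert np.allclose(conv, mating_type_offspring(pop, alpha), atol=1e-12)

    def test_monomorphic_fixed_point(self):
        mono = [1, 0, 0, 0, 0, 0, 0]
        assert np.allclose(hx.next_generation(mono, 0.2), mono)

    def test_printed_mating_cells(self, rng):
        # published per-mating-type offspring polynomials, spot-checked
        for alpha in rng.uniform(0, ALPHA_MAX, size=10):
            t = hx.transmission_matrix(alpha)
            # 5A1a x 5A1a -> 6A : (1/2 + alpha/6)^2
            row = np.convolve(t[1], t[1])
            assert row[0] == pytest.approx(
                1 / 4 + alpha / 6 + alpha**2 / 36, abs=1e-14
            )
            # 5A1a x 5A1a -> 4A2a : 1/4 + 1/6 a^2 - 1/6 a
            assert row[2] == pytest.approx(
                1 / 4 + alpha**2 / 6 - alpha / 6, abs=1e-14
            )
            # 4A2a x 3A3a -> 1A5a : 1/100 + 19/300 a (the alpha^2 terms cancel)
            cell = np.convolve(t[2], t[3])[5]
            assert cell == pytest.approx(1 / 100 + 19 * alpha / 300, abs=1e-14)
            # 3A3a x 3A3a -> 3A3a : 41/100 + 9/100 a^2 - 6/25 a
            assert np.convolve(t[3], t[3])[3] == pytest.approx(
                41 / 100 + 9 * alpha**2 / 100 - 6 * alpha / 25, abs=1e-14
            )

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(raw=simplex_raw, alpha=alphas)
    def test_allele_frequency_conserved(self, raw, alpha):
        pop = hx.GenotypeDistribution(np.asarray(raw) / np.sum(raw))
        off = hx.next_generation(pop, alpha)
        assert off.allele_freq == pytest.approx(pop.allele_freq, abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(raw=simplex_raw, alpha=alphas)
    def test_label_swap_commutes(self, raw, alpha):
        pop = hx.GenotypeDistribution(np.asarray(raw) / np.sum(raw))
        direct = hx.next_generation(pop.swap_alleles(), alpha)
        swapped = hx.next_generation(pop, alpha).swap_alleles()
        assert np.allclose(np.asarray(direct), np.asarray(swapped), atol=1e-14)


# ------------------------------------------------------------ trajectory
class TestTrajectory:
    def test_structure_and_recursion(self, rng):
        init = simplex7(rng)
        traj = hx.iterate_generations(init, 1 / 7, 5)
        assert len(traj) == 6
        assert traj.generations == 5
        assert np.allclose(np.asarray(traj[0]), init)
        for t in range(5):
            assert np.allclose(
                np.asarray(traj[t + 1]),
                np.asarray(hx.next_generation(traj[t], 1 / 7)),
            )

    def test_monomorphic_constant(self):
        traj = hx.iterate_generations([0, 0, 0, 0, 0, 0, 1], 0.1, 10)
        for d in traj:
            assert np.allclose(np.asarray(d), [0, 0, 0, 0, 0, 0, 1])

    @pytest.mark.parametrize("alpha", [0.0, 1 / 7, 1 / 5, ALPHA_MAX])
    def test_stabilizes_by_generation_8(self, alpha):
        init = [0.1, 0.05, 0.2, 0.25, 0.13, 0.1, 0.17]
        traj = hx.iterate_generations(init, alpha, 9)
        change = np.max(np.abs(np.asarray(traj[9]) - np.asarray(traj[8])))
        assert change < 1e-3

    def test_allele_frequency_conserved_along_trajectory(self, rng):
        init = hx.GenotypeDistribution(simplex7(rng))
        traj = hx.iterate_generations(init, 0.22, 12)
        for d in traj:
            assert d.allele_freq == pytest.approx(init.allele_freq, abs=1e-12)

    def test_negative_generations_rejected(self):
        with pytest.raises(ValueError):
            hx.iterate_generations([1, 0, 0, 0, 0, 0, 0], 0.0, -1)

    def test_tsv_export(self, tmp_path):
        traj = hx.iterate_generations(
            [0.1, 0.05, 0.2, 0.25, 0.13, 0.1, 0.17], 0.0, 12
        )
        path = tmp_path / "traj.tsv"
        traj.to_tsv(path)
        lines = path.read_text().strip().split("\n")
        assert len(lines) == 14  # header + 13 generations
        assert lines[0].split("\t")[0] == "generation"


class TestEquilibrium:
    def test_monomorphic_converges_immediately(self):
        res = hx.equilibrium_distribution([1, 0, 0, 0, 0, 0, 0], 0.1)
        assert res.converged
        assert res.generations <= 1

    def test_alpha0_limit_is_binomial(self, rng):
        init = hx.GenotypeDistribution(simplex7(rng))
        res = hx.equilibrium_distribution(init, 0.0, tol=1e-12, max_generations=500)
        assert res.converged
        limit = hx.binomial_genotype_distribution(init.allele_freq)
        assert np.allclose(np.asarray(res.distribution), np.asarray(limit), atol=1e-8)

    @pytest.mark.parametrize("p", [0.1, 0.35, 0.5, 0.9])
    def test_binomial_is_fixed_point_at_alpha0(self, p):
        b = hx.binomial_genotype_distribution(p)
        assert np.allclose(
            np.asarray(hx.next_generation(b, 0.0)), np.asarray(b), atol=1e-14
        )

    def test_double_reduction_shifts_equilibrium(self):
        init = [0.1, 0.05, 0.2, 0.25, 0.13, 0.1, 0.17]
        r0 = hx.equilibrium_distribution(init, 0.0, tol=1e-10, max_generations=500)
        r1 = hx.equilibrium_distribution(init, ALPHA_MAX, tol=1e-10, max_generations=500)
        assert not np.allclose(
            np.asarray(r0.distribution), np.asarray(r1.distribution), atol=1e-3
        )

    def test_nonconvergence_is_flagged(self, rng):
        init = simplex7(rng)
        with pytest.warns(UserWarning):
            res = hx.equilibrium_distribution(init, 0.0, tol=1e-15, max_generations=2)
        assert not res.converged


# ---------------------------------------------------------- closed forms
class TestZygoteConstructions:
    def test_product_formulas(self):
        gam = [0.3, 0.2, 0.35, 0.15]
        q = np.asarray(hx.zygote_freqs_from_gametes(gam))
        assert np.allclose(
            q, [0.09, 0.12, 0.25, 0.23, 0.1825, 0.105, 0.0225], atol=1e-12
        )

    def test_product_mirror_symmetry(self, rng):
        gam = random_simplex(rng, 4)
        direct = np.asarray(hx.zygote_freqs_from_gametes(gam[::-1]))
        mirrored = np.asarray(hx.zygote_freqs_from_gametes(gam))[::-1]
        assert np.allclose(direct, mirrored, atol=1e-14)

    def test_monomorphic_gametes(self):
        q = np.asarray(hx.zygote_freqs_from_gametes([1, 0, 0, 0]))
        assert np.allclose(q, [1, 0, 0, 0, 0, 0, 0])

    def test_reduced_equals_recursion_at_alpha0(self, rng):
        for _ in range(20):
            parent = simplex7(rng)
            assert np.allclose(
                np.asarray(hx.reduced_zygote_freqs_alpha0(parent)),
                np.asarray(hx.next_generation(parent, 0.0)),
                atol=1e-14,
            )

    def test_published_closed_forms(self, rng):
        # the homozygote and single-mixture classes have clean closed forms
        for _ in range(20):
            p6, p5, p4, p3, p2, p1, p0 = simplex7(rng)
            r = np.asarray(
                hx.reduced_zygote_freqs_alpha0([p6, p5, p4, p3, p2, p1, p0])
            )
            assert r[0] == pytest.approx(
                (p6 + p5 / 2 + p4 / 5 + p3 / 20) ** 2, abs=1e-12
            )
            assert r[1] == pytest.approx(
                (20 * p6 + 10 * p5 + 4 * p4 + p3)
                * (10 * p5 + 12 * p4 + 9 * p3 + 4 * p2)
                / 200,
                abs=1e-12,
            )
            assert r[5] == pytest.approx(
                (4 * p4 + 9 * p3 + 12 * p2 + 10 * p1)
                * (p3 + 4 * p2 + 10 * p1 + 20 * p0)
                / 200,
                abs=1e-12,
            )
            assert r[6] == pytest.approx(
                (p3 / 20 + p2 / 5 + p1 / 2 + p0) ** 2, abs=1e-12
            )

    def test_all_heterozygote_parent(self):
        r = np.asarray(hx.reduced_zygote_freqs_alpha0([0, 0, 0, 1, 0, 0, 0]))
        assert r[0] == pytest.approx(1 / 400, abs=1e-15)
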