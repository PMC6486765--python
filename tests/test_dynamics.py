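"""Single-population recursion: selection, gamete pool, random union,
releases, trajectories, and the classical limits they must respect."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from daisydrive import (
    Allele,
    DriveArchitecture,
    ExtinctionError,
    FitnessModel,
    GenotypeDistribution,
    ReleaseSchedule,
    apply_selection,
    daisy_architecture,
    initialize_population,
    next_generation,
    produce_gamete_pool,
    simulate,
    standard_drive_architecture,
)
from daisydrive.genetics import haplotype_index

from conftest import W, D, R


def neutral(n):
    return FitnessModel((0.0,) * n, 0.0)


class TestInitializePopulation:
    def test_zero_release_is_pure_wild(self):
        dist = initialize_population(3, ReleaseSchedule(0.0))
        assert dist.genotype_frequency(((W, W, W), (W, W, W))) == 1.0

    def test_two_percent_release(self):
        dist = initialize_population(3, ReleaseSchedule(0.02))
        assert dist.genotype_frequency(((W, W, W), (W, W, W))) == pytest.approx(0.98)
        assert dist.genotype_frequency(((D, D, D), (D, D, D))) == pytest.approx(0.02)

    def test_inundative_release_leaves_residual_wild(self):
        dist = initialize_population(1, ReleaseSchedule(0.999))
        assert dist.genotype_frequency(((D,), (D,))) == pytest.approx(0.999)
        assert dist.genotype_frequency(((W,), (W,))) == pytest.approx(0.001)


class TestApplySelection:
    def test_neutral_fitness_is_identity(self):
        dist = initialize_population(2, ReleaseSchedule(0.3))
        out = apply_selection(dist, neutral(2))
        np.testing.assert_allclose(out.F, dist.F)

    def test_lethal_class_removed(self):
        # cargo-resistant heterozygote is dominant lethal
        dist = GenotypeDistribution.from_point_masses(
            1, {((W,), (W,)): 0.5, ((W,), (R,)): 0.5}
        )
        out = apply_selection(dist, FitnessModel((0.0,), 1.0))
        assert out.genotype_frequency(((W,), (W,))) == pytest.approx(1.0)

    def test_hand_normalized_frequencies(self):
        # 0.5 at w=1 and 0.5 at w=0.9 -> 10/19 and 9/19
        dist = GenotypeDistribution.from_point_masses(
            1, {((W,), (W,)): 0.5, ((W,), (D,)): 0.5}
        )
        out = apply_selection(dist, FitnessModel((0.1,), 1.0))
        assert out.genotype_frequency(((W,), (W,))) == pytest.approx(10 / 19)
        assert out.genotype_frequency(((W,), (D,))) == pytest.approx(9 / 19)

    def test_zero_mean_fitness_raises_extinction(self):
        dist = GenotypeDistribution.from_point_masses(1, {((R,), (R,)): 1.0})
        with pytest.raises(ExtinctionError):
            apply_selection(dist, FitnessModel((0.0,), 1.0))


class TestGametePool:
    def test_pure_wild_point_mass(self, daisy3):
        dist = initialize_population(3, ReleaseSchedule(0.0))
        pool = produce_gamete_pool(dist, daisy3)
        assert pool[0] == pytest.approx(1.0)

    def test_one_locus_het_without_driver_is_mendelian(self):
        arch = daisy_architecture(1, 0.95)  # one-element chain drives nothing
        dist = GenotypeDistribution.from_point_masses(1, {((W,), (D,)): 1.0})
        np.testing.assert_allclose(produce_gamete_pool(dist, arch), [0.5, 0.5, 0.0])

    def test_driven_heterozygote_pool(self):
        arch = daisy_architecture(2, 0.95)
        dist = GenotypeDistribution.from_point_masses(2, {((D, W), (D, D)): 1.0})
        pool = produce_gamete_pool(dist, arch)
        assert pool[haplotype_index((D, D))] == pytest.approx(0.975)
        assert pool[haplotype_index((D, R))] == pytest.approx(0.025)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 2**32 - 1), st.integers(1, 3), st.floats(0, 1))
    def test_pool_is_probability_vector(self, seed, n, H):
        rng = np.random.default_rng(seed)
        M = 3**n
        F = rng.random((M, M))
        F = (F + F.T) / 2
        dist = GenotypeDistribution(n, F / F.sum())
        pool = produce_gamete_pool(dist, daisy_architecture(n, H))
        assert np.all(pool >= -1e-15)
        assert abs(pool.sum() - 1.0) < 1e-9


class TestNextGeneration:
    def test_neutral_mendelian_reaches_hardy_weinberg(self):
        arch = DriveArchitecture(n=2, target_map={1: 2}, H=0.9, kappa=0)
        sched = ReleaseSchedule(0.2)
        dist = initialize_population(2, sched)
        p0 = dist.allele_frequencies()
        nxt = next_generation(dist, arch, neutral(2), ReleaseSchedule())
        # allele frequencies conserved ...
        np.testing.assert_allclose(nxt.allele_frequencies(), p0, atol=1e-15)
        # ... and genotypes at Hardy-Weinberg proportions after one round
        pD = p0[0, int(D)]
        dd = ((D, D), (D, D))
        het = ((W, W), (D, D))
        assert nxt.genotype_frequency(dd) == pytest.approx(pD**2, abs=1e-15)
        assert nxt.genotype_frequency(het) == pytest.approx(2 * pD * (1 - pD), abs=1e-15)

    def test_standard_drive_heterozygotes_fix_in_one_generation(self):
        arch = standard_drive_architecture(1.0)
        dist = GenotypeDistribution.from_point_masses(1, {((W,), (D,)): 1.0})
        nxt = next_generation(dist, arch, neutral(1), ReleaseSchedule())
        assert nxt.genotype_frequency(((D,), (D,))) == pytest.approx(1.0)

    def test_two_locus_random_union_by_enumeration(self):
        # 50/50 wild and complete-drive homozygotes, H=1, neutral:
        # pool is {WW: 0.5, DD: 0.5}; zygotes 1/4, 1/2, 1/4
        arch = daisy_architecture(2, 1.0)
        dist = GenotypeDistribution.from_point_masses(
            2, {((W, W), (W, W)): 0.5, ((D, D), (D, D)): 0.5}
        )
        nxt = next_generation(dist, arch, neutral(2), ReleaseSchedule())
        assert nxt.genotype_frequency(((W, W), (W, W))) == pytest.approx(0.25)
        assert nxt.genotype_frequency(((D, D), (D, D))) == pytest.approx(0.25)
        assert nxt.genotype_frequency(((W, W), (D, D))) == pytest.approx(0.5)

    def test_continuous_release_injects_fraction(self):
        arch = daisy_architecture(2, 0.95)
        sched = ReleaseSchedule(0.0, continuous_fraction=0.1)
        dist = initialize_population(2, ReleaseSchedule(0.0))
        nxt = next_generation(dist, arch, neutral(2), sched)
        assert nxt.genotype_frequency(((D, D), (D, D))) == pytest.approx(0.1)
        assert nxt.genotype_frequency(((W, W), (W, W))) == pytest.approx(0.9)

    @settings(deadline=None, max_examples=20)
    @given(st.integers(0, 2**32 - 1), st.integers(1, 3))
    def test_frequency_conservation(self, seed, n):
        rng = np.random.default_rng(seed)
        M = 3**n
        F = rng.random((M, M))
        F = (F + F.T) / 2
        dist = GenotypeDistribution(n, F / F.sum())
        fit = FitnessModel(tuple(rng.random(n) * 0.3), 0.5)
        nxt = next_generation(
            dist, daisy_architecture(n, 0.8), fit, ReleaseSchedule(0, 0.05)
        )
        assert abs(nxt.total() - 1.0) < 1e-9
        assert np.all(nxt.F >= 0)
        freqs = nxt.allele_frequencies()
        np.testing.assert_allclose(freqs.sum(axis=1), 1.0, atol=1e-9)


class TestSimulate:
    def test_wild_population_stays_wild(self, daisy3):
        traj = simulate(daisy3, FitnessModel.daisy(3, 0.1, 0.0001), ReleaseSchedule(0.0), 1)
        assert traj.generations == 1
        np.testing.assert_allclose(traj.frequency(1, W), [1.0, 1.0])

    def test_neutral_mendelian_frequencies_constant(self):
        arch = DriveArchitecture(n=2, target_map={1: 2}, H=0.9, kappa=0)
        traj = simulate(arch, neutral(2), ReleaseSchedule(0.3), 25)
        for locus in (1, 2):
            for allele in (W, D, R):
                f = traj.frequency(locus, allele)
                np.testing.assert_allclose(f, f[0], atol=1e-14)

    def test_single_locus_perfect_drive_sweeps_to_fixation(self):
        arch = standard_drive_architecture(1.0)
        traj = simulate(arch, neutral(1), ReleaseSchedule(0.01), 30)
        f = traj.frequency(1, D)
        assert np.all(np.diff(f) >= 0)
        # conversion acts in heterozygote germlines, so growth shows from
        # the first post-release generation on
        assert np.all(np.diff(f[1:10]) > 0)
        assert f[-1] > 0.999

    def test_high_efficiency_drive_spreads_cargo(self):
        traj = simulate(
            daisy_architecture(3, 0.95),
            FitnessModel.daisy(3, 0.08, 0.0001),
            ReleaseSchedule(0.02),
            100,
        )
        assert traj.cargo_frequency().max() > 0.95

    def test_low_efficiency_drive_fails_to_spread(self):
        traj = simulate(
            daisy_architecture(3, 0.60),
            FitnessModel.daisy(3, 0.08, 0.0001),
            ReleaseSchedule(0.02),
            100,
        )
        assert traj.cargo_frequency().max() <= 0.5

    def test_weak_daisy_chain_exhausts_and_population_reverts(self):
        # drive too weak to spread the cargo: every element decays and the
        # population returns toward its wild-type state
        traj = simulate(
            daisy_architecture(3, 0.6),
            FitnessModel.daisy(3, 0.10, 0.0001, s=1.0),
            ReleaseSchedule(0.02),
            500,
        )
        for locus in (1, 2, 3):
            assert traj.frequency(locus, D)[-1] < 0.02  # below the release size
        assert traj.frequency(3, D)[-1] < 1e-6

    def test_trajectory_long_table_shape(self, daisy3):
        traj = simulate(daisy3, FitnessModel.daisy(3, 0.1, 0.0001), ReleaseSchedule(0.02), 5)
        df = traj.to_frame()
        assert list(df.columns) == ["generation", "locus", "allele", "frequency"]
        assert len(df) == 6 * 3 * 3
        sums = df.groupby(["generation", "locus"])["frequency"].sum()
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)
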