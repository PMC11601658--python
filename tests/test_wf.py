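import math

import numpy as np
import pytest

from popout import (
    SimConfig,
    SimPopulation,
    centile_architecture_summary,
    continue_with_selection,
    enrichment_log_or,
    extreme_carrier_fraction,
    gaussian_fitness,
    run_simulation,
    watterson_expected_sites,
)

TINY = dict(pop_size=100, mu=2.36e-6, recomb=1e-6)  # 100x rescale, theta preserved


@pytest.fixture(scope="module")
def tiny_run():
    return run_simulation(SimConfig(**TINY, seed=42))


class TestGaussianFitness:
    def test_neutral_limit(self):
        assert gaussian_fitness(3.1, 0.0, 1.0, 0.0) == 1.0

    def test_value_at_mode(self):
        assert gaussian_fitness(0.0, 0.0, 1.0, 1.0) == pytest.approx(1.3989, abs=1e-4)

    def test_value_one_sd_from_mode(self):
        assert gaussian_fitness(1.0, 0.0, 1.0, 1.0) == pytest.approx(1.2420, abs=1e-4)

    def test_maximum_at_optimum(self):
        xs = np.linspace(-3, 3, 61)
        w = gaussian_fitness(xs, 0.5, 1.0, 2.0)
        assert xs[np.argmax(w)] == pytest.approx(0.5)

    def test_invalid_sigma_raises(self):
        with pytest.raises(ValueError):
            gaussian_fitness(0.0, 0.0, -1.0, 1.0)


class TestRunSimulation:
    def test_fixed_seed_reproduces_identical_snapshots(self):
        cfg = SimConfig(**TINY, seed=7, burnin_gens=300, selection_gens=50)
        a, b = run_simulation(cfg), run_simulation(cfg)
        np.testing.assert_array_equal(a.final_snapshot.genotypes, b.final_snapshot.genotypes)
        np.testing.assert_array_equal(a.final_snapshot.effects, b.final_snapshot.effects)
        np.testing.assert_array_equal(a.log_trait_mean, b.log_trait_mean)

    def test_registry_counts_match_carriage(self, tiny_run):
        for snap in (tiny_run.burnin_snapshot, tiny_run.final_snapshot):
            np.testing.assert_array_equal(snap.counts, snap.genotypes.sum(axis=0))
            assert np.all(snap.counts > 0)
            assert np.all(snap.counts < snap.genotypes.shape[0])

    def test_trait_bookkeeping(self, tiny_run):
        snap = tiny_run.final_snapshot
        np.testing.assert_allclose(snap.recompute_traits(), snap.traits, atol=1e-9)

    def test_segregating_sites_near_watterson(self, tiny_run):
        expected = watterson_expected_sites(TINY["pop_size"], TINY["mu"], 100_000)
        observed = tiny_run.log_segregating[-500:].mean()
        assert observed == pytest.approx(expected, rel=0.25)

    def test_selection_reduces_trait_variance(self):
        cfg = SimConfig(**TINY, seed=3, k=100.0)
        res = run_simulation(cfg)
        assert res.final_snapshot.traits.std() < res.burnin_snapshot.traits.std()

    def test_haplotype_sets_roundtrip(self, tiny_run):
        snap = tiny_run.burnin_snapshot
        sets = snap.haplotype_sets()
        assert len(sets) == snap.genotypes.shape[0]
        row = snap.genotypes[0]
        assert sets[0] == set(snap.mutation_id[row])


class TestContinueWithSelection:
    def test_freezes_optimum_from_snapshot(self, tiny_run):
        snap = tiny_run.burnin_snapshot
        cfg = SimConfig(**TINY, seed=1, selection_gens=20)
        out = continue_with_selection(snap, cfg, k=10.0, seed=5)
        assert out.fitness_mu == pytest.approx(snap.traits.mean())
        assert out.fitness_sigma == pytest.approx(snap.traits.std(ddof=0))
        assert out.generation == snap.generation + 20


class TestCentileSummary:
    def test_counts_partition_all_alleles(self, tiny_run):
        cfg = SimConfig(**TINY)
        s = centile_architecture_summary(tiny_run.burnin_snapshot, cfg)
        total = s.n_rare_alleles.sum() + s.n_common_alleles.sum()
        dosage_total = tiny_run.burnin_snapshot.genotypes.sum()
        assert total == dosage_total

    def test_no_rare_alleles_means_zero_counts(self, rng):
        # hand-built population where every site is common
        n2, S = 200, 5
        G = rng.random((n2, S)) < 0.5
        G[:, :] |= ~G.any(axis=0)  # ensure nonzero
        pop = SimPopulation(
            genotypes=G,
            positions=np.arange(S, dtype=np.int64),
            effects=rng.normal(0, 0.01, S),
            origin_generation=np.zeros(S, dtype=np.int64),
            mutation_id=np.arange(S, dtype=np.int64),
            baseline=0.0,
            traits=np.zeros(n2 // 2),
            generation=0,
        )
        pop.traits = pop.recompute_traits()
        s = centile_architecture_summary(pop, SimConfig(**TINY))
        assert s.n_rare_alleles.sum() == 0
        assert s.n_common_alleles.sum() == G.sum()

    def test_mean_trait_is_monotone_across_centiles(self, tiny_run):
        s = centile_architecture_summary(tiny_run.burnin_snapshot, SimConfig(**TINY))
        assert np.all(np.diff(s.mean_trait) >= -1e-12)


class TestEnrichmentLogOR:
    def test_identical_collections_give_zero(self, tiny_run):
        cfg = SimConfig(**TINY)
        s = centile_architecture_summary(tiny_run.burnin_snapshot, cfg)
        out = enrichment_log_or([s], [s], [1, 2, 99, 100])
        for cls in out.values():
            assert cls["mean_log_or"] == 0.0

    def test_two_by_two_arithmetic(self):
        # counts (rare_sel=20, common_sel=100, rare_neu=10, common_neu=100)
        mk = lambda rare, common: centile_stub(rare, common)
        out = enrichment_log_or([mk(20, 100)], [mk(10, 100)], [1])
        assert out["rare"]["mean_log_or"] == pytest.approx(math.log(2.0), abs=1e-12)

    def test_empty_tail_set_raises(self, tiny_run):
        s = centile_architecture_summary(tiny_run.burnin_snapshot, SimConfig(**TINY))
        with pytest.raises(ValueError):
            enrichment_log_or([s], [s], [])


def centile_stub(rare, common):
    """Minimal CentileSummary carrying the given counts in centile 1."""
    from popout import CentileSummary

    z = np.zeros(100)
    r = z.copy()
    r[0] = rare
    c = z.copy()
    c[0] = common
    return CentileSummary(
        n_rare_alleles=r,
        n_very_rare_alleles=z.copy(),
        n_common_alleles=c,
        n_rare_large_alleles=z.copy(),
        n_very_rare_large_alleles=z.copy(),
        n_large_effect_rare_carriers=z.copy(),
        mean_trait=z.copy(),
        mean_common_prs=z.copy(),
        popout_like_effect=z.copy(),
    )


class TestExtremeCarrierFraction:
    def _build_population(self):
        """200 individuals; 3 of the top-2-centile members carry a causal rare allele."""
        rng = np.random.default_rng(0)
        N, S = 200, 12
        n2 = 2 * N
        G = np.zeros((n2, S), dtype=bool)
        effects = np.full(S, 0.001)
        # common background sites
        for s in range(8):
            G[rng.choice(n2, n2 // 2, replace=False), s] = True
        # large-effect rare alleles pushing specific individuals up; the
        # carriers get clean backgrounds so removal unambiguously drops
        # them below the tail boundary
        effects[8:] = [2.0, 2.0, 0.5, 0.0005]
        for j, ind in zip(range(8, 12), [0, 1, 2, 3]):
            G[2 * ind, :8] = False
            G[2 * ind + 1, :8] = False
            G[2 * ind, j] = True
        pop = SimPopulation(
            genotypes=G,
            positions=np.arange(S, dtype=np.int64),
            effects=effects,
            origin_generation=np.zeros(S, dtype=np.int64),
            mutation_id=np.arange(S, dtype=np.int64),
            baseline=0.0,
            traits=np.zeros(N),
            generation=0,
        )
        pop.traits = pop.recompute_traits()
        return pop

    def test_matches_brute_force_count(self):
        pop = self._build_population()
        cfg = SimConfig(pop_size=200, mu=2.36e-6, recomb=1e-6)
        frac = extreme_carrier_fraction(pop, cfg, [99, 100])
        # brute force: enumerate tail individuals and their qualifying alleles
        order = np.argsort(pop.traits)
        tail = order[-4:]  # top 2 centiles of 200 = 4 individuals
        thr = pop.traits[order[-5]]
        n2 = pop.genotypes.shape[0]
        maf = np.minimum(pop.counts / n2, 1 - pop.counts / n2)
        hits = 0
        for i in tail:
            carried = pop.genotypes[2 * i] | pop.genotypes[2 * i + 1]
            ok = carried & (maf < 0.01) & (pop.effects > 0)
            ok &= np.abs(pop.effects) >= (pop.traits[i] - thr)
            hits += int(ok.any())
        assert frac == hits / 4
        assert hits == 3  # carriers of the three 2.0-effect alleles

    def test_no_rare_alleles_gives_zero(self, rng):
        n2, S = 200, 3
        G = np.zeros((n2, S), dtype=bool)
        G[: n2 // 2] = True  # all sites at 50% frequency
        pop = SimPopulation(
            genotypes=G,
            positions=np.arange(S, dtype=np.int64),
            effects=np.full(S, 0.5),
            origin_generation=np.zeros(S, dtype=np.int64),
            mutation_id=np.arange(S, dtype=np.int64),
            baseline=0.0,
            traits=np.zeros(n2 // 2),
            generation=0,
        )
        pop.traits = pop.recompute_traits()
        frac = extreme_carrier_fraction(pop, SimConfig(pop_size=100, mu=1e-6), [100])
        assert frac == 0.0
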