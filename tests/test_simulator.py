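"""Crossbreeding simulator: meiosis, drift, breed structure, panels."""

import numpy as np
import pytest

from crossrel.panels import AlleleFrequencies
from crossrel.simulator import (
    Genome,
    Population,
    SimConfig,
    _PedigreeRecorder,
    _random_union_offspring,
    found_breeds,
    meiosis,
    sample_reference_and_candidates,
    select_snp_panel,
    simulate,
    simulate_breed_generations,
    simulate_historical,
)

from conftest import tiny_sim_config


def single_chromosome_genome(n_loci=10, length=1.0, seed=0):
    rng = np.random.default_rng(seed)
    return Genome(chrom=np.zeros(n_loci, dtype=int),
                  pos=np.sort(rng.uniform(0, length, n_loci)),
                  lengths=np.array([length]))


class TestMeiosis:
    def test_no_mutation_no_crossover_copies_parental_haplotype(self):
        genome = single_chromosome_genome(8)
        rng = np.random.default_rng(0)
        haps = np.stack([np.zeros((50, 8), np.uint8),
                         np.ones((50, 8), np.uint8)], axis=1)
        gametes, counts = meiosis(haps, genome, rng, 0.0,
                                  return_crossover_counts=True)
        pure = counts == 0
        assert pure.any()
        row_sets = gametes[pure].sum(axis=1)
        assert np.all((row_sets == 0) | (row_sets == 8))

    def test_crossover_count_is_poisson_one_per_morgan(self):
        genome = single_chromosome_genome(4, length=1.0)
        rng = np.random.default_rng(1)
        haps = np.zeros((200_000, 2, 4), np.uint8)
        _, counts = meiosis(haps, genome, rng, 0.0, return_crossover_counts=True)
        assert counts.mean() == pytest.approx(1.0, abs=0.01)
        assert counts.var() == pytest.approx(1.0, abs=0.02)

    def test_mutation_rate_recovered_empirically(self):
        genome = single_chromosome_genome(2000)
        rng = np.random.default_rng(2)
        haps = np.zeros((1000, 2, 2000), np.uint8)  # monomorphic parents
        gametes = meiosis(haps, genome, rng, 2.5e-4)
        rate = gametes.mean()
        assert rate == pytest.approx(2.5e-4, abs=5e-5)

    def test_monomorphic_stays_monomorphic_without_mutation(self):
        genome = single_chromosome_genome(30)
        rng = np.random.default_rng(3)
        haps = np.ones((40, 2, 30), np.uint8)
        gametes = meiosis(haps, genome, rng, 0.0)
        assert np.all(gametes == 1)


class TestDrift:
    def test_one_generation_frequency_change_matches_wright_fisher(self):
        """Mean change ~ 0 and variance ~ p(1-p)/2N over replicate matings."""
        genome = single_chromosome_genome(200)
        rng = np.random.default_rng(4)
        n = 100
        p0 = rng.uniform(0.2, 0.8, 200)
        haps = (rng.random((n, 2, 200)) < p0).astype(np.uint8)
        pop = Population(ids=np.zeros(n, np.int64),
                         sex=np.array(["M", "F"] * (n // 2)), haplotypes=haps)
        p_parent = pop.genotypes().mean(axis=0) / 2.0
        keep = (p_parent > 0.05) & (p_parent < 0.95)
        reps = 50
        changes = np.empty((reps, keep.sum()))
        for r in range(reps):
            off = _random_union_offspring(pop, n, genome, rng, 0.0)
            p_off = off.sum(axis=1).mean(axis=0) / 2.0
            changes[r] = (p_off - p_parent)[keep]
        assert abs(changes.mean()) < 5e-3
        expected_var = (p_parent * (1 - p_parent) / (2 * n))[keep]
        ratio = changes.var(axis=0, ddof=1).mean() / expected_var.mean()
        assert ratio == pytest.approx(1.0, abs=0.05)


class TestHistoricalAndBreeds:
    def test_zero_historical_generations_keep_founder_draw(self):
        cfg = tiny_sim_config()
        cfg = type(cfg)(**{**cfg.__dict__, "generations_constant": 0,
                           "generations_decline": 0})
        rng = np.random.default_rng(5)
        pop, genome = simulate_historical(cfg, rng)
        assert pop.n == cfg.size_constant
        assert genome.n_loci == cfg.n_chromosomes * cfg.candidate_snps_per_chromosome

    def test_breed_founding_is_disjoint_and_deterministic(self):
        cfg = tiny_sim_config()
        rng = np.random.default_rng(6)
        pop, genome = simulate_historical(cfg, rng)
        a1, b1 = found_breeds(pop, cfg, np.random.default_rng(9), _PedigreeRecorder())
        a2, b2 = found_breeds(pop, cfg, np.random.default_rng(9), _PedigreeRecorder())
        assert np.array_equal(a1.haplotypes, a2.haplotypes)
        assert len(np.intersect1d(a1.ids, b1.ids)) == 0
        assert a1.n == cfg.breed_founder_males + cfg.breed_founder_females

    def test_breed_generation_litter_counts_and_sires(self):
        cfg = tiny_sim_config()
        rng = np.random.default_rng(7)
        pop, genome = simulate_historical(cfg, rng)
        recorder = _PedigreeRecorder()
        breed_a, _ = found_breeds(pop, cfg, rng, recorder)
        cfg1 = type(cfg)(**{**cfg.__dict__, "divergence_generations": 1})
        out = simulate_breed_generations(breed_a, cfg1, genome, rng, recorder,
                                         "breedA")
        assert out.n == cfg.breed_females_start * cfg.litter_size
        rec = recorder.pedigree().records
        offspring = rec[rec["generation"] == 1]
        founder_males = rec[(rec["generation"] == 0) & (rec["sex"] == "M")]["id"]
        assert set(offspring["sire"]).issubset(set(founder_males))

    def test_divergence_increases_between_breed_distance(self):
        """More divergence generations -> larger |p_A - p_B| on average."""
        diffs = {}
        for gens in (2, 12):
            cfg = tiny_sim_config()
            cfg = type(cfg)(**{**cfg.__dict__, "divergence_generations": gens})
            gaps = []
            for rep in range(3):
                sim = simulate(cfg, seed=11, replicate=rep)
                fa = AlleleFrequencies.from_panels(
                    sim.purebred_panels[("breedA", 2)])
                fb = AlleleFrequencies.from_panels(
                    sim.purebred_panels[("breedB", 2)])
                gaps.append(np.abs(fa.freqs["breedA"] - fb.freqs["breedB"]).mean())
            diffs[gens] = np.mean(gaps)
        assert diffs[12] > diffs[2]


class TestPanelSelection:
    def test_maf_threshold_boundary_is_inclusive(self):
        genome = single_chromosome_genome(3)
        # frequencies 0.01, 0.05, 0.5 -> the latter two qualify
        geno = np.zeros((100, 2, 3), np.uint8)
        geno[:1, :, 0] = 1   # p = 0.01
        geno[:5, :, 1] = 1   # p = 0.05
        geno[:50, :, 2] = 1  # p = 0.5
        pop = Population(ids=np.zeros(100, np.int64),
                         sex=np.array(["M", "F"] * 50), haplotypes=geno)
        cfg = tiny_sim_config()
        cfg = type(cfg)(**{**cfg.__dict__, "n_chromosomes": 1,
                           "candidate_snps_per_chromosome": 3,
                           "panel_snps_per_chromosome": 2})
        idx = select_snp_panel(pop, genome, cfg, np.random.default_rng(0))
        assert set(idx) == {1, 2}
        cfg0 = type(cfg)(**{**cfg.__dict__, "maf_threshold": 0.0,
                            "panel_snps_per_chromosome": 3})
        assert len(select_snp_panel(pop, genome, cfg0,
                                    np.random.default_rng(0))) == 3

    def test_insufficient_loci_error_reports_counts(self):
        genome = single_chromosome_genome(3)
        pop = Population(ids=np.zeros(10, np.int64),
                         sex=np.array(["M", "F"] * 5),
                         haplotypes=np.zeros((10, 2, 3), np.uint8))
        cfg = tiny_sim_config()
        cfg = type(cfg)(**{**cfg.__dict__, "n_chromosomes": 1,
                           "candidate_snps_per_chromosome": 3,
                           "panel_snps_per_chromosome": 2})
        with pytest.raises(ValueError, match="only 0"):
            select_snp_panel(pop, genome, cfg, np.random.default_rng(0))


class TestFullSimulation:
    def test_crossbred_cohort_counts_and_parent_breeds(self, tiny_sim, tiny_cfg):
        assert sorted(tiny_sim.crossbred_panels) == list(
            range(1, tiny_cfg.cross_generations + 1))
        for gen, panel in tiny_sim.crossbred_panels.items():
            assert panel.n_animals == tiny_cfg.crossbred_per_generation
        rec = tiny_sim.pedigree.records.set_index("id")
        cross = rec[rec["population"] == "crossAB"]
        parents_pop = {
            frozenset((rec.loc[s, "population"], rec.loc[d, "population"]))
            for s, d in zip(cross["sire"], cross["dam"])
        }
        assert parents_pop == {frozenset(("breedA", "breedB"))}

    def test_breed_origin_reconstruction_identity(self, tiny_sim):
        for gen in tiny_sim.origin_panels:
            tiny_sim.origin_panels[gen].check_consistency(
                tiny_sim.crossbred_panels[gen])

    def test_seed_reproducibility(self, tiny_cfg, tiny_sim):
        again = simulate(tiny_cfg, seed=3)
        assert np.array_equal(again.crossbred_panels[2].genotypes,
                              tiny_sim.crossbred_panels[2].genotypes)
        assert again.pedigree.records.equals(tiny_sim.pedigree.records)

    def test_reference_candidate_sampling(self, tiny_sim, tiny_cfg):
        rng = np.random.default_rng(0)
        sets = sample_reference_and_candidates(tiny_sim, "CB+PB-PB", 0, rng)
        assert len(sets["refs_A"]) == tiny_cfg.reference_group_sizes[-1]
        assert len(sets["refs_AB"]) == tiny_cfg.reference_group_sizes[0]
        groups = sets["candidates"]
        assert set(groups) == {"G1", "G2", "G3"}
        all_c = np.concatenate(list(groups.values()))
        assert len(np.unique(all_c)) == len(all_c)
        assert len(np.intersect1d(all_c, sets["refs_A"])) == 0
        sets2 = sample_reference_and_candidates(tiny_sim, "CB+PB-PB", 0,
                                                np.random.default_rng(0))
        assert np.array_equal(sets2["refs_AB"], sets["refs_AB"])

    def test_unknown_scenario_rejected(self, tiny_sim):
        with pytest.raises(ValueError):
            sample_reference_and_candidates(tiny_sim, "nope", 0,
                                            np.random.default_rng(0))


def test_sim_config_validation():
    with pytest.raises(ValueError):
        SimConfig(mutation_rate=2.0)
    with pytest.raises(ValueError):
        SimConfig(panel_snps_per_chromosome=10**6)
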