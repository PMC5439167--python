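"""Forward-in-time simulator of a two-way crossbreeding program.

The simulated design has three phases:

1. **Historical population** -- discrete random-mating generations at
   constant size followed by a gradual (linear) decline, building up
   linkage disequilibrium by drift and recurrent mutation.
2. **Breed formation** -- two disjoint random samples founded from the last
   historical generation diverge for a configurable number of random-mating
   generations (few generations = closely related breeds, many = unrelated
   breeds), with litters of four (2M/2F) per dam and a ramp-up of the
   number of breeding females.
3. **Crossbreeding program** -- each breed is propagated by random
   selection/mating while F1 crossbred AB cohorts are produced every
   generation from random A x B matings; the breed of origin of every
   crossbred allele is recorded exactly.

Meiosis places a Poisson(L) number of crossovers uniformly on each
chromosome of length L Morgan (no interference) and flips each transmitted
allele with the recurrent mutation probability.

Full-scale defaults describe a realistic pig-type program (10,000-animal
history, 10-Morgan genome, 20k-SNP panel, 4000 crossbreds per generation);
``SimConfig.scaled`` gives a desk-sized profile with the same structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from crossrel.panels import BreedOriginPanel, GenotypePanel
from crossrel.pedigree import Pedigree

__all__ = [
    "SimConfig",
    "Genome",
    "Population",
    "SimOutput",
    "meiosis",
    "simulate",
    "simulate_historical",
    "found_breeds",
    "simulate_breed_generations",
    "simulate_crossbreeding_program",
    "select_snp_panel",
    "sample_reference_and_candidates",
]


@dataclass
class SimConfig:
    """All knobs of the crossbreeding simulation (full-scale defaults)."""

    # historical phase
    generations_constant: int = 1000
    size_constant: int = 10000
    generations_decline: int = 1000
    size_final: int = 2000
    # breed phase
    divergence_generations: int = 10  # 10 = related breeds, 100 = unrelated
    breed_founder_males: int = 500
    breed_founder_females: int = 500
    litter_size: int = 4  # 2 males + 2 females
    breed_males_selected: int = 500
    breed_females_start: int = 500
    breed_females_final: int = 800
    breed_females_ramp_generations: int = 4
    # crossbreeding phase
    cross_generations: int = 5
    cross_males: int = 1000
    cross_females: int = 3000
    crossbred_per_generation: int = 4000
    # genome
    n_chromosomes: int = 10
    chromosome_length: float = 1.0  # Morgan
    candidate_snps_per_chromosome: int = 4000
    mutation_rate: float = 2.5e-4
    maf_threshold: float = 0.05
    panel_snps_per_chromosome: int = 2000
    # validation sampling
    reference_group_sizes: tuple = (2000, 4000)
    candidates_per_generation: int = 1000

    def __post_init__(self) -> None:
        for name in (
            "size_constant", "size_final", "breed_founder_males",
            "breed_founder_females", "litter_size", "breed_males_selected",
            "breed_females_start", "breed_females_final", "cross_males",
            "cross_females", "crossbred_per_generation", "n_chromosomes",
            "candidate_snps_per_chromosome", "panel_snps_per_chromosome",
            "candidates_per_generation",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise ValueError("mutation_rate must be a probability")
        if not 0.0 <= self.maf_threshold <= 0.5:
            raise ValueError("maf_threshold must be in [0, 0.5]")
        if self.panel_snps_per_chromosome > self.candidate_snps_per_chromosome:
            raise ValueError("panel larger than candidate locus count")

    @classmethod
    def scaled(cls, divergence_generations: int = 10) -> "SimConfig":
        """Desk-sized profile preserving the study's structure."""
        return cls(
            generations_constant=100,
            size_constant=400,
            generations_decline=100,
            size_final=200,
            divergence_generations=divergence_generations,
            breed_founder_males=50,
            breed_founder_females=50,
            breed_males_selected=50,
            breed_females_start=50,
            breed_females_final=80,
            cross_generations=5,
            cross_males=100,
            cross_females=300,
            crossbred_per_generation=400,
            n_chromosomes=5,
            candidate_snps_per_chromosome=400,
            panel_snps_per_chromosome=200,
            reference_group_sizes=(200, 400),
            candidates_per_generation=100,
        )


@dataclass
class Genome:
    """Locus map: chromosome index and Morgan position per locus."""

    chrom: np.ndarray
    pos: np.ndarray
    lengths: np.ndarray  # per-chromosome length in Morgan

    @classmethod
    def random(cls, cfg: SimConfig, rng: np.random.Generator) -> "Genome":
        chroms = []
        positions = []
        for c in range(cfg.n_chromosomes):
            p = np.sort(rng.uniform(0.0, cfg.chromosome_length,
                                    cfg.candidate_snps_per_chromosome))
            chroms.append(np.full(cfg.candidate_snps_per_chromosome, c))
            positions.append(p)
        return cls(
            chrom=np.concatenate(chroms),
            pos=np.concatenate(positions),
            lengths=np.full(cfg.n_chromosomes, cfg.chromosome_length),
        )

    @property
    def n_loci(self) -> int:
        return len(self.pos)

    def chromosome_spans(self):
        for c in range(len(self.lengths)):
            idx = np.flatnonzero(self.chrom == c)
            if idx.size:
                yield slice(idx[0], idx[-1] + 1), float(self.lengths[c])

    def subset(self, index) -> "Genome":
        index = np.asarray(index)
        return Genome(chrom=self.chrom[index], pos=self.pos[index],
                      lengths=self.lengths)


@dataclass
class Population:
    """A cohort of diploid animals: ids, sexes and phased haplotypes."""

    ids: np.ndarray          # global animal ids (0 is reserved for unknown)
    sex: np.ndarray          # 'M'/'F'
    haplotypes: np.ndarray   # (n, 2, n_loci) uint8

    @property
    def n(self) -> int:
        return len(self.ids)

    def genotypes(self) -> np.ndarray:
        return self.haplotypes.sum(axis=1, dtype=np.int16)

    def males(self) -> np.ndarray:
        return np.flatnonzero(self.sex == "M")

    def females(self) -> np.ndarray:
        return np.flatnonzero(self.sex == "F")


@dataclass
class SimOutput:
    """Everything the validation workflow needs from one replicate."""

    config: SimConfig
    genome: Genome                       # restricted to the selected panel
    pedigree: Pedigree
    purebred_panels: dict = field(default_factory=dict)  # (breed, gen) -> GenotypePanel
    crossbred_panels: dict = field(default_factory=dict)  # gen -> GenotypePanel
    origin_panels: dict = field(default_factory=dict)     # gen -> BreedOriginPanel
    seed: int | None = None
    replicate: int | None = None


def meiosis(
    haplotypes: np.ndarray,
    genome: Genome,
    rng: np.random.Generator,
    mutation_rate: float,
    return_crossover_counts: bool = False,
):
    """One gamete per parent row of ``haplotypes`` ((n, 2, m) uint8).

    Per chromosome of length L: crossover count ~ Poisson(L), positions
    uniform, no interference; the starting haplotype is chosen at random.
    Each transmitted allele is flipped with probability ``mutation_rate``.
    """
    haplotypes = np.asarray(haplotypes)
    n, _, m = haplotypes.shape
    gametes = np.empty((n, m), dtype=np.uint8)
    total_crossovers = np.zeros(n, dtype=np.int64)
    for sl, length in genome.chromosome_spans():
        pos = genome.pos[sl]
        k = rng.poisson(length, size=n)
        total_crossovers += k
        start = rng.integers(0, 2, size=n)
        maxk = int(k.max()) if n else 0
        if maxk == 0:
            choose = np.repeat(start[:, None], len(pos), axis=1)
        else:
            x = rng.uniform(0.0, length, size=(n, maxk))
            x[np.arange(maxk)[None, :] >= k[:, None]] = np.inf
            crossed = (x[:, None, :] <= pos[None, :, None]).sum(axis=2)
            choose = (start[:, None] + crossed) & 1
        gametes[:, sl] = np.take_along_axis(
            haplotypes[:, :, sl], choose[:, None, :], axis=1
        )[:, 0, :]
    if mutation_rate > 0:
        flips = rng.random((n, m)) < mutation_rate
        gametes ^= flips.astype(np.uint8)
    if return_crossover_counts:
        return gametes, total_crossovers
    return gametes


def _random_union_offspring(
    pop: Population,
    n_offspring: int,
    genome: Genome,
    rng: np.random.Generator,
    mutation_rate: float,
    batch: int = 4000,
) -> np.ndarray:
    """Haplotypes of offspring from random union of gametes (parents drawn
    uniformly with replacement from the male and female pools)."""
    males = pop.males()
    females = pop.females()
    if males.size == 0 or females.size == 0:
        raise ValueError("population lacks one sex entirely")
    out = np.empty((n_offspring, 2, genome.n_loci), dtype=np.uint8)
    for lo in range(0, n_offspring, batch):
        hi = min(lo + batch, n_offspring)
        sires = rng.choice(males, size=hi - lo)
        dams = rng.choice(females, size=hi - lo)
        out[lo:hi, 0] = meiosis(pop.haplotypes[sires], genome, rng, mutation_rate)
        out[lo:hi, 1] = meiosis(pop.haplotypes[dams], genome, rng, mutation_rate)
    return out


def _alternating_sexes(n: int) -> np.ndarray:
    sex = np.empty(n, dtype="<U1")
    sex[0::2] = "M"
    sex[1::2] = "F"
    return sex


def simulate_historical(cfg: SimConfig, rng: np.random.Generator,
                        genome: Genome | None = None) -> tuple[Population, Genome]:
    """Historical random-mating phase; returns the final generation.

    Founder allele frequencies are drawn uniform(0.05, 0.95) per locus; the
    configured generations of drift and recurrent mutation then shape the
    final allele-frequency spectrum.  The population size stays at
    ``size_constant`` and then declines linearly to ``size_final``.
    """
    if genome is None:
        genome = Genome.random(cfg, rng)
    m = genome.n_loci
    p0 = rng.uniform(0.05, 0.95, size=m)
    n0 = cfg.size_constant
    haps = (rng.random((n0, 2, m)) < p0).astype(np.uint8)
    pop = Population(ids=np.zeros(n0, dtype=np.int64),
                     sex=_alternating_sexes(n0), haplotypes=haps)
    sizes = [cfg.size_constant] * cfg.generations_constant
    if cfg.generations_decline > 0:
        sizes += list(np.linspace(cfg.size_constant, cfg.size_final,
                                  cfg.generations_decline + 1)[1:].round().astype(int))
    for n_next in sizes:
        haps = _random_union_offspring(pop, int(n_next), genome, rng,
                                       cfg.mutation_rate)
        pop = Population(ids=np.zeros(int(n_next), dtype=np.int64),
                         sex=_alternating_sexes(int(n_next)), haplotypes=haps)
    return pop, genome


def select_snp_panel(pop: Population, genome: Genome, cfg: SimConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """Indices of the analysis panel: per chromosome, a uniform sample of
    ``panel_snps_per_chromosome`` loci with MAF >= threshold (inclusive)."""
    p = pop.genotypes().mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    qualifying = maf >= cfg.maf_threshold
    chosen = []
    for sl, _ in genome.chromosome_spans():
        idx = np.flatnonzero(qualifying[sl]) + sl.start
        if idx.size < cfg.panel_snps_per_chromosome:
            raise ValueError(
                f"chromosome starting at locus {sl.start} has only {idx.size} "
                f"loci with MAF >= {cfg.maf_threshold}, "
                f"need {cfg.panel_snps_per_chromosome}"
            )
        chosen.append(np.sort(rng.choice(idx, cfg.panel_snps_per_chromosome,
                                         replace=False)))
    return np.concatenate(chosen)


class _PedigreeRecorder:
    """Assigns global ids and accumulates pedigree rows."""

    def __init__(self) -> None:
        self.next_id = 1
        self.rows: list[tuple] = []

    def register(self, n: int, sires, dams, sex, generation: int,
                 population: str) -> np.ndarray:
        ids = np.arange(self.next_id, self.next_id + n, dtype=np.int64)
        self.next_id += n
        sires = np.broadcast_to(np.asarray(sires, dtype=np.int64), (n,))
        dams = np.broadcast_to(np.asarray(dams, dtype=np.int64), (n,))
        for i in range(n):
            self.rows.append((int(ids[i]), int(sires[i]), int(dams[i]),
                              sex[i], generation, population))
        return ids

    def pedigree(self) -> Pedigree:
        df = pd.DataFrame(self.rows, columns=["id", "sire", "dam", "sex",
                                              "generation", "population"])
        return Pedigree(df)


def found_breeds(historical: Population, cfg: SimConfig,
                 rng: np.random.Generator,
                 recorder: _PedigreeRecorder) -> tuple[Population, Population]:
    """Two disjoint random samples founding breeds A and B.

    Founders are registered in the pedigree with unknown parents."""
    need_m = 2 * cfg.breed_founder_males
    need_f = 2 * cfg.breed_founder_females
    males = historical.males()
    females = historical.females()
    if males.size < need_m or females.size < need_f:
        raise ValueError("historical population too small to found two breeds")
    pick_m = rng.choice(males, size=need_m, replace=False)
    pick_f = rng.choice(females, size=need_f, replace=False)
    breeds = []
    for b, label in enumerate(("breedA", "breedB")):
        rows = np.concatenate([pick_m[b::2], pick_f[b::2]])
        sex = np.array(["M"] * cfg.breed_founder_males
                       + ["F"] * cfg.breed_founder_females)
        ids = recorder.register(len(rows), 0, 0, sex, 0, label)
        breeds.append(Population(ids=ids, sex=sex,
                                 haplotypes=historical.haplotypes[rows].copy()))
    return breeds[0], breeds[1]


def _litter_generation(
    pop: Population,
    n_sires: int,
    n_dams: int,
    cfg: SimConfig,
    genome: Genome,
    rng: np.random.Generator,
    recorder: _PedigreeRecorder,
    generation: int,
    label: str,
) -> Population:
    """One breed-phase generation: each breeding female produces a litter of
    ``litter_size`` (half males) by one randomly drawn breeding male."""
    males = pop.males()
    females = pop.females()
    sel_m = rng.choice(males, size=min(n_sires, males.size), replace=False)
    sel_f = rng.choice(females, size=min(n_dams, females.size), replace=False)
    litter = cfg.litter_size
    dam_rows = np.repeat(sel_f, litter)
    sire_rows = np.repeat(rng.choice(sel_m, size=len(sel_f)), litter)
    n_off = len(dam_rows)
    haps = np.empty((n_off, 2, genome.n_loci), dtype=np.uint8)
    haps[:, 0] = meiosis(pop.haplotypes[sire_rows], genome, rng, cfg.mutation_rate)
    haps[:, 1] = meiosis(pop.haplotypes[dam_rows], genome, rng, cfg.mutation_rate)
    sex = np.tile(_alternating_sexes(litter), len(sel_f))
    ids = recorder.register(n_off, pop.ids[sire_rows], pop.ids[dam_rows],
                            sex, generation, label)
    return Population(ids=ids, sex=sex, haplotypes=haps)


def simulate_breed_generations(
    breed: Population,
    cfg: SimConfig,
    genome: Genome,
    rng: np.random.Generator,
    recorder: _PedigreeRecorder,
    label: str,
    start_generation: int = 1,
) -> Population:
    """Divergence phase: random selection and litter mating for
    ``divergence_generations`` generations, with the breeding-female count
    ramping from ``breed_females_start`` to ``breed_females_final``."""
    if cfg.divergence_generations < 1:
        raise ValueError("divergence_generations must be >= 1")
    ramp = np.linspace(cfg.breed_females_start, cfg.breed_females_final,
                       cfg.breed_females_ramp_generations + 1)[1:]
    pop = breed
    for g in range(cfg.divergence_generations):
        if g == 0 or len(ramp) == 0:
            # founders are the first breeders
            n_dams = cfg.breed_females_start
        else:
            n_dams = int(round(ramp[min(g - 1, len(ramp) - 1)]))
        pop = _litter_generation(pop, cfg.breed_males_selected, n_dams, cfg,
                                 genome, rng, recorder, start_generation + g,
                                 label)
    return pop


def _random_mating_cohort(
    pop: Population,
    n_males: int,
    n_females: int,
    cfg: SimConfig,
    genome: Genome,
    rng: np.random.Generator,
    recorder: _PedigreeRecorder,
    generation: int,
    label: str,
) -> Population:
    n_offspring = n_males + n_females
    males = pop.males()
    females = pop.females()
    sire_rows = rng.choice(males, size=n_offspring)
    dam_rows = rng.choice(females, size=n_offspring)
    haps = np.empty((n_offspring, 2, genome.n_loci), dtype=np.uint8)
    haps[:, 0] = meiosis(pop.haplotypes[sire_rows], genome, rng, cfg.mutation_rate)
    haps[:, 1] = meiosis(pop.haplotypes[dam_rows], genome, rng, cfg.mutation_rate)
    sex = np.array(["M"] * n_males + ["F"] * n_females)
    ids = recorder.register(n_offspring, pop.ids[sire_rows], pop.ids[dam_rows],
                            sex, generation, label)
    return Population(ids=ids, sex=sex, haplotypes=haps)


def _select_breeders(pop: Population, n_males: int, n_females: int,
                     rng: np.random.Generator) -> Population:
    males = rng.choice(pop.males(), size=min(n_males, len(pop.males())),
                       replace=False)
    females = rng.choice(pop.females(), size=min(n_females, len(pop.females())),
                         replace=False)
    rows = np.concatenate([males, females])
    return Population(ids=pop.ids[rows], sex=pop.sex[rows],
                      haplotypes=pop.haplotypes[rows])


def simulate_crossbreeding_program(
    breed_a: Population,
    breed_b: Population,
    cfg: SimConfig,
    genome: Genome,
    rng: np.random.Generator,
    recorder: _PedigreeRecorder,
    start_generation: int,
    panel_index: np.ndarray,
    out: SimOutput,
) -> None:
    """Crossbreeding phase: per generation, purebred replacement cohorts of
    ``cross_males + cross_females`` per breed plus ``crossbred_per_generation``
    F1 AB animals from random A x B matings.

    Crossbred sires alternate between breeds by offspring index; the gamete
    from the breed-A (breed-B) parent is recorded as the A-origin (B-origin)
    haplotype, so the origin split is exact by construction.
    """
    pools = {
        "breedA": _select_breeders(breed_a, cfg.cross_males, cfg.cross_females, rng),
        "breedB": _select_breeders(breed_b, cfg.cross_males, cfg.cross_females, rng),
    }
    panel_genome = out.genome
    for g in range(1, cfg.cross_generations + 1):
        gen = start_generation + g
        n_cross = cfg.crossbred_per_generation
        half = n_cross - n_cross // 2
        a_pool, b_pool = pools["breedA"], pools["breedB"]
        # even offspring index: A sire x B dam; odd: B sire x A dam
        a_sires = rng.choice(a_pool.males(), size=half)
        b_dams = rng.choice(b_pool.females(), size=half)
        b_sires = rng.choice(b_pool.males(), size=n_cross // 2)
        a_dams = rng.choice(a_pool.females(), size=n_cross // 2)

        hap_a = np.empty((n_cross, genome.n_loci), dtype=np.uint8)
        hap_b = np.empty((n_cross, genome.n_loci), dtype=np.uint8)
        hap_a[0::2] = meiosis(a_pool.haplotypes[a_sires], genome, rng,
                              cfg.mutation_rate)
        hap_b[0::2] = meiosis(b_pool.haplotypes[b_dams], genome, rng,
                              cfg.mutation_rate)
        hap_b[1::2] = meiosis(b_pool.haplotypes[b_sires], genome, rng,
                              cfg.mutation_rate)
        hap_a[1::2] = meiosis(a_pool.haplotypes[a_dams], genome, rng,
                              cfg.mutation_rate)
        sires = np.empty(n_cross, dtype=np.int64)
        dams = np.empty(n_cross, dtype=np.int64)
        sires[0::2] = a_pool.ids[a_sires]
        dams[0::2] = b_pool.ids[b_dams]
        sires[1::2] = b_pool.ids[b_sires]
        dams[1::2] = a_pool.ids[a_dams]
        sex = _alternating_sexes(n_cross)
        ids = recorder.register(n_cross, sires, dams, sex, gen, "crossAB")

        geno = (hap_a[:, panel_index].astype(np.int16)
                + hap_b[:, panel_index].astype(np.int16))
        locus_ids = np.array([f"snp{j}" for j in panel_index])
        out.crossbred_panels[g] = GenotypePanel(
            animal_ids=ids, populations=np.full(n_cross, "crossAB"),
            genotypes=geno, locus_ids=locus_ids,
            chromosome=panel_genome.chrom, position=panel_genome.pos,
        )
        out.origin_panels[g] = BreedOriginPanel(
            animal_ids=ids, allele_a=hap_a[:, panel_index],
            allele_b=hap_b[:, panel_index], locus_ids=locus_ids,
        )

        # purebred replacement cohorts (same parent pools as the crossbreds)
        for label in ("breedA", "breedB"):
            cohort = _random_mating_cohort(
                pools[label], cfg.cross_males, cfg.cross_females, cfg, genome,
                rng, recorder, gen, label,
            )
            out.purebred_panels[(label, g)] = _panel_from_population(
                cohort, label, panel_index, panel_genome)
            pools[label] = cohort


def _panel_from_population(pop: Population, label: str, panel_index: np.ndarray,
                           panel_genome: Genome) -> GenotypePanel:
    locus_ids = np.array([f"snp{j}" for j in panel_index])
    return GenotypePanel(
        animal_ids=pop.ids,
        populations=np.full(pop.n, label),
        genotypes=pop.haplotypes[:, :, panel_index].sum(axis=1, dtype=np.int16),
        locus_ids=locus_ids,
        chromosome=panel_genome.chrom,
        position=panel_genome.pos,
    )


def simulate(cfg: SimConfig, seed: int | None = None,
             replicate: int = 0) -> SimOutput:
    """Run one full replicate: history, breed divergence, crossbreeding.

    Per-phase child RNGs are spawned deterministically from the master seed
    and replicate index, so any phase is reproducible in isolation.
    """
    master = np.random.SeedSequence(seed).spawn(replicate + 1)[replicate]
    keys = master.spawn(4)
    rng_hist = np.random.default_rng(keys[0])
    rng_panel = np.random.default_rng(keys[1])
    rng_breed = np.random.default_rng(keys[2])
    rng_cross = np.random.default_rng(keys[3])

    historical, genome = simulate_historical(cfg, rng_hist)
    panel_index = select_snp_panel(historical, genome, cfg, rng_panel)
    panel_genome = genome.subset(panel_index)

    recorder = _PedigreeRecorder()
    breed_a, breed_b = found_breeds(historical, cfg, rng_breed, recorder)
    del historical
    breed_a = simulate_breed_generations(breed_a, cfg, genome, rng_breed,
                                         recorder, "breedA")
    breed_b = simulate_breed_generations(breed_b, cfg, genome, rng_breed,
                                         recorder, "breedB")

    out = SimOutput(config=cfg, genome=panel_genome, pedigree=None,  # type: ignore
                    seed=seed, replicate=replicate)
    cross_start = cfg.divergence_generations
    simulate_crossbreeding_program(breed_a, breed_b, cfg, genome, rng_cross,
                                   recorder, cross_start, panel_index, out)
    out.pedigree = recorder.pedigree()
    return out


def sample_reference_and_candidates(
    sim: SimOutput,
    scenario: str,
    group: int,
    rng: np.random.Generator,
) -> dict:
    """Reference and candidate animal ids for one validation cell.

    Reference animals come from crossbreeding generation 2; candidates are
    breed A animals from generations 3, 4 and 5 (groups G1, G2, G3), all
    disjoint from the reference sets.

    ``scenario`` is one of ``"PB-PB"``, ``"CB-PB"``, ``"CB+PB-PB"``;
    ``group`` indexes ``config.reference_group_sizes``.
    """
    cfg = sim.config
    sizes = cfg.reference_group_sizes
    if group not in range(len(sizes)):
        raise ValueError(f"group must index {sizes}")
    ref_gen = 2
    out: dict = {"scenario": scenario, "group": group}

    def pick(ids: np.ndarray, n: int) -> np.ndarray:
        if len(ids) < n:
            raise ValueError(f"only {len(ids)} animals available, need {n}")
        return rng.choice(ids, size=n, replace=False)

    breed_a_ref_pool = sim.purebred_panels[("breedA", ref_gen)].animal_ids
    cross_ref_pool = sim.crossbred_panels[ref_gen].animal_ids
    if scenario == "PB-PB":
        out["refs_A"] = pick(breed_a_ref_pool, sizes[group])
    elif scenario == "CB-PB":
        out["refs_AB"] = pick(cross_ref_pool, sizes[group])
    elif scenario == "CB+PB-PB":
        out["refs_A"] = pick(breed_a_ref_pool, sizes[-1])
        out["refs_AB"] = pick(cross_ref_pool, sizes[group])
    else:
        raise ValueError(f"unknown scenario {scenario!r}")

    candidates = {}
    for g_idx, gen in enumerate(range(3, 3 + min(3, cfg.cross_generations - 2))):
        pool = sim.purebred_panels[("breedA", gen)].animal_ids
        pool = np.setdiff1d(pool, out.get("refs_A", np.array([], dtype=np.int64)))
        candidates[f"G{g_idx + 1}"] = pick(pool, cfg.candidates_per_generation)
    out["candidates"] = candidates
    return out
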