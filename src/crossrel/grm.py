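"""Genomic relationship matrices, full and breed-of-origin partial.

All matrices follow VanRaden's second method: genotypes are standardized
per locus, ``Z_lk = (M_lk - 2 p_k) / sqrt(2 p_k (1 - p_k))``, and
``G = Z Z' / m`` with ``m`` the number of loci.  When reference animals and
candidates belong to different populations each population is standardized
with its own frequencies before the stacked product is formed.  For the
breed-specific model, a crossbred's breed-b origin allele (0/1) is
standardized as ``(M - p_bk) / sqrt(2 p_bk (1 - p_bk))`` with the purebred
breed-b frequency, giving partial relationship matrices ``G^(b)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from crossrel.panels import AlleleFrequencies, BreedOriginPanel, GenotypePanel

__all__ = [
    "RelationshipSet",
    "standardize_genotypes",
    "build_grm",
    "build_multipop_grm",
    "build_partial_grm",
    "rescale_to_pedigree_base",
]

logger = logging.getLogger(__name__)

SYM_TOL = 1e-10


@dataclass
class RelationshipSet:
    """Named genomic relationship blocks sharing one locus count ``m``.

    Blocks are keyed by name (e.g. ``"G_AA"``, ``"GA_ABAB"``); each block
    carries its row/column animal ids in ``row_ids`` / ``col_ids``.
    """

    m: int
    blocks: dict = field(default_factory=dict)
    row_ids: dict = field(default_factory=dict)
    col_ids: dict = field(default_factory=dict)
    frequency_source: str = ""

    def add(self, name: str, block: np.ndarray, row_ids=None, col_ids=None) -> None:
        block = np.asarray(block, dtype=float)
        if block.shape[0] == block.shape[1] and row_ids is col_ids:
            asym = np.abs(block - block.T).max() if block.size else 0.0
            if asym > SYM_TOL:
                raise ValueError(f"square block {name!r} not symmetric ({asym:.2e})")
        self.blocks[name] = block
        if row_ids is not None:
            self.row_ids[name] = np.asarray(row_ids)
        if col_ids is not None:
            self.col_ids[name] = np.asarray(col_ids)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.blocks[name]

    def __contains__(self, name: str) -> bool:
        return name in self.blocks

    def to_long_frame(self, name: str) -> pd.DataFrame:
        """Long-format (animal_i, animal_j, value) view of one block."""
        block = self.blocks[name]
        rows = self.row_ids.get(name, np.arange(block.shape[0]))
        cols = self.col_ids.get(name, np.arange(block.shape[1]))
        ii, jj = np.meshgrid(np.arange(block.shape[0]), np.arange(block.shape[1]), indexing="ij")
        return pd.DataFrame(
            {
                "animal_i": np.asarray(rows)[ii.ravel()],
                "animal_j": np.asarray(cols)[jj.ravel()],
                "value": block.ravel(),
            }
        )


def standardize_genotypes(
    genotypes: np.ndarray, p: np.ndarray, locus_ids=None
) -> np.ndarray:
    """Standardize a 0/1/2 genotype matrix with frequencies ``p``.

    Raises if any retained locus is fixed (p in {0, 1}), naming the locus.
    """
    genotypes = np.asarray(genotypes, dtype=float)
    p = np.asarray(p, dtype=float)
    if genotypes.shape[1] != p.shape[0]:
        raise ValueError(
            f"frequency/panel locus mismatch: {genotypes.shape[1]} columns "
            f"vs {p.shape[0]} frequencies"
        )
    fixed = (p <= 0.0) | (p >= 1.0)
    if fixed.any():
        k = int(np.argmax(fixed))
        name = locus_ids[k] if locus_ids is not None else k
        raise ValueError(f"locus {name!r} is fixed (p={p[k]}); drop it before standardizing")
    return (genotypes - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))


def standardize_origin_alleles(
    alleles: np.ndarray, p: np.ndarray, locus_ids=None
) -> np.ndarray:
    """Standardize 0/1 breed-origin alleles of crossbreds: (M - p)/sqrt(2p(1-p))."""
    alleles = np.asarray(alleles, dtype=float)
    p = np.asarray(p, dtype=float)
    if alleles.shape[1] != p.shape[0]:
        raise ValueError("frequency/panel locus mismatch for origin alleles")
    fixed = (p <= 0.0) | (p >= 1.0)
    if fixed.any():
        k = int(np.argmax(fixed))
        name = locus_ids[k] if locus_ids is not None else k
        raise ValueError(f"locus {name!r} is fixed (p={p[k]}); drop it before standardizing")
    return (alleles - p) / np.sqrt(2.0 * p * (1.0 - p))


def build_grm(Z: np.ndarray, m: int) -> np.ndarray:
    """``G = Z Z' / m`` for a standardized genotype matrix."""
    if m <= 0:
        raise ValueError("locus count m must be positive")
    Z = np.asarray(Z, dtype=float)
    if Z.shape[1] != m:
        raise ValueError(f"m={m} does not match Z columns ({Z.shape[1]})")
    G = Z @ Z.T / m
    return 0.5 * (G + G.T)


def _filter_informative(
    panels: list[GenotypePanel], freqs: AlleleFrequencies, pops: list[str]
):
    mask = freqs.informative_mask(pops)
    dropped = int((~mask).sum())
    if dropped:
        logger.info("dropping %d loci fixed in at least one population", dropped)
        panels = [p.subset_loci(mask) for p in panels]
        freqs = freqs.subset_loci(mask)
    return panels, freqs, int(mask.sum())


def build_multipop_grm(
    panels: list[GenotypePanel],
    freqs: AlleleFrequencies,
    populations: list[str] | None = None,
) -> RelationshipSet:
    """Joint GRM across populations, each standardized with its own p.

    ``panels`` are stacked in order; every animal is standardized with the
    frequency vector of its own population label.  Loci fixed in any used
    population are dropped from all panels and from ``m``.  Blocks named
    ``G_<i>_<j>`` (panel indices) are stored along with the joint ``G``.
    """
    locus_ids = panels[0].locus_ids
    for p in panels[1:]:
        if not np.array_equal(p.locus_ids, locus_ids):
            raise ValueError("locus sets differ between panels")
    if populations is None:
        populations = sorted({pop for p in panels for pop in np.unique(p.populations)})
    panels, freqs, m = _filter_informative(list(panels), freqs, populations)
    if m == 0:
        raise ValueError("no informative loci left after filtering")
    Zs = []
    for panel in panels:
        Z = np.empty(panel.genotypes.shape, dtype=float)
        for pop in np.unique(panel.populations):
            rows = panel.populations == pop
            Z[rows] = standardize_genotypes(
                panel.genotypes[rows], freqs.freqs[pop], panel.locus_ids
            )
        Zs.append(Z)
    Zfull = np.vstack(Zs)
    G = build_grm(Zfull, m)
    rel = RelationshipSet(m=m, frequency_source="per-population observed")
    all_ids = np.concatenate([p.animal_ids for p in panels])
    rel.add("G", G, all_ids, all_ids)
    offsets = np.cumsum([0] + [p.n_animals for p in panels])
    for i in range(len(panels)):
        for j in range(len(panels)):
            blk = G[offsets[i] : offsets[i + 1], offsets[j] : offsets[j + 1]]
            ri = panels[i].animal_ids
            cj = panels[j].animal_ids
            rel.add(f"G_{i}{j}", blk, ri, ri if i == j else cj)
    return rel


def build_partial_grm(
    origin: BreedOriginPanel,
    purebred_a: GenotypePanel,
    purebred_b: GenotypePanel,
    freqs: AlleleFrequencies,
    pop_a: str = "breedA",
    pop_b: str = "breedB",
    candidates_a: GenotypePanel | None = None,
) -> RelationshipSet:
    """Breed-of-origin partial GRMs for crossbreds and purebred breed A.

    Crossbred origin alleles are standardized with the purebred parental
    frequencies (``p_Ak`` for the A-origin allele, ``p_Bk`` for B);
    purebred animals keep the full 0/1/2 coding but the same frequencies.
    Returns blocks ``GA_ABAB``, ``GB_ABAB``, ``GA_AA``, ``GA_AAB`` and,
    when breed-A candidates are given, ``GA_aAB``, ``GA_aA``, ``GA_aa``.
    """
    locus_ids = origin.locus_ids
    for panel in filter(None, (purebred_a, purebred_b, candidates_a)):
        if not np.array_equal(panel.locus_ids, locus_ids):
            raise ValueError("locus sets differ between origin and purebred panels")
    mask = freqs.informative_mask([pop_a, pop_b])
    dropped = int((~mask).sum())
    if dropped:
        logger.info("dropping %d loci fixed in a parental breed", dropped)
    m = int(mask.sum())
    if m == 0:
        raise ValueError("no informative loci left after filtering")
    origin = origin.subset_loci(mask)
    purebred_a = purebred_a.subset_loci(mask)
    purebred_b = purebred_b.subset_loci(mask)
    freqs = freqs.subset_loci(mask)
    if candidates_a is not None:
        candidates_a = candidates_a.subset_loci(mask)

    pA = freqs.freqs[pop_a]
    pB = freqs.freqs[pop_b]
    ZA_cross = standardize_origin_alleles(origin.allele_a, pA, origin.locus_ids)
    ZB_cross = standardize_origin_alleles(origin.allele_b, pB, origin.locus_ids)
    ZA_pure = standardize_genotypes(purebred_a.genotypes, pA, purebred_a.locus_ids)

    rel = RelationshipSet(m=m, frequency_source="purebred parental breeds")
    cid = origin.animal_ids
    aid = purebred_a.animal_ids
    rel.add("GA_ABAB", build_grm(ZA_cross, m), cid, cid)
    rel.add("GB_ABAB", build_grm(ZB_cross, m), cid, cid)
    rel.add("GA_AA", build_grm(ZA_pure, m), aid, aid)
    rel.add("GA_AAB", ZA_pure @ ZA_cross.T / m, aid, cid)
    if candidates_a is not None:
        Za = standardize_genotypes(candidates_a.genotypes, pA, candidates_a.locus_ids)
        kid = candidates_a.animal_ids
        rel.add("GA_aAB", Za @ ZA_cross.T / m, kid, cid)
        rel.add("GA_aA", Za @ ZA_pure.T / m, kid, aid)
        rel.add("GA_aa", build_grm(Za, m), kid, kid)
    return rel


def rescale_to_pedigree_base(G: np.ndarray, mean_inbreeding: float) -> np.ndarray:
    """Rescale a genomic block to the pedigree base: ``(1-F̄) G + 2 F̄ J``.

    ``J`` is the all-ones matrix of the block's shape and ``F̄`` the mean
    pedigree inbreeding of the animals involved.
    """
    if not 0.0 <= mean_inbreeding <= 1.0:
        raise ValueError(f"mean inbreeding {mean_inbreeding} outside [0, 1]")
    G = np.asarray(G, dtype=float)
    return (1.0 - mean_inbreeding) * G + 2.0 * mean_inbreeding * np.ones_like(G)
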