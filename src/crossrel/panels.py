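"""Genotype containers: allele-count panels, breed-of-origin splits, frequencies.

Genotypes are coded 0/1/2 (copies of the counted allele).  For F1 crossbred
animals the 0/1/2 genotype splits into two 0/1 alleles, one inherited from
the breed-A parent and one from the breed-B parent; the split is what the
breed-specific allele substitution model operates on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypePanel", "BreedOriginPanel", "AlleleFrequencies"]


@dataclass
class GenotypePanel:
    """Animals x loci allele-count matrix with population labels.

    Parameters
    ----------
    animal_ids:
        One identifier per row; must be unique.
    populations:
        Population label per animal (e.g. ``"breedA"``, ``"breedB"``,
        ``"crossAB"``).
    genotypes:
        Integer matrix with entries in {0, 1, 2}.
    locus_ids:
        One identifier per column.
    chromosome, position:
        Optional chromosome index and map position in Morgan per locus.
    """

    animal_ids: np.ndarray
    populations: np.ndarray
    genotypes: np.ndarray
    locus_ids: np.ndarray
    chromosome: np.ndarray | None = None
    position: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids)
        self.populations = np.asarray(self.populations)
        self.genotypes = np.asarray(self.genotypes)
        self.locus_ids = np.asarray(self.locus_ids)
        n, m = self.genotypes.shape
        if len(self.animal_ids) != n:
            raise ValueError("animal_ids length does not match genotype rows")
        if len(self.populations) != n:
            raise ValueError("populations length does not match genotype rows")
        if len(self.locus_ids) != m:
            raise ValueError("locus_ids length does not match genotype columns")
        if len(np.unique(self.animal_ids)) != n:
            raise ValueError("duplicate animal ids in panel")
        vals = np.unique(self.genotypes)
        if vals.size and (vals.min() < 0 or vals.max() > 2):
            raise ValueError("genotype entries must be in {0, 1, 2}")

    @property
    def n_animals(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.genotypes.shape[1]

    def subset_animals(self, ids) -> "GenotypePanel":
        """Row-subset the panel to ``ids`` (in the given order)."""
        lookup = {a: i for i, a in enumerate(self.animal_ids)}
        try:
            idx = np.array([lookup[i] for i in ids])
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"animal {exc.args[0]!r} not in panel") from exc
        return GenotypePanel(
            animal_ids=self.animal_ids[idx],
            populations=self.populations[idx],
            genotypes=self.genotypes[idx],
            locus_ids=self.locus_ids,
            chromosome=self.chromosome,
            position=self.position,
        )

    def subset_loci(self, mask_or_index) -> "GenotypePanel":
        idx = np.asarray(mask_or_index)
        return GenotypePanel(
            animal_ids=self.animal_ids,
            populations=self.populations,
            genotypes=self.genotypes[:, idx],
            locus_ids=self.locus_ids[idx],
            chromosome=None if self.chromosome is None else self.chromosome[idx],
            position=None if self.position is None else self.position[idx],
        )


@dataclass
class BreedOriginPanel:
    """Breed-of-origin allele split for F1 crossbred animals.

    ``allele_a[l, k]`` (``allele_b[l, k]``) is the 0/1 allele that crossbred
    ``l`` inherited from its breed-A (breed-B) parent at locus ``k``.  The
    two origin alleles sum to the 0/1/2 genotype at every locus.
    """

    animal_ids: np.ndarray
    allele_a: np.ndarray
    allele_b: np.ndarray
    locus_ids: np.ndarray

    def __post_init__(self) -> None:
        self.animal_ids = np.asarray(self.animal_ids)
        self.allele_a = np.asarray(self.allele_a)
        self.allele_b = np.asarray(self.allele_b)
        self.locus_ids = np.asarray(self.locus_ids)
        if self.allele_a.shape != self.allele_b.shape:
            raise ValueError("origin allele matrices differ in shape")
        for name, arr in (("allele_a", self.allele_a), ("allele_b", self.allele_b)):
            vals = np.unique(arr)
            if vals.size and (vals.min() < 0 or vals.max() > 1):
                raise ValueError(f"{name} entries must be in {{0, 1}}")

    @property
    def n_animals(self) -> int:
        return self.allele_a.shape[0]

    def genotypes(self) -> np.ndarray:
        """Reconstruct 0/1/2 genotypes (A-origin + B-origin allele)."""
        return self.allele_a.astype(np.int16) + self.allele_b.astype(np.int16)

    def check_consistency(self, panel: GenotypePanel) -> None:
        """Verify the origin split reproduces ``panel``'s genotypes exactly.

        Raises ``ValueError`` naming the first offending animal/locus.
        """
        sub = panel.subset_animals(self.animal_ids)
        if not np.array_equal(sub.locus_ids, self.locus_ids):
            raise ValueError("locus sets differ between origin and genotype panel")
        diff = self.genotypes() != sub.genotypes
        if diff.any():
            l, k = np.argwhere(diff)[0]
            raise ValueError(
                f"breed-origin alleles inconsistent with genotype for animal "
                f"{self.animal_ids[l]!r} at locus {self.locus_ids[k]!r}"
            )

    def subset_animals(self, ids) -> "BreedOriginPanel":
        lookup = {a: i for i, a in enumerate(self.animal_ids)}
        idx = np.array([lookup[i] for i in ids])
        return BreedOriginPanel(
            animal_ids=self.animal_ids[idx],
            allele_a=self.allele_a[idx],
            allele_b=self.allele_b[idx],
            locus_ids=self.locus_ids,
        )

    def subset_loci(self, mask_or_index) -> "BreedOriginPanel":
        idx = np.asarray(mask_or_index)
        return BreedOriginPanel(
            animal_ids=self.animal_ids,
            allele_a=self.allele_a[:, idx],
            allele_b=self.allele_b[:, idx],
            locus_ids=self.locus_ids[idx],
        )


@dataclass
class AlleleFrequencies:
    """Per-population allele frequencies on a common locus set."""

    locus_ids: np.ndarray
    freqs: dict = field(default_factory=dict)  # population -> array of p

    def __post_init__(self) -> None:
        self.locus_ids = np.asarray(self.locus_ids)
        m = len(self.locus_ids)
        for pop, p in self.freqs.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (m,):
                raise ValueError(f"frequency vector for {pop!r} has wrong length")
            if (p < 0).any() or (p > 1).any():
                raise ValueError(f"frequencies for {pop!r} outside [0, 1]")
            self.freqs[pop] = p

    @classmethod
    def from_panels(cls, *panels: GenotypePanel) -> "AlleleFrequencies":
        """Observed frequencies per population, pooling all given panels.

        Animals from all panels sharing a population label are pooled; the
        frequency is the mean allele count divided by two.
        """
        locus_ids = panels[0].locus_ids
        sums: dict = {}
        counts: dict = {}
        for panel in panels:
            if not np.array_equal(panel.locus_ids, locus_ids):
                raise ValueError("panels have different locus sets")
            for pop in np.unique(panel.populations):
                rows = panel.genotypes[panel.populations == pop]
                sums[pop] = sums.get(pop, 0) + rows.sum(axis=0, dtype=np.int64)
                counts[pop] = counts.get(pop, 0) + rows.shape[0]
        freqs = {pop: sums[pop] / (2.0 * counts[pop]) for pop in sums}
        return cls(locus_ids=locus_ids, freqs=freqs)

    def informative_mask(self, populations=None) -> np.ndarray:
        """Loci segregating (0 < p < 1) in every listed population."""
        pops = list(self.freqs) if populations is None else list(populations)
        mask = np.ones(len(self.locus_ids), dtype=bool)
        for pop in pops:
            p = self.freqs[pop]
            mask &= (p > 0.0) & (p < 1.0)
        return mask

    def subset_loci(self, mask_or_index) -> "AlleleFrequencies":
        idx = np.asarray(mask_or_index)
        return AlleleFrequencies(
            locus_ids=self.locus_ids[idx],
            freqs={pop: p[idx] for pop, p in self.freqs.items()},
        )


def read_plink_raw(path) -> GenotypePanel:
    """Read a PLINK ``.raw``-style whitespace table into a panel.

    Expects columns FID IID PAT MAT SEX PHENOTYPE followed by one 0/1/2
    column per SNP.  FID is used as the population label and IID as the
    animal id.
    """
    df = pd.read_csv(path, sep=r"\s+")
    meta = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    snp_cols = [c for c in df.columns if c not in meta]
    return GenotypePanel(
        animal_ids=df["IID"].to_numpy(),
        populations=df["FID"].to_numpy(),
        genotypes=df[snp_cols].to_numpy(dtype=np.int8),
        locus_ids=np.array(snp_cols),
    )


def write_plink_raw(panel: GenotypePanel, path) -> None:
    """Write a panel as a PLINK ``.raw``-style whitespace table."""
    df = pd.DataFrame(panel.genotypes, columns=panel.locus_ids.tolist())
    df.insert(0, "PHENOTYPE", -9)
    df.insert(0, "SEX", 0)
    df.insert(0, "MAT", 0)
    df.insert(0, "PAT", 0)
    df.insert(0, "IID", panel.animal_ids)
    df.insert(0, "FID", panel.populations)
    df.to_csv(path, sep=" ", index=False)


def read_breed_origin(path) -> BreedOriginPanel:
    """Read a breed-origin table: one row per crossbred, column ``id`` then
    two columns per locus named ``<locus>_A`` and ``<locus>_B``."""
    df = pd.read_csv(path, sep=r"\s+")
    a_cols = [c for c in df.columns if c.endswith("_A")]
    b_cols = [c[:-2] + "_B" for c in a_cols]
    locus_ids = np.array([c[:-2] for c in a_cols])
    return BreedOriginPanel(
        animal_ids=df["id"].to_numpy(),
        allele_a=df[a_cols].to_numpy(dtype=np.uint8),
        allele_b=df[b_cols].to_numpy(dtype=np.uint8),
        locus_ids=locus_ids,
    )


def write_breed_origin(origin: BreedOriginPanel, path) -> None:
    cols = {}
    for k, locus in enumerate(origin.locus_ids):
        cols[f"{locus}_A"] = origin.allele_a[:, k]
        cols[f"{locus}_B"] = origin.allele_b[:, k]
    df = pd.DataFrame({"id": origin.animal_ids, **cols})
    df.to_csv(path, sep=" ", index=False)
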