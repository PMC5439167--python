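"""Validation workflow: parametric vs selection-index reliabilities.

Runs simulated replicates of the two-way crossbreeding program and, for
every combination of reference scenario (purebred / crossbred / mixed),
SNP-effect model (across-breed / breed-specific), heritability, genetic
correlation, reference-group size and candidate generation, computes the
reliability of genomic EBV both ways:

* *with data* -- selection-index equations on the realized genomic
  relationship blocks of the replicate;
* *without data* -- parametric equations fed with the same replicate's
  effective-segment numbers (Me), estimated from the variance of the
  differences between the pedigree-base-rescaled genomic block and the
  pedigree block for the same candidate/reference pair.

The breed-specific Me (breed-A segments shared with crossbred reference
animals) is taken equal to the candidates-vs-purebred Me, the study-design
assumption valid when purebred and crossbred reference animals descend from
the same parental pool.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from crossrel import grm, parametric, segments, selection_index
from crossrel.panels import AlleleFrequencies, GenotypePanel
from crossrel.pedigree import build_a_block
from crossrel.simulator import SimConfig, SimOutput, sample_reference_and_candidates, simulate

__all__ = ["ValidationGrid", "run_validation", "summarize"]

RELATEDNESS_DIVERGENCE = {"related": 10, "unrelated": 100}


@dataclass
class ValidationGrid:
    """Factor grid of the validation experiment."""

    scenarios: tuple = ("PB-PB", "CB-PB", "CB+PB-PB")
    models: tuple = ("ASGM", "BSAM")
    heritabilities: tuple = (0.20, 0.40, 0.95)
    r_pc: tuple = (0.3, 0.7)
    reference_groups: tuple = (0, 1)
    candidate_groups: tuple = ("G1", "G2", "G3")
    relatedness: tuple = ("related", "unrelated")
    replicates: int = 10

    def __post_init__(self) -> None:
        for name in ("scenarios", "models", "heritabilities", "r_pc",
                     "reference_groups", "candidate_groups", "relatedness"):
            if not len(getattr(self, name)):
                raise ValueError(f"grid field {name} is empty")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")

    def cells(self):
        """(scenario, model) pairs; the single-breed purebred scenario has
        no breed-specific variant."""
        for scenario in self.scenarios:
            for model in self.models:
                if scenario == "PB-PB" and model == "BSAM":
                    continue
                yield scenario, model


def _stack_candidates(sim: SimOutput, candidates: dict) -> tuple[GenotypePanel, dict]:
    """One breed-A panel over all candidate groups plus per-group slices."""
    panels = []
    slices = {}
    offset = 0
    for g_idx, (gname, ids) in enumerate(sorted(candidates.items())):
        gen = 3 + g_idx
        panels.append(sim.purebred_panels[("breedA", gen)].subset_animals(ids))
        slices[gname] = slice(offset, offset + len(ids))
        offset += len(ids)
    stacked = GenotypePanel(
        animal_ids=np.concatenate([p.animal_ids for p in panels]),
        populations=np.concatenate([p.populations for p in panels]),
        genotypes=np.vstack([p.genotypes for p in panels]),
        locus_ids=panels[0].locus_ids,
        chromosome=panels[0].chromosome,
        position=panels[0].position,
    )
    return stacked, slices


def _me_between(sim: SimOutput, g_cross: np.ndarray, cand_ids, ref_ids) -> float:
    """Variance-of-differences Me between candidates and a reference set.

    The genomic block is rescaled to the pedigree base with the mean
    pedigree inbreeding of the union of the two sets before differencing."""
    a_block = build_a_block(sim.pedigree, cand_ids, ref_ids)
    fbar = float(np.mean(list(a_block.inbreeding.values())))
    g_rescaled = grm.rescale_to_pedigree_base(g_cross, fbar)
    est = segments.me_from_g_a(g_rescaled, a_block.values)
    return est.value


def _asgm_single_pop(sim: SimOutput, ref_ids, cand_panel: GenotypePanel):
    """Joint single-population G over breed A refs and candidates."""
    ref_panel = sim.purebred_panels[("breedA", 2)].subset_animals(ref_ids)
    freqs = AlleleFrequencies.from_panels(ref_panel, cand_panel)
    rel = grm.build_multipop_grm([ref_panel, cand_panel], freqs)
    return rel


def _asgm_two_pop(sim: SimOutput, ref_ab_ids, cand_panel: GenotypePanel):
    ref_panel = sim.crossbred_panels[2].subset_animals(ref_ab_ids)
    freqs = AlleleFrequencies.from_panels(ref_panel, cand_panel)
    rel = grm.build_multipop_grm([ref_panel, cand_panel], freqs)
    return rel


def _bsam_blocks(sim: SimOutput, ref_ab_ids, cand_panel: GenotypePanel,
                 ref_a_ids=None):
    """Breed-of-origin partial blocks for the crossbred reference set,
    candidates and (optionally) the purebred reference set."""
    origin = sim.origin_panels[2].subset_animals(ref_ab_ids)
    pure_a = sim.purebred_panels[("breedA", 2)]
    pure_b = sim.purebred_panels[("breedB", 2)]
    freqs = AlleleFrequencies.from_panels(pure_a, cand_panel, pure_b)
    if ref_a_ids is not None:
        pure_a_refs = pure_a.subset_animals(ref_a_ids)
    else:
        pure_a_refs = pure_a
    return grm.build_partial_grm(origin, pure_a_refs, pure_b, freqs,
                                 candidates_a=cand_panel)


def _evaluate_cell(sim: SimOutput, sets: dict, grid: ValidationGrid,
                   scenario: str, model: str, group: int) -> list[dict]:
    """All grid rows for one (scenario, model, reference-group) cell."""
    cand_panel, slices = _stack_candidates(sim, sets["candidates"])
    cand_ids = cand_panel.animal_ids
    n_a = len(sets.get("refs_A", ()))
    n_ab = len(sets.get("refs_AB", ()))
    rows: list[dict] = []

    def emit(gname, h2, rpc, with_mean, without):
        rows.append({
            "scenario": scenario, "model": model, "group": group,
            "n_ref_A": n_a, "n_ref_AB": n_ab, "h2": h2,
            "r_PC": rpc, "candidate_group": gname,
            "reliability_with": with_mean,
            "reliability_without": without,
            "difference": without - with_mean,
        })

    if scenario == "PB-PB":
        rel = _asgm_single_pop(sim, sets["refs_A"], cand_panel)
        G_AA, G_aA, G_aa = rel["G_00"], rel["G_10"], rel["G_11"]
        me = {g: _me_between(sim, G_aA[sl], cand_ids[sl], sets["refs_A"])
              for g, sl in slices.items()}
        for h2 in grid.heritabilities:
            for rpc in grid.r_pc:
                res = selection_index.rel_pbpb_asgm_with(
                    G_AA, G_aA, np.diag(G_aa), h2, rpc)
                for gname, sl in slices.items():
                    params = parametric.ScenarioParams(
                        N_A=n_a, h2_a=h2, r_PC=rpc, Me_aA=me[gname])
                    emit(gname, h2, rpc,
                         float(np.nanmean(res.per_candidate[sl])),
                         parametric.rel_pbpb_asgm(params))

    elif scenario == "CB-PB" and model == "ASGM":
        rel = _asgm_two_pop(sim, sets["refs_AB"], cand_panel)
        G_ABAB, G_aAB, G_aa = rel["G_00"], rel["G_10"], rel["G_11"]
        me = {g: _me_between(sim, G_aAB[sl], cand_ids[sl], sets["refs_AB"])
              for g, sl in slices.items()}
        for h2 in grid.heritabilities:
            res = selection_index.rel_cbpb_asgm_with(
                G_ABAB, G_aAB, np.diag(G_aa), h2)
            for gname, sl in slices.items():
                params = parametric.ScenarioParams(
                    N_AB=n_ab, h2_c=h2, Me_aAB=me[gname])
                emit(gname, h2, float("nan"),
                     float(np.nanmean(res.per_candidate[sl])),
                     parametric.rel_cbpb_asgm(params))

    elif scenario == "CB-PB" and model == "BSAM":
        rel = _bsam_blocks(sim, sets["refs_AB"], cand_panel)
        me_a = _breed_a_me(sim, sets, cand_panel, slices, n_ab)
        for h2 in grid.heritabilities:
            res = selection_index.rel_cbpb_bsam_with(
                rel["GA_ABAB"], rel["GB_ABAB"], rel["GA_aAB"],
                np.diag(rel["GA_aa"]), h2, h2)
            for gname, sl in slices.items():
                params = parametric.ScenarioParams(
                    N_AB=n_ab, h2_cA=h2, h2_cB=h2, Me_aAB_A=me_a[gname])
                emit(gname, h2, float("nan"),
                     float(np.nanmean(res.per_candidate[sl])),
                     parametric.rel_cbpb_bsam(params))

    elif scenario == "CB+PB-PB" and model == "ASGM":
        ref_a_panel = sim.purebred_panels[("breedA", 2)].subset_animals(sets["refs_A"])
        ref_ab_panel = sim.crossbred_panels[2].subset_animals(sets["refs_AB"])
        freqs = AlleleFrequencies.from_panels(ref_a_panel, ref_ab_panel, cand_panel)
        rel = grm.build_multipop_grm([ref_a_panel, ref_ab_panel, cand_panel], freqs)
        G_AA, G_ABAB, G_A_AB = rel["G_00"], rel["G_11"], rel["G_01"]
        G_aA, G_aAB, G_aa = rel["G_20"], rel["G_21"], rel["G_22"]
        me_pb = {g: _me_between(sim, G_aA[sl], cand_ids[sl], sets["refs_A"])
                 for g, sl in slices.items()}
        me_cb = {g: _me_between(sim, G_aAB[sl], cand_ids[sl], sets["refs_AB"])
                 for g, sl in slices.items()}
        for h2 in grid.heritabilities:
            for rpc in grid.r_pc:
                res = selection_index.rel_mixed_asgm_with(
                    G_AA, G_ABAB, G_A_AB, G_aA, G_aAB, np.diag(G_aa),
                    h2, h2, rpc)
                for gname, sl in slices.items():
                    params = parametric.ScenarioParams(
                        N_A=n_a, N_AB=n_ab, h2_a=h2, h2_c=h2, r_PC=rpc,
                        Me_aA=me_pb[gname], Me_aAB=me_cb[gname])
                    emit(gname, h2, rpc,
                         float(np.nanmean(res.per_candidate[sl])),
                         parametric.rel_mixed_asgm(params))

    elif scenario == "CB+PB-PB" and model == "BSAM":
        rel = _bsam_blocks(sim, sets["refs_AB"], cand_panel,
                           ref_a_ids=sets["refs_A"])
        # purebred-vs-candidate Me on the across-breed G (frequency base of
        # the full genotypes), reused as the breed-A-origin Me
        rel_pb = _asgm_single_pop(sim, sets["refs_A"], cand_panel)
        me_a = {g: _me_between(sim, rel_pb["G_10"][sl], cand_ids[sl],
                               sets["refs_A"])
                for g, sl in slices.items()}
        for h2 in grid.heritabilities:
            for rpc in grid.r_pc:
                res = selection_index.rel_mixed_bsam_with(
                    rel["GA_AA"], rel["GA_ABAB"], rel["GB_ABAB"],
                    rel["GA_AAB"], rel["GA_aA"], rel["GA_aAB"],
                    np.diag(rel["GA_aa"]), h2, h2, h2, rpc)
                for gname, sl in slices.items():
                    params = parametric.ScenarioParams(
                        N_A=n_a, N_AB=n_ab, h2_a=h2, h2_cA=h2, h2_cB=h2,
                        r_PC_A=rpc, Me_aA=me_a[gname], Me_aAB_A=me_a[gname])
                    emit(gname, h2, rpc,
                         float(np.nanmean(res.per_candidate[sl])),
                         parametric.rel_mixed_bsam(params))
    else:  # pragma: no cover - guarded by ValidationGrid.cells
        raise ValueError(f"unsupported cell {scenario}/{model}")
    return rows


def _breed_a_me(sim: SimOutput, sets: dict, cand_panel: GenotypePanel,
                slices: dict, n_ref: int) -> dict:
    """Candidates-vs-purebred Me used as the breed-A-origin Me when the
    scenario has no purebred reference set of its own."""
    pool = sim.purebred_panels[("breedA", 2)].animal_ids
    ref_a = pool[:min(n_ref, len(pool))]
    rel_pb = _asgm_single_pop(sim, ref_a, cand_panel)
    cand_ids = cand_panel.animal_ids
    return {g: _me_between(sim, rel_pb["G_10"][sl], cand_ids[sl], ref_a)
            for g, sl in slices.items()}


def run_validation(grid: ValidationGrid, sim_cfg: SimConfig,
                   seed: int | None = None) -> pd.DataFrame:
    """Run the full validation grid; one row per cell x candidate group.

    Each replicate simulates the configured crossbreeding program once per
    relatedness setting (divergence generations 10 vs 100 by default) and
    evaluates every scenario/model/parameter combination on it.  Me values
    are re-estimated within each replicate.  Cells that fail are flagged in
    the ``error`` column and the run continues.
    """
    all_rows: list[dict] = []
    for rep in range(grid.replicates):
        for rel_label in grid.relatedness:
            cfg = replace(sim_cfg,
                          divergence_generations=RELATEDNESS_DIVERGENCE[rel_label])
            sim = simulate(cfg, seed=seed, replicate=rep)
            rng = np.random.default_rng(
                np.random.SeedSequence([0 if seed is None else seed, rep, 7]))
            for scenario, model in grid.cells():
                for group in grid.reference_groups:
                    sets = sample_reference_and_candidates(sim, scenario, group, rng)
                    try:
                        rows = _evaluate_cell(sim, sets, grid, scenario, model,
                                              group)
                    except Exception as exc:  # noqa: BLE001 - cell isolation
                        rows = [{"scenario": scenario, "model": model,
                                 "group": group, "error": str(exc)}]
                    for row in rows:
                        row.update({"replicate": rep, "relatedness": rel_label})
                        row.setdefault("error", "")
                    all_rows.extend(rows)
    table = pd.DataFrame(all_rows)
    if (table.get("error", pd.Series(dtype=str)) != "").any():
        failed = int((table["error"] != "").sum())
        import warnings

        warnings.warn(f"{failed} validation cells failed", RuntimeWarning,
                      stacklevel=2)
    return table


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and SD across replicates for every grid cell."""
    if table.empty:
        raise ValueError("empty validation table")
    keys = ["relatedness", "scenario", "model", "group", "n_ref_A", "n_ref_AB",
            "h2", "r_PC", "candidate_group"]
    keys = [k for k in keys if k in table.columns]
    ok = table[table.get("error", "") == ""] if "error" in table.columns else table
    agg = ok.groupby(keys, dropna=False).agg(
        reliability_with_mean=("reliability_with", "mean"),
        reliability_with_sd=("reliability_with", "std"),
        reliability_without_mean=("reliability_without", "mean"),
        reliability_without_sd=("reliability_without", "std"),
        difference_mean=("difference", "mean"),
        n_replicates=("replicate", "nunique"),
    ).reset_index()
    single = agg["n_replicates"] == 1
    agg.loc[single, ["reliability_with_sd", "reliability_without_sd"]] = \
        agg.loc[single, ["reliability_with_sd", "reliability_without_sd"]].fillna(0.0)
    return agg
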