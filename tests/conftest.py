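import numpy as np
import pytest

from crossrel.simulator import SimConfig, simulate
from crossrel.validation import ValidationGrid, run_validation


def tiny_sim_config() -> SimConfig:
    """A miniature crossbreeding program that keeps every structural feature
    of the full design (history, divergence, five crossbred cohorts)."""
    return SimConfig(
        generations_constant=10,
        size_constant=60,
        generations_decline=10,
        size_final=40,
        divergence_generations=3,
        breed_founder_males=8,
        breed_founder_females=8,
        breed_males_selected=8,
        breed_females_start=8,
        breed_females_final=10,
        breed_females_ramp_generations=2,
        cross_generations=5,
        cross_males=10,
        cross_females=20,
        crossbred_per_generation=30,
        n_chromosomes=2,
        candidate_snps_per_chromosome=80,
        panel_snps_per_chromosome=30,
        reference_group_sizes=(12, 20),
        candidates_per_generation=8,
    )


@pytest.fixture(scope="session")
def tiny_cfg() -> SimConfig:
    return tiny_sim_config()


@pytest.fixture(scope="session")
def tiny_sim(tiny_cfg):
    return simulate(tiny_cfg, seed=3)


@pytest.fixture(scope="session")
def scaled_validation_table():
    """One scaled replicate of the full validation grid (both relatedness
    settings); shared by the simulation-validation checks."""
    grid = ValidationGrid(replicates=1)
    return run_validation(grid, SimConfig.scaled(), seed=1)


def random_grm_blocks(rng, n_ref, n_cand, m=50):
    """A random PSD genomic matrix partitioned into reference and candidate
    blocks (refs first)."""
    Z = rng.normal(size=(n_ref + n_cand, m))
    G = Z @ Z.T / m
    return {
        "G_RR": G[:n_ref, :n_ref],
        "G_cR": G[n_ref:, :n_ref],
        "diag_c": np.diag(G)[n_ref:],
        "G": G,
    }
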