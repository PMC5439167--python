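"""Selection-index reliabilities vs the GBLUP prediction-error-variance oracle."""

import numpy as np
import pytest

from crossrel.selection_index import (
    ReliabilityResult,
    WeightedPhenotypeSpec,
    asgm_joint_covariance,
    bsam_joint_covariance,
    gblup_pev_reliability,
    rel_cbpb_asgm_with,
    rel_cbpb_bsam_with,
    rel_mixed_asgm_with,
    rel_mixed_bsam_with,
    rel_pbpb_asgm_with,
    rel_weighted_with,
)

from conftest import random_grm_blocks


def naive_pev_reliability(var_y, cov_cy, var_c):
    """Second, fully naive oracle route: explicit matrix inversion."""
    inv = np.linalg.inv(var_y)
    out = np.empty(len(var_c))
    for i in range(len(var_c)):
        out[i] = cov_cy[i] @ inv @ cov_cy[i] / var_c[i]
    return out


def random_two_pop(rng, n_a, n_ab, n_c, m=60):
    Z = rng.normal(size=(n_a + n_ab + n_c, m))
    G = Z @ Z.T / m
    s1, s2 = slice(0, n_a), slice(n_a, n_a + n_ab)
    sc = slice(n_a + n_ab, None)
    return {
        "G_AA": G[s1, s1], "G_ABAB": G[s2, s2], "G_A_AB": G[s1, s2],
        "G_aA": G[sc, s1], "G_aAB": G[sc, s2], "diag": np.diag(G)[sc],
    }


class TestPurebredAsgm:
    def test_unrelated_candidate_gets_zero(self):
        res = rel_pbpb_asgm_with(np.eye(3), np.zeros((2, 3)), np.ones(2),
                                 0.3, 0.7)
        assert np.all(res.per_candidate == 0.0)

    def test_single_reference_genetic_copy(self):
        # one reference that is a genomic copy (g=2), h2=0.5 -> lambda=1
        res = rel_pbpb_asgm_with(np.array([[2.0]]), np.array([[2.0]]),
                                 np.array([2.0]), 0.5, 1.0)
        assert res.per_candidate[0] == pytest.approx(2.0 / 3.0, abs=1e-12)

    def test_rpc_scaling_is_exact(self):
        rng = np.random.default_rng(1)
        blocks = random_grm_blocks(rng, 6, 2)
        base = rel_pbpb_asgm_with(blocks["G_RR"], blocks["G_cR"],
                                  blocks["diag_c"], 0.4, 1.0).per_candidate
        scaled = rel_pbpb_asgm_with(blocks["G_RR"], blocks["G_cR"],
                                    blocks["diag_c"], 0.4, 0.6).per_candidate
        assert np.allclose(scaled, 0.36 * base, atol=1e-14)

    def test_reference_permutation_invariance(self):
        rng = np.random.default_rng(2)
        blocks = random_grm_blocks(rng, 7, 3)
        perm = rng.permutation(7)
        r1 = rel_pbpb_asgm_with(blocks["G_RR"], blocks["G_cR"],
                                blocks["diag_c"], 0.4, 0.8).per_candidate
        r2 = rel_pbpb_asgm_with(blocks["G_RR"][np.ix_(perm, perm)],
                                blocks["G_cR"][:, perm],
                                blocks["diag_c"], 0.4, 0.8).per_candidate
        assert np.allclose(r1, r2, atol=1e-12)

    def test_adding_reference_never_decreases_reliability(self):
        rng = np.random.default_rng(3)
        blocks = random_grm_blocks(rng, 10, 3)
        full = rel_pbpb_asgm_with(blocks["G_RR"], blocks["G_cR"],
                                  blocks["diag_c"], 0.4, 0.8).per_candidate
        sub = rel_pbpb_asgm_with(blocks["G_RR"][:6, :6],
                                 blocks["G_cR"][:, :6],
                                 blocks["diag_c"], 0.4, 0.8).per_candidate
        assert np.all(full >= sub - 1e-12)

    def test_negative_candidate_diagonal_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            rel_pbpb_asgm_with(np.eye(2), np.ones((1, 2)), np.array([-0.1]),
                               0.4, 0.8)


class TestCrossbredAsgm:
    def test_hand_two_reference_instance(self):
        G_ABAB = np.array([[1.0, 0.25], [0.25, 1.0]])
        G_aAB = np.array([[0.5, 0.3]])
        h2 = 0.4
        lam = (1 - h2) / h2
        expected = G_aAB[0] @ np.linalg.inv(G_ABAB + lam * np.eye(2)) @ G_aAB[0]
        res = rel_cbpb_asgm_with(G_ABAB, G_aAB, np.array([1.1]), h2)
        assert res.per_candidate[0] == pytest.approx(expected / 1.1, abs=1e-12)

    def test_zero_relationships_zero_reliability(self):
        res = rel_cbpb_asgm_with(np.eye(4), np.zeros((2, 4)), np.ones(2), 0.3)
        assert np.all(res.per_candidate == 0.0)


class TestOracleEquivalence:
    """Each closed form must agree with the PEV conditioning oracle, which
    itself agrees with a naive explicit-inverse implementation."""

    def test_purebred_asgm(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            n_ref = int(rng.integers(5, 20))
            blocks = random_grm_blocks(rng, n_ref, int(rng.integers(1, 5)))
            h2 = float(rng.uniform(0.05, 1.0))
            rpc = float(rng.uniform(-1, 1))
            closed = rel_pbpb_asgm_with(blocks["G_RR"], blocks["G_cR"],
                                        blocks["diag_c"], h2, rpc).per_candidate
            vy, cov, vc = asgm_joint_covariance(
                blocks["G_RR"], None, None, blocks["G_cR"], None,
                blocks["diag_c"], h2, h2, rpc)
            oracle = gblup_pev_reliability(vy, cov, vc).per_candidate
            assert np.allclose(closed, oracle, atol=1e-8)
            assert np.allclose(oracle, naive_pev_reliability(vy, cov, vc),
                               atol=1e-10)

    def test_crossbred_asgm(self):
        rng = np.random.default_rng(11)
        for _ in range(25):
            blocks = random_grm_blocks(rng, int(rng.integers(5, 20)),
                                       int(rng.integers(1, 5)))
            h2 = float(rng.uniform(0.05, 1.0))
            closed = rel_cbpb_asgm_with(blocks["G_RR"], blocks["G_cR"],
                                        blocks["diag_c"], h2).per_candidate
            vy, cov, vc = asgm_joint_covariance(
                None, blocks["G_RR"], None, None, blocks["G_cR"],
                blocks["diag_c"], None, h2, 0.0)
            oracle = gblup_pev_reliability(vy, cov, vc).per_candidate
            assert np.allclose(closed, oracle, atol=1e-8)

    def test_mixed_asgm(self):
        rng = np.random.default_rng(12)
        for _ in range(25):
            b = random_two_pop(rng, int(rng.integers(3, 10)),
                               int(rng.integers(3, 10)), int(rng.integers(1, 4)))
            h2a, h2c = rng.uniform(0.05, 0.99, 2)
            rpc = float(rng.uniform(-1, 1))
            closed = rel_mixed_asgm_with(
                b["G_AA"], b["G_ABAB"], b["G_A_AB"], b["G_aA"], b["G_aAB"],
                b["diag"], h2a, h2c, rpc).per_candidate
            vy, cov, vc = asgm_joint_covariance(
                b["G_AA"], b["G_ABAB"], b["G_A_AB"], b["G_aA"], b["G_aAB"],
                b["diag"], h2a, h2c, rpc)
            oracle = gblup_pev_reliability(vy, cov, vc).per_candidate
            assert np.allclose(closed, oracle, atol=1e-8)

    def test_crossbred_bsam(self):
        rng = np.random.default_rng(13)
        for _ in range(25):
            n_ab = int(rng.integers(5, 15))
            n_c = int(rng.integers(1, 4))
            bA = random_grm_blocks(rng, n_ab, n_c)
            GB = random_grm_blocks(rng, n_ab, 0)["G_RR"]
            h2ca, h2cb = rng.uniform(0.05, 0.9, 2)
            closed = rel_cbpb_bsam_with(bA["G_RR"], GB, bA["G_cR"],
                                        bA["diag_c"], h2ca, h2cb).per_candidate
            vy, cov, vc = bsam_joint_covariance(
                None, bA["G_RR"], GB, None, None, bA["G_cR"], bA["diag_c"],
                None, h2ca, h2cb, 0.0)
            oracle = gblup_pev_reliability(vy, cov, vc).per_candidate
            assert np.allclose(closed, oracle, atol=1e-8)

    def test_mixed_bsam(self):
        rng = np.random.default_rng(14)
        for _ in range(25):
            n_a = int(rng.integers(3, 8))
            n_ab = int(rng.integers(3, 8))
            b = random_two_pop(rng, n_a, n_ab, int(rng.integers(1, 4)))
            GB = random_grm_blocks(rng, n_ab, 0)["G_RR"]
            h2aa, h2ca, h2cb = rng.uniform(0.05, 0.9, 3)
            rpca = float(rng.uniform(-1, 1))
            closed = rel_mixed_bsam_with(
                b["G_AA"], b["G_ABAB"], GB, b["G_A_AB"], b["G_aA"],
                b["G_aAB"], b["diag"], h2aa, h2ca, h2cb, rpca).per_candidate
            vy, cov, vc = bsam_joint_covariance(
                b["G_AA"], b["G_ABAB"], GB, b["G_A_AB"], b["G_aA"],
                b["G_aAB"], b["diag"], h2aa, h2ca, h2cb, rpca)
            oracle = gblup_pev_reliability(vy, cov, vc).per_candidate
            assert np.allclose(closed, oracle, atol=1e-8)


class TestReductions:
    def test_mixed_asgm_zero_rpc_reduces_to_crossbred_only(self):
        rng = np.random.default_rng(20)
        b = random_two_pop(rng, 5, 6, 3)
        mixed = rel_mixed_asgm_with(b["G_AA"], b["G_ABAB"], b["G_A_AB"],
                                    b["G_aA"], b["G_aAB"], b["diag"],
                                    0.4, 0.3, 0.0).per_candidate
        cb = rel_cbpb_asgm_with(b["G_ABAB"], b["G_aAB"], b["diag"],
                                0.3).per_candidate
        assert np.allclose(mixed, cb, atol=1e-10)

    def test_mixed_bsam_zero_rpc_reduces_to_crossbred_only(self):
        rng = np.random.default_rng(21)
        b = random_two_pop(rng, 5, 6, 3)
        GB = random_grm_blocks(rng, 6, 0)["G_RR"]
        mixed = rel_mixed_bsam_with(b["G_AA"], b["G_ABAB"], GB, b["G_A_AB"],
                                    b["G_aA"], b["G_aAB"], b["diag"],
                                    0.4, 0.3, 0.3, 0.0).per_candidate
        cb = rel_cbpb_bsam_with(b["G_ABAB"], GB, b["G_aAB"], b["diag"],
                                0.3, 0.3).per_candidate
        assert np.allclose(mixed, cb, atol=1e-10)

    def test_bsam_degenerate_b_limit_matches_direct_system(self):
        # with GB = 0 and h2_cB = 0 the BSAM system is an ASGM-like system
        # with shrinkage (1 - h2_cA/2)/h2_cA
        rng = np.random.default_rng(22)
        bA = random_grm_blocks(rng, 6, 2)
        h2ca = 0.4
        closed = rel_cbpb_bsam_with(bA["G_RR"], np.zeros((6, 6)), bA["G_cR"],
                                    bA["diag_c"], h2ca, 0.0).per_candidate
        lhs = bA["G_RR"] + (1 - 0.5 * h2ca) / h2ca * np.eye(6)
        expected = np.array([
            bA["G_cR"][i] @ np.linalg.inv(lhs) @ bA["G_cR"][i] / bA["diag_c"][i]
            for i in range(2)
        ])
        assert np.allclose(closed, expected, atol=1e-10)


class TestWeightedRecords:
    def test_identity_weights_reproduce_plain_equation(self):
        rng = np.random.default_rng(30)
        blocks = random_grm_blocks(rng, 6, 2)
        spec = WeightedPhenotypeSpec(np.arange(6), np.ones(6))
        weighted = rel_weighted_with(blocks["G_RR"], blocks["G_cR"],
                                     blocks["diag_c"], 0.4, 0.8, spec).per_candidate
        plain = rel_pbpb_asgm_with(blocks["G_RR"], blocks["G_cR"],
                                   blocks["diag_c"], 0.4, 0.8).per_candidate
        assert np.array_equal(weighted, plain)

    def test_duplicated_records_increase_reliability(self):
        rng = np.random.default_rng(31)
        blocks = random_grm_blocks(rng, 5, 2)
        single = rel_weighted_with(blocks["G_RR"], blocks["G_cR"],
                                   blocks["diag_c"], 0.4, 0.8,
                                   WeightedPhenotypeSpec(np.arange(5),
                                                         np.ones(5)))
        double = rel_weighted_with(blocks["G_RR"], blocks["G_cR"],
                                   blocks["diag_c"], 0.4, 0.8,
                                   WeightedPhenotypeSpec(
                                       np.repeat(np.arange(5), 2), np.ones(10)))
        assert np.all(double.per_candidate > single.per_candidate)

    def test_weighted_matches_dense_solve_oracle(self):
        rng = np.random.default_rng(32)
        blocks = random_grm_blocks(rng, 4, 2)
        rec_map = np.array([0, 0, 1, 2, 3, 3])
        weights = np.array([1.0, 1.0, 0.5, 2.0, 1.0, 0.25])
        spec = WeightedPhenotypeSpec(rec_map, weights)
        h2, rpc = 0.3, 0.9
        W = np.zeros((6, 4))
        W[np.arange(6), rec_map] = 1.0
        lhs = W @ blocks["G_RR"] @ W.T + (1 - h2) / h2 * np.diag(weights)
        expected = np.array([
            rpc**2 * blocks["G_cR"][i] @ W.T @ np.linalg.inv(lhs) @ W
            @ blocks["G_cR"][i] / blocks["diag_c"][i]
            for i in range(2)
        ])
        res = rel_weighted_with(blocks["G_RR"], blocks["G_cR"],
                                blocks["diag_c"], h2, rpc, spec)
        assert np.allclose(res.per_candidate, expected, atol=1e-10)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            WeightedPhenotypeSpec(np.array([0]), np.array([0.0]))


class TestGblupOracle:
    def test_single_animal_own_record(self):
        for h2 in (0.2, 0.5, 0.95):
            vy = np.array([[1.0]])  # unit phenotypic variance
            cov = np.array([[h2]])  # own genetic effect, G diag = 1
            res = gblup_pev_reliability(vy, cov, np.array([h2]))
            assert res.per_candidate[0] == pytest.approx(h2, abs=1e-12)

    def test_no_phenotyped_animals(self):
        res = gblup_pev_reliability(np.zeros((0, 0)), np.zeros((2, 0)),
                                    np.array([0.3, 0.3]))
        assert np.all(res.per_candidate == 0.0)

    def test_non_psd_covariance_rejected(self):
        vy = np.array([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValueError, match="PSD"):
            gblup_pev_reliability(vy, np.array([[0.1, 0.1]]), np.array([1.0]))


def test_reliability_result_bounds_enforced():
    with pytest.raises(ValueError):
        ReliabilityResult(np.array([1.5]))
    res = ReliabilityResult(np.array([0.25, 0.75]))
    assert res.mean == pytest.approx(0.5)
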