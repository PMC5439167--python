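"""Selection-index reliabilities of genomic EBV ("with genotype data").

Once genotypes of reference animals and selection candidates exist, the
reliability of each candidate's genomic EBV for crossbred performance
follows from selection-index (SI) theory: the candidate's relationship row
into the reference set, solved against the reference-side coefficient
matrix (relationships plus a heritability shrinkage on the diagonal),
divided by the candidate's own genomic diagonal.

The reference-side matrix is factorized once per call (Cholesky) and shared
across candidates; no explicit inverse is formed.  ``gblup_pev_reliability``
implements the equivalent prediction-error-variance route on the raw
variance-component scale and serves as the independent cross-check for the
closed forms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

__all__ = [
    "ReliabilityResult",
    "WeightedPhenotypeSpec",
    "rel_pbpb_asgm_with",
    "rel_cbpb_asgm_with",
    "rel_cbpb_bsam_with",
    "rel_mixed_asgm_with",
    "rel_mixed_bsam_with",
    "rel_weighted_with",
    "gblup_pev_reliability",
]

_DIAG_TOL = 1e-8


@dataclass
class ReliabilityResult:
    """Per-candidate reliabilities plus their mean."""

    per_candidate: np.ndarray
    candidate_ids: np.ndarray | None = None
    scenario: str = ""
    model: str = ""
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.per_candidate = np.asarray(self.per_candidate, dtype=float)
        finite = self.per_candidate[np.isfinite(self.per_candidate)]
        if finite.size and (finite.min() < -1e-8 or finite.max() > 1.0 + 1e-8):
            raise ValueError("per-candidate reliability outside [0, 1]")

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.per_candidate))


@dataclass
class WeightedPhenotypeSpec:
    """Map from (pseudo-)phenotype records to reference animals.

    ``record_to_ref[r]`` is the reference-animal index of record ``r``;
    ``r_diag[r]`` is the diagonal of the residual weight matrix R (1 for a
    raw record, 1/weight for a deregressed proof)."""

    record_to_ref: np.ndarray
    r_diag: np.ndarray

    def __post_init__(self) -> None:
        self.record_to_ref = np.asarray(self.record_to_ref, dtype=np.int64)
        self.r_diag = np.asarray(self.r_diag, dtype=float)
        if self.record_to_ref.shape != self.r_diag.shape:
            raise ValueError("record map and weights differ in length")
        if (self.r_diag <= 0).any():
            raise ValueError("record weights must be positive")

    def incidence(self, n_ref: int) -> np.ndarray:
        if self.record_to_ref.size and self.record_to_ref.max() >= n_ref:
            raise ValueError("record maps to a non-existent reference animal")
        W = np.zeros((len(self.record_to_ref), n_ref))
        W[np.arange(len(self.record_to_ref)), self.record_to_ref] = 1.0
        return W


def _lambda(h2: float) -> float:
    if not 0.0 < h2 <= 1.0:
        raise ValueError(f"heritability {h2} outside (0, 1]")
    return (1.0 - h2) / h2


def _solve_quadratic(lhs: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """q_i' lhs^-1 q_i for every column q_i of rhs, via one factorization."""
    try:
        cf = linalg.cho_factor(lhs)
    except linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular reference system: {exc}") from exc
    sol = linalg.cho_solve(cf, rhs)
    return np.einsum("ij,ij->j", rhs, sol)


def _per_candidate(numerators: np.ndarray, diag: np.ndarray, ids) -> np.ndarray:
    diag = np.asarray(diag, dtype=float)
    out = np.full(diag.shape, np.nan)
    bad = diag < _DIAG_TOL
    if bad.any() and (diag < 0).any():
        i = int(np.argmax(diag < 0))
        name = ids[i] if ids is not None else i
        raise ValueError(f"candidate {name!r} has non-positive genomic diagonal")
    out[~bad] = numerators[~bad] / diag[~bad]
    return out


def rel_pbpb_asgm_with(
    G_AA: np.ndarray,
    G_aA: np.ndarray,
    g_aa_diag: np.ndarray,
    h2_a: float,
    r_PC: float,
    candidate_ids=None,
) -> ReliabilityResult:
    """Purebred reference, across-breed model:
    r2_i = r_PC^2 G_aiA (G_AA + I(1-h2)/h2)^-1 G_Aai / G_aiai."""
    G_AA = np.asarray(G_AA, dtype=float)
    G_aA = np.atleast_2d(np.asarray(G_aA, dtype=float))
    lhs = G_AA + _lambda(h2_a) * np.eye(G_AA.shape[0])
    quad = _solve_quadratic(lhs, G_aA.T)
    rel = _per_candidate(r_PC**2 * quad, g_aa_diag, candidate_ids)
    return ReliabilityResult(rel, candidate_ids, scenario="PB-PB", model="ASGM",
                             params={"h2_a": h2_a, "r_PC": r_PC})


def rel_cbpb_asgm_with(
    G_ABAB: np.ndarray,
    G_aAB: np.ndarray,
    g_aa_diag: np.ndarray,
    h2_c: float,
    candidate_ids=None,
) -> ReliabilityResult:
    """Crossbred reference, across-breed model."""
    G_ABAB = np.asarray(G_ABAB, dtype=float)
    G_aAB = np.atleast_2d(np.asarray(G_aAB, dtype=float))
    lhs = G_ABAB + _lambda(h2_c) * np.eye(G_ABAB.shape[0])
    quad = _solve_quadratic(lhs, G_aAB.T)
    rel = _per_candidate(quad, g_aa_diag, candidate_ids)
    return ReliabilityResult(rel, candidate_ids, scenario="CB-PB", model="ASGM",
                             params={"h2_c": h2_c})


def rel_cbpb_bsam_with(
    GA_ABAB: np.ndarray,
    GB_ABAB: np.ndarray,
    GA_aAB: np.ndarray,
    gA_aa_diag: np.ndarray,
    h2_cA: float,
    h2_cB: float,
    candidate_ids=None,
) -> ReliabilityResult:
    """Crossbred reference, breed-specific model.

    The reference-side matrix mixes the two partial GRMs weighted by the
    breed-specific heritabilities plus the residual shrinkage
    (1 - h2_cA/2 - h2_cB/2)/h2_cA."""
    if not 0.0 < h2_cA <= 1.0:
        raise ValueError(f"h2_cA {h2_cA} outside (0, 1]")
    GA = np.asarray(GA_ABAB, dtype=float)
    GB = np.asarray(GB_ABAB, dtype=float)
    GA_aAB = np.atleast_2d(np.asarray(GA_aAB, dtype=float))
    shrink = (1.0 - 0.5 * h2_cA - 0.5 * h2_cB) / h2_cA
    lhs = GA + GB * (h2_cB / h2_cA) + shrink * np.eye(GA.shape[0])
    quad = _solve_quadratic(lhs, GA_aAB.T)
    rel = _per_candidate(quad, gA_aa_diag, candidate_ids)
    return ReliabilityResult(rel, candidate_ids, scenario="CB-PB", model="BSAM",
                             params={"h2_cA": h2_cA, "h2_cB": h2_cB})


def rel_mixed_asgm_with(
    G_AA: np.ndarray,
    G_ABAB: np.ndarray,
    G_A_AB: np.ndarray,
    G_aA: np.ndarray,
    G_aAB: np.ndarray,
    g_aa_diag: np.ndarray,
    h2_a: float,
    h2_c: float,
    r_PC: float,
    candidate_ids=None,
) -> ReliabilityResult:
    """Purebred + crossbred reference, across-breed model (block SI system).

    The off-diagonal reference block is r_PC * G_A,AB and the candidate row
    is [r_PC G_aiA, G_aiAB]; one factorization of the joint block matrix is
    reused across candidates."""
    G_AA = np.asarray(G_AA, dtype=float)
    G_ABAB = np.asarray(G_ABAB, dtype=float)
    G_A_AB = np.asarray(G_A_AB, dtype=float)
    G_aA = np.atleast_2d(np.asarray(G_aA, dtype=float))
    G_aAB = np.atleast_2d(np.asarray(G_aAB, dtype=float))
    lhs = np.block([
        [G_AA + _lambda(h2_a) * np.eye(G_AA.shape[0]), r_PC * G_A_AB],
        [r_PC * G_A_AB.T, G_ABAB + _lambda(h2_c) * np.eye(G_ABAB.shape[0])],
    ])
    rhs = np.hstack([r_PC * G_aA, G_aAB]).T
    quad = _solve_quadratic(lhs, rhs)
    rel = _per_candidate(quad, g_aa_diag, candidate_ids)
    return ReliabilityResult(rel, candidate_ids, scenario="CB+PB-PB", model="ASGM",
                             params={"h2_a": h2_a, "h2_c": h2_c, "r_PC": r_PC})


def rel_mixed_bsam_with(
    GA_AA: np.ndarray,
    GA_ABAB: np.ndarray,
    GB_ABAB: np.ndarray,
    GA_A_AB: np.ndarray,
    GA_aA: np.ndarray,
    GA_aAB: np.ndarray,
    gA_aa_diag: np.ndarray,
    h2_aA: float,
    h2_cA: float,
    h2_cB: float,
    r_PC_A: float,
    candidate_ids=None,
) -> ReliabilityResult:
    """Purebred + crossbred reference, breed-specific model (block system).

    All blocks are breed-A partial relationships except GB_ABAB, which
    enters the crossbred diagonal block weighted by h2_cB/h2_cA."""
    if not 0.0 < h2_cA <= 1.0:
        raise ValueError(f"h2_cA {h2_cA} outside (0, 1]")
    GA_AA = np.asarray(GA_AA, dtype=float)
    GA_ABAB = np.asarray(GA_ABAB, dtype=float)
    GB_ABAB = np.asarray(GB_ABAB, dtype=float)
    GA_A_AB = np.asarray(GA_A_AB, dtype=float)
    GA_aA = np.atleast_2d(np.asarray(GA_aA, dtype=float))
    GA_aAB = np.atleast_2d(np.asarray(GA_aAB, dtype=float))
    shrink = (1.0 - 0.5 * h2_cA - 0.5 * h2_cB) / h2_cA
    lhs = np.block([
        [GA_AA + _lambda(h2_aA) * np.eye(GA_AA.shape[0]), r_PC_A * GA_A_AB],
        [r_PC_A * GA_A_AB.T, GA_ABAB + GB_ABAB * (h2_cB / h2_cA)
         + shrink * np.eye(GA_ABAB.shape[0])],
    ])
    rhs = np.hstack([r_PC_A * GA_aA, GA_aAB]).T
    quad = _solve_quadratic(lhs, rhs)
    rel = _per_candidate(quad, gA_aa_diag, candidate_ids)
    return ReliabilityResult(rel, candidate_ids, scenario="CB+PB-PB", model="BSAM",
                             params={"h2_aA": h2_aA, "h2_cA": h2_cA,
                                     "h2_cB": h2_cB, "r_PC_A": r_PC_A})


def rel_weighted_with(
    G_AA: np.ndarray,
    G_aA: np.ndarray,
    g_aa_diag: np.ndarray,
    h2: float,
    r_PC: float,
    spec: WeightedPhenotypeSpec,
    candidate_ids=None,
) -> ReliabilityResult:
    """Purebred-reference reliability with repeated or pseudo-phenotypes.

    r2_i = r_PC^2 G_aiA W'(W G_AA W' + R (1-h2)/h2)^-1 W G_Aai / G_aiai,
    with W the record-to-animal incidence matrix and R the diagonal record
    weight matrix.  With W = I and R = I this is the plain purebred
    selection-index reliability."""
    G_AA = np.asarray(G_AA, dtype=float)
    G_aA = np.atleast_2d(np.asarray(G_aA, dtype=float))
    W = spec.incidence(G_AA.shape[0])
    lhs = W @ G_AA @ W.T + _lambda(h2) * np.diag(spec.r_diag)
    rhs = W @ G_aA.T
    quad = _solve_quadratic(lhs, rhs)
    rel = _per_candidate(r_PC**2 * quad, g_aa_diag, candidate_ids)
    return ReliabilityResult(rel, candidate_ids, scenario="PB-PB",
                             model="ASGM-weighted",
                             params={"h2": h2, "r_PC": r_PC})


def gblup_pev_reliability(
    var_y: np.ndarray,
    cov_cy: np.ndarray,
    var_c: np.ndarray,
    candidate_ids=None,
    scenario: str = "",
    model: str = "",
) -> ReliabilityResult:
    """Reliability from GBLUP prediction error variance, by conditioning.

    Given the joint covariance of the reference phenotypes ``var_y``
    (genetic covariances plus residuals, on the variance-component scale),
    the covariance ``cov_cy`` between each candidate's target genetic effect
    and the phenotypes, and the target-effect variances ``var_c``:

        PEV_i = Var_i - cov_i' Var(y)^-1 cov_i,   r2_i = 1 - PEV_i / Var_i.

    With no phenotyped animals every reliability is 0; a single animal with
    its own record and unit genomic diagonal recovers r2 = h2.
    """
    var_y = np.asarray(var_y, dtype=float)
    cov_cy = np.atleast_2d(np.asarray(cov_cy, dtype=float))
    var_c = np.asarray(var_c, dtype=float)
    if var_y.size == 0:
        return ReliabilityResult(np.zeros_like(var_c), candidate_ids,
                                 scenario=scenario, model=model)
    eig_min = linalg.eigvalsh(var_y)[0]
    if eig_min < -1e-8 * max(1.0, np.abs(var_y).max()):
        raise ValueError("phenotype covariance matrix is not PSD")
    quad = _solve_quadratic(var_y, cov_cy.T)
    rel = _per_candidate(quad, var_c, candidate_ids)
    return ReliabilityResult(rel, candidate_ids, scenario=scenario, model=model)


def asgm_joint_covariance(
    G_AA: np.ndarray | None,
    G_ABAB: np.ndarray | None,
    G_A_AB: np.ndarray | None,
    G_aA: np.ndarray | None,
    G_aAB: np.ndarray | None,
    g_aa_diag: np.ndarray,
    h2_a: float | None,
    h2_c: float,
    r_PC: float,
):
    """Assemble (var_y, cov_cy, var_c) for the across-breed model.

    Phenotypic variances are set to 1 for both traits, so sigma2_a = h2_a,
    sigma2_c = h2_c and sigma_ac = r_PC sqrt(h2_a h2_c).  Pass ``None`` for
    the blocks of an absent reference source."""
    parts_y = []
    parts_c = []
    g_aa_diag = np.asarray(g_aa_diag, dtype=float)
    n_cand = g_aa_diag.shape[0]
    if G_AA is not None:
        s_ac = r_PC * math.sqrt(h2_a * h2_c)
        vy_a = np.asarray(G_AA) * h2_a + (1.0 - h2_a) * np.eye(len(G_AA))
        parts_y.append(("A", vy_a))
        parts_c.append(np.asarray(G_aA) * s_ac)
    if G_ABAB is not None:
        vy_c = np.asarray(G_ABAB) * h2_c + (1.0 - h2_c) * np.eye(len(G_ABAB))
        parts_y.append(("AB", vy_c))
        parts_c.append(np.asarray(G_aAB) * h2_c)
    if not parts_y:
        return np.zeros((0, 0)), np.zeros((n_cand, 0)), g_aa_diag * h2_c
    if len(parts_y) == 2:
        s_ac = r_PC * math.sqrt(h2_a * h2_c)
        off = np.asarray(G_A_AB) * s_ac
        var_y = np.block([[parts_y[0][1], off], [off.T, parts_y[1][1]]])
        cov_cy = np.hstack(parts_c)
    else:
        var_y = parts_y[0][1]
        cov_cy = parts_c[0]
    return var_y, cov_cy, g_aa_diag * h2_c


def bsam_joint_covariance(
    GA_AA: np.ndarray | None,
    GA_ABAB: np.ndarray,
    GB_ABAB: np.ndarray,
    GA_A_AB: np.ndarray | None,
    GA_aA: np.ndarray | None,
    GA_aAB: np.ndarray,
    gA_aa_diag: np.ndarray,
    h2_aA: float | None,
    h2_cA: float,
    h2_cB: float,
    r_PC_A: float,
):
    """Assemble (var_y, cov_cy, var_c) for the breed-specific model.

    Crossbred phenotypic variance is 1, so sigma2_cA = h2_cA, sigma2_cB =
    h2_cB and sigma2_eAB = 1 - h2_cA/2 - h2_cB/2; purebred phenotypic
    variance is 1 with sigma2_aA = h2_aA.  The target effect is the
    candidate's breed-A-origin genetic effect with variance
    G^(A)_aiai sigma2_cA."""
    gA_aa_diag = np.asarray(gA_aa_diag, dtype=float)
    s2_eAB = 1.0 - 0.5 * h2_cA - 0.5 * h2_cB
    vy_ab = (np.asarray(GA_ABAB) * h2_cA + np.asarray(GB_ABAB) * h2_cB
             + s2_eAB * np.eye(len(GA_ABAB)))
    cov_ab = np.asarray(GA_aAB) * h2_cA
    if GA_AA is None:
        return vy_ab, cov_ab, gA_aa_diag * h2_cA
    s_ac = r_PC_A * math.sqrt(h2_aA * h2_cA)
    vy_a = np.asarray(GA_AA) * h2_aA + (1.0 - h2_aA) * np.eye(len(GA_AA))
    off = np.asarray(GA_A_AB) * s_ac
    var_y = np.block([[vy_a, off], [off.T, vy_ab]])
    cov_cy = np.hstack([np.asarray(GA_aA) * s_ac, cov_ab])
    return var_y, cov_cy, gA_aa_diag * h2_cA
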