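"""Parametric ("no genotype data yet") reliability prediction equations.

When designing a breeding program the genotypes of future reference animals
and candidates do not exist, so the reliability of genomic EBV for crossbred
performance has to be predicted from population parameters alone: reference
sizes N, heritabilities h2, the purebred-crossbred genetic correlation r_PC,
and the effective number of chromosome segments Me.

Five predictors are provided, one per reference-population scenario and
SNP-effect model:

========================  ===========================================
purebred-only, ASGM       ``rel_pbpb_asgm``   r_PC^2 N h2 / (N h2 + Me)
crossbred-only, ASGM      ``rel_cbpb_asgm``   N h2 / (N h2 + Me)
crossbred-only, BSAM      ``rel_cbpb_bsam``   N h2_cA / (N h2_cA + 2 Me^(A))
mixed reference, ASGM     ``rel_mixed_asgm``  b' Q^-1 b (two sources)
mixed reference, BSAM     ``rel_mixed_bsam``  b' Q^-1 b (two sources)
========================  ===========================================

The factor 2 in the breed-specific equations accounts for the doubled
number of allele substitution effects fitted when every crossbred allele
gets a breed-of-origin-specific effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ScenarioParams",
    "h2_breed_specific",
    "rel_pbpb_asgm",
    "rel_cbpb_asgm",
    "rel_cbpb_bsam",
    "rel_mixed_asgm",
    "rel_mixed_bsam",
    "pig_program_sweep",
    "break_even_rpc",
]

_COND_LIMIT = 1e12


@dataclass
class ScenarioParams:
    """Scalar population parameters for the parametric predictors.

    Any subset may be filled; each predictor validates the fields it needs
    and raises naming a missing one.  If the raw variance components are
    supplied, the derived heritabilities/correlations must match the scalar
    fields (checked to 1e-10).

    Fields
    ------
    N_A, N_AB:
        Number of purebred (breed A) and crossbred (AB) reference animals.
    h2_a, h2_c:
        Heritability of purebred and crossbred performance.
    h2_cA, h2_cB:
        Breed-specific heritabilities of crossbred performance
        (sigma2_cX / (sigma2_cA/2 + sigma2_cB/2 + sigma2_eAB)).
    r_PC, r_PC_A:
        Genetic correlation between purebred and crossbred performance
        (across-breed, and breed-A-specific).
    Me_aA, Me_aAB, Me_aAB_A:
        Effective chromosome segments shared by candidates with purebred
        refs, with crossbred refs, and (breed-A origin only) with crossbred
        refs.
    """

    N_A: float | None = None
    N_AB: float | None = None
    h2_a: float | None = None
    h2_c: float | None = None
    h2_cA: float | None = None
    h2_cB: float | None = None
    r_PC: float | None = None
    r_PC_A: float | None = None
    Me_aA: float | None = None
    Me_aAB: float | None = None
    Me_aAB_A: float | None = None
    variance_components: dict | None = None

    def __post_init__(self) -> None:
        for name in ("h2_a", "h2_c", "h2_cA", "h2_cB"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("r_PC", "r_PC_A"):
            v = getattr(self, name)
            if v is not None and not -1.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [-1, 1]")
        for name in ("Me_aA", "Me_aAB", "Me_aAB_A"):
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ValueError(f"{name}={v} must be positive")
        for name in ("N_A", "N_AB"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{name}={v} must be non-negative")
        if self.variance_components:
            self._check_variance_components()

    def _check_variance_components(self) -> None:
        vc = self.variance_components
        tol = 1e-10

        def close(a, b):
            return a is None or abs(a - b) <= tol

        if {"s2_a", "s2_eA"} <= vc.keys():
            h2 = vc["s2_a"] / (vc["s2_a"] + vc["s2_eA"])
            if not close(self.h2_a, h2):
                raise ValueError("h2_a inconsistent with variance components")
        if {"s2_c", "s2_eAB"} <= vc.keys():
            h2 = vc["s2_c"] / (vc["s2_c"] + vc["s2_eAB"])
            if not close(self.h2_c, h2):
                raise ValueError("h2_c inconsistent with variance components")
        if {"s2_a", "s2_c", "s_ac"} <= vc.keys():
            r = vc["s_ac"] / math.sqrt(vc["s2_a"] * vc["s2_c"])
            if not close(self.r_PC, r):
                raise ValueError("r_PC inconsistent with variance components")
        if {"s2_cA", "s2_cB", "s2_eAB"} <= vc.keys():
            h2a, h2b = h2_breed_specific(vc["s2_cA"], vc["s2_cB"], vc["s2_eAB"])
            if not (close(self.h2_cA, h2a) and close(self.h2_cB, h2b)):
                raise ValueError("breed-specific h2 inconsistent with variance components")

    def require(self, *names: str) -> list[float]:
        vals = []
        for name in names:
            v = getattr(self, name)
            if v is None:
                raise ValueError(f"missing required parameter {name!r}")
            vals.append(v)
        return vals


def h2_breed_specific(sigma2_cA: float, sigma2_cB: float,
                      sigma2_eAB: float) -> tuple[float, float]:
    """Breed-specific heritabilities of crossbred performance.

    h2_cX = sigma2_cX / (sigma2_cA/2 + sigma2_cB/2 + sigma2_eAB); an F1
    carries half its additive variance from each parental breed, so the
    denominator is the crossbred phenotypic variance.
    """
    if sigma2_cA < 0 or sigma2_cB < 0 or sigma2_eAB < 0:
        raise ValueError("variances must be non-negative")
    denom = 0.5 * sigma2_cA + 0.5 * sigma2_cB + sigma2_eAB
    if denom <= 0:
        raise ValueError("crossbred phenotypic variance is zero")
    return sigma2_cA / denom, sigma2_cB / denom


def _daetwyler(n: float, h2: float, me: float) -> float:
    if n == 0 or h2 == 0:
        return 0.0
    return n * h2 / (n * h2 + me)


def rel_pbpb_asgm(params: ScenarioParams) -> float:
    """Purebred-only reference, across-breed model:
    r2 = r_PC^2 * N_A h2_a / (N_A h2_a + Me_aA)."""
    n, h2, rpc, me = params.require("N_A", "h2_a", "r_PC", "Me_aA")
    return rpc**2 * _daetwyler(n, h2, me)


def rel_cbpb_asgm(params: ScenarioParams) -> float:
    """Crossbred-only reference, across-breed model:
    r2 = N_AB h2_c / (N_AB h2_c + Me_aAB)."""
    n, h2, me = params.require("N_AB", "h2_c", "Me_aAB")
    return _daetwyler(n, h2, me)


def rel_cbpb_bsam(params: ScenarioParams, simplified: bool = True,
                  tol: float = 1e-10, max_iter: int = 100) -> float:
    """Crossbred-only reference, breed-specific model:
    r2 = N_AB h2_cA / (N_AB h2_cA + 2 Me^(A)_aAB).

    With ``simplified=False`` the self-referential form retaining the
    ``(1 - h2_cA r2/2 - h2_cB r2/2)`` error-variance reduction is solved by
    fixed-point iteration started at the simplified value (the same
    reliability is assumed for the effects of both breeds).
    """
    n, h2ca, me = params.require("N_AB", "h2_cA", "Me_aAB_A")
    r = _daetwyler(n, h2ca, 2.0 * me)
    if simplified:
        return r
    (h2cb,) = params.require("h2_cB")
    for _ in range(max_iter):
        shrink = 1.0 - 0.5 * h2ca * r - 0.5 * h2cb * r
        r_new = _daetwyler(n, h2ca, 2.0 * me * shrink)
        if abs(r_new - r) < tol:
            return r_new
        r = r_new
    raise RuntimeError("fixed-point iteration for the full BSAM equation did not converge")


def _two_source(b1: float, q11: float, b2: float, q22: float, q12: float,
                n1: float, n2: float) -> float:
    """b' Q^-1 b for the two-information-source parametric system.

    Q = [[q11 + 1/n1, q12], [q12, q22 + 1/n2]].  A source with n = 0 is
    dropped (its equation degenerates as 1/n -> inf)."""
    if n1 == 0 and n2 == 0:
        return 0.0
    if n1 == 0:
        return b2**2 / (q22 + 1.0 / n2)
    if n2 == 0:
        return b1**2 / (q11 + 1.0 / n1)
    Q = np.array([[q11 + 1.0 / n1, q12], [q12, q22 + 1.0 / n2]])
    if np.linalg.cond(Q) > _COND_LIMIT:
        raise np.linalg.LinAlgError("two-source system is numerically singular")
    b = np.array([b1, b2])
    return float(b @ np.linalg.solve(Q, b))


def rel_mixed_asgm(params: ScenarioParams) -> float:
    """Purebred + crossbred reference, across-breed model.

    Information from N_A purebred records (weighted by r_PC) and N_AB
    crossbred records is combined in a 2x2 selection-index system on the
    scale of effects per chromosome segment."""
    h2a, h2c, rpc, me_a, me_c = params.require("h2_a", "h2_c", "r_PC", "Me_aA", "Me_aAB")
    n_a = params.N_A or 0.0
    n_ab = params.N_AB or 0.0
    b1 = rpc * math.sqrt(h2a / me_a)
    b2 = math.sqrt(h2c / me_c)
    q12 = rpc * math.sqrt(h2a * h2c / (me_a * me_c))
    return _two_source(b1, h2a / me_a, b2, h2c / me_c, q12, n_a, n_ab)


def rel_mixed_bsam(params: ScenarioParams) -> float:
    """Purebred + crossbred reference, breed-specific model.

    Same two-source system with the crossbred source carrying
    h2_cA / (2 Me^(A)_aAB) and the breed-A-specific correlation r_PC^(A)."""
    h2a, h2ca, rpc, me_a, me_c = params.require(
        "h2_a", "h2_cA", "r_PC_A", "Me_aA", "Me_aAB_A"
    )
    n_a = params.N_A or 0.0
    n_ab = params.N_AB or 0.0
    u = h2ca / (2.0 * me_c)
    b1 = rpc * math.sqrt(h2a / me_a)
    b2 = math.sqrt(u)
    q12 = rpc * math.sqrt(u * h2a / me_a)
    return _two_source(b1, h2a / me_a, b2, u, q12, n_a, n_ab)


def pig_program_sweep(
    n_a: float = 10000,
    n_ab_grid=tuple(range(0, 10001, 1000)),
    r_pc_a_grid=tuple(np.round(np.arange(0.0, 1.01, 0.1), 2)),
    h2: float = 0.2,
    me: float = 476.6,
) -> pd.DataFrame:
    """Reliability surface for adding crossbreds to a purebred reference.

    Evaluates the mixed-reference breed-specific predictor over a grid of
    crossbred reference sizes and breed-A purebred-crossbred correlations,
    with a fixed purebred reference and equal heritabilities and Me for
    both sources.  One row per (N_AB, r_PC_A).
    """
    n_ab_grid = list(n_ab_grid)
    r_pc_a_grid = list(r_pc_a_grid)
    if not n_ab_grid or not r_pc_a_grid:
        raise ValueError("grids must be non-empty")
    rows = []
    for rpc in r_pc_a_grid:
        for n_ab in n_ab_grid:
            params = ScenarioParams(
                N_A=n_a, N_AB=n_ab, h2_a=h2, h2_cA=h2, r_PC_A=rpc,
                Me_aA=me, Me_aAB_A=me,
            )
            rows.append({"N_AB": n_ab, "r_PC_A": rpc,
                         "reliability": rel_mixed_bsam(params)})
    return pd.DataFrame(rows)


def break_even_rpc(n: float, h2: float, me: float) -> float:
    """Genetic correlation at which a purebred-only across-breed reference
    matches a crossbred-only breed-specific reference of the same size.

    Setting r_PC^2 N h2/(N h2 + Me) = N h2/(N h2 + 2 Me) gives
    r_PC = sqrt((N h2 + Me) / (N h2 + 2 Me))."""
    if n <= 0 or h2 <= 0 or me <= 0:
        raise ValueError("N, h2 and Me must be positive")
    return math.sqrt((n * h2 + me) / (n * h2 + 2.0 * me))
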