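"""Effective number of independently segregating chromosome segments (Me).

Me governs how many "effective" marker effects a reference population has
to estimate, and therefore drives every parametric reliability equation.
Two estimators are provided:

* ``me_from_g_a`` -- the reciprocal of the empirical variance of the
  element-wise differences between a (pedigree-base rescaled) genomic
  relationship block and the corresponding pedigree relationship block,
  computed between selection candidates and reference animals.
* ``me_from_ne_l`` -- the population-genetics closed form
  ``Me = 2 Ne L / ln(4 Ne L)`` from the effective population size and the
  genome length in Morgan.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = ["MeEstimate", "me_from_g_a", "me_from_ne_l", "me_partial_from_g_a"]


@dataclass
class MeEstimate:
    """An Me value with its provenance.

    ``infinite`` flags a zero variance of G - A differences (G coincides
    with A), in which case ``value`` is ``math.inf``.
    """

    value: float
    method: str  # {"variance_of_differences", "ne_l_formula", "assumed"}
    n_entries: int = 0
    infinite: bool = False

    def __post_init__(self) -> None:
        if not self.infinite and not self.value > 0:
            raise ValueError("Me must be positive")


def me_from_g_a(G: np.ndarray, A: np.ndarray, ddof: int = 1) -> MeEstimate:
    """Me = 1 / var(G - A) over all entries of the difference block.

    ``G`` must already be rescaled to the pedigree base.  The variance uses
    denominator ``n - ddof`` (default: the sample variance, n - 1).
    """
    G = np.asarray(G, dtype=float)
    A = np.asarray(A, dtype=float)
    if G.shape != A.shape:
        raise ValueError(f"blocks not conformable: {G.shape} vs {A.shape}")
    diff = (G - A).ravel()
    if diff.size < 2:
        raise ValueError("need at least 2 entries to estimate a variance")
    var = float(np.var(diff, ddof=ddof))
    if var == 0.0:
        return MeEstimate(value=math.inf, method="variance_of_differences",
                          n_entries=diff.size, infinite=True)
    return MeEstimate(value=1.0 / var, method="variance_of_differences",
                      n_entries=diff.size)


def me_from_ne_l(ne: float, genome_length: float) -> MeEstimate:
    """Me = 2 Ne L / ln(4 Ne L), L in Morgan."""
    if ne <= 0 or genome_length <= 0:
        raise ValueError("Ne and L must be positive")
    x = 4.0 * ne * genome_length
    if x <= 1.0:
        raise ValueError("4 Ne L must exceed 1 for the formula to be defined")
    return MeEstimate(value=2.0 * ne * genome_length / math.log(x),
                      method="ne_l_formula")


def me_partial_from_g_a(G_partial: np.ndarray, A: np.ndarray,
                        ddof: int = 1) -> MeEstimate:
    """Experimental: variance-of-differences Me on a breed-origin partial
    genomic block against half the pedigree block.

    The partial relationship of a crossbred with a purebred relative tracks
    only the alleles of that purebred's breed, i.e. half of the expected
    numerator relationship, so A is halved before differencing.  Provided
    for exploration only; the validation workflow instead assumes the
    breed-specific Me equals the purebred-vs-candidate Me (the study-design
    assumption when purebred and crossbred reference animals share parents).
    """
    return me_from_g_a(np.asarray(G_partial, dtype=float),
                       0.5 * np.asarray(A, dtype=float), ddof=ddof)
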