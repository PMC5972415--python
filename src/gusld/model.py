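"""Probability kernels for two-locus linkage disequilibrium under HWE.

The population model: at two biallelic loci with reference-allele
frequencies ``pA1`` and ``pA2``, the four haplotype frequencies are

    P(A1A2) = pA1*pA2 + D      P(A1B2) = pA1*(1-pA2) - D
    P(B1A2) = (1-pA1)*pA2 - D  P(B1B2) = (1-pA1)*(1-pA2) + D

where ``D`` is the disequilibrium coefficient. Under random mating each
individual draws two haplotypes independently, which induces the 3x3
table of unphased joint genotype probabilities (the double heterozygote
pools the coupling and repulsion phases).

The observation model: the reference-allele read count at one locus in
one individual is a binomial sample of size ``d`` (the sequencing depth)
whose success probability depends on the latent genotype — ``1 - eps``
for the reference homozygote, ``1/2`` for the heterozygote and ``eps``
for the alternate homozygote, where ``eps`` is the per-read sequencing
error rate. A depth of zero carries no information (likelihood 1 under
every genotype).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, xlog1py, xlogy

__all__ = [
    "LDParams",
    "GENOTYPES",
    "d_bounds",
    "haplotype_freqs",
    "joint_genotype_probs",
    "genotype_read_probs",
    "read_count_prob",
    "log_binom_coeff",
]

#: genotype codes, indexed by the number of *alternate* alleles:
#: 0 = AA (ref hom), 1 = AB (het), 2 = BB (alt hom)
GENOTYPES = ("AA", "AB", "BB")

# reference-allele indicator of each haplotype (A1A2, A1B2, B1A2, B1B2)
# at locus 1 and locus 2; used to collapse ordered haplotype pairs onto
# unphased genotypes
_HAP_A1 = np.array([1, 1, 0, 0])
_HAP_A2 = np.array([1, 0, 1, 0])
# genotype row/col index (0=AA, 1=AB, 2=BB) for each ordered pair of haplotypes
_PAIR_G1 = 2 - (_HAP_A1[:, None] + _HAP_A1[None, :])
_PAIR_G2 = 2 - (_HAP_A2[:, None] + _HAP_A2[None, :])


class ConstraintError(ValueError):
    """Parameter vector violates the model's feasibility constraints."""


def d_bounds(pA1: float, pA2: float) -> tuple[float, float]:
    """Feasible range of the disequilibrium coefficient D.

    Haplotype frequencies must be non-negative, so D is confined to

        max(-pA1*pA2, -(1-pA1)*(1-pA2)) <= D <= min(pA1*(1-pA2), pA2*(1-pA1))

    Parameters
    ----------
    pA1, pA2
        Reference-allele frequencies, strictly inside (0, 1).

    Returns
    -------
    (Dmin, Dmax) with Dmin < 0 < Dmax.
    """
    if not (0.0 < pA1 < 1.0 and 0.0 < pA2 < 1.0):
        raise ConstraintError(
            f"allele frequencies must lie strictly in (0,1); got "
            f"pA1={pA1!r}, pA2={pA2!r} (monomorphic locus?)"
        )
    qA1, qA2 = 1.0 - pA1, 1.0 - pA2
    dmin = max(-pA1 * pA2, -qA1 * qA2)
    dmax = min(pA1 * qA2, pA2 * qA1)
    return dmin, dmax


@dataclass(frozen=True)
class LDParams:
    """Model parameter vector (pA1, pA2, D, eps).

    Attributes
    ----------
    pA1, pA2 : float
        Reference-allele frequencies at the two loci, in (0, 1).
    D : float
        Disequilibrium coefficient; must lie within ``d_bounds(pA1, pA2)``.
    eps : float
        Per-read sequencing error rate, in [0, 0.5). At 0.5 the three
        genotype read models coincide and the model is unidentifiable.
    """

    pA1: float
    pA2: float
    D: float = 0.0
    eps: float = 0.0

    def __post_init__(self) -> None:
        dmin, dmax = d_bounds(self.pA1, self.pA2)  # validates frequencies
        if not (dmin - 1e-12 <= self.D <= dmax + 1e-12):
            raise ConstraintError(
                f"D={self.D} outside feasible range [{dmin:.6g}, {dmax:.6g}] "
                f"for pA1={self.pA1}, pA2={self.pA2}"
            )
        if not (0.0 <= self.eps < 0.5):
            raise ConstraintError(f"eps must be in [0, 0.5); got {self.eps}")


def haplotype_freqs(params: LDParams) -> np.ndarray:
    """Frequencies of the four haplotypes (A1A2, A1B2, B1A2, B1B2)."""
    p1, p2, D = params.pA1, params.pA2, params.D
    q1, q2 = 1.0 - p1, 1.0 - p2
    h = np.array([p1 * p2 + D, p1 * q2 - D, q1 * p2 - D, q1 * q2 + D])
    # D within bounds guarantees non-negativity up to rounding
    return np.clip(h, 0.0, None)


def joint_genotype_probs(params: LDParams) -> np.ndarray:
    """3x3 joint genotype probabilities under HWE with disequilibrium.

    Rows index the genotype at locus 1 and columns at locus 2, both in
    the order (AA, AB, BB). Obtained by drawing two haplotypes
    independently from :func:`haplotype_freqs` and collapsing ordered
    pairs onto unphased genotypes; the double heterozygote (row AB,
    col AB) therefore pools the coupling and repulsion phases.
    """
    h = haplotype_freqs(params)
    pair = np.outer(h, h)
    out = np.zeros((3, 3))
    np.add.at(out, (_PAIR_G1, _PAIR_G2), pair)
    return out


def genotype_read_probs(eps: float) -> np.ndarray:
    """Per-read reference-allele probability for genotypes (AA, AB, BB)."""
    return np.array([1.0 - eps, 0.5, eps])


def log_binom_coeff(y: np.ndarray, d: np.ndarray) -> np.ndarray:
    """log C(d, y), computed via gammaln so large depths do not overflow."""
    y = np.asarray(y, dtype=float)
    d = np.asarray(d, dtype=float)
    return gammaln(d + 1.0) - gammaln(y + 1.0) - gammaln(d - y + 1.0)


def read_count_prob(y, d, genotype: str, eps: float):
    """P(reference read count = y | depth d, latent genotype, error rate eps).

    Binomial with success probability ``1-eps`` (AA), ``1/2`` (AB) or
    ``eps`` (BB). ``d = 0`` returns 1 for every genotype: an unobserved
    site carries no information. Accepts scalars or arrays.
    """
    y_arr = np.asarray(y)
    d_arr = np.asarray(d)
    if np.any(d_arr < 0) or np.any(y_arr < 0) or np.any(y_arr > d_arr):
        raise ValueError("require 0 <= y <= d and d >= 0")
    if not (0.0 <= eps < 0.5):
        raise ValueError(f"eps must be in [0, 0.5); got {eps}")
    try:
        g = GENOTYPES.index(genotype)
    except ValueError:
        raise ValueError(f"genotype must be one of {GENOTYPES}; got {genotype!r}")
    q = genotype_read_probs(eps)[g]
    logp = (
        log_binom_coeff(y_arr, d_arr)
        + xlogy(np.asarray(y_arr, dtype=float), q)
        + xlog1py(np.asarray(d_arr - y_arr, dtype=float), -q)
    )
    out = np.exp(logp)
    return float(out) if np.isscalar(y) and np.isscalar(d) else out
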