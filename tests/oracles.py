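"""Independent reference implementations used only to check the package.

These deliberately avoid the package's computational paths: genotype
probabilities come from literal enumeration of the 16 ordered haplotype
pairs, read probabilities from scipy.stats.binom, and the genotype-table
MLE from an EM algorithm over haplotype frequencies.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binom

# haplotypes: (ref at locus1, ref at locus2) for A1A2, A1B2, B1A2, B1B2
HAPS = [(1, 1), (1, 0), (0, 1), (0, 0)]


def haplotype_freq_list(p1: float, p2: float, D: float) -> list[float]:
    return [
        p1 * p2 + D,
        p1 * (1 - p2) - D,
        (1 - p1) * p2 - D,
        (1 - p1) * (1 - p2) + D,
    ]


def enum_joint_genotype_probs(p1: float, p2: float, D: float) -> np.ndarray:
    """3x3 joint genotype probabilities by brute-force enumeration of
    ordered haplotype pairs (genotype = ref-allele dosage)."""
    h = haplotype_freq_list(p1, p2, D)
    P = np.zeros((3, 3))
    for a in range(4):
        for b in range(4):
            g1 = 2 - (HAPS[a][0] + HAPS[b][0])
            g2 = 2 - (HAPS[a][1] + HAPS[b][1])
            P[g1, g2] += h[a] * h[b]
    return P


def read_prob(y: int, d: int, g: int, eps: float) -> float:
    """Binomial read-count probability; g is alt-allele dosage 0/1/2."""
    q = [1.0 - eps, 0.5, eps][g]
    return float(binom.pmf(y, d, q))


def brute_force_loglik(y1, d1, y2, d2, p1, p2, D, eps) -> float:
    """Literal double-loop evaluation of the latent-genotype likelihood."""
    P = enum_joint_genotype_probs(p1, p2, D)
    total = 0.0
    for i in range(len(y1)):
        s = 0.0
        for g1 in range(3):
            for g2 in range(3):
                s += (
                    read_prob(int(y1[i]), int(d1[i]), g1, eps)
                    * read_prob(int(y2[i]), int(d2[i]), g2, eps)
                    * P[g1, g2]
                )
        total += np.log(s) if s > 0 else -np.inf
    return total


def em_haplotype_freqs(
    table: np.ndarray,
    tol: float = 1e-13,
    max_iter: int = 20000,
    starts: int = 3,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """EM MLE of the four haplotype frequencies from a complete 3x3
    joint-genotype count table (rows/cols: ref-hom, het, alt-hom).

    Only the double-heterozygote cell has ambiguous phase; the E-step
    splits it between coupling and repulsion by their current odds.
    Returns (h, loglik); the best of several starts is kept.
    """
    table = np.asarray(table, dtype=float)
    n2 = 2.0 * table.sum()
    rng = np.random.default_rng(seed)

    # haplotype contribution of each unambiguous cell: counts of
    # (A1A2, A1B2, B1A2, B1B2) per individual
    fixed = {
        (0, 0): (2, 0, 0, 0), (0, 1): (1, 1, 0, 0), (0, 2): (0, 2, 0, 0),
        (1, 0): (1, 0, 1, 0), (1, 2): (0, 1, 0, 1),
        (2, 0): (0, 0, 2, 0), (2, 1): (0, 0, 1, 1), (2, 2): (0, 0, 0, 2),
    }

    def loglik(h):
        P = np.zeros((3, 3))
        for (g1, g2), c in fixed.items():
            # product of the two contributing haplotype freqs, with the
            # ordered-pair factor 2 for heterozygous composition
            idx = [k for k, m in enumerate(c) for _ in range(m)]
            P[g1, g2] = h[idx[0]] * h[idx[1]] * (1 if idx[0] == idx[1] else 2)
        P[1, 1] = 2 * h[0] * h[3] + 2 * h[1] * h[2]
        with np.errstate(divide="ignore"):
            lp = np.where(table > 0, np.log(np.where(P > 0, P, 1.0)), 0.0)
        if np.any((table > 0) & (P <= 0)):
            return -np.inf
        return float((table * lp).sum())

    best_h, best_ll = None, -np.inf
    for s in range(starts):
        h = np.full(4, 0.25) if s == 0 else rng.dirichlet(np.ones(4))
        for _ in range(max_iter):
            counts = np.zeros(4)
            for (g1, g2), c in fixed.items():
                counts += table[g1, g2] * np.asarray(c, dtype=float)
            denom = h[0] * h[3] + h[1] * h[2]
            w = 0.5 if denom == 0 else h[0] * h[3] / denom
            counts += table[1, 1] * np.array([w, 1 - w, 1 - w, w])
            new_h = counts / n2
            if np.max(np.abs(new_h - h)) < tol:
                h = new_h
                break
            h = new_h
        ll = loglik(h)
        if ll > best_ll:
            best_h, best_ll = h, ll
    return best_h, best_ll


def em_ld_estimates(table: np.ndarray, **kw) -> dict[str, float]:
    """p1, p2 and D implied by the EM haplotype-frequency MLE."""
    h, ll = em_haplotype_freqs(table, **kw)
    p1 = h[0] + h[1]
    p2 = h[0] + h[2]
    return {"p1": p1, "p2": p2, "D": h[0] - p1 * p2, "loglik": ll}
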