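"""Synthetic sequencing-data generator and Monte-Carlo experiments.

Each simulated individual draws two haplotypes i.i.d. from the
haplotype frequencies implied by (pA1, pA2, D), giving a joint
genotype. Per locus, a sequencing depth is drawn from a Poisson
distribution and alleles are then sampled from the genotype with equal
probability and replacement, each read miscalled (flipped to the other
allele) with probability eps. A depth of zero yields a missing
observation. For a fixed genotype the per-read flip construction
collapses to a binomial reference-read count with success probability
1-eps (ref hom), 1/2 (het) or eps (alt hom); the default fast path
samples that binomial directly, and a literal per-read path is kept for
validation — the two are distributionally identical.

Two experiment designs:

* :func:`run_bias_experiment` — fixed sample size across a grid of
  mean depths and true-parameter cells; summarizes bias and SE of the
  LD measures (and of the error-rate estimate) for both the full-model
  and genotype-call estimators.
* :func:`run_fixed_effort_experiment` — holds total sequencing effort
  (individuals x loci x mean depth) constant, trading depth against
  sample size, and summarizes mean square errors.

Default study conditions: eps = 0.01, 100 individuals, depth grid
(1, 2, 3, 4, 5, 7.5, 10, 15), effort 600 reads over two loci.
Replicates default to 1000 per cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimation import (
    EstimationError,
    PairCounts,
    fit_gusld,
    fit_standard,
    naive_genotype_calls,
)
from .model import LDParams, d_bounds, genotype_read_probs, haplotype_freqs

__all__ = [
    "SimConfig",
    "DEPTH_GRID",
    "PARAMETER_CELLS",
    "simulate_pair",
    "run_bias_experiment",
    "run_fixed_effort_experiment",
    "fixed_effort_sample_sizes",
]

#: mean read depths used throughout the simulation studies
DEPTH_GRID = (1.0, 2.0, 3.0, 4.0, 5.0, 7.5, 10.0, 15.0)

#: the three allele-frequency scenarios with their true-D grids
PARAMETER_CELLS = {
    1: {"pA1": 0.5, "pA2": 0.5, "D": (-0.15, 0.0, 0.05, 0.15, 0.25)},
    2: {"pA1": 0.5, "pA2": 0.75, "D": (-0.01, 0.0, 0.05, 0.1, 0.125)},
    3: {"pA1": 0.9, "pA2": 0.9, "D": (-0.01, 0.03, 0.06, 0.09)},
}


@dataclass(frozen=True)
class SimConfig:
    """Truth and sampling configuration for one simulation cell."""

    n: int = 100
    pA1: float = 0.5
    pA2: float = 0.5
    D: float = 0.0
    eps: float = 0.01
    mu1: float = 2.0      # mean depth at locus 1 (Poisson mean)
    mu2: float = 2.0
    replicates: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        dmin, dmax = d_bounds(self.pA1, self.pA2)
        if not (dmin - 1e-12 <= self.D <= dmax + 1e-12):
            raise ValueError(f"D={self.D} outside [{dmin:.6g}, {dmax:.6g}]")
        if not (0.0 <= self.eps < 0.5):
            raise ValueError(f"eps must be in [0, 0.5); got {self.eps}")
        if self.mu1 < 0 or self.mu2 < 0:
            raise ValueError("mean depths must be >= 0")
        if self.n < 2:
            raise ValueError("need n >= 2")

    @property
    def params(self) -> LDParams:
        return LDParams(self.pA1, self.pA2, self.D, self.eps)


def simulate_pair(
    config: SimConfig,
    rng: np.random.Generator | None = None,
    per_read: bool = False,
) -> tuple[PairCounts, np.ndarray]:
    """Simulate read counts for one pair of loci.

    Returns the counts and the true genotype codes, an (n, 2) array
    with 0=AA, 1=AB, 2=BB per locus. With ``per_read=True`` the reads
    are sampled literally one allele at a time with per-read error
    flips (slow; for validation of the binomial fast path).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h = haplotype_freqs(config.params)
    h = h / h.sum()
    # haplotype index 0..3 = (A1A2, A1B2, B1A2, B1B2); ref indicator per locus
    hap = rng.choice(4, size=(config.n, 2), p=h)
    ref1 = (hap < 2).sum(axis=1)          # ref-allele dosage at locus 1
    ref2 = (hap % 2 == 0).sum(axis=1)
    geno = np.stack([2 - ref1, 2 - ref2], axis=1)  # 0=AA, 1=AB, 2=BB

    q = genotype_read_probs(config.eps)
    counts = []
    for j, mu in enumerate((config.mu1, config.mu2)):
        d = rng.poisson(mu, size=config.n)
        if per_read:
            y = np.zeros(config.n, dtype=np.int64)
            for i in range(config.n):
                if d[i] == 0:
                    continue
                # sample alleles from the genotype with replacement ...
                is_ref = rng.random(d[i]) < (2 - geno[i, j]) / 2.0
                # ... then flip each read with probability eps
                flip = rng.random(d[i]) < config.eps
                y[i] = int(np.sum(is_ref ^ flip))
        else:
            y = rng.binomial(d, q[geno[:, j]])
        counts.append((y, d))
    (y1, d1), (y2, d2) = counts
    return PairCounts(y1, d1, y2, d2), geno


# ---------------------------------------------------------------------------
# experiment machinery

_MEASURES = ("D", "Dprime", "r2", "eps")


def _true_measures(config: SimConfig) -> dict[str, float]:
    from .estimation import d_prime, r_squared

    return {
        "D": config.D,
        "Dprime": d_prime(config.D, config.pA1, config.pA2),
        "r2": r_squared(config.D, config.pA1, config.pA2),
        "eps": config.eps,
    }


def _run_cell(config: SimConfig, seed_seq: np.random.SeedSequence) -> pd.DataFrame:
    """Fit both estimators on each replicate of one cell and summarize.

    SE is the population (ddof=0) standard deviation of the estimates,
    so bias^2 + SE^2 = MSE holds as an exact identity.
    """
    rngs = [np.random.default_rng(s) for s in seed_seq.spawn(config.replicates)]
    est: dict[str, dict[str, list[float]]] = {
        m: {meas: [] for meas in _MEASURES} for m in ("gusld", "standard")
    }
    failures = {"gusld": 0, "standard": 0}
    for rng in rngs:
        counts, _ = simulate_pair(config, rng=rng)
        try:
            g = fit_gusld(counts)
            est["gusld"]["D"].append(g.D_hat)
            est["gusld"]["Dprime"].append(g.d_prime)
            est["gusld"]["r2"].append(g.r2)
            est["gusld"]["eps"].append(g.eps_hat)
        except EstimationError:
            failures["gusld"] += 1
        try:
            calls1 = naive_genotype_calls(counts.y1, counts.d1)
            calls2 = naive_genotype_calls(counts.y2, counts.d2)
            s = fit_standard(calls1, calls2)
            est["standard"]["D"].append(s.D_hat)
            est["standard"]["Dprime"].append(s.d_prime)
            est["standard"]["r2"].append(s.r2)
        except EstimationError:
            failures["standard"] += 1

    truth = _true_measures(config)
    rows = []
    for method in ("gusld", "standard"):
        for measure in _MEASURES:
            vals = np.asarray(est[method][measure], dtype=float)
            if measure == "eps" and method == "standard":
                continue  # the baseline does not estimate an error rate
            if vals.size == 0:
                continue
            err = vals - truth[measure]
            bias = float(err.mean())
            se = float(vals.std(ddof=0))
            mse = float((err**2).mean())
            rows.append({
                "mu": config.mu1, "n": config.n,
                "pA1": config.pA1, "pA2": config.pA2, "D_true": config.D,
                "eps_true": config.eps, "method": method, "measure": measure,
                "truth": truth[measure], "bias": bias, "se": se, "mse": mse,
                "mcse_bias": se / np.sqrt(vals.size),
                "mcse_se": se / np.sqrt(2 * max(vals.size - 1, 1)),
                "mcse_mse": float((err**2).std(ddof=0)) / np.sqrt(vals.size),
                "n_ok": int(vals.size), "n_fail": failures[method],
            })
    return pd.DataFrame(rows)


def run_bias_experiment(
    depths=DEPTH_GRID,
    cells=((0.5, 0.5, 0.15),),
    n: int = 100,
    eps: float = 0.01,
    replicates: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Bias/SE of both estimators over a depth x parameter grid.

    ``cells`` is an iterable of (pA1, pA2, D) truth triples. Returns a
    tidy frame, one row per (depth, cell, method, measure), with the
    bias, SE, MSE and their Monte-Carlo standard errors. Per-replicate
    fit failures are counted in ``n_fail`` and excluded from the
    summaries. Deterministic given ``seed``.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    root = np.random.SeedSequence(seed)
    out = []
    for ci, (pA1, pA2, D) in enumerate(cells):
        for di, mu in enumerate(depths):
            cfg = SimConfig(n=n, pA1=pA1, pA2=pA2, D=D, eps=eps,
                            mu1=mu, mu2=mu, replicates=replicates)
            out.append(_run_cell(cfg, np.random.SeedSequence((seed, ci, di))))
    return pd.concat(out, ignore_index=True)


def fixed_effort_sample_sizes(effort: float, depths=DEPTH_GRID, n_loci: int = 2):
    """Sample size per depth holding effort = n * loci * depth fixed."""
    return [max(2, round(effort / (n_loci * mu))) for mu in depths]


def run_fixed_effort_experiment(
    effort: float = 600.0,
    depths=DEPTH_GRID,
    cells=((0.5, 0.5, 0.15),),
    eps: float = 0.01,
    replicates: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """MSE of both estimators at constant total sequencing effort.

    Sequencing effort is individuals x loci x mean depth; for each mean
    depth the sample size is ``round(effort / (2 * depth))`` (two
    loci), so at effort 600 the depth grid (1, 2, 3, 4, 5, 7.5, 10, 15)
    runs with 300, 150, 100, 75, 60, 40, 30 and 20 individuals.
    """
    if replicates < 2:
        raise ValueError("need at least 2 replicates")
    ns = fixed_effort_sample_sizes(effort, depths)
    out = []
    for ci, (pA1, pA2, D) in enumerate(cells):
        for di, (mu, n) in enumerate(zip(depths, ns)):
            cfg = SimConfig(n=n, pA1=pA1, pA2=pA2, D=D, eps=eps,
                            mu1=mu, mu2=mu, replicates=replicates)
            out.append(_run_cell(cfg, np.random.SeedSequence((seed, 1000 + ci, di))))
    return pd.concat(out, ignore_index=True)
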