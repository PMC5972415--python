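"""Pairwise LD estimation from allele read counts.

Two estimators share one optimizer:

* :func:`fit_gusld` — the full model. The latent joint genotype of each
  individual is summed out of the likelihood, so undercalled
  heterozygotes (allelic dropout at low depth) and per-read sequencing
  errors are accounted for. Four parameters are estimated jointly:
  the two reference-allele frequencies, the disequilibrium coefficient
  D, and the sequencing error rate eps.

* :func:`fit_standard` — the classical genotype-based likelihood that
  treats naive genotype calls as the true genotypes (no error model).
  It maximizes the multinomial likelihood of the observed 3x3 joint
  genotype table under the HWE joint-genotype probabilities.

Both apply the small-sample bias correction D_hat = D_raw * 2n/(2n-1)
(n = individuals observed at both loci) clamped to the feasible range,
and derive Lewontin's D' and the squared allelic correlation r^2 from
the corrected D and the frequency MLEs.

The frequency-dependent constraint Dmin(p) <= D <= Dmax(p) is enforced
by construction: the optimizer works on (logit pA1, logit pA2, t,
logit 2*eps) with D = Dmin + sigmoid(t) * (Dmax - Dmin) recomputed from
the current frequencies at every evaluation, turning a moving-boundary
problem into smooth box-bounded optimization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit, xlog1py, xlogy

from .model import ConstraintError, LDParams, d_bounds, log_binom_coeff

__all__ = [
    "PairCounts",
    "LDEstimate",
    "EstimationError",
    "MonomorphicLocusError",
    "pair_log_likelihood",
    "fit_gusld",
    "fit_standard",
    "naive_genotype_call",
    "naive_genotype_calls",
    "genotype_table",
    "bias_correct",
    "d_prime",
    "r_squared",
    "pairwise_ld",
]

MISSING = -1  # genotype-call code for depth-zero observations

#: snap tolerance: fitted D this close to a feasibility boundary is
#: reported at the boundary exactly, so D' = +/-1 comes out exact
_BOUNDARY_SNAP = 1e-6

_X_FREQ_BOUND = 12.0   # |logit p| bound: p within ~6e-6 of (0,1)
_T_BOUND = 30.0        # sigmoid(30) ~ 1 - 1e-13: D can reach its bounds
_EPS_LO, _EPS_HI = 1e-9, 0.49


class EstimationError(RuntimeError):
    """Estimation cannot proceed on this input."""


class MonomorphicLocusError(EstimationError):
    """A locus carries only one allele, so LD is undefined."""


@dataclass(frozen=True)
class PairCounts:
    """Observed read counts for one pair of loci.

    ``y1[i]``/``y2[i]`` are reference-allele read counts for individual
    ``i`` at locus 1/2 and ``d1``/``d2`` the total depths; ``d == 0``
    marks a missing observation.
    """

    y1: np.ndarray
    d1: np.ndarray
    y2: np.ndarray
    d2: np.ndarray

    def __post_init__(self) -> None:
        for name in ("y1", "d1", "y2", "d2"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=np.int64))
        n = self.y1.shape[0]
        if n < 2:
            raise ValueError("need at least 2 individuals")
        if not (self.d1.shape == self.y2.shape == self.d2.shape == (n,)):
            raise ValueError("y1, d1, y2, d2 must be 1-D and equal length")
        for y, d, j in ((self.y1, self.d1, 1), (self.y2, self.d2, 2)):
            if np.any(d < 0) or np.any(y < 0) or np.any(y > d):
                raise ValueError(f"require 0 <= y <= d at locus {j}")

    @property
    def n(self) -> int:
        return self.y1.shape[0]

    @property
    def n_used(self) -> int:
        """Individuals with nonzero depth at both loci (bias-correction n)."""
        return int(np.sum((self.d1 > 0) & (self.d2 > 0)))


@dataclass(frozen=True)
class LDEstimate:
    """Fitted LD parameters and derived measures for one locus pair."""

    pA1_hat: float
    pA2_hat: float
    D_hat: float          # bias-corrected
    D_raw: float          # maximum-likelihood estimate before correction
    d_prime: float        # signed Lewontin D'
    r2: float
    loglik: float
    n_used: int
    converged: bool
    eps_hat: float | None = None  # absent for the genotype-call baseline
    method: str = "gusld"


def _joint_probs_from_haplotypes(h: np.ndarray) -> np.ndarray:
    """3x3 genotype table from haplotype freqs (A1A2, A1B2, B1A2, B1B2),
    two independent draws collapsed in closed form; the double
    heterozygote pools the coupling and repulsion phases. Identical to
    :func:`gusld.model.joint_genotype_probs` (asserted in tests) but
    cheap enough for an optimizer inner loop."""
    h1, h2, h3, h4 = h
    return np.array([
        [h1 * h1, 2 * h1 * h2, h2 * h2],
        [2 * h1 * h3, 2 * h1 * h4 + 2 * h2 * h3, 2 * h2 * h4],
        [h3 * h3, 2 * h3 * h4, h4 * h4],
    ])


class _PairLikelihood:
    """Collapsed GUS-LD log-likelihood for one pair of loci.

    Observations are grouped into unique (y1, d1, y2, d2) rows with
    multiplicity weights, the log binomial coefficients are
    precomputed, and the per-genotype read-probability matrices are
    cached on eps (the frequency/D coordinates of a finite-difference
    step leave them unchanged), so each evaluation is a handful of
    small vector ops.
    """

    def __init__(self, counts: PairCounts):
        obs = np.stack([counts.y1, counts.d1, counts.y2, counts.d2], axis=1)
        # individuals unsequenced at both loci have likelihood 1 under
        # every parameter value; dropping them keeps that exact
        obs = obs[(obs[:, 1] > 0) | (obs[:, 3] > 0)]
        uniq, w = np.unique(obs, axis=0, return_counts=True)
        self.w = w.astype(float)
        self.y1, self.d1, self.y2, self.d2 = (uniq[:, k].astype(float) for k in range(4))
        self.logC1 = log_binom_coeff(self.y1, self.d1)
        self.logC2 = log_binom_coeff(self.y2, self.d2)
        self._eps_cache: tuple[float, np.ndarray, np.ndarray] | None = None

    def _locus_probs(self, y, d, logC, eps: float) -> np.ndarray:
        """(m, 3) matrix of P(y | d, genotype) for genotypes (AA, AB, BB)."""
        out = np.empty((y.shape[0], 3))
        for g, q in enumerate((1.0 - eps, 0.5, eps)):
            out[:, g] = np.exp(logC + xlogy(y, q) + xlog1py(d - y, -q))
        return out

    def _read_matrices(self, eps: float) -> tuple[np.ndarray, np.ndarray]:
        if self._eps_cache is None or self._eps_cache[0] != eps:
            L1 = self._locus_probs(self.y1, self.d1, self.logC1, eps)
            L2 = self._locus_probs(self.y2, self.d2, self.logC2, eps)
            self._eps_cache = (eps, L1, L2)
        return self._eps_cache[1], self._eps_cache[2]

    def __call__(self, pA1: float, pA2: float, D: float, eps: float) -> float:
        q1, q2 = 1.0 - pA1, 1.0 - pA2
        h = np.array([pA1 * pA2 + D, pA1 * q2 - D, q1 * pA2 - D, q1 * q2 + D])
        if np.any(h < -1e-12):
            return -np.inf
        P = _joint_probs_from_haplotypes(np.clip(h, 0.0, None))
        L1, L2 = self._read_matrices(eps)
        py = ((L1 @ P) * L2).sum(axis=1)
        if np.any(py <= 0.0):
            return -np.inf
        return float(self.w @ np.log(py))


def pair_log_likelihood(counts: PairCounts, params: LDParams) -> float:
    """GUS-LD log-likelihood of the observed read counts.

    Sums the latent joint genotype out of each individual's likelihood:
    ``sum_i ln sum_g P(y_i1|g_1) P(y_i2|g_2) P(g)``. Depth-zero
    observations contribute a factor of one. Returns ``-inf`` when some
    individual's reads have probability zero (possible only at
    ``eps = 0`` or on a constraint boundary).
    """
    return _PairLikelihood(counts)(params.pA1, params.pA2, params.D, params.eps)


# ---------------------------------------------------------------------------
# parameter transforms

def _unpack(x: np.ndarray, fix_eps: float | None) -> tuple[float, float, float, float]:
    p1 = float(expit(x[0]))
    p2 = float(expit(x[1]))
    dmin, dmax = d_bounds(p1, p2)
    D = dmin + float(expit(x[2])) * (dmax - dmin)
    eps = fix_eps if fix_eps is not None else 0.5 * float(expit(x[3]))
    return p1, p2, D, eps


def _pooled_freq(y: np.ndarray, d: np.ndarray) -> float:
    tot = d.sum()
    return float(y.sum() / tot) if tot > 0 else 0.5


def _check_polymorphic(y: np.ndarray, d: np.ndarray, locus: int) -> None:
    if y.sum() == 0 or y.sum() == d.sum() or d.sum() == 0:
        raise MonomorphicLocusError(
            f"locus {locus} is monomorphic in the observed reads"
        )


def _multistart_points(p1_init: float, p2_init: float, with_eps: bool) -> list[np.ndarray]:
    """Initial points: D at the midpoint of its range and pushed toward
    each boundary (t = 0, +2, -2); eps starts at 1%."""
    x1 = float(logit(np.clip(p1_init, 0.01, 0.99)))
    x2 = float(logit(np.clip(p2_init, 0.01, 0.99)))
    starts = []
    for t in (0.0, 2.0, -2.0):
        x = [x1, x2, t]
        if with_eps:
            x.append(float(logit(2 * 0.01)))
        starts.append(np.array(x))
    return starts


def _maximize(
    negloglik, starts: list[np.ndarray], fix_eps: float | None,
    polish: bool = False,
) -> tuple[np.ndarray, float, bool]:
    """Run L-BFGS-B from each start; return best x, loglik, convergence.

    With ``polish`` the winner is refined at tight tolerances (used for
    the cheap genotype-table likelihood, whose optimum is compared to
    external solutions at 1e-6)."""
    bounds = [(-_X_FREQ_BOUND, _X_FREQ_BOUND)] * 2 + [(-_T_BOUND, _T_BOUND)]
    if fix_eps is None:
        bounds.append((float(logit(2 * _EPS_LO)), float(logit(2 * _EPS_HI))))
    best = None
    any_ok = False
    for x0 in starts:
        res = minimize(
            negloglik, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-10, "gtol": 1e-8, "maxiter": 500},
        )
        if not res.success:
            # the D-bound reparameterization has derivative kinks on the
            # lines pA1 = pA2 and pA1 = 1 - pA2; when the quasi-Newton
            # line search aborts there, refine with a simplex search,
            # which tolerates non-smooth objectives
            x_nm = res.x if res.fun <= negloglik(x0) else x0
            nm = minimize(
                negloglik, x_nm, method="Nelder-Mead",
                options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000},
            )
            if nm.fun <= res.fun:
                res = nm
        any_ok = any_ok or bool(res.success)
        if best is None:
            best = res
            continue
        # ties broken toward smaller |D|
        if res.fun < best.fun - 1e-9 or (
            abs(res.fun - best.fun) <= 1e-9
            and abs(_unpack(res.x, fix_eps)[2]) < abs(_unpack(best.x, fix_eps)[2])
        ):
            best = res
    if polish:
        res = minimize(
            negloglik, best.x, method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-13, "maxiter": 4000},
        )
        if res.fun <= best.fun:
            best = res
    return best.x, -float(best.fun), any_ok


def _finalize(
    p1: float, p2: float, D_raw: float, eps: float | None,
    loglik: float, n_used: int, converged: bool, method: str,
) -> LDEstimate:
    D_hat = bias_correct(D_raw, n_used, p1, p2)
    dmin, dmax = d_bounds(p1, p2)
    if abs(D_hat - dmax) <= _BOUNDARY_SNAP:
        D_hat = dmax
    elif abs(D_hat - dmin) <= _BOUNDARY_SNAP:
        D_hat = dmin
    return LDEstimate(
        pA1_hat=p1, pA2_hat=p2, D_hat=D_hat, D_raw=D_raw,
        d_prime=d_prime(D_hat, p1, p2), r2=r_squared(D_hat, p1, p2),
        loglik=loglik, n_used=n_used, converged=converged,
        eps_hat=eps, method=method,
    )


def fit_gusld(counts: PairCounts, fix_eps: float | None = None) -> LDEstimate:
    """Maximum-likelihood LD estimate from read counts (GUS-LD).

    Maximizes the latent-genotype likelihood jointly over the allele
    frequencies, D and the sequencing error rate, subject to the
    feasibility constraint on D. The bias correction ``2n/(2n-1)`` uses
    the number of individuals sequenced at both loci.

    Parameters
    ----------
    counts
        Read counts for the locus pair.
    fix_eps
        If given, the sequencing error rate is held at this value
        instead of being estimated (``fix_eps=0`` recovers an
        error-free read model).

    Raises
    ------
    MonomorphicLocusError
        If either locus shows only one allele across all reads.
    """
    _check_polymorphic(counts.y1, counts.d1, 1)
    _check_polymorphic(counts.y2, counts.d2, 2)
    if fix_eps is not None and not (0.0 <= fix_eps < 0.5):
        raise ValueError(f"fix_eps must be in [0, 0.5); got {fix_eps}")

    lik = _PairLikelihood(counts)

    def negloglik(x: np.ndarray) -> float:
        p1, p2, D, eps = _unpack(x, fix_eps)
        ll = lik(p1, p2, D, eps)
        return -ll if np.isfinite(ll) else 1e12

    starts = _multistart_points(
        _pooled_freq(counts.y1, counts.d1),
        _pooled_freq(counts.y2, counts.d2),
        with_eps=fix_eps is None,
    )
    x, loglik, converged = _maximize(negloglik, starts, fix_eps)
    p1, p2, D_raw, eps = _unpack(x, fix_eps)
    return _finalize(p1, p2, D_raw, eps, loglik, counts.n_used, converged, "gusld")


# ---------------------------------------------------------------------------
# genotype-call baseline

def naive_genotype_call(y: int, d: int) -> str:
    """Call a genotype from raw counts: all-reference reads -> AA,
    all-alternate -> BB, mixed -> AB, no reads -> missing.

    At low depth a heterozygote frequently shows only one allele and is
    miscalled homozygous (allelic dropout) — the error the full model
    corrects and this baseline deliberately ignores.
    """
    if y < 0 or d < 0 or y > d:
        raise ValueError("require 0 <= y <= d")
    if d == 0:
        return "missing"
    if y == d:
        return "AA"
    if y == 0:
        return "BB"
    return "AB"


def naive_genotype_calls(y: np.ndarray, d: np.ndarray) -> np.ndarray:
    """Vectorized genotype codes: 0=AA, 1=AB, 2=BB, -1=missing."""
    y = np.asarray(y)
    d = np.asarray(d)
    if np.any(y < 0) or np.any(d < 0) or np.any(y > d):
        raise ValueError("require 0 <= y <= d")
    out = np.ones(y.shape, dtype=np.int64)          # AB
    out[(y == d) & (d > 0)] = 0                      # AA
    out[(y == 0) & (d > 0)] = 2                      # BB
    out[d == 0] = MISSING
    return out


def genotype_table(g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
    """3x3 joint genotype count table from per-locus call codes,
    using only individuals called at both loci."""
    keep = (g1 != MISSING) & (g2 != MISSING)
    table = np.zeros((3, 3))
    np.add.at(table, (g1[keep], g2[keep]), 1.0)
    return table


def fit_standard(g1: np.ndarray, g2: np.ndarray) -> LDEstimate:
    """Genotype-call LD estimate (the classical likelihood approach).

    Treats the calls as the true genotypes and maximizes the
    multinomial likelihood of the observed 3x3 joint genotype table
    under the HWE joint-genotype probabilities — the error-free limit
    of the full model. Individuals missing at either locus are
    excluded; the same bias correction and LD measures are applied.

    Parameters
    ----------
    g1, g2
        Per-individual genotype codes at each locus
        (0=AA, 1=AB, 2=BB, -1=missing), e.g. from
        :func:`naive_genotype_calls`.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    table = genotype_table(g1, g2)
    n_used = int(table.sum())
    if n_used < 2:
        raise EstimationError("fewer than 2 individuals called at both loci")
    # reference-allele dosage margins over the complete pairs
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    for margin, locus in ((row, 1), (col, 2)):
        ref = 2 * margin[0] + margin[1]
        if ref == 0 or ref == 2 * margin.sum():
            raise MonomorphicLocusError(
                f"locus {locus} is monomorphic among the genotype calls"
            )

    def negloglik(x: np.ndarray) -> float:
        p1, p2, D, _ = _unpack(x, 0.0)
        h = np.array([p1 * p2 + D, p1 * (1 - p2) - D, (1 - p1) * p2 - D,
                      (1 - p1) * (1 - p2) + D])
        P = _joint_probs_from_haplotypes(np.clip(h, 0.0, None))
        ll = float(xlogy(table, P).sum())
        return -ll if np.isfinite(ll) else 1e12

    p1_init = (2 * row[0] + row[1]) / (2 * row.sum())
    p2_init = (2 * col[0] + col[1]) / (2 * col.sum())
    starts = _multistart_points(p1_init, p2_init, with_eps=False)
    x, loglik, converged = _maximize(negloglik, starts, fix_eps=0.0, polish=True)
    p1, p2, D_raw, _ = _unpack(x, 0.0)
    return _finalize(p1, p2, D_raw, None, loglik, n_used, converged, "standard")


# ---------------------------------------------------------------------------
# bias correction and LD measures

def bias_correct(D_raw: float, n_used: int, pA1: float, pA2: float) -> float:
    """Remove the small-sample bias of the D MLE.

    The MLE has expectation ``(2n-1)/(2n) * D``; multiplying by
    ``2n/(2n-1)`` removes it. The result is clamped back into the
    feasible range for the given allele frequencies.
    """
    if n_used < 1:
        raise ValueError("n_used must be >= 1")
    dmin, dmax = d_bounds(pA1, pA2)
    return float(np.clip(D_raw * 2 * n_used / (2 * n_used - 1), dmin, dmax))


def d_prime(D: float, pA1: float, pA2: float) -> float:
    """Lewontin's D': D scaled by its maximum attainable magnitude.

    Signed; the normalizer is ``min(pA1*pA2, (1-pA1)*(1-pA2))`` for
    negative D and ``min(pA1*(1-pA2), pA2*(1-pA1))`` for positive D.
    Zero D gives zero.
    """
    dmin, dmax = d_bounds(pA1, pA2)
    if D == 0:
        return 0.0
    dmax_norm = -dmin if D < 0 else dmax
    return float(np.clip(D / dmax_norm, -1.0, 1.0))


def r_squared(D: float, pA1: float, pA2: float) -> float:
    """Squared correlation of allelic indicators:
    ``D^2 / (pA1 (1-pA1) pA2 (1-pA2))``, in [0, 1]."""
    d_bounds(pA1, pA2)  # validates frequencies
    denom = pA1 * (1 - pA1) * pA2 * (1 - pA2)
    return float(np.clip(D * D / denom, 0.0, 1.0))


# ---------------------------------------------------------------------------
# all pairs

def pairwise_ld(
    y: np.ndarray,
    d: np.ndarray,
    method: str = "gusld",
    fix_eps: float | None = None,
    min_pair_overlap: int = 2,
):
    """LD estimates for every unordered pair among L loci.

    Parameters
    ----------
    y, d
        (n individuals x L loci) reference-read counts and total depths.
    method
        ``"gusld"`` for the read-count model, ``"standard"`` for the
        genotype-call baseline.
    fix_eps
        Optional fixed sequencing error rate (gusld only).
    min_pair_overlap
        Minimum number of individuals observed at both loci; pairs
        below it are reported with status ``insufficient_overlap``.

    Returns
    -------
    pandas.DataFrame
        One row per pair (L*(L-1)/2 rows) with the fitted quantities
        and a ``status`` column; failed pairs are reported with a
        failure code, never dropped.
    """
    import pandas as pd

    if method not in ("gusld", "standard"):
        raise ValueError(f"unknown method {method!r}")
    y = np.asarray(y)
    d = np.asarray(d)
    n, L = y.shape
    if L < 2:
        raise ValueError("need at least two loci")
    if method == "standard":
        calls = naive_genotype_calls(y, d)
    rows = []
    for j in range(L - 1):
        for k in range(j + 1, L):
            rec = {
                "locus1": j, "locus2": k,
                "n_used": int(np.sum((d[:, j] > 0) & (d[:, k] > 0))),
                "pA1_hat": np.nan, "pA2_hat": np.nan, "D_hat": np.nan,
                "Dprime": np.nan, "r2": np.nan, "eps_hat": np.nan,
                "loglik": np.nan, "status": "ok",
            }
            try:
                if rec["n_used"] < min_pair_overlap:
                    rec["status"] = "insufficient_overlap"
                else:
                    if method == "gusld":
                        est = fit_gusld(
                            PairCounts(y[:, j], d[:, j], y[:, k], d[:, k]),
                            fix_eps=fix_eps,
                        )
                    else:
                        est = fit_standard(calls[:, j], calls[:, k])
                    rec.update(
                        pA1_hat=est.pA1_hat, pA2_hat=est.pA2_hat,
                        D_hat=est.D_hat, Dprime=est.d_prime, r2=est.r2,
                        eps_hat=est.eps_hat if est.eps_hat is not None else np.nan,
                        loglik=est.loglik, n_used=est.n_used,
                        status="ok" if est.converged else "not_converged",
                    )
            except MonomorphicLocusError:
                rec["status"] = "monomorphic"
            except (EstimationError, ConstraintError, ValueError) as exc:
                rec["status"] = f"error:{type(exc).__name__}"
            rows.append(rec)
    return pd.DataFrame(rows)
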