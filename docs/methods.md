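# Methods

## Model

Two biallelic loci, reference/alternate alleles A/B, reference-allele
frequencies `pA1`, `pA2` in (0, 1). The disequilibrium coefficient
`D = P(A1A2) - pA1*pA2` is confined by non-negativity of the four
haplotype frequencies to

    max(-pA1*pA2, -(1-pA1)(1-pA2)) <= D <= min(pA1*(1-pA2), pA2*(1-pA1)).

Random mating (Hardy–Weinberg) forms each individual's joint genotype
from two independent haplotype draws; the 3×3 unphased genotype table
is computed by collapsing the 16 ordered haplotype pairs, with the
double heterozygote pooling coupling and repulsion phases. We
deliberately construct this table from the haplotype frequencies rather
than hard-coding its algebraic entries; the construction is validated
in tests against literal enumeration, the D = 0 factorization and the
simplex invariants.

Observation model: given the true genotype, the reference read count at
depth `d` is `Binomial(d, q)` with `q = 1-eps` (ref hom), `1/2` (het),
`eps` (alt hom); `eps` is the **per-read** error rate, so its estimate
is not directly comparable to per-genotype error rates quoted
elsewhere. `d = 0` contributes likelihood 1 under every genotype, so
individuals missing at one locus still inform the allele frequencies.
Reads are assumed independent between loci given the genotypes (valid
when the two SNPs are not on the same sequencing read; `gusld estimate
--min-distance` can enforce a separation), errors independent between
reads, missingness random, and alleles sampled without preference.

Assumptions the model does not relax: biallelic SNPs, unrelated
individuals, HWE, no preferential allele sampling, `eps < 0.5`
(at 0.5 the three genotype read models coincide and the model is
unidentifiable; the search is capped at 0.49).

## Estimation

The log-likelihood sums the nine latent joint genotypes out of each
individual's read-count likelihood and is maximized jointly over
`(pA1, pA2, D, eps)`.

* **Parameterization.** Unconstrained coordinates
  `(logit pA1, logit pA2, t, logit 2*eps)` with
  `D = Dmin(p) + sigmoid(t) * (Dmax(p) - Dmin(p))` recomputed from the
  current frequencies at each evaluation, so the frequency-dependent
  D constraint holds by construction. The min/max in the bounds leaves
  derivative kinks on the lines `pA1 = pA2` and `pA1 = 1 - pA2`; when
  the L-BFGS-B line search aborts on such a kink the point is refined
  with a Nelder–Mead simplex, which is insensitive to non-smoothness.
* **Starts.** Three: `t = 0` (D mid-range, near 0) and `t = ±2`;
  frequencies initialized at the read-pooled allele proportions,
  `eps` at 0.01. Best log-likelihood wins; ties (within 1e-9) break
  toward smaller |D|. The likelihood can be multimodal near the D
  boundaries, which the ± starts cover.
* **Tolerances.** `ftol 1e-10`, `gtol 1e-8`, box bounds
  `|logit p| <= 12`, `|t| <= 30`, `eps` in `[1e-9, 0.49]`; `eps` may be
  fixed by flag (fixing it at 0 gives the error-free read model).
  Fitted D within 1e-6 of a boundary is reported exactly on it, so
  `D' = ±1` is exact.
* **Bias correction.** `D_hat = D_raw * 2n/(2n-1)` clamped to the
  feasible range, with `n` the number of individuals with nonzero
  depth at **both** loci. `D'` (signed; summaries report |D'|) and
  `r^2` are derived from the corrected `D_hat` and the frequency MLEs.
* **Implementation.** Observations are collapsed to unique
  `(y1, d1, y2, d2)` rows with multiplicity weights; log binomial
  coefficients are precomputed with `gammaln` (no overflow at large
  depth); the per-genotype read matrices are cached on `eps`.
  Individuals unsequenced at both loci are dropped exactly (their
  likelihood factor is 1).

The baseline estimator treats naive calls (all-ref reads → AA, all-alt
→ BB, mixed → AB, no reads → missing) as true genotypes and maximizes
the multinomial likelihood of the complete-pairs 3×3 table under the
same HWE genotype probabilities, through the same optimizer with `eps`
absent and a Nelder–Mead polish (its optimum is compared to external
solutions at 1e-6, tighter than a quasi-Newton stop on a 3-parameter
surface reliably gives). Tests cross-check it against an independently
written EM over haplotype frequencies. Its `n` for the bias correction
is the number of individuals called at both loci.

## Simulator

Haplotype pairs are drawn i.i.d. from the truth-implied haplotype
frequencies; depths are Poisson with per-locus means; reads are drawn
from the genotype with replacement and flipped with probability `eps`.
For a fixed genotype the per-read construction is distributionally
identical to a single binomial draw with the genotype's success
probability, and the fast path samples that binomial directly; the
literal per-read path is retained (`per_read=True`) and checked against
the fast path distributionally in tests.

Default study conditions: `eps = 0.01`; bias/SE design with 100
individuals per dataset over mean depths (1, 2, 3, 4, 5, 7.5, 10, 15)
and three allele-frequency scenarios — (0.5, 0.5) with
D ∈ {−0.15, 0, 0.05, 0.15, 0.25}, (0.5, 0.75) with
D ∈ {−0.01, 0, 0.05, 0.1, 0.125}, (0.9, 0.9) with
D ∈ {−0.01, 0.03, 0.06, 0.09}; fixed-effort design with
effort = individuals × loci × mean depth held at 600 reads, i.e.
sample sizes (300, 150, 100, 75, 60, 40, 30, 20) across the depth
grid (`n = round(effort / (2 mu))`; the printed sizes are exact
divisions, so rounding only matters for user-supplied efforts). The
first scenario's D grid also circulates in a variant starting at
−0.05 instead of −0.15; the CLI exposes both (`table2-sim1` vs
`fig1`). The two loci share a mean depth by default; `mu1`/`mu2`
allow unequal means.

Summary statistics per cell, method and measure: bias, SE, MSE and
Monte-Carlo standard errors. SE is the population (ddof = 0) standard
deviation so that `MSE = bias² + SE²` is an exact identity. Replicate
fits that land on a D boundary are retained — they are legitimate
constrained MLEs and the source of the boundary bias visible when the
true D sits on or near a bound. Failed fits (e.g. a locus drawn
monomorphic at small n) are counted and excluded.

Replicates default to 1000 per cell. The heavy validation runs
(the depth-2 bias contrast and the fixed-effort MSE sweep) use 1000
replicates; Monte-Carlo standard errors are carried through all
assertions, so conclusions are resolution-aware. Seeding uses
`numpy.random.SeedSequence` spawning, making every experiment
bit-reproducible from a single integer seed.

What the generator emulates — and does not: it produces exactly the
model's data (HWE, unrelated individuals, Poisson depths, random
allele sampling, independent errors). It does not simulate preferential
allele sampling, depth overdispersion beyond Poisson, correlated errors,
related individuals or multi-locus haplotype structure. Passing tests
therefore demonstrate correctness of the estimator under its own
assumptions and the claimed contrasts with the genotype-call baseline;
they do not certify robustness to violations of those assumptions on
real data.

## Interfaces

Input: VCF 4.x with a per-sample `AD` FORMAT field (biallelic records;
multiallelic records skipped with a logged count, or rejected), or
paired delimited matrices of reference counts and depths. Missing AD
(`./.`) becomes `y = d = 0`. AD vectors longer than 2 on a biallelic
line are tolerated: depth is their sum (logged warning). Coordinates
stay 1-based.

SNP filters, applied before pair estimation: pooled minor allele
frequency > 0.05 and missing proportion < 0.25 by default. MAF is the
read-pooled proportion (Σy/Σd folded to minor) — the conventional,
error-agnostic pre-filter — not a per-locus ML estimate. Pairs with
fewer than 2 individuals observed at both loci are reported as
`insufficient_overlap`. An optional `--min-distance` drops the
lower-MAF SNP of same-chromosome pairs closer than a given bp, for
callers that emit several SNPs per read; it is off by default.

Output: tidy TSV, one row per pair with a status code (failures are
reported, never silently dropped), plus optional square |D′| and r²
CSV matrices and a summary line with mean |D′| and mean r².

## Known limitations

* No standard errors or confidence intervals for the estimates.
* D estimates near a feasibility boundary remain biased (constrained
  MLE truncation); the correction factor removes only the
  O(1/n) multiplicative bias.
* `eps` is biased upward at very low mean depth (errors and true
  minor-allele reads are then hard to separate); LD estimates remain
  accurate regardless.
* The baseline estimator discards individuals missing at either locus;
  the full model uses them for frequency information.
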