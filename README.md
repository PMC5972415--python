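# gusld

Maximum-likelihood estimation of pairwise linkage disequilibrium (LD)
from low-coverage high-throughput sequencing data.

## The problem

Genotyping-by-sequencing and other reduced-representation methods
produce shallow, variable read depths. At low depth a heterozygote
often shows only one of its two alleles and is miscalled homozygous
(*allelic dropout*), and individual reads carry sequencing errors.
Both act like genotyping errors, and genotyping errors attenuate LD
estimates toward zero — badly, even at error rates of a few percent.
Standard LD estimation from called genotypes is therefore biased for
low-coverage data, and filtering on depth throws away most of it.

`gusld` estimates LD directly from the allele read counts, treating the
true genotypes as latent. No haplotype phasing, locus ordering or
depth filtering is required.

## The model

For two biallelic loci with reference-allele frequencies
$p_{A_1}, p_{A_2}$, the disequilibrium coefficient is
$D = p_{A_1A_2} - p_{A_1} p_{A_2}$, constrained to

$$\max(-p_{A_1}p_{A_2},\,-(1-p_{A_1})(1-p_{A_2})) \le D \le \min(p_{A_1}(1-p_{A_2}),\,p_{A_2}(1-p_{A_1})).$$

Under Hardy–Weinberg equilibrium the nine joint genotype probabilities
$P_g$ follow from drawing two haplotypes independently. Given the true
genotype, the reference read count $Y_{ij}$ at depth $d_{ij}$ is
binomial with success probability $1-\varepsilon$ (ref hom), $1/2$
(het) or $\varepsilon$ (alt hom), where $\varepsilon$ is the per-read
sequencing error rate. The log-likelihood sums the latent genotype out:

$$\ell(p_{A_1}, p_{A_2}, D, \varepsilon) = \sum_{i=1}^n \ln \sum_{g=1}^{9} \Big(\prod_{j=1,2} P(Y_{ij} \mid G_{ij}=g_j)\Big) P_g .$$

It is maximized numerically subject to the constraint on $D$; the MLE
$\hat D$ is multiplied by $2n/(2n-1)$ (with $n$ the number of
individuals sequenced at both loci) to remove its small-sample bias,
and $D'$ and $r^2$ are derived from $\hat D$ and the frequency MLEs.
The classical genotype-call estimator (the error-free multinomial
likelihood on the called 3×3 genotype table) is included as a baseline;
a simulator and Monte-Carlo experiment drivers reproduce the regimes
where the two differ.

## Worked example

```python
import numpy as np
from gusld import SimConfig, simulate_pair, fit_gusld, fit_standard, naive_genotype_calls

# 100 individuals at mean depth 2, true D = 0.15, 1% sequencing error
cfg = SimConfig(n=100, pA1=0.5, pA2=0.5, D=0.15, eps=0.01, mu1=2, mu2=2, seed=2)
counts, _ = simulate_pair(cfg)

full = fit_gusld(counts)
base = fit_standard(naive_genotype_calls(counts.y1, counts.d1),
                    naive_genotype_calls(counts.y2, counts.d2))
print(f"full model:    D = {full.D_hat:.3f}  r2 = {full.r2:.3f}  eps = {full.eps_hat:.4f}")
print(f"call baseline: D = {base.D_hat:.3f}  r2 = {base.r2:.3f}")
```

prints

```
full model:    D = 0.117  r2 = 0.218  eps = 0.0173
call baseline: D = 0.063  r2 = 0.065
```

One replicate is noisy, but the pattern is systematic: over 1000 such
replicates the latent-genotype estimator is unbiased for D = 0.15
(mean bias ≈ 0.00) while the genotype-call baseline is attenuated by
about a third (bias ≈ −0.07), because dropout miscalls roughly half of
the depth-1 and a quarter of the depth-2 heterozygotes.

From the command line:

```sh
gusld estimate --vcf snps.vcf --out ld.tsv           # all-pairs LD table
gusld simulate --preset table2-sim1 --reps 1000 --seed 1 --out bias.tsv
gusld simulate --effort 600 --reps 1000 --seed 1 --out mse.tsv
```

`gusld estimate` filters SNPs to pooled minor allele frequency > 0.05
and < 25% missing by default, writes one row per SNP pair
(frequencies, D̂, D′, r², ε̂, log-likelihood, status), and prints the
mean |D′| and mean r² over successful pairs.

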