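# Methods

This note documents the statistical models, the synthetic-data generator,
and the numerical choices in `gsel`. Everything quantitative stated here is
computed by the test suite or the example scripts; nothing is quoted from
elsewhere.

## The prediction problem

Given a herd of n genotyped animals with phenotypes
`y = Xb + (genetic value) + e`, the goal is each animal's genomic
estimated breeding value (GEBV) — its predicted additive genetic merit
from SNP markers. Fixed effects are the overall mean, the contemporary
group (year-of-birth × season-of-calving) and the dam-age class, coded as
reference-level dummies with an explicit intercept. Two model families are
implemented, identical in the fixed part:

**GBLUP.** `y = Xb + Zg + e`, `g ~ N(0, G σg²)`, `e ~ N(0, I σe²)`, with
G the VanRaden genomic relationship matrix `G = WWᵀ / 2Σ pᵢ(1−pᵢ)` built
from the 2p-centered dosage matrix `W = M − 2P`. Heritability is
`h² = σg²/(σg² + σe²)`. For fixed variances the estimates solve the mixed
model equations

```
[ XᵀX   XᵀZ           ] [b]   [Xᵀy]
[ ZᵀX   ZᵀZ + G⁻¹ λ   ] [g] = [Zᵀy],   λ = σe²/σg²
```

(`solve_mme`, exact). The Bayesian treatment samples (b, g, σg², σe²) by
Gibbs with scaled-inverse-χ² priors on both variances.

**Marker regression (Bayesian alphabet).** `y = Xb + Wm + e` with a prior
per SNP effect mᵢ: with probability π the effect is exactly 0, otherwise
`mᵢ ~ N(0, σ²mᵢ)`. The methods differ in π and the variance prior:

| method | π    | variance prior |
|--------|------|----------------|
| BayesA | 0    | per-SNP σ²mᵢ ~ scaled-inv-χ²(ν, S) |
| BayesB | 0.95 | per-SNP σ²mᵢ ~ scaled-inv-χ²(ν, S) |
| BayesC | 0.95 | one shared σ²m ~ scaled-inv-χ²(ν, S) |
| BL     | 0    | σ²mᵢ = τᵢ² σe², τᵢ² ~ Exp(λ²/2), λ² ~ Gamma |

π is fixed, never estimated. GEBV = W m̂ with the posterior-mean effects
and the *training* allele frequencies retained for centering, so a
validation animal's GEBV is the same function of its genotypes as a
training animal's.

### Sampling scheme

One iteration updates, in order: the fixed effects from their joint
normal full conditional (a weakly-informative N(0, 10⁶·var(y)) prior
keeps XᵀX invertible when a factor level is absent from a training fold);
every SNP effect by single-site Gibbs; the variance hyperparameters; and
σe². In the single-site sweep the inclusion indicator is sampled from the
normal likelihood ratio with the effect integrated out, *conditional* on
the current σ²mᵢ; when a BayesB SNP is excluded its variance is refreshed
from the prior. (Integrating the variance itself out analytically is not
possible here — the effect-marginal is Student-t, and the convolution with
the Gaussian residual likelihood has no closed form — so the chain
conditions on the variance instead; given the RNG stream the update is
still deterministic and testable.) All per-SNP random draws are
pre-generated from one numpy Generator and passed into the (numba-jitted)
sweep, so a fit is a pure function of (data, spec, seed).

GBLUP uses the eigendecomposition `G* = UΛUᵀ` of the blended matrix
(below): in the rotated basis `a = Uᵀg` the full conditional is diagonal,
making each iteration O(n²) rather than O(n³).

For marker models the reported σg² of a posterior draw is the realized
genomic variance var(Wm) of that draw; for GBLUP it is the scale parameter
σg² itself (G has mean diagonal ≈ 1, so the two scales agree; no trace
correction is applied). The identity h² = σg²/(σg²+σe²) is applied per
draw, and h² is the posterior mean of that ratio.

### Priors and defaults

Auto prior scales split the phenotypic variance with an expected
marker-explained share R² = 0.5: `Se = (1−R²)·var(y)·(νe−2)/νe` and, for
the marker variance, `S` chosen so `(1−π)·Σⱼvar(wⱼ)·E[σ²m] = R²·var(y)`.
Defaults ν = νe = 5. For BL, λ² starts at `2σe²Σⱼvar(wⱼ)/(R²·var(y))` with
a Gamma(1.1, rate matched) hyperprior; τᵢ⁻² has the standard
inverse-Gaussian full conditional. Chain defaults are 20,000 iterations,
5,000 burn-in, thinning 10; the tests and examples use 1,200–3,000
iterations, which the parameter-recovery checks show is enough at n ≈ 400.

**Blending.** G from a few hundred related animals can be numerically
singular. Before inversion or eigendecomposition it is blended,
`G* = 0.99·G + 0.01·I` (configurable). The cross-relationship block used
for prediction is unaffected (blending only touches the diagonal).

## Fold design and evaluation

The dissimilarity `d.. = 1 − a../√(a.. a..)` (one minus Wright's
relationship coefficient, from the tabular-method A matrix) turns
relatedness into a metric: full sibs of non-inbred parents sit at 0.5,
unrelated animals at 1. Each animal's feature vector is its row of D —
equivalent to handing the D matrix directly to a k-means routine — and a
Hartigan–Wong-style k-means (first-improvement single-point relocation
with the exact n/(n±1) WSS transfer factors, 25 random restarts by
default) produces k = 10 folds. A classical-MDS embedding of D is
available behind `embed="mds"`. Cluster folds are *not* rebalanced; a
singleton cluster is possible and such a fold is later excluded from
correlation pooling (a correlation needs ≥ 2 values). Random folds are
balanced permutation splits, five replicates by default.

Per fold, the model is trained on the other nine folds;
predictive ability is the Pearson correlation r(y, ŷ) in the held-out
fold, with ŷ = X b̂ + GEBV including the fixed effects (an
adjusted-phenotype mode, y − X b̂ vs GEBV, exists for comparison). GBLUP
predicts held-out animals by the conditional expectation
`G_vt G_tt⁻¹ ĝ`; marker models back-solve `W_val m̂`; the two agree to
r > 0.99 on matched fits (tested). Correlations are computed per fold and
then averaged (a concatenation mode is not offered; fold-wise pooling is
what the accuracy arithmetic below assumes).

**GEBV accuracy** is `r/√h²` with r the pooled validation correlation and
h² the pooled *training* heritability. Training h² is used because a
10-fold validation set is too small to estimate h² on its own, and because
the published accuracy tables this package reproduces are arithmetically
consistent only under that reading. Accuracies above 1 — which genuinely
occur when a method underestimates h² — are reported as-is with a logged
warning, never truncated: that inflation is a finding, not an artifact to
hide.

## The synthetic herd generator

No public dataset accompanies the reference analysis, so every stage is
driven by a generator that emulates its design: several hundred animals
from a shallow pedigree (default 40 founders + 3 generations × 30 matings
× 4 offspring = 400 animals), 3 birth years × 2 calving seasons as 6
contemporary groups, 3 dam-age classes, ~2,500 SNPs on 5 × 40 Mb
chromosomes after a MAF ≥ 0.10 floor, and traits at h² ≈ 0.2–0.4
(default 0.30).

**Founders.** Default founder haplotypes come from a neutral coalescent
(msprime), Ne = 1,500, recombination 10⁻⁸/bp, mutation 1.2×10⁻⁸/bp, with
segregating sites filtered to MAF ≥ 0.10 and thinned evenly to the
requested panel size. Ne was chosen once from `E[r²] ≈ 1/(1+4·Ne·c)` so
the decay profile is cattle-like: measured on the default herd, mean r² ≈
0.18 for pairs under 0.1 Mb falling to ≈ 0.04 beyond 0.5 Mb, about 11% of
sub-0.1-Mb pairs above r² = 0.5. An `independent` founder mode (per-locus
frequencies uniform on [maf_floor, 0.5], loci independent — exact HWE, no
LD) is kept for tests that need clean expectations, e.g. mean diag(G) ≈ 1.

**Gene dropping.** Each meiosis draws Poisson(L/100 Mb) crossovers at
uniform positions (1 cM/Mb, no interference) and copies the parental
haplotype with phase switching at each crossover. Haplotypes are retained
on the herd object, which gives the tests a free phase oracle (Mendelian
consistency, haplotype-count r²).

**Phenotypes.** QTL are a uniform draw from the marker panel (they remain
genotyped — there are no hidden causal loci), with normal effects rescaled
to unit genetic variance. `σe² = var(BV)(1−h²)/h²`, and the realized
residual vector is rescaled to that variance exactly, mirroring the BV
scaling — so realized h² equals the target by construction rather than to
within sampling noise. Contemporary-group and dam-age effects are
N(0, 0.5²) in genetic-standard-deviation units; their magnitudes are a
documented choice, not an estimate from any dataset.

**What the generator does not emulate:** selection or assortative mating
across generations, sex-specific inheritance for X-linked markers,
genotyping-error structure, genotype-by-environment interaction,
non-additive gene action. Passing tests therefore show the estimators are
correct and well-calibrated under an additive, neutrally-mating world —
not that any particular real herd satisfies those assumptions.

## Quality control conventions

Filters run strictly in sequence — animals (> 50% missing), then SNP
call rate (> 5% missing among surviving animals), then MAF (< 10%,
computed after the first two removals) — and the order is observable: a
matrix exists where swapping the animal and MAF stages changes the
survivor set (tested). "> 5% missing" and "< 95% call rate" are one rule,
not two. Removal is strict (`>` missingness, `<` MAF). Imputation is
per-SNP mean dosage by default (fractional values, fine for G and LD but
not writable as .ped alleles) or two Bernoulli(p) draws for an
integer-valued matrix. Allele frequencies used downstream (G, centering)
are always recomputed from the post-QC, post-imputation matrix of the
animals actually in the analysis. The X chromosome, when simulated or
loaded, is treated as autosomal throughout. Map coordinates are held in
Mb; .map files are written/read in base pairs.

## Numerical choices and degenerate inputs

- Two-locus EM for haplotype frequencies iterates only over the
  double-heterozygote ambiguity; tolerance 10⁻¹², cap 1,000 iterations.
  r² is undefined for a monomorphic locus: such pairs are skipped and
  counted, never reported as 0.
- Empty LD distance bins report NaN, not 0; bins are left-closed.
- k-means never empties a cluster (a relocation from a singleton is
  disallowed); ties in the WSS improvement break toward the
  lowest-indexed cluster; restarts keep the best WSS.
- The A matrix is built by the tabular method in topological order;
  a cyclic pedigree raises an error naming the cycle. An exact
  rational-arithmetic kinship recursion serves as the test oracle.
- Chains raise on any non-finite draw, reporting the iteration index.
- `π = 1` (no SNP ever included) is rejected as degenerate.
- Seeds: every stochastic component takes an explicit seed; per-fold
  chain seeds are spawned from (base seed, fold, replicate) via numpy
  SeedSequence, so CV results are reproducible fold-by-fold.

## Known limitations

- Pedigree inverse-A by Henderson's rules is not implemented; matrices
  are dense and desk-scale (n ≲ a few thousand).
- LD is computed within chromosomes only; the Bayesian samplers are
  single-trait; π is fixed, not estimated (no BayesCπ); REML is not
  offered (the Gibbs posterior mean plays that role).
- The BayesB indicator update conditions on the per-SNP variance rather
  than integrating it out (see above); with the prior-refresh step the
  chain remains a valid Gibbs sampler for the stated model.
- On herds with little family structure, k-means folds on D are close to
  random folds and the two schemes' predictive abilities converge; the
  scheme contrast in the tests uses explicit 10-family herds.
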