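# Methods

## The model

`crossblup` estimates additive and dominance genetic variation jointly in
two pure lines (P1, P2) and their F1 cross from SNP genotypes and
repeated phenotype records.

### Single-locus theory

A biallelic locus with alleles B/b has genotypic values `a` (BB), `d`
(Bb), `-a` (bb) measured from the homozygote midpoint; `a` and `d` are
the *biological* additive and dominance effects.  With allele-B
frequencies `p` in line 1 and `p'` in line 2 (both lines non-inbred and
in Hardy–Weinberg equilibrium), an F1 individual carries one gamete from
each line, so

    E(G)   = (pp' - qq') a + (pq' + qp') d,
    alpha1 = a + d(q' - p'),      alpha2 = a + d(q - p),

where `alpha1` is the substitution effect of a line-1 gamete when mated
into line 2 (and vice versa): in a cross, a parent's breeding value
depends on the mate population's allele frequencies.  The F1 genetic
variance decomposes into gametic (general-combining-ability) variances
and a dominance (specific-combining-ability) variance:

    var_A1 = 2pq [a + (q'-p')d]^2,     var_A2 = 2p'q' [a + (q-p)d]^2,
    var_A  = var_A1/2 + var_A2/2,      var_D  = 4 pq p'q' d^2,
    var_G  = var_A + var_D.

The `a*d` cross-term of `var_G` is entirely inside the gametic
variances; no separate covariance component exists.  Treating the marker
effects as random with per-SNP variances `sigma2_a`, `sigma2_d`,
`Cov(a, d) = 0`, and summing over loci in linkage equilibrium gives the
multi-locus formulas (module `locus`), including the within-line
analogues obtained by setting `p' = p`.  Every closed form is verified
in the tests against exact enumeration of the four F1 gamete
combinations.

### Genomic relationship matrices

Genotypes are coded without frequency centering: `Z` maps BB/Bb/bb to
1/0/−1 and `W` maps them to 0/1/0.  The covariance kernels are the
trace-normalized cross-products

    G = ZZ' / tZ,   tZ = tr(ZZ')/n,      D = WW' / tW,   tW = tr(WW')/n,

so the mean diagonal of each is exactly 1 and a population-scale
variance component divided by `tZ` (or `tW`) is a per-SNP variance.
Note that `tZ * sigma2_a` is the scale of the *uncentered* genotypic
values, not a population variance; population-level genetic variances
are always produced through the multi-locus formulas above.

One `G` and one `D` are built over all genotyped individuals jointly and
normalized by the overall trace — the multi-population covariance
`G_o (x) G` presumes a single shared relationship matrix.  Missing calls
are mean-imputed from the individual's own population's allele frequency
(`2p − 1` for Z, `2p(1−p)` for W), which preserves population means
without inventing rare genotypes.  QC order is: SNP minor-allele
frequency (pooled panel, default ≥ 0.05), then SNP call rate (≥ 0.90),
then individual call rate (≥ 0.90), each computed on the current panel.

### The mixed model

Records in the three populations are treated as three correlated traits;
each individual expresses only its own population's trait.  For records
`y`,

    y = X beta + u* + v* + p + e,

with `Var(u*) = G_o (x) G` and `Var(v*) = D_o (x) D`, where `G_o` and
`D_o` are 3×3 covariance matrices among the population scales;
permanent-environment and residual variances are population-specific and
diagonal across populations.  The fixed design holds population means,
user-named categorical effects, covariates, and the genomic homozygosity
`F_Ho = N_hom / N_observed` as a *population-specific* regression — its
coefficient, scaled by 0.10, is the inbreeding depression per 10 %
increase in homozygosity.

Because each individual expresses one trait, the observed-data
covariance collapses to Hadamard products: the genetic covariance
between individuals i and j is `G_o[pop(i), pop(j)] * G[i, j]` plus the
dominance analogue.  All likelihood computations are done at individual
scale through the Woodbury identity: with `K` the n×n collapsed kernel,
`A = K + (Z'R^{-1}Z)^{-1}` is the only matrix factorized per iteration,
and `Z'V^{-1}Z = A^{-1}` exactly.  No record-level (N×N) matrix is ever
formed.

## Estimation

### EM-REML

Variance components are estimated by EM-REML.  The conditional
expectations for `G_o` and `D_o` are taken in *marker space* (complete
data = scaled SNP effect vectors, `m` per population scale), giving the
update

    G_o <- G_o - [W_k' (M o G) W_l - r' W_k G W_l r] / m,

with `M = Z'PZ`, `r = Z'Py`, and `W_k = diag(G_o[k, pop(i)])`.  This
form never inverts `G` and therefore remains exact when `G` has
deficient rank (fewer markers than individuals), which is the normal
situation at the package's validation scale.  Permanent-environment and
residual variances use the classical trace-form updates.  Divisors are
`m` for the kernel matrices, and the per-population individual and
record counts for the diagonal components.  The restricted
log-likelihood is non-decreasing across iterations and is asserted to be
so in the test suite.

Plain EM crawls along the near-ridge between the dominance and
permanent-environment components (both are individual-level effects; `D`
is close to a scaled identity among nominally unrelated animals, so the
data separate them only weakly).  The default fit therefore extrapolates
the EM map with a squared-step scheme (SQUAREM-type: two EM steps define
a secant direction, a clamped step-length multiplier extrapolates along
it, and the cap adapts upward while extrapolations succeed).  An
extrapolated point is accepted only if its restricted log-likelihood is
not below the plain EM step's, so the accepted sequence stays monotone;
otherwise the plain EM step is taken.  In practice this shortens
convergence on the ridge by roughly an order of magnitude.  Plain EM is
available via `accelerate=False`.

Convergence is declared when the relative change of the full parameter
vector in one step falls below `tol` (default 1e-8; the validation
experiments use 1e-5, which moves every component by far less than its
sampling SD); `max_iter` caps the number of likelihood evaluations
(default 500).  Updates of `G_o`/`D_o` are projected to the nearest PSD
matrix if numerical noise produces a negative eigenvalue (with a
warning); residual variances are floored at 1e-8 of the phenotypic
variance; Cholesky factorizations retry with escalating diagonal jitter
up to 1e-6 before failing.

**Initialization.**  Default starting values are method-of-moments: the
pooled within-individual mean square of OLS residuals starts the
residual variance; the remaining phenotypic variance is split one half
to the additive, one quarter each to the dominance and
permanent-environment components; covariances start at 0.  This starts
the residual variance (by far the largest component for a litter-size
type trait) close to its estimate and saves several hundred EM
evaluations over a flat equal split.  Explicit starting values can be
supplied.

### Standard errors and derived quantities

After the EM loop, one average-information evaluation at the final
estimates builds the AI matrix `0.5 (dV_i Py)' P (dV_j Py)` over all 18
parameters; its pseudo-inverse provides asymptotic SEs (pseudo-inverse
because components estimated at or near a zero boundary make the AI
matrix singular).  SEs of derived quantities — per-SNP variances
(`sigma2_a = G_o[k,k]/tZ`), genotypic correlations
(`r = cov/sqrt(v1 v2)`), F1 variances from the multi-locus formulas —
propagate by the delta method; the F1 variances are linear in the SNP
variances, so their delta-method SEs are exact linear combinations.

BLUPs of `u*` and `v*` are produced on *every* population scale
(`u_hat[k] = (G_o[k, pop(.)] o r)' G`), so a pure-line animal also gets
a prediction of its genotypic value on the crossbred scale; solutions
are validated against a dense GLS oracle in the tests.

## Synthetic data generator

The generator emulates the structure of a two-line pig crossbreeding
study on litter size: allele frequencies per line drawn from Beta(2, 2)
(or fixed explicitly); pure-line dosages Binomial(2, p); F1 dosages
Bernoulli(p) + Bernoulli(p'); biological additive and dominance SNP
effects drawn per population with cross-population correlation 0.8
(additive) and 0.5 (dominance) and `Cov(a, d) = 0` within population;
phenotypes with population means near 13, parity and contemporary-group
fixed effects, a population-specific regression on realized genomic
homozygosity (about −12 per unit, i.e. roughly −1.2 per 10 % inbreeding),
permanent-environment variances 0.4–0.9 shared by an individual's 2–5
records, and residual variances near 7.  Default per-SNP variances
(2.25e-3 additive, 1e-3 dominance at m = 1000) put the within-line
additive variance near 0.9 and dominance near 0.17 — the
low-heritability (~0.1) regime of litter size.  Default sizes are 500
individuals per population and 1000 markers, the scale at which the
package's recovery experiments run on one CPU; all randomness flows from
one mandatory seed (genotype and phenotype streams are split
sub-sequences of it), and the exact theoretical variance components for
the drawn frequencies are stored alongside the data.

What the generator does **not** emulate: linkage disequilibrium within
lines (markers are independent), pedigree structure or selection within
lines, reciprocal-cross effects, genotype-by-environment interaction,
and effect-size distributions other than Gaussian.  Passing recovery
tests therefore demonstrates correctness of the estimation machinery
under the model's own assumptions, not robustness to LD or family
structure in real panels.

## Validation experiments and their sizes

- Closed-form theory vs. exact enumeration: 10^4 random parameter sets,
  1e-12 relative agreement.
- EM-REML vs. a direct Nelder–Mead maximization of the dense restricted
  likelihood: one single-population dataset of 30 individuals × 50
  markers with 6–8 records each, agreement to 1e-4 relative on all four
  components.  The fixture was chosen so that the REML optimum is
  interior: when an optimum sits on a zero boundary (common at this tiny
  size for the dominance/permanent-environment pair) EM approaches it
  only asymptotically and a relative comparison is not meaningful.
- Three-population parameter recovery: 20 replicates of the default
  generator (1500 individuals, 1000 markers); each variance component
  must land within 3 empirical SDs of truth in at least 90 % of
  replicates, and the likelihood trace must be monotone in every run.
- Null simulation: 300 individuals with zero genetic variance; the
  genetic estimates must be within 3 asymptotic SEs of zero.

## Known limitations

- Dominance and permanent-environment components are weakly separated in
  data without close relatives; expect large, anticorrelated SEs (this
  mirrors the real-data situation, where dominance SEs are of the order
  of the estimates).
- Phenotyped individuals must be genotyped (no single-step H-matrix).
- The AI matrix is evaluated once at the EM solution; SEs inherit EM's
  convergence accuracy.
- No epistasis, no Cov(a, d) models, no pedigree-based fallback.
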