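# Methods

`breedarch` dissects the genetic architecture of a non-inbred (S0) breeding
generation and evaluates genomic prediction for its *per se* performance. It
combines a breeding-population simulator with NOIA-coded Bayesian
whole-genome regression, posterior variance decomposition, window-based
Bayesian GWAS, and cross-validated prediction. This note documents the
models, the choices made where the design was genuinely open, and what the
synthetic studies do and do not establish.

## Phenotype adjustment

Field trials for large S0 populations are unreplicated: each candidate is
grown once, in one of two blocks, while a small set of check genotypes is
replicated in every block. Per trait we fit

    y_ik = mu + g_i + b_k + e_ik

with candidate effects `g_i ~ N(0, s2_g)` (random), check effects fixed,
block effects `b_k ~ N(0, s2_b)` and residuals `N(0, s2_e)`. Variance
components are estimated by EM-REML on the mixed-model equations
(convergence: relative REML log-likelihood change < 1e-8, at most 10,000
iterations; variances floored at 1e-10 x var(y), a floored component is
reported as 0). The adjusted value is `mu_hat + g_hat_i` — the BLUP for
candidates, the generalized-least-squares estimate for checks. EM is slower
than average-information REML but is monotone and robust for this
two-component model; the unit tests verify the fixed point against a direct
GLS/BLUP matrix solve. With a single block the block variance is fixed at
zero (with a warning); without any genotype spanning blocks the model is
refused as inestimable.

## NOIA coding and kernels

Additive and dominance marker codings follow the natural-and-orthogonal-
interactions parameterization built from observed genotype frequencies
(p_AA, p_Aa, p_aa), not allele frequencies, so the additive and dominance
columns of every locus are exactly orthogonal in the analyzed population —
no Hardy-Weinberg assumption, which matters for an intercross population
under selection. With alternate-allele counts 2/1/0:

    W_a = count - (p_Aa + 2 p_AA)
    W_d = { -2 p_Aa p_aa / D,  4 p_AA p_aa / D,  -2 p_AA p_Aa / D }
    D   = p_AA + p_aa - (p_AA - p_aa)^2

Loci with `D < 1e-12` (monomorphic or all-heterozygous) are flagged
degenerate and contribute additive information only (W_d = 0), which
preserves the orthogonality identities trivially. Genotype frequencies are
computed from observed calls; missing cells are then mean-imputed in W_a and
zeroed in W_d.

Relationship matrices are trace-normalized to n: `A = Wa Wa' / (tr/n)`, `D`
likewise; first-order epistatic covariances are the Hadamard products
`Vaa = (A o A)`, `Vad = (A o D)` (covering both additive-by-dominance
directions) and `Vdd = (D o D)`, each trace-normalized. Pairwise epistatic
coefficient products are never materialized — the
additive-dominance-epistasis (ADE) model is always fitted through these
kernels. The Gaussian kernel is `K = exp(-h S)` on squared-Euclidean
genotype distances, with the bandwidth h selected by REML over the grid
{0.01, 0.05, 0.1, 0.25, 0.5, 1, 2, 5, 10} / median(nonzero S) in each
training set (ties, including the degenerate flat profile for a constant
response, resolve to the smallest h). REML identifies h only weakly unless
the genetic signal is strong; this is a property of single-kernel RKHS
regression, not of the implementation.

## Bayesian regression models

Four model classes share one single-site Gibbs sampler:

* **A** — `y~ = mu + Wa a + e`
* **AD** — adds `Wd d`
* **ADE** — adds kernel random effects for Vaa, Vad, Vdd
* **GK** — `y~ = mu + u + e`, `u ~ N(0, K s2_u)`

Marker-effect blocks take one of four priors — BRR (one common variance),
BayesA (per-marker scaled-inv-chi^2 variances), BayesB (spike-and-slab with
per-marker slab variances), BayesC (spike-and-slab, common slab) — with the
same prior applied to the additive and dominance blocks. Spike-and-slab
indicators are sampled from the exact single-site marginal odds with the
effect integrated out.

Hyperparameters follow the conventions of the reference Bayesian-alphabet
implementations: all scaled-inverse-chi-square priors use df = 5 with scales
set so the prior mode matches an R2 = 0.5 partition of var(y~), split
equally across active genetic terms (marker-block scales divide by the sum
of coefficient-column variances; BayesB/C additionally by the prior
inclusion probability). The inclusion probability has a Beta(2, 8) prior
(mean 0.2) and is updated. The residual variance prior mode is
(1 - R2) var(y~). Defaults: 30,000 iterations, 15,000 burn-in, thinning 5
(thinning is an artifact choice; posterior summaries are invariant to it in
expectation). All randomness flows from one numpy Generator, so chains are
bit-reproducible given a seed.

Kernel random effects are sampled in the eigenbasis of their matrix
(one eigendecomposition per kernel; eigenvalues below 1e-8 truncated), giving
O(n) per-coordinate updates and making positive-semi-definiteness explicit —
a kernel with eigenvalues below -1e-8 is refused by name.

Missing phenotypes are sampled from their full conditional each iteration.
Cross-validation uses exactly this mechanism: the model is fitted on the
full population's designs and kernels with the test fold's phenotypes set
to missing, so kernel terms extend to held-out individuals without any
train/test kernel inversion.

## Variance decomposition and heritability

Per retained draw, each component's genotypic values are computed across all
genotypes (`g_a = Wa a_hat`, `g_d = Wd d_hat`, epistatic and GK values
directly from the sampled random-effect vectors) and the component variance
is the population variance (divide by n) of those values. The total genetic
variance is the variance of the summed values — not the sum of component
variances, which differs whenever components covary within a draw. Genomic
heritability `h2 = s2_g / (s2_g + s2_e)` is formed per draw and then
summarized, preserving the posterior of the ratio. Reports include both raw
components and shares of s2_g.

A documented consequence of this estimator class: because each draw's
sampled effects carry conditional noise, weakly identified terms (the three
epistatic kernels above all) contribute their near-prior variance to s2_g
in every draw. On a purely additive simulated trait (true h2 = 0.6,
n = 500) the ADE posterior-mean h2 is ~0.75-0.78 while the A model is
calibrated (~0.63) — the ADE model overestimates total genetic variance,
consistent with the behaviour reported for this model family. The
additive share of genetic variance remains correctly dominant (> 0.7 with
the BayesB prior).

## Window-based GWAS (WPPA)

The genome is tiled into non-overlapping physical windows (default 1 Mb,
1-based inclusive; a marker at exactly the boundary belongs to the earlier
window; empty windows are omitted). Per draw, the window's additive
genotypic values are built from the sampled effects at its markers, their
population variance is divided by the draw's total genetic variance
(variance-of-sum; configurable), and WPPA is the fraction of draws in which
this share strictly exceeds 1%. Dominance WPPA is computed identically from
W_d; degenerate-coded loci contribute zero. GWAS always runs on the
full-data fit, never on cross-validation fits.

## The simulator

The generator emulates a three-generation intercross program for hybrid
bioenergy sorghum: 13 fully inbred founders; F1 hybrids; segregating
second-generation families; and a large set of non-inbred S0 full-sib
families that constitute the analysis population. Meiosis uses the Haldane
model (no interference): crossover counts are Poisson with mean equal to
chromosome length in Morgans, positions uniform on the genetic map; the
default map uses 1 cM = 1 Mb. Founder alternate-allele frequencies are
Uniform(0.1, 0.9).

The default scaled plan (9 F1s, 5 gen-2 families of 8 sibs, 60 S0 families
of 4 sibs; about quarter scale) concentrates ancestry the way the real
program did: crossing is confined to two tester-specific subpopulations
drawn from partially overlapping founder pools (one founder shared), and
each pool's gen-2 crosses cycle over a small selected subset of its F1s so
every pair of gen-2 families within a pool shares an F1 parent. This
structure — not a tuned parameter — is what keeps per-group mean marker
heterozygosity inside the empirically observed 20-40% band; with unrelated
gen-2 parents the S0 heterozygosity expectation (~2 E[p(1-p)] = 0.39)
crowds the upper band edge. Groups are defined by the pair of gen-2 parent
families (the scaled analogue of ancestry-defined groups); the scaled plan
yields fewer groups (4-7) than the full program's 13.

Trait architectures place QTL on the realized NOIA codings, so the
simulated truth decomposes into exactly the components the models estimate:
additive effects i.i.d. normal (or Laplace), dominance effects k|a|
(directional dominance), epistatic pairs drawn among the QTL with the
phenotypic contribution defined through the NOIA coefficient products. An
optional rescaling fixes the realized component-variance ratios, which is
how study conditions like "30% dominance variance" are constructed. Field
trials add block effects and Gaussian noise with the residual variance
derived from a target broad-sense heritability against the realized genetic
variance.

What the simulator does **not** emulate: genotyping error and depth
variation, imputation artifacts, selection during the program (allele
frequencies drift only through the pedigree), genotype-by-environment
interaction, spatial field trends beyond two blocks, and real linkage maps.
Passing synthetic studies therefore demonstrates correctness of the
machinery under the stated generative model, not performance on real
RAD-seq data.

## Study problem sizes

The packaged studies (in `breedarch.studies`, used by the tests and
`scripts/acceptance.py`) run at sizes chosen to keep a full desk run in
minutes while preserving the phenomena of interest: recovery and
cross-validation studies use 500 S0 individuals (125 families x 4); the two
quantities known to require the full population size — dominance-share
recovery and single-window QTL detection under ADE — run at 1,000
individuals (250 families x 4), matching the emulated program's S0
generation (1,020 phenotyped individuals). At n = 500 those two are
unstable: the epistatic kernels absorb directional-dominance signal and
major-QTL patterns (which in 4-sib families are largely between-family
contrasts lying in the top eigenspace of Vaa). Cross-validation studies use
20 replications of fivefold CV at 2,000-iteration chains and trait
heritability 0.5 (the generator default).

## Numerical conventions

* Genotype codes: alternate-allele counts (VCF orientation); NOIA centering
  makes A invariant to the orientation choice and W_d is symmetric in it.
* Coordinates: 1-based bp, preserved end-to-end; LD pruning is a greedy
  left-to-right scan within chromosomes on squared Pearson correlation of
  0/1/2 codes over pairwise-complete individuals (r^2 >= 0.95 drops the
  later marker); monomorphic markers are retained as unlinked and logged.
* Missing data: per-marker mean imputation for PCA, codings and kernels
  (imputation happens after frequency computation). Depth/quality filters
  belong to variant calling and are out of scope.
* Population variance (divide by n) everywhere in the posterior
  decomposition; the choice is immaterial at n ~ 1000 but fixed so oracle
  tests are exact.
* Tukey comparisons use replication-level Fisher-z values as independent
  one-way observations, studentized-range quantiles, and an interval-based
  compact letter display (exact under equal replication); with zero
  within-group variance any mean difference separates groups; display ties
  break by descending mean.
* Per-stage pipeline seeds are sha256(master_seed, stage name) reduced mod
  2^31 - 1.

## Known limitations

* Epistatic variance components are mutually correlated and unreliable as
  functional measurements; the package reports them but does not attempt
  post-hoc orthogonalization.
* The ADE h2 overestimation described above is inherent to the
  sampled-value variance estimator with informative kernel priors.
* No multi-trait models, no BayesC-pi-fixed variants, no leave-one-family
  -out CV schemes, no higher-order epistatic kernels.
* EM-REML for the adjustment model estimates the block variance from very
  few block levels; with two blocks that component is effectively a
  nuisance absorbed into adjustment, not an interpretable quantity.
* At moderate population sizes (n ~ 500) the ADE model carries a small,
  systematic cross-validation penalty on purely additive traits: the signal
  its kernels absorb transfers to held-out folds less efficiently than
  marker effects do, so ADE can score significantly below the A model there
  even though both are correctly specified for the additive part. The
  penalty shrinks with population size.
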