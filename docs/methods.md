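# Methods

This package screens all pairs of SNPs for epistatic association with a
binary or continuous trait and corrects the resulting family of tests for
multiple testing by step-down maxT, with an optional gamma-tail shortcut
that removes the dominant cost of the permutation procedure. This note
records the model, the estimators, the numerical choices, and what the
synthetic experiments do and do not establish.

## The pair statistic

For a SNP pair the nine two-locus genotype cells (additive coding 0/1/2 at
each locus, individuals missing at either locus excluded) are first
labelled **H** (higher risk), **L** (lower risk) or **O** (undecided) by a
one-vs-rest association test per cell at a lenient level `alpha_cell`
(default 0.1): a 2×2 Pearson chi-squared for case/control traits, a squared
pooled-variance Student t for continuous traits. A cell is H when its test
is significant and its case rate (or trait mean) exceeds the rest, L in the
opposite direction, O otherwise; empty cells and cells whose test is
incomputable (zero margin, empty contrast group, zero pooled variance) are
O. The pair's statistic is

    T = max(T_H, T_L),

where `T_H` tests the pooled H cells against all other individuals with
the same test family, and `T_L` likewise. An absent category contributes
zero, so an all-O table yields an exact 0.0 — these exact zeros are common
under the null and are modelled explicitly below. Both test families put
`T` on the scale of a chi-squared with one degree of freedom.

**Why a pooled-variance t rather than Welch.** With per-group (Welch)
variances, a pooled H group of two near-identical trait values has a
vanishing standard error and the statistic explodes (null values in the
thousands were observed). That breaks the comparability of the binary and
continuous scales and, more importantly, destroys the shifted-gamma tail
behaviour that the fast correction relies on. The pooled-variance t² keeps
small groups bounded (the pooled variance is dominated by the large group)
and reproduces the expected null-tail magnitudes (location ≈ 8, shape ≈ 1,
scale ≈ 2) on both trait scales.

**Main-effect correction.** `correct_main_effects` residualizes the trait
on codominant two-dummy encodings of selected SNPs (missing genotypes
mean-imputed in dummy space) and returns a continuous-trait dataset; the
scan also offers a pair-local variant that residualizes on the four dummies
of the pair under test. The high-level engines apply the global variant
once, up front, when asked to adjust; the pure-epistasis simulations used
in the experiments have no main effects, so the default runs leave the
trait unadjusted.

## Step-down maxT and the memory-bounded rewrite

Classical Westfall–Young maxT computes, for B trait permutations, the
statistics of all `m = s(s-1)/2` pairs, enforces monotonicity along the
observed ranking (a suffix maximum), counts exceedances per rank, and
converts to adjusted p-values `p_j = (1 + #{T_i,j >= T_0,j}) / (B + 1)`
with a final step-down monotonicity pass. Its memory-bounded rewrite
stores only the `n` best observed pairs (default 1000); each permutation
contributes its top-pair statistics plus the single maximum `M_i` over the
`m - n` unstored pairs, which is provably sufficient to reproduce the
classical top-`n` adjusted p-values exactly. The test suite asserts this
equivalence bit for bit under shared permutation streams.

## The gamma-tail estimate of the permutation maximum

Computing `M_i` exhaustively costs O(m) per permutation. The shortcut
models the null statistics of the unstored pairs as a mixture of a point
mass at zero (probability `1 - pi`) and a continuous positive part whose
top `tail_fraction` (default 10 %) follows a three-parameter gamma with
location `y0`, shape `k`, scale `theta`. Estimation, once every
`refit_interval` (default 20) permutations:

1. draw pair indices uniformly with replacement from the unstored pairs
   until `S` strictly positive statistics are collected, counting zeros in
   `z` (`pi = S / (z + S)`);
2. keep the top `tail_fraction` of the positives; `y0` is their minimum;
3. `k` by gamma MLE: closed-form start
   `k0 = (3 - s + sqrt((s-3)^2 + 24 s)) / (12 s)` with
   `s = ln(mean(v - y0)) - mean(ln(v - y0))`, refined by Newton–Raphson on
   `ln k - psi(k) - s` (digamma/trigamma), tolerance 1e-6;
4. `theta = mean(v - y0) / k`.

The maximum of the `q = (m - n) * pi * tail_fraction` tail values is then
distributed as `F_Z(z) = [P(Y <= z)]^q` (regularized incomplete gamma to
the power `q`, with `q` a real number), and `M_i` is *sampled* from `F_Z`
by inverse transform — a bisection from an initial guess (default 1000,
doubled if the fitted tail exceeds it) with step halving to precision 1e-6.
Sampling rather than plugging in an expectation is essential: the
permutation distribution being estimated is a distribution of maxima, not
a point value.

Numerical guards: values equal to `y0` are excluded from both means in the
shape estimate (their log-excess is −infinity); an all-zero source, a
zero-variance tail, or Newton non-convergence raise informative errors
rather than returning garbage; `S` is capped at `max(100, m - n)` so toy
problems remain tractable; `q = 0` (no unstored pairs) makes `F_Z ≡ 1` and
`M_i = 0` by the empty-maximum convention.

**Serving the statistic source.** The sampler only needs a callable from
pair indices to statistics. When the unstored set is no larger than a few
times `S`, the engine evaluates every unstored pair once per refit
(vectorized) and serves lookups — cheaper than on-demand evaluation of
with-replacement draws; for larger problems it evaluates only the
requested pairs in batches. Both routes produce identical values.

## Randomness and parallelism

One master seed; permutation `i` draws its trait shuffle, any tail
sampling, and its `M_i` from an independent substream keyed by
`(seed, i)`. Permutation blocks are aligned to refit boundaries
(`i ≡ 1 mod refit_interval`), so a blocked or multi-process run is
bit-identical to the serial run. The scan side splits the lexicographic
pair enumeration into contiguous blocks whose per-worker top lists merge
(ties broken toward the lower pair id) into exactly the single-worker top
list. File formats (topfile, per-block count vectors, results) mirror this
workflow so external schedulers can drive it.

## Synthetic data

- **Null datasets**: per-SNP minor allele frequencies uniform on
  [0.05, 0.5] (configurable), Hardy–Weinberg genotypes, trait independent
  of genotypes — exactly ⌊n/2⌋ cases for binary traits, standard normal
  for continuous ones.
- **Pure epistasis**: a 3×3 penetrance table `base + a·C` where `C` is a
  rank-one contrast with zero Hardy–Weinberg marginals at both loci (the
  ±1 checkerboard at MAF 0.5), so single-locus penetrances are constant —
  no main effects at any amplitude. The canonical table (baseline 0.05,
  deviation 0.05, MAF 0.5) has prevalence K = 0.05 and heritability
  `h² = Σ p (f - K)² / (K(1-K)) = 0.0025/0.0475 ≈ 0.0526`.
  `calibrate_penetrance` solves the amplitude for a target h² by Brent
  root-finding (round-trip error < 1e-6) and reports the maximum
  achievable h² when a target is out of range (low MAFs cap it, since the
  contrast steepens as 1/heterozygote frequency).
- **Binary sampling** is by rejection: individuals are drawn from the
  genotype distribution, affected with probability `pen[g1, g2]`, until
  the balanced case/control design fills. **Continuous analogue**:
  `trait = mu·z + N(0,1)` with `z` the standardized epistatic contrast and
  `mu` chosen so the pair explains h² of the trait variance.
- **Missingness**: independent per-genotype dropout at a configurable
  rate; the trait is never blanked.

What this emulates — and does not. The generators reproduce the study
conditions of the validation experiments: independent SNPs, Hardy–Weinberg
equilibrium, a single causal pair, balanced designs. Real cohorts add
linkage disequilibrium, stratification, covariates and genotyping error;
passing tests here say nothing about those. They do establish that the
correction controls the family-wise error rate and loses almost no power
relative to exhaustive maxT *under the model's own assumptions*.

## Problem sizes used in the checks

Experiments are sized for a single CPU: family-wise error rate is measured
on 100 null datasets per trait scale (200 SNPs, 500 individuals, B = 199,
S = 10⁴, n = 1000); power on datasets of 200 SNPs and 1000 balanced
individuals (B = 199; 200 replicates in the reproduction script, 120 in
the test suite); the paired gamma-vs-exact power comparison on 50 SNPs,
500 individuals, B = 99, 50 replicates per heritability in
{0.01, 0.02, 0.03}; and the maxima-distribution comparison on 150-SNP,
400-individual datasets with 500 exact and 500 sampled maxima per
replicate. The exact references make larger designs impractical at test
time; the gamma engine itself handles much larger inputs.

## Known limitations

- At small sample sizes the fitted gamma tail can be slightly heavier than
  the true (grainy, discrete-valued) binary statistic tail, making the
  sampled maxima stochastically larger than the exact ones and the
  correction conservative. The effect shrinks visibly from 500 to 1000
  individuals; it is a property of the tail approximation at reduced
  scale, not of the step-down procedure, whose exact backends remain
  available as references.
- The i.i.d. assumption behind `F_Z = F_Y^q` ignores the dependence of
  statistics for pairs sharing a SNP; the dependent fraction of pair-pairs
  decays as ~2/s and is negligible at genome scale but noticeable on very
  small panels.
- The optimal `tail_fraction` is scale-dependent: 10 % is the validated
  default at genome scale, but on small panels (where the maximum of only
  ~10³ tail values is being predicted) smaller fractions can fit the
  maxima distribution at least as well.
- Censored traits, three-locus scans and covariate adjustment beyond SNP
  main effects are out of scope.
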