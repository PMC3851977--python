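# Methods

## Model

A sequenced site in one sample contributes `(n, m, Q)`: `n` variant-
supporting reads out of `m`, with `Q` the average Phred quality of the
variant-supporting bases.  Conditional on a true variant allele frequency
`f` and a per-site read error probability `e`, each read reports the
variant with probability `f + e − 2ef` (a true variant read survives with
probability `1 − e`; a reference read is misread with probability `e`), and
`n` is binomial.  The error is a nuisance parameter with a uniform prior on
`[0, E]`, `E = 10^(−Q/10)`; integrating it out leaves the averaged kernel

    B_{m,n}(a, b) = 1/(b−a) ∫_a^b x^n (1−x)^(m−n) dx,   a = f, b = f + E − 2Ef.

Assumptions worth keeping in mind:

* **one nuisance error per site**, not per read — the model treats the
  average quality as describing a common error level for the site;
* **random errors only** — systematic sequencer or alignment artifacts are
  outside the model;
* **independence across sites and across samples** — paired-sample
  posteriors are products of per-sample posteriors;
* **single variant allele per site** — multi-allelic records must be split
  upstream.

Priors and posteriors are discrete distributions on the frequency grid
`{0, 0.01, …, 1}` (`FrequencyGrid`, resolution 0.01).  The normalization
constant is a discrete sum over the grid; nothing is ever represented as a
continuous density.  Working at 1% precision matches the resolving power of
typical exome depths (the binomial standard error at depth 55 is several
grid steps wide), and every downstream decision (cutoffs, credible sets) is
defined on the same grid, so no interpolation is needed anywhere.

## Parameters

| parameter | default | meaning |
|---|---|---|
| grid resolution | 0.01 | frequency spacing; 1/resolution must be an integer |
| `alpha` | 1e-6 | per-site credible level for presence/difference calls; with ~10^7 tested sites, (1−α)^N ≈ 1 − Nα keeps the genome-wide posterior high (a Bonferroni-style argument) |
| `f_cut` | 0.01 | smallest frequency that counts as "present" (one grid step above zero) |
| `d_cut` | 0.10 | smallest tumor−normal difference for a somatic/LOH call; re-derivable from a validation set via mutual information |
| floor quality | 20 | Phred value used for the error window when a site has no variant-supporting base to average (`n = 0`); the likelihood at `f = 0` still needs an error window, and Q20 (E = 0.01) is a conservative base-calling floor |
| KL tolerance | 1e-3 bits | stop the empirical-prior iteration once consecutive priors differ by no more than this |
| max iterations | 30 | hard cap on prior iterations |
| prior floor | 1e-12 | per-atom floor applied to each prior iterate so a zeroed frequency is not absorbed forever (KL against a zero is infinite) |

## Theoretical diploid prior

For a human-exome-scale experiment with `P ≈ 10^7` coding positions and
`V ≈ 10^4` expected variant positions, the prior places atoms at 0, ½ and 1
with masses proportional to `3(P−V) : 2V : V`.  The 2 : 1 ratio between
heterozygous and homozygous-variant classes follows from placement: a
heterozygous variant can sit on either of the two homologues, a homozygous
variant occupies both at once.  The integer-scaled masses make the ratio
exact in floating point.

## Empirical prior

The empirical prior solves the self-consistency requirement that the prior,
pushed through the likelihood, reproduce the observed data distribution.
The iteration

    p_{i+1}(f) = (1/N) Σ_j P_i(f | D_j)

averages the current posteriors over all N sites with equal weight (a
zero-depth site contributes the prior itself, since its likelihood is
flat).  The per-site kernels do not depend on the prior, so they are
computed once as an (N × G) matrix and each iteration is a single
multiply-and-normalize pass — iteration cost is independent of depth.

Convergence is monitored by the KL divergence (bits) between consecutive
iterates.  No global convergence guarantee is claimed.  Two practical
regimes matter:

* **KL-step stopping (default, 1e-3 bits):** reached in ~10 iterations on
  realistic diploid data.  The mode *locations* and total mode masses are
  accurate at this point, but the heterozygous mode is still close to the
  width of the averaged raw posteriors (binomial spread at the typical
  depth).
* **Tight convergence (tolerance ~1e-8, hundreds of iterations):** the
  iteration continues to sharpen the modes; at the fixed point the mass
  within ±0.02 of each zygosity frequency matches the generating mixture
  proportions to within ±0.02 on the synthetic data used in the tests.
  The test suite checks mixture recovery in this regime, and checks the
  stopping behaviour (KL below 1e-3 bits within 30 iterations) separately.

The same operation runs unchanged on the restricted three-point support
`{0, ½, 1}` for diploid somatic screening.  Priors can be exported/imported
as two-column TSV, which also supports the "estimate on the normal sample,
apply to the tumor" workflow; the default for paired analysis is a single
shared prior, with per-sample priors available through the API.

## Numerical choices

* **Kernel evaluation.**  `B_{m,n}(a,b)` is computed as a difference of
  regularized incomplete-beta values times the complete-beta factor, all in
  log space (the linear value underflows for deep sites, e.g. `2^-500` at
  m = 500).  When the incomplete-beta difference would lose more than half
  its significand to cancellation (relative difference below √ε ≈ 1.5e-8),
  a 64-node Gauss–Legendre rule on `[a, b]` is used instead; a degenerate
  interval `a = b` evaluates the integrand pointwise.  The kernel is
  symmetric in `(a, b)` by construction (bounds are sorted), which handles
  `b < a` for `f > ½`.
* **Posterior assembly.**  Log prior + log kernel, shifted by the maximum
  before exponentiation, then normalized.  All probability accumulation is
  in double precision; a zero total unnormalized mass raises an error.
* **Grid canonicalization.**  Grid and delta values are rounded to 12
  decimals at construction so that they survive text round trips exactly
  and cutoff grids from different code paths are identical floats.
* **Difference posterior.**  The cross-correlation accumulates products in
  ascending-`f2`-within-ascending-`f1` order, making the result
  bit-identical to the naive double loop and hence exactly antisymmetric
  under sample swap.
* **Tie-breaks.**  MAP frequency ties go to the lowest frequency
  (conservative toward reference); genotype ties go to the reference class;
  equal-weight atoms in credible sets are ordered by ascending frequency;
  mutual-information ties in cutoff selection go to the smallest cutoff
  (keeps more candidates above threshold for validation); pileup variant
  alleles tie alphabetically.
* **Degenerate inputs.**  `m = 0` returns the prior as posterior;
  `n = 0` sites have no average variant quality and use the floor quality;
  zero depth in either sample fails the candidate-somatic screen (fails
  closed) but leaves the difference posterior defined.

## Synthetic data

The generators produce the statistical structure the model assumes, with
one integer seed making every run bit-reproducible:

* true frequencies from the diploid zygosity mixture — default proportions
  (0.90, 0.0667, 0.0333), keeping the 2 : 1 het : hom ratio at a variant
  fraction high enough that desk-scale runs (10^4–10^5 sites) populate all
  three modes;
* depths negative-binomial with mean 55 and size r = 5 (the global depth
  distribution of an exome behaves like a Poisson mixed over long-tailed
  local rates, i.e. negative binomial; r = 5 gives clearly visible
  overdispersion), or fixed depth when the dispersion is disabled;
* a fresh error `e ~ U[0, 10^(−Q/10)]` per site (matching the single-`e`
  likelihood), then `n ~ Binomial(m, f + e − 2ef)`; base quality Q = 30 by
  default, optionally jittered;
* paired data add somatic point mutations at germline-reference sites
  (tumor-cell frequency 0.5 by default, rate 0.01) and copy-neutral LOH at
  germline-heterozygous sites (rate 0.01), both diluted toward the germline
  frequency by tumor purity.

What the generator does **not** emulate: read-level artifacts, mapping
error, strand bias, systematic (non-random) base-calling error, correlated
errors across sites, copy-number variation beyond the LOH idealization.
Passing tests therefore demonstrate correctness of the statistical
machinery under the model's own assumptions, not robustness to artifacts
real pipelines must filter upstream.

Problem sizes used in the test suite: 10^4 sites for prior recovery,
genotyping and the somatic end-to-end study (fixed depth 50 for the paired
study, where constant depth isolates the frequency signal); 10^5 sites for
generator law-of-large-numbers checks; 200 randomized cases for the
quadrature-oracle comparison.

## Design choices on open points

* Only the frequency marginal of the joint posterior `P(f, e)` is exposed;
  the error coordinate is a nuisance and is never reported.
* Normalization is over the grid, not the continuum.
* Empirical priors are built per sample by default; pooling or
  transferring a prior between samples goes through the TSV interface.
* Paired calls share one prior by default; independent per-sample priors
  are a parameter away.
* The candidate grid for cutoff selection defaults to the full frequency
  (or difference) grid at 1% steps.
* Aggregated posteriors are exported unnormalized (total mass = number of
  sites), with a normalized option for plotting.

## Known limitations

* Pairwise sample comparison only; k-sample hypothesis algebra is not
  implemented.
* One variant allele per site; indels and multi-allelic records are out of
  scope.
* No copy-number or purity estimation — frequency shifts are reported as
  such, their mechanistic interpretation is the user's.
* The empirical-prior iteration concentrates slowly near its fixed point;
  KL-step stopping is a practical compromise, not a proximity guarantee.
* Mutual-information cutoff selection is a point estimate; no significance
  testing or cross-validation of the selected cutoff is provided.
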