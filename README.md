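# varfreq

Empirical-Bayes estimation of variant allele frequencies from sequencing
read counts, with single-sample variant calling and paired tumor/normal
comparison for somatic mutations and loss of heterozygosity (LOH).

`varfreq` is aimed at analyses where a binary present/absent call on ad hoc
read-count thresholds is too coarse: impure tumor samples, subclonal
populations, copy-number-distorted genomes, RNA-seq allele ratios — any
setting where the allele frequency itself, with honest uncertainty, is the
quantity of interest.

## The model

At a genomic site, the evidence is `(n, m, Q)`: `n` reads supporting the
variant allele out of `m` total, with average Phred quality `Q` on the
variant-supporting bases.  A read is misread with probability `e`, so a
variant base is observed with probability

    f + e − 2ef

for true allele frequency `f`.  The nuisance error `e` is uniform on
`[0, E]` with `E = 10^(−Q/10)`, and marginalising it inside the binomial
likelihood yields the averaged kernel

    B_{m,n}(a, b) = 1/(b−a) ∫_a^b x^n (1−x)^(m−n) dx,

evaluated at `a = f`, `b = f + E − 2Ef`.  Posteriors live on a discrete
frequency grid `{0, 0.01, …, 1}`:

    P(f) ∝ p(f) · B_{m,n}(f, f + E − 2Ef).

The prior `p(f)` can be the theoretical diploid prior (zygosity classes
`0 : ½ : 1` in proportions ≈ 10³ : 2 : 1 for a human exome) or an
**empirical prior**, the fixed point of averaging per-site posteriors over
the dataset:

    p_{i+1}(f) = (1/N) Σ_j P_i(f | D_j),

iterated until the Kullback–Leibler divergence between consecutive iterates
is negligible.

Decisions are credible-bound tests: a variant is *present* when the event
"frequency ≥ f_cut" has posterior mass ≥ 1 − α (defaults `f_cut = 0.01`,
`α = 10⁻⁶`).  For a tumor/normal pair, the posterior of the difference
Δ = f_t − f_n is the cross-correlation of the two sample posteriors; a
somatic gain is called when "Δ ≥ d_cut" is credible (default
`d_cut = 0.10`), a loss when "Δ ≤ −d_cut" is, and LOH screens use |Δ|.
Cutoffs themselves can be calibrated against a truth set by maximizing the
mutual information of the call/truth contingency table.

## Worked example

```python
from varfreq import GridDistribution, SiteObservation, call_variant
from varfreq.priors import empirical_prior
from varfreq.synthetic import SimulationConfig, simulate_sample
from varfreq.compare import PairedObservation, call_frequency_shift

# build an empirical prior from 5,000 synthetic diploid sites
config = SimulationConfig(n_sites=5_000, seed=1)
observations, truth = simulate_sample(config)
prior, trace = empirical_prior(observations, GridDistribution.uniform())
print(f"prior converged after {trace.iterations_run} iterations "
      f"(last KL step {trace.kl_steps[-1]:.2e} bits)")

# a candidate site: 21 variant-supporting reads out of 48, average Q 31
obs = SiteObservation(n_variant=21, m_total=48, q_avg=31.0)
call = call_variant(obs, prior, f_cut=0.01, alpha=1e-6)
print(f"present={call.present}  MAP f={call.map_frequency:.2f}  "
      f"E[f]={call.expected_frequency:.3f}  "
      f"max confident f={call.max_confident_frequency:.2f}")

# paired comparison: the same site is clean in the matched normal
pair = PairedObservation(tumor=obs, normal=SiteObservation(0, 45, None))
shift = call_frequency_shift(pair, prior, prior, d_cut=0.10, alpha=1e-6,
                             direction="gain")
print(f"somatic gain called: {shift.present}  "
      f"E[delta]={shift.expected_delta:.3f}  "
      f"95% delta interval={shift.credible_interval}")
```

Output:

```
prior converged after 11 iterations (last KL step 8.73e-04 bits)
present=True  MAP f=0.49  E[f]=0.490  max confident f=0.22
somatic gain called: True  E[delta]=0.490  95% delta interval=(0.21, 0.64)
```

The site is confidently present: its most likely frequency is 0.49 and even
the conservative one-sided bound guarantees a frequency of at least 0.22 at
the 1 − 10⁻⁶ level.  Against a clean normal (0/45 reads), the frequency
*difference* is credibly above the 10% cutoff, so the variant is flagged as
a somatic gain.

## Command line

The same pipeline is available as subcommands, chaining through plain TSV
tables and VCF:

```sh
varfreq simulate --out-prefix sim --paired --n-sites 5000 --seed 1
varfreq prior    --input sim.counts.tsv --sample normal --out-prefix sim
varfreq call     --input sim.counts.tsv --sample tumor \
                 --prior sim.prior.tsv --out calls.tsv --vcf calls.vcf
varfreq somatic  --input sim.counts.tsv --prior sim.prior.tsv \
                 --out somatic.tsv
varfreq cutoff   --scores scores.tsv --candidates difference --out mi.tsv
```

Counts tables have one row per site with `n_<sample>`, `m_<sample>`,
`q_<sample>` columns; `samtools mpileup` text can be ingested with
`varfreq.io_cli.parse_pileup`.

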