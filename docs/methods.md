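# Methods

`gwasprec` quantifies, by simulation, the mapping precision of genome-wide
association studies: how far — in base pairs and in LD r² — the top
associated variant of a scan sits from the true causal variant, under
different genotyping strategies (full sequence, SNP array, array imputed to
a reference panel), together with null calibration of the genome-wide
false-positive rate (GWFPR, the family-wise error rate) and power analysis
via the non-centrality parameter of the association test.

## Phenotype model

Each replicate samples one causal variant and simulates

    y = g + e,   g = w·u,   w = (x − 2f) / √(2f(1−f))

with `x` the 0/1/2 causal genotype, `f` its coded-allele frequency, and
`u ~ N(0,1)` the effect per standardized genotype (per-allele effect
`b = u/√(2f(1−f))`). Residuals are drawn `e ~ N(0, var(g)(1/q² − 1))`, using
the *realized* variance of `g`, so the causal variant explains exactly the
fraction `q²` of phenotypic variance in the population sense. `q² = 0` gives
the null model `y ~ N(0,1)` with no genetic effect.

Power at the causal site is governed by the non-centrality parameter of the
1-df chi-square statistic,

    NCP = n·q²/(1 − q²) ≈ n·q² ≈ 2·n·f·b²  (small q²),

and the package's power simulations are validated against the closed-form
non-central chi-square tail probability.

A rank-based inverse-normal transformation (INF) is provided for skewed
phenotypes: `z_i = Φ⁻¹((r_i − c)/(n + 1 − 2c))` with average ranks for ties
and Blom's offset `c = 0.375` by default (`c = 0.5` available). Results
depend on ranks only, so the offset and tie policy are asserted as
invariance properties rather than assumed.

## Synthetic population

Real WGS panels are not redistributable, so the study population is
generated by a two-stage founder-mosaic model chosen to reproduce the
*qualitative* features the analysis depends on, not any particular cohort:

1. **Founders.** Per-site target frequencies follow a truncated power-law
   spectrum (density ∝ p^−`sfs_shape`, neutral 1/p at the default shape 1,
   truncated to [`sfs_floor`, 0.5]). Founder alleles are marginally
   Bernoulli(p) but coupled along the chromosome by a Gaussian-copula
   latent field with correlation exp(−d/`ld_length`) (default 30 kb), and
   the target frequencies themselves vary smoothly on the same scale.
   Common variants therefore sit on shared haplotype backgrounds with
   high-LD proxies. Sites with target frequency ≤ `young_freq` (default
   0.02) are treated as *young*: their latent field is partially decoupled
   (loading `young_mixing = 0.6` on the shared field), leaving rare
   variants a few moderate-LD co-inherited partners but far fewer strong
   proxies than common variants — the age/frequency structure of sequence
   data.

2. **Population mosaic.** Study and reference haplotypes are Li–Stephens
   style mosaics over the founders: the copied template switches between
   consecutive sites with probability 1 − exp(−`switch_rate`·Δbp) (default
   2×10⁻⁶/bp, ~500 kb segments), and each copied allele is flipped with
   probability `mutation_rate` (default 2×10⁻⁴). Founder contributions are
   Zipf-weighted (w_k ∝ 1/k^1.3): a few high-weight ancestors form the
   common backbone that any reference panel captures, while the many
   low-weight ancestors carry private alleles that realize as *inherited*
   rare variants — present in a reference panel exactly when their carriers
   are sampled into it, which is what makes the
   causal-present-versus-absent reference contrast meaningful.

QC mirrors sequencing practice: sites with minor-allele count below
`min_mac = 3` (singletons and doubletons, the most error-prone calls) are
removed; variants are classed common (MAF > 0.01) or rare
(0.0003 < MAF ≤ 0.01). All generators are deterministic given a master
seed; per-replicate streams are derived through SeedSequence spawn keys so
interrupted runs resume reproducibly.

Verified generator properties (each a test): the frequency sampler matches
the truncated 1/p density against a numerical-integration oracle; mean LD
r² decays monotonically across distance bins; rare variants have fewer
r² > 0.8 partners within 100 kb than common variants; template-switch
counts match their closed-form expectation.

What the generator does **not** emulate: demographic history and multiple
populations, selection, sequencing error and missingness, sex chromosomes,
genotyping-array ascertainment beyond a MAF-stratified density rule, and
the deep multiplicity of real WGS (~17.6M tests versus ~5×10³ sites here).
Passing tests therefore demonstrate the *direction and mechanism* of the
strategy contrasts, not cohort-specific magnitudes.

## Genotyping strategies

* **wgs** — all retained sites, true genotypes.
* **array** — markers sampled without replacement at genome-wide array
  density (312,264 markers / 3 Gbp ≈ 1.04×10⁻⁴ per bp, ≈ 2082 markers on
  20 Mbp), with selection weights heavily favouring common variants.
* **imputed** — array markers imputed against a held-out reference panel of
  `n_ref` individuals covering the markers plus a configurable fraction (or
  explicit mask) of the remaining sites.

Imputation is a Li–Stephens hidden Markov model on truth-phased haplotypes
(phasing is deliberately not re-estimated, isolating the imputation
effect). Transitions switch to a uniformly random reference haplotype with
probability 1 − exp(−ρ·d/K) over a gap of d bp (K reference haplotypes;
default ρ = 4×10⁻⁴ matches the population switch rate at K = 200);
emissions at typed sites mismatch with probability ε = 5×10⁻³ (ε = 0 is
rejected — it zeroes the likelihood whenever no reference path matches).
Because the uniform-switch kernel composes over distance, posteriors at
untyped sites are interpolated exactly from the flanking typed sites; the
whole forward–backward pass is checked against exhaustive path enumeration
to 1e-10 on small instances. Typed sites return the observed hard genotypes
with INFO = 1. The INFO score is the IMPUTE-style information measure
1 − (mean posterior dosage variance)/(2f̂(1−f̂)), clamped to [0,1], with
INFO = 0 at monomorphic dosages; no INFO-based filtering is applied by
default. Dosages (not hard calls) are tested by default; a hard-call flag
exists for sensitivity analysis.

At the default scale the model imputes untyped common variants at mean
true r² ≈ 0.7 and rare variants ≈ 0.2 — the common ≫ rare stratification
that drives the results; pushing common accuracy to modern-panel levels
(>0.9) is not attainable jointly with inherited rare variants at ~2000
markers and n_ref ≤ 250, and the analyses here depend on the contrast, not
the absolute level.

## Association scan and summaries

Each polymorphic site is tested by OLS of the phenotype on dosage with
intercept; the Wald 1-df chi-square uses normal-approximation P values
(indistinguishable from t at GWAS sample sizes). Zero-variance columns are
flagged and skipped. The batched scan (`scan_many`) is one matrix product,
algebraically identical to the per-replicate scan (`χ² = (n−2)R²/(1−R²)`),
and is what makes 10³–10⁴-replicate grids tractable on one CPU.

The top hit of a replicate is the smallest-P site within a window around
the causal position (default 20 Mbp) passing the significance threshold;
ties break to the nearest site, then the smallest position. Replicates with
no passing site count toward power's denominator only — precision CDFs
condition on detected loci. Hit records carry the distance, the MAF
difference, the LD r² with the causal variant (always computed on true
genotypes), and the variance explained q²_GWAS, which in expectation
decomposes as q²·R²_imp·r².

Variance explained by a single variant is estimated by the Ezekiel-adjusted
squared correlation, 1 − (1−r²)(n−1)/(n−2), which removes the upward
O((1−ρ²)²/n) bias of the raw R² so replicate means recover q²; the
unselected decomposition E[q̂²(proxy)] = q²·r² is verified directly.

λ_GC is median(χ²)/0.4549 (the χ²₁ median). A caveat established by both
analysis and simulation: scanning a *squared* (skewed) null phenotype
against rare variants inflates the extreme tail of the statistic
distribution — the GWFPR — by more than an order of magnitude while leaving
the median (hence λ_GC) essentially at 1, because the statistic at a rare
site is a squared standardized Gamma mean whose median sits slightly
*below* the χ²₁ median. The INF restores nominal tail calibration; the
package's tests assert the tail phenomenon and its repair directly.

## Experiment designs and problem sizes

The default scenario scales the design to desk size while preserving the
signal regime: n = 2000 diploid individuals on a 20 Mbp chromosome with
5000 sites, 2000 precision replicates at q² = 2%, a 0–3% q² power grid in
0.2% steps, and a 1000-replicate null calibration on the 5e-8…1e-11
threshold grid. Raising q² keeps NCP in the published operating range
(NCP ≈ 74 corresponds to n = 3642 at q² = 2%, and equivalently to
n ≈ 250,000 at q² ≈ 0.03%), so conclusions transfer by the NCP equivalence
argument rather than by raw sample size.

Two threshold regimes are used deliberately. Strategy contrasts at common
scale run at genome-wide 5e-8. The reference coverage-versus-size
experiment instead uses a multiplicity-matched per-test threshold of 1e-4:
on ~4.3×10³ tests this reproduces the family-wise regime that 5e-8 induces
at full sequencing multiplicity (millions of tests), and
without it the conditional distance CDFs saturate at 1 and the coverage
effect is invisible. "Doubling n_ref at fixed coverage" is implemented as a
nested reference — the doubled panel contains the base panel's individuals
and imputes exactly the base panel's covered polymorphic sites — because an
independently drawn larger panel changes variant coverage and sample size
together and the two effects cannot be separated.

## Numerical choices and degenerate inputs

P values are floored at 1e-300 to stay in (0,1]; forward–backward
variables are renormalized at every typed site; monomorphic causal
genotypes with q² > 0 raise an error (the standardized genotype is
undefined), as do constant phenotypes under INF, empty replicate sets in
the aggregators, and queries with no criterion. Empty causal-MAF bins
report NaN (undefined), never 0.

## Known limitations

Single causal variant per replicate (no allelic heterogeneity), quantitative
traits only (no case-control ascertainment), no covariates or relatedness
(individuals are unrelated by construction), one linear chromosome, no
genotyping error or missingness, and LD magnitudes that are tuned to
qualitative targets rather than matched to any real cohort. The hosted
query service of the original analysis is replaced by the `query`
CLI/library operation over hit tables.
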