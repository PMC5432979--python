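# gwasprec

Simulation framework for quantifying the **mapping precision of genome-wide
association studies**: the physical distance — and the LD r² — between the
top associated variant of a GWAS and the true causal variant, compared
across genotyping strategies (whole-genome sequence, SNP array, and array
data imputed to a reference panel), together with genome-wide
false-positive-rate calibration and non-centrality-based power analysis.

It is written for statistical geneticists who design fine-mapping
experiments or sequencing/genotyping strategies and want a controlled,
fully synthetic testbed: how close to the causal variant should I expect
the top hit to be, for common versus rare causal variants, and how much
does the imputation reference's variant coverage or sample size matter?

## The model in brief

Each replicate samples a causal variant and simulates a quantitative trait

    y = g + e,  g = w·u,  w = (x − 2f)/√(2f(1−f)),  u ~ N(0,1),
    e ~ N(0, var(g)(1/q² − 1)),

so the causal variant explains a fraction q² of phenotypic variance; q² = 0
is the null. Detection power is governed by the non-centrality parameter of
the 1-df association chi-square,

    NCP = n·q²/(1 − q²) ≈ 2·n·f·b².

A per-variant OLS scan selects the top hit passing a significance
threshold; aggregating replicates yields power, the family-wise error rate
under the null (GWFPR), and mapping-precision CDFs over distance, MAF
difference and LD r². Populations come from a founder-mosaic generator
(truncated 1/p frequency spectrum, distance-decaying LD, young rare
variants with few LD proxies, Zipf-skewed founder genealogy); imputation is
a Li–Stephens copying HMM on truth-phased haplotypes, verified against
exhaustive path enumeration. See `docs/methods.md` for the full account.

## Worked example

Run a scaled mapping-precision experiment from a declarative config:

```bash
cat > demo_cfg.json <<'EOF'
{
 "n_individuals": 800,
 "region_length": 8000000,
 "n_sites": 2000,
 "precision_replicates": 400,
 "precision_q2": 0.05,
 "p_threshold": 1e-06,
 "strategies": [
  {"name": "wgs", "kind": "wgs"},
  {"name": "array", "kind": "array"},
  {"name": "imputed", "kind": "imputed", "n_ref": 100, "coverage": 0.6}
 ],
 "seed": 1
}
EOF
gwasprec precision --config demo_cfg.json --out demo_run
```

which prints (deterministic for this config and seed):

```
             array common: 326/400 powered, 80% of hits within 0.2 Kbp
             array   rare: 25/400 powered, 80% of hits within 3.1 Kbp
           imputed common: 339/400 powered, 80% of hits within 0.0 Kbp
           imputed   rare: 66/400 powered, 80% of hits within 6.4 Kbp
               wgs common: 384/400 powered, 80% of hits within 0.0 Kbp
               wgs   rare: 383/400 powered, 80% of hits within 0.0 Kbp
```

Reading the numbers: `powered` counts replicates whose scan produced any
significant hit near the causal variant — full sequence detects rare causal
variants in 383/400 replicates while the array alone manages 25/400,
because rare variants are poorly tagged and poorly imputed. Conditional on
detection, 80% of full-sequence hits are *at* the causal variant (0.0 Kbp),
while imputed rare-variant hits spread out to several Kbp. Per-replicate
hit tables land in `demo_run/precision_{common,rare}.tsv`; a query in the
style of an online mapping-precision lookup intersects distance and LD
thresholds:

```bash
gwasprec query --hits demo_run/precision_rare.tsv --max-distance 33500 --min-r2 0.8
```

```
array: 0.6000 of 25 hits satisfy the query
imputed: 0.6970 of 66 hits satisfy the query
wgs: 0.9948 of 383 hits satisfy the query
```

i.e. 99.5% of sequence-based rare-variant hits are within 33.5 Kbp *and* in
r² ≥ 0.8 with the causal variant, versus ~70% for the imputed strategy.
Other subcommands: `simulate-pop` (write a synthetic phased panel as VCF),
`calibrate-null` (GWFPR over a threshold grid, with optional skewed /
inverse-normal-transformed phenotypes), `power` (power over a q² grid) and
`fixtures` (tiny deterministic dataset).

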