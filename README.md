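# qtsmap

Mixed-model mapping of quantitative-trait SNPs (QTS) under a **full genetic
model** — additive (`a`), dominance (`d`), digenic epistasis (`aa`, `ad`,
`da`, `dd`) and random environment-interaction effects (`ae`, `de`, `aae`,
`ade`, `dae`, `dde`) — for multi-family (NAM-style) inbred-line panels,
with heritability partitioning and prediction of superior genotype
combinations.

The package covers the whole analysis chain:

| stage | module | what it does |
|---|---|---|
| simulate | `qtsmap.nam_simulator` | NAM-style population: biparental families crossed to a common parent, selfed with Haldane recombination; MCAR or heterozygote-biased genotype masking; phenotypes generated under the full model |
| prescan | `qtsmap.prescan_gmdr` | GMDR-style 1D/2D candidate pre-selection by cross-validated high/low-risk cell classification |
| map | `qtsmap.assoc_mixedmodel` | Henderson method III (fitting-constants) F-tests of each candidate term, experiment-wise thresholds from a within-environment permutation max-F null, backward pruning |
| estimate | `qtsmap.effect_estimation` | Normal/inverse-gamma Gibbs sampler for fixed effects, G×E deviation levels and variance components; heritability partition into the 12 per-kind components plus `h2_T` and `h2_D+` |
| predict | `qtsmap.genotype_prediction` | Total genotypic values; best observed line (BL); exact superior line (SL, homozygous-only) and superior hybrid (SH, heterozygotes allowed) via per-component exhaustive enumeration of the epistasis graph |
| validate | `qtsmap.validation_study` | Monte-Carlo harnesses: missing-genotype policy check, permutation-threshold calibration, end-to-end parameter recovery |

Genotype calls are `QQ` / `Qq` / `qq` / `NA` with `Q` the non-reference
allele; the additive coefficient codes `QQ → +1`, `qq → −1`, and **missing
calls are analyzed as heterozygotes** (the dominance coefficient is the
heterozygote indicator). `validation_study.missing_genotype_experiment`
quantifies when that policy is safe.

## CLI

Every subcommand takes a YAML config plus optional `--seed`, `--out-dir`,
`--log-level` overrides, and stages communicate through TSV/CSV files in
the output directory:

```sh
qtsmap simulate cfg.yaml   # genotypes.csv, phenotypes.csv, truth.tsv
qtsmap prescan  cfg.yaml   # candidates_<trait>.tsv
qtsmap map      cfg.yaml   # scan_<trait>.tsv (F, p_point, p_EW, selected)
qtsmap estimate cfg.yaml   # effects_<trait>.tsv, heritability.tsv, architecture_<trait>.tsv
qtsmap predict  cfg.yaml   # prediction_<trait>.tsv (QQ/qq/F1/BL/SL/SH x G, G+GE_h), edges, plan diffs
qtsmap report   cfg.yaml   # Monte-Carlo validation report
```

A minimal config:

```yaml
seed: 1
out_dir: out
genotypes: {path: out/genotypes.csv, dialect: matrix-csv}   # or hapmap-like
phenotypes: out/phenotypes.csv
traits: [trait]
model: full            # or additive
n_perm: 2000
alpha_ew: 0.05
mcmc: {n_iter: 20000, burn_in: 2000, thin: 5}
prescan: {dim: 2, folds: 10, top_k: 20, top_m: 20}
predict: {direction: {trait: "+"}}
simulate:
  n_families: 25
  lines_per_family: 200
  selfing_generations: 5
  missing_rate: 0.23
  environments: 4
  architecture: truth.tsv   # effects-table TSV, optional
```

Genotype dialects: a simple matrix CSV (`line[,family],S1_100,...` with
letter or 2/1/0/NA cells) and a HapMap-like tab format
(`rs alleles chrom pos` + one column of two-letter calls per line).
Phenotypes are long-format CSV (`line,environment,trait,value`).

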