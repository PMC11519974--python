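# expresso

Gene-expression prediction models trained **entirely from eQTL summary
statistics**, with annotation-aware penalization — plus the downstream
analyses that make the models useful: summary-based TWAS, a cross-cell-type
effect-heterogeneity test, cell-type specificity enrichment, and
drug-repurposing signatures.

## Who this is for

The largest bulk and single-cell eQTL resources are released as summary
statistics only, while classical TWAS weight training needs individual-level
genotypes and expression.  This package closes that gap for statistical
geneticists who want to (a) train prediction weights from marginal eQTL
z-scores and a reference LD panel, (b) test genes against GWAS summary
statistics, and (c) ask whether a gene's trait effect differs between cell
types.

## The model

With standardized genotypes and expression, the weights solve the
summary-statistics elastic net with a *partitioned* penalty

```
min_beta  beta' G beta - 2 beta' r
          + (lambda/4) sum_j m_j beta_j^2 + (lambda/2) sum_j m_j |beta_j|
```

where `G` is reference-panel LD, `r_j = z_j / sqrt(z_j^2 + n_j - 2)` the
marginal correlation recovered from the eQTL z-score, and `m_j = phi < 1`
for "essential" variants overlapping epigenomic annotation (H3K27ac,
H3K4me3, DNase, CTCF), 1 otherwise.  Tuning is the interesting part:

* **lambda** is set by *pseudo-variable selection*: simulate null predictors
  with the same LD (`r_pi ~ N(0, G/N)`), and take the smallest penalty that
  expels all of them — averaged over ten replicates.
* **phi and the cis-window** (linear flanks or 3D-genome regions: loops,
  TADs, domains, pcHi-C) are chosen by 5-fold cross-validation run purely on
  summary statistics, by decomposing `X'y` into simulated per-individual
  contributions that sum exactly to the observed vector.

Downstream, gene-trait association uses the weighted-burden statistic
`Z = w'z / sqrt(w'Gw)`, and the cross-cell-type heterogeneity of TWAS
z-scores `U_1..U_K` is tested with `H = sum_k (U_k - Ubar)^2`, whose null is
a weighted sum of chi-squares with weights from the eigenvalues of the
centered LD-induced correlation of `U`.

See `docs/methods.md` for assumptions, defaults, and numerical choices.

## Worked example

Simulate a gene (50 cis-variants, 1,000 eQTL samples, cis-h2 0.3, five
causal variants enriched in annotated intervals, mediated GWAS effect),
train a model, and run the TWAS:

```yaml
# cfg.yaml — overrides of the generator defaults
p: 50
n_ref: 500
n_eqtl: 1000
n_gwas: 50000
alpha_med: 0.2
```

```bash
expresso simulate --config cfg.yaml --seed 7 --out-dir sim
expresso train --eqtl sim/eqtl.tsv --ld-ref sim/reference.dosage.tsv \
    --genes sim/genes.tsv \
    --tracks sim/tracks/H3K27ac.bed --tracks sim/tracks/H3K4me3.bed \
    --tracks sim/tracks/DNase.bed  --tracks sim/tracks/CTCF.bed \
    --flank-bp 20000,60000 --seed 1 --out models
expresso twas --models models --gwas sim/gwas.tsv \
    --ld-ref sim/reference.dosage.tsv --out assoc
```

which prints

```
wrote 10 file(s) under sim
trained 1 model(s)
1 gene(s) tested, 1 significant, 1 locus/loci
```

The trained model (`models.meta.json`) selected the small window, a strong
mitigation `phi = 1/6` (annotated variants get one sixth of the penalty) and
`lambda = 0.285`:

```
"GENE1::NA": {
 "chosen_lambda": 0.28503613466293193,
 "chosen_phi": 0.1667,
 "chosen_window": "linear_20000",
 "training_n": 1000.0
}
```

and the association table (`assoc.twas.tsv`) shows the gene is picked up
with overwhelming evidence under the simulated mediated effect:

```
gene    cell_type  z          p              n_weights_used  low_coverage
GENE1   NA         25.754     2.90e-146      8               False
```

`z` is the weighted-burden TWAS z-score of the gene, `p` its two-sided
normal p-value, and `n_weights_used` the number of model variants found in
the GWAS after allele harmonization.  The locus table places the gene in a
single 1 Mb locus around its midpoint.  A null gene (`h2_cis: 0`) run
through the same commands reports `trained 0 model(s)`: genes whose best
cross-validated loss never beats the empty model are emitted as "no model".

Further subcommands: `expresso het` (cross-cell-type heterogeneity test),
`expresso enrich` (cell-type specificity enrichment of TWAS hits),
`expresso signature` (ranked up/down gene lists, eligible with >= 10 genes
per side).  Everything is also callable as a library; the CLI is a thin
layer over `expresso.tuning.train_model`, `expresso.association`,
`expresso.heterogeneity` and friends.

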