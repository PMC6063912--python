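# splitomics

Tools for the two computational arms of a two-group (treatment vs.
control) multi-omics study of the kind used in nutritional-intervention
work on the mouse gut:

1. **Dichotomised transcriptome analysis** — call differentially
   expressed genes (DEGs) on a log2 expression matrix, split them into
   up- and down-regulated sets, test each set for gene-ontology-style
   term enrichment, summarise how disjoint the two enriched-term lists
   are (the "dichotomisation" of metabolic vs. immune programmes), and
   analyse a signed, directed interactome for genes whose interaction
   partners are over-represented among the DEGs (regulator hubs), with
   subnetwork, hub-ranking and downstream/upstream (d/u) annotation.
2. **¹H-NMR chemometrics** — unit-variance scaling, PCA, and O-PLS-DA
   of binned spectra against a two-class dummy, with stratified 8-fold
   cross-validated Q²Y, Y-permutation significance, back-scaled
   correlation loadings filtered at the critical Pearson correlation,
   spectral-region integration, and multiplicity-corrected group
   comparison of the integrals.

A seeded synthetic-data module generates every input with planted
effects (up/down gene sets, term collections, regulator hubs,
discriminatory metabolites), so the whole pipeline is testable by
parameter recovery without any external data.

## The statistics at the core

**Over-representation.** Enrichment of a query gene set (or of a gene's
interaction partners) is the one-sided hypergeometric tail

&nbsp;&nbsp;&nbsp;&nbsp;P(X ≥ k), X ~ Hypergeom(N, K, n),

with overlap *k*, query (or partner) size *n*, marked-set size *K* and
background size *N*, computed in log space so extreme tails stay
representable. Fold enrichment is (k/n)/(K/N). Families are adjusted by
Benjamini–Hochberg (default), Šidák or Bonferroni.

**O-PLS-DA.** Spectra **X** (mean-centred, unit-variance scaled) are
regressed on a −1/+1 class dummy **y**. The predictive weight is
**w** ∝ **X**ᵀ**y**; each orthogonal component is extracted from the
predictive loading after removing its projection on **w**
(**w**ₒ = **p** − (**w**ᵀ**p**)**w**) and deflated from **X**, so the
orthogonal scores are exactly uncorrelated with **y**. With zero
orthogonal components the model is one-component NIPALS PLS1. Model
quality is R²Y on the training data and Q²Y = 1 − PRESS/SS from
stratified k-fold cross-validation (scaling refit inside each training
fold); significance is the Y-permutation p = (1 + #{Q²ₚₑᵣₘ ≥ Q²ₒᵦₛ}) /
(B + 1). Per-bin interpretation uses the Pearson correlation *r* of the
raw bin with the predictive score, back-scaled as *r*·sd(bin) so the
loading trace keeps spectral line shapes and signs; bins are flagged
when |r| exceeds the critical correlation r\* = t\*/√(t\*² + n − 2).

## Worked example

```python
from splitomics import (DifferentialExpression, connectivity_enrichment,
                        encode_dummy, enrich, permutation_test, term_dichotomy)
from splitomics.simulate import (generate_expression, generate_gene_sets,
                                 generate_network, generate_spectra)

expr, groups, truth = generate_expression(seed=42)        # 2000 genes, 8 vs 8
deg = DifferentialExpression(p_threshold=0.05, fc_threshold=1.5).fit(expr, groups)
print(f"DEGs: {len(deg.up_)} up, {len(deg.down_)} down of {len(expr)} genes")

sets, labels = generate_gene_sets(truth, seed=42)
up = enrich(deg.up_, sets, set(expr.index))
down = enrich(deg.down_, sets, set(expr.index))
print("enriched terms (up-only, down-only, shared):", term_dichotomy(up, down))

net, net_truth = generate_network(truth=truth, seed=42)
conn = connectivity_enrichment(net, deg.up_ | deg.down_, set(expr.index))
print("over-connected genes:", (conn.p_adjusted < 0.05).sum())

spectra, _ = generate_spectra(seed=42)                    # 10 vs 10, 400 bins
y, _ = encode_dummy(spectra.labels.values)
res = permutation_test(spectra.X, y, n_orth=1, n_permutations=1000, seed=42)
print(f"O-PLS-DA: Q2Y = {res.q2_observed:.3f}, permutation p = {res.p_value:.4g}")
```

prints

```
DEGs: 100 up, 100 down of 2000 genes
enriched terms (up-only, down-only, shared): (11, 11, 0)
over-connected genes: 8
O-PLS-DA: Q2Y = 0.543, permutation p = 0.000999
```

All 200 planted DEGs are recovered with the correct direction; the up-
and down-enriched term lists share no term (the dichotomy); the eight
over-connected genes are exactly the eight planted regulators; and the
planted doubled metabolite yields a cross-validated Q²Y of 0.54 that no
permuted class labelling matches in 1000 tries.

The same steps are available from a shell via the `splitomics` CLI
(`simulate`, `deg`, `enrich`, `connect`, `network`, `pca`, `opls`,
`integrate`); every stochastic subcommand takes `--seed`.

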