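# pagenet

Cross-process transcriptome comparison: parametric gene-set enrichment
(PAGE), fold-change differential gene sets, and Fisher's-exact gene-set
association networks.

## What it is for

A recurring question in regeneration biology is whether a tissue repairing
itself re-activates the transcriptional programs of its own development —
for example kidney regenerating after ischemia-reperfusion (I/R) injury
versus embryonic/postnatal kidney development. Answering it from expression
data takes a chain of standard steps that must agree on conventions:
per-platform quantile normalization, variable-gene hierarchical clustering
(per experiment and merged across species via orthologs), per-comparison
fold changes, gene-set enrichment, thresholded differential (DE) gene
lists, and a pairwise overlap network linking the two processes.

`pagenet` implements that chain as a tested Python library, and ships a
synthetic-data generator that emulates the paired study design — an injury
time course (two tissues; sham vs 6 h/24 h/120 h; n = 3 arrays per group)
and a developmental time course (E16d vs PN1d/PN7d; n = 5) — with planted
differential gene sets and a planted cross-process "shared program", so
every stage is validated against known ground truth without external data.

## The statistics at the core

For a comparison, each gene's log2 fold change is the difference of group
means of log2(x+1). PAGE converts a gene set's mean fold change into a
Z-score against the all-gene background:

    Z = (Sm − μ) · √m / δ

where Sm is the mean fold change of the set's m profiled members, and μ, δ
are the mean and (population) standard deviation of all genes' fold
changes; p = 2·(1 − Φ(|Z|)), Bonferroni-corrected over the tested sets.
Significant sets carry a *leading edge*: members whose signed linear fold
change (r if r ≥ 1 else −1/r) strictly exceeds ±1.5.

DE gene sets are the genes beyond the same ±1.5 fold cutoff, up and down,
per comparison (8 comparisons → 16 sets). Association between two gene
sets A, B within a universe of N measured genes is the one-sided
hypergeometric tail P(X ≥ |A∩B|), X ~ Hypergeom(N, |A|, |B|) — Fisher's
exact test for over-representation — Bonferroni-corrected over all tested
pairs; significant pairs become network edges. Cross-species pairs are
tested within the ortholog-shared universe. Sample clustering uses
1 − Pearson correlation over log2 intensities with unweighted average
linkage (UPGMA) and a deterministic tie-break.

## Worked example

```sh
python examples/03_page_enrichment.py
```

prints, for the injury-peak comparison of the default synthetic dataset
(seed 1):

```
cortex_24h_vs_sham: mu=-0.0000, delta=0.4285 over 6000 genes
7 of 300 tested sets significant:
  set168  m= 24  Z= +12.19  p_adj=1.11e-31  up    leading edge: 21 genes
  set298  m= 22  Z= +12.07  p_adj=4.39e-31  up    leading edge: 21 genes
  set030  m= 25  Z= -11.70  p_adj=3.88e-29  down  leading edge: 22 genes
  ...
planted for this comparison: ['set133', 'set298', 'set124', 'set168', 'set263'] + ['set030', 'set254']
```

The seven significant sets are exactly the five planted up (including the
three shared-program sets) and two planted down; each Z is the set's mean
fold change standardized against the background, and the leading edge
counts its members past 1.5-fold. `examples/04_overlap_network.py`
continues to the association network and prints the four cross-process
edges connecting the 24 h up-sets to the postnatal down-sets — the planted
shared program recovered as injury↔development association.

Other entry points: `examples/01`–`05` cover simulation, clustering,
enrichment, the network, and the full pipeline; the `pagenet` CLI wraps
the same stages (`pagenet all --outdir out --seed 1`, plus `simulate`,
`normalize`, `cluster`, `enrich`, `network`).

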