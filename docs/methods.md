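# Methods

## Analysis model

`pagenet` compares two biological processes measured as expression time
courses — the motivating case is kidney regeneration after
ischemia-reperfusion (I/R) injury versus kidney development — through a
fixed chain of stages operating on gene × sample matrices of nonnegative
linear-scale intensities.

**Normalization.** Columns are quantile-normalized: each sample's k-th
order statistic is replaced by the cross-sample mean of k-th order
statistics. Tied values within a column receive the mean of the normalized
values their rank range spans (the usual tie dialect of the method; the
method's name alone does not pin it down). On tie-free data the operation
makes every column's sorted vector identical and is an exact fixed point;
with ties the equality is only approximate, which is why the exactness
property is asserted on continuous data.

**Fold changes.** For a comparison (test group vs reference group, each
with ≥ 2 samples), a gene's log2 fold change (lfc) is the difference of
group means of log2(x+1). Averaging on the log scale (rather than taking
the log of mean intensities) keeps replicate noise approximately Gaussian
per gene, which is the distributional premise of the PAGE statistic. The
signed linear fold change maps ratio r = 2^lfc to r when r ≥ 1 and −1/r
otherwise, so "−1.5" reads as 1.5-fold down and the cutoff is symmetric.

**PAGE enrichment.** A gene set with m members in the profile, member mean
fold change Sm, against a background with mean μ and standard deviation δ
over all profiled genes, scores Z = (Sm − μ)·√m/δ, with a two-sided normal
p-value and Bonferroni correction over the sets actually tested. Choices
the statistic's usual description leaves open, pinned here: δ uses the
population (n) denominator; sets with fewer than `min_set_size` (default
10) profiled members are skipped, because Z for tiny sets is dominated by
single genes; direction is the sign of Z; the leading edge of a
significant set is its members whose signed fold change strictly exceeds
the ±1.5 default cutoff in the set's direction.

**DE gene sets and the association network.** Per comparison, the up and
down DE sets are the genes strictly beyond ±1.5 signed fold change (eight
comparisons → sixteen sets). Association between two gene sets is the
one-sided over-representation tail of the hypergeometric distribution
(Fisher's exact test), computed by `scipy.stats.hypergeom.sf`. Two
Bonferroni families are used in sequence, mirroring the two stages of the
analysis: (DE sets × catalog sets) to select annotation nodes, then all
node pairs actually tested for edges. Each pair is tested inside the
intersection of its endpoints' universes: rat nodes use the rat measured
genes; mouse-derived nodes use the ortholog-mapped gene set translated to
the shared (rat-ID) namespace, so cross-species pairs are judged against
the ortholog-shared background. Isolated DE nodes (no significant edge)
are dropped by default — the network is about association, and an
unconnected threshold artifact carries no information (the analogous
manual exclusion in published association maps motivated making this a
rule). Exports: SIF, GraphML and node/edge TSVs, Cytoscape-readable.

**Clustering.** Samples are clustered on 1 − Pearson correlation of log2
intensities over the top-k variance genes (k = 2000 by default; variance
on log2(x+1), matching the downstream fold-change scale). Linkage is
unweighted average (UPGMA), implemented in-package because the merge order
under tied distances is part of the contract: among minimum-distance
pairs, the pair whose (smallest leaf ID, largest leaf ID) is
lexicographically smallest merges first, making trees bit-reproducible.
UPGMA heights are non-decreasing and this is asserted on every run.
Newick export places a node merged at height h at ultrametric height h/2.
For the merged cross-species clustering, rows are ortholog pairs (keyed by
the first species' IDs); many-to-many map components are collapsed to the
single pair with the largest summed log2 variance; by default each gene is
median-centered per species before concatenation, since two platforms'
absolute intensities are not comparable and without baseline removal the
tree would simply split by platform. The centering flag is exposed because
no universally right answer exists for cross-platform rescaling.

## Synthetic data: what it emulates and what it does not

The generator reproduces the structure of a paired two-species study: a
rat-like injury experiment (cortex and medulla; sham, 6 h, 24 h, 120 h;
3 replicates per group) and a mouse-like developmental experiment (E16d,
PN1d, PN7d; 5 replicates per group). Log2 intensity = per-gene baseline
(Gaussian, mean 7.0, SD 1.5 — typical array log-intensity spread) +
planted group shift + Gaussian replicate noise; intensities are emitted as
2^log2. The catalog holds 300 sets of 10–50 genes drawn from 6000 genes;
80% of genes have one-to-one orthologs. Per comparison, 2 sets are planted
up and 2 down by ±1.0 log2 units in the test group (all planted sets
globally distinct); a 3-set shared program is planted up in both 24 h
groups and in E16d, so it surfaces as up-regulation at the injury peak and
down-regulation postnatally — the planted analog of regeneration re-using
a developmental program. Effect size 1.0 and noise SD 0.5 are calibration
choices (a clear but not overwhelming twofold shift against realistic
replicate noise), not values taken from any dataset. A single global seed
drives named substreams (catalog, planting, baseline, per-matrix noise),
so adding a stage never perturbs another stage's draws and all outputs are
bit-reproducible.

Deliberately not modeled: probe-level/bead-level structure, background
correction, batch and dye effects, dropout or count noise, tissue-specific
baselines, many-to-many orthology (exercised only through hand-built
fixtures), and realistic effect-size distributions. Passing tests
therefore demonstrate that the chain recovers coherent set-level shifts
under log-normal noise with the study's group sizes — not that it is
robust to array artifacts the generator does not produce.

## Evaluation against planted truth

Enrichment recovery is scored per comparison: planted sets found
significant with the correct direction, and unplanted sets flagged.
Network recovery compares recovered DE–DE edges with the pairs of DE sets
that share a planted set in the matching direction.

One scoring choice matters and is worth stating plainly. Comparisons that
reuse reference arrays — the three injury timepoints of one tissue all
divide by the same sham triplicate; both postnatal days divide by the same
E16d group — have fold-change noise correlated at ρ ≈ 0.5. At replicate
noise 0.5 with n = 3, roughly 7–8% of null genes pass the 1.5-fold cutoff
per direction, and the correlation concentrates the same noise genes in
both lists, so Fisher's test (whose null assumes the two lists are
independent draws from the universe) flags every same-direction,
shared-reference pair essentially always, planted or not. That is a
property of the design, not an implementation error — published
association maps of this kind draw such within-process edges and read them
as temporal continuity. Edge precision/recall and null false-positive
rates are therefore scored over *sample-disjoint* comparison pairs (92 of
the 120 DE–DE pairs), which include every cross-process pair — exactly the
family the shared-program question is about. The full network still
contains the within-process edges; only the truth-scoring restricts.

## Numerical and degenerate-input conventions

Fold-change profiles with zero spread (δ = 0) are an error, as Z is
undefined. Zero-variance samples are rejected before correlation distance
with the offending sample named. Correlation distances are clipped to
[0, 2] and symmetrized against rounding. Fisher p-values are exact to
floating precision (validated against rational-arithmetic enumeration for
N ≤ 25) and clamped into (0, 1]. Bonferroni is min(1, p·family size).
Matrices are written with full float repr so read(write(m)) is exact and
reruns are byte-identical. All readers tolerate `#` comment lines.

## Problem sizes used in validation

The default study scale (6000 genes, 300 sets, 39 arrays, 8 comparisons)
runs the full pipeline in ~10 s on one CPU, so validation uses replicate
studies at full scale: 20 seeded runs for recovery rates (50-gene sets for
the enrichment power check, matching a well-powered category size), 2000
random size-20 sets for null calibration, 50 null runs for the network
false-positive bound, and 200 random ≤ 12-leaf matrices for the clustering
oracle. The acceptance script reproduces the same quantities with 10 runs
per stochastic measure, which keeps it around a minute while leaving
Monte-Carlo error well inside the stated margins.
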