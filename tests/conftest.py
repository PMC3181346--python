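"""Shared fixtures and independent oracle implementations.

The oracles here deliberately take different computational routes from the
package: UPGMA distances are recomputed from scratch as means over original
cross-pairs (the package uses the Lance-Williams update), and hypergeometric
tails are summed in exact rational arithmetic.
"""

from fractions import Fraction
from math import comb

import numpy as np
import pandas as pd
import pytest

from pagenet.expression import ExpressionMatrix


def make_matrix(values, gene_ids=None, sample_ids=None, groups=None, species="rat") -> ExpressionMatrix:
    """Build a small ExpressionMatrix from a 2-D array of linear intensities."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or [f"g{i + 1}" for i in range(n_genes)]
    sample_ids = sample_ids or [f"s{j + 1}" for j in range(n_samples)]
    groups = groups or ["all"] * n_samples
    df = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
    samples = pd.DataFrame(
        {
            "species": species,
            "tissue": "na",
            "timepoint": "na",
            "group": groups,
        },
        index=pd.Index(sample_ids, name="sample"),
    )
    return ExpressionMatrix(df, samples)


def upgma_oracle(item_ids, d):
    """Naive UPGMA: at every step recompute each cluster pair's distance as
    the mean of all original cross-pair distances, merge the minimum (ties:
    lexicographically smallest (min leaf ID, max leaf ID) pair).

    Returns (heights, partitions): the n-1 merge heights, and the leaf
    partition *after* each merge as a frozenset of frozensets of leaf IDs.
    """
    d = np.asarray(d, dtype=float)
    clusters = [frozenset([i]) for i in range(len(item_ids))]
    heights, partitions = [], []
    while len(clusters) > 1:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                pairs = [(i, j) for i in clusters[x] for j in clusters[y]]
                dist = sum(d[i, j] for i, j in pairs) / len(pairs)
                ids_x = min(item_ids[i] for i in clusters[x])
                ids_y = min(item_ids[i] for i in clusters[y])
                key = (dist, (min(ids_x, ids_y), max(ids_x, ids_y)))
                if best is None or key < best[0]:
                    best = (key, x, y)
        (dist, _), x, y = best
        merged = clusters[x] | clusters[y]
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)] + [merged]
        heights.append(dist)
        partitions.append(
            frozenset(frozenset(item_ids[i] for i in c) for c in clusters)
        )
    return heights, partitions


def dendrogram_partitions(dendrogram):
    """Leaf partition after each merge of a package Dendrogram, in the same
    frozenset-of-frozensets form as the oracle."""
    from pagenet.cluster import cut_clusters

    n = dendrogram.n_leaves
    out = []
    for k in range(n - 1, 0, -1):
        assignment = cut_clusters(dendrogram, k)
        groups = {}
        for leaf, c in assignment.items():
            groups.setdefault(c, set()).add(leaf)
        out.append(frozenset(frozenset(g) for g in groups.values()))
    return out


def hypergeom_upper_tail(n_universe: int, a: int, b: int, k: int) -> Fraction:
    """Exact P(X >= k) for X ~ Hypergeom(N, a, b), by rational enumeration."""
    total = comb(n_universe, a)
    acc = Fraction(0)
    for j in range(k, min(a, b) + 1):
        acc += Fraction(comb(b, j) * comb(n_universe - b, a - j), total)
    return acc


@pytest.fixture
def toy_matrix():
    """4 genes x 4 samples in two groups of two, easy numbers."""
    return make_matrix(
        [
            [1.0, 3.0, 7.0, 7.0],
            [15.0, 15.0, 3.0, 1.0],
            [7.0, 7.0, 7.0, 7.0],
            [0.0, 2.0, 5.0, 9.0],
        ],
        groups=["ctrl", "ctrl", "case", "case"],
    )
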