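"""Expression matrices: containers, TSV/GMT IO, normalization, gene selection,
and cross-species ortholog merging.

Conventions
-----------
Expression values are stored on the linear intensity scale (nonnegative).
All log-scale computations in this package use ``log2(x + 1)`` so that the
scale matches the fold changes used downstream.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .errors import EmptyMergeError, FormatError

logger = logging.getLogger(__name__)

SAMPLE_COLUMNS = ("species", "tissue", "timepoint", "group")


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of nonnegative linear-scale intensities.

    Parameters
    ----------
    values : DataFrame
        Rows indexed by gene ID, columns by sample ID, finite and >= 0.
    samples : DataFrame
        One row per sample (index = sample ID) with columns
        ``species``, ``tissue``, ``timepoint`` and ``group``; every sample
        must carry a group label.
    """

    values: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        dup_genes = self.values.index[self.values.index.duplicated()].unique()
        if len(dup_genes):
            raise FormatError(f"duplicate gene IDs: {', '.join(map(str, dup_genes[:5]))}")
        dup_samples = self.values.columns[self.values.columns.duplicated()].unique()
        if len(dup_samples):
            raise FormatError(f"duplicate sample IDs: {', '.join(map(str, dup_samples[:5]))}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression values must be numeric")
        if not np.isfinite(arr).all():
            raise FormatError("expression values must be finite")
        if (arr < 0).any():
            raise FormatError("expression values must be nonnegative")
        if not self.samples.index.equals(self.values.columns):
            self.samples = self.samples.reindex(self.values.columns)
        if self.samples.isna().any(axis=None) or "group" not in self.samples.columns:
            missing = self.samples.index[self.samples.isna().any(axis=1)].tolist()
            raise FormatError(f"samples with missing metadata: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def log2(self) -> pd.DataFrame:
        """log2(x + 1) view of the intensities."""
        return np.log2(self.values + 1.0)

    def samples_in_group(self, group: str) -> list[str]:
        mask = self.samples["group"] == group
        return list(self.samples.index[mask])

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[list(gene_ids)], self.samples.copy())


@dataclass
class OrthologMap:
    """Pairs of (species-A gene ID, species-B gene ID); may be many-to-many."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise FormatError("duplicate ortholog pairs")

    def a_to_b(self) -> dict[str, str]:
        """One-to-one view; raises if the map is not one-to-one."""
        a_ids = [a for a, _ in self.pairs]
        b_ids = [b for _, b in self.pairs]
        if len(set(a_ids)) != len(a_ids) or len(set(b_ids)) != len(b_ids):
            raise FormatError("ortholog map is not one-to-one")
        return dict(self.pairs)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class GeneSetCatalog:
    """Named gene sets (GO-like categories) with unique nonempty memberships."""

    sets: dict[str, tuple[str, list[str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise FormatError(f"gene set {name!r} is empty")
            if len(set(members)) != len(members):
                raise FormatError(f"gene set {name!r} has duplicate members")

    def add(self, name: str, description: str, members: list[str]) -> None:
        if name in self.sets:
            raise FormatError(f"duplicate gene set name {name!r}")
        if not members or len(set(members)) != len(members):
            raise FormatError(f"gene set {name!r} must have unique, nonempty members")
        self.sets[name] = (description, list(members))

    def members(self, name: str) -> list[str]:
        return list(self.sets[name][1])

    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __contains__(self, name: str) -> bool:
        return name in self.sets


# ---------------------------------------------------------------------------
# TSV / GMT readers and writers (all readers tolerate '#' comment lines)
# ---------------------------------------------------------------------------

def write_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write intensities as TSV: header row = sample IDs, first column = gene ID."""
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


def read_matrix(path, samples: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Read a gene x sample TSV.

    If ``samples`` is omitted, minimal metadata is derived from sample IDs of
    the form ``<tissue>_<time>_r<k>`` (group = ``<tissue>_<time>``).
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    dup = df.index[df.index.duplicated()].unique()
    if len(dup):
        raise FormatError(f"duplicate gene row(s): {', '.join(map(str, dup[:5]))}")
    num = pd.DataFrame(index=df.index)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            gene = df.index[bad][0]
            raise FormatError(f"non-numeric cell at gene {gene!r}, sample {col!r}")
        num[col] = converted
    if samples is None:
        samples = infer_sample_table(list(num.columns))
    return ExpressionMatrix(num, samples)


def infer_sample_table(sample_ids: list[str], species: str = "unknown") -> pd.DataFrame:
    """Derive a sample table from ``<tissue>_<time>_r<k>`` / ``<time>_r<k>`` IDs."""
    rows = []
    for sid in sample_ids:
        parts = sid.rsplit("_r", 1)[0].split("_")
        tissue = parts[0] if len(parts) > 1 else "na"
        timepoint = parts[-1]
        rows.append((sid, species, tissue, timepoint, sid.rsplit("_r", 1)[0]))
    return pd.DataFrame(rows, columns=("sample", *SAMPLE_COLUMNS)).set_index("sample")


def write_sample_table(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index_label="sample")


def read_sample_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype=str)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"sample table missing columns: {missing}")
    return df


def write_gmt(catalog: GeneSetCatalog, path) -> None:
    with open(path, "w") as fh:
        for name, (desc, members) in catalog.sets.items():
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_gmt(path) -> GeneSetCatalog:
    catalog = GeneSetCatalog()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"GMT line with <3 fields: {line[:60]!r}")
            catalog.add(fields[0], fields[1], fields[2:])
    return catalog


def write_ortholog_map(omap: OrthologMap, path) -> None:
    with open(path, "w") as fh:
        for a, b in omap.pairs:
            fh.write(f"{a}\t{b}\n")


def read_ortholog_map(path) -> OrthologMap:
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise FormatError(f"ortholog map line with !=2 fields: {line[:60]!r}")
            pairs.append((fields[0], fields[1]))
    return OrthologMap(pairs)


# ---------------------------------------------------------------------------
# Normalization, selection, merging
# ---------------------------------------------------------------------------

def quantile_normalize(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Quantile-normalize columns to the mean order-statistic vector.

    After normalization every column holds the same multiset of values:
    the cross-sample mean of each order statistic. Ties within a column
    receive the mean of the normalized values their rank range spans.
    """
    if matrix.n_samples < 2:
        warnings.warn("quantile_normalize: single sample, returning input unchanged")
        return ExpressionMatrix(matrix.values.copy(), matrix.samples.copy())
    vals = matrix.values.to_numpy(dtype=float)
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(vals.shape[1]):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(ref)
        assigned[order] = ref
        # ties: average the reference values spanned by each tied block
        tied = pd.Series(assigned).groupby(pd.Series(col)).transform("mean")
        out[:, j] = tied.to_numpy()
    values = pd.DataFrame(out, index=matrix.values.index, columns=matrix.values.columns)
    return ExpressionMatrix(values, matrix.samples.copy())


def select_top_variable(matrix: ExpressionMatrix, k: int) -> ExpressionMatrix:
    """Keep the k genes with the largest variance of log2 intensities.

    Ties are broken by lexicographic gene ID; the original gene order is
    preserved in the output.
    """
    if k > matrix.n_genes:
        raise ValueError(f"k={k} exceeds gene count {matrix.n_genes}")
    log2 = matrix.log2()
    var = log2.var(axis=1, ddof=0)
    ranked = sorted(matrix.gene_ids, key=lambda g: (-var[g], g))
    keep = set(ranked[:k])
    kept_in_order = [g for g in matrix.gene_ids if g in keep]
    return matrix.subset_genes(kept_in_order)


def merge_orthologs(
    mat_a: ExpressionMatrix,
    mat_b: ExpressionMatrix,
    omap: OrthologMap,
    center: bool = False,
) -> ExpressionMatrix:
    """Merge two species' matrices on ortholog pairs, keyed by species-A IDs.

    Pairs referencing genes absent from either matrix are dropped (and the
    drop count logged). Many-to-many groups are resolved by keeping, per
    connected component of the map, the single pair with the largest summed
    log2 variance. With ``center=True`` each gene's log2 values are
    median-centered within each species before concatenation (values are
    re-exponentiated so the output stays on the linear scale).
    """
    genes_a = set(mat_a.gene_ids)
    genes_b = set(mat_b.gene_ids)
    retained = [(a, b) for a, b in omap.pairs if a in genes_a and b in genes_b]
    dropped = len(omap.pairs) - len(retained)
    if dropped:
        logger.info("merge_orthologs: dropped %d pair(s) absent from a matrix", dropped)
    if not retained:
        raise EmptyMergeError("no ortholog pairs usable after dropping absent genes")

    log_a = mat_a.log2()
    log_b = mat_b.log2()
    var_a = log_a.var(axis=1, ddof=0)
    var_b = log_b.var(axis=1, ddof=0)

    graph = nx.Graph()
    graph.add_edges_from((("A", a), ("B", b)) for a, b in retained)
    chosen: list[tuple[str, str]] = []
    for component in nx.connected_components(graph):
        cand = [
            (a, b)
            for a, b in retained
            if ("A", a) in component and ("B", b) in component
        ]
        best = max(cand, key=lambda p: (var_a[p[0]] + var_b[p[1]], (p[0], p[1])))
        chosen.append(best)
    chosen.sort()

    rows_a = log_a.loc[[a for a, _ in chosen]]
    rows_b = log_b.loc[[b for _, b in chosen]]
    if center:
        rows_a = rows_a.sub(rows_a.median(axis=1), axis=0)
        rows_b = rows_b.sub(rows_b.median(axis=1), axis=0)
    rows_b.index = rows_a.index
    merged_log = pd.concat([rows_a, rows_b], axis=1)
    merged = np.power(2.0, merged_log) - 1.0 if not center else np.power(2.0, merged_log)
    merged = merged.clip(lower=0.0)
    samples = pd.concat([mat_a.samples, mat_b.samples])
    return ExpressionMatrix(merged, samples)
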