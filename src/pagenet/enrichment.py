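"""Fold-change profiles and parametric gene-set enrichment (PAGE).

For one comparison, each gene gets a log2 fold change (difference of group
means of log2(x + 1)) and a signed linear fold change (ratio r reported as r
when r >= 1 and -1/r when r < 1). A gene set's enrichment statistic is

    Z = (Sm - mu) * sqrt(m) / delta

where Sm is the mean log2 fold change of the m set members present in the
profile and mu, delta are the mean and (population) standard deviation of
the fold changes of all genes. Under no enrichment Z is approximately
standard normal, giving a two-sided p-value; families of tests are
Bonferroni-corrected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateProfileError
from .expression import ExpressionMatrix, GeneSetCatalog, OrthologMap

logger = logging.getLogger(__name__)

DEFAULT_MIN_SET_SIZE = 10
DEFAULT_FC_CUTOFF = 1.5


@dataclass(frozen=True)
class Comparison:
    """A labeled test-vs-reference contrast within one experiment."""

    name: str
    test: str
    reference: str
    stratum: str = ""

    def __post_init__(self) -> None:
        if self.test == self.reference:
            raise ValueError("test and reference groups must differ")


@dataclass
class FoldChangeProfile:
    """Per-gene fold changes for one comparison, with the PAGE background.

    Attributes
    ----------
    lfc : Series
        log2 fold change per gene.
    sfc : Series
        Signed linear fold change (+1 when lfc == 0; |sfc| >= 1).
    mu, delta : float
        Mean and population standard deviation of all lfc values.
    """

    comparison: Comparison
    lfc: pd.Series
    sfc: pd.Series
    mu: float
    delta: float

    @property
    def genes(self) -> pd.Index:
        return self.lfc.index


@dataclass
class EnrichmentResult:
    set_name: str
    m: int
    s_m: float
    z: float
    p: float
    direction: str
    p_adj: float | None = None
    significant: bool = False
    leading_edge: list[str] = field(default_factory=list)


def signed_fold_change(lfc: np.ndarray | pd.Series) -> np.ndarray | pd.Series:
    """Map log2 fold change to signed linear fold change.

    Ratio r = 2**lfc is reported as r when r >= 1 and as -1/r otherwise, so
    a 1.5-fold decrease reads -1.5. lfc == 0 maps to +1.
    """
    return np.where(np.asarray(lfc) >= 0, np.power(2.0, lfc), -np.power(2.0, -np.asarray(lfc)))


def compute_fold_changes(matrix: ExpressionMatrix, comparison: Comparison) -> FoldChangeProfile:
    """Per-gene lfc = mean log2(x+1) over test samples minus reference samples."""
    test_ids = matrix.samples_in_group(comparison.test)
    ref_ids = matrix.samples_in_group(comparison.reference)
    for label, ids in ((comparison.test, test_ids), (comparison.reference, ref_ids)):
        if len(ids) < 2:
            raise ValueError(
                f"group {label!r} has {len(ids)} sample(s); need >= 2 for {comparison.name}"
            )
    log2 = matrix.log2()
    lfc = log2[test_ids].mean(axis=1) - log2[ref_ids].mean(axis=1)
    delta = float(lfc.std(ddof=0))
    if delta == 0.0:
        raise DegenerateProfileError(
            f"all fold changes identical in comparison {comparison.name!r}"
        )
    sfc = pd.Series(signed_fold_change(lfc), index=lfc.index)
    return FoldChangeProfile(comparison, lfc, sfc, float(lfc.mean()), delta)


def translate_profile(profile: FoldChangeProfile, omap: OrthologMap) -> FoldChangeProfile:
    """Rename profile genes from species B to species A via a one-to-one map.

    Genes without an ortholog are dropped; the background mu and delta are
    recomputed over the retained genes.
    """
    b_to_a = {b: a for a, b in omap.pairs}
    keep = [g for g in profile.genes if g in b_to_a]
    dropped = len(profile.genes) - len(keep)
    if dropped:
        logger.info("translate_profile: dropped %d gene(s) without orthologs", dropped)
    lfc = profile.lfc.loc[keep]
    lfc.index = [b_to_a[g] for g in keep]
    delta = float(lfc.std(ddof=0))
    if delta == 0.0:
        raise DegenerateProfileError("translated profile has zero fold-change spread")
    sfc = pd.Series(signed_fold_change(lfc), index=lfc.index)
    return FoldChangeProfile(profile.comparison, lfc, sfc, float(lfc.mean()), delta)


def page_z(
    profile: FoldChangeProfile,
    members: list[str],
    set_name: str = "",
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
) -> EnrichmentResult | None:
    """PAGE Z-score for one gene set; None if fewer than min_set_size members
    intersect the profile (the skip is logged)."""
    present = profile.lfc.index.intersection(members)
    m = len(present)
    if m < min_set_size:
        logger.debug("page_z: set %r skipped (m=%d < %d)", set_name, m, min_set_size)
        return None
    s_m = float(profile.lfc.loc[present].mean())
    z = (s_m - profile.mu) * np.sqrt(m) / profile.delta
    p = float(2.0 * stats.norm.sf(abs(z)))
    return EnrichmentResult(
        set_name=set_name,
        m=m,
        s_m=s_m,
        z=float(z),
        p=p,
        direction="up" if z > 0 else "down",
    )


def leading_edge(
    result: EnrichmentResult,
    profile: FoldChangeProfile,
    members: list[str],
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
) -> list[str]:
    """Members whose signed fold change strictly exceeds the cutoff in the
    direction of the set's Z-score."""
    if fc_cutoff <= 1:
        raise ValueError("fc_cutoff must exceed 1")
    present = profile.sfc.index.intersection(members)
    sfc = profile.sfc.loc[present]
    if result.direction == "up":
        hits = sfc.index[sfc > fc_cutoff]
    else:
        hits = sfc.index[sfc < -fc_cutoff]
    return sorted(hits)


def enrich_catalog(
    profile: FoldChangeProfile,
    catalog: GeneSetCatalog,
    alpha: float = 0.05,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
) -> list[EnrichmentResult]:
    """PAGE over a whole catalog with Bonferroni correction.

    The correction family is the number of sets actually tested (those with
    at least min_set_size members in the profile). Results come back sorted
    by p ascending, ties broken by set name.
    """
    results = []
    for name in catalog.names():
        res = page_z(profile, catalog.members(name), name, min_set_size)
        if res is not None:
            results.append(res)
    if not results:
        logger.warning(
            "enrich_catalog: no testable sets for comparison %r", profile.comparison.name
        )
        return []
    n_tested = len(results)
    for res in results:
        res.p_adj = min(1.0, res.p * n_tested)
        res.significant = res.p_adj < alpha
        res.leading_edge = leading_edge(res, profile, catalog.members(res.set_name), fc_cutoff)
    results.sort(key=lambda r: (r.p, r.set_name))
    return results


def write_enrichment_tsv(results: list[EnrichmentResult], path) -> None:
    """One row per tested set: name, m, Sm, Z, p, p_adj, direction, leading edge."""
    with open(path, "w") as fh:
        fh.write("set\tm\tSm\tZ\tp\tp_adj\tdirection\tleading_edge\n")
        for r in results:
            fh.write(
                f"{r.set_name}\t{r.m}\t{r.s_m:.6g}\t{r.z:.6g}\t{r.p:.6g}\t"
                f"{r.p_adj:.6g}\t{r.direction}\t{','.join(r.leading_edge)}\n"
            )
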