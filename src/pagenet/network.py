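"""Differential gene sets, Fisher overlap tests, and the association network.

Per comparison, the up- and down-regulated gene lists are defined purely by
a signed linear fold-change threshold (strict, default 1.5). Pairwise
association between gene sets is the one-sided (over-representation)
hypergeometric tail P(X >= k) against a stated gene universe, Bonferroni
corrected over all pairs tested. The resulting graph mirrors the functional
association maps drawn in Cytoscape: gene sets are nodes (sized by member
count, colored by a curated functional category) and significant overlaps
are edges.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
from scipy import stats

from .enrichment import DEFAULT_FC_CUTOFF, FoldChangeProfile
from .errors import PagenetError
from .expression import GeneSetCatalog

logger = logging.getLogger(__name__)

FUNCTIONAL_CATEGORIES = (
    "cell cycle/mitosis",
    "immune/inflammation",
    "transport",
    "metabolism",
    "cytoskeleton",
    "others",
)


@dataclass
class DEGeneSet:
    """Genes up- or down-regulated past the fold-change cutoff in one comparison."""

    name: str
    comparison_name: str
    direction: str
    members: frozenset
    universe_tag: str


@dataclass
class OverlapTest:
    set_a: str
    set_b: str
    n_universe: int
    a: int
    b: int
    k: int
    p: float
    p_adj: float | None = None
    significant: bool = False


@dataclass
class AssociationNetwork:
    """Graph of gene sets; wraps a networkx.Graph.

    Node attributes: ``node_class`` (de_set | annotation), ``size`` (member
    count within the node's universe), ``category`` (one of the curated
    functional classes or "unassigned"). Edge attributes: ``p_adj``, ``k``
    (overlap count) and ``overlap_genes`` (comma-joined, DE-DE edges only).
    """

    graph: nx.Graph

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_de_sets(
    profiles: list[FoldChangeProfile],
    fc_cutoff: float = DEFAULT_FC_CUTOFF,
    universe_tags: dict[str, str] | None = None,
) -> list[DEGeneSet]:
    """Two sets (up, down) per profile, via strict signed fold-change cutoffs."""
    if not profiles:
        raise ValueError("profiles must be nonempty")
    if fc_cutoff <= 1:
        raise ValueError("fc_cutoff must exceed 1")
    universe_tags = universe_tags or {}
    out = []
    for profile in profiles:
        cname = profile.comparison.name
        tag = universe_tags.get(cname, "measured")
        up = frozenset(profile.sfc.index[profile.sfc > fc_cutoff])
        down = frozenset(profile.sfc.index[profile.sfc < -fc_cutoff])
        out.append(DEGeneSet(f"{cname}_up", cname, "up", up, tag))
        out.append(DEGeneSet(f"{cname}_down", cname, "down", down, tag))
    return out


def fisher_overlap(a_members, b_members, universe) -> OverlapTest:
    """One-sided over-representation test of |A∩B| against Hypergeom(N, a, b)."""
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be nonempty")
    a_members = set(a_members)
    b_members = set(b_members)
    stray = (a_members | b_members) - universe
    if stray:
        raise PagenetError(
            f"members outside universe: {', '.join(sorted(stray)[:10])}"
        )
    n_u = len(universe)
    a = len(a_members)
    b = len(b_members)
    k = len(a_members & b_members)
    # P(X >= k) for X ~ Hypergeom(N, a, b); k = 0 is the certain event
    p = float(stats.hypergeom.sf(k - 1, n_u, a, b)) if k > 0 else 1.0
    p = min(1.0, max(p, 5e-324))
    return OverlapTest("", "", n_u, a, b, k, p)


def select_annotation_nodes(
    de_sets: list[DEGeneSet],
    catalog: GeneSetCatalog,
    universes: dict[str, set],
    alpha: float = 0.05,
) -> list[str]:
    """Catalog sets significantly over-represented in at least one DE set.

    Bonferroni family = (number of DE sets) x (number of catalog sets).
    """
    names = catalog.names()
    n_tests = len(de_sets) * len(names)
    selected = set()
    for name in names:
        members = set(catalog.members(name))
        for de in de_sets:
            universe = universes[de.universe_tag]
            test = fisher_overlap(de.members & universe, members & universe, universe)
            if min(1.0, test.p * n_tests) < alpha:
                selected.add(name)
                break
    return sorted(selected)


def build_network(
    de_sets: list[DEGeneSet],
    annotation_nodes: list[str],
    catalog: GeneSetCatalog,
    universes: dict[str, set],
    alpha: float = 0.05,
    drop_isolated: bool = True,
    category_table: dict[str, str] | None = None,
    annotation_universe_tag: str | None = None,
) -> AssociationNetwork:
    """Assemble the gene-set association network.

    Nodes are the DE sets plus the selected annotation sets; edges are pairs
    whose one-sided Fisher p, Bonferroni-corrected over all tested pairs, is
    below alpha. Each pair is tested within the intersection of its two
    endpoints' universes (so a cross-species pair is judged against the
    ortholog-shared background). With ``drop_isolated``, DE-set nodes left
    without any significant edge are removed from the graph.
    """
    category_table = category_table or {}
    if annotation_universe_tag is None:
        annotation_universe_tag = max(universes, key=lambda t: len(universes[t]))

    nodes: dict[str, dict] = {}
    members_of: dict[str, set] = {}
    tag_of: dict[str, str] = {}
    for de in de_sets:
        universe = universes[de.universe_tag]
        members_of[de.name] = set(de.members) & universe
        tag_of[de.name] = de.universe_tag
        nodes[de.name] = {
            "node_class": "de_set",
            "size": len(members_of[de.name]),
            "category": category_table.get(de.name, "unassigned"),
        }
    for name in annotation_nodes:
        universe = universes[annotation_universe_tag]
        members_of[name] = set(catalog.members(name)) & universe
        tag_of[name] = annotation_universe_tag
        nodes[name] = {
            "node_class": "annotation",
            "size": len(members_of[name]),
            "category": category_table.get(name, "unassigned"),
        }

    graph = nx.Graph()
    for name, attrs in nodes.items():
        graph.add_node(name, **attrs)
    if not nodes:
        warnings.warn("build_network: empty node list")
        return AssociationNetwork(graph)

    ordered = sorted(nodes)
    tests: list[OverlapTest] = []
    for i, name_a in enumerate(ordered):
        for name_b in ordered[i + 1 :]:
            universe = universes[tag_of[name_a]] & universes[tag_of[name_b]]
            if not universe:
                continue
            test = fisher_overlap(
                members_of[name_a] & universe, members_of[name_b] & universe, universe
            )
            test.set_a, test.set_b = name_a, name_b
            tests.append(test)
    n_tests = len(tests)
    for test in tests:
        test.p_adj = min(1.0, test.p * n_tests)
        test.significant = test.p_adj < alpha
        if test.significant:
            overlap = sorted(members_of[test.set_a] & members_of[test.set_b])
            attrs = {"p_adj": test.p_adj, "k": test.k}
            if (
                nodes[test.set_a]["node_class"] == "de_set"
                and nodes[test.set_b]["node_class"] == "de_set"
            ):
                attrs["overlap_genes"] = ",".join(overlap)
            graph.add_edge(test.set_a, test.set_b, **attrs)

    if drop_isolated:
        lonely = [
            name
            for name, attrs in graph.nodes(data=True)
            if attrs["node_class"] == "de_set" and graph.degree(name) == 0
        ]
        if lonely:
            logger.info("build_network: dropping isolated DE set(s): %s", ", ".join(lonely))
            graph.remove_nodes_from(lonely)
    return AssociationNetwork(graph)


def export_network(network: AssociationNetwork, outdir, formats=("sif", "graphml", "tsv")) -> list:
    """Write the network in Cytoscape-friendly interchange formats.

    ``sif``: "nodeA<tab>overlap<tab>nodeB" lines, isolated nodes as bare
    names. ``graphml``: full node/edge attributes. ``tsv``: separate edge
    and node attribute tables.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    known = {"sif", "graphml", "tsv"}
    bad = set(formats) - known
    if bad:
        raise ValueError(f"unsupported format(s): {sorted(bad)}; choose from {sorted(known)}")
    graph = network.graph
    written = []
    if "sif" in formats:
        path = outdir / "network.sif"
        with open(path, "w") as fh:
            seen = set()
            for u, v in sorted(map(sorted, graph.edges())):
                fh.write(f"{u}\toverlap\t{v}\n")
                seen.update((u, v))
            for node in sorted(set(graph.nodes()) - seen):
                fh.write(f"{node}\n")
        written.append(path)
    if "graphml" in formats:
        path = outdir / "network.graphml"
        nx.write_graphml(graph, path)
        written.append(path)
    if "tsv" in formats:
        npath = outdir / "network_nodes.tsv"
        with open(npath, "w") as fh:
            fh.write("node\tnode_class\tsize\tcategory\n")
            for node, attrs in sorted(graph.nodes(data=True)):
                fh.write(
                    f"{node}\t{attrs['node_class']}\t{attrs['size']}\t{attrs['category']}\n"
                )
        epath = outdir / "network_edges.tsv"
        with open(epath, "w") as fh:
            fh.write("node_a\tnode_b\tp_adj\tk\toverlap_genes\n")
            for u, v in sorted(map(sorted, graph.edges())):
                attrs = graph.edges[u, v]
                fh.write(
                    f"{u}\t{v}\t{attrs['p_adj']:.6g}\t{attrs['k']}\t"
                    f"{attrs.get('overlap_genes', '')}\n"
                )
        written.extend([npath, epath])
    return written


def read_category_table(path) -> dict[str, str]:
    """Two-column TSV mapping set name -> curated functional category."""
    table = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise PagenetError(f"category table line with !=2 fields: {line[:60]!r}")
            table[fields[0]] = fields[1]
    return table
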