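"""Planted-truth evaluation of a synthetic study.

Utilities to run the analysis chain on one synthetic dataset and score what
was recovered against what was planted: enrichment recovery per comparison
and association-network edge confusion.

A statistical caveat drives one scoring choice here. Comparisons that reuse
reference arrays (the three injury timepoints of one tissue all divide by
the same sham triplicate; both postnatal days divide by the same embryonic
group) have positively correlated fold-change noise, so their DE gene lists
overlap far beyond what an independence-based Fisher test expects — such
within-process edges are real properties of the design, not method errors,
and analyses of this kind read them as signal. Edge-level precision/recall
and null false-positive rates are therefore scored over *sample-disjoint*
comparison pairs only (which include every cross-process pair, the pairs
the shared-program plant is about); ``sample_disjoint_node_pairs`` makes
the scored family explicit.
"""

from __future__ import annotations

from dataclasses import dataclass

from . import expression as _expr
from . import network as _net
from . import synthetic as _syn
from .enrichment import FoldChangeProfile, compute_fold_changes, enrich_catalog, translate_profile
from .expression import ExpressionMatrix, GeneSetCatalog, OrthologMap
from .synthetic import GroundTruth, SyntheticConfig


@dataclass
class StudyRun:
    """One synthetic dataset pushed through normalization and fold changes."""

    config: SyntheticConfig
    catalog: GeneSetCatalog
    rat: ExpressionMatrix
    mouse: ExpressionMatrix
    omap: OrthologMap
    truth: GroundTruth
    profiles: list[FoldChangeProfile]
    universes: dict[str, set]
    universe_tags: dict[str, str]


def run_study(config: SyntheticConfig, normalize: bool = True) -> StudyRun:
    """Generate one synthetic study and compute all eight fold-change profiles
    (mouse profiles translated into the shared ortholog namespace)."""
    catalog = _syn.generate_catalog(config)
    rat, mouse, omap, truth = _syn.generate_experiment_pair(config, catalog)
    rat_n = _expr.quantile_normalize(rat) if normalize else rat
    mouse_n = _expr.quantile_normalize(mouse) if normalize else mouse
    profiles, tags = [], {}
    for comp in _syn.ALL_COMPARISONS:
        in_rat = comp in _syn.RAT_COMPARISONS
        profile = compute_fold_changes(rat_n if in_rat else mouse_n, comp)
        if not in_rat:
            profile = translate_profile(profile, omap)
        profiles.append(profile)
        tags[comp.name] = "rat" if in_rat else "mouse"
    universes = {
        "rat": set(rat.gene_ids),
        "mouse": {a for a, _ in omap.pairs},
    }
    return StudyRun(config, catalog, rat_n, mouse_n, omap, truth, profiles, universes, tags)


def enrichment_confusion(
    run: StudyRun, comparison_name: str, alpha: float = 0.05, **enrich_kwargs
) -> dict:
    """Planted-set recovery for one comparison's catalog-wide enrichment.

    Returns counts of planted sets recovered with the correct direction,
    planted sets missed, and unplanted sets flagged, plus the family sizes.
    """
    profile = next(p for p in run.profiles if p.comparison.name == comparison_name)
    results = enrich_catalog(profile, run.catalog, alpha=alpha, **enrich_kwargs)
    expected = {name: "up" for name in run.truth.expected_up(comparison_name)}
    expected.update({name: "down" for name in run.truth.expected_down(comparison_name)})
    flagged = {r.set_name: r.direction for r in results if r.significant}
    recovered = sum(
        1 for name, direction in expected.items() if flagged.get(name) == direction
    )
    false_pos = sum(1 for name in flagged if name not in expected)
    tested = len(results)
    return {
        "planted": len(expected),
        "recovered": recovered,
        "false_positives": false_pos,
        "unplanted_tested": tested - sum(1 for r in results if r.set_name in expected),
    }


def de_network(run: StudyRun, alpha: float = 0.05, fc_cutoff: float = 1.5,
               with_annotation: bool = True, drop_isolated: bool = False):
    """DE sets plus the association network for one study run."""
    de_sets = _net.build_de_sets(run.profiles, fc_cutoff, universe_tags=run.universe_tags)
    annotation = (
        _net.select_annotation_nodes(de_sets, run.catalog, run.universes, alpha)
        if with_annotation
        else []
    )
    net = _net.build_network(
        de_sets, annotation, run.catalog, run.universes,
        alpha=alpha, drop_isolated=drop_isolated, annotation_universe_tag="rat",
    )
    return de_sets, annotation, net


def sample_disjoint_node_pairs() -> set[frozenset]:
    """All unordered DE-set node-name pairs whose comparisons share no arrays."""
    comp_of = {c.name: c for c in _syn.ALL_COMPARISONS}
    experiment_of = _syn.experiment_of_comparisons()
    names = [f"{c.name}_{d}" for c in _syn.ALL_COMPARISONS for d in ("up", "down")]
    pairs = set()
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            ca = comp_of[a.rsplit("_", 1)[0]]
            cb = comp_of[b.rsplit("_", 1)[0]]
            if not _syn.comparisons_share_samples(ca, cb, experiment_of):
                pairs.add(frozenset((a, b)))
    return pairs


def edge_confusion(run: StudyRun, alpha: float = 0.05, fc_cutoff: float = 1.5,
                   with_annotation: bool = True) -> dict:
    """Confusion counts of recovered vs planted DE-DE association edges,
    scored over the sample-disjoint pair family (see module docstring)."""
    de_sets, _, net = de_network(run, alpha, fc_cutoff, with_annotation)
    family = sample_disjoint_node_pairs()
    de_names = {d.name for d in de_sets}
    recovered = {
        frozenset((u, v))
        for u, v in net.graph.edges()
        if u in de_names and v in de_names
    } & family
    truth_edges = _syn.truth_association_edges(run.truth) & family
    return {
        "tp": len(recovered & truth_edges),
        "fp": len(recovered - truth_edges),
        "fn": len(truth_edges - recovered),
        "recovered": recovered,
        "truth_edges": truth_edges,
        "family_size": len(family),
    }
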