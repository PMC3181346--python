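"""End-to-end orchestration: synthesize-or-load, normalize, select, cluster,
enrich, build the association network, and write a structured run report.

The stage sequence mirrors a two-process transcriptome comparison: quantile
normalization per platform, top-variable-gene hierarchical clustering per
experiment plus a merged cross-species clustering over orthologs, PAGE
enrichment for every configured comparison, fold-change DE gene sets, and a
pairwise Fisher overlap network spanning both processes.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from . import cluster as _cluster
from . import expression as _expr
from . import network as _net
from . import synthetic as _syn
from .enrichment import (
    Comparison,
    compute_fold_changes,
    enrich_catalog,
    translate_profile,
    write_enrichment_tsv,
)
from .errors import InvalidConfigError

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Run configuration with the analysis defaults baked in."""

    synthetic: bool = True
    synthetic_config: _syn.SyntheticConfig = field(default_factory=_syn.SyntheticConfig)
    rat_matrix: str | None = None
    rat_samples: str | None = None
    mouse_matrix: str | None = None
    mouse_samples: str | None = None
    gmt: str | None = None
    ortholog_map: str | None = None
    category_table: str | None = None
    k_variable: int = 2000
    fc_cutoff: float = 1.5
    alpha: float = 0.05
    min_set_size: int = 10
    comparisons: list[Comparison] = field(default_factory=lambda: list(_syn.ALL_COMPARISONS))
    centering: bool = True
    outdir: str = "pagenet_out"
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        if self.fc_cutoff <= 1:
            problems.append("fc_cutoff must exceed 1")
        if not 0 < self.alpha < 1:
            problems.append("alpha must lie in (0, 1)")
        if self.k_variable < 1:
            problems.append("k_variable must be positive")
        if self.min_set_size < 1:
            problems.append("min_set_size must be positive")
        if not self.synthetic:
            for key in ("rat_matrix", "rat_samples", "mouse_matrix", "mouse_samples",
                        "gmt", "ortholog_map"):
                path = getattr(self, key)
                if path is None:
                    problems.append(f"{key} is required when synthetic is false")
                elif not Path(path).exists():
                    problems.append(f"{key} path does not exist: {path}")
        if problems:
            raise InvalidConfigError("; ".join(problems))


_CONFIG_KEYS = {
    "synthetic", "synthetic_config", "rat_matrix", "rat_samples", "mouse_matrix",
    "mouse_samples", "gmt", "ortholog_map", "category_table", "k_variable",
    "fc_cutoff", "alpha", "min_set_size", "comparisons", "centering", "outdir", "seed",
}
_SYN_KEYS = {f.name for f in _syn.SyntheticConfig.__dataclass_fields__.values()}


def validate_config(path) -> PipelineConfig:
    """Parse a YAML config file into a defaulted, validated PipelineConfig.

    Unknown keys are errors; all schema violations are reported at once.
    An empty file yields the fully-defaulted synthetic configuration.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise InvalidConfigError("config file must hold a mapping")
    problems = [f"unknown key {k!r}" for k in raw if k not in _CONFIG_KEYS]
    syn_raw = raw.pop("synthetic_config", {}) or {}
    if isinstance(syn_raw, dict):
        problems += [
            f"unknown synthetic_config key {k!r}" for k in syn_raw if k not in _SYN_KEYS
        ]
    else:
        problems.append("synthetic_config must be a mapping")
        syn_raw = {}
    comp_raw = raw.pop("comparisons", None)
    comparisons = None
    if comp_raw is not None:
        comparisons = []
        for entry in comp_raw:
            missing = {"name", "test", "reference"} - set(entry)
            if missing:
                problems.append(f"comparison entry missing keys: {sorted(missing)}")
            else:
                comparisons.append(
                    Comparison(entry["name"], entry["test"], entry["reference"],
                               entry.get("stratum", ""))
                )
    for key in ("set_size_range", "replicates_per_group"):
        if key in syn_raw:
            syn_raw[key] = tuple(syn_raw[key])
    raw = {k: v for k, v in raw.items() if k in _CONFIG_KEYS}
    if "seed" in raw and "seed" not in syn_raw:
        syn_raw["seed"] = raw["seed"]
    config = None
    try:
        syn_config = _syn.SyntheticConfig(**{k: v for k, v in syn_raw.items() if k in _SYN_KEYS})
        kwargs = dict(raw, synthetic_config=syn_config)
        if comparisons is not None:
            kwargs["comparisons"] = comparisons
        config = PipelineConfig(**kwargs)
    except InvalidConfigError as exc:
        problems.append(str(exc))
    if problems:
        raise InvalidConfigError("; ".join(problems))
    return config


@dataclass
class RunReport:
    """Per-stage accounting of a pipeline run."""

    seed: int
    config: dict
    stages: dict = field(default_factory=dict)

    def record(self, stage: str, duration: float, **counts) -> None:
        self.stages[stage] = {"wall_clock_s": round(duration, 3), **counts}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True, default=str)


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute every stage and write all artifacts under ``config.outdir``."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_dict = asdict(config)
    cfg_dict["comparisons"] = [c.name for c in config.comparisons]
    report = RunReport(seed=config.seed, config=cfg_dict)

    # --- stage: inputs (simulate or load) ---------------------------------
    t0 = time.perf_counter()
    if config.synthetic:
        syn = config.synthetic_config
        catalog = _syn.generate_catalog(syn)
        rat, mouse, omap, truth = _syn.generate_experiment_pair(syn, catalog)
        _expr.write_gmt(catalog, outdir / "catalog.gmt")
        _expr.write_matrix(rat, outdir / "rat_expression.tsv")
        _expr.write_sample_table(rat.samples, outdir / "rat_samples.tsv")
        _expr.write_matrix(mouse, outdir / "mouse_expression.tsv")
        _expr.write_sample_table(mouse.samples, outdir / "mouse_samples.tsv")
        _expr.write_ortholog_map(omap, outdir / "ortholog_map.tsv")
        truth.to_json(outdir / "ground_truth.json")
    else:
        catalog = _expr.read_gmt(config.gmt)
        rat = _expr.read_matrix(config.rat_matrix, _expr.read_sample_table(config.rat_samples))
        mouse = _expr.read_matrix(config.mouse_matrix, _expr.read_sample_table(config.mouse_samples))
        omap = _expr.read_ortholog_map(config.ortholog_map)
        truth = None
    category_table = (
        _net.read_category_table(config.category_table) if config.category_table else {}
    )
    report.record(
        "inputs", time.perf_counter() - t0,
        rat_genes=rat.n_genes, rat_samples=rat.n_samples,
        mouse_genes=mouse.n_genes, mouse_samples=mouse.n_samples,
        catalog_sets=len(catalog), ortholog_pairs=len(omap),
    )

    # --- stage: normalization ---------------------------------------------
    t0 = time.perf_counter()
    rat = _expr.quantile_normalize(rat)
    mouse = _expr.quantile_normalize(mouse)
    _expr.write_matrix(rat, outdir / "rat_normalized.tsv")
    _expr.write_matrix(mouse, outdir / "mouse_normalized.tsv")
    report.record("normalize", time.perf_counter() - t0)

    # --- stage: clustering -------------------------------------------------
    t0 = time.perf_counter()
    cluster_counts = {}
    for tag, mat in (("rat", rat), ("mouse", mouse)):
        k = min(config.k_variable, mat.n_genes)
        top = _expr.select_top_variable(mat, k)
        dnd = _cluster.average_linkage(_cluster.correlation_distance(top))
        (outdir / f"{tag}_samples.nwk").write_text(_cluster.to_newick(dnd) + "\n")
        n_groups = mat.samples["group"].nunique()
        _cluster.write_clusters(
            _cluster.cut_clusters(dnd, n_groups), outdir / f"{tag}_clusters.tsv"
        )
        cluster_counts[f"{tag}_variable_genes"] = k
    merged = _expr.merge_orthologs(rat, mouse, omap, center=config.centering)
    k = min(config.k_variable, merged.n_genes)
    top = _expr.select_top_variable(merged, k)
    dnd = _cluster.average_linkage(_cluster.correlation_distance(top))
    (outdir / "merged_samples.nwk").write_text(_cluster.to_newick(dnd) + "\n")
    cluster_counts["merged_genes"] = merged.n_genes
    report.record("cluster", time.perf_counter() - t0, **cluster_counts)

    # --- stage: enrichment -------------------------------------------------
    t0 = time.perf_counter()
    experiment_of = _syn.experiment_of_comparisons()
    rat_groups = set(rat.samples["group"])
    profiles = []
    enrich_counts = {}
    for comp in config.comparisons:
        in_rat = comp.test in rat_groups
        profile = compute_fold_changes(rat if in_rat else mouse, comp)
        experiment_of.setdefault(comp.name, "rat" if in_rat else "mouse")
        if not in_rat:
            profile = translate_profile(profile, omap)
        profiles.append(profile)
        results = enrich_catalog(
            profile, catalog, alpha=config.alpha,
            min_set_size=config.min_set_size, fc_cutoff=config.fc_cutoff,
        )
        write_enrichment_tsv(results, outdir / f"enrichment_{comp.name}.tsv")
        enrich_counts[comp.name] = sum(r.significant for r in results)
    report.record("enrich", time.perf_counter() - t0, significant_sets=enrich_counts)

    # --- stage: network ----------------------------------------------------
    t0 = time.perf_counter()
    tags = {p.comparison.name: experiment_of[p.comparison.name] for p in profiles}
    de_sets = _net.build_de_sets(profiles, config.fc_cutoff, universe_tags=tags)
    rat_universe = set(rat.gene_ids)
    mouse_universe = {a for a, b in omap.pairs if b in set(mouse.gene_ids)}
    universes = {"rat": rat_universe, "mouse": mouse_universe}
    annotation = _net.select_annotation_nodes(de_sets, catalog, universes, config.alpha)
    net = _net.build_network(
        de_sets, annotation, catalog, universes,
        alpha=config.alpha, drop_isolated=True, category_table=category_table,
        annotation_universe_tag="rat",
    )
    _net.export_network(net, outdir)
    with open(outdir / "de_sets.tsv", "w") as fh:
        fh.write("name\tcomparison\tdirection\tn_genes\tgenes\n")
        for de in de_sets:
            fh.write(
                f"{de.name}\t{de.comparison_name}\t{de.direction}\t"
                f"{len(de.members)}\t{','.join(sorted(de.members))}\n"
            )
    report.record(
        "network", time.perf_counter() - t0,
        de_sets=len(de_sets), annotation_nodes=len(annotation),
        nodes=net.n_nodes, edges=net.n_edges,
    )

    report.to_json(outdir / "run_report.json")
    return report
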