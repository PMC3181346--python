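"""Synthetic two-experiment expression data with planted ground truth.

The generator emulates a paired study design: an injury time course in rat
kidney (cortex and medulla sampled at sham, 6 h, 24 h and 120 h after
ischemia-reperfusion, triplicate arrays per group) and a developmental time
course in mouse kidney (embryonic day 16 versus postnatal days 1 and 7,
five arrays per group). Gene intensities are log-normal: log2 intensity =
per-gene baseline + planted group shift + Gaussian replicate noise, emitted
on the linear scale.

Differential structure is planted at the gene-set level: for each of the
eight canonical comparisons a configurable number of catalog sets is
shifted up (and as many down) by ``effect_lfc`` in the comparison's test
group. A separate "shared program" of sets is shifted up in both 24 h
groups and in the embryonic reference, so it surfaces as up-regulation at
the injury peak and down-regulation postnatally — the planted analog of a
regeneration/development overlap. A machine-readable GroundTruth records
everything planted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._rng import substream
from .enrichment import Comparison
from .errors import InvalidConfigError
from .expression import ExpressionMatrix, GeneSetCatalog, OrthologMap

RAT_TISSUES = ("cortex", "medulla")
RAT_TIMES = ("sham", "6h", "24h", "120h")
MOUSE_TIMES = ("E16d", "PN1d", "PN7d")

#: Comparisons of the emulated design: six injury (each post-ischemia time
#: against sham, per tissue) and two development (each postnatal day against
#: the embryonic reference).
RAT_COMPARISONS = tuple(
    Comparison(f"{tissue}_{time}_vs_sham", f"{tissue}_{time}", f"{tissue}_sham", tissue)
    for tissue in RAT_TISSUES
    for time in RAT_TIMES[1:]
)
MOUSE_COMPARISONS = tuple(
    Comparison(f"{time}_vs_E16d", time, "E16d", "kidney") for time in MOUSE_TIMES[1:]
)
ALL_COMPARISONS = RAT_COMPARISONS + MOUSE_COMPARISONS

#: Groups in which the shared program is shifted up.
SHARED_UP_GROUPS = ("cortex_24h", "medulla_24h", "E16d")


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic study; defaults mirror the emulated design."""

    n_genes: int = 6000
    n_sets: int = 300
    set_size_range: tuple[int, int] = (10, 50)
    ortholog_fraction: float = 0.8
    replicates_per_group: tuple[int, int] = (3, 5)  # (rat-like, mouse-like)
    baseline_log2_mean: float = 7.0
    baseline_log2_sd: float = 1.5
    noise_sd: float = 0.5
    effect_lfc: float = 1.0
    planted_sets_per_comparison: int = 2
    shared_program_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.set_size_range
        problems = []
        if lo < 2:
            problems.append("set_size_range.min must be >= 2")
        if lo > hi:
            problems.append("set_size_range must be (min, max) with min <= max")
        if hi > self.n_genes:
            problems.append("set_size_range.max exceeds n_genes")
        if self.noise_sd <= 0:
            problems.append("noise_sd must be > 0")
        if not 0 <= self.ortholog_fraction <= 1:
            problems.append("ortholog_fraction must lie in [0, 1]")
        if min(self.n_genes, self.n_sets, *self.replicates_per_group) < 1:
            problems.append("n_genes, n_sets and replicate counts must be positive")
        if self.planted_sets_per_comparison < 0 or self.shared_program_size < 0:
            problems.append("planted counts must be nonnegative")
        needed = 2 * self.planted_sets_per_comparison * len(ALL_COMPARISONS) + self.shared_program_size
        if needed > self.n_sets:
            problems.append(
                f"planting requires {needed} distinct sets but n_sets={self.n_sets}"
            )
        if problems:
            raise InvalidConfigError("; ".join(problems))


@dataclass
class GroundTruth:
    """What was planted, per comparison and overall.

    ``planted_up`` / ``planted_down`` list each comparison's own planted set
    names (excluding the shared program); ``shared_program`` names the sets
    planted up at the injury peak and in the embryonic reference;
    ``true_shift`` stores each gene's nonzero true log2 shift per comparison
    (genes absent from a comparison's dict have true shift exactly 0).
    """

    planted_up: dict[str, list[str]] = field(default_factory=dict)
    planted_down: dict[str, list[str]] = field(default_factory=dict)
    shared_program: list[str] = field(default_factory=list)
    shared_up_comparisons: list[str] = field(default_factory=list)
    shared_down_comparisons: list[str] = field(default_factory=list)
    true_shift: dict[str, dict[str, float]] = field(default_factory=dict)

    def expected_up(self, comparison_name: str) -> list[str]:
        """Set names expected up-regulated in a comparison (own + shared)."""
        names = list(self.planted_up.get(comparison_name, []))
        if comparison_name in self.shared_up_comparisons:
            names += self.shared_program
        return names

    def expected_down(self, comparison_name: str) -> list[str]:
        names = list(self.planted_down.get(comparison_name, []))
        if comparison_name in self.shared_down_comparisons:
            names += self.shared_program
        return names

    def shift_of(self, comparison_name: str, gene_id: str) -> float:
        return self.true_shift.get(comparison_name, {}).get(gene_id, 0.0)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _gene_id(i: int) -> str:
    return f"g{i + 1:06d}"


def _mouse_id(i: int) -> str:
    return f"m{i + 1:06d}"


def generate_catalog(config: SyntheticConfig) -> GeneSetCatalog:
    """Draw n_sets gene sets with sizes uniform on set_size_range.

    Members are unique within a set; sets may overlap each other.
    Deterministic given the config seed.
    """
    rng = substream(config.seed, "catalog")
    lo, hi = config.set_size_range
    catalog = GeneSetCatalog()
    width = len(str(config.n_sets))
    for s in range(config.n_sets):
        size = int(rng.integers(lo, hi + 1))
        idx = rng.choice(config.n_genes, size=size, replace=False)
        members = [_gene_id(i) for i in sorted(idx)]
        catalog.add(f"set{s + 1:0{width}d}", "synthetic gene set", members)
    return catalog


def _plant_assignments(config: SyntheticConfig, set_names: list[str]):
    """Pick shared-program sets and each comparison's own up/down sets,
    all distinct, from the catalog."""
    rng = substream(config.seed, "planting")
    n_own = 2 * config.planted_sets_per_comparison * len(ALL_COMPARISONS)
    picked = rng.choice(len(set_names), size=config.shared_program_size + n_own, replace=False)
    picked = [set_names[i] for i in picked]
    shared = sorted(picked[: config.shared_program_size])
    rest = picked[config.shared_program_size :]
    planted_up: dict[str, list[str]] = {}
    planted_down: dict[str, list[str]] = {}
    pos = 0
    p = config.planted_sets_per_comparison
    for comp in ALL_COMPARISONS:
        planted_up[comp.name] = sorted(rest[pos : pos + p])
        planted_down[comp.name] = sorted(rest[pos + p : pos + 2 * p])
        pos += 2 * p
    return shared, planted_up, planted_down


def generate_experiment_pair(
    config: SyntheticConfig, catalog: GeneSetCatalog
) -> tuple[ExpressionMatrix, ExpressionMatrix, OrthologMap, GroundTruth]:
    """Emit the rat-like and mouse-like matrices, the ortholog map, and truth."""
    if len(catalog) == 0:
        raise InvalidConfigError("catalog must be nonempty")
    n = config.n_genes
    member_idx = {
        name: np.array([int(g[1:]) - 1 for g in catalog.members(name)])
        for name in catalog.names()
    }
    shared, planted_up, planted_down = _plant_assignments(config, catalog.names())

    # per-group true log2 shift vectors over the common gene index space
    rat_groups = [f"{t}_{x}" for t in RAT_TISSUES for x in RAT_TIMES]
    mouse_groups = list(MOUSE_TIMES)
    shift = {g: np.zeros(n) for g in rat_groups + mouse_groups}
    for comp in ALL_COMPARISONS:
        for name in planted_up[comp.name]:
            shift[comp.test][member_idx[name]] += config.effect_lfc
        for name in planted_down[comp.name]:
            shift[comp.test][member_idx[name]] -= config.effect_lfc
    for group in SHARED_UP_GROUPS:
        for name in shared:
            shift[group][member_idx[name]] += config.effect_lfc

    baseline = substream(config.seed, "baseline").normal(
        config.baseline_log2_mean, config.baseline_log2_sd, size=n
    )

    def build_matrix(groups, reps, noise_name, gene_ids, species):
        rng = substream(config.seed, noise_name)
        cols, names, meta = [], [], []
        for group in groups:
            for r in range(1, reps + 1):
                log2 = baseline + shift[group] + rng.normal(0.0, config.noise_sd, size=n)
                cols.append(np.power(2.0, log2))
                names.append(f"{group}_r{r}")
                parts = group.split("_")
                tissue = parts[0] if len(parts) > 1 else "kidney"
                timepoint = parts[-1]
                meta.append((names[-1], species, tissue, timepoint, group))
        values = pd.DataFrame(np.column_stack(cols), index=gene_ids, columns=names)
        samples = pd.DataFrame(
            meta, columns=("sample", "species", "tissue", "timepoint", "group")
        ).set_index("sample")
        return ExpressionMatrix(values, samples)

    rat_ids = [_gene_id(i) for i in range(n)]
    mouse_ids = [_mouse_id(i) for i in range(n)]
    rat = build_matrix(rat_groups, config.replicates_per_group[0], "noise_rat", rat_ids, "rat")
    mouse = build_matrix(mouse_groups, config.replicates_per_group[1], "noise_mouse", mouse_ids, "mouse")

    n_orth = int(round(config.ortholog_fraction * n))
    orth_idx = np.sort(substream(config.seed, "orthologs").choice(n, size=n_orth, replace=False))
    omap = OrthologMap([(_gene_id(i), _mouse_id(i)) for i in orth_idx])

    truth = GroundTruth(
        planted_up=planted_up,
        planted_down=planted_down,
        shared_program=shared,
        shared_up_comparisons=[
            c.name for c in ALL_COMPARISONS if c.test in SHARED_UP_GROUPS
        ],
        shared_down_comparisons=[
            c.name for c in ALL_COMPARISONS if c.reference in SHARED_UP_GROUPS
        ],
        true_shift={},
    )
    for comp in ALL_COMPARISONS:
        diff = shift[comp.test] - shift[comp.reference]
        nonzero = np.flatnonzero(diff)
        ids = mouse_ids if comp in MOUSE_COMPARISONS else rat_ids
        truth.true_shift[comp.name] = {ids[i]: float(diff[i]) for i in nonzero}
    return rat, mouse, omap, truth


def truth_association_edges(truth: GroundTruth) -> set[frozenset]:
    """DE-set node-name pairs that share at least one planted set in the
    matching direction — the ground-truth edges of the association network."""
    expected = {}
    for comp in ALL_COMPARISONS:
        expected[f"{comp.name}_up"] = set(truth.expected_up(comp.name))
        expected[f"{comp.name}_down"] = set(truth.expected_down(comp.name))
    names = sorted(expected)
    edges = set()
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if expected[a] & expected[b]:
                edges.add(frozenset((a, b)))
    return edges


def comparisons_share_samples(c1: Comparison, c2: Comparison, experiment_of: dict[str, str]) -> bool:
    """True when two comparisons draw on overlapping sample groups (e.g. the
    three injury timepoints of one tissue all reuse the same sham arrays)."""
    if experiment_of[c1.name] != experiment_of[c2.name]:
        return False
    return bool({c1.test, c1.reference} & {c2.test, c2.reference})


def experiment_of_comparisons() -> dict[str, str]:
    out = {c.name: "rat" for c in RAT_COMPARISONS}
    out.update({c.name: "mouse" for c in MOUSE_COMPARISONS})
    return out
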