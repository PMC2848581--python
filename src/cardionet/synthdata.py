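"""Seeded synthetic inputs with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage has a recoverable answer:

* two platforms, each measuring the same gene universe over 3 biological
  replicates of a progenitor condition and 3 of a reference condition;
* a planted conserved module (up- and down-regulated genes changed in
  the same direction on both platforms), platform-specific differential
  genes, and a non-changing background;
* Present/Marginal/Absent calls derived from a latent expression
  threshold and corrupted at a configurable miscall rate;
* an interaction network grown by preferential attachment with triad
  closure (power-law degrees plus degree-dependent clustering), with a
  planted set of highest-degree hubs;
* ligand-receptor axes whose receptors are planted up-regulated genes,
  including a planted minimal covering set: its receptors' direct
  neighborhoods jointly include every hub, and no other axis subset of
  the same or smaller size does.

Expression is simulated on the log2 scale with Gaussian replicate
noise and reported linear (2**x), so t-tests on log2 values are exact
for the generator's model. One integer seed drives named substreams for
the expression, network and annotation stages; identical seeds give
byte-identical outputs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from itertools import combinations

import networkx as nx
import numpy as np
import pandas as pd

from .enrich import AnnotationCollection
from .errors import ConfigError, GenerationError
from .exprfilter import ExpressionDataset
from .netbuild import Axis, InteractionDB

CONDITION = "progenitor"
REFERENCE = "baseline"

# latent log2 thresholds for presence calls: Absent below ABSENT_BELOW,
# Present at or above PRESENT_ABOVE, Marginal in the narrow band between
ABSENT_BELOW = 6.5
PRESENT_ABOVE = 7.0
# expressed genes draw baselines from EXPRESSED_RANGE, silent background
# genes from SILENT_RANGE (below the Absent threshold)
EXPRESSED_RANGE = (8.0, 12.0)
SILENT_RANGE = (4.0, 6.0)
SILENT_BACKGROUND_FRACTION = 0.25
# planted effects are clipped to at least MIN_EFFECT on the log2 scale so
# every planted differential gene is genuinely differential (>= ~1.4-fold)
MIN_EFFECT = 0.5


@dataclass
class SynthConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study conditions the pipeline is meant to
    recover: a conserved pool of 55 up- and 233 down-regulated genes,
    three biological replicates per condition per platform, nine network
    hubs and a three-axis planted cover.
    """

    n_conserved_up: int = 55
    n_conserved_down: int = 233
    n_platform_specific: int = 150  # per platform per direction
    n_background: int = 2000
    n_replicates: int = 3
    log2_effect_mean: float = 1.0
    log2_effect_sd: float = 0.25
    noise_sd: float = 0.25
    flag_miscall_rate: float = 0.02
    n_network_nodes: int = 400
    n_hubs: int = 9
    n_axes: int = 10
    planted_cover_size: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            "n_conserved_up",
            "n_conserved_down",
            "n_platform_specific",
            "n_background",
            "n_replicates",
            "n_network_nodes",
            "n_hubs",
            "n_axes",
            "planted_cover_size",
        )
        for name in counts:
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value < 0:
                raise ConfigError(f"{name} must be a non-negative integer, got {value!r}")
        for name in ("log2_effect_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not 0 <= self.flag_miscall_rate < 0.5:
            raise ConfigError(
                f"flag_miscall_rate must be in [0, 0.5), got {self.flag_miscall_rate}"
            )
        if self.planted_cover_size > self.n_axes:
            raise ConfigError("planted_cover_size cannot exceed n_axes")
        if self.n_hubs > self.n_network_nodes:
            raise ConfigError("n_hubs cannot exceed n_network_nodes")
        if self.planted_cover_size and self.n_hubs < self.planted_cover_size:
            raise ConfigError("n_hubs must be >= planted_cover_size (one hub group per axis)")

    def substream(self, label: str) -> np.random.Generator:
        """Named, reproducible random substream derived from the seed."""
        return np.random.default_rng(
            np.random.SeedSequence(self.seed, spawn_key=(zlib.crc32(label.encode()),))
        )


@dataclass
class SynthTruth:
    """Planted ground truth for recovery tests."""

    conserved_up: frozenset[str]
    conserved_down: frozenset[str]
    platform_specific: dict[str, dict[str, frozenset[str]]]  # platform -> direction -> genes
    background: frozenset[str]
    effects: dict[str, dict[str, float]] = field(default_factory=dict)  # platform -> gene -> log2
    planted_hubs: frozenset[str] = frozenset()
    planted_cover: tuple[str, ...] = ()

    @property
    def conserved(self) -> frozenset[str]:
        return self.conserved_up | self.conserved_down

    @property
    def genes(self) -> frozenset[str]:
        out = self.conserved | self.background
        for per_dir in self.platform_specific.values():
            for genes in per_dir.values():
                out |= genes
        return out


def _gene_ids(n_total: int, rng: np.random.Generator) -> list[str]:
    ids = [f"g{i:05d}" for i in range(1, n_total + 1)]
    rng.shuffle(ids)
    return ids


def generate_expression(
    config: SynthConfig,
) -> tuple[ExpressionDataset, ExpressionDataset, SynthTruth]:
    """Generate the two platform datasets and the planted truth.

    Both platforms measure the same gene universe; conserved genes carry
    the same true log2 effect (sign and magnitude) on both platforms,
    platform-specific genes an effect on one platform only, background
    genes none. A quarter of the background is silent (latent expression
    below the Absent threshold) so the flag filter has genuine work.
    """
    rng = config.substream("expression")
    n_cons = config.n_conserved_up + config.n_conserved_down
    n_ps = 4 * config.n_platform_specific  # two platforms x two directions
    ids = _gene_ids(n_cons + n_ps + config.n_background, rng)

    cursor = 0

    def take(n: int) -> list[str]:
        nonlocal cursor
        out = ids[cursor : cursor + n]
        cursor += n
        return out

    conserved_up = take(config.n_conserved_up)
    conserved_down = take(config.n_conserved_down)
    ps = {
        platform: {
            "up": take(config.n_platform_specific),
            "down": take(config.n_platform_specific),
        }
        for platform in ("A", "B")
    }
    background = take(config.n_background)
    all_genes = ids[:cursor]

    def effect_magnitudes(n: int) -> np.ndarray:
        mags = np.abs(rng.normal(config.log2_effect_mean, config.log2_effect_sd, size=n))
        return np.maximum(mags, MIN_EFFECT)

    # conserved effects are shared across platforms (same sign and size)
    shared = {}
    for gene, mag in zip(conserved_up, effect_magnitudes(len(conserved_up))):
        shared[gene] = float(mag)
    for gene, mag in zip(conserved_down, effect_magnitudes(len(conserved_down))):
        shared[gene] = float(-mag)

    effects: dict[str, dict[str, float]] = {}
    for platform in ("A", "B"):
        eff = dict(shared)
        for direction, sign in (("up", 1.0), ("down", -1.0)):
            genes = ps[platform][direction]
            for gene, mag in zip(genes, effect_magnitudes(len(genes))):
                eff[gene] = float(sign * mag)
        effects[platform] = eff

    n_silent = int(round(SILENT_BACKGROUND_FRACTION * config.n_background))
    silent = set(background[:n_silent])

    samples = [f"{CONDITION}_r{i+1}" for i in range(config.n_replicates)] + [
        f"{REFERENCE}_r{i+1}" for i in range(config.n_replicates)
    ]
    conditions = {
        s: CONDITION if s.startswith(CONDITION) else REFERENCE for s in samples
    }
    is_condition = np.array([conditions[s] == CONDITION for s in samples])

    datasets = []
    for platform in ("A", "B"):
        lo, hi = EXPRESSED_RANGE
        baseline = rng.uniform(lo, hi, size=len(all_genes))
        silent_mask = np.array([g in silent for g in all_genes])
        baseline[silent_mask] = rng.uniform(*SILENT_RANGE, size=int(silent_mask.sum()))

        eff = np.array([effects[platform].get(g, 0.0) for g in all_genes])
        latent = (
            baseline[:, None]
            + np.outer(eff, is_condition.astype(float))
            + rng.normal(0.0, config.noise_sd, size=(len(all_genes), len(samples)))
        )
        flags = np.where(
            latent < ABSENT_BELOW, "A", np.where(latent < PRESENT_ABOVE, "M", "P")
        )
        if config.flag_miscall_rate > 0:
            miscall = rng.random(flags.shape) < config.flag_miscall_rate
            # replace a miscalled flag by one of the two other symbols
            others = {"P": ("M", "A"), "M": ("P", "A"), "A": ("P", "M")}
            pick = rng.integers(0, 2, size=flags.shape)
            for sym, (first, second) in others.items():
                where = miscall & (flags == sym)
                flags[where] = np.where(pick[where] == 0, first, second)

        datasets.append(
            ExpressionDataset(
                platform=platform,
                values=pd.DataFrame(2.0**latent, index=all_genes, columns=samples),
                flags=pd.DataFrame(flags, index=all_genes, columns=samples),
                conditions=conditions,
                reference=REFERENCE,
            )
        )

    truth = SynthTruth(
        conserved_up=frozenset(conserved_up),
        conserved_down=frozenset(conserved_down),
        platform_specific={
            p: {d: frozenset(g) for d, g in per.items()} for p, per in ps.items()
        },
        background=frozenset(background),
        effects=effects,
    )
    return datasets[0], datasets[1], truth


def preferential_attachment_graph(
    n: int, m: int = 2, triad_p: float = 0.3, seed: int | None = None
) -> nx.Graph:
    """Preferential-attachment graph with triad closure.

    Each new node attaches ``m`` edges preferentially by degree; with
    probability ``triad_p`` an attachment closes a triangle instead,
    which induces degree-dependent clustering on top of the power-law
    degree distribution (the hierarchical + scale-free combination).
    The sparse default ``m=2`` yields the cleanest power-law tail for
    topology diagnostics; the interaction-database generator uses a
    denser ``m=4`` to mimic realistic interactome degree levels."""
    return nx.powerlaw_cluster_graph(n, m, triad_p, seed=seed)


def _partition_hubs(hubs: list[str], n_groups: int) -> list[list[str]]:
    groups: list[list[str]] = [[] for _ in range(n_groups)]
    for i, hub in enumerate(hubs):
        groups[i % n_groups].append(hub)
    return groups


def _verify_unique_minimal_cover(
    axes: list[Axis],
    planted: tuple[str, ...],
    hub_set: frozenset[str],
    graph: nx.Graph,
) -> bool:
    hits = {
        a.name: frozenset(graph.neighbors(a.receptor)) & hub_set
        for a in axes
        if a.receptor in graph
    }
    size = len(planted)
    for k in range(1, size + 1):
        for subset in combinations(axes, k):
            union = frozenset().union(*(hits.get(a.name, frozenset()) for a in subset))
            if union == hub_set:
                if k < size:
                    return False
                if tuple(sorted(a.name for a in subset)) != tuple(sorted(planted)):
                    return False
    return True


def generate_interactions(
    config: SynthConfig, truth: SynthTruth, max_retries: int = 10
) -> InteractionDB:
    """Build the interaction database around the planted truth.

    The molecule graph is grown by preferential attachment with triad
    closure, conserved genes are scattered over its nodes, and the
    ``n_hubs`` highest-degree nodes become the planted hubs. Receptor
    nodes for ``n_axes`` ligand-receptor axes are drawn from the planted
    up-regulated genes; the planted covering axes split the hubs into
    one group each and are wired to exactly their group, while every
    other axis touches fewer hubs than the smallest group -- which makes
    the planted cover the unique minimum (verified exhaustively, with
    regeneration on failure). Hub degrees are topped up with edges to
    conserved genes until every planted hub out-ranks every other node
    even inside the grown sub-network.

    Also attaches named annotation gene sets, one of which (the
    "Cardiovascular Development" stand-in) is enriched for the planted
    up-regulated conserved genes.
    """
    placeable_up = min(
        len(truth.conserved_up), max(0, config.n_network_nodes - config.n_hubs)
    )
    if config.n_axes > placeable_up:
        raise ConfigError(
            f"n_axes={config.n_axes} exceeds the {placeable_up} up-regulated "
            "conserved genes placeable in the network (axis receptors are "
            "planted up-regulated genes)"
        )
    truth.planted_hubs = frozenset()
    truth.planted_cover = ()
    for attempt in range(max_retries):
        rng = config.substream(f"network-{attempt}")
        db = _generate_interactions_once(config, truth, rng)
        if db is not None:
            db.annotations = _generate_annotations(config, truth)
            return db
    raise GenerationError(
        f"could not plant a uniquely minimal {config.planted_cover_size}-axis "
        f"cover in {max_retries} attempts"
    )


def _generate_interactions_once(
    config: SynthConfig, truth: SynthTruth, rng: np.random.Generator
) -> InteractionDB | None:
    n = config.n_network_nodes
    if n == 0:
        return InteractionDB(graph=nx.Graph(), axes=[])
    m = min(4, max(1, n - 1))
    graph = preferential_attachment_graph(n, m=m, triad_p=0.3, seed=int(rng.integers(2**31)))

    # hubs = top-degree integer nodes; conserved genes fill other slots
    by_degree = sorted(graph.degree, key=lambda kv: (-kv[1], kv[0]))
    hub_ints = [v for v, _ in by_degree[: config.n_hubs]]
    other_ints = [v for v, _ in by_degree[config.n_hubs :]]
    rng.shuffle(other_ints)

    # up-regulated genes fill slots first so axis receptors exist even
    # when the network is smaller than the conserved pool
    conserved = sorted(truth.conserved_up) + sorted(truth.conserved_down)
    placeable = conserved[: len(other_ints)]
    mapping: dict[int, str] = {}
    for node, gene in zip(other_ints, placeable):
        mapping[node] = gene
    for i, node in enumerate(other_ints[len(placeable) :], start=1):
        mapping[node] = f"px{i:04d}"
    for i, node in enumerate(hub_ints, start=1):
        mapping[node] = f"px{len(other_ints) - len(placeable) + i:04d}"
    graph = nx.relabel_nodes(graph, mapping)
    hubs = [mapping[v] for v in hub_ints]
    hub_set = frozenset(hubs)

    placed_up = sorted(set(placeable) & truth.conserved_up)
    receptors = (
        [str(r) for r in rng.choice(placed_up, size=config.n_axes, replace=False)]
        if config.n_axes
        else []
    )

    # clear pre-existing receptor-hub adjacency, then wire the plant
    for receptor in receptors:
        for hub in hubs:
            if graph.has_edge(receptor, hub):
                graph.remove_edge(receptor, hub)

    axes: list[Axis] = []
    planted_names: list[str] = []
    if config.n_axes:
        groups = _partition_hubs(hubs, config.planted_cover_size) if config.planted_cover_size else []
        min_group = min((len(g) for g in groups), default=0)
        for i, receptor in enumerate(receptors, start=1):
            name = f"axis{i:02d}"
            ligand = f"lg{i:02d}"
            axes.append(Axis(ligand=ligand, receptor=receptor, name=name))
            graph.add_node(ligand)
            graph.add_edge(ligand, receptor, interaction="binds")
        for axis, group in zip(axes, groups):
            planted_names.append(axis.name)
            for hub in group:
                graph.add_edge(axis.receptor, hub, interaction="activates")
        # decoys touch strictly fewer hubs than the smallest planted group
        max_decoy = max(0, min_group - 1)
        for axis in axes[len(planted_names) :]:
            k = int(rng.integers(0, max_decoy + 1)) if max_decoy else 0
            for hub in rng.choice(hubs, size=k, replace=False) if k else []:
                graph.add_edge(axis.receptor, hub, interaction="activates")

    # top up hub degrees until hubs dominate even within the grown subnet:
    # every hub's seed-neighbor count must exceed every non-hub's degree
    seeds = set(placeable)
    eligible = sorted(seeds - set(receptors))
    if eligible and hubs:
        for _ in range(200 * max(1, config.n_hubs)):
            seed_deg = {
                h: sum(1 for nb in graph.neighbors(h) if nb in seeds) for h in hubs
            }
            max_other = max(
                (k for v, k in graph.degree if v not in hub_set), default=0
            )
            weakest = min(hubs, key=lambda h: seed_deg[h])
            if seed_deg[weakest] > max_other:
                break
            candidates = [g for g in eligible if not graph.has_edge(weakest, g)]
            if not candidates:
                break
            graph.add_edge(weakest, candidates[int(rng.integers(len(candidates)))])
        else:
            return None

    if graph.number_of_nodes() and not nx.is_connected(graph):
        components = sorted(nx.connected_components(graph), key=len, reverse=True)
        anchor = next(iter(sorted(components[0])))
        for comp in components[1:]:
            graph.add_edge(sorted(comp)[0], anchor, interaction="bridge")

    # verify the plant end to end
    top = sorted(graph.degree, key=lambda kv: (-kv[1], str(kv[0])))
    if config.n_hubs:
        boundary_in = top[config.n_hubs - 1][1]
        boundary_out = top[config.n_hubs][1] if len(top) > config.n_hubs else -1
        if set(v for v, _ in top[: config.n_hubs]) != hub_set or boundary_in <= boundary_out:
            return None
    if config.n_axes and not _verify_unique_minimal_cover(
        axes, tuple(planted_names), hub_set, graph
    ):
        return None

    for node in graph.nodes:
        kind = "gene"
        if node.startswith("lg"):
            kind = "ligand"
        elif node in {a.receptor for a in axes}:
            kind = "receptor"
        elif node.startswith("px"):
            kind = "other"
        graph.nodes[node]["kind"] = kind
    for u, v, data in graph.edges(data=True):
        data.setdefault("interaction", "pp")

    truth.planted_hubs = hub_set
    truth.planted_cover = tuple(sorted(planted_names))
    return InteractionDB(graph=graph, axes=axes)


CARDIO_CATEGORY = "Cardiovascular Development"


def _generate_annotations(config: SynthConfig, truth: SynthTruth) -> AnnotationCollection:
    rng = config.substream("annotations")
    universe = sorted(truth.genes)
    categories: dict[str, frozenset[str]] = {}
    if universe:
        up = sorted(truth.conserved_up)
        n_hit = max(1, int(round(0.6 * len(up)))) if up else 0
        members = set(rng.choice(up, size=n_hit, replace=False)) if n_hit else set()
        n_extra = min(30, len(universe))
        members |= set(rng.choice(universe, size=n_extra, replace=False))
        categories[CARDIO_CATEGORY] = frozenset(members)
        for i in range(1, 16):
            size = int(rng.integers(30, 121))
            size = min(size, len(universe))
            categories[f"Process {i:02d}"] = frozenset(
                rng.choice(universe, size=size, replace=False)
            )
    return AnnotationCollection(categories=categories, universe=frozenset(universe))


def config_to_dict(config: SynthConfig) -> dict:
    return asdict(config)


def write_fixtures(datasets, db, truth, directory):
    """Write the generated bundle as plain-text fixtures (see :mod:`cardionet.io`)."""
    from .io import write_fixtures as _write

    return _write(datasets, db, truth, directory)
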