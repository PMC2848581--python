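"""End-to-end orchestration: expression filtering through axis cover.

The pipeline runs, per platform, the flag filter, reference
normalization, differential test and volcano filter; intersects the two
signatures into the conserved pool; scores annotation categories on the
conserved up/down lists (Fisher right tail plus the weighted
developmental score); grows the interaction sub-network from the
conserved seeds; computes its topology diagnostics; identifies hubs,
ranks up-regulated genes by relative pathway connectivity; and solves
the minimal ligand-receptor axis cover.

Inputs come either from files (two expression TSVs, a GMT, a SIF and an
axis TSV) or from the synthetic generator; a :class:`RunConfig` holds
exactly one of the two, plus every stage threshold. Identical config
and seed give an identical report hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import crossref, enrich, exprfilter, hubrank, io, netbuild, synthdata
from .enrich import AnnotationCollection
from .errors import ConfigError

logger = logging.getLogger(__name__)


@dataclass
class InputPaths:
    expression_a: str
    expression_b: str
    annotations: str
    network: str
    axes: str
    reference_a: str = synthdata.REFERENCE
    reference_b: str = synthdata.REFERENCE


@dataclass
class RunConfig:
    """Everything a full run needs: inputs plus stage thresholds."""

    inputs: InputPaths | None = None
    synth: synthdata.SynthConfig | None = None
    min_called: int = 2
    min_fold: float = 1.2
    alpha: float = 0.05
    test: str = "welch"
    fold_method: str = "mean_ratio"
    adjust: str | None = None
    min_seed_links: int = 2
    n_hubs: int = 9
    exact_limit: int = 20
    hit_path_length: int = 1
    top_categories: int = 10
    outdir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.inputs is None) == (self.synth is None):
            raise ConfigError("exactly one of 'inputs' and 'synth' must be given")
        if self.hit_path_length < 1:
            raise ConfigError("hit_path_length must be >= 1")
        if self.min_seed_links < 1:
            raise ConfigError("min_seed_links must be >= 1")

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        inputs = raw.pop("inputs", None)
        synth = raw.pop("synth", None)
        known = {f.name for f in dataclasses.fields(cls)} - {"inputs", "synth"}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        if inputs is not None:
            inputs = InputPaths(**inputs)
        if synth is not None:
            synth = synthdata.SynthConfig(**synth)
            if "seed" in raw:
                synth = dataclasses.replace(synth, seed=raw["seed"])
        return cls(inputs=inputs, synth=synth, **raw)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(raw)


def _signature_for_platform(dataset, config: RunConfig):
    filtered = exprfilter.flag_filter(dataset, min_called=config.min_called)
    ratios = exprfilter.normalize_to_reference(filtered)
    table = exprfilter.differential_test(
        ratios, filtered, test=config.test, fold_method=config.fold_method
    )
    signature = exprfilter.volcano_filter(
        table,
        platform=dataset.platform,
        min_fold=config.min_fold,
        alpha=config.alpha,
        adjust=config.adjust,
    )
    logger.info(
        "platform %s: %d/%d genes pass the flag filter; %d up, %d down",
        dataset.platform,
        len(filtered.genes),
        len(dataset.genes),
        len(signature.up),
        len(signature.down),
    )
    return filtered, table, signature


def run_all(config: RunConfig) -> dict:
    """Execute every stage and return the serializable run report.

    The report carries, per stage, the input/output sizes and the
    parameters used, plus the final conserved sets, enrichment tables,
    topology diagnostics, hub set, connectivity scores and axis cover.
    Stage artifacts are written under ``config.outdir`` when set.
    """
    if config.synth is not None:
        ds_a, ds_b, truth = synthdata.generate_expression(config.synth)
        db = synthdata.generate_interactions(config.synth, truth)
        annotations = db.annotations
    else:
        paths = config.inputs
        ds_a = io.read_expression_tsv(paths.expression_a, "A", paths.reference_a)
        ds_b = io.read_expression_tsv(paths.expression_b, "B", paths.reference_b)
        db = io.read_interaction_db(paths.network, paths.axes, paths.annotations)
        annotations = db.annotations
        truth = None

    filtered_a, table_a, sig_a = _signature_for_platform(ds_a, config)
    filtered_b, table_b, sig_b = _signature_for_platform(ds_b, config)

    conserved = crossref.intersect_signatures(sig_a, sig_b)
    logger.info(
        "conserved: %d up, %d down, %d discordant (reduction %.1f%%)",
        len(conserved.conserved_up),
        len(conserved.conserved_down),
        len(conserved.discordant),
        100 * conserved.reduction_fraction,
    )

    # Fisher background: all genes surviving the flag filter on either platform
    universe = frozenset(filtered_a.genes) | frozenset(filtered_b.genes)
    categories = annotations.categories if annotations is not None else {}
    collection = AnnotationCollection(categories=dict(categories), universe=universe)
    enrich_up = enrich.fisher_enrichment(conserved.conserved_up, collection)
    enrich_down = enrich.fisher_enrichment(conserved.conserved_down, collection)
    scores_table = enrich.weighted_development_score(enrich_up, enrich_down)
    top = enrich.rank_categories(enrich_up, top_n=config.top_categories)

    net = netbuild.grow_network(conserved.conserved, db, min_seed_links=config.min_seed_links)
    topo = netbuild.topology_report(net)
    logger.info(
        "grown network: %d nodes, %d edges, average degree %.2f",
        net.n_nodes,
        net.n_edges,
        topo.average_degree,
    )

    hubs = hubrank.identify_hubs(net, n_hubs=config.n_hubs)
    conn = hubrank.relative_connectivity_score(conserved.conserved_up, hubs, net)
    cover = hubrank.minimal_axis_cover(
        db.axes,
        hubs,
        net,
        upregulated=conserved.conserved_up,
        exact_limit=config.exact_limit,
        path_length=config.hit_path_length,
        scores=conn,
    )
    logger.info(
        "hubs: %s; cover size %d (feasible=%s, minimal=%s)",
        ",".join(hubs.hubs),
        cover.size,
        cover.feasible,
        cover.minimal,
    )

    report = {
        "config": _config_record(config),
        "stages": {
            "flag_filter": {
                "A": {"in": len(ds_a.genes), "out": len(filtered_a.genes)},
                "B": {"in": len(ds_b.genes), "out": len(filtered_b.genes)},
            },
            "volcano": {
                "A": {"up": len(sig_a.up), "down": len(sig_a.down)},
                "B": {"up": len(sig_b.up), "down": len(sig_b.down)},
            },
            "network": {"nodes": net.n_nodes, "edges": net.n_edges},
        },
        "signatures": {
            "A": {"up": sorted(sig_a.up), "down": sorted(sig_a.down)},
            "B": {"up": sorted(sig_b.up), "down": sorted(sig_b.down)},
        },
        "conserved": {
            "up": sorted(conserved.conserved_up),
            "down": sorted(conserved.conserved_down),
            "discordant": sorted(conserved.discordant),
            "only_a": sorted(conserved.only_a),
            "only_b": sorted(conserved.only_b),
            "reduction_fraction": conserved.reduction_fraction,
        },
        "enrichment": {
            "up": _frame_record(enrich_up),
            "down": _frame_record(enrich_down),
            "weighted_score": _frame_record(scores_table),
            "top_up": _frame_record(top),
        },
        "topology": {
            "n_k": {str(k): v for k, v in topo.n_k.items()},
            "p_k": {str(k): v for k, v in topo.p_k.items()},
            "c_k": {str(k): v for k, v in topo.c_k.items()},
            "average_degree": topo.average_degree,
            "mean_neighbor_count": topo.mean_neighbor_count,
            "scale_free": list(topo.scale_free) if topo.scale_free else None,
            "hierarchy": list(topo.hierarchy) if topo.hierarchy else None,
        },
        "hubs": {
            "members": list(hubs.hubs),
            "connectivity": hubs.connectivity,
            "rule": hubs.rule,
            "tie_expanded": hubs.tie_expanded,
        },
        "connectivity_scores": _frame_record(conn),
        "axis_cover": {
            "axes": [list(a) for a in cover.axes],
            "hits": {name: sorted(hit) for name, hit in cover.hits.items()},
            "size": cover.size,
            "feasible": cover.feasible,
            "minimal": cover.minimal,
            "uncovered": sorted(cover.uncovered),
        },
    }
    report["report_hash"] = report_hash(report)

    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if config.synth is not None:
            io.write_fixtures((ds_a, ds_b), db, truth, outdir / "inputs")
        table_a.to_csv(outdir / "differential_A.tsv", sep="\t")
        table_b.to_csv(outdir / "differential_B.tsv", sep="\t")
        enrich_up.to_csv(outdir / "enrichment_up.tsv", sep="\t")
        enrich_down.to_csv(outdir / "enrichment_down.tsv", sep="\t")
        scores_table.to_csv(outdir / "weighted_scores.tsv", sep="\t")
        conn.to_csv(outdir / "connectivity_scores.tsv", sep="\t")
        io.write_sif(net.graph, outdir / "grown_network.sif")
        io.write_graphml(net, outdir / "grown_network.graphml")
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
            fh.write("\n")
    return report


def report_hash(report: dict) -> str:
    """Stable hash of a report (ignoring any embedded hash field)."""
    payload = {k: v for k, v in report.items() if k != "report_hash"}
    canon = json.dumps(payload, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(canon.encode()).hexdigest()


def _config_record(config: RunConfig) -> dict:
    record = dataclasses.asdict(config)
    return record


def _frame_record(frame) -> dict:
    return {str(idx): {k: _plain(v) for k, v in row.items()} for idx, row in frame.iterrows()}


def _plain(value):
    try:
        return value.item()
    except AttributeError:
        return value
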