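"""Plain-text readers and writers for the pipeline's exchange formats.

* expression TSV -- ``gene_id`` column followed by one value column and
  one ``<sample>.flag`` column per sample; sample names encode condition
  and replicate as ``<condition>_r<k>``;
* GMT -- one annotation set per line: name, description, members,
  tab-separated;
* SIF -- ``node TAB interaction-type TAB node`` per edge, a bare node
  name per isolated node;
* axis TSV -- ``ligand_id  receptor_id  axis_name``;
* truth JSON -- the planted ground-truth sets of a synthetic run;
* GraphML -- export only, for viewing grown networks elsewhere.

All formats round-trip losslessly (expression values are written with
17 significant digits). Malformed lines raise :class:`ParseError`
naming the file and line number.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import networkx as nx
import pandas as pd

from .enrich import AnnotationCollection
from .errors import ParseError
from .exprfilter import VALID_FLAGS, ExpressionDataset
from .netbuild import Axis, GrownNetwork, InteractionDB
from .synthdata import SynthTruth

FLAG_SUFFIX = ".flag"


# -- expression ---------------------------------------------------------------


def write_expression_tsv(dataset: ExpressionDataset, path: str | Path) -> Path:
    path = Path(path)
    samples = list(dataset.values.columns)
    with open(path, "w") as fh:
        header = ["gene_id"]
        for s in samples:
            header += [s, s + FLAG_SUFFIX]
        fh.write("\t".join(header) + "\n")
        for gene in dataset.values.index:
            row = [str(gene)]
            for s in samples:
                row += [format(dataset.values.at[gene, s], ".17g"), dataset.flags.at[gene, s]]
            fh.write("\t".join(row) + "\n")
    return path


def read_expression_tsv(
    path: str | Path, platform: str, reference: str
) -> ExpressionDataset:
    """Read an expression TSV; conditions are parsed from sample names
    (everything before the final ``_r<k>`` suffix)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "gene_id":
            raise ParseError(f"{path}:1: expected first column 'gene_id'")
        samples = [c for c in header[1:] if not c.endswith(FLAG_SUFFIX)]
        expected = ["gene_id"]
        for s in samples:
            expected += [s, s + FLAG_SUFFIX]
        if header != expected:
            raise ParseError(f"{path}:1: columns must alternate value/flag per sample")
        genes, values, flags = [], [], []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(header):
                raise ParseError(f"{path}:{lineno}: expected {len(header)} fields")
            gene = fields[0]
            try:
                vals = [float(f) for f in fields[1::2]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad value for gene {gene}: {exc}")
            flgs = fields[2::2]
            bad = set(flgs) - VALID_FLAGS
            if bad:
                raise ParseError(
                    f"{path}:{lineno}: invalid flag {sorted(bad)} for gene {gene}"
                )
            genes.append(gene)
            values.append(vals)
            flags.append(flgs)
    conditions = {s: s.rsplit("_r", 1)[0] for s in samples}
    return ExpressionDataset(
        platform=platform,
        values=pd.DataFrame(values, index=genes, columns=samples),
        flags=pd.DataFrame(flags, index=genes, columns=samples),
        conditions=conditions,
        reference=reference,
    )


# -- gene sets (GMT) ----------------------------------------------------------


def write_gmt(categories: dict[str, Iterable[str]], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name in sorted(categories):
            members = sorted(categories[name])
            fh.write("\t".join([name, "synthetic"] + members) + "\n")
    return path


def read_gmt(path: str | Path) -> dict[str, frozenset[str]]:
    path = Path(path)
    categories: dict[str, frozenset[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: GMT line needs name and description")
            name = fields[0]
            if name in categories:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            categories[name] = frozenset(fields[2:])
    return categories


# -- networks (SIF, axis TSV, GraphML) ---------------------------------------


def write_sif(graph: nx.Graph, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for u, v, data in sorted(graph.edges(data=True), key=lambda e: (str(e[0]), str(e[1]))):
            fh.write(f"{u}\t{data.get('interaction', 'pp')}\t{v}\n")
        for node in sorted(graph.nodes, key=str):
            if graph.degree(node) == 0:
                fh.write(f"{node}\n")
    return path


def read_sif(path: str | Path) -> nx.Graph:
    path = Path(path)
    graph = nx.Graph()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) == 1:
                graph.add_node(fields[0])
            elif len(fields) == 3:
                u, kind, v = fields
                if u != v:
                    graph.add_edge(u, v, interaction=kind)
            else:
                raise ParseError(
                    f"{path}:{lineno}: SIF line must have 1 or 3 tab-separated fields"
                )
    return graph


def write_axes_tsv(axes: Iterable[Axis], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("ligand_id\treceptor_id\taxis_name\n")
        for axis in sorted(axes, key=lambda a: a.name):
            fh.write(f"{axis.ligand}\t{axis.receptor}\t{axis.name}\n")
    return path


def read_axes_tsv(path: str | Path) -> list[Axis]:
    path = Path(path)
    axes: list[Axis] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["ligand_id", "receptor_id", "axis_name"]:
            raise ParseError(f"{path}:1: bad axis TSV header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 3:
                raise ParseError(f"{path}:{lineno}: expected 3 fields")
            axes.append(Axis(ligand=fields[0], receptor=fields[1], name=fields[2]))
    return axes


def read_interaction_db(
    sif_path: str | Path,
    axes_path: str | Path,
    gmt_path: str | Path | None = None,
    universe: Iterable[str] | None = None,
) -> InteractionDB:
    """Assemble an :class:`InteractionDB` from SIF + axis TSV (+ GMT).

    Node kinds are inferred from the axis annotations (ligand/receptor)
    and default to ``gene``; ligands named in axes but absent from the
    SIF are added as isolated molecules.
    """
    graph = read_sif(sif_path)
    axes = read_axes_tsv(axes_path)
    for axis in axes:
        graph.add_node(axis.ligand)
        graph.add_node(axis.receptor)
    ligands = {a.ligand for a in axes}
    receptors = {a.receptor for a in axes}
    for node in graph.nodes:
        if node in ligands:
            graph.nodes[node]["kind"] = "ligand"
        elif node in receptors:
            graph.nodes[node]["kind"] = "receptor"
        else:
            graph.nodes[node].setdefault("kind", "gene")
    annotations = None
    if gmt_path is not None:
        categories = read_gmt(gmt_path)
        if universe is None:
            universe = set().union(*categories.values()) if categories else set()
        annotations = AnnotationCollection(
            categories=dict(categories), universe=frozenset(universe)
        )
    return InteractionDB(graph=graph, axes=axes, annotations=annotations)


def write_graphml(net: GrownNetwork | nx.Graph, path: str | Path) -> Path:
    graph = net.graph if isinstance(net, GrownNetwork) else net
    path = Path(path)
    nx.write_graphml(graph, path)
    return path


# -- truth JSON ---------------------------------------------------------------


def write_truth_json(truth: SynthTruth, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "conserved_up": sorted(truth.conserved_up),
        "conserved_down": sorted(truth.conserved_down),
        "platform_specific": {
            p: {d: sorted(genes) for d, genes in per.items()}
            for p, per in truth.platform_specific.items()
        },
        "background": sorted(truth.background),
        "effects": {p: dict(sorted(e.items())) for p, e in truth.effects.items()},
        "planted_hubs": sorted(truth.planted_hubs),
        "planted_cover": sorted(truth.planted_cover),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return path


def read_truth_json(path: str | Path) -> SynthTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return SynthTruth(
        conserved_up=frozenset(payload["conserved_up"]),
        conserved_down=frozenset(payload["conserved_down"]),
        platform_specific={
            p: {d: frozenset(genes) for d, genes in per.items()}
            for p, per in payload["platform_specific"].items()
        },
        background=frozenset(payload["background"]),
        effects=payload.get("effects", {}),
        planted_hubs=frozenset(payload.get("planted_hubs", [])),
        planted_cover=tuple(payload.get("planted_cover", [])),
    )


# -- fixture bundles ----------------------------------------------------------


def write_fixtures(
    datasets: tuple[ExpressionDataset, ExpressionDataset],
    db: InteractionDB,
    truth: SynthTruth,
    directory: str | Path,
) -> dict[str, Path]:
    """Write a full synthetic input bundle to ``directory``.

    Returns the written paths keyed by role. Everything round-trips
    losslessly through the readers in this module.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression_a": write_expression_tsv(datasets[0], directory / "expression_A.tsv"),
        "expression_b": write_expression_tsv(datasets[1], directory / "expression_B.tsv"),
        "network": write_sif(db.graph, directory / "network.sif"),
        "axes": write_axes_tsv(db.axes, directory / "axes.tsv"),
        "truth": write_truth_json(truth, directory / "truth.json"),
    }
    if db.annotations is not None:
        paths["annotations"] = write_gmt(
            {k: v for k, v in db.annotations.categories.items()},
            directory / "annotations.gmt",
        )
    return paths
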