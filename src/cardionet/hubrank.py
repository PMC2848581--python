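"""Hub identification, relative pathway connectivity, and the minimal
ligand-receptor axis cover.

Hubs are the most highly connected nodes of the grown sub-network; a
hub's *local module connectivity* is simply its within-subnetwork
degree. Each up-regulated gene i is then scored by its relative pathway
connectivity

    Y_i = x_i / N

where x_i is the number of hubs it is directly connected to and N the
total number of hubs. Finally, treating each ligand-receptor couple as
a unit that "hits" every hub adjacent to its receptor node, the minimal
axis cover is the smallest set of axes whose hit-sets jointly include
every hub -- solved exactly by subset enumeration at the scales this
analysis runs at (a handful of axes, around nine hubs), with a greedy
max-coverage fallback beyond ``exact_limit``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .errors import DataError
from .netbuild import Axis, GrownNetwork

import logging

logger = logging.getLogger(__name__)


@dataclass
class HubSet:
    """Hub identifiers with their local module connectivity.

    ``connectivity`` is sorted descending; ``tie_expanded`` records
    whether a tie at the selection boundary forced the set beyond the
    requested count (tied nodes are never dropped arbitrarily).
    """

    hubs: tuple[str, ...]
    connectivity: dict[str, int]
    rule: str
    tie_expanded: bool = False

    def __post_init__(self) -> None:
        self.connectivity = dict(
            sorted(self.connectivity.items(), key=lambda kv: (-kv[1], str(kv[0])))
        )
        self.hubs = tuple(self.connectivity)

    def __len__(self) -> int:
        return len(self.hubs)

    def __iter__(self):
        return iter(self.hubs)


@dataclass
class AxisCover:
    """A set of ligand-receptor axes with the hubs each one hits.

    ``minimal`` is True only when the exact solver ran, in which case no
    smaller cover exists; ``feasible`` is False when even the full axis
    set leaves hubs uncovered (listed in ``uncovered``).
    """

    axes: tuple[Axis, ...]
    hits: dict[str, frozenset[str]]  # axis name -> hubs hit
    feasible: bool
    minimal: bool
    uncovered: frozenset[str] = frozenset()
    tie_break: dict = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.axes)

    @property
    def covered(self) -> frozenset[str]:
        out: frozenset[str] = frozenset()
        for axis in self.axes:
            out |= self.hits[axis.name]
        return out


def local_module_connectivity(subnet: GrownNetwork | nx.Graph) -> dict[str, int]:
    """Within-subnetwork degree of every node (local module connectivity)."""
    graph = subnet.graph if isinstance(subnet, GrownNetwork) else subnet
    if graph.number_of_nodes() == 0:
        raise DataError("local module connectivity of an empty network")
    return {node: int(k) for node, k in graph.degree()}


def identify_hubs(
    subnet: GrownNetwork | nx.Graph,
    n_hubs: int = 9,
    min_connectivity: int | None = None,
) -> HubSet:
    """Select hubs as the most highly connected nodes.

    By default the top ``n_hubs`` nodes by local module connectivity are
    returned; a tie at the boundary expands the set to include every
    tied node (recorded in ``tie_expanded``). Alternatively
    ``min_connectivity`` selects all nodes at or above a degree
    threshold. Permutation-invariant with respect to node input order.
    """
    conn = local_module_connectivity(subnet)
    if min_connectivity is not None:
        chosen = {v: k for v, k in conn.items() if k >= min_connectivity}
        return HubSet(
            hubs=tuple(chosen),
            connectivity=chosen,
            rule=f"min_connectivity>={min_connectivity}",
        )
    if n_hubs < 1 or n_hubs > len(conn):
        raise DataError(f"n_hubs={n_hubs} out of range for a {len(conn)}-node network")
    ranked = sorted(conn.items(), key=lambda kv: (-kv[1], str(kv[0])))
    boundary = ranked[n_hubs - 1][1]
    chosen = {v: k for v, k in ranked if k >= boundary}
    expanded = len(chosen) > n_hubs
    if expanded:
        logger.info(
            "hub boundary tie at connectivity %d expanded the hub set to %d nodes",
            boundary,
            len(chosen),
        )
    return HubSet(
        hubs=tuple(chosen),
        connectivity=chosen,
        rule=f"top-{n_hubs}",
        tie_expanded=expanded,
    )


def relative_connectivity_score(
    genes: Iterable[str], hubs: HubSet, net: GrownNetwork | nx.Graph
) -> pd.DataFrame:
    """Relative pathway connectivity Y_i = x_i / N for each gene.

    x_i counts the hubs directly adjacent to gene i in the network; a
    gene absent from the network scores 0 with a logged note. Returned
    sorted descending by Y with ties broken by gene name.
    """
    graph = net.graph if isinstance(net, GrownNetwork) else net
    if len(hubs) == 0:
        raise DataError("hub set is empty")
    hub_set = set(hubs.hubs)
    rows = []
    missing = 0
    for gene in sorted(set(genes)):
        if gene in graph:
            x = sum(1 for nb in graph.neighbors(gene) if nb in hub_set)
        else:
            x = 0
            missing += 1
        rows.append((gene, x))
    if missing:
        logger.info("%d scored genes absent from the network were assigned Y=0", missing)
    n = len(hubs)
    table = pd.DataFrame(rows, columns=["gene", "x"]).set_index("gene")
    table["n_hubs"] = n
    table["Y"] = table["x"] / n
    return table.sort_values(["Y", "gene"], ascending=[False, True], kind="stable")


def axis_hits(
    axes: Iterable[Axis],
    hubs: HubSet,
    net: GrownNetwork | nx.Graph,
    upregulated: Iterable[str] | None = None,
    path_length: int = 1,
) -> tuple[list[Axis], dict[str, frozenset[str]]]:
    """Candidate axes and the hub set each one hits.

    An axis is a candidate when its receptor is in the network and,
    if ``upregulated`` is given, in the up-regulated set (the receptor
    anchors the axis; an absent ligand does not disqualify it). Axis a
    hits hub h iff the receptor node is within ``path_length`` edges of
    h (default 1: direct adjacency).
    """
    graph = net.graph if isinstance(net, GrownNetwork) else net
    hub_set = set(hubs.hubs)
    up = set(upregulated) if upregulated is not None else None
    candidates: list[Axis] = []
    hits: dict[str, frozenset[str]] = {}
    for axis in axes:
        if axis.receptor not in graph:
            continue
        if up is not None and axis.receptor not in up:
            continue
        if path_length == 1:
            reach = set(graph.neighbors(axis.receptor))
        else:
            lengths = nx.single_source_shortest_path_length(
                graph, axis.receptor, cutoff=path_length
            )
            reach = set(lengths) - {axis.receptor}
        candidates.append(axis)
        hits[axis.name] = frozenset(reach & hub_set)
    return candidates, hits


def _greedy_cover(
    candidates: list[Axis], hits: Mapping[str, frozenset[str]], target: frozenset[str]
) -> list[Axis]:
    chosen: list[Axis] = []
    covered: frozenset[str] = frozenset()
    remaining = list(candidates)
    while covered != target and remaining:
        best = max(
            remaining,
            key=lambda a: (len(hits[a.name] - covered), -_name_rank(remaining, a)),
        )
        if not (hits[best.name] - covered):
            break
        chosen.append(best)
        covered |= hits[best.name]
        remaining.remove(best)
    return chosen


def _name_rank(axes: list[Axis], axis: Axis) -> int:
    return sorted(a.name for a in axes).index(axis.name)


def minimal_axis_cover(
    axes: Iterable[Axis],
    hubs: HubSet,
    net: GrownNetwork | nx.Graph,
    upregulated: Iterable[str] | None = None,
    exact_limit: int = 20,
    path_length: int = 1,
    scores: pd.DataFrame | None = None,
) -> AxisCover:
    """Smallest set of axes whose hit-sets jointly include every hub.

    With at most ``exact_limit`` candidate axes the solver enumerates
    subsets by increasing size, so the returned cover carries an exact
    minimality certificate; larger instances fall back to greedy
    max-coverage with ``minimal=False``. Ties among equal-size covers
    break by the larger summed relative connectivity Y of the receptors
    (when ``scores`` is given), then lexicographically by axis names.
    If no feasible cover exists, the best partial cover is returned with
    ``feasible=False`` and the uncovered hubs listed. An empty hub set
    yields an empty, vacuously feasible cover.
    """
    target = frozenset(hubs.hubs) if len(hubs) else frozenset()
    candidates, hits = axis_hits(axes, hubs, net, upregulated, path_length)
    if not target:
        return AxisCover(axes=(), hits={}, feasible=True, minimal=True)

    reachable = frozenset().union(*hits.values()) if hits else frozenset()
    y_of: dict[str, float] = {}
    if scores is not None:
        y_of = scores["Y"].to_dict()

    def tie_key(subset: tuple[Axis, ...]):
        summed_y = sum(y_of.get(a.receptor, 0.0) for a in subset)
        names = tuple(sorted(a.name for a in subset))
        return (-summed_y, names)

    if reachable != target:
        partial = _greedy_cover(candidates, hits, reachable)
        return AxisCover(
            axes=tuple(partial),
            hits={a.name: hits[a.name] for a in partial},
            feasible=False,
            minimal=False,
            uncovered=target - reachable,
        )

    if len(candidates) <= exact_limit:
        for size in range(1, len(candidates) + 1):
            feasible = [
                subset
                for subset in combinations(candidates, size)
                if frozenset().union(*(hits[a.name] for a in subset)) == target
            ]
            if feasible:
                best = min(feasible, key=tie_key)
                return AxisCover(
                    axes=tuple(best),
                    hits={a.name: hits[a.name] for a in best},
                    feasible=True,
                    minimal=True,
                    tie_break={
                        "equal_size_candidates": len(feasible),
                        "rule": "max summed Y, then lexicographic names",
                    },
                )
        # unreachable: reachable == target guarantees the full set covers
        raise AssertionError("cover search exhausted despite feasible union")

    chosen = _greedy_cover(candidates, hits, target)
    return AxisCover(
        axes=tuple(chosen),
        hits={a.name: hits[a.name] for a in chosen},
        feasible=True,
        minimal=False,
        tie_break={"rule": "greedy max-coverage"},
    )
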