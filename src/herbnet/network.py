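"""Interactome loading, shortest paths, and degree binning.

The interactome is an undirected, unweighted protein-protein interaction
graph over gene symbols. Edge weights never appear: all biological weight
in this package lives on nodes. Distances are exact unweighted shortest
paths (breadth-first search); unreachable pairs are carried as an explicit
marker and never as a substitute finite distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import networkx as nx

from .weighting import WeightedProteinSet

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionNetwork",
    "DistanceTable",
    "DegreeBinning",
    "load_edge_list",
    "load_id_map",
    "write_edge_list",
    "shortest_path_lengths",
    "neighbors",
    "build_degree_bins",
    "restrict_to_network",
]


@dataclass(frozen=True)
class InteractionNetwork:
    """Undirected interactome with self-loops removed and duplicates merged."""

    graph: nx.Graph

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def degree_index(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def has_node(self, symbol: str) -> bool:
        return self.graph.has_node(symbol)

    def adjacency(self, symbol: str) -> set[str]:
        return set(self.graph.neighbors(symbol))


@dataclass(frozen=True)
class DistanceTable:
    """Shortest-path lengths between a source set and a target set.

    ``lengths[s]`` maps reachable targets to their distance from ``s``;
    a target absent from that inner map is unreachable from ``s``.
    """

    lengths: Mapping[str, Mapping[str, int]]
    sources: frozenset[str]
    targets: frozenset[str]

    def get(self, source: str, target: str) -> int | None:
        """Distance, or None when the pair is unreachable."""
        if source not in self.sources or target not in self.targets:
            raise KeyError(f"pair ({source!r}, {target!r}) outside the table")
        return self.lengths[source].get(target)


@dataclass(frozen=True)
class DegreeBinning:
    """Partition of network nodes into degree intervals for null sampling.

    ``intervals`` are half-open ``[lo, hi)`` degree ranges in ascending
    order; ``bin_of`` assigns every node to exactly one interval index and
    ``members`` lists each bin's nodes (sorted, for determinism).
    """

    intervals: tuple[tuple[int, int], ...]
    bin_of: Mapping[str, int]
    members: tuple[tuple[str, ...], ...]
    min_bin_size: int

    def bin_members(self, symbol: str) -> tuple[str, ...]:
        return self.members[self.bin_of[symbol]]


def load_id_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV mapping source identifiers to gene symbols."""
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(parts)}"
                )
            mapping[parts[0]] = parts[1]
    return mapping


def load_edge_list(
    path: str | Path,
    id_map: Mapping[str, str] | str | Path | None = None,
    skip_header: bool = False,
) -> InteractionNetwork:
    """Load an undirected interactome from a two-column TSV edge list.

    Identifiers are optionally mapped through ``id_map`` (many-to-one
    allowed); rows with unmapped identifiers are dropped with a warning.
    Self-loops (including those arising from the mapping) are removed and
    duplicate edges merged; the counts are logged.
    """
    if id_map is not None and not isinstance(id_map, Mapping):
        id_map = load_id_map(id_map)

    graph: nx.Graph = nx.Graph()
    n_rows = n_unmapped = n_self = n_dup = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            raw = line.rstrip("\n")
            if not raw or raw.startswith("#"):
                continue
            if skip_header:
                skip_header = False
                continue
            parts = raw.split("\t")
            if len(parts) != 2:
                raise ValueError(
                    f"{path}: line {lineno}: expected 2 columns, got {len(parts)}"
                )
            a, b = parts
            n_rows += 1
            if id_map is not None:
                if a not in id_map or b not in id_map:
                    n_unmapped += 1
                    continue
                a, b = id_map[a], id_map[b]
            if a == b:
                n_self += 1
                graph.add_node(a)
                continue
            if graph.has_edge(a, b):
                n_dup += 1
                continue
            graph.add_edge(a, b)
    if graph.number_of_nodes() == 0:
        raise ValueError(f"{path}: no usable interactions found")
    logger.info(
        "loaded %d nodes / %d edges from %d rows (%d unmapped, %d self-loops, "
        "%d duplicates dropped)",
        graph.number_of_nodes(),
        graph.number_of_edges(),
        n_rows,
        n_unmapped,
        n_self,
        n_dup,
    )
    return InteractionNetwork(graph)


def write_edge_list(net: InteractionNetwork, path: str | Path) -> None:
    """Write the normalized edge list (sorted endpoints, sorted rows)."""
    rows = sorted(tuple(sorted(e)) for e in net.graph.edges)
    with open(path, "w") as fh:
        for a, b in rows:
            fh.write(f"{a}\t{b}\n")


def shortest_path_lengths(
    net: InteractionNetwork, sources: set[str], targets: set[str]
) -> DistanceTable:
    """Exact BFS shortest-path lengths for every (source, target) pair.

    BFS runs from whichever side is smaller (the graph is undirected), so
    the cost is ``O(min(|S|, |T|) * (V + E))``.
    """
    if not sources or not targets:
        raise ValueError("sources and targets must be nonempty")
    missing = (sources | targets) - net.nodes
    if missing:
        raise ValueError(
            f"{len(missing)} node(s) absent from the network, e.g. "
            f"{sorted(missing)[:5]}; restrict the sets first"
        )
    flip = len(targets) < len(sources)
    bfs_side, other_side = (targets, sources) if flip else (sources, targets)
    table: dict[str, dict[str, int]] = {s: {} for s in sources}
    for origin in bfs_side:
        dist = nx.single_source_shortest_path_length(net.graph, origin)
        for node in other_side:
            if node in dist:
                if flip:
                    table[node][origin] = dist[node]
                else:
                    table[origin][node] = dist[node]
    return DistanceTable(table, frozenset(sources), frozenset(targets))


def neighbors(net: InteractionNetwork, H: set[str]) -> set[str]:
    """Union of first-degree neighborhoods of the nodes in ``H``."""
    out: set[str] = set()
    for h in H:
        out.update(net.graph.neighbors(h))
    return out


def build_degree_bins(net: InteractionNetwork, min_bin_size: int = 100) -> DegreeBinning:
    """Partition nodes into log2-spaced degree bins of at least ``min_bin_size``.

    Interval boundaries are powers of two ([0,1), [1,2), [2,4), [4,8), ...);
    ascending intervals are pooled until the accumulated bin holds at least
    ``min_bin_size`` nodes, and an undersized tail is merged into the last
    closed bin. This preserves the degree profile of reference sets drawn on
    heavy-tailed interactomes while guaranteeing enough exchangeable nodes
    per bin.
    """
    if min_bin_size < 1:
        raise ValueError("min_bin_size must be >= 1")
    degrees = net.degree_index
    if min_bin_size > len(degrees):
        raise ValueError(
            f"min_bin_size={min_bin_size} exceeds the network size {len(degrees)}"
        )
    max_degree = max(degrees.values())
    boundaries = [0, 1]
    while boundaries[-1] <= max_degree:
        boundaries.append(boundaries[-1] * 2)
    raw_intervals = list(zip(boundaries[:-1], boundaries[1:]))

    by_interval: list[list[str]] = [[] for _ in raw_intervals]
    for node in sorted(degrees):
        d = degrees[node]
        idx = 0 if d == 0 else d.bit_length()  # [2^(k-1), 2^k) has index k
        by_interval[idx].append(node)

    intervals: list[tuple[int, int]] = []
    members: list[list[str]] = []
    acc_nodes: list[str] = []
    acc_lo: int | None = None
    for (lo, hi), nodes_here in zip(raw_intervals, by_interval):
        if not nodes_here and acc_lo is None:
            continue
        if acc_lo is None:
            acc_lo = lo
        acc_nodes.extend(nodes_here)
        if len(acc_nodes) >= min_bin_size:
            intervals.append((acc_lo, hi))
            members.append(acc_nodes)
            acc_nodes, acc_lo = [], None
    if acc_nodes:
        if intervals:
            lo, _ = intervals[-1]
            intervals[-1] = (lo, raw_intervals[-1][1])
            members[-1] = members[-1] + acc_nodes
        else:
            intervals.append((acc_lo if acc_lo is not None else 0, raw_intervals[-1][1]))
            members.append(acc_nodes)

    bin_of = {
        node: idx for idx, nodes_here in enumerate(members) for node in nodes_here
    }
    return DegreeBinning(
        intervals=tuple(intervals),
        bin_of=bin_of,
        members=tuple(tuple(sorted(m)) for m in members),
        min_bin_size=min_bin_size,
    )


def restrict_to_network(
    net: InteractionNetwork, S: WeightedProteinSet
) -> tuple[WeightedProteinSet, int]:
    """Drop members of ``S`` absent from the network; return (kept, n_dropped)."""
    kept = {s: w for s, w in S.weights.items() if net.has_node(s)}
    dropped = len(S) - len(kept)
    if not kept:
        raise ValueError(
            f"no member of the {S.label!r} set maps onto the network; "
            "metrics are undefined"
        )
    if dropped:
        logger.warning(
            "%d/%d members of the %r set are absent from the network and were dropped",
            dropped,
            len(S),
            S.label,
        )
    return WeightedProteinSet(kept, S.label), dropped
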