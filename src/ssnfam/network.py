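"""Sequence similarity networks over an E-value threshold grid.

An SSN at threshold t has every sequence as a node and an edge for every pair
whose alignment E-value is at or below t (isolated nodes are retained, so the
node set is the full input at every threshold). As t tightens, connected
components only ever split, giving the refinement "flow" across the grid that
drives subfamily delineation. For display, nodes that are mutually connected
at a much stricter threshold can be contracted into metanodes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy.cluster.hierarchy import DisjointSet

from .pairwise import HitTable

#: Default grid: 1e-5 down to 1e-120 in steps of 5 logs (24 thresholds).
DEFAULT_GRID: tuple[float, ...] = tuple(10.0 ** (-e) for e in range(5, 125, 5))

#: Default threshold at which highly similar sequences merge into metanodes.
DEFAULT_MERGE_THRESHOLD = 1e-85


class NetworkError(ValueError):
    pass


@dataclass
class SSNGraph:
    """Undirected similarity network induced by one E-value threshold."""

    graph: nx.Graph
    threshold: float

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclass
class Partition:
    """Disjoint clusters covering the node set, induced at a threshold.

    Cluster ids are deterministic: 1..k by descending size, ties broken by
    the lexicographically smallest member id.
    """

    clusters: dict[int, frozenset[str]]
    threshold: float

    @classmethod
    def from_components(
        cls, components: Iterable[Iterable[str]], threshold: float
    ) -> "Partition":
        comps = [frozenset(c) for c in components]
        comps.sort(key=lambda c: (-len(c), min(c)))
        return cls({i + 1: c for i, c in enumerate(comps)}, threshold)

    def membership(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for cid, members in self.clusters.items():
            for m in members:
                out[m] = cid
        return out

    def sizes(self) -> dict[int, int]:
        return {cid: len(m) for cid, m in self.clusters.items()}

    def __len__(self) -> int:
        return len(self.clusters)


def build_graph(hits: HitTable, node_ids: Iterable[str], threshold: float) -> SSNGraph:
    """Materialize the SSN at one threshold: edge iff pair E-value <= threshold."""
    if threshold <= 0:
        raise NetworkError("threshold must be positive")
    nodes = set(node_ids)
    g = nx.Graph()
    g.add_nodes_from(sorted(nodes))
    for a, b, hit in hits.pairs():
        if a not in nodes or b not in nodes:
            raise NetworkError(f"hit references unknown node: {a!r}/{b!r}")
        if hit.evalue <= threshold:
            g.add_edge(a, b, evalue=hit.evalue, bit_score=hit.bit_score)
    return SSNGraph(graph=g, threshold=threshold)


def connected_components(graph: SSNGraph) -> Partition:
    """Partition of the node set into connected components (union-find)."""
    nodes = sorted(graph.graph.nodes)
    if not nodes:
        return Partition({}, graph.threshold)
    ds = DisjointSet(nodes)
    for a, b in graph.graph.edges:
        ds.merge(a, b)
    return Partition.from_components(ds.subsets(), graph.threshold)


@dataclass
class ThresholdScan:
    """Family partitions at each grid threshold plus parent->child links.

    ``thresholds`` is strictly decreasing (loosest first). ``parents[i]``
    maps each cluster id at ``thresholds[i]`` to the id of the cluster at
    ``thresholds[i-1]`` that contains it (``parents[0]`` is empty).
    """

    thresholds: tuple[float, ...]
    partitions: list[Partition]
    parents: list[dict[int, int]] = field(default_factory=list)

    def partition_at(self, threshold: float) -> Partition:
        for t, p in zip(self.thresholds, self.partitions):
            if t == threshold:
                return p
        raise NetworkError(f"threshold {threshold} not in scan grid")

    def to_table(self) -> pd.DataFrame:
        """Long-format scan summary: one row per (threshold, cluster).

        Mirrors the tabular SSN summary (clusters x thresholds with sizes and
        their lineage across adjacent thresholds).
        """
        rows = []
        for i, (t, part) in enumerate(zip(self.thresholds, self.partitions)):
            for cid in sorted(part.clusters):
                rows.append(
                    {
                        "threshold": t,
                        "cluster": cid,
                        "size": len(part.clusters[cid]),
                        "parent_cluster": self.parents[i].get(cid, 0) if i > 0 else 0,
                    }
                )
        return pd.DataFrame(rows, columns=["threshold", "cluster", "size", "parent_cluster"])


def threshold_scan(
    hits: HitTable,
    node_ids: Iterable[str],
    thresholds: Sequence[float] = DEFAULT_GRID,
) -> ThresholdScan:
    """Index the hit table over the threshold grid and track refinement.

    Works from the strictest threshold outward with an incremental union-find
    (edges are only ever added as the threshold loosens), so the scan costs a
    single pass over the sorted edge list.
    """
    thresholds = tuple(thresholds)
    if not thresholds:
        raise NetworkError("empty threshold grid")
    if any(t2 >= t1 for t1, t2 in zip(thresholds, thresholds[1:])):
        raise NetworkError("threshold grid must be strictly decreasing")
    nodes = sorted(set(node_ids))
    edges = sorted(
        ((hit.evalue, a, b) for a, b, hit in hits.pairs()),
        key=lambda e: e[0],
    )
    unknown = hits.node_ids() - set(nodes)
    if unknown:
        raise NetworkError(f"hits reference unknown nodes: {sorted(unknown)[:5]}")

    ds = DisjointSet(nodes)
    partitions_strict_first: list[Partition] = []
    idx = 0
    for t in reversed(thresholds):  # strictest -> loosest
        while idx < len(edges) and edges[idx][0] <= t:
            ds.merge(edges[idx][1], edges[idx][2])
            idx += 1
        partitions_strict_first.append(Partition.from_components(ds.subsets(), t))
    partitions = list(reversed(partitions_strict_first))

    parents: list[dict[int, int]] = [{}]
    for i in range(1, len(thresholds)):
        parent_membership = partitions[i - 1].membership()
        links: dict[int, int] = {}
        for cid, members in partitions[i].clusters.items():
            links[cid] = parent_membership[min(members)]
        parents.append(links)
    return ThresholdScan(thresholds=thresholds, partitions=partitions, parents=parents)


def _dfs_components(nodes: Sequence[str], adjacency: Mapping[str, list[str]]) -> list[set[str]]:
    """Connected components by iterative depth-first search."""
    seen: set[str] = set()
    comps = []
    for start in nodes:
        if start in seen:
            continue
        comp = set()
        stack = [start]
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v)
            for w in adjacency.get(v, ()):
                if w not in comp:
                    stack.append(w)
        seen |= comp
        comps.append(comp)
    return comps


def contract_metanodes(
    graph: SSNGraph, merge_threshold: float = DEFAULT_MERGE_THRESHOLD
) -> SSNGraph:
    """Contract groups of highly similar sequences into metanodes.

    Metanodes are the connected components of the sub-threshold edge set
    (E <= merge_threshold), found by depth-first search. Each metanode is
    named after its lexicographically smallest member and carries ``members``
    and ``size`` attributes; contracted edges are deduplicated keeping the
    minimum E-value. Component structure at the display threshold is
    preserved exactly.
    """
    if merge_threshold > graph.threshold:
        raise NetworkError(
            "merge threshold must be at least as strict as the display threshold"
        )
    nodes = sorted(graph.graph.nodes)
    adjacency: dict[str, list[str]] = {v: [] for v in nodes}
    for a, b, data in graph.graph.edges(data=True):
        if data["evalue"] <= merge_threshold:
            adjacency[a].append(b)
            adjacency[b].append(a)
    meta_of: dict[str, str] = {}
    members_of: dict[str, frozenset[str]] = {}
    for comp in _dfs_components(nodes, adjacency):
        name = min(comp)
        members_of[name] = frozenset(comp)
        for v in comp:
            meta_of[v] = name

    g = nx.Graph()
    for name, members in sorted(members_of.items()):
        g.add_node(name, size=len(members), members=",".join(sorted(members)))
    for a, b, data in graph.graph.edges(data=True):
        ma, mb = meta_of[a], meta_of[b]
        if ma == mb:
            continue
        if g.has_edge(ma, mb):
            g[ma][mb]["evalue"] = min(g[ma][mb]["evalue"], data["evalue"])
        else:
            g.add_edge(ma, mb, evalue=data["evalue"])
    return SSNGraph(graph=g, threshold=graph.threshold)


def write_graphml(graph: SSNGraph, path: str | Path) -> None:
    nx.write_graphml(graph.graph, str(Path(path)))


def write_edge_list(graph: SSNGraph, path: str | Path) -> None:
    """Plain 3-column (source, target, evalue) edge list, Cytoscape-importable."""
    with open(path, "w") as fh:
        fh.write("source\ttarget\tevalue\n")
        for a, b in sorted(map(tuple, map(sorted, graph.graph.edges))):
            fh.write(f"{a}\t{b}\t{graph.graph[a][b]['evalue']:.3e}\n")


def write_partition(partition: Partition, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tthreshold\tcluster\n")
        membership = partition.membership()
        for rid in sorted(membership):
            fh.write(f"{rid}\t{partition.threshold:.0e}\t{membership[rid]}\n")
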