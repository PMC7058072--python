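"""Causal-path enumeration and disease-connectivity classification.

Given an inferred multilevel network, enumerate all simple directed paths
from a source node (a gene, SNP or methylation site) to a disease node by
iterative depth-first search, and label query nodes per disease as
*directly* connected (a causal edge straight to the disease, or an external
causal test rejecting), *indirectly* connected (reaching the disease only
through a path of two or more edges), *both*, or *not* connected.  A
two-disease cross-tabulation of these labels summarizes sharing between two
diseases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = [
    "CausalPath",
    "CausalPathSet",
    "ConnectivityClass",
    "find_causal_paths",
    "classify_connectivity",
    "shared_connection_table",
    "SharedConnectionResult",
]

CLASSES = ("direct", "indirect", "both", "none")


@dataclass(frozen=True)
class CausalPath:
    """One simple directed path (no repeated nodes)."""

    nodes: tuple[str, ...]

    @property
    def edges(self) -> list[tuple[str, str]]:
        return list(zip(self.nodes[:-1], self.nodes[1:]))

    @property
    def length(self) -> int:
        return len(self.nodes) - 1


@dataclass
class CausalPathSet:
    """Enumerated paths plus a truncation flag (path-count cap reached)."""

    paths: list[CausalPath]
    truncated: bool = False

    def __iter__(self):
        return iter(self.paths)

    def __len__(self) -> int:
        return len(self.paths)

    def __getitem__(self, i):
        return self.paths[i]


def _as_digraph(network) -> nx.DiGraph:
    if isinstance(network, nx.Graph):
        return network
    return network.graph


def _searchable_graph(g: nx.DiGraph, keep: set[str], diseases_terminal: bool) -> nx.DiGraph:
    """Disease nodes other than the endpoints are not traversed as intermediates."""
    if not diseases_terminal:
        return g
    blocked = {
        n for n, d in g.nodes(data=True) if d.get("layer") == "disease" and n not in keep
    }
    return g.subgraph(set(g.nodes) - blocked) if blocked else g


def find_causal_paths(
    network,
    source: str,
    target: str,
    max_length: int = 10,
    max_paths: int = 100_000,
    diseases_terminal: bool = True,
) -> CausalPathSet:
    """All simple directed paths source -> target of length <= ``max_length``.

    Enumeration uses an iterative-stack depth-first search (no recursion
    limit).  Disease nodes other than the endpoints are excluded as
    intermediates by default.  Paths are returned in lexicographic node
    order; if more than ``max_paths`` exist the result is truncated and
    flagged.
    """
    g = _as_digraph(network)
    for n in (source, target):
        if n not in g:
            raise KeyError(f"node {n!r} not in network")
    if source == target:
        raise ValueError("source and target must differ")
    g = _searchable_graph(g, {source, target}, diseases_terminal)

    paths: list[tuple[str, ...]] = []
    truncated = False
    # stack of (node, iterator over successors); visited holds the current path
    succ = {n: sorted(g.successors(n)) for n in g.nodes}
    stack: list[tuple[str, int]] = [(source, 0)]
    on_path = {source}
    path = [source]
    while stack:
        node, idx = stack[-1]
        children = succ[node]
        # len(path) - 1 edges so far; one more edge would exceed max_length
        if idx >= len(children) or len(path) - 1 >= max_length:
            stack.pop()
            on_path.discard(node)
            path.pop()
            continue
        stack[-1] = (node, idx + 1)
        nxt = children[idx]
        if nxt in on_path:
            continue
        if nxt == target:
            paths.append(tuple(path) + (target,))
            if len(paths) >= max_paths:
                truncated = True
                warnings.warn(f"path enumeration truncated at {max_paths} paths")
                break
            continue
        stack.append((nxt, 0))
        on_path.add(nxt)
        path.append(nxt)
    paths.sort()
    return CausalPathSet(paths=[CausalPath(nodes=p) for p in paths], truncated=truncated)


@dataclass
class ConnectivityClass:
    """Per-disease connectivity label of one query node."""

    node: str
    disease: str
    label: str  # one of CLASSES


def _has_indirect_path(g: nx.DiGraph, node: str, disease: str) -> bool:
    """True when a simple path node -> disease of length >= 2 exists."""
    if node not in g or disease not in g:
        return False
    rest = g.subgraph(set(g.nodes) - {node})
    for m in g.successors(node):
        if m == disease:
            continue
        if m in rest and nx.has_path(rest, m, disease):
            return True
    return False


def classify_connectivity(
    network,
    query_nodes: list[str],
    disease_node: str,
    direct_test_results: dict[str, float] | None = None,
    alpha: float = 0.05,
    diseases_terminal: bool = True,
) -> list[ConnectivityClass]:
    """Label each query node's connectivity to one disease node.

    *direct*: a network edge node -> disease exists, or an external causal
    test p-value (``direct_test_results``) falls below ``alpha``.
    *indirect*: a simple directed path of length >= 2 exists.  Nodes with
    both are labelled *both*; with neither, *none*.
    """
    g = _as_digraph(network)
    if disease_node not in g:
        raise KeyError(f"disease node {disease_node!r} not in network")
    keep = set(query_nodes) | {disease_node}
    gs = _searchable_graph(g, keep, diseases_terminal)
    out = []
    for node in query_nodes:
        direct = bool(node in g and g.has_edge(node, disease_node))
        if direct_test_results is not None and node in direct_test_results:
            direct = direct or direct_test_results[node] < alpha
        indirect = node in gs and _has_indirect_path(gs, node, disease_node)
        if direct and indirect:
            label = "both"
        elif direct:
            label = "direct"
        elif indirect:
            label = "indirect"
        else:
            label = "none"
        out.append(ConnectivityClass(node=node, disease=disease_node, label=label))
    return out


@dataclass
class SharedConnectionResult:
    """Cross-tabulated two-disease connectivity labels."""

    table: pd.DataFrame  # 4x4 counts, rows disease_a classes, cols disease_b
    shared_nodes: set[str] = field(default_factory=set)


def shared_connection_table(
    network,
    query_nodes: list[str],
    disease_a: str,
    disease_b: str,
    direct_test_results_a: dict[str, float] | None = None,
    direct_test_results_b: dict[str, float] | None = None,
    alpha: float = 0.05,
) -> SharedConnectionResult:
    """4x4 cross-tabulation of connectivity classes to two diseases.

    Also reports the set of nodes connected (any class except *none*) to
    both diseases.  Cell counts partition the query nodes, so the table sums
    to ``len(query_nodes)`` and its marginals equal the single-disease
    classification counts.
    """
    class_a = {
        c.node: c.label
        for c in classify_connectivity(
            network, query_nodes, disease_a, direct_test_results_a, alpha
        )
    }
    class_b = {
        c.node: c.label
        for c in classify_connectivity(
            network, query_nodes, disease_b, direct_test_results_b, alpha
        )
    }
    table = pd.DataFrame(0, index=list(CLASSES), columns=list(CLASSES))
    shared = set()
    for node in query_nodes:
        la, lb = class_a[node], class_b[node]
        table.loc[la, lb] += 1
        if la != "none" and lb != "none":
            shared.add(node)
    table.index.name = f"to_{disease_a}"
    table.columns.name = f"to_{disease_b}"
    return SharedConnectionResult(table=table, shared_nodes=shared)
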