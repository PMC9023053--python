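"""CDR3 similarity graphs and convergence clusters.

Edges follow the graph rule: two nodes are connected iff their CDR3 amino
acid sequences have equal length and Hamming distance <= 1.  V/J identity is
deliberately NOT required for edges (unlike the neighbor test, which
conditions on the VJ pair).  Distance-0 edges arise between distinct nodes
carrying the same CDR3 with different V/J or from different samples.

Node identity is ``(cdr3_aa, v_gene, j_gene, sample_id)``; composite graphs
keep identical clonotypes from different samples as separate nodes.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import networkx as nx

from .repertoire_io import Clonotype, ClonotypeKey, Repertoire

__all__ = [
    "NodeId",
    "ClusterSet",
    "build_graph",
    "build_composite_graph",
    "extract_clusters",
    "cluster_weight",
    "export_gml",
    "import_gml",
    "hits_plus_neighbors",
]

NodeId = Tuple[str, str, str, str]  # (cdr3_aa, v_gene, j_gene, sample_id)


@dataclass
class ClusterSet:
    """A similarity graph with its connected-component clusters.

    ``clusters`` maps a deterministic cluster id (the lexicographically
    smallest member node, joined with ``|``) to the sorted member list;
    ``weights`` maps cluster id to the cumulative frequency of members.
    """

    graph: nx.Graph
    min_size: int = 2
    clusters: Dict[str, List[NodeId]] = field(default_factory=dict)
    weights: Dict[str, float] = field(default_factory=dict)


def _node_id(c: Clonotype, sample_id: str) -> NodeId:
    return (c.cdr3_aa, c.v_gene, c.j_gene, sample_id)


def _hamming1_edges(nodes: Sequence[NodeId]) -> Set[Tuple[NodeId, NodeId]]:
    """All node pairs with equal CDR3 length and Hamming distance <= 1."""
    edges: Set[Tuple[NodeId, NodeId]] = set()
    by_len: Dict[int, List[NodeId]] = defaultdict(list)
    for n in nodes:
        by_len[len(n[0])].append(n)
    for L, group in by_len.items():
        for pos in range(L):
            buckets: Dict[str, List[NodeId]] = defaultdict(list)
            for n in group:
                s = n[0]
                buckets[s[:pos] + s[pos + 1 :]].append(n)
            for members in buckets.values():
                if len(members) < 2:
                    continue
                for i in range(len(members)):
                    for k in range(i + 1, len(members)):
                        a, b = members[i], members[k]
                        edges.add((a, b) if a <= b else (b, a))
    return edges


def build_graph(
    clonotypes: Iterable[Clonotype],
    sample_id: str = "",
    edge_rule: str = "hamming1",
    hit_keys: Optional[Set[ClonotypeKey]] = None,
) -> nx.Graph:
    """Build the CDR3 similarity graph over one clonotype collection."""
    if edge_rule != "hamming1":
        raise ValueError(f"unknown edge rule {edge_rule!r}")
    g = nx.Graph()
    for c in sorted(clonotypes, key=lambda c: c.key):
        node = _node_id(c, sample_id)
        g.add_node(
            node,
            cdr3_aa=c.cdr3_aa,
            v_gene=c.v_gene,
            j_gene=c.j_gene,
            sample=sample_id,
            freq=c.freq,
            hit=bool(hit_keys and c.key in hit_keys),
            specificity="",
        )
    g.add_edges_from(sorted(_hamming1_edges(list(g.nodes))))
    return g


def build_composite_graph(
    reps: Sequence[Repertoire],
    node_sets: Optional[Sequence[Optional[Set[ClonotypeKey]]]] = None,
    edge_rule: str = "hamming1",
    hit_keys_per_rep: Optional[Sequence[Set[ClonotypeKey]]] = None,
) -> nx.Graph:
    """Multi-sample graph: identical clonotypes from different repertoires
    become separate nodes, joined by distance-0 edges."""
    if edge_rule != "hamming1":
        raise ValueError(f"unknown edge rule {edge_rule!r}")
    g = nx.Graph()
    for i, rep in enumerate(reps):
        keep = node_sets[i] if node_sets is not None else None
        hits = hit_keys_per_rep[i] if hit_keys_per_rep is not None else None
        for c in sorted(rep.clonotypes, key=lambda c: c.key):
            if keep is not None and c.key not in keep:
                continue
            node = _node_id(c, rep.sample_id)
            g.add_node(
                node,
                cdr3_aa=c.cdr3_aa,
                v_gene=c.v_gene,
                j_gene=c.j_gene,
                sample=rep.sample_id,
                freq=c.freq,
                hit=bool(hits and c.key in hits),
                specificity="",
            )
    g.add_edges_from(sorted(_hamming1_edges(list(g.nodes))))
    return g


def extract_clusters(graph: nx.Graph, min_size: int = 2) -> ClusterSet:
    """Connected components of size >= min_size, with cumulative frequencies."""
    cs = ClusterSet(graph=graph, min_size=min_size)
    for component in nx.connected_components(graph):
        if len(component) < min_size:
            continue
        members = sorted(component)
        cid = "|".join(members[0])
        cs.clusters[cid] = members
        cs.weights[cid] = float(
            sum(graph.nodes[n].get("freq", 0.0) for n in members)
        )
    return cs


def cluster_weight(members: Iterable[NodeId], rep: Repertoire) -> float:
    """Cumulative frequency of the cluster members within ``rep``."""
    freqs = {c.key: c.freq for c in rep.clonotypes}
    total = 0.0
    for node in members:
        key = tuple(node[:3])
        if key not in freqs:
            raise ValueError(f"cluster member {key} absent from repertoire {rep.sample_id}")
        total += freqs[key]
    return total


def hits_plus_neighbors(
    rep: Repertoire, hit_keys: Set[ClonotypeKey]
) -> Set[ClonotypeKey]:
    """Default cluster node set: hits plus every repertoire clonotype within
    Hamming distance <= 1 (graph edge rule, so V/J-agnostic) of a hit."""
    clonotypes = rep.aggregated().clonotypes
    nodes = [_node_id(c, rep.sample_id) for c in clonotypes]
    edges = _hamming1_edges(nodes)
    keep: Set[ClonotypeKey] = set(hit_keys)
    for a, b in edges:
        ka, kb = tuple(a[:3]), tuple(b[:3])
        if ka in hit_keys:
            keep.add(kb)
        if kb in hit_keys:
            keep.add(ka)
    return keep


def _gml_name(node: NodeId) -> str:
    return "|".join(node)


def export_gml(graph: nx.Graph, path) -> None:
    """Write the graph to GML with stable node ordering (byte-deterministic)."""
    out = nx.Graph()
    for node in sorted(graph.nodes):
        attrs = graph.nodes[node]
        out.add_node(
            _gml_name(node),
            label=attrs.get("cdr3_aa", node[0]),
            freq=float(attrs.get("freq", 0.0)),
            sample=str(attrs.get("sample", "")),
            specificity=str(attrs.get("specificity", "")),
            hit=int(bool(attrs.get("hit", False))),
        )
    for a, b in sorted(graph.edges):
        out.add_edge(_gml_name(a), _gml_name(b))
    nx.write_gml(out, Path(path))


def import_gml(path) -> nx.Graph:
    """Read a GML file written by :func:`export_gml` back into node tuples."""
    raw = nx.read_gml(Path(path))
    g = nx.Graph()
    for name, attrs in raw.nodes(data=True):
        node = tuple(name.split("|"))
        g.add_node(node, **attrs)
    for a, b in raw.edges:
        g.add_edge(tuple(a.split("|")), tuple(b.split("|")))
    return g
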