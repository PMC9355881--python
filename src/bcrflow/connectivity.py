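"""Intra-compartment clonal expansion and inter-compartment sharing.

Clonotype size measures how many distinct somatic variants a clone has
accumulated within one compartment; lineages whose members span several
sorted compartments reveal intercompartmental expansion.  Lineage graphs
are simplified relatedness graphs — a minimum spanning tree over pairwise
Hamming distances rooted at the clonal germline — rather than full
maximum-parsimony phylogenies.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import networkx as nx

from .airr_io import Repertoire, concat_repertoires
from .clonal_clustering import (
    CloneCluster,
    define_clones,
    detect_threshold,
    nearest_neighbor_distances,
)
from .error_correction import hamming
from .repertoire_stats import downsample_unique

logger = logging.getLogger(__name__)

__all__ = [
    "SharingResult",
    "clonotype_connectivity",
    "cross_compartment_sharing",
    "build_lineage_graph",
]


@dataclass
class SharingResult:
    """Cross-compartment lineage sharing summary."""

    pair_counts: dict = field(default_factory=dict)  # frozenset({A,B}) -> n lineages
    triple_count: int = 0
    lineages: list[dict] = field(default_factory=list)
    threshold: float = float("nan")
    threshold_method: str = ""
    downsample_n: int = 0
    seed: int = 0

    @property
    def total_connections(self) -> int:
        return sum(self.pair_counts.values())


def clonotype_connectivity(clones: list[CloneCluster]) -> dict:
    """Intra-compartment clonal connectivity summary.

    'Average number of clonal connections' is ambiguous between mean
    clonotype size, mean (size - 1) and mean relatedness-graph degree;
    all three are emitted, none privileged.
    """
    if not clones:
        raise ValueError("no clones")
    sizes = [c.clone_size for c in clones]
    n = len(sizes)
    mean_size = sum(sizes) / n
    mean_connections = sum(s - 1 for s in sizes) / n
    # a spanning tree over s members has s-1 edges, hence mean degree 2(s-1)/s
    mean_degree = sum(2 * (s - 1) / s for s in sizes) / n
    dist: dict[int, int] = {}
    for s in sizes:
        dist[s] = dist.get(s, 0) + 1
    return {
        "n_clones": n,
        "mean_clone_size": mean_size,
        "mean_connections": mean_connections,
        "mean_graph_degree": mean_degree,
        "size_distribution": dict(sorted(dist.items())),
    }


def cross_compartment_sharing(
    reps: dict[str, Repertoire],
    n: int = 10_000,
    seed: int = 0,
    tau: float | None = None,
    **threshold_kwargs,
) -> SharingResult:
    """Count lineages spanning pairs (and the triple) of compartments.

    Each repertoire is downsampled to ``n`` unique sequences (all if
    fewer), the samples pooled, one threshold detected on the pooled set
    so lineages are defined consistently across compartments, and each
    lineage labeled by the compartments of its members.
    """
    sampled = []
    for comp, rep in reps.items():
        sub = downsample_unique(rep, n, seed)
        for r in sub.records:
            if r.compartment != comp:
                r = r.copy(compartment=comp)
            sampled.append(r)
    pooled = Repertoire(records=sampled)

    method = "manual"
    if tau is None:
        try:
            profile = detect_threshold(
                nearest_neighbor_distances(pooled), **threshold_kwargs
            )
            tau, method = profile.threshold, profile.method
        except ValueError:
            tau, method = threshold_kwargs.get("fallback_threshold", 0.1), "fallback"
            logger.warning("too few distances on pooled set; fallback threshold %.3f", tau)

    clones = define_clones(pooled, tau)
    result = SharingResult(threshold=tau, threshold_method=method,
                           downsample_n=n, seed=seed)
    for clone in clones:
        comps: dict[str, int] = {}
        for m in clone.members:
            comps[m.compartment] = comps.get(m.compartment, 0) + 1
        if len(comps) >= 2:
            for a, b in itertools.combinations(sorted(comps), 2):
                key = frozenset((a, b))
                result.pair_counts[key] = result.pair_counts.get(key, 0) + 1
        if len(comps) >= 3:
            result.triple_count += 1
        result.lineages.append(
            {
                "clone_id": clone.clone_id,
                "compartments": dict(sorted(comps.items())),
                "clone_copies": clone.clone_copies,
                "spanning": len(comps),
            }
        )
    return result


def build_lineage_graph(clone: CloneCluster, germline: str) -> nx.Graph:
    """Simplified lineage graph of one clone.

    Minimum spanning tree (Kruskal with lexicographic tie-breaking) over
    pairwise Hamming distances among the unique member sequences plus the
    germline root.  Node attribute ``duplicate_count`` carries abundance
    (germline: 0, flagged ``is_root``); edge attribute ``label`` is the
    nucleotide difference count.  The graph attribute ``kind`` is
    'simplified_mst' to distinguish it from parsimony trees.
    """
    root = "germline"
    nodes = {root: germline}
    weights = {root: 0}
    for m in clone.members:
        nodes[m.sequence_id] = m.sequence_alignment
        weights[m.sequence_id] = m.duplicate_count

    names = sorted(nodes)
    edges = []
    for a, b in itertools.combinations(names, 2):
        d = hamming(nodes[a], nodes[b])
        if d is None:
            d = max(len(nodes[a]), len(nodes[b]))  # incomparable: large weight
        edges.append((d, a, b))
    edges.sort()

    g = nx.Graph(kind="simplified_mst", clone_id=clone.clone_id)
    for name in names:
        g.add_node(name, duplicate_count=weights[name], is_root=(name == root))
    parent = {n: n for n in names}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for d, a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
            g.add_edge(a, b, weight=d, label=d)
    return g
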