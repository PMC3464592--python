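"""Markov clustering of the weighted similarity graph into duplication sets.

MCL simulates random walks on the similarity graph: the column-stochastic
transition matrix is alternately expanded (squared) and inflated
(element-wise powered and renormalised) until it converges to a doubly
idempotent limit whose attractor systems are the clusters.  Inflation
controls granularity; weights are -log10 E-values capped at a ceiling.
Clusters of at least two genes become duplication sets.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np


@dataclass
class DuplicationSet:
    """An MCL cluster of two or more paralogous genes."""

    set_id: str
    members: list[str]
    pair_labels: dict[tuple[str, str], str] = field(default_factory=dict)
    set_labels: set[str] = field(default_factory=set)
    mixed: bool = False

    @property
    def size(self) -> int:
        return len(self.members)


def edge_weight(evalue: float, mul: float = 0.4343, ceil: float = 200.0) -> float:
    """MCL edge weight from a BLAST-style E-value.

    weight = min(ceil, max(0, -mul * ln E)); with mul = log10(e) this is the
    capped -log10 of the E-value, and E = 0 maps to the ceiling.
    """
    if evalue < 0:
        raise ValueError("evalue must be non-negative")
    if evalue == 0:
        return ceil
    return min(ceil, max(0.0, -mul * math.log(evalue)))


def _mcl_component(sub: nx.Graph, nodes: list[str], inflation: float,
                   expansion: int, prune_threshold: float, max_iter: int,
                   tol: float, on_iteration=None) -> tuple[list[set[str]], bool]:
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    M = np.zeros((n, n))
    for u, v, data in sub.edges(data=True):
        w = float(data.get("weight", 1.0))
        M[idx[u], idx[v]] = w
        M[idx[v], idx[u]] = w
    # self-loops at the max incident weight guard against period-2 oscillation
    loops = M.max(axis=0)
    loops[loops == 0] = 1.0
    np.fill_diagonal(M, loops)
    M /= M.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        previous = M
        M = np.linalg.matrix_power(M, expansion)
        M = np.power(M, inflation)
        M[M < prune_threshold] = 0.0
        M /= M.sum(axis=0, keepdims=True)
        if on_iteration is not None:
            on_iteration(M)
        if np.abs(M - previous).max() < tol:
            converged = True
            break
    # attractors are nodes retaining mass on their own diagonal; each
    # attractor row spans one cluster, overlapping systems are merged
    attractors = np.flatnonzero(M.diagonal() > prune_threshold)
    clusters: list[set[int]] = []
    for a in attractors:
        support = set(np.flatnonzero(M[a] > prune_threshold)) | {int(a)}
        merged = False
        for c in clusters:
            if c & support:
                c |= support
                merged = True
                break
        if merged:
            # cascade merges in case one support bridges two clusters
            changed = True
            while changed:
                changed = False
                for i in range(len(clusters)):
                    for j in range(i + 1, len(clusters)):
                        if clusters[i] & clusters[j]:
                            clusters[i] |= clusters.pop(j)
                            changed = True
                            break
                    if changed:
                        break
        else:
            clusters.append(support)
    assigned = set().union(*clusters) if clusters else set()
    for i in range(n):
        if i not in assigned:
            clusters.append({i})
    return [{nodes[i] for i in c} for c in clusters], converged


def mcl(edges, inflation: float = 2.0, expansion: int = 2,
        prune_threshold: float = 1e-5, max_iter: int = 100,
        tol: float = 1e-6, on_iteration=None) -> list[set[str]]:
    """Partition the nodes of a weighted edge collection by Markov clustering.

    ``edges`` is either a networkx Graph or an iterable of objects with
    gene_a/gene_b/weight attributes.  Each connected component is clustered
    independently (random walks cannot cross components), which keeps the
    dense iteration small.  Deterministic given node order.
    """
    if inflation <= 1:
        raise ValueError("inflation must be > 1")
    if isinstance(edges, nx.Graph):
        graph = edges
    else:
        graph = nx.Graph()
        for e in edges:
            if e.weight <= 0:
                raise ValueError(f"non-positive weight on edge {e.gene_a}-{e.gene_b}")
            graph.add_edge(e.gene_a, e.gene_b, weight=e.weight)
    partition: list[set[str]] = []
    for component in nx.connected_components(graph):
        nodes = sorted(component)
        if len(nodes) == 1:
            partition.append(set(nodes))
            continue
        clusters, converged = _mcl_component(graph.subgraph(nodes), nodes, inflation,
                                             expansion, prune_threshold, max_iter, tol,
                                             on_iteration)
        if not converged:
            warnings.warn(f"MCL did not converge within {max_iter} iterations on a "
                          f"component of {len(nodes)} nodes; using current state")
        partition.extend(clusters)
    return sorted(partition, key=lambda c: sorted(c)[0])


def clusters_to_sets(partition: list[set[str]], min_size: int = 2) -> list[DuplicationSet]:
    """Clusters with >= min_size members become DuplicationSets.

    Set IDs are assigned in order of each cluster's smallest member ID, so
    they are stable across runs on the same input.
    """
    big = sorted((sorted(c) for c in partition if len(c) >= min_size),
                 key=lambda m: m[0])
    return [DuplicationSet(set_id=f"set{i + 1:05d}", members=members)
            for i, members in enumerate(big)]


def read_sets(path) -> list[DuplicationSet]:
    sets = []
    with open(path) as fh:
        header = fh.readline()
        assert header.startswith("set_id")
        for line in fh:
            set_id, _, members = line.rstrip("\n").split("\t")
            sets.append(DuplicationSet(set_id=set_id, members=members.split(",")))
    return sets


def write_sets(sets: list[DuplicationSet], path) -> None:
    with open(path, "w") as fh:
        fh.write("set_id\tsize\tmembers\n")
        for s in sets:
            fh.write(f"{s.set_id}\t{s.size}\t{','.join(s.members)}\n")
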