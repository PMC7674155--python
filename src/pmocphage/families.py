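"""Two-tier protein clustering and presence/absence analysis.

Proteins are first grouped into subfamilies by a greedy set-cover over a
pairwise-similarity edge list (pre-filtered at e-value <= 0.001 and
coverage >= 0.5). Subfamilies are then linked by profile-comparison edges
(probability >= 0.95, coverage >= 0.5, weight = probability x coverage)
and clustered into families with the Markov Cluster Algorithm at
inflation 2.0. Families present in at least ``min_genomes`` genomes form a
binary presence/absence matrix, which is clustered by Jaccard distance
with complete linkage; group-exclusive families (present in every group
member, absent elsewhere) identify proteins specific to a phage group.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

SUBFAMILY_MAX_EVALUE = 1e-3
SUBFAMILY_MIN_COVER = 0.5
FAMILY_MIN_PROBABILITY = 0.95
FAMILY_MIN_COVER = 0.5
MCL_INFLATION = 2.0
MCL_TOL = 1e-6
MCL_MAX_ITER = 200
MCL_PRUNE = 1e-8
PRESENCE_MIN_GENOMES = 5


@dataclass(frozen=True)
class SimilarityEdge:
    """One pairwise similarity: protein-level (evalue/cover) or
    subfamily-level (probability/cover)."""

    a: str
    b: str
    evalue: float = 0.0
    cover: float = 1.0
    probability: float | None = None

    @property
    def weight(self) -> float:
        if self.probability is None:
            raise ValueError("weight defined only for subfamily-level edges")
        return self.probability * self.cover


def build_subfamilies(
    proteins: list[str],
    edges: list[SimilarityEdge],
    max_evalue: float = SUBFAMILY_MAX_EVALUE,
    min_cover: float = SUBFAMILY_MIN_COVER,
) -> dict[str, str]:
    """Greedy set-cover subclustering; returns protein -> subfamily id.

    Repeatedly pick the unassigned protein covering the most unassigned
    neighbours (ties: more neighbours first, then lexicographic id); it and
    its unassigned neighbours form a subfamily named after the centroid.
    Singletons become their own subfamily.
    """
    neighbours: dict[str, set[str]] = {p: set() for p in proteins}
    for e in edges:
        if e.evalue > max_evalue or e.cover < min_cover:
            continue
        if e.a in neighbours and e.b in neighbours and e.a != e.b:
            neighbours[e.a].add(e.b)
            neighbours[e.b].add(e.a)

    unassigned = set(proteins)
    assignment: dict[str, str] = {}
    while unassigned:
        centroid = min(
            unassigned, key=lambda p: (-len(neighbours[p] & unassigned), p)
        )
        members = {centroid} | (neighbours[centroid] & unassigned)
        for m in members:
            assignment[m] = centroid
        unassigned -= members
    return assignment


def family_graph(
    profile_edges: list[SimilarityEdge],
    subfamilies: list[str],
    min_probability: float = FAMILY_MIN_PROBABILITY,
    min_cover: float = FAMILY_MIN_COVER,
) -> nx.Graph:
    """Weighted subfamily graph from profile-comparison edges.

    Keeps edges with probability >= 0.95 and coverage >= 0.5; the weight is
    probability x coverage.
    """
    graph = nx.Graph()
    graph.add_nodes_from(subfamilies)
    for e in profile_edges:
        if e.probability is None:
            raise ValueError(f"edge {e.a}-{e.b} lacks a probability score")
        if not (0.0 <= e.probability <= 1.0 and 0.0 <= e.cover <= 1.0):
            raise ValueError(f"edge {e.a}-{e.b}: probability/cover outside [0,1]")
        if e.probability >= min_probability and e.cover >= min_cover:
            graph.add_edge(e.a, e.b, weight=e.weight)
    return graph


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = MCL_INFLATION,
    tol: float = MCL_TOL,
    max_iter: int = MCL_MAX_ITER,
    prune: float = MCL_PRUNE,
) -> tuple[list[frozenset[str]], bool]:
    """Markov clustering of a weighted graph.

    Self-loops are set to each node's maximum incident edge weight (1.0 for
    isolated nodes); iteration alternates expansion (matrix square) and
    inflation (entrywise power, column renormalization) with light pruning
    until the matrix is stable. Clusters are read from attractor rows;
    overlapping clusters are merged. Returns (clusters, converged).
    """
    nodes = sorted(graph.nodes)
    n = len(nodes)
    if n == 0:
        return [], True
    idx = {v: i for i, v in enumerate(nodes)}
    m = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w < 0:
            raise ValueError("MCL requires non-negative weights")
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = w
    loop = m.max(axis=0)
    loop[loop == 0] = 1.0
    m[np.diag_indices(n)] = loop
    m /= m.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        expanded = m @ m
        inflated = expanded**inflation
        inflated[inflated < prune] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated /= colsum
        if np.abs(inflated - m).max() < tol:
            m = inflated
            converged = True
            break
        m = inflated

    clusters: list[set[int]] = []
    attractors = np.flatnonzero(m.diagonal() > tol)
    for a in attractors:
        members = set(np.flatnonzero(m[a] > tol))
        merged = False
        for c in clusters:
            if c & members:
                c |= members
                merged = True
                break
        if merged:  # merging may chain clusters together
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
            clusters.append(members)
    assigned = set().union(*clusters) if clusters else set()
    for i in range(n):
        if i not in assigned:
            clusters.append({i})
    out = sorted(
        (frozenset(nodes[i] for i in c) for c in clusters), key=lambda c: sorted(c)
    )
    return out, converged


def cluster_families(
    proteins: list[str],
    protein_edges: list[SimilarityEdge],
    profile_edges: list[SimilarityEdge],
    inflation: float = MCL_INFLATION,
) -> dict[str, str]:
    """Full two-tier clustering; returns protein -> family id."""
    sub_of = build_subfamilies(proteins, protein_edges)
    subfamilies = sorted(set(sub_of.values()))
    graph = family_graph(profile_edges, subfamilies)
    clusters, _ = mcl_cluster(graph, inflation=inflation)
    family_of_sub: dict[str, str] = {}
    for cluster in clusters:
        fam_id = "fam_" + min(cluster)
        for sub in cluster:
            family_of_sub[sub] = fam_id
    return {p: family_of_sub[s] for p, s in sub_of.items()}


def presence_matrix(
    family_of: dict[str, str],
    genome_of: dict[str, str],
    min_genomes: int = PRESENCE_MIN_GENOMES,
) -> pd.DataFrame:
    """Binary genome x family matrix keeping families in >= min_genomes genomes."""
    rows = sorted(set(genome_of.values()))
    cols = sorted(set(family_of.values()))
    mat = pd.DataFrame(0, index=rows, columns=cols, dtype=int)
    for protein, family in family_of.items():
        mat.loc[genome_of[protein], family] = 1
    keep = mat.columns[mat.sum(axis=0) >= min_genomes]
    return mat[keep]


def cluster_genomes(matrix: pd.DataFrame) -> "hierarchy.ClusterNode":
    """Complete-linkage tree on Jaccard distances between genome rows.

    Genomes with no families are at distance 1 from everything (and from
    each other). Returns the scipy dendrogram root; leaves are in the
    matrix's (sorted) row order.
    """
    matrix = matrix.sort_index()
    n = len(matrix)
    if n < 2:
        raise ValueError("need at least two genomes to cluster")
    rows = matrix.to_numpy(dtype=bool)
    dist = np.ones((n, n))
    np.fill_diagonal(dist, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            union = np.count_nonzero(rows[i] | rows[j])
            if union:
                inter = np.count_nonzero(rows[i] & rows[j])
                dist[i, j] = dist[j, i] = 1.0 - inter / union
    linkage = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    root = hierarchy.to_tree(linkage)
    root.labels = list(matrix.index)  # type: ignore[attr-defined]
    return root


def dendrogram_newick(root: "hierarchy.ClusterNode", labels: list[str]) -> str:
    """Serialize a scipy cluster tree as a Newick string."""

    def render(node: "hierarchy.ClusterNode", parent_dist: float) -> str:
        length = max(parent_dist - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.6g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return f"({render(root.left, root.dist)},{render(root.right, root.dist)});"


def specific_families(matrix: pd.DataFrame, group: set[str]) -> list[str]:
    """Families present in every group genome and absent from all others."""
    if not group:
        raise ValueError("empty genome group")
    missing = group - set(matrix.index)
    if missing:
        raise ValueError(f"genomes not in matrix: {sorted(missing)}")
    in_group = matrix.index.isin(group)
    present_all = matrix.loc[in_group].all(axis=0)
    absent_rest = (
        ~matrix.loc[~in_group].any(axis=0)
        if (~in_group).any()
        else pd.Series(True, index=matrix.columns)
    )
    return sorted(matrix.columns[present_all & absent_rest])
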