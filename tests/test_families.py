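"""Protein subfamily/family clustering, presence matrix, genome trees."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pmocphage.families import (
    SimilarityEdge,
    build_subfamilies,
    cluster_genomes,
    dendrogram_newick,
    family_graph,
    mcl_cluster,
    presence_matrix,
    specific_families,
)


def simple_mcl(nodes, weighted_edges, inflation=2.0, tol=1e-6, max_iter=200,
               prune=1e-8):
    """Plain-Python Markov clustering used as an independent oracle."""
    nodes = sorted(nodes)
    n = len(nodes)
    pos = {v: i for i, v in enumerate(nodes)}
    m = [[0.0] * n for _ in range(n)]
    for a, b, w in weighted_edges:
        m[pos[a]][pos[b]] = w
        m[pos[b]][pos[a]] = w
    for j in range(n):
        incident = max(m[i][j] for i in range(n))
        m[j][j] = incident if incident > 0 else 1.0
    for j in range(n):
        s = sum(m[i][j] for i in range(n))
        for i in range(n):
            m[i][j] /= s
    for _ in range(max_iter):
        sq = [
            [sum(m[i][k] * m[k][j] for k in range(n)) for j in range(n)]
            for i in range(n)
        ]
        infl = [[v**inflation if v**inflation >= prune else 0.0 for v in row]
                for row in sq]
        for j in range(n):
            s = sum(infl[i][j] for i in range(n)) or 1.0
            for i in range(n):
                infl[i][j] /= s
        delta = max(
            abs(infl[i][j] - m[i][j]) for i in range(n) for j in range(n)
        )
        m = infl
        if delta < tol:
            break
    clusters = []
    for a in range(n):
        if m[a][a] > tol:
            members = {j for j in range(n) if m[a][j] > tol}
            merged = False
            for c in clusters:
                if c & members:
                    c |= members
                    merged = True
            if not merged:
                clusters.append(members)
    changed = True
    while changed:
        changed = False
        for i, j in itertools.combinations(range(len(clusters)), 2):
            if clusters[i] & clusters[j]:
                clusters[i] |= clusters.pop(j)
                changed = True
                break
    covered = set().union(*clusters) if clusters else set()
    clusters += [{i} for i in range(n) if i not in covered]
    return {frozenset(nodes[i] for i in c) for c in clusters}


class TestSubfamilies:
    def test_no_edges_gives_singletons(self):
        assert build_subfamilies(["a", "b"], []) == {"a": "a", "b": "b"}

    def test_star_collapses_to_hub(self):
        leaves = [f"leaf{i}" for i in range(5)]
        edges = [SimilarityEdge("hub", leaf, 1e-10, 0.9) for leaf in leaves]
        sub = build_subfamilies(["hub"] + leaves, edges)
        assert set(sub.values()) == {"hub"}

    def test_low_coverage_edge_ignored(self):
        edges = [SimilarityEdge("a", "b", 1e-10, 0.4)]
        assert build_subfamilies(["a", "b"], edges) == {"a": "a", "b": "b"}

    def test_high_evalue_edge_ignored(self):
        edges = [SimilarityEdge("a", "b", 0.01, 0.9)]
        assert build_subfamilies(["a", "b"], edges) == {"a": "a", "b": "b"}

    def test_partition_property(self, rng):
        proteins = [f"p{i}" for i in range(40)]
        edges = [
            SimilarityEdge(*rng.choice(proteins, 2, replace=False), 1e-9, 0.8)
            for _ in range(60)
        ]
        sub = build_subfamilies(proteins, edges)
        assert set(sub) == set(proteins)  # everyone assigned exactly once


class TestFamilyGraph:
    def test_weight_is_probability_times_cover(self):
        g = family_graph(
            [SimilarityEdge("s1", "s2", cover=0.6, probability=0.96)], ["s1", "s2"]
        )
        assert g["s1"]["s2"]["weight"] == pytest.approx(0.576)

    def test_probability_below_95_dropped(self):
        g = family_graph(
            [SimilarityEdge("s1", "s2", cover=0.8, probability=0.94)], ["s1", "s2"]
        )
        assert g.number_of_edges() == 0

    def test_cover_below_half_dropped(self):
        g = family_graph(
            [SimilarityEdge("s1", "s2", cover=0.49, probability=0.99)], ["s1", "s2"]
        )
        assert g.number_of_edges() == 0


class TestMcl:
    def test_two_disjoint_triangles(self):
        g = nx.Graph()
        for offset in (0, 3):
            for i, j in itertools.combinations(range(offset, offset + 3), 2):
                g.add_edge(f"n{i}", f"n{j}", weight=1.0)
        clusters, converged = mcl_cluster(g)
        assert converged
        assert {frozenset(c) for c in clusters} == {
            frozenset({"n0", "n1", "n2"}),
            frozenset({"n3", "n4", "n5"}),
        }

    def test_isolated_node_is_singleton(self):
        g = nx.Graph()
        g.add_node("solo")
        clusters, _ = mcl_cluster(g)
        assert clusters == [frozenset({"solo"})]

    def test_barbell_matches_independent_implementation(self):
        g = nx.Graph()
        edges = []
        for offset in (0, 6):
            for i, j in itertools.combinations(range(offset, offset + 6), 2):
                edges.append((f"n{i}", f"n{j}", 1.0))
        edges.append(("n0", "n6", 1.0))  # bridge
        for a, b, w in edges:
            g.add_edge(a, b, weight=w)
        ours = {frozenset(c) for c in mcl_cluster(g)[0]}
        oracle = simple_mcl(list(g.nodes), edges)
        assert ours == oracle

    def test_random_graphs_match_oracle(self):
        rng = np.random.default_rng(77)
        for trial in range(10):
            n = int(rng.integers(4, 25))
            nodes = [f"v{i}" for i in range(n)]
            edges = []
            for i, j in itertools.combinations(range(n), 2):
                if rng.random() < 0.2:
                    edges.append((nodes[i], nodes[j], float(rng.uniform(0.3, 1.0))))
            g = nx.Graph()
            g.add_nodes_from(nodes)
            for a, b, w in edges:
                g.add_edge(a, b, weight=w)
            ours = {frozenset(c) for c in mcl_cluster(g)[0]}
            oracle = simple_mcl(nodes, edges)
            assert ours == oracle, f"trial {trial}"

    def test_invariant_to_uniform_weight_scaling(self):
        rng = np.random.default_rng(5)
        g1, g2 = nx.Graph(), nx.Graph()
        for i, j in itertools.combinations(range(12), 2):
            if rng.random() < 0.3:
                w = float(rng.uniform(0.2, 1.0))
                g1.add_edge(f"n{i}", f"n{j}", weight=w)
                g2.add_edge(f"n{i}", f"n{j}", weight=10.0 * w)
        assert {frozenset(c) for c in mcl_cluster(g1)[0]} == {
            frozenset(c) for c in mcl_cluster(g2)[0]
        }


class TestPresenceMatrix:
    def make(self):
        family_of = {}
        genome_of = {}
        for g in range(6):
            for fam in range(8):
                if (g + fam) % 2 == 0 or fam < 2:
                    pid = f"g{g}_f{fam}"
                    family_of[pid] = f"fam{fam}"
                    genome_of[pid] = f"genome{g}"
        return family_of, genome_of

    def test_min_genomes_filter_matches_hand_count(self):
        family_of, genome_of = self.make()
        full = presence_matrix(family_of, genome_of, min_genomes=1)
        kept = presence_matrix(family_of, genome_of, min_genomes=5)
        expected = [c for c in full.columns if full[c].sum() >= 5]
        assert list(kept.columns) == expected

    def test_family_in_four_genomes_excluded_at_min_five(self):
        family_of = {f"p{i}": "famX" for i in range(4)}
        genome_of = {f"p{i}": f"g{i}" for i in range(4)}
        assert presence_matrix(family_of, genome_of, 5).shape[1] == 0

    def test_universal_family_retained(self):
        family_of, genome_of = self.make()
        mat = presence_matrix(family_of, genome_of, 5)
        assert (mat["fam0"] == 1).all()


class TestGenomeClustering:
    def test_jaccard_distance_example(self):
        mat = pd.DataFrame(
            [[1, 1, 0], [1, 0, 1]], index=["a", "b"], columns=["f1", "f2", "f3"]
        )
        root = cluster_genomes(mat)
        assert root.dist == pytest.approx(2 / 3)

    def test_identical_rows_merge_first(self):
        mat = pd.DataFrame(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [1, 0, 1, 0]],
            index=["a", "b", "c", "d"],
            columns=list("wxyz"),
        )
        root = cluster_genomes(mat)
        newick = dendrogram_newick(root, sorted(mat.index))
        assert "(a:0,b:0)" in newick or "(b:0,a:0)" in newick

    def test_merge_heights_match_exhaustive_complete_linkage(self):
        rng = np.random.default_rng(3)
        mat = pd.DataFrame(
            rng.integers(0, 2, size=(4, 6)),
            index=[f"g{i}" for i in range(4)],
            columns=[f"f{j}" for j in range(6)],
        )

        def jaccard(a, b):
            union = np.count_nonzero(a | b)
            return 1.0 - (np.count_nonzero(a & b) / union if union else 0.0)

        # brute-force agglomeration over all cluster pairs
        clusters = {i: [i] for i in range(4)}
        rows = mat.to_numpy(dtype=bool)
        heights = []
        while len(clusters) > 1:
            best = min(
                itertools.combinations(clusters, 2),
                key=lambda ab: max(
                    jaccard(rows[x], rows[y])
                    for x in clusters[ab[0]]
                    for y in clusters[ab[1]]
                ),
            )
            height = max(
                jaccard(rows[x], rows[y])
                for x in clusters[best[0]]
                for y in clusters[best[1]]
            )
            heights.append(height)
            clusters[best[0]] += clusters.pop(best[1])

        root = cluster_genomes(mat)

        def collect(node, out):
            if not node.is_leaf():
                out.append(node.dist)
                collect(node.left, out)
                collect(node.right, out)
            return out

        ours = sorted(collect(root, []))
        assert np.allclose(ours, sorted(heights))

    def test_zero_family_genome_at_distance_one(self):
        mat = pd.DataFrame(
            [[1, 1], [0, 0], [1, 0]], index=["a", "b", "c"], columns=["f1", "f2"]
        )
        root = cluster_genomes(mat)
        assert root.dist == pytest.approx(1.0)


class TestSpecificFamilies:
    def test_planted_exclusive_family_unique(self, fast_config):
        from dataclasses import replace

        from pmocphage.synthetic import (
            fabricate_profile_edges,
            fabricate_protein_edges,
            simulate_community,
            true_families,
        )

        config = replace(fast_config, seed=9)
        genomes, truth = simulate_community(config)
        family_of_true, genome_of = true_families(genomes, truth)
        edges = fabricate_protein_edges(family_of_true, seed=9)
        sub_of = build_subfamilies(sorted(family_of_true), edges)
        profile_edges = fabricate_profile_edges(sub_of, family_of_true, seed=9)
        graph = family_graph(profile_edges, sorted(set(sub_of.values())))
        clusters, _ = mcl_cluster(graph)
        fam_of = {s: "fam_" + min(c) for c in clusters for s in c}
        protein_family = {p: fam_of[s] for p, s in sub_of.items()}
        matrix = presence_matrix(protein_family, genome_of, 5)
        group = {g for g in matrix.index if truth.pmoc_genes.get(g)}
        result = specific_families(matrix, group)
        pmoc_fams = {
            protein_family[gid]
            for gids in truth.pmoc_genes.values()
            for gid in gids
            if gid in protein_family
        }
        assert len(result) == 1
        assert set(result) == pmoc_fams

    def test_family_missing_in_one_member_not_returned(self):
        mat = pd.DataFrame(
            [[1, 1], [0, 1], [0, 0]],
            index=["a", "b", "c"],
            columns=["f1", "f2"],
        )
        assert specific_families(mat, {"a", "b"}) == ["f2"]

    def test_group_of_all_genomes(self):
        mat = pd.DataFrame(
            [[1, 1], [1, 0]], index=["a", "b"], columns=["f1", "f2"]
        )
        assert specific_families(mat, {"a", "b"}) == ["f1"]

    def test_empty_group_rejected(self):
        mat = pd.DataFrame([[1]], index=["a"], columns=["f1"])
        with pytest.raises(ValueError):
            specific_families(mat, set())
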