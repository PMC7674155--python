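"""Two-tier protein families and the presence/absence analysis.

Subfamilies come from a greedy set-cover over protein similarity edges;
families from Markov clustering (inflation 2.0) of the subfamily profile
graph. Families in >=5 genomes form a binary matrix; the question is which
family is present in every pmoC-phage and absent from related phages.
"""

from pmocphage import CommunityConfig, simulate_community
from pmocphage.families import (
    build_subfamilies,
    cluster_genomes,
    dendrogram_newick,
    family_graph,
    mcl_cluster,
    presence_matrix,
    specific_families,
)
from pmocphage.synthetic import (
    fabricate_profile_edges,
    fabricate_protein_edges,
    true_families,
)

genomes, truth = simulate_community(CommunityConfig(seed=42))
family_truth, genome_of = true_families(genomes, truth)

protein_edges = fabricate_protein_edges(family_truth, seed=42)
sub_of = build_subfamilies(sorted(family_truth), protein_edges)
profile_edges = fabricate_profile_edges(sub_of, family_truth, seed=42)
graph = family_graph(profile_edges, sorted(set(sub_of.values())))
clusters, converged = mcl_cluster(graph)

fam_of = {s: "fam_" + min(c) for c in clusters for s in c}
protein_family = {p: fam_of[s] for p, s in sub_of.items()}
matrix = presence_matrix(protein_family, genome_of, min_genomes=5)

print(f"{len(set(sub_of.values()))} subfamilies -> "
      f"{len(clusters)} families (MCL converged: {converged})")
print(f"presence matrix: {matrix.shape[0]} phages x {matrix.shape[1]} families")

pmoc_group = {g for g in matrix.index if truth.pmoc_genes.get(g)}
print("families specific to the pmoC-phage group:",
      specific_families(matrix, pmoc_group))
print(dendrogram_newick(cluster_genomes(matrix), sorted(matrix.index)))
# Exactly one family is exclusive to the pmoC-phages: the pmoC family -
# structural genes are shared with the related phages.
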