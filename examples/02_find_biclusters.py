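"""Recover a planted expression bicluster with the SAMBA-style search.

Plants a 6-miRNA x 5-sample block shifted by +3 noise standard
deviations in a 30 x 60 background, standardizes each miRNA,
discretizes to up/down responses and searches the weighted bipartite
response graph for heavy subgraphs. The top-scoring bicluster should
coincide with the planted block (Jaccard near 1).
"""

from sfssclass import (
    build_graph,
    discretize,
    find_biclusters,
    make_planted_bicluster_data,
    standardize_features,
)

matrix, truth = make_planted_bicluster_data(
    p=30, n=60, blocks=[(6, 5, 3.0)], noise_sd=1.0, seed=0
)
graph = build_graph(discretize(standardize_features(matrix), t=1.2), p_c=0.9)
biclusters = find_biclusters(graph, d=30, coherent_signs=True)

planted = set(truth.blocks[0]["feature_ids"]) | set(truth.blocks[0]["sample_ids"])
top = biclusters[0]
found = top.features | top.samples
jaccard = len(found & planted) / len(found | planted)

print(f"response-graph density: {graph.density:.3f} "
      f"(present weight {graph.w_present:.2f}, absent {graph.w_absent:.2f})")
print(f"biclusters found: {len(biclusters)}")
print(f"top bicluster: {len(top.features)} miRNAs x {len(top.samples)} samples, "
      f"score {top.score:.2f}")
print(f"overlap with the planted block (Jaccard): {jaccard:.2f}")
print("-> a Jaccard near 1 means the heavy-subgraph search isolated exactly the")
print("   co-expressed block despite discretization losses and background noise.")
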