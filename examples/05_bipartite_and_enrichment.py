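"""Connect aging and AD biomarkers through the network; test enrichment.

Shortest paths (BFS; unit weights) are queried between every aging marker
and every AD marker inside the acceleration network; reachable pairs form
the aging-AD bipartite graph.  Path gene sets are then tested for
over-representation against a gene-set collection with the hypergeometric
test and BH FDR.
"""

from agingaccel import (GeneSetCollection, SimulationSpec, build_bipartite_graph,
                        build_network, build_reference_pools,
                        compute_aging_scores, enrich, generate_cohort,
                        pair_product_correlations, shortest_paths_between_sets,
                        zscore_normalize)

spec = SimulationSpec(seed=11)
cohort, truth = generate_cohort(spec)
cohort = zscore_normalize(cohort)
pools = build_reference_pools(cohort, truth.aging_markers)
scores = compute_aging_scores(cohort, pools)["atan"]
records = {dx: pair_product_correlations(
    cohort.where(cohort.samples["diagnosis"] == dx), scores)
    for dx in ("AD", "normal")}
network = build_network(records["AD"], records["normal"], cohort.genes)

pairs = shortest_paths_between_sets(network, truth.aging_markers,
                                    truth.ad_markers)
summary = build_bipartite_graph(pairs)
print(f"bipartite graph: {summary['n_pairs']} connected (aging, AD) pairs "
      f"out of {len(truth.aging_markers)}*{len(truth.ad_markers)} queries")
print(f"connected markers: {summary['n_aging_connected']} aging, "
      f"{summary['n_ad_connected']} AD")
top_aging = next(iter(summary["aging_degree"]))
print(f"the aging marker linking the most AD markers: {top_aging} "
      f"({summary['aging_degree'][top_aging]} links)")

sets = GeneSetCollection(sets={
    "PLANTED_AGING": truth.aging_markers,
    "PLANTED_AD": truth.ad_markers,
    "UNRELATED": cohort.genes[-50:],
}, source="ground truth")
path_genes = pairs[0].path
res = enrich(path_genes, sets, cohort.genes)
print(f"\nenrichment of the first path ({'-'.join(path_genes)}):")
for r in res:
    flag = "significant" if r.significant else "ns"
    print(f"  {r.set_name}: overlap {r.x}/{r.n}, p = {r.p:.2e}, "
          f"FDR = {r.fdr:.2e} [{flag}]")
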