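"""Overall topology indices and normalized node-connectivity ranks.

Computes average geodesic distance, average clustering coefficient and
greedy modularity for one group network, then ranks node connectivities
onto the comparable 1-100 scale (1 = hub) and derives connectivity scores.
"""

import warnings

import menconserve as mc

warnings.simplefilter("ignore")

metadata = mc.generate_metadata(seed=7)
grouping = mc.assign_ph_groups(metadata, 6)
table = mc.generate_layer(metadata, n_features=120, archetype_weights=mc.TRAIT_PRESET,
                          layer="trait", seed=7)

sub = mc.prevalence_filter(table, grouping.samples_in("G3"))
corr = mc.correlation_matrix(mc.standardize_features(sub))
net = mc.build_network(corr, mc.rmt_threshold(corr, on_fail="best").chosen,
                       layer="trait", group="G3")

summary = mc.summarize_topology(net)
print(f"G3 network: {summary.n_nodes} nodes, {summary.n_edges} edges")
print(f"  avgGD = {summary.avg_gd:.3f}   (mean shortest path over reachable pairs)")
print(f"  avgCC = {summary.avg_cc:.3f}   (mean local clustering)")
print(f"  Q     = {summary.modularity:.3f}   (greedy modularity)")

conn = mc.node_connectivity(net)
ranks = mc.normalize_connectivity_ranks(conn)
hub = min(ranks, key=ranks.get)
print(f"hub {hub}: degree {conn[hub]}, normalized rank {ranks[hub]:.1f}, "
      f"connectivity score {101 - ranks[hub]:.1f}")
least = max(ranks, key=ranks.get)
print(f"least-connected {least}: degree {conn[least]}, normalized rank {ranks[least]:.1f}")

# Normalized ranks run from 1 (most connected) to 100 (least connected)
# regardless of network size, so node positions compare across groups;
# the score (101 - rank) puts hubs at 100 and absent nodes at 0.
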