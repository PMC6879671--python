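"""Classify hubs and bottlenecks and induce the regulator-allied subnetwork.

Hubs exceed mean + 2*SD of the degree distribution; bottlenecks are the
top 25% by normalized betweenness.  The subnetwork is induced on
hubs ∪ bottlenecks ∪ panel, with centrality always taken from the full
network.
"""

from coexdriver import (
    build_rapin,
    disruption_scenario,
    edge_node_ratio,
    select_bottlenecks,
    select_hubs,
)

scenario = disruption_scenario(rng_seed=1)
net = scenario.network

hubs = select_hubs(net)
bottlenecks = select_bottlenecks(net, fraction=0.25)
rapin = build_rapin(net, hubs, bottlenecks, scenario.panel)

print(f"full network: {net.number_of_nodes()} nodes, {net.number_of_edges()} edges "
      f"(edge/node ratio {edge_node_ratio(net):.2f})")
print(f"hubs: {len(hubs)}; planted high-degree nodes recovered: "
      f"{len(hubs & scenario.truth.planted_hubs)}/{len(scenario.truth.planted_hubs)}")
print(f"bottlenecks: {len(bottlenecks)}")
sub = rapin.subnetwork
print(f"regulator-allied subnetwork: {sub.number_of_nodes()} nodes, "
      f"{sub.number_of_edges()} edges")
# Every edge of the subnetwork exists in the input graph; panel genes absent
# from the network would be listed in rapin.missing_panel_genes.
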