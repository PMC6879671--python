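"""Generate a complete synthetic two-condition study with known answers.

The generator plants differential expression (mean shifts), condition-
specific co-expression modules, scale-free interactions with extra-degree
hubs, and a small ontology — everything the downstream stages consume.
"""

from coexdriver import disruption_scenario

scenario = disruption_scenario(rng_seed=1)

print(f"expression matrix: {scenario.matrix.values.shape[0]} genes x "
      f"{scenario.matrix.values.shape[1]} samples")
print(f"interaction graph: {scenario.network.number_of_nodes()} nodes, "
      f"{scenario.network.number_of_edges()} edges")
print(f"panel: {sorted(scenario.panel.seeds)} seeds + {sorted(scenario.panel.nkpf)} nkpf")
print(f"planted DE genes: {len(scenario.truth.de_genes)}")
print(f"planted control-only regulator pair: {sorted(scenario.truth.seed_nkpf_lost_pairs)}")

# The lost pair is the ground truth the driver-gene stage should recover:
# it is co-expressed (r ~ 0.96) in control samples only.
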