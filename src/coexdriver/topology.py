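"""Centrality-based hub/bottleneck classification and subnetwork induction.

Hubs are nodes whose degree exceeds mean(degree) + 2*SD(degree) of the full
interactome; bottlenecks are the top quarter of nodes by normalized
betweenness centrality.  The regulator-allied subnetwork is the subgraph
induced by hubs, bottlenecks and the curated regulator panel, with
centrality always computed on the whole network first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io import GenePanel


def degree_centrality(net: nx.Graph) -> dict[str, int]:
    """Degree of each node (number of interaction partners)."""
    return {n: int(d) for n, d in net.degree()}


def betweenness_centrality(net: nx.Graph) -> dict[str, float]:
    """Betweenness centrality, normalized by (N-1)(N-2)/2 to lie in [0, 1].

    Fractions of shortest paths through each node are accumulated over all
    connected source/target pairs (Brandes); disconnected pairs contribute
    nothing.  Graphs with fewer than three nodes have no interior vertices,
    so every value is 0.
    """
    if net.number_of_nodes() < 3:
        return {n: 0.0 for n in net.nodes()}
    return {n: float(b) for n, b in nx.betweenness_centrality(net, normalized=True).items()}


def hub_threshold(degree_values, sd_mode: str = "sample", multiplier: float = 2.0) -> float:
    """Degree cutoff mean + multiplier*SD (sample SD by default)."""
    degrees = np.asarray(list(degree_values), dtype=float)
    if degrees.size < 2:
        raise ValueError("need at least 2 nodes for a hub threshold")
    ddof = 1 if sd_mode == "sample" else 0
    return float(degrees.mean() + multiplier * degrees.std(ddof=ddof))


def select_hubs(net: nx.Graph, sd_mode: str = "sample", multiplier: float = 2.0) -> set[str]:
    """Nodes with degree strictly above the mean + 2*SD cutoff.

    The strict inequality means regular graphs (SD = 0) yield no hubs.
    """
    if net.number_of_nodes() == 0:
        raise ValueError("empty graph")
    dc = degree_centrality(net)
    if len(dc) < 2:
        return set()
    cutoff = hub_threshold(dc.values(), sd_mode=sd_mode, multiplier=multiplier)
    return {n for n, d in dc.items() if d > cutoff}


def select_bottlenecks(
    net: nx.Graph,
    fraction: float = 0.25,
    bc: dict[str, float] | None = None,
) -> set[str]:
    """Top ``fraction`` of nodes by betweenness centrality.

    Nodes are ranked by descending centrality with lexicographic
    tie-breaking; the first ceil(fraction*N) are taken and the cut is
    extended to include every node tied with the last one in.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    if net.number_of_nodes() == 0:
        return set()
    if bc is None:
        bc = betweenness_centrality(net)
    ranked = sorted(bc, key=lambda n: (-bc[n], n))
    k = math.ceil(fraction * len(ranked))
    cut_value = bc[ranked[k - 1]]
    return {n for n in ranked[:k]} | {n for n in ranked[k:] if bc[n] == cut_value}


@dataclass(frozen=True)
class RapinResult:
    """Regulator-allied subnetwork plus panel genes absent from the net."""

    subnetwork: nx.Graph
    missing_panel_genes: set[str]


def build_rapin(
    net: nx.Graph,
    hubs: set[str],
    bottlenecks: set[str],
    panel: GenePanel,
) -> RapinResult:
    """Induce the subgraph on hubs ∪ bottlenecks ∪ (panel ∩ network).

    Panel genes missing from the network are reported, not silently
    dropped, so a run manifest can surface them.
    """
    present_panel = panel.members & set(net.nodes())
    nodes = hubs | bottlenecks | present_panel
    if not nodes:
        raise ValueError("hub/bottleneck/panel union is empty")
    return RapinResult(
        subnetwork=net.subgraph(nodes).copy(),
        missing_panel_genes=panel.members - present_panel,
    )


def edge_node_ratio(net: nx.Graph) -> float:
    """Mean edges per node, |E| / |V|."""
    n = net.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    return net.number_of_edges() / n


def write_centrality_report(
    net: nx.Graph,
    hubs: set[str],
    bottlenecks: set[str],
    panel: GenePanel,
    path,
) -> None:
    dc = degree_centrality(net)
    bc = betweenness_centrality(net)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tdc\tbc\tis_hub\tis_bottleneck\tis_seed\tis_nkpf\n")
        for gene in sorted(net.nodes()):
            cat = panel.category_of.get(gene, "")
            fh.write(
                f"{gene}\t{dc[gene]}\t{bc[gene]:.6g}\t{int(gene in hubs)}\t"
                f"{int(gene in bottlenecks)}\t{int(cat == 'seed')}\t{int(cat == 'nkpf')}\n"
            )
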