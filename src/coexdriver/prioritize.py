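"""Driver-gene calling, hypergeometric over-representation, GWAS overlap.

A "driver" is a panel gene (seed or NF-κB family member) whose filtered
co-expression connectivity to the opposite panel category exists in the
control condition — directly or through one intermediate gene — but is
absent within the same path bound in the disease condition.  Drivers are
then characterized by hypergeometric over-representation against gene-set
collections and by joining a GWAS-catalog-style association table.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
from scipy.stats import hypergeom

from .coexpr import Pair
from .diffexpr import benjamini_hochberg
from .io import AssociationRecord, GenePanel


@dataclass(frozen=True)
class DriverCall:
    gene: str
    category: str  # "seed" or "nkpf"
    lost_partners: tuple[tuple[str, int], ...]  # (opposite-category gene, path length)

    def __post_init__(self) -> None:
        if not self.lost_partners:
            raise ValueError("a driver call needs at least one lost partner")


def _bounded_reach(graph: nx.Graph, source: str, max_path: int) -> set[str]:
    """Nodes reachable from ``source`` within ``max_path`` edges."""
    if source not in graph:
        return set()
    return set(nx.single_source_shortest_path_length(graph, source, cutoff=max_path))


def driver_genes(
    filtered_control: Iterable[Pair],
    filtered_case: Iterable[Pair],
    panel: GenePanel,
    max_path: int = 2,
) -> list[DriverCall]:
    """Panel genes whose cross-category connectivity is control-only.

    ``filtered_control`` / ``filtered_case`` are the per-condition pair
    graphs that survived the correlation, differential-correlation and
    semantic filters.  For every seed–nkpf pair connected within
    ``max_path`` edges in the control graph but not in the case graph, both
    endpoints are called drivers, with the lost partner and the control
    path length recorded.
    """
    seeds = sorted(panel.seeds)
    nkpf = sorted(panel.nkpf)
    if not seeds or not nkpf:
        raise ValueError("panel must contain both a seed and an nkpf category")
    g_control = nx.Graph(list(filtered_control))
    g_case = nx.Graph(list(filtered_case))
    lost: dict[str, list[tuple[str, int]]] = {}
    for s in seeds:
        if s not in g_control:
            continue
        dist = nx.single_source_shortest_path_length(g_control, s, cutoff=max_path)
        case_reach = _bounded_reach(g_case, s, max_path)
        for n in nkpf:
            if n in dist and n not in case_reach:
                lost.setdefault(s, []).append((n, dist[n]))
                lost.setdefault(n, []).append((s, dist[n]))
    calls = [
        DriverCall(
            gene=g,
            category=panel.category_of[g],
            lost_partners=tuple(sorted(partners)),
        )
        for g, partners in sorted(lost.items())
    ]
    return calls


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap_count: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    q_value: float


def hypergeometric_enrichment(
    query: Iterable[str],
    gene_sets: Mapping[str, set[str]],
    universe: Iterable[str],
    min_set: int = 2,
    p_max: float = 0.01,
    fdr_max: float = 0.05,
) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation of a query gene list.

    Gene sets are intersected with the universe and tested only when the
    effective size is at least ``min_set``; BH correction runs across the
    tested sets and results are filtered on both raw p and FDR.
    """
    universe = set(universe)
    query = set(query)
    if not universe or not query:
        raise ValueError("universe and query must be non-empty")
    if not query <= universe:
        raise ValueError(f"query genes outside universe: {sorted(query - universe)[:5]}")
    tested: list[tuple[str, int, int]] = []
    for name in sorted(gene_sets):
        members = gene_sets[name] & universe
        if len(members) >= min_set:
            tested.append((name, len(members), len(members & query)))
    if not tested:
        return []
    big_n, n_query = len(universe), len(query)
    p_values = [
        float(hypergeom.sf(overlap - 1, big_n, set_size, n_query))
        for _, set_size, overlap in tested
    ]
    p_values = [min(max(p, 5e-324), 1.0) for p in p_values]
    q_values = benjamini_hochberg(p_values)
    results = [
        EnrichmentResult(
            set_name=name,
            overlap_count=overlap,
            set_size=set_size,
            query_size=n_query,
            universe_size=big_n,
            p_value=p,
            q_value=q,
        )
        for (name, set_size, overlap), p, q in zip(tested, p_values, q_values)
        if p <= p_max and q < fdr_max
    ]
    results.sort(key=lambda r: (r.p_value, r.set_name))
    return results


@dataclass(frozen=True)
class GwasOverlap:
    hits: tuple[AssociationRecord, ...]  # grouped by trait, then gene
    drivers_without_hits: tuple[str, ...]


def gwas_overlap(
    drivers: Iterable[str],
    associations: Sequence[AssociationRecord],
    p_max: float = 0.01,
) -> GwasOverlap:
    """Catalog rows for driver genes at p <= p_max, grouped by trait.

    Drivers with no catalog row at all are reported separately so absence
    of evidence stays visible in the output.
    """
    drivers = set(drivers)
    hits = sorted(
        (rec for rec in associations if rec.gene in drivers and rec.p_value <= p_max),
        key=lambda r: (r.trait, r.gene, r.p_value),
    )
    with_hits = {rec.gene for rec in hits}
    return GwasOverlap(
        hits=tuple(hits),
        drivers_without_hits=tuple(sorted(drivers - with_hits)),
    )


def write_driver_report(calls: Iterable[DriverCall], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tcategory\tlost_partner\tcontrol_path_length\n")
        for call in sorted(calls, key=lambda c: c.gene):
            for partner, length in call.lost_partners:
                fh.write(f"{call.gene}\t{call.category}\t{partner}\t{length}\n")


def write_enrichment_report(results: Iterable[EnrichmentResult], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("set_name\toverlap\tset_size\tquery_size\tuniverse_size\tp\tq\n")
        for r in results:
            fh.write(
                f"{r.set_name}\t{r.overlap_count}\t{r.set_size}\t{r.query_size}\t"
                f"{r.universe_size}\t{r.p_value:.3e}\t{r.q_value:.3e}\n"
            )


def write_gwas_report(overlap: GwasOverlap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("trait\tgene\tp_value\n")
        for rec in overlap.hits:
            fh.write(f"{rec.trait}\t{rec.gene}\t{rec.p_value:g}\n")
        for gene in overlap.drivers_without_hits:
            fh.write(f"no_hit\t{gene}\tNA\n")
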