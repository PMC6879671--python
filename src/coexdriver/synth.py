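"""Synthetic inputs with the statistical structure the pipeline assumes.

Expression is simulated from a one-factor Gaussian module model: each
planted module shares a per-sample latent value z_s, and a member gene's
log2 intensity is baseline + a*z_s + Gaussian noise.  Two members of the
same module then have Pearson correlation a^2 / (a^2 + noise_sd^2) in
closed form, which is what makes planted co-expression recoverable by a
hard correlation threshold.  Interaction networks grow by preferential
attachment (scale-free degree distribution) with optional extra-degree
"planted hubs", and ontologies are single-rooted random DAGs with is_a
edges.  All generators are pure functions of an explicit integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .coexpr import Pair, pair_key
from .io import (
    ExpressionMatrix,
    GenePanel,
    write_annotations,
    write_associations,
    write_edge_list,
    write_expression,
    write_gene_list,
    write_gmt,
    AssociationRecord,
)
from .semsim import GoDag


@dataclass(frozen=True)
class ModuleSpec:
    """A planted co-expression module: member genes and factor loading a."""

    members: tuple[str, ...]
    loading: float = 0.9

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("module needs at least 2 members")
        if not (0 < self.loading < 1):
            raise ValueError("loading must lie in (0, 1)")


@dataclass
class SyntheticTruth:
    """Ground truth of a generated dataset, for recovery checks."""

    de_genes: dict[str, float] = field(default_factory=dict)
    modules_control: list[set[str]] = field(default_factory=list)
    modules_case: list[set[str]] = field(default_factory=list)
    planted_hubs: set[str] = field(default_factory=set)
    seed_nkpf_lost_pairs: set[Pair] = field(default_factory=set)


def gene_names(n: int, prefix: str = "G") -> list[str]:
    return [f"{prefix}{i:04d}" for i in range(1, n + 1)]


def generate_expression(
    n_genes: int,
    n_control: int,
    n_case: int,
    modules_spec: Mapping[str, Sequence[ModuleSpec]] | None = None,
    de_spec: Mapping[str, float] | None = None,
    noise_sd: float = 0.3,
    rng_seed: int = 0,
    baseline_mean: float = 7.0,
    baseline_sd: float = 0.5,
) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Two-condition log2 expression with planted modules and mean shifts.

    ``modules_spec`` maps "control"/"case" to module lists active in that
    condition; ``de_spec`` maps gene → log2 shift added to case samples.
    Module memberships must be disjoint within a condition.
    """
    if n_control < 3 or n_case < 3:
        raise ValueError("need at least 3 samples per condition")
    if noise_sd <= 0:
        raise ValueError("noise_sd must be positive")
    modules_spec = {k: list(v) for k, v in (modules_spec or {}).items()}
    bad_cond = set(modules_spec) - {"control", "case"}
    if bad_cond:
        raise ValueError(f"unknown conditions in modules_spec: {bad_cond}")
    genes = gene_names(n_genes)
    gene_index = {g: i for i, g in enumerate(genes)}
    for cond, modules in modules_spec.items():
        seen: set[str] = set()
        for mod in modules:
            if len(mod.members) > n_genes:
                raise ValueError("module larger than the gene universe")
            for g in mod.members:
                if g not in gene_index:
                    raise ValueError(f"module gene {g!r} not in generated matrix")
                if g in seen:
                    raise ValueError(f"gene {g!r} in two {cond} modules")
                seen.add(g)
    de_spec = dict(de_spec or {})
    for g in de_spec:
        if g not in gene_index:
            raise ValueError(f"DE gene {g!r} not in generated matrix")

    rng = np.random.default_rng(rng_seed)
    baseline = rng.normal(baseline_mean, baseline_sd, size=n_genes)
    samples = {
        "control": [f"ctl{i:03d}" for i in range(1, n_control + 1)],
        "case": [f"case{i:03d}" for i in range(1, n_case + 1)],
    }
    blocks = {}
    for cond in ("control", "case"):
        n_s = len(samples[cond])
        values = baseline[:, None] + rng.normal(0.0, noise_sd, size=(n_genes, n_s))
        for mod in modules_spec.get(cond, []):
            z = rng.normal(0.0, 1.0, size=n_s)
            for g in mod.members:
                values[gene_index[g]] = (
                    baseline[gene_index[g]]
                    + mod.loading * z
                    + rng.normal(0.0, noise_sd, size=n_s)
                )
        blocks[cond] = values
    for g, delta in de_spec.items():
        blocks["case"][gene_index[g]] += delta

    frame = pd.DataFrame(
        np.hstack([blocks["control"], blocks["case"]]),
        index=genes,
        columns=samples["control"] + samples["case"],
    )
    condition_of = {s: "control" for s in samples["control"]}
    condition_of.update({s: "case" for s in samples["case"]})
    truth = SyntheticTruth(
        de_genes=dict(de_spec),
        modules_control=[set(m.members) for m in modules_spec.get("control", [])],
        modules_case=[set(m.members) for m in modules_spec.get("case", [])],
    )
    return ExpressionMatrix(values=frame, condition_of=condition_of), truth


def module_correlation(loading: float, noise_sd: float) -> float:
    """Closed-form within-module Pearson r of the one-factor model."""
    return loading**2 / (loading**2 + noise_sd**2)


def generate_ppi(
    n_nodes: int,
    edges_per_node: int,
    n_planted_hubs: int = 0,
    hub_extra_degree: int = 0,
    rng_seed: int = 0,
    node_names: Sequence[str] | None = None,
) -> tuple[nx.Graph, SyntheticTruth]:
    """Scale-free interaction graph with optional high-degree planted hubs.

    Preferential-attachment growth first, then each planted hub is wired to
    ``hub_extra_degree`` additional uniform-random non-neighbors, keeping
    the graph simple.
    """
    if edges_per_node >= n_nodes:
        raise ValueError("edges_per_node must be smaller than n_nodes")
    names = list(node_names) if node_names is not None else gene_names(n_nodes)
    if len(names) != n_nodes:
        raise ValueError("node_names length must equal n_nodes")
    rng = np.random.default_rng(rng_seed)
    seed_int = int(rng.integers(0, 2**31 - 1))
    graph = nx.barabasi_albert_graph(n_nodes, edges_per_node, seed=seed_int)
    graph = nx.relabel_nodes(graph, dict(enumerate(names)))
    hubs = set(rng.choice(names, size=n_planted_hubs, replace=False)) if n_planted_hubs else set()
    for hub in sorted(hubs):
        candidates = [n for n in names if n != hub and not graph.has_edge(hub, n)]
        extra = min(hub_extra_degree, len(candidates))
        for partner in rng.choice(candidates, size=extra, replace=False):
            graph.add_edge(hub, partner)
    return graph, SyntheticTruth(planted_hubs=hubs)


def generate_go_dag(
    n_terms: int,
    max_parents: int,
    n_genes: int,
    annotations_per_gene: int,
    rng_seed: int = 0,
    gene_ids: Sequence[str] | None = None,
    namespace: str = "molecular_function",
) -> tuple[GoDag, dict[str, set[str]]]:
    """Single-rooted random is_a DAG plus gene → term annotations.

    Every non-root term chooses 1..max_parents parents among earlier terms,
    which guarantees acyclicity and that the root is an ancestor of every
    term; every gene receives at least one annotation.
    """
    if n_terms < 2:
        raise ValueError("need at least 2 terms")
    if max_parents < 1 or annotations_per_gene < 1:
        raise ValueError("max_parents and annotations_per_gene must be >= 1")
    rng = np.random.default_rng(rng_seed)
    terms = [f"T{i:07d}" for i in range(n_terms)]
    parents_of: dict[str, dict[str, str]] = {terms[0]: {}}
    for i in range(1, n_terms):
        k = int(rng.integers(1, min(max_parents, i) + 1))
        chosen = rng.choice(i, size=k, replace=False)
        parents_of[terms[i]] = {terms[int(j)]: "is_a" for j in chosen}
    dag = GoDag(parents_of=parents_of, namespace_of={t: namespace for t in terms})
    genes = list(gene_ids) if gene_ids is not None else gene_names(n_genes)
    annotations: dict[str, set[str]] = {}
    for g in genes:
        k = min(annotations_per_gene, n_terms)
        chosen = rng.choice(n_terms, size=k, replace=False)
        annotations[g] = {terms[int(j)] for j in chosen}
    return dag, annotations


# ---------------------------------------------------------------------------
# A complete end-to-end scenario with known answers
# ---------------------------------------------------------------------------


@dataclass
class Scenario:
    """All pipeline inputs for one synthetic study, plus the ground truth."""

    matrix: ExpressionMatrix
    network: nx.Graph
    panel: GenePanel
    dag: GoDag
    annotations: dict[str, set[str]]
    gene_sets: dict[str, set[str]]
    associations: list[AssociationRecord]
    truth: SyntheticTruth


def disruption_scenario(
    n_genes: int = 120,
    n_control: int = 20,
    n_case: int = 20,
    loading: float = 0.95,
    noise_sd: float = 0.2,
    de_shift: float = 1.5,
    rng_seed: int = 0,
) -> Scenario:
    """A study in which regulator connectivity is lost in the disease state.

    One module containing a seed and an nkpf gene is active in control
    only (the planted "lost" co-expression), one module containing a
    different seed/nkpf pair is active in both conditions, and every panel
    or module gene carries a mean shift so it survives the differential
    expression filter, mirroring the design where the regulator panel is
    itself differentially expressed.  The default shift of 1.5 log2 units
    (linear fold change ~2.8) sits in the range reported for such panels;
    module genes need a shift of this size because the shared latent factor
    inflates the sampling noise of their group means.
    """
    if n_genes < 40:
        raise ValueError("the scenario needs at least 40 genes")
    genes = gene_names(n_genes)
    seeds = genes[:4]
    nkpf = genes[4:6]
    panel = GenePanel(
        name="synthetic_panel",
        members=set(seeds) | set(nkpf),
        category_of={**{g: "seed" for g in seeds}, **{g: "nkpf" for g in nkpf}},
    )
    lost_module = ModuleSpec(members=(seeds[0], nkpf[0], genes[6], genes[7]), loading=loading)
    stable_module = ModuleSpec(members=(seeds[1], nkpf[1], genes[8], genes[9]), loading=loading)
    extra_de = genes[10:16]
    de_genes = set(panel.members) | set(lost_module.members) | set(stable_module.members)
    de_spec = {g: de_shift for g in sorted(de_genes)}
    de_spec.update({g: -de_shift for g in extra_de})
    matrix, truth = generate_expression(
        n_genes=n_genes,
        n_control=n_control,
        n_case=n_case,
        modules_spec={"control": [lost_module, stable_module], "case": [stable_module]},
        de_spec=de_spec,
        noise_sd=noise_sd,
        rng_seed=rng_seed,
    )
    truth.seed_nkpf_lost_pairs = {pair_key(seeds[0], nkpf[0])}
    network, net_truth = generate_ppi(
        n_nodes=n_genes,
        edges_per_node=2,
        n_planted_hubs=4,
        hub_extra_degree=30,
        rng_seed=rng_seed + 1,
        node_names=genes,
    )
    truth.planted_hubs = net_truth.planted_hubs
    dag, annotations = generate_go_dag(
        n_terms=40,
        max_parents=2,
        n_genes=n_genes,
        annotations_per_gene=2,
        rng_seed=rng_seed + 2,
        gene_ids=genes,
    )
    # module members share a dedicated term so their pairwise similarity is 1
    terms = sorted(dag.terms)
    for module, term in ((lost_module, terms[-1]), (stable_module, terms[-2])):
        for g in module.members:
            annotations[g] = {term}
    gene_sets = {
        "planted_lost_module": set(lost_module.members),
        "planted_stable_module": set(stable_module.members),
        "random_set": set(genes[20:40]),
    }
    associations = [
        AssociationRecord(trait="synthetic inflammatory trait", gene=seeds[0], p_value=8e-7),
        AssociationRecord(trait="synthetic inflammatory trait", gene=nkpf[0], p_value=2e-4),
        AssociationRecord(trait="unrelated trait", gene=seeds[0], p_value=0.2),
        AssociationRecord(trait="unrelated trait", gene=genes[-1], p_value=1e-9),
    ]
    return Scenario(
        matrix=matrix,
        network=network,
        panel=panel,
        dag=dag,
        annotations=annotations,
        gene_sets=gene_sets,
        associations=associations,
        truth=truth,
    )


def write_fixture_dir(scenario: Scenario, out_dir: str | Path) -> dict[str, Path]:
    """Write a complete fixture directory of pipeline inputs as plain text."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "conditions": out / "conditions.tsv",
        "edges": out / "edges.tsv",
        "obo": out / "ontology.obo",
        "annotations": out / "annotations.tsv",
        "seed_panel": out / "seed_genes.txt",
        "nkpf_panel": out / "nkpf_genes.txt",
        "gene_sets": out / "gene_sets.gmt",
        "associations": out / "associations.tsv",
        "truth": out / "truth.json",
    }
    write_expression(scenario.matrix, paths["expression"], paths["conditions"])
    write_edge_list(scenario.network, paths["edges"])
    write_obo(scenario.dag, paths["obo"])
    write_annotations(scenario.annotations, paths["annotations"])
    write_gene_list(sorted(scenario.panel.seeds), paths["seed_panel"])
    write_gene_list(sorted(scenario.panel.nkpf), paths["nkpf_panel"])
    write_gmt(scenario.gene_sets, paths["gene_sets"])
    write_associations(scenario.associations, paths["associations"])
    truth = scenario.truth
    import json

    paths["truth"].write_text(
        json.dumps(
            {
                "de_genes": truth.de_genes,
                "modules_control": [sorted(m) for m in truth.modules_control],
                "modules_case": [sorted(m) for m in truth.modules_case],
                "planted_hubs": sorted(truth.planted_hubs),
                "seed_nkpf_lost_pairs": [list(p) for p in sorted(truth.seed_nkpf_lost_pairs)],
            },
            indent=2,
            sort_keys=True,
        )
    )
    return paths


def write_obo(dag: GoDag, path: str | Path) -> None:
    """Minimal OBO dump of a DAG (term stanzas with is_a/relationship lines)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("format-version: 1.2\nontology: synthetic\n")
        for term in sorted(dag.parents_of):
            fh.write(f"\n[Term]\nid: {term}\nname: {term.lower()}\n")
            fh.write(f"namespace: {dag.namespace_of[term]}\n")
            for parent, rel in sorted(dag.parents_of[term].items()):
                if rel == "is_a":
                    fh.write(f"is_a: {parent} ! {parent.lower()}\n")
                else:
                    fh.write(f"relationship: {rel} {parent} ! {parent.lower()}\n")
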