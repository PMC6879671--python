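"""Wang graph-based GO semantic similarity with best-match-average combining.

A term X is represented by its ancestor closure T_X.  Each ancestor t gets a
semantic contribution S_X(t): 1 for X itself, and otherwise the maximum over
children c of t (restricted to T_X) of w(c→t) * S_X(c), where the edge
weight w is 0.8 for is_a and 0.6 for part_of.  Two terms are compared as

    sim(X, Y) = sum_{t in T_X ∩ T_Y} (S_X(t) + S_Y(t))
                -------------------------------------
                 sum_{t in T_X} S_X(t) + sum_{t in T_Y} S_Y(t)

which lies in [0, 1] and is 1 exactly for X = Y.  Gene-level similarity is
the best-match average of the term-pair matrix over the two genes'
annotation sets, restricted to a single namespace (molecular_function by
default, matching how this measure is normally applied to co-expressed
pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from .coexpr import DiffCoexRecord, Pair

DEFAULT_WEIGHTS = {"is_a": 0.8, "part_of": 0.6}


@dataclass
class GoDag:
    """Acyclic ontology: child→parent edges labelled is_a / part_of.

    ``parents_of[term]`` maps each parent term to its relation label;
    ``namespace_of`` assigns every term a namespace.  Terms in different
    namespaces never share ancestors and compare as 0.
    """

    parents_of: dict[str, dict[str, str]]
    namespace_of: dict[str, str]
    weights: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_WEIGHTS))
    alias_of: dict[str, str] = field(default_factory=dict)

    def canonical(self, term: str) -> str:
        return self.alias_of.get(term, term)

    def __post_init__(self) -> None:
        for term, parents in self.parents_of.items():
            for parent, rel in parents.items():
                if rel not in self.weights:
                    raise ValueError(f"unknown relation {rel!r} on {term}->{parent}")
                if parent not in self.parents_of:
                    raise ValueError(f"parent {parent!r} of {term!r} is not a term")
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}
        for start in self.parents_of:
            if state.get(start):
                continue
            stack = [(start, iter(self.parents_of[start]))]
            state[start] = 1
            while stack:
                node, it = stack[-1]
                for parent in it:
                    s = state.get(parent, 0)
                    if s == 1:
                        raise ValueError(f"cycle through {parent!r}")
                    if s == 0:
                        state[parent] = 1
                        stack.append((parent, iter(self.parents_of[parent])))
                        break
                else:
                    state[node] = 2
                    stack.pop()

    @property
    def terms(self) -> set[str]:
        return set(self.parents_of)

    def ancestors(self, term: str) -> set[str]:
        """All ancestors of ``term`` including the term itself (T_X)."""
        if term not in self.parents_of:
            raise KeyError(term)
        seen = {term}
        frontier = [term]
        while frontier:
            node = frontier.pop()
            for parent in self.parents_of[node]:
                if parent not in seen:
                    seen.add(parent)
                    frontier.append(parent)
        return seen

    def roots(self) -> set[str]:
        return {t for t, p in self.parents_of.items() if not p}


def load_obo(path: str | Path, weights: Mapping[str, float] | None = None) -> GoDag:
    """Load an OBO ontology, resolving alt_ids and dropping obsolete terms.

    Only is_a and part_of relationships are retained; terms without a
    namespace are rejected.
    """
    import obonet

    graph = obonet.read_obo(path)  # obsolete terms are excluded by obonet
    weights = dict(weights or DEFAULT_WEIGHTS)
    parents_of: dict[str, dict[str, str]] = {}
    namespace_of: dict[str, str] = {}
    alias_of: dict[str, str] = {}
    for term, data in graph.nodes(data=True):
        ns = data.get("namespace")
        if ns is None:
            raise ValueError(f"term {term} has no namespace")
        parents_of[term] = {}
        namespace_of[term] = ns
        for alt in data.get("alt_id", ()):
            alias_of[alt] = term
    for child, parent, rel in graph.edges(keys=True):
        if rel in weights and parent in parents_of:
            parents_of[child][parent] = rel
    return GoDag(
        parents_of=parents_of,
        namespace_of=namespace_of,
        weights=weights,
        alias_of=alias_of,
    )


def s_values(term: str, dag: GoDag) -> dict[str, float]:
    """Semantic contributions S_X(t) of every ancestor t of ``term``.

    Computed by the max-over-children recursion restricted to the ancestor
    closure of X, i.e. the best (maximum-product) weighted path from X up to
    each ancestor.
    """
    closure = dag.ancestors(term)
    memo: dict[str, float] = {term: 1.0}
    # children within the closure, per ancestor
    children_in: dict[str, list[tuple[str, str]]] = {t: [] for t in closure}
    for child in closure:
        for parent, rel in dag.parents_of[child].items():
            if parent in closure:
                children_in[parent].append((child, rel))

    def value(t: str) -> float:
        if t in memo:
            return memo[t]
        best = max(dag.weights[rel] * value(child) for child, rel in children_in[t])
        memo[t] = best
        return best

    # iterative evaluation to avoid deep recursion on long chains
    order = _topological_upward(term, closure, dag)
    for t in order:
        value(t)
    return memo


def _topological_upward(term: str, closure: set[str], dag: GoDag) -> list[str]:
    """Closure terms ordered so every child precedes its parents."""
    indeg = {t: 0 for t in closure}
    for child in closure:
        for parent in dag.parents_of[child]:
            if parent in closure:
                indeg[parent] += 1
    frontier = [t for t, d in indeg.items() if d == 0]
    order: list[str] = []
    while frontier:
        node = frontier.pop()
        order.append(node)
        for parent in dag.parents_of[node]:
            if parent in closure:
                indeg[parent] -= 1
                if indeg[parent] == 0:
                    frontier.append(parent)
    return order


def term_similarity(x: str, y: str, dag: GoDag) -> float:
    """Pairwise term similarity; 0 when the ancestor closures are disjoint."""
    if dag.namespace_of.get(x) != dag.namespace_of.get(y):
        return 0.0
    sx = s_values(x, dag)
    sy = s_values(y, dag)
    common = set(sx) & set(sy)
    if not common:
        return 0.0
    num = sum(sx[t] + sy[t] for t in common)
    den = sum(sx.values()) + sum(sy.values())
    # guard against float summation-order excursions outside [0, 1]
    return min(1.0, max(0.0, num / den))


class UnannotatedGeneError(KeyError):
    """A gene has no usable annotations in the requested namespace."""


def gene_similarity_bma(
    g1: str,
    g2: str,
    annotations: Mapping[str, set[str]],
    dag: GoDag,
    namespace: str = "molecular_function",
    _cache: dict | None = None,
) -> float:
    """Best-match-average similarity of two genes' annotation sets.

    BMA averages, over both annotation sets, each term's best match in the
    other gene's set: (sum_i max_j sim + sum_j max_i sim) / (m + n).
    """
    terms1 = _usable_terms(g1, annotations, dag, namespace)
    terms2 = _usable_terms(g2, annotations, dag, namespace)
    cache = _cache if _cache is not None else {}

    def sim(a: str, b: str) -> float:
        key = (a, b) if a < b else (b, a)
        if key not in cache:
            cache[key] = term_similarity(a, b, dag)
        return cache[key]

    row_max = [max(sim(a, b) for b in terms2) for a in terms1]
    col_max = [max(sim(a, b) for a in terms1) for b in terms2]
    return (sum(row_max) + sum(col_max)) / (len(terms1) + len(terms2))


def _usable_terms(gene, annotations, dag: GoDag, namespace: str) -> list[str]:
    terms = {
        dag.canonical(t)
        for t in annotations.get(gene, ())
        if dag.canonical(t) in dag.parents_of
        and dag.namespace_of[dag.canonical(t)] == namespace
    }
    if not terms:
        raise UnannotatedGeneError(gene)
    return sorted(terms)


@dataclass(frozen=True)
class SemSimRecord:
    """A differentially co-expressed pair with its functional similarity."""

    pair: Pair
    score: float
    r_control: float
    r_case: float
    direction: str


def score_pairs(
    records: Iterable[DiffCoexRecord],
    annotations: Mapping[str, set[str]],
    dag: GoDag,
    namespace: str = "molecular_function",
) -> tuple[list[SemSimRecord], list[Pair]]:
    """Score each pair with BMA similarity; unannotated pairs are skipped.

    Returns the scored records and the list of skipped pairs so callers can
    log them rather than silently treating missing annotation as score 0.
    """
    scored: list[SemSimRecord] = []
    skipped: list[Pair] = []
    cache: dict = {}
    for rec in records:
        a, b = rec.pair
        try:
            score = gene_similarity_bma(a, b, annotations, dag, namespace, _cache=cache)
        except UnannotatedGeneError:
            skipped.append(rec.pair)
            continue
        scored.append(
            SemSimRecord(
                pair=rec.pair,
                score=score,
                r_control=rec.r_control,
                r_case=rec.r_case,
                direction=rec.direction,
            )
        )
    return scored, skipped


def filter_semsim(records: Iterable[SemSimRecord], score_min: float = 0.5) -> list[SemSimRecord]:
    """Keep pairs whose functional similarity passes the robustness cutoff."""
    return [r for r in records if r.score >= score_min]


def read_semsim(path) -> list[SemSimRecord]:
    from .coexpr import pair_key

    records = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("geneA\tgeneB"):
            raise ValueError(f"{path}: not a semantic-similarity table")
        for line in fh:
            a, b, r_ctl, r_case, _diff, score, direction = line.rstrip("\n").split("\t")
            records.append(
                SemSimRecord(
                    pair=pair_key(a, b),
                    score=float(score),
                    r_control=float(r_ctl),
                    r_case=float(r_case),
                    direction=direction,
                )
            )
    return records


def write_semsim(records: Iterable[SemSimRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("geneA\tgeneB\tr_control\tr_case\tabs_diff\tsemantic_score\tdirection\n")
        for rec in sorted(records, key=lambda r: (r.direction, r.pair)):
            a, b = rec.pair
            fh.write(
                f"{a}\t{b}\t{rec.r_control:.6f}\t{rec.r_case:.6f}\t"
                f"{abs(rec.r_control - rec.r_case):.6f}\t{rec.score:.6f}\t{rec.direction}\n"
            )
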