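"""Readers and writers for the plain-text formats the pipeline consumes.

All text I/O is UTF-8 and tab-separated; lines starting with ``#`` are
comments.  Gene symbols are uppercased and whitespace-stripped on ingest so
that expression rows, interaction edges, annotations and panels key on the
same identifier space.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

CONDITIONS = ("control", "case")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _norm(symbol: str) -> str:
    return str(symbol).strip().upper()


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Gene-by-sample matrix of log2 intensities with a condition per sample.

    ``values`` is a pandas DataFrame indexed by unique, uppercased gene
    symbols with one column per sample.  ``condition_of`` maps every sample
    to ``"control"`` or ``"case"``; each condition must contain at least two
    samples and every value must be finite.
    """

    values: pd.DataFrame
    condition_of: dict[str, str]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise FormatError(f"duplicate gene ids: {sorted(dups)[:5]}")
        missing = [s for s in self.values.columns if s not in self.condition_of]
        if missing:
            raise FormatError(f"samples missing from condition map: {missing}")
        bad = {s: c for s, c in self.condition_of.items() if c not in CONDITIONS}
        if bad:
            raise FormatError(f"conditions must be one of {CONDITIONS}, got {bad}")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise FormatError("expression values must be finite")
        for cond in CONDITIONS:
            if len(self.samples_in(cond)) < 2:
                raise FormatError(f"fewer than 2 samples in condition {cond!r}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in(self, condition: str) -> list[str]:
        return [s for s in self.values.columns if self.condition_of[s] == condition]

    def submatrix(self, condition: str, genes: Iterable[str] | None = None) -> pd.DataFrame:
        cols = self.samples_in(condition)
        frame = self.values[cols]
        if genes is not None:
            frame = frame.loc[list(genes)]
        return frame


def read_expression(path: str | Path, condition_map_path: str | Path) -> ExpressionMatrix:
    """Read an expression TSV (genes in rows, samples in columns).

    Duplicate gene rows (e.g. several probes per symbol) are collapsed by
    keeping the row with the highest mean intensity.
    """
    frame = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if frame.empty:
        raise FormatError(f"no expression rows in {path}")
    nonnum = frame.columns[[not pd.api.types.is_numeric_dtype(frame[c]) for c in frame.columns]]
    if len(nonnum):
        raise FormatError(f"non-numeric expression values in columns {list(nonnum)}")
    frame.index = [_norm(g) for g in frame.index]
    frame.columns = [str(c).strip() for c in frame.columns]
    if frame.index.has_duplicates:
        # probe-level rows for the same symbol: keep the brightest probe
        frame["__mean"] = frame.mean(axis=1)
        frame = (
            frame.sort_values("__mean", ascending=False, kind="stable")
            .groupby(level=0, sort=True)
            .head(1)
            .drop(columns="__mean")
            .sort_index()
        )
    condition_of = read_condition_map(condition_map_path)
    return ExpressionMatrix(values=frame.astype(float), condition_of=condition_of)


def read_condition_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping sample id to 'control' or 'case'."""
    out: dict[str, str] = {}
    for lineno, parts in _iter_rows(path):
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
        out[parts[0].strip()] = parts[1].strip().lower()
    if not out:
        raise FormatError(f"empty condition map {path}")
    return out


def write_expression(matrix: ExpressionMatrix, path: str | Path, condition_map_path: str | Path | None = None) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")
    if condition_map_path is not None:
        with open(condition_map_path, "w", encoding="utf-8") as fh:
            for sample in matrix.sample_ids:
                fh.write(f"{sample}\t{matrix.condition_of[sample]}\n")


# ---------------------------------------------------------------------------
# Interaction networks
# ---------------------------------------------------------------------------


def read_edge_list(path: str | Path) -> nx.Graph:
    """Read an undirected interaction table (2/3-column TSV or SIF).

    Self-loops are dropped and duplicate or reversed-duplicate edges are
    collapsed so the result is always a simple undirected graph.  SIF rows
    with several targets (``A pp B C``) produce one edge per target.
    """
    with open(path, encoding="utf-8") as fh:
        lines = [
            (i, line.rstrip("\n"))
            for i, line in enumerate(fh, start=1)
            if line.strip() and not line.lstrip().startswith("#")
        ]
    # SIF rows are whitespace-delimited (node relation target...); plain edge
    # tables are tab-delimited (nodeA nodeB [relation]).
    sif = str(path).lower().endswith(".sif") or all("\t" not in line for _, line in lines)
    graph = nx.Graph()
    n_rows = 0
    for lineno, line in lines:
        parts = line.split() if sif else line.split("\t")
        if len(parts) < 2:
            raise FormatError(f"{path}:{lineno}: interaction row needs at least 2 columns")
        n_rows += 1
        source = _norm(parts[0])
        if sif and len(parts) >= 3:
            targets = [_norm(p) for p in parts[2:]]
        else:
            targets = [_norm(parts[1])]
        for target in targets:
            if source != target:
                graph.add_edge(source, target)
    if n_rows == 0 or graph.number_of_edges() == 0:
        raise FormatError(f"no interactions found in {path}")
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Gene panels
# ---------------------------------------------------------------------------


@dataclass
class GenePanel:
    """A curated regulator panel split into 'seed' and 'nkpf' categories.

    The nkpf category holds the NF-κB transcription-factor family; seeds are
    the pathway regulators recovered from the RNAi screens.
    """

    name: str
    members: set[str]
    category_of: dict[str, str] = field(repr=False)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("panel has no members")
        uncat = self.members - set(self.category_of)
        if uncat:
            raise ValueError(f"panel members without category: {sorted(uncat)}")

    def genes(self, category: str) -> set[str]:
        return {g for g in self.members if self.category_of[g] == category}

    @property
    def seeds(self) -> set[str]:
        return self.genes("seed")

    @property
    def nkpf(self) -> set[str]:
        return self.genes("nkpf")


def merge_regulator_panels(
    list_tnf: Iterable[str],
    list_lps: Iterable[str],
    list_family: Iterable[str],
    name: str = "regulators",
) -> GenePanel:
    """Union the two screen hit lists with the transcription-factor family.

    Duplicates are removed; a gene appearing in the family list is
    categorized ``nkpf`` even when it was also a screen hit, all others are
    ``seed``.
    """
    family = {_norm(g) for g in list_family if str(g).strip()}
    if not family:
        raise ValueError("family gene list is empty")
    screens = {_norm(g) for g in list_tnf if str(g).strip()} | {
        _norm(g) for g in list_lps if str(g).strip()
    }
    members = screens | family
    category_of = {g: ("nkpf" if g in family else "seed") for g in members}
    return GenePanel(name=name, members=members, category_of=category_of)


def read_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; '#' comments and blanks ignored."""
    out = []
    for _lineno, parts in _iter_rows(path, also_split_whitespace=True):
        out.append(_norm(parts[0]))
    if not out:
        raise FormatError(f"empty gene list {path}")
    return out


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for g in genes:
            fh.write(f"{g}\n")


# ---------------------------------------------------------------------------
# Annotations, gene sets, association tables
# ---------------------------------------------------------------------------


def read_annotations(path: str | Path) -> dict[str, set[str]]:
    """Two-column TSV of (gene, term) pairs, returned as gene → term set."""
    out: dict[str, set[str]] = {}
    for lineno, parts in _iter_rows(path):
        if len(parts) != 2:
            raise FormatError(f"{path}:{lineno}: expected gene<TAB>term")
        out.setdefault(_norm(parts[0]), set()).add(parts[1].strip())
    if not out:
        raise FormatError(f"no annotations in {path}")
    return out


def write_annotations(annotations: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene in sorted(annotations):
            for term in sorted(annotations[gene]):
                fh.write(f"{gene}\t{term}\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT gene-set collection: name, description, then member genes."""
    sets: dict[str, set[str]] = {}
    for lineno, parts in _iter_rows(path):
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: GMT row needs name, description, >=1 gene")
        sets[parts[0].strip()] = {_norm(g) for g in parts[2:] if g.strip()}
    if not sets:
        raise FormatError(f"no gene sets in {path}")
    return sets


def write_gmt(sets: Mapping[str, set[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(sets):
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tna\t{genes}\n")


@dataclass(frozen=True)
class AssociationRecord:
    """One GWAS-catalog-style row: trait, gene, association p-value."""

    trait: str
    gene: str
    p_value: float

    def __post_init__(self) -> None:
        if not (0 < self.p_value <= 1):
            raise ValueError(f"p_value must be in (0,1], got {self.p_value}")


def read_associations(path: str | Path) -> list[AssociationRecord]:
    """TSV with header trait/gene/p_value."""
    records: list[AssociationRecord] = []
    header: list[str] | None = None
    for lineno, parts in _iter_rows(path):
        if header is None:
            header = [p.strip().lower() for p in parts]
            if header[:3] != ["trait", "gene", "p_value"]:
                raise FormatError(f"{path}:{lineno}: expected header trait/gene/p_value")
            continue
        if len(parts) < 3:
            raise FormatError(f"{path}:{lineno}: expected 3 columns")
        try:
            p = float(parts[2])
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: non-numeric p-value {parts[2]!r}") from exc
        try:
            records.append(AssociationRecord(trait=parts[0].strip(), gene=_norm(parts[1]), p_value=p))
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    if not records:
        raise FormatError(f"no association records in {path}")
    return records


def write_associations(records: Iterable[AssociationRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("trait\tgene\tp_value\n")
        for rec in records:
            fh.write(f"{rec.trait}\t{rec.gene}\t{rec.p_value:g}\n")


# ---------------------------------------------------------------------------
# shared row iterator
# ---------------------------------------------------------------------------


def _iter_rows(path: str | Path, also_split_whitespace: bool = False):
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) == 1 and also_split_whitespace:
                parts = line.split()
            yield lineno, parts
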