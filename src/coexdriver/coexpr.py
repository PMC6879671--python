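"""Condition-specific Pearson correlation maps and differential co-expression.

Each condition gets its own map of pairwise Pearson correlations computed
across that condition's samples only.  Pairs with high positive correlation
(r >= 0.8 by default, signed, not absolute) are "co-expressed"; a pair whose
correlation moves by at least 0.5 in absolute value between conditions is
differentially co-expressed.  The absolute difference of two correlations
is bounded by 2, attained only for perfect correlations of opposite sign.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np

from .io import ExpressionMatrix

Pair = tuple[str, str]


def pair_key(a: str, b: str) -> Pair:
    """Canonical unordered gene-pair key."""
    if a == b:
        raise ValueError(f"self pair {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class CorrelationMap:
    """Per-condition map of unordered gene pair → Pearson r.

    Pairs involving a zero-variance gene are excluded from ``r_of`` and
    tracked in ``degenerate_pairs`` instead of being assigned r = 0.
    """

    condition: str
    r_of: dict[Pair, float]
    n_samples: int
    degenerate_pairs: set[Pair]


def correlation_map(
    matrix: ExpressionMatrix,
    condition: str,
    gene_subset: Iterable[str] | None = None,
) -> CorrelationMap:
    """Pearson r for every unordered pair of genes within one condition."""
    genes = list(gene_subset) if gene_subset is not None else matrix.gene_ids
    unknown = set(genes) - set(matrix.gene_ids)
    if unknown:
        raise ValueError(f"genes not in matrix: {sorted(unknown)[:5]}")
    if len(genes) < 2:
        raise ValueError("need at least 2 genes for a correlation map")
    data = matrix.submatrix(condition, genes).to_numpy(dtype=float)
    n_samples = data.shape[1]
    if n_samples < 3:
        raise ValueError(f"need at least 3 samples in condition {condition!r}")
    sd = data.std(axis=1)
    constant = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data)
    r_of: dict[Pair, float] = {}
    degenerate: set[Pair] = set()
    for i in range(len(genes)):
        for j in range(i + 1, len(genes)):
            key = pair_key(genes[i], genes[j])
            if constant[i] or constant[j]:
                degenerate.add(key)
            else:
                # clip tiny numerical excursions outside [-1, 1]
                r_of[key] = float(min(1.0, max(-1.0, corr[i, j])))
    return CorrelationMap(
        condition=condition, r_of=r_of, n_samples=n_samples, degenerate_pairs=degenerate
    )


def threshold_pairs(cmap: CorrelationMap, r_min: float = 0.8) -> set[Pair]:
    """Pairs with signed r >= r_min (high positive co-expression)."""
    return {p for p, r in cmap.r_of.items() if r >= r_min}


def genes_of(pairs: Iterable[Pair]) -> set[str]:
    """Distinct endpoint genes of a pair collection."""
    out: set[str] = set()
    for a, b in pairs:
        out.add(a)
        out.add(b)
    return out


@dataclass(frozen=True)
class DiffCoexRecord:
    """A pair co-expressed in condition a whose correlation shifts in b."""

    pair: Pair
    r_control: float
    r_case: float
    direction: str  # which condition the pair was selected in

    @property
    def abs_diff(self) -> float:
        return abs(self.r_control - self.r_case)


def cross_condition_delta(
    pairs: Iterable[Pair],
    cmap_a: CorrelationMap,
    cmap_b: CorrelationMap,
    delta_min: float = 0.5,
) -> tuple[list[DiffCoexRecord], set[Pair]]:
    """Map condition-a pairs onto condition b and keep |r_a - r_b| >= delta_min.

    Returns the kept records plus the pairs that were degenerate in b (no
    correlation there); call twice with swapped maps to cover both mapping
    directions.
    """
    records: list[DiffCoexRecord] = []
    missing: set[Pair] = set()
    maps = {cmap_a.condition: cmap_a, cmap_b.condition: cmap_b}
    if set(maps) != {"control", "case"}:
        raise ValueError("expected one control and one case correlation map")
    for p in pairs:
        if p not in cmap_a.r_of:
            raise ValueError(f"pair {p} not drawn from the source correlation map")
        if p not in cmap_b.r_of:
            missing.add(p)
            continue
        rec = DiffCoexRecord(
            pair=p,
            r_control=maps["control"].r_of[p],
            r_case=maps["case"].r_of[p],
            direction=cmap_a.condition,
        )
        if rec.abs_diff >= delta_min:
            records.append(rec)
    records.sort(key=lambda r: r.pair)
    return records, missing


def panel_neighborhood(
    records: Iterable[DiffCoexRecord],
    panel_members: set[str],
) -> tuple[list[DiffCoexRecord], set[str]]:
    """Records touching the regulator panel, plus their non-panel partners."""
    kept: list[DiffCoexRecord] = []
    partners: set[str] = set()
    for rec in records:
        a, b = rec.pair
        if a in panel_members or b in panel_members:
            kept.append(rec)
            partners.update(g for g in rec.pair if g not in panel_members)
    return kept, partners


def write_correlation_map(cmap: CorrelationMap, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("geneA\tgeneB\tr\n")
        for (a, b) in sorted(cmap.r_of):
            fh.write(f"{a}\t{b}\t{cmap.r_of[(a, b)]:.6f}\n")


def read_diffcoex(path) -> list[DiffCoexRecord]:
    records = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("geneA\tgeneB"):
            raise ValueError(f"{path}: not a differential co-expression table")
        for line in fh:
            a, b, r_ctl, r_case, _diff, direction = line.rstrip("\n").split("\t")
            records.append(
                DiffCoexRecord(
                    pair=pair_key(a, b),
                    r_control=float(r_ctl),
                    r_case=float(r_case),
                    direction=direction,
                )
            )
    return records


def write_diffcoex(records: Iterable[DiffCoexRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("geneA\tgeneB\tr_control\tr_case\tabs_diff\tdirection_of_mapping\n")
        for rec in sorted(records, key=lambda r: (r.direction, r.pair)):
            a, b = rec.pair
            fh.write(
                f"{a}\t{b}\t{rec.r_control:.6f}\t{rec.r_case:.6f}\t"
                f"{rec.abs_diff:.6f}\t{rec.direction}\n"
            )
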