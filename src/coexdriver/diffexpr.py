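"""Two-group differential expression on log2 intensities.

Per gene, a two-sided Welch t-test compares case against control samples;
p-values are adjusted with the Benjamini–Hochberg step-up procedure and
genes are selected on adjusted p and a signed linear fold change.  The
signed fold-change convention is the microarray one: 2**log2fc for
upregulation, the negative reciprocal for downregulation, so its magnitude
is always >= 1 and a threshold of 1.2 means "at least a 1.2-fold change in
either direction".
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionMatrix

_TINY_P = float(np.nextafter(0, 1))


@dataclass(frozen=True)
class DEResult:
    gene: str
    mean_control: float
    mean_case: float
    log2fc: float
    signed_fc: float
    t_stat: float
    p_value: float
    q_value: float | None = None
    degenerate: bool = False

    @property
    def call(self) -> str:
        return "degenerate" if self.degenerate else "tested"


def signed_fold_change(log2fc: float) -> float:
    """Linear fold change, negative-reciprocal coded for downregulation."""
    if log2fc >= 0:
        return 2.0 ** log2fc
    return -(2.0 ** (-log2fc))


def de_statistics(matrix: ExpressionMatrix, equal_var: bool = False) -> list[DEResult]:
    """Per-gene two-sided t-test of case vs control (Welch by default).

    Genes with zero variance in both groups are flagged degenerate with
    t = 0 and p = 1 rather than propagating NaNs.
    """
    ctl = matrix.submatrix("control").to_numpy(dtype=float)
    cas = matrix.submatrix("case").to_numpy(dtype=float)
    if ctl.shape[1] < 2 or cas.shape[1] < 2:
        raise ValueError("need at least 2 samples per condition")
    mean_c = ctl.mean(axis=1)
    mean_t = cas.mean(axis=1)
    var_c = ctl.var(axis=1, ddof=1)
    var_t = cas.var(axis=1, ddof=1)
    t_arr, p_arr = stats.ttest_ind(cas, ctl, axis=1, equal_var=equal_var)
    results: list[DEResult] = []
    for i, gene in enumerate(matrix.gene_ids):
        log2fc = float(mean_t[i] - mean_c[i])
        degenerate = var_c[i] == 0 and var_t[i] == 0
        if degenerate or not math.isfinite(t_arr[i]):
            t, p, degenerate = 0.0, 1.0, True
        else:
            t = float(t_arr[i])
            p = max(float(p_arr[i]), _TINY_P)
        results.append(
            DEResult(
                gene=gene,
                mean_control=float(mean_c[i]),
                mean_case=float(mean_t[i]),
                log2fc=log2fc,
                signed_fc=signed_fold_change(log2fc),
                t_stat=t,
                p_value=p,
                degenerate=degenerate,
            )
        )
    return results


def benjamini_hochberg(p_values: Sequence[float]) -> list[float]:
    """Step-up BH adjusted p-values (q-values), input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def attach_q_values(results: Iterable[DEResult]) -> list[DEResult]:
    results = list(results)
    q = benjamini_hochberg([r.p_value for r in results])
    return [replace(r, q_value=qi) for r, qi in zip(results, q)]


@dataclass(frozen=True)
class DEGSelection:
    up: set[str]
    down: set[str]

    @property
    def selected(self) -> set[str]:
        return self.up | self.down


def select_degs(
    results: Iterable[DEResult],
    p_max: float = 0.05,
    fc_min: float = 1.2,
    use_raw_p: bool = False,
) -> DEGSelection:
    """Keep genes passing both the (adjusted) p and fold-change filters.

    ``use_raw_p`` switches the p filter to unadjusted p-values for runs
    where the FDR step is applied elsewhere.
    """
    if fc_min < 1:
        raise ValueError("fc_min must be >= 1 (signed fold-change scale)")
    up: set[str] = set()
    down: set[str] = set()
    for r in results:
        p = r.p_value if use_raw_p else r.q_value
        if p is None:
            raise ValueError("results carry no q-values; run attach_q_values first")
        if p <= p_max:
            if r.signed_fc >= fc_min:
                up.add(r.gene)
            elif r.signed_fc <= -fc_min:
                down.add(r.gene)
    return DEGSelection(up=up, down=down)


def write_de_report(results: Iterable[DEResult], selection: DEGSelection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("gene\tmean_control\tmean_case\tlog2fc\tsigned_fc\tt\tp\tq\tcall\n")
        for r in sorted(results, key=lambda r: (r.p_value, r.gene)):
            call = "up" if r.gene in selection.up else "down" if r.gene in selection.down else "ns"
            fh.write(
                f"{r.gene}\t{r.mean_control:.4f}\t{r.mean_case:.4f}\t{r.log2fc:.4f}\t"
                f"{r.signed_fc:.4f}\t{r.t_stat:.4f}\t{r.p_value:.3e}\t{r.q_value:.3e}\t{call}\n"
            )
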