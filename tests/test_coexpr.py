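"""Per-condition correlation maps and differential co-expression."""

import numpy as np
import pandas as pd
import pytest

from coexdriver.coexpr import (
    DiffCoexRecord,
    correlation_map,
    cross_condition_delta,
    genes_of,
    pair_key,
    panel_neighborhood,
    read_diffcoex,
    threshold_pairs,
    write_diffcoex,
    CorrelationMap,
)
from coexdriver.io import ExpressionMatrix


def make_matrix(rows: dict, n_control: int, n_case: int) -> ExpressionMatrix:
    cols = [f"c{i}" for i in range(n_control)] + [f"t{i}" for i in range(n_case)]
    frame = pd.DataFrame(rows, index=cols).T
    cond = {c: ("control" if c.startswith("c") else "case") for c in cols}
    return ExpressionMatrix(values=frame.astype(float), condition_of=cond)


class TestCorrelationMap:
    def test_perfectly_correlated_pair(self):
        m = make_matrix({"X": [1, 2, 3, 0, 0, 1], "Y": [2, 4, 6, 0, 1, 0]}, 3, 3)
        cmap = correlation_map(m, "control")
        assert cmap.r_of[pair_key("X", "Y")] == pytest.approx(1.0)

    def test_hand_computed_r(self):
        # x=[1,2,3], y=[1,3,2]: covariance sum 1, denominator 2 -> r = 0.5
        m = make_matrix({"X": [1, 2, 3, 0, 1, 2], "Y": [1, 3, 2, 0, 1, 2]}, 3, 3)
        cmap = correlation_map(m, "control")
        assert cmap.r_of[pair_key("X", "Y")] == pytest.approx(0.5)

    def test_all_pairs_present_for_clean_input(self):
        rng = np.random.default_rng(0)
        rows = {f"G{i}": rng.normal(size=8) for i in range(10)}
        m = make_matrix(rows, 4, 4)
        cmap = correlation_map(m, "case")
        assert len(cmap.r_of) == 10 * 9 // 2
        assert not cmap.degenerate_pairs

    def test_zero_variance_gene_pairs_are_degenerate(self):
        m = make_matrix({"X": [1, 2, 3, 0, 1, 2], "F": [5, 5, 5, 5, 5, 5],
                         "Y": [3, 1, 2, 0, 1, 2]}, 3, 3)
        cmap = correlation_map(m, "control")
        assert pair_key("X", "F") in cmap.degenerate_pairs
        assert pair_key("F", "Y") in cmap.degenerate_pairs
        assert pair_key("X", "Y") in cmap.r_of

    def test_matches_product_moment_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            x = rng.normal(size=6)
            y = rng.normal(size=6)
            m = make_matrix({"X": list(x) + [0, 0, 0], "Y": list(y) + [0, 0, 0]}, 6, 3)
            r = correlation_map(m, "control").r_of[pair_key("X", "Y")]
            # textbook product-moment formula
            want = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
                np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
            )
            assert r == pytest.approx(want, abs=1e-12)

    def test_small_subset_rejected(self):
        m = make_matrix({"X": [1, 2, 3, 0, 1, 2], "Y": [1, 3, 2, 0, 1, 2]}, 3, 3)
        with pytest.raises(ValueError):
            correlation_map(m, "control", gene_subset=["X"])

    def test_unknown_subset_gene_rejected(self):
        m = make_matrix({"X": [1, 2, 3, 0, 1, 2], "Y": [1, 3, 2, 0, 1, 2]}, 3, 3)
        with pytest.raises(ValueError, match="not in matrix"):
            correlation_map(m, "control", gene_subset=["X", "NOPE"])


class TestThreshold:
    def _cmap(self, r_of):
        return CorrelationMap(condition="control", r_of=r_of, n_samples=5,
                              degenerate_pairs=set())

    def test_signed_threshold(self):
        cmap = self._cmap({("A", "B"): 0.85, ("A", "C"): 0.5, ("B", "C"): -0.9})
        assert threshold_pairs(cmap, r_min=0.8) == {("A", "B")}

    def test_genes_of(self):
        assert genes_of({("A", "B"), ("B", "C")}) == {"A", "B", "C"}

    def test_empty_map(self):
        assert threshold_pairs(self._cmap({}), r_min=0.8) == set()


class TestCrossConditionDelta:
    def _maps(self, r_control, r_case):
        ctl = CorrelationMap("control", r_control, 5, set())
        cas = CorrelationMap("case", r_case, 5, set())
        return ctl, cas

    def test_kept_and_dropped(self):
        ctl, cas = self._maps({("A", "B"): 0.9, ("A", "C"): 0.9},
                              {("A", "B"): 0.2, ("A", "C"): 0.6})
        records, missing = cross_condition_delta({("A", "B"), ("A", "C")}, ctl, cas)
        assert [r.pair for r in records] == [("A", "B")]
        assert records[0].abs_diff == pytest.approx(0.7)
        assert not missing

    def test_opposite_perfect_correlations_bound(self):
        ctl, cas = self._maps({("A", "B"): 0.9}, {("A", "B"): -0.9})
        records, _ = cross_condition_delta({("A", "B")}, ctl, cas)
        assert records[0].abs_diff == pytest.approx(1.8)
        assert records[0].abs_diff <= 2.0

    def test_pair_missing_in_target_reported(self):
        ctl, cas = self._maps({("A", "B"): 0.9}, {})
        records, missing = cross_condition_delta({("A", "B")}, ctl, cas)
        assert not records and missing == {("A", "B")}

    def test_pair_not_in_source_rejected(self):
        ctl, cas = self._maps({("A", "B"): 0.9}, {("A", "B"): 0.2})
        with pytest.raises(ValueError, match="not drawn"):
            cross_condition_delta({("A", "C")}, ctl, cas)

    def test_case_direction_mapping(self):
        ctl, cas = self._maps({("A", "B"): 0.1}, {("A", "B"): 0.95})
        records, _ = cross_condition_delta({("A", "B")}, cas, ctl)
        assert records[0].direction == "case"
        assert records[0].r_control == pytest.approx(0.1)
        assert records[0].r_case == pytest.approx(0.95)


class TestPanelNeighborhood:
    def _rec(self, a, b):
        return DiffCoexRecord(pair=pair_key(a, b), r_control=0.9, r_case=0.1,
                              direction="control")

    def test_panel_endpoint_retained(self):
        records = [self._rec("S1", "X"), self._rec("X", "Y")]
        kept, partners = panel_neighborhood(records, {"S1"})
        assert [r.pair for r in kept] == [pair_key("S1", "X")]
        assert partners == {"X"}

    def test_no_panel_endpoint(self):
        kept, partners = panel_neighborhood([self._rec("X", "Y")], {"S1"})
        assert kept == [] and partners == set()

    def test_both_endpoints_in_panel_retained_once(self):
        kept, partners = panel_neighborhood([self._rec("S1", "S2")], {"S1", "S2"})
        assert len(kept) == 1 and partners == set()


def test_diffcoex_round_trip(tmp_path):
    records = [
        DiffCoexRecord(pair=("A", "B"), r_control=0.9, r_case=0.1, direction="control"),
        DiffCoexRecord(pair=("B", "C"), r_control=0.2, r_case=0.85, direction="case"),
    ]
    write_diffcoex(records, tmp_path / "d.tsv")
    back = read_diffcoex(tmp_path / "d.tsv")
    assert {r.pair for r in back} == {("A", "B"), ("B", "C")}
    assert {r.direction for r in back} == {"control", "case"}
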