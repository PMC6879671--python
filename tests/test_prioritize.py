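"""Driver-gene calling, over-representation and GWAS-table overlap."""

import itertools

import numpy as np
import pytest

from coexdriver.io import AssociationRecord, GenePanel
from coexdriver.prioritize import (
    driver_genes,
    gwas_overlap,
    hypergeometric_enrichment,
)
from oracles import hypergeom_upper_tail, lost_pairs_by_exhaustive_check


def make_panel(seeds, nkpf):
    return GenePanel(
        name="p",
        members=set(seeds) | set(nkpf),
        category_of={**{g: "seed" for g in seeds}, **{g: "nkpf" for g in nkpf}},
    )


class TestDriverGenes:
    def test_direct_edge_lost_in_case(self):
        panel = make_panel(["S"], ["N"])
        calls = driver_genes([("N", "S")], [], panel)
        assert {c.gene for c in calls} == {"S", "N"}
        (s_call,) = [c for c in calls if c.gene == "S"]
        assert s_call.lost_partners == (("N", 1),)

    def test_connection_via_intermediate(self):
        panel = make_panel(["S"], ["N"])
        control = [("S", "X"), ("N", "X")]
        calls = driver_genes(control, [], panel)
        assert {c.gene for c in calls} == {"S", "N"}
        (s_call,) = [c for c in calls if c.gene == "S"]
        assert s_call.lost_partners == (("N", 2),)

    def test_same_connectivity_no_calls(self):
        panel = make_panel(["S"], ["N"])
        pairs = [("N", "S")]
        assert driver_genes(pairs, pairs, panel) == []

    def test_case_connection_through_different_intermediate_blocks_call(self):
        panel = make_panel(["S"], ["N"])
        control = [("S", "X"), ("N", "X")]
        case = [("S", "Y"), ("N", "Y")]
        assert driver_genes(control, case, panel) == []

    def test_three_hop_control_path_not_counted(self):
        panel = make_panel(["S"], ["N"])
        control = [("S", "X"), ("X", "Y"), ("Y", "N")]
        assert driver_genes(control, [], panel) == []

    def test_missing_category_rejected(self):
        panel = GenePanel(name="p", members={"S"}, category_of={"S": "seed"})
        with pytest.raises(ValueError, match="category"):
            driver_genes([], [], panel)

    def test_matches_exhaustive_pair_check_on_random_graphs(self):
        rng = np.random.default_rng(17)
        nodes = [f"n{i}" for i in range(12)]
        seeds, nkpf = nodes[:3], nodes[3:5]
        panel = make_panel(seeds, nkpf)
        all_pairs = list(itertools.combinations(nodes, 2))
        for _ in range(50):
            control = [p for p in all_pairs if rng.random() < 0.15]
            case = [p for p in all_pairs if rng.random() < 0.15]
            calls = driver_genes(control, case, panel)
            want_pairs = lost_pairs_by_exhaustive_check(control, case, seeds, nkpf)
            want_genes = {g for pair in want_pairs for g in pair}
            assert {c.gene for c in calls} == want_genes
            # swapping conditions yields the complementary "gained" side
            gained = driver_genes(case, control, panel)
            gained_want = lost_pairs_by_exhaustive_check(case, control, seeds, nkpf)
            assert {c.gene for c in gained} == {g for p in gained_want for g in p}


class TestEnrichment:
    def test_full_overlap_hand_value(self):
        universe = [f"u{i}" for i in range(20)]
        query = universe[:5]
        results = hypergeometric_enrichment(
            query, {"S": set(query)}, universe, p_max=1.0, fdr_max=1.1
        )
        (r,) = results
        # P(all 5 drawn) = 1 / C(20,5)
        assert r.p_value == pytest.approx(1 / 15504, rel=1e-9)
        assert r.overlap_count == 5

    def test_disjoint_query_p_is_one(self):
        universe = [f"u{i}" for i in range(10)]
        results = hypergeometric_enrichment(
            universe[:3], {"S": set(universe[5:])}, universe, p_max=1.0, fdr_max=1.1
        )
        assert results[0].p_value == pytest.approx(1.0)

    def test_small_sets_excluded_by_min_set(self):
        universe = [f"u{i}" for i in range(10)]
        results = hypergeometric_enrichment(
            universe[:3], {"tiny": {universe[0]}}, universe, p_max=1.0, fdr_max=1.1
        )
        assert results == []

    def test_empty_query_or_universe_rejected(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment([], {"S": {"a"}}, ["a"])
        with pytest.raises(ValueError):
            hypergeometric_enrichment(["a"], {"S": {"a"}}, [])

    def test_query_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="outside universe"):
            hypergeometric_enrichment(["zzz"], {"S": {"a"}}, ["a"])

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            n_universe = int(rng.integers(5, 13))
            set_size = int(rng.integers(2, n_universe + 1))
            query_size = int(rng.integers(1, n_universe + 1))
            universe = [f"u{i}" for i in range(n_universe)]
            members = set(universe[:set_size])
            query = set(rng.choice(universe, size=query_size, replace=False))
            results = hypergeometric_enrichment(
                query, {"S": members}, universe, p_max=1.0, fdr_max=1.1
            )
            overlap = len(members & query)
            want = hypergeom_upper_tail(n_universe, set_size, query_size, overlap)
            assert results[0].p_value == pytest.approx(want, rel=1e-9)


class TestGwasOverlap:
    RECORDS = [
        AssociationRecord("Rheumatoid arthritis", "REL", 8e-7),
        AssociationRecord("Some trait", "REL", 0.02),
        AssociationRecord("Other trait", "TLR4", 1e-8),
    ]

    def test_significant_driver_hit_retained(self):
        overlap = gwas_overlap(["REL", "SNW1"], self.RECORDS)
        assert any(
            r.trait == "Rheumatoid arthritis" and r.gene == "REL" for r in overlap.hits
        )

    def test_weak_association_dropped(self):
        overlap = gwas_overlap(["REL"], self.RECORDS)
        assert all(r.p_value <= 0.01 for r in overlap.hits)

    def test_driver_with_no_rows_reported_as_no_hit(self):
        overlap = gwas_overlap(["SNW1", "NFKB2", "REL"], self.RECORDS)
        assert overlap.drivers_without_hits == ("NFKB2", "SNW1")

    def test_non_driver_rows_ignored(self):
        overlap = gwas_overlap(["SNW1"], self.RECORDS)
        assert overlap.hits == ()
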