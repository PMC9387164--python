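"""Hypergeometric ORA, BH correction and weight re-ranking."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from wcnp.enrichment import (
    GeneSetCollection,
    enrich_and_rerank,
    hypergeom_enrich,
    read_gmt,
    rerank_by_weight,
    write_gmt,
)
from wcnp.errors import ValidationError
from wcnp.gene_sets import GeneSet
from wcnp.weighting import TargetMap, compute_weights


def exhaustive_upper_tail(N, K, n, k):
    """P(overlap >= k) by enumerating every n-subset of an N-universe."""
    universe = range(N)
    pathway = set(range(K))
    total = 0
    hits = 0
    for draw in itertools.combinations(universe, n):
        total += 1
        if len(pathway & set(draw)) >= k:
            hits += 1
    return hits / total


def bh_step_up(pvals):
    """BH as the definition: min over j >= i of m*p_(j)/j, capped at 1."""
    m = len(pvals)
    order = np.argsort(pvals, kind="stable")
    adjusted = np.empty(m)
    running = 1.0
    for rank_from_end, idx in enumerate(reversed(order)):
        i = m - rank_from_end  # 1-based rank of this p-value
        running = min(running, m * pvals[idx] / i)
        adjusted[idx] = running
    return adjusted


def _collection(sets, universe):
    return GeneSetCollection.from_sets(
        {pid: (pid, frozenset(genes)) for pid, genes in sets.items()},
        universe=frozenset(universe),
    )


def _query(symbols):
    return GeneSet.from_symbols("q", symbols)


class TestHypergeomEnrich:
    def test_zero_overlap_gives_p_one(self):
        coll = _collection({"P": ["A", "B"]}, ["A", "B", "C", "D", "Q"])
        res = hypergeom_enrich(_query(["Q"]), coll)
        assert res.table.loc[0, "p_value"] == pytest.approx(1.0)

    def test_n5_k2_n2_k2_is_exactly_one_tenth(self):
        # C(5,2)=10 draws; only one contains both pathway genes
        coll = _collection({"P": ["A", "B"]}, ["A", "B", "C", "D", "E"])
        res = hypergeom_enrich(_query(["A", "B"]), coll)
        row = res.table.iloc[0]
        assert (row["N"], row["K"], row["n"], row["k"]) == (5, 2, 2, 2)
        assert row["p_value"] == pytest.approx(0.1, abs=1e-12)
        assert row["p_value"] == pytest.approx(exhaustive_upper_tail(5, 2, 2, 2))

    def test_matches_exhaustive_enumeration_small_universes(self):
        for N in range(2, 9):
            for K in range(1, N + 1):
                for n in range(1, N + 1):
                    universe = [f"g{i}" for i in range(N)]
                    coll = _collection({"P": universe[:K]}, universe)
                    # query the first n genes: overlap k = min(K, n)
                    res = hypergeom_enrich(_query(universe[:n]), coll)
                    row = res.table.iloc[0]
                    expected = exhaustive_upper_tail(N, K, n, int(row["k"]))
                    assert row["p_value"] == pytest.approx(expected, rel=1e-9)

    def test_bh_hand_case(self):
        # p = (0.01, 0.02, 0.03) -> BH = (0.03, 0.03, 0.03)
        universe = [f"g{i}" for i in range(40)]
        rng = np.random.default_rng(0)
        # three pathways engineered to give distinct p-values, then check the
        # BH column against the step-up definition
        coll = _collection(
            {"P1": universe[:10], "P2": universe[5:20], "P3": universe[20:25]},
            universe,
        )
        res = hypergeom_enrich(_query(universe[:8]), coll)
        expected = bh_step_up(res.table["p_value"].to_numpy())
        assert res.table["fdr_bh"].to_numpy() == pytest.approx(expected)
        # the literal hand case on the raw routine
        from scipy.stats import false_discovery_control

        assert false_discovery_control([0.01, 0.02, 0.03], method="bh") == pytest.approx(
            [0.03, 0.03, 0.03]
        )

    def test_bh_matches_step_up_on_random_vectors(self):
        from scipy.stats import false_discovery_control

        rng = np.random.default_rng(7)
        for _ in range(50):
            p = rng.uniform(size=int(rng.integers(1, 30)))
            assert false_discovery_control(p, method="bh") == pytest.approx(
                bh_step_up(p)
            )

    def test_empty_universe_and_disjoint_query_error(self):
        coll = _collection({"P": ["A"]}, ["A", "B"])
        with pytest.raises(ValidationError):
            hypergeom_enrich(_query(["ZZZ"]), coll)
        with pytest.raises(ValidationError):
            hypergeom_enrich(
                _query(["A"]),
                GeneSetCollection.from_sets({}, universe=frozenset()),
            )

    def test_unweighted_rank_is_permutation(self, default_bundle):
        b = default_bundle
        key = GeneSet.from_symbols("q", b.manifest["key_targets"])
        res = hypergeom_enrich(key, b.pathways)
        ranks = sorted(res.table["unweighted_rank"])
        assert ranks == list(range(1, len(res) + 1))

    def test_k_min_filters_before_bh(self):
        universe = [f"g{i}" for i in range(20)]
        coll = _collection(
            {"P1": universe[:5], "P2": universe[10:15]}, universe
        )
        res = hypergeom_enrich(_query(universe[:5]), coll, k_min=1)
        assert list(res.table["pathway_id"]) == ["P1"]


class TestRerank:
    def _toy_result(self):
        universe = [f"g{i}" for i in range(30)]
        coll = _collection(
            {"P1": universe[:6], "P2": universe[6:14], "P3": universe[14:20]},
            universe,
        )
        return hypergeom_enrich(_query(universe[:6] + universe[6:9]), coll)

    def test_equal_weights_preserve_p_order(self):
        res = self._toy_result()
        rr = rerank_by_weight(res, {pid: 5.0 for pid in res.table["pathway_id"]})
        assert list(rr.table["pathway_id"]) == list(res.table["pathway_id"])
        assert (rr.table["rank_delta"] == 0).all()

    def test_sort_by_descending_c(self):
        res = self._toy_result()
        p_order = list(res.table["pathway_id"])
        c = {p_order[0]: 1.0, p_order[1]: 5.0, p_order[2]: 3.0}
        rr = rerank_by_weight(res, c)
        assert list(rr.table["pathway_id"]) == [p_order[1], p_order[2], p_order[0]]

    def test_pure_permutation_and_idempotent(self):
        res = self._toy_result()
        c = {pid: float(i) for i, pid in enumerate(res.table["pathway_id"])}
        rr = rerank_by_weight(res, c)
        rr2 = rerank_by_weight(rr, c)
        assert rr2.table.equals(rr.table)
        for col in ["p_value", "fdr_bh", "k", "K", "n", "N", "unweighted_rank"]:
            before = sorted(res.table[col])
            after = sorted(rr.table[col])
            assert before == after
        assert sorted(rr.table["weighted_rank"]) == list(range(1, len(rr) + 1))

    def test_rank_delta_twelve_to_two_is_plus_ten(self):
        # a pathway promoted from unweighted position 12 to weighted position 2
        universe = [f"g{i:02d}" for i in range(60)]
        sets = {f"P{i:02d}": universe[i * 2: i * 2 + 14] for i in range(15)}
        coll = _collection(sets, universe)
        res = hypergeom_enrich(_query(universe[:14]), coll)
        p_order = list(res.table["pathway_id"])
        target = p_order[11]  # unweighted rank 12
        c = {pid: 1.0 for pid in p_order}
        c[target] = 100.0          # best C
        c[p_order[0]] = 200.0      # one pathway still above it
        rr = rerank_by_weight(res, c)
        row = rr.table[rr.table["pathway_id"] == target].iloc[0]
        assert row["unweighted_rank"] == 12
        assert row["weighted_rank"] == 2
        assert row["rank_delta"] == 10

    def test_missing_c_treated_as_zero_with_warning(self, caplog):
        res = self._toy_result()
        pids = list(res.table["pathway_id"])
        with caplog.at_level("WARNING"):
            rr = rerank_by_weight(res, {pids[0]: 1.0})
        assert "C = 0" in caplog.text
        assert rr.table.iloc[0]["pathway_id"] == pids[0]


class TestEnrichAndRerank:
    def test_empty_edge_map_keeps_unweighted_order(self, toy_table):
        universe = ["T1", "T2", "T3", "T7", "T8", "T9"]
        coll = _collection({"P1": ["T1", "T2"], "P2": ["T7", "T8"]}, universe)
        res = enrich_and_rerank(
            _query(["T1", "T2"]), coll, toy_table, TargetMap(frozenset())
        )
        assert (res.table["weight_c"] == 0).all()
        assert (res.table["rank_delta"] == 0).all()

    def test_single_pathway_both_ranks_one(self, toy_table, toy_edges):
        coll = _collection({"P1": ["T1", "T2"]}, ["T1", "T2", "T3"])
        res = enrich_and_rerank(_query(["T1"]), coll, toy_table, toy_edges)
        row = res.table.iloc[0]
        assert row["unweighted_rank"] == row["weighted_rank"] == 1
        assert row["rank_delta"] == 0

    def test_equals_staged_composition(self, toy_table, toy_edges, toy_collection):
        q = _query(["T1", "T3"])
        composed = enrich_and_rerank(q, toy_collection, toy_table, toy_edges)
        staged = rerank_by_weight(
            hypergeom_enrich(q, toy_collection),
            compute_weights(toy_table, toy_edges, toy_collection.as_gene_map()).c_scores,
        )
        assert composed.table.equals(staged.table)

    def test_planted_pathway_promoted(self, default_bundle):
        b = default_bundle
        key = GeneSet.from_symbols("q", b.manifest["key_targets"])
        res = enrich_and_rerank(key, b.pathways, b.component_table, b.target_map)
        row = res.table[
            res.table["pathway_id"] == b.manifest["planted_pathway_id"]
        ].iloc[0]
        assert row["weighted_rank"] < row["unweighted_rank"]
        assert row["weighted_rank"] == 1


class TestGmtIO:
    def test_round_trip(self, tmp_path, toy_collection):
        path = tmp_path / "sets.gmt"
        write_gmt(toy_collection, path)
        back = read_gmt(path, universe=toy_collection.universe)
        assert back.as_gene_map() == toy_collection.as_gene_map()

    def test_default_universe_is_annotation_union(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("P1\tdesc\tA\tB\nP2\tdesc\tB\tC\n")
        coll = read_gmt(path)
        assert coll.universe == {"A", "B", "C"}
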