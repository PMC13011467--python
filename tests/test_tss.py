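"""TSS calling: end counting, chaining, consensus, merging, classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from saltomics.exceptions import InvalidAnnotationError, InvalidRecordError
from saltomics.tss import (
    TSSCluster,
    classify_tss,
    cluster_positions,
    compare_tss_sets,
    count_five_prime_ends,
    merge_conditions,
    replicate_consensus,
)

import oracles


def frag(start, end, strand, chrom="chr"):
    return {"chrom": chrom, "start": start, "end": end, "name": "r", "score": 1,
            "strand": strand}


def ends(pairs, strand="+"):
    """Build an end-count table from (position, count) pairs."""
    return pd.DataFrame(
        {"position": [p for p, _ in pairs], "strand": strand,
         "count": [c for _, c in pairs]}
    )


def clusters(pairs, strand="+"):
    return [
        TSSCluster(representative=p, strand=strand, total_count=c,
                   member_positions=(p,))
        for p, c in pairs
    ]


class TestEndCounting:
    def test_strand_aware_coordinate_conversion(self):
        df = pd.DataFrame([frag(100, 151, "+"), frag(100, 151, "-")])
        out = count_five_prime_ends(df)
        plus = out[out["strand"] == "+"].iloc[0]
        minus = out[out["strand"] == "-"].iloc[0]
        assert plus["position"] == 101
        # BED [100,151) covers 1-based bases 101..151; the rightmost base,
        # i.e. the minus-strand 5' end, is 151 (== the BED end field)
        assert minus["position"] == 151

    def test_duplicate_fragments_aggregate(self):
        df = pd.DataFrame([frag(100, 151, "+")] * 3)
        out = count_five_prime_ends(df)
        assert len(out) == 1 and out["count"].iloc[0] == 3

    def test_bad_strand_and_interval_rejected(self):
        with pytest.raises(InvalidRecordError):
            count_five_prime_ends(pd.DataFrame([frag(1, 10, ".")]))
        with pytest.raises(InvalidRecordError):
            count_five_prime_ends(pd.DataFrame([frag(10, 10, "+")]))


class TestClustering:
    def test_gap_boundary_splits_clusters(self):
        out = cluster_positions(ends([(100, 5), (103, 8), (109, 2)]))
        assert [(c.representative, c.total_count) for c in out] == [(103, 13), (109, 2)]
        assert out[0].member_positions == (100, 103)

    def test_tie_breaks_to_smaller_coordinate(self):
        out = cluster_positions(ends([(100, 5), (105, 5)]))
        assert len(out) == 1 and out[0].representative == 100

    def test_strands_never_mix(self):
        df = pd.concat([ends([(100, 3)], "+"), ends([(100, 3)], "-")])
        assert len(cluster_positions(df)) == 2

    def test_count_conservation(self):
        rng = np.random.default_rng(0)
        df = ends([(int(p), int(c)) for p, c in
                   zip(rng.integers(1, 500, 60), rng.integers(1, 9, 60))])
        df = df.drop_duplicates("position")
        out = cluster_positions(df)
        assert sum(c.total_count for c in out) == df["count"].sum()

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        positions=st.lists(st.integers(0, 400), min_size=0, max_size=60, unique=True),
        counts_seed=st.integers(0, 10_000),
        window=st.integers(1, 10),
    )
    def test_matches_brute_force_single_linkage(self, positions, counts_seed, window):
        rng = np.random.default_rng(counts_seed)
        counts = [int(c) for c in rng.integers(1, 20, len(positions))]
        out = cluster_positions(ends(list(zip(positions, counts))), window)
        got = sorted((c.representative, c.total_count, c.member_positions) for c in out)
        assert got == oracles.brute_single_linkage(positions, counts, window)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        positions=st.lists(st.integers(0, 300), min_size=1, max_size=40, unique=True),
        w1=st.integers(1, 9),
    )
    def test_wider_window_never_more_clusters(self, positions, w1):
        df = ends([(p, 1) for p in positions])
        assert len(cluster_positions(df, w1 + 1)) <= len(cluster_positions(df, w1))

    def test_idempotent_on_spread_representatives(self):
        out = cluster_positions(ends([(100, 4), (120, 2), (150, 9)]), 5)
        again = cluster_positions(
            ends([(c.representative, c.total_count) for c in out]), 5
        )
        assert [c.representative for c in again] == [c.representative for c in out]


class TestConsensus:
    def test_all_replicates_required(self):
        by_rep = {1: clusters([(100, 5)]), 2: clusters([(102, 7)]), 3: clusters([(104, 2)])}
        out = replicate_consensus(by_rep)
        assert len(out) == 1
        assert out[0].representative == 102  # greatest count member
        assert out[0].total_count == 14
        assert out[0].replicate_set == frozenset({1, 2, 3})

    def test_partial_detection_dropped(self):
        by_rep = {1: clusters([(100, 5)]), 2: clusters([(100, 5)]), 3: []}
        assert replicate_consensus(by_rep) == []

    def test_mixed_chains(self):
        by_rep = {
            1: clusters([(100, 5), (120, 1)]),
            2: clusters([(101, 5), (120, 1)]),
            3: clusters([(99, 5)]),
        }
        out = replicate_consensus(by_rep)
        assert len(out) == 1
        assert out[0].representative == 99  # count tie -> smallest coordinate


class TestMergeConditions:
    def test_condition_sets_and_tally(self):
        by_cond = {"A": clusters([(100, 5)]), "B": clusters([(103, 2)]), "C": [], "D": []}
        unique, tally = merge_conditions(by_cond)
        assert len(unique) == 1
        assert unique[0].condition_set == frozenset({"A", "B"})
        assert tally == {frozenset({"A", "B"}): 1}

    def test_detection_conservation(self):
        by_cond = {"A": clusters([(100, 1)]), "B": clusters([(200, 1)])}
        unique, tally = merge_conditions(by_cond)
        assert len(unique) == 2
        assert sum(len(u.condition_set) for u in unique) == 2

    def test_all_four_conditions(self):
        by_cond = {c: clusters([(500, 3)]) for c in "ABCD"}
        unique, _ = merge_conditions(by_cond)
        assert len(unique) == 1 and len(unique[0].condition_set) == 4


class TestClassification:
    GENES = pd.DataFrame(
        [{"gene_id": "gA", "start": 1000, "end": 2000, "strand": "+"}]
    )

    def tss(self, pos, strand="+"):
        return TSSCluster(representative=pos, strand=strand, total_count=1,
                          member_positions=(pos,))

    @pytest.mark.parametrize(
        "pos,strand,cls,dist",
        [
            (700, "+", "upstream", 300),
            (600, "+", "upstream", 400),   # inclusive boundary
            (599, "+", "orphan", None),    # distance 401
            (1500, "+", "internal", 500),
            (1500, "-", "antisense", 500),
            (2500, "+", "orphan", None),
        ],
    )
    def test_category_and_distance(self, pos, strand, cls, dist):
        out = classify_tss([self.tss(pos, strand)], self.GENES)[0]
        assert out.classification == cls
        assert out.distance_to_start == dist
        assert out.assigned_gene == ("gA" if cls != "orphan" else None)

    def test_minus_strand_upstream_window(self):
        genes = pd.DataFrame(
            [{"gene_id": "gB", "start": 1000, "end": 2000, "strand": "-"}]
        )
        assert classify_tss([self.tss(2400, "-")], genes)[0].classification == "upstream"
        assert classify_tss([self.tss(2401, "-")], genes)[0].classification == "orphan"

    def test_upstream_priority_over_internal(self):
        genes = pd.DataFrame(
            [
                {"gene_id": "gA", "start": 1000, "end": 2000, "strand": "+"},
                {"gene_id": "gB", "start": 2100, "end": 3000, "strand": "+"},
            ]
        )
        out = classify_tss([self.tss(1900)], genes)[0]
        assert out.classification == "upstream"
        assert out.assigned_gene == "gB"

    def test_partition_is_exhaustive(self):
        rng = np.random.default_rng(3)
        genes = pd.DataFrame(
            {"gene_id": [f"g{i}" for i in range(10)],
             "start": np.arange(10) * 1000 + 200,
             "end": np.arange(10) * 1000 + 800,
             "strand": np.where(rng.random(10) < 0.5, "+", "-")}
        )
        tss_list = [self.tss(int(p), s) for p, s in
                    zip(rng.integers(1, 10_000, 200),
                        np.where(rng.random(200) < 0.5, "+", "-"))]
        out = classify_tss(tss_list, genes)
        assert all(t.classification in
                   {"upstream", "internal", "antisense", "orphan"} for t in out)
        assert len(out) == len(tss_list)

    def test_malformed_gene_rejected(self):
        bad = pd.DataFrame([{"gene_id": "g", "start": 100, "end": 50, "strand": "+"}])
        with pytest.raises(InvalidAnnotationError):
            classify_tss([self.tss(10)], bad)


class TestCompareSets:
    def test_simple_match_and_strand(self):
        a = clusters([(100, 1)])
        assert len(compare_tss_sets(a, clusters([(104, 1)]))[0]) == 1
        assert len(compare_tss_sets(a, clusters([(100, 1)], strand="-"))[0]) == 0

    def test_greedy_tie_to_smaller_coordinate(self):
        a = clusters([(100, 1), (106, 1)])
        b = clusters([(103, 1)])
        pairs, a_only, _ = compare_tss_sets(a, b)
        assert len(pairs) == 1
        assert pairs[0][0].representative == 100
        assert [t.representative for t in a_only] == [106]
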