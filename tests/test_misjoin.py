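"""Join testing: liftover, Kadane, cutoff clique, iteration control."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hicscaf import synthetic_data as sd
from hicscaf.io_formats import HiCPair, ReadEnd
from hicscaf.layout import Layout
from hicscaf.misjoin import (
    Blacklist,
    ScaffoldMap,
    correct_iteration,
    lift_pair_spans,
    max_sum_subarray,
    scaffold_coverage,
    stopping_rule,
)
from hicscaf.misjoin import test_join as check_join
from hicscaf.scaffold_graph import HiCEdge, NodeEnd


# --- Kadane ----------------------------------------------------------------

@pytest.mark.parametrize(
    "arr,expected",
    [
        ([-1, -1, 1, 1, -1], (2, 4, 2)),
        ([-1, -1, -1], (0, 1, -1)),
        ([1, 1, 1], (0, 3, 3)),
        ([1, -1, 1], (0, 1, 1)),  # leftmost then shortest tie rule
    ],
)
def test_max_sum_subarray_examples(arr, expected):
    assert max_sum_subarray(np.array(arr)) == expected


def test_max_sum_subarray_matches_quadratic_oracle(rng):
    for _ in range(30):
        a = rng.choice([-1, 1], size=60)
        s, e, best = max_sum_subarray(a)
        sums = {
            (i, j): int(a[i:j].sum())
            for i in range(len(a))
            for j in range(i + 1, len(a) + 1)
        }
        oracle_best = max(sums.values())
        assert best == oracle_best == sums[(s, e)]
        # leftmost start, then shortest, among optima
        opts = [k for k, v in sums.items() if v == oracle_best]
        smin = min(i for i, _ in opts)
        emin = min(j for i, j in opts if i == smin)
        assert (s, e) == (smin, emin)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.sampled_from([-1, 1]), min_size=1, max_size=40))
def test_max_sum_subarray_property(arr):
    a = np.array(arr)
    s, e, best = max_sum_subarray(a)
    assert 0 <= s < e <= len(a)
    assert int(a[s:e].sum()) == best
    assert best == max(
        a[i:j].sum() for i in range(len(a)) for j in range(i + 1, len(a) + 1)
    )


# --- liftover --------------------------------------------------------------

def test_liftover_round_trip_identity():
    walk = [("a", "+"), ("b", "-"), ("c", "+")]
    smap = ScaffoldMap(walk, {"a": 100, "b": 200, "c": 50}, gap_length=10)
    assert smap.length == 100 + 10 + 200 + 10 + 50
    for cid, s, e in [("a", 5, 30), ("b", 20, 80), ("c", 0, 50)]:
        ls, le = smap.lift_interval(cid, s, e)
        assert smap.drop_interval(ls, le) == (cid, s, e)


def test_liftover_reverse_orientation_coordinates():
    smap = ScaffoldMap([("a", "-")], {"a": 100}, gap_length=10)
    assert smap.lift_interval("a", 0, 10) == (90, 100)


def test_lift_pair_spans_orientation_aware():
    smap = ScaffoldMap([("a", "+"), ("b", "-")], {"a": 100, "b": 100}, 10)
    pairs = [
        HiCPair("r1", ReadEnd("a", 90, 100), ReadEnd("b", 90, 100)),
        HiCPair("r2", ReadEnd("a", 0, 10), ReadEnd("zz", 0, 10)),  # outside
    ]
    spans = lift_pair_spans(smap, pairs)
    # b's [90,100) maps to scaffold [110,120) under reversal
    assert spans.tolist() == [[90, 120]]


def test_scaffold_coverage_clips_spans():
    spans = np.array([[0, 50], [40, 120], [200, 300]])
    cov = scaffold_coverage(spans, 30, 110)
    expect = np.zeros(80)
    expect[:20] += 1  # [0,50) clipped to [30,50)
    expect[10:] += 1  # [40,120) clipped to [40,110)
    assert np.array_equal(cov, expect)


# --- join testing ----------------------------------------------------------

def test_flat_coverage_not_flagged():
    flagged, _ = check_join(np.full(1000, 40), position=500)
    assert not flagged


def test_trough_at_join_flagged():
    cov = np.full(1000, 40)
    cov[480:520] = 0
    flagged, region = check_join(cov, position=500)
    assert flagged
    s, e = region
    assert s <= 500 <= e


def test_trough_elsewhere_not_flagged():
    cov = np.full(1000, 40)
    cov[100:140] = 0
    flagged, region = check_join(cov, position=500)
    assert not flagged
    assert region[0] <= 120 <= region[1]


def test_flagging_monotone_in_trough_depth():
    flagged_prev = False
    for depth in (0, 5, 10, 20, 40):
        cov = np.full(1000, 40)
        cov[490:510] = 40 - depth
        flagged, _ = check_join(cov, position=500)
        assert flagged or not flagged_prev  # deepening never un-flags
        flagged_prev = flagged_prev or flagged
    assert flagged_prev  # the deepest trough is caught


# --- iteration control -----------------------------------------------------

def test_no_joins_no_changes(small_sim):
    layout = Layout(walks=[[(c.id, "+")] for c in small_sim["contigs"]])
    out, bl, frac, tests = correct_iteration(
        layout, small_sim["pairs"], small_sim["contig_lengths"]
    )
    assert frac == 0.0 and tests == [] and out.walks == layout.walks


def test_correct_scaffolds_not_broken(small_sim):
    layout, labels = sd.make_erroneous_scaffolds(
        small_sim["contigs"], small_sim["truth"], 0, 10, seed=5
    )
    out, bl, frac, tests = correct_iteration(
        layout, small_sim["pairs"], small_sim["contig_lengths"]
    )
    assert frac == 0.0
    assert len(tests) == sum(len(w) - 1 for w in layout.walks)
    assert out.walks == layout.walks and len(bl) == 0


def test_chimeric_joins_flagged_and_split_restores_walks(small_sim):
    # alternating truth-adjacent blocks: every second join is chimeric
    blocks = [("chr1_c1", "chr1_c2"), ("chr2_c11", "chr2_c12"),
              ("chr1_c21", "chr1_c22")]
    walk = [(c, "+") for blk in blocks for c in blk]
    edges = [
        HiCEdge(NodeEnd(walk[i][0], "E"), NodeEnd(walk[i + 1][0], "B"), 1, 1.0)
        for i in range(len(walk) - 1)
    ]
    layout = Layout(walks=[walk], joins=[edges])
    out, bl, frac, tests = correct_iteration(
        layout, small_sim["pairs"], small_sim["contig_lengths"],
        window=80_000,
    )
    flagged = {t.junction_index for t in tests if t.flagged}
    assert flagged == {1, 3}  # exactly the cross-block joins
    assert frac == pytest.approx(2 / 5)
    assert [len(w) for w in out.walks] == [2, 2, 2]
    # the split is the inverse of the joins
    assert out.walks == [
        [("chr1_c1", "+"), ("chr1_c2", "+")],
        [("chr2_c11", "+"), ("chr2_c12", "+")],
        [("chr1_c21", "+"), ("chr1_c22", "+")],
    ]
    assert {k for k in bl.keys} == {edges[1].key, edges[3].key}


def test_only_new_joins_tested(small_sim):
    walk = [("chr1_c1", "+"), ("chr1_c2", "+"), ("chr1_c3", "+")]
    old = HiCEdge(NodeEnd("chr1_c1", "E"), NodeEnd("chr1_c2", "B"), 1, 1.0)
    new = HiCEdge(NodeEnd("chr1_c2", "E"), NodeEnd("chr1_c3", "B"), 1, 1.0)
    layout = Layout(walks=[walk], joins=[[old, new]])
    _, _, _, tests = correct_iteration(
        layout, small_sim["pairs"], small_sim["contig_lengths"],
        new_edge_keys={new.key},
    )
    assert [(t.junction_index) for t in tests] == [1]


def test_blacklist_grows_monotonically():
    bl = Blacklist()
    k1 = (NodeEnd("a", "E"), NodeEnd("b", "B"))
    bl.add(k1)
    assert k1 in bl and len(bl) == 1
    bl.add(k1)
    assert len(bl) == 1


@pytest.mark.parametrize(
    "frac,n_joins,stop",
    [(0.6, 10, True), (0.4, 10, False), (0.5, 10, False), (0.0, 0, True)],
)
def test_stopping_rule(frac, n_joins, stop):
    assert stopping_rule(frac, n_joins) is stop
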