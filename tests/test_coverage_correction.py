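"""Physical coverage, suspicious intervals, clique calling, splitting."""

import numpy as np
import pytest

from hicscaf import synthetic_data as sd
from hicscaf.coverage_correction import (
    BreakRegion,
    PhysicalCoverageProfile,
    break_contig,
    correct_assembly,
    detect_misassembly,
    maximal_clique_interval,
    physical_coverage,
    physical_coverage_from_spans,
    sweep_suspicious_intervals,
)
from hicscaf.io_formats import Contig, HiCPair, ReadEnd


def _pair(cid, s1, e1, s2, e2, rid="r"):
    return HiCPair(rid, ReadEnd(cid, s1, e1), ReadEnd(cid, s2, e2))


def _naive_coverage(spans, length):
    cov = np.zeros(length)
    for s, e in spans:
        cov[s:e] += 1
    return cov


# --- physical coverage -----------------------------------------------------

def test_single_pair_span():
    prof = physical_coverage([_pair("c", 10, 40, 60, 90)], 100, bin_size=1)
    expect = np.zeros(100)
    expect[10:90] = 1
    assert np.array_equal(prof.cov, expect)


def test_zero_pairs_all_zero():
    prof = physical_coverage([], 100, bin_size=1, contig_id="c")
    assert prof.cov.shape == (100,) and not prof.cov.any()


def test_random_spans_match_naive_oracle(rng):
    length = 500
    starts = rng.integers(0, length - 1, size=50)
    ends = np.minimum(starts + 1 + rng.integers(0, 200, size=50), length)
    cov = physical_coverage_from_spans(starts, ends, length, bin_size=1)
    assert np.allclose(cov, _naive_coverage(zip(starts, ends), length))


def test_binned_coverage_conserves_span_mass(rng):
    length = 10_000
    starts = rng.integers(0, length - 1, size=200)
    ends = np.minimum(starts + 1 + rng.integers(0, 3000, size=200), length)
    cov = physical_coverage_from_spans(starts, ends, length, bin_size=250)
    assert np.isclose(cov.sum() * 250, (ends - starts).sum())


def test_mixed_contig_pair_rejected():
    bad = HiCPair("r", ReadEnd("a", 0, 10), ReadEnd("b", 0, 10))
    with pytest.raises(ValueError):
        physical_coverage([bad], 100, bin_size=1)


# --- threshold sweep -------------------------------------------------------

def _profile(cov, bin_size=1):
    cov = np.asarray(cov, dtype=float)
    return PhysicalCoverageProfile("c", cov, bin_size, len(cov) * bin_size)


def test_sweep_flat_profile_no_interval():
    prof = _profile(np.full(100, 5.0))
    assert sweep_suspicious_intervals(prof, [3.0]) == []


def test_sweep_single_dip_shared_by_thresholds():
    cov = np.full(100, 5.0)
    cov[40:60] = 0.0
    out = sweep_suspicious_intervals(_profile(cov), [1.0, 3.0])
    assert [(iv.start, iv.end) for iv in out] == [(40, 60), (40, 60)]


def _oracle_longest_run(cov, delta):
    runs, start = [], None
    for i, v in enumerate(cov):
        if v < delta and start is None:
            start = i
        elif v >= delta and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(cov)))
    if not runs:
        return None
    return max(runs, key=lambda r: (r[1] - r[0], -r[0]))


def test_sweep_matches_run_enumeration_oracle(rng):
    for _ in range(20):
        cov = rng.integers(0, 8, size=120).astype(float)
        deltas = [1.0, 3.0, 5.0, 7.0]
        got = {
            iv.threshold: (iv.start, iv.end)
            for iv in sweep_suspicious_intervals(
                _profile(cov), deltas, ignore_end_bins=False
            )
        }
        for d in deltas:
            expect = _oracle_longest_run(cov, d)
            assert got.get(d) == expect


def test_sweep_ignores_contig_end_runs():
    cov = np.full(50, 5.0)
    cov[:10] = 0.0  # end artifact
    cov[20:25] = 0.0
    (iv,) = sweep_suspicious_intervals(_profile(cov), [1.0])
    assert (iv.start, iv.end) == (20, 25)


# --- maximal clique --------------------------------------------------------

def test_clique_nested_intervals():
    region, depth = maximal_clique_interval([(0, 10), (2, 8), (4, 6)])
    assert region == (4, 6) and depth == 3


def test_clique_disjoint_intervals():
    region, depth = maximal_clique_interval([(0, 5), (10, 15)])
    assert depth == 1 and region == (0, 5)


def test_clique_empty_raises():
    with pytest.raises(ValueError):
        maximal_clique_interval([])


def test_clique_matches_point_depth_oracle(rng):
    for _ in range(10):
        starts = rng.integers(0, 200, size=100)
        ends = starts + 1 + rng.integers(0, 60, size=100)
        ivs = list(zip(starts.tolist(), ends.tolist()))
        _, depth = maximal_clique_interval(ivs)
        points = sorted({p for iv in ivs for p in iv})
        oracle = max(
            sum(1 for s, e in ivs if s <= p < e) for p in points
        )
        assert depth == oracle


# --- misassembly detection -------------------------------------------------

def test_uniform_coverage_no_break():
    prof = _profile(np.full(50, 20.0), bin_size=1000)
    assert detect_misassembly(prof) is None


def test_short_contig_no_break():
    prof = _profile([5.0], bin_size=1000)
    assert detect_misassembly(prof) is None


def test_simulated_chimera_break_near_junction():
    genome = sd.make_genome(2, 500_000, seed=21)
    contigs, truth, _ = sd.fragment(genome, 40_000)
    contigs2, truth2, (rec,) = sd.inject_chimeras(contigs, truth, 1, seed=22)
    pairs = sd.simulate_hic(truth2, 40_000, seed=23)
    intra = [p for p in pairs if p.intra and p.end1.contig_id == rec.contig_id]
    prof = physical_coverage(intra, 80_000, bin_size=1000, contig_id=rec.contig_id)
    region = detect_misassembly(prof)
    assert region is not None
    assert region.start - 2000 <= rec.junction <= region.end + 2000


# --- contig splitting ------------------------------------------------------

def test_three_piece_split_lengths():
    contig = Contig("c", 100_000)
    pieces, _ = break_contig(contig, BreakRegion("c", 40_000, 42_000))
    assert [p.length for p in pieces] == [40_000, 2_000, 58_000]
    assert [p.id for p in pieces] == ["c.1", "c.2", "c.3"]


def test_split_region_at_boundary_two_pieces():
    pieces, _ = break_contig(Contig("c", 100), BreakRegion("c", 0, 30))
    assert [p.length for p in pieces] == [30, 70]


def test_pair_left_of_cut_untouched():
    contig = Contig("c", 1000)
    _, pairs = break_contig(
        contig, BreakRegion("c", 500, 600), [_pair("c", 10, 50, 100, 150)]
    )
    (p,) = pairs
    assert p.end1 == ("c.1", 10, 50, "+") and p.end2 == ("c.1", 100, 150, "+")


def test_split_remap_matches_reintersection_oracle(rng):
    contig = Contig("c", 10_000)
    region = BreakRegion("c", 4_000, 4_500)
    pairs = []
    for i in range(200):
        s1 = int(rng.integers(0, 9_900))
        s2 = int(rng.integers(0, 9_900))
        pairs.append(_pair("c", s1, s1 + 100, s2, s2 + 100, rid=f"r{i}"))
    pieces, remapped = break_contig(contig, region, pairs)
    bounds = [("c.1", 0, 4_000), ("c.2", 4_000, 4_500), ("c.3", 4_500, 10_000)]

    def oracle(end):
        for pid, lo, hi in bounds:
            if lo <= end.start and end.end <= hi:
                return (pid, end.start - lo, end.end - lo)
        return None

    expected = []
    for p in pairs:
        o1, o2 = oracle(p.end1), oracle(p.end2)
        if o1 and o2:
            expected.append((p.read_id, o1, o2))
    got = [(p.read_id, tuple(p.end1[:3]), tuple(p.end2[:3])) for p in remapped]
    assert got == expected
    assert sum(p.length for p in pieces) == contig.length


def test_split_conserves_sequence():
    seq = "ACGT" * 250
    contig = Contig("c", 1000, seq)
    pieces, _ = break_contig(contig, BreakRegion("c", 300, 400))
    assert "".join(p.sequence for p in pieces) == seq
    assert all(p.length > 0 for p in pieces)


# --- whole-assembly correction ---------------------------------------------

def test_coordinate_map_tiles_broken_contigs():
    genome = sd.make_genome(2, 500_000, seed=61)
    contigs, truth, _ = sd.fragment(genome, 40_000)
    contigs2, truth2, (rec,) = sd.inject_chimeras(contigs, truth, 1, seed=62)
    n = sd.pairs_for_physical_coverage(truth2, 30.0, seed=63)
    pairs = sd.simulate_hic(truth2, n, seed=64)
    corrected, _, breaks, coord_map = correct_assembly(contigs2, pairs)
    assert breaks
    by_old = {}
    for new_id, old_id, start, end in coord_map:
        by_old.setdefault(old_id, []).append((start, end, new_id))
    lengths = {c.id: c.length for c in contigs2}
    for old_id, spans in by_old.items():
        spans.sort()
        assert spans[0][0] == 0 and spans[-1][1] == lengths[old_id]
        assert all(a[1] == b[0] for a, b in zip(spans, spans[1:]))

def test_clean_assembly_no_breaks(small_sim):
    contigs, pairs, breaks, coord_map = correct_assembly(
        small_sim["contigs"], small_sim["pairs"], rounds=1
    )
    assert breaks == []
    assert [c.id for c in contigs] == [c.id for c in small_sim["contigs"]]


def test_injected_chimeras_mostly_recovered():
    genome = sd.make_genome(2, 1_000_000, seed=31)
    contigs, truth, _ = sd.fragment(genome, 40_000)
    contigs2, truth2, records = sd.inject_chimeras(contigs, truth, 5, seed=32)
    n = sd.pairs_for_physical_coverage(truth2, 30.0, seed=33)
    pairs = sd.simulate_hic(truth2, n, seed=34)
    _, _, breaks, _ = correct_assembly(contigs2, pairs, rounds=1)
    junctions = {r.contig_id: r.junction for r in records}
    hits = sum(
        1
        for b in breaks
        if b.contig_id in junctions
        and b.start - 2000 <= junctions[b.contig_id] <= b.end + 2000
    )
    assert hits >= 4
    assert all(b.contig_id in junctions for b in breaks)


def test_two_rounds_find_both_junctions_of_double_chimera():
    genome = sd.make_genome(2, 600_000, seed=41)
    contigs, truth, _ = sd.fragment(genome, 40_000)
    by_id = {c.id: c for c in contigs}
    # alternate chromosomes so both junctions are genuine chimeric joins
    a, b, c = by_id["chr1_c3"], by_id["chr2_c8"], by_id["chr1_c12"]
    glued = Contig(
        "glued", a.length + b.length + c.length,
        a.sequence + b.sequence + c.sequence,
    )
    truth2 = sd.TruthSet(chrom_lengths=dict(truth.chrom_lengths))
    offset = 0
    for src in (a, b, c):
        seg = truth.single_record(src.id)
        truth2.add("glued", sd.TruthSegment(
            seg.chrom, seg.genome_start, seg.genome_end, offset))
        offset += src.length
    for cid in sorted(truth.segments):
        if cid not in {a.id, b.id, c.id}:
            truth2.add(cid, truth.single_record(cid))
    others = [x for x in contigs if x.id not in {a.id, b.id, c.id}]
    n = sd.pairs_for_physical_coverage(truth2, 30.0, seed=42)
    pairs = sd.simulate_hic(truth2, n, seed=43)
    _, _, breaks, _ = correct_assembly([glued] + others, pairs, rounds=2)
    glued_breaks = [x for x in breaks if x.contig_id.startswith("glued")]
    assert len(glued_breaks) >= 2
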