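"""Iterative misjoin detection on scaffold joins (the stopping engine).

Every join made in the latest round is tested: read pairs are lifted to
scaffold coordinates, physical coverage is computed in a window around
the join, and per coverage-cutoff the longest low stretch is located as
a maximum-sum subarray of a ±1 auxiliary array. If the join position
falls inside the maximal clique of those stretches the join is broken
and its edge blacklisted. When the majority of a round's joins fail,
scaffolding stops and the previous round's result stands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from hicscaf.coverage_correction import maximal_clique_interval
from hicscaf.io_formats import HiCPair
from hicscaf.layout import Layout, Walk
from hicscaf.scaffold_graph import EdgeKey


@dataclass
class ScaffoldMap:
    """Orientation-aware liftover between contig and scaffold coordinates."""

    walk: Walk
    contig_lengths: Dict[str, int]
    gap_length: int = 500
    offsets: Dict[str, int] = field(default_factory=dict)
    length: int = 0

    def __post_init__(self) -> None:
        pos = 0
        for i, (cid, _) in enumerate(self.walk):
            if i > 0:
                pos += self.gap_length
            self.offsets[cid] = pos
            pos += self.contig_lengths[cid]
        self.length = pos

    def orientation(self, cid: str) -> str:
        for c, o in self.walk:
            if c == cid:
                return o
        raise KeyError(cid)

    def lift_interval(self, cid: str, start: int, end: int) -> Tuple[int, int]:
        """Contig interval [start, end) -> scaffold interval [s, e)."""
        off = self.offsets[cid]
        clen = self.contig_lengths[cid]
        if self.orientation(cid) == "+":
            return off + start, off + end
        return off + clen - end, off + clen - start

    def drop_interval(self, s: int, e: int) -> Tuple[str, int, int]:
        """Scaffold interval back to (contig, start, end); gap-free only."""
        for cid, _ in self.walk:
            off = self.offsets[cid]
            clen = self.contig_lengths[cid]
            if off <= s and e <= off + clen:
                if self.orientation(cid) == "+":
                    return cid, s - off, e - off
                return cid, off + clen - e, off + clen - s
        raise ValueError(f"interval [{s},{e}) not inside a single contig")

    def join_position(self, junction_idx: int) -> int:
        """Scaffold coordinate of the gap center after walk[junction_idx]."""
        cid = self.walk[junction_idx][0]
        return self.offsets[cid] + self.contig_lengths[cid] + self.gap_length // 2


def lift_pair_spans(
    smap: ScaffoldMap, pairs: Iterable[HiCPair]
) -> np.ndarray:
    """Spanning intervals on scaffold coordinates for pairs whose two
    mates both fall inside this scaffold. Shape (n, 2)."""
    members = {cid for cid, _ in smap.walk}
    spans: List[Tuple[int, int]] = []
    for p in pairs:
        if p.end1.contig_id not in members or p.end2.contig_id not in members:
            continue
        s1, e1 = smap.lift_interval(p.end1.contig_id, p.end1.start, p.end1.end)
        s2, e2 = smap.lift_interval(p.end2.contig_id, p.end2.start, p.end2.end)
        spans.append((min(s1, s2), max(e1, e2)))
    if not spans:
        return np.empty((0, 2), dtype=np.int64)
    return np.array(spans, dtype=np.int64)


def scaffold_coverage(
    spans: np.ndarray, window_start: int, window_end: int
) -> np.ndarray:
    """Per-base physical coverage inside a scaffold window.

    Pairs whose span intersects the window contribute their clipped span.
    """
    n = window_end - window_start
    cov = np.zeros(n + 1, dtype=np.int64)
    if spans.size:
        s = np.clip(spans[:, 0] - window_start, 0, n)
        e = np.clip(spans[:, 1] - window_start, 0, n)
        keep = e > s
        np.add.at(cov, s[keep], 1)
        np.subtract.at(cov, e[keep], 1)
    return np.cumsum(cov)[:-1]


def max_sum_subarray(a: np.ndarray) -> Tuple[int, int, int]:
    """Maximum-sum subarray (Kadane via prefix sums), half-open [s, e).

    Ties resolve to the leftmost start, then the shortest subarray.
    """
    a = np.asarray(a)
    if a.size == 0:
        raise ValueError("array must be nonempty")
    prefix = np.concatenate(([0], np.cumsum(a)))
    running_min = np.minimum.accumulate(prefix)
    # first index attaining each running minimum
    idx = np.arange(len(prefix))
    is_new_min = np.concatenate(([True], prefix[1:] < running_min[:-1]))
    first_min_idx = np.maximum.accumulate(np.where(is_new_min, idx, -1))
    best_ending = prefix[1:] - running_min[:-1]
    best = best_ending.max()
    ends = np.flatnonzero(best_ending == best) + 1
    starts = first_min_idx[ends - 1]
    s = int(starts.min())
    e = int(ends[starts == s].min())
    return s, e, int(best)


@dataclass(frozen=True)
class JoinTest:
    """Outcome of testing one scaffold join."""

    walk_index: int
    junction_index: int
    position: int
    flagged: bool
    clique_region: Optional[Tuple[int, int]] = None
    low_confidence: bool = False


def test_join(
    coverage: np.ndarray, position: int, n_cutoffs: int = 10
) -> Tuple[bool, Optional[Tuple[int, int]]]:
    """Flag a join when it sits inside the consensus low-coverage region.

    ``position`` is relative to the coverage window. For each of
    ``n_cutoffs`` evenly spaced cutoffs spanning [min, max] coverage, the
    auxiliary array (+1 where coverage <= cutoff, −1 above) is reduced to
    its maximum-sum subarray; the maximal clique of those intervals is
    the consensus trough. Constant coverage carries no trough evidence
    and is never flagged.
    """
    if n_cutoffs < 2:
        raise ValueError("need at least two cutoffs")
    cov = np.asarray(coverage)
    if cov.size == 0:
        return False, None
    lo, hi = float(cov.min()), float(cov.max())
    if hi <= lo:
        return False, None
    intervals = []
    for delta in np.linspace(lo, hi, n_cutoffs):
        aux = np.where(cov <= delta, 1, -1)
        s, e, _ = max_sum_subarray(aux)
        if e > s:
            intervals.append((s, e))
    if not intervals:
        return False, None
    (s, e), _ = maximal_clique_interval(intervals)
    return (s <= position <= e), (s, e)


@dataclass
class Blacklist:
    """Edge keys banned from all future scaffold graphs; grows monotonically."""

    keys: Set[EdgeKey] = field(default_factory=set)

    def add(self, key: EdgeKey) -> None:
        self.keys.add(key)

    def __contains__(self, key: EdgeKey) -> bool:
        return key in self.keys

    def __len__(self) -> int:
        return len(self.keys)


def _split_walk(
    walk: Walk, joins: List, break_after: Sequence[int]
) -> Tuple[List[Walk], List[List]]:
    """Split a walk after the given junction indices (inverse of joining)."""
    cuts = sorted(set(break_after))
    walks, joinlists = [], []
    prev = 0
    for cut in cuts + [len(walk) - 1]:
        walks.append(walk[prev : cut + 1])
        joinlists.append(joins[prev:cut])
        prev = cut + 1
    return walks, joinlists


def correct_iteration(
    layout: Layout,
    pairs: Sequence[HiCPair],
    contig_lengths: Dict[str, int],
    blacklist: Optional[Blacklist] = None,
    window: int = 200_000,
    n_cutoffs: int = 10,
    gap_length: int = 500,
    new_edge_keys: Optional[Set[EdgeKey]] = None,
) -> Tuple[Layout, Blacklist, float, List[JoinTest]]:
    """Test this round's joins, break the flagged ones, blacklist edges.

    Only joins whose edge key appears in ``new_edge_keys`` are tested
    (all joins when None). Returns the corrected layout, the grown
    blacklist, the flagged fraction among tested joins (0 when none
    tested) and the per-join test records.
    """
    blacklist = blacklist or Blacklist()
    tests: List[JoinTest] = []
    tested = flagged_count = 0
    breaks: Dict[int, List[int]] = {}

    smaps: Dict[int, ScaffoldMap] = {}
    testable: Dict[int, List[int]] = {}
    for wi, walk in enumerate(layout.walks):
        if len(walk) < 2:
            continue
        junctions = []
        for ji in range(len(walk) - 1):
            edge = layout.joins[wi][ji] if layout.joins else None
            if new_edge_keys is not None and (
                edge is None or edge.key not in new_edge_keys
            ):
                continue
            junctions.append(ji)
        if junctions:
            smaps[wi] = ScaffoldMap(walk, contig_lengths, gap_length)
            testable[wi] = junctions

    # single pass lifting every pair onto whichever tested scaffold holds it
    info: Dict[str, Tuple[int, int, bool, int]] = {}
    for wi, smap in smaps.items():
        for cid, orient in smap.walk:
            info[cid] = (
                wi, smap.offsets[cid], orient == "+", contig_lengths[cid]
            )
    span_lists: Dict[int, List[Tuple[int, int]]] = {wi: [] for wi in smaps}
    for p in pairs:
        a = info.get(p.end1.contig_id)
        b = info.get(p.end2.contig_id)
        if a is None or b is None or a[0] != b[0]:
            continue
        wi, off1, fwd1, len1 = a
        _, off2, fwd2, len2 = b
        s1 = off1 + p.end1.start if fwd1 else off1 + len1 - p.end1.end
        e1 = off1 + p.end1.end if fwd1 else off1 + len1 - p.end1.start
        s2 = off2 + p.end2.start if fwd2 else off2 + len2 - p.end2.end
        e2 = off2 + p.end2.end if fwd2 else off2 + len2 - p.end2.start
        span_lists[wi].append((min(s1, s2), max(e1, e2)))

    for wi in sorted(testable):
        smap = smaps[wi]
        spans = (
            np.array(span_lists[wi], dtype=np.int64)
            if span_lists[wi]
            else np.empty((0, 2), dtype=np.int64)
        )
        for ji in testable[wi]:
            edge = layout.joins[wi][ji] if layout.joins else None
            p = smap.join_position(ji)
            ws = max(0, p - window // 2)
            we = min(smap.length, p + window // 2)
            low_conf = (we - ws) < window
            cov = scaffold_coverage(spans, ws, we)
            is_flagged, region = test_join(cov, p - ws, n_cutoffs)
            tests.append(
                JoinTest(wi, ji, p, is_flagged, region, low_confidence=low_conf)
            )
            tested += 1
            if is_flagged:
                flagged_count += 1
                breaks.setdefault(wi, []).append(ji)
                if edge is not None:
                    blacklist.add(edge.key)

    new_walks: List[Walk] = []
    new_joins: List[List] = []
    for wi, walk in enumerate(layout.walks):
        joins = layout.joins[wi] if layout.joins else [None] * (len(walk) - 1)
        if wi in breaks:
            ws, js = _split_walk(walk, joins, breaks[wi])
            new_walks.extend(ws)
            new_joins.extend(js)
        else:
            new_walks.append(walk)
            new_joins.append(joins)
    frac = flagged_count / tested if tested else 0.0
    return Layout(walks=new_walks, joins=new_joins), blacklist, frac, tests


def stopping_rule(frac_flagged: float, n_new_joins: int) -> bool:
    """Stop when a strict majority of the round's joins failed, or when
    the round made no joins at all; the penultimate round's corrected
    layout is then the final result."""
    return n_new_joins == 0 or frac_flagged > 0.5
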