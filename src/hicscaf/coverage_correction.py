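"""Misassembly detection and contig splitting from Hi-C physical coverage.

The physical coverage of a read pair is the whole region spanned from the
start of its leftmost mate to the end of its rightmost mate. A genuine
chimeric junction shows a trough in this signal because no pairs span it.
Detection sweeps a ladder of coverage thresholds, keeps the longest low
stretch per threshold, and calls a misassembly where most thresholds
agree — the maximal clique of the suspicious-interval graph. The contig is
then split into the piece left of the clique's smallest interval, the
junction region itself, and the piece to the right.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from hicscaf.io_formats import Contig, HiCPair, ReadEnd, count_cut_sites


@dataclass
class PhysicalCoverageProfile:
    """Binned physical coverage along one contig.

    ``cov[b]`` is the mean per-base spanning-pair depth within bin ``b``
    (exact integer depth when ``bin_size == 1``).
    """

    contig_id: str
    cov: np.ndarray
    bin_size: int
    contig_length: int


@dataclass(frozen=True)
class SuspiciousInterval:
    """Longest low-coverage stretch for one threshold (base coordinates)."""

    start: int
    end: int
    threshold: float


@dataclass(frozen=True)
class BreakRegion:
    """Called misassembly region: the smallest interval of the clique."""

    contig_id: str
    start: int
    end: int
    clique_size: int = 0


def physical_coverage_from_spans(
    starts: np.ndarray, ends: np.ndarray, contig_length: int, bin_size: int = 1000
) -> np.ndarray:
    """Accumulate spans [s, e) into a binned coverage array.

    Partial bin overlap contributes fractionally, so
    ``cov.sum() * bin_size == total span length`` exactly (up to float
    rounding).
    """
    n_bins = (contig_length + bin_size - 1) // bin_size
    cov = np.zeros(n_bins + 1)
    starts = np.asarray(starts, dtype=np.int64)
    ends = np.asarray(ends, dtype=np.int64)
    if starts.size:
        if starts.min() < 0 or ends.max() > contig_length or (starts >= ends).any():
            raise ValueError("span outside contig or empty")
        b0 = starts // bin_size
        b1 = (ends - 1) // bin_size
        np.add.at(cov, b0, 1.0)
        np.subtract.at(cov, b1 + 1, 1.0)
        cov = np.cumsum(cov)[:-1]
        # trim partial overlap at span edges
        np.subtract.at(cov, b0, (starts - b0 * bin_size) / bin_size)
        np.subtract.at(cov, b1, ((b1 + 1) * bin_size - ends) / bin_size)
    else:
        cov = cov[:-1]
    return cov


def physical_coverage(
    pairs: Iterable[HiCPair], contig_length: int, bin_size: int = 1000,
    contig_id: Optional[str] = None,
) -> PhysicalCoverageProfile:
    """Physical coverage of intra-contig pairs on one contig."""
    starts, ends = [], []
    cid = contig_id
    for p in pairs:
        if not p.intra:
            raise ValueError(f"pair {p.read_id!r} is not intra-contig")
        if cid is None:
            cid = p.end1.contig_id
        elif p.end1.contig_id != cid:
            raise ValueError(
                f"pair {p.read_id!r} is on {p.end1.contig_id!r}, expected {cid!r}"
            )
        starts.append(min(p.end1.start, p.end2.start))
        ends.append(max(p.end1.end, p.end2.end))
    cov = physical_coverage_from_spans(
        np.array(starts, dtype=np.int64),
        np.array(ends, dtype=np.int64),
        contig_length,
        bin_size,
    )
    return PhysicalCoverageProfile(cid or "", cov, bin_size, contig_length)


def _low_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) bin runs where mask is True."""
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    diff = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def sweep_suspicious_intervals(
    profile: PhysicalCoverageProfile,
    thresholds: Sequence[float],
    ignore_end_bins: bool = True,
) -> list[SuspiciousInterval]:
    """For each threshold, the longest run of bins with coverage below it.

    Runs touching the first or last bin are discarded when
    ``ignore_end_bins`` — contig ends naturally lack spanning pairs and
    would otherwise always look suspicious. Ties on run length go to the
    leftmost run. Thresholds producing no run contribute nothing.
    """
    if len(thresholds) == 0:
        raise ValueError("thresholds must be non-empty")
    cov = profile.cov
    n = len(cov)
    out: list[SuspiciousInterval] = []
    for delta in thresholds:
        runs = _low_runs(cov < delta)
        if ignore_end_bins:
            runs = [r for r in runs if r[0] > 0 and r[1] < n]
        if not runs:
            continue
        start, end = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
        out.append(
            SuspiciousInterval(
                start=start * profile.bin_size,
                end=min(end * profile.bin_size, profile.contig_length),
                threshold=float(delta),
            )
        )
    return out


def maximal_clique_interval(
    intervals: Sequence,
) -> tuple[tuple[int, int], int]:
    """Maximum-overlap point of an interval set, via an endpoint sweep.

    Intervals pairwise intersecting form a clique of the interval graph;
    by Helly's property on intervals the maximum clique is realized at a
    single point, found in O(N log N). Returns the smallest interval
    (shortest, then lowest start) among those covering the leftmost
    maximum-depth point, and the depth.
    """
    if len(intervals) == 0:
        raise ValueError("need at least one interval")
    spans = [(int(iv.start), int(iv.end)) for iv in intervals] if hasattr(
        intervals[0], "start"
    ) else [(int(s), int(e)) for s, e in intervals]
    events = []
    for s, e in spans:
        events.append((s, 1))
        events.append((e, -1))
    events.sort()  # ends sort before starts at equal coords (half-open)
    depth = best_depth = 0
    best_point = spans[0][0]
    for coord, delta in events:
        depth += delta
        if depth > best_depth:
            best_depth = depth
            best_point = coord
    covering = [(e - s, s, e) for s, e in spans if s <= best_point < e]
    _, s, e = min(covering)
    return (s, e), best_depth


def detect_misassembly(
    profile: PhysicalCoverageProfile,
    n_thresholds: int = 10,
    min_clique_frac: float = 0.5,
) -> Optional[BreakRegion]:
    """Call at most one misassembly region on a contig.

    Thresholds are ``n_thresholds`` evenly spaced values over
    (min nonzero coverage, max coverage]. A break is reported only when
    the clique depth reaches ``min_clique_frac`` of all tested cutoffs —
    low coverage for the majority of them. A genuine junction trough sits
    below most cutoffs; ordinary coverage noise yields intervals for only
    the one or two lowest.
    """
    cov = profile.cov
    if len(cov) < 2:
        return None
    nonzero = cov[cov > 0]
    if nonzero.size == 0:
        return None
    lo, hi = float(nonzero.min()), float(cov.max())
    if hi <= lo:
        return None
    thresholds = lo + (hi - lo) * np.arange(1, n_thresholds + 1) / n_thresholds
    intervals = sweep_suspicious_intervals(profile, thresholds)
    if not intervals:
        return None
    (s, e), depth = maximal_clique_interval(intervals)
    if depth < min_clique_frac * n_thresholds:
        return None
    return BreakRegion(profile.contig_id, s, e, clique_size=depth)


def _remap_end(end: ReadEnd, pieces: list[tuple[str, int, int]]) -> Optional[ReadEnd]:
    """Shift one mate onto the piece fully containing it; None if straddling."""
    for piece_id, lo, hi in pieces:
        if lo <= end.start and end.end <= hi:
            return ReadEnd(piece_id, end.start - lo, end.end - lo, end.strand)
    return None


def break_contig(
    contig: Contig,
    region: BreakRegion,
    pairs: Iterable[HiCPair] = (),
) -> tuple[list[Contig], list[HiCPair]]:
    """Split a contig at a break region into (up to) three pieces.

    Pieces are left of the region, the junction region itself, and right
    of it; a region touching a contig boundary yields two pieces. Mates
    are shifted onto their piece; any pair with a mate straddling a cut
    is dropped, and pairs whose mates land on different pieces become
    inter-contig pairs. Cut sites are recomputed from sequence when
    present, else apportioned by length.
    """
    s, e = region.start, region.end
    if not (0 <= s < e <= contig.length):
        raise ValueError("break region outside contig")
    bounds = [b for b in (0, s, e, contig.length) if 0 <= b <= contig.length]
    bounds = sorted(set(bounds))
    pieces: list[tuple[str, int, int]] = []
    contigs: list[Contig] = []
    for idx, (lo, hi) in enumerate(zip(bounds[:-1], bounds[1:]), start=1):
        piece_id = f"{contig.id}.{idx}"
        seq = contig.sequence[lo:hi] if contig.sequence is not None else None
        if seq is not None:
            cut = count_cut_sites(seq)
        else:
            cut = round(contig.cut_sites * (hi - lo) / contig.length)
        contigs.append(Contig(id=piece_id, length=hi - lo, sequence=seq, cut_sites=cut))
        pieces.append((piece_id, lo, hi))
    remapped: list[HiCPair] = []
    for p in pairs:
        new1 = _remap_end(p.end1, pieces) if p.end1.contig_id == contig.id else p.end1
        new2 = _remap_end(p.end2, pieces) if p.end2.contig_id == contig.id else p.end2
        if new1 is None or new2 is None:
            continue
        remapped.append(HiCPair(p.read_id, new1, new2, p.mapq))
    return contigs, remapped


def correct_assembly(
    contigs: Sequence[Contig],
    pairs: Sequence[HiCPair],
    rounds: int = 1,
    bin_size: int = 1000,
    n_thresholds: int = 10,
    min_clique_frac: float = 0.5,
) -> tuple[list[Contig], list[HiCPair], list[BreakRegion]]:
    """Iteratively detect and split misassembled contigs.

    One break per contig per round; up to ``rounds`` passes. Returns the
    corrected contig set, the remapped pair set and all break regions
    (on the coordinates of the contig as it existed when broken). The
    coordinate map back to the original assembly is available through
    :func:`coordinate_map`.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    current = list(contigs)
    current_pairs = list(pairs)
    all_breaks: list[BreakRegion] = []
    origin: dict[str, tuple[str, int]] = {c.id: (c.id, 0) for c in contigs}
    for _ in range(rounds):
        intra: dict[str, list[HiCPair]] = {}
        for p in current_pairs:
            if p.intra:
                intra.setdefault(p.end1.contig_id, []).append(p)
        broke_any = False
        next_contigs: list[Contig] = []
        replacements: dict[str, list[Contig]] = {}
        regions: dict[str, BreakRegion] = {}
        for contig in current:
            contig_pairs = intra.get(contig.id, [])
            profile = physical_coverage(
                contig_pairs, contig.length, bin_size, contig_id=contig.id
            )
            region = detect_misassembly(profile, n_thresholds, min_clique_frac)
            if region is None or region.end - region.start >= contig.length:
                next_contigs.append(contig)
                continue
            pieces, _ = break_contig(contig, region)
            replacements[contig.id] = pieces
            regions[contig.id] = region
            next_contigs.extend(pieces)
            all_breaks.append(region)
            broke_any = True
            orig_id, orig_off = origin.pop(contig.id)
            lo = 0
            for piece in pieces:
                origin[piece.id] = (orig_id, orig_off + lo)
                lo += piece.length
        if not broke_any:
            break
        # remap every pair through all breaks of this round
        piece_map = {
            cid: [
                (piece.id, lo, lo + piece.length)
                for piece, lo in zip(
                    pieces,
                    np.concatenate(
                        ([0], np.cumsum([pc.length for pc in pieces[:-1]]))
                    ).astype(int).tolist(),
                )
            ]
            for cid, pieces in replacements.items()
        }
        new_pairs: list[HiCPair] = []
        for p in current_pairs:
            e1, e2 = p.end1, p.end2
            if e1.contig_id in piece_map:
                e1 = _remap_end(e1, piece_map[e1.contig_id])
            if e2 is not None and e2.contig_id in piece_map:
                e2 = _remap_end(e2, piece_map[e2.contig_id])
            if e1 is None or e2 is None:
                continue
            new_pairs.append(HiCPair(p.read_id, e1, e2, p.mapq))
        current = next_contigs
        current_pairs = new_pairs
    final_lengths = {c.id: c.length for c in current}
    coord_map = sorted(
        (cid, orig, off, off + final_lengths[cid])
        for cid, (orig, off) in origin.items()
        if cid != orig
    )
    return current, current_pairs, all_breaks, coord_map


def write_coordinate_map(coord_map, path) -> None:
    """TSV mapping corrected pieces back to original contig intervals."""
    with open(path, "w") as fh:
        fh.write("new_contig\told_contig\told_start\told_end\n")
        for new_id, old_id, start, end in coord_map:
            fh.write(f"{new_id}\t{old_id}\t{start}\t{end}\n")
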