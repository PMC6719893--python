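"""Scaffold accuracy metrics against a truth layout.

Three error classes: orientation (a contig's strand disagrees with its
scaffold's consensus direction relative to the truth), ordering (three
adjacent contigs with non-monotonic truth coordinates) and chimera (two
adjacent contigs from different truth chromosomes). Scaffolds broken at
every error yield corrected block lengths, the NGA50 statistic, and the
feature response curve (cumulative assembly size vs cumulative error %,
largest scaffolds first).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

from hicscaf.layout import Layout

TruthRecord = Tuple[str, int, int, str]  # chrom, start, end, strand


@dataclass
class ScaffoldErrors:
    orientation: int = 0
    ordering: int = 0
    chimera: int = 0
    error_junctions: set = field(default_factory=set)

    @property
    def total(self) -> int:
        return self.orientation + self.ordering + self.chimera


@dataclass
class ErrorReport:
    orientation_errors: int
    ordering_errors: int
    chimera_errors: int
    per_scaffold: List[ScaffoldErrors]

    @property
    def total(self) -> int:
        return self.orientation_errors + self.ordering_errors + self.chimera_errors


def _walk_truth(walk, truth: Dict[str, TruthRecord]):
    known = []
    for cid, orient in walk:
        rec = truth.get(cid)
        if rec is None:
            warnings.warn(f"contig {cid!r} has no truth record; excluded")
            continue
        known.append((cid, orient, rec))
    return known


def classify_errors(layout: Layout, truth: Dict[str, TruthRecord]) -> ErrorReport:
    """Count orientation, ordering and chimera errors per scaffold.

    Orientation uses the scaffold's consensus direction (majority of
    per-contig agreement between scaffold strand and truth strand; ties
    go to the first contig), so reversing a whole scaffold changes
    nothing. Ordering counts each non-monotonic same-chromosome triple
    once; chimera counts each cross-chromosome adjacency once.
    """
    per_scaffold: List[ScaffoldErrors] = []
    for walk in layout.walks:
        errs = ScaffoldErrors()
        items = _walk_truth(walk, truth)
        if items:
            dirs = [1 if orient == rec[3] else -1 for _, orient, rec in items]
            consensus = 1 if sum(dirs) > 0 else -1 if sum(dirs) < 0 else dirs[0]
            for i, d in enumerate(dirs):
                if d != consensus:
                    errs.orientation += 1
                    errs.error_junctions.update({i - 1, i})
            for i in range(len(items) - 1):
                if items[i][2][0] != items[i + 1][2][0]:
                    errs.chimera += 1
                    errs.error_junctions.add(i)
            for i in range(len(items) - 2):
                recs = [items[i + k][2] for k in range(3)]
                if len({r[0] for r in recs}) != 1:
                    continue
                mids = [(r[1] + r[2]) / 2 for r in recs]
                if not (mids[0] <= mids[1] <= mids[2]
                        or mids[0] >= mids[1] >= mids[2]):
                    errs.ordering += 1
                    errs.error_junctions.add(i + 1)
        errs.error_junctions = {
            j for j in errs.error_junctions if 0 <= j < len(items) - 1
        }
        per_scaffold.append(errs)
    return ErrorReport(
        orientation_errors=sum(e.orientation for e in per_scaffold),
        ordering_errors=sum(e.ordering for e in per_scaffold),
        chimera_errors=sum(e.chimera for e in per_scaffold),
        per_scaffold=per_scaffold,
    )


def scaffold_lengths(
    layout: Layout, contig_lengths: Dict[str, int], gap_length: int = 0
) -> List[int]:
    return [
        sum(contig_lengths[cid] for cid, _ in walk) + gap_length * (len(walk) - 1)
        for walk in layout.walks
    ]


def corrected_blocks(
    layout: Layout,
    truth: Dict[str, TruthRecord],
    contig_lengths: Dict[str, int],
    gap_length: int = 0,
    report: ErrorReport = None,
) -> List[int]:
    """Error-free block lengths: walks split at every error junction."""
    if report is None:
        report = classify_errors(layout, truth)
    blocks: List[int] = []
    for walk, errs in zip(layout.walks, report.per_scaffold):
        items = [cid for cid, _ in walk if cid in truth]
        prev = 0
        cuts = sorted(errs.error_junctions) + [len(items) - 1]
        for cut in cuts:
            chunk = items[prev : cut + 1]
            if chunk:
                blocks.append(
                    sum(contig_lengths[c] for c in chunk)
                    + gap_length * (len(chunk) - 1)
                )
            prev = cut + 1
    return blocks


def ng50(lengths: Sequence[int], genome_size: int) -> int:
    """Largest L such that sequences of length >= L cover half the genome."""
    if genome_size <= 0:
        raise ValueError("genome_size must be > 0")
    acc = 0
    for length in sorted(lengths, reverse=True):
        acc += length
        if acc >= genome_size / 2:
            return length
    return 0


def nga50(blocks: Sequence[int], genome_size: int) -> int:
    """NG50 of the error-corrected blocks."""
    return ng50(blocks, genome_size)


def frc(
    layout: Layout,
    truth: Dict[str, TruthRecord],
    contig_lengths: Dict[str, int],
    gap_length: int = 0,
    report: ErrorReport = None,
) -> List[Tuple[float, int]]:
    """Feature response curve: scan scaffolds largest-first, plotting
    cumulative error percentage against cumulative assembly size."""
    if report is None:
        report = classify_errors(layout, truth)
    lengths = scaffold_lengths(layout, contig_lengths, gap_length)
    order = sorted(
        range(len(lengths)), key=lambda i: (-lengths[i], layout.scaffold_name(i))
    )
    total_err = report.total
    total_size = sum(lengths)
    points: List[Tuple[float, int]] = []
    cum_err = cum_size = 0
    for i in order:
        cum_err += report.per_scaffold[i].total
        cum_size += lengths[i]
        x = 100.0 * cum_err / total_err if total_err else 0.0
        points.append((x, cum_size))
    if total_err == 0 and points:
        points.append((100.0, total_size))
    return points
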