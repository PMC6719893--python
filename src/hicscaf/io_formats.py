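"""Readers and writers for the external formats the scaffolder touches.

Formats: contig FASTA, GFA v1 assembly graphs (S/L lines), a 10-column
BEDPE dialect for pre-aligned Hi-C read pairs, AGP v2.0 scaffold layouts
and BED3+label breakpoint reports.

Coordinate conventions: everything internal is 0-based half-open; AGP
output is converted to the standard 1-based inclusive coordinates.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, NamedTuple, Optional, Sequence

from Bio import SeqIO
from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

DEFAULT_ENZYME_MOTIFS = ("GATC", "GANTC")
"""Arima two-enzyme chemistry: DpnII (GATC) and HinfI-family (GANTC) sites."""


class FormatError(ValueError):
    """Malformed input file."""


@dataclass
class Contig:
    """A sequence unit of the input assembly.

    ``cut_sites`` is C(V), the number of restriction-enzyme cut sites on
    the contig, used to normalize Hi-C contact counts.
    """

    id: str
    length: int
    sequence: Optional[str] = None
    cut_sites: int = 0

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"contig {self.id!r}: length must be > 0")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"contig {self.id!r}: length {self.length} != sequence "
                f"length {len(self.sequence)}"
            )
        if self.cut_sites < 0:
            raise ValueError(f"contig {self.id!r}: cut_sites must be >= 0")


class ReadEnd(NamedTuple):
    """One mate's mapped interval on a contig (0-based half-open)."""

    contig_id: str
    start: int
    end: int
    strand: str = "+"


@dataclass(frozen=True)
class HiCPair:
    """One Hi-C read pair: two mapped intervals, optionally with MAPQ."""

    read_id: str
    end1: ReadEnd
    end2: ReadEnd
    mapq: Optional[int] = None

    @property
    def intra(self) -> bool:
        """True when both mates map to the same contig."""
        return self.end1.contig_id == self.end2.contig_id


@dataclass
class AgpRecord:
    """One AGP v2.0 line: an oriented contig component or a gap."""

    scaffold_id: str
    scaffold_start: int  # 1-based inclusive
    scaffold_end: int
    part_number: int
    component_type: str  # "W" for contig, "N" for gap
    component_id: Optional[str] = None
    component_start: Optional[int] = None
    component_end: Optional[int] = None
    orientation: Optional[str] = None
    gap_length: Optional[int] = None


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> list[Contig]:
    """Read contigs from FASTA; ``cut_sites`` is left unset (0)."""
    contigs: list[Contig] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {record.id!r}")
        seen.add(record.id)
        seq = str(record.seq).upper()
        if not seq:
            raise FormatError(f"{path}: empty sequence for {record.id!r}")
        contigs.append(Contig(id=record.id, length=len(seq), sequence=seq))
    return contigs


def write_fasta(contigs: Iterable[Contig], path) -> None:
    with open(path, "w") as fh:
        for contig in contigs:
            if contig.sequence is None:
                raise ValueError(f"contig {contig.id!r} carries no sequence")
            fh.write(f">{contig.id}\n")
            for i in range(0, contig.length, 80):
                fh.write(contig.sequence[i : i + 80] + "\n")


# ---------------------------------------------------------------------------
# Restriction cut sites

_IUPAC_ALLOWED = set(ambiguous_dna_values)


def _motif_to_regex(motif: str) -> str:
    parts = []
    for base in motif.upper():
        if base not in _IUPAC_ALLOWED:
            raise ValueError(f"non-IUPAC character {base!r} in motif {motif!r}")
        expansion = ambiguous_dna_values[base]
        parts.append(base if len(expansion) == 1 else f"[{expansion}]")
    return "".join(parts)


def count_cut_sites(
    sequence: str, motifs: Sequence[str] = DEFAULT_ENZYME_MOTIFS
) -> int:
    """Count forward-strand occurrences of restriction motifs.

    Occurrences may overlap, and multiple motifs are summed. IUPAC
    ambiguity codes in the motif (e.g. the N in GANTC) match any base
    they denote. Both default motifs are reverse-complement palindromes,
    so forward-strand counting loses nothing.
    """
    seq = sequence.upper()
    total = 0
    for motif in motifs:
        # lookahead so overlapping occurrences are all counted
        total += len(re.findall(f"(?={_motif_to_regex(motif)})", seq))
    return total


def annotate_cut_sites(
    contigs: Iterable[Contig], motifs: Sequence[str] = DEFAULT_ENZYME_MOTIFS
) -> None:
    """Set ``cut_sites`` in place for every contig that has a sequence."""
    for contig in contigs:
        if contig.sequence is not None:
            contig.cut_sites = count_cut_sites(contig.sequence, motifs)


# ---------------------------------------------------------------------------
# BEDPE Hi-C pairs

def read_bedpe_pairs(
    path,
    contigs: Optional[Sequence[Contig]] = None,
    min_mapq: int = 10,
    strict: bool = True,
) -> Iterator[HiCPair]:
    """Stream Hi-C pairs from a whitespace-delimited BEDPE dialect.

    Columns: chrom1 start1 end1 chrom2 start2 end2 name [mapq strand1
    strand2]. When ``contigs`` is given, pairs touching unknown contigs
    or out-of-bounds coordinates are skipped with a warning. Pairs with
    mapq below ``min_mapq`` (when the column is present) are dropped.
    In non-strict mode malformed lines warn and are skipped instead of
    raising.
    """
    lengths = {c.id: c.length for c in contigs} if contigs is not None else None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            try:
                if len(fields) < 7:
                    raise FormatError(
                        f"{path}:{lineno}: expected >= 7 columns, got {len(fields)}"
                    )
                try:
                    s1, e1 = int(fields[1]), int(fields[2])
                    s2, e2 = int(fields[4]), int(fields[5])
                except ValueError as exc:
                    raise FormatError(
                        f"{path}:{lineno}: non-integer coordinate"
                    ) from exc
                mapq = None
                if len(fields) >= 8:
                    try:
                        mapq = int(fields[7])
                    except ValueError as exc:
                        raise FormatError(
                            f"{path}:{lineno}: non-integer mapq"
                        ) from exc
                strand1 = fields[8] if len(fields) >= 9 else "+"
                strand2 = fields[9] if len(fields) >= 10 else "+"
                if s1 < 0 or s1 >= e1 or s2 < 0 or s2 >= e2:
                    raise FormatError(
                        f"{path}:{lineno}: invalid interval coordinates"
                    )
            except FormatError as exc:
                if strict:
                    raise
                warnings.warn(str(exc))
                continue
            if mapq is not None and mapq < min_mapq:
                continue
            if lengths is not None:
                skip = False
                for cid, end in ((fields[0], e1), (fields[3], e2)):
                    if cid not in lengths:
                        warnings.warn(
                            f"{path}:{lineno}: unknown contig {cid!r}, skipped"
                        )
                        skip = True
                    elif end > lengths[cid]:
                        warnings.warn(
                            f"{path}:{lineno}: interval exceeds contig "
                            f"{cid!r} length, skipped"
                        )
                        skip = True
                if skip:
                    continue
            yield HiCPair(
                read_id=fields[6],
                end1=ReadEnd(fields[0], s1, e1, strand1),
                end2=ReadEnd(fields[3], s2, e2, strand2),
                mapq=mapq,
            )


def write_bedpe_pairs(pairs: Iterable[HiCPair], path) -> None:
    with open(path, "w") as fh:
        for p in pairs:
            mapq = p.mapq if p.mapq is not None else 60
            fh.write(
                f"{p.end1.contig_id}\t{p.end1.start}\t{p.end1.end}\t"
                f"{p.end2.contig_id}\t{p.end2.start}\t{p.end2.end}\t"
                f"{p.read_id}\t{mapq}\t{p.end1.strand}\t{p.end2.strand}\n"
            )


# ---------------------------------------------------------------------------
# GFA v1

def parse_gfa(path):
    """Parse a GFA v1 file (S and L lines) into an :class:`AssemblyGraph`.

    Segment length comes from the sequence field or, when the sequence is
    ``*``, from the LN tag. Link overlap CIGARs are ignored; the two
    recordings of the same bidirected link canonicalize to one edge.
    """
    from hicscaf.graph_prior import AssemblyGraph

    segments: dict[str, int] = {}
    links: list[tuple[str, str, str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line[0] not in "SL":
                continue
            fields = line.split("\t")
            if fields[0] == "S":
                if len(fields) < 3:
                    raise FormatError(f"{path}:{lineno}: malformed S line")
                name, seq = fields[1], fields[2]
                length = None
                if seq != "*":
                    length = len(seq)
                else:
                    for tag in fields[3:]:
                        if tag.startswith("LN:i:"):
                            length = int(tag[5:])
                if length is None:
                    raise FormatError(
                        f"{path}:{lineno}: segment {name!r} has no sequence "
                        "and no LN tag"
                    )
                segments[name] = length
            elif fields[0] == "L":
                if len(fields) < 5:
                    raise FormatError(f"{path}:{lineno}: malformed L line")
                a, oa, b, ob = fields[1], fields[2], fields[3], fields[4]
                if oa not in "+-" or ob not in "+-":
                    raise FormatError(f"{path}:{lineno}: bad link orientation")
                links.append((a, oa, b, ob))
    graph = AssemblyGraph(segments)
    for a, oa, b, ob in links:
        if a not in segments or b not in segments:
            missing = a if a not in segments else b
            raise FormatError(f"{path}: link references unknown segment {missing!r}")
        graph.add_link(a, oa, b, ob)
    return graph


def write_gfa(segments: dict[str, int], links, path) -> None:
    """Write a minimal GFA v1 file (sequence-less S lines with LN tags)."""
    with open(path, "w") as fh:
        fh.write("H\tVN:Z:1.0\n")
        for name in segments:
            fh.write(f"S\t{name}\t*\tLN:i:{segments[name]}\n")
        for a, oa, b, ob in links:
            fh.write(f"L\t{a}\t{oa}\t{b}\t{ob}\t0M\n")


# ---------------------------------------------------------------------------
# AGP + scaffold FASTA

def _iter_agp_records(layout, contigs_by_id, gap_length: int):
    for walk_idx, walk in enumerate(layout.walks):
        scaffold_id = layout.scaffold_name(walk_idx)
        pos = 0  # 0-based running coordinate
        part = 0
        for i, (cid, orient) in enumerate(walk):
            if cid not in contigs_by_id:
                raise ValueError(f"layout references unknown contig {cid!r}")
            length = contigs_by_id[cid].length
            if i > 0:
                part += 1
                yield AgpRecord(
                    scaffold_id, pos + 1, pos + gap_length, part, "N",
                    gap_length=gap_length,
                )
                pos += gap_length
            part += 1
            yield AgpRecord(
                scaffold_id, pos + 1, pos + length, part, "W",
                component_id=cid, component_start=1, component_end=length,
                orientation=orient,
            )
            pos += length


def write_agp(layout, contigs: Sequence[Contig], path, gap_length: int = 500) -> None:
    """Write a layout as AGP v2.0 (1-based inclusive coordinates)."""
    contigs_by_id = {c.id: c for c in contigs}
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.0\n")
        for r in _iter_agp_records(layout, contigs_by_id, gap_length):
            if r.component_type == "W":
                fh.write(
                    f"{r.scaffold_id}\t{r.scaffold_start}\t{r.scaffold_end}\t"
                    f"{r.part_number}\tW\t{r.component_id}\t{r.component_start}\t"
                    f"{r.component_end}\t{r.orientation}\n"
                )
            else:
                fh.write(
                    f"{r.scaffold_id}\t{r.scaffold_start}\t{r.scaffold_end}\t"
                    f"{r.part_number}\tN\t{r.gap_length}\tscaffold\tyes\tproximity_ligation\n"
                )


def read_agp(path):
    """Parse an AGP file written by :func:`write_agp` back into a Layout."""
    from hicscaf.layout import Layout

    walks: dict[str, list[tuple[str, str]]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: malformed AGP line")
            scaffold_id, ctype = fields[0], fields[4]
            if scaffold_id not in walks:
                walks[scaffold_id] = []
                order.append(scaffold_id)
            if ctype == "W":
                walks[scaffold_id].append((fields[5], fields[8]))
    return Layout(walks=[walks[s] for s in order], names=order)


def write_scaffold_fasta(
    layout, contigs: Sequence[Contig], path, gap_length: int = 500
) -> None:
    """Emit scaffold sequences; gaps are runs of N, '-' components are
    reverse-complemented."""
    contigs_by_id = {c.id: c for c in contigs}
    with open(path, "w") as fh:
        for walk_idx, walk in enumerate(layout.walks):
            parts: list[str] = []
            for cid, orient in walk:
                contig = contigs_by_id.get(cid)
                if contig is None:
                    raise ValueError(f"layout references unknown contig {cid!r}")
                if contig.sequence is None:
                    raise ValueError(f"contig {cid!r} carries no sequence")
                seq = contig.sequence
                if orient == "-":
                    seq = str(Seq(seq).reverse_complement())
                parts.append(seq)
            scaffold = ("N" * gap_length).join(parts)
            fh.write(f">{layout.scaffold_name(walk_idx)}\n")
            for i in range(0, len(scaffold), 80):
                fh.write(scaffold[i : i + 80] + "\n")


def write_breakpoints_bed(breaks, path) -> None:
    """Write break regions as BED3+label (contig, start, end, label)."""
    with open(path, "w") as fh:
        for contig_id, start, end, label in breaks:
            fh.write(f"{contig_id}\t{start}\t{end}\t{label}\n")
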