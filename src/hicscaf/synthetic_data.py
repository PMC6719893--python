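"""Synthetic genomes, assemblies and Hi-C libraries with full truth tracking.

The generator mirrors the benchmark design the scaffolder is meant for:
a random genome is sliced into fixed-size contigs, the assembly graph is
linear (edges between genome-adjacent contigs only), and Hi-C pairs are
drawn with a power-law distance decay (contact probability ∝ s^-alpha,
alpha = 1 by default). Misassemblies are injected by concatenating
distant contig pairs, and erroneous scaffolds chain contigs that violate
genome adjacency; every junction carries a truth label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from hicscaf.graph_prior import AssemblyGraph
from hicscaf.io_formats import Contig, HiCPair, ReadEnd, count_cut_sites
from hicscaf.layout import Layout, Walk

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class TruthSegment:
    """One genome interval inside a contig (chimeras carry two)."""

    chrom: str
    genome_start: int
    genome_end: int
    contig_offset: int
    orient: str = "+"


@dataclass
class TruthSet:
    """contig -> genome mapping; segments tile each chromosome exactly."""

    chrom_lengths: Dict[str, int]
    segments: Dict[str, List[TruthSegment]] = field(default_factory=dict)

    def add(self, contig_id: str, seg: TruthSegment) -> None:
        self.segments.setdefault(contig_id, []).append(seg)

    def contig_length(self, contig_id: str) -> int:
        return sum(s.genome_end - s.genome_start for s in self.segments[contig_id])

    def single_record(self, contig_id: str) -> TruthSegment:
        segs = self.segments[contig_id]
        if len(segs) != 1:
            raise ValueError(f"contig {contig_id!r} is chimeric in truth")
        return segs[0]

    def evaluation_records(self) -> Dict[str, Tuple[str, int, int, str]]:
        """(chrom, start, end, orient) per single-segment contig."""
        out = {}
        for cid, segs in self.segments.items():
            if len(segs) == 1:
                s = segs[0]
                out[cid] = (s.chrom, s.genome_start, s.genome_end, s.orient)
        return out

    def genome_index(self) -> Dict[str, Tuple[np.ndarray, np.ndarray, list]]:
        """Per chromosome: sorted segment starts, ends and (cid, seg) list."""
        per_chrom: Dict[str, list] = {c: [] for c in self.chrom_lengths}
        for cid, segs in self.segments.items():
            for seg in segs:
                per_chrom[seg.chrom].append((seg.genome_start, seg.genome_end, cid, seg))
        index = {}
        for chrom, items in per_chrom.items():
            items.sort()
            starts = np.array([i[0] for i in items], dtype=np.int64)
            ends = np.array([i[1] for i in items], dtype=np.int64)
            index[chrom] = (starts, ends, [(i[2], i[3]) for i in items])
        return index

    def map_locus(
        self,
        index,
        chrom: str,
        gpos: int,
        read_len: int,
    ) -> Tuple[str, int, int]:
        """Genome position -> (contig, start, end), clipped at segment edge."""
        starts, ends, items = index[chrom]
        i = int(np.searchsorted(starts, gpos, side="right")) - 1
        if i < 0 or gpos >= ends[i]:
            raise ValueError(f"position {chrom}:{gpos} not covered by truth")
        cid, seg = items[i]
        gend = min(gpos + read_len, seg.genome_end)
        if seg.orient == "+":
            s = seg.contig_offset + (gpos - seg.genome_start)
            return cid, s, s + (gend - gpos)
        e = seg.contig_offset + (seg.genome_end - gpos)
        return cid, e - (gend - gpos), e

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("contig\tchrom\tstart\tend\tstrand\tcontig_offset\n")
            for cid in sorted(self.segments):
                for s in self.segments[cid]:
                    fh.write(
                        f"{cid}\t{s.chrom}\t{s.genome_start}\t{s.genome_end}\t"
                        f"{s.orient}\t{s.contig_offset}\n"
                    )


def make_genome(
    n_chrom: int = 2, chrom_length: int = 2_000_000, seed: int = 0
) -> Dict[str, str]:
    """i.i.d. uniform-ACGT chromosomes, deterministic per seed."""
    rng = np.random.default_rng(seed)
    genome = {}
    for i in range(n_chrom):
        draws = rng.integers(0, 4, size=chrom_length)
        genome[f"chr{i + 1}"] = _BASES[draws].tobytes().decode("ascii")
    return genome


def fragment(
    genome: Dict[str, str], contig_size: int = 40_000
) -> Tuple[List[Contig], TruthSet, AssemblyGraph]:
    """Slice each chromosome into fixed-size contigs and build the
    linear assembly graph (links between genome-adjacent slices only)."""
    truth = TruthSet(chrom_lengths={c: len(s) for c, s in genome.items()})
    contigs: List[Contig] = []
    graph = AssemblyGraph()
    for chrom in genome:
        seq = genome[chrom]
        n = len(seq)
        if contig_size >= n:
            raise ValueError("contig_size must be smaller than the chromosome")
        prev: Optional[str] = None
        for k, start in enumerate(range(0, n, contig_size)):
            end = min(start + contig_size, n)
            if end - start == 0:
                continue
            cid = f"{chrom}_c{k + 1}"
            sub = seq[start:end]
            contigs.append(
                Contig(id=cid, length=end - start, sequence=sub,
                       cut_sites=count_cut_sites(sub))
            )
            truth.add(cid, TruthSegment(chrom, start, end, 0))
            graph.add_segment(cid, end - start)
            if prev is not None:
                graph.add_link(prev, "+", cid, "+")
            prev = cid
    return contigs, truth, graph


def _sample_separations(
    rng: np.random.Generator, n: int, s_min: float, s_max: float, alpha: float
) -> np.ndarray:
    """Inverse-CDF draws from p(s) ∝ s^-alpha on [s_min, s_max]."""
    if alpha <= 0:
        raise ValueError("decay_alpha must be > 0")
    u = rng.random(n)
    if abs(alpha - 1.0) < 1e-12:
        s = s_min * (s_max / s_min) ** u
    else:
        a = 1.0 - alpha
        s = (s_min**a + u * (s_max**a - s_min**a)) ** (1.0 / a)
    return s.astype(np.int64)


def simulate_hic(
    truth: TruthSet,
    n_pairs: int,
    decay_alpha: float = 1.0,
    read_len: int = 100,
    noise_frac: float = 0.0,
    max_separation: Optional[int] = None,
    seed: int = 0,
) -> List[HiCPair]:
    """Distance-decay Hi-C pairs on contig coordinates.

    Each pair picks a chromosome (∝ length), a uniform first locus and a
    genomic separation from the power-law decay, truncated to the
    chromosome (and to ``max_separation`` for short-range libraries).
    ``noise_frac`` of pairs are uniform inter-chromosomal noise. Loci
    are lifted through the truth to contig coordinates.
    """
    rng = np.random.default_rng(seed)
    chroms = sorted(truth.chrom_lengths)
    lengths = np.array([truth.chrom_lengths[c] for c in chroms], dtype=np.float64)
    index = truth.genome_index()

    n_noise = int(round(n_pairs * noise_frac))
    n_decay = n_pairs - n_noise

    chrom_idx = rng.choice(len(chroms), size=n_decay, p=lengths / lengths.sum())
    pairs: List[HiCPair] = []
    strands = rng.integers(0, 2, size=(n_pairs, 2))
    pair_no = 0
    for ci in range(len(chroms)):
        sel = np.flatnonzero(chrom_idx == ci)
        if sel.size == 0:
            continue
        L = int(lengths[ci])
        s_max = float(L - read_len - 1)
        if max_separation is not None:
            s_max = min(s_max, float(max_separation))
        s_min = float(read_len)
        loc1 = rng.integers(0, L - read_len, size=sel.size)
        sep = _sample_separations(rng, sel.size, s_min, s_max, decay_alpha)
        direction = rng.choice([-1, 1], size=sel.size)
        loc2 = loc1 + direction * sep
        out = (loc2 < 0) | (loc2 > L - read_len)
        loc2[out] = loc1[out] - direction[out] * sep[out]
        loc2 = np.clip(loc2, 0, L - read_len)
        chrom = chroms[ci]
        for k in range(sel.size):
            c1, s1, e1 = truth.map_locus(index, chrom, int(loc1[k]), read_len)
            c2, s2, e2 = truth.map_locus(index, chrom, int(loc2[k]), read_len)
            pairs.append(
                HiCPair(
                    read_id=f"p{pair_no}",
                    end1=ReadEnd(c1, s1, e1, "+-"[strands[pair_no, 0]]),
                    end2=ReadEnd(c2, s2, e2, "+-"[strands[pair_no, 1]]),
                    mapq=60,
                )
            )
            pair_no += 1

    if n_noise:
        if len(chroms) < 2:
            raise ValueError("inter-chromosomal noise needs >= 2 chromosomes")
        for _ in range(n_noise):
            ci1, ci2 = rng.choice(len(chroms), size=2, replace=False)
            l1 = int(rng.integers(0, int(lengths[ci1]) - read_len))
            l2 = int(rng.integers(0, int(lengths[ci2]) - read_len))
            c1, s1, e1 = truth.map_locus(index, chroms[ci1], l1, read_len)
            c2, s2, e2 = truth.map_locus(index, chroms[ci2], l2, read_len)
            pairs.append(
                HiCPair(
                    read_id=f"p{pair_no}",
                    end1=ReadEnd(c1, s1, e1, "+-"[strands[pair_no, 0]]),
                    end2=ReadEnd(c2, s2, e2, "+-"[strands[pair_no, 1]]),
                    mapq=60,
                )
            )
            pair_no += 1
    return pairs


def pairs_for_physical_coverage(
    truth: TruthSet,
    target_coverage: float,
    decay_alpha: float = 1.0,
    read_len: int = 100,
    seed: int = 0,
    probe_pairs: int = 20_000,
) -> int:
    """Pair count delivering ~``target_coverage``× intra-contig physical
    coverage, estimated by Monte Carlo through the simulator itself."""
    probe = simulate_hic(truth, probe_pairs, decay_alpha, read_len, seed=seed)
    genome = sum(truth.chrom_lengths.values())
    span_total = sum(
        max(p.end1.end, p.end2.end) - min(p.end1.start, p.end2.start)
        for p in probe
        if p.intra
    )
    if span_total == 0:
        raise ValueError("probe produced no intra-contig pairs")
    per_pair = span_total / probe_pairs / genome
    return int(math.ceil(target_coverage / per_pair))


@dataclass(frozen=True)
class ChimeraRecord:
    """Truth for one injected chimeric join."""

    contig_id: str
    junction: int  # position of the false join on the chimeric contig
    left_id: str
    right_id: str


def inject_chimeras(
    contigs: Sequence[Contig],
    truth: TruthSet,
    n_joins: int,
    min_separation: Optional[int] = None,
    seed: int = 0,
) -> Tuple[List[Contig], TruthSet, List[ChimeraRecord]]:
    """Concatenate ``n_joins`` distant contig pairs into chimeric contigs.

    Joined pairs must be on different chromosomes or farther apart than
    ``min_separation`` (default: 1/320 of the genome, the benchmark's
    10 Mbp-of-3.2 Gbp rule rescaled). Truth segments follow the moved
    sequence, so Hi-C simulation through the mutated truth lands on
    chimeric coordinates.
    """
    rng = np.random.default_rng(seed)
    genome_size = sum(truth.chrom_lengths.values())
    if min_separation is None:
        min_separation = genome_size // 320
    pool = sorted(
        c.id for c in contigs if len(truth.segments[c.id]) == 1
    )
    if 2 * n_joins > len(pool):
        raise ValueError("not enough contigs to inject that many chimeras")

    def far_apart(a: str, b: str) -> bool:
        sa, sb = truth.single_record(a), truth.single_record(b)
        if sa.chrom != sb.chrom:
            return True
        gap = max(sb.genome_start - sa.genome_end, sa.genome_start - sb.genome_end)
        return gap > min_separation

    by_id = {c.id: c for c in contigs}
    chosen: List[Tuple[str, str]] = []
    available = pool.copy()
    attempts = 0
    while len(chosen) < n_joins:
        attempts += 1
        if attempts > 1000 * n_joins:
            raise RuntimeError("could not satisfy the separation rule")
        a, b = rng.choice(len(available), size=2, replace=False)
        a_id, b_id = available[int(a)], available[int(b)]
        if not far_apart(a_id, b_id):
            continue
        chosen.append((a_id, b_id))
        available = [x for x in available if x not in (a_id, b_id)]

    new_truth = TruthSet(chrom_lengths=dict(truth.chrom_lengths))
    removed = {x for pair in chosen for x in pair}
    new_contigs = [c for c in contigs if c.id not in removed]
    for cid in sorted(truth.segments):
        if cid not in removed:
            for seg in truth.segments[cid]:
                new_truth.add(cid, seg)
    records: List[ChimeraRecord] = []
    for a_id, b_id in chosen:
        ca, cb = by_id[a_id], by_id[b_id]
        new_id = f"{a_id}~{b_id}"
        seq = None
        if ca.sequence is not None and cb.sequence is not None:
            seq = ca.sequence + cb.sequence
        new_contigs.append(
            Contig(
                id=new_id,
                length=ca.length + cb.length,
                sequence=seq,
                cut_sites=(count_cut_sites(seq) if seq is not None
                           else ca.cut_sites + cb.cut_sites),
            )
        )
        sa, sb = truth.single_record(a_id), truth.single_record(b_id)
        new_truth.add(new_id, TruthSegment(sa.chrom, sa.genome_start,
                                           sa.genome_end, 0, sa.orient))
        new_truth.add(new_id, TruthSegment(sb.chrom, sb.genome_start,
                                           sb.genome_end, ca.length, sb.orient))
        records.append(ChimeraRecord(new_id, ca.length, a_id, b_id))
    return new_contigs, new_truth, records


def make_erroneous_scaffolds(
    contigs: Sequence[Contig],
    truth: TruthSet,
    n_scaffolds: int,
    contigs_per_scaffold: int = 10,
    min_separation: Optional[int] = None,
    seed: int = 0,
) -> Tuple[Layout, List[List[bool]]]:
    """Build a mixture of erroneous and truth-correct scaffolds.

    ``n_scaffolds`` erroneous scaffolds chain randomly drawn contigs
    whose consecutive members violate genome adjacency (different
    chromosome or separation beyond the rule); all remaining contigs are
    chained ``contigs_per_scaffold`` at a time in true order and
    orientation. Returns the layout and, per walk, a correctness label
    for each join (True = correct join).
    """
    if contigs_per_scaffold < 2:
        raise ValueError("contigs_per_scaffold must be >= 2")
    rng = np.random.default_rng(seed)
    genome_size = sum(truth.chrom_lengths.values())
    if min_separation is None:
        min_separation = genome_size // 320
    ids = sorted(c.id for c in contigs)
    needed = n_scaffolds * contigs_per_scaffold
    if needed > len(ids):
        raise ValueError("not enough contigs for the requested scaffolds")

    def far_apart(a: str, b: str) -> bool:
        sa, sb = truth.single_record(a), truth.single_record(b)
        if sa.chrom != sb.chrom:
            return True
        gap = max(sb.genome_start - sa.genome_end, sa.genome_start - sb.genome_end)
        return gap > min_separation

    available = ids.copy()
    walks: List[Walk] = []
    labels: List[List[bool]] = []
    for _ in range(n_scaffolds):
        walk: Walk = []
        attempts = 0
        while len(walk) < contigs_per_scaffold:
            attempts += 1
            if attempts > 10_000:
                raise RuntimeError("could not satisfy the separation rule")
            pick = available[int(rng.integers(0, len(available)))]
            if walk and not far_apart(walk[-1][0], pick):
                continue
            walk.append((pick, "+"))
            available.remove(pick)
        walks.append(walk)
        labels.append([False] * (contigs_per_scaffold - 1))

    # remaining contigs: correct scaffolds in true order per chromosome
    def true_key(cid: str):
        s = truth.single_record(cid)
        return (s.chrom, s.genome_start)

    remaining = sorted(available, key=true_key)
    i = 0
    while i < len(remaining):
        chunk = [remaining[i]]
        while (
            len(chunk) < contigs_per_scaffold
            and i + len(chunk) < len(remaining)
        ):
            prev = truth.single_record(chunk[-1])
            nxt_id = remaining[i + len(chunk)]
            nxt = truth.single_record(nxt_id)
            # only genuinely genome-adjacent contigs make a correct join
            if nxt.chrom != prev.chrom or nxt.genome_start != prev.genome_end:
                break
            chunk.append(nxt_id)
        walk = [(cid, truth.single_record(cid).orient) for cid in chunk]
        walks.append(walk)
        labels.append([True] * (len(walk) - 1))
        i += len(chunk)
    return Layout(walks=walks), labels
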