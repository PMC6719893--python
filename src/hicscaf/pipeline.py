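"""End-to-end scaffolding pipeline.

Orchestrates optional contig correction, then the iteration loop: build
the residual scaffold graph over current scaffold ends (used and
blacklisted edges withheld), filter by best-buddy ratio, reconcile with
the assembly-graph prior, extend scaffolds by one greedy matching round,
test the new joins and apply the majority stopping rule. Unplaced
contigs are inserted once at the end. Fully deterministic for a given
configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

from hicscaf import io_formats
from hicscaf.coverage_correction import correct_assembly, write_coordinate_map
from hicscaf.graph_prior import AssemblyGraph, GraphScore, reconcile, score_contig_pair
from hicscaf.io_formats import Contig, HiCPair
from hicscaf.layout import (
    Layout,
    Walk,
    _walk_end_nodes,
    greedy_matching,
    insert_small_contigs,
)
from hicscaf.misjoin import Blacklist, correct_iteration, stopping_rule
from hicscaf.scaffold_graph import (
    EdgeKey,
    HiCEdge,
    NodeEnd,
    ScaffoldGraph,
    compute_best_buddy,
    edge_key,
    effective_cut_sites,
    filter_best_buddy,
    tally_end_pairs,
)


@dataclass
class PipelineConfig:
    """All knobs of a scaffolding run."""

    enzymes: Tuple[str, ...] = io_formats.DEFAULT_ENZYME_MOTIFS
    correct: bool = True
    use_graph: bool = True
    bin_size: int = 1000
    correction_rounds: int = 1
    n_thresholds: int = 10
    window: int = 200_000
    n_cutoffs: int = 10
    min_support: int = 5
    min_mapq: int = 10
    insertion_ratio: float = 1.0
    gap_length: int = 500
    max_iterations: int = 20
    graph_hop_cap: int = 10
    seed: int = 42

    def to_dict(self) -> dict:
        return {
            "enzymes": list(self.enzymes),
            "correct": self.correct,
            "use_graph": self.use_graph,
            "bin_size": self.bin_size,
            "correction_rounds": self.correction_rounds,
            "n_thresholds": self.n_thresholds,
            "window": self.window,
            "n_cutoffs": self.n_cutoffs,
            "min_support": self.min_support,
            "min_mapq": self.min_mapq,
            "insertion_ratio": self.insertion_ratio,
            "gap_length": self.gap_length,
            "max_iterations": self.max_iterations,
            "graph_hop_cap": self.graph_hop_cap,
            "seed": self.seed,
        }


@dataclass
class IterationReport:
    iteration: int
    joins_made: int
    joins_flagged: int
    frac_flagged: float
    stopped: bool


@dataclass
class PipelineResult:
    layout: Layout
    contigs: List[Contig]
    breaks: list
    coord_map: list
    iterations: List[IterationReport]
    join_log: List[dict]
    summary: Dict[str, int]
    config: PipelineConfig


def alignment_summary(pairs: Sequence[HiCPair]) -> Tuple[int, int, int]:
    """(total, intra-contig, inter-contig) pair tallies."""
    intra = sum(1 for p in pairs if p.intra)
    return len(pairs), intra, len(pairs) - intra


def _flip_walk(walk: Walk) -> Walk:
    return [(cid, "-" if o == "+" else "+") for cid, o in reversed(walk)]


def _merge_walks(
    walk_u: Walk, joins_u: list, walk_v: Walk, joins_v: list, edge: HiCEdge
) -> Tuple[Walk, list]:
    """Join two walks so the edge's two contig-ends face each other."""
    left_u, right_u = _walk_end_nodes(walk_u)
    if edge.u == right_u:
        left_part, left_joins = walk_u, joins_u
    elif edge.u == left_u:
        left_part, left_joins = _flip_walk(walk_u), list(reversed(joins_u))
    else:
        raise AssertionError("edge endpoint is not a terminal end of its walk")
    left_v, right_v = _walk_end_nodes(walk_v)
    if edge.v == left_v:
        right_part, right_joins = walk_v, joins_v
    elif edge.v == right_v:
        right_part, right_joins = _flip_walk(walk_v), list(reversed(joins_v))
    else:
        raise AssertionError("edge endpoint is not a terminal end of its walk")
    return left_part + right_part, left_joins + [edge] + right_joins


def _build_residual_graph(
    walks: List[Walk],
    contigs_by_id: Dict[str, Contig],
    tally: Dict[EdgeKey, int],
    used: Set[EdgeKey],
    blacklist: Blacklist,
    min_support: int,
) -> Tuple[ScaffoldGraph, Dict[NodeEnd, int]]:
    """Scaffold graph over the terminal contig-ends of the current walks."""
    end_owner: Dict[NodeEnd, int] = {}
    for wi, walk in enumerate(walks):
        left, right = _walk_end_nodes(walk)
        end_owner[left] = wi
        end_owner[right] = wi
    graph = ScaffoldGraph(contigs=contigs_by_id)
    for key, n in tally.items():
        if n < min_support or key in used or key in blacklist:
            continue
        u, v = key
        wu, wv = end_owner.get(u), end_owner.get(v)
        if wu is None or wv is None or wu == wv:
            continue
        c = effective_cut_sites(contigs_by_id[u.contig_id]) + effective_cut_sites(
            contigs_by_id[v.contig_id]
        )
        graph.add_edge(HiCEdge(u, v, n=n, w=n / c))
    return graph, end_owner


def _graph_prior_scores(
    graph: ScaffoldGraph,
    asm_graph: AssemblyGraph,
    end_owner: Dict[NodeEnd, int],
    used: Set[EdgeKey],
    blacklist: Blacklist,
    cache: Dict[Tuple[str, str], GraphScore],
    hop_cap: int,
) -> List[GraphScore]:
    """Orientation scores for every Hi-C pair plus GFA-adjacent pairs
    whose graph-implied ends are both exposed."""
    pairs: Set[Tuple[str, str]] = set()
    for u, v in graph.edges:
        a, b = sorted((u.contig_id, v.contig_id))
        pairs.add((a, b))
    for a, _, b, _ in asm_graph.links:
        if a != b:
            pairs.add(tuple(sorted((a, b))))
    scores = []
    for a, b in sorted(pairs):
        if a not in asm_graph.segments or b not in asm_graph.segments:
            continue
        if (a, b) not in cache:
            cache[(a, b)] = score_contig_pair(asm_graph, a, b, hop_cap)
        score = cache[(a, b)]
        if not score.retained:
            continue
        bu, bv = score.best_end_pair
        key = edge_key(bu, bv)
        if key in used or key in blacklist:
            continue
        if key not in graph.edges and (
            bu not in end_owner
            or bv not in end_owner
            or end_owner[bu] == end_owner[bv]
        ):
            continue
        scores.append(score)
    return scores


def scaffold(
    contigs: Sequence[Contig],
    pairs: Sequence[HiCPair],
    asm_graph: Optional[AssemblyGraph] = None,
    config: Optional[PipelineConfig] = None,
) -> PipelineResult:
    """Run the full scaffolding pipeline on in-memory inputs."""
    config = config or PipelineConfig()
    contigs = list(contigs)
    pairs = list(pairs)
    if not pairs:
        raise ValueError("zero usable Hi-C pairs (0 total, 0 intra, 0 inter)")

    breaks: list = []
    coord_map: list = []
    if config.correct:
        contigs, pairs, breaks, coord_map = correct_assembly(
            contigs,
            pairs,
            rounds=config.correction_rounds,
            bin_size=config.bin_size,
            n_thresholds=config.n_thresholds,
        )

    total, intra, inter = alignment_summary(pairs)
    summary = {"total_pairs": total, "intra_pairs": intra, "inter_pairs": inter}
    if inter == 0:
        raise ValueError(
            f"zero usable inter-contig pairs (total={total}, intra={intra}, inter=0)"
        )

    contigs_by_id = {c.id: c for c in contigs}
    lengths = {c.id: c.length for c in contigs}
    inter_pairs = [p for p in pairs if not p.intra]
    tally = tally_end_pairs(inter_pairs, contigs_by_id)

    walks: List[Walk] = [[(cid, "+")] for cid in sorted(contigs_by_id)]
    joins: List[list] = [[] for _ in walks]
    used: Set[EdgeKey] = set()
    blacklist = Blacklist()
    score_cache: Dict[Tuple[str, str], GraphScore] = {}
    iterations: List[IterationReport] = []
    join_log: List[dict] = []
    use_graph = config.use_graph and asm_graph is not None

    for it in range(1, config.max_iterations + 1):
        graph, end_owner = _build_residual_graph(
            walks, contigs_by_id, tally, used, blacklist, config.min_support
        )
        if use_graph:
            scores = _graph_prior_scores(
                graph, asm_graph, end_owner, used, blacklist,
                score_cache, config.graph_hop_cap,
            )
            reconcile(graph, scores)
        compute_best_buddy(graph)
        filtered = filter_best_buddy(graph)
        matching = greedy_matching(filtered.edges.values())

        prev_walks = [list(w) for w in walks]
        prev_joins = [list(j) for j in joins]
        new_keys: Set[EdgeKey] = set()
        walk_of: Dict[NodeEnd, int] = dict(end_owner)
        alive = {i: (walks[i], joins[i]) for i in range(len(walks))}
        for e in matching:
            wu, wv = walk_of.get(e.u), walk_of.get(e.v)
            if wu is None or wv is None:
                continue
            used.add(e.key)
            if wu == wv:
                continue  # would close a cycle on one scaffold; skip the join
            new_keys.add(e.key)
            join_log.append(
                {
                    "iteration": it,
                    "u": f"{e.u.contig_id}:{e.u.side}",
                    "v": f"{e.v.contig_id}:{e.v.side}",
                    "n": e.n,
                    "w": round(e.w, 6),
                    "bb": e.bb if e.bb != float("inf") else "inf",
                    "source": e.source,
                }
            )
            walk_u, joins_u = alive.pop(wu)
            walk_v, joins_v = alive.pop(wv)
            merged, merged_joins = _merge_walks(walk_u, joins_u, walk_v, joins_v, e)
            new_id = min(wu, wv)
            alive[new_id] = (merged, merged_joins)
            for end in _walk_end_nodes(merged):
                walk_of[end] = new_id
            walk_of.pop(e.u, None)
            walk_of.pop(e.v, None)

        ordered = [alive[k] for k in sorted(alive)]
        walks = [w for w, _ in ordered]
        joins = [j for _, j in ordered]

        if not new_keys:
            iterations.append(IterationReport(it, 0, 0, 0.0, True))
            break

        layout = Layout(walks=walks, joins=joins)
        corrected, blacklist, frac, tests = correct_iteration(
            layout,
            pairs,
            lengths,
            blacklist,
            window=config.window,
            n_cutoffs=config.n_cutoffs,
            gap_length=config.gap_length,
            new_edge_keys=new_keys,
        )
        flagged = sum(1 for t in tests if t.flagged)
        stop = stopping_rule(frac, len(new_keys))
        iterations.append(
            IterationReport(it, len(new_keys), flagged, frac, stop)
        )
        if stop:
            # majority of this round's joins were bad: report the
            # penultimate round's (corrected) scaffolds
            walks, joins = prev_walks, prev_joins
            break
        walks = corrected.walks
        joins = corrected.joins

    layout = Layout(walks=walks, joins=joins)
    # weight lookups for insertion use the complete edge set
    weight_graph = ScaffoldGraph(contigs=contigs_by_id)
    for key, n in tally.items():
        if n < config.min_support:
            continue
        u, v = key
        c = effective_cut_sites(contigs_by_id[u.contig_id]) + effective_cut_sites(
            contigs_by_id[v.contig_id]
        )
        weight_graph.add_edge(HiCEdge(u, v, n=n, w=n / c))
    layout = insert_small_contigs(
        layout, weight_graph, insertion_ratio=config.insertion_ratio
    )
    layout.validate()
    return PipelineResult(
        layout=layout,
        contigs=contigs,
        breaks=breaks,
        coord_map=coord_map,
        iterations=iterations,
        join_log=join_log,
        summary=summary,
        config=config,
    )


def write_outputs(result: PipelineResult, outdir) -> None:
    """Emit scaffolds.agp, joins.tsv, iterations.tsv, breakpoints.bed,
    manifest.json and (when sequences are present) scaffolds.fasta."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gap = result.config.gap_length
    io_formats.write_agp(result.layout, result.contigs, outdir / "scaffolds.agp", gap)
    if all(c.sequence is not None for c in result.contigs):
        io_formats.write_scaffold_fasta(
            result.layout, result.contigs, outdir / "scaffolds.fasta", gap
        )
    io_formats.write_breakpoints_bed(
        [(b.contig_id, b.start, b.end, "misassembly") for b in result.breaks],
        outdir / "breakpoints.bed",
    )
    write_coordinate_map(result.coord_map, outdir / "correction_map.tsv")
    with open(outdir / "joins.tsv", "w") as fh:
        fh.write("iteration\tu\tv\tn\tw\tbb\tsource\n")
        for row in result.join_log:
            fh.write(
                f"{row['iteration']}\t{row['u']}\t{row['v']}\t{row['n']}\t"
                f"{row['w']}\t{row['bb']}\t{row['source']}\n"
            )
    with open(outdir / "iterations.tsv", "w") as fh:
        fh.write("iteration\tjoins_made\tjoins_flagged\tfrac_flagged\tstopped\n")
        for r in result.iterations:
            fh.write(
                f"{r.iteration}\t{r.joins_made}\t{r.joins_flagged}\t"
                f"{r.frac_flagged:.4f}\t{int(r.stopped)}\n"
            )
    manifest = {
        "config": result.config.to_dict(),
        "alignment_summary": result.summary,
        "n_contigs": len(result.contigs),
        "n_scaffolds": len(result.layout.walks),
        "n_breaks": len(result.breaks),
        "iterations_run": len(result.iterations),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
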