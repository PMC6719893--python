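# hicscaf

Chromosome-scale genome scaffolding from Hi-C proximity-ligation data,
guided by the assembly graph.

Long-read assemblies arrive as contigs; Hi-C read pairs carry linking
information across tens of megabases because contact frequency decays
with one-dimensional genomic distance, so they can order and orient
contigs into chromosome-scale scaffolds. Pure Hi-C scaffolders are
prone to inversion errors on short contigs and need a chromosome-count
guess to know when to stop. `hicscaf` addresses both: it fuses Hi-C
linkage with the ambiguous-adjacency edges of the assembler's GFA graph
to fix orientations, and it stops on its own when the iteration's joins
start failing a coverage-based misjoin test. It is written for assembly
practitioners who have contigs, a pre-aligned Hi-C library and
(optionally) the assembler's unitig graph.

## Method

The pipeline has four stages:

1. **Contig correction.** The *physical coverage* at a position is the
   number of read pairs whose outermost span covers it. A misassembled
   junction shows a coverage trough because no genuine pairs span it.
   For a ladder of coverage thresholds δ the longest low run is
   recorded; the maximal clique of these intervals (an endpoint sweep,
   O(N log N)) marks the misassembly when it holds for the majority of
   cutoffs, and the contig is split into the piece left of the clique's
   smallest interval, the junction region, and the piece to the right.

2. **Scaffold graph.** Every contig contributes two nodes, B and E
   (its two halves about the midpoint). Inter-contig pairs accumulate
   raw counts N(u, v) per end pair, normalized by restriction cut-site
   content: W(u, v) = N(u, v) / (C(u) + C(v)), with C counted for the
   GATC and GANTC motifs of the two-enzyme chemistry. The best-buddy
   ratio BB(u, v) divides W(u, v) by the heaviest competing edge at
   either endpoint; only mutually-best edges (BB > 1) survive. With the
   GFA present, σ(x, y) hop-count shortest paths over the four relative
   orientations of each contig pair give Score = second-shortest σ /
   shortest σ; when Score > 1 the graph's orientation wins and
   conflicting Hi-C edges are deleted.

3. **Layout.** Surviving edges are matched greedily, best-first — a
   maximal matching within 1/2 of the maximum-weight matching — and the
   implicit B–E edge of each contig turns the matching into walks;
   cycles are broken at their lowest-weight join. Each round's joins
   extend the scaffolds; used edges leave the pool, so previously
   out-competed edges can become mutually best later.

4. **Misjoin testing and stopping.** Each new join is re-examined: read
   pairs are lifted to scaffold coordinates, physical coverage is
   computed in a window w around the join, and per coverage cutoff the
   longest low stretch is found as a maximum-sum subarray of a ±1
   auxiliary array. A join sitting inside the maximal clique of these
   stretches is broken and its edge blacklisted. When the majority of a
   round's joins fail, scaffolding stops and the previous round's
   scaffolds are reported — no chromosome count required.

A synthetic-data module generates genomes, fixed-size contigs, a linear
assembly graph, distance-decay Hi-C libraries (contact probability
∝ s^−α), injected chimeric contigs and labeled erroneous scaffolds,
with full truth tracking; an evaluation module scores orientation /
ordering / chimera errors, corrected block lengths, NGA50 and feature
response curves against that truth.

## Worked example

Simulate a two-chromosome 2 Mbp genome cut into 40 kbp contigs with
100k Hi-C pairs, then scaffold it using the linear assembly graph:

```bash
hicscaf simulate -o demo/sim --chromosomes 2 --chrom-length 1000000 \
    --contig-size 40000 --pairs 100000 --seed 7
# simulated 50 contigs, 100000 pairs -> demo/sim

hicscaf scaffold -a demo/sim/contigs.fasta -b demo/sim/pairs.bedpe \
    -g demo/sim/assembly.gfa -o demo/out --seed 7
# pairs: 100000 total, 54634 intra-contig, 45366 inter-contig
# scaffolds: 2 (from 50 contigs, 0 breaks)
```

The run reports 54,634 intra-contig and 45,366 inter-contig pairs (only
the latter link contigs) and ends with exactly two scaffolds — one per
simulated chromosome, with every contig placed in true order and
orientation. `demo/out/iterations.tsv` shows the stopping rule at work:
round 1 makes 48 joins with none flagged, round 2 finds no joinable
edges left and stops:

```
iteration  joins_made  joins_flagged  frac_flagged  stopped
1          48          0              0.0000        0
2          0           0              0.0000        1
```

Outputs: `scaffolds.fasta`, `scaffolds.agp` (1-based AGP v2.0 with
500 bp gaps), `breakpoints.bed` plus the old↔new `correction_map.tsv`
for any split contigs, per-join provenance `joins.tsv`,
`iterations.tsv` and a reproducibility `manifest.json`. The library API
mirrors the CLI: `hicscaf.scaffold(contigs, pairs, asm_graph, config)`.

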