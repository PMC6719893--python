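# Methods

This note documents the models, parameter choices and numerical
conventions behind `hicscaf`, and what the synthetic benchmarks do and
do not demonstrate.

## Model and assumptions

Hi-C contact frequency between two loci decays with their 1-D genomic
distance; read pairs mapped to different contigs therefore carry order
and orientation signal, strongest between adjacent contigs. The method
assumes: (i) pairs are pre-aligned, with multi-mappers and PCR
duplicates already removed upstream (a `min_mapq` filter, default 10,
guards the residue); (ii) Hi-C sampling is roughly proportional to
restriction-site density, motivating the cut-site normalization
W = N/(C(u)+C(v)); (iii) the input assembly is haploid-like —
duplicated haplotigs are out of scope and should be purged beforehand.

Contig ends, not whole contigs, are the graph nodes: a read is assigned
to the B or E node by which half of the contig its start falls in
(half-open halves, a start exactly at L/2 counts as E). This lets a
contig pair carry up to four edges, one per relative orientation, and
makes the layout a matching problem: each end is used at most once, and
the implicit B–E edges force contigs to appear intact in walks.

## Contig correction

Physical coverage is accumulated from pair spans via a difference
array, binned (default `bin_size` 1 kbp, fractional weighting at bin
edges so total mass equals total span length). Thresholds are K = 10
evenly spaced values over (min nonzero coverage, max coverage]; per
threshold the longest strict-minority run of low bins is kept, ties to
the leftmost. Runs touching the first or last bin are discarded:
spanning pairs necessarily thin out toward contig ends, so end troughs
are expected, not suspicious — on simulated clean contigs the coverage
profile is dome-shaped and essentially every threshold's run touches an
end, which is what gives the detector its specificity. A break is
called when the interval clique's depth reaches half of all K tested
cutoffs (not merely of the thresholds that produced intervals; the
weaker denominator flags the one-or-two-cutoff noise runs that any
profile exhibits and destroys specificity — measured on clean
simulations it broke over half the contigs). The reported region is
the smallest clique interval (shortest, then lowest start), the contig
splits into up to three pieces, mates are shifted onto their piece,
mate intervals straddling a cut are dropped, and pairs whose mates land
on different pieces become ordinary inter-contig pairs. One break per
contig per round; `rounds` controls repetition. The junction (middle)
piece re-enters scaffolding as an ordinary contig.

Known limitation: a chimera joining loci that are *near* each other on
the same chromosome is masked — genuine long-range pairs span the false
junction and fill the trough. The benchmark's separation rule (joined
pieces on different chromosomes or farther apart than 1/320 of the
genome, the 10 Mbp-of-3.2 Gbp rule rescaled) reflects exactly the
regime the detector is designed for.

## Scaffold graph and the assembly-graph prior

Edges below `min_support` raw pairs (default 5) are dropped as noise.
Contigs with zero cut sites take C = 1 to avoid division blow-up. The
best-buddy ratio is computed in O(|E|) by caching the top two incident
weights per node; an edge whose endpoints have no competitors gets
BB = +∞ (trivially mutually best). Retention is strict (BB > 1), so
equal-best ties eliminate each other; the surviving edge set touches
each node once and is itself a matching.

Orientation evidence from the GFA uses unweighted hop counts: σ for
the four orientation classes by BFS over oriented segments, capped at
10 hops (long paths carry no orientation signal; the cap also bounds
cost on dense graphs). The score is the second-shortest σ over *all*
other orientation classes divided by the shortest; a tie for shortest
means no evidence (score 1). The orientation class ↔ end-pair bijection
is: (+,+) → u.E–v.B, (+,−) → u.E–v.E, (−,+) → u.B–v.B, (−,−) → u.B–v.E.
Where the retained graph orientation contradicts a Hi-C edge, the Hi-C
edge is removed and the graph's edge installed at the pair's maximum
Hi-C weight — or, for pairs with no Hi-C support at all, at the
maximum weight observed in the graph, so assembler-implied adjacencies
sort first in the matching.

## Layout and iteration

Edges sort by (BB desc, W desc, endpoint ids) — a deterministic total
order; greedy matching scans once, which yields a maximal matching and
a 1/2-approximation of the maximum-weight matching. The pipeline runs
one matching round per iteration over the *residual* graph: nodes are
the terminal ends of current scaffolds, an edge's weight still derives
from the terminal contigs' end tallies and cut sites (the aggregation
convention for multi-contig scaffolds is this package's choice), and
used or blacklisted end pairs are withheld. A matching edge landing on
the two ends of one scaffold would close a cycle and is consumed
without joining. Walk merging flips whichever side is needed so the
matched ends face each other; a walk entering a contig at B records it
as `+`. Unscaffolded contigs are inserted once, after the last
iteration, between adjacent contigs (a, b) when W(a,c) and W(c,b) both
exceed W(a,b) × `insertion_ratio` (default 1.0), best combined weight
first, ties by contig id. Gap length in output coordinates is fixed
(default 500 bp).

## Misjoin testing and stopping

Only the current round's joins are tested. Pairs are lifted to scaffold
coordinates orientation-aware; coverage in a window w (default
200 kbp) around the join uses spans clipped to the window. Per cutoff
(K = 10 evenly spaced over [min, max] coverage inclusive) the ±1
auxiliary array (+1 where coverage ≤ δ) is reduced by Kadane's
algorithm (ties: leftmost start, then shortest, resolved exactly by a
vectorized prefix-sum scan); the join is flagged when it lies inside
the maximal clique interval of those stretches (containment
s ≤ p ≤ e). Constant coverage across the window is treated as no
trough evidence and never flagged — the literal ±1 reduction would
make the entire window the clique and flag every such join. Flagged
joins split the scaffold back into its two constituent walks (the
exact inverse of the join) and blacklist the edge permanently. The
stopping rule is strict majority (frac > 0.5) or a round with no
joins; on majority failure the previous round's corrected scaffolds
are the final result.

The window is a real tradeoff: w much larger than the contig size
averages several junctions into one window and can attribute the
consensus trough to a neighboring join (lower sensitivity), while w
near the contig size sharpens sensitivity but lets the ordinary
coverage dip at gap positions get flagged (lower specificity). The
default 200 kbp favors specificity, matching the method's conservative
stopping role; `--window` exposes the knob. Joins within w/2 of a
scaffold end are tested on a truncated window and marked
low-confidence.

## Synthetic data

Defaults emulate the benchmark design at desk scale: 2 chromosomes ×
2 Mbp of i.i.d. uniform ACGT, 40 kbp contigs, a strictly linear GFA
(links between genome-adjacent slices only, never across chromosomes),
2×10⁵ pairs. Separations are drawn from p(s) ∝ s^−α by inverse CDF
(default α = 1, the standard contact-decay scaling; steeper α imitates
mitotic-like libraries and a `max_separation` cap imitates short-range
in-vitro libraries), read length 100 bp, optional uniform
inter-chromosomal noise. Loci out of chromosome bounds reflect
direction and finally clip, a negligible distortion of the decay tail.
Chimeras concatenate distant contig pairs with the junction recorded;
erroneous scaffolds chain contigs violating the separation rule, and
correct scaffolds chain only genuinely genome-adjacent runs. All
outputs are deterministic per seed.

What the simulation does not model: TAD structure and other contact
heterogeneity, GC/mappability bias, restriction-fragment-level
resolution, heterozygosity and duplication, chimeric read-through
artifacts. Passing tests therefore demonstrate the algorithms' correct
mechanics and their behavior under idealized contact statistics, not
performance on real libraries, where contact noise is structured
rather than uniform.

## Evaluation conventions

Orientation errors count contigs disagreeing with their scaffold's
consensus direction (majority of per-contig truth-strand agreement,
ties to the first contig), so whole-scaffold reversal is free. Each
non-monotonic same-chromosome triple counts one ordering error
(sliding window of three, per-triple); each cross-chromosome adjacency
one chimera error. Corrected blocks split walks at every junction
adjacent to an error (the chimera junction; both junctions of a
misoriented contig; the junction after the middle of a bad triple);
NGA50 is the NG50 of those blocks against the known genome size. The
feature response curve scans scaffolds largest-first and plots
cumulative error percentage against cumulative size.

## Problem sizes used in the checks

The acceptance experiment regenerates its inputs at the simulation's
default scale (4 Mbp genome, 100 contigs, 90 correct joins, 2×10⁵
pairs); matching-approximation checks use 200 random graphs of up to
12 nodes against an exact matcher; oracle-equivalence checks run exact
brute force at sizes where that is instant (≤ 30 segments, ≤ 10³
edges). These sizes were chosen so every check is exact or
statistically comfortable while the whole suite stays interactive.
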