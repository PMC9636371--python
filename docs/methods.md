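# Methods

## Problem and model

`hapcorrect` performs self-correction of noisy long reads (PacBio-CLR- or
ONT-like, 5–15% error) sampled from *mixtures* of closely related
sequences: polyploid genomes, strain mixtures, metagenomes with several
strains per species. Plain consensus polishing corrects such reads against
a single consensus template, which erases the very variants (ANI 96–99%
between haplotypes means one diagnostic base every 25–100 bp) that
distinguish the haplotypes. The method instead corrects each read against
a *variation graph* in which every haplotype present in the sample remains
a distinct path, and removes only the graph structure that is attributable
to random sequencing error.

Two cycles are run:

**Cycle 1 — error removal by graph pruning.** All-vs-all overlaps are
computed from minimizer seeds and filtered (minimum mapped length > 500 bp,
no self-overlaps, no internal matches by the overhang heuristic, and the
mapping-length ratio test |1 − min(Lq,Lt)/max(Lq,Lt)| ≥ e with e = 0.3).
For each target read, overlapping reads are trimmed to their overlap,
aligned to the target by global edit distance (edlib), and cut at fixed
500-bp target windows. Per window, a partial-order graph is built with the
target subread as backbone; nodes are single bases, edges are observed
dinucleotide adjacencies, every subread is a path. Two statistics from
frequent-itemset mining are computed per edge *e* = (v_i, v_j), with reads
as baskets and nodes as items:

    w(v) = Σ_{r∈R(v)} (1 − p_{r,v})          node weight
    w(e) = Σ_{r∈R(e)} (1 − ½p_{r,v_i} − ½p_{r,v_j})
    Support(e)    = w(e)
    Confidence(e) = max( w(e)/Σ_{v'∈S(v_i)} w(v_i,v'),
                         w(e)/Σ_{v'∈P(v_j)} w(v',v_j) )

where p_{r,v} is the Phred-derived error probability of the read base on
v (0 for FASTA input, making all weights exact read counts). Edges with
Support < s or Confidence < c are pruned, where c = 0.2 and s = 0.2·C
with C = Σ_v w(v)/L the average per-position coverage of the window
(L = window length). Errors are private to single reads (Support ≈ 1,
Confidence ≈ 1/coverage → pruned); true variants recur in all reads of a
haplotype (Support ≈ coverage/2, Confidence ≈ allele fraction → kept).
Pruning, read realignment against the smaller graph (read-only; the graph
is never re-modified), and statistics recomputation are iterated up to 3
rounds or until no edge is removed. Finally the target subread is
realigned against the pruned graph and the walk of its optimal alignment
is spelled out as the pre-corrected subread; subreads are concatenated in
window order.

**Cycle 2 — residual cleanup by haplotype-pure consensus.** The same
steps run on the pre-corrected reads, with two changes. Overlaps are
recomputed with base-level identity (global alignment of the mapped
substrings) and additionally filtered at identity ≥ δ; after cycle 1 the
residual error is below ~0.5%, so same-haplotype overlaps have identity
≥ 1 − 2·0.5% = 0.99 while cross-haplotype overlaps sit near the ANI
(≈0.975 at ANI 98%), and δ = 0.99 (0.98 for noisier real data) separates
them. Window piles therefore contain same-haplotype reads only, and each
window graph is collapsed to its heaviest bundle — the maximum-weight
source-to-sink path under the edge weights w(e) — instead of iterative
pruning. Corrected reads shorter than 500 bp are dropped from the output.

## Sequence-to-graph alignment

Alignment to the DAG is a banded dynamic program over the topological
order: `H[i, j]` is the best score of a walk ending at node *i* having
consumed *j* sequence characters, with moves substitution (from any
predecessor), node deletion (from any predecessor, no character),
insertion (consume a character in place), and free fresh starts (the walk
may begin and end at any node; the sequence is consumed entirely).
Per node only a window of `±band` columns around the node's approximate
window coordinate is evaluated (`band = 75` by default, full DP on
fallback when the band misses the final column). The kernels are
numba-compiled; only the int16 score matrix is stored and the traceback
re-derives moves by rescanning candidates in a fixed order, which makes
alignments bit-reproducible. Scores default to match +3, mismatch −4,
gap −4 (see design choices).

## Synthetic data

The generator emulates mixed-strain sequencing: `ploidy` haplotypes are
derived from one random ancestor, each receiving an edit budget of
`L(1−ANI)/2` bases (90% substitutions, 10% indels of ≤3 bp), so realized
pairwise ANI lands within ±0.3 points of the target. Reads are sampled
per haplotype (Poisson count at the requested coverage, Normal lengths
with mean 10 kb / sd 3 kb truncated to ≥1 kb, uniform starts, both
strands) and errors are injected i.i.d. per base at the requested rate
with a 25:35:40 mismatch:insertion:deletion mix, mimicking CLR-like indel
dominance. All bases receive the same Phred score Q = −10·log₁₀(rate).

What this does *not* emulate: homopolymer-dependent and clustered errors,
quality-score variation along reads, chimeras, structural variants between
haplotypes, circular genomes, and genome-scale repeat structure. Passing
tests on this generator show the statistical machinery works at realistic
coverage, error rate, and divergence; they do not certify performance on
real instrument data.

The evaluator aligns each corrected read (both strands) against every
truth haplotype with infix edit-distance alignment and reports the
aggregate error rate (mismatch rate + indel rate over alignment columns)
and haplotype coverage (fraction of truth bases covered by ≥1 aligned
read). A separate harness checks haplotype preservation: the fraction of
corrected reads that carry their origin haplotype's allele at *every*
truth SNP they span.

## Parameters

| parameter | default | meaning |
|---|---|---|
| window length | 500 bp | target window size; last window shorter |
| c | 0.2 | confidence pruning threshold |
| s | 0.2·C | support threshold, C = window coverage |
| prune iterations | 3 | prune → realign rounds |
| e | 0.3 | overlap length-ratio error threshold |
| min overlap length | 500 bp | overlaps not exceeding this are dropped |
| δ | 0.99 / 0.98 | cycle-2 identity threshold (simulated / real) |
| k, w | 15, 5 | minimizer size and window |
| min_chain | 4 | minimum clustered seed matches per overlap |
| band | 75 | alignment band half-width (columns) |
| match/mismatch/gap | 3/−4/−4 | alignment scores |
| min_window_reads | 4 | below this, the subread passes through raw |
| max_frags | 200 | per-window fragment cap (inactive at ≤100×) |
| min_frag_len | 50 bp | minimum fragment contribution per window |

## Design choices made where the design was open

* **Alignment scores.** With the conventional consensus-polishing scores
  (3/−5/−4, mismatch costlier than gap), a read whose substitution-error
  node has been pruned realigns its erroneous base as an
  insertion-plus-skip rather than as a mismatch on the main chain; such
  reads then inflate the Support of error-induced skip edges (prominent
  around homopolymer deletions) and deflate the main chain, leaving
  deletion paths just above the Confidence threshold. Making the mismatch
  no costlier than a gap (3/−4/−4) routes those reads back through the
  main columns; on the diploid benchmark this cut cycle-1 residual error
  from ~0.61% to ~0.43% (measured at two seeds).
* **Statistics after realignment.** A read's basket contains the nodes it
  actually spells (matches and mismatches). An edge is supported only by
  reads that spell both endpoints adjacently (no intervening insertion),
  mirroring construction-time paths; nodes consumed as deletions are not
  covered.
* **Extraction.** The corrected subread spells every consumed node
  (matches, mismatches, and deletions — so target deletions are
  restored); interior insertions are dropped as target errors. Unaligned
  leading/trailing target bases pass through as raw sequence: graph
  support ends a few bases before the window's own ends (the last
  minimizer anchor), and terminal sequence must never be truncated. Ties
  in the extraction alignment are resolved toward insertions so that
  unaligned bases collect at the walk ends. If the walk spells less than
  half the subread (an over-pruned, disconnected graph), the raw subread
  passes through whole and is counted.
* **Collapse guard.** A pruning round after which the window reads can
  align less than 80% of their bases to the graph has disconnected it;
  the round is rolled back and iteration stops. This is rare (~1% of
  windows) and caused by construction-order path splintering, which the
  prune/realign iteration cannot repair once the main chain is gone.
* **Cycle-1 fusion order.** The target subread is the backbone; fragments
  are fused in read-id order (cycle 1 has no identity to rank by). In
  cycle 2 fragments are ranked by descending overlap identity.
* **C per round.** The coverage normalization C is recomputed from the
  current paths at the start of every pruning round; convergence means a
  round that removes no edge.
* **Ties at thresholds.** Edges exactly at Support = s or Confidence = c
  are kept (strict `<` pruning).
* **Non-ACGT input.** Replaced deterministically by `A` and counted; the
  graph alphabet is exactly {A, C, G, T}.

## Problem sizes

The bundled benchmark corrects a deterministic subset of reads — 100 in
`scripts/acceptance.py`, 60 in the acceptance test suite — while every
read contributes to overlaps and piles, so each corrected read still sees
the full ~60× combined pile coverage. The aggregate error rate is then
measured over ~0.6–1 Mb of corrected sequence, ample for a rate of a few
tenths of a percent. Haplotypes are 50 kb; at this scale reads within
~10 kb of a haplotype end see reduced pile coverage (a linear-molecule
edge effect that vanishes on Mb-scale genomes) and carry most of the
residual error.

## Known limitations

* Progressive POA without aligned-node bookkeeping can splinter support
  across duplicate chains in pathological windows; the collapse guard and
  extraction fallbacks bound the damage but such windows stay at raw
  error level.
* The second cycle needs the corrected read set itself to provide
  coverage; correcting a small subset of reads gives cycle 2 thin piles
  and correspondingly less residual cleanup than a full run.
* Per-read haplotype assignment is implicit (via the identity filter);
  no explicit phasing or switch-error accounting is performed.
* The overlapper is a seed-and-cluster heuristic adequate for 5–15%
  error; precomputed PAF from a dedicated overlapper can be supplied to
  bypass it.
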