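# Methods

## Problem and model

Circular extrachromosomal DNA (ecDNA) carries amplified oncogenes in many
cancers.  From long-read whole-genome sequencing, two signals describe an
ecDNA element: the structural-variant (SV) junctions its rearranged
structure creates, and the elevated read-depth over the genomic segments it
carries.  `amplicycle` reconstructs circular elements from these two
signals and estimates each element's proportion (copy-coverage), including
the hard case where several distinct circles share genomic footprint.

The pipeline, in order:

1. **SV filtering.**  Sniffles-style VCF records are kept when flagged
   `PASS` or `STRANDBIAS`, with on-target coverage >= 5x and variant allele
   frequency >= 0.01.  On-target coverage is `DV + DR` when both counts
   exist, else the coverage-profile value at the breakend.  The
   variant-supporting read count (`DV`/`RE`/`SUPPORT`) is the SV edge
   weight.
2. **Genome fragmentation.**  All breakends are clustered per chromosome by
   single linkage with a 50 bp gap; each cluster's median (rounded down)
   becomes a clean breakpoint.  The amplified regions (profile coverage
   strictly above the 5x pruning threshold, merged, plus a 1 kb pad around
   every retained breakend) are segmented at the clean breakpoints: n
   breakpoints strictly inside a contiguous region give n + 1 fragments,
   each annotated with its length-weighted mean coverage.
3. **Graph encoding.**  Each fragment becomes a tail (start) and head (end)
   vertex joined by a fragment edge weighted by mean coverage.  SV edges
   follow the junction type: `DEL`/`BND` head-tail, `DUP` tail-head,
   `INV`/`INVDUP` both head-head and tail-tail; a `BND` with strand or
   bracket information gets exactly the one edge those strands dictate
   (this covers translocations and foldback junctions, whose two breakends
   nearly coincide).  Spatial edges join consecutive retained fragments on
   a chromosome (head of left to tail of right), weighted by
   junction-spanning reads when an alignment is available, else by
   `min(coverage left of the junction, coverage right of it)`.  Fragments
   with mean coverage <= 5x, or with no SV/spatial connection, are pruned
   to a fixpoint, and adjacency is recomputed across pruned gaps.
4. **Simple-cycle search.**  A cycle is an alternating closed walk
   (fragment edge, junction edge, ...); entering a fragment at the tail
   exits at the head ("+" orientation) and vice versa.  An exhaustive
   depth-first search rooted at each fragment in genomic order -- expanding
   junction edges by descending weight, with deterministic tie-breaks --
   enumerates every simple cycle (no fragment repeated).  Cycles are stored
   canonically: rotated to the 5'-leftmost fragment, direction chosen as
   the lexicographically smaller traversal, so rotation and reflection
   duplicates collapse.
5. **Clustering and derived cycles.**  Simple cycles sharing at least one
   fragment form clusters (connected components; fragment-disjoint by
   construction).  Within a cluster, the up-to-8 best-supported simple
   cycles (minimum junction weight, descending) are spliced pairwise -- and
   once more with a third ring -- at their leftmost shared fragment,
   reversing the inserted ring when orientations disagree.  Only rings with
   fragment-multiset Jaccard similarity <= 0.8 are merged, and at most 256
   derived rings are kept; this bounds the design matrix while still
   representing tandem and interspersed duplications, which are never
   simple cycles (they repeat a fragment).
6. **Quantification.**  Per cluster, fragment mean coverages `Y` are
   regressed on the occurrence matrix `X` (`x_ji` = times fragment `j`
   appears in cycle `i`) by non-negative LASSO with unpenalized intercept:

       (1/|F_k|) * sum_j (y_j - b0 - sum_i x_ji b_i)^2 + alpha * sum_i w_i |b_i|

   with `alpha = 0.1`.  Columns are not standardized, so coefficients stay
   in coverage units and read directly as proportions.  Cycles with
   `b_i > t` are kept, where `t` = (max over cycles of the minimum fragment
   coverage within that cycle) / 4, strictly.
7. **Candidate selection and output.**  Cycles with proportion <= the WGS
   background coverage are dropped; survivors longer than 0.1 Mb are
   labeled `ecDNA`, shorter ones `circular`.  Outputs are BED-like thread
   records (ring order, orientation, coverage, proportion, topology,
   label), a summary table, and optionally the ring sequence in FASTA.

## Design choices where the design was open

**Intercept anchoring.**  The intercept models linear-genome background
coverage, but every cluster row is an amplified fragment; when a cycle
covers all cluster fragments once, its column is exactly collinear with the
intercept and the L1 penalty would zero the proportion out.  The fit
therefore augments the system with a few rows (`max(2, |F_k|//4)`) of
background coverage with zero cycle membership, anchoring the intercept at
the genome-wide level.  The background level defaults to the
length-weighted median of the profile outside the amplified regions.

**Derived-cycle penalty weights.**  A spliced ring's column equals the sum
of its parents' columns, so coverage and junction data cannot distinguish
"one merged element" from "the co-occurring parents" -- the two scenarios
produce identical signals.  Plain L1 always prefers the merged ring (one
unit of its coefficient explains more coverage).  We weight the penalty of
a k-parent splice by `k * 1.01`: penalties become commensurate and the 1%
surcharge breaks the tie toward the parent decomposition, so
overlapping-footprint elements are reported separately with their own
proportions.  Derived rings are still selected whenever a parent is absent
from the simple set.

**Column deduplication.**  Two cycles with identical fragment multisets
(e.g. a called deletion junction parallel to a plain reference adjacency)
produce identical collinear columns; the pipeline keeps one representative,
preferring more SV-supported junctions, then higher minimum junction
weight.  Breakend evidence wins over trivially-available adjacency.

**Threshold scoping.**  The selection threshold formula is read as
`t = max over cycles ( min over that cycle's fragments of coverage ) / 4`.

**Spatial adjacency.**  Spatial edges connect only consecutive retained
fragments (immediate genomic neighbours), not all ordered pairs; all-pairs
edges would make every ordering reachable and square the cycle space.  The
maximum adjacency gap is unlimited by default and configurable.

**Multiregion gap.**  Two fragments on one chromosome belong to different
regions when separated by >= 10 kb (configurable); smaller gaps read as
deletions.  The seven-rank topology classifier assigns the highest matching
rank: Foldbacks (consecutive opposite-orientation fragments overlapping
genomically) > Duplications (a region > 50 bp covered twice by the ring) >
Multichromosomal > Multiregion > MixedSVs > SimpleSVs >
SimpleCircularization.  Junction typing is geometric: orientation flips
mark inversions; sub-10 kb footprint gaps mark deletions; the single
backward circularization junction every ring carries counts as neither.

## Synthetic data

The simulator draws template rings on a two-chromosome, 5 Mb-each toy
genome.  Defaults (chosen once as realistic study conditions): region
length U(50-500 kb); small deletions U(0.1-5 kb); inverted, duplicated and
folded segments U(5-50 kb); per-element proportions U(20-200) copies over a
5x background; engineered breakpoints at least 2 kb apart.  Topology
targeting uses per-class recipes (e.g. a Foldbacks template folds back over
the last 5-50 kb of a segment and resumes forward) with rejection sampling
against the classifier, capped at 50 retries.

Instead of simulating reads, the emitter writes what read simulation,
alignment and SV calling would yield under ideal conditions: one VCF record
per ring junction (type inferred from junction geometry, support = rounded
proportion, reference reads = rounded background, `STRANDS` annotation for
breakend-level orientation), a bedGraph equal to background plus
proportion x multiplicity per position, and a truth BED ring.  Tunable
imperfections: Gaussian per-100 bp-bin coverage noise on amplified
segments, uniform breakend jitter, and junction false-negative dropout.
In-silico dilutions scale proportions and background linearly and merge
records, mirroring BAM downsampling and merging.

What this does *not* emulate: sequencing error and chimeric reads,
mappability and GC bias, SV caller artifacts (imprecise or mistyped calls
beyond positional jitter), and segmental-duplication-induced ambiguity.
Passing tests therefore demonstrate the correctness of the graph/LASSO
machinery under the stated noise model, not robustness to every real-data
failure mode upstream of the VCF.

## Evaluation metrics

**Normalized largest contig** treats both reconstruction and truth as
circular sequences of oriented intervals and finds the longest contiguous
common stretch: pieces of base-pair overlap joined across junctions whose
exit/entry boundaries agree within 50 bp, free at both ends, stopped after
a full joint lap.  The stretch length divided by the true total length can
exceed 1 for reconstructions that repeat the truth.  This interval-ring
metric equals an alignment-based contiguity score on idealized fixtures
while staying deterministic and dependency-free; FASTA export is available
for external alignment-based scoring.

**Breakpoint recall/precision** match truth and reconstruction junctions
(breakend pairs with side labels) greedily one-to-one by smallest offset
within a 50 bp tolerance.  With no reconstructed junctions precision is
vacuously 1.0 and flagged.

A structural note: rings that traverse a fragment twice (pure palindromes,
tandem repeats) admit no simple-cycle representation; duplications are
recovered through the derived-ring splice, while a fold-back's repeated
segment is traversed once, so fold-back reconstructions score below 1 by
roughly the folded fraction.  This is inherent to the breakpoint-graph
model, and is why complex-topology performance is stated as a
largest-contig bound rather than exact identity.

## Numerical choices

The penalized fit uses scikit-learn coordinate descent (tolerance 1e-6, at
most 1e5 iterations, non-convergence raises); its `(1/2n)` MSE convention
means the penalty passed down is `alpha/2`, and the reported objective is
always re-evaluated with the `(1/n)` formula above.  `alpha = 0` falls back
to bounded least squares.  Coefficients below 1e-12 are clamped to zero.
All randomness flows from integer seeds through `numpy` `SeedSequence`
spawning; enumeration orders, tie-breaks and output sorting are
deterministic, so identical inputs produce byte-identical outputs.

Benchmark batteries run at desk scale: 100 templates per complex class for
the contiguity battery, 50 per simple class for the exactness battery, a
6-ratio dilution series and 20 noisy seeds for recall -- sizes chosen so a
full run completes in minutes on one core while estimating percentages to
a few points.

## Known limitations

- Repeat-dense structures beyond one splice depth (three parents) are not
  represented; the order of repeated segments can stay ambiguous.
- Proportion estimates for overlapping-footprint elements rest on the
  parent-preferring tie-break convention described above; the data alone
  cannot identify the merged/split decomposition.
- Elements whose diluted support falls below the SV filter, the 5x pruning
  threshold or the background level are invisible by design.
- The spatial-edge weight from coverage alone overestimates
  junction-spanning reads next to called junctions; supply a BAM for exact
  counts.
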