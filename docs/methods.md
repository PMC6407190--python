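# Methods

This note documents the models, parameter choices, numerical conventions and
known limitations of `karyoevo`.  Everything quantitative stated here is
computed by the test suite or by `scripts/acceptance.py`.

## The event algebra

Genes are atomic, ordered units; a chromosome is a list of gene loci with one
active centromere (a split point in `0..n`) and, after fusions, possibly
inactive centromeres whose positions are retained for bookkeeping.  All
operations are pure functions that deep-copy the genome and append a typed
event record.

* **NCF** `apply_ncf(donor, recipient, l, r, p)`: the donor interior `[l, r)`
  — which must carry the donor centromere — is inserted at ordinal `p` of the
  recipient; the donor's two distal fragments concatenate (left then right)
  into one satellite.  The recipient's centromere stays active, the donor's is
  flagged inactive.  `p` must lie in the pericentromeric window
  `centromere ± max(1, ceil(0.05 n))`; the 5 % half-width is a modeling
  choice (the biological description gives no distance) and is a parameter.
* **EEJ** `apply_eej(a, b, cut_a, cut_b)`: merged = `a[:cut_a] + b[cut_b:]`
  (junction at the cut ends, so the paint reads a-then-b), satellite =
  `a[cut_a:] + b[:cut_b]`.  Cuts must fall in the telomere-proximal windows
  (outermost `max(1, ceil(0.10 n))` ordinals per arm; again a parameter).
  `a`'s centromere stays active.
* **Reciprocal translocation**: arms distal to the cuts are exchanged; both
  cuts must be at or beyond the active centromeres so each product keeps
  exactly one; no satellite.
* **Inversion** reverses `[from, to)` and flips strands; it does not change
  origin labels and is therefore invisible to paint-level inference (it shows
  only as dotplot orientation).
* **Satellite loss** removes every satellite, one logged event each.

Ordinal splits are half-open (`a cut at k` separates `[0,k)` from `[k,n)`).
Physical coordinates are recomputed after every event by laying loci
end-to-end with their original lengths and a fixed 10 kb inter-gene gap, so
the chainer's distance-based gap penalty stays meaningful after arbitrarily
many rearrangements.

Event scripts are JSON; positions may be integer ordinals, fractions of the
current gene count, or the keyword `"centromere"`, which lets one script
serve any reference size.  The two bundled scripts encode the lineage
trajectories; for the double nestings (Bd1, Bd3, Bd4) the temporal order of
the two insertions is undetermined from the final paint — the scripts fix one
order arbitrarily, and both orders yield the same inferred event multiset.
The mechanism split of the two simple Triticeae fusions (T2, T7) is stated
only in aggregate ("4 NCFs and 1 end-end merge") in the source material;
the scripts encode them as NCFs to match that count, with the
smaller-numbered chromosome as recipient.

## The synthetic-data generator

`simulate` emulates a post-tetraploidy grass genome: `n_proto = 7`
proto-chromosomes of 200 genes (2 kb genes, 10 kb spacing), duplicated by a
WGD into 7 homoeologous pairs, fractionated (each duplicated copy survives
with probability `retention_rate = 0.7`, the biased mode deleting the
duplicate copy so one lineage stays complete), then rearranged by events
drawn from an NCF-dominated mix (weights 11 : 1 : 1 for
NCF : EEJ : translocation, the observed event census across the two studied
lineages; inversions default to 0 because paint-level inference cannot score
them).  Similarity is drawn per homology layer on the log10 E scale:
ortholog ~ N(−80, 10), outparalog ~ N(−30, 10), optional noise ~ N(−8, 2),
truncated to [−180, 0]; self-hits sit at the −180 floor.  Only the relative
ordering of layers matters downstream; the cap at 50 in the chain score makes
the exact ortholog mean irrelevant beyond being ≤ −50.

Two sampler constraints exist for recoverability, not realism:

* breakpoints are kept ≥ 5 genes away from origin-run boundaries, and NCF
  donors must have origin-uniform segment ends (an EEJ product inserted whole
  would leave a paint no parser could attribute);
* insertion points must have origin-uniform flanks.

A breakpoint closer to a boundary than the painting detectability limit
(`min_segment_anchors = 5`) leaves the true event underdetermined by *any*
method reading the final paint, so such events are excluded from the
benchmark regime by construction.  What passing the recovery benchmark shows
is therefore: on genomes whose events are in-principle recoverable, the
pipeline recovers them; it does not bound performance on events that erase
their own evidence.  Other realities the generator ignores: no sequence
evolution, no tandem duplication, no repeat content, no gene-length
variation, uniform gene spacing.

## Homology filtering and chaining

Hits are filtered per query to the best 5 non-self hits at E ≤ 1e−5
(optionally budgeted per subject genome), stored as canonical unordered
pairs.  Pairs touching a family with ≥ 30 members on a single chromosome are
removed; when no family table is supplied, families are single-linkage
components of the retained pairs.

Chaining is per chromosome pair and orientation: anchors sorted by query
ordinal; the DP transition allows at most `mg = 40` intervening genes on both
chromosomes and strict monotonicity (increasing subject ordinals forward,
decreasing reverse); anchor score `min(−log10 E, 50)` (E = 0 counts as the
cap); gap penalty 1 per 10 kb of inter-anchor distance summed over the two
chromosomes (a per-chromosome-maximum mode is selectable).  Chains are
extracted greedily best-first with deterministic tie-breaks (score, anchor
count, forward before reverse, lexicographic ids); each anchor lands in at
most one block; chains below 5 anchors stop the extraction.  Optimality of
the DP is property-tested against exhaustive subset enumeration.

### Block significance

The reporting threshold is E ≤ 1e−10.  The default closed form is an
expected-count bound: among `N` uniformly placed background pairs on an
`na × nb` gene grid, the expected number of monotone `k`-chains confined to
an `l1 × l2` ordinal window is

    C(N, k) · k! · na · nb · C(l1−2, k−2) · C(l2−2, k−2) / (na·nb)^k ,

evaluated in log space; the reported E-value is the minimum over sub-sizes
`k ≤ m` within the observed block's window, which makes it monotone
non-increasing in anchor count.  Tightness carries the signal: a gap-free
run has a single increment configuration, a diffuse chance chain pays the
full combinatorial factor — so a 20-anchor gap-free diagonal among a handful
of stray pairs is reported far below 1e−10, while a 20-anchor chain diffused
over a 200×200 grid dense with 400 random pairs is correctly insignificant
(random monotone chains of that length are *expected* there).  The
selectable permutation alternative shuffles the subject chromosome's gene
labels, re-runs the chainer, and fits a right Gumbel tail to the null
maxima; it is the assumption-free oracle used in tests (2000 shuffles
suffice because the fitted tail, prescribed precisely because empirical
resolution ends at 1/reps, is what is being read).

### Primary vs secondary, and painting

Blocks are classified per query-chromosome region: the best-scoring block is
primary, lower-scoring blocks overlapping ≥ 50 % of their own span with
primary territory are secondary; within-genome self-comparisons are always
secondary (paralogy from the ancestral polyploidy).  Ties break by anchor
count, then lower subject chromosome id, then leftmost start.

Painting is anchor-resolved rather than block-resolved: every anchor
position on the painted chromosome goes to the highest per-anchor similarity
weight among all blocks covering it (ties: block score).  This is
deliberate: on perfectly collinear synthetic data a single chain can
*straddle homology layers* — outparalog anchors of one region continuing
into ortholog anchors of the next — and any block-level primary choice then
mislabels one of the regions, whereas the pointwise rule keeps orthologous
evidence (capped at 50) above paralogous evidence (~30) wherever both exist.
Same-label runs merge; runs below `min_segment_anchors = 5` are absorbed
when flanked by one label on both sides, otherwise dropped.  Projection onto
the 7-letter proto alphabet uses the shipped Os→proto map (an editable
assumption: the tabulated correspondence pairs the two members of each
homoeologous pair, which is a simplification of the segment-level
literature) and merges adjacent same-label segments, so it never increases
the segment count.

## Trajectory inference

A chromosome's reduced label sequence is parsed by a small grammar: a
chromosome is a concatenation of units, a unit being a host label with
nested units strictly inside its span.  Each nested unit is one NCF
(invading = child root, invaded = host root — for insertions into an
already-fused intermediate the invaded label is the host's outer label);
each junction between top-level units is one EEJ; label sequences violating
the grammar (e.g. X,Y,X,Y) surface as AMBIGUOUS and are excluded from
counts with a warning, never guessed.  Reciprocal translocations are called
from pairs of chromosomes whose terminal units carry reciprocally exchanged
labels (each terminal root occurring natively in the partner); their
junctions are then not double-counted as EEJs, and a clean two-chromosome
exchange — which matches symmetrically at both end pairs — is reported once.
Chained translocations through the same chromosome can imply more pairwise
terminal exchanges than events occurred; only the single-translocation case
is claimed and tested.  NCF identity is directional (invading vs invaded);
EEJ and translocation identities are unordered, which makes the inferred
multiset invariant under paint reversal (property-tested).

Implied satellites = #NCF + #EEJ; the initial chromosome count is the final
count plus implied satellites.  Cross-lineage comparison matches events on
(type, label pair) with NCF direction significant.

## The fusion null

`homoeologous_fusion_pvalue` evaluates
∏<sub>i=0..k−1</sub> (n_pairs − i)/C(2·n_pairs − 2i, 2) in exact rational
arithmetic (`fractions.Fraction`); for the observed configuration
(7 pairs, k = 3) the internal rational is exactly 210/270270, reported as
0.00078 at 2 significant figures.  This formula is the probability that the
*first k sequential* fusions are all homoeologous, not a tail probability;
because the biological question arguably matches "k homoeologous among n
fusions in any order", the Monte-Carlo reports both: scheme (a), the oracle
for the closed form, and scheme (b), P(≥ k among n).  The simulator draws a
uniformly random perfect matching by pairing consecutive slots of a random
permutation — the first slot pair is a uniform pair and conditionally each
next pair is uniform among survivors, i.e. exactly sequential uniform
pairing — which vectorizes to one `permuted` call per grid cell.  The null
lives on the ancestral 14-chromosome karyotype: merged chromosomes count as
independent ancestral segments, which is why 7 fusions can occur although
the extant 12-chromosome pair map lists only 6 pairs.

## Problem sizes and determinism

Replayed lineage analyses use 100 genes per reference chromosome (1200
genes), enough that every paint segment clears the 5-anchor floor by a wide
margin; the recovery benchmark runs 20 seeds × {retention 1.0, 0.7} at the
same size with 2–6 NCF/EEJ events per run; the Monte-Carlo grid uses 1e5
replicates per cell.  These sizes were chosen so the full suite exercises
every stage in well under a minute of compute per criterion while leaving
each check's statistical resolution far finer than the tolerances asserted.
Every stochastic stage takes an explicit seed; the CLI fans a single global
seed out to stages by stable hashing, and rendering output is byte-stable
(fixed float formatting, stable element ordering) so identical inputs give
identical SVG bytes.

## Known limitations

* Real genome assemblies and real BLAST output are out of scope; the
  similarity generator stands in for them, and the pipeline's file formats
  (GFF3, BLAST tabular, TSV, BED) are the seam where real data would enter.
* Temporal order of independent events is not inferred (it is not present in
  the final paint).
* Inversions are rendered, not event-called.
* The homoeolog-pair map and Os→proto projection are perfect-matching
  simplifications shipped as config; segment-level homoeology (one
  chromosome pairing with two others over different segments) is not
  modeled.
* The analytic significance bound ignores the mg constraint (conservative
  for diffuse chains) and anchor-score heterogeneity; the permutation oracle
  is the reference when the two disagree.
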