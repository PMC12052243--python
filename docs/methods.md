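# Methods

## Problem and model

`kandel` calls deletion structural variants (≥ 50 bp) from long-read
alignments against a small reference. The signal is alignment-level:
a read whose sequenced molecule spans a deletion aligns with a large
`D` CIGAR operation, while sequencing noise contributes only short
indels. The caller therefore (i) converts each primary alignment into a
small typed graph, (ii) classifies graph nodes as deletion evidence or
background with a relational GCN + KAN network, and (iii) consolidates
per-read evidence into consensus intervals by density clustering.

### Graph construction

Each alignment is decomposed into segments typed match/insertion/
deletion/clip (codes 0–3). Insertions and deletions shorter than
`min_svlen` (default 50 bp, the conventional SV floor) are *absorbed*:
they advance the appropriate coordinate cursor but are fused into the
flanking match context rather than emitting a segment. The alternative
reading — discarding any read containing a small indel — would discard
essentially every long read at realistic error rates, so absorption is
the only workable interpretation; `min_svlen` is configurable.

Every segment yields a read-side node; reference-consuming segments
(match, deletion) also yield a ref-side node. Three edge relations are
stored as directed pairs in both directions: consecutive ref-side nodes
(ref-ref), consecutive read-side nodes (read-read), and the two copies
of each segment (ref-read; insertion/clip nodes, having no ref-side
copy, attach to the nearest preceding reference-consuming segment's
ref node, or the following one at a left edge). Self-loops are not
stored because the convolution has an explicit self-weight term.

Node features are `(v1, v2, v3, v4, start, end)`: one-hot over the
type scaled by segment length, plus the node's start/end coordinates —
read coordinates as-is, reference coordinates anchored to the alignment
start. All six entries are multiplied by `length_scale` (default 10⁻³,
recorded in the checkpoint and verified at prediction time): raw
genomic magnitudes (~10⁶) would otherwise swamp the 6-d feature space.
Graphs are per-read; no edges cross reads, and ref-side nodes are
duplicated per read rather than shared, which keeps batching a pure
disjoint union (batch output provably equals concatenated per-graph
outputs).

### Classifier

Pipeline: conv(6→8) → conv(8→4) → KAN(4→4) → linear(4→2) → softmax.
Each conv layer computes, per node *i* and relation set *R*,

    H_i' = ReLU( Σ_{r∈R} Σ_{j∈N_i^r} W_r H_j / C_{i,r} + W_0 H_i + b )

with `C_{i,r}` the in-degree of *i* under *r* (a relation with no
in-neighbours contributes nothing). In-degree normalization is the
simplest rule that "incorporates node degree information"; symmetric
√(d_i d_j) normalization was considered and not taken, as the
asymmetric ref/read chains make in-degree the natural notion.

The KAN layer replaces fixed activations with learnable univariate
functions summed over inputs:

    φ_{q,p}(x) = base_{q,p}·silu(x) + scale_{q,p}·Σ_m c_{q,p,m} B_m(x)

where `B_m` are the G + k cubic B-spline bases (G = 5 grid intervals,
order k = 3) on a uniform extended knot vector over [−2, 2]. Inputs
are clamped to the grid range (never an exception); the clamp gradient
is zero outside the range. Post-ReLU activations at these widths stay
within a few units, so a fixed [−2, 2] range suffices without batch
statistics. Alternative heads for ablation: `fc` (linear only), `kan`
(single KAN to 2 classes), `kan2` (two stacked KAN layers).

Parameter accounting for the default `kan_fc` head:
conv1 = 4·6·8 + 8 = 200, conv2 = 4·8·4 + 4 = 132,
KAN 4→4 = 16·(1 base + 1 scale + 8 coefficients) = 160,
linear = 4·2 + 2 = 10 — **502 scalars** (~5 × 10⁻⁴ M). `count_params`
walks the parameter arrays and must reproduce this closed form.

Training minimizes

    Loss = −(1/N) Σ_i w_{y_i} log p_{i,y_i} + (λ/2)‖W‖²₂

with class weights `[1−w, w]` (default w = 0.9; positives are rare),
λ = 10⁻⁴ over *all* trainable arrays (including spline coefficients),
log probabilities clamped at 10⁻¹², Adam at lr 10⁻³, 50 epochs,
minibatches of 32 graphs, all in float64 NumPy with hand-derived
gradients. The backward pass is validated against central finite
differences for every head. Fixed seeds give bit-identical training
runs. Hard labels are `argmax`, with the exact tie `p₀ = p₁` documented
as class 0.

### Consolidation

Positive, deletion-typed, ref-side nodes become candidate intervals
(read-side copies are skipped to avoid double counting). Per
chromosome, candidates are DBSCAN-clustered as 3-vectors
`(svlen, start, end)` under unscaled Euclidean distance — eps = 500 bp
and min_samples = 2 by default, sized to the O(100 bp) breakpoint
jitter of long-read aligners; no standardization, since the three
coordinates share base-pair units. Candidates left as noise pass
through the fragment-merge rule: adjacent fragments merge when
`start₂ − end₁ < α` (α = 3000 bp) **or** their shorter/longer length
ratio exceeds 0.7; both inequalities are strict, the or-gate follows
the rule's "any condition" reading, and an and-gate (`mode="all"`) is
available. Merged fragments span the hull of their members and are
density-clustered once more (min_samples = 1 — a lone merged hull is
already consolidated evidence). Finally the union of cluster-consensus
fragments and merged-noise fragments passes one *conjunctive* adjacency
merge: sub-clusters of a single fragmented long event sit within α of
each other at similar lengths and fuse, whereas applying the or-gate at
this level would wrongly fuse distant events that merely share a
length. Calls carry member-wise median breakpoints (the clustering
exists to produce accurate region centers), distinct-read support
(default min_support = 2, configurable to 1 for ultra-low coverage) and
mean classifier probability.

### Scoring

A predicted call matches a truth deletion when both breakpoints agree
within 1000 bp and reciprocal overlap (overlap / longer interval) is
≥ 0.7 — standard SV-benchmarking criteria, both configurable. Matching
is greedy one-to-one by descending reciprocal overlap with leftmost
tie-break. Precision bins by predicted length and recall by truth
length over the five bins [50,200), [200,500), [500,1000),
[1000,5000), [5000,∞), half-open to avoid double counting.

## Synthetic data generator

The generator emulates a microbial long-read resequencing experiment:

* uniform-composition multi-chromosome reference (default 2 × 1.2 Mb);
* 50 implanted deletions with log-uniform lengths on [50, 20000] bp —
  covering all five evaluation bins — placed non-overlapping with gaps
  of twice the maximum read length so no read spans two events;
* reads with lognormal lengths (median 10 kb, σ = 0.25, truncated to
  [2, 15] kb) at 30× depth, with ONT-like ~8% error split as 5.4%
  substitutions and 1.3% + 1.3% small insertions/deletions (event
  lengths 1–20 bp, capped below 50 bp so no noise op can reach the SV
  floor), optional end clips on 10% of reads;
* FLAG decoys — secondary (256) / supplementary (2048) duplicates of
  primary reads and unmapped (4) records — to exercise the record
  filter.

Alignments are computed *analytically* from the known donor→reference
map rather than with an external aligner: every read crossing a
deletion junction carries the event as a single `D` op of exactly the
implanted length. This keeps the desk-scale pipeline
dependency-light while matching minimap2's CIGAR semantics, but it is
also the generator's main departure from real data: a real aligner
would soft-clip short flanks, split very long events across
supplementary alignments, and produce locus-dependent breakpoint
jitter and occasional ≥ 50 bp noise indels in repeats. Passing tests on
this generator therefore demonstrate the correctness of the graph
construction, classifier and consolidation machinery under controlled
conditions — not calling accuracy on real ONT/PacBio data, chemistry-
specific (e.g. homopolymer-biased) error profiles, or non-deletion SV
types, all of which are out of scope.

All generator stages are seeded (`numpy` `default_rng` with per-stage
seed sequences); identical configurations produce byte-identical
FASTA/SAM/VCF outputs.

## Problem sizes used in the shipped analyses

The test suite and the acceptance script run three scenarios chosen to
exercise every claim at desk scale: a noise-free run (2 × 0.7 Mb, 20
deletions, 20×), the standard benchmark above (trained on chrI,
scored on held-out chrII, with the FC vs KAN+FC head ablation and the
raw-candidates vs consolidated-calls comparison), and a long-deletion
panel (ten 5–20 kb deletions at 30×). Together they complete in a few
minutes on one CPU.

## Known limitations

* Deletions only; insertions, inversions, duplications and
  translocations are not modeled (the FLAG filter even removes the
  split-read evidence such callers use).
* No MAPQ filtering and no genotyping.
* The conjunctive final merge assumes fragments of one event have
  similar lengths; a long event split very asymmetrically can remain
  two calls.
* Reference N/ambiguity codes and BAM `=`/`X` subtleties beyond
  normalization to `M` are untested against real aligner output.
* On htslib-backed VCF output, symbolic `<DEL>` records follow the
  padding-base convention with `END` derived from `SVLEN`; callers
  using `POS` = first deleted base will appear shifted by one.
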