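# Methods

## The consensus model

`sparsecons` polishes a draft sequence (the *backbone*) using query
sequences aligned to it.  The backbone is encoded as a linear chain of
position-anchored k-mers: an anchor is stored every `g` bases, and the
edge between consecutive anchors carries the `g` intervening bases as
its label, so emitting the first anchor's k-mer and then concatenating
edge labels along the chain reproduces the backbone exactly (a few
trailing bases shorter than one step are carried separately as the
tail).  Unlike a de Bruijn graph, the same k-mer string at two backbone
positions is two distinct nodes: position specificity is what lets a
single graph represent a megabase-scale alignment pileup without
collapsing repeats.

Each query alignment is threaded through this graph one anchor-to-anchor
step at a time.  Where the query agrees with an existing path the edge
weights are incremented (implicit merging); where it proposes a variant,
new branch nodes and edges are allocated — one node per `g` emitted
bases, keyed by `(left anchor, ordinal along the branch, k-mer)` so two
queries carrying the same variant in the same place share nodes and
accumulate weight.  An anchor whose entire k-mer window is deleted in
the query is jumped, giving a deletion edge whose label may be shorter
than `g`, or empty.  Alignment overhangs that do not complete a step are
discarded rather than partially credited, so every unit of weight is
attached to a well-defined edge.

Edge weight is multiplicity: the number of alignments supporting the
link, our proxy for confidence.  Before the path search every edge
weight is reduced by a penalty

```
p = max(c, t * mean backbone multiplicity)
```

— a soft threshold (an l1 penalty on the weights).  Without it the path
with the most summed weight can be a long single-read insertion (many
edges, each weight 1); with it such paths score `(1 - p)` per edge and
lose to genuinely supported alternatives.  The adaptive term scales the
penalty with coverage.  Negative adjusted weights are kept, never
clamped, and edges are never deleted: a weak true path flanked by strong
ones remains recoverable.

The consensus is the heaviest path under adjusted weights.  Because the
graph is a DAG ordered by `(anchor, branch offset)`, one relaxation pass
in that order computes, for every node, the best accumulated score and
its predecessor; the consensus is the backtrack from the highest-scoring
*backbone* node.  Ties prefer the larger anchor (the longer consensus),
then a backbone predecessor, then the lexicographically smaller incoming
label — determinism, not science.  The backbone tail is appended only
when the terminal is the last anchor.

Polishing iterates: the round-one consensus becomes the round-two
backbone, reads are re-aligned, and the graph is rebuilt.  Two rounds
capture most of the gain; error-free full-coverage input is a fixed
point.

## Parameters

| parameter | default | meaning / working range |
| --- | --- | --- |
| `k` | 1 | anchor k-mer size; 1–3.  Larger k enforces stricter merges (helpful at high error or for polyploid data) at more memory. |
| `g` | 1 | anchor spacing; 1–5.  Sparse anchors cut memory roughly 1/g with similar resolving power. |
| `c` | 2.0 | fixed penalty floor; 1–3. |
| `t` | 0.2 | adaptive penalty as a fraction of mean backbone multiplicity; 0.1–0.3. |
| `b` | 0 | extra weight per high-quality (NGS) query supporting an edge; 5–15 in hybrid runs.  Applied additively per alignment (increment `1 + b`). |
| `rounds` | 2 | polishing iterations. |

`k = 1, g = 1` suits ~15% error (PacBio-like) input; `k = 2, g = 2`
suits ~40% (Nanopore-like) input.  High-quality queries are identified
by a name prefix (default `hq`).

One deliberately global choice: the adaptive penalty uses the *mean*
backbone multiplicity of the whole contig rather than a per-region
coverage estimate.  Windowed penalties would react to coverage dips but
also to alignment dropouts; the global mean is the simpler, more
predictable reading and is what all tests pin down.  The mean is taken
over anchor-to-anchor backbone edges only — the virtual-source edge is
structural (it emits the first k-mer, is shared by every path, and is
never incremented because overhanging first steps are discarded), so
including it would bias the estimate down.

## The internal aligner

The polishing loop needs query-to-backbone alignments each round; an
external mapper's M5 output can be supplied instead, but the built-in
aligner keeps the loop self-contained.  It is deliberately simple:

* **locate** — exact `seed_len`-mer matches (default 10) voted on
  64-wide diagonal bins, both strands; seeds occurring more than 16
  times on the backbone are skipped.  The winning bin (with neighbours)
  gives strand and diagonal; fewer than two votes means unplaced.
* **banded align** — a banded DP around the seeded diagonal, global in
  the read, free start/end in the target, linear gap costs (match +1,
  mismatch −1, gap −1).  The automatic band half-width is
  `max(64, 0.3·L + 16)` for a read of length `L`, covering the indel
  drift of even 40%-error reads.  With a band at least the sequence
  length the result provably equals the unbanded optimum, which is how
  the tests pin it.  The emitted M5 `score` field is the negated
  alignment score (negative-is-better, matching the external tool
  convention).

Alignments are reported with gapped strings in target-forward
orientation for both strands (minus-strand reads are
reverse-complemented before the DP), so the graph threading never has to
reorient anything.  Each read keeps only its best placement (most
pattern-recomputed matches, then lower score field, then first seen).

## Synthetic data

The generator emulates a long-read polishing experiment at desk scale:

* uniform i.i.d. A/C/G/T reference;
* reads sampled on both strands with lengths N(2000, 500) truncated at
  100 bp, start positions drawn from `[-(L-1), G-1]` and clipped to the
  reference so that coverage is *uniform across the whole target*.  This
  models polishing a contig whose supporting reads extend beyond its
  ends (the situation of real assembly backbones); sampling only
  fully-interior reads would instead taper coverage to zero at the ends
  and any coverage-adaptive method would truncate or mispolish there;
* per-base errors: delete with `del_rate`, else substitute with
  `sub_rate` (to a different base), and independently insert uniform
  bases after the position, geometrically repeated with `ins_rate`.
  Presets: `pacbio` = 0.01/0.09/0.05 (≈15% total, indel-dominated),
  `nanopore` = 0.12/0.08/0.20 (≈40% total, deletion-heavy);
* the draft backbone is the reference corrupted with the same profile —
  a deliberately bad draft, matching the error level of the raw data it
  came from;
* hybrid runs add error-free `hq`-prefixed queries (default 2 kb) at low
  coverage, standing in for accurate short-read contigs.

What the generator does *not* emulate: homopolymer-biased and otherwise
context-dependent error profiles, chimeric reads, quality strings,
repeats and heterozygosity.  Passing tests therefore demonstrate the
graph/penalty/search machinery under realistic error *rates*, not
performance on the hard structure of real genomes.

The evaluator is a global edit alignment (via edlib) of consensus
against truth; the error rate is (mismatches + insertions + deletions) /
alignment columns, an n-base gap counting as n errors — a desk-scale
stand-in for whole-assembly diff tools.

## Numerical and degenerate-input choices

* Weights are floats (boost values need not be integral); all score
  comparisons are exact float comparisons on sums of identical terms,
  which is deterministic for identical inputs.
* The DP uses int32 with a −2²⁸ sentinel for unreachable cells; the
  traceback re-derives moves by value checks on the stored matrix.
* Empty edge labels (full deletion of a step) are legal and emit
  nothing.
* A backbone shorter than `k` is an argument error; a backbone with a
  single anchor has no backbone edges and reports multiplicity 1.
* k-mers containing N never merge with backbone anchors (they always
  branch).
* Reads that cannot be located, or whose alignment spans less than
  `min_span` (50 bp) of target, are counted and skipped, never fatal;
  an alignment crediting no complete step is likewise only counted.

## Problem sizes used in the test and acceptance runs

The desk-scale twin of a full polishing experiment is a 20 kb genome at
30× PacBio-preset coverage with 2 kb reads, two rounds, `k=1, g=1, c=2,
t=0.2`, ten seeds — small enough to re-run routinely, large enough that
per-base error rates are estimated on ~20 000 columns.  Trend checks
(round-over-round improvement, 30× vs 10×, hybrid vs non-hybrid at the
Nanopore preset) run on 4–6 kb genomes with 800 bp reads over 8–20
paired seeds.  These sizes are the package's chosen study conditions and
are fixed in the tests.

## Known limitations

* The first `k` backbone bases are emitted unconditionally by the
  virtual-source edge, so an error in the very first anchor k-mer
  cannot be corrected (one base at the defaults).
* Branch k-mers inherit the query's rolling context, so the same variant
  preceded by different nearby errors in two reads can split support
  across two branch paths; deep coverage makes this immaterial.
* The aligner is a straightforward banded DP without affine gaps or
  SIMD; it is the package's plumbing, not a general-purpose mapper, and
  makes no attempt to reproduce any external aligner's scores.
* Multi-contig inputs are polished independently; in reads mode a query
  that places on several contigs is simply aligned to each.
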