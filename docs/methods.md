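# Methods

## The problem

Short-read aligners map each read to the reference independently. Reads
that observe the same non-reference allele are highly correlated, yet
independent alignment scatters that evidence: indels near read ends get
traded for mismatches or soft clips, equivalent indel placements disagree
across reads, and nearby variants push local alignments apart. The result
is false variant calls — most visibly at apparently heterozygous sites —
and reference-biased allele counts.

`srma` performs *local re-alignment*: it pools all alignments overlapping a
small genomic window into a variant graph and re-aligns each read to that
graph, so a variant observed by at least one read can anchor the
alignments of every other read that covers it. It is a micro re-aligner:
it never moves a read far from its original location and never invents a
variant no read observed.

## The variant graph

Nodes are single bases anchored to 1-based forward-strand reference
coordinates, of three types: reference, substitution, and insertion.
Inserted bases take the position of the next non-inserted reference base
and an offset 1..k within the inserted run; this gives the canonical total
node order (position; insertion block before its anchor base, by offset;
type; base) that makes the graph a DAG in either traversal direction.
Adjacent read bases contribute undirected edges; a deletion is an edge
between zero-offset nodes more than one position apart. Nodes count the
alignments through them (coverage) and edges count the alignments
containing the adjacency; `N` at a position is the total zero-offset
coverage there.

Practical choices:

* Soft-clipped bases are not aligned bases and contribute nothing; hard
  clips are ignored.
* A read base of `N` (or any non-ACGT code) or with quality 0 that
  mismatches the reference is routed through the reference node rather
  than creating a substitution node. This keeps the path property and the
  coverage bookkeeping intact while preventing no-calls from minting
  spurious variant nodes.
* Insertions merge by node identity on (position, offset, base), which
  merges common prefixes of co-located insertions. Suffix merging of
  unequal-length insertions is not implemented: with begin-anchored
  offsets the suffixes occupy different offsets, and merging them would
  require re-anchoring; differing suffixes therefore remain distinct
  paths.
* The graph is never edited by the coverage filters; filtering happens at
  path-expansion time, so one graph serves any `(c, p)` setting.

## Coverage filters

Two OR-combined filters decide whether a path may use a node or edge
observed `n` times at a position with depth `N`: an absolute minimum
`c` (default 2), and a binomial test `Pr(x <= n | N) >= p` (default 0.1)
with `x ~ Binomial(N, 1/2)` — the balanced-allele model for a diploid
genome. At high depth the binomial term suppresses rare observations
(sequencing errors); at low depth it keeps alleles that simply were not
sampled often. The edge test is anchored on the genome-later endpoint's
`N`, making filtering independent of traversal direction. Deletion edges
carry no `N` of their own and use the same rule.

## Re-alignment

Paths may start at any node within `w` (default 20) reference positions of
the original alignment start — the 5' end in the read's strand direction,
so reverse-strand reads traverse the graph backwards. The search is a
heap-ordered breadth-first dynamic program: the heap sorts partial paths
by canonical node order, then path length, then score, which on a DAG
guarantees every entry into a state is pushed before that state pops.
Partial paths sharing `(node, path length)` are pruned to the best score
(on ties, the prefix lying on the original alignment's path survives, so
the "prefer the original alignment" rule is respected at merge points).

Scoring: a matching base costs nothing; a mismatch costs the base's Phred
quality, capped at 40. There are no gap penalties — indels are legal graph
edges, priced implicitly by the coverage filters. The original alignment's
score, recomputed against the reference along its own CIGAR, bounds the
search from below: scores only decrease along a path, so anything below
the bound is dropped. If no surviving complete path reaches the bound the
read keeps its original alignment. Complete-path ties prefer the original
alignment, then fewer indel operations, then the leftmost start, then
canonical node order — determinism the tests rely on.

Two engineering notes. First, a read whose original alignment already
scores 0 cannot be improved (ties keep the original), so the search is
skipped; this is what makes whole-genome throughput acceptable, since most
reads are error-free and variant-free. Second, the statement that a node
is visited at most `w` times per re-alignment describes the traversal's
complexity, not an enforced prune: a hard per-node cap can cut off an
optimal path (start offsets plus deletions can legitimately give a node
more distinct path lengths), and the implementation's exactness is tested
against exhaustive enumeration. A configurable cap (`max_node_visits`) and
a heap-size valve (default 8192 entries; overflow returns the original
alignment, flagged) bound the pathological cases.

Soft-clipped bases are preserved verbatim and only the aligned core is
re-aligned. Mate fields and mapping quality are never changed; re-aligned
records get POS/CIGAR rewritten, NM recomputed, and a `ZR:i:1` tag.

## Color space

ABI SOLiD reads are sequenced as two-base-encoded colors: the color of a
dibase is the XOR of the 2-bit base codes, so a true base change alters
two adjacent colors while a single sequencing error alters one. Decoding
errors therefore bias decoded bases toward the reference. When a record
carries CS/CQ tags, re-alignment scores the *original* colors against the
colors expected from consecutive path bases (the first from the adapter —
complemented for reverse-strand reads — or the adjacent clipped base),
with a mismatch costing the color quality, capped at 40. Decoded bases are
constrained to equal the path bases, so the state space is identical to
base-space scoring (the tests count expanded states to confirm). Records
without CS/CQ fall back to base-space scoring automatically.

## Streaming

Input must be coordinate-sorted. Each record is added to the graph on
arrival and re-aligned once the stream has advanced `w + max_indel`
(default 120) bases past its end, so its graph window is complete; the
graph is pruned behind the earliest pending read. Output order is restored
with a small reorder heap (re-alignment can shift a start by at most `w`).
Peak memory therefore holds one window of reads, not the file. Region
processing re-aligns only reads starting inside the region while feeding
the graph from a margin around it; processing adjacent regions and
merging reproduces the whole-file result, which is how large inputs
parallelise.

## Simulator

The generator emulates the study conditions of a diploid human
re-sequencing experiment:

| parameter | default | meaning |
| --- | --- | --- |
| polymorphism_rate | 1/1000 | per-base probability a site is variant |
| homozygous_prob | 1/3 | variant on both haplotypes, else one at random |
| indel_fraction_each | 0.05 | fraction of variants that are INS (and DEL) |
| indel_extension_prob | 0.3 | per-extra-base extension; mean length 1/0.7 |
| read_length | 50 | bases per end |
| haploid_coverage | 15 | depth per haplotype (total ~2x this) |
| insert_mean / insert_sd | 500 / 50 | outer pair distance, normal, rounded |
| base_error_rate | 0.01 | uniform substitution error (base space) |
| color_error_rate | 0.05 | uniform color error (color space) |

Base qualities are uniform and derived from the error rate (Q20 at 1%).
Insertion alleles are uniform random bases. Deletions may not overlap each
other on a haplotype (colliding ones are re-placed uniformly); other
overlaps are allowed, so a SNP inside a deletion is simply invisible on
that haplotype. Error positions are i.i.d.; real error rates rise toward
read ends, which is deliberately not modelled, so passing tests say
nothing about position-dependent error structure, PCR artifacts,
contamination, or repeat-induced mis-mapping — the initial aligner is
anchored near each read's true origin, so mapping error is out of scope
by construction.

Color-space reads store the corrupted color stream in CS/CQ and carry the
naive cumulative decode of those colors as their base sequence — the
honest alignment-free behaviour in which one color error corrupts the
downstream decode.

### Stand-in initial aligner

Reads are aligned within a window around their true origin (span ± 35)
using unit-cost semi-global alignment (edlib); alignments that look like a
real mapper's output (at most one contiguous indel block, few edits) are
accepted, anything messier is re-aligned with an affine-gap Gotoh DP
(match 0, mismatch 3, gap 10 + 1/base; ties prefer consuming more
reference so spanned deletions beat equal-cost read insertions). This
reproduces the upstream behaviour the method expects: well-anchored indels
are reported, indels within ~15 bases of a read end are traded for
mismatches or clipped. It is a stand-in, not a re-implementation of any
production aligner.

### Stand-in caller

Variant calling is a simple quality-agnostic diploid genotype likelihood
per column (and per indel allele grouped by position and allele string),
with symmetric per-base error (default 1%, indels 1e-3), flat genotype
prior, variant quality = Phred posterior of homozygous reference, and
minimum evidence of 2 alternate observations at depth >= 4. It is labelled
a stand-in: all before/after comparisons run the same caller on both
alignment sets so caller bias cancels, and no claim is made of numerical
agreement with any production consensus model.

## Evaluation

ROC: a call is a true positive when a truth row of the same type exists at
the same position; indels match within ±5 bases, since equivalent
placements shift against the reference. Sensitivity is truth sites hit;
the false-positive rate divides unmatched calls by callable reference
positions (genome length minus truth sites) — the denominator is a
convention, fixed and documented. Catalog concordance calls an indel
concordant when a catalog entry within ±5 bases has exactly the same
length. The allele-frequency spectrum reports non-reference frequency
(alt count / depth) per call, split by zygosity and type; heterozygous
sites should centre on 0.5 and homozygous near 1.0, and the shift of
those medians before vs after re-alignment is the reference-bias readout.

## Problem sizes

The end-to-end checks run a 2 Mb genome in the acceptance script and a
1.05 Mb genome in the test suite (both keep >= 1e6 callable negative
positions, so an FPR of 1e-6 is measurable); parameter recovery uses an
11 Mb truth table (>= 10^4 variants, >= 10^3 indels) and >= 10^4 read
pairs. These sizes are the package's chosen compromise between statistical
resolution and a few minutes of single-CPU runtime.

## Known limitations

* No iterative re-application, no flow-space (454) homopolymer model, no
  known-variant priors, no CRAM, no mate-aware rescue.
* Suffix merging of co-located insertions is not performed (see above).
* Gap-free scoring means an initial alignment that hides errors inside a
  spurious insertion can set a bound no honest path beats; such reads keep
  their original alignment.
* The binomial filter assumes two alleles at a site; heavily multiallelic
  columns are handled but the filter is then conservative.
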