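# Methods

## Problem and model

CRISPR arrays record past phage and plasmid encounters as an ordered series
of ~30 nt spacers.  Because acquisition is polarized to the 5' end of the
array, the 3' end holds the oldest, most conserved spacers; comparing spacer
content across bacterial isolates is therefore both a typing method and a
phage-exposure history.  The standard presentation colors each distinct
spacer and draws arrays as rows of glyphs.  `spacerviz` automates that
presentation from CRISPRDetect GFF3 output.

The unit of comparison is the **adjusted number of nucleotide mismatches**
between two spacers.  Given the optimal local alignment of a query spacer of
length `q` against a subject, with `L` alignment columns, `m` mismatch
columns and `g` gap columns,

```
adjusted = q − (L − m − g)
```

i.e. the query length minus the number of identical aligned columns.  A
partial local alignment is penalized over the full query length: trimmed
overhangs count exactly like mismatches.  Two spacers are treated as "the
same" when the adjusted score, minimized over the two query directions, is
at most a user cutoff (**default 2**, which absorbs point mutations and the
occasional sequencing error without linking unrelated sequences; cutoff 0
demands sequence identity).  Similarity is then closed transitively: clusters
are the connected components of the pairwise similarity graph, so a chain
A–B–C shares one cluster even if A and C individually exceed the cutoff.  No
attempt is made to distinguish diverged spacers from independent acquisition
events at nearby protospacer positions — with a low cutoff the two are not
separable from sequence alone.

## Alignment engine

Alignments are computed by a built-in affine-gap Smith–Waterman (Gotoh)
implementation with DNA-style scoring: match +5, mismatch −4, gap open −12
for the first gap column, −4 per additional column.  `N` and all other IUPAC
ambiguity codes match nothing.  Among equal-scoring local alignments the
engine deterministically prefers more aligned columns, then fewer gap
columns, then more identical columns; this total objective
(score, columns, −gaps, matches) makes the reported statistics well defined,
because co-optimal alignments can otherwise disagree on the adjusted score
(e.g. trading three mismatches against a gap opening).  The DP packs the
four-component objective into one integer (weights 10^12 / 10^6 / 10^3 / 1,
valid for sequences up to 400 nt) and recovers the column statistics by
traceback.  The test suite checks the engine cell-for-cell against an
independent tuple-valued reference implementation on thousands of random
pairs.

Spacers are orientation-normalized at parse time (arrays on the minus strand
are reverse-complemented and renumbered 5'→3'), so only the forward strand
is aligned; a spacer and its reverse complement are deliberately unrelated.
Identical sequences are grouped before alignment; the statistics of one
alignment per unique pair are fanned out to all record pairs, which cannot
change any score.  The symmetric pair score is the minimum over the two
query directions, which equals `min(len_a, len_b) − matches` since the
alignment statistics are direction-independent.

## Colors

Each cluster is drawn as a square plus an inscribed diamond, each with a
3-digit HEX color.  Squares are unique across clusters (so the square alone
identifies a cluster), the diamond differs from its square, and the reserved
gray-out glyph (white `#fff` square, light-gray `#ccc` diamond) is never
assigned; this caps a figure at 4095 colored clusters, beyond which the
package suggests graying out unique spacers.  Colors are drawn from a seeded
`random.Random`; with a fixed seed the store is bit-identical across runs.

Append mode re-links clusters of a rerun to a saved store through one
representative sequence per cluster (the sequence of the id-smallest
member): exact match first, otherwise alignment within the clustering
cutoff.  Matching representatives rather than re-aligning against every
prior spacer is an optimization; the two agree whenever prior clusters obey
the cutoff, and tests cover the id-drift case where a new mutated member
changes the cluster id.  If appended spacers bridge two prior clusters, the
merged cluster keeps the pair of the larger prior cluster (tie: smaller
cluster id) — a policy choice for a case the original workflow leaves
unspecified; the store therefore records cluster sizes.

## Ordering

The default row order comes from a guide tree: the pairwise shared-spacer
count (per cluster, the minimum of the two samples' abundance; all loci of a
sample pooled) is converted to Bray–Curtis dissimilarity
`D = 1 − 2·shared/(S_i + S_j)` and clustered with UPGMA.  The UPGMA
implementation is in-package so that tie-breaking is fully specified: among
equally close pairs, the pair whose earliest-input member comes first is
merged, and the earlier-input subtree is placed left.  An all-equal matrix
therefore reproduces the input order exactly.  On tie-free matrices the
ultrametric heights are checked against SciPy's average-linkage cophenetic
distances.  The tree is a display aid, not a phylogeny, and can be exported
as Newick.  A plain-text custom list (or raw input order) can replace the
tree order; unknown ids and unlisted samples are warnings, never errors.

## Rendering

One row per sample; one column per locus number with CRISPR 1 rightmost and
higher numbers extending leftward (a flag reverses this); within a column
every locus is right-aligned so conserved 3'-terminal spacers line up
vertically.  Geometry defaults: 20-unit cells, 2-unit gaps, 30-unit column
gap, diamond vertices at edge midpoints — all parameters, chosen to match
published figure proportions.  The SVG uses only `rect`, `polygon` and
`text` elements, integer coordinates and a fixed element order, so identical
scenes serialize byte-identically; fonts are referenced, not embedded,
because the intended workflow ends in a vector editor.  Length labels
(drawn on grayed cells, or everywhere with `label_all`) support the manual
check for mis-split loci.

## Sanity warnings

The mean spacer length is computed over the whole dataset and any spacer
strictly more than 1.5× longer or shorter than the mean is flagged (a
spacer at exactly 1.5× is not — the boundary is exclusive by choice, to
avoid warning on exact multiples).  Such outliers usually mean the upstream
miner fused a repeat and spacer.  A dataset whose samples carry different
numbers of loci gets one informational note, since that is when locus
numbering across samples is most often inconsistent; renumbering is left to
the user (edit the spacer FASTA and restart — the FASTA round-trips every
identity field).

## Synthetic data

The fixture generator emulates the structure the figures exploit: samples
are assigned to "sharing pools"; locus 1 of each sample ends with a suffix
of its pool's ancestral array (conserved 3' content) and acquires unique
random spacers at the 5' end; additional loci are all-unique.  Spacer
lengths are uniform on 28–38 nt, loci land on either strand with
probability 0.3, repeats are emitted as `direct_repeat` features, and
shared copies can be mutated at a per-nucleotide substitution rate
(default 0, i.e. clonal sharing).  Defaults are 6 samples, 1–2 loci per
sample, 4–12 spacers per locus, 2 pools of 8 ancestral spacers.  The
generator writes ground truth (true cluster per spacer, true shared counts
per sample pair) and is fully seeded.

What the generator does **not** emulate: repeat/spacer mis-splits, internal
spacer deletions, locus misnumbering across samples, sequencing-error
indels, and realistic phylogenetic signal — so passing recovery tests shows
the pipeline is correct on clean, well-polarized data, not that upstream
mining errors are handled automatically (they are surfaced as warnings for
manual curation by design).

## Problem sizes and numerical choices

The test and verification surface runs on desk-scale data: the standard
fixture (seed 1) has 6 samples and 74 spacers; aligner/oracle agreement is
checked on 300–1000 random pairs of 20–40 nt; clustering is checked against
Floyd–Warshall reachability on up to 200 random graphs of ≤50 nodes;
guide-tree recovery uses 100 replicates of a 9-sample, 3-pool design at
mutation rate 0, scoring a replicate as successful when every pool's
members are contiguous in leaf order.  All randomness flows from explicit
seeds.  Distances are exact rationals up to float arithmetic; the only
tolerance in the package's own checks is 1e-7 on cophenetic distances,
reflecting the 10-significant-digit branch lengths written to Newick.

## Known limitations

- All-vs-all alignment is quadratic in unique spacers; the pure-Python DP
  handles hundreds of spacers in seconds but is not intended for >10^5
  spacers (no banding or seeding).
- Transitive closure can chain well beyond the cutoff in dense datasets;
  this is faithful to the clustering definition but worth remembering when
  interpreting shared colors.
- Color assignment optimizes distinctness, not perceptual spacing or
  colorblind safety; the SVG is meant to be edited.
- The guide tree is ultrametric display scaffolding; do not read it as a
  phylogeny.
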