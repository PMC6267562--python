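# spacerviz

Compare, cluster, order and draw CRISPR spacer arrays across bacterial
isolates, starting from CRISPRDetect GFF3 output and ending in a
presentation-ready SVG figure.

CRISPR arrays archive past phage and plasmid encounters as ordered ~30 nt
spacers, with new spacers added at the 5' end and the oldest, most conserved
ones at the 3' end.  Comparing spacer content across strains is a classic
typing method, and the field's standard figure draws each array as a row of
colored glyphs in which identical spacers share a color.  `spacerviz`
automates that figure for anyone doing CRISPR typing or phage-exposure
studies on more than a handful of genomes.

## What it computes

1. **Spacer extraction** — spacers are read from `repeat_region` /
   `binding_site` (or `Spacer`) features, reverse-complemented and
   renumbered 5'→3' for minus-strand arrays, and exported to one
   dataset-wide FASTA (headers
   `sample|locus<k>|spacer<j>|start|end|length|strand`) that can be
   hand-edited and fed back in.
2. **Pairwise comparison** — every spacer pair is locally aligned
   (built-in affine Smith–Waterman: match +5, mismatch −4, gap open −12,
   extend −4) and scored by the *adjusted number of nucleotide mismatches*

   `adjusted = q − (L − m − g)`

   for query length *q*, alignment length *L*, *m* mismatches and *g* gap
   columns — the query length minus the identical aligned columns, so
   partial alignments are penalized over the full query.
3. **Clustering** — pairs with adjusted score ≤ cutoff (default **2**;
   0 = exact identity) are linked and clusters are the transitive closure:
   if A is similar to B and B to C, all three form one cluster.
4. **Colors** — each cluster receives a seeded-random pair of 3-digit HEX
   codes (square + center diamond); a saved color store keeps colors stable
   when the dataset grows.  Unique or shared spacers can be grayed out
   (white square, light-gray diamond).
5. **Ordering** — strains are sorted by the leaf order of a UPGMA guide
   tree built on Bray–Curtis dissimilarities of shared-spacer counts
   (`D = 1 − 2·shared/(S_i+S_j)`), or by a custom list, or left in input
   order.
6. **Rendering** — rows per sample, one column per locus (CRISPR 1
   rightmost), every locus right-aligned so conserved 3' spacers line up
   vertically; output is deterministic SVG 1.1 meant for post-editing in
   Inkscape or Illustrator.

See `docs/methods.md` for the model details, tie-breaking rules and known
limitations.

## Worked example

The package ships a seeded generator of synthetic CRISPRDetect-style
datasets with known ground truth:

```sh
python -c "from spacerviz.fixtures import FixtureSpec, generate_fixture; \
           generate_fixture(FixtureSpec(seed=1), 'demo/gff')"
spacerviz -i demo/gff --seed 7 --out-dir demo/out
```

prints

```
6 samples, 74 spacers, 59 clusters at cutoff 2
figure: demo/out/figure.svg
spacer FASTA: demo/out/spacers.fasta
color store: demo/out/colors.tsv

1 warning(s) for manual inspection:
  - samples carry differing numbers of CRISPR loci (S001:2, S002:1, S003:1, S004:1, S005:1, S006:2); check locus numbering for consistency
```

74 spacers collapse into 59 clusters: the six samples draw their 3'-terminal
spacers from two ancestral pools, so pool-mates share clusters (and colors)
while 5' spacers are unique.  The warning is the manual-inspection aid — a
mix of 1- and 2-locus samples is exactly the situation in which upstream
locus numbering deserves a look.  `demo/out/clusters.tsv` lists every
spacer's cluster, e.g.

```
spacer_id               cluster_id              cluster_size
S001|locus1|spacer3     S001|locus1|spacer3     2
S003|locus1|spacer3     S001|locus1|spacer3     2
```

and `demo/out/guide_tree.nwk` holds the guide tree whose leaf order sorts
the rows, placing the pool-mates (S001, S003, S005) and (S002, S004, S006)
in adjacent blocks.  Rerunning with `--colors demo/out/colors.tsv` after
appending new genomes keeps every existing cluster's colors; `--gray unique`
or `--gray shared` switches the gray-out mode; `--cutoff 0` splits every
mismatching pair into its own color.

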