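# Methods

## Overview

metaprof analyses a shotgun metagenome in two arms.  The taxonomic arm
detects rRNA marker fragments in raw reads with a profile HMM, maps them to
taxonomy-annotated reference sets, and aggregates the assignments into
per-rank abundance profiles.  The functional arm predicts genes on
pre-assembled contigs, transfers annotations from a reference protein set
by best hit, and summarises them as GO-slim and 4-level SEED profiles.
Both arms feed deterministic visual exports.  Assembly is deliberately
consumed, not performed: any assembler's contig FASTA is accepted.

## Read simulator

The simulator emulates a whole-genome shotgun run over a defined community.
Per read: source genome ~ multinomial(abundance vector); start position
uniform over valid offsets; strand uniform; each base substituted with
probability `err_rate` to a uniformly chosen different base.  Defaults are
100 bp reads and a 1% substitution rate — the standard short-read regime
this kind of pipeline is evaluated in.  The error model is substitutions
only: no indels, no position- or quality-dependent error decay, no
platform-specific artifacts.  Every read is logged in a truth table
(genome, interval, strand, error count), which is the ground truth for all
accuracy statements.

Community abundance vectors pin the 2–3 dominant taxa to chosen values and
split the remaining mass by a symmetric Dirichlet(1) draw — "a few known
dominants, the rest random" — so recovered profiles can be compared to an
exactly known structure.

## Fixture universe

`make_fixture_bundle(seed, outdir)` writes a miniature analysis world, all
derived from one seeded generator and byte-identical across runs:

- **8 toy genomes**, 9–11 kb each, random background with one planted
  150 bp rRNA-like marker per genome.  All markers are mutated copies
  (~6% divergence) of a shared consensus, emulating the conservation that
  makes rRNA a usable marker.  Genome lengths are kept similar on purpose:
  the pipeline applies no marker copy-number or genome-length correction,
  so strongly unequal genome lengths would bias recovered abundances by
  construction rather than by method error.
- **Two reference databases.**  The habitat-specific database holds each
  genome's exact planted marker (the specialised-database analogue); the
  general database holds further-diverged variants (~3%) plus two decoy
  taxa (the complete-but-generic analogue).  Both carry 7-rank lineage
  tables over a synthetic taxonomy (8 species, 8 genera, 4 families,
  2 phyla).
- **A training alignment** of 12 additional consensus variants (~5%
  divergence, ungapped) from which the scanning HMM is built.
- **A mini GO DAG** (~31 terms, 3 namespaces, occasional double parents via
  part_of, one obsolete term) with a designated slim subset; **a 4-level
  SEED table** (12 function ids); **16 annotated proteins**; and **6
  contigs** with 2–3 planted genes each (reverse-translated proteins with
  an in-frame stop codon planted immediately upstream, so the called ORF
  coordinates are exactly the planted ones).

The fixtures reproduce the *structure* of real analyses, not their scale or
messiness: real rRNA genes are ~1.5 kb with variable regions and multiple
copies per genome, real databases disagree with each other, and real reads
have indels and quality decay.  Passing tests therefore demonstrate the
correctness of the machinery and its behaviour under the stated noise
model, not field accuracy on real databases.

## Profile HMM and fragment calling

The model is the classic match/insert/delete profile architecture.
Alignment columns with a gap fraction below `match_frac` (default 0.5)
become match states; emissions and transitions receive Laplace (+1)
pseudocounts; the background is the alignment's overall base composition.
Scoring is log-odds in bits; `N` emits at background (contribution 0);
transitions contribute log2 of their probability.  Allowed transitions are
M→{M,I,D}, I→{M,I}, D→{M,D}.

Scanning is local on both sequence and model (free entry into and exit from
any match state, unaligned read flanks free) because a 100 bp read covers
only a window of a full-length marker model.  Both strands are scanned in
memory; the higher-scoring strand is kept, ties broken toward `+`.

The calling threshold defaults to **0.25 bits per match state**
(0.25 · L total bits, 37.5 bits for the L = 150 fixture model).  This is an
artifact convention — chosen so that reads overlapping a marker by ≥ 60 bp
(scoring roughly 1.3–1.8 bits per aligned state) clear it comfortably while
the best random local hit (≈ 10–15 bits at these sizes) never does.  The
Viterbi recursion is verified against exhaustive path enumeration on small
models, and recall/false-positive behaviour against the fixture truth
(≥ 95% recall of marker-bearing reads, ≤ 1% false positives; in practice
100% / 0%).

## Mapper

References are indexed by exact k-mers (k = 8 nucleotide, k = 4 protein).
Every (reference, strand) pair sharing at least one seed with the query is
aligned with a full-matrix affine-gap local DP under fixed scoring
(+1 / −1, gap open −2, extend −1; a gap of length g costs 2 + (g − 1)).
The references here are short marker or protein sequences, so the full
matrix is cheap and makes the best hit *exactly* the Smith–Waterman
optimum whenever a seed exists — the banded-extension shortcut usual for
long references is unnecessary.  Single best hit per query; ties break by
score, then identity, then smallest reference id, then `+` strand.  Work
is chunked; because each chunk is a pure function of (queries, index,
parameters), output is identical for every worker count and chunk size.
`min_identity` defaults to 75%, the weakest rank threshold.

## Taxonomy

Hit lineages are truncated at the deepest rank whose identity threshold
the hit meets (97/95/90/85/80/75 for species→phylum; domain always kept).
These thresholds follow common rRNA practice and are configurable; the
truncation-by-identity rule itself is this package's documented choice
(alternatives would be LCA over multiple hits, which the top-1 mapper does
not produce, or accepting species outright).  Abundance is raw read
counts — no copy-number correction.  At every rank, counts plus the
unclassified tally equal the total assigned reads (checked on every
profile).

Integration across databases is the arithmetic mean of relative abundances
over databases (absent taxa contribute 0), renormalized per rank — the
simplest symmetric combination.

## Comparison statistics

The error rate between actual (V) and predicted (V′) structures at a rank
is `E = 100 · sqrt(Σ (Vᵢ − V′ᵢ)²)` over the union of both supports with
zero-fill — an unnormalized Euclidean distance on the percent scale.
Normalized variants (÷√N, ÷2) are available as options for cross-study
comparability; the default is the plain distance.  E is a metric on
abundance vectors restricted to a common support.

The phylogenetic view computes pairwise p-distances from global affine
alignments (the mapper's aligner) and builds a neighbor-joining tree
(scikit-bio) with fragment ids as leaves; two sequences yield a cherry with
d/2 branches.  NJ recovers the generating topology exactly on additive
matrices, which the tests exercise with constructed quartets.

## Functional arm

Gene prediction is an explicit 6-frame ORF finder: start codons ATG/GTG/
TTG, stops TAA/TAG/TGA, one ORF per stop-to-stop segment per frame
(opened at the first start), edge-running ORFs truncated to the last full
codon, default minimum length 300 nt.  This is a deliberate, documented
stand-in for trained gene finders with error models; external gene calls
can be substituted as a FASTA adapter.  Annotation transfer is top-1
protein identity mapping (default minimum identity 60%).

GO-slim rollup: per gene, the reflexive ancestor closure of its GO terms
under is_a and part_of is intersected with the slim set; each slim term
counts **once per gene** (so duplicated GO lists and sibling terms under
one slim ancestor do not double-count).  The profile keeps the top 20 slim
terms per namespace by default.  SEED rollup expands each annotated gene's
function id to its fixed 4-level path; level-k marginals are conserved for
k = 1..4.

## Visual exports

One layout engine serves taxonomic and functional hierarchies: wedge
angles are proportional to counts within each parent, mass resolved at a
parent but not at any child becomes a gray Unclassified wedge, so every
ring conserves angle exactly (root = 360°).  Colors are a deterministic
hash of the lineage path (Unclassified gray).  The HTML export inlines
SVG and a small script (sample switching, click-to-zoom) with no external
resources; the global view draws the comparison table as a tree with
per-sample abundance bars.  All exports are byte-deterministic.

## Numerical conventions and degenerate inputs

- All randomness flows through a single seeded NumPy generator per
  operation; reruns with one seed are bit-identical.
- Tables are UTF-8, Unix newlines, deterministic ordering (rank order,
  descending count, lexicographic path); abundances printed to 6 decimals.
- Empty read sets, empty query lists and empty profiles produce empty (or
  "no data") outputs, not errors; an empty alignment, a cyclic ontology or
  a lineage table missing a reference are hard errors naming the culprit.
- Strand ties in the HMM scan go to `+`; mapper ties to the smallest
  reference id — determinism over arbitrary preference.

## Problem sizes used by the test and acceptance runs

The shipped evaluation simulates 20,000 × 100 bp reads (the accuracy run),
50,000 reads for the multinomial sampling check, and 500,000 bases for the
substitution-rate check; the fixture model has 150 match states.  These
sizes give the statistics comfortable resolution (≈ 400 marker-bearing
reads in the accuracy run, binomial standard error ≈ 0.014% on the error
rate) while keeping a full suite run under a minute of compute.

## Known limitations

- The ORF finder has no coding-potential model; on real contigs it
  over-calls short spurious ORFs (filtered only by length) relative to
  trained gene finders.
- No 16S copy-number correction, no LCA assignment, no E-values or
  multi-hit reporting; identity thresholds are global, not clade-specific.
- The simulator's substitution-only error model understates real
  platform error structure; indel robustness is exercised only through
  the aligners' gap handling, not the generator.
- Database integration by averaging treats all databases as equally
  trustworthy.
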