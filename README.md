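# metaprof

Taxonomic and functional profiling of shotgun metagenomes, built as a
self-contained, fully tested pipeline:

1. **rRNA fragment extraction** — a profile hidden Markov model
   (match/insert/delete architecture, local Viterbi in bits) is built from a
   reference rRNA alignment and scans every read on both strands in memory.
2. **Marker mapping** — extracted fragments are mapped to taxonomy-annotated
   reference databases with an exact k-mer-seeded, affine-gap local aligner
   (match +1, mismatch −1, gap open −2, gap extend −1), single best hit per
   query, deterministic under any worker count.
3. **Taxonomic profiling** — hit lineages are truncated by per-rank identity
   thresholds (species 97 / genus 95 / family 90 / order 85 / class 80 /
   phylum 75), aggregated into per-rank abundance tables, and optionally
   integrated across databases by averaging relative abundances.
4. **Comparison** — multi-sample tables at any rank, neighbor-joining trees
   over fragments (p-distance), and the taxonomic error-rate statistic

   E = 100 · √( Σᵢ (Vᵢ − V′ᵢ)² )   [percent]

   where Vᵢ and V′ᵢ are the actual and predicted relative abundances of
   taxon Tᵢ over the union of both supports — the Euclidean distance between
   community structures.
5. **Functional arm** — 6-frame ORF prediction on assembled contigs, best-hit
   annotation transfer from an annotated protein set, GO→GO-slim rollup via
   is_a/part_of ancestor closure, and 4-level SEED subsystem rollup.
6. **Visual exports** — standalone multi-ring (Krona-style) HTML sample
   views, a tree-with-bars global comparison SVG, all byte-deterministic.

A community read simulator (multinomial genome sampling, uniform starts and
strands, per-base substitution errors, per-read truth table) and a fixture
generator (toy genomes with planted rRNA markers, two reference databases,
a mini GO DAG, a SEED table, annotated proteins and contigs) provide ground
truth for every accuracy claim.

## Worked example

```python
from pathlib import Path
from metaprof import cli, simulator as sim

root = Path("demo")
b = sim.make_fixture_bundle(7, root / "bundle")
spec = sim.community_from_bundle(b, n_reads=20_000, seed=42)
reads, truth = sim.simulate_reads(spec)
out = sim.write_sample(reads, truth, root / "sample")

config = cli.PipelineConfig(
    reads=str(out["fasta"]),
    contigs=str(b.contigs_fasta),
    hmm_alignment=str(b.training_alignment),
    databases={
        "habitat": {"fasta": str(b.db_habitat_fasta),
                    "lineages": str(b.db_habitat_lineages)},
        "general": {"fasta": str(b.db_general_fasta),
                    "lineages": str(b.db_general_lineages)},
    },
    obo=str(b.obo), slim_ids=str(b.slim_ids), seed_table=str(b.seed_table),
    ref_proteins=str(b.proteins_fasta),
    ref_annotations=str(b.protein_annotations),
    truth=str(out["truth"]), genome_lineages=str(b.lineages_by_genome),
    outdir=str(root / "out"), seed=42,
)
cli.run_pipeline(config)
```

The manifest of this run reports, among others:

```
"extract_rrna":  {"n_fragments": 394, "threshold_bits": 37.5}
"map_and_profile": {"habitat": {"n_assigned": 394}, "general": {"n_assigned": 394}}
"error_rate":    {"habitat": 6.67, "general": 16.31}
"functional":    {"n_genes": 17, "n_identified": 16}
```

Of 20,000 × 100 bp reads at a 1% substitution rate, 394 carry enough of a
planted rRNA marker to clear the 37.5-bit calling threshold; all of them map,
and the genus-level community structure recovered against the
habitat-specific database is within E = 6.67% of the simulated truth.  The
habitat database (exact marker sequences, the specialised-database analogue)
beats the general one (extra divergence plus decoy taxa), mirroring the
expected specialised-vs-general accuracy ordering.  The genus rows of
`profile_habitat.tsv` for this run:

```
genus  ...Famula;Genulus        125  0.317259
genus  ...Famula;Mockerella      74  0.187817
genus  ...Famulopsis;Simulomonas 53  0.134518
...
```

with the two manually pinned dominant species at 30% and 20% recovered at
31.7% and 18.8%.  The same run also writes the integrated profile, a genus
comparison table, GO-slim and SEED functional tables, a Newick tree, the
ring-view HTML and the global-view SVG.

The equivalent shell session uses the `metaprof` console script
(`metaprof simulate`, `metaprof extract-rrna`, `metaprof map`,
`metaprof profile`, `metaprof integrate`, `metaprof compare`,
`metaprof error-rate`, `metaprof phylo`, `metaprof functional`,
`metaprof visualize`, `metaprof run --config config.yaml`).

## Documentation

`docs/methods.md` describes the models, parameter defaults, numerical
conventions and the limits of what the synthetic fixtures can show.
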