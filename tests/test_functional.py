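"""functional: ORF prediction, annotation transfer, GO-slim/SEED rollups."""

from __future__ import annotations

import json

import numpy as np
import pandas as pd
import pytest

from metaprof import functional, io_formats as io
from metaprof.simulator import revcomp

from oracles import closure_bruteforce


def _rand_dna(rng, n):
    return "".join("ACGT"[j] for j in rng.integers(0, 4, size=n))


def _sense_codons(rng, n):
    """n codons that are neither stop nor start-irrelevant; avoids stops."""
    stops = {"TAA", "TAG", "TGA"}
    out = []
    while len(out) < n:
        c = _rand_dna(rng, 3)
        if c not in stops:
            out.append(c)
    return "".join(out)


def brute_force_orfs(seq: str, min_len: int):
    """Independent ORF scan: per strand and frame, first start after each
    stop opens an ORF that runs to the next stop or the last full codon."""
    starts = {"ATG", "GTG", "TTG"}
    stops = {"TAA", "TAG", "TGA"}
    found = set()
    n = len(seq)
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        for frame in range(3):
            open_at = None
            i = frame
            while i + 3 <= len(s):
                codon = s[i:i + 3]
                if open_at is None and codon in starts:
                    open_at = i
                elif open_at is not None and codon in stops:
                    if i + 3 - open_at >= min_len:
                        found.add((strand, open_at, i + 3))
                    open_at = None
                i += 3
            if open_at is not None:
                end = open_at + ((len(s) - open_at) // 3) * 3
                if end - open_at >= min_len:
                    found.add((strand, open_at, end))
    out = set()
    for strand, a, b in found:
        if strand == "+":
            out.add((a, b, "+"))
        else:
            out.add((n - b, n - a, "-"))
    return out


class TestPredictGenes:
    def test_constructed_orf_single_call(self):
        rng = np.random.default_rng(0)
        body = _sense_codons(rng, 100)
        contig = "CCC" + "ATG" + body + "TAA" + "CCC"
        calls = [c for c in functional.predict_genes(
            [io.SequenceRecord(id="c", seq=contig)]) if c.strand == "+"]
        assert len(calls) == 1
        call = calls[0]
        assert (call.start, call.end) == (3, 3 + 306)
        assert call.end - call.start == 306
        assert call.protein.startswith("M")
        assert len(call.protein) == 101

    def test_reverse_complement_flips_strands(self):
        rng = np.random.default_rng(1)
        contig = _rand_dna(rng, 1500)
        rec = io.SequenceRecord(id="c", seq=contig)
        rc = io.SequenceRecord(id="c", seq=revcomp(contig))
        fwd = functional.predict_genes([rec], min_len_nt=120)
        rev = functional.predict_genes([rc], min_len_nt=120)
        n = len(contig)
        flipped = sorted((n - c.end, n - c.start, "-" if c.strand == "+" else "+")
                         for c in fwd)
        assert flipped == sorted((c.start, c.end, c.strand) for c in rev)
        assert sorted(c.seq for c in fwd) == sorted(c.seq for c in rev)

    def test_matches_bruteforce_frame_scan_on_random_contigs(self):
        rng = np.random.default_rng(2)
        for trial in range(50):
            contig = _rand_dna(rng, 1000)
            calls = functional.predict_genes(
                [io.SequenceRecord(id="c", seq=contig)], min_len_nt=90)
            got = {(c.start, c.end, c.strand) for c in calls}
            assert got == brute_force_orfs(contig, 90), trial

    def test_non_nucleotide_contig_rejected(self):
        with pytest.raises(io.FormatError, match="non-nucleotide"):
            functional.predict_genes([io.SequenceRecord(id="c", seq="ATGXXXTAA")])

    def test_deterministic_order(self):
        rng = np.random.default_rng(3)
        contigs = [io.SequenceRecord(id=f"c{i}", seq=_rand_dna(rng, 800))
                   for i in range(4)]
        calls = functional.predict_genes(contigs, min_len_nt=90)
        keys = [(c.contig_id, c.start) for c in calls]
        assert keys == sorted(keys)


class TestIdentifyGenes:
    def test_planted_genes_transfer_annotations(self, bundle):
        contigs = io.read_fasta(bundle.contigs_fasta)
        genes = functional.predict_genes(contigs)
        annotations = io.read_annotation_table(bundle.protein_annotations)
        refs = io.read_fasta(bundle.proteins_fasta, alphabet="aa")
        identified = functional.identify_genes(genes, annotations, ref_seqs=refs)
        truth = json.loads(bundle.gene_truth.read_text())
        planted = {(t["contig_id"], t["start"], t["end"]): t["protein_id"]
                   for t in truth}
        by_coord = {(g.contig_id, g.start, g.end): g for g in genes}
        recovered = 0
        for coord, pid in planted.items():
            g = by_coord.get(coord)
            if g is not None and g.gene_id in identified:
                assert identified[g.gene_id].ref_id == pid
                recovered += 1
        assert recovered / len(planted) >= 0.9

    def test_exact_gene_full_identity(self, bundle):
        refs = io.read_fasta(bundle.proteins_fasta, alphabet="aa")
        annotations = io.read_annotation_table(bundle.protein_annotations)
        prot = refs[0]
        gene = functional.GeneCall(contig_id="c", start=0, end=6, strand="+",
                                   frame=0, seq="ATGTAA", protein=prot.seq)
        identified = functional.identify_genes([gene], annotations, ref_seqs=refs)
        assert identified[gene.gene_id].ref_id == prot.id
        assert identified[gene.gene_id].identity == 100.0

    def test_no_hit_gene_absent(self, bundle):
        refs = io.read_fasta(bundle.proteins_fasta, alphabet="aa")
        annotations = io.read_annotation_table(bundle.protein_annotations)
        gene = functional.GeneCall(contig_id="c", start=0, end=6, strand="+",
                                   frame=0, seq="ATGTAA", protein="W" * 50)
        assert functional.identify_genes([gene], annotations, ref_seqs=refs) == {}

    def test_worker_invariance(self, bundle):
        contigs = io.read_fasta(bundle.contigs_fasta)
        genes = functional.predict_genes(contigs)
        annotations = io.read_annotation_table(bundle.protein_annotations)
        refs = io.read_fasta(bundle.proteins_fasta, alphabet="aa")
        one = functional.identify_genes(genes, annotations, ref_seqs=refs, n_workers=1)
        four = functional.identify_genes(genes, annotations, ref_seqs=refs, n_workers=4)
        assert one == four


def _random_ontology(rng, n_terms=30):
    ids = [f"GO:{i:04d}" for i in range(n_terms)]
    terms = {t: {"name": t, "namespace": "ns"} for t in ids}
    edges = set()
    for i in range(1, n_terms):
        n_par = int(rng.integers(1, 3))
        for p in rng.choice(i, size=min(i, n_par), replace=False):
            rel = "is_a" if rng.random() < 0.7 else "part_of"
            edges.add((ids[i], ids[int(p)], rel))
    return io.OntologyGraph(terms=terms, edges=edges), ids, edges


class TestRollupGoslim:
    def test_direct_slim_annotation_counts_once(self):
        rng = np.random.default_rng(4)
        ont, ids, _ = _random_ontology(rng)
        slim = [ids[0], ids[3]]
        prof = functional.rollup_goslim({"gene1": [ids[3]]}, ont, slim)
        assert prof.counts[("ns", ids[3])] == 1
        assert prof.total_annotated == 1

    def test_two_children_of_same_slim_ancestor_dedup(self):
        terms = {t: {"name": t, "namespace": "ns"} for t in ("root", "a", "b")}
        edges = {("a", "root", "is_a"), ("b", "root", "is_a")}
        ont = io.OntologyGraph(terms=terms, edges=edges)
        prof = functional.rollup_goslim({"g": ["a", "b"]}, ont, ["root"])
        assert prof.counts[("ns", "root")] == 1

    def test_duplicated_go_list_idempotent(self):
        rng = np.random.default_rng(5)
        ont, ids, _ = _random_ontology(rng)
        slim = ids[:5]
        annos = {"g": [ids[10], ids[20]]}
        doubled = {"g": [ids[10], ids[20], ids[10], ids[20]]}
        assert functional.rollup_goslim(annos, ont, slim).counts == \
            functional.rollup_goslim(doubled, ont, slim).counts

    def test_matches_bruteforce_closure_30_terms_50_genes(self):
        """Rollup equals per-gene brute-force transitive closure
        intersection on a random 30-term DAG."""
        rng = np.random.default_rng(6)
        ont, ids, edges = _random_ontology(rng, 30)
        slim = sorted(rng.choice(ids, size=8, replace=False))
        annos = {f"g{i:02d}": [str(t) for t in
                               rng.choice(ids, size=int(rng.integers(1, 4)),
                                          replace=False)]
                 for i in range(50)}
        prof = functional.rollup_goslim(annos, ont, slim, top_n=1000)
        expected: dict[str, int] = {}
        for gene, gos in annos.items():
            closure = set()
            for t in gos:
                closure |= closure_bruteforce(edges, t)
            for s in closure & set(slim):
                expected[s] = expected.get(s, 0) + 1
        assert {k[1]: v for k, v in prof.counts.items()} == expected

    def test_unknown_slim_id_named(self):
        rng = np.random.default_rng(7)
        ont, ids, _ = _random_ontology(rng)
        with pytest.raises(ValueError, match="GO:9999"):
            functional.rollup_goslim({}, ont, ["GO:9999"])

    def test_top_n_per_namespace(self):
        terms = {}
        edges = set()
        for ns in ("bp", "mf"):
            for i in range(5):
                terms[f"{ns}{i}"] = {"name": f"{ns}{i}", "namespace": ns}
        ont = io.OntologyGraph(terms=terms, edges=edges)
        annos = {f"g{i}": [t for t in terms if int(t[2]) <= i % 5]
                 for i in range(10)}
        prof = functional.rollup_goslim(annos, ont, list(terms), top_n=2)
        by_ns = {}
        for (ns, t) in prof.counts:
            by_ns.setdefault(ns, []).append(t)
        assert all(len(v) <= 2 for v in by_ns.values())


class TestRollupSeed:
    def _hierarchy(self):
        rows = [("L1a", "L2a", "L3a", "L4a", "fig|1"),
                ("L1a", "L2a", "L3b", "L4b", "fig|2"),
                ("L1b", "L2b", "L3c", "L4c", "fig|3")]
        return io.SeedHierarchy(rows=rows)

    def test_single_gene_single_path(self):
        prof = functional.rollup_seed({"g": "fig|1"}, self._hierarchy())
        assert prof.counts == {("L1a", "L2a", "L3a", "L4a"): 1}
        assert sum(prof.level_marginal(1).values()) == 1

    def test_every_key_has_four_levels(self, bundle):
        contigs = io.read_fasta(bundle.contigs_fasta)
        genes = functional.predict_genes(contigs)
        annotations = io.read_annotation_table(bundle.protein_annotations)
        refs = io.read_fasta(bundle.proteins_fasta, alphabet="aa")
        identified = functional.identify_genes(genes, annotations, ref_seqs=refs)
        hier = io.read_seed_table(bundle.seed_table)
        prof = functional.rollup_seed(
            {g: a.seed_id for g, a in identified.items() if a.seed_id}, hier)
        assert prof.total_annotated > 0
        assert all(len(k) == 4 for k in prof.counts)

    def test_level_marginals_match_groupby(self):
        """Level-k marginals equal a direct group-by of the gene table."""
        rng = np.random.default_rng(8)
        hier = self._hierarchy()
        fids = hier.function_ids()
        annos = {f"g{i}": fids[int(rng.integers(0, len(fids)))] for i in range(40)}
        prof = functional.rollup_seed(annos, hier)
        df = pd.DataFrame([{"gene": g,
                            **{f"l{i+1}": hier.path(f)[i] for i in range(4)}}
                           for g, f in annos.items()])
        for k in range(1, 5):
            cols = [f"l{i+1}" for i in range(k)]
            expected = df.groupby(cols).size()
            got = prof.level_marginal(k)
            assert len(got) == len(expected)
            for key, count in expected.items():
                key_t = (key,) if isinstance(key, str) else tuple(key)
                assert got[key_t] == count

    def test_mass_conserved_across_levels(self):
        rng = np.random.default_rng(9)
        hier = self._hierarchy()
        fids = hier.function_ids()
        annos = {f"g{i}": fids[int(rng.integers(0, len(fids)))] for i in range(25)}
        prof = functional.rollup_seed(annos, hier)
        totals = {k: sum(prof.level_marginal(k).values()) for k in range(1, 5)}
        assert set(totals.values()) == {25}
        assert prof.total_annotated == 25

    def test_unknown_function_id_rejected(self):
        with pytest.raises(KeyError, match="fig|99"):
            functional.rollup_seed({"g": "fig|99"}, self._hierarchy())
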