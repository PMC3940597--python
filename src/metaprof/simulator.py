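"""Synthetic shotgun community simulator and test fixture generators.

The read simulator emulates a whole-genome shotgun run over a defined
community: genomes are sampled per read from a multinomial over the
community abundance vector, read start positions are uniform, strands are
uniform, and sequencing noise is a per-base substitution process at a
configurable rate (default 1% on 100 bp reads).  Every read is logged in a
truth table (source genome, interval, strand, error count) so downstream
profiling accuracy can be measured against ground truth.

The fixture bundle builds a miniature but complete analysis universe:
toy genomes with planted rRNA-like marker regions sampled from a shared
consensus, two taxonomy-annotated reference databases (a "general" one
with extra divergence and decoy taxa, and a "habitat-specific" one holding
the exact planted markers), a small GO DAG with a slim subset, a 4-level
SEED hierarchy, an annotated protein set and contigs with planted genes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_formats import (
    RANKS,
    LineageTable,
    SequenceRecord,
    SeedHierarchy,
    write_annotation_table,
    write_fasta,
    write_fastq,
    write_lineage_table,
    write_seed_table,
)

__all__ = [
    "CommunitySpec",
    "TruthRow",
    "TruthTable",
    "draw_abundances",
    "simulate_reads",
    "write_truth_table",
    "read_truth_table",
    "FixtureBundle",
    "make_fixture_bundle",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: Default read length in bases.
DEFAULT_READ_LEN = 100
#: Default per-base substitution rate.
DEFAULT_ERR_RATE = 0.01


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, size=length)]).decode("ascii")


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> tuple[str, int]:
    """Substitute each base with probability *rate* to a different base."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = rng.random(len(arr)) < rate
    n = int(hit.sum())
    if n:
        idx = np.nonzero(hit)[0]
        for i in idx:
            choices = _BASES[_BASES != arr[i]]
            arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode("ascii"), n


# ---------------------------------------------------------------------------
# community specification
# ---------------------------------------------------------------------------

@dataclass
class CommunitySpec:
    """Ground truth for one simulated sample.

    ``genomes`` is a list of ``(genome_id, SequenceRecord, lineage)`` with a
    7-rank lineage tuple per genome; ``abundances`` must sum to one.
    """

    genomes: list[tuple[str, SequenceRecord, tuple[str, ...]]]
    abundances: Sequence[float]
    n_reads: int
    read_len: int = DEFAULT_READ_LEN
    err_rate: float = DEFAULT_ERR_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.abundances) != len(self.genomes):
            raise ValueError("abundances must have one entry per genome")
        ab = np.asarray(self.abundances, dtype=float)
        if np.any(ab < 0) or np.any(ab > 1):
            raise ValueError("abundance fractions must lie in [0, 1]")
        if abs(float(ab.sum()) - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {ab.sum()}, expected 1")
        if self.n_reads <= 0:
            raise ValueError("n_reads must be positive")
        min_len = min(len(rec.seq) for _, rec, _ in self.genomes)
        if self.read_len > min_len:
            raise ValueError(
                f"read_len {self.read_len} exceeds shortest genome length {min_len}"
            )
        for _, _, lin in self.genomes:
            if len(lin) != len(RANKS):
                raise ValueError("each genome lineage must have 7 ranks")


@dataclass(frozen=True)
class TruthRow:
    read_id: str
    genome_id: str
    start: int          # 0-based, half-open interval on the forward genome
    end: int
    strand: str         # '+' or '-'
    n_errors: int


@dataclass
class TruthTable:
    rows: list[TruthRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.rows)

    def genome_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for row in self.rows:
            counts[row.genome_id] = counts.get(row.genome_id, 0) + 1
        return counts

    def abundance_by_genome(self) -> dict[str, float]:
        counts = self.genome_counts()
        total = sum(counts.values())
        return {g: c / total for g, c in counts.items()}


# ---------------------------------------------------------------------------
# abundance model
# ---------------------------------------------------------------------------

def draw_abundances(n_taxa: int, n_manual: int, manual_values: Sequence[float],
                    seed: int | np.random.Generator) -> np.ndarray:
    """Community abundance vector with manually pinned dominant taxa.

    The most abundant ``n_manual`` (2-3) taxa get the given values; the
    remaining probability mass is split among the other taxa by a symmetric
    Dirichlet(1) draw.
    """
    if not 2 <= n_manual <= 3:
        raise ValueError("n_manual must be 2 or 3")
    if n_manual > n_taxa:
        raise ValueError("n_manual cannot exceed n_taxa")
    manual = list(manual_values)
    if len(manual) != n_manual:
        raise ValueError("manual_values must have n_manual entries")
    if any(not 0 < v < 1 for v in manual):
        raise ValueError("manual values must lie in (0, 1)")
    if sorted(manual, reverse=True) != manual:
        raise ValueError("manual values must be in descending order")
    total_manual = sum(manual)
    n_rest = n_taxa - n_manual
    if n_rest == 0:
        if abs(total_manual - 1.0) > 1e-9:
            raise ValueError("manual values must sum to 1 when they cover all taxa")
        return np.asarray(manual, dtype=float)
    if total_manual >= 1.0:
        raise ValueError(f"manual abundance mass {total_manual} leaves nothing for the rest")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rest = rng.dirichlet(np.ones(n_rest)) * (1.0 - total_manual)
    out = np.concatenate([np.asarray(manual, dtype=float), rest])
    # tidy the floating point residue so downstream sum-to-one checks hold
    out[-1] += 1.0 - out.sum()
    return out


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------

def simulate_reads(spec: CommunitySpec) -> tuple[list[SequenceRecord], TruthTable]:
    """Emit shotgun reads for a community spec, with a per-read truth table.

    For each read: source genome ~ multinomial(abundances), start uniform
    over valid positions, strand uniform, then per-base substitution noise
    at ``spec.err_rate``.  Fully reproducible from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    n_genomes = len(spec.genomes)
    ab = np.asarray(spec.abundances, dtype=float)
    ab = ab / ab.sum()
    genome_idx = rng.choice(n_genomes, size=spec.n_reads, p=ab)

    reads: list[SequenceRecord] = []
    rows: list[TruthRow] = []
    # constant quality consistent with the substitution rate
    q = max(2, int(round(-10 * np.log10(max(spec.err_rate, 1e-9)))))
    for i in range(spec.n_reads):
        gid, rec, _ = spec.genomes[int(genome_idx[i])]
        glen = len(rec.seq)
        start = int(rng.integers(0, glen - spec.read_len + 1))
        end = start + spec.read_len
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        frag = rec.seq[start:end]
        if strand == "-":
            frag = revcomp(frag)
        seq, n_err = _mutate(frag, spec.err_rate, rng)
        read_id = f"read_{i:06d}"
        reads.append(SequenceRecord(id=read_id, seq=seq,
                                    qual=tuple([q] * spec.read_len)))
        rows.append(TruthRow(read_id, gid, start, end, strand, n_err))
    return reads, TruthTable(rows=rows)


def write_truth_table(truth: TruthTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("read_id\tgenome_id\tstart\tend\tstrand\tn_errors\n")
        for r in truth.rows:
            fh.write(f"{r.read_id}\t{r.genome_id}\t{r.start}\t{r.end}\t{r.strand}\t{r.n_errors}\n")


def read_truth_table(path: str | Path) -> TruthTable:
    rows: list[TruthRow] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("read_id\t"):
                continue
            rid, gid, s, e, strand, n = line.split("\t")
            rows.append(TruthRow(rid, gid, int(s), int(e), strand, int(n)))
    return TruthTable(rows=rows)


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

# species catalogue for the toy community: 8 species in 8 genera,
# 4 families, 2 phyla within Bacteria (names are synthetic).
_SPECIES = [
    ("g1", "Bacteria", "Toxophylum", "Alphaclassia", "Alphorder", "Famula", "Genulus", "Genulus_primus"),
    ("g2", "Bacteria", "Toxophylum", "Alphaclassia", "Alphorder", "Famula", "Mockerella", "Mockerella_orisi"),
    ("g3", "Bacteria", "Toxophylum", "Alphaclassia", "Betorder", "Famuletta", "Fictivibrio", "Fictivibrio_salivus"),
    ("g4", "Bacteria", "Toxophylum", "Betaclassia", "Gammorder", "Famulina", "Pseudogenus", "Pseudogenus_dentis"),
    ("g5", "Bacteria", "Synthophyta", "Deltaclassia", "Deltorder", "Famulopsis", "Simulomonas", "Simulomonas_gingivae"),
    ("g6", "Bacteria", "Synthophyta", "Deltaclassia", "Deltorder", "Famulopsis", "Exemplococcus", "Exemplococcus_mitis"),
    ("g7", "Bacteria", "Synthophyta", "Deltaclassia", "Epsorder", "Famulora", "Modelibacter", "Modelibacter_rudis"),
    ("g8", "Bacteria", "Synthophyta", "Epsilonclassia", "Zetorder", "Famulix", "Specimenella", "Specimenella_parva"),
]

# decoy taxa present only in the "general" reference database
_DECOYS = [
    ("d1", "Bacteria", "Toxophylum", "Alphaclassia", "Alphorder", "Famula", "Decoyella", "Decoyella_absentis"),
    ("d2", "Bacteria", "Synthophyta", "Deltaclassia", "Deltorder", "Famulopsis", "Phantomonas", "Phantomonas_nulla"),
]

#: Length of the planted rRNA-like marker region (a conserved core).
RRNA_LEN = 150
#: Divergence of each genome's marker from the shared consensus.
RRNA_DIVERGENCE = 0.06
#: Extra divergence of "general" database entries from the planted markers.
GENERAL_DB_DIVERGENCE = 0.03

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"], "D": ["GAT", "GAC"],
    "E": ["GAA", "GAG"], "F": ["TTT", "TTC"], "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"], "K": ["AAA", "AAG"],
    "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"], "M": ["ATG"],
    "N": ["AAT", "AAC"], "P": ["CCT", "CCC", "CCA", "CCG"],
    "Q": ["CAA", "CAG"], "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"], "T": ["ACT", "ACC", "ACA", "ACG"],
    "V": ["GTT", "GTC", "GTA", "GTG"], "W": ["TGG"], "Y": ["TAT", "TAC"],
}


@dataclass
class FixtureBundle:
    """Paths to every file written by :func:`make_fixture_bundle`."""

    root: Path
    genomes_fasta: Path
    rrna_truth: Path
    training_alignment: Path
    db_general_fasta: Path
    db_general_lineages: Path
    db_habitat_fasta: Path
    db_habitat_lineages: Path
    obo: Path
    slim_ids: Path
    seed_table: Path
    proteins_fasta: Path
    protein_annotations: Path
    contigs_fasta: Path
    gene_truth: Path
    lineages_by_genome: Path


def _plant(genome: str, insert: str, pos: int) -> str:
    return genome[:pos] + insert + genome[pos + len(insert):]


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(_CODONS[aa][rng.integers(0, len(_CODONS[aa]))] for aa in protein)


def _write_obo(path: Path, terms: list[dict], header_date: str = "01:01:2014") -> None:
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("format-version: 1.2\n")
        fh.write(f"date: {header_date} 12:00\n")
        fh.write("ontology: mini-go\n\n")
        for t in terms:
            fh.write("[Term]\n")
            fh.write(f"id: {t['id']}\n")
            fh.write(f"name: {t['name']}\n")
            fh.write(f"namespace: {t['namespace']}\n")
            for parent in t.get("is_a", ()):  # type: ignore[assignment]
                fh.write(f"is_a: {parent}\n")
            for parent in t.get("part_of", ()):
                fh.write(f"relationship: part_of {parent}\n")
            if t.get("obsolete"):
                fh.write("is_obsolete: true\n")
            fh.write("\n")


def _make_go_dag(rng: np.random.Generator) -> tuple[list[dict], list[str], list[str]]:
    """A ~30-term, 3-namespace GO-like DAG with a designated slim subset.

    Returns (terms, slim_ids, leaf_ids) where leaf ids are the terms used
    to annotate proteins.
    """
    terms: list[dict] = []
    slim: list[str] = []
    leaves: list[str] = []
    counter = 1

    def tid() -> str:
        nonlocal counter
        s = f"GO:{counter:07d}"
        counter += 1
        return s

    for ns, root_name in (
        ("biological_process", "biological process"),
        ("molecular_function", "molecular function"),
        ("cellular_component", "cellular component"),
    ):
        root = tid()
        terms.append({"id": root, "name": root_name, "namespace": ns, "is_a": []})
        slim.append(root)
        mids = []
        for m in range(3):
            mid = tid()
            terms.append({"id": mid, "name": f"{root_name} branch {m+1}",
                          "namespace": ns, "is_a": [root]})
            mids.append(mid)
            if m < 2:
                slim.append(mid)  # two of three mid terms per namespace are slim
        for m, mid in enumerate(mids):
            for c in range(2):
                leaf = tid()
                parents = [mid]
                # occasional second parent via part_of to make it a true DAG
                extra: list[str] = []
                if rng.random() < 0.4:
                    other = mids[int(rng.integers(0, len(mids)))]
                    if other != mid:
                        extra = [other]
                terms.append({"id": leaf, "name": f"{root_name} leaf {m+1}.{c+1}",
                              "namespace": ns, "is_a": parents, "part_of": extra})
                leaves.append(leaf)
    obs = tid()
    terms.append({"id": obs, "name": "withdrawn term",
                  "namespace": "biological_process", "is_a": [], "obsolete": True})
    return terms, slim, leaves


def _make_seed_hierarchy() -> SeedHierarchy:
    rows = []
    cats = [
        ("Carbohydrates", "Central carbohydrate metabolism"),
        ("DNA Metabolism", "DNA replication"),
        ("Protein Metabolism", "Protein biosynthesis"),
        ("Amino Acids and Derivatives", "Lysine biosynthesis"),
    ]
    fid = 1
    for l1, l2 in cats:
        for j in range(3):
            l3 = f"{l2} subsystem {j+1}"
            l4 = f"{l1.split()[0]} function {j+1}"
            rows.append((l1, l2, l3, l4, f"fig|{fid:05d}"))
            fid += 1
    return SeedHierarchy(rows=rows)


def make_fixture_bundle(seed: int, outdir: str | Path) -> FixtureBundle:
    """Write a complete, deterministic fixture universe under *outdir*.

    Contents: 8 toy genomes (9-11 kb) each carrying one planted rRNA-like
    region drawn from a shared consensus; an ungapped training alignment of
    additional consensus variants; "general" and "habitat-specific" rRNA
    reference databases with lineage tables; a mini GO DAG (OBO) with slim
    ids; a 4-level SEED table; an annotated protein set; and contigs with
    planted genes.  The same seed yields a byte-identical bundle.
    """
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    consensus = _random_dna(rng, RRNA_LEN)

    genome_recs: list[SequenceRecord] = []
    rrna_truth_rows: list[tuple[str, int, int]] = []
    habitat_refs: list[SequenceRecord] = []
    general_refs: list[SequenceRecord] = []
    hab_lineages = LineageTable()
    gen_lineages = LineageTable()
    genome_lineages = LineageTable()

    for gid, *lineage in _SPECIES:
        lin = tuple(lineage)
        glen = int(rng.integers(9000, 11001))
        genome = _random_dna(rng, glen)
        marker, _ = _mutate(consensus, RRNA_DIVERGENCE, rng)
        pos = int(rng.integers(500, glen - RRNA_LEN - 500))
        genome = _plant(genome, marker, pos)
        genome_recs.append(SequenceRecord(id=gid, description=lineage[-1], seq=genome))
        rrna_truth_rows.append((gid, pos, pos + RRNA_LEN))
        genome_lineages.add(gid, lin)

        hab_id = f"hab_{gid}"
        habitat_refs.append(SequenceRecord(id=hab_id, seq=marker))
        hab_lineages.add(hab_id, lin)

        gen_id = f"gen_{gid}"
        diverged, _ = _mutate(marker, GENERAL_DB_DIVERGENCE, rng)
        general_refs.append(SequenceRecord(id=gen_id, seq=diverged))
        gen_lineages.add(gen_id, lin)

    for did, *lineage in _DECOYS:
        gen_id = f"gen_{did}"
        decoy, _ = _mutate(consensus, 0.12, rng)
        general_refs.append(SequenceRecord(id=gen_id, seq=decoy))
        gen_lineages.add(gen_id, tuple(lineage))

    # ungapped training alignment: consensus variants at fixture divergence
    training = [SequenceRecord(id=f"train_{i:02d}", seq=_mutate(consensus, 0.05, rng)[0])
                for i in range(12)]

    # GO DAG + slim, SEED hierarchy
    go_terms, slim_ids, go_leaves = _make_go_dag(rng)
    seed_hier = _make_seed_hierarchy()
    seed_fids = seed_hier.function_ids()

    # annotated protein set
    proteins: list[SequenceRecord] = []
    annotations: dict[str, dict[str, object]] = {}
    for i in range(16):
        plen = int(rng.integers(120, 161))
        prot = "".join(_AA20[j] for j in rng.integers(0, 20, size=plen))
        pid = f"prot_{i:02d}"
        proteins.append(SequenceRecord(id=pid, seq=prot))
        n_go = int(rng.integers(1, 4))
        gos = sorted(str(go_leaves[j]) for j in rng.choice(len(go_leaves), size=n_go, replace=False))
        fid = seed_fids[int(rng.integers(0, len(seed_fids)))]
        annotations[pid] = {"go_terms": tuple(gos), "seed_id": fid}

    # contigs with planted genes (2-3 per contig, either strand)
    contigs: list[SequenceRecord] = []
    gene_truth: list[dict] = []
    prot_cycle = list(range(len(proteins)))
    pi = 0
    for c in range(6):
        clen = int(rng.integers(1500, 2500))
        contig = _random_dna(rng, clen)
        n_genes = int(rng.integers(2, 4))
        cursor = 30
        cid = f"contig_{c:02d}"
        for _ in range(n_genes):
            prot = proteins[prot_cycle[pi % len(proteins)]]
            pi += 1
            gene_nt = "ATG" + _reverse_translate(prot.seq, rng) + "TAA"
            # an in-frame stop right before the start pins the called ORF
            # to the planted coordinates
            full = "TAA" + gene_nt
            if cursor + len(full) + 30 > clen:
                break
            strand = "+" if rng.integers(0, 2) == 0 else "-"
            insert = full if strand == "+" else revcomp(full)
            contig = _plant(contig, insert, cursor)
            if strand == "+":
                start, end = cursor + 3, cursor + 3 + len(gene_nt)
            else:
                start, end = cursor, cursor + len(gene_nt)
            gene_truth.append({"contig_id": cid, "start": start, "end": end,
                               "strand": strand, "protein_id": prot.id})
            cursor += len(full) + int(rng.integers(40, 120))
        contigs.append(SequenceRecord(id=cid, seq=contig))

    # ---- write everything ------------------------------------------------
    b = FixtureBundle(
        root=outdir,
        genomes_fasta=outdir / "genomes.fasta",
        rrna_truth=outdir / "rrna_regions.tsv",
        training_alignment=outdir / "rrna_training_alignment.fasta",
        db_general_fasta=outdir / "db_general.fasta",
        db_general_lineages=outdir / "db_general.lineages.tsv",
        db_habitat_fasta=outdir / "db_habitat.fasta",
        db_habitat_lineages=outdir / "db_habitat.lineages.tsv",
        obo=outdir / "mini_go.obo",
        slim_ids=outdir / "goslim_ids.txt",
        seed_table=outdir / "seed_hierarchy.tsv",
        proteins_fasta=outdir / "proteins.fasta",
        protein_annotations=outdir / "protein_annotations.tsv",
        contigs_fasta=outdir / "contigs.fasta",
        gene_truth=outdir / "gene_truth.json",
        lineages_by_genome=outdir / "genome_lineages.tsv",
    )
    write_fasta(genome_recs, b.genomes_fasta)
    with b.rrna_truth.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("genome_id\tstart\tend\n")
        for gid, s, e in rrna_truth_rows:
            fh.write(f"{gid}\t{s}\t{e}\n")
    write_fasta(training, b.training_alignment)
    write_fasta(general_refs, b.db_general_fasta)
    write_lineage_table(gen_lineages, b.db_general_lineages)
    write_fasta(habitat_refs, b.db_habitat_fasta)
    write_lineage_table(hab_lineages, b.db_habitat_lineages)
    _write_obo(b.obo, go_terms)
    b.slim_ids.write_text("\n".join(slim_ids) + "\n", encoding="utf-8")
    write_seed_table(seed_hier, b.seed_table)
    write_fasta(proteins, b.proteins_fasta)
    write_annotation_table(annotations, b.protein_annotations)
    write_fasta(contigs, b.contigs_fasta)
    with b.gene_truth.open("w", encoding="utf-8", newline="\n") as fh:
        json.dump(gene_truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    write_lineage_table(genome_lineages, b.lineages_by_genome)
    return b


def community_from_bundle(bundle: FixtureBundle, n_reads: int,
                          manual_values: Sequence[float] = (0.30, 0.20),
                          read_len: int = DEFAULT_READ_LEN,
                          err_rate: float = DEFAULT_ERR_RATE,
                          seed: int = 0) -> CommunitySpec:
    """Build a :class:`CommunitySpec` over the bundle's genomes.

    The 2-3 most abundant species are pinned manually (the default pins two
    at 30% and 20%), the remainder drawn from a Dirichlet split.
    """
    from .io_formats import read_fasta, read_lineage_table

    genomes = read_fasta(bundle.genomes_fasta)
    lineages = read_lineage_table(bundle.lineages_by_genome)
    entries = [(rec.id, rec, lineages[rec.id]) for rec in genomes]
    ab = draw_abundances(len(entries), len(manual_values), manual_values, seed)
    return CommunitySpec(genomes=entries, abundances=ab, n_reads=n_reads,
                         read_len=read_len, err_rate=err_rate, seed=seed)


def write_sample(reads: list[SequenceRecord], truth: TruthTable,
                 prefix: str | Path, fastq: bool = True) -> dict[str, Path]:
    """Write a simulated sample as FASTA (+ optional FASTQ) plus truth TSV."""
    prefix = Path(prefix)
    out = {"fasta": prefix.with_suffix(".fasta"), "truth": prefix.with_suffix(".truth.tsv")}
    write_fasta(reads, out["fasta"])
    write_truth_table(truth, out["truth"])
    if fastq:
        out["fastq"] = prefix.with_suffix(".fastq")
        write_fastq(reads, out["fastq"])
    return out
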