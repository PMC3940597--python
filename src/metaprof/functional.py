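"""Functional arm: gene prediction on contigs, best-hit annotation
transfer, GO -> GO-slim rollup and 4-level SEED rollup.

Gene prediction is an explicit 6-frame ORF finder (start codon ATG/GTG/TTG,
stop at TAA/TAG/TGA or the contig edge, one ORF per stop-to-stop segment
per frame).  Predicted proteins are mapped to an annotated reference
protein set with the package's seed-and-align mapper, and each gene
inherits its best hit's GO terms and/or SEED function id.

GO terms are rolled up through the ontology's is_a/part_of ancestor
closure (reflexive) and intersected with the slim subset, counting each
slim term at most once per gene.  SEED function ids expand to their fixed
4-level paths; counts are aggregable at any level with mass conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

from .io_formats import FormatError, OntologyGraph, SeedHierarchy, SequenceRecord
from .mapper import KmerIndex, ReferenceHit, build_index, map_all
from .simulator import revcomp

__all__ = [
    "GeneCall",
    "FunctionalProfile",
    "predict_genes",
    "identify_genes",
    "rollup_goslim",
    "rollup_seed",
]

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = ("TAA", "TAG", "TGA")
DEFAULT_MIN_GENE_LEN = 300
DEFAULT_PROTEIN_K = 4
DEFAULT_PROTEIN_MIN_IDENTITY = 60.0


@dataclass(frozen=True)
class GeneCall:
    """One predicted gene on a contig.

    The interval is 0-based half-open on the forward contig; ``frame`` is
    0-2 within the strand.  The nucleotide sequence is in gene orientation
    and includes the stop codon when one terminates the ORF.
    """

    contig_id: str
    start: int
    end: int
    strand: str
    frame: int
    seq: str
    protein: str

    def __post_init__(self) -> None:
        if (self.end - self.start) % 3 != 0:
            raise ValueError("gene length must be a multiple of 3")
        if self.seq[:3] not in START_CODONS:
            raise ValueError(f"gene does not begin with a start codon: {self.seq[:3]}")

    @property
    def gene_id(self) -> str:
        return f"{self.contig_id}:{self.start}-{self.end}({self.strand})"


def _orfs_in_frame(seq: str, frame: int) -> list[tuple[int, int]]:
    """ORFs (start, end offsets on *seq*) for one frame of one strand.

    Within each stop-to-stop segment the first start codon opens the ORF;
    ORFs running off the edge end at the last complete codon.
    """
    orfs: list[tuple[int, int]] = []
    start: int | None = None
    i = frame
    while i + 3 <= len(seq):
        codon = seq[i:i + 3]
        if start is None:
            if codon in START_CODONS:
                start = i
        elif codon in STOP_CODONS:
            orfs.append((start, i + 3))
            start = None
        i += 3
    if start is not None:
        end = start + ((len(seq) - start) // 3) * 3
        if end > start:
            orfs.append((start, end))
    return orfs


def predict_genes(contigs: Iterable[SequenceRecord],
                  min_len_nt: int = DEFAULT_MIN_GENE_LEN) -> list[GeneCall]:
    """6-frame ORF scan over contigs; calls sorted by (contig, start)."""
    if min_len_nt < 30:
        raise ValueError("min_len_nt must be >= 30")
    calls: list[GeneCall] = []
    for rec in contigs:
        bad = set(rec.seq.upper()) - set("ACGTN")
        if bad:
            raise FormatError(f"contig {rec.id!r} contains non-nucleotide characters {sorted(bad)}")
        fwd = rec.seq.upper()
        rev = revcomp(fwd)
        n = len(fwd)
        for strand, seq in (("+", fwd), ("-", rev)):
            for frame in range(3):
                for s, e in _orfs_in_frame(seq, frame):
                    if e - s < min_len_nt:
                        continue
                    nt = seq[s:e]
                    if strand == "+":
                        start, end = s, e
                    else:
                        start, end = n - e, n - s
                    protein = str(Seq(nt).translate(table=1)).rstrip("*")
                    calls.append(GeneCall(contig_id=rec.id, start=start, end=end,
                                          strand=strand, frame=frame,
                                          seq=nt, protein=protein))
    calls.sort(key=lambda c: (c.contig_id, c.start, c.end, c.strand))
    return calls


# ---------------------------------------------------------------------------
# annotation transfer
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RefAnnotation:
    ref_id: str
    go_terms: tuple[str, ...]
    seed_id: str | None
    identity: float


def identify_genes(genes: Sequence[GeneCall],
                   annotated_refs: Mapping[str, Mapping[str, object]],
                   index: KmerIndex | None = None,
                   ref_seqs: Sequence[SequenceRecord] | None = None,
                   min_identity: float = DEFAULT_PROTEIN_MIN_IDENTITY,
                   n_workers: int = 1) -> dict[str, RefAnnotation]:
    """Transfer annotations from the best reference protein hit per gene.

    ``annotated_refs`` maps ref id -> {"go_terms": ..., "seed_id": ...};
    either a prebuilt protein k-mer *index* or the reference records must
    be given.  Genes without a hit are absent from the result.
    """
    if index is None:
        if ref_seqs is None:
            raise ValueError("either index or ref_seqs is required")
        index = build_index(ref_seqs, k=DEFAULT_PROTEIN_K)
    queries = [SequenceRecord(id=g.gene_id, seq=g.protein, qual=None)
               for g in genes]
    hits = map_all(queries, index, n_workers=n_workers,
                   min_identity=min_identity, nucleotide=False)
    out: dict[str, RefAnnotation] = {}
    for gene, hit in zip(genes, hits):
        if hit is None:
            continue
        ann = annotated_refs.get(hit.ref_id)
        if ann is None:
            continue
        out[gene.gene_id] = RefAnnotation(
            ref_id=hit.ref_id,
            go_terms=tuple(ann.get("go_terms", ())),  # type: ignore[arg-type]
            seed_id=ann.get("seed_id"),               # type: ignore[arg-type]
            identity=hit.identity,
        )
    return out


# ---------------------------------------------------------------------------
# functional profiles
# ---------------------------------------------------------------------------

@dataclass
class FunctionalProfile:
    """Abundance table over GO-slim terms or 4-level SEED paths."""

    engine: str                                  # "goslim" or "seed"
    counts: dict[tuple[str, ...], int] = field(default_factory=dict)
    total_annotated: int = 0

    def __post_init__(self) -> None:
        if self.engine not in ("goslim", "seed"):
            raise ValueError(f"unknown engine {self.engine!r}")
        for key, c in self.counts.items():
            if c <= 0 or int(c) != c:
                raise ValueError(f"count for {key} must be a positive integer")
            if self.engine == "seed" and len(key) != 4:
                raise ValueError(f"SEED key {key} must have exactly 4 levels")

    def rows(self) -> Iterable[tuple[str, tuple[str, ...], float, float]]:
        total = sum(self.counts.values())
        for key in sorted(self.counts, key=lambda k: (-self.counts[k], k)):
            rel = self.counts[key] / total if total else 0.0
            rank = "seed_level4" if self.engine == "seed" else "goslim"
            yield rank, key, float(self.counts[key]), rel

    def level_marginal(self, level: int) -> dict[tuple[str, ...], int]:
        """SEED counts aggregated at hierarchy level 1-4."""
        if self.engine != "seed":
            raise ValueError("level_marginal applies to the seed engine")
        if not 1 <= level <= 4:
            raise ValueError("level must be 1..4")
        out: dict[tuple[str, ...], int] = {}
        for path, c in self.counts.items():
            key = path[:level]
            out[key] = out.get(key, 0) + c
        return out


def rollup_goslim(annotations: Mapping[str, Sequence[str]],
                  ontology: OntologyGraph,
                  slim_ids: Iterable[str],
                  top_n: int = 20) -> FunctionalProfile:
    """Roll gene GO annotations up to the slim subset.

    For each gene the reflexive is_a/part_of ancestor closure of its GO
    terms is intersected with the slim set; every slim term found counts
    once per gene.  Only the ``top_n`` most abundant slim terms per
    namespace are kept (ties broken by term id).
    """
    slim = set(slim_ids)
    for sid in sorted(slim):
        if sid not in ontology.terms:
            raise ValueError(f"slim id {sid!r} is not a term of the ontology")
    term_counts: dict[str, int] = {}
    n_genes = 0
    for gene_id in sorted(annotations):
        terms = annotations[gene_id]
        closure: set[str] = set()
        for t in set(terms):
            if t not in ontology.terms:
                continue
            closure |= ontology.ancestors(t, reflexive=True)
        found = closure & slim
        if not found:
            continue
        n_genes += 1
        for sid in found:
            term_counts[sid] = term_counts.get(sid, 0) + 1
    # keep top_n per namespace
    by_ns: dict[str, list[str]] = {}
    for sid in term_counts:
        by_ns.setdefault(ontology.namespace(sid), []).append(sid)
    kept: dict[tuple[str, ...], int] = {}
    for ns, sids in by_ns.items():
        sids.sort(key=lambda s: (-term_counts[s], s))
        for sid in sids[:top_n]:
            kept[(ns, sid)] = term_counts[sid]
    return FunctionalProfile(engine="goslim", counts=kept, total_annotated=n_genes)


def rollup_seed(annotations: Mapping[str, str],
                hierarchy: SeedHierarchy) -> FunctionalProfile:
    """Expand gene SEED function ids to their 4-level paths and count."""
    counts: dict[tuple[str, ...], int] = {}
    n_genes = 0
    for gene_id in sorted(annotations):
        fid = annotations[gene_id]
        if fid not in hierarchy:
            raise KeyError(f"function id {fid!r} is not in the SEED hierarchy")
        path = hierarchy.path(fid)
        counts[path] = counts.get(path, 0) + 1
        n_genes += 1
    return FunctionalProfile(engine="seed", counts=counts, total_annotated=n_genes)
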