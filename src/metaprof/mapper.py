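"""k-mer-seeded best-hit read mapper with a deterministic parallel contract.

Queries are seeded against an exact k-mer index over the forward strand of
the references; every (reference, strand) pair sharing at least one seed
with the query is then aligned with an affine-gap local (Smith-Waterman)
dynamic program under fixed scoring (match +1, mismatch -1, gap open -2,
gap extend -1; a gap of length g costs 2 + (g-1)).  The single best hit is
reported, with ties broken by score, then identity, then smallest
reference id.  Results are a pure function of (queries, index,
parameters): chunking and worker count never change the output.

The aligner is alphabet-agnostic (plain character comparison), so the same
machinery maps nucleotide rRNA fragments and translated protein sequences.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .io_formats import SequenceRecord
from .simulator import revcomp

__all__ = [
    "KmerIndex",
    "ReferenceHit",
    "build_index",
    "map_query",
    "map_all",
    "global_align",
    "MATCH", "MISMATCH", "GAP_OPEN", "GAP_EXTEND",
]

logger = logging.getLogger(__name__)

MATCH = 1
MISMATCH = -1
GAP_OPEN = -2    # score of the first residue of a gap
GAP_EXTEND = -1  # score of each further residue

DEFAULT_K = 8
DEFAULT_MIN_IDENTITY = 75.0


@dataclass
class KmerIndex:
    """Exact k-mer index over the forward strand of the references."""

    k: int
    kmers: dict[str, list[tuple[str, int]]] = field(default_factory=dict)
    refs: dict[str, str] = field(default_factory=dict)

    @property
    def n_positions(self) -> int:
        return sum(len(v) for v in self.kmers.values())

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.kmers.get(kmer, [])


@dataclass(frozen=True)
class ReferenceHit:
    """Best alignment of one query against the reference set."""

    query_id: str
    ref_id: str
    identity: float        # percent over aligned columns
    aln_len: int           # aligned columns (matches + mismatches + gaps)
    score: int
    query_interval: tuple[int, int]   # on the original (+) query
    ref_interval: tuple[int, int]
    strand: str            # '+' or '-'

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 100.0:
            raise ValueError("identity must lie in [0, 100]")


def build_index(refs: Iterable[SequenceRecord], k: int = DEFAULT_K) -> KmerIndex:
    """Index every k-mer of every reference (forward strand)."""
    if k < 4:
        raise ValueError("k must be >= 4")
    index = KmerIndex(k=k)
    for rec in refs:
        if rec.id in index.refs:
            raise ValueError(f"duplicate reference id {rec.id!r}")
        index.refs[rec.id] = rec.seq
        if len(rec.seq) < k:
            logger.warning("reference %s shorter than k=%d; indexed with zero seeds",
                           rec.id, k)
            continue
        for pos in range(len(rec.seq) - k + 1):
            index.kmers.setdefault(rec.seq[pos:pos + k], []).append((rec.id, pos))
    return index


# ---------------------------------------------------------------------------
# affine local alignment (numba)
# ---------------------------------------------------------------------------

@njit(cache=False)
def _sw_affine(q, r):
    """Affine-gap Smith-Waterman; returns (best, bi, bj, ptr).

    ptr encodes, per cell of the H matrix, the move that produced it:
    0 stop, 1 diagonal, 2 gap in query (from E), 3 gap in ref (from F);
    per cell of E/F, whether the gap was opened (0) or extended (1).
    """
    n, m = q.shape[0], r.shape[0]
    H = np.zeros((n + 1, m + 1))
    E = np.full((n + 1, m + 1), -1e18)   # gap in query (move along ref)
    F = np.full((n + 1, m + 1), -1e18)   # gap in ref (move along query)
    ph = np.zeros((n + 1, m + 1), dtype=np.int8)
    pe = np.zeros((n + 1, m + 1), dtype=np.int8)
    pf = np.zeros((n + 1, m + 1), dtype=np.int8)
    best = 0.0
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e_open = H[i, j - 1] + GAP_OPEN
            e_ext = E[i, j - 1] + GAP_EXTEND
            if e_ext > e_open:
                E[i, j] = e_ext
                pe[i, j] = 1
            else:
                E[i, j] = e_open
                pe[i, j] = 0
            f_open = H[i - 1, j] + GAP_OPEN
            f_ext = F[i - 1, j] + GAP_EXTEND
            if f_ext > f_open:
                F[i, j] = f_ext
                pf[i, j] = 1
            else:
                F[i, j] = f_open
                pf[i, j] = 0
            sub = MATCH if q[i - 1] == r[j - 1] else MISMATCH
            diag = H[i - 1, j - 1] + sub
            h = 0.0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ph[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, ph, pe, pf


@njit(cache=False)
def _nw_affine_score(q, r):
    """Global affine alignment score plus match/column counts.

    Returns (score, matches, columns) for the optimal global alignment;
    used for p-distances on gap-free-ish fragment pairs.
    """
    n, m = q.shape[0], r.shape[0]
    NEG = -1e18
    H = np.full((n + 1, m + 1), NEG)
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    ph = np.zeros((n + 1, m + 1), dtype=np.int8)
    H[0, 0] = 0.0
    for j in range(1, m + 1):
        E[0, j] = GAP_OPEN + (j - 1) * GAP_EXTEND
        H[0, j] = E[0, j]
        ph[0, j] = 2
    for i in range(1, n + 1):
        F[i, 0] = GAP_OPEN + (i - 1) * GAP_EXTEND
        H[i, 0] = F[i, 0]
        ph[i, 0] = 3
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i, j] = max(H[i, j - 1] + GAP_OPEN, E[i, j - 1] + GAP_EXTEND)
            F[i, j] = max(H[i - 1, j] + GAP_OPEN, F[i - 1, j] + GAP_EXTEND)
            sub = MATCH if q[i - 1] == r[j - 1] else MISMATCH
            diag = H[i - 1, j - 1] + sub
            h = diag
            p = 1
            if E[i, j] > h:
                h = E[i, j]
                p = 2
            if F[i, j] > h:
                h = F[i, j]
                p = 3
            H[i, j] = h
            ph[i, j] = p
    # traceback for match / column counts
    i, j = n, m
    matches = 0
    columns = 0
    while i > 0 or j > 0:
        p = ph[i, j]
        columns += 1
        if p == 1:
            if q[i - 1] == r[j - 1]:
                matches += 1
            i -= 1
            j -= 1
        elif p == 2:
            j -= 1
        else:
            i -= 1
    return H[n, m], matches, columns


def _enc(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8).astype(np.int64)


@dataclass(frozen=True)
class _Alignment:
    score: int
    matches: int
    columns: int
    q_interval: tuple[int, int]
    r_interval: tuple[int, int]


def _local_align(query: str, ref: str) -> _Alignment | None:
    best, bi, bj, ph, pe, pf = _sw_affine(_enc(query), _enc(ref))
    if best <= 0:
        return None
    # traceback
    i, j = bi, bj
    matches = 0
    columns = 0
    state = 0  # 0 = H, 2 = E, 3 = F
    while True:
        if state == 0:
            p = ph[i, j]
            if p == 0:
                break
            if p == 1:
                columns += 1
                if query[i - 1] == ref[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            else:
                state = p
        elif state == 2:
            columns += 1
            opened = pe[i, j] == 0
            j -= 1
            if opened:
                state = 0
        else:
            columns += 1
            opened = pf[i, j] == 0
            i -= 1
            if opened:
                state = 0
    return _Alignment(score=int(round(best)), matches=matches, columns=columns,
                      q_interval=(i, bi), r_interval=(j, bj))


def global_align(a: str, b: str) -> tuple[int, int, int]:
    """Global affine alignment of two sequences.

    Returns ``(score, matches, columns)``; the p-distance of the pair is
    ``1 - matches / columns``.
    """
    score, matches, columns = _nw_affine_score(_enc(a), _enc(b))
    return int(round(score)), int(matches), int(columns)


# ---------------------------------------------------------------------------
# query mapping
# ---------------------------------------------------------------------------

def _candidate_refs(seq: str, index: KmerIndex) -> set[str]:
    k = index.k
    cands: set[str] = set()
    for pos in range(0, max(0, len(seq) - k + 1)):
        for ref_id, _ in index.lookup(seq[pos:pos + k]):
            cands.add(ref_id)
    return cands


def map_query(query: SequenceRecord, index: KmerIndex,
              min_identity: float = DEFAULT_MIN_IDENTITY,
              nucleotide: bool = True) -> ReferenceHit | None:
    """Best reference hit for one query, or None.

    Both strands are seeded for nucleotide queries.  Candidates sharing at
    least one exact k-mer are aligned locally; the best (score, identity,
    lexicographically smallest ref id) hit with identity >= *min_identity*
    is returned.
    """
    if not query.seq:
        return None
    variants = [("+", query.seq)]
    if nucleotide:
        variants.append(("-", revcomp(query.seq)))
    best: tuple | None = None
    for strand, seq in variants:
        for ref_id in sorted(_candidate_refs(seq, index)):
            aln = _local_align(seq, index.refs[ref_id])
            if aln is None or aln.columns < index.k:
                continue
            identity = 100.0 * aln.matches / aln.columns
            if identity < min_identity:
                continue
            key = (-aln.score, -identity, ref_id, strand)
            if best is None or key < best[0]:
                qs, qe = aln.q_interval
                if strand == "-":
                    qs, qe = len(seq) - qe, len(seq) - qs
                hit = ReferenceHit(
                    query_id=query.id, ref_id=ref_id, identity=identity,
                    aln_len=aln.columns, score=aln.score,
                    query_interval=(qs, qe), ref_interval=aln.r_interval,
                    strand=strand,
                )
                best = (key, hit)
    return None if best is None else best[1]


def _map_chunk(chunk: Sequence[SequenceRecord], index: KmerIndex,
               min_identity: float, nucleotide: bool) -> list[ReferenceHit | None]:
    return [map_query(q, index, min_identity, nucleotide) for q in chunk]


def map_all(queries: Sequence[SequenceRecord], index: KmerIndex,
            n_workers: int = 1, min_identity: float = DEFAULT_MIN_IDENTITY,
            nucleotide: bool = True, chunk_size: int = 256) -> list[ReferenceHit | None]:
    """Map every query; output order follows input order.

    The work is split into fixed chunks handed to a thread pool; because
    each chunk is a pure function of its queries and the index, the result
    is identical for every worker count and chunk size.
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    queries = list(queries)
    if not queries:
        return []
    chunks = [queries[i:i + chunk_size] for i in range(0, len(queries), chunk_size)]
    if n_workers == 1 or len(chunks) == 1:
        results = [_map_chunk(c, index, min_identity, nucleotide) for c in chunks]
    else:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            results = list(pool.map(
                lambda c: _map_chunk(c, index, min_identity, nucleotide), chunks))
    out: list[ReferenceHit | None] = []
    for r in results:
        out.extend(r)
    return out


def write_hits(hits: Iterable[ReferenceHit | None], path) -> None:
    """Write hits as TSV (unmapped queries are omitted)."""
    from pathlib import Path
    with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("query_id\tref_id\tidentity\taln_len\tscore\t"
                 "qstart\tqend\trstart\trend\tstrand\n")
        for h in hits:
            if h is None:
                continue
            fh.write(f"{h.query_id}\t{h.ref_id}\t{h.identity:.4f}\t{h.aln_len}\t"
                     f"{h.score}\t{h.query_interval[0]}\t{h.query_interval[1]}\t"
                     f"{h.ref_interval[0]}\t{h.ref_interval[1]}\t{h.strand}\n")


def read_hits(path) -> list[ReferenceHit]:
    from pathlib import Path
    hits: list[ReferenceHit] = []
    with Path(path).open("r", encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("query_id\t"):
                continue
            (qid, rid, ident, alen, score, qs, qe, rs, re_, strand) = line.split("\t")
            hits.append(ReferenceHit(
                query_id=qid, ref_id=rid, identity=float(ident), aln_len=int(alen),
                score=int(score), query_interval=(int(qs), int(qe)),
                ref_interval=(int(rs), int(re_)), strand=strand))
    return hits
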