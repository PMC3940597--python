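"""Readers and writers for every on-disk format the pipeline touches.

All dialects are deliberately strict: readers reject and name the first
malformed record instead of skipping it, writers emit UTF-8, Unix newlines
and deterministic row order so that outputs are bit-reproducible.

Formats
-------
FASTA / FASTQ (Phred+33)      sequence data
lineage tables                ``ref_id <TAB> domain;...;species``
OBO 1.2                       Gene Ontology graphs (via :mod:`obonet`)
SEED tables                   4-level functional hierarchy, TSV
profile tables                rank / path / count / relative abundance, TSV
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet
import pandas as pd

__all__ = [
    "RANKS",
    "UNCLASSIFIED",
    "FormatError",
    "SequenceRecord",
    "LineageTable",
    "OntologyGraph",
    "SeedHierarchy",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "write_fastq",
    "read_lineage_table",
    "write_lineage_table",
    "read_obo",
    "read_seed_table",
    "write_seed_table",
    "read_annotation_table",
    "write_annotation_table",
    "write_profile_table",
    "read_profile_table",
]

#: The seven taxonomic ranks, in hierarchy order.
RANKS: tuple[str, ...] = (
    "domain", "phylum", "class", "order", "family", "genus", "species",
)

#: Sentinel used for ranks that could not be resolved.
UNCLASSIFIED = "Unclassified"

_NT_ALPHABET = frozenset("ACGTN")
# 20 amino acids + ambiguity codes B/Z/X + stop '*'
_AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYBZX*")


class FormatError(ValueError):
    """A file violated the expected dialect; the message names the culprit."""


# ---------------------------------------------------------------------------
# sequence records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SequenceRecord:
    """One named sequence with an optional per-base Phred quality vector."""

    id: str
    description: str = ""
    seq: str = ""
    qual: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise FormatError(
                f"record {self.id!r}: quality length {len(self.qual)} "
                f"!= sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def _validate_alphabet(rec: SequenceRecord, alphabet: str | None, where: str) -> None:
    if alphabet is None:
        return
    allowed = _NT_ALPHABET if alphabet == "nt" else _AA_ALPHABET
    bad = set(rec.seq.upper()) - allowed
    if bad:
        raise FormatError(
            f"{where}: record {rec.id!r} contains characters {sorted(bad)} "
            f"outside the {alphabet} alphabet"
        )


def read_fasta(path: str | Path, alphabet: str | None = "nt") -> list[SequenceRecord]:
    """Read a FASTA file into a list of records, in file order.

    Multi-line sequences are concatenated; the description is the header
    text after the first whitespace.  Malformed headers, empty sequences
    and duplicate ids raise :class:`FormatError` naming the line.

    Parameters
    ----------
    path:
        FASTA file.
    alphabet:
        ``"nt"`` (default), ``"aa"`` or ``None`` to skip validation.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    header: str | None = None
    header_line = 0
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise FormatError(f"{path}:{header_line}: empty sequence for header {header!r}")
        name, _, desc = header.partition(" ")
        if not name:
            raise FormatError(f"{path}:{header_line}: header with empty id")
        if name in seen:
            raise FormatError(f"{path}:{header_line}: duplicate id {name!r}")
        seen.add(name)
        rec = SequenceRecord(id=name, description=desc.strip(), seq=seq.upper())
        _validate_alphabet(rec, alphabet, str(path))
        records.append(rec)

    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
                if not header:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
            else:
                if header is None:
                    raise FormatError(
                        f"{path}:{lineno}: sequence data before any '>' header"
                    )
                chunks.append(line.strip())
    flush()
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path,
                width: int = 70) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            head = f">{rec.id} {rec.description}".rstrip()
            fh.write(head + "\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i:i + width] + "\n")


def read_fastq(path: str | Path, alphabet: str | None = "nt") -> list[SequenceRecord]:
    """Read 4-line FASTQ records with Phred+33 qualities."""
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with path.open("r", encoding="utf-8") as fh:
        lines = [ln.rstrip("\n").rstrip("\r") for ln in fh]
    while lines and not lines[-1]:
        lines.pop()
    if len(lines) % 4 != 0:
        raise FormatError(f"{path}: truncated FASTQ (line count {len(lines)} not a multiple of 4)")
    for i in range(0, len(lines), 4):
        head, seq, plus, qual = lines[i:i + 4]
        lineno = i + 1
        if not head.startswith("@"):
            raise FormatError(f"{path}:{lineno}: expected '@' header, got {head[:20]!r}")
        if not plus.startswith("+"):
            raise FormatError(f"{path}:{lineno + 2}: expected '+' separator")
        name, _, desc = head[1:].partition(" ")
        if not name:
            raise FormatError(f"{path}:{lineno}: empty FASTQ id")
        if name in seen:
            raise FormatError(f"{path}:{lineno}: duplicate id {name!r}")
        seen.add(name)
        if len(seq) != len(qual):
            raise FormatError(
                f"{path}: record {name!r}: sequence length {len(seq)} != quality length {len(qual)}"
            )
        if not seq:
            raise FormatError(f"{path}:{lineno}: empty sequence for record {name!r}")
        quals = tuple(ord(c) - 33 for c in qual)
        if any(q < 0 or q > 93 for q in quals):
            raise FormatError(f"{path}: record {name!r}: quality character outside Phred+33 range")
        rec = SequenceRecord(id=name, description=desc.strip(), seq=seq.upper(), qual=quals)
        _validate_alphabet(rec, alphabet, str(path))
        records.append(rec)
    return records


def write_fastq(records: Iterable[SequenceRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for rec in records:
            if rec.qual is None:
                raise FormatError(f"record {rec.id!r} has no qualities; cannot write FASTQ")
            head = f"@{rec.id} {rec.description}".rstrip()
            fh.write(head + "\n" + rec.seq + "\n+\n")
            fh.write("".join(chr(q + 33) for q in rec.qual) + "\n")


# ---------------------------------------------------------------------------
# lineage tables
# ---------------------------------------------------------------------------

@dataclass
class LineageTable:
    """Mapping from reference id to its ordered 7-rank lineage."""

    lineages: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ref_id, lin in self.lineages.items():
            self._check(ref_id, lin)

    @staticmethod
    def _check(ref_id: str, lin: Sequence[str]) -> None:
        if len(lin) != len(RANKS):
            raise FormatError(f"lineage for {ref_id!r} has {len(lin)} ranks, expected {len(RANKS)}")
        if any(not part for part in lin):
            raise FormatError(f"lineage for {ref_id!r} contains an empty rank entry")

    def __getitem__(self, ref_id: str) -> tuple[str, ...]:
        return self.lineages[ref_id]

    def __contains__(self, ref_id: str) -> bool:
        return ref_id in self.lineages

    def __len__(self) -> int:
        return len(self.lineages)

    def add(self, ref_id: str, lineage: Sequence[str]) -> None:
        lin = tuple(lineage)
        self._check(ref_id, lin)
        self.lineages[ref_id] = lin


def read_lineage_table(path: str | Path) -> LineageTable:
    """Read ``ref_id <TAB> semicolon-joined lineage``.

    Missing trailing ranks are padded with the ``Unclassified`` sentinel.
    """
    path = Path(path)
    table = LineageTable()
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 tab-separated fields")
            ref_id, lin_str = parts
            ranks = [p.strip() for p in lin_str.split(";")]
            if len(ranks) > len(RANKS):
                raise FormatError(f"{path}:{lineno}: more than {len(RANKS)} ranks")
            ranks += [UNCLASSIFIED] * (len(RANKS) - len(ranks))
            if ref_id in table:
                raise FormatError(f"{path}:{lineno}: duplicate ref id {ref_id!r}")
            table.add(ref_id, ranks)
    return table


def write_lineage_table(table: LineageTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for ref_id in sorted(table.lineages):
            fh.write(f"{ref_id}\t{';'.join(table.lineages[ref_id])}\n")


# ---------------------------------------------------------------------------
# ontology graphs (OBO 1.2)
# ---------------------------------------------------------------------------

@dataclass
class OntologyGraph:
    """GO-style DAG restricted to ``is_a`` / ``part_of`` edges.

    ``edges`` point child -> parent.  Obsolete terms are recorded but carry
    no edges.  Acyclicity is a load-time invariant.
    """

    terms: dict[str, dict[str, str]]
    edges: set[tuple[str, str, str]]
    obsolete: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for child, parent, rel in self.edges:
            for tid in (child, parent):
                if tid not in self.terms:
                    raise FormatError(f"ontology edge endpoint {tid!r} is not a known term")
                if tid in self.obsolete:
                    raise FormatError(f"ontology edge endpoint {tid!r} is obsolete")
            if rel not in ("is_a", "part_of"):
                raise FormatError(f"unexpected ontology relation {rel!r}")
        g = self._digraph()
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise FormatError(f"ontology contains a cycle: {cycle}")

    def _digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from((c, p) for c, p, _ in self.edges)
        return g

    def ancestors(self, term_id: str, reflexive: bool = True) -> set[str]:
        """All terms reachable from *term_id* by is_a/part_of, optionally
        including the term itself."""
        if term_id not in self.terms:
            raise KeyError(term_id)
        anc = nx.descendants(self._digraph(), term_id)  # child->parent direction
        if reflexive:
            anc.add(term_id)
        return anc

    def namespace(self, term_id: str) -> str:
        return self.terms[term_id].get("namespace", "")


def read_obo(path: str | Path) -> OntologyGraph:
    """Parse an OBO 1.2 ontology into an :class:`OntologyGraph`.

    Only ``is_a`` and ``relationship: part_of`` edges are followed; obsolete
    terms are excluded from the edge set.  A cyclic ontology is a hard
    error listing one offending cycle.
    """
    graph = obonet.read_obo(Path(path), ignore_obsolete=False)
    terms: dict[str, dict[str, str]] = {}
    obsolete: set[str] = set()
    edges: set[tuple[str, str, str]] = set()
    for node, data in graph.nodes(data=True):
        terms[node] = {
            "name": data.get("name", ""),
            "namespace": data.get("namespace", ""),
        }
        if str(data.get("is_obsolete", "false")).lower() == "true":
            obsolete.add(node)
    for child, parent, rel in graph.edges(keys=True):
        if rel not in ("is_a", "part_of"):
            continue
        if child in obsolete or parent in obsolete:
            continue
        edges.add((child, parent, rel))
    return OntologyGraph(terms=terms, edges=edges, obsolete=obsolete)


# ---------------------------------------------------------------------------
# SEED hierarchy tables
# ---------------------------------------------------------------------------

@dataclass
class SeedHierarchy:
    """4-level SEED-style functional hierarchy.

    Each function id maps to exactly one (level1..level4) path.
    """

    rows: list[tuple[str, str, str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._lookup: dict[str, tuple[str, str, str, str]] = {}
        for row in self.rows:
            if len(row) != 5:
                raise FormatError(f"SEED row {row!r} must have 5 fields")
            l1, l2, l3, l4, fid = row
            if not all((l1, l2, l3, l4, fid)):
                raise FormatError(f"SEED row for {fid!r} contains an empty field")
            if fid in self._lookup and self._lookup[fid] != (l1, l2, l3, l4):
                raise FormatError(f"function id {fid!r} maps to two different paths")
            self._lookup[fid] = (l1, l2, l3, l4)

    def path(self, function_id: str) -> tuple[str, str, str, str]:
        return self._lookup[function_id]

    def __contains__(self, function_id: str) -> bool:
        return function_id in self._lookup

    def function_ids(self) -> list[str]:
        return sorted(self._lookup)


def read_seed_table(path: str | Path) -> SeedHierarchy:
    path = Path(path)
    rows: list[tuple[str, str, str, str, str]] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("level1\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 tab-separated fields")
            rows.append(tuple(parts))  # type: ignore[arg-type]
    return SeedHierarchy(rows=rows)


def write_seed_table(hierarchy: SeedHierarchy, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("level1\tlevel2\tlevel3\tlevel4\tfunction_id\n")
        for row in sorted(hierarchy.rows, key=lambda r: (r[4], r[:4])):
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# reference annotation tables (functional arm)
# ---------------------------------------------------------------------------

def read_annotation_table(path: str | Path) -> dict[str, dict[str, object]]:
    """Read ``ref_id, go_terms (pipe-separated), seed_function_id`` TSV.

    Returns a map ref_id -> {"go_terms": tuple[str, ...], "seed_id": str | None}.
    """
    path = Path(path)
    out: dict[str, dict[str, object]] = {}
    with path.open("r", encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("ref_id\t"):
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise FormatError(f"{path}:{lineno}: expected 3 tab-separated fields")
            ref_id, go_str, seed_id = parts
            if ref_id in out:
                raise FormatError(f"{path}:{lineno}: duplicate ref id {ref_id!r}")
            go_terms = tuple(t for t in go_str.split("|") if t)
            out[ref_id] = {"go_terms": go_terms, "seed_id": seed_id or None}
    return out


def write_annotation_table(annotations: Mapping[str, Mapping[str, object]],
                           path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("ref_id\tgo_terms\tseed_function_id\n")
        for ref_id in sorted(annotations):
            ann = annotations[ref_id]
            go = "|".join(ann.get("go_terms", ()))  # type: ignore[arg-type]
            seed = ann.get("seed_id") or ""
            fh.write(f"{ref_id}\t{go}\t{seed}\n")


# ---------------------------------------------------------------------------
# profile tables
# ---------------------------------------------------------------------------

_RANK_ORDER = {r: i for i, r in enumerate(RANKS)}


def write_profile_table(profile, path: str | Path) -> None:
    """Write a taxonomic or functional profile as a deterministic TSV.

    Columns: rank, full_path (semicolon-joined), count, relative_abundance
    (6 decimal places).  Rows are sorted by rank order, then descending
    count, then path.
    """
    rows = list(profile.rows())
    rows.sort(key=lambda r: (_RANK_ORDER.get(r[0], len(RANKS)), r[0], -r[2], r[1]))
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("rank\tfull_path\tcount\trelative_abundance\n")
        for rank, full_path, count, rel in rows:
            count_str = str(int(count)) if float(count).is_integer() else f"{count:.6f}"
            fh.write(f"{rank}\t{';'.join(full_path)}\t{count_str}\t{rel:.6f}\n")


def read_profile_table(path: str | Path) -> pd.DataFrame:
    """Read a profile table back into a DataFrame (paths as tuples)."""
    df = pd.read_csv(path, sep="\t", dtype={"rank": str, "full_path": str})
    expected = ["rank", "full_path", "count", "relative_abundance"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    df["full_path"] = df["full_path"].map(lambda s: tuple(str(s).split(";")))
    return df


def stable_hash(text: str) -> int:
    """Deterministic 64-bit hash used for e.g. color assignment."""
    return int.from_bytes(hashlib.md5(text.encode("utf-8")).digest()[:8], "big")
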