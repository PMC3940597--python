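"""Multi-sample comparison, the taxonomic error-rate statistic, and the
phylogenetic view.

The error rate between an actual and a predicted community structure at a
rank is the Euclidean distance between the two relative-abundance vectors
over the union of their taxa, expressed in percent:

    E = 100 * sqrt( sum_i (V_i - V'_i)^2 )

Larger E means higher error; E is a metric on abundance vectors restricted
to a common support.  Optional normalizations (by sqrt(N) or by 2) are
available for cross-study comparability.

The phylogenetic view builds a neighbor-joining tree over extracted rRNA
fragments from p-distances computed on pairwise global alignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from skbio import DistanceMatrix
from skbio.tree import nj

from .io_formats import RANKS, SequenceRecord
from .mapper import global_align
from .taxonomy import TaxonomicProfile

__all__ = [
    "AbundancePair",
    "ComparisonTable",
    "error_rate",
    "abundance_pair",
    "compare_profiles",
    "p_distance",
    "build_phylo_tree",
]


@dataclass(frozen=True)
class AbundancePair:
    """Actual (V) and predicted (V') abundances over a shared taxa list."""

    taxa: tuple
    actual: tuple[float, ...]
    predicted: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.taxa) == len(self.actual) == len(self.predicted)):
            raise ValueError("taxa, actual and predicted must have equal length")
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxa must be unique")
        for v in (*self.actual, *self.predicted):
            if not 0.0 <= v <= 1.0 + 1e-12:
                raise ValueError(f"abundance {v} outside [0, 1]")

    @property
    def n(self) -> int:
        return len(self.taxa)


def error_rate(pair: AbundancePair, normalization: str = "none") -> float:
    """Taxonomic error rate E in percent.

    ``normalization`` is ``"none"`` (default), ``"sqrt_n"`` (divide by
    sqrt(N)) or ``"half"`` (divide by 2).
    """
    v = np.asarray(pair.actual)
    vp = np.asarray(pair.predicted)
    e = 100.0 * math.sqrt(float(np.sum((v - vp) ** 2)))
    if normalization == "none":
        return e
    if normalization == "sqrt_n":
        return e / math.sqrt(pair.n)
    if normalization == "half":
        return e / 2.0
    raise ValueError(f"unknown normalization {normalization!r}")


def abundance_pair(actual: Mapping, predicted: Mapping) -> AbundancePair:
    """Zero-filled :class:`AbundancePair` over the union of both supports."""
    taxa = tuple(sorted(set(actual) | set(predicted)))
    return AbundancePair(
        taxa=taxa,
        actual=tuple(float(actual.get(t, 0.0)) for t in taxa),
        predicted=tuple(float(predicted.get(t, 0.0)) for t in taxa),
    )


@dataclass
class ComparisonTable:
    """Per-sample relative abundances at one rank, union of taxa."""

    rank: str
    sample_labels: tuple[str, ...]
    rows: list[tuple[tuple[str, ...], tuple[float, ...]]]

    def column_sums(self) -> tuple[float, ...]:
        sums = [0.0] * len(self.sample_labels)
        for _, values in self.rows:
            for i, v in enumerate(values):
                sums[i] += v
        return tuple(sums)

    def write(self, path) -> None:
        from pathlib import Path
        with Path(path).open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("rank\tfull_path\t" + "\t".join(self.sample_labels) + "\n")
            for path_t, values in self.rows:
                fh.write(f"{self.rank}\t{';'.join(path_t)}\t"
                         + "\t".join(f"{v:.6f}" for v in values) + "\n")


def compare_profiles(profiles: Sequence[TaxonomicProfile], rank: str) -> ComparisonTable:
    """Side-by-side relative abundances of >= 2 profiles at one rank.

    Absent taxa are filled with zero; rows sorted by descending mean
    abundance, then path.
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}")
    if len(profiles) < 2:
        raise ValueError("compare_profiles requires at least two profiles")
    rels = [p.relative_abundance(rank) for p in profiles]
    support: set[tuple[str, ...]] = set()
    for rel in rels:
        support |= set(rel)
    rows = [
        (path, tuple(rel.get(path, 0.0) for rel in rels))
        for path in support
    ]
    rows.sort(key=lambda r: (-sum(r[1]) / len(r[1]), r[0]))
    return ComparisonTable(
        rank=rank,
        sample_labels=tuple(p.database for p in profiles),
        rows=rows,
    )


# ---------------------------------------------------------------------------
# phylogenetic view
# ---------------------------------------------------------------------------

def p_distance(a: str, b: str) -> float:
    """Proportion of differing positions on a global pairwise alignment."""
    _, matches, columns = global_align(a, b)
    if columns == 0:
        return 0.0
    return 1.0 - matches / columns


def build_phylo_tree(fragments: Sequence[SequenceRecord]) -> str:
    """Neighbor-joining tree over fragments as a Newick string.

    Distances are pairwise p-distances; leaf names are fragment ids.  Two
    sequences produce a single cherry with branch lengths d/2 each.
    """
    if len(fragments) < 2:
        raise ValueError("need at least two fragments for a tree")
    ids = [f.id for f in fragments]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate fragment ids")
    if len(fragments) == 2:
        d = p_distance(fragments[0].seq, fragments[1].seq)
        return f"({ids[0]}:{d / 2:.6f},{ids[1]}:{d / 2:.6f});"
    n = len(fragments)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = p_distance(fragments[i].seq, fragments[j].seq)
            dm[i, j] = dm[j, i] = d
    tree = nj(DistanceMatrix(dm, ids=ids))
    return str(tree).strip()
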