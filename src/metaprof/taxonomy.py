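"""Taxonomic profiling: lineage assignment and per-rank abundance tables.

Reference hits are turned into lineages truncated by per-rank identity
thresholds (an rRNA-style rank calling convention: e.g. a 92%-identity hit
keeps its lineage down to family but not genus or species), aggregated
into per-rank count tables per database, and optionally integrated across
databases by averaging relative abundances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .io_formats import RANKS, UNCLASSIFIED, LineageTable
from .mapper import ReferenceHit

__all__ = [
    "DEFAULT_RANK_THRESHOLDS",
    "AnnotationError",
    "TaxonomicProfile",
    "assign_lineage",
    "build_profile",
    "integrate_databases",
]

#: Minimum percent identity required to keep each rank of the hit lineage.
#: Domain is always retained for any accepted hit.
DEFAULT_RANK_THRESHOLDS: dict[str, float] = {
    "phylum": 75.0,
    "class": 80.0,
    "order": 85.0,
    "family": 90.0,
    "genus": 95.0,
    "species": 97.0,
}


class AnnotationError(KeyError):
    """A hit references an id missing from the lineage table."""


def assign_lineage(hit: ReferenceHit, lineages: LineageTable,
                   rank_thresholds: Mapping[str, float] | None = None
                   ) -> tuple[str, ...]:
    """Lineage of the hit reference, truncated by identity.

    Ranks whose threshold exceeds the hit identity become ``Unclassified``;
    the result always has 7 entries.
    """
    if rank_thresholds is None:
        rank_thresholds = DEFAULT_RANK_THRESHOLDS
    if hit.ref_id not in lineages:
        raise AnnotationError(f"reference id {hit.ref_id!r} has no lineage entry")
    full = lineages[hit.ref_id]
    out = list(full)
    for i, rank in enumerate(RANKS):
        if rank == "domain":
            continue
        threshold = rank_thresholds.get(rank, 0.0)
        if hit.identity < threshold:
            for j in range(i, len(RANKS)):
                out[j] = UNCLASSIFIED
            break
    return tuple(out)


@dataclass
class TaxonomicProfile:
    """Per-rank abundance table over a lineage tree, for one database.

    ``counts[rank]`` maps a lineage *prefix* path (tuple up to that rank)
    to its read count; reads unresolved at a rank are tallied in
    ``unclassified[rank]``.  Counts are integers for profiles built from
    assignments and may be fractional for integrated profiles.
    """

    database: str
    counts: dict[str, dict[tuple[str, ...], float]] = field(default_factory=dict)
    unclassified: dict[str, float] = field(default_factory=dict)
    total_assigned: float = 0.0

    def __post_init__(self) -> None:
        for rank in RANKS:
            self.counts.setdefault(rank, {})
            self.unclassified.setdefault(rank, 0.0)
        self.check_conservation()

    # ----- invariants -----------------------------------------------------

    def check_conservation(self) -> None:
        """Sum of counts + unclassified must equal total assigned at every
        rank, and child paths must extend parent paths."""
        for rank in RANKS:
            total = sum(self.counts[rank].values()) + self.unclassified[rank]
            if abs(total - self.total_assigned) > 1e-6:
                raise ValueError(
                    f"{self.database}: mass not conserved at rank {rank}: "
                    f"{total} != {self.total_assigned}"
                )
        for ri in range(1, len(RANKS)):
            parents = self.counts[RANKS[ri - 1]]
            for path in self.counts[RANKS[ri]]:
                if path[:-1] not in parents:
                    raise ValueError(
                        f"{self.database}: child path {path} has no parent entry"
                    )

    # ----- accessors ------------------------------------------------------

    def relative_abundance(self, rank: str) -> dict[tuple[str, ...], float]:
        """Fraction of assigned reads per lineage path at *rank*."""
        if self.total_assigned == 0:
            return {}
        return {p: c / self.total_assigned for p, c in self.counts[rank].items()}

    def rows(self) -> Iterable[tuple[str, tuple[str, ...], float, float]]:
        """(rank, path, count, relative abundance) rows for the table writer."""
        for rank in RANKS:
            rel = self.relative_abundance(rank)
            for path, count in self.counts[rank].items():
                yield rank, path, count, rel[path]


def build_profile(assignments: Iterable[tuple[str, ...]],
                  database_label: str) -> TaxonomicProfile:
    """Aggregate truncated lineages into a per-rank profile.

    Each assignment is a 7-rank lineage (possibly with ``Unclassified``
    suffix).  At each rank a read counts toward its lineage prefix, or
    toward the rank's unclassified tally once its lineage is unresolved.
    """
    counts: dict[str, dict[tuple[str, ...], float]] = {r: {} for r in RANKS}
    unclassified: dict[str, float] = {r: 0.0 for r in RANKS}
    total = 0
    for lineage in assignments:
        if len(lineage) != len(RANKS):
            raise ValueError(f"assignment {lineage!r} must have 7 ranks")
        total += 1
        for i, rank in enumerate(RANKS):
            if lineage[i] == UNCLASSIFIED:
                unclassified[rank] += 1
            else:
                path = tuple(lineage[:i + 1])
                counts[rank][path] = counts[rank].get(path, 0) + 1
    return TaxonomicProfile(database=database_label, counts=counts,
                            unclassified=unclassified, total_assigned=total)


def integrate_databases(profiles: Sequence[TaxonomicProfile]) -> TaxonomicProfile:
    """Average relative abundances over databases, renormalized per rank.

    Taxa absent from a database contribute zero to the mean.  The result
    carries fractional "counts" equal to the renormalized relative
    abundances (total 1 per rank) under the label ``integrated``.
    """
    if not profiles:
        raise ValueError("integrate_databases requires at least one profile")
    counts: dict[str, dict[tuple[str, ...], float]] = {r: {} for r in RANKS}
    unclassified: dict[str, float] = {r: 0.0 for r in RANKS}
    n = len(profiles)
    for rank in RANKS:
        support: set[tuple[str, ...]] = set()
        for p in profiles:
            support |= set(p.relative_abundance(rank))
        means = {
            path: sum(p.relative_abundance(rank).get(path, 0.0) for p in profiles) / n
            for path in support
        }
        total = sum(means.values())
        if total > 0:
            counts[rank] = {path: v / total for path, v in means.items()}
            unclassified[rank] = 0.0
        else:
            counts[rank] = {}
            unclassified[rank] = 1.0
    # renormalizing each rank independently can leave a child with slightly
    # more mass than its parent; reconcile by reinserting missing parents
    for ri in range(1, len(RANKS)):
        parents = counts[RANKS[ri - 1]]
        for path in counts[RANKS[ri]]:
            parents.setdefault(path[:-1], 0.0)
    return TaxonomicProfile(database="integrated", counts=counts,
                            unclassified=unclassified, total_assigned=1.0)
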