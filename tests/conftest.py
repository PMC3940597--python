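"""Shared fixtures: the fixture bundle and one full pipeline run.

The expensive artifacts (fixture universe, profile HMM, 20,000-read
community analysis) are built once per session and shared by the module
and acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import pytest

from metaprof import io_formats as io
from metaprof import mapper, rrna_hmm, simulator as sim, taxonomy

BUNDLE_SEED = 7
COMMUNITY_SEED = 42
E2E_N_READS = 20_000


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    return sim.make_fixture_bundle(BUNDLE_SEED, tmp_path_factory.mktemp("bundle"))


@pytest.fixture(scope="session")
def hmm(bundle):
    return rrna_hmm.build_profile(io.read_fasta(bundle.training_alignment))


@pytest.fixture(scope="session")
def rrna_regions(bundle):
    """Planted rRNA region coordinates per genome, from the truth sidecar."""
    regions = {}
    for line in bundle.rrna_truth.read_text(encoding="utf-8").splitlines():
        if line.startswith("genome_id"):
            continue
        gid, s, e = line.split("\t")
        regions[gid] = (int(s), int(e))
    return regions


@dataclass
class EndToEnd:
    """One simulated community analysed against both reference databases."""

    spec: sim.CommunitySpec
    reads: list
    truth: sim.TruthTable
    fragments: list
    hits: list
    profiles: dict          # db label -> TaxonomicProfile
    maps: dict              # db label -> list of ReferenceHit | None
    genome_lineages: io.LineageTable


@pytest.fixture(scope="session")
def e2e(bundle, hmm) -> EndToEnd:
    spec = sim.community_from_bundle(bundle, n_reads=E2E_N_READS,
                                     seed=COMMUNITY_SEED)
    reads, truth = sim.simulate_reads(spec)
    hits = rrna_hmm.extract_fragments(reads, hmm)
    fragments = [io.SequenceRecord(id=h.read_id, seq=h.fragment) for h in hits]
    profiles = {}
    maps = {}
    for label, fasta, lineage_path in (
        ("general", bundle.db_general_fasta, bundle.db_general_lineages),
        ("habitat", bundle.db_habitat_fasta, bundle.db_habitat_lineages),
    ):
        index = mapper.build_index(io.read_fasta(fasta))
        lineages = io.read_lineage_table(lineage_path)
        mapped = mapper.map_all(fragments, index)
        assignments = [taxonomy.assign_lineage(h, lineages)
                       for h in mapped if h is not None]
        profiles[label] = taxonomy.build_profile(assignments, label)
        maps[label] = mapped
    return EndToEnd(spec=spec, reads=reads, truth=truth, fragments=fragments,
                    hits=hits, profiles=profiles, maps=maps,
                    genome_lineages=io.read_lineage_table(bundle.lineages_by_genome))


def truth_abundances(e2e_obj: EndToEnd, rank: str) -> dict[str, float]:
    """Ground-truth relative abundances at a rank, from the truth table."""
    idx = io.RANKS.index(rank)
    out: dict[str, float] = {}
    for gid, frac in e2e_obj.truth.abundance_by_genome().items():
        name = e2e_obj.genome_lineages[gid][idx]
        out[name] = out.get(name, 0.0) + frac
    return out


def predicted_abundances(profile: taxonomy.TaxonomicProfile, rank: str) -> dict[str, float]:
    return {path[-1]: v for path, v in profile.relative_abundance(rank).items()}
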