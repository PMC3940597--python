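"""compare: error-rate statistic, comparison tables, NJ phylogeny."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from metaprof import compare, io_formats as io, taxonomy

from oracles import four_point_split

LIN_A = ("Bacteria", "PhyA", "ClsA", "OrdA", "FamA", "GenA", "SpA")
LIN_B = ("Bacteria", "PhyB", "ClsB", "OrdB", "FamB", "GenB", "SpB")


class TestErrorRate:
    def test_identical_vectors_zero(self):
        pair = compare.AbundancePair(taxa=("a", "b"), actual=(0.6, 0.4),
                                     predicted=(0.6, 0.4))
        assert compare.error_rate(pair) == 0.0

    def test_closed_form_opposite_unit_vectors(self):
        pair = compare.AbundancePair(taxa=("a", "b"), actual=(1.0, 0.0),
                                     predicted=(0.0, 1.0))
        assert compare.error_rate(pair) == pytest.approx(100 * math.sqrt(2))
        assert compare.error_rate(pair) == pytest.approx(141.42, abs=0.01)

    def test_vectorized_equals_elementwise_loop(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(1, 12))
            v = rng.dirichlet(np.ones(n))
            vp = rng.dirichlet(np.ones(n))
            pair = compare.AbundancePair(taxa=tuple(range(n)),
                                         actual=tuple(v), predicted=tuple(vp))
            manual = 100 * math.sqrt(sum((a - b) ** 2 for a, b in zip(v, vp)))
            assert compare.error_rate(pair) == pytest.approx(manual, abs=1e-9)

    def test_normalization_options(self):
        pair = compare.AbundancePair(taxa=("a", "b"), actual=(1.0, 0.0),
                                     predicted=(0.0, 1.0))
        e = compare.error_rate(pair)
        assert compare.error_rate(pair, "sqrt_n") == pytest.approx(e / math.sqrt(2))
        assert compare.error_rate(pair, "half") == pytest.approx(e / 2)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compare.AbundancePair(taxa=("a",), actual=(1.0,), predicted=(0.5, 0.5))

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(2, 8), st.integers(0, 2 ** 32 - 1))
    def test_metric_properties(self, n, seed):
        """Symmetry, non-negativity, identity and triangle inequality on a
        common support."""
        rng = np.random.default_rng(seed)
        x, y, z = (rng.dirichlet(np.ones(n)) for _ in range(3))
        taxa = tuple(range(n))

        def e(a, b):
            return compare.error_rate(compare.AbundancePair(
                taxa=taxa, actual=tuple(a), predicted=tuple(b)))

        assert e(x, y) == pytest.approx(e(y, x))
        assert e(x, y) >= 0
        assert e(x, x) == pytest.approx(0.0, abs=1e-9)
        assert e(x, z) <= e(x, y) + e(y, z) + 1e-9


class TestCompareProfiles:
    def _profiles(self):
        p1 = taxonomy.build_profile([LIN_A] * 8 + [LIN_B] * 2, "s1")
        p2 = taxonomy.build_profile([LIN_B] * 5, "s2")
        return p1, p2

    def test_identical_profiles_equal_columns(self):
        p = taxonomy.build_profile([LIN_A] * 4, "s1")
        q = taxonomy.build_profile([LIN_A] * 9, "s2")
        table = compare.compare_profiles([p, q], "species")
        assert len(table.rows) == 1
        assert table.rows[0][1] == (1.0, 1.0)

    def test_disjoint_profiles_one_nonzero_per_row(self):
        p1 = taxonomy.build_profile([LIN_A] * 3, "s1")
        p2 = taxonomy.build_profile([LIN_B] * 3, "s2")
        table = compare.compare_profiles([p1, p2], "genus")
        assert len(table.rows) == 2
        for _, values in table.rows:
            assert sum(1 for v in values if v > 0) == 1

    def test_column_sums_match_profile_totals(self):
        p1, p2 = self._profiles()
        table = compare.compare_profiles([p1, p2], "species")
        sums = table.column_sums()
        for i, prof in enumerate((p1, p2)):
            expected = sum(prof.relative_abundance("species").values())
            assert sums[i] == pytest.approx(expected)
            assert sums[i] <= 1.0 + 1e-9

    def test_rows_sorted_by_mean_abundance(self):
        p1, p2 = self._profiles()
        table = compare.compare_profiles([p1, p2], "species")
        means = [sum(v) / len(v) for _, v in table.rows]
        assert means == sorted(means, reverse=True)

    def test_unknown_rank_rejected(self):
        p1, p2 = self._profiles()
        with pytest.raises(ValueError, match="rank"):
            compare.compare_profiles([p1, p2], "kingdom")


class TestPhylo:
    def test_p_distance_hand_count(self):
        assert compare.p_distance("AAAA", "AAAT") == pytest.approx(0.25)
        assert compare.p_distance("ACGT", "ACGT") == 0.0

    def test_two_leaf_cherry(self):
        frags = [io.SequenceRecord(id="a", seq="AAAA"),
                 io.SequenceRecord(id="b", seq="AAAT")]
        nwk = compare.build_phylo_tree(frags)
        assert nwk == "(a:0.125000,b:0.125000);"

    def test_duplicate_ids_rejected(self):
        frags = [io.SequenceRecord(id="a", seq="AAAA"),
                 io.SequenceRecord(id="a", seq="AAAT")]
        with pytest.raises(ValueError, match="duplicate"):
            compare.build_phylo_tree(frags)

    @staticmethod
    def _additive_quartet(rng, split_pair):
        """Four sequences whose p-distances form an additive tree with the
        given cherry pairing, built by mutating disjoint position blocks."""
        length = 240
        anc = "".join("ACGT"[j] for j in rng.integers(0, 4, size=length))
        # branch lengths in mutated positions: two cherries + internal edge
        sizes = {"w": 10, "x": 16, "internal": 12, "y": 8, "z": 14}
        blocks = {}
        pos = 0
        for name, size in sizes.items():
            blocks[name] = list(range(pos, pos + size))
            pos += size

        def mutate(seq, block):
            out = list(seq)
            for p in block:
                out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
            return "".join(out)

        side1 = mutate(anc, blocks["internal"])
        leaves = {}
        a, b = split_pair[0]
        c, d = split_pair[1]
        leaves[a] = mutate(anc, blocks["w"])
        leaves[b] = mutate(anc, blocks["x"])
        leaves[c] = mutate(side1, blocks["y"])
        leaves[d] = mutate(side1, blocks["z"])
        return [io.SequenceRecord(id=k, seq=leaves[k]) for k in sorted(leaves)]

    @pytest.mark.parametrize("pairing", [
        (("A", "B"), ("C", "D")),
        (("A", "C"), ("B", "D")),
        (("A", "D"), ("B", "C")),
    ])
    def test_nj_recovers_additive_quartet_topology(self, pairing):
        """NJ on an additive 4-taxon matrix recovers the generating
        topology, cross-checked against four-point-condition enumeration."""
        seed = sum(ord(c) for pair in pairing for name in pair for c in name)
        rng = np.random.default_rng(seed)
        frags = self._additive_quartet(rng, pairing)
        ids = [f.id for f in frags]
        d = np.zeros((4, 4))
        for i in range(4):
            for j in range(i + 1, 4):
                d[i, j] = d[j, i] = compare.p_distance(frags[i].seq, frags[j].seq)
        expected = four_point_split(d)
        idx = {name: i for i, name in enumerate(ids)}
        assert frozenset([frozenset(idx[n] for n in pairing[0]),
                          frozenset(idx[n] for n in pairing[1])]) == expected
        nwk = compare.build_phylo_tree(frags)
        from skbio import TreeNode
        from io import StringIO
        tree = TreeNode.read(StringIO(nwk))
        # the quartet split is the set of leaf pairs separated by the
        # internal edge: find the cherry
        pair0 = set(pairing[0])
        tips_by_parent = {}
        for tip in tree.tips():
            tips_by_parent.setdefault(id(tip.parent), set()).add(tip.name)
        cherries = [v for v in tips_by_parent.values() if len(v) == 2]
        assert any(ch in (set(pairing[0]), set(pairing[1])) for ch in cherries)

    def test_nj_invariant_to_input_order(self):
        rng = np.random.default_rng(17)
        frags = self._additive_quartet(rng, (("A", "B"), ("C", "D")))
        nwk1 = compare.build_phylo_tree(frags)
        nwk2 = compare.build_phylo_tree(list(reversed(frags)))
        from skbio import TreeNode
        from io import StringIO
        t1 = TreeNode.read(StringIO(nwk1))
        t2 = TreeNode.read(StringIO(nwk2))
        assert t1.compare_rfd(t2) == 0.0
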