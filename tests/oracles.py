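"""Independent brute-force oracles used by the unit and acceptance tests.

Each oracle re-derives the expected result of a pipeline operation by
exhaustive enumeration or direct definition, sharing no code with the
implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np
from Bio import Align


# ---------------------------------------------------------------------------
# profile HMM: exhaustive path enumeration
# ---------------------------------------------------------------------------

_BASE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def enumerate_viterbi(hmm, seq: str) -> float:
    """Best score over every legal local alignment path, by enumeration.

    The path grammar: enter any match state at any residue, move via
    M->{M,I,D}, I->{M,I}, D->{M,D}, exit from any match state.  Emissions
    score log2(p/background) (N scores 0); transitions score log2(prob).
    """
    L = hmm.L
    n = len(seq)
    enc = [_BASE.get(c, 4) for c in seq.upper()]

    def emis(table, j, x):
        if x == 4:
            return 0.0
        return math.log2(table[j][x] / hmm.background[x])

    def trans(name, j):
        return math.log2(getattr(hmm, name)[j])

    best = [-math.inf]

    def extend(state: str, i: int, j: int, score: float) -> None:
        # i = index of next unconsumed residue; j = current node
        if state == "M":
            best[0] = max(best[0], score)  # free exit from M
        if state == "M":
            if j < L and i < n:
                extend("M", i + 1, j + 1,
                       score + trans("t_mm", j) + emis(hmm.match_emis, j + 1, enc[i]))
            if i < n:
                extend("I", i + 1, j,
                       score + trans("t_mi", j) + emis(hmm.insert_emis, j, enc[i]))
            if j < L:
                extend("D", i, j + 1, score + trans("t_md", j))
        elif state == "I":
            if j < L and i < n:
                extend("M", i + 1, j + 1,
                       score + trans("t_im", j) + emis(hmm.match_emis, j + 1, enc[i]))
            if i < n:
                extend("I", i + 1, j,
                       score + trans("t_ii", j) + emis(hmm.insert_emis, j, enc[i]))
        else:  # D
            if j < L and i < n:
                extend("M", i + 1, j + 1,
                       score + trans("t_dm", j) + emis(hmm.match_emis, j + 1, enc[i]))
            if j < L:
                extend("D", i, j + 1, score + trans("t_dd", j))

    for i0 in range(n):
        for j0 in range(1, L + 1):
            extend("M", i0 + 1, j0, emis(hmm.match_emis, j0, enc[i0]))
    return best[0]


# ---------------------------------------------------------------------------
# mapper: exhaustive Smith-Waterman over all references
# ---------------------------------------------------------------------------

def _aligner():
    a = Align.PairwiseAligner(mode="local")
    a.match_score = 1
    a.mismatch_score = -1
    a.open_gap_score = -2
    a.extend_gap_score = -1
    return a


def sw_best_hit(query: str, refs: dict[str, str], revcomp) -> tuple[str, float] | None:
    """(ref_id, score) of the best local alignment over both query strands,
    ties broken toward the smallest ref id."""
    a = _aligner()
    best = None
    for ref_id in sorted(refs):
        score = max(a.score(refs[ref_id], query),
                    a.score(refs[ref_id], revcomp(query)))
        if score > 0 and (best is None or score > best[1]):
            best = (ref_id, score)
    return best


# ---------------------------------------------------------------------------
# ontology: brute-force transitive closure
# ---------------------------------------------------------------------------

def closure_bruteforce(edges: set[tuple[str, str, str]], term: str) -> set[str]:
    """Reflexive ancestor set by iterating edge expansion to fixpoint."""
    parents: dict[str, set[str]] = {}
    for child, parent, _ in edges:
        parents.setdefault(child, set()).add(parent)
    out = {term}
    changed = True
    while changed:
        changed = False
        for t in list(out):
            for p in parents.get(t, ()):
                if p not in out:
                    out.add(p)
                    changed = True
    return out


# ---------------------------------------------------------------------------
# neighbor joining: four-point condition on additive 4-taxon matrices
# ---------------------------------------------------------------------------

def four_point_split(d: np.ndarray) -> frozenset:
    """The topology {0,1}|{2,3}, {0,2}|{1,3} or {0,3}|{1,2} minimizing the
    sum of within-pair distances (the additive-tree split)."""
    options = {
        frozenset([frozenset([0, 1]), frozenset([2, 3])]): d[0, 1] + d[2, 3],
        frozenset([frozenset([0, 2]), frozenset([1, 3])]): d[0, 2] + d[1, 3],
        frozenset([frozenset([0, 3]), frozenset([1, 2])]): d[0, 3] + d[1, 2],
    }
    return min(options, key=options.get)
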