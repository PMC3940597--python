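"""Profile HMM construction and scanning for rRNA fragment extraction.

A profile hidden Markov model (match/insert/delete architecture) is built
from a multiple alignment of reference rRNA sequences.  Reads are scanned
with a local Viterbi dynamic program on both strands, and the higher-
scoring strand is reported when it clears the calling threshold.  All
scanning is done in memory on the forward and reverse-complement
orientations of each read; no temporary files are involved.

Scoring model
-------------
Emissions are log-odds in bits against the alignment's background base
composition; ``N`` emits at background (contribution 0).  Transitions
contribute ``log2`` of their probability.  Alignments are local on both
the sequence and the model: a path may enter any match state for free,
must follow the match/insert/delete grammar (M->{M,I,D}, I->{M,I},
D->{M,D}) between nodes, and may exit from any match state for free.
Unaligned flanking read bases are free.  The score of a path is the sum
of its emission log-odds plus its internal transition log-probabilities,
and the Viterbi score is the maximum over all such paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from numba import njit

from .io_formats import SequenceRecord
from .simulator import revcomp

__all__ = [
    "ProfileHMM",
    "RrnaHit",
    "ViterbiResult",
    "build_profile",
    "viterbi_score",
    "extract_fragments",
    "save_hmm",
    "load_hmm",
    "DEFAULT_THRESHOLD_BITS_PER_STATE",
]

#: Default calling threshold, expressed in bits per match state of the model.
DEFAULT_THRESHOLD_BITS_PER_STATE = 0.25

_GAP_CHARS = frozenset("-.")
_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


class ModelError(ValueError):
    """The alignment cannot produce a valid profile model."""


@dataclass
class ProfileHMM:
    """Match/insert/delete profile model with log-odds emissions.

    ``match_emis``/``insert_emis`` hold emission *probabilities* (rows sum
    to one); the log-odds arrays used for scoring are derived against
    ``background``.  Transition probability arrays are indexed by source
    node: ``t_mm[k]`` is P(M_k -> M_{k+1}) etc.; node 0 is the begin node.
    """

    L: int
    match_emis: np.ndarray      # (L+1, 4), row 0 unused
    insert_emis: np.ndarray     # (L+1, 4)
    background: np.ndarray      # (4,)
    t_mm: np.ndarray
    t_mi: np.ndarray
    t_md: np.ndarray
    t_im: np.ndarray
    t_ii: np.ndarray
    t_dm: np.ndarray
    t_dd: np.ndarray

    def __post_init__(self) -> None:
        if self.L < 1:
            raise ModelError("profile must have at least one match state")
        for k in range(1, self.L + 1):
            if abs(self.match_emis[k].sum() - 1.0) > 1e-9:
                raise ModelError(f"match emissions at state {k} do not sum to 1")
        for k in range(self.L + 1):
            if abs(self.insert_emis[k].sum() - 1.0) > 1e-9:
                raise ModelError(f"insert emissions at node {k} do not sum to 1")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ModelError("background frequencies do not sum to 1")
        # outgoing transition distributions must each sum to one
        for k in range(self.L + 1):
            m_out = self.t_mm[k] + self.t_mi[k] + self.t_md[k]
            i_out = self.t_im[k] + self.t_ii[k]
            d_out = self.t_dm[k] + self.t_dd[k]
            for name, total in (("M", m_out), ("I", i_out), ("D", d_out)):
                if abs(total - 1.0) > 1e-9:
                    raise ModelError(
                        f"{name} transitions at node {k} sum to {total}, expected 1"
                    )

    # ----- derived scoring arrays -----------------------------------------

    def _log_odds(self) -> tuple[np.ndarray, np.ndarray]:
        """Emission log-odds (bits) with a 5th column for N (zero)."""
        m = np.zeros((self.L + 1, 5))
        i = np.zeros((self.L + 1, 5))
        m[:, :4] = np.log2(self.match_emis / self.background[None, :])
        i[:, :4] = np.log2(self.insert_emis / self.background[None, :])
        m[0, :] = 0.0
        return m, i

    def _log_trans(self) -> tuple[np.ndarray, ...]:
        def lg(a: np.ndarray) -> np.ndarray:
            with np.errstate(divide="ignore"):
                return np.log2(a)
        return tuple(lg(a) for a in (self.t_mm, self.t_mi, self.t_md,
                                     self.t_im, self.t_ii,
                                     self.t_dm, self.t_dd))

    def default_threshold(self) -> float:
        return DEFAULT_THRESHOLD_BITS_PER_STATE * self.L


@dataclass(frozen=True)
class ViterbiResult:
    """Best local alignment of a sequence to the model."""

    score: float                       # bits; -inf when no alignment exists
    path: tuple[tuple[str, int], ...]  # (state, node) pairs, e.g. ("M", 3)
    interval: tuple[int, int]          # emitted residues, 0-based half-open

    @property
    def is_hit(self) -> bool:
        return math.isfinite(self.score)


@dataclass(frozen=True)
class RrnaHit:
    """A called rRNA fragment on one read."""

    read_id: str
    strand: str                 # '+' or '-'
    start: int                  # interval on the original read, half-open
    end: int
    score: float                # bits
    fragment: str               # re-oriented to the model (+) strand


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def build_profile(alignment: Sequence[SequenceRecord],
                  match_frac: float = 0.5) -> ProfileHMM:
    """Build a profile HMM from an aligned set of sequences.

    Columns whose gap fraction is below *match_frac* become match states.
    Emissions and transitions get Laplace (+1) pseudocounts; the background
    is the overall base composition of the alignment.
    """
    if not alignment:
        raise ModelError("empty alignment")
    if not 0 < match_frac <= 1:
        raise ModelError("match_frac must lie in (0, 1]")
    ncol = len(alignment[0].seq)
    if any(len(rec.seq) != ncol for rec in alignment):
        raise ModelError("aligned sequences must all have equal length")
    n_seq = len(alignment)

    is_match = []
    for c in range(ncol):
        gaps = sum(1 for rec in alignment if rec.seq[c] in _GAP_CHARS)
        is_match.append(gaps / n_seq < match_frac)
    L = sum(is_match)
    if L == 0:
        raise ModelError("alignment has no match columns (all-gap or too gappy)")

    # background from all residues, +1 pseudocount
    bg_counts = np.ones(4)
    for rec in alignment:
        for ch in rec.seq.upper():
            idx = _BASE_IDX.get(ch)
            if idx is not None and idx < 4:
                bg_counts[idx] += 1
    background = bg_counts / bg_counts.sum()

    match_counts = np.ones((L + 1, 4))
    insert_counts = np.ones((L + 1, 4))
    # transition counts, Laplace +1 over each state's allowed outgoing set
    t = {name: np.ones(L + 1) for name in
         ("mm", "mi", "md", "im", "ii", "dm", "dd")}

    for rec in alignment:
        # path through the model: begin node 0, then M/D at match columns,
        # I at insert columns
        prev_state, prev_node = "M", 0  # begin acts as M_0
        for c, ch in enumerate(rec.seq.upper()):
            gap = ch in _GAP_CHARS
            if is_match[c]:
                node = sum(is_match[:c + 1])
                state = "D" if gap else "M"
                if not gap:
                    idx = _BASE_IDX.get(ch)
                    if idx is not None and idx < 4:
                        match_counts[node, idx] += 1
                t[f"{prev_state.lower()}{state.lower()}"][prev_node] += 1
                prev_state, prev_node = state, node
            elif not gap:
                node = sum(is_match[:c + 1])
                idx = _BASE_IDX.get(ch)
                if idx is not None and idx < 4:
                    insert_counts[node, idx] += 1
                if prev_state != "I":
                    t[f"{prev_state.lower()}i"][prev_node] += 1
                else:
                    t["ii"][prev_node] += 1
                prev_state, prev_node = "I", node
        # closing M_L -> end transition is implicit in normalization below

    match_emis = match_counts / match_counts.sum(axis=1, keepdims=True)
    insert_emis = insert_counts / insert_counts.sum(axis=1, keepdims=True)

    m_tot = t["mm"] + t["mi"] + t["md"]
    i_tot = t["im"] + t["ii"]
    d_tot = t["dm"] + t["dd"]
    return ProfileHMM(
        L=L,
        match_emis=match_emis,
        insert_emis=insert_emis,
        background=background,
        t_mm=t["mm"] / m_tot, t_mi=t["mi"] / m_tot, t_md=t["md"] / m_tot,
        t_im=t["im"] / i_tot, t_ii=t["ii"] / i_tot,
        t_dm=t["dm"] / d_tot, t_dd=t["dd"] / d_tot,
    )


# ---------------------------------------------------------------------------
# Viterbi scan
# ---------------------------------------------------------------------------

_NEG = -1e30


@njit(cache=False)
def _viterbi_dp(enc, m_lo, i_lo, lt_mm, lt_mi, lt_md, lt_im, lt_ii, lt_dm, lt_dd):
    """Local Viterbi over the M/I/D grammar; returns score, end cell and
    traceback pointers (0 entry, 1 from M, 2 from I, 3 from D)."""
    n = enc.shape[0]
    L = m_lo.shape[0] - 1
    vm = np.full((n + 1, L + 1), _NEG)
    vi = np.full((n + 1, L + 1), _NEG)
    vd = np.full((n + 1, L + 1), _NEG)
    pm = np.zeros((n + 1, L + 1), dtype=np.int8)
    pi = np.zeros((n + 1, L + 1), dtype=np.int8)
    pd = np.zeros((n + 1, L + 1), dtype=np.int8)
    best = _NEG
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        x = enc[i - 1]
        for j in range(1, L + 1):
            # match: free local entry (score 0) or continue from node j-1
            sc = 0.0
            ptr = 0
            if vm[i - 1, j - 1] + lt_mm[j - 1] > sc:
                sc = vm[i - 1, j - 1] + lt_mm[j - 1]
                ptr = 1
            if vi[i - 1, j - 1] + lt_im[j - 1] > sc:
                sc = vi[i - 1, j - 1] + lt_im[j - 1]
                ptr = 2
            if vd[i - 1, j - 1] + lt_dm[j - 1] > sc:
                sc = vd[i - 1, j - 1] + lt_dm[j - 1]
                ptr = 3
            vm[i, j] = sc + m_lo[j, x]
            pm[i, j] = ptr
            if vm[i, j] > best:
                best = vm[i, j]
                bi = i
                bj = j
            # insert at node j (between match j and j+1)
            si = vm[i - 1, j] + lt_mi[j]
            pti = 1
            if vi[i - 1, j] + lt_ii[j] > si:
                si = vi[i - 1, j] + lt_ii[j]
                pti = 2
            vi[i, j] = si + i_lo[j, x]
            pi[i, j] = pti
            # delete at node j (no emission)
            sd = vm[i, j - 1] + lt_md[j - 1]
            ptd = 1
            if vd[i, j - 1] + lt_dd[j - 1] > sd:
                sd = vd[i, j - 1] + lt_dd[j - 1]
                ptd = 3
            vd[i, j] = sd
            pd[i, j] = ptd
    return best, bi, bj, pm, pi, pd


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_IDX.get(ch, 4) for ch in seq.upper()], dtype=np.int64)


def viterbi_score(hmm: ProfileHMM, seq: str) -> ViterbiResult:
    """Best local alignment (score in bits, path, emitted interval).

    An empty sequence yields a no-hit result rather than an exception.
    """
    if not seq:
        return ViterbiResult(score=-math.inf, path=(), interval=(0, 0))
    enc = _encode(seq)
    m_lo, i_lo = hmm._log_odds()
    lt = hmm._log_trans()
    best, bi, bj, pm, pi, pd = _viterbi_dp(enc, m_lo, i_lo, *lt)
    if best <= _NEG / 2:
        return ViterbiResult(score=-math.inf, path=(), interval=(0, 0))
    # traceback from the best-scoring match cell
    path: list[tuple[str, int]] = []
    state, i, j = "M", bi, bj
    end_i = bi
    start_i = bi
    while True:
        path.append((state, j))
        if state == "M":
            start_i = i
            ptr = pm[i, j]
            i, j = i - 1, j - 1
        elif state == "I":
            start_i = i
            ptr = pi[i, j]
            i = i - 1
        else:  # D
            ptr = pd[i, j]
            j = j - 1
        if state == "M" and ptr == 0:
            break
        state = {1: "M", 2: "I", 3: "D"}[int(ptr)]
    path.reverse()
    return ViterbiResult(score=float(best), path=tuple(path),
                         interval=(start_i - 1, end_i))


def extract_fragments(reads: Iterable[SequenceRecord], hmm: ProfileHMM,
                      threshold_bits: float | None = None) -> list[RrnaHit]:
    """Scan reads on both strands and call rRNA fragments.

    Each read is scored on its forward sequence and on its reverse
    complement; the higher-scoring strand (ties toward '+') is kept when
    the score reaches *threshold_bits* (default: 0.25 bits per match
    state).  Hit intervals are reported in original read coordinates and
    the fragment sequence is re-oriented to the model strand.
    """
    if threshold_bits is None:
        threshold_bits = hmm.default_threshold()
    if not math.isfinite(threshold_bits):
        raise ValueError("threshold_bits must be finite")
    hits: list[RrnaHit] = []
    for rec in reads:
        fwd = viterbi_score(hmm, rec.seq)
        rc_seq = revcomp(rec.seq)
        rev = viterbi_score(hmm, rc_seq)
        if rev.score > fwd.score:
            res, strand, scanned = rev, "-", rc_seq
        else:
            res, strand, scanned = fwd, "+", rec.seq
        if not res.is_hit or res.score < threshold_bits:
            continue
        qs, qe = res.interval
        if strand == "+":
            start, end = qs, qe
        else:
            start, end = len(rec.seq) - qe, len(rec.seq) - qs
        hits.append(RrnaHit(read_id=rec.id, strand=strand, start=start, end=end,
                            score=res.score, fragment=scanned[qs:qe]))
    return hits


# ---------------------------------------------------------------------------
# model serialization (versioned TSV)
# ---------------------------------------------------------------------------

_HMM_FORMAT_VERSION = "metaprof-hmm/1"


def save_hmm(hmm: ProfileHMM, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"#format\t{_HMM_FORMAT_VERSION}\n")
        fh.write(f"L\t{hmm.L}\n")
        fh.write("background\t" + "\t".join(f"{v:.12g}" for v in hmm.background) + "\n")
        for name, arr in (("match_emis", hmm.match_emis), ("insert_emis", hmm.insert_emis)):
            for k in range(arr.shape[0]):
                fh.write(f"{name}\t{k}\t" + "\t".join(f"{v:.12g}" for v in arr[k]) + "\n")
        for name in ("t_mm", "t_mi", "t_md", "t_im", "t_ii", "t_dm", "t_dd"):
            arr = getattr(hmm, name)
            fh.write(f"{name}\t" + "\t".join(f"{v:.12g}" for v in arr) + "\n")


def load_hmm(path: str | Path) -> ProfileHMM:
    path = Path(path)
    lines = path.read_text(encoding="utf-8").splitlines()
    if not lines or not lines[0].startswith(f"#format\t{_HMM_FORMAT_VERSION}"):
        raise ModelError(f"{path}: not a {_HMM_FORMAT_VERSION} file")
    L = None
    background = None
    fields: dict[str, dict[int, list[float]]] = {"match_emis": {}, "insert_emis": {}}
    trans: dict[str, list[float]] = {}
    for line in lines[1:]:
        parts = line.split("\t")
        key = parts[0]
        if key == "L":
            L = int(parts[1])
        elif key == "background":
            background = np.array([float(v) for v in parts[1:]])
        elif key in fields:
            fields[key][int(parts[1])] = [float(v) for v in parts[2:]]
        elif key.startswith("t_"):
            trans[key] = [float(v) for v in parts[1:]]
    if L is None or background is None:
        raise ModelError(f"{path}: missing L or background")
    match_emis = np.array([fields["match_emis"][k] for k in range(L + 1)])
    insert_emis = np.array([fields["insert_emis"][k] for k in range(L + 1)])
    return ProfileHMM(L=L, match_emis=match_emis, insert_emis=insert_emis,
                      background=background,
                      **{k: np.array(v) for k, v in trans.items()})
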