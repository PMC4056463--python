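"""Local transition alignment across multiple genomic loci.

A Smith-Waterman-like dynamic program over a three-dimensional matrix
M[i, k, j] (read position i, locus k, locus position j).  In addition to
the usual local-alignment recursions, every cell may start a new
fragment in locus k by carrying over the best score reached in any
preceding locus k' < k up to read position i-1 (the ``lms`` table of
running row maxima), minus a transition penalty tau.  The traceback of
the globally maximal cell yields an ordered multi-fragment split
alignment of the read; a single window reduces exactly to
Smith-Waterman.

The transition move consumes the first aligned pair of the new fragment,
i.e. M[i,k,j] may take lms[k', i-1] - tau + s(r_i, w_j): the incoming
read base is scored against the new locus so that an error-free split
read of length m scores m * match - tau per transition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import edlib
import numpy as np
from numba import njit

from .chaining import Chain, Locus, merge_collinear
from .genome import ReferenceGenome, revcomp


@dataclass
class AlignParams:
    """Scoring parameters of the transition alignment.

    match / mismatch: s(a, b) for equal / unequal bases (N never
    matches).  gap: indel penalty delta (> 0, subtracted).  transition:
    penalty tau applied to each locus transition.  boundary_extension:
    nucleotides added on both sides of each seed-defined locus window.
    min_fragment_length: fragments covering fewer read bases are dropped
    from the traceback with score recomputation.
    """

    match: int = 1
    mismatch: int = -1
    gap: int = 1
    transition: int = 3
    boundary_extension: int = 10
    min_fragment_length: int = 15

    def __post_init__(self) -> None:
        if self.gap <= 0:
            raise ValueError("gap penalty delta must be > 0")
        if self.transition < 0:
            raise ValueError("transition penalty tau must be >= 0")
        if self.boundary_extension < 0:
            raise ValueError("boundary_extension must be >= 0")


@dataclass
class Window:
    """One locus window handed to the transition alignment."""

    seq: str
    chrom: str
    ref_start: int
    ref_end: int
    strand: str


@dataclass
class Fragment:
    """One local alignment piece of a split read."""

    read_start: int  # 0-based, inclusive
    read_end: int  # 0-based, exclusive
    chrom: str
    ref_start: int
    ref_end: int
    strand: str
    ops: str  # per-column edit string over =, X, I (read ins), D (read del)
    score: int


@dataclass
class SplitAlignment:
    read_id: str
    fragments: List[Fragment]
    score: int
    transitions: int
    unique: bool = True

    @property
    def is_split(self) -> bool:
        return len(self.fragments) > 1


_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}


def _encode(s: str) -> np.ndarray:
    return np.asarray([_CODE.get(c, 4) for c in s], dtype=np.int8)


@njit(cache=True)
def _fill(M, r, w, best_prev, match, mismatch, delta, tau, allow_trans,
          lms, lms_i, lms_j):
    m = r.shape[0]
    n = w.shape[0]
    run_max = 0
    ri = 0
    rj = 0
    for i in range(1, m + 1):
        a = r[i - 1]
        tbase = best_prev[i - 1] - tau
        for j in range(1, n + 1):
            b = w[j - 1]
            s = match if (a == b and a < 4) else mismatch
            v = M[i - 1, j - 1] + s
            if allow_trans and tbase + s > v:
                v = tbase + s
            u = M[i - 1, j] - delta
            if u > v:
                v = u
            u = M[i, j - 1] - delta
            if u > v:
                v = u
            if v < 0:
                v = 0
            M[i, j] = v
            if v > run_max:
                run_max = v
                ri = i
                rj = j
        lms[i] = run_max
        lms_i[i] = ri
        lms_j[i] = rj


def semi_global_align(read: str, window: str) -> Tuple[int, int, str]:
    """Best edit distance of ``read`` against any substring of ``window``.

    Returns ``(distance, end, ops)`` where ``end`` is the 0-based
    inclusive end position of the leftmost-ending optimal alignment in
    ``window`` and ``ops`` the per-column edit string (=, X, I, D).
    """
    if not read or not window:
        raise ValueError("read and window must be non-empty")
    res = edlib.align(read, window, mode="HW", task="locations")
    end = min(loc[1] for loc in res["locations"])
    res = edlib.align(read, window[: end + 1], mode="HW", task="path")
    ops = _expand_cigar(res["cigar"])
    return res["editDistance"], end, ops


def _expand_cigar(cigar: str) -> str:
    out = []
    num = ""
    for c in cigar:
        if c.isdigit():
            num += c
        else:
            out.append(c * int(num))
            num = ""
    return "".join(out)


def extract_windows(
    loci: Sequence[Locus], genome: ReferenceGenome, params: AlignParams
) -> List[Window]:
    """One window per (merged) chain locus, in chain order.

    The seed-defined reference interval is widened by
    ``boundary_extension`` on both sides (clipped to the chromosome);
    minus-strand windows hold the reverse complement of the forward
    slice, so the read aligns against them directly.  Because errors
    near a splice boundary can push the seed away from it, each window
    is additionally widened by the unseeded read gap towards its
    neighbouring loci, so every read base has at least one window it
    can align in.
    """
    windows = []
    for idx, loc in enumerate(loci):
        gap_before = (
            loc.read_start - loci[idx - 1].read_end - 1 if idx > 0
            else loc.read_start
        )
        gap_after = (
            loci[idx + 1].read_start - loc.read_end - 1 if idx + 1 < len(loci)
            else 0
        )
        before = params.boundary_extension + max(0, gap_before)
        after = params.boundary_extension + max(0, gap_after)
        n = len(genome[loc.chrom])
        if loc.strand == "+":
            a = max(0, loc.ref_start - before)
            b = min(n, loc.ref_end + after)
        else:  # read direction runs right-to-left on the genome
            a = max(0, loc.ref_start - after)
            b = min(n, loc.ref_end + before)
        seq = genome.slice(loc.chrom, a, b)
        if loc.strand == "-":
            seq = revcomp(seq)
        windows.append(Window(seq=seq, chrom=loc.chrom, ref_start=a, ref_end=b,
                              strand=loc.strand))
    return windows


def _window_to_genome(win: Window, ws: int, we: int) -> Tuple[int, int]:
    """Map a half-open window interval to forward genome coordinates."""
    if win.strand == "+":
        return win.ref_start + ws, win.ref_start + we
    return win.ref_end - we, win.ref_end - ws


@dataclass
class _DPState:
    """Filled matrices, exposed for verification in tests."""

    M: List[np.ndarray]
    lms: np.ndarray
    lms_i: np.ndarray
    lms_j: np.ndarray


def _fill_all(read_codes: np.ndarray, win_codes: List[np.ndarray],
              params: AlignParams) -> _DPState:
    m = read_codes.shape[0]
    K = len(win_codes)
    Ms: List[np.ndarray] = []
    lms = np.zeros((K, m + 1), dtype=np.int32)
    lms_i = np.zeros((K, m + 1), dtype=np.int32)
    lms_j = np.zeros((K, m + 1), dtype=np.int32)
    best_prev = np.zeros(m + 1, dtype=np.int32)
    for k, w in enumerate(win_codes):
        M = np.zeros((m + 1, w.shape[0] + 1), dtype=np.int32)
        if k > 0:
            best_prev = np.max(lms[:k], axis=0).astype(np.int32)
        _fill(M, read_codes, w, best_prev,
              np.int32(params.match), np.int32(params.mismatch),
              np.int32(params.gap), np.int32(params.transition),
              k > 0, lms[k], lms_i[k], lms_j[k])
        Ms.append(M)
    return _DPState(M=Ms, lms=lms, lms_i=lms_i, lms_j=lms_j)


def _traceback(
    state: _DPState,
    read_codes: np.ndarray,
    win_codes: List[np.ndarray],
    windows: Sequence[Window],
    params: AlignParams,
) -> List[Tuple[int, int, int, int, int, str]]:
    """Trace the maximal cell back to fragments.

    Returns fragments as ``(k, qs, qe, ws, we, ops)`` in read order with
    half-open read/window intervals.  Tie preference at each cell:
    continue diagonally, end the alignment, gaps, then transition
    (fewer transitions win ties).
    """
    m = read_codes.shape[0]
    K = len(win_codes)
    # global maximum: highest score; ties -> smallest k, then the
    # first-encountered (topmost/leftmost) cell recorded by the kernel
    best_k = 0
    for k in range(1, K):
        if state.lms[k, m] > state.lms[best_k, m]:
            best_k = k
    if state.lms[best_k, m] <= 0:
        return []
    k = best_k
    i = int(state.lms_i[k, m])
    j = int(state.lms_j[k, m])
    match, mismatch, delta, tau = (
        params.match, params.mismatch, params.gap, params.transition,
    )
    frags_rev: List[Tuple[int, int, int, int, int, str]] = []
    ops_rev: List[str] = []
    qe, we = i, j
    while True:
        M = state.M[k]
        v = int(M[i, j])
        a, b = read_codes[i - 1], win_codes[k][j - 1]
        s = match if (a == b and a < 4) else mismatch
        op = "=" if (a == b and a < 4) else "X"
        diag = int(M[i - 1, j - 1])
        if diag > 0 and v == diag + s:
            ops_rev.append(op)
            i -= 1
            j -= 1
            continue
        if v == s:  # fresh local start: alignment begins here
            ops_rev.append(op)
            i -= 1
            j -= 1
            frags_rev.append((k, i, qe, j, we, "".join(reversed(ops_rev))))
            break
        if v == int(M[i - 1, j]) - delta:
            ops_rev.append("I")
            i -= 1
            continue
        if v == int(M[i, j - 1]) - delta:
            ops_rev.append("D")
            j -= 1
            continue
        # transition from the best preceding locus
        took = False
        if k > 0:
            bp = int(np.max(state.lms[:k, i - 1]))
            if v == bp - tau + s:
                ops_rev.append(op)
                frags_rev.append(
                    (k, i - 1, qe, j - 1, we, "".join(reversed(ops_rev)))
                )
                kprev = int(np.argmax(state.lms[:k, i - 1]))
                ii = int(state.lms_i[kprev, i - 1])
                jj = int(state.lms_j[kprev, i - 1])
                k, i, j = kprev, ii, jj
                qe, we = i, j
                ops_rev = []
                took = True
        if took:
            continue
        raise AssertionError("traceback failed: inconsistent DP matrix")
    return list(reversed(frags_rev))


def _ops_score(ops: str, params: AlignParams) -> int:
    return (
        ops.count("=") * params.match
        + ops.count("X") * params.mismatch
        - (ops.count("I") + ops.count("D")) * params.gap
    )


def transition_align(
    read: str,
    windows: Sequence[Window],
    params: AlignParams,
    read_id: str = "read",
    _return_state: bool = False,
) -> Optional[SplitAlignment]:
    """Optimal local split alignment of ``read`` across ``windows``.

    Windows must be given in chain (read) order; transitions are only
    permitted forward in that order.  Returns ``None`` when no local
    alignment scores above zero.  Fragments shorter than
    ``min_fragment_length`` read bases are dropped and the total score
    recomputed.
    """
    if not windows:
        raise ValueError("at least one window is required")
    read = read.upper()
    read_codes = _encode(read)
    win_codes = [_encode(w.seq) for w in windows]
    state = _fill_all(read_codes, win_codes, params)
    raw = _traceback(state, read_codes, win_codes, windows, params)
    fragments: List[Fragment] = []
    for (k, qs, qe, ws, we, ops) in raw:
        win = windows[k]
        gs, ge = _window_to_genome(win, ws, we)
        fragments.append(
            Fragment(
                read_start=qs,
                read_end=qe,
                chrom=win.chrom,
                ref_start=gs,
                ref_end=ge,
                strand=win.strand,
                ops=ops,
                score=_ops_score(ops, params),
            )
        )
    fragments = [
        f for f in fragments if f.read_end - f.read_start >= params.min_fragment_length
    ]
    if not fragments:
        return None
    transitions = len(fragments) - 1
    total = sum(f.score for f in fragments) - params.transition * transitions
    aln = SplitAlignment(
        read_id=read_id,
        fragments=fragments,
        score=total,
        transitions=transitions,
    )
    if _return_state:
        return aln, state  # type: ignore[return-value]
    return aln
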