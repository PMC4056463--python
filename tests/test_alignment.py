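"""Semi-global alignment and the local transition alignment DP,
checked against brute-force oracles."""

import itertools

import numpy as np
import pytest
from numba import njit

from splitmap.alignment import (
    AlignParams,
    Window,
    _encode,
    extract_windows,
    semi_global_align,
    transition_align,
)
from splitmap.chaining import Chain, Locus
from splitmap.genome import ReferenceGenome, revcomp

from conftest import random_sequence


# ----------------------------------------------------------------------
# independent oracles


def edit_distance_infix_oracle(read: str, window: str) -> int:
    """Quadratic DP: min edit distance of read vs any window substring."""
    m, n = len(read), len(window)
    prev = [0] * (n + 1)  # free leading gaps in the window
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cost = 0 if read[i - 1] == window[j - 1] else 1
            cur[j] = min(prev[j - 1] + cost, prev[j] + 1, cur[j - 1] + 1)
        prev = cur
    return min(prev)


@njit(cache=True)
def _sw(read, window, match, mismatch, delta):
    best = 0
    m, n = read.shape[0], window.shape[0]
    M = np.zeros((m + 1, n + 1), dtype=np.int32)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            s = match if (read[i - 1] == window[j - 1] and read[i - 1] < 4) else mismatch
            v = M[i - 1, j - 1] + s
            if M[i - 1, j] - delta > v:
                v = M[i - 1, j] - delta
            if M[i, j - 1] - delta > v:
                v = M[i, j - 1] - delta
            if v < 0:
                v = 0
            M[i, j] = v
            if v > best:
                best = v
    return best


def split_point_oracle(read: str, windows, params: AlignParams) -> int:
    """Enumerate every fragment-boundary placement and window
    subsequence; score fragments by textbook Smith-Waterman minus the
    transition penalty per boundary."""
    r = _encode(read)
    ws = [_encode(w.seq) for w in windows]
    m = len(read)
    K = len(ws)
    best = 0
    for f in range(1, min(3, K) + 1):
        for subset in itertools.combinations(range(K), f):
            for bounds in itertools.combinations(range(1, m), f - 1):
                cuts = (0,) + bounds + (m,)
                total = -params.transition * (f - 1)
                for seg in range(f):
                    piece = r[cuts[seg]:cuts[seg + 1]]
                    total += _sw(piece, ws[subset[seg]], params.match,
                                 params.mismatch, params.gap)
                best = max(best, total)
    return best


def _win(seq: str, chrom="chr1", start=0, strand="+") -> Window:
    return Window(seq=seq, chrom=chrom, ref_start=start,
                  ref_end=start + len(seq), strand=strand)


# ----------------------------------------------------------------------


class TestSemiGlobalAlign:
    def test_exact_containment(self):
        dist, end, ops = semi_global_align("ACGT", "TTACGTTT")
        assert (dist, end) == (0, 5)
        assert ops == "===="

    def test_single_substitution(self):
        dist, _, _ = semi_global_align("ACGT", "TTAGGTTT")
        assert dist == 1

    def test_matches_quadratic_dp_oracle(self, rng):
        for _ in range(200):
            read = random_sequence(rng, int(rng.integers(5, 40)))
            window = random_sequence(rng, int(rng.integers(10, 80)))
            dist, _, _ = semi_global_align(read, window)
            assert dist == edit_distance_infix_oracle(read, window)


class TestExtractWindows:
    def _chain_locus(self, rs, re, strand="+", qs=0, qe=49):
        return Locus(chrom="chr1", ref_start=rs, ref_end=re, strand=strand,
                     read_start=qs, read_end=qe)

    def test_extension_widens_both_sides(self, small_genome):
        loci = [self._chain_locus(100, 150)]
        w = extract_windows(loci, small_genome, AlignParams())[0]
        assert (w.ref_start, w.ref_end) == (90, 160)

    def test_left_clip_at_chromosome_start(self, small_genome):
        loci = [self._chain_locus(0, 50)]
        w = extract_windows(loci, small_genome, AlignParams())[0]
        assert (w.ref_start, w.ref_end) == (0, 60)

    def test_minus_strand_window_is_reverse_complement(self, small_genome):
        loci = [self._chain_locus(100, 150, strand="-")]
        w = extract_windows(loci, small_genome, AlignParams())[0]
        assert w.seq == revcomp(small_genome["chr1"][90:160])

    def test_unseeded_read_gap_is_covered(self, small_genome):
        loci = [
            self._chain_locus(1000, 1050, qs=0, qe=49),
            self._chain_locus(5000, 5040, qs=60, qe=99),
        ]
        ws = extract_windows(loci, small_genome, AlignParams())
        # second window must reach back far enough for read bases 50..59
        assert ws[1].ref_start <= 5000 - 10 - 10


class TestTransitionAlign:
    def test_single_window_reduces_to_smith_waterman(self, rng):
        params = AlignParams()
        for _ in range(50):
            read = random_sequence(rng, 40)
            window = random_sequence(rng, 30) + read + random_sequence(rng, 30)
            aln = transition_align(read, [_win(window)], params)
            assert len(aln.fragments) == 1
            assert aln.transitions == 0
            assert aln.score == _sw(_encode(read), _encode(window), 1, -1, 1)

    def test_perfect_containment_scores_full_matches(self):
        read = "ACGTACGTACGTACGTACGT"
        aln = transition_align(read, [_win("TT" + read + "GG")], AlignParams())
        assert aln.score == len(read)
        assert aln.fragments[0].ops == "=" * len(read)

    def test_two_locus_read_pays_one_transition(self, rng):
        params = AlignParams()
        a = random_sequence(rng, 50)
        b = random_sequence(rng, 50)
        aln = transition_align(
            a + b,
            [_win(a, start=1000), _win(b, start=9000)],
            params,
        )
        assert len(aln.fragments) == 2
        assert [f.read_start for f in aln.fragments] == [0, 50]
        assert [f.read_end for f in aln.fragments] == [50, 100]
        assert aln.score == 100 - params.transition

    def test_circular_windows_invert_genomic_order(self, rng):
        genome_seq = random_sequence(rng, 1000)
        tail, head = genome_seq[500:550], genome_seq[100:150]
        read = tail + head
        aln = transition_align(
            read,
            [_win(genome_seq[480:570], start=480),
             _win(genome_seq[80:170], start=80)],
            AlignParams(),
        )
        assert len(aln.fragments) == 2
        assert aln.fragments[0].ref_start > aln.fragments[1].ref_start

    def test_all_zero_matrix_returns_none(self):
        aln = transition_align("AAAA" * 10, [_win("CCCC" * 10)],
                               AlignParams(min_fragment_length=1))
        assert aln is None

    def test_matches_split_point_oracle(self, rng):
        """Total score equals brute-force boundary enumeration on <= 3
        windows with <= 2 injected errors."""
        params = AlignParams(transition=2, min_fragment_length=1)
        for _ in range(200):
            k = int(rng.integers(1, 4))
            segs = [random_sequence(rng, int(rng.integers(10, 18))) for _ in range(k)]
            read = list("".join(segs))
            for _ in range(int(rng.integers(0, 3))):  # inject <= 2 errors
                p = int(rng.integers(0, len(read)))
                read[p] = "ACGT"[int(rng.integers(0, 4))]
            read = "".join(read)
            windows = [
                _win(random_sequence(rng, 8) + s + random_sequence(rng, 8),
                     start=2000 * (i + 1))
                for i, s in enumerate(segs)
            ]
            aln = transition_align(read, windows, params)
            got = aln.score if aln else 0
            assert got == split_point_oracle(read, windows, params)

    def test_transition_count_monotone_in_tau(self, rng):
        a = random_sequence(rng, 30)
        b = random_sequence(rng, 30)
        read = a + b
        windows = [_win(a, start=100), _win(b, start=5000)]
        prev_transitions = None
        for tau in (0, 2, 20, 40):
            aln = transition_align(
                read, windows, AlignParams(transition=tau, min_fragment_length=1)
            )
            t = aln.transitions if aln else 0
            if prev_transitions is not None:
                assert t <= prev_transitions
            prev_transitions = t

    def test_score_at_least_best_single_window(self, rng):
        for _ in range(30):
            read = random_sequence(rng, 60)
            windows = [
                _win(random_sequence(rng, 40) + read[20:40], start=100 * i)
                for i in range(3)
            ]
            aln = transition_align(read, windows,
                                   AlignParams(min_fragment_length=1))
            best_single = max(
                _sw(_encode(read), _encode(w.seq), 1, -1, 1) for w in windows
            )
            assert (aln.score if aln else 0) >= best_single

    def test_lms_equals_prefix_maxima_of_matrix(self, rng):
        from splitmap.alignment import _fill_all

        read = random_sequence(rng, 25)
        wins = [random_sequence(rng, 30) for _ in range(3)]
        state = _fill_all(_encode(read), [_encode(w) for w in wins], AlignParams())
        for k, M in enumerate(state.M):
            running = 0
            for i in range(M.shape[0]):
                running = max(running, int(M[i].max()))
                assert state.lms[k, i] == running

    def test_reverse_complement_symmetry(self, rng):
        genome_seq = random_sequence(rng, 2000)
        a, b = genome_seq[100:150], genome_seq[900:950]
        read = a + b
        g = ReferenceGenome({"chr1": genome_seq})
        params = AlignParams()
        fwd_windows = [
            Window(seq=genome_seq[90:160], chrom="chr1", ref_start=90,
                   ref_end=160, strand="+"),
            Window(seq=genome_seq[890:960], chrom="chr1", ref_start=890,
                   ref_end=960, strand="+"),
        ]
        rev_windows = [
            Window(seq=revcomp(genome_seq[890:960]), chrom="chr1",
                   ref_start=890, ref_end=960, strand="-"),
            Window(seq=revcomp(genome_seq[90:160]), chrom="chr1",
                   ref_start=90, ref_end=160, strand="-"),
        ]
        fwd = transition_align(read, fwd_windows, params)
        rev = transition_align(revcomp(read), rev_windows, params)
        assert fwd.score == rev.score
        # the split point may slide within the breakpoint ambiguity
        # interval; the canonical junction must agree exactly
        from splitmap.junctions import extract_junctions, make_junction

        jf = extract_junctions(fwd)[0]
        jr = extract_junctions(rev)[0]
        assert make_junction(g, jf.donor, jf.acceptor).key == \
            make_junction(g, jr.donor, jr.acceptor).key
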