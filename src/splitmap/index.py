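"""Suffix-array index over the reference genome.

The index concatenates all chromosomes (separated by a sentinel that can
never match a nucleotide) and builds a plain suffix array by prefix
doubling with numpy.  Queries locate the longest exact prefix of a
pattern anywhere on the forward strand; reverse-strand hits are obtained
by the callers querying the reverse complement of the read and are
reported in forward coordinates with strand ``-``.
"""

from __future__ import annotations

from typing import List, Tuple

import numpy as np

from .genome import ReferenceGenome

INDEX_VERSION = 1

_SENTINEL = "\x01"


def _suffix_array(codes: np.ndarray) -> np.ndarray:
    """Suffix array of an integer sequence via prefix doubling."""
    n = codes.size
    if n == 0:
        return np.empty(0, dtype=np.int64)
    rank = codes.astype(np.int64)
    idx = np.arange(n, dtype=np.int64)
    k = 1
    while True:
        second = np.full(n, -1, dtype=np.int64)
        second[: n - k] = rank[k:]
        order = np.lexsort((second, rank))
        new_rank = np.empty(n, dtype=np.int64)
        pair_prev = (
            (rank[order[1:]] != rank[order[:-1]])
            | (second[order[1:]] != second[order[:-1]])
        )
        new_rank[order] = np.concatenate(([0], np.cumsum(pair_prev)))
        rank = new_rank
        if rank[order[-1]] == n - 1:
            return order
        k *= 2


class SuffixIndex:
    """Searchable suffix-array index of a :class:`ReferenceGenome`."""

    def __init__(self, genome: ReferenceGenome):
        self.genome = genome
        names: List[str] = []
        starts: List[int] = []
        parts: List[str] = []
        pos = 0
        for name, seq in genome.items():
            names.append(name)
            starts.append(pos)
            parts.append(seq)
            pos += len(seq) + 1  # sentinel
            parts.append(_SENTINEL)
        self.text: str = "".join(parts)
        self.names = names
        self.starts = np.asarray(starts, dtype=np.int64)
        self.chrom_lengths = np.asarray(
            [len(genome[n]) for n in names], dtype=np.int64
        )
        codes = np.frombuffer(self.text.encode("latin-1"), dtype=np.uint8)
        self.sa = _suffix_array(codes)

    # ------------------------------------------------------------------
    def _lower_bound(self, pattern: str) -> int:
        sa, text, plen = self.sa, self.text, len(pattern)
        lo, hi = 0, sa.size
        while lo < hi:
            mid = (lo + hi) // 2
            s = int(sa[mid])
            if text[s:s + plen] < pattern:
                lo = mid + 1
            else:
                hi = mid
        return lo

    def _lcp(self, s: int, pattern: str) -> int:
        """Length of the longest common prefix of text[s:] and pattern."""
        text = self.text
        n, plen = len(text), len(pattern)
        k = 0
        chunk = 64
        while k < plen:
            step = min(chunk, plen - k)
            if text[s + k:s + k + step] == pattern[k:k + step]:
                k += step
                continue
            while k < plen and s + k < n and text[s + k] == pattern[k]:
                k += 1
            break
        return min(k, n - s)

    def longest_match(
        self, pattern: str, max_occurrences: int | None = None
    ) -> Tuple[int, List[Tuple[str, int]]]:
        """Longest exact prefix of ``pattern`` occurring in the genome.

        Returns ``(match_length, occurrences)`` where occurrences are
        ``(chromosome, forward_start)`` pairs.  When the number of
        occurrences exceeds ``max_occurrences`` the list is returned
        empty (the caller treats the seed as a repeat and drops it) but
        the length is still reported.
        """
        if not pattern:
            return 0, []
        lo = self._lower_bound(pattern)
        best = 0
        for idx in (lo, lo - 1):
            if 0 <= idx < self.sa.size:
                best = max(best, self._lcp(int(self.sa[idx]), pattern))
        if best == 0:
            return 0, []
        prefix = pattern[:best]
        left = self._lower_bound(prefix)
        right = self._lower_bound(prefix + "\x7f")
        count = right - left
        if max_occurrences is not None and count > max_occurrences:
            return best, []
        occs = []
        for p in sorted(int(x) for x in self.sa[left:right]):
            ci = int(np.searchsorted(self.starts, p, side="right")) - 1
            occs.append((self.names[ci], p - int(self.starts[ci])))
        return best, occs

    def find(self, pattern: str) -> List[Tuple[str, int, str]]:
        """All exact occurrences of ``pattern`` on both strands.

        Reverse-strand hits carry forward coordinates of the matching
        genomic interval start and strand ``-``.
        """
        from .genome import revcomp

        out = []
        length, occs = self.longest_match(pattern)
        if length == len(pattern):
            out.extend((c, p, "+") for c, p in occs)
        length, occs = self.longest_match(revcomp(pattern))
        if length == len(pattern):
            out.extend((c, p, "-") for c, p in occs)
        return sorted(out)

    # ------------------------------------------------------------------
    def save(self, path) -> None:
        np.savez_compressed(
            path,
            version=np.asarray([INDEX_VERSION]),
            text=np.frombuffer(self.text.encode("latin-1"), dtype=np.uint8),
            sa=self.sa,
            names=np.asarray(self.names),
            starts=self.starts,
        )

    @classmethod
    def load(cls, path) -> "SuffixIndex":
        data = np.load(path, allow_pickle=False)
        if int(data["version"][0]) != INDEX_VERSION:
            raise ValueError("incompatible index version")
        text = data["text"].tobytes().decode("latin-1")
        names = [str(n) for n in data["names"]]
        starts = data["starts"]
        seqs = {}
        for i, name in enumerate(names):
            s = int(starts[i])
            e = int(starts[i + 1]) - 1 if i + 1 < len(names) else len(text) - 1
            seqs[name] = text[s:e]
        obj = cls.__new__(cls)
        obj.genome = ReferenceGenome(seqs)
        obj.text = text
        obj.names = names
        obj.starts = np.asarray(starts, dtype=np.int64)
        obj.chrom_lengths = np.asarray([len(seqs[n]) for n in names], dtype=np.int64)
        obj.sa = data["sa"]
        return obj


def build_index(genome: ReferenceGenome) -> SuffixIndex:
    """Build a suffix-array index supporting both-strand pattern location."""
    return SuffixIndex(genome)
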