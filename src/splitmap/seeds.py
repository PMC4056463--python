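"""Seed collection: entropy-filtered exact-match seeding of read suffixes.

For a read of length m and minimum suffix length l, at most 2(m - l)
suffixes (read and reverse complement) are considered.  Each considered
suffix contributes its longest exact prefix match in the genome as a
seed; the scan then restarts past the first unmatched position, so a
sequencing error or a splice boundary simply starts the next seed.  A
single mismatch may be bridged for unique seeds when the error budget
allows it.

Seeds are filtered by Shannon entropy of the read substring (to drop
poly-A tails and other low-complexity matches), by a maximum occurrence
count (repeats) and by the minimum seed length.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from typing import List, Tuple

from .genome import revcomp
from .index import SuffixIndex

logger = logging.getLogger(__name__)

Occurrence = Tuple[str, int, str]  # chromosome, forward start, strand


@dataclass
class SeedParams:
    """Filters applied during seeding.

    min_suffix_length
        Minimum seed length l in nt; suffixes shorter than this are not
        considered.
    max_occurrences
        Seeds matching more genomic loci than this are treated as
        repeats and discarded.
    max_seed_errors
        Edit budget inside one seed.  With the exact-match seeder this
        enables bridging a single mismatch for unique seeds.
    entropy_threshold
        Minimum Shannon entropy (bits) of the read substring of a seed.
    min_accuracy
        Minimum percent identity for a semi-global (unsplit) alignment
        of the full read to be reported.
    """

    min_suffix_length: int = 20
    max_occurrences: int = 50
    max_seed_errors: int = 1
    entropy_threshold: float = 1.5
    min_accuracy: float = 85.0

    def __post_init__(self) -> None:
        if self.min_suffix_length < 10:
            raise ValueError("min_suffix_length must be >= 10")
        if self.entropy_threshold < 0:
            raise ValueError("entropy_threshold must be >= 0")
        if self.max_occurrences < 1:
            raise ValueError("max_occurrences must be >= 1")


@dataclass
class Seed:
    """A suffix-prefix match of the read at one or more genomic loci.

    ``read_start``/``read_end`` are 0-based inclusive read offsets;
    ``ref_start``/``ref_end`` is the 0-based half-open forward-strand
    interval of the (first) occurrence.  ``score`` is matches minus
    (mismatches + insertions + deletions).
    """

    read_start: int
    read_end: int
    score: int
    chrom: str
    ref_start: int
    ref_end: int
    strand: str
    occurrences: List[Occurrence] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.read_end - self.read_start + 1


def shannon_entropy(s: str) -> float:
    """Shannon entropy H(S) = -sum p(s_i) log2 p(s_i) of a sequence, in bits.

    ``p`` is the empirical mononucleotide frequency within ``s``.
    """
    if not s:
        raise ValueError("entropy of an empty string is undefined")
    n = len(s)
    h = 0.0
    for count in Counter(s).values():
        p = count / n
        h -= p * math.log2(p)
    return h


def _scan_orientation(
    seq: str,
    index: SuffixIndex,
    params: SeedParams,
) -> List[Tuple[int, int, int, List[Tuple[str, int]]]]:
    """Greedy suffix scan of one read orientation.

    Returns tuples ``(start, matched_length, score, occurrences)`` in
    scan coordinates of ``seq``.  The scan restarts one position past
    the end of each maximal match, so each sequencing error or splice
    boundary costs at most one skipped position.
    """
    out = []
    m = len(seq)
    ell = params.min_suffix_length
    i = 0
    while i + ell <= m:
        length, occs = index.longest_match(seq[i:], params.max_occurrences)
        if length >= ell and occs:
            score = length
            total = length
            if (
                params.max_seed_errors >= 1
                and len(occs) == 1
                and i + length + 1 < m
            ):
                # bridge one mismatch if a solid run continues behind it
                chrom, p = occs[0]
                ref = index.genome[chrom]
                q = i + length + 1
                r = p + length + 1
                ext = 0
                while (
                    q + ext < m
                    and r + ext < len(ref)
                    and seq[q + ext] == ref[r + ext]
                    and ref[r + ext] != "N"
                ):
                    ext += 1
                if ext >= 4:
                    total = length + 1 + ext
                    score = length + ext - 1
            out.append((i, total, score, occs))
            i += total + 1
        else:
            i += max(length, 1) + 1
    return out


def collect_seeds(read: str, index: SuffixIndex, params: SeedParams) -> List[Seed]:
    """Entropy- and occurrence-filtered seeds for a read, both strands.

    Reverse-strand seeds carry forward-strand reference coordinates and
    read coordinates reflected back onto the original read.
    """
    read = read.upper()
    m = len(read)
    if m <= params.min_suffix_length:
        logger.warning(
            "read of length %d not longer than minimum suffix length %d; "
            "no seeds collected", m, params.min_suffix_length,
        )
        return []
    seeds: List[Seed] = []
    for strand, seq in (("+", read), ("-", revcomp(read))):
        for start, length, score, occs in _scan_orientation(seq, index, params):
            if strand == "+":
                qs, qe = start, start + length - 1
            else:
                qs, qe = m - start - length, m - start - 1
            sub = read[qs:qe + 1]
            if shannon_entropy(sub) < params.entropy_threshold:
                continue
            occurrences = [(c, p, strand) for c, p in occs]
            chrom, p0, _ = occurrences[0]
            seeds.append(
                Seed(
                    read_start=qs,
                    read_end=qe,
                    score=score,
                    chrom=chrom,
                    ref_start=p0,
                    ref_end=p0 + length,
                    strand=strand,
                    occurrences=occurrences,
                )
            )
    seeds.sort(key=lambda s: (s.read_start, s.read_end, s.strand, s.chrom, s.ref_start))
    return seeds
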