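"""Greedy score-based seed chaining and occurrence resolution.

The score of a chain c = (c[1], ..., c[|c|]), seeds ordered along the
read, is

    sigma(c) = sum_k psi(c[k]) - sum_{k>=2} |pi_e(c[k-1]) - pi_s(c[k])|

where psi is the seed alignment score and pi_s / pi_e are the seed's
start and end offsets in the read.  The gap term penalizes both gaps
and overlaps between consecutive seeds; note that perfectly adjacent
seeds (pi_e = 29 followed by pi_s = 30) cost 1.

Chaining is the classic sorted sweep: seeds are sorted by pi_s, every
seed starts as a chain of its own, and each chain is concatenated with
the best preceding chain whenever that improves its score.  Because the
score of an extension depends on the preceding chain only through its
total score and the read end of its last seed, the sweep is exact: the
top chain attains the maximum of sigma over all read-ordered seed
subsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

from .seeds import Seed


@dataclass
class ChainParams:
    """min_coverage: minimum fraction of read positions the top chain
    must cover for the read to proceed to alignment (default 0.80, i.e.
    the chain must cover more than 80% of the read)."""

    min_coverage: float = 0.80

    def __post_init__(self) -> None:
        if not (0 < self.min_coverage <= 1):
            raise ValueError("min_coverage must be in (0, 1]")


@dataclass
class Chain:
    seeds: List[Seed]
    score: int
    read_coverage: float = 0.0

    def __len__(self) -> int:
        return len(self.seeds)


def chain_score(seeds: Sequence[Seed]) -> int:
    """Evaluate sigma(c) for seeds ordered by read start."""
    if not seeds:
        raise ValueError("cannot score an empty chain")
    score = sum(s.score for s in seeds)
    for prev, cur in zip(seeds, seeds[1:]):
        score -= abs(prev.read_end - cur.read_start)
    return score


def _coverage(seeds: Sequence[Seed], read_length: int) -> float:
    covered = 0
    last_end = -1
    for s in sorted(seeds, key=lambda x: x.read_start):
        lo = max(s.read_start, last_end + 1)
        if s.read_end >= lo:
            covered += s.read_end - lo + 1
            last_end = s.read_end
    return covered / read_length


def _sort_key(s: Seed):
    return (s.read_start, s.read_end, s.strand, s.chrom, s.ref_start)


def greedy_chain(seeds: Sequence[Seed], stats: Optional[Dict[str, int]] = None) -> List[Chain]:
    """Greedy chaining: each seed is extended by its best predecessor.

    Returns chains sorted by score descending (ties: fewer fragments,
    then leftmost genomic coordinate).  Every input seed appears in at
    least one returned chain.  The pairwise comparison count is at most
    |C|(|C|-1)/2 and is reported through ``stats['comparisons']``.
    """
    if stats is not None:
        stats["comparisons"] = 0
    if not seeds:
        return []
    order = sorted(seeds, key=_sort_key)
    n = len(order)
    best_chain: List[List[Seed]] = [[s] for s in order]
    best_score: List[int] = [s.score for s in order]
    comparisons = 0
    for i in range(1, n):
        s = order[i]
        best_j = -1
        best_val = best_score[i]
        for j in range(i):
            comparisons += 1
            prev = best_chain[j][-1]
            if _sort_key(prev) >= _sort_key(s):
                continue
            val = best_score[j] + s.score - abs(prev.read_end - s.read_start)
            if val > best_val:
                best_val = val
                best_j = j
        if best_j >= 0:
            best_chain[i] = best_chain[best_j] + [s]
            best_score[i] = best_val
    if stats is not None:
        stats["comparisons"] = comparisons
    chains = [Chain(seeds=c, score=sc) for c, sc in zip(best_chain, best_score)]
    chains.sort(
        key=lambda c: (
            -c.score,
            len(c.seeds),
            c.seeds[0].chrom,
            c.seeds[0].ref_start,
            c.seeds[0].read_start,
        )
    )
    return chains


def select_chain(
    chains: Sequence[Chain], read_length: int, params: ChainParams
) -> Optional[Chain]:
    """Return the top-ranking chain iff it covers more than
    ``min_coverage`` of the read, else ``None`` (read stays unmapped)."""
    if not chains:
        return None
    top = chains[0]
    cov = _coverage(top.seeds, read_length)
    if cov <= params.min_coverage:
        return None
    return Chain(seeds=top.seeds, score=top.score, read_coverage=cov)


_CROSS_CHROM = 10 ** 9


def _occ_distance(a, b) -> int:
    if a[0] != b[0]:
        return _CROSS_CHROM
    return abs(b[1] - a[1])


def resolve_occurrences(chain: Chain) -> Chain:
    """Fix each multi-hit seed to exactly one genomic occurrence.

    Among all per-seed occurrence combinations the selection minimizes
    the summed genomic distance between consecutive seeds, preferring
    same-strand (and implicitly same-chromosome) candidates as the
    tie-break; computed exactly by dynamic programming over the
    occurrence lists.
    """
    seeds = chain.seeds
    occ_lists = [s.occurrences if s.occurrences else [(s.chrom, s.ref_start, s.strand)]
                 for s in seeds]
    n = len(seeds)
    # cost: (total distance, strand switches, position tuple for determinism)
    prev_costs = [(0, 0, (occ[0], occ[1])) for occ in occ_lists[0]]
    back: List[List[int]] = []
    for k in range(1, n):
        costs = []
        ptr = []
        for occ in occ_lists[k]:
            best = None
            best_j = 0
            for j, prev_occ in enumerate(occ_lists[k - 1]):
                pc = prev_costs[j]
                cand = (
                    pc[0] + _occ_distance(prev_occ, occ),
                    pc[1] + (0 if prev_occ[2] == occ[2] else 1),
                    pc[2] + (occ[0], occ[1]),
                )
                if best is None or cand < best:
                    best = cand
                    best_j = j
            costs.append(best)
            ptr.append(best_j)
        prev_costs = costs
        back.append(ptr)
    j = min(range(len(prev_costs)), key=lambda i: prev_costs[i])
    picks = [0] * n
    picks[n - 1] = j
    for k in range(n - 2, -1, -1):
        picks[k] = back[k][picks[k + 1]]
    resolved = []
    for s, occ_list, pick in zip(seeds, occ_lists, picks):
        chrom, pos, strand = occ_list[pick]
        length = s.ref_end - s.ref_start
        resolved.append(
            replace(
                s,
                chrom=chrom,
                ref_start=pos,
                ref_end=pos + length,
                strand=strand,
                occurrences=[(chrom, pos, strand)],
            )
        )
    return Chain(seeds=resolved, score=chain.score, read_coverage=chain.read_coverage)


@dataclass
class Locus:
    """A merged run of collinear seeds: one genomic window candidate."""

    chrom: str
    ref_start: int
    ref_end: int
    strand: str
    read_start: int
    read_end: int
    multi: bool = False  # any contributing seed had multiple occurrences


def merge_collinear(chain: Chain, diag_tolerance: int = 30) -> List[Locus]:
    """Merge read-adjacent seeds lying on the same genomic diagonal.

    Seeds separated only by sequencing errors fall on (nearly) the same
    diagonal of the same locus; merging them prevents the transition
    alignment from seeing one locus as two windows.  True splice
    junctions shift the diagonal by the intron length and are never
    merged (``diag_tolerance`` is far below any plausible intron).
    """
    loci: List[Locus] = []
    for s in chain.seeds:
        multi = len(s.occurrences) > 1
        if s.strand == "+":
            diag = s.ref_start - s.read_start
        else:
            diag = s.ref_end + s.read_start
        if loci:
            last = loci[-1]
            if last.chrom == s.chrom and last.strand == s.strand:
                if s.strand == "+":
                    last_diag = last.ref_start - last.read_start
                else:
                    last_diag = last.ref_end + last.read_start
                if abs(diag - last_diag) <= diag_tolerance and (
                    (s.strand == "+" and s.ref_start >= last.ref_start)
                    or (s.strand == "-" and s.ref_end <= last.ref_end)
                ):
                    last.ref_start = min(last.ref_start, s.ref_start)
                    last.ref_end = max(last.ref_end, s.ref_end)
                    last.read_start = min(last.read_start, s.read_start)
                    last.read_end = max(last.read_end, s.read_end)
                    last.multi = last.multi or multi
                    continue
        loci.append(
            Locus(
                chrom=s.chrom,
                ref_start=s.ref_start,
                ref_end=s.ref_end,
                strand=s.strand,
                read_start=s.read_start,
                read_end=s.read_end,
                multi=multi,
            )
        )
    return loci
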