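"""End-to-end read mapping: seeds -> chain -> transition alignment -> junctions.

Every input read yields exactly one of {unmapped, unsplit alignment,
split alignment}.  Split alignments are serialized to SAM as one primary
record plus supplementary records per additional fragment; junction
calls are aggregated over all reads with their split-read support.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, List, Optional, Tuple

import pysam

from .alignment import (
    AlignParams,
    Fragment,
    SplitAlignment,
    extract_windows,
    transition_align,
)
from .chaining import ChainParams, greedy_chain, merge_collinear, resolve_occurrences, select_chain
from .genome import ReferenceGenome, revcomp
from .index import SuffixIndex
from .junctions import (
    Junction,
    JunctionParams,
    aggregate_support,
    extract_junctions,
    make_junction,
)
from .seeds import SeedParams, collect_seeds

logger = logging.getLogger(__name__)


@dataclass
class MapParams:
    seed: SeedParams = field(default_factory=SeedParams)
    chain: ChainParams = field(default_factory=ChainParams)
    align: AlignParams = field(default_factory=AlignParams)
    junction: JunctionParams = field(default_factory=JunctionParams)


@dataclass
class MapStats:
    total: int = 0
    unmapped: int = 0
    unsplit: int = 0
    split: int = 0
    malformed: int = 0


def map_read(
    read_id: str,
    sequence: str,
    index: SuffixIndex,
    params: Optional[MapParams] = None,
) -> Optional[SplitAlignment]:
    """Map one single-end read; ``None`` means unmapped."""
    params = params or MapParams()
    genome = index.genome
    seeds = collect_seeds(sequence, index, params.seed)
    if not seeds:
        return None
    chains = greedy_chain(seeds)
    chain = select_chain(chains, len(sequence), params.chain)
    if chain is None:
        return None
    chain = resolve_occurrences(chain)
    loci = merge_collinear(chain)
    windows = extract_windows(loci, genome, params.align)
    aln = transition_align(sequence, windows, params.align, read_id=read_id)
    if aln is None:
        return None
    aln.unique = not any(loc.multi for loc in loci)
    return aln


class MapResult:
    def __init__(self) -> None:
        self.alignments: List[SplitAlignment] = []
        self.junctions: List[Junction] = []
        self.stats = MapStats()
        self.unmapped_ids: List[str] = []


def map_reads(
    reads: Iterable[Tuple[str, str]],
    index: SuffixIndex,
    params: Optional[MapParams] = None,
) -> MapResult:
    """Map an iterable of ``(read_id, sequence)`` pairs.

    Junctions from uniquely resolved split reads are normalized,
    classified, merged and support-filtered per ``params.junction``.
    """
    params = params or MapParams()
    genome = index.genome
    result = MapResult()
    observations: List[Junction] = []
    for read_id, seq in reads:
        result.stats.total += 1
        aln = map_read(read_id, seq, index, params)
        if aln is None:
            result.stats.unmapped += 1
            result.unmapped_ids.append(read_id)
            continue
        result.alignments.append(aln)
        if aln.is_split:
            result.stats.split += 1
            for raw in extract_junctions(aln):
                observations.append(
                    make_junction(genome, raw.donor, raw.acceptor, params.junction)
                )
        else:
            result.stats.unsplit += 1
    result.junctions = aggregate_support(observations, params.junction)
    return result


# ----------------------------------------------------------------------
# FASTQ input


def read_fastq_lenient(path, stats: Optional[MapStats] = None) -> Iterator[Tuple[str, str]]:
    """Yield ``(id, sequence)`` from FASTQ, skipping malformed records
    with a logged warning (and a count in ``stats.malformed``)."""
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header:
                break
            if not header.startswith("@"):
                logger.warning("skipping malformed FASTQ header: %r", header.strip())
                if stats is not None:
                    stats.malformed += 1
                continue
            seq = fh.readline().strip()
            plus = fh.readline()
            qual = fh.readline().strip()
            if not plus.startswith("+") or len(qual) != len(seq) or not seq:
                logger.warning("skipping malformed FASTQ record %r", header.strip())
                if stats is not None:
                    stats.malformed += 1
                continue
            yield header[1:].split()[0], seq.upper()


# ----------------------------------------------------------------------
# SAM output

_OP_TO_SAM = {"=": 7, "X": 8, "I": 1, "D": 2}


def _cigartuples(frag: Fragment, read_length: int) -> List[Tuple[int, int]]:
    ops: List[Tuple[int, int]] = []
    run_op, run_len = None, 0
    body = frag.ops if frag.strand == "+" else frag.ops[::-1]
    for c in body:
        code = _OP_TO_SAM[c]
        if code == run_op:
            run_len += 1
        else:
            if run_op is not None:
                ops.append((run_op, run_len))
            run_op, run_len = code, 1
    if run_op is not None:
        ops.append((run_op, run_len))
    if frag.strand == "+":
        pre, post = frag.read_start, read_length - frag.read_end
    else:
        pre, post = read_length - frag.read_end, frag.read_start
    if pre:
        ops.insert(0, (4, pre))
    if post:
        ops.append((4, post))
    return ops


def sam_header(genome: ReferenceGenome) -> pysam.AlignmentHeader:
    return pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "unsorted"},
            "SQ": [
                {"SN": name, "LN": length}
                for name, length in genome.lengths.items()
            ],
            "PG": [{"ID": "splitmap", "PN": "splitmap"}],
        }
    )


def write_sam(
    path,
    genome: ReferenceGenome,
    alignments: Iterable[Tuple[SplitAlignment, str]],
    unmapped: Iterable[Tuple[str, str]] = (),
) -> None:
    """SAM with one primary record per read and supplementary records
    for the additional fragments of split reads.

    ``alignments`` pairs each :class:`SplitAlignment` with the original
    read sequence; minus-strand records carry the reverse complement per
    SAM convention and CIGAR soft clips are placed accordingly.
    """
    header = sam_header(genome)
    refs = list(genome.lengths)
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for aln, seq in alignments:
            for i, frag in enumerate(aln.fragments):
                rec = pysam.AlignedSegment(header)
                rec.query_name = aln.read_id
                rec.flag = (16 if frag.strand == "-" else 0) | (2048 if i else 0)
                rec.reference_id = refs.index(frag.chrom)
                rec.reference_start = frag.ref_start
                rec.mapping_quality = 60 if aln.unique else 1
                rec.cigartuples = _cigartuples(frag, len(seq))
                rec.query_sequence = seq if frag.strand == "+" else revcomp(seq)
                rec.set_tag("AS", frag.score)
                out.write(rec)
        for read_id, seq in unmapped:
            rec = pysam.AlignedSegment(header)
            rec.query_name = read_id
            rec.flag = 4
            rec.query_sequence = seq
            out.write(rec)


def alignments_from_sam(path) -> List[SplitAlignment]:
    """Reconstruct split alignments (fragment geometry only) from SAM."""
    by_name: dict = {}
    with pysam.AlignmentFile(str(path), "r") as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            strand = "-" if rec.is_reverse else "+"
            cig = rec.cigartuples or []
            pre = cig[0][1] if cig and cig[0][0] == 4 else 0
            post = cig[-1][1] if cig and cig[-1][0] == 4 else 0
            qlen = sum(l for op, l in cig if op in (0, 1, 4, 7, 8))
            if strand == "+":
                qs, qe = pre, qlen - post
            else:
                qs, qe = post, qlen - pre
            ops = "".join(
                {0: "=", 7: "=", 8: "X", 1: "I", 2: "D"}[op] * l
                for op, l in cig
                if op in (0, 1, 2, 7, 8)
            )
            if strand == "-":
                ops = ops[::-1]
            frag = Fragment(
                read_start=qs,
                read_end=qe,
                chrom=rec.reference_name,
                ref_start=rec.reference_start,
                ref_end=rec.reference_end,
                strand=strand,
                ops=ops,
                score=rec.get_tag("AS") if rec.has_tag("AS") else 0,
            )
            by_name.setdefault(rec.query_name, []).append(frag)
    out = []
    for name, frags in by_name.items():
        frags.sort(key=lambda f: f.read_start)
        out.append(
            SplitAlignment(
                read_id=name,
                fragments=frags,
                score=sum(f.score for f in frags),
                transitions=len(frags) - 1,
            )
        )
    return out
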