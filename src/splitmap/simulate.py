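"""Spliced-read simulator: synthetic genomes, isoforms and error-model reads.

The simulator is the desk-scale stand-in for a genome-plus-transcript
benchmark: it draws a uniform random genome, samples multi-exon isoforms
from it, optionally perturbs a fraction of the exons (strand flips and
distant/inter-chromosomal substitutions, producing strand-reversing and
long-range junctions), optionally circularizes isoforms (reads may span
the end-to-start back-splice), and samples single-end reads under an
Illumina-like (substitution-dominated) or 454-like (indel-dominated,
homopolymer-scaled) error model.  Every dataset comes with a ground
truth: the per-isoform junction catalog and, per read, the junctions the
read overlaps with at least ``anchor`` nt on both sides.

All sampling is driven by a single seed; identical configurations yield
byte-identical FASTQ and truth tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .genome import ReferenceGenome, revcomp
from .junctions import (
    Breakpoint,
    Junction,
    JunctionParams,
    make_junction,
)

_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SimConfig:
    """Study conditions of one simulated dataset.

    Defaults emulate the benchmark protocol: multi-exon isoforms, 20%
    irregular exons in the mixed datasets, 100 nt (Illumina-like) or
    400 nt (454-like) single-end reads at 10-20x coverage.
    """

    genome_size: int = 3_000_000
    n_chromosomes: int = 2
    decoy_fraction: float = 0.0  # fraction of genome in poly-A decoy tracts
    n_isoforms: int = 200
    exons_per_isoform: Tuple[int, int] = (3, 8)
    exon_length: Tuple[int, int] = (150, 450)
    intron_length: Tuple[int, int] = (200, 2000)
    irregular_fraction: float = 0.20
    flip_fraction: float = 0.5  # irregular exons: flip vs distant substitution
    circular: bool = False
    read_length: int = 100
    full_length_reads: bool = False  # one read spans the whole transcript
    coverage: float = 10.0
    error_model: str = "illumina"  # or "454"
    substitution_rate: Optional[float] = None
    insertion_rate: Optional[float] = None
    deletion_rate: Optional[float] = None
    homopolymer_factor: float = 5.0  # 454 indel scaling cap inside runs
    anchor: int = 10  # min nt on both sides for a read to witness a junction
    antisense_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.irregular_fraction <= 1):
            raise ValueError("irregular_fraction must be in [0, 1]")
        if self.error_model not in ("illumina", "454"):
            raise ValueError("error_model must be 'illumina' or '454'")
        for r in (self.substitution_rate, self.insertion_rate, self.deletion_rate):
            if r is not None and not (0 <= r <= 0.1):
                raise ValueError("error rates must be in [0, 0.1]")

    def rates(self) -> Tuple[float, float, float]:
        """(substitution, insertion, deletion) per-base rates in effect."""
        if self.error_model == "illumina":
            defaults = (0.005, 0.0002, 0.0002)
        else:  # 454: indel-dominated
            defaults = (0.001, 0.002, 0.002)
        sub = self.substitution_rate if self.substitution_rate is not None else defaults[0]
        ins = self.insertion_rate if self.insertion_rate is not None else defaults[1]
        dele = self.deletion_rate if self.deletion_rate is not None else defaults[2]
        return sub, ins, dele


@dataclass
class Exon:
    chrom: str
    start: int
    end: int
    strand: str
    irregular: bool = False  # perturbed: strand-flipped or distant substitute

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class Isoform:
    name: str
    exons: List[Exon]
    sequence: str
    circular: bool
    junctions: List[Tuple[int, Junction]]  # (transcript breakpoint, junction)


def simulate_genome(config: SimConfig) -> ReferenceGenome:
    """I.i.d. uniform A/C/G/T chromosomes, optionally salted with
    low-complexity poly-A decoy tracts for entropy-filter testing."""
    if config.genome_size < 10_000:
        raise ValueError("genome_size must be >= 10 kb")
    rng = np.random.default_rng(config.seed)
    size = config.genome_size // config.n_chromosomes
    seqs: Dict[str, str] = {}
    for c in range(config.n_chromosomes):
        codes = rng.integers(0, 4, size=size)
        arr = _ALPHABET[codes]
        if config.decoy_fraction > 0:
            total = int(size * config.decoy_fraction)
            placed = 0
            while placed < total:
                tract = int(rng.integers(50, 201))
                pos = int(rng.integers(0, size - tract))
                arr[pos:pos + tract] = ord("A")
                placed += tract
        seqs[f"chr{c + 1}"] = arr.tobytes().decode("ascii")
    return ReferenceGenome(seqs)


def _exon_sequence(genome: ReferenceGenome, exon: Exon) -> str:
    s = genome.slice(exon.chrom, exon.start, exon.end)
    return s if exon.strand == "+" else revcomp(s)


def _exon_boundaries(exon: Exon) -> Tuple[Breakpoint, Breakpoint]:
    """(first transcribed base, last transcribed base) of an exon."""
    if exon.strand == "+":
        return (exon.chrom, exon.start, "+"), (exon.chrom, exon.end - 1, "+")
    return (exon.chrom, exon.end - 1, "-"), (exon.chrom, exon.start, "-")


def simulate_isoforms(
    genome: ReferenceGenome, config: SimConfig
) -> Tuple[List[Isoform], pd.DataFrame]:
    """Sample isoforms as exon-chain concatenations with ground truth.

    With probability ``irregular_fraction`` an exon is strand-flipped in
    place or substituted by an exon more than 200 kb away or on another
    chromosome.  When ``circular`` is set, an additional end-to-start
    junction is recorded and reads may be sampled across it.  Returns
    the isoforms and a junction truth table (one row per isoform
    junction, canonical coordinates, class labels).
    """
    rng = np.random.default_rng(config.seed + 1)
    jparams = JunctionParams()
    chroms = list(genome.sequences)
    lengths = genome.lengths
    isoforms: List[Isoform] = []
    rows = []
    for iso_i in range(config.n_isoforms):
        n_ex = int(rng.integers(config.exons_per_isoform[0],
                                config.exons_per_isoform[1] + 1))
        ex_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1,
                               size=n_ex)
        introns = rng.integers(config.intron_length[0], config.intron_length[1] + 1,
                               size=max(0, n_ex - 1))
        span = int(ex_lens.sum() + introns.sum())
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(0, lengths[chrom] - span))
        exons: List[Exon] = []
        pos = start
        for k in range(n_ex):
            exons.append(Exon(chrom, pos, pos + int(ex_lens[k]), strand))
            pos += int(ex_lens[k])
            if k < n_ex - 1:
                pos += int(introns[k])
        if strand == "-":
            exons = exons[::-1]  # transcription runs right to left
        # irregular perturbations
        for k in range(len(exons)):
            if rng.random() >= config.irregular_fraction:
                continue
            if rng.random() < config.flip_fraction:
                e = exons[k]
                exons[k] = Exon(e.chrom, e.start, e.end,
                                "-" if e.strand == "+" else "+", irregular=True)
            else:
                exons[k] = _distant_exon(rng, genome, exons[k], config)
        seq_parts = [_exon_sequence(genome, e) for e in exons]
        sequence = "".join(seq_parts)
        junctions: List[Tuple[int, Junction]] = []
        t = 0
        for e1, e2 in zip(exons, exons[1:]):
            t += e1.length
            donor = _exon_boundaries(e1)[1]
            acceptor = _exon_boundaries(e2)[0]
            junctions.append((t, make_junction(genome, donor, acceptor, jparams)))
        if config.circular:
            donor = _exon_boundaries(exons[-1])[1]
            acceptor = _exon_boundaries(exons[0])[0]
            junctions.append(
                (len(sequence), make_junction(genome, donor, acceptor, jparams))
            )
        name = f"iso{iso_i:05d}"
        isoforms.append(Isoform(name, exons, sequence, config.circular, junctions))
        for t, j in junctions:
            rows.append(
                {
                    "isoform": name,
                    "transcript_pos": t,
                    "donor_chrom": j.donor[0],
                    "donor_pos": j.donor[1],
                    "donor_strand": j.donor[2],
                    "acceptor_chrom": j.acceptor[0],
                    "acceptor_pos": j.acceptor[1],
                    "acceptor_strand": j.acceptor[2],
                    "class": j.cls,
                }
            )
    truth = pd.DataFrame(
        rows,
        columns=[
            "isoform", "transcript_pos",
            "donor_chrom", "donor_pos", "donor_strand",
            "acceptor_chrom", "acceptor_pos", "acceptor_strand", "class",
        ],
    )
    return isoforms, truth


def _distant_exon(rng, genome: ReferenceGenome, exon: Exon, config: SimConfig) -> Exon:
    """Uniform replacement exon > 200 kb away or on another chromosome."""
    chroms = list(genome.sequences)
    lengths = genome.lengths
    length = exon.length
    for _ in range(100):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos = int(rng.integers(0, lengths[chrom] - length))
        if chrom != exon.chrom or abs(pos - exon.start) > 200_000:
            return Exon(chrom, pos, pos + length, exon.strand, irregular=True)
    # tiny genomes may not offer a distant locus; fall back to another chromosome
    others = [c for c in chroms if c != exon.chrom]
    chrom = others[0] if others else exon.chrom
    pos = int(rng.integers(0, lengths[chrom] - length))
    return Exon(chrom, pos, pos + length, exon.strand, irregular=True)


# ----------------------------------------------------------------------
# read sampling


@dataclass
class ReadRecord:
    name: str
    sequence: str
    quality: str


def _apply_errors(seq: str, rng, config: SimConfig) -> str:
    sub, ins, dele = config.rates()
    if sub == 0 and ins == 0 and dele == 0:
        return seq
    is454 = config.error_model == "454"
    out = []
    i = 0
    n = len(seq)
    run_len = 1
    while i < n:
        if i > 0 and seq[i] == seq[i - 1]:
            run_len += 1
        else:
            run_len = 1
        scale = min(run_len, config.homopolymer_factor) if is454 else 1.0
        r = rng.random()
        p_ins, p_del, p_sub = ins * scale, dele * scale, sub
        if r < p_ins:
            out.append(seq[i])  # homopolymer-style duplication
            out.append(seq[i])
            i += 1
        elif r < p_ins + p_del:
            i += 1  # base dropped
        elif r < p_ins + p_del + p_sub:
            b = seq[i]
            choices = [c for c in "ACGT" if c != b]
            out.append(choices[int(rng.integers(0, 3))])
            i += 1
        else:
            out.append(seq[i])
            i += 1
    return "".join(out)


def simulate_reads(
    isoforms: Sequence[Isoform], config: SimConfig
) -> Tuple[List[ReadRecord], pd.DataFrame]:
    """Error-model reads drawn uniformly along each isoform.

    Returns FASTQ-ready records plus the per-read truth: one row per
    (read, junction) pair where the read covers the junction with at
    least ``anchor`` nt on both sides.  Circular isoforms are sampled
    from their doubled sequence so reads span the back-splice point.
    """
    rng = np.random.default_rng(config.seed + 2)
    reads: List[ReadRecord] = []
    rows = []
    for iso in isoforms:
        L = len(iso.sequence)
        if config.full_length_reads:
            n_reads = max(1, int(round(config.coverage)))
        else:
            if config.read_length > L:
                continue
            n_reads = math.ceil(config.coverage * L / config.read_length)
        for r_i in range(n_reads):
            if iso.circular:
                start = int(rng.integers(0, L))
                rlen = L if config.full_length_reads else config.read_length
                template = (iso.sequence + iso.sequence)[start:start + rlen]
            else:
                rlen = L if config.full_length_reads else config.read_length
                start = 0 if rlen >= L else int(rng.integers(0, L - rlen + 1))
                template = iso.sequence[start:start + rlen]
            name = f"{iso.name}_r{r_i:04d}"
            witnessed = []
            for t, j in iso.junctions:
                for tpos in ((t, t + L) if iso.circular else (t,)):
                    if (
                        tpos - start >= config.anchor
                        and start + rlen - tpos >= config.anchor
                    ):
                        witnessed.append(j)
                        break
            seq = _apply_errors(template, rng, config)
            if rng.random() < config.antisense_fraction:
                seq = revcomp(seq)
            if len(seq) < 2 * config.anchor:
                continue
            reads.append(ReadRecord(name=name, sequence=seq, quality="I" * len(seq)))
            for j in witnessed:
                rows.append(
                    {
                        "read_id": name,
                        "isoform": iso.name,
                        "donor_chrom": j.donor[0],
                        "donor_pos": j.donor[1],
                        "donor_strand": j.donor[2],
                        "acceptor_chrom": j.acceptor[0],
                        "acceptor_pos": j.acceptor[1],
                        "acceptor_strand": j.acceptor[2],
                        "class": j.cls,
                    }
                )
    read_truth = pd.DataFrame(
        rows,
        columns=[
            "read_id", "isoform",
            "donor_chrom", "donor_pos", "donor_strand",
            "acceptor_chrom", "acceptor_pos", "acceptor_strand", "class",
        ],
    )
    return reads, read_truth


def write_fastq(path, reads: Sequence[ReadRecord]) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.name}\n{r.sequence}\n+\n{r.quality}\n")


def truth_junction_catalog(read_truth: pd.DataFrame) -> pd.DataFrame:
    """Unique witnessed junction loci (the recall denominator)."""
    cols = [
        "donor_chrom", "donor_pos", "donor_strand",
        "acceptor_chrom", "acceptor_pos", "acceptor_strand", "class",
    ]
    if read_truth.empty:
        return pd.DataFrame(columns=cols)
    return (
        read_truth[cols]
        .drop_duplicates()
        .sort_values(cols[:6])
        .reset_index(drop=True)
    )
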