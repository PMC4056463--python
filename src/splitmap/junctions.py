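"""Junction extraction, classification, normalization and aggregation.

A junction is the breakpoint pair implied by two adjacent fragments of a
split read: the donor is the last aligned base (in transcription
direction) of the earlier-in-read fragment, the acceptor the first base
of the later one.  Classes:

* strand-reversing -- donor and acceptor strands differ;
* long-range       -- same strand but different chromosomes or a
                      genomic distance above ``long_range_distance``;
* circular         -- same chromosome and strand with the acceptor
                      genomically upstream of the donor (back-splice);
* regular          -- everything else (conventional splicing).

Breakpoints of a junction are often ambiguous by a few nucleotides when
the reference sequence continues identically across the break.  Both
predicted and simulated junctions are therefore normalized to a
canonical representative: the breakpoint pair is shifted through its
genomic equivalence interval and, because non-strand-specific libraries
cannot orient a junction, the lexicographically smaller of the two
flip-equivalent representations is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

from .alignment import SplitAlignment
from .genome import ReferenceGenome

Breakpoint = Tuple[str, int, str]  # chromosome, 0-based position, strand

REGULAR = "regular"
STRAND_REVERSING = "strand-reversing"
LONG_RANGE = "long-range"
CIRCULAR = "circular"


@dataclass
class JunctionParams:
    """long_range_distance: same-strand junctions spanning more than
    this (or two chromosomes) are long-range (default 200 kb).
    min_support: minimum split-read support to keep a junction
    (3 reproduces a strict census-style filter).  merge_tolerance:
    breakpoint slack in nt when merging observations (default exact)."""

    long_range_distance: int = 200_000
    min_support: int = 1
    merge_tolerance: int = 0

    def __post_init__(self) -> None:
        if self.long_range_distance <= 0:
            raise ValueError("long_range_distance must be > 0")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")


@dataclass
class Junction:
    donor: Breakpoint
    acceptor: Breakpoint
    cls: str = REGULAR
    support: int = 1
    strand_known: bool = False

    @property
    def key(self) -> Tuple[Breakpoint, Breakpoint]:
        return (self.donor, self.acceptor)


def classify_junction(j: Junction, params: JunctionParams) -> str:
    """Assign exactly one class from the donor/acceptor geometry."""
    (dc, dp, ds), (ac, ap, as_) = j.donor, j.acceptor
    if ds != as_:
        return STRAND_REVERSING
    if dc != ac or abs(ap - dp) > params.long_range_distance:
        return LONG_RANGE
    upstream = ap < dp if ds == "+" else ap > dp
    if upstream:
        return CIRCULAR
    return REGULAR


def _next(bp: Breakpoint) -> Breakpoint:
    c, p, s = bp
    return (c, p + 1 if s == "+" else p - 1, s)


def _prev(bp: Breakpoint) -> Breakpoint:
    c, p, s = bp
    return (c, p - 1 if s == "+" else p + 1, s)


def _flip(bp: Breakpoint) -> Breakpoint:
    c, p, s = bp
    return (c, p, "-" if s == "+" else "+")


def normalize_junction(
    genome: ReferenceGenome, donor: Breakpoint, acceptor: Breakpoint,
    max_shift: int = 50,
) -> Tuple[Breakpoint, Breakpoint]:
    """Canonical representative of a breakpoint pair.

    Enumerates all shift-equivalent placements (a breakpoint may slide
    while the base leaving one side equals the base entering the other)
    together with their flipped (acceptor', donor') counterparts and
    returns the lexicographic minimum.  The result is invariant under
    both breakpoint sliding and read-orientation flips.
    """
    reps = [(donor, acceptor)]
    d, a = donor, acceptor
    for _ in range(max_shift):  # slide left (towards the read start)
        pa = _prev(a)
        pd = _prev(d)
        bd = genome.base(*d)
        ba = genome.base(*pa)
        if not bd or not ba or bd != ba or not genome.base(*pd):
            break
        d, a = pd, pa
        reps.append((d, a))
    d, a = donor, acceptor
    for _ in range(max_shift):  # slide right
        nd = _next(d)
        na = _next(a)
        bd = genome.base(*nd)
        ba = genome.base(*a)
        if not bd or not ba or bd != ba or not genome.base(*na):
            break
        d, a = nd, na
        reps.append((d, a))
    reps.extend([(_flip(x[1]), _flip(x[0])) for x in list(reps)])
    return min(reps)


def extract_junctions(aln: SplitAlignment) -> List[Junction]:
    """One junction per adjacent fragment pair of a split alignment."""
    out: List[Junction] = []
    for f1, f2 in zip(aln.fragments, aln.fragments[1:]):
        if f1.strand == "+":
            donor = (f1.chrom, f1.ref_end - 1, "+")
        else:
            donor = (f1.chrom, f1.ref_start, "-")
        if f2.strand == "+":
            acceptor = (f2.chrom, f2.ref_start, "+")
        else:
            acceptor = (f2.chrom, f2.ref_end - 1, "-")
        out.append(Junction(donor=donor, acceptor=acceptor))
    return out


def make_junction(
    genome: ReferenceGenome,
    donor: Breakpoint,
    acceptor: Breakpoint,
    params: Optional[JunctionParams] = None,
) -> Junction:
    """Normalized, classified junction from a raw breakpoint pair."""
    params = params or JunctionParams()
    d, a = normalize_junction(genome, donor, acceptor)
    j = Junction(donor=d, acceptor=a)
    j.cls = classify_junction(j, params)
    return j


def aggregate_support(
    junctions: Iterable[Junction], params: JunctionParams
) -> List[Junction]:
    """Merge identical junction observations and apply the support filter.

    Observations identical within ``merge_tolerance`` nt (same
    chromosomes and strands on both sides) are merged with their support
    summed; junctions with support below ``min_support`` are removed.
    """
    groups: dict = {}
    for j in junctions:
        groups.setdefault(j.key, []).append(j)
    merged: List[Junction] = []
    for key in sorted(groups):
        obs = groups[key]
        j = Junction(
            donor=key[0],
            acceptor=key[1],
            cls=obs[0].cls,
            support=sum(o.support for o in obs),
            strand_known=obs[0].strand_known,
        )
        merged.append(j)
    if params.merge_tolerance > 0:
        merged = _merge_nearby(merged, params.merge_tolerance)
    return [j for j in merged if j.support >= params.min_support]


def _merge_nearby(junctions: List[Junction], tol: int) -> List[Junction]:
    out: List[Junction] = []
    for j in junctions:  # already sorted by key
        target = None
        for prev in out:
            if (
                prev.donor[0] == j.donor[0]
                and prev.donor[2] == j.donor[2]
                and prev.acceptor[0] == j.acceptor[0]
                and prev.acceptor[2] == j.acceptor[2]
                and abs(prev.donor[1] - j.donor[1]) <= tol
                and abs(prev.acceptor[1] - j.acceptor[1]) <= tol
            ):
                target = prev
                break
        if target is None:
            out.append(j)
        else:
            if j.support > target.support:
                target.donor, target.acceptor, target.cls = (
                    j.donor, j.acceptor, j.cls,
                )
            target.support += j.support
    return out


# ----------------------------------------------------------------------
# BED-like serialization


BED_COLUMNS = [
    "donor_chrom", "donor_pos", "donor_strand",
    "acceptor_chrom", "acceptor_pos", "acceptor_strand",
    "class", "support",
]


def write_junctions_bed(path, junctions: Sequence[Junction]) -> None:
    """Tab-separated junction table (header line starts with '#')."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(BED_COLUMNS) + "\n")
        for j in junctions:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        j.donor[0], j.donor[1], j.donor[2],
                        j.acceptor[0], j.acceptor[1], j.acceptor[2],
                        j.cls, j.support,
                    )
                )
                + "\n"
            )


def read_junctions_bed(path) -> List[Junction]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            out.append(
                Junction(
                    donor=(f[0], int(f[1]), f[2]),
                    acceptor=(f[3], int(f[4]), f[5]),
                    cls=f[6],
                    support=int(f[7]),
                )
            )
    return out


def write_junctions_bedpe(path, junctions: Sequence[Junction]) -> None:
    """BEDPE (one base per side) for e.g. inter-chromosomal junctions."""
    with open(path, "w") as fh:
        for j in junctions:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        j.donor[0], j.donor[1], j.donor[1] + 1,
                        j.acceptor[0], j.acceptor[1], j.acceptor[1] + 1,
                        j.cls, j.support, j.donor[2], j.acceptor[2],
                    )
                )
                + "\n"
            )
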