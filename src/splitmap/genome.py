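"""Reference genome container and FASTA I/O.

Sequences are held in memory as upper-case strings over the alphabet
{A, C, G, T, N}.  All coordinates in this package are 0-based, half-open
on the forward strand; reverse-strand features carry forward coordinates
plus a ``-`` strand flag.
"""

from __future__ import annotations

import re
from typing import Dict, Iterator, Tuple

from Bio import SeqIO

_VALID = re.compile(r"^[ACGTN]*$")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    """Reverse complement of a nucleotide string (N maps to N)."""
    return s.translate(_COMPLEMENT)[::-1]


def complement_base(b: str) -> str:
    return b.translate(_COMPLEMENT)


class ReferenceGenome:
    """An ordered collection of named chromosome sequences.

    Parameters
    ----------
    sequences
        Mapping of chromosome name to nucleotide string.  Sequences are
        upper-cased on input and must be non-empty and restricted to
        A, C, G, T, N.
    """

    def __init__(self, sequences: Dict[str, str]):
        if not sequences:
            raise ValueError("genome must contain at least one sequence")
        self.sequences: Dict[str, str] = {}
        for name, seq in sequences.items():
            seq = seq.upper()
            if not seq:
                raise ValueError(f"sequence {name!r} is empty")
            if not _VALID.match(seq):
                bad = sorted(set(seq) - set("ACGTN"))
                raise ValueError(
                    f"sequence {name!r} contains non-ACGTN characters: {bad}"
                )
            if name in self.sequences:
                raise ValueError(f"duplicate sequence name {name!r}")
            self.sequences[name] = seq

    @property
    def lengths(self) -> Dict[str, int]:
        return {name: len(s) for name, s in self.sequences.items()}

    def __contains__(self, name: str) -> bool:
        return name in self.sequences

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def items(self) -> Iterator[Tuple[str, str]]:
        return iter(self.sequences.items())

    def slice(self, chrom: str, start: int, end: int) -> str:
        """Forward-strand slice, clipped to chromosome bounds."""
        seq = self.sequences[chrom]
        return seq[max(0, start):min(len(seq), end)]

    def base(self, chrom: str, pos: int, strand: str) -> str:
        """Strand-aware base: the transcribed nucleotide at ``pos``.

        Returns the empty string when ``pos`` is out of bounds, which is
        convenient for breakpoint-shift loops near chromosome ends.
        """
        seq = self.sequences[chrom]
        if pos < 0 or pos >= len(seq):
            return ""
        b = seq[pos]
        return b if strand == "+" else complement_base(b)

    @classmethod
    def from_fasta(cls, path) -> "ReferenceGenome":
        records = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            records[rec.id] = str(rec.seq)
        return cls(records)

    def write_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n")
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")
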