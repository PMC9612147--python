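"""Sequence and coordinate primitives shared by all pipeline stages.

Coordinates are 1-based and inclusive throughout, so the interval 5649-6048
spans exactly 400 nt.  Genomes may be circular; an interval with
``end < start`` wraps across the origin and is legal only on a circular
sequence.  Circularity is declared in FASTA with a ``[circular]`` token in
the header line.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_DNA = frozenset("ACGTRYSWKMBDHVN")
UNAMBIGUOUS = frozenset("ACGT")

CIRCULAR_TOKEN = "[circular]"


class FastaParseError(ValueError):
    """Raised for malformed FASTA input (empty file, illegal characters)."""


class CoordinateError(ValueError):
    """Raised for intervals that are invalid on the genome they address."""


class CompositionError(ValueError):
    """Raised when base composition is undefined (no unambiguous bases)."""


@dataclass(frozen=True)
class Interval:
    """A 1-based inclusive interval; ``wraps`` marks wrap-around on a circle."""

    start: int
    end: int
    wraps: bool = False

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < 1:
            raise CoordinateError(
                f"interval bounds must be >= 1, got {self.start}-{self.end}"
            )
        if self.wraps and self.end >= self.start:
            raise CoordinateError(
                f"wrapping interval requires end < start, got {self.start}-{self.end}"
            )
        if not self.wraps and self.end < self.start:
            raise CoordinateError(
                f"end < start ({self.start}-{self.end}); set wraps=True on a "
                "circular genome"
            )

    def span(self, genome_length: int | None = None) -> int:
        """Number of positions covered; wrapping spans need the genome length."""
        if not self.wraps:
            return self.end - self.start + 1
        if genome_length is None:
            raise CoordinateError("wrapping interval span requires genome_length")
        return genome_length - self.start + 1 + self.end

    def positions(self, genome_length: int) -> Iterator[int]:
        """Yield the covered 1-based positions in order."""
        if not self.wraps:
            yield from range(self.start, self.end + 1)
        else:
            yield from range(self.start, genome_length + 1)
            yield from range(1, self.end + 1)

    def contains(self, pos: int, genome_length: int | None = None) -> bool:
        if not self.wraps:
            return self.start <= pos <= self.end
        return pos >= self.start or pos <= self.end

    def overlaps(self, other: "Interval", genome_length: int) -> bool:
        """True if the two intervals share at least one position on the circle."""
        mine = set(self.positions(genome_length))
        return any(p in mine for p in other.positions(genome_length))

    def __str__(self) -> str:  # "5649-6048"
        return f"{self.start}-{self.end}"


@dataclass
class CircularGenome:
    """A DNA sequence with an id and a circular/linear flag.

    The sequence is stored uppercase and restricted to the IUPAC DNA
    alphabet (ACGT plus ambiguity codes and N).
    """

    id: str
    seq: str
    circular: bool = False

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise FastaParseError(f"record {self.id!r}: empty sequence")
        for i, c in enumerate(self.seq, start=1):
            if c not in IUPAC_DNA:
                raise FastaParseError(
                    f"record {self.id!r}: non-IUPAC character {c!r} at position {i}"
                )

    @property
    def length(self) -> int:
        return len(self.seq)

    def validate_interval(self, iv: Interval) -> None:
        if iv.start > self.length or iv.end > self.length:
            raise CoordinateError(
                f"interval {iv} exceeds genome length {self.length}"
            )
        if iv.wraps and not self.circular:
            raise CoordinateError(
                f"wrapping interval {iv} on linear genome {self.id!r}"
            )


def read_fasta(path: str | Path) -> list[CircularGenome]:
    """Read a multi-record FASTA into genomes.

    A ``[circular]`` token anywhere in the header marks the record circular;
    records default to linear.  Sequences are uppercased.  Raises
    :class:`FastaParseError` on empty files or non-IUPAC characters, naming
    the offending record and position.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    genomes = []
    for rec in records:
        circular = CIRCULAR_TOKEN in rec.description
        genomes.append(CircularGenome(id=rec.id, seq=str(rec.seq), circular=circular))
    return genomes


def write_fasta(genomes: Iterable[CircularGenome], path: str | Path) -> None:
    """Write genomes as FASTA, 70 columns, marking circular records."""
    recs = []
    for g in genomes:
        desc = CIRCULAR_TOKEN if g.circular else ""
        recs.append(SeqRecord(Seq(g.seq), id=g.id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=70)
        writer.write_file(recs)


def genome_stats(genome: CircularGenome) -> dict[str, float]:
    """Length and AT/GC composition of a genome.

    Composition fractions are taken over unambiguous A/C/G/T positions only,
    so they remain well defined on partially ambiguous assemblies; length
    counts every position.
    """
    s = genome.seq
    counts = {b: s.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    if denom == 0:
        raise CompositionError(
            f"genome {genome.id!r}: no unambiguous bases, composition undefined"
        )
    at = (counts["A"] + counts["T"]) / denom
    return {"length": genome.length, "at_fraction": at, "gc_fraction": 1.0 - at}


def revcomp(seq: str) -> str:
    """Reverse complement of IUPAC DNA text (ambiguity codes included)."""
    for i, c in enumerate(seq.upper(), start=1):
        if c not in IUPAC_DNA:
            raise ValueError(f"non-IUPAC character {c!r} at position {i}")
    return str(Seq(seq.upper()).reverse_complement())


def subseq(genome: CircularGenome, iv: Interval) -> str:
    """Extract the interval's sequence; wrapping concatenates suffix+prefix."""
    genome.validate_interval(iv)
    if not iv.wraps:
        return genome.seq[iv.start - 1 : iv.end]
    return genome.seq[iv.start - 1 :] + genome.seq[: iv.end]
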