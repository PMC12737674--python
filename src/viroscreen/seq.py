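"""Nucleotide sequence model and FASTA/GFF3 I/O shared by every pipeline stage.

All coordinates in this package are 0-based half-open; minus-strand features
store forward-strand coordinates. Conversion to 1-based inclusive happens only
when writing GFF3. RNA input (viral genomes) is normalized to the DNA alphabet
on ingest; reports may render terminal motifs with U.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")
#: IUPAC ambiguity letters accepted on input and collapsed to N.
IUPAC_AMBIGUITY = frozenset("RYSWKMBDHV")


class SequenceError(ValueError):
    """Invalid sequence content or malformed sequence input."""


class FastaParseError(SequenceError):
    """Structurally malformed FASTA input."""


def normalize_sequence(raw: str, *, context: str = "sequence") -> str:
    """Uppercase, U->T, IUPAC ambiguity -> N; reject anything else.

    Raises :class:`SequenceError` for characters outside the accepted
    alphabet and for empty results.
    """
    out = []
    for ch in raw.strip().upper().replace("U", "T"):
        if ch in DNA_ALPHABET:
            out.append(ch)
        elif ch in IUPAC_AMBIGUITY:
            out.append("N")
        else:
            raise SequenceError(f"invalid character {ch!r} in {context}")
    if not out:
        raise SequenceError(f"empty sequence in {context}")
    return "".join(out)


@dataclass(frozen=True)
class Contig:
    """A nucleotide sequence with identity and provenance.

    ``sequence`` must already be normalized (uppercase, DNA alphabet, N for
    ambiguity); use :func:`read_fasta` or :func:`normalize_sequence` on input.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise SequenceError(f"contig id {self.id!r} is empty or contains whitespace")
        if not self.sequence:
            raise SequenceError(f"contig {self.id!r} has an empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise SequenceError(
                f"contig {self.id!r} contains non-normalized characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class Interval:
    """0-based half-open interval with strand; '-' features keep forward coords."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(sequence: str) -> str:
    """Watson-Crick reverse complement over {A,C,G,T,N}."""
    bad = set(sequence) - DNA_ALPHABET
    if bad:
        raise SequenceError(f"invalid character(s) {sorted(bad)} in sequence")
    # Seq.reverse_complement handles IUPAC too, but we restrict to the
    # normalized alphabet so downstream codon logic never sees ambiguity
    # beyond N.
    return str(Seq(sequence).reverse_complement())


def read_fasta(path: str | Path) -> list[Contig]:
    """Read a multi-record FASTA file into normalized :class:`Contig` objects.

    Order is preserved. Duplicate ids, empty records and files that do not
    start with a header line are rejected.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip() == "":
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: line {lineno}: expected FASTA header '>', got {line.strip()[:30]!r}"
                )
            break
        else:
            raise FastaParseError(f"{path}: no FASTA records found")

    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        seq = normalize_sequence(str(rec.seq), context=f"record {rec.id!r}")
        desc = rec.description[len(rec.id):].strip() if rec.description.startswith(rec.id) else rec.description
        contigs.append(Contig(id=rec.id, sequence=seq, description=desc))
    if not contigs:
        raise FastaParseError(f"{path}: no FASTA records found")
    return contigs


def write_fasta(contigs: Iterable[Contig], path: str | Path, width: int = 70) -> None:
    """Write contigs as wrapped FASTA, round-tripping id and sequence exactly."""
    records = [
        SeqRecord(Seq(c.sequence), id=c.id, description=c.description)
        for c in contigs
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


@dataclass(frozen=True)
class Gff3Record:
    seqid: str
    source: str
    ftype: str
    interval: Interval
    score: str = "."
    phase: str = "."
    attributes: Mapping[str, str] = field(default_factory=dict)

    def to_line(self) -> str:
        attrs = ";".join(f"{k}={v}" for k, v in self.attributes.items()) or "."
        return "\t".join(
            [
                self.seqid,
                self.source,
                self.ftype,
                str(self.interval.start + 1),  # GFF3 is 1-based inclusive
                str(self.interval.end),
                self.score,
                self.interval.strand,
                self.phase,
                attrs,
            ]
        )


def write_gff3(records: Sequence[Gff3Record], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in records:
            fh.write(rec.to_line() + "\n")
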