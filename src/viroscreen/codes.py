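"""Codon-table registry and six-frame ORF discovery under arbitrary NCBI tables.

The discriminating observation behind this package is that some mitochondrial
mobile elements (retroplasmids, mitoviruses, group II introns) only reveal a
long open reading frame when translated with the mold/protozoan mitochondrial
code (NCBI table 4, TGA=Trp) rather than the standard code (table 1,
TGA=stop). Everything here is therefore parameterized by the translation
table.

Conventions
-----------
* A *complete* ORF runs from a start codon (default {ATG}, configurable) to
  the next in-frame stop; its interval includes the stop codon and
  ``length_aa`` excludes it (matching the ``-m`` semantics of common ORF
  callers).
* ORFs truncated by the contig edge are reported as ``5prime_partial`` (edge
  to stop), ``3prime_partial`` (start codon to edge) or ``internal`` (no
  start, no stop in the frame).
* Per frame and stop codon, nested complete ORFs are collapsed to the longest
  (earliest start); set ``one_per_stop=False`` to emit every start.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio.Data import CodonTable

from .seq import Contig, Gff3Record, Interval, SequenceError, reverse_complement

STOP = "*"
BASES = "TCAG"
ALL_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)

COMPLETENESS_TAGS = ("complete", "5prime_partial", "3prime_partial", "internal")


class GeneticCodeError(ValueError):
    """Malformed or inconsistent codon-table definition."""


@dataclass(frozen=True)
class GeneticCode:
    """An NCBI-style translation table: 64 codons to amino acid or stop."""

    table_id: int
    codon_map: Mapping[str, str]
    start_codons: frozenset[str]

    def __post_init__(self) -> None:
        if set(self.codon_map) != set(ALL_CODONS):
            raise GeneticCodeError(
                f"table {self.table_id}: codon map must cover exactly the 64 codons"
            )
        if not self.start_codons:
            raise GeneticCodeError(f"table {self.table_id}: no start codons")
        for c in self.start_codons:
            if c not in self.codon_map:
                raise GeneticCodeError(f"table {self.table_id}: bad start codon {c!r}")

    @property
    def stop_codons(self) -> frozenset[str]:
        return frozenset(c for c, aa in self.codon_map.items() if aa == STOP)

    @classmethod
    def from_ncbi(
        cls, table_id: int, start_codons: Iterable[str] = ("ATG",)
    ) -> "GeneticCode":
        """Build from Biopython's NCBI codon-table registry.

        ``start_codons`` defaults to {ATG}: a reportable, strict definition of
        "complete"; NCBI's own (more permissive) start set is available via
        ``start_codons=None``.
        """
        try:
            table = CodonTable.unambiguous_dna_by_id[table_id]
        except KeyError as exc:
            raise GeneticCodeError(f"unknown NCBI translation table {table_id}") from exc
        codon_map = dict(table.forward_table)
        for stop in table.stop_codons:
            codon_map[stop] = STOP
        starts = table.start_codons if start_codons is None else start_codons
        return cls(
            table_id=table_id,
            codon_map=codon_map,
            start_codons=frozenset(s.upper().replace("U", "T") for s in starts),
        )


_REGISTRY: dict[tuple[int, frozenset[str]], GeneticCode] = {}


def get_code(table_id: int, start_codons: Iterable[str] = ("ATG",)) -> GeneticCode:
    """Cached accessor for NCBI tables (1 and 4 are the pipeline defaults)."""
    key = (table_id, frozenset(s.upper().replace("U", "T") for s in start_codons))
    if key not in _REGISTRY:
        _REGISTRY[key] = GeneticCode.from_ncbi(table_id, start_codons=key[1])
    return _REGISTRY[key]


def load_code_config(path: str | Path) -> dict[int, GeneticCode]:
    """Load extra codon tables from YAML keyed by NCBI table id.

    Format::

        11:
          codon_map: {TTT: F, ..., TGA: "*"}   # all 64 codons
          start_codons: [ATG, GTG]
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise GeneticCodeError(f"{path}: expected a mapping of table ids")
    codes: dict[int, GeneticCode] = {}
    for table_id, spec in raw.items():
        try:
            tid = int(table_id)
        except (TypeError, ValueError) as exc:
            raise GeneticCodeError(f"{path}: non-integer table id {table_id!r}") from exc
        codon_map = {
            str(c).upper().replace("U", "T"): str(a) for c, a in spec["codon_map"].items()
        }
        codes[tid] = GeneticCode(
            table_id=tid,
            codon_map=codon_map,
            start_codons=frozenset(
                str(s).upper().replace("U", "T") for s in spec.get("start_codons", ["ATG"])
            ),
        )
    return codes


def translate(
    sequence: str,
    code: GeneticCode,
    stop_policy: str = "truncate_at_stop",
) -> str:
    """Translate left to right; trailing 1-2 nt ignored; N-containing codons -> X.

    ``stop_policy`` is either ``truncate_at_stop`` (stop ends translation, not
    included in the output) or ``read_through_marked`` (stops rendered as '*'
    and translation continues).
    """
    if stop_policy not in ("truncate_at_stop", "read_through_marked"):
        raise ValueError(f"unknown stop_policy {stop_policy!r}")
    if len(sequence) < 3:
        raise SequenceError("sequence shorter than one codon")
    out = []
    for i in range(0, len(sequence) - len(sequence) % 3, 3):
        codon = sequence[i : i + 3]
        if "N" in codon:
            out.append("X")
            continue
        aa = code.codon_map[codon]
        if aa == STOP:
            if stop_policy == "truncate_at_stop":
                break
            out.append(STOP)
        else:
            out.append(aa)
    return "".join(out)


@dataclass(frozen=True)
class OrfRecord:
    """A located open reading frame under a specific genetic code."""

    contig_id: str
    interval: Interval
    code_table_id: int
    frame: int  # 0..2 on its own strand
    completeness: str
    protein: str
    length_aa: int

    @property
    def span_key(self) -> tuple[int, int, str]:
        """Coordinate identity used by the code-differential comparison."""
        return (self.interval.start, self.interval.end, self.interval.strand)


def _frame_codons(seq: str, frame: int) -> list[str]:
    usable = len(seq) - frame
    return [seq[frame + 3 * i : frame + 3 * i + 3] for i in range(usable // 3)]


def _scan_frame(
    codons: Sequence[str],
    code: GeneticCode,
    one_per_stop: bool,
) -> list[tuple[int, int, str]]:
    """Return (codon_start, codon_end_exclusive, completeness) for one frame.

    Codon spans for complete/5'-partial ORFs include the stop codon.
    """
    stops = [i for i, c in enumerate(codons) if code.codon_map.get(c) == STOP]
    is_start = [c in code.start_codons for c in codons]
    found: list[tuple[int, int, str]] = []

    prev = 0
    at_edge = True
    for s in stops:
        starts_here = [i for i in range(prev, s) if is_start[i]]
        if starts_here:
            if one_per_stop:
                starts_here = starts_here[:1]
            for a in starts_here:
                found.append((a, s + 1, "complete"))
        if at_edge and s > prev and not (starts_here and starts_here[0] == prev):
            # frame open at the 5' edge: edge-to-stop ORF, TransDecoder-style
            found.append((prev, s + 1, "5prime_partial"))
        prev = s + 1
        at_edge = False

    if prev < len(codons):
        tail_starts = [i for i in range(prev, len(codons)) if is_start[i]]
        if tail_starts:
            found.append((tail_starts[0], len(codons), "3prime_partial"))
        elif at_edge:
            found.append((0, len(codons), "internal"))
    return found


def find_orfs(
    contig: Contig,
    code: GeneticCode,
    min_len_aa: int = 100,
    strands: str = "both",
    completeness_filter: Iterable[str] | None = None,
    one_per_stop: bool = True,
) -> list[OrfRecord]:
    """Six-frame ORF scan under ``code``; see module docstring for conventions.

    ``strands`` is "both", "+" or "-"; ``completeness_filter`` restricts the
    reported completeness tags. Output is sorted by forward-strand position,
    then strand, then frame.
    """
    if min_len_aa < 1:
        raise ValueError("min_len_aa must be >= 1")
    wanted = set(COMPLETENESS_TAGS if completeness_filter is None else completeness_filter)
    bad_tags = wanted - set(COMPLETENESS_TAGS)
    if bad_tags:
        raise ValueError(f"unknown completeness tags {sorted(bad_tags)}")
    strand_list = {"both": ("+", "-"), "+": ("+",), "-": ("-",)}.get(strands)
    if strand_list is None:
        raise ValueError(f"strands must be 'both', '+' or '-', got {strands!r}")

    n = len(contig.sequence)
    records: list[OrfRecord] = []
    for strand in strand_list:
        seq = contig.sequence if strand == "+" else reverse_complement(contig.sequence)
        for frame in range(3):
            codons = _frame_codons(seq, frame)
            for cstart, cend, tag in _scan_frame(codons, code, one_per_stop):
                ends_at_stop = tag in ("complete", "5prime_partial")
                length_aa = (cend - cstart) - (1 if ends_at_stop else 0)
                if length_aa < min_len_aa or tag not in wanted:
                    continue
                coding = codons[cstart : cend - 1] if ends_at_stop else codons[cstart:cend]
                protein = "".join(
                    "X" if "N" in c else code.codon_map[c] for c in coding
                )
                s_nt = frame + 3 * cstart
                e_nt = frame + 3 * cend
                if strand == "+":
                    interval = Interval(s_nt, e_nt, "+")
                else:
                    interval = Interval(n - e_nt, n - s_nt, "-")
                records.append(
                    OrfRecord(
                        contig_id=contig.id,
                        interval=interval,
                        code_table_id=code.table_id,
                        frame=frame,
                        completeness=tag,
                        protein=protein,
                        length_aa=length_aa,
                    )
                )
    records.sort(
        key=lambda r: (r.interval.start, r.interval.end, r.interval.strand == "-", r.frame)
    )
    return records


def orfs_to_gff3(orfs: Iterable[OrfRecord]) -> list[Gff3Record]:
    """Render ORFs as GFF3 CDS records carrying table id and completeness."""
    out = []
    for i, orf in enumerate(orfs):
        out.append(
            Gff3Record(
                seqid=orf.contig_id,
                source="viroscreen",
                ftype="CDS",
                interval=orf.interval,
                phase="0",
                attributes={
                    "ID": f"orf{i:05d}",
                    "code_table": str(orf.code_table_id),
                    "completeness": orf.completeness,
                    "length_aa": str(orf.length_aa),
                },
            )
        )
    return out
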