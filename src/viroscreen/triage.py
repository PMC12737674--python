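"""Contig screening funnel: virus-keyword retention, follow-up categories,
host-like calls, and flags for host sequence misassembled at contig ends.

The pipeline consumes similarity-search results as tabular files (the
12-column BLAST/DIAMOND ``outfmt 6`` dialect, optionally extended with query
coverage, subject title and subject organism columns) rather than running a
search engine itself.

Screening precedence, applied once per contig:

1. best-hit title contains "virus" (case-insensitive, also inside words such
   as "mitovirus")            -> virus_candidate
2. no ORF of qualifying length under any configured translation table
                              -> followup_no_orf
3. ORFs exist but the contig has no hit at all
                              -> followup_unannotated_orf
4. best hit is not a host protein and identity < threshold (default 90% aa)
                              -> followup_divergent_hit
5. otherwise                  -> host_like
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

from .codes import OrfRecord
from .seq import Contig, Interval

UNKNOWN = "unknown"

#: Standard 12-column tabular dialect (BLAST/DIAMOND ``-outfmt 6``).
OUTFMT6 = (
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
)
#: Extended dialect with query coverage, subject title and organism label.
OUTFMT6_EXT = OUTFMT6 + ("qcovs", "stitle", "sorganism")

DIALECTS: dict[str, tuple[str, ...]] = {"outfmt6": OUTFMT6, "outfmt6_ext": OUTFMT6_EXT}

TRIAGE_CATEGORIES = (
    "virus_candidate",
    "followup_no_orf",
    "followup_unannotated_orf",
    "followup_divergent_hit",
    "host_like",
)


class HitTableError(ValueError):
    """Malformed similarity-search table."""


@dataclass(frozen=True)
class HitRecord:
    """One row of a sequence-similarity search result (outfmt-6-like)."""

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    query_start: int  # 1-based inclusive, as in BLAST tabular
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bitscore: float
    query_coverage: float | None = None
    subject_title: str = UNKNOWN
    subject_organism_label: str = UNKNOWN

    def __post_init__(self) -> None:
        if not (0.0 <= self.percent_identity <= 100.0):
            raise HitTableError(
                f"percent identity {self.percent_identity} outside [0, 100]"
            )
        if self.evalue < 0:
            raise HitTableError(f"negative evalue {self.evalue}")
        # normalize reversed query coordinates (minus-strand nucleotide hits)
        if self.query_start > self.query_end:
            lo, hi = self.query_end, self.query_start
            object.__setattr__(self, "query_start", lo)
            object.__setattr__(self, "query_end", hi)


def _resolve_dialect(dialect: str | Sequence[str]) -> tuple[str, ...]:
    if isinstance(dialect, str):
        try:
            return DIALECTS[dialect]
        except KeyError as exc:
            raise HitTableError(
                f"unknown dialect {dialect!r}; declare column order explicitly"
            ) from exc
    cols = tuple(dialect)
    missing = set(OUTFMT6) - set(cols)
    if missing:
        raise HitTableError(f"dialect missing required columns {sorted(missing)}")
    return cols


def read_hit_table(path: str | Path, dialect: str | Sequence[str] = "outfmt6") -> list[HitRecord]:
    """Parse a tabular hit file under a declared column dialect.

    Missing optional columns are filled with the sentinel ``unknown`` (text)
    or ``None`` (query coverage). Rows with the wrong column count or
    non-numeric numeric fields raise :class:`HitTableError` naming the row.
    """
    cols = _resolve_dialect(dialect)
    hits: list[HitRecord] = []
    with open(path, newline="") as fh:
        for rowno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if row[0].startswith("#"):
                continue
            if len(row) != len(cols):
                raise HitTableError(
                    f"{path}: row {rowno}: expected {len(cols)} columns, got {len(row)}"
                )
            rec = dict(zip(cols, row))

            def num(key: str, cast, *, row_no=rowno):
                try:
                    return cast(rec[key])
                except ValueError as exc:
                    raise HitTableError(
                        f"{path}: row {row_no}: non-numeric {key} {rec[key]!r}"
                    ) from exc

            qcovs = rec.get("qcovs")
            hits.append(
                HitRecord(
                    query_id=rec["qseqid"],
                    subject_id=rec["sseqid"],
                    percent_identity=num("pident", float),
                    alignment_length=int(num("length", float)),
                    query_start=int(num("qstart", float)),
                    query_end=int(num("qend", float)),
                    subject_start=int(num("sstart", float)),
                    subject_end=int(num("send", float)),
                    evalue=num("evalue", float),
                    bitscore=num("bitscore", float),
                    query_coverage=None if qcovs in (None, "", UNKNOWN) else num("qcovs", float),
                    subject_title=rec.get("stitle", UNKNOWN) or UNKNOWN,
                    subject_organism_label=rec.get("sorganism", UNKNOWN) or UNKNOWN,
                )
            )
    return hits


def write_hit_table(
    hits: Iterable[HitRecord], path: str | Path, dialect: str | Sequence[str] = "outfmt6_ext"
) -> None:
    cols = _resolve_dialect(dialect)
    getters = {
        "qseqid": lambda h: h.query_id,
        "sseqid": lambda h: h.subject_id,
        "pident": lambda h: f"{h.percent_identity:.1f}",
        "length": lambda h: str(h.alignment_length),
        "mismatch": lambda h: "0",
        "gapopen": lambda h: "0",
        "qstart": lambda h: str(h.query_start),
        "qend": lambda h: str(h.query_end),
        "sstart": lambda h: str(h.subject_start),
        "send": lambda h: str(h.subject_end),
        "evalue": lambda h: f"{h.evalue:.2e}",
        "bitscore": lambda h: f"{h.bitscore:.1f}",
        "qcovs": lambda h: UNKNOWN if h.query_coverage is None else f"{h.query_coverage:.1f}",
        "stitle": lambda h: h.subject_title,
        "sorganism": lambda h: h.subject_organism_label,
    }
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join(getters[c](h) for c in cols) + "\n")


def best_hit_per_query(hits: Iterable[HitRecord]) -> dict[str, HitRecord]:
    """Best hit = lowest evalue; ties by bitscore desc, identity desc, subject id asc."""
    best: dict[str, HitRecord] = {}

    def rank(h: HitRecord):
        return (h.evalue, -h.bitscore, -h.percent_identity, h.subject_id)

    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or rank(h) < rank(cur):
            best[h.query_id] = h
    return best


@dataclass(frozen=True)
class TriageDecision:
    contig_id: str
    category: str
    end_contamination: str = "none"
    rationale: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.category not in TRIAGE_CATEGORIES:
            raise ValueError(f"unknown triage category {self.category!r}")


def _is_host(organism: str, host_label: str, related: Sequence[str]) -> bool:
    return organism == host_label or organism in related


def triage_contigs(
    contigs: Sequence[Contig],
    orfs_by_code: Mapping[int, Sequence[OrfRecord]],
    best_hits: Mapping[str, HitRecord],
    host_label: str = "Botrytis cinerea",
    identity_threshold: float = 90.0,
    related_host_labels: Sequence[str] = (),
) -> list[TriageDecision]:
    """Assign each contig exactly one screening category (precedence above).

    ``orfs_by_code`` holds already length-filtered ORFs per translation table
    (at minimum the nuclear and mitochondrial defaults).
    """
    contig_ids = {c.id for c in contigs}
    stray = set(best_hits) - contig_ids
    if stray:
        raise ValueError(
            f"hit table references contigs absent from the contig set: {sorted(stray)[:5]}"
        )
    has_orf: set[str] = set()
    for orfs in orfs_by_code.values():
        has_orf.update(o.contig_id for o in orfs)

    decisions = []
    for contig in contigs:
        hit = best_hits.get(contig.id)
        if hit is not None and "virus" in hit.subject_title.lower():
            decisions.append(
                TriageDecision(
                    contig.id,
                    "virus_candidate",
                    rationale=(f"best hit titled {hit.subject_title!r}",),
                )
            )
        elif contig.id not in has_orf:
            decisions.append(
                TriageDecision(
                    contig.id,
                    "followup_no_orf",
                    rationale=("no qualifying ORF under any configured table",),
                )
            )
        elif hit is None:
            decisions.append(
                TriageDecision(
                    contig.id,
                    "followup_unannotated_orf",
                    rationale=("ORFs present but no similarity hit",),
                )
            )
        elif (
            not _is_host(hit.subject_organism_label, host_label, related_host_labels)
            and hit.percent_identity < identity_threshold
        ):
            decisions.append(
                TriageDecision(
                    contig.id,
                    "followup_divergent_hit",
                    rationale=(
                        f"best hit {hit.subject_organism_label!r} at "
                        f"{hit.percent_identity:.1f}% identity (< {identity_threshold:g}%)",
                    ),
                )
            )
        else:
            decisions.append(
                TriageDecision(
                    contig.id,
                    "host_like",
                    rationale=(
                        f"best hit {hit.subject_organism_label!r} at "
                        f"{hit.percent_identity:.1f}% identity",
                    ),
                )
            )
    return decisions


class EndFlag(NamedTuple):
    """End-contamination call with the flagged windows (for trimming)."""

    call: str  # none | left | right | both
    left: Interval | None
    right: Interval | None


def flag_end_contamination(
    contig: Contig,
    hits: Iterable[HitRecord],
    host_label: str = "Botrytis cinerea",
    related_host_labels: Sequence[str] = (),
    end_window_frac: float = 0.2,
    host_identity_min: float = 90.0,
    min_window_cover: float = 0.5,
) -> EndFlag:
    """Flag terminal host sequence misassembled onto a contig end.

    An end is flagged when a nucleotide-level host hit with identity >=
    ``host_identity_min`` covers at least ``min_window_cover`` of the terminal
    window (``end_window_frac`` x contig length) without extending past the
    contig midpoint; whole-contig host hits are the triage stage's business,
    not a trimming case.
    """
    n = contig.length
    w = max(1, int(round(end_window_frac * n)))
    mid = n / 2.0
    left_hit = right_hit = None
    for h in hits:
        if h.query_id != contig.id:
            continue
        if not _is_host(h.subject_organism_label, host_label, related_host_labels):
            continue
        if h.percent_identity < host_identity_min:
            continue
        q0, q1 = h.query_start - 1, h.query_end  # to 0-based half-open
        left_overlap = max(0, min(q1, w) - q0)
        if left_overlap >= min_window_cover * w and q1 <= mid:
            s = Interval(q0, q1, "+")
            left_hit = s if left_hit is None else Interval(
                min(left_hit.start, s.start), max(left_hit.end, s.end), "+"
            )
        right_overlap = max(0, q1 - max(q0, n - w))
        if right_overlap >= min_window_cover * w and q0 >= mid:
            s = Interval(q0, q1, "+")
            right_hit = s if right_hit is None else Interval(
                min(right_hit.start, s.start), max(right_hit.end, s.end), "+"
            )
    if left_hit and right_hit:
        call = "both"
    elif left_hit:
        call = "left"
    elif right_hit:
        call = "right"
    else:
        call = "none"
    return EndFlag(call, left_hit, right_hit)
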