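"""Domain-architecture classification of mitochondrially coded proteins.

A configurable PROSITE-style pattern matcher stands in for external
domain-search services: patterns are configuration, not hard-coded biology.
The default configuration ships a reverse-transcriptase core (the canonical
Y-x-D-D catalytic box, generalized), a group-II-intron maturase placeholder,
an HNH endonuclease placeholder and an RdRP G-D-D placeholder; the synthetic
generator embeds exactly the configured patterns, so pipeline tests are
self-consistent without claiming profile-HMM fidelity.

Architecture rules (in precedence):

* reverse transcriptase + (maturase or HNH endonuclease) -> group II intron
* reverse transcriptase alone, single-ORF element        -> retroplasmid
* RdRP core                                              -> mitovirus-like
* anything else                                          -> unknown mitochondrial element
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

from .coding import CodingSystemCall

AA_LETTERS = "ACDEFGHIKLMNPQRSTVWYX"

#: Canonical role names used by the classification rules.
RVT = "RVT_1"
MATURASE = "Intron_maturas2"
HNH = "AI2M_like_HNH"
RDRP = "RdRP_core"

ELEMENT_CLASSES = (
    "retroplasmid",
    "group_II_intron",
    "mitovirus_like",
    "unknown_mito_element",
    "not_applicable",
)


class MotifConfigError(ValueError):
    """Malformed motif pattern or motif configuration file."""


# One PROSITE-style element: fixed residue, [class], {negated class}, or gap.
_ELEMENT_RE = re.compile(
    r"^(?:(?P<res>[A-Z])|\[(?P<cls>[A-Z]+)\]|\{(?P<neg>[A-Z]+)\}|"
    r"x(?:\((?P<lo>\d+)(?:,(?P<hi>\d+))?\))?)$"
)


def parse_pattern(pattern: str) -> list[tuple[str, object]]:
    """Parse 'Y-[AIV]-D-D' / 'H-x(2,5)-H' style patterns into elements.

    Returns tuples of (kind, payload) with kind in {res, cls, neg, gap};
    gap payload is (lo, hi). Unbounded gaps are rejected.
    """
    if not pattern or not pattern.strip():
        raise MotifConfigError("empty motif pattern")
    elements: list[tuple[str, object]] = []
    for token in pattern.strip().split("-"):
        m = _ELEMENT_RE.match(token)
        if m is None:
            raise MotifConfigError(f"malformed pattern element {token!r} in {pattern!r}")
        if m.group("res"):
            elements.append(("res", m.group("res")))
        elif m.group("cls"):
            elements.append(("cls", m.group("cls")))
        elif m.group("neg"):
            elements.append(("neg", m.group("neg")))
        else:
            lo = int(m.group("lo")) if m.group("lo") else 1
            hi = int(m.group("hi")) if m.group("hi") else lo
            if hi < lo:
                raise MotifConfigError(f"gap bounds reversed in {token!r}")
            elements.append(("gap", (lo, hi)))
    return elements


def compile_pattern(pattern: str) -> re.Pattern[str]:
    parts = []
    for kind, payload in parse_pattern(pattern):
        if kind == "res":
            parts.append(re.escape(payload))
        elif kind == "cls":
            parts.append(f"[{payload}]")
        elif kind == "neg":
            parts.append(f"[^{payload}]")
        else:
            lo, hi = payload
            parts.append(f".{{{lo},{hi}}}" if hi != lo else f".{{{lo}}}")
    return re.compile("".join(parts))


@dataclass(frozen=True)
class MotifDefinition:
    """A degenerate protein pattern with the match count needed to call it."""

    name: str
    pattern: str
    min_score: int = 1

    def __post_init__(self) -> None:
        if self.min_score < 1:
            raise MotifConfigError(f"motif {self.name!r}: min_score must be >= 1")
        compile_pattern(self.pattern)  # validate at load time

    @property
    def regex(self) -> re.Pattern[str]:
        return compile_pattern(self.pattern)

    @property
    def elements(self) -> list[tuple[str, object]]:
        return parse_pattern(self.pattern)


def default_motifs() -> list[MotifDefinition]:
    """Shipped pattern set; see module docstring for what these stand for."""
    return [
        MotifDefinition(RVT, "[YF]-[AGSTV]-D-D"),
        MotifDefinition(MATURASE, "L-[AG]-x(2,4)-P-Q-G"),
        MotifDefinition(HNH, "H-N-H-x(2,5)-H"),
        MotifDefinition(RDRP, "[SG]-D-D"),
    ]


def load_motif_config(path: str | Path) -> list[MotifDefinition]:
    """Load motifs from a YAML/JSON list of {name, pattern, min_score}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, list):
        raise MotifConfigError(f"{path}: expected a list of motif definitions")
    motifs = []
    for i, item in enumerate(raw):
        try:
            motifs.append(
                MotifDefinition(
                    name=str(item["name"]),
                    pattern=str(item["pattern"]),
                    min_score=int(item.get("min_score", 1)),
                )
            )
        except (KeyError, TypeError) as exc:
            raise MotifConfigError(f"{path}: entry {i}: {exc}") from exc
    return motifs


@dataclass(frozen=True)
class DomainAnnotation:
    protein_id: str
    motif_name: str
    position: int  # aa offset of the match
    matched_span: str


def scan_motifs(
    protein: str,
    motifs: Sequence[MotifDefinition],
    protein_id: str = "",
) -> list[DomainAnnotation]:
    """All non-overlapping leftmost matches of each pattern, in motif order."""
    annotations = []
    for motif in motifs:
        for m in motif.regex.finditer(protein):
            annotations.append(
                DomainAnnotation(
                    protein_id=protein_id,
                    motif_name=motif.name,
                    position=m.start(),
                    matched_span=m.group(0),
                )
            )
    return annotations


def motif_presence(
    annotations: Iterable[DomainAnnotation],
    motifs: Sequence[MotifDefinition] | None = None,
) -> set[str]:
    """Motif names whose match count reaches the motif's ``min_score``."""
    counts: dict[str, int] = {}
    for a in annotations:
        counts[a.motif_name] = counts.get(a.motif_name, 0) + 1
    if motifs is None:
        return {name for name, n in counts.items() if n >= 1}
    return {m.name for m in motifs if counts.get(m.name, 0) >= m.min_score}


@dataclass(frozen=True)
class ElementCall:
    """Classified identity of a mitochondrially coded contig, with evidence."""

    contig_id: str
    element_class: str
    evidence: tuple[DomainAnnotation, ...] = ()
    coding_call: CodingSystemCall | None = None

    def __post_init__(self) -> None:
        if self.element_class not in ELEMENT_CLASSES:
            raise ValueError(f"unknown element class {self.element_class!r}")


def classify_element(
    coding_call: CodingSystemCall,
    annotations: Sequence[DomainAnnotation],
    motifs: Sequence[MotifDefinition] | None = None,
) -> ElementCall:
    """Apply the domain-architecture precedence rules (module docstring).

    Contigs that are not mitochondrially coded pass through as
    ``not_applicable``; the retroplasmid call additionally requires the
    single-ORF property, a defining feature of these elements.
    """
    if coding_call.call != "mitochondrial_coding":
        return ElementCall(coding_call.contig_id, "not_applicable", coding_call=coding_call)
    present = motif_presence(annotations, motifs)
    if RVT in present and (MATURASE in present or HNH in present):
        cls = "group_II_intron"
    elif RVT in present and coding_call.single_orf:
        cls = "retroplasmid"
    elif RDRP in present:
        cls = "mitovirus_like"
    else:
        cls = "unknown_mito_element"
    return ElementCall(
        contig_id=coding_call.contig_id,
        element_class=cls,
        evidence=tuple(annotations),
        coding_call=coding_call,
    )
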