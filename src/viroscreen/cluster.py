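"""Redundancy removal at identity/coverage thresholds via pairwise alignment
and CD-HIT-style greedy clustering.

Identity is computed over aligned columns excluding terminal overhangs (free
end gaps); coverage over the shorter sequence, so a fragment of a longer
element is redundant with it — the point of the dedup. Defaults mirror the
>=95% identity / >=95% coverage thresholds used to collapse whole-genome
shotgun hits into distinct elements.

Scoring: match +1, mismatch -1; a gap of length k costs open + (k-1)*extend
with defaults -2/-1. Dynamic programming is delegated to
``Bio.Align.PairwiseAligner``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from Bio import Align

from .seq import Contig

NT_ALPHABET = frozenset("ACGTUN")


class AlignmentError(ValueError):
    """Incompatible or empty alignment inputs."""


def _looks_nt(seq: str) -> bool:
    return bool(seq) and set(seq) <= NT_ALPHABET


def make_aligner(
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
    mode: str = "global_overlap",
) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_internal_gap_score = gap_open
    aligner.extend_internal_gap_score = gap_extend
    if mode == "global_overlap":
        aligner.mode = "global"
        aligner.open_end_gap_score = 0.0
        aligner.extend_end_gap_score = 0.0
    elif mode == "local":
        aligner.mode = "local"
        aligner.open_end_gap_score = gap_open
        aligner.extend_end_gap_score = gap_extend
    else:
        raise ValueError(f"mode must be 'global_overlap' or 'local', got {mode!r}")
    return aligner


@dataclass(frozen=True)
class PairwiseStats:
    id_a: str
    id_b: str
    identity: float  # percent over aligned columns, terminal overhangs excluded
    coverage: float  # percent of the shorter sequence spanned by the alignment
    alignment_length: int
    score: float


def pairwise_stats(
    seq_a: str | Contig,
    seq_b: str | Contig,
    mode: str = "global_overlap",
    id_a: str = "a",
    id_b: str = "b",
    **scoring: float,
) -> PairwiseStats:
    """Align two same-alphabet sequences and report identity/coverage.

    Inputs are canonically ordered (longer first) before aligning so the
    statistics are symmetric in (a, b) even when co-optimal alignments exist.
    """
    if isinstance(seq_a, Contig):
        id_a, seq_a = seq_a.id, seq_a.sequence
    if isinstance(seq_b, Contig):
        id_b, seq_b = seq_b.id, seq_b.sequence
    if not seq_a or not seq_b:
        raise AlignmentError("empty sequence")
    if _looks_nt(seq_a) != _looks_nt(seq_b):
        raise AlignmentError("mixed nucleotide/protein alphabets")

    x, y = (seq_a, seq_b)
    if (len(y), y) > (len(x), x):  # canonical order: longer (then lexicographic max) first
        x, y = y, x
    aligner = make_aligner(mode=mode, **scoring)
    alignment = aligner.align(x, y)[0]

    blocks_x, blocks_y = alignment.aligned
    if len(blocks_x) == 0:
        return PairwiseStats(id_a, id_b, 0.0, 0.0, 0, alignment.score)
    matches = 0
    columns = 0
    prev = None
    for (xs, xe), (ys, ye) in zip(blocks_x, blocks_y):
        for cx, cy in zip(x[xs:xe], y[ys:ye]):
            matches += cx == cy
        columns += xe - xs
        if prev is not None:
            columns += (xs - prev[0]) + (ys - prev[1])  # internal gap columns
        prev = (xe, ye)
    shorter = y if len(y) <= len(x) else x
    if shorter is y:
        span = blocks_y[-1][1] - blocks_y[0][0]
    else:
        span = blocks_x[-1][1] - blocks_x[0][0]
    return PairwiseStats(
        id_a=id_a,
        id_b=id_b,
        identity=100.0 * matches / columns,
        coverage=100.0 * span / len(shorter),
        alignment_length=columns,
        score=alignment.score,
    )


@dataclass(frozen=True)
class ClusterResult:
    representatives: tuple[str, ...]
    membership: Mapping[str, str]  # member id -> representative id


def greedy_cluster(
    sequences: Mapping[str, str] | Sequence[Contig],
    min_identity: float = 95.0,
    min_coverage: float = 95.0,
    mode: str = "global_overlap",
    **scoring: float,
) -> ClusterResult:
    """Greedy longest-first clustering (CD-HIT style).

    Sequences are visited by descending length (ties by id); each joins the
    first existing representative reaching both thresholds, else founds a new
    cluster. Deterministic and order-stable.
    """
    if isinstance(sequences, Mapping):
        items = dict(sequences)
    else:
        items = {c.id: c.sequence for c in sequences}
    if not items:
        raise AlignmentError("no sequences to cluster")

    order = sorted(items, key=lambda i: (-len(items[i]), i))
    reps: list[str] = []
    membership: dict[str, str] = {}
    for sid in order:
        assigned = None
        for rep in reps:
            st = pairwise_stats(items[rep], items[sid], mode=mode, id_a=rep, id_b=sid, **scoring)
            if st.identity >= min_identity and st.coverage >= min_coverage:
                assigned = rep
                break
        if assigned is None:
            reps.append(sid)
            membership[sid] = sid
        else:
            membership[sid] = assigned
    return ClusterResult(representatives=tuple(reps), membership=membership)
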