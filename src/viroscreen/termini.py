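"""Conserved 5'/3' terminal sequences shared by the segments of a
multi-segment virus.

Partitivirus genome segments share short terminal motifs; this module
recovers the longest terminal consensus common to all segments of a declared
group. By default the consensus is strict (zero mismatches), matching the
exact shared termini seen in segment alignments; a per-segment substitution
budget is exposed for noisy termini, in which case a column-majority
candidate is tested. A length cap prevents a degenerate whole-sequence
"consensus" for identical inputs.

Results are rendered in the RNA alphabet (U) for reports, stored as DNA
internally like every other sequence in the package.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence

from .seq import Contig

_BASE_ORDER = "ACGTN"


class TerminiError(ValueError):
    """Invalid segment group."""


@dataclass(frozen=True)
class TerminalConsensus:
    virus_id: str
    five_prime: str  # RNA alphabet
    three_prime: str
    n_segments: int
    max_mismatch_used: int


def _majority_column(chars: Sequence[str]) -> str:
    counts = Counter(chars)
    return max(counts, key=lambda b: (counts[b], -_BASE_ORDER.find(b)))


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _longest_terminal(
    windows_by_len: "callable", cap: int, min_len: int, max_mismatch: int
) -> str:
    for length in range(cap, min_len - 1, -1):
        windows = windows_by_len(length)
        candidate = "".join(_majority_column(col) for col in zip(*windows))
        if all(_hamming(w, candidate) <= max_mismatch for w in windows):
            return candidate
    return ""


def conserved_termini(
    segments: Sequence[Contig | str],
    virus_id: str = "",
    max_mismatch: int = 0,
    min_len: int = 3,
    max_len: int = 30,
) -> TerminalConsensus:
    """Longest shared prefix/suffix across >=2 segments, within the mismatch
    budget; empty string when nothing of ``min_len`` qualifies.

    Invariant to segment order; at ``max_mismatch=0`` the result is exactly
    the longest common prefix/suffix (capped at ``max_len``).
    """
    if len(segments) < 2:
        raise TerminiError("need at least 2 segments to derive conserved termini")
    seqs = [s.sequence if isinstance(s, Contig) else str(s) for s in segments]
    cap = min(max_len, min(len(s) for s in seqs))

    five = _longest_terminal(
        lambda L: [s[:L] for s in seqs], cap, min_len, max_mismatch
    )
    three = _longest_terminal(
        lambda L: [s[-L:] for s in seqs], cap, min_len, max_mismatch
    )
    return TerminalConsensus(
        virus_id=virus_id,
        five_prime=five.replace("T", "U"),
        three_prime=three.replace("T", "U"),
        n_segments=len(segments),
        max_mismatch_used=max_mismatch,
    )
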