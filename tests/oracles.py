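"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results by a different route than the package:
the ORF enumerator tests every start position per frame and strand, and the
alignment oracle is a from-scratch Gotoh dynamic program. They share only the
public data types.
"""

from __future__ import annotations

from viroscreen import Contig, GeneticCode, Interval, OrfRecord
from viroscreen.seq import reverse_complement


def _translate_codons(codons, code):
    return "".join("X" if "N" in c else code.codon_map[c] for c in codons)


def brute_force_orfs(
    contig: Contig,
    code: GeneticCode,
    min_len_aa: int = 100,
) -> list[OrfRecord]:
    """Enumerate ORFs start-position by start-position (one per stop per frame,
    earliest start kept; edge-open frames reported as partials)."""
    n = len(contig.sequence)
    out: list[OrfRecord] = []
    for strand in "+-":
        seq = contig.sequence if strand == "+" else reverse_complement(contig.sequence)
        for frame in range(3):
            ncod = (n - frame) // 3
            codons = [seq[frame + 3 * i : frame + 3 * i + 3] for i in range(ncod)]

            def is_stop(i):
                return "N" not in codons[i] and code.codon_map[codons[i]] == "*"

            def is_start(i):
                return codons[i] in code.start_codons

            stop_idx = [i for i in range(ncod) if is_stop(i)]

            def emit(cs, ce, tag):
                ends_at_stop = tag in ("complete", "5prime_partial")
                length_aa = (ce - cs) - (1 if ends_at_stop else 0)
                if length_aa < min_len_aa:
                    return
                body = codons[cs : ce - 1] if ends_at_stop else codons[cs:ce]
                s_nt, e_nt = frame + 3 * cs, frame + 3 * ce
                interval = (
                    Interval(s_nt, e_nt, "+")
                    if strand == "+"
                    else Interval(n - e_nt, n - s_nt, "-")
                )
                out.append(
                    OrfRecord(
                        contig_id=contig.id,
                        interval=interval,
                        code_table_id=code.table_id,
                        frame=frame,
                        completeness=tag,
                        protein=_translate_codons(body, code),
                        length_aa=length_aa,
                    )
                )

            # complete ORFs and the 3'-partial tail, one per start position
            for i in range(ncod):
                if not is_start(i):
                    continue
                prev_stop = max((s for s in stop_idx if s < i), default=-1)
                if any(is_start(k) for k in range(prev_stop + 1, i)):
                    continue  # an earlier start shares this stop: collapsed
                next_stop = next((s for s in stop_idx if s >= i), None)
                if next_stop is None:
                    emit(i, ncod, "3prime_partial")
                else:
                    emit(i, next_stop + 1, "complete")
            # edge-open 5' region
            if stop_idx:
                j0 = stop_idx[0]
                if j0 > 0 and not is_start(0):
                    emit(0, j0 + 1, "5prime_partial")
            elif ncod > 0 and not any(is_start(i) for i in range(ncod)):
                emit(0, ncod, "internal")
    out.sort(
        key=lambda r: (r.interval.start, r.interval.end, r.interval.strand == "-", r.frame)
    )
    return out


def gotoh_overlap_score(
    a: str,
    b: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap_open: float = -2.0,
    gap_extend: float = -1.0,
) -> float:
    """Optimal overlap-alignment score: affine internal gaps (a gap of length
    k costs open + (k-1)*extend), terminal gaps free."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0  # free leading gap
    for j in range(1, m + 1):
        Y[0][j] = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] + gap_open, X[i - 1][j] + gap_extend,
                          Y[i - 1][j] + gap_open)
            Y[i][j] = max(M[i][j - 1] + gap_open, Y[i][j - 1] + gap_extend,
                          X[i][j - 1] + gap_open)
    best = 0.0  # empty alignment: all-gap, terminal gaps free
    for i in range(n + 1):
        best = max(best, M[i][m], X[i][m], Y[i][m])
    for j in range(m + 1):
        best = max(best, M[n][j], X[n][j], Y[n][j])
    return best
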