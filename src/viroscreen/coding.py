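"""Code-differential signature: call a contig mitochondrially coded when long
complete ORFs exist only under the mitochondrial translation table.

Because the mitochondrial table's stop set (TAA, TAG) is a strict subset of
the standard table's (TAA, TAG, TGA), every nuclear ORF also appears under
table 4. "Mito-specific" evidence therefore requires a table-4 ORF that is
*not* reproduced at identical coordinates under table 1; without this rule
every nuclear transcript would trivially count as mitochondrially coded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from .codes import GeneticCode, OrfRecord, find_orfs, get_code
from .seq import Contig

CODING_CALLS = ("nuclear_coding", "mitochondrial_coding", "dual_coding", "noncoding")


@dataclass(frozen=True)
class CodingSystemCall:
    contig_id: str
    call: str
    n_orfs_table1: int
    n_orfs_table4: int
    single_orf: bool | None  # exactly one qualifying ORF under the calling table
    longest_aa_table1: int
    longest_aa_table4: int

    def __post_init__(self) -> None:
        if self.call not in CODING_CALLS:
            raise ValueError(f"unknown coding call {self.call!r}")


def classify_coding_system(
    contig: Contig,
    min_len_aa: int = 100,
    nuclear_table: int = 1,
    mito_table: int = 4,
    require_complete: bool = True,
    start_codons: Iterable[str] = ("ATG",),
) -> CodingSystemCall:
    """Count qualifying ORFs under both tables and call the coding system.

    Qualifying = complete (unless ``require_complete`` is off, when edge
    partials also count) and at least ``min_len_aa`` amino acids.
    """
    completeness = ("complete",) if require_complete else None
    nuc = find_orfs(
        contig, get_code(nuclear_table, start_codons), min_len_aa,
        completeness_filter=completeness,
    )
    mito = find_orfs(
        contig, get_code(mito_table, start_codons), min_len_aa,
        completeness_filter=completeness,
    )
    nuc_spans = {o.span_key for o in nuc}
    mito_specific = [o for o in mito if o.span_key not in nuc_spans]

    n1, n4 = len(nuc), len(mito)
    if n1 == 0 and n4 == 0:
        call, single = "noncoding", None
    elif n1 > 0 and not mito_specific:
        call, single = "nuclear_coding", n1 == 1
    elif n1 == 0:
        call, single = "mitochondrial_coding", n4 == 1
    else:
        call, single = "dual_coding", None

    return CodingSystemCall(
        contig_id=contig.id,
        call=call,
        n_orfs_table1=n1,
        n_orfs_table4=n4,
        single_orf=single,
        longest_aa_table1=max((o.length_aa for o in nuc), default=0),
        longest_aa_table4=max((o.length_aa for o in mito), default=0),
    )


def calling_table_orfs(
    contig: Contig,
    call: CodingSystemCall,
    min_len_aa: int = 100,
    nuclear_table: int = 1,
    mito_table: int = 4,
    require_complete: bool = True,
    start_codons: Iterable[str] = ("ATG",),
) -> list[OrfRecord]:
    """ORFs under the table that produced the call (mito preferred for dual)."""
    if call.call == "noncoding":
        return []
    table = nuclear_table if call.call == "nuclear_coding" else mito_table
    completeness = ("complete",) if require_complete else None
    return find_orfs(
        contig, get_code(table, start_codons), min_len_aa,
        completeness_filter=completeness,
    )
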