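import numpy as np
import pytest

from viroscreen import Contig, GeneticCodeError, find_orfs, get_code, translate
from viroscreen.codes import ALL_CODONS, GeneticCode

from .conftest import random_contig_seq
from .oracles import brute_force_orfs

T1 = get_code(1)
T4 = get_code(4)


class TestGeneticCode:
    def test_table_1_vs_4_tga(self):
        assert T1.codon_map["TGA"] == "*"
        assert T4.codon_map["TGA"] == "W"
        assert T4.stop_codons < T1.stop_codons  # strict subset

    def test_covers_all_64_codons(self):
        assert set(T1.codon_map) == set(ALL_CODONS)

    def test_incomplete_table_rejected(self):
        partial = {c: "A" for c in ALL_CODONS[:-1]}
        with pytest.raises(GeneticCodeError):
            GeneticCode(99, partial, frozenset({"ATG"}))

    def test_unknown_table_rejected(self):
        with pytest.raises(GeneticCodeError):
            get_code(999)


class TestTranslate:
    @pytest.mark.parametrize(
        "seq,code,policy,expected",
        [
            ("ATGAAATGA", T1, "truncate_at_stop", "MK"),
            ("ATGAAATGA", T4, "truncate_at_stop", "MKW"),
            ("ATGNNA", T1, "read_through_marked", "MX"),
            ("ATGTAAAAA", T1, "read_through_marked", "M*K"),
            ("ATGAA", T1, "truncate_at_stop", "M"),  # trailing nt ignored
        ],
    )
    def test_examples(self, seq, code, policy, expected):
        assert translate(seq, code, policy) == expected

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            translate("AT", T1)


FORCED = Contig("forced", "ATG" + "GCA" * 300 + "TGA" + "GCA" * 300 + "TAA")


class TestFindOrfs:
    def test_codon_table_forcing(self):
        """An internal in-frame TGA truncates the standard-code ORF; the
        mitochondrial code reads through it as Trp."""
        o1 = [o for o in find_orfs(FORCED, T1, 100) if o.completeness == "complete"]
        o4 = [o for o in find_orfs(FORCED, T4, 100) if o.completeness == "complete"]
        assert max(o.length_aa for o in o1) == 301
        assert max(o.length_aa for o in o4) == 602
        best1 = max(o1, key=lambda o: o.length_aa)
        best4 = max(o4, key=lambda o: o.length_aa)
        # table-1 ORF ends at the TGA; table-4 ORF at the final TAA
        assert FORCED.sequence[best1.interval.end - 3 : best1.interval.end] == "TGA"
        assert FORCED.sequence[best4.interval.end - 3 : best4.interval.end] == "TAA"
        assert best4.protein == "M" + "A" * 300 + "W" + "A" * 300

    def test_short_contig_yields_nothing(self):
        rng = np.random.default_rng(0)
        contig = Contig("short", random_contig_seq(rng, 50))
        assert find_orfs(contig, T4, 100) == []

    def test_no_stop_in_protein_and_stop_follows_complete(self):
        rng = np.random.default_rng(1)
        for i in range(30):
            contig = Contig(f"r{i}", random_contig_seq(rng, 900))
            for code in (T1, T4):
                for orf in find_orfs(contig, code, 30):
                    assert "*" not in orf.protein
                    if orf.completeness == "complete":
                        assert orf.interval.length % 3 == 0
                        assert orf.length_aa == orf.interval.length // 3 - 1

    def test_min_len_monotonicity(self):
        rng = np.random.default_rng(2)
        contig = Contig("m", random_contig_seq(rng, 1200))
        for code in (T1, T4):
            lo = {(o.interval, o.completeness) for o in find_orfs(contig, code, 20)}
            hi = {(o.interval, o.completeness) for o in find_orfs(contig, code, 60)}
            assert hi <= lo

    def test_table_nesting(self):
        """Every table-1 complete ORF is matched or contained by a table-4 ORF
        (complete, or 3'-partial when no TAA/TAG follows) of >= length."""
        rng = np.random.default_rng(3)
        for i in range(40):
            contig = Contig(f"n{i}", random_contig_seq(rng, 600))
            nested = find_orfs(contig, T4, 10)
            for orf in find_orfs(contig, T1, 10, completeness_filter=("complete",)):
                partners = [
                    o
                    for o in nested
                    if o.interval.strand == orf.interval.strand
                    and o.frame == orf.frame
                    and o.completeness in ("complete", "3prime_partial")
                    and o.length_aa >= orf.length_aa
                    and (
                        (orf.interval.strand == "+" and o.interval.start <= orf.interval.start)
                        or (orf.interval.strand == "-" and o.interval.end >= orf.interval.end)
                    )
                ]
                assert partners, (contig.id, orf)

    def test_matches_brute_force_enumerator(self):
        rng = np.random.default_rng(4)
        for i in range(40):
            contig = Contig(f"bf{i}", random_contig_seq(rng, 400))
            for code in (T1, T4):
                assert find_orfs(contig, code, 20) == brute_force_orfs(contig, code, 20)

    def test_completeness_tags_on_edges(self):
        # start without stop -> 3'-partial; stop without start -> 5'-partial
        assert [o.completeness for o in find_orfs(Contig("a", "ATG" + "AAA" * 5), T1, 1)
                if o.interval.strand == "+" and o.frame == 0] == ["3prime_partial"]
        orfs = find_orfs(Contig("b", "AAA" * 5 + "TAA"), T1, 1, strands="+")
        assert ("5prime_partial" in {o.completeness for o in orfs if o.frame == 0})

    def test_completeness_filter_and_strand_selection(self):
        rng = np.random.default_rng(5)
        contig = Contig("f", random_contig_seq(rng, 900))
        only_complete = find_orfs(contig, T4, 10, completeness_filter=("complete",))
        assert all(o.completeness == "complete" for o in only_complete)
        plus = find_orfs(contig, T4, 10, strands="+")
        assert all(o.interval.strand == "+" for o in plus)
        with pytest.raises(ValueError):
            find_orfs(contig, T4, 10, completeness_filter=("bogus",))

    def test_one_per_stop_collapse(self):
        # two in-frame starts sharing one stop: collapsed to the earlier one
        seq = "ATGAAAATGAAATAA"
        collapsed = find_orfs(Contig("c", seq), T1, 1, strands="+")
        complete = [o for o in collapsed if o.completeness == "complete"]
        assert len(complete) == 1 and complete[0].length_aa == 4
        expanded = find_orfs(Contig("c", seq), T1, 1, strands="+", one_per_stop=False)
        assert sorted(
            o.length_aa for o in expanded if o.completeness == "complete"
        ) == [2, 4]

    def test_custom_start_codons(self):
        seq = "GTGAAATAA"
        assert find_orfs(Contig("g", seq), get_code(1), 1, strands="+",
                         completeness_filter=("complete",)) == []
        alt = get_code(1, start_codons=("ATG", "GTG"))
        (orf,) = find_orfs(Contig("g", seq), alt, 1, strands="+",
                           completeness_filter=("complete",))
        assert orf.length_aa == 2
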