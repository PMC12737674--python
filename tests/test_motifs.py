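import pytest

from viroscreen import (
    CodingSystemCall,
    MotifConfigError,
    MotifDefinition,
    classify_element,
    default_motifs,
    load_motif_config,
    scan_motifs,
)
from viroscreen.motifs import HNH, MATURASE, RDRP, RVT, compile_pattern, motif_presence


def mito_call(single_orf=True):
    return CodingSystemCall(
        contig_id="c", call="mitochondrial_coding",
        n_orfs_table1=0, n_orfs_table4=1 if single_orf else 2,
        single_orf=single_orf, longest_aa_table1=0, longest_aa_table4=300,
    )


class TestPatternCompiler:
    @pytest.mark.parametrize(
        "pattern,text,matches",
        [
            ("Y-[AIV]-D-D", "GGYADDGG", True),
            ("Y-[AIV]-D-D", "GGYLDDGG", False),
            ("A-x(2,4)-C", "AKKC", True),
            ("A-x(2,4)-C", "AKKKKC", True),
            ("A-x(2,4)-C", "AKKKKKC", False),  # gap of 5 exceeds the bound
            ("A-x-C", "AKC", True),
            ("A-x(3)-C", "AKKKC", True),
            ("A-x(3)-C", "AKKC", False),
            ("{P}-D-D", "PDD", False),
            ("{P}-D-D", "ADD", True),
        ],
    )
    def test_match_semantics(self, pattern, text, matches):
        assert bool(compile_pattern(pattern).search(text)) is matches

    @pytest.mark.parametrize("bad", ["", "Y--D", "[]-D", "x(4,2)", "Y-*-D", "y-d"])
    def test_malformed_patterns_rejected_at_load(self, bad):
        with pytest.raises(MotifConfigError):
            MotifDefinition("m", bad)

    def test_min_score_validated(self):
        with pytest.raises(MotifConfigError):
            MotifDefinition("m", "Y-D-D", min_score=0)


class TestScanMotifs:
    def test_planted_motif_found_at_offset(self):
        motif = MotifDefinition("rt", "Y-[AIV]-D-D")
        protein = "M" * 10 + "YADD" + "G" * 5
        (ann,) = scan_motifs(protein, [motif], protein_id="p")
        assert (ann.position, ann.matched_span) == (10, "YADD")

    def test_empty_motif_list(self):
        assert scan_motifs("MYADD", []) == []

    def test_non_overlapping_leftmost(self):
        motif = MotifDefinition("aa", "A-A")
        anns = scan_motifs("AAAA", [motif])
        assert [a.position for a in anns] == [0, 2]

    def test_min_score_requires_repeat_matches(self):
        motif = MotifDefinition("rep", "C-C", min_score=2)
        one = scan_motifs("GGCCGG", [motif])
        two = scan_motifs("CCGGCC", [motif])
        assert motif_presence(one, [motif]) == set()
        assert motif_presence(two, [motif]) == {"rep"}

    def test_config_round_trip(self, write_text):
        p = write_text(
            "motifs.yaml",
            "- {name: RVT_1, pattern: 'Y-x-D-D'}\n- {name: GDD, pattern: G-D-D, min_score: 2}\n",
        )
        motifs = load_motif_config(p)
        assert [(m.name, m.min_score) for m in motifs] == [("RVT_1", 1), ("GDD", 2)]
        with pytest.raises(MotifConfigError):
            load_motif_config(write_text("bad.yaml", "name: notalist\n"))


class TestClassifyElement:
    MOTIFS = default_motifs()

    def ann(self, *names):
        from viroscreen import DomainAnnotation

        return [DomainAnnotation("c", n, 0, "span") for n in names]

    @pytest.mark.parametrize(
        "names,single,expected",
        [
            ((RVT,), True, "retroplasmid"),
            ((RVT, MATURASE, HNH), True, "group_II_intron"),
            ((RVT, MATURASE), True, "group_II_intron"),
            ((RVT, HNH), False, "group_II_intron"),
            ((RVT,), False, "unknown_mito_element"),  # multi-ORF: not a retroplasmid
            ((RDRP,), True, "mitovirus_like"),
            ((), True, "unknown_mito_element"),
            ((MATURASE,), True, "unknown_mito_element"),
        ],
    )
    def test_precedence_table(self, names, single, expected):
        call = classify_element(mito_call(single), self.ann(*names), self.MOTIFS)
        assert call.element_class == expected

    def test_group_ii_intron_outranks_retroplasmid(self):
        call = classify_element(
            mito_call(single_orf=True), self.ann(RVT, HNH), self.MOTIFS
        )
        assert call.element_class == "group_II_intron"

    def test_non_mito_passes_through(self):
        nuclear = CodingSystemCall("c", "nuclear_coding", 1, 1, True, 200, 200)
        assert classify_element(nuclear, self.ann(RVT), self.MOTIFS).element_class == "not_applicable"

    def test_zero_noise_generator_classes_recovered(self, small_dataset):
        from viroscreen import classify_coding_system, find_orfs, get_code

        ds = small_dataset
        expected = {"R": "retroplasmid", "G2": "group_II_intron", "M": "mitovirus_like"}
        for cid, label in ds.labels.items():
            if label not in expected:
                continue
            contig = ds.contig(cid)
            cc = classify_coding_system(contig)
            anns = []
            for orf in find_orfs(contig, get_code(4), 100, completeness_filter=("complete",)):
                anns.extend(scan_motifs(orf.protein, self.MOTIFS, protein_id=cid))
            assert classify_element(cc, anns, self.MOTIFS).element_class == expected[label]
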