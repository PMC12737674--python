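import numpy as np
import pytest

from viroscreen import (
    Contig,
    HitRecord,
    HitTableError,
    best_hit_per_query,
    find_orfs,
    flag_end_contamination,
    get_code,
    read_hit_table,
    triage_contigs,
    write_hit_table,
)

from .conftest import random_contig_seq


def make_hit(**kw) -> HitRecord:
    base = dict(
        query_id="q1", subject_id="s1", percent_identity=90.0, alignment_length=100,
        query_start=1, query_end=100, subject_start=1, subject_end=100,
        evalue=1e-50, bitscore=200.0,
    )
    base.update(kw)
    return HitRecord(**base)


class TestReadHitTable:
    ROW12 = "q1\ts1\t97.5\t100\t2\t0\t1\t100\t5\t104\t1e-50\t200.0"

    def test_twelve_column_row(self, write_text):
        p = write_text("h.tsv", self.ROW12 + "\n")
        (hit,) = read_hit_table(p, "outfmt6")
        assert hit.subject_title == "unknown"
        assert hit.query_coverage is None
        assert hit.percent_identity == 97.5

    def test_extended_row_populates_title(self, write_text):
        p = write_text("h.tsv", self.ROW12 + "\t88.2\tsome mitovirus protein\tBotrytis cinerea\n")
        (hit,) = read_hit_table(p, "outfmt6_ext")
        assert hit.subject_title == "some mitovirus protein"
        assert hit.subject_organism_label == "Botrytis cinerea"
        assert hit.query_coverage == 88.2

    def test_empty_file(self, write_text):
        assert read_hit_table(write_text("h.tsv", "")) == []

    def test_column_count_mismatch_names_row(self, write_text):
        p = write_text("h.tsv", self.ROW12 + "\n" + "q2\ts2\t50\n")
        with pytest.raises(HitTableError, match="row 2"):
            read_hit_table(p, "outfmt6")

    def test_non_numeric_identity_names_row(self, write_text):
        p = write_text("h.tsv", self.ROW12.replace("97.5", "high") + "\n")
        with pytest.raises(HitTableError, match="pident"):
            read_hit_table(p, "outfmt6")

    def test_round_trip(self, tmp_path):
        hits = [make_hit(subject_title="t", subject_organism_label="o", query_coverage=50.0)]
        path = tmp_path / "rt.tsv"
        write_hit_table(hits, path, "outfmt6_ext")
        assert read_hit_table(path, "outfmt6_ext") == hits

    def test_reversed_query_coordinates_normalized(self):
        h = make_hit(query_start=300, query_end=101)
        assert (h.query_start, h.query_end) == (101, 300)


class TestBestHitPerQuery:
    def test_lowest_evalue_wins(self):
        hits = [make_hit(evalue=1e-10, subject_id="weak"), make_hit(evalue=1e-50, subject_id="strong")]
        assert best_hit_per_query(hits)["q1"].subject_id == "strong"

    def test_evalue_tie_broken_by_bitscore(self):
        hits = [make_hit(bitscore=180.0, subject_id="lo"), make_hit(bitscore=200.0, subject_id="hi")]
        assert best_hit_per_query(hits)["q1"].subject_id == "hi"

    def test_matches_exhaustive_max_under_shuffling(self):
        rng = np.random.default_rng(11)
        hits = [
            make_hit(
                query_id=f"q{rng.integers(5)}",
                subject_id=f"s{i}",
                evalue=float(10.0 ** -rng.integers(5, 50)),
                bitscore=float(rng.integers(50, 400)),
                percent_identity=float(rng.integers(30, 100)),
            )
            for i in range(100)
        ]

        # oracle: full sort by the documented rank, take the head per query
        def rank(h):
            return (h.evalue, -h.bitscore, -h.percent_identity, h.subject_id)

        expected = {}
        for h in sorted(hits, key=rank):
            expected.setdefault(h.query_id, h)
        for _ in range(5):
            perm = [hits[i] for i in rng.permutation(len(hits))]
            assert best_hit_per_query(perm) == expected


def _triage_one(contig, hit, **kw):
    orfs = {
        t: find_orfs(contig, get_code(t), 100, completeness_filter=("complete",))
        for t in (1, 4)
    }
    best = {} if hit is None else {contig.id: hit}
    return triage_contigs([contig], orfs, best, **kw)[0]


class TestTriageContigs:
    CODING = Contig("c", "ATG" + "GCT" * 150 + "TAA")
    NONCODING = Contig("c", "ACGT" * 30)

    def test_virus_keyword_matches_inside_words(self):
        d = _triage_one(
            self.NONCODING,
            make_hit(query_id="c", subject_title="Botrytis cinerea mitovirus 1 isolate BCS1_DN4879"),
        )
        assert d.category == "virus_candidate"

    def test_divergent_non_host_hit(self):
        d = _triage_one(
            self.CODING,
            make_hit(
                query_id="c",
                subject_title="hypothetical protein",
                subject_organism_label="Trichoderma harzianum",
                percent_identity=45.0,
            ),
        )
        assert d.category == "followup_divergent_hit"

    def test_high_identity_host_hit_is_host_like(self):
        d = _triage_one(
            self.CODING,
            make_hit(
                query_id="c",
                subject_title="hypothetical protein",
                subject_organism_label="Botrytis cinerea",
                percent_identity=98.0,
            ),
        )
        assert d.category == "host_like"

    def test_no_orf_category_precedes_divergence(self):
        d = _triage_one(
            self.NONCODING,
            make_hit(
                query_id="c",
                subject_title="hypothetical protein",
                subject_organism_label="Trichoderma harzianum",
                percent_identity=45.0,
            ),
        )
        assert d.category == "followup_no_orf"

    def test_orf_without_hit(self):
        assert _triage_one(self.CODING, None).category == "followup_unannotated_orf"

    def test_virus_keyword_outranks_everything(self):
        d = _triage_one(
            self.NONCODING,
            make_hit(query_id="c", subject_title="PARTITIVIRUS coat protein",
                     subject_organism_label="Botrytis cinerea", percent_identity=99.0),
        )
        assert d.category == "virus_candidate"

    def test_divergent_but_related_host_is_host_like(self):
        d = _triage_one(
            self.CODING,
            make_hit(query_id="c", subject_title="hypothetical protein",
                     subject_organism_label="Botrytis byssoidea", percent_identity=70.0),
            related_host_labels=("Botrytis byssoidea",),
        )
        assert d.category == "host_like"

    def test_unknown_query_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            triage_contigs([self.CODING], {1: [], 4: []}, {"ghost": make_hit(query_id="ghost")})

    def test_exactly_one_decision_per_contig(self, small_dataset):
        from viroscreen import best_hit_per_query

        ds = small_dataset
        orfs = {
            t: [
                o
                for c in ds.contigs
                for o in find_orfs(c, get_code(t), 100, completeness_filter=("complete",))
            ]
            for t in (1, 4)
        }
        decisions = triage_contigs(ds.contigs, orfs, best_hit_per_query(ds.protein_hits))
        assert sorted(d.contig_id for d in decisions) == sorted(c.id for c in ds.contigs)


class TestEndContamination:
    @staticmethod
    def contig_3000():
        rng = np.random.default_rng(21)
        return Contig("c", random_contig_seq(rng, 3000))

    def test_right_end_host_hit(self):
        hit = make_hit(query_id="c", query_start=2701, query_end=3000,
                       subject_organism_label="Botrytis cinerea", percent_identity=99.0)
        flag = flag_end_contamination(self.contig_3000(), [hit])
        assert flag.call == "right"
        assert (flag.right.start, flag.right.end) == (2700, 3000)

    def test_no_host_hits(self):
        assert flag_end_contamination(self.contig_3000(), []).call == "none"

    def test_whole_contig_host_hit_not_flagged(self):
        hit = make_hit(query_id="c", query_start=1, query_end=3000,
                       subject_organism_label="Botrytis cinerea", percent_identity=99.0)
        assert flag_end_contamination(self.contig_3000(), [hit]).call == "none"

    def test_both_ends(self):
        hits = [
            make_hit(query_id="c", query_start=1, query_end=400,
                     subject_organism_label="Botrytis cinerea", percent_identity=95.0),
            make_hit(query_id="c", query_start=2651, query_end=3000,
                     subject_organism_label="Botrytis cinerea", percent_identity=95.0),
        ]
        assert flag_end_contamination(self.contig_3000(), hits).call == "both"

    def test_low_identity_or_non_host_ignored(self):
        low = make_hit(query_id="c", query_start=2701, query_end=3000,
                       subject_organism_label="Botrytis cinerea", percent_identity=80.0)
        alien = make_hit(query_id="c", query_start=2701, query_end=3000,
                         subject_organism_label="Fusarium oxysporum", percent_identity=99.0)
        assert flag_end_contamination(self.contig_3000(), [low, alien]).call == "none"
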