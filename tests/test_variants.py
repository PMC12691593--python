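import itertools

import pytest

from conftest import make_callset
from mutkit.variants import (
    DEFAULT_HARD_FILTERS,
    MutationRecord,
    SNM_TYPES,
    apply_hard_filters,
    classify,
    classify_substitution,
    cluster_complex,
    read_mutation_table,
    read_vcf,
    subtract_ancestral,
)

_COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


class TestClassification:
    def test_strand_collapse_exhaustive(self):
        """classify(X>Y) == classify(comp(X)>comp(Y)) for all 12 substitutions."""
        for ref, alt in itertools.permutations("ACGT", 2):
            t = classify_substitution(ref, alt)
            assert t == classify_substitution(_COMP[ref], _COMP[alt])
            assert t in SNM_TYPES
            assert t[:2] == ("GC" if ref in "GC" else "AT")

    @pytest.mark.parametrize(
        "ref, alt, mclass, snm_type, dlen",
        [
            ("G", "A", "SNM", "GC>AT", 0),
            ("C", "T", "SNM", "GC>AT", 0),
            ("ACT", "A", "deletion", None, -2),
            ("A", "ATT", "insertion", None, 2),
        ],
    )
    def test_classify_examples(self, ref, alt, mclass, snm_type, dlen):
        rec = classify("L01", 100, ref, alt)
        assert (rec.mclass, rec.snm_type, rec.length_change) == (mclass, snm_type, dlen)

    def test_ref_equals_alt_rejected(self):
        with pytest.raises(ValueError):
            classify("L01", 1, "A", "A")


class TestReadMutationTable:
    def test_roundtrip_with_rejects(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text(
            "line_id\tposition\tref\talt\n"
            "L01\t100\tG\tA\n"
            "L01\t500\tACT\tA\n"
            "L02\t100\tC\tT\n"
            "L02\tx\tA\tG\n"
            "L02\t7\tA\tA\n"
        )
        callsets = read_mutation_table(path)
        by_line = {cs.line_id: cs for cs in callsets}
        assert by_line["L01"].records[0].snm_type == "GC>AT"
        assert by_line["L01"].records[1].mclass == "deletion"
        assert len(by_line["L02"].records) == 1
        reasons = [r for _, r in by_line["L02"].excluded]
        assert len(reasons) == 2  # bad position and ref==alt

    def test_missing_columns(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("line_id\tpos\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_mutation_table(path)

    def test_qc_columns_attached(self, tmp_path):
        path = tmp_path / "m.tsv"
        path.write_text("line_id\tposition\tref\talt\tQD\tQUAL\nL01\t5\tG\tT\t1.5\t99\n")
        (cs,) = read_mutation_table(path)
        assert cs.records[0].qc == {"QD": 1.5, "QUAL": 99.0}


class TestHardFilters:
    def test_failing_field_named(self):
        cs = make_callset("L01", [(100, "G", "A")])
        cs.records[0] = MutationRecord("L01", 100, "G", "A", "SNM", "GC>AT",
                                       qc={"QD": 1.9, "MQ": 50.0})
        out = apply_hard_filters(cs)
        assert not out.records
        assert out.excluded[0][1] == "hard filter: QD"

    def test_exact_thresholds_retained(self):
        qc = {"QD": 2.0, "SOR": 5.0, "FS": 60.0, "MQ": 40.0, "QUAL": 30.0,
              "MQRankSum": -20.0, "ReadPosRankSum": -8.0, "F_MISSING": 0.0}
        cs = make_callset("L01", [(100, "G", "A")])
        cs.records[0] = MutationRecord("L01", 100, "G", "A", "SNM", "GC>AT", qc=qc)
        out = apply_hard_filters(cs)
        assert len(out.records) == 1

    def test_no_qc_is_noop(self):
        cs = make_callset("L01", [(100, "G", "A"), (200, "A", "T")])
        out = apply_hard_filters(cs)
        assert [r.position for r in out.records] == [100, 200]
        assert not out.excluded

    def test_unknown_threshold_key(self):
        cs = make_callset("L01", [(100, "G", "A")])
        with pytest.raises(KeyError):
            apply_hard_filters(cs, {"BOGUS": ("ge", 1)})

    def test_idempotent(self):
        cs = make_callset("L01", [(100, "G", "A")])
        cs.records[0] = MutationRecord("L01", 100, "G", "A", "SNM", "GC>AT", qc={"FS": 99.0})
        once = apply_hard_filters(cs)
        twice = apply_hard_filters(once)
        assert once == twice


class TestSubtractAncestral:
    def test_empty_set_is_identity(self):
        cs = make_callset("L01", [(100, "G", "A")])
        assert subtract_ancestral(cs, set()).records == cs.records

    def test_shared_variant_removed_everywhere(self):
        lines = [make_callset(f"L{i}", [(100, "G", "A"), (200, "A", "C")]) for i in range(3)]
        out = [subtract_ancestral(cs, {(100, "G", "A")}) for cs in lines]
        assert all(len(cs.records) == 1 for cs in out)
        assert sum(len(cs.excluded) for cs in out) == 3

    def test_five_distinct_keys(self):
        anc = {(i * 10, "G", "A") for i in range(1, 6)}
        cs = make_callset("L01", [(i * 10, "G", "A") for i in range(1, 8)])
        out = subtract_ancestral(cs, anc)
        assert len(out.excluded) == 5
        assert len(out.records) == 2


class TestClusterComplex:
    def test_pair_within_window_collapses(self):
        cs = make_callset("L01", [(100, "G", "A"), (130, "C", "T")])
        out = cluster_complex(cs)
        assert [r.mclass for r in out.records] == ["complex"]
        assert len(out.records[0].members) == 2
        assert not [r for r in out.records if r.mclass == "SNM"]

    def test_exactly_window_apart_retained(self):
        cs = make_callset("L01", [(100, "G", "A"), (150, "C", "T")])
        out = cluster_complex(cs)
        assert [r.mclass for r in out.records] == ["SNM", "SNM"]

    def test_chain_closure(self):
        cs = make_callset("L01", [(100, "G", "A"), (140, "C", "T"), (185, "A", "G")])
        out = cluster_complex(cs)
        assert len(out.complexes) == 1
        assert len(out.records[0].members) == 3

    def test_mixed_snm_indel_chain(self):
        cs = make_callset("L01", [(100, "G", "A"), (120, "ACT", "A")])
        out = cluster_complex(cs)
        assert out.records[0].mclass == "complex"
        assert out.records[0].length_change == -2

    def test_conservation_and_idempotence(self):
        cs = make_callset("L01", [(1, "G", "A"), (200, "C", "T"), (230, "A", "G"), (900, "A", "C")])
        out = cluster_complex(cs)
        survivors = {r.position for r in out.records}
        members = {m.position for r in out.complexes for m in r.members}
        excluded = {r.position for r, _ in out.excluded}
        assert members == excluded == {200, 230}
        assert survivors == {1, 200, 900}
        again = cluster_complex(out)
        assert [r.position for r in again.records] == [r.position for r in out.records]


class TestVCFImport:
    def test_minimal_haploid_vcf(self, tmp_path):
        vcf = tmp_path / "calls.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=QD,Number=1,Type=Float,Description="qd">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">\n'
            "##contig=<ID=chrom,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tL01\tL02\n"
            "chrom\t100\t.\tG\tA\t50\t.\tQD=12.1\tGT\t1\t0\n"
            "chrom\t200\t.\tA\tC,ACT\t60\t.\tQD=30\tGT\t2\t1\n"
        )
        callsets = read_vcf(vcf)
        by_line = {cs.line_id: cs for cs in callsets}
        assert by_line["L01"].records[0].snm_type == "GC>AT"
        assert by_line["L01"].records[0].qc["QD"] == pytest.approx(12.1)
        # multi-allelic split: L01 got the insertion, L02 the SNM
        assert by_line["L01"].records[1].mclass == "insertion"
        assert by_line["L02"].records[0].snm_type == "AT>CG"
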