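"""Data-model invariants and file round-trips."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from famseg.datamodel import (
    MISSING,
    ContingencyTable2x2,
    GeneSet,
    GenotypeMatrix,
    PedigreeSet,
    Sample,
    VariantAnnotation,
    VariantKey,
)
from famseg.io import (
    ParseError,
    merge_annotations,
    read_candidates,
    read_count_table,
    read_gene_set,
    read_ped,
    read_tier_report_counts,
    read_vcf,
    write_candidates,
    write_ped,
    write_tier_report,
    write_vcf,
)


class TestVariantKey:
    def test_rejects_bad_fields(self):
        with pytest.raises(ValueError):
            VariantKey("chr1", 0, "A", "G")
        with pytest.raises(ValueError):
            VariantKey("chr1", 5, "", "G")
        with pytest.raises(ValueError):
            VariantKey("chr1", 5, "A", "N")

    @given(
        pos=st.integers(min_value=1, max_value=10**9),
        ref=st.text(alphabet="ACGT", min_size=1, max_size=5),
        alt=st.text(alphabet="ACGT", min_size=1, max_size=5),
    )
    def test_parse_roundtrip(self, pos, ref, alt):
        key = VariantKey("chr5", pos, ref, alt)
        assert VariantKey.parse(str(key)) == key


class TestDomainInvariants:
    def test_matrix_rejects_fractional_and_shape(self):
        keys = [VariantKey("chr1", 1, "A", "G")]
        with pytest.raises(ValueError):
            GenotypeMatrix(keys, ["S1"], np.array([[3]], dtype=np.int8))
        with pytest.raises(ValueError):
            GenotypeMatrix(keys, ["S1", "S2"], np.zeros((1, 1), dtype=np.int8))
        with pytest.raises(ValueError):
            GenotypeMatrix(keys, ["S1", "S1"], np.zeros((1, 2), dtype=np.int8))

    def test_onset_age_only_for_affected(self):
        with pytest.raises(ValueError):
            Sample(sample_id="x", family_id="f", affection="unaffected", onset_age=44)

    def test_one_proband_per_family(self):
        members = [
            Sample(sample_id="a", family_id="f", affection="affected", is_proband=True),
            Sample(sample_id="b", family_id="f", affection="affected", is_proband=True),
        ]
        with pytest.raises(ValueError):
            PedigreeSet(families={"f": members})

    def test_contingency_rejects_negative_and_empty(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)
        with pytest.raises(ValueError):
            ContingencyTable2x2(0, 0, 0, 0)

    def test_gene_set_uppercases_and_rejects_empty(self):
        gs = GeneSet(name="x", genes=frozenset({"pcdhga10"}))
        assert "PCDHGA10" in gs
        with pytest.raises(ValueError):
            GeneSet(name="x", genes=frozenset())

    def test_annotation_bounds(self):
        key = VariantKey("chr1", 1, "A", "G")
        with pytest.raises(ValueError):
            VariantAnnotation(key=key, maf=1.5)
        with pytest.raises(ValueError):
            VariantAnnotation(key=key, impact="SEVERE")


class TestVcf:
    def _write(self, tmp_path, body, samples=("S1",)):
        path = tmp_path / "t.vcf"
        header = (
            "##fileformat=VCFv4.2\n##contig=<ID=chr5>\n"
            '##INFO=<ID=MAF,Number=A,Type=Float,Description="x">\n'
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="x">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(samples) + "\n"
        )
        path.write_text(header + body)
        return path

    def test_basic_dosage_mapping(self, tmp_path):
        path = self._write(
            tmp_path,
            "chr5\t1000\t.\tA\tAA\t.\tPASS\t.\tGT\t0/1\n"
            "chr5\t2000\t.\tA\tG\t.\tPASS\t.\tGT\t1/1\n"
            "chr5\t3000\t.\tA\tG\t.\tPASS\t.\tGT\t./.\n",
        )
        matrix, _ = read_vcf(path)
        assert matrix.dosage(VariantKey("chr5", 1000, "A", "AA"), "S1") == 1
        assert matrix.dosage(VariantKey("chr5", 2000, "A", "G"), "S1") == 2
        assert matrix.dosage(VariantKey("chr5", 3000, "A", "G"), "S1") == MISSING

    def test_phased_treated_as_unphased(self, tmp_path):
        path = self._write(tmp_path, "chr5\t1000\t.\tA\tG\t.\tPASS\t.\tGT\t1|0\n")
        matrix, _ = read_vcf(path)
        assert matrix.dosage(VariantKey("chr5", 1000, "A", "G"), "S1") == 1

    def test_multiallelic_split_conserves_dosage(self, tmp_path):
        path = self._write(
            tmp_path,
            "chr5\t1000\t.\tA\tAA,AT\t.\tPASS\tMAF=0.01,0.2\tGT\t1/2\t0/1\t2/2\n",
            samples=("S1", "S2", "S3"),
        )
        matrix, ann = read_vcf(path)
        k1 = VariantKey("chr5", 1000, "A", "AA")
        k2 = VariantKey("chr5", 1000, "A", "AT")
        assert matrix.n_variants == 2
        # per-sample alt dosage at the site is conserved across the split
        for sample, total in (("S1", 2), ("S2", 1), ("S3", 2)):
            assert matrix.dosage(k1, sample) + matrix.dosage(k2, sample) == total
        by_key = {a.key: a for a in ann}
        assert by_key[k1].maf == pytest.approx(0.01)
        assert by_key[k2].maf == pytest.approx(0.2)

    def test_rectangular_call_count(self, tmp_path):
        path = self._write(
            tmp_path,
            "chr5\t1000\t.\tA\tG\t.\tPASS\t.\tGT\t0/1\t0/0\n"
            "chr5\t2000\t.\tA\tG\t.\tPASS\t.\tGT\t1/1\t0/1\n",
            samples=("S1", "S2"),
        )
        matrix, _ = read_vcf(path)
        assert matrix.dosages.shape == (2, 2)

    def test_haploid_record_is_parse_error(self, tmp_path):
        path = self._write(tmp_path, "chr5\t1000\t.\tA\tG\t.\tPASS\t.\tGT\t1\n")
        with pytest.raises(ParseError, match="chr5:1000"):
            read_vcf(path)

    def test_write_read_roundtrip(self, ideal_cohort, tmp_path):
        cohort = ideal_cohort
        path = tmp_path / "c.vcf"
        write_vcf(cohort.matrix, path, cohort.annotations)
        matrix, _ = read_vcf(path)
        vidx = [matrix.variant_index(v) for v in cohort.matrix.variants]
        sidx = [matrix.sample_index(s) for s in cohort.matrix.samples]
        assert (matrix.dosages[np.ix_(vidx, sidx)] == cohort.matrix.dosages).all()


class TestPed:
    def test_core_six_columns(self, tmp_path):
        path = tmp_path / "p.ped"
        path.write_text("FB001\tII-2\t0\t0\t2\t2\n")
        ped = read_ped(path)
        sample = ped.families["FB001"][0]
        assert sample.sex == "female"
        assert sample.affection == "affected"
        assert sample.father_id is None and sample.mother_id is None

    def test_extension_columns(self, tmp_path):
        path = tmp_path / "p.ped"
        path.write_text(
            "FID\tIID\tPAT\tMAT\tSEX\tPHENO\tPROBAND\tONSET_AGE\n"
            "FB001\tII-2\t0\t0\t2\t2\t1\t44\n"
        )
        sample = read_ped(path).families["FB001"][0]
        assert sample.is_proband and sample.onset_age == 44.0

    def test_duplicate_iid_rejected(self, tmp_path):
        path = tmp_path / "p.ped"
        path.write_text("F1\tA\t0\t0\t1\t2\nF1\tA\t0\t0\t1\t2\n")
        with pytest.raises(ParseError, match="duplicate"):
            read_ped(path)

    def test_proband_on_unaffected_rejected(self, tmp_path):
        path = tmp_path / "p.ped"
        path.write_text(
            "FID\tIID\tPAT\tMAT\tSEX\tPHENO\tPROBAND\nF1\tA\t0\t0\t1\t1\t1\n"
        )
        with pytest.raises(ParseError, match="proband"):
            read_ped(path)

    def test_two_probands_in_family_rejected(self, tmp_path):
        path = tmp_path / "p.ped"
        path.write_text(
            "FID\tIID\tPAT\tMAT\tSEX\tPHENO\tPROBAND\n"
            "F1\tA\t0\t0\t1\t2\t1\nF1\tB\t0\t0\t1\t2\t1\n"
        )
        with pytest.raises(ValueError):
            read_ped(path)

    def test_write_read_roundtrip(self, ideal_cohort, tmp_path):
        path = tmp_path / "c.ped"
        write_ped(ideal_cohort.pedigrees, path)
        ped = read_ped(path)
        orig = {s.sample_id: s for s in ideal_cohort.pedigrees.all_samples()}
        back = {s.sample_id: s for s in ped.all_samples()}
        assert set(orig) == set(back)
        for sid, s in orig.items():
            b = back[sid]
            assert (b.family_id, b.affection, b.is_proband, b.sex) == (
                s.family_id, s.affection, s.is_proband, s.sex
            )
            if s.onset_age is not None:
                assert b.onset_age == pytest.approx(s.onset_age, abs=0.05)


class TestTables:
    def test_count_table(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("SOURCE\tPOS\tNEG\nExAC\t11\t2739\n")
        assert read_count_table(path) == [("ExAC", 11, 2739)]

    def test_count_table_rejects_negative(self, tmp_path):
        path = tmp_path / "c.tsv"
        path.write_text("SOURCE\tPOS\tNEG\nExAC\t-1\t2739\n")
        with pytest.raises(ParseError):
            read_count_table(path)

    def test_gene_set_reads_and_rejects_empty(self, tmp_path):
        path = tmp_path / "g.txt"
        path.write_text("pcdhga10\nOTOF\n")
        gs = read_gene_set(path)
        assert gs.genes == {"PCDHGA10", "OTOF"}
        empty = tmp_path / "e.txt"
        empty.write_text("\n")
        with pytest.raises(ParseError):
            read_gene_set(empty)

    def test_candidates_roundtrip_identity(self, tmp_path):
        anns = [
            VariantAnnotation(
                key=VariantKey("chr5", 100, "A", "AA"),
                gene="PCDHGA10", impact="HIGH", maf=0.005, cadd=25.0,
                rsid="rs113784532",
            ),
            VariantAnnotation(key=VariantKey("chr2", 50, "C", "T")),
        ]
        path = tmp_path / "cand.tsv"
        write_candidates(anns, path)
        back = {a.key: a for a in read_candidates(path)}
        for a in anns:
            b = back[a.key]
            assert (b.gene, b.impact, b.maf, b.cadd, b.rsid) == (
                a.gene, a.impact, a.maf, a.cadd, a.rsid
            )

    def test_tier_report_roundtrip_counts(self, toy_family, tmp_path):
        from famseg.filtering import FilterConfig, family_segregation, TierReport

        members, matrix, annotations = toy_family
        states = family_segregation(members, matrix, FilterConfig())
        report = TierReport(
            per_family_candidates={"F1": states},
            after_freq_impact={"F1": states},
            after_cross_family={s.key for s in states},
            prioritized=[],
        )
        path = tmp_path / "tiers.tsv"
        write_tier_report(report, path)
        counts = read_tier_report_counts(path)
        assert counts[("segregating", "F1")] == len(states)
        assert counts[("cross_family", "global")] == len(report.after_cross_family)

    def test_merge_side_tsv_wins(self):
        key = VariantKey("chr1", 10, "A", "G")
        base = [VariantAnnotation(key=key, gene="OLD", maf=0.3)]
        override = [VariantAnnotation(key=key, gene="NEW")]
        merged = merge_annotations(base, override)[0]
        assert merged.gene == "NEW"
        assert merged.maf == 0.3  # absent override fields fall back
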