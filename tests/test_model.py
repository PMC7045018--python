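import io

import pytest
from hypothesis import given, strategies as st

from varcount.errors import ParseError, ValidationError
from varcount.model import (
    Genotype,
    Parameters,
    Region,
    TranscriptEffect,
    VariantRecord,
    parse_effect_annotation,
    read_bed,
    read_parameters,
    read_sample_info,
    read_vcf,
    restrict_to_regions,
    write_vcf,
)

VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=ANN,Number=.,Type=String,Description="ann">
##INFO=<ID=AF_1000G,Number=A,Type=Float,Description="af">
##FILTER=<ID=LowQual,Description="low">
##FORMAT=<ID=GT,Number=1,Type=String,Description="gt">
##contig=<ID=chr1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3
"""


def make_vcf(*rows):
    return io.StringIO(VCF_HEADER + "".join(r + "\n" for r in rows))


class TestReadVcf:
    def test_phase_and_missing_genotypes(self):
        samples, records = read_vcf(
            make_vcf("chr1\t100\t.\tA\tG\t50\tPASS\t.\tGT\t0|1\t0/1\t./.")
        )
        assert samples == ["S1", "S2", "S3"]
        (rec,) = records
        assert rec.genotypes["S1"] == Genotype((0, 1), phased=True)
        assert rec.genotypes["S2"] == Genotype((0, 1), phased=False)
        assert rec.genotypes["S3"].is_missing
        assert not rec.genotypes["S3"].carries_alt

    def test_record_and_sample_counts(self):
        _, records = read_vcf(
            make_vcf(
                "chr1\t100\t.\tA\tG\t50\tPASS\t.\tGT\t0|1\t0/0\t0/0",
                "chr1\t200\t.\tC\tT\t50\tPASS\t.\tGT\t0/0\t1/1\t0/0",
            )
        )
        assert len(records) == 2
        assert all(len(r.genotypes) == 3 for r in records)

    def test_multiallelic_parsed_intact_and_flagged(self):
        _, records = read_vcf(
            make_vcf("chr1\t100\t.\tA\tG,T\t50\tPASS\t.\tGT\t1/2\t0/0\t0/0")
        )
        assert records[0].multiallelic
        assert records[0].alts == ("G", "T")

    def test_filter_and_af_fields(self):
        _, records = read_vcf(
            make_vcf(
                "chr1\t100\t.\tA\tG\t50\tLowQual\tAF_1000G=0.25\tGT\t0/0\t0/0\t0/0"
            )
        )
        assert not records[0].filter_status.is_pass
        assert records[0].annotated_afs["1000G"] == pytest.approx(0.25)

    def test_missing_fileformat_rejected(self):
        with pytest.raises(ParseError, match="line 1"):
            read_vcf(io.StringIO("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"))

    def test_gt_absent_rejected(self):
        stream = make_vcf("chr1\t100\t.\tA\tG\t50\tPASS\t.\tDP\t3\t4\t5")
        with pytest.raises(ParseError, match="GT absent"):
            read_vcf(stream)

    def test_malformed_line_names_line_number(self):
        stream = io.StringIO(VCF_HEADER + "chr1\t100\tmissing-columns\n")
        with pytest.raises(ParseError, match="line 8"):
            read_vcf(stream)


class TestRoundTrip:
    @given(
        st.lists(
            st.tuples(
                st.integers(1, 10_000),  # pos
                st.lists(
                    st.tuples(
                        st.sampled_from([(0, 0), (0, 1), (1, 0), (1, 1), (None, None)]),
                        st.booleans(),
                    ),
                    min_size=3,
                    max_size=3,
                ),
            ),
            min_size=1,
            max_size=8,
            unique_by=lambda t: t[0],
        )
    )
    def test_write_then_read_preserves_sites_and_genotypes(self, spec):
        samples = ["S1", "S2", "S3"]
        records = [
            VariantRecord(
                chrom="chr1",
                pos=pos,
                ref="A",
                alts=("G",),
                genotypes={
                    s: Genotype(alleles, phased)
                    for s, (alleles, phased) in zip(samples, gts)
                },
            )
            for pos, gts in spec
        ]
        buf = io.StringIO()
        write_vcf(buf, samples, records)
        buf.seek(0)
        samples2, records2 = read_vcf(buf)
        assert samples2 == samples
        assert [(r.chrom, r.pos, r.ref, r.alts) for r in records2] == [
            (r.chrom, r.pos, r.ref, r.alts) for r in records
        ]
        for r1, r2 in zip(records, records2):
            assert r1.genotypes == r2.genotypes


class TestEffectAnnotation:
    ANN = (
        "A|missense_variant|MODERATE|TNC|ENSG00000041982|transcript|"
        "NM_002160.3|protein_coding|1/1|c.1A>G||||||"
    )

    def test_single_entry(self):
        (eff,) = parse_effect_annotation(self.ANN)
        assert eff.impact == "MODERATE"
        assert eff.transcript_id == "NM_002160.3"
        assert eff.gene_symbol == "TNC"
        assert eff.effect_term == "missense_variant"

    def test_two_entries_and_prefix(self):
        second = self.ANN.replace("NM_002160.3", "NM_999999.1").replace(
            "MODERATE", "HIGH"
        )
        effects = parse_effect_annotation("ANN=" + self.ANN + "," + second)
        assert len(effects) == 2
        assert {e.impact for e in effects} == {"MODERATE", "HIGH"}

    def test_absent_annotation_gives_empty_list(self):
        assert parse_effect_annotation("") == []
        _, records = read_vcf(
            make_vcf("chr1\t100\t.\tA\tG\t50\tPASS\t.\tGT\t0/0\t0/0\t0/0")
        )
        assert records[0].effects == []

    def test_unknown_impact_skipped_with_warning(self):
        bad = self.ANN.replace("MODERATE", "CATASTROPHIC")
        with pytest.warns(UserWarning, match="unknown impact"):
            assert parse_effect_annotation(bad) == []

    def test_malformed_entry_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="malformed"):
            effects = parse_effect_annotation("A|missense|MODERATE," + self.ANN)
        assert len(effects) == 1


def _record(chrom, pos):
    return VariantRecord(chrom=chrom, pos=pos, ref="A", alts=("G",))


class TestRegions:
    def test_half_open_boundaries(self):
        rec = _record("chr1", 100)
        assert restrict_to_regions([rec], [Region("chr1", 99, 100)]) == [rec]
        assert restrict_to_regions([rec], [Region("chr1", 100, 200)]) == []
        assert restrict_to_regions([rec], [Region("chr1", 50, 99)]) == []
        assert restrict_to_regions([rec], [Region("chr2", 99, 100)]) == []

    def test_empty_region_set(self):
        assert restrict_to_regions([_record("chr1", 5)], []) == []

    @given(
        st.lists(st.tuples(st.sampled_from(["chr1", "chr2"]), st.integers(1, 200)), max_size=30),
        st.lists(
            st.tuples(
                st.sampled_from(["chr1", "chr2"]),
                st.integers(0, 180),
                st.integers(1, 40),
            ),
            max_size=8,
        ),
    )
    def test_matches_bruteforce_membership(self, record_spec, region_spec):
        records = [_record(c, p) for c, p in record_spec]
        regions = [Region(c, s, s + w) for c, s, w in region_spec]
        kept = restrict_to_regions(records, regions)
        expected = [
            r
            for r in records
            if any(
                g.chrom == r.chrom and g.start < r.pos <= g.end for g in regions
            )
        ]
        assert [(r.chrom, r.pos) for r in kept] == [
            (r.chrom, r.pos) for r in expected
        ]

    def test_read_bed(self):
        regions = read_bed(io.StringIO("chr1\t0\t500\tNM_1\nchr2\t10\t20\tNM_2\n"))
        assert regions == [Region("chr1", 0, 500, "NM_1"), Region("chr2", 10, 20, "NM_2")]

    def test_region_requires_start_before_end(self):
        with pytest.raises(ValidationError):
            Region("chr1", 10, 10)


class TestSampleInfo:
    HEADER = "sample_id\tsex\tancestry\trole\tfamily_id\n"

    def test_basic_row(self):
        (s,) = read_sample_info(io.StringIO(self.HEADER + "S1\tfemale\tEU\tproband\tF1\n"))
        assert (s.sample_id, s.sex, s.ancestry, s.role, s.family_id) == (
            "S1", "female", "EU", "proband", "F1",
        )

    def test_duplicate_id_rejected(self):
        text = self.HEADER + "S1\tfemale\tEU\tcontrol\t.\nS1\tmale\tEU\tcontrol\t.\n"
        with pytest.raises(ValidationError, match="line 3.*duplicate"):
            read_sample_info(io.StringIO(text))

    def test_unknown_role_names_row(self):
        with pytest.raises(ValidationError, match="line 2.*role"):
            read_sample_info(io.StringIO(self.HEADER + "S1\tfemale\tEU\tcousin\tF1\n"))

    def test_family_must_have_one_proband(self):
        text = self.HEADER + "S1\tfemale\tEU\tmother\tF1\nS2\tmale\tEU\tfather\tF1\n"
        with pytest.raises(ValidationError, match="exactly one proband"):
            read_sample_info(io.StringIO(text))

    def test_control_with_family_rejected(self):
        with pytest.raises(ValidationError, match="control"):
            read_sample_info(io.StringIO(self.HEADER + "S1\tfemale\tEU\tcontrol\tF1\n"))


class TestParameters:
    def test_study_one_percent_run(self):
        params = read_parameters(
            io.StringIO(
                "level=transcript\nimpacts=HIGH,MODERATE\nmaf_threshold=0.01\n"
                "maf_sources=within_dataset,1000G,ExAC,EVS\nmode=compound_het\n"
            )
        )
        assert params == Parameters(
            level="transcript",
            impact_classes=frozenset({"HIGH", "MODERATE"}),
            maf_threshold=0.01,
            maf_sources=frozenset({"within_dataset", "1000G", "ExAC", "EVS"}),
            mode="compound_het",
        )

    def test_threshold_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            Parameters(maf_threshold=0.0)
        with pytest.raises(ValidationError):
            Parameters(maf_threshold=1.5)

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValidationError):
            read_parameters(io.StringIO("mode=dominant\n"))
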