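import pytest
from hypothesis import given, strategies as st

from varcount.filtering import (
    FilterReport,
    filter_impact,
    filter_maf,
    flip_orientation,
    harmonize,
    recode_major_minor,
    remove_flagged,
    remove_multiallelic,
    within_cohort_af,
)
from varcount.model import FilterStatus, Genotype, TranscriptEffect, VariantRecord


def make_record(pos=100, chrom="chr1", ref="A", alts=("G",), filter_raw="PASS",
                effects=(), afs=None, genotypes=None):
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alts=tuple(alts),
        filter_status=FilterStatus(filter_raw),
        effects=list(effects),
        annotated_afs=dict(afs or {}),
        genotypes=dict(genotypes or {}),
    )


def eff(impact, transcript="T1"):
    return TranscriptEffect(transcript, "G1", impact, "missense_variant")


class TestQualityFlags:
    def test_pass_and_dot_kept_lowqual_removed(self):
        records = [
            make_record(1, filter_raw="PASS"),
            make_record(2, filter_raw="LowQual"),
            make_record(3, filter_raw="."),
        ]
        kept = remove_flagged(records)
        assert [r.pos for r in kept] == [1, 3]

    def test_report_counts_removed(self):
        records = [make_record(p, filter_raw=f) for p, f in
                   [(1, "PASS"), (2, "LowQual"), (3, "VQSRTrancheSNP"), (4, "."), (5, "PASS")]]
        report = FilterReport()
        kept = remove_flagged(records, report)
        assert len(kept) == 3
        assert report.counts_removed == {"quality": 2}


class TestMultiallelic:
    def test_single_line_multiallelic_removed(self):
        records = [make_record(1, alts=("A", "T")), make_record(2, alts=("A",))]
        assert [r.pos for r in remove_multiallelic(records)] == [2]

    def test_same_position_different_alts_both_removed(self):
        records = [
            make_record(1, ref="C", alts=("A",)),
            make_record(1, ref="C", alts=("T",)),
            make_record(2, ref="C", alts=("T",)),
        ]
        report = FilterReport()
        kept = remove_multiallelic(records, report)
        assert [r.pos for r in kept] == [2]
        assert report.counts_removed == {"multiallelic": 2}


class TestImpact:
    def test_modifier_only_removed(self):
        assert filter_impact([make_record(effects=[eff("MODIFIER")])],
                             {"HIGH", "MODERATE"}) == []

    def test_effect_list_reduced_to_qualifying(self):
        rec = make_record(effects=[eff("HIGH", "T1"), eff("MODIFIER", "T2")])
        (kept,) = filter_impact([rec], {"HIGH", "MODERATE"})
        assert [e.transcript_id for e in kept.effects] == ["T1"]

    def test_moderate_qualifies(self):
        rec = make_record(effects=[eff("MODERATE")])
        assert filter_impact([rec], {"HIGH", "MODERATE"}) == [rec]

    def test_no_effects_removed(self):
        report = FilterReport()
        assert filter_impact([make_record()], {"HIGH"}, report) == []
        assert report.counts_removed == {"impact": 1}


class TestWithinCohortAf:
    def test_direct_count(self):
        gts = {"S1": Genotype((0, 1)), "S2": Genotype((0, 0)),
               "S3": Genotype((0, 0)), "S4": Genotype((0, 0))}
        assert within_cohort_af(make_record(genotypes=gts)) == pytest.approx(1 / 8)

    def test_all_hom_alt(self):
        gts = {s: Genotype((1, 1), True) for s in ("S1", "S2", "S3")}
        assert within_cohort_af(make_record(genotypes=gts)) == 1.0

    def test_missing_excluded_from_denominator(self):
        gts = {"S1": Genotype((0, 1)), "S2": Genotype((None, None)),
               "S3": Genotype((0, 0))}
        assert within_cohort_af(make_record(genotypes=gts)) == pytest.approx(1 / 4)

    def test_all_missing_is_undefined(self):
        gts = {"S1": Genotype((None, None))}
        assert within_cohort_af(make_record(genotypes=gts)) is None

    def test_subset_denominator(self):
        gts = {"S1": Genotype((0, 1)), "S2": Genotype((1, 1))}
        rec = make_record(genotypes=gts)
        assert within_cohort_af(rec, ["S1"]) == pytest.approx(0.5)


class TestRecode:
    def test_major_alt_flipped_and_afs_complemented(self):
        gts = {"S1": Genotype((1, 1), True), "S2": Genotype((1, 1), True),
               "S3": Genotype((0, 1), True), "S4": Genotype((0, 0), True)}
        rec = make_record(ref="A", alts=("G",), afs={"1000G": 0.7}, genotypes=gts)
        out = recode_major_minor(rec)
        assert out.recoded
        assert (out.ref, out.alt) == ("G", "A")
        assert out.annotated_afs["1000G"] == pytest.approx(0.3)
        assert out.genotypes["S1"] == Genotype((0, 0), True)
        assert out.genotypes["S3"] == Genotype((1, 0), True)

    def test_half_is_not_recoded(self):
        gts = {"S1": Genotype((0, 1)), "S2": Genotype((1, 0))}
        rec = make_record(genotypes=gts)
        assert recode_major_minor(rec) is rec

    def test_carriers_of_minor_allele_after_recode(self):
        gts = {"S1": Genotype((0, 1), True), "S2": Genotype((1, 1), True)}
        out = recode_major_minor(make_record(genotypes=gts, afs={"ExAC": 0.9}))
        carriers = [s for s, g in out.genotypes.items() if g.carries_alt]
        assert carriers == ["S1"]

    @given(
        st.dictionaries(
            st.sampled_from([f"S{i}" for i in range(8)]),
            st.tuples(
                st.sampled_from([(0, 0), (0, 1), (1, 0), (1, 1), (None, None)]),
                st.booleans(),
            ),
            min_size=1,
        ),
        st.floats(0.0, 1.0),
    )
    def test_flip_is_involution_and_recode_idempotent(self, gt_spec, af):
        gts = {s: Genotype(a, p) for s, (a, p) in gt_spec.items()}
        rec = make_record(genotypes=gts, afs={"1000G": af})
        twice = flip_orientation(flip_orientation(rec))
        assert twice.genotypes == rec.genotypes
        assert (twice.ref, twice.alts) == (rec.ref, rec.alts)
        assert twice.annotated_afs["1000G"] == pytest.approx(af)
        assert twice.recoded == rec.recoded
        once = recode_major_minor(rec)
        assert recode_major_minor(once) == once


class TestMafFilter:
    def test_conjunction_over_sources(self):
        rec = make_record(afs={"ExAC": 0.004, "1000G": 0.02})
        assert filter_maf([rec], 0.005, {"1000G", "ExAC", "EVS"}) == []

    def test_missing_sources_are_not_failures(self):
        gts = {f"S{i}": Genotype((0, 0)) for i in range(249)}
        gts["S249"] = Genotype((0, 1))
        rec = make_record(genotypes=gts)  # within AF = 1/500 = 0.002
        kept = filter_maf([rec], 0.01, {"within_dataset", "1000G", "ExAC", "EVS"})
        assert kept == [rec]

    def test_boundary_is_strict(self):
        gts = {f"S{i}": Genotype((0, 0)) for i in range(49)}
        gts["S49"] = Genotype((0, 1))  # AF exactly 0.01
        rec = make_record(genotypes=gts)
        assert filter_maf([rec], 0.01, {"within_dataset"}) == []

    def test_undefined_within_af_removed_when_selected(self):
        rec = make_record(genotypes={"S1": Genotype((None, None))})
        assert filter_maf([rec], 0.01, {"within_dataset"}) == []
        assert filter_maf([rec], 0.01, {"1000G"}) == [rec]


class TestHarmonize:
    def test_removed_in_one_removed_from_other(self):
        shared = make_record(1, ref="A", alts=("G",))
        other = make_record(3)
        # cohort A removed the pos-1 variant (e.g. by MAF); B still carries it
        kept_a, kept_b = harmonize(
            [other], [shared, make_record(3)],
            removed_a={shared.key}, removed_b=set(),
        )
        assert [r.pos for r in kept_b] == [3]
        assert [r.pos for r in kept_a] == [3]

    def test_disjoint_sets_unchanged(self):
        a = [make_record(1)]
        b = [make_record(2)]
        kept_a, kept_b = harmonize(a, b)
        assert (kept_a, kept_b) == (a, b)

    def test_orientation_conflict_removed_from_both(self):
        rec_a = make_record(5, ref="G", alts=("A",), genotypes={"S1": Genotype((0, 1))})
        rec_b = make_record(5, ref="A", alts=("G",))
        with pytest.warns(UserWarning, match="mismatch"):
            kept_a, kept_b = harmonize([rec_a], [rec_b])
        assert kept_a == [] and kept_b == []

    def test_reports_count_harmonization_removals(self):
        rec = make_record(1)
        ra, rb = FilterReport(), FilterReport()
        harmonize([rec], [], removed_b={rec.key}, report_a=ra, report_b=rb)
        assert ra.counts_removed == {"harmonization": 1}
        assert rb.counts_removed == {}


class TestConservationAndIdempotence:
    def _records(self):
        return [
            make_record(1, filter_raw="LowQual", effects=[eff("HIGH")]),
            make_record(2, alts=("A", "T"), effects=[eff("HIGH")]),
            make_record(3, effects=[eff("MODIFIER")]),
            make_record(4, effects=[eff("HIGH")], afs={"ExAC": 0.5}),
            make_record(5, effects=[eff("MODERATE")],
                        genotypes={"S1": Genotype((0, 1)), "S2": Genotype((0, 0))}),
        ]

    def test_input_equals_output_plus_removals(self):
        records = self._records()
        report = FilterReport()
        out = remove_flagged(records, report)
        out = remove_multiallelic(out, report)
        out = filter_impact(out, {"HIGH", "MODERATE"}, report)
        out = filter_maf(out, 0.26, {"within_dataset", "ExAC"}, report=report)
        assert len(records) == len(out) + report.total_removed

    @pytest.mark.parametrize(
        "op",
        [
            remove_flagged,
            remove_multiallelic,
            lambda rs: filter_impact(rs, {"HIGH", "MODERATE"}),
            lambda rs: filter_maf(rs, 0.26, {"within_dataset", "ExAC"}),
        ],
    )
    def test_filters_idempotent(self, op):
        once = op(self._records())
        assert op(once) == once
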