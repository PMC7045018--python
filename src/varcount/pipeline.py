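"""End-to-end orchestration of the counting pipeline.

Mirrors the study workflow: restrict to coding regions, remove flagged and
multiallelic sites, keep protein-changing effects, recode to minor-allele
orientation, apply the multi-source MAF filter, harmonize the two cohorts,
count carriers (directly on phased controls; via two-variant candidates plus
trio transmission phasing on unphased cases), and test each universe locus.
"""

from __future__ import annotations

from typing import Optional, Sequence

from . import counting, enrichment, filtering, trio
from .filtering import FilterReport
from .model import Parameters, Region, SampleInfo, VariantRecord, restrict_to_regions

__all__ = ["filter_cohort", "count_cohort", "run_trio_case_control"]


def filter_cohort(
    records: Sequence[VariantRecord],
    params: Parameters,
    sample_ids: Optional[Sequence[str]] = None,
    regions: Optional[Sequence[Region]] = None,
    report: Optional[FilterReport] = None,
) -> tuple:
    """Apply the full variant-level filter chain; returns (records, report).

    ``sample_ids`` restricts the within-cohort AF denominator (and later
    counting) to a subset, e.g. one ancestry.
    """
    if report is None:
        report = FilterReport()
    if regions is not None:
        kept = restrict_to_regions(records, regions)
        kept_ids = {id(r) for r in kept}  # restriction preserves object identity
        dropped = [r for r in records if id(r) not in kept_ids]
        report.record_removed("region", dropped)
        records = kept
    records = filtering.remove_flagged(records, report)
    records = filtering.remove_multiallelic(records, report)
    records = filtering.filter_impact(records, params.impact_classes, report)
    records = [
        filtering.recode_major_minor(rec, sample_ids, report) for rec in records
    ]
    records = filtering.filter_maf(
        records, params.maf_threshold, params.maf_sources, sample_ids, report
    )
    return records, report


def count_cohort(
    records: Sequence[VariantRecord],
    sample_ids: Sequence[str],
    params: Parameters,
    mode: Optional[str] = None,
) -> list:
    """Group filtered records by locus and count carriers under a mode."""
    loci = counting.group_by_locus(records, params.level)
    return counting.count_carriers(loci, sample_ids, mode or params.mode)


def _subset(samples: Sequence[SampleInfo], role: str, ancestry: Optional[str]) -> list:
    return [
        s.sample_id
        for s in samples
        if s.role == role and (ancestry is None or s.ancestry == ancestry)
    ]


def run_trio_case_control(
    case_proband_records: Sequence[VariantRecord],
    case_mother_records: Sequence[VariantRecord],
    case_father_records: Sequence[VariantRecord],
    case_samples: Sequence[SampleInfo],
    control_records: Sequence[VariantRecord],
    control_samples: Sequence[SampleInfo],
    params: Parameters,
    regions: Optional[Sequence[Region]] = None,
    ancestry: Optional[str] = None,
) -> tuple:
    """Full case/control run on an unphased trio cohort vs a phased control cohort.

    Compound-het mode counts phase-agnostic two-variant candidates in the
    probands and resolves them against parental genotypes with de novo
    exclusion; controls are counted directly from phase. Returns
    ``(results, case_sets, control_sets, reports, audit)`` where results is the
    sorted :class:`~varcount.enrichment.EnrichmentResult` list.
    """
    proband_ids = _subset(case_samples, "proband", ancestry)
    control_ids = _subset(control_samples, "control", ancestry)
    if not proband_ids or not control_ids:
        raise ValueError("ancestry restriction left an empty cohort")

    case_filtered, case_report = filter_cohort(
        case_proband_records, params, proband_ids, regions
    )
    control_filtered, control_report = filter_cohort(
        control_records, params, control_ids, regions
    )
    case_filtered, control_filtered = filtering.harmonize(
        case_filtered,
        control_filtered,
        case_report.removed_keys,
        control_report.removed_keys,
        case_report,
        control_report,
    )

    control_sets = count_cohort(control_filtered, control_ids, params)

    audit = []
    if params.mode == "compound_het":
        candidates = count_cohort(case_filtered, proband_ids, params, mode="two_variants")
        pedigree = trio.Pedigree.from_sample_info(case_samples)
        parent_records = list(case_mother_records) + list(case_father_records)
        case_sets, audit = trio.resolve_trio_cohort(
            candidates, case_filtered, parent_records, pedigree, mode="compound_het"
        )
    elif params.mode == "homozygous":
        candidates = count_cohort(case_filtered, proband_ids, params)
        pedigree = trio.Pedigree.from_sample_info(case_samples)
        parent_records = list(case_mother_records) + list(case_father_records)
        case_sets, audit = trio.resolve_trio_cohort(
            candidates, case_filtered, parent_records, pedigree, mode="homozygous"
        )
    else:
        case_sets = count_cohort(case_filtered, proband_ids, params)

    results = enrichment.run_enrichment(
        case_sets, control_sets, len(proband_ids), len(control_ids)
    )
    return results, case_sets, control_sets, (case_report, control_report), audit
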