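"""Variant-level exclusions and transformations applied before counting.

The pipeline order is: region restriction, quality-flag removal, multiallelic
removal, impact filtering, major/minor recoding, multi-source MAF filtering,
and finally cross-cohort harmonization. Every removal is tallied in a
:class:`FilterReport` so that input count = output count + removals, audited
per reason.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

from .model import VariantRecord

__all__ = [
    "FilterReport",
    "remove_flagged",
    "remove_multiallelic",
    "filter_impact",
    "within_cohort_af",
    "flip_orientation",
    "recode_major_minor",
    "filter_maf",
    "harmonize",
]


@dataclass
class FilterReport:
    """Audit of a filtering run: removals per reason and recode count."""

    counts_removed: dict = field(default_factory=dict)
    counts_recoded: int = 0
    removed_keys: set = field(default_factory=set)

    def record_removed(self, reason: str, records: Iterable[VariantRecord]) -> None:
        n = 0
        for rec in records:
            n += 1
            self.removed_keys.add(rec.key)
        if n:
            self.counts_removed[reason] = self.counts_removed.get(reason, 0) + n

    @property
    def total_removed(self) -> int:
        return sum(self.counts_removed.values())

    def to_tsv(self) -> str:
        lines = ["reason\tremoved"]
        for reason in sorted(self.counts_removed):
            lines.append(f"{reason}\t{self.counts_removed[reason]}")
        lines.append(f"recoded\t{self.counts_recoded}")
        return "\n".join(lines) + "\n"


def _split(records, keep_pred):
    kept, dropped = [], []
    for rec in records:
        (kept if keep_pred(rec) else dropped).append(rec)
    return kept, dropped


def remove_flagged(
    records: Sequence[VariantRecord], report: Optional[FilterReport] = None
) -> list:
    """Keep only records whose FILTER is PASS or '.'."""
    kept, dropped = _split(records, lambda r: r.filter_status.is_pass)
    if report is not None:
        report.record_removed("quality", dropped)
    return kept


def remove_multiallelic(
    records: Sequence[VariantRecord], report: Optional[FilterReport] = None
) -> list:
    """Keep only biallelic sites.

    A site is multiallelic if a single line carries more than one ALT, or if
    several lines at the same chrom/pos spell more than two nucleotide values
    between them; in the latter case every line at the site is removed.
    """
    alleles_at = {}
    for rec in records:
        site = (rec.chrom, rec.pos)
        alleles_at.setdefault(site, set()).update({rec.ref, *rec.alts})

    def biallelic(rec: VariantRecord) -> bool:
        return len(rec.alts) == 1 and len(alleles_at[(rec.chrom, rec.pos)]) <= 2

    kept, dropped = _split(records, biallelic)
    if report is not None:
        report.record_removed("multiallelic", dropped)
    return kept


def filter_impact(
    records: Sequence[VariantRecord],
    impact_classes,
    report: Optional[FilterReport] = None,
) -> list:
    """Keep records with >=1 effect in ``impact_classes``; prune other effects.

    A kept variant retains only its qualifying effects, so it later counts
    only toward transcripts where its predicted impact qualifies.
    """
    impact_classes = frozenset(impact_classes)
    kept, dropped = [], []
    for rec in records:
        qualifying = [e for e in rec.effects if e.impact in impact_classes]
        if qualifying:
            if len(qualifying) != len(rec.effects):
                rec = replace(rec, effects=qualifying)
            kept.append(rec)
        else:
            dropped.append(rec)
    if report is not None:
        report.record_removed("impact", dropped)
    return kept


def within_cohort_af(
    record: VariantRecord, samples: Optional[Sequence[str]] = None
) -> Optional[float]:
    """Alternate-allele frequency among non-missing alleles of the cohort.

    ``samples`` restricts the denominator to a subset (e.g. one ancestry);
    default is every genotyped sample on the record. Returns None when every
    genotype is missing.
    """
    ids = record.genotypes.keys() if samples is None else samples
    alt = 0
    total = 0
    for sid in ids:
        gt = record.genotypes.get(sid)
        if gt is None:
            continue
        for a in gt.alleles:
            if a is not None:
                total += 1
                if a >= 1:
                    alt += 1
    if total == 0:
        return None
    return alt / total


def flip_orientation(record: VariantRecord) -> VariantRecord:
    """Swap ref/alt roles unconditionally: an involution.

    Every genotype allele index flips (0<->1, missing unchanged), REF and ALT
    strings swap, annotated source AFs are complemented, and the recoded flag
    toggles. Applying it twice restores the original record exactly.
    """
    return replace(
        record,
        ref=record.alt,
        alts=(record.ref,) + record.alts[1:],
        annotated_afs={src: 1.0 - v for src, v in record.annotated_afs.items()},
        genotypes={sid: gt.flipped() for sid, gt in record.genotypes.items()},
        recoded=not record.recoded,
    )


def recode_major_minor(
    record: VariantRecord,
    samples: Optional[Sequence[str]] = None,
    report: Optional[FilterReport] = None,
) -> VariantRecord:
    """Flip ref/alt orientation when the alternate allele is the major one.

    Orientation is decided by the within-cohort AF (the only frequency always
    available): when it is strictly greater than 0.5 the record is passed
    through :func:`flip_orientation` so downstream MAF filtering and carrier
    logic operate on the minor allele. At AF exactly 0.5, or on a record
    already in minor-allele orientation, nothing changes — the operation is
    idempotent, and on minor-orientation records it is the identity.
    """
    af = within_cohort_af(record, samples)
    if af is None or af <= 0.5:
        return record
    if report is not None:
        report.counts_recoded += 1
    return flip_orientation(record)


def filter_maf(
    records: Sequence[VariantRecord],
    threshold: float,
    maf_sources,
    samples: Optional[Sequence[str]] = None,
    report: Optional[FilterReport] = None,
) -> list:
    """Keep records rare in every selected frequency source.

    A record survives iff its minor-allele frequency is strictly below
    ``threshold`` in each selected source for which a value exists (a variant
    common in any panel is not rare); sources with no value are not failures.
    ``within_dataset`` uses the within-cohort AF; a record whose within-cohort
    AF is undefined (all genotypes missing) is removed when that source is
    selected. Records must already be recoded to minor-allele orientation.
    """
    maf_sources = frozenset(maf_sources)

    def rare(rec: VariantRecord) -> bool:
        if "within_dataset" in maf_sources:
            af = within_cohort_af(rec, samples)
            if af is None or af >= threshold:
                return False
        for src, af in rec.annotated_afs.items():
            if src in maf_sources and af >= threshold:
                return False
        return True

    kept, dropped = _split(records, rare)
    if report is not None:
        report.record_removed("maf", dropped)
    return kept


def harmonize(
    records_a: Sequence[VariantRecord],
    records_b: Sequence[VariantRecord],
    removed_a=(),
    removed_b=(),
    report_a: Optional[FilterReport] = None,
    report_b: Optional[FilterReport] = None,
) -> tuple:
    """Cross-reference two filtered cohorts so removals apply to both.

    A variant key (chrom, pos, ref, alt in post-recode orientation) removed
    from one cohort by any upstream filter (``removed_a``/``removed_b``, e.g.
    ``FilterReport.removed_keys``) is removed from the other. Sites present in
    both cohorts with conflicting ref/alt — including a recode applied in only
    one cohort — are removed from both with a warning. Cohort-private variants
    are untouched.
    """
    removed_a = set(removed_a)
    removed_b = set(removed_b)

    sites_a = {}
    sites_b = {}
    for rec in records_a:
        sites_a.setdefault((rec.chrom, rec.pos), set()).add(rec.key)
    for rec in records_b:
        sites_b.setdefault((rec.chrom, rec.pos), set()).add(rec.key)
    conflict_sites = set()
    for site in sites_a.keys() & sites_b.keys():
        if sites_a[site] != sites_b[site]:
            conflict_sites.add(site)
            warnings.warn(
                f"ref/alt mismatch between cohorts at {site[0]}:{site[1]}; "
                "removed from both"
            )

    def keep_a(rec):
        return rec.key not in removed_b and (rec.chrom, rec.pos) not in conflict_sites

    def keep_b(rec):
        return rec.key not in removed_a and (rec.chrom, rec.pos) not in conflict_sites

    kept_a, dropped_a = _split(records_a, keep_a)
    kept_b, dropped_b = _split(records_b, keep_b)
    if report_a is not None:
        report_a.record_removed("harmonization", dropped_a)
    if report_b is not None:
        report_b.record_removed("harmonization", dropped_b)
    return kept_a, kept_b
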