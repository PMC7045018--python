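"""The counting engine: per-locus carrier sets under an inheritance mode.

The unit of counting is the individual, not the variant or variant pair: a
sample with several qualifying variants or several qualifying in-trans pairs
at one transcript is counted once (indicator-function collapsing).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .errors import PhaseError
from .model import VariantRecord

__all__ = [
    "TranscriptCarrierSet",
    "group_by_locus",
    "carrier_status",
    "count_carriers",
    "write_counts",
    "write_carriers",
    "write_sample_variants",
    "read_sample_variants",
    "format_key",
    "parse_key",
]


@dataclass
class TranscriptCarrierSet:
    """Individuals carrying qualifying variants at one transcript (or gene)."""

    locus_id: str
    carriers: set = field(default_factory=set)
    #: sample id -> supporting variant keys (for compound_het: in-trans pairs)
    carrier_variants: dict = field(default_factory=dict)

    @property
    def count(self) -> int:
        return len(self.carriers)


def group_by_locus(records: Sequence[VariantRecord], level: str = "transcript") -> dict:
    """Group records by transcript id or gene symbol of their retained effects.

    A variant appears under every locus in its effect list (once per locus
    even with several effects there); variants with no effects appear nowhere.
    """
    attr = "transcript_id" if level == "transcript" else "gene_symbol"
    loci: dict = {}
    for rec in records:
        seen = set()
        for eff in rec.effects:
            locus = getattr(eff, attr)
            if locus in seen:
                continue
            seen.add(locus)
            loci.setdefault(locus, []).append(rec)
    return loci


def _carried(genotype_items) -> list:
    return [(k, gt) for k, gt in genotype_items if gt is not None and gt.carries_alt]


def carrier_status(genotype_items: Sequence[tuple], mode: str) -> tuple:
    """Decide carrier status of one sample given its genotypes at a locus.

    ``genotype_items`` is a sequence of (variant key, Genotype or None) over
    the locus's qualifying variants; missing genotypes never support carrier
    status. Returns ``(is_carrier, supporting)`` where supporting is the list
    of qualifying variant keys, or of in-trans key pairs for compound_het.

    Modes: ``heterozygous_one`` needs >=1 variant with an alternate allele;
    ``two_variants`` needs >=2 distinct such variants (candidate compound
    heterozygote, phase-agnostic); ``homozygous`` needs >=1 hom-alt call;
    ``compound_het`` needs alternates of two distinct variants on opposite
    haplotypes, so a single phased hom-alt site satisfies homozygous but never
    compound_het, while hom-alt plus a het elsewhere does.
    """
    carried = _carried(genotype_items)
    if mode == "heterozygous_one":
        keys = [k for k, _ in carried]
        return (len(keys) >= 1, keys)
    if mode == "two_variants":
        keys = [k for k, _ in carried]
        return (len(keys) >= 2, keys if len(keys) >= 2 else [])
    if mode == "homozygous":
        keys = [k for k, gt in carried if gt.is_hom_alt]
        return (len(keys) >= 1, keys)
    if mode == "compound_het":
        hap_a, hap_b = [], []
        for k, gt in carried:
            if len(gt.alleles) < 2:
                continue  # hemizygous calls cannot be compound heterozygous
            if not gt.phased:
                raise PhaseError(
                    f"unphased genotype at {k} in compound_het mode; "
                    "use trio-based resolution for unphased cohorts"
                )
            if gt.alleles[0] is not None and gt.alleles[0] >= 1:
                hap_a.append(k)
            if gt.alleles[1] is not None and gt.alleles[1] >= 1:
                hap_b.append(k)
        pairs = [(v, w) for v in hap_a for w in hap_b if v != w]
        return (len(pairs) >= 1, pairs)
    raise ValueError(f"unknown mode: {mode!r}")


def count_carriers(
    locus_map: Mapping[str, Sequence[VariantRecord]],
    samples: Sequence[str],
    mode: str,
) -> list:
    """Evaluate carrier status of every sample at every locus.

    Returns one :class:`TranscriptCarrierSet` per locus with at least one
    carrier, sorted by locus id. Loci with zero carriers are omitted (the
    enrichment stage reconstructs the test universe from both cohorts).
    """
    out = []
    for locus in sorted(locus_map):
        recs = locus_map[locus]
        cs = TranscriptCarrierSet(locus)
        for sample in samples:
            items = [(rec.key, rec.genotypes.get(sample)) for rec in recs]
            is_carrier, supporting = carrier_status(items, mode)
            if is_carrier:
                cs.carriers.add(sample)
                cs.carrier_variants[sample] = supporting
        if cs.carriers:
            out.append(cs)
    return out


# ---------------------------------------------------------------------------
# Output files (counts / carrier / per-sample variants)
# ---------------------------------------------------------------------------

def format_key(key: tuple) -> str:
    chrom, pos, ref, alt = key
    return f"{chrom}:{pos}:{ref}:{alt}"


def parse_key(text: str) -> tuple:
    chrom, pos, ref, alt = text.split(":")
    return (chrom, int(pos), ref, alt)


def _flatten_keys(supporting) -> list:
    keys = []
    for item in supporting:
        if item and isinstance(item[0], tuple):  # an in-trans pair
            keys.extend(item)
        else:
            keys.append(item)
    seen = []
    for k in keys:
        if k not in seen:
            seen.append(k)
    return seen


def write_counts(dest, carrier_sets: Sequence[TranscriptCarrierSet]) -> None:
    _write(dest, "".join(f"{cs.locus_id}\t{cs.count}\n" for cs in carrier_sets))


def write_carriers(dest, carrier_sets: Sequence[TranscriptCarrierSet]) -> None:
    _write(
        dest,
        "".join(
            f"{cs.locus_id}\t{','.join(sorted(cs.carriers))}\n" for cs in carrier_sets
        ),
    )


def write_sample_variants(dest, carrier_sets: Sequence[TranscriptCarrierSet]) -> None:
    lines = []
    for cs in carrier_sets:
        for sample in sorted(cs.carriers):
            keys = _flatten_keys(cs.carrier_variants[sample])
            lines.append(
                f"{sample}\t{cs.locus_id}\t{','.join(format_key(k) for k in keys)}\n"
            )
    _write(dest, "".join(lines))


def read_sample_variants(source) -> list:
    """Rebuild carrier sets (keys only, no pair structure) from the TSV."""
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source, "rt") as fh:
            lines = fh.read().splitlines()
    by_locus: dict = {}
    for line in lines:
        if not line.strip():
            continue
        sample, locus, keys = line.split("\t")
        cs = by_locus.setdefault(locus, TranscriptCarrierSet(locus))
        cs.carriers.add(sample)
        cs.carrier_variants[sample] = [parse_key(k) for k in keys.split(",") if k]
    return [by_locus[locus] for locus in sorted(by_locus)]


def _write(dest, text: str) -> None:
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        with open(dest, "wt") as fh:
            fh.write(text)
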