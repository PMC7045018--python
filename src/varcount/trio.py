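"""Transmission phasing of candidate compound heterozygotes in trios.

Probands sequenced without phasing cannot be queried for in-trans pairs
directly; parental genotypes determine which parent transmitted each variant.
Two variants inherited from different single parents are in trans; two from
the same single parent are in cis. De novo variants (in neither parent) are
excluded, as are pairs whose transmission cannot be established.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

from .counting import TranscriptCarrierSet, format_key
from .model import Genotype, SampleInfo, VariantRecord

__all__ = [
    "TrioGenotypes",
    "PhaseCall",
    "Pedigree",
    "transmission_origin",
    "classify_pair",
    "resolve_trio_cohort",
    "write_phase_audit",
]

ORIGINS = (
    "maternal_only",
    "paternal_only",
    "both_parents",
    "neither_parent",
    "indeterminate",
)

CALLS = ("in_trans", "in_cis", "ambiguous", "excluded_de_novo", "excluded_missing")


@dataclass(frozen=True)
class TrioGenotypes:
    """Genotypes of one variant in one trio (parents may be missing)."""

    key: tuple
    proband: Genotype
    mother: Optional[Genotype] = None
    father: Optional[Genotype] = None


@dataclass(frozen=True)
class PhaseCall:
    """Transmission classification of one candidate variant pair."""

    pair: tuple  # (variant key, variant key)
    call: str

    def __post_init__(self):
        if self.call not in CALLS:
            raise ValueError(f"unknown phase call: {self.call!r}")


def _parent_state(gt: Optional[Genotype]) -> Optional[bool]:
    """True if carrier (>=1 alt, any zygosity), False if confirmed non-carrier,
    None if missing."""
    if gt is None or gt.is_missing:
        return None
    return gt.carries_alt


def transmission_origin(tg: TrioGenotypes) -> str:
    """Classify which parent(s) could have transmitted the proband's alternate.

    Requires both parental genotypes; either missing yields ``indeterminate``.
    A Mendelian-inconsistent configuration — proband hom-alt with a confirmed
    non-carrier parent — is also ``indeterminate`` (likely genotyping error;
    it cannot inform phase). ``neither_parent`` is the de novo signal.
    """
    mother = _parent_state(tg.mother)
    father = _parent_state(tg.father)
    if mother is None or father is None:
        return "indeterminate"
    if tg.proband.is_hom_alt and not (mother and father):
        return "indeterminate"  # Mendelian error: hom-alt child needs both
    if mother and father:
        return "both_parents"
    if mother:
        return "maternal_only"
    if father:
        return "paternal_only"
    return "neither_parent"


def classify_pair(tg1: TrioGenotypes, tg2: TrioGenotypes) -> PhaseCall:
    """Decide whether two candidate variants of one proband are in trans.

    De novo exclusion dominates (either variant in neither parent), then
    missing-data exclusion; a maternal-only plus a paternal-only transmission
    is in trans; two transmissions from the same single parent are in cis; any
    configuration involving a both-parent carrier is ambiguous (transmission
    alone cannot phase it). Symmetric in its arguments.
    """
    o1, o2 = transmission_origin(tg1), transmission_origin(tg2)
    pair = (tg1.key, tg2.key)
    if "neither_parent" in (o1, o2):
        return PhaseCall(pair, "excluded_de_novo")
    if "indeterminate" in (o1, o2):
        return PhaseCall(pair, "excluded_missing")
    if "both_parents" in (o1, o2):
        return PhaseCall(pair, "ambiguous")
    if o1 != o2:
        return PhaseCall(pair, "in_trans")
    return PhaseCall(pair, "in_cis")


@dataclass
class Pedigree:
    """Maps proband ids to their registered parents."""

    parents: dict = field(default_factory=dict)  # proband -> (mother, father)

    @classmethod
    def from_sample_info(cls, samples: Sequence[SampleInfo]) -> "Pedigree":
        by_family: dict = {}
        for s in samples:
            if s.family_id is not None:
                by_family.setdefault(s.family_id, {})[s.role] = s.sample_id
        parents = {}
        for members in by_family.values():
            if "proband" in members:
                parents[members["proband"]] = (
                    members.get("mother"),
                    members.get("father"),
                )
        return cls(parents)


def _genotype_index(records: Sequence[VariantRecord]) -> dict:
    # mother/father cohorts arrive as separate record lists over the same
    # sites; merge their genotype maps per variant key
    index: dict = {}
    for rec in records:
        index.setdefault(rec.key, {}).update(rec.genotypes)
    return index


def resolve_trio_cohort(
    candidates: Sequence[TranscriptCarrierSet],
    proband_records: Sequence[VariantRecord],
    parent_records: Sequence[VariantRecord],
    pedigree: Pedigree,
    mode: str = "compound_het",
) -> tuple:
    """Resolve candidate carriers to trio-confirmed carriers.

    ``candidates`` come from :func:`varcount.counting.count_carriers` run in
    ``two_variants`` mode (for compound_het resolution) or ``homozygous`` mode.
    ``parent_records`` are the raw parental VCF records queried for genotypes.

    A proband is a final compound-het carrier at a locus iff at least one pair
    of its qualifying variants is called in_trans; one de novo member poisons
    its pair but not the proband's other pairs. A candidate homozygote is
    confirmed iff both parents carry the alternate. Probands without
    registered parents are excluded and audited.

    Returns ``(carrier_sets, audit)`` where audit rows are
    (proband, locus, key1, key2, call).
    """
    proband_gt = _genotype_index(proband_records)
    parent_gt = _genotype_index(parent_records)
    audit = []
    resolved = []
    for cand in candidates:
        cs = TranscriptCarrierSet(cand.locus_id)
        for proband in sorted(cand.carriers):
            if proband not in pedigree.parents:
                audit.append((proband, cand.locus_id, ".", ".", "excluded_missing"))
                continue
            mother_id, father_id = pedigree.parents[proband]
            keys = cand.carrier_variants[proband]

            def tg(key):
                mgt = parent_gt.get(key, {}).get(mother_id) if mother_id else None
                fgt = parent_gt.get(key, {}).get(father_id) if father_id else None
                pgt = proband_gt.get(key, {}).get(proband)
                return TrioGenotypes(key, pgt, mgt, fgt)

            if mode == "homozygous":
                supporting = []
                for key in keys:
                    origin = transmission_origin(tg(key))
                    confirmed = origin == "both_parents"
                    call = "in_trans" if confirmed else (
                        "excluded_de_novo" if origin == "neither_parent"
                        else "excluded_missing"
                    )
                    audit.append(
                        (proband, cand.locus_id, format_key(key), ".", call)
                    )
                    if confirmed:
                        supporting.append(key)
                if supporting:
                    cs.carriers.add(proband)
                    cs.carrier_variants[proband] = supporting
                continue

            trios = {key: tg(key) for key in keys}
            trans_pairs = []
            for i, k1 in enumerate(keys):
                for k2 in keys[i + 1:]:
                    call = classify_pair(trios[k1], trios[k2])
                    audit.append(
                        (
                            proband,
                            cand.locus_id,
                            format_key(k1),
                            format_key(k2),
                            call.call,
                        )
                    )
                    if call.call == "in_trans":
                        trans_pairs.append((k1, k2))
            if trans_pairs:
                cs.carriers.add(proband)
                cs.carrier_variants[proband] = trans_pairs
        if cs.carriers:
            resolved.append(cs)
    return resolved, audit


def write_phase_audit(dest, audit) -> None:
    text = "proband\tlocus\tvariant1\tvariant2\tcall\n" + "".join(
        "\t".join(row) + "\n" for row in audit
    )
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        with open(dest, "wt") as fh:
            fh.write(text)
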