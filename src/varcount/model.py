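"""Domain types and readers/writers for VCF, BED regions, parameters and sample info.

Coordinate conventions: VCF positions are 1-based; BED regions are 0-based
half-open. The conversion between the two happens only inside
:func:`restrict_to_regions`.
"""

from __future__ import annotations

import os
import re
import tempfile
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Optional, Sequence, Union

from intervaltree import IntervalTree

from .errors import ParseError, ValidationError

__all__ = [
    "Genotype",
    "TranscriptEffect",
    "FilterStatus",
    "VariantRecord",
    "SampleInfo",
    "Parameters",
    "Region",
    "MISSING",
    "IMPACT_CLASSES",
    "DEFAULT_AF_KEYS",
    "read_vcf",
    "write_vcf",
    "parse_effect_annotation",
    "read_bed",
    "restrict_to_regions",
    "read_sample_info",
    "read_parameters",
    "variant_key",
]

#: Sentinel for a missing allele call.
MISSING: Optional[int] = None

IMPACT_CLASSES = frozenset({"HIGH", "MODERATE", "LOW", "MODIFIER"})

#: Default mapping of annotated allele-frequency source name -> VCF INFO key.
DEFAULT_AF_KEYS: Mapping[str, str] = {
    "1000G": "AF_1000G",
    "ExAC": "AF_ExAC",
    "EVS": "AF_EVS",
}

MODES = ("heterozygous_one", "two_variants", "homozygous", "compound_het")
LEVELS = ("transcript", "gene")
ROLES = ("proband", "mother", "father", "control")
SEXES = ("male", "female", "unknown")


@dataclass(frozen=True)
class Genotype:
    """One sample's called genotype at one site.

    ``alleles`` is an ordered tuple of allele indices (0 = reference,
    1 = alternate, ``None`` = missing); length 1 for hemizygous calls.
    ``phased`` is True when the haplotype order of ``alleles`` is meaningful
    ('|' separator in the VCF).
    """

    alleles: tuple
    phased: bool = False

    @property
    def is_missing(self) -> bool:
        return all(a is None for a in self.alleles)

    @property
    def alt_count(self) -> int:
        return sum(1 for a in self.alleles if a is not None and a >= 1)

    @property
    def carries_alt(self) -> bool:
        return self.alt_count >= 1

    @property
    def is_hom_alt(self) -> bool:
        return (
            len(self.alleles) == 2
            and all(a is not None and a >= 1 for a in self.alleles)
        )

    def flipped(self) -> "Genotype":
        """Swap ref/alt allele indices (0<->1); missing alleles unchanged."""
        return Genotype(
            tuple(None if a is None else (1 - a) for a in self.alleles),
            self.phased,
        )

    def gt_string(self) -> str:
        sep = "|" if self.phased else "/"
        return sep.join("." if a is None else str(a) for a in self.alleles)


@dataclass(frozen=True)
class TranscriptEffect:
    """Predicted effect of a variant on one overlapping transcript."""

    transcript_id: str
    gene_symbol: str
    impact: str
    effect_term: str

    def __post_init__(self):
        if self.impact not in IMPACT_CLASSES:
            raise ValidationError(f"unknown impact class: {self.impact!r}")


@dataclass(frozen=True)
class FilterStatus:
    """The VCF FILTER column: pass flag plus the raw value."""

    raw: str = "PASS"

    @property
    def is_pass(self) -> bool:
        return self.raw in ("PASS", ".")


@dataclass
class VariantRecord:
    """One VCF site with per-sample genotypes, effects, and source allele frequencies.

    Multiallelic lines are parsed intact (``alts`` longer than 1 and
    ``multiallelic`` True); removing them is the filtering stage's job so the
    number removed can be audited.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple
    filter_status: FilterStatus = field(default_factory=FilterStatus)
    effects: list = field(default_factory=list)
    annotated_afs: dict = field(default_factory=dict)
    genotypes: dict = field(default_factory=dict)  # sample id -> Genotype
    recoded: bool = False

    def __post_init__(self):
        if self.pos < 1:
            raise ValidationError(f"position must be >= 1, got {self.pos}")
        for src, af in self.annotated_afs.items():
            if not (0.0 <= af <= 1.0):
                raise ValidationError(f"AF for {src} outside [0,1]: {af}")

    @property
    def alt(self) -> str:
        return self.alts[0]

    @property
    def multiallelic(self) -> bool:
        return len(self.alts) > 1

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


def variant_key(record: VariantRecord) -> tuple:
    """Variant identity key: (chrom, pos, ref, alt) in current orientation."""
    return record.key


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    sex: str = "unknown"
    ancestry: str = "unknown"
    role: str = "control"
    family_id: Optional[str] = None


@dataclass(frozen=True)
class Parameters:
    """Run qualifications: counting level, qualifying impacts, MAF rule, mode."""

    level: str = "transcript"
    impact_classes: frozenset = frozenset({"HIGH", "MODERATE"})
    maf_threshold: float = 0.01
    maf_sources: frozenset = frozenset({"within_dataset", "1000G", "ExAC", "EVS"})
    mode: str = "compound_het"

    def __post_init__(self):
        if self.level not in LEVELS:
            raise ValidationError(f"level must be one of {LEVELS}, got {self.level!r}")
        if self.mode not in MODES:
            raise ValidationError(f"mode must be one of {MODES}, got {self.mode!r}")
        bad = frozenset(self.impact_classes) - IMPACT_CLASSES
        if bad:
            raise ValidationError(f"unknown impact classes: {sorted(bad)}")
        if not (0.0 < self.maf_threshold <= 1.0):
            raise ValidationError(
                f"maf_threshold must be in (0, 1], got {self.maf_threshold}"
            )


@dataclass(frozen=True)
class Region:
    """A BED interval: 0-based start (inclusive), 0-based end (exclusive)."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self):
        if not self.start < self.end:
            raise ValidationError(
                f"region start must be < end, got [{self.start}, {self.end})"
            )


# ---------------------------------------------------------------------------
# VCF reading / writing
# ---------------------------------------------------------------------------

_GT_RE = re.compile(r"^(\.|\d+)([/|](\.|\d+))?$")


def _prescan_vcf(path: str) -> None:
    """Cheap structural validation producing line numbers before htslib parsing."""
    n_header_cols = None
    saw_chrom_line = False
    with open(path, "rt") as fh:
        first = fh.readline()
        if not first.startswith("##fileformat=VCFv4"):
            raise ParseError("line 1: missing ##fileformat=VCFv4.x header")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##"):
                continue
            if line.startswith("#CHROM"):
                cols = line.split("\t")
                if cols[:8] != [
                    "#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO",
                ]:
                    raise ParseError(f"line {lineno}: malformed #CHROM header line")
                saw_chrom_line = True
                n_header_cols = len(cols)
                continue
            if not saw_chrom_line:
                raise ParseError(f"line {lineno}: data before #CHROM header line")
            cols = line.split("\t")
            if len(cols) != n_header_cols:
                raise ParseError(
                    f"line {lineno}: expected {n_header_cols} columns, got {len(cols)}"
                )
            if n_header_cols > 8:
                fmt = cols[8].split(":")
                if "GT" not in fmt:
                    raise ParseError(f"line {lineno}: GT absent from FORMAT")
            if not cols[1].isdigit():
                raise ParseError(f"line {lineno}: POS is not a positive integer")
    if not saw_chrom_line:
        raise ParseError("missing #CHROM header line")


def read_vcf(
    source: Union[str, os.PathLike, IO],
    af_keys: Mapping[str, str] = DEFAULT_AF_KEYS,
) -> tuple:
    """Read a VCF 4.x file (path or text stream) into (sample ids, VariantRecords).

    Genotype phase is taken per sample per site from the '|' vs '/' separator;
    missing calls are preserved. Multiallelic lines are returned intact with
    their flag set, one :class:`VariantRecord` per line.
    """
    from cyvcf2 import VCF

    tmp = None
    try:
        if hasattr(source, "read"):
            text = source.read()
            tmp = tempfile.NamedTemporaryFile(
                "wt", suffix=".vcf", delete=False, encoding="utf-8"
            )
            tmp.write(text)
            tmp.close()
            path = tmp.name
        else:
            path = os.fspath(source)
        _prescan_vcf(path)
        try:
            vcf = VCF(path)
            samples = list(vcf.samples)
        except Exception as exc:  # htslib-level failure
            raise ParseError(f"could not open VCF {path}: {exc}") from exc
        records = []
        for rec in vcf:
            if "GT" not in (rec.FORMAT or []):
                raise ParseError(
                    f"{rec.CHROM}:{rec.POS}: GT absent from FORMAT"
                )
            genotypes = {}
            for sample, gt in zip(samples, rec.genotypes):
                *alleles, phased = gt
                genotypes[sample] = Genotype(
                    tuple(None if a < 0 else int(a) for a in alleles),
                    bool(phased),
                )
            afs = {}
            for src, key in af_keys.items():
                val = rec.INFO.get(key)
                if val is not None:
                    if isinstance(val, (tuple, list)):
                        val = val[0]
                    afs[src] = float(val)
            ann = rec.INFO.get("ANN")
            effects = parse_effect_annotation(ann) if ann else []
            records.append(
                VariantRecord(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alts=tuple(rec.ALT),
                    filter_status=FilterStatus(rec.FILTER or "PASS"),
                    effects=effects,
                    annotated_afs=afs,
                    genotypes=genotypes,
                )
            )
        return samples, records
    finally:
        if tmp is not None:
            os.unlink(tmp.name)


def _effect_to_ann(alt: str, eff: TranscriptEffect) -> str:
    # standard 16-subfield ANN entry; unused subfields left blank
    fields = [""] * 16
    fields[0] = alt
    fields[1] = eff.effect_term
    fields[2] = eff.impact
    fields[3] = eff.gene_symbol
    fields[4] = eff.gene_symbol
    fields[5] = "transcript"
    fields[6] = eff.transcript_id
    fields[7] = "protein_coding"
    return "|".join(fields)


def write_vcf(
    dest: Union[str, os.PathLike, IO],
    samples: Sequence[str],
    records: Iterable[VariantRecord],
    af_keys: Mapping[str, str] = DEFAULT_AF_KEYS,
) -> None:
    """Write records as uncompressed VCF 4.2 text.

    Round-trips chrom/pos/ref/alt/genotypes/phase bit-exactly through
    :func:`read_vcf`.
    """
    records = list(records)
    contigs = sorted({r.chrom for r in records})
    lines = ["##fileformat=VCFv4.2"]
    lines.append(
        '##INFO=<ID=ANN,Number=.,Type=String,Description="Functional annotations: '
        "'Allele | Annotation | Annotation_Impact | Gene_Name | Gene_ID | "
        "Feature_Type | Feature_ID | Transcript_BioType | Rank | HGVS.c | HGVS.p | "
        "cDNA.pos / cDNA.length | CDS.pos / CDS.length | AA.pos / AA.length | "
        "Distance | ERRORS / WARNINGS / INFO'\">"
    )
    for src, key in af_keys.items():
        lines.append(
            f'##INFO=<ID={key},Number=A,Type=Float,Description="{src} allele frequency">'
        )
    lines.append('##FILTER=<ID=LowQual,Description="Low quality">')
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for c in contigs:
        lines.append(f"##contig=<ID={c}>")
    header = ["#CHROM", "POS", "ID", "REF", "ALT", "QUAL", "FILTER", "INFO", "FORMAT"]
    header.extend(samples)
    lines.append("\t".join(header))
    key_by_src = dict(af_keys)
    for rec in records:
        info_parts = []
        if rec.effects:
            ann = ",".join(_effect_to_ann(rec.alt, e) for e in rec.effects)
            info_parts.append(f"ANN={ann}")
        for src, af in rec.annotated_afs.items():
            key = key_by_src.get(src, src)
            info_parts.append(f"{key}={af:.6g}")
        info = ";".join(info_parts) if info_parts else "."
        row = [
            rec.chrom,
            str(rec.pos),
            ".",
            rec.ref,
            ",".join(rec.alts),
            ".",
            rec.filter_status.raw,
            info,
            "GT",
        ]
        for sample in samples:
            gt = rec.genotypes.get(sample)
            row.append(gt.gt_string() if gt is not None else "./.")
        lines.append("\t".join(row))
    text = "\n".join(lines) + "\n"
    if hasattr(dest, "write"):
        dest.write(text)
    else:
        with open(dest, "wt") as fh:
            fh.write(text)


# ---------------------------------------------------------------------------
# SnpEff ANN parsing
# ---------------------------------------------------------------------------

def parse_effect_annotation(info_field: str) -> list:
    """Parse a SnpEff ``ANN`` annotation into TranscriptEffects.

    Accepts either the bare INFO value or a string with the ``ANN=`` prefix.
    One effect per comma-separated entry; pipe-delimited subfields with impact
    at index 2, gene symbol at 3, transcript (feature) id at 6. Malformed
    entries — too few subfields or an unrecognised impact class — are skipped
    with a warning. An empty/absent annotation yields an empty list.
    """
    if not info_field:
        return []
    value = info_field
    if value.startswith("ANN="):
        value = value[4:]
    effects = []
    for entry in value.split(","):
        fields = entry.split("|")
        if len(fields) < 7:
            warnings.warn(f"skipping malformed ANN entry: {entry!r}")
            continue
        impact = fields[2].strip()
        if impact not in IMPACT_CLASSES:
            warnings.warn(f"skipping ANN entry with unknown impact {impact!r}")
            continue
        effects.append(
            TranscriptEffect(
                transcript_id=fields[6].strip(),
                gene_symbol=fields[3].strip(),
                impact=impact,
                effect_term=fields[1].strip(),
            )
        )
    return effects


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------

def read_bed(source: Union[str, os.PathLike, IO]) -> list:
    """Read BED 3+1 intervals (chrom, start, end, name)."""
    if hasattr(source, "read"):
        fh = source
        close = False
    else:
        fh = open(source, "rt")
        close = True
    regions = []
    try:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ParseError(f"line {lineno}: BED needs >= 3 columns")
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as exc:
                raise ParseError(f"line {lineno}: non-integer BED coordinates") from exc
            name = cols[3] if len(cols) > 3 else ""
            regions.append(Region(cols[0], start, end, name))
    finally:
        if close:
            fh.close()
    return regions


def restrict_to_regions(
    records: Sequence[VariantRecord], regions: Sequence[Region]
) -> list:
    """Keep records whose 1-based position falls in some region on the same chromosome.

    A 0-based half-open region [start, end) covers 1-based positions p with
    start < p <= end. Record order is preserved; an empty region set yields an
    empty output.
    """
    trees: dict = {}
    for region in regions:
        trees.setdefault(region.chrom, IntervalTree()).addi(
            region.start, region.end, region.name
        )
    out = []
    for rec in records:
        tree = trees.get(rec.chrom)
        if tree is not None and tree.overlaps(rec.pos - 1):
            out.append(rec)
    return out


# ---------------------------------------------------------------------------
# Sample info and parameters files
# ---------------------------------------------------------------------------

_SAMPLE_HEADER = ["sample_id", "sex", "ancestry", "role", "family_id"]


def read_sample_info(source: Union[str, os.PathLike, IO]) -> list:
    """Read the tab-separated sample information file.

    Columns: sample_id, sex, ancestry, role, family_id ('.' or empty for
    none). Duplicate sample ids, unknown sex/role tokens, and malformed trio
    families are rejected with the offending row number.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source, "rt") as fh:
            lines = fh.read().splitlines()
    if not lines:
        raise ParseError("empty sample information file")
    header = lines[0].split("\t")
    if header != _SAMPLE_HEADER:
        raise ParseError(
            f"line 1: expected header {_SAMPLE_HEADER}, got {header}"
        )
    samples = []
    seen = set()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != 5:
            raise ParseError(f"line {lineno}: expected 5 columns, got {len(cols)}")
        sid, sex, ancestry, role, fam = (c.strip() for c in cols)
        if sid in seen:
            raise ValidationError(f"line {lineno}: duplicate sample id {sid!r}")
        seen.add(sid)
        if sex not in SEXES:
            raise ValidationError(f"line {lineno}: unknown sex token {sex!r}")
        if role not in ROLES:
            raise ValidationError(f"line {lineno}: unknown role token {role!r}")
        if not ancestry:
            raise ValidationError(f"line {lineno}: empty ancestry token")
        family_id = fam if fam not in (".", "") else None
        if role == "control" and family_id is not None:
            raise ValidationError(
                f"line {lineno}: control sample {sid!r} must not have a family"
            )
        samples.append(SampleInfo(sid, sex, ancestry, role, family_id))
    _validate_families(samples)
    return samples


def _validate_families(samples: Sequence[SampleInfo]) -> None:
    by_family: dict = {}
    for s in samples:
        if s.family_id is not None:
            by_family.setdefault(s.family_id, []).append(s)
    for fam, members in by_family.items():
        roles = [m.role for m in members]
        if roles.count("proband") != 1:
            raise ValidationError(
                f"family {fam!r} must have exactly one proband, got {roles.count('proband')}"
            )
        if roles.count("mother") > 1 or roles.count("father") > 1:
            raise ValidationError(f"family {fam!r} has more than one mother or father")


def read_parameters(source: Union[str, os.PathLike, IO]) -> Parameters:
    """Read the key=value parameters file.

    Keys: level, impacts (comma list), maf_threshold, maf_sources (comma
    list), mode.
    """
    if hasattr(source, "read"):
        lines = source.read().splitlines()
    else:
        with open(source, "rt") as fh:
            lines = fh.read().splitlines()
    kv = {}
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ParseError(f"line {lineno}: expected key=value, got {line!r}")
        key, _, value = line.partition("=")
        kv[key.strip()] = value.strip()
    kwargs = {}
    if "level" in kv:
        kwargs["level"] = kv["level"]
    if "impacts" in kv:
        kwargs["impact_classes"] = frozenset(
            t.strip() for t in kv["impacts"].split(",") if t.strip()
        )
    if "maf_threshold" in kv:
        try:
            kwargs["maf_threshold"] = float(kv["maf_threshold"])
        except ValueError as exc:
            raise ParseError(f"maf_threshold is not a number: {kv['maf_threshold']!r}") from exc
    if "maf_sources" in kv:
        kwargs["maf_sources"] = frozenset(
            t.strip() for t in kv["maf_sources"].split(",") if t.strip()
        )
    if "mode" in kv:
        kwargs["mode"] = kv["mode"]
    return Parameters(**kwargs)
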