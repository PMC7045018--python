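"""Synthetic cohorts with planted truth, emulating the study's two input shapes.

Two generators cover the study designs: a phased multi-sample control cohort
(1000 Genomes-like) queried directly for in-trans pairs, and an unphased
case-trio cohort (exome trio study-like) whose compound heterozygotes must be
resolved through parental transmission. Every qualifying carrier is planted
deliberately and recorded in a truth table, so pipeline output can be compared
exactly; nuisance sites (quality-flagged, multiallelic, MODIFIER-only, common,
and non-coding) are constructed to be removed by the corresponding filter and
therefore count-neutral.

Sites live on one synthetic chromosome per transcript; no real genome build is
involved. Case and control sites use disjoint position parities so the two
cohorts never share a variant key.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError
from .model import (
    Genotype,
    Region,
    SampleInfo,
    TranscriptEffect,
    VariantRecord,
    FilterStatus,
    write_vcf,
)

__all__ = [
    "TranscriptPlan",
    "SimulationConfig",
    "SimulatedControls",
    "SimulatedTrios",
    "simulate_controls",
    "simulate_trios",
    "inject_nuisance",
    "epi4k_like_config",
]

MODES = ("heterozygous_one", "two_variants", "homozygous", "compound_het")


@dataclass(frozen=True)
class TranscriptPlan:
    """Planted carrier counts for one synthetic transcript."""

    transcript_id: str
    gene_symbol: str = ""
    length: int = 20000
    n_background_sites: int = 4
    trans_pairs_cases: int = 0
    cis_pairs_cases: int = 0
    de_novo_pairs_cases: int = 0
    hom_carriers_cases: int = 0
    trans_pairs_controls: int = 0
    cis_pairs_controls: int = 0
    hom_carriers_controls: int = 0

    @property
    def gene(self) -> str:
        return self.gene_symbol or self.transcript_id

    @property
    def planted_cases(self) -> int:
        return (
            self.trans_pairs_cases
            + self.cis_pairs_cases
            + self.de_novo_pairs_cases
            + self.hom_carriers_cases
        )

    @property
    def planted_controls(self) -> int:
        return (
            self.trans_pairs_controls
            + self.cis_pairs_controls
            + self.hom_carriers_controls
        )


def _default_transcripts() -> tuple:
    # A small study-like panel: one strong case signal, one shared signal,
    # one EU-ancestry signal, plus loci exercising cis/de novo/homozygous
    # plants and pure background.
    return (
        TranscriptPlan("NM_PRTG.1", "PRTG", trans_pairs_cases=3),
        TranscriptPlan("NM_TNC.1", "TNC", trans_pairs_cases=2, trans_pairs_controls=1),
        TranscriptPlan("NM_MACF1.1", "MACF1", trans_pairs_cases=3),
        TranscriptPlan(
            "NM_OSBP2.1",
            "OSBP2",
            cis_pairs_cases=2,
            de_novo_pairs_cases=1,
            hom_carriers_cases=1,
        ),
        TranscriptPlan(
            "NM_STAB1.1",
            "STAB1",
            trans_pairs_controls=2,
            cis_pairs_controls=1,
            hom_carriers_controls=1,
        ),
        TranscriptPlan("NM_ABCC11.1", "ABCC11"),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """Cohort sizes, planted carriers, and nuisance-site composition.

    Defaults are the study conditions: 264 case trios (207 of European
    ancestry) against 2504 phased controls (503 European), rare-variant regime
    at 1% MAF. ``seed`` fully determines the output byte-for-byte.
    """

    n_controls: int = 2504
    n_trios: int = 264
    n_controls_eu: int = 503
    n_trios_eu: int = 207
    transcripts: tuple = field(default_factory=_default_transcripts)
    maf_threshold: float = 0.01
    planted_af: float = 5e-4
    background_af_range: tuple = (1e-4, 1e-3)
    common_af_range: tuple = (0.25, 0.75)
    af_jitter: float = 0.1
    impact_high_fraction: float = 0.3
    n_modifier_sites: int = 2
    n_multiallelic_sites: int = 1
    n_flagged_sites: int = 1
    n_common_sites: int = 1
    n_noncoding_sites: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.n_controls_eu > self.n_controls or self.n_trios_eu > self.n_trios:
            raise ValidationError("EU subset larger than cohort")
        if not (0 < self.maf_threshold <= 1):
            raise ValidationError("maf_threshold must be in (0, 1]")
        jit = 1 + self.af_jitter
        if self.background_af_range[1] * jit >= self.maf_threshold:
            raise ValidationError(
                "background AF range too close to the MAF threshold for exact truth"
            )
        if self.planted_af * jit >= self.maf_threshold:
            raise ValidationError("planted_af too close to the MAF threshold")
        lo, hi = self.common_af_range
        if lo * (1 - self.af_jitter) <= self.maf_threshold or (1 - hi) * (
            1 - self.af_jitter
        ) <= self.maf_threshold:
            raise ValidationError(
                "common AF range must stay above the MAF threshold on both "
                "minor-allele orientations"
            )
        for plan in self.transcripts:
            if plan.planted_cases > self.n_trios_eu:
                raise ValidationError(
                    f"{plan.transcript_id}: more planted case carriers than EU probands"
                )
            if plan.planted_controls > self.n_controls_eu:
                raise ValidationError(
                    f"{plan.transcript_id}: more planted control carriers than EU controls"
                )


def epi4k_like_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The bundled study-scale preset (264 trios / 2504 controls)."""
    return SimulationConfig(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

_HOM_REF_P = Genotype((0, 0), True)
_HOM_REF_U = Genotype((0, 0), False)
_BASES = ("A", "C", "G", "T")


def _ancestries(n: int, n_eu: int) -> list:
    return ["EU"] * n_eu + ["EAS"] * (n - n_eu)


def _positions(rng, length: int, n: int, parity: int, used: set, offset: int = 0) -> list:
    """Draw n distinct unused positions of the given parity in (offset, offset+length]."""
    half = length // 2
    if n > half:
        raise ValidationError("transcript too short for the requested site count")
    out = []
    while len(out) < n:
        pos = offset + 2 * int(rng.integers(1, half + 1)) - (1 - parity)
        if pos not in used:
            used.add(pos)
            out.append(pos)
    return out


def _alleles(rng) -> tuple:
    ref, alt = rng.choice(4, size=2, replace=False)
    return _BASES[ref], _BASES[alt]


def _jittered_afs(rng, af: float, jitter: float) -> dict:
    return {
        src: float(np.clip(af * (1 + rng.uniform(-jitter, jitter)), 0.0, 1.0))
        for src in ("1000G", "ExAC", "EVS")
    }


def _effect(rng, plan: TranscriptPlan, cfg: SimulationConfig, impact=None):
    if impact is None:
        high = rng.random() < cfg.impact_high_fraction
        impact = "HIGH" if high else "MODERATE"
        term = "stop_gained" if high else "missense_variant"
    else:
        term = {"MODIFIER": "intron_variant", "LOW": "synonymous_variant"}.get(
            impact, "missense_variant"
        )
    return TranscriptEffect(plan.transcript_id, plan.gene, impact, term)


def _site(
    rng,
    plan,
    cfg,
    chrom,
    pos,
    af,
    genotypes,
    *,
    impact=None,
    filter_raw="PASS",
    alts=None,
):
    ref, alt = _alleles(rng)
    return VariantRecord(
        chrom=chrom,
        pos=pos,
        ref=ref,
        alts=alts if alts is not None else (alt,),
        filter_status=FilterStatus(filter_raw),
        effects=[_effect(rng, plan, cfg, impact)],
        annotated_afs=_jittered_afs(rng, af, cfg.af_jitter),
        genotypes=genotypes,
    )


def _background_cap(cfg: SimulationConfig, n_samples: int) -> int:
    # strictly below threshold even in the worst subset: see methods note
    return max(0, math.ceil(2 * n_samples * cfg.maf_threshold) - 1)


class _Truth:
    def __init__(self):
        self.sets = {}

    def add(self, transcript_id: str, mode: str, sample_id: str) -> None:
        self.sets.setdefault((transcript_id, mode), set()).add(sample_id)

    def get(self, transcript_id: str, mode: str) -> frozenset:
        return frozenset(self.sets.get((transcript_id, mode), set()))

    def to_tsv(self) -> str:
        lines = ["transcript_id\tmode\tcarriers"]
        for (tid, mode), carriers in sorted(self.sets.items()):
            lines.append(f"{tid}\t{mode}\t{','.join(sorted(carriers))}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# control cohort (phased)
# ---------------------------------------------------------------------------

@dataclass
class SimulatedControls:
    config: SimulationConfig
    samples: list  # SampleInfo
    records: list  # VariantRecord
    regions: list  # Region
    truth: _Truth

    @property
    def sample_ids(self) -> list:
        return [s.sample_id for s in self.samples]

    def write(self, out_dir) -> None:
        os.makedirs(out_dir, exist_ok=True)
        write_vcf(os.path.join(out_dir, "controls.vcf"), self.sample_ids, self.records)
        _write_bed(os.path.join(out_dir, "regions.bed"), self.regions)
        _write_samples(os.path.join(out_dir, "samples.tsv"), self.samples)
        with open(os.path.join(out_dir, "truth.tsv"), "wt") as fh:
            fh.write(self.truth.to_tsv())


def simulate_controls(config: SimulationConfig) -> SimulatedControls:
    """Generate the phased control cohort with its truth table.

    Planted in-trans pairs appear as 0|1 at one site plus 1|0 at another of the
    target transcript; cis pairs put both alternates on the same haplotype.
    Each planted carrier has its own dedicated pair of sites, and unplanted
    samples receive at most one qualifying rare variant per transcript, so the
    per-mode truth is exact by construction.
    """
    rng = np.random.default_rng([config.seed, 17])
    ids = [f"C{i:05d}" for i in range(1, config.n_controls + 1)]
    ancestries = _ancestries(config.n_controls, config.n_controls_eu)
    samples = [
        SampleInfo(sid, "female" if i % 2 else "male", anc, "control", None)
        for i, (sid, anc) in enumerate(zip(ids, ancestries))
    ]
    eu_ids = [s.sample_id for s in samples if s.ancestry == "EU"]
    truth = _Truth()
    records = []
    regions = []
    cap = _background_cap(config, config.n_controls)

    for idx, plan in enumerate(config.transcripts):
        chrom = f"chr{idx + 1}"
        regions.append(Region(chrom, 0, plan.length, plan.transcript_id))
        used: set = set()
        taken: set = set()  # samples with a qualifying variant in this transcript

        def planted_gt(carrier, pattern):
            gts = dict.fromkeys(ids, _HOM_REF_P)
            gts[carrier] = Genotype(pattern, True)
            return gts

        n_planted = plan.planted_controls
        carriers = (
            [str(x) for x in rng.choice(eu_ids, size=n_planted, replace=False)]
            if n_planted
            else []
        )
        it = iter(carriers)

        for _ in range(plan.trans_pairs_controls):
            carrier = next(it)
            taken.add(carrier)
            p1, p2 = _positions(rng, plan.length, 2, 0, used)
            records.append(
                _site(rng, plan, config, chrom, p1, config.planted_af, planted_gt(carrier, (0, 1)))
            )
            records.append(
                _site(rng, plan, config, chrom, p2, config.planted_af, planted_gt(carrier, (1, 0)))
            )
            for mode in ("compound_het", "two_variants", "heterozygous_one"):
                truth.add(plan.transcript_id, mode, carrier)
        for _ in range(plan.cis_pairs_controls):
            carrier = next(it)
            taken.add(carrier)
            for pos in _positions(rng, plan.length, 2, 0, used):
                records.append(
                    _site(rng, plan, config, chrom, pos, config.planted_af, planted_gt(carrier, (0, 1)))
                )
            for mode in ("two_variants", "heterozygous_one"):
                truth.add(plan.transcript_id, mode, carrier)
        for _ in range(plan.hom_carriers_controls):
            carrier = next(it)
            taken.add(carrier)
            (pos,) = _positions(rng, plan.length, 1, 0, used)
            records.append(
                _site(rng, plan, config, chrom, pos, config.planted_af, planted_gt(carrier, (1, 1)))
            )
            for mode in ("homozygous", "heterozygous_one"):
                truth.add(plan.transcript_id, mode, carrier)

        # rare background: at most one qualifying variant per unplanted sample
        for pos in _positions(rng, plan.length, plan.n_background_sites, 0, used):
            af = rng.uniform(*config.background_af_range)
            pool = [s for s in ids if s not in taken]
            k = min(int(rng.binomial(2 * config.n_controls, af)), cap, len(pool))
            gts = dict.fromkeys(ids, _HOM_REF_P)
            chosen = [str(x) for x in rng.choice(pool, size=k, replace=False)] if k else []
            for carrier in chosen:
                taken.add(carrier)
                gts[carrier] = Genotype((0, 1) if rng.random() < 0.5 else (1, 0), True)
                truth.add(plan.transcript_id, "heterozygous_one", carrier)
            records.append(_site(rng, plan, config, chrom, pos, af, gts))

        records.extend(
            _nuisance_sites_controls(rng, plan, config, chrom, ids, used)
        )

    records.sort(key=lambda r: (r.chrom, r.pos))
    return SimulatedControls(config, samples, records, regions, truth)


def _nuisance_sites_controls(rng, plan, cfg, chrom, ids, used) -> list:
    out = []

    def sprinkle(phased=True, allele=1):
        gts = dict.fromkeys(ids, _HOM_REF_P)
        for sid in rng.choice(ids, size=min(3, len(ids)), replace=False):
            gts[sid] = Genotype((0, allele), phased)
        return gts

    for pos in _positions(rng, plan.length, cfg.n_modifier_sites, 0, used):
        af = rng.uniform(*cfg.background_af_range)
        out.append(_site(rng, plan, cfg, chrom, pos, af, sprinkle(), impact="MODIFIER"))
    for pos in _positions(rng, plan.length, cfg.n_flagged_sites, 0, used):
        af = rng.uniform(*cfg.background_af_range)
        out.append(_site(rng, plan, cfg, chrom, pos, af, sprinkle(), filter_raw="LowQual"))
    for pos in _positions(rng, plan.length, cfg.n_multiallelic_sites, 0, used):
        af = rng.uniform(*cfg.background_af_range)
        gts = sprinkle(allele=int(rng.integers(1, 3)))
        ref, a1 = _alleles(rng)
        a2 = next(b for b in _BASES if b not in (ref, a1))
        out.append(
            _site(rng, plan, cfg, chrom, pos, af, gts, alts=(a1, a2))
        )
    for pos in _positions(rng, plan.length, cfg.n_common_sites, 0, used):
        af = rng.uniform(*cfg.common_af_range)
        gts = {
            sid: Genotype(
                (int(rng.random() < af), int(rng.random() < af)), True
            )
            for sid in ids
        }
        out.append(_site(rng, plan, cfg, chrom, pos, af, gts))
    # qualifying-impact sites outside the coding regions, removed by the
    # region restriction
    for pos in _positions(rng, plan.length, cfg.n_noncoding_sites, 0, used, offset=plan.length):
        af = rng.uniform(*cfg.background_af_range)
        out.append(_site(rng, plan, cfg, chrom, pos, af, sprinkle()))
    return out


# ---------------------------------------------------------------------------
# trio cohort (unphased)
# ---------------------------------------------------------------------------

@dataclass
class SimulatedTrios:
    config: SimulationConfig
    samples: list  # SampleInfo for probands, mothers, fathers
    proband_records: list
    mother_records: list
    father_records: list
    regions: list
    truth: _Truth

    @property
    def proband_ids(self) -> list:
        return [s.sample_id for s in self.samples if s.role == "proband"]

    def write(self, out_dir) -> None:
        os.makedirs(out_dir, exist_ok=True)
        mothers = [s.sample_id for s in self.samples if s.role == "mother"]
        fathers = [s.sample_id for s in self.samples if s.role == "father"]
        write_vcf(os.path.join(out_dir, "probands.vcf"), self.proband_ids, self.proband_records)
        write_vcf(os.path.join(out_dir, "mothers.vcf"), mothers, self.mother_records)
        write_vcf(os.path.join(out_dir, "fathers.vcf"), fathers, self.father_records)
        _write_bed(os.path.join(out_dir, "regions.bed"), self.regions)
        _write_samples(os.path.join(out_dir, "samples.tsv"), self.samples)
        with open(os.path.join(out_dir, "truth.tsv"), "wt") as fh:
            fh.write(self.truth.to_tsv())


class _TrioSiteBuilder:
    """Accumulates one site's genotypes across the three per-role VCFs."""

    def __init__(self, probands, mothers, fathers):
        self.probands = probands
        self.mothers = mothers
        self.fathers = fathers
        self.reset()

    def reset(self):
        self.p = dict.fromkeys(self.probands, _HOM_REF_U)
        self.m = dict.fromkeys(self.mothers, _HOM_REF_U)
        self.f = dict.fromkeys(self.fathers, _HOM_REF_U)


def simulate_trios(config: SimulationConfig) -> SimulatedTrios:
    """Generate the unphased case-trio cohort with its truth table.

    Planted in-trans pairs are realized as one maternally and one paternally
    transmitted heterozygote; cis pairs come from a single parent; de novo
    pairs have one member absent from both parents. All other genotypes are
    Mendelian-consistent. Planted carriers are drawn from the European-
    ancestry probands so ancestry-restricted runs see the same planted counts.
    """
    rng = np.random.default_rng([config.seed, 29])
    n = config.n_trios
    probands = [f"P{i:04d}" for i in range(1, n + 1)]
    mothers = [f"M{i:04d}" for i in range(1, n + 1)]
    fathers = [f"F{i:04d}" for i in range(1, n + 1)]
    ancestries = _ancestries(n, config.n_trios_eu)
    samples = []
    for i in range(n):
        fam = f"FAM{i + 1:04d}"
        samples.append(SampleInfo(probands[i], "male" if i % 2 else "female", ancestries[i], "proband", fam))
        samples.append(SampleInfo(mothers[i], "female", ancestries[i], "mother", fam))
        samples.append(SampleInfo(fathers[i], "male", ancestries[i], "father", fam))
    mother_of = dict(zip(probands, mothers))
    father_of = dict(zip(probands, fathers))
    eu_probands = [probands[i] for i in range(n) if ancestries[i] == "EU"]

    truth = _Truth()
    p_records, m_records, f_records = [], [], []
    regions = []
    cap = _background_cap(config, n)
    het = Genotype((0, 1), False)
    hom = Genotype((1, 1), False)

    for idx, plan in enumerate(config.transcripts):
        chrom = f"chr{idx + 1}"
        regions.append(Region(chrom, 0, plan.length, plan.transcript_id))
        used: set = set()
        taken: set = set()
        builder = _TrioSiteBuilder(probands, mothers, fathers)

        def emit(pos, af, *, impact=None, filter_raw="PASS", alts=None):
            p_records.append(
                _site(rng, plan, config, chrom, pos, af, builder.p,
                      impact=impact, filter_raw=filter_raw, alts=alts)
            )
            # identical site definition, per-role genotypes
            for recs, gts in ((m_records, builder.m), (f_records, builder.f)):
                last = p_records[-1]
                recs.append(
                    VariantRecord(
                        chrom=chrom, pos=pos, ref=last.ref, alts=last.alts,
                        filter_status=last.filter_status, effects=list(last.effects),
                        annotated_afs=dict(last.annotated_afs), genotypes=gts,
                    )
                )
            builder.reset()

        n_planted = plan.planted_cases
        carriers = (
            [str(x) for x in rng.choice(eu_probands, size=n_planted, replace=False)]
            if n_planted
            else []
        )
        it = iter(carriers)

        for _ in range(plan.trans_pairs_cases):
            carrier = next(it)
            taken.add(carrier)
            first_maternal = bool(rng.random() < 0.5)
            for pos, maternal in zip(
                _positions(rng, plan.length, 2, 1, used),
                (first_maternal, not first_maternal),
            ):
                builder.p[carrier] = het
                side = builder.m if maternal else builder.f
                side[mother_of[carrier] if maternal else father_of[carrier]] = het
                emit(pos, config.planted_af)
            for mode in ("compound_het", "two_variants", "heterozygous_one"):
                truth.add(plan.transcript_id, mode, carrier)
        for _ in range(plan.cis_pairs_cases):
            carrier = next(it)
            taken.add(carrier)
            maternal = bool(rng.random() < 0.5)
            for pos in _positions(rng, plan.length, 2, 1, used):
                builder.p[carrier] = het
                side = builder.m if maternal else builder.f
                side[mother_of[carrier] if maternal else father_of[carrier]] = het
                emit(pos, config.planted_af)
            for mode in ("two_variants", "heterozygous_one"):
                truth.add(plan.transcript_id, mode, carrier)
        for _ in range(plan.de_novo_pairs_cases):
            carrier = next(it)
            taken.add(carrier)
            p1, p2 = _positions(rng, plan.length, 2, 1, used)
            maternal = bool(rng.random() < 0.5)
            builder.p[carrier] = het
            side = builder.m if maternal else builder.f
            side[mother_of[carrier] if maternal else father_of[carrier]] = het
            emit(p1, config.planted_af)
            builder.p[carrier] = het  # de novo: absent from both parents
            emit(p2, config.planted_af)
            for mode in ("two_variants", "heterozygous_one"):
                truth.add(plan.transcript_id, mode, carrier)
        for _ in range(plan.hom_carriers_cases):
            carrier = next(it)
            taken.add(carrier)
            (pos,) = _positions(rng, plan.length, 1, 1, used)
            builder.p[carrier] = hom
            builder.m[mother_of[carrier]] = het
            builder.f[father_of[carrier]] = het
            emit(pos, config.planted_af)
            for mode in ("homozygous", "heterozygous_one"):
                truth.add(plan.transcript_id, mode, carrier)

        for pos in _positions(rng, plan.length, plan.n_background_sites, 1, used):
            af = rng.uniform(*config.background_af_range)
            pool = [s for s in probands if s not in taken]
            k = min(int(rng.binomial(2 * n, af)), cap, len(pool))
            chosen = [str(x) for x in rng.choice(pool, size=k, replace=False)] if k else []
            for carrier in chosen:
                taken.add(carrier)
                builder.p[carrier] = het
                maternal = bool(rng.random() < 0.5)
                side = builder.m if maternal else builder.f
                side[mother_of[carrier] if maternal else father_of[carrier]] = het
                truth.add(plan.transcript_id, "heterozygous_one", carrier)
            emit(pos, af)

        _nuisance_sites_trios(
            rng, plan, config, chrom, used, builder, emit,
            probands, mother_of, father_of,
        )

    for recs in (p_records, m_records, f_records):
        recs.sort(key=lambda r: (r.chrom, r.pos))
    return SimulatedTrios(
        config, samples, p_records, m_records, f_records, regions, truth
    )


def _nuisance_sites_trios(
    rng, plan, cfg, chrom, used, builder, emit, probands, mother_of, father_of
):
    het = Genotype((0, 1), False)

    def sprinkle(allele=1):
        g = Genotype((0, allele), False)
        for sid in rng.choice(probands, size=min(3, len(probands)), replace=False):
            builder.p[sid] = g
            side = builder.m if rng.random() < 0.5 else builder.f
            side[mother_of[sid] if side is builder.m else father_of[sid]] = g

    for pos in _positions(rng, plan.length, cfg.n_modifier_sites, 1, used):
        sprinkle()
        emit(pos, rng.uniform(*cfg.background_af_range), impact="MODIFIER")
    for pos in _positions(rng, plan.length, cfg.n_flagged_sites, 1, used):
        sprinkle()
        emit(pos, rng.uniform(*cfg.background_af_range), filter_raw="LowQual")
    for pos in _positions(rng, plan.length, cfg.n_multiallelic_sites, 1, used):
        sprinkle(allele=int(rng.integers(1, 3)))
        ref, a1 = _alleles(rng)
        a2 = next(b for b in _BASES if b not in (ref, a1))
        emit(pos, rng.uniform(*cfg.background_af_range), alts=(a1, a2))
    for pos in _positions(rng, plan.length, cfg.n_common_sites, 1, used):
        af = rng.uniform(*cfg.common_af_range)
        for sid in probands:
            mgt = Genotype((int(rng.random() < af), int(rng.random() < af)), False)
            fgt = Genotype((int(rng.random() < af), int(rng.random() < af)), False)
            builder.m[mother_of[sid]] = mgt
            builder.f[father_of[sid]] = fgt
            builder.p[sid] = Genotype(
                (
                    mgt.alleles[int(rng.random() < 0.5)],
                    fgt.alleles[int(rng.random() < 0.5)],
                ),
                False,
            )
        emit(pos, af)
    for pos in _positions(rng, plan.length, cfg.n_noncoding_sites, 1, used, offset=plan.length):
        sprinkle()
        emit(pos, rng.uniform(*cfg.background_af_range))


# ---------------------------------------------------------------------------
# standalone nuisance injection
# ---------------------------------------------------------------------------

def inject_nuisance(
    records: Sequence[VariantRecord],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> list:
    """Add filter-removable nuisance sites to an existing phased record set.

    Adds, per transcript represented in ``records``: MODIFIER-only sites,
    quality-flagged sites, multiallelic sites, and common (above-threshold AF)
    sites, at fresh positions. All injected sites are removed by the standard
    filter chain, so final counts are unchanged. Returns a new sorted list.
    """
    if rng is None:
        rng = np.random.default_rng([config.seed, 43])
    by_transcript: dict = {}
    sample_ids: list = []
    for rec in records:
        if rec.genotypes and not sample_ids:
            sample_ids = list(rec.genotypes)
        for eff in rec.effects:
            by_transcript.setdefault((rec.chrom, eff.transcript_id, eff.gene_symbol), set()).add(rec.pos)
    out = list(records)
    for (chrom, tid, gene), used_pos in sorted(by_transcript.items()):
        plan = TranscriptPlan(tid, gene, length=max(used_pos) + 10000)
        used = set(used_pos)
        out.extend(
            _nuisance_sites_controls(rng, plan, config, chrom, sample_ids, used)
        )
    out.sort(key=lambda r: (r.chrom, r.pos))
    return out


# ---------------------------------------------------------------------------
# bundle writers
# ---------------------------------------------------------------------------

def _write_bed(path, regions) -> None:
    with open(path, "wt") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")


def _write_samples(path, samples) -> None:
    with open(path, "wt") as fh:
        fh.write("sample_id\tsex\tancestry\trole\tfamily_id\n")
        for s in samples:
            fam = s.family_id if s.family_id is not None else "."
            fh.write(f"{s.sample_id}\t{s.sex}\t{s.ancestry}\t{s.role}\t{fam}\n")


def config_to_json(config: SimulationConfig) -> str:
    d = asdict(config)
    d["transcripts"] = [asdict(t) for t in config.transcripts]
    return json.dumps(d, indent=2)


def config_from_json(text: str) -> SimulationConfig:
    d = json.loads(text)
    if "transcripts" in d:
        d["transcripts"] = tuple(TranscriptPlan(**t) for t in d["transcripts"])
    for key in ("background_af_range", "common_af_range"):
        if key in d:
            d[key] = tuple(d[key])
    return SimulationConfig(**d)
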