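# varcount

Per-individual quantification of qualifying variants from annotated VCFs, with
compound-heterozygote resolution and case/control enrichment testing.

## The problem

Recessive disease can arise not only from homozygous variants but from
**compound heterozygotes (CH)**: two different rare variants in the same gene,
one on each parental chromosome copy (*in trans*). Detecting them requires
phase. Phased reference cohorts (such as population panels) can be queried for
in-trans pairs directly; patient exomes usually cannot, but when the patient is
sequenced as a **trio** (proband plus both parents), transmission phases the
variants: a pair inherited one from each parent is in trans, a pair from the
same single parent is in cis, and *de novo* variants (in neither parent) are
uninformative and excluded.

`varcount` implements this workflow as a library and CLI:

1. **Filter** an annotated multi-sample VCF: restrict to coding regions (BED),
   drop quality-flagged and multiallelic sites, keep variants with a HIGH or
   MODERATE predicted impact (SnpEff `ANN` annotations), recode ref/alt when
   the alternate is the major allele, and keep only variants whose minor
   allele frequency is below a threshold in *every* selected source
   (within-dataset plus annotated panels such as 1000G, ExAC, EVS). Filtered
   case and control cohorts are harmonized so a variant removed from one is
   removed from the other.
2. **Count** the individuals carrying qualifying variants per transcript (or
   gene) under a mode: `heterozygous_one` (≥1 variant), `two_variants` (≥2
   distinct variants; the phase-agnostic CH candidate set), `homozygous`, or
   `compound_het` (alternates of two distinct variants on opposite
   haplotypes). Counting is an indicator function per individual: extra
   qualifying pairs never inflate a count.
3. **Resolve** candidate compound heterozygotes in unphased probands with
   parental genotypes, excluding de novo variants and transmission patterns
   that cannot establish phase.
4. **Test** each transcript's carrier proportions between cases and controls
   with a two-sided Fisher's exact test (probability-mass rule, exact integer
   arithmetic), reporting odds ratios with Bonferroni and Benjamini–Hochberg
   adjustment over all transcripts with at least one carrier in either cohort.

A synthetic-cohort generator (`varcount.simulate`) produces both input shapes
— a phased control cohort and an unphased trio cohort — with planted in-trans,
in-cis, de novo, and homozygous carriers plus filter-removable nuisance sites,
and a per-mode truth table for validation.

## The statistic

For transcript *t*, let *a* of *n₁* cases and *c* of *n₂* controls carry
qualifying variants under the selected mode. The 2×2 table (a, b = n₁−a;
c, d = n₂−c) is tested with Fisher's exact test: conditioning on the margins,

p = Σ P(X = k) over all tables k with P(X = k) ≤ P(X = a), where X ~
Hypergeometric(n₁+n₂, n₁, a+c),

with odds ratio (a·d)/(b·c) (infinite when b·c = 0). With m transcripts
tested, Bonferroni reports min(1, m·p) and Benjamini–Hochberg the step-up
q-values.

## Worked example

Simulate study-scale cohorts — 264 unphased case trios and 2504 phased
controls — with three planted in-trans carriers at two case transcripts, two
at a third (plus one control carrier), and run the full pipeline at a 1% MAF
threshold:

```python
from varcount import pipeline, simulate
from varcount.model import Parameters
from varcount.enrichment import results_frame

config = simulate.epi4k_like_config(seed=1)
controls = simulate.simulate_controls(config)
trios = simulate.simulate_trios(config)
params = Parameters(maf_threshold=0.01, mode="compound_het")
results, *_ = pipeline.run_trio_case_control(
    trios.proband_records, trios.mother_records, trios.father_records,
    trios.samples, controls.records, controls.samples, params,
    regions=controls.regions,
)
print(results_frame(results).to_string(index=False))
```

```
  locus_id  a   b  c    d       OR        p  p_bonferroni     p_bh  m
NM_MACF1.1  3 261  0 2504      inf 0.000859      0.003435 0.001717  4
 NM_PRTG.1  3 261  0 2504      inf 0.000859      0.003435 0.001717  4
  NM_TNC.1  2 262  1 2503 19.10687 0.025479      0.101915 0.033972  4
NM_STAB1.1  0 264  2 2502  0.00000 1.000000      1.000000 1.000000  4
```

Each row is one transcript in the test universe (m = 4 transcripts had at
least one carrier somewhere). Three trio-resolved compound-het carriers among
264 probands against none of 2504 controls give the single-test p = 0.00086;
the transcript carried only by controls has OR = 0 and p = 1. A planted locus
whose case pairs were all in cis, de novo, or homozygous contributes no
compound-het carriers and does not enter the universe.

The same run from the shell:

```bash
varcount simulate --out-dir sim                 # study-scale preset
varcount count --vcf sim/trios/probands.vcf --regions sim/trios/regions.bed \
    --samples sim/trios/samples.tsv --params params.txt --out-dir candidates
varcount trio-resolve --candidates candidates/sample_variants.tsv \
    --proband-vcf sim/trios/probands.vcf --mother-vcf sim/trios/mothers.vcf \
    --father-vcf sim/trios/fathers.vcf --samples sim/trios/samples.tsv \
    --out-dir resolved
varcount count --vcf sim/controls/controls.vcf --regions sim/controls/regions.bed \
    --samples sim/controls/samples.tsv --params params_ch.txt --out-dir ctrl
varcount enrich --case-counts resolved/counts.tsv --control-counts ctrl/counts.tsv \
    --n-cases 264 --n-controls 2504 --out-dir enriched
```

where `params.txt` selects `mode=two_variants` for the unphased probands and
`params_ch.txt` selects `mode=compound_het` for the phased controls (see
`docs/methods.md` for the parameter file format).

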