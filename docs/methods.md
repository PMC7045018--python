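# Methods

## Inputs and conventions

The package consumes VCF 4.x (uncompressed text; `GT` required, per-genotype
phase read from the `|` vs `/` separator), SnpEff-style `ANN` effect
annotations (pipe-delimited subfields; impact at index 2, gene symbol at 3,
feature/transcript id at 6), annotated allele frequencies in INFO keys
(defaults `AF_1000G`, `AF_ExAC`, `AF_EVS`; configurable), BED 3+1 coding
regions, a tab-separated sample-information file (`sample_id, sex, ancestry,
role, family_id`) and a `key=value` parameters file (`level`, `impacts`,
`maf_threshold`, `maf_sources`, `mode`).

VCF positions are 1-based; BED regions are 0-based half-open. The conversion
happens in exactly one place, `restrict_to_regions`, which keeps a record at
position p iff some same-chromosome region satisfies start < p ≤ end.
Transcript identifiers are opaque keys — the package does not care whether
they are RefSeq or Ensembl, only that the annotation uses them consistently.

Multiallelic lines are parsed intact and flagged rather than split, so the
filtering stage can report how many were removed. A site is treated as
multiallelic if one line carries two ALTs *or* several lines at one position
spell more than two nucleotide values between them.

## Filtering

Order: region restriction → quality flags → multiallelic → impact →
major/minor recoding → MAF → cross-cohort harmonization. Each removal is
tallied per reason in a `FilterReport`, and input count = output count + Σ
removals on every run (tested).

* **Quality**: only `PASS` or `.` FILTER values survive.
* **Impact**: a record is kept iff at least one effect's impact is in the
  selected classes (default HIGH + MODERATE, the protein-changing set); the
  kept record retains only qualifying effects, so a variant never counts
  toward a transcript where its impact does not qualify.
* **Recoding**: when the within-cohort alternate allele frequency exceeds 0.5
  the record's orientation is flipped (allele indices 0↔1, REF/ALT swapped,
  annotated AFs complemented) so all downstream logic operates on the minor
  allele. The decision uses the within-cohort AF because it is the only
  frequency guaranteed to exist; annotated AFs are complemented, not
  consulted. The underlying flip is an involution; the conditional recode is
  idempotent and is the identity on records already in minor orientation. At
  AF exactly 0.5 nothing changes.
* **MAF**: a record survives iff its frequency is **strictly below** the
  threshold in *every* selected source for which a value exists — a variant
  common in any panel is not rare. Missing sources are not failures. The
  `within_dataset` source is the recomputed within-cohort AF over non-missing
  alleles of the analyzed samples; a record whose within-cohort AF is
  undefined (all genotypes missing) is removed when that source is selected.
  The strict inequality and the conjunction rule are package policy choices
  on points where reasonable implementations differ.
* **Harmonization**: after both cohorts are filtered with identical
  parameters, any variant key (chrom, pos, ref, alt in post-recode
  orientation) removed from one cohort by any filter is removed from the
  other; sites present in both cohorts with conflicting ref/alt — including a
  recode applied in only one — are removed from both with a warning.

Missing genotypes are never carriers and never contribute to AF denominators.
Genotype-quality (GQ/DP) thresholds are out of scope: filtering acts on the
FILTER column only.

## Counting

`group_by_locus` lists a variant under every transcript (or gene, with
`level=gene`) in its retained effect list. `carrier_status` evaluates one
sample at one locus:

* `heterozygous_one` — ≥1 variant with an alternate allele;
* `two_variants` — ≥2 distinct such variants (the phase-agnostic compound-het
  candidate definition used for unphased probands);
* `homozygous` — ≥1 hom-alt call;
* `compound_het` — two **distinct** variants with alternates on opposite
  haplotypes. A single phased hom-alt site is homozygous, not compound-het; a
  hom-alt plus a het at another site qualifies (alternates on both
  haplotypes at distinct variants). Requires phase: an unphased alternate
  raises an error directing the caller to trio resolution. Hemizygous
  single-allele calls (male X/Y) are taken as given and can never form a
  compound heterozygote; no imputation is attempted.

The count is the number of individuals, not pairs: a sample with several
qualifying pairs counts once. Counts output omits zero-carrier loci; the
enrichment stage reconstructs the test universe from both cohorts.

## Trio transmission phasing

For each candidate proband and variant, `transmission_origin` classifies the
possible transmitting parent from parental carrier status (carrier = ≥1
alternate, any zygosity — a hom-alt parent transmits necessarily and is
treated as a carrier): maternal-only, paternal-only, both-parents,
neither-parent (the de novo signal), or indeterminate when a parental
genotype is missing. A Mendelian-inconsistent configuration (hom-alt proband
with a confirmed non-carrier parent) is indeterminate and surfaces in the
audit file rather than silently informing phase.

`classify_pair` then calls a pair of candidate variants: de novo exclusion
dominates (either member in neither parent poisons the pair — but only that
pair; the proband's other pairs still compete), then missing-data exclusion;
maternal-only + paternal-only is **in trans**; two same-parent transmissions
are in cis; any configuration involving a both-parent carrier is
**ambiguous** and not counted — transmission alone cannot establish phase
there, and the package prefers specificity over recall. A proband is a final
carrier iff at least one pair is in trans. Homozygous candidates bypass
pairing: confirmed iff both parents carry the alternate. Probands without
registered parents are excluded and audited. Every pair decision is written
to a phase-audit TSV.

On configurations where both parents are unambiguous single-variant carriers,
transmission phasing is sound (never calls a truly-cis pair in trans) and
complete (tested on secretly-phased simulations).

## Enrichment

One 2×2 table per universe locus (universe = loci with ≥1 carrier in either
cohort; its size m is the number of tests; loci carried in only one cohort
get a zero cell, never dropped). The two-sided p-value follows the
probability-mass rule — the sum of hypergeometric probabilities of all
fixed-margin tables no more probable than the observed — computed on exact
integer numerators over the common denominator C(n, a+c), so cohorts of
thousands lose no precision and ties are compared exactly. The odds ratio is
the unconditional cross-product ratio with an infinity sentinel when b·c = 0
and no continuity correction. Bonferroni is min(1, m·p); Benjamini–Hochberg
is the step-up procedure with the monotonicity pass, returned in input order.
Results are sorted by (p, locus id) for determinism. The reported per-locus
p-values are single-test values; the adjusted columns are the multiple-testing
view.

## Synthetic cohorts

`simulate_controls` emulates a phased population panel; `simulate_trios`
emulates an unphased proband cohort with parental VCFs. Defaults are the
study conditions: 2504 controls (503 European), 264 trios (207 European), 1%
MAF regime. Each transcript lives on its own synthetic chromosome with a BED
region `[0, length)`; case and control sites use disjoint position parities so
the cohorts never share a variant key and harmonization is exercised as a
no-op on clean data (its behaviour is unit-tested separately).

Planting is deterministic given the seed and exact by construction:

* every planted carrier receives its **own dedicated pair of sites** (so each
  site's within-cohort AF is 1/(2n), comfortably below both the 0.5% and 1%
  thresholds at study scale, and planted counts survive ancestry
  subsetting);
* in-trans pairs are 0|1 + 1|0 in controls, or one maternally plus one
  paternally transmitted het in trios; cis pairs put both alternates on one
  haplotype / one parent; de novo pairs have one member absent from both
  parents; homozygous carriers are 1/1 with both parents het;
* rare background sites give **at most one qualifying variant per sample per
  transcript**, capped so the within-cohort allele count stays strictly below
  the threshold, so they can enlarge only the `heterozygous_one` truth set and
  never create unplanned pairs;
* planted case carriers are drawn from the European-ancestry probands, so
  ancestry-restricted runs see the same planted pair counts (background
  `heterozygous_one` truth is defined for unrestricted runs);
* nuisance sites — MODIFIER-only, quality-flagged, multiallelic, common
  (AF in a band that stays above the threshold under jitter, on both allele
  orientations, so the recode path is exercised organically), and
  qualifying-impact sites outside the BED regions — are all removed by the
  corresponding filter and are count-neutral end-to-end (tested);
* annotated panel AFs (1000G/ExAC/EVS keys) are the generating AF with ±10%
  relative jitter, exercising multi-source disagreement;
* all other genotypes are Mendelian-consistent, including common sites where
  parents are drawn binomially and the proband inherits one allele from each.

Nuisance-site counts are fixed integers per transcript rather than fractions,
which keeps count-neutrality exact. What the simulations do **not** emulate:
linkage disequilibrium, realistic site-frequency spectra, mutation-rate
heterogeneity, genotyping error, or real exome capture geometry. Passing the
truth-recovery tests therefore demonstrates the correctness of the counting
and phasing logic, not calibration on real sequencing data.

## Numerical and design choices

* Fisher p-values use exact rational arithmetic (integer binomial numerators;
  `Fraction` only for the final division), avoiding the tie-breaking epsilon
  floating-point implementations need; the test suite checks equality with an
  independent factorial-form enumeration to 1e-10 on a thousand random tables
  and cross-checks scipy.
* `adjust(pvalues, m)` accepts m ≥ len(pvalues) so a caller may adjust a
  subset of the universe; m < len is an error.
* The within-cohort AF denominator counts non-missing **alleles** (handling
  hemizygous calls naturally) rather than assuming diploid completeness.
* Deterministic orderings throughout: loci sorted in counts output, results
  sorted by (p, locus), simulation driven by a single seeded generator, so
  identical inputs and seed give byte-identical outputs.
* Problem sizes in the test suite are deliberately small (tens of samples,
  a few transcripts) with the study-scale configuration exercised in the
  headline end-to-end checks; at study scale the full pipeline runs in about
  a second.

## Known limitations

* Compound-het detection on unphased data is only as good as transmission
  phasing: both-parent-carrier configurations are discarded as ambiguous, so
  recall is conservative where population phasing might resolve them.
* Harmonization requires the caller to supply the removed-key sets collected
  during filtering (the pipeline does this); from surviving records alone,
  "removed in the other cohort" and "never present there" are
  indistinguishable.
* Streaming huge VCFs, structural variants, SnpEff execution, and
  covariate-adjusted or weighted burden tests are out of scope.
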