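# Methods

## The analysis model

The pipeline treats a candidate-gene rare-variant screen as a fixed chain:

    ingest → qualify → novelty/QC → consensus scoring → per-gene burden

Cases contribute per-sample genotype calls (VCF with GT/AD/DP/GQ) joined to
an annotated variant table (1-based hg19-style coordinates, refGene-style
consequence strings, dbNSFP-style prediction columns with `.` for missing).
Controls contribute only frequency summaries: per-dataset carrier or allele
counts with a known sample size. The default panel is the 18 tryptophan-
metabolism genes (1 protein-synthesis, 4 serotonin, 13 kynurenine-pathway),
each pinned to one RefSeq accession; gene symbols resolve through aliases
(CCBL1→KYAT1, CCBL2→KYAT3, INDO→IDO1, INDOL1→IDO2). One conflict in the
published panel description — MAOA listed with NM_001270458 in the methods
but NM_000240 in the variant table — is resolved in favour of the panel
definition (NM_001270458), with the alternative noted in the gene-set YAML.

### Qualifying filter

`qualifies = protein_altering AND (∀ dataset: MAF ≤ threshold)` with
protein-altering = {missense, stop gain, stop loss, frameshift indel,
in-frame indel, splice}. Thresholds are **inclusive** (the definitions read
"equal to or less than"): 0.005 by default, 0.0001 for gnomAD nNFE. A
variant absent from a dataset has MAF exactly 0 and is rare there — this is
forced by the inclusive rule. When a dataset publishes allele counts, MAF =
AC/2N; when it publishes only carrier counts, MAF ≈ carriers/2N, a
documented approximation that is exact for the rare heterozygous-dominated
regime the filter targets. Multi-transcript consequence cells resolve to
the panel's canonical accession when annotated there, else to the most
severe class (stopgain > frameshift > stoploss > splice > missense >
in-frame > synonymous > UTR > intronic). Indels are restricted to
coding/splice-region classes; UTR indels do not qualify.

### Novelty and sequencing QC

Novel = at most **one carrier summed across all control datasets** (the
stricter reading of "absent, or only present in a single individual"; a
per-dataset mode is one flag away). A dbSNP rs-identifier alone does not
veto novelty — dbSNP records without frequency evidence exist — unless the
strict `dbsnp_vetoes` switch is enabled. QC for novel calls: depth ≥ 25,
GQ ≥ 99 (99 is the caller cap, so equality-only would be caller-dependent),
and for heterozygous calls an alternate-read fraction in [0.35, 0.65]
inclusive; hom/hemi calls skip the balance window since a 50:50 expectation
has no meaning there. Calls whose DP/AD/GQ cannot be read are a distinct
*unevaluable* outcome, never silently dropped. X-chromosome calls are
treated as diploid unless a sex sidecar marks the sample male, in which
case single-allele calls are hemizygous. Manual read-level inspection is
out of scope; the novel-variant report carries an empty `inspect` column as
the placeholder.

### Consensus pathogenicity score

score = d/n over predictors with results; displayed rounded
half-away-from-zero to 2 decimals (matching printed values such as 0.92 =
11/12 and 0.83 = 10/12), full precision retained internally. The per-tool
deleterious categories follow dbNSFP conventions and ship as an editable
YAML table (SIFT D; PolyPhen2 D/P; LRT D; MutationTaster A/D;
MutationAssessor H/M; FATHMM D; PROVEAN D; MetaSVM/MetaLR/M-CAP D). CADD
has no categorical output, so a phred cutoff is required; the conventional
20 is the default and configurable. REVEL (0.5) and BayesDel (−0.057)
cutoffs are inclusive — the published thresholds do not state strictness
and inclusive is the common convention. Splice variants are scored over
MutationTaster (carrying NNSplice), CADD, BayesDel and an *imported* Human
Splicing Finder verdict column (HSF is a web service and is never queried);
any tool without a result drops out of the denominator. Both the rounded
and unrounded fractions are exposed, so ">80 % of tools" statements can be
evaluated either way.

## Exact 2×2 tests

Conditioning on both margins, the case count follows a central
hypergeometric distribution. The package implements the three standard
two-sided conventions — central (2·min tail, capped at 1), minlike (sum of
outcomes no more likely than observed), blaker (sum of outcomes whose
smaller-tail acceptability does not exceed the observed one) — and the
one-sided enrichment tail. The default is **central**, matching the default
of the exact2x2 R package that candidate-gene screens of this kind cite.

Numerics: masses are computed as `exp(hypergeom.logpmf)` over the support
and renormalised to sum to one (the conditional support carries all the
mass; renormalisation removes ~1e-10 accumulation error that would
otherwise leave exact-1 p-values at 0.9999999998). Likelihood and
acceptability comparisons use a relative tolerance of 1e-7 (R's convention)
so exact ties across tails are honoured. p-values are clamped to
[P(observed), 1] and snapped to 1 within 1e-9. The implementation is tested
against an exact-integer enumeration oracle (binomial-coefficient weights,
no floating point in the tie comparisons) exhaustively for all tables with
grand total ≤ 24 and on seeded samples up to total 60, for every method,
and cross-checked against `scipy.stats.fisher_exact` (minlike) and a frozen
R `fisher.test` value.

### Burden construction

Units are individuals: (count, denominator − count) per cohort, with an
allele-based construction (2N denominators) available for allele-count
summaries. The default counting mode is **observations** (distinct
variant × individual pairs; a homozygote counts once per variant), since
published reports label the counts "variants" while dividing by cohort
size; a carriers mode (distinct individuals) is one flag away. Control
counts per gene sum each dataset's carriers over the gene's annotated
qualifying sites; annotation rows without case observations still
contribute their control carriers, which keeps case and control counts
symmetric under the null. A dataset that cannot assess a gene
(`covered_genes`) yields an `n/a` row rather than a p-value. Bonferroni
corrects for the number of genes only (0.05/18 ≈ 0.00278, matching the
printed threshold), not genes × datasets, and significance is strict
(p < threshold).

### Reproduction of the published p-values

The published burden table's p = 1 rows (AADAT, GOT2, KYNU vs nNFE) are
reproduced exactly by the central and blaker methods; minlike agrees for
GOT2 and KYNU but gives 0.6167 for AADAT, where the observed count sits off
the mode of the conditional support — confirmed by exact enumeration and by
R's `fisher.test`. The borderline printed values (AFMID 0.0023, HAAO
0.0012, TPH1 0.0005, WARS 0.0022, KMO 0.0030, IDO1 0.0338, MAOA 0.1264,
TPH2 0.2814, QPRT 0.0279) are **not** reproduced by any of the eight
combinations of {central, minlike, blaker, one-sided} × {individual,
allele} constructions on the printed counts; they sit consistently between
the one-sided and central values (e.g. AFMID: central 0.0015, minlike
0.0007). The package therefore anchors its regression and acceptance
checks on the method-invariant p = 1 rows, the percentage columns
(every populated cell reproduces under half-away-from-zero rounding) and
the Bonferroni threshold. One visible consequence: under the default
central construction KMO's p-value is 0.0021 < 0.00278, so it crosses the
Bonferroni threshold although the published report (p = 0.0030) counts it
as not significant; the five published burdened genes (AFMID, HAAO, KYAT1,
TPH1, WARS) are all recovered.

## Synthetic cohort generator

`simulate_cohort` emulates the study inputs at configurable scale:

- **Geometry defaults**: 614 cases; controls nNFE n=51,592, AOGC n=967,
  MGRB n=1,144; the 18-gene panel; 8 sites per gene.
- **Sites**: positions uniform within per-gene intervals on the gene's
  contig (positions are inert to the statistics); 50 % protein-altering
  (6 % of those splice); frequencies log-uniform on [2e-6, 5e-5] for the
  80 % "rare" sites and [3e-4, 5e-3] for the rest, so most protein-altering
  sites pass the MAF gates while common sites exercise the filter.
- **Counts**: control allele counts ~ Binomial(2N, f); case carriers ~
  Binomial(n_cases, q₁) with q₁ the odds-ratio-adjusted carrier probability
  q₁ = OR·q₀/(1−q₀+OR·q₀), q₀ = 1−(1−f)², applied at protein-altering
  sites of genes with configured enrichment. Genotype QC fields: depth ~
  Poisson(40) clipped at 10, heterozygous alt reads ~ Binomial(DP, 0.5),
  GQ 99 with probability 0.97.
- **Predictions**: per tool independently missing at rate 0.08, else
  deleterious with probability 0.9 (latent deleterious) or 0.05 (benign);
  REVEL ~ Beta(8,2)/Beta(2,8) and BayesDel ~ N(±0.3, 0.15) class-
  conditionally.
- **Ground truth** is recorded from the realized draws (a site qualifies
  iff its class is protein-altering and every realized control MAF is under
  threshold), so pipeline recovery can be checked variant-by-variant.
- **Planted novel variants** appear in exactly one case with chosen QC
  attributes and ≤ 1 control carrier.

Identical parameters and seed give byte-identical fixture files.

What the generator does **not** emulate: linkage/haplotype structure
(sites are independent), sequencing-read errors and mapping artefacts
(QC fields are drawn, not derived from reads), population stratification
between control datasets, and case-ascertainment correlation between
variants. Passing tests therefore demonstrate the pipeline's logic and the
test's calibration under the assumed binomial sampling model — not
robustness to the technical and population artefacts that real WGS
comparisons face.

The count-level companion `simulate_burden_counts` draws per-gene case and
control counts directly from the same binomial model (the 2×2 model the
burden test assumes) and is used for the calibration and power studies,
where fixture files would add nothing.

## Problem sizes used by the checks

Cohort-level counts of the original screen (311 non-intergenic variants,
84 qualifying, 9 novel) depend on undeposited WGS data and are not
reproducible at desk scale; the suite substitutes property checks at sizes
chosen to keep the full run in tens of seconds: fixture-level cohorts of
120–150 cases with 5–6 sites per gene for planted-truth recovery (precision
and recall are required to be exactly 1), 2,000 count-level replicates per
gene for null calibration (rejection rate at α=0.05 must stay within
0.05 + 2 Monte-Carlo SE ≈ 0.0597; observed worst ≈ 0.018, reflecting the
conservatism of exact conditional tests), 400 replicates for power
monotonicity in the odds ratio, and ~24,000 tables for the enumeration-
oracle comparison.

## Known limitations

- Control burden counts sum carriers over annotated qualifying sites; if
  the annotation table omits control-only sites, control burden is
  understated relative to a full per-gene control scan.
- The carriers≈alleles approximation overstates MAF slightly for datasets
  reporting carrier counts with many homozygotes.
- Splice-impact assessment consumes precomputed verdicts only; no
  sequence-based splice prediction is attempted.
- CNVs/SVs and in-frame/frameshift inference from sequence are out of
  scope; consequence classes are taken from the annotation.
- The one-sided ≤ central p-value ordering holds only for
  enrichment-direction tables (observed count at or above its conditional
  expectation); the property tests scope it accordingly.
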