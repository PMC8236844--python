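# kpburden

Candidate-gene rare-variant burden analysis for the tryptophan-metabolism /
kynurenine-pathway gene panel, built for case–control screens of the kind
run on sporadic amyotrophic lateral sclerosis (SALS) whole-genome cohorts.
It is aimed at statistical geneticists who have per-sample annotated variant
calls (ANNOVAR/dbNSFP-style tables plus VCF genotypes) for a case cohort and
only frequency summaries (gnomAD-style carrier or allele counts) for their
controls.

The package implements four pieces as a single pipeline, each usable on its
own:

1. **Qualifying-variant filter.** A variant *qualifies* for burden testing
   when it alters the protein sequence (missense, stop gain/loss, coding
   indel, splice-site) **and** is rare in *every* control dataset:
   MAF ≤ 0.005 per dataset, tightened to MAF ≤ 0.0001 for very large
   cohorts such as the gnomAD non-Finnish European non-neurological subset
   (n = 51,592). Both thresholds are inclusive, and absence from a dataset
   counts as rarity. Zygosity never disqualifies a call.
2. **Novel-variant QC.** A case variant is *novel* when at most one carrier
   is seen across all control datasets (dbSNP presence tracked separately).
   Novel calls are trusted only with depth ≥ 25×, heterozygous allele
   balance within 0.50 ± 0.15 and GQ ≥ 99.
3. **Consensus pathogenicity score.** For a variant with calls from *n* of
   the 12 dbNSFP missense predictors (SIFT, PolyPhen2-HDIV/HVAR, LRT,
   MutationTaster, MutationAssessor, FATHMM, PROVEAN, MetaSVM, MetaLR,
   M-CAP, CADD), of which *d* are deleterious, the score is
   `round(d / n, 2)` — 1 means every tool with a result called the variant
   deleterious. Splice variants are scored over the splice-capable set
   (MutationTaster/NNSplice, CADD, BayesDel, imported HSF verdicts). REVEL
   (≥ 0.5 pathogenic) and BayesDel (≥ −0.057 damaging) verdicts ride along.
4. **Gene burden test.** Per gene *g* and control dataset *k*, the 2×2 table

   |           | qualifying | rest          |
   |-----------|-----------:|--------------:|
   | cases     | a          | n_cases − a   |
   | controls  | c          | N_k − c       |

   is tested with an exact conditional test; under the null, `a` follows a
   hypergeometric law given the margins. Three two-sided conventions are
   implemented — **central** (doubled smaller tail, the default of the
   exact2x2 R package and this package), **minlike** (classical Fisher,
   what R's `fisher.test` and scipy report) and **blaker** (acceptability
   method) — plus the one-sided enrichment test. Significance uses a
   Bonferroni threshold α/18 = 0.05/18 ≈ 0.00278 for the 18-gene panel.

A synthetic-cohort generator (`kpburden.simulate`) emulates the full input
file set at the study's geometry (614 cases; nNFE/AOGC/MGRB control
summaries) with planted ground truth for every stage, so the pipeline is
testable without access to any real genomes.

## Worked example

The package ships the published per-gene qualifying-variant counts from a
614-case SALS screen of this panel as reference data:

```python
from kpburden.reference import reference_burden_model

results = reference_burden_model().fit()   # central exact test, n_tests=18
print(round(results.bonferroni, 5))        # 0.00278
frame = results.frame
print(frame[(frame.dataset == "nNFE")
            & (frame.gene.isin(["AFMID", "KYAT1", "AADAT", "KYNU"]))])
```

```
 gene dataset  case_count  case_pct  control_count  control_pct  p_value p_display significant
AADAT    nNFE           1      0.16           80.0         0.16 1.000000    1.0000       False
AFMID    nNFE           8      1.30          155.0         0.30 0.001478    0.0015        True
KYAT1    nNFE          11      1.79          173.0         0.34 0.000026    0.0000        True
 KYNU    nNFE           2      0.33          170.0         0.33 1.000000    1.0000       False
```

Reading: AFMID has 8 qualifying-variant observations among 614 cases
(1.30 %) against 155 among 51,592 gnomAD nNFE controls (0.30 %); the
central exact p-value 0.0015 is below the Bonferroni threshold, so the gene
shows a case burden against this dataset. AADAT and KYNU have essentially
identical case and control proportions and give p = 1 under any two-sided
method. `results.summary()` renders the full 18-gene × 3-dataset report;
`results.significant_genes` lists the burdened genes per dataset (see
`docs/methods.md` for why KMO sits on the threshold under the central
method).

The same objects work from synthetic data end to end:

```sh
kpburden simulate --seed 1 --out-dir fx/
kpburden run --annotation fx/annotation.tsv --vcf fx/cases.vcf \
    --control nNFE=fx/controls_nNFE.tsv --control AOGC=fx/controls_AOGC.tsv \
    --control MGRB=fx/controls_MGRB.tsv --dbsnp fx/dbsnp.tsv \
    --sex fx/sex.tsv --out-dir reports/
```

which writes `burden.tsv`, `novel_variants.tsv`, `inventory.tsv` and a
`manifest.json` (input checksums + parameters) under `reports/`.

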