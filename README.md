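# editscan

De novo RNA-editing detection and clinical-relevance analysis for tumor/normal
RNA-seq cohorts.

RNA editing — most commonly adenosine-to-inosine (A-to-I) deamination by ADAR
enzymes, read as A>G by sequencers — rewires transcripts without touching the
genome. In hepatocellular carcinoma and other tumors, editing sites gained or
lost relative to normal tissue can alter protein sequence, destroy or create
miRNA binding sites, shift gene expression, and stratify patient survival.
`editscan` is a tested, reusable implementation of that whole analysis chain
for researchers who already have per-sample variant calls (VCF) from RNA-seq,
plus the usual companions: somatic-mutation calls, known-SNP positions, gene
models (GTF), genome and miRNA sequences (FASTA), raw expression counts and a
clinical table.

## What it computes

**1. Editing-site catalog.** Candidate variant observations pass a
multi-stage filter cascade: (i) per-sample somatic-mutation removal; (ii)
known-SNP and indel removal; (iii) quality gates — drop an observation when
Fisher Strand FS > 20, Quality-by-Depth QD < 2, fewer than 2 edited reads, or
coverage < 10 — plus a site-level spread rule requiring the 90% and 10%
quantiles of the editing degree across the whole cohort (zeros included) to
differ by at least 0.10; (iv) removal of 100%-degree observations (full
editing is treated as artifact); (v) recurrence in at least ⌈1%⌉ of samples.
Sites on non-canonical contigs or covered by genes on both strands are
dropped. The *editing degree* of sample *s* at a site is

```
degree = edited reads / total mapped reads
```

**2. Differential editing.** Per site, a two-sided Fisher exact test on the
edited/unedited × tumor/normal table with Benjamini–Hochberg correction.
*Gain* sites: BH p < 0.05 and edited in ≤ 5% of normals; *loss* sites the
mirror. *Dys-edited* sites are screened in the paired subcohort with a paired
t test on per-pair degree differences: BH p < 0.2 AND raw p < 0.01 AND at
least two pairs shifted by more than 0.25 in the direction of the mean.
Implicated genes are tested for gene-set over-representation
(hypergeometric, BH).

**3. Functional consequences.** CDS sites are translated codon-wise
(synonymous / non-synonymous / stop gain / stop loss; intronic sites within
2 bp of an exon boundary are splice-affecting). For 3'UTR sites, the
reference and edited 101-nt windows are scored against the mature-miRNA
catalog with a miRanda-style duplex engine (local alignment over
complementarity with seed weighting and affine gaps; nearest-neighbour stack
free energy). A miRNA–target hit requires score > 140 and ΔG < −14 kcal/mol;
per miRNA, a hit present only with the edit is an *edited gain*, only without
it an *edited loss*, and a |ΔΔG| > 14 kcal/mol shift an *edited change* —
more than 10 such changes give the site a miRNA-regulation consequence.
Editing–expression coupling is tested as the Pearson correlation between
degree and median-of-ratios-normalized expression of the host gene over the
samples where the site is edited (BH p < 0.05).

**4. Prognosis.** For HCC-related, consequence-bearing genic sites, the
per-patient editing risk score is

```
Risk = Σ_i  β_i · Exp_gene(i) · Edit_i ,   β_i = sign of the univariate Cox coefficient
```

summed over the model's sites with nonzero degree in that patient. Patients
are median-split into high/low risk (Kaplan–Meier curves, log-rank test),
scores are compared across tumor grades/stages (Wilcoxon rank-sum on the
1 / 2 / 3-plus groups), and the score is adjusted for gender, age, BMI, grade
and stage in a multivariate proportional-hazards fit (Efron ties).

**5. Synthetic cohort generator.** `editscan.simulate` emits a complete
cohort in the standard formats — genome, GTF, per-sample VCFs, mutations,
SNPs, miRNAs, counts, clinical table — with planted gain/loss/dys sites,
expression-linked and survival-linked sites, miRNA-rewiring constructs, and
artifact/confounder sites at known positions, together with ground-truth
tables sufficient to score every downstream stage. All tests and the
acceptance script run on it.

## Worked example

```
$ editscan simulate --out demo --seed 7
cohort written to demo (2000 candidate sites)

$ editscan run --cohort demo --out demo_analysis
1760 editing sites; 50 gain, 48 loss, 112 dys-edited; 110 with functional consequence
median-split log-rank p = 0.000416
```

Reading: of 2,000 candidate sites, 1,760 survive the cascade (the planted
100%-degree, low-coverage, low-quality, low-spread, SNP-overlap, dual-strand
and non-canonical artifacts are all removed). The Fisher screen recovers the
50 planted gain sites and 48 of the 50 planted loss sites; the dys screen
flags the 20 planted dys sites plus gain/loss sites that also shift within
pairs (the disjoint per-class accounting is in
`demo_analysis/differential.tsv`, column `hcc_class`). 110 sites carry a
functional consequence, and the editing risk score built from the
HCC-related consequence sites separates high- from low-risk patients at
log-rank p ≈ 4e-4 — the cohort plants its survival signal through exactly
that score form. Per-stage tables (`sites.tsv`, `annotations.tsv`,
`rewiring.tsv`, `expression_link.tsv`, `risk_model.tsv`, `multivariate.tsv`,
…) land in `demo_analysis/`.

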