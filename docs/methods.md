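# Methods

This note documents the models, decision rules, default parameters and
numerical choices behind `editscan`, and what the synthetic cohort does and
does not emulate.

## Coordinates and formats

All internal coordinates are 0-based half-open; VCF positions are shifted on
read and restored on write, BED output is emitted 0-based. Chromosome names
are normalized to the UCSC `chr` prefix. Multi-allelic VCF records are split
into one observation per alternate allele, each filtered independently.
Missing FS/QD annotations are recorded as absent — never coerced to zero —
and treated as passing the quality gate (missing metadata should not silently
delete data); the count of such observations is logged.

## Filter cascade

Observations carry (sample, site, ref, alt, ref_reads, alt_reads, FS, QD).
The per-observation predicates are applied first — per-sample mutation
overlap, cohort-wide SNP-position overlap (position-based, not
allele-matched), indel removal, the FS/QD/support/coverage gate, and the
100%-degree rule — followed by the site-level rules (quantile spread,
recurrence) computed over the surviving observations, then chromosome
restriction and dual-strand removal. The per-observation predicates commute,
so this ordering is a presentation choice, not a semantic one; a test asserts
identical output under permuted application.

Numerical conventions, fixed once and pinned by oracle tests:

* All threshold comparisons are strict as stated: FS = 20, QD = 2, support
  = 2 and coverage = 10 all survive.
* The 100%-degree rule is applied per observation by default (a single
  homozygous-like artifact should not delete a site genuinely edited in many
  samples); a `site` mode removes the whole site instead.
* The spread rule computes Q90 − Q10 by linear interpolation over the full
  cohort's degree vector, with zeros for unedited samples, and keeps the
  site when the difference is ≥ 0.10. A consequence worth knowing: with
  zeros included, a site edited in fewer than ~10–15% of samples has Q90 ≈ 0
  and is removed regardless of its degrees. The rule as stated is therefore
  also an implicit prevalence filter; the generator's planted classes are
  given prevalences above that floor so the statistical screens, not the
  spread rule, decide their fate.
* Recurrence keeps sites edited in at least ⌈0.01 × cohort size⌉ samples
  (ceiling; the fraction refers to the full tumor+normal cohort).

## Differential editing

The Fisher screen is two-sided (the ≤ 5% complementary-fraction restrictions
already impose direction); BH correction runs across all catalog sites.
"Edited" means a degree is present and > 0 after all filters. Gain requires
additionally tumor fraction > normal fraction (loss the mirror) so the two
labels cannot collide on degenerate tables. Zero-margin tables carry no
information and report p = 1.

The dys screen runs on the paired subcohort only, on per-pair differences
with absent degrees read as 0. The dual threshold is read as BH-adjusted
p < 0.2 AND raw p < 0.01 — the only reading in which both numbers bind — and
a flag restores the BH-only alternative. Zero-variance difference vectors
(t undefined) are excluded with a log message. Because a site edited only in
tumors also shifts within pairs, the gain/loss and dys screens overlap; the
reported `hcc_class` column resolves the overlap by giving the cohort-wide
Fisher label precedence, so per-class counts are disjoint, while the raw
`dys` flag is kept separately.

Gene-set enrichment is a hypergeometric upper tail against the universe of
genes carrying any catalog site, BH-corrected across terms. At the default
desk scale (60 genes) nearly every gene hosts a differential site, so the
enrichment stage is exercised for correctness (its p-values are pinned to a
combinatorial oracle) rather than for power.

## Annotation and coding consequences

Isoform conflicts resolve by the fixed precedence CDS > 3'UTR > 5'UTR >
intron (ties broken by gene id); exonic positions of non-coding transcripts
are reported as `noncoding_exon`. A-to-I is called when the reference-strand
variant is A>G on a + gene or T>C on a − gene; intergenic sites cannot be
oriented and are never flagged. Coding consequences translate the edited
codon with the standard code; intronic positions within 2 bp of an exon
boundary (the canonical donor/acceptor dinucleotides) are splice-affecting.
Transcripts with missing frames, frame offsets, or CDS length not divisible
by 3 report `unknown` rather than a guess. An exhaustive test agrees with
brute-force translation of the fully edited CDS over every single-base
substitution of ten synthetic transcripts, on both strands.

## miRNA-target rewiring

The duplex engine is a self-contained miRanda-style scorer, not a wrapper:
a three-state affine-gap local alignment of the reversed miRNA against the
101-nt target window over a complementarity scheme — Watson–Crick pair +5,
G:U wobble +2, mismatch −3, all doubled at miRNA seed positions 2–8, gap
open −4 / extend −9 — followed by an overall scale factor of 1.25, so a
perfect 22-mer scores 181.25 and the decision threshold score > 140 sits
well inside the dynamic range. The scale factor is the package's own
calibration: the published decision logic fixes the thresholds (score > 140,
ΔG < −14 kcal/mol, |ΔΔG| > 14 kcal/mol, > 10 changes for a consequence) but
not the scorer's absolute scale, and no result here depends on reproducing
another engine's exact score values. With these gap penalties a length-1 gap
(−4) costs barely more than a mismatch (−3), so optimal alignments of weakly
complementary pairs routinely carry several short gaps; the test suite
therefore checks the DP against a fully exhaustive independent oracle rather
than a single-gap enumeration.

Duplex free energy is a nearest-neighbour sum over consecutively aligned
pairs: a 16-entry Turner-like Watson–Crick stack table (kcal/mol), wobble
stacks approximated at −1.0, +4.1 duplex initiation, with unpaired and
gapped positions contributing nothing. The table is deliberately approximate
— it orders duplexes correctly and keeps the −14 kcal/mol gate meaningful,
which is all the classification uses.

Per miRNA and site, hits are aggregated across transcript windows by best
score (then lowest ΔG) before classification, so a pair yields at most one
regulation change. ΔΔG for `edited_change` is compared in absolute value
(the direction of an energy shift is not what the rule is about).

## Expression link

Size factors are median-of-ratios: the per-sample median of count/geometric
mean over genes with nonzero counts in every sample. When no such gene
exists the default is a hard error; an explicit flag enables a per-sample
pseudo-reference fallback. Normalized counts are used untransformed (a
log2(x+1) option exists). Correlations use Pearson's r with the t-transform
p-value over samples with degree > 0 and measured expression, minimum 3
such samples, BH across all tested sites.

## Prognosis

Univariate Cox fits (lifelines, Efron ties) of survival on per-site editing
degree supply the ±1 weights; non-identifiable fits — fewer than 10
patients, no event variation, constant degree, or non-convergence after a
small-ridge retry — exclude the site with a log message. The risk score sums
β · normalized expression · degree over the model's sites with nonzero
degree in the patient; patients with none score 0. The median split sends
ties to the low-risk group (a deterministic rule is needed; the choice is
immaterial for continuous scores). Grade/stage associations collapse grade 4
and stage 4 into "3 plus" before adjacent-group rank-sum tests, exact for
small tie-free groups and normal-approximated with tie correction otherwise.
The multivariate fit dummy-codes grade/stage against G1/T1, drops constant
covariates with a log message, and reports hazard ratios with 95% Wald
intervals. Sites "significantly correlated with survival" for the restricted
three-site style analysis are those with raw univariate Cox p < 0.05 (the
same fits that supplied the signs).

## Synthetic cohort: what it emulates, and what it does not

Default scale (chosen once as a desk-scale stand-in for a ~373 tumor /
50 normal cohort, minutes not hours): 80 tumor / 30 normal samples with 20
pairs; 2 chromosomes × 100 kb; 60 three-exon genes (equal strands) plus one
overlapping +/− gene pair; 2,000 candidate sites.

* Coverage ~ NegBin(mean 50, dispersion 8); edited reads ~ Binomial(n,
  degree); background degrees ~ Beta(2, 5) (mode ~0.2–0.3), prevalence ~
  U(0.15, 0.5) shared between groups.
* 50 gain sites: edited in 40% of tumors, 0% of normals, degrees ~
  Beta(8, 6). 50 loss sites: 70% of normals, 3% of tumors. The loss-side
  prevalence must exceed ~15% of the whole cohort or the spread rule removes
  the site before the statistics see it (see above); 70% of 30 normals is
  19% of the cohort.
* 20 dys sites: all pairs edited, tumor member shifted ±0.3 (direction drawn
  per site) around a shared pair-level random effect (σ = 0.05), plus
  matched prevalence outside the pairs so the Fisher screen stays null.
* ~60% of genic sites are strand-oriented A-to-I; the remainder spreads over
  T-to-C, G-to-A, C-to-T and the other substitutions in decreasing weight.
  ~55% of sites sit in 3'UTRs, then introns, CDS, 5'UTRs and intergenic.
* Artifacts at known positions exercise every filter: 100%-degree sites,
  low-coverage sites, FS/QD-violating sites, forced-constant-degree
  (low-spread) sites, SNP-overlap sites, per-sample mutation overlaps,
  dual-strand and non-canonical-contig sites, indels; plus a 3% global
  FS/QD violation rate and 2% absent-annotation rate.
* 20 expression-linked sites: gene's Poisson/log-normal mean multiplied by
  exp(−s·(degree − ½)) with s solved so the degree/normalized-expression
  Pearson correlation targets −0.6 at noise σ = 0.3.
* 5 of the gain sites carry constructed miRNAs: an 18-nt perfect complement
  of the edited (or reference) window with the edited base at miRNA seed
  position 5, so one window clears both gates (score ≈ 156 > 140) and the
  other falls below (≈ 136) — planted `edited_gain` / `edited_loss` events
  with known identity.
* 10 survival-linked sites are CDS gain sites with a forced AAA→GAA
  (Lys→Glu) edit — a guaranteed non-synonymous consequence. The true linear
  predictor is the risk-score form itself: the standardized sum of
  normalized expression × degree over these sites; survival is exponential
  with log-hazard 1.5 per SD of that score, censoring uniform on
  [100, 3000] days. Tumor grade and stage probabilities increase with the
  same predictor.

Not emulated: read-level artifacts (alignment error, strand bias actually
correlated with sequence context), linkage between neighboring sites,
Alu-cluster hyper-editing, isoform diversity (one transcript per generated
gene; multi-isoform precedence is tested on constructed models), batch
effects in expression, and non-exponential survival. Passing tests
demonstrate that the statistical machinery recovers effects of the stated
sizes under clean generative assumptions — not that the cascade's fixed
thresholds are optimal for any particular real library preparation.

## Problem sizes in the validation suite

The suite and the acceptance script run the full pipeline on the default
2,000-site cohort (and a zero-effect twin), check the filter cascade against
a brute-force oracle on 5,000 stressed observations, translate ~10⁴ edited
codons against a full-translation oracle, and use 50-replicate simulations
at n = 200 for the survival power and coverage checks — sizes chosen so the
whole suite completes in a few minutes on one CPU while keeping every
stochastic assertion comfortably away from its threshold.

## Known limitations

* The duplex scorer reproduces decision logic, not miRanda's numeric scores;
  its ΔG table is approximate.
* Site-level screens treat sites independently; no multiplicity interplay
  between the Fisher and dys families, matching the described procedure.
* The risk model inherits the instability of univariate Cox signs for
  weakly informative sites; signs are reported with their p-values so
  downstream users can restrict to stable sites.
* `quantile_spread` + zeros makes low-prevalence sites undetectable by
  construction (documented above); cohorts where rare recurrent editing
  matters need a different spread rule.
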