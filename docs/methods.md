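# Methods

`biallelic-scan` implements an exome-wide analysis of *bi-allelic* gene
alterations in tumor/normal cohorts — a damaging germline variant plus a
second somatic hit in the same gene — and of their association with somatic
phenotypes: microsatellite instability (MSI) burden, mutational signature
exposures, and age of cancer diagnosis. This note documents the models, the
defaults, the synthetic-data design, and the numerical choices.

## Alteration calling

### Germline filtering

Inputs are pre-annotated variant tables; the package never recomputes VQSR,
LOF predictions, CADD scores or ClinVar ratings. A germline variant enters
the damaging LOF set when it (1) carries the VQSR pass flag, (2) has a
high-confidence LOF consequence, (3) has allele frequency < 0.05 in every
ancestry group with a recorded frequency (seven reference-panel groups:
African, Admixed American, East Asian, Finnish, non-Finnish European, South
Asian, other), and (4) is not a homopolymer indel artifact — an indel in or
adjacent to a run of ≥ 4 identical bases whose quality-by-depth (QD) score
is < 1. Variants absent from the frequency resource are treated as novel
(AF 0): rare pathogenic variants are systematically missing from population
panels, so treating absence as failure would discard exactly the variants
of interest. "AF < 0.05 in all groups" is evaluated over groups with data;
missing groups do not fail a variant.

ClinVar pathogenicity uses a majority rule: at least half of the
contributing sources must rate the variant Pathogenic or Likely Pathogenic;
an empty rating list is not pathogenic. Two CADD cutoffs are used and kept
distinct: ≥ 30 for predicted-pathogenic germline missense, ≥ 20 for
damaging somatic missense (a deliberately more permissive somatic
sensitivity analysis). A stricter AF < 0.005 threshold is carried as a named
config key (`af_max_vus`) for rare-missense VUS candidate screens.

### Methylation silencing

Beta values (array intensity ratios in [0, 1], one probe per gene —
upstream the probe most anti-correlated with expression; an optional helper
performs that collapse when a probe-level matrix is supplied) are converted
to Z-scores within each cancer type; a sample is hyper-methylated at
Z ≥ 3 (inclusive). Choices the source conventions leave open, decided here:

* **Sample (n−1) standard deviation.** Population-vs-sample sd is
  unstated upstream; at the group sizes involved the difference is
  negligible and the sample sd is the safer default.
* **min_group_size = 10** samples per cancer type. Below that, the sd
  estimate is too unstable for a 3-sd outlier rule to mean anything;
  smaller groups yield no calls. Zero-variance groups likewise.

A gene's calls count as silencing events only if validated against
expression: an OLS fit of `log10(E + 1) ~ cancer-type + M` must give the
binary methylation indicator M a negative coefficient with two-sided
p ≤ 0.05. The +1 pseudocount handles expression zeros and is recorded in
output metadata; at typical expression levels (≥ ~100) it perturbs the
coefficient by well under 1%. Genes with zero calls are not validated;
designs where calls are perfectly confounded with one cancer type are
singular and the gene is dropped with a diagnostic.

Z-score outlier calling has an intrinsic operating range: it assumes
hyper-methylated samples are rare within a cancer type. As the contaminated
fraction grows the group mean and sd absorb the outliers and sensitivity
degrades; at the defaults (≈ 2% planted carriers, baseline beta mean 0.15,
hyper mean 0.7) sensitivity is essentially 1.

### Allelic imbalance and LOH

At each heterozygous germline site with paired read counts, a one-sided
Fisher's exact test on `[[normal_ref, normal_alt], [tumor_ref, tumor_alt]]`
asks whether the alternate (germline) allele fraction increased in the
tumor; the implementation evaluates the exact hypergeometric upper tail and
is verified against both an independent Fisher implementation and an exact
rational-arithmetic enumeration oracle to 1e-10. Sites where the germline
allele was not observed in the tumor (tumor_alt = 0) are excluded outright.
Significant sites (p ≤ 0.05, inclusive) are allelic imbalance (AI); an AI
site becomes LOH when the variant lies inside a same-sample copy-number
segment with fold change ≤ 0.9 — the value expected when 20% of tumor
cells carry a single-copy loss of a diploid locus (mean copies
f·1 + (1−f)·2 over 2, i.e. 1 − f/2). Multi-allelic (duplicated) sites are
dropped with a warning. SEG input is 1-based inclusive and converted to
0-based half-open internally; a 1-bp variant at 1-based position p is in a
segment iff start ≤ p−1 < end, and any one qualifying overlapping segment
suffices. AI-as-LOH is available as a sensitivity switch
(`use_ai_as_loh`); the strict-LOH bi-allelic set is always a subset of the
AI-mode set. No copy-neutral LOH, purity or ploidy modeling is attempted.

### Integration

A (sample, gene) is bi-allelic when a damaging germline variant co-occurs
with a second somatic hit; the mechanism label follows the priority
germline:somatic > germline:methylation > germline:LOH when several second
hits co-occur. The priority affects only the label — never whether the
pair is bi-allelic. germline:somatic events are subtyped Bi-LOF (both hits
LOF) vs Bi-Miss (at least one hit missense). By default only germline LOF
enters integration; ClinVar-pathogenic missense germline variants and
CADD ≥ 20 somatic missense are config switches. Gene-set categories are
mutually exclusive and exhaustive per sample × set: Bi-allelic > Mixed
(germline and somatic hits in different set genes) > Germ > Som > None.
LOH status comes solely from the LOH caller; no additional
tumor-observation filtering is applied to the variant after loss of the
wild-type allele.

## Association models

* **MSI model:** OLS of log10(MSI burden) on binary alteration indicators
  plus cancer-type dummies, PC1, PC2. MSI burdens of exactly 0 receive a
  half-minimum pseudocount before the log (recorded in output metadata).
  Folds are reported as 10^coefficient. Classical (non-robust) standard
  errors are the default, matching an ordinary linear-model fit; the
  statsmodels fit object supports robust alternatives if wanted.
* **Age model:** the same design on raw age; coefficients in years.
* **Age Z-scores** use each cancer type's mean and (n−1) sd.
* **DDR gene scan:** one MSI model per gene × layer (germline LOF /
  somatic LOF / methylation), Bonferroni within layer across genes actually
  testable (≥ 1 carrier and ≥ 1 non-carrier). Two exclusions restore
  causal direction: somatic frameshifts overlapping microsatellite loci are
  removed from the somatic layer (they are consequences of MSI, not
  causes — the generator plants exactly this confounding so the exclusion
  is testable), and bi-allelic MMR carriers are dropped from the cohort so
  the germline layer measures mono-allelic effects.
* **Co-occurrence:** one-sided Fisher enrichment of alteration B among
  A-positive samples, after excluding hypermutators (> 5000 somatic
  mutations).
* **Power:** the smallest N whose single-coefficient noncentral-F power
  reaches the target: df1 = 1, df2 = N − k − 1 for k predictors,
  noncentrality λ = N·f², critical value at level α. For
  f² = 6.83e−4, α = 0.05, power 0.80, k = 20 this convention gives
  N = 11,494; commonly used power software prints a value ~0.1% lower for
  the same inputs because its sub-procedure (t- vs F-family, df rounding)
  differs slightly. The convention here is frozen and verified against an
  independent Poisson-mixture evaluation of the noncentral-F distribution.

## Enrichment and signatures

Genes are ranked by bi-allelic conversion fraction (n bi-allelic / n
germline LOF carriers); genes with fewer than three germline LOF carriers
are excluded as noise. Ties break by carrier count then gene label, so the
ranking is deterministic. Preranked GSEA uses the weighted
Kolmogorov–Smirnov running sum (weight exponent 1 on |stat|; zero-stat
genes carry weight 1e−12 to keep the sum defined), defaults
minSize 3 / maxSize 500 / 20,000 permutations. The null permutes set
membership over gene labels — the only null available to a preranked
analysis. The permutation p is the +1-smoothed fraction of *same-sign*
permutation scores at least as extreme as the observed ES; conditioning on
sign is required for null p-values to be uniform (the unconditional
fraction is bounded away from 1 by P(ES ≥ 0)). NES divides ES by the mean
|permutation ES| of the same sign; q-values are Benjamini–Hochberg across
sets.

Mutation spectra use the standard 96 trinucleotide channels
(pyrimidine-strand C>A/C>G/C>T/T>A/T>C/T>G × 5′ base × 3′ base);
purine-reference substitutions are reverse-complemented, non-SNVs and
non-ACGT contexts skipped with a tally. Exposures solve non-negative least
squares on the spectrum normalized to proportions against a
column-stochastic signature matrix; relative weights < 0.06 are pruned and
the rest renormalized. This is a deliberate simplification of the
iterative forward-selection refit used by the established per-sample
deconvolution tool: with 30 signatures and one sample, plain NNLS + pruning
has the same fixed points and its recovery properties are tested directly
(identity recovery to residual < 1e−8; mixture recovery within multinomial
sampling error). No trinucleotide genome-frequency re-weighting is applied
by default (synthetic contexts are uniform); a hook accepts a 96-vector of
context weights for real-exome use.

The carrier-vs-signature test uses the Wilcoxon rank-sum statistic
(midranks for ties) with a label-shuffling permutation null:
p = (#{permuted statistic ≥ observed} + 1)/(nperm + 1), one-sided toward
higher carrier exposures by default, with a two-sided variant (doubled
smaller tail, capped at 1) available. Constant exposures report p = 1 with
a degeneracy flag. BH q-values run across the 30 signatures.

## The synthetic cohort generator

The generator emulates every data layer of a pan-cancer exome study with
planted ground truth, under the study conditions the pipeline is designed
for: 5,000 samples across nine cancer-type strata with weights, MSI and age
parameters loosely shaped like a pan-cancer cohort (GI/endometrial types
get higher baseline MSI).

**MSI burden is log-normal per cancer type.** The association model works
on log10 MSI, so a log-normal burden makes planted multiplicative folds
exactly linear on the model scale; the distributional family of real MSI
burden is not asserted, this is a modeling convenience aligned with the
log10 link. Planted carrier groups are disjoint sample sets, each with its
own fold applied on the log scale:

| group            | second hit                     | MSI fold | other effects |
|------------------|--------------------------------|----------|----------------|
| `bilof`          | somatic LOF (dual LOF)         | 2.35     | age −14 y, MMR-like signature |
| `bimiss`         | somatic missense (CADD ≥ 20)  | 1.50     | MMR-like signature |
| `biallelic`      | somatic LOF (generic dual hit) | 2.8      | MMR-like signature |
| `meth_biallelic` | hyper-methylation              | 1.0      | background signature |
| `loh`            | AI + deletion segment          | 1.0      | — |
| `somatic_only`   | somatic LOF, no germline       | 1.0      | comparison group |
| `meth_silenced`  | hyper-methylation (no germline)| 2.4      | 16% expression drop |

The three germline:somatic folds cannot coexist on one carrier group: 2.35
and 1.50 are the Bi-LOF/Bi-Miss medians against somatic-only samples while
2.8 describes dual-hit carriers against any other alteration type, so the
generator plants them on three separate groups and each is recovered by its
own indicator. The `meth_biallelic` group deliberately carries *null*
signature weights so that mixing silencing-mediated carriers into a
signature association dilutes it — the behavior the signature analysis is
supposed to expose.

Other layers: betas are Beta(7.5, 42.5) baseline (mean 0.15) with
hyper-methylated samples drawn from Beta(35, 15) (mean 0.7 — far beyond
baseline + 4 sd, so the Z ≥ 3 caller has near-perfect operating
characteristics at the default contamination); expression is log10-normal
(mean 3.0, sd 0.1) with methylated samples multiplied by (1 − 0.16);
normal allele counts are Binomial(80, 0.5), tumor counts Binomial(60, 0.5)
or Binomial(60, 0.8) at planted LOH sites (giving Fisher sensitivity
≈ 0.98 at α = 0.05), each LOH carrier also receiving an overlapping
deletion segment at fold 0.8; spectra are multinomial draws from mixtures
over a synthetic column-stochastic 96 × 30 signature matrix (sparse
Dirichlet profiles — a labelled synthetic stand-in for a reference
catalog, not a copy of one); hypermutators (1% of samples) get 6,000
mutations against a Poisson(50) background; microsatellite-overlap
frameshift counts are Poisson with rate proportional to each sample's MSI
burden (rate 30 × burden), planting the reverse-causality confounding the
DDR scan must exclude. Background germline LOF (rate 0.002 per
sample × gene) and somatic events (0.002 LOF, 0.004 missense) are
independent of all phenotypes.

Each data layer draws from its own RNG stream spawned from the master seed,
so adding or resizing one layer never perturbs another's draws;
regeneration with the same config is byte-identical.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: linkage and haplotype structure, read-level
error, purity/subclonality, correlated probe effects, realistic gene
length/mutability variation, and population stratification beyond two
small nuisance PCs. Recovery results here certify the *estimators*, not
cohort-level biology.

## Problem sizes

Simulation-based tests and the acceptance script use 5,000-sample cohorts
(the cohort size the MSI analyses are specified at), 10 seeds for
recovery averages, and reduced permutation counts (hundreds) in pipeline
round-trip tests where only plumbing is under test; full defaults
(20,000 GSEA / 10,000 label permutations) remain the production values.

## Known limitations

* The LOH caller is intentionally simple: no copy-neutral LOH, no
  subclonal modeling; AI-mode is the honest sensitivity bound.
* NNLS + pruning can split weight among correlated signatures when a
  spectrum is shallow; recovery bounds are only tested at the generator's
  depths.
* Z-score methylation calling degrades when hyper-methylation is common
  within a cancer type (see above); MLH1-like heavily methylated types in
  real cohorts would need a different caller.
* The gene-set category "Mixed" depends on set membership curation;
  categories are only as meaningful as the supplied GMT.
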