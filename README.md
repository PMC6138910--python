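# biallelic-scan

Two-hit ("bi-allelic") gene inactivation calling for paired tumor/normal
cohorts, and association of the resulting carrier groups with somatic
phenotypes. A damaging germline variant generally needs a second somatic
hit — a somatic mutation, epigenetic silencing, or loss of heterozygosity
(LOH) — before it can shape a tumor's mutational profile. This package
finds such events exome-wide and quantifies their phenotypic consequences,
for statistical geneticists and cancer genomicists working with
TCGA-shaped tabular inputs (annotated germline calls, somatic MAF,
methylation beta and expression matrices, SEG copy-number segments, paired
allele counts, per-sample clinical covariates).

## The models at the core

**Calling.** Germline LOF variants are filtered on VQSR pass, LOF
confidence, population allele frequency (< 0.05 in every ancestry group
with data) and a homopolymer-indel artifact rule (run ≥ 4, QD < 1).
Methylation silencing: per-gene, per-cancer-type Z-scores of beta values,
call at Z ≥ 3, validated by requiring the call to predict *decreased*
expression in `log10(E) ~ cancer_type + M` (p ≤ 0.05). LOH: a one-sided
Fisher exact test on `[[normal_ref, normal_alt], [tumor_ref, tumor_alt]]`
for an increased germline-allele fraction in the tumor (p ≤ 0.05), upgraded
from "allelic imbalance" to LOH when the site lies in a same-sample
copy-number segment with fold change ≤ 0.9 — the value expected for a
single-copy loss in 20% of tumor cells, since (f·1 + (1−f)·2)/2 = 1 − f/2.

**Association.** With per-sample indicators G (germline), S (somatic),
Me (methylation) for a gene or gene set:

    log10(M_i) ~ G_ij + S_ij + Me_ij + X_i        (MSI burden)
    A_i        ~ G_ij + X_i                       (age of diagnosis)

where X_i = cancer type + two ancestry PCs; fold effects are
10^coefficient. Gene ranking by bi-allelic conversion fraction feeds a
preranked permutation GSEA (weighted KS running sum, 20,000 gene-label
permutations); per-sample 96-channel spectra are deconvolved against a
30-signature matrix by non-negative least squares, and carrier/exposure
associations use a label-permutation Wilcoxon rank-sum test. A
noncentral-F routine computes the cohort size required to detect a given
Cohen's f² for one coefficient among 20 predictors.

Everything is testable without external data: `biallelic_scan.synthetic`
generates full cohorts with planted ground truth (carrier groups, MSI
folds, age shifts, expression drops, signature mixtures) under one master
seed. See `docs/methods.md` for the full model description and design
rationale.

## Worked example

```bash
python analysis/01_simulate_cohort.py     # 5,000 samples -> scratch/cohort/
python analysis/02_run_pipeline.py        # all stages   -> scratch/run/
python analysis/03_phenotype_models.py
python analysis/04_ddr_gene_scan.py
python analysis/05_enrichment_and_signatures.py
```

On the default cohort (seed 2018: 6 Bi-LOF + 4 Bi-Miss dual-hit carriers,
20 germline+methylation carriers, 50 LOH carriers, 100 samples with a
silenced translesion-synthesis gene), the pipeline reports:

```
bi-allelic events by mechanism:
germline:LOH            49
germline:methylation    20
germline:somatic        18
```

i.e. 49/50 planted LOH carriers recovered (one Fisher test underpowered at
its sampled read depths), all 20 methylation carriers, the 10 planted
dual-hit carriers plus 8 background coincidences. The gene scan finds
exactly one Bonferroni-significant methylation association:

```
 gene       layer     coef            p  n_carriers
SHPRH methylation 0.385336 3.570599e-51         100
```

10^0.385 ≈ 2.43 — the planted 2.4-fold MSI increase in samples with the
silenced gene. The MSI model on mismatch-repair-set indicators shows the
mono-allelic germline indicator near null (fold 1.08, p = 0.21) while the
somatic indicator stays inflated (fold 1.18, p = 4.3e-9) because
microsatellite-locus frameshifts accumulate *as a consequence of* MSI —
the reverse-causality confounding that the gene scan's
microsatellite-overlap exclusion removes. The dual-hit carriers' exposure
to the mismatch-repair-like signature is the top signature association
(permutation p = 1e-4, q = 0.003), and the power routine reports that
11,494 individuals would be needed to detect the mono-allelic germline MSI
effect (f² = 6.83e-4) at 80% power.

The same stages are scriptable via the `biallelic-scan` CLI
(`simulate`, `filter-germline`, `call-methylation`, `call-loh`, `gsea`,
`signatures`, `power`, `run`, `report`).

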