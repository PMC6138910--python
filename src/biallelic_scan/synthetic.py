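"""Synthetic TCGA-like cohort generator with planted ground truth.

Emulates the data layers of a pan-cancer exome study — annotated germline
variants, somatic MAF, per-gene methylation beta and expression matrices,
copy-number segments, paired tumor/normal allele counts, per-sample clinical
phenotypes, and 96-channel mutation spectra — with configurable planted
carrier groups whose effect sizes default to the cohort-scale estimates the
pipeline is designed to recover:

* Bi-LOF carriers (dual germline+somatic LOF): 2.35-fold higher MSI burden
  and a 14-year-earlier age of diagnosis;
* Bi-Miss carriers (one missense hit): 1.50-fold higher MSI burden;
* generic germline:somatic carriers: 2.8-fold higher MSI burden;
* a hyper-methylated, expression-silenced gene (``SHPRH``): a 16% expression
  decrease and a 2.4-fold MSI increase in methylated samples.

MSI burden is log-normal per cancer type (the association model works on
log10 MSI; fold effects are multiplicative). One RNG stream per data layer
is derived from the master seed so adding a layer never perturbs another
layer's draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from biallelic_scan.enrichment import read_gmt, write_gmt
from biallelic_scan.germline import GERMLINE_COLUMNS
from biallelic_scan.loh import ALLELE_COUNT_COLUMNS
from biallelic_scan.signatures import CHANNELS, synthetic_signature_matrix

MAF_COLUMNS = [
    "Hugo_Symbol",
    "Chromosome",
    "Start_Position",
    "End_Position",
    "Reference_Allele",
    "Tumor_Seq_Allele2",
    "Variant_Classification",
    "Tumor_Sample_Barcode",
    "ref_context",
    "cadd",
    "overlaps_microsatellite",
]

LOF_CLASSIFICATIONS = {
    "Nonsense_Mutation",
    "Frame_Shift_Del",
    "Frame_Shift_Ins",
    "Splice_Site",
}

L_MMR_GENES = ("MLH1", "MSH2", "MSH6", "PMS2")


@dataclass(frozen=True)
class CancerTypeSpec:
    """Per-cancer-type sampling parameters."""

    name: str
    weight: float
    msi_log10_mean: float
    msi_log10_sd: float
    age_mean: float
    age_sd: float


@dataclass(frozen=True)
class GeneSpec:
    """Gene with 0-based half-open exome coordinates."""

    name: str
    chrom: str
    start: int
    end: int


def default_cancer_types() -> tuple[CancerTypeSpec, ...]:
    # Mix loosely shaped like a pan-cancer cohort: MSI-prone GI/endometrial
    # types have higher baseline microsatellite instability.
    return (
        CancerTypeSpec("colon", 0.10, -1.7, 0.25, 65.0, 11.0),
        CancerTypeSpec("uterine", 0.08, -1.7, 0.25, 62.0, 10.0),
        CancerTypeSpec("stomach", 0.06, -1.8, 0.25, 64.0, 10.0),
        CancerTypeSpec("breast", 0.18, -2.1, 0.25, 57.0, 12.0),
        CancerTypeSpec("lung", 0.16, -2.0, 0.25, 66.0, 9.0),
        CancerTypeSpec("prostate", 0.12, -2.2, 0.25, 61.0, 8.0),
        CancerTypeSpec("glioma", 0.10, -2.2, 0.25, 50.0, 14.0),
        CancerTypeSpec("PCPG", 0.04, -2.3, 0.25, 47.0, 13.0),
        CancerTypeSpec("breast_other", 0.16, -2.1, 0.25, 58.0, 11.0),
    )


def default_gene_panel(n_filler: int = 44) -> tuple[GeneSpec, ...]:
    named = [
        "MLH1", "MSH2", "MSH6", "PMS2", "MSH5", "MLH3", "PMS1", "EXO1",
        "BRCA1", "BRCA2", "RAD51", "PALB2",
        "SHPRH", "POLH", "REV1", "POLK",
    ]
    names = named + [f"DDR{i:03d}" for i in range(1, n_filler + 1)]
    genes = []
    for i, name in enumerate(names):
        chrom = f"chr{(i % 20) + 1}"
        start = 1_000_000 + 100_000 * (i // 20)
        genes.append(GeneSpec(name, chrom, start, start + 20_000))
    return tuple(genes)


def default_gene_sets(panel_names: list[str]) -> dict[str, list[str]]:
    """Pathway-style gene sets over the default panel (GMT content)."""
    sets = {
        "MMR": ["MLH1", "MSH2", "MSH6", "PMS2", "MSH5", "MLH3", "PMS1", "EXO1"],
        "HR": ["BRCA1", "BRCA2", "RAD51", "PALB2", "DDR001", "DDR002"],
        "TLS": ["SHPRH", "POLH", "REV1", "POLK", "DDR003"],
        "NHEJ": ["DDR004", "DDR005", "DDR006", "DDR007"],
        "BER": ["DDR008", "DDR009", "DDR010", "DDR011", "DDR012"],
        "NER": ["DDR013", "DDR014", "DDR015", "DDR016", "DDR017", "DDR018"],
        "FA": ["BRCA2", "PALB2", "DDR019", "DDR020", "DDR021", "DDR022"],
        "TS": ["BRCA1", "BRCA2", "MLH1", "MSH2", "DDR023", "DDR024", "DDR025"],
        "OG": ["DDR026", "DDR027", "DDR028", "DDR029", "DDR030"],
        "PRE": ["MLH1", "MSH2", "MSH6", "PMS2", "BRCA1", "BRCA2", "DDR031"],
    }
    # filler sets so permutation nulls have company
    for i in range(8):
        lo = 31 + i
        sets[f"SET{i + 1:02d}"] = [f"DDR{j:03d}" for j in range(lo, lo + 6)]
    return {k: [g for g in v if g in set(panel_names)] for k, v in sets.items()}


def _default_mixtures() -> dict[str, dict[str, float]]:
    background = {"Signature.1": 0.6, "Signature.5": 0.4}
    mmr = {"Signature.6": 0.5, "Signature.1": 0.3, "Signature.5": 0.2}
    return {
        "background": background,
        "biallelic": mmr,
        "bilof": mmr,
        "bimiss": mmr,
        "meth_biallelic": background,  # null weights: silencing-only carriers
        "loh": background,
        "somatic_only": background,
        "meth_silenced": background,
    }


@dataclass
class ScenarioConfig:
    """Study conditions for one synthetic cohort.

    Planted carrier groups are disjoint sample sets; each receives the
    germline variant and configured second hit in its target gene plus the
    group's multiplicative MSI fold (applied on the log10 scale), the
    Bi-LOF age shift, and its signature mixture.
    """

    n_samples: int = 5000
    seed: int = 0
    cancer_types: tuple[CancerTypeSpec, ...] = field(default_factory=default_cancer_types)
    gene_panel: tuple[GeneSpec, ...] = field(default_factory=default_gene_panel)

    # planted carrier counts (disjoint groups)
    n_biallelic: int = 0          # generic germline:somatic (fold below)
    n_bilof: int = 6              # dual-LOF germline:somatic
    n_bimiss: int = 4             # germline LOF + somatic damaging missense
    n_meth_biallelic: int = 20    # germline LOF + hyper-methylation
    n_loh: int = 50               # germline LOF + allelic imbalance + deletion
    n_somatic_only: int = 200     # somatic LOF without germline hit
    n_meth_silenced: int = 100    # methylation-silenced gene, no germline hit

    # effect sizes
    msi_fold_bilof: float = 2.35
    msi_fold_bimiss: float = 1.50
    msi_fold_any_biallelic: float = 2.8
    age_shift_years_bilof: float = -14.0
    meth_expression_drop_fraction: float = 0.16
    meth_msi_fold: float = 2.4

    # background rates
    background_germline_lof_rate: float = 0.002   # per sample x gene
    background_somatic_lof_rate: float = 0.002    # per sample x gene
    background_somatic_missense_rate: float = 0.004
    ms_frameshift_scale: float = 30.0  # MSI-coupled microsatellite frameshifts
    hypermutator_fraction: float = 0.01
    hypermutator_mutations: int = 6000
    mutations_per_sample: float = 50.0

    # nuisance parameters
    expression_log10_mean: float = 3.0
    expression_log10_sd: float = 0.1
    beta_baseline: tuple[float, float] = (7.5, 42.5)   # Beta(a, b), mean 0.15
    beta_hyper: tuple[float, float] = (35.0, 15.0)     # mean 0.7, far beyond +4 sd
    normal_depth: int = 80
    tumor_depth: int = 60
    loh_alt_fraction: float = 0.8
    loh_seg_fold: float = 0.8
    n_background_het_sites: int = 2  # balanced het sites per sample

    signature_mixtures: dict[str, dict[str, float]] = field(default_factory=_default_mixtures)
    n_signatures: int = 30

    def validate(self) -> None:
        if not self.gene_panel:
            raise ValueError("empty gene panel")
        counts = [
            self.n_biallelic, self.n_bilof, self.n_bimiss, self.n_meth_biallelic,
            self.n_loh, self.n_somatic_only, self.n_meth_silenced,
        ]
        if any(c < 0 for c in counts):
            raise ValueError("planted carrier counts must be nonnegative")
        if sum(counts) > self.n_samples:
            raise ValueError(
                f"planted carriers ({sum(counts)}) exceed cohort size ({self.n_samples})"
            )
        for fold in (
            self.msi_fold_bilof, self.msi_fold_bimiss,
            self.msi_fold_any_biallelic, self.meth_msi_fold,
        ):
            if fold <= 0:
                raise ValueError("MSI fold changes must be positive")
        if not 0 <= self.meth_expression_drop_fraction < 1:
            raise ValueError("expression drop fraction must be in [0, 1)")
        for g in self.gene_panel:
            if g.start >= g.end:
                raise ValueError(f"degenerate interval for gene {g.name}")
        for group, w in self.signature_mixtures.items():
            if abs(sum(w.values()) - 1.0) > 1e-8:
                raise ValueError(f"signature mixture {group!r} does not sum to 1")

    def null(self) -> "ScenarioConfig":
        """Copy with no planted carriers and no planted effects."""
        return replace(
            self,
            n_biallelic=0, n_bilof=0, n_bimiss=0, n_meth_biallelic=0,
            n_loh=0, n_somatic_only=0, n_meth_silenced=0,
        )


@dataclass
class CohortBundle:
    """All data layers of one synthetic cohort plus the planted truth."""

    samples: pd.DataFrame
    germline: pd.DataFrame
    somatic: pd.DataFrame
    beta: pd.DataFrame
    expression: pd.DataFrame
    segments: pd.DataFrame  # 1-based inclusive SEG convention, as on disk
    allele_counts: pd.DataFrame
    spectra: pd.DataFrame
    truth: pd.DataFrame
    gene_sets: dict[str, list[str]]
    signature_matrix: pd.DataFrame

    def __eq__(self, other) -> bool:  # full-content equality
        if not isinstance(other, CohortBundle):
            return NotImplemented
        try:
            for name in (
                "samples", "germline", "somatic", "beta", "expression",
                "segments", "allele_counts", "spectra", "truth", "signature_matrix",
            ):
                pd.testing.assert_frame_equal(getattr(self, name), getattr(other, name))
        except AssertionError:
            return False
        return self.gene_sets == other.gene_sets


_GROUPS = (
    "biallelic", "bilof", "bimiss", "meth_biallelic",
    "loh", "somatic_only", "meth_silenced",
)

_NONHOMOPOLYMER_CONTEXT = "ACGTACGTACG"  # 5-base flanks, max run 1


def generate_cohort(config: ScenarioConfig) -> CohortBundle:
    """Generate a full cohort with planted ground truth (deterministic per seed)."""
    config.validate()
    streams = _streams(config.seed)
    genes = {g.name: g for g in config.gene_panel}
    gene_names = list(genes)

    # --- samples -----------------------------------------------------------
    rng = streams["samples"]
    n = config.n_samples
    sample_ids = np.array([f"S{i:05d}" for i in range(n)])
    weights = np.array([c.weight for c in config.cancer_types], dtype=float)
    weights = weights / weights.sum()
    type_idx = rng.choice(len(config.cancer_types), size=n, p=weights)
    ctypes = np.array([config.cancer_types[i].name for i in type_idx])
    age_mean = np.array([config.cancer_types[i].age_mean for i in type_idx])
    age_sd = np.array([config.cancer_types[i].age_sd for i in type_idx])
    age = np.maximum(age_mean + age_sd * rng.standard_normal(n), 1.0)
    msi_mean = np.array([config.cancer_types[i].msi_log10_mean for i in type_idx])
    msi_sd = np.array([config.cancer_types[i].msi_log10_sd for i in type_idx])
    log_msi = msi_mean + msi_sd * rng.standard_normal(n)
    pc1, pc2 = rng.standard_normal(n) * 0.02, rng.standard_normal(n) * 0.02

    # --- carrier assignment ------------------------------------------------
    rng_a = streams["assignment"]
    order = rng_a.permutation(n)
    cursor = 0
    group_of = np.full(n, "", dtype=object)
    members: dict[str, np.ndarray] = {}
    for group, count in zip(
        _GROUPS,
        (config.n_biallelic, config.n_bilof, config.n_bimiss,
         config.n_meth_biallelic, config.n_loh, config.n_somatic_only,
         config.n_meth_silenced),
    ):
        idx = order[cursor : cursor + count]
        cursor += count
        members[group] = idx
        group_of[idx] = group
    free = order[cursor:]
    n_hyper = int(round(config.hypermutator_fraction * n))
    hyper_idx = free[:n_hyper]

    # --- apply phenotype effects ------------------------------------------
    fold_of = {
        "biallelic": config.msi_fold_any_biallelic,
        "bilof": config.msi_fold_bilof,
        "bimiss": config.msi_fold_bimiss,
        "meth_biallelic": 1.0,
        "loh": 1.0,
        "somatic_only": 1.0,
        "meth_silenced": config.meth_msi_fold,
    }
    for group, idx in members.items():
        log_msi[idx] += np.log10(fold_of[group])
    age[members["bilof"]] += config.age_shift_years_bilof
    age = np.maximum(age, 1.0)
    msi_burden = 10.0**log_msi
    msi_high = log_msi >= msi_mean + 2.0 * np.maximum(msi_sd, 0.25)

    # --- target genes per planted carrier ---------------------------------
    target_cycle = {
        "biallelic": ["MLH1"],
        "bilof": ["MSH2", "MSH6", "PMS2", "MLH1", "MSH5"],
        "bimiss": ["MSH2", "MSH6"],
        "meth_biallelic": ["MLH1"],
        "loh": ["BRCA1", "BRCA2"],
        "somatic_only": list(L_MMR_GENES),
        "meth_silenced": ["SHPRH"],
    }
    target_cycle = {
        g: [x for x in cyc if x in genes] or [gene_names[0]]
        for g, cyc in target_cycle.items()
    }
    truth_rows = []
    target_gene = np.full(n, "", dtype=object)
    for group, idx in members.items():
        cyc = target_cycle[group]
        for j, i in enumerate(idx):
            target_gene[i] = cyc[j % len(cyc)]
    mech_of = {
        "biallelic": ("germline:somatic", "Bi-LOF"),
        "bilof": ("germline:somatic", "Bi-LOF"),
        "bimiss": ("germline:somatic", "Bi-Miss"),
        "meth_biallelic": ("germline:methylation", "n/a"),
        "loh": ("germline:LOH", "n/a"),
        "somatic_only": ("none", "n/a"),
        "meth_silenced": ("none", "n/a"),
    }
    for group, idx in members.items():
        mech, sub = mech_of[group]
        for i in idx:
            truth_rows.append(
                {
                    "sample": sample_ids[i],
                    "gene": target_gene[i],
                    "group": group,
                    "mechanism": mech,
                    "subtype": sub,
                    "msi_fold": fold_of[group],
                    "age_shift": config.age_shift_years_bilof if group == "bilof" else 0.0,
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=["sample", "gene", "group", "mechanism", "subtype", "msi_fold", "age_shift"],
    )

    # --- germline variants -------------------------------------------------
    rng_g = streams["germline"]
    germ_rows = []

    def _germline_row(i: int, gene: GeneSpec, consequence: str = "LOF_HC") -> dict:
        pos = int(rng_g.integers(gene.start + 6, gene.end - 5)) + 1  # 1-based
        return {
            "sample": sample_ids[i],
            "gene": gene.name,
            "chrom": gene.chrom,
            "pos": pos,
            "ref": "C",
            "alt": "T",
            "vqsr_pass": True,
            "qd": float(np.round(5.0 + 10.0 * rng_g.random(), 3)),
            "consequence": consequence,
            "cadd": float(np.round(25.0 + 15.0 * rng_g.random(), 2)),
            "af_afr": 0.001, "af_amr": 0.001, "af_eas": 0.001, "af_fin": 0.001,
            "af_nfe": 0.001, "af_sas": 0.001, "af_oth": 0.001,
            "clinvar": "",
            "ref_context": _NONHOMOPOLYMER_CONTEXT,
        }

    germline_groups = ("biallelic", "bilof", "bimiss", "meth_biallelic", "loh")
    for group in germline_groups:
        for i in members[group]:
            germ_rows.append(_germline_row(i, genes[target_gene[i]]))
    if config.background_germline_lof_rate > 0:
        hits = rng_g.random((n, len(gene_names))) < config.background_germline_lof_rate
        for i, j in zip(*np.nonzero(hits)):
            if group_of[i] == "" or gene_names[j] != target_gene[i]:
                germ_rows.append(_germline_row(i, genes[gene_names[j]]))
    germline = pd.DataFrame(germ_rows, columns=GERMLINE_COLUMNS)

    # --- somatic MAF --------------------------------------------------------
    rng_s = streams["somatic"]
    som_rows = []

    def _somatic_row(i, gene: GeneSpec, classification, cadd, overlaps_ms=False):
        pos = int(rng_s.integers(gene.start + 6, gene.end - 5)) + 1
        if classification in LOF_CLASSIFICATIONS and "Frame" in classification:
            ref, alt = "CT", "C"
        else:
            ref, alt = "C", "A"
        return {
            "Hugo_Symbol": gene.name,
            "Chromosome": gene.chrom,
            "Start_Position": pos,
            "End_Position": pos + len(ref) - 1,
            "Reference_Allele": ref,
            "Tumor_Seq_Allele2": alt,
            "Variant_Classification": classification,
            "Tumor_Sample_Barcode": sample_ids[i],
            "ref_context": "ACA",
            "cadd": cadd,
            "overlaps_microsatellite": overlaps_ms,
        }

    for group in ("biallelic", "bilof", "somatic_only"):
        for i in members[group]:
            som_rows.append(
                _somatic_row(i, genes[target_gene[i]], "Nonsense_Mutation", 35.0)
            )
    for i in members["bimiss"]:
        som_rows.append(
            _somatic_row(i, genes[target_gene[i]], "Missense_Mutation", 28.0)
        )
    if config.background_somatic_lof_rate > 0:
        hits = rng_s.random((n, len(gene_names))) < config.background_somatic_lof_rate
        for i, j in zip(*np.nonzero(hits)):
            if group_of[i] == "" or gene_names[j] != target_gene[i]:
                som_rows.append(
                    _somatic_row(i, genes[gene_names[j]], "Nonsense_Mutation", 33.0)
                )
    if config.background_somatic_missense_rate > 0:
        hits = rng_s.random((n, len(gene_names))) < config.background_somatic_missense_rate
        for i, j in zip(*np.nonzero(hits)):
            if group_of[i] == "" or gene_names[j] != target_gene[i]:
                cadd = float(np.round(5.0 + 25.0 * rng_s.random(), 2))
                som_rows.append(
                    _somatic_row(i, genes[gene_names[j]], "Missense_Mutation", cadd)
                )
    if config.ms_frameshift_scale > 0:
        # microsatellite-locus frameshifts accumulate with MSI burden itself;
        # they must be excluded from causal modeling of the somatic layer
        lam = config.ms_frameshift_scale * msi_burden
        counts = rng_s.poisson(lam)
        for i in np.nonzero(counts)[0]:
            for _ in range(int(counts[i])):
                j = int(rng_s.integers(len(gene_names)))
                som_rows.append(
                    _somatic_row(
                        i, genes[gene_names[j]], "Frame_Shift_Del", 22.0, overlaps_ms=True
                    )
                )
    somatic = pd.DataFrame(som_rows, columns=MAF_COLUMNS)

    # --- methylation beta + expression -------------------------------------
    rng_m = streams["methylation"]
    a0, b0 = config.beta_baseline
    beta_vals = rng_m.beta(a0, b0, size=(len(gene_names), n))
    a1, b1 = config.beta_hyper
    hyper_pairs = [
        (target_gene[i], i) for g in ("meth_biallelic", "meth_silenced") for i in members[g]
    ]
    gene_pos = {g: k for k, g in enumerate(gene_names)}
    for gname, i in hyper_pairs:
        beta_vals[gene_pos[gname], i] = rng_m.beta(a1, b1)
    beta = pd.DataFrame(beta_vals, index=gene_names, columns=sample_ids)
    beta.index.name = "gene"

    rng_e = streams["expression"]
    log_expr = config.expression_log10_mean + config.expression_log10_sd * rng_e.standard_normal(
        (len(gene_names), n)
    )
    drop = config.meth_expression_drop_fraction
    if drop > 0:
        for gname, i in hyper_pairs:
            log_expr[gene_pos[gname], i] += np.log10(1.0 - drop)
    expression = pd.DataFrame(10.0**log_expr, index=gene_names, columns=sample_ids)
    expression.index.name = "gene"

    # --- copy-number segments (SEG, 1-based inclusive on disk) -------------
    rng_c = streams["cnv"]
    seg_rows = []
    for i in members["loh"]:
        g = genes[target_gene[i]]
        pad = int(rng_c.integers(5_000, 50_000))
        seg_rows.append(
            {
                "sample": sample_ids[i],
                "chrom": g.chrom,
                "start": max(g.start - pad, 0) + 1,
                "end": g.end + pad,
                "num_mark": int(rng_c.integers(30, 200)),
                "fold_change": config.loh_seg_fold,
            }
        )
    chrom_names = sorted({g.chrom for g in config.gene_panel})
    for i in range(n):
        for _ in range(2):  # neutral background segments
            chrom = chrom_names[int(rng_c.integers(len(chrom_names)))]
            start = int(rng_c.integers(1, 2_000_000))
            length = int(rng_c.integers(10_000, 200_000))
            fc = float(np.round(max(rng_c.normal(1.0, 0.04), 0.92), 4))
            seg_rows.append(
                {
                    "sample": sample_ids[i], "chrom": chrom, "start": start,
                    "end": start + length, "num_mark": int(rng_c.integers(30, 200)),
                    "fold_change": fc,
                }
            )
    segments = pd.DataFrame(
        seg_rows, columns=["sample", "chrom", "start", "end", "num_mark", "fold_change"]
    )

    # --- paired allele counts at germline het sites -------------------------
    rng_l = streams["allele_counts"]
    loh_samples = set(sample_ids[members["loh"]])
    ac_rows = []
    for row in germline.itertuples(index=False):
        na = int(rng_l.binomial(config.normal_depth, 0.5))
        is_loh_site = row.sample in loh_samples and row.gene == target_gene[
            int(row.sample[1:])
        ]
        frac = config.loh_alt_fraction if is_loh_site else 0.5
        ta = int(rng_l.binomial(config.tumor_depth, frac))
        ac_rows.append(
            {
                "sample": row.sample,
                "variant": f"{row.chrom}:{row.pos}:{row.ref}:{row.alt}",
                "chrom": row.chrom,
                "pos": row.pos,
                "normal_ref": config.normal_depth - na,
                "normal_alt": na,
                "tumor_ref": config.tumor_depth - ta,
                "tumor_alt": ta,
            }
        )
    for i in range(n):  # balanced background het sites
        for _ in range(config.n_background_het_sites):
            g = genes[gene_names[int(rng_l.integers(len(gene_names)))]]
            pos = int(rng_l.integers(g.start + 1, g.end)) + 1
            na = int(rng_l.binomial(config.normal_depth, 0.5))
            ta = int(rng_l.binomial(config.tumor_depth, 0.5))
            ac_rows.append(
                {
                    "sample": sample_ids[i],
                    "variant": f"{g.chrom}:{pos}:A:G",
                    "chrom": g.chrom,
                    "pos": pos,
                    "normal_ref": config.normal_depth - na,
                    "normal_alt": na,
                    "tumor_ref": config.tumor_depth - ta,
                    "tumor_alt": ta,
                }
            )
    allele_counts = pd.DataFrame(ac_rows, columns=ALLELE_COUNT_COLUMNS)
    allele_counts = allele_counts.drop_duplicates(subset=["sample", "variant"])

    # --- mutation spectra ----------------------------------------------------
    rng_p = streams["spectra"]
    sig = synthetic_signature_matrix(config.n_signatures)
    mixtures = config.signature_mixtures
    S = sig.to_numpy()
    spec = np.zeros((n, 96), dtype=np.int64)
    n_mut = rng_p.poisson(config.mutations_per_sample, size=n)
    n_mut[hyper_idx] = config.hypermutator_mutations
    for i in range(n):
        group = group_of[i] if group_of[i] in mixtures else "background"
        w = mixtures.get(group, mixtures["background"])
        p = np.zeros(96)
        for name, weight in w.items():
            p += weight * S[:, sig.columns.get_loc(name)]
        p = p / p.sum()
        if n_mut[i] > 0:
            spec[i] = rng_p.multinomial(n_mut[i], p)
    spectra = pd.DataFrame(spec, index=sample_ids, columns=list(CHANNELS))
    spectra.index.name = "sample"

    samples = pd.DataFrame(
        {
            "sample": sample_ids,
            "cancer_type": ctypes,
            "age": np.round(age, 2),
            "msi_burden": msi_burden,
            "msi_high": msi_high,
            "pc1": np.round(pc1, 6),
            "pc2": np.round(pc2, 6),
            "total_somatic_mutations": spec.sum(axis=1),
        }
    )

    return CohortBundle(
        samples=samples,
        germline=germline,
        somatic=somatic,
        beta=beta,
        expression=expression,
        segments=segments,
        allele_counts=allele_counts,
        spectra=spectra,
        truth=truth,
        gene_sets=default_gene_sets(gene_names),
        signature_matrix=sig,
    )


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = (
        "samples", "assignment", "germline", "somatic", "methylation",
        "expression", "cnv", "allele_counts", "spectra",
    )
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


# --- on-disk bundle ---------------------------------------------------------

_FILES = {
    "samples": "samples.tsv",
    "germline": "germline.tsv",
    "somatic": "somatic.maf",
    "beta": "beta.tsv",
    "expression": "expression.tsv",
    "segments": "cnv.seg",
    "allele_counts": "allele_counts.tsv",
    "spectra": "spectra.tsv",
    "truth": "truth.tsv",
    "signature_matrix": "signatures.tsv",
}

_REQUIRED = {
    "samples": ["sample", "cancer_type", "age", "msi_burden", "pc1", "pc2"],
    "germline": GERMLINE_COLUMNS,
    "somatic": MAF_COLUMNS[:9],
    "segments": ["sample", "chrom", "start", "end", "fold_change"],
    "allele_counts": ALLELE_COUNT_COLUMNS,
    "truth": ["sample", "gene", "group", "mechanism"],
}


def write_bundle(bundle: CohortBundle, directory) -> list[Path]:
    """Write all cohort layers to a directory (TSV / MAF / SEG / GMT)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for attr, fname in _FILES.items():
        df: pd.DataFrame = getattr(bundle, attr)
        path = directory / fname
        indexed = attr in ("beta", "expression", "spectra", "signature_matrix")
        df.to_csv(path, sep="\t", index=indexed)
        written.append(path)
    gmt = directory / "genesets.gmt"
    write_gmt(bundle.gene_sets, gmt)
    written.append(gmt)
    return written


def read_bundle(directory) -> CohortBundle:
    """Read a bundle directory back; validates schemas, round-trips write_bundle."""
    directory = Path(directory)
    frames = {}
    for attr, fname in _FILES.items():
        path = directory / fname
        if not path.exists():
            raise FileNotFoundError(f"bundle file missing: {fname}")
        if attr in ("beta", "expression", "spectra", "signature_matrix"):
            frames[attr] = pd.read_csv(path, sep="\t", index_col=0)
        else:
            frames[attr] = pd.read_csv(path, sep="\t")
        required = _REQUIRED.get(attr)
        if required:
            missing = [c for c in required if c not in frames[attr].columns]
            if missing:
                raise ValueError(f"{fname}: missing required column(s) {missing}")
    seg = frames["segments"]
    if (seg["end"] <= seg["start"]).any():
        raise ValueError("cnv.seg: segment with end <= start")
    if ((frames["beta"] < 0) | (frames["beta"] > 1)).any().any():
        raise ValueError("beta.tsv: beta values outside [0, 1]")
    frames["germline"]["clinvar"] = frames["germline"]["clinvar"].fillna("")
    return CohortBundle(
        samples=frames["samples"],
        germline=frames["germline"],
        somatic=frames["somatic"],
        beta=frames["beta"],
        expression=frames["expression"],
        segments=frames["segments"],
        allele_counts=frames["allele_counts"],
        spectra=frames["spectra"],
        truth=frames["truth"],
        gene_sets=read_gmt(directory / "genesets.gmt"),
        signature_matrix=frames["signature_matrix"],
    )


def somatic_events(maf: pd.DataFrame, *, cadd_somatic: float = 20.0) -> pd.DataFrame:
    """Derive the integration-layer somatic event table from a MAF frame.

    Adds ``sample``, ``gene``, ``consequence`` (LOF / missense / other) and
    ``damaging_missense`` columns; microsatellite-overlap flags pass through.
    """
    out = pd.DataFrame(
        {
            "sample": maf["Tumor_Sample_Barcode"],
            "gene": maf["Hugo_Symbol"],
        }
    )
    cls = maf["Variant_Classification"]
    out["consequence"] = np.where(
        cls.isin(LOF_CLASSIFICATIONS), "LOF",
        np.where(cls == "Missense_Mutation", "missense", "other"),
    )
    cadd = maf["cadd"] if "cadd" in maf.columns else pd.Series(np.nan, index=maf.index)
    out["cadd"] = cadd
    out["damaging_missense"] = (out["consequence"] == "missense") & (
        cadd.fillna(-1) >= cadd_somatic
    )
    if "overlaps_microsatellite" in maf.columns:
        out["overlaps_microsatellite"] = maf["overlaps_microsatellite"].astype(bool)
    else:
        out["overlaps_microsatellite"] = False
    return out
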