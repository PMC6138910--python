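"""End-to-end pipeline orchestration with a run manifest.

Stage order: germline filters -> methylation calling/validation -> allelic
imbalance & LOH -> bi-allelic integration -> {enrichment, signatures,
associations}. Every stage writes a TSV under the output directory and the
manifest records thresholds, seeds, row counts and output hashes; an
identical config yields identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from biallelic_scan import associations as assoc
from biallelic_scan import enrichment as enr
from biallelic_scan import germline as germ
from biallelic_scan import integration as integ
from biallelic_scan import loh as lohmod
from biallelic_scan import methylation as meth
from biallelic_scan import signatures as sig
from biallelic_scan.synthetic import read_bundle, somatic_events


@dataclass
class RunConfig:
    """All inputs and thresholds for one pipeline run."""

    input_dir: str = ""
    output_dir: str = "out"
    seed: int = 0
    # germline / somatic filters
    af_max: float = 0.05
    af_max_vus: float = 0.005
    cadd_germline: float = 30.0
    cadd_somatic: float = 20.0
    qd_min: float = 1.0
    homopolymer_len: int = 4
    # methylation
    z_threshold: float = 3.0
    min_group_size: int = 10
    meth_alpha: float = 0.05
    # LOH
    loh_alpha: float = 0.05
    deletion_fc: float = 0.9
    # integration switches
    include_pathogenic_missense: bool = False
    include_somatic_cadd20: bool = False
    use_ai_as_loh: bool = False
    # enrichment
    min_lof: int = 3
    gsea_nperm: int = 20000
    gsea_min_size: int = 3
    gsea_max_size: int = 500
    # signatures
    sig_prune: float = 0.06
    perm_nperm: int = 10000
    # associations
    max_mutations: int = 5000
    exclude_biallelic_mmr: bool = True

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a plain-text ``key = value`` config file; unknown keys rejected."""
        fields = {f.name: f for f in dataclasses.fields(cls)}
        kwargs = {}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ValueError(f"{path}:{lineno}: expected key = value")
                key, value = (part.strip() for part in line.split("=", 1))
                if key not in fields:
                    raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
                ftype = fields[key].type
                if ftype in ("int", int):
                    kwargs[key] = int(value)
                elif ftype in ("float", float):
                    kwargs[key] = float(value)
                elif ftype in ("bool", bool):
                    kwargs[key] = value.lower() in ("1", "true", "yes")
                else:
                    kwargs[key] = value
        return cls(**kwargs)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


def _log(stage: str, message: str) -> None:
    print(f"[{stage}] {message}", file=sys.stderr)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages on a bundle directory; returns the manifest dict."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": "0.1.0",
        "config": dataclasses.asdict(config),
        "stages": {},
    }
    outputs: dict[str, pd.DataFrame] = {}

    def _stage(name):
        def wrap(fn):
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - abort with stage name
                raise StageError(name, str(exc)) from exc

        return wrap

    bundle = None

    @_stage("load")
    def _load():
        nonlocal bundle
        bundle = read_bundle(config.input_dir)
        _log("load", f"{len(bundle.samples)} samples, {len(bundle.germline)} germline rows")

    @_stage("filter-germline")
    def _filter():
        kept = germ.filter_germline_lof(
            bundle.germline,
            af_max=config.af_max,
            qd_min=config.qd_min,
            homopolymer_len=config.homopolymer_len,
        ).copy()
        kept["pathogenic"] = [
            germ.classify_clinvar_pathogenic(germ.parse_clinvar_field(v))
            for v in kept["clinvar"]
        ]
        outputs["germline_filtered"] = kept
        _log("filter-germline", f"kept {len(kept)} / {len(bundle.germline)}")

    @_stage("call-methylation")
    def _meth():
        labels = bundle.samples.set_index("sample")["cancer_type"]
        calls = meth.call_hypermethylation(
            bundle.beta,
            labels,
            z_threshold=config.z_threshold,
            min_group_size=config.min_group_size,
        )
        validation = meth.validate_all_genes(
            bundle.expression, calls, labels, alpha=config.meth_alpha
        )
        retained = set(validation.loc[validation["retained"], "gene"])
        silenced = calls.loc[calls["called"] & calls["gene"].isin(retained)]
        outputs["methylation_calls"] = silenced.reset_index(drop=True)
        outputs["methylation_validation"] = validation
        _log("call-methylation", f"{len(silenced)} silencing events in {len(retained)} genes")

    @_stage("call-loh")
    def _loh():
        ai = lohmod.test_allelic_imbalance(bundle.allele_counts, alpha=config.loh_alpha)
        seg = bundle.segments.copy()
        seg["start"] = seg["start"].astype(np.int64) - 1  # SEG -> half-open
        calls = lohmod.call_loh(ai, seg, deletion_threshold=config.deletion_fc)
        germline_keys = bundle.germline.assign(
            variant=lambda d: d["chrom"].astype(str)
            + ":" + d["pos"].astype(str) + ":" + d["ref"] + ":" + d["alt"]
        )[["sample", "variant", "gene"]]
        calls = calls.merge(germline_keys, on=["sample", "variant"], how="left")
        outputs["loh_calls"] = calls
        _log("call-loh", f"{int((calls['status'] == 'LOH').sum())} LOH, "
             f"{int((calls['status'] == 'AI').sum())} AI")

    @_stage("integrate")
    def _integrate():
        som = somatic_events(bundle.somatic, cadd_somatic=config.cadd_somatic)
        loh_calls = outputs["loh_calls"].dropna(subset=["gene"])
        records = integ.build_records(
            outputs["germline_filtered"],
            som.loc[som["consequence"] != "other"],
            outputs["methylation_calls"],
            loh_calls,
            include_pathogenic_missense=config.include_pathogenic_missense,
            include_somatic_cadd20=config.include_somatic_cadd20,
            use_ai_as_loh=config.use_ai_as_loh,
        )
        outputs["records"] = records
        outputs["mechanism_counts"] = integ.count_mechanisms(records)
        outputs["categories"] = integ.categorize_genesets(
            records, bundle.gene_sets, bundle.samples["sample"].tolist()
        )
        n_bi = int((records["mechanism"] != "none").sum())
        _log("integrate", f"{len(records)} records, {n_bi} bi-allelic")

    @_stage("gsea")
    def _gsea():
        germline_all = bundle.germline.loc[bundle.germline["consequence"] == "LOF_HC"]
        lof_counts = germline_all.groupby("gene")["sample"].nunique()
        ranked = enr.rank_genes(outputs["records"], lof_counts, min_lof=config.min_lof)
        outputs["ranking"] = ranked
        try:
            outputs["gsea"] = enr.preranked_gsea(
                ranked,
                bundle.gene_sets,
                nperm=config.gsea_nperm,
                min_size=config.gsea_min_size,
                max_size=config.gsea_max_size,
                seed=config.seed,
            )
        except ValueError as exc:
            _log("gsea", f"skipped: {exc}")
            outputs["gsea"] = pd.DataFrame(
                columns=["gene_set", "size", "es", "nes", "p", "leading_edge", "q"]
            )

    @_stage("signatures")
    def _signatures():
        exposures = sig.estimate_exposures_matrix(
            bundle.spectra, bundle.signature_matrix, prune_threshold=config.sig_prune
        )
        outputs["exposures"] = exposures.rename_axis("sample").reset_index()
        records = outputs["records"]
        mmr = set(bundle.gene_sets.get("MMR", []))
        carriers = set(
            records.loc[
                (records["mechanism"] == "germline:somatic")
                & records["gene"].isin(mmr),
                "sample",
            ]
        )
        carrier = bundle.samples["sample"].isin(carriers)
        carrier.index = bundle.samples["sample"]
        if carrier.sum() >= 2 and (~carrier).sum() >= 2:
            res = sig.permutation_exposure_test(
                exposures.loc[carrier.index],
                carrier,
                nperm=config.perm_nperm,
                seed=config.seed,
            )
        else:
            _log("signatures", "fewer than 2 carriers; association test skipped")
            res = pd.DataFrame(columns=["signature", "stat", "p", "degenerate", "q"])
        outputs["signature_assoc"] = res

    @_stage("associate")
    def _associate():
        profiles = bundle.samples.set_index("sample")
        records = outputs["records"]
        mmr = set(bundle.gene_sets.get("MMR", []))
        idx = profiles.index
        g = idx.isin(outputs["germline_filtered"].loc[
            outputs["germline_filtered"]["gene"].isin(mmr), "sample"])
        som = somatic_events(bundle.somatic, cadd_somatic=config.cadd_somatic)
        s = idx.isin(som.loc[(som["consequence"] == "LOF") & som["gene"].isin(mmr), "sample"])
        me = idx.isin(outputs["methylation_calls"].loc[
            outputs["methylation_calls"]["gene"].isin(mmr), "sample"])
        ind = pd.DataFrame({"G": g, "S": s, "Me": me}, index=idx)
        outputs["msi_model"] = assoc.fit_msi_model(profiles, ind)
        bi = idx.isin(records.loc[
            (records["mechanism"] == "germline:somatic") & records["gene"].isin(mmr),
            "sample"])
        outputs["age_model"] = assoc.fit_age_model(
            profiles, pd.DataFrame({"G_biallelic_mmr": bi}, index=idx)
        )
        # per-gene DDR scan with the causal-direction exclusions
        scan_profiles = profiles
        if config.exclude_biallelic_mmr:
            scan_profiles = profiles.loc[~bi]
        genes = sorted(bundle.beta.index)
        layers = {}
        gf = outputs["germline_filtered"]
        layers["germline"] = _indicator(scan_profiles.index, gf, "sample", "gene", genes)
        som_clean = som.loc[
            (som["consequence"] == "LOF") & ~som["overlaps_microsatellite"]
        ]
        layers["somatic"] = _indicator(scan_profiles.index, som_clean, "sample", "gene", genes)
        layers["methylation"] = _indicator(
            scan_profiles.index, outputs["methylation_calls"], "sample", "gene", genes
        )
        outputs["ddr_scan"] = assoc.ddr_scan(scan_profiles, layers)

    for path in [
        "germline_filtered", "methylation_calls", "methylation_validation",
        "loh_calls", "records", "mechanism_counts", "categories", "ranking",
        "gsea", "exposures", "signature_assoc", "msi_model", "age_model",
        "ddr_scan",
    ]:
        df = outputs[path]
        fpath = outdir / f"{path}.tsv"
        df.to_csv(fpath, sep="\t", index=False)
        manifest["stages"][path] = {"rows": int(len(df)), "sha256": _sha256(fpath)}

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _indicator(samples: pd.Index, events: pd.DataFrame, sample_col, gene_col, genes):
    mat = pd.DataFrame(False, index=samples, columns=genes)
    for smp, gene in zip(events[sample_col], events[gene_col]):
        if smp in mat.index and gene in mat.columns:
            mat.loc[smp, gene] = True
    return mat
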