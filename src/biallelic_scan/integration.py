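"""Integration of germline, somatic, methylation and LOH events.

A bi-allelic alteration is a damaging germline variant plus a second somatic
hit in the same gene and sample, via one of three mechanisms:

* ``germline:somatic``     — second hit is a somatic mutation
* ``germline:methylation`` — second hit is epigenetic silencing
* ``germline:LOH``         — second hit is loss of the wild-type allele

germline:somatic events are further subtyped: Bi-LOF (both hits LOF) vs
Bi-Miss (at least one hit is a missense event). At the gene-set level each
sample gets exactly one of five mutually exclusive categories: Bi-allelic,
Mixed (germline and somatic hits in *different* set genes), Germ, Som, None.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

MECHANISMS = ("germline:somatic", "germline:methylation", "germline:LOH")
GERMLINE_CLASSES = ("none", "LOF", "pathogenic_missense")
SOMATIC_CLASSES = ("none", "LOF", "damaging_missense")
CATEGORIES = ("Bi-allelic", "Mixed", "Germ", "Som", "None")


@dataclass
class BiallelicRecord:
    """Per-sample, per-gene integrated alteration call."""

    sample: str
    gene: str
    germline_class: str = "none"
    somatic_class: str = "none"
    methylated: bool = False
    loh: bool = False
    mechanism: str = "none"
    subtype: str = "n/a"


def integrate_gene(
    sample: str,
    gene: str,
    *,
    germline_class: str = "none",
    somatic_class: str = "none",
    methylated: bool = False,
    loh: bool = False,
) -> BiallelicRecord:
    """Combine one gene's event layers into a mechanism + subtype call.

    When several second hits co-occur the mechanism label follows the
    reporting priority germline:somatic > germline:methylation >
    germline:LOH; the priority affects only the label, never whether the
    (sample, gene) is bi-allelic. Subtypes apply to germline:somatic only:
    Bi-LOF iff both classes are LOF, Bi-Miss iff at least one is missense.
    """
    if germline_class not in GERMLINE_CLASSES:
        raise ValueError(f"bad germline_class {germline_class!r}")
    if somatic_class not in SOMATIC_CLASSES:
        raise ValueError(f"bad somatic_class {somatic_class!r}")
    mechanism, subtype = "none", "n/a"
    if germline_class != "none":
        if somatic_class != "none":
            mechanism = "germline:somatic"
            both_lof = germline_class == "LOF" and somatic_class == "LOF"
            subtype = "Bi-LOF" if both_lof else "Bi-Miss"
        elif methylated:
            mechanism = "germline:methylation"
        elif loh:
            mechanism = "germline:LOH"
    return BiallelicRecord(
        sample, gene, germline_class, somatic_class, methylated, loh, mechanism, subtype
    )


def build_records(
    germline_events: pd.DataFrame,
    somatic_events: pd.DataFrame,
    methylation_calls: pd.DataFrame,
    loh_calls: pd.DataFrame,
    *,
    include_pathogenic_missense: bool = False,
    include_somatic_cadd20: bool = False,
    use_ai_as_loh: bool = False,
) -> pd.DataFrame:
    """Build the integrated per-(sample, gene) record table.

    ``germline_events``: filtered germline table with a ``consequence``
    column (``LOF_HC`` rows always enter; rows flagged ``pathogenic``
    enter as pathogenic_missense when ``include_pathogenic_missense``).
    ``somatic_events``: somatic mutations with ``consequence`` (LOF rows
    always; ``damaging_missense``-flagged rows when
    ``include_somatic_cadd20``). ``methylation_calls``: validated calls
    (gene, sample, called). ``loh_calls``: imbalance table with ``status``;
    ``use_ai_as_loh`` treats AI as sufficient (sensitivity mode, a superset
    of the strict-LOH record set).
    """
    germ: dict[tuple, str] = {}
    for row in germline_events.itertuples(index=False):
        key = (row.sample, row.gene)
        if row.consequence == "LOF_HC":
            germ[key] = "LOF"
        elif include_pathogenic_missense and getattr(row, "pathogenic", False):
            germ.setdefault(key, "pathogenic_missense")

    som: dict[tuple, str] = {}
    for row in somatic_events.itertuples(index=False):
        key = (row.sample, row.gene)
        if row.consequence in ("LOF", "LOF_HC"):
            som[key] = "LOF"
        elif include_somatic_cadd20 and getattr(row, "damaging_missense", False):
            som.setdefault(key, "damaging_missense")

    meth = set()
    if len(methylation_calls):
        called = methylation_calls.loc[methylation_calls["called"].astype(bool)]
        meth = set(zip(called["sample"], called["gene"]))

    loh = set()
    if len(loh_calls):
        ok = {"LOH", "AI"} if use_ai_as_loh else {"LOH"}
        hit = loh_calls.loc[loh_calls["status"].isin(ok)]
        loh = set(zip(hit["sample"], hit["gene"]))

    keys = sorted(set(germ) | set(som) | meth | loh)
    records = [
        integrate_gene(
            s,
            g,
            germline_class=germ.get((s, g), "none"),
            somatic_class=som.get((s, g), "none"),
            methylated=(s, g) in meth,
            loh=(s, g) in loh,
        ).__dict__
        for s, g in keys
    ]
    return pd.DataFrame(
        records,
        columns=[
            "sample",
            "gene",
            "germline_class",
            "somatic_class",
            "methylated",
            "loh",
            "mechanism",
            "subtype",
        ],
    )


def categorize_genesets(
    records: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    samples: list[str] | pd.Index,
) -> pd.DataFrame:
    """Assign each sample one exclusive category per gene set.

    Bi-allelic: any set gene with mechanism != none. Mixed: a germline event
    in one set gene and a somatic/methylation event in a *different* set
    gene. Germ: germline events only. Som: somatic mutation or methylation
    only. None: no events. Exactly one category per sample x set.
    """
    rows = []
    for name, genes in gene_sets.items():
        if not genes:
            raise ValueError(f"gene set {name!r} is empty")
        sub = records.loc[records["gene"].isin(genes)]
        by_sample = dict(iter(sub.groupby("sample")))
        for smp in samples:
            grp = by_sample.get(smp)
            rows.append({"sample": smp, "gene_set": name, "category": _categorize(grp)})
    return pd.DataFrame(rows)


def _categorize(grp: pd.DataFrame | None) -> str:
    if grp is None or grp.empty:
        return "None"
    if (grp["mechanism"] != "none").any():
        return "Bi-allelic"
    germ_genes = set(grp.loc[grp["germline_class"] != "none", "gene"])
    som_genes = set(
        grp.loc[(grp["somatic_class"] != "none") | grp["methylated"], "gene"]
    )
    if germ_genes and som_genes - germ_genes:
        return "Mixed"
    if germ_genes and not som_genes:
        return "Germ"
    if som_genes and not germ_genes:
        return "Som"
    if germ_genes and som_genes:
        # same-gene germline + somatic would have been bi-allelic; here the
        # somatic genes are a subset of germline genes only via LOH/meth
        # flags that did not pair (no germline in that gene) — treat as Mixed
        return "Mixed"
    return "None"


def count_mechanisms(records: pd.DataFrame) -> pd.DataFrame:
    """Tally bi-allelic events per mechanism and per gene.

    A gene with a germline hit and several second hits counts once per
    mechanism it realizes under the priority labeling (one mechanism per
    record), matching separate per-mechanism reporting.
    """
    hit = records.loc[records["mechanism"] != "none"]
    if hit.empty:
        return pd.DataFrame(columns=["mechanism", "gene", "n"]).astype({"n": int})
    out = (
        hit.groupby(["mechanism", "gene"], sort=True)
        .size()
        .rename("n")
        .reset_index()
    )
    return out
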