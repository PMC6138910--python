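"""Per-gene hyper-methylation calling with expression validation.

Methylation beta values (array intensity ratios in [0, 1], already collapsed
to one probe per gene — the probe most anti-correlated with expression) are
converted to Z-scores within each cancer type; samples at Z >= 3 are called
hyper-methylated. Each gene's calls are then validated against expression:
only genes where the methylation indicator is nominally associated
(p <= 0.05) with *decreased* expression in a cancer-type-adjusted linear
model are retained as silencing events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

Z_THRESHOLD = 3.0
MIN_GROUP_SIZE = 10  # below this, within-type sd is too unstable for Z >= 3
VALIDATION_ALPHA = 0.05
PSEUDOCOUNT = 1.0  # expression handled as log10(E + 1)


def call_hypermethylation(
    beta: pd.DataFrame,
    cancer_labels: pd.Series,
    *,
    z_threshold: float = Z_THRESHOLD,
    min_group_size: int = MIN_GROUP_SIZE,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Call hyper-methylated (gene, sample) pairs.

    ``beta`` is genes x samples; ``cancer_labels`` maps sample -> cancer
    type. Within each gene and cancer type, z = (beta - mean) / sd with the
    sample (n-1) standard deviation; a sample is called iff z >= threshold
    (inclusive). Groups smaller than ``min_group_size`` or with zero
    variance yield no calls.

    Returns a long table: gene, sample, cancer_type, beta, z, called.
    """
    if genes is not None:
        missing = set(genes) - set(beta.index)
        if missing:
            raise KeyError(f"gene(s) absent from beta matrix: {sorted(missing)}")
        beta = beta.loc[genes]
    labels = cancer_labels.reindex(beta.columns)
    if labels.isna().any():
        raise ValueError("every beta-matrix sample needs a cancer-type label")

    frames = []
    for ctype in labels.unique():
        cols = labels.index[labels == ctype]
        sub = beta[cols]
        vals = sub.to_numpy(dtype=float)
        ok = np.isfinite(vals)
        n = ok.sum(axis=1)
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(np.where(ok, vals, np.nan), axis=1)
            sd = np.nanstd(np.where(ok, vals, np.nan), axis=1, ddof=1)
        z = (vals - mean[:, None]) / sd[:, None]
        callable_gene = (n >= min_group_size) & (sd > 0)
        called = callable_gene[:, None] & ok & (z >= z_threshold)
        long = pd.DataFrame(
            {
                "gene": np.repeat(sub.index.to_numpy(), len(cols)),
                "sample": np.tile(cols.to_numpy(), len(sub.index)),
                "cancer_type": ctype,
                "beta": vals.ravel(),
                "z": np.where(callable_gene[:, None], z, np.nan).ravel(),
                "called": called.ravel(),
            }
        )
        frames.append(long)
    return pd.concat(frames, ignore_index=True)


@dataclass
class GeneMethylationValidation:
    """Expression-model check of one gene's methylation calls."""

    gene: str
    coef: float
    p: float
    retained: bool
    n_called: int
    note: str = ""


def validate_methylation_gene(
    expression_row: pd.Series,
    called: pd.Series,
    cancer_labels: pd.Series,
    *,
    alpha: float = VALIDATION_ALPHA,
    pseudocount: float = PSEUDOCOUNT,
    gene: str = "",
) -> GeneMethylationValidation:
    """Validate one gene's methylation calls against its expression.

    Fits ``log10(E + pseudocount) ~ cancer-type indicators + M`` by OLS,
    where M is the binary hyper-methylation call. The gene is retained iff
    the M coefficient is negative with two-sided p <= alpha. Genes with no
    calls, or with calls fully confounded with a cancer type (singular
    design), are dropped.
    """
    gene = gene or str(expression_row.name or "")
    samples = expression_row.index
    m = called.reindex(samples).fillna(False).astype(float)
    n_called = int(m.sum())
    if n_called == 0:
        return GeneMethylationValidation(gene, np.nan, np.nan, False, 0, "no calls")
    if (len(samples) - n_called) < 2:
        return GeneMethylationValidation(
            gene, np.nan, np.nan, False, n_called, "fewer than 2 uncalled samples"
        )
    y = np.log10(expression_row.to_numpy(dtype=float) + pseudocount)
    ct = pd.get_dummies(cancer_labels.reindex(samples), drop_first=True, dtype=float)
    X = pd.concat([ct, m.rename("M")], axis=1)
    X = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        return GeneMethylationValidation(
            gene,
            np.nan,
            np.nan,
            False,
            n_called,
            "singular design: calls confounded with cancer type",
        )
    fit = sm.OLS(y, X).fit()
    coef = float(fit.params["M"])
    p = float(fit.pvalues["M"])
    retained = bool(p <= alpha and coef < 0)
    return GeneMethylationValidation(gene, coef, p, retained, n_called)


def validate_all_genes(
    expression: pd.DataFrame,
    calls: pd.DataFrame,
    cancer_labels: pd.Series,
    *,
    alpha: float = VALIDATION_ALPHA,
    pseudocount: float = PSEUDOCOUNT,
) -> pd.DataFrame:
    """Run :func:`validate_methylation_gene` for every gene with >= 1 call."""
    rows = []
    called_wide = calls.pivot_table(
        index="gene", columns="sample", values="called", aggfunc="any", fill_value=False
    )
    for gene in called_wide.index:
        if gene not in expression.index:
            continue
        res = validate_methylation_gene(
            expression.loc[gene],
            called_wide.loc[gene],
            cancer_labels,
            alpha=alpha,
            pseudocount=pseudocount,
            gene=gene,
        )
        rows.append(res.__dict__)
    return pd.DataFrame(
        rows, columns=["gene", "coef", "p", "retained", "n_called", "note"]
    )


def choose_probe(
    probe_beta: pd.DataFrame, probe_gene: pd.Series, expression: pd.DataFrame
) -> pd.DataFrame:
    """Collapse a probe-level beta matrix to one probe per gene.

    For each gene, picks the probe whose beta is most anti-correlated
    (Pearson) with the gene's expression across shared samples.
    """
    shared = probe_beta.columns.intersection(expression.columns)
    rows = {}
    for gene, probes in probe_gene.groupby(probe_gene).groups.items():
        if gene not in expression.index:
            continue
        expr = expression.loc[gene, shared].astype(float)
        best_probe, best_r = None, np.inf
        for probe in probes:
            r = probe_beta.loc[probe, shared].astype(float).corr(expr)
            if pd.notna(r) and r < best_r:
                best_probe, best_r = probe, r
        if best_probe is not None:
            rows[gene] = probe_beta.loc[best_probe]
    return pd.DataFrame.from_dict(rows, orient="index")
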