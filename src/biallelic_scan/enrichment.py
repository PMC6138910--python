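"""Gene ranking by bi-allelic conversion and preranked permutation GSEA.

Genes are ranked by the fraction of their germline LOF variants that
acquired a second somatic alteration (n bi-allelic / n germline LOF); genes
with fewer than three germline LOF carriers in the cohort are excluded.
Enrichment of gene sets along that ranking uses the standard weighted
Kolmogorov-Smirnov running-sum enrichment score with a gene-label
permutation null.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

MIN_LOF = 3
NPERM = 20_000
MIN_SIZE = 3
MAX_SIZE = 500
_WEIGHT_EPS = 1e-12  # keeps the running sum defined for zero-stat genes


def read_gmt(path) -> dict[str, list[str]]:
    """Read GMT gene sets (name <tab> description <tab> genes...)."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        for name, genes in gene_sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def rank_genes(
    records: pd.DataFrame,
    germline_lof_counts: pd.Series,
    *,
    min_lof: int = MIN_LOF,
) -> pd.DataFrame:
    """Rank genes by bi-allelic conversion fraction.

    ``germline_lof_counts``: gene -> number of germline LOF carriers in the
    cohort. ``records``: integrated records; a record counts as converted
    when its mechanism is not none. Genes with fewer than ``min_lof``
    germline LOF carriers are excluded. Sorted by fraction descending, ties
    broken by carrier count descending then gene label (deterministic).
    """
    counts = germline_lof_counts[germline_lof_counts >= min_lof]
    bial = (
        records.loc[records["mechanism"] != "none"].groupby("gene").size()
        if len(records)
        else pd.Series(dtype=int)
    )
    out = pd.DataFrame(
        {
            "gene": counts.index,
            "n_germline_lof": counts.to_numpy(dtype=int),
            "n_biallelic": bial.reindex(counts.index).fillna(0).to_numpy(dtype=int),
        }
    )
    out["n_biallelic"] = np.minimum(out["n_biallelic"], out["n_germline_lof"])
    out["fraction"] = out["n_biallelic"] / out["n_germline_lof"]
    out = out.sort_values(
        ["fraction", "n_germline_lof", "gene"], ascending=[False, False, True]
    ).reset_index(drop=True)
    return out


def enrichment_score(
    stats: np.ndarray, in_set: np.ndarray, *, weight: float = 1.0
) -> float:
    """Weighted KS enrichment score for one set on a ranked stat vector.

    ``stats`` must be ordered (best rank first); ``in_set`` is a boolean
    mask over the same order. Hit steps are |stat|^weight normalized over
    set members; miss steps are uniform. Returns the maximum-deviation
    (signed) running-sum value.
    """
    es = _es_batch(stats, in_set[None, :], weight=weight)
    return float(es[0])


def _es_batch(stats: np.ndarray, in_set: np.ndarray, *, weight: float = 1.0) -> np.ndarray:
    n = stats.shape[0]
    w = np.abs(np.asarray(stats, dtype=float)) ** weight
    w = np.maximum(w, _WEIGHT_EPS)
    k = in_set.sum(axis=1)
    if np.any(k == 0) or np.any(k == n):
        raise ValueError("set must be a proper non-empty subset of ranked genes")
    hit_w = in_set * w[None, :]
    hit = np.cumsum(hit_w, axis=1) / hit_w.sum(axis=1, keepdims=True)
    miss = np.cumsum(~in_set, axis=1) / (n - k)[:, None]
    run = hit - miss
    idx = np.argmax(np.abs(run), axis=1)
    return run[np.arange(run.shape[0]), idx]


def preranked_gsea(
    ranked: pd.DataFrame,
    gene_sets: dict[str, list[str]],
    *,
    stat_col: str = "fraction",
    nperm: int = NPERM,
    min_size: int = MIN_SIZE,
    max_size: int = MAX_SIZE,
    weight: float = 1.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Preranked GSEA with a gene-label permutation null.

    ``ranked``: output of :func:`rank_genes` (or any frame with ``gene``
    and the ranking statistic, ordered best-first). Sets are intersected
    with the ranked genes and filtered to [min_size, max_size]. The null
    shuffles set membership over gene labels (equivalently: random same-size
    gene subsets). p is the +1-smoothed fraction of *same-sign* permutation
    scores at least as extreme as the observed ES (the sign-conditional
    convention keeps null p-values uniform); NES = ES / mean(|permutation
    ES| of the same sign); q = Benjamini-Hochberg across sets.
    """
    genes = ranked["gene"].to_numpy()
    stats = ranked[stat_col].to_numpy(dtype=float)
    n = len(genes)
    pos = {g: i for i, g in enumerate(genes)}
    rng = np.random.default_rng(seed)

    surviving: list[tuple[str, np.ndarray]] = []
    for name, members in gene_sets.items():
        idx = np.array(sorted({pos[g] for g in members if g in pos}), dtype=int)
        if min_size <= len(idx) <= max_size and len(idx) < n:
            surviving.append((name, idx))
    if not surviving:
        raise ValueError("no gene set survives size filtering")

    rows = []
    for name, idx in surviving:
        mask = np.zeros(n, dtype=bool)
        mask[idx] = True
        es = enrichment_score(stats, mask, weight=weight)
        k = len(idx)
        # gene-label permutation: k random positions per permutation
        perm_mask = np.zeros((nperm, n), dtype=bool)
        draws = np.argsort(rng.random((nperm, n)), axis=1)[:, :k]
        perm_mask[np.arange(nperm)[:, None], draws] = True
        perm_es = _es_batch(stats, perm_mask, weight=weight)
        # sign-conditional tail: compare against same-sign permutations only,
        # otherwise null p-values are bounded away from 1 by P(ES >= 0)
        same_sign = perm_es >= 0 if es >= 0 else perm_es <= 0
        extreme = same_sign & (perm_es >= es if es >= 0 else perm_es <= es)
        p = (int(extreme.sum()) + 1) / (int(same_sign.sum()) + 1)
        denom = np.abs(perm_es[same_sign]).mean() if same_sign.any() else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        # leading edge: members at or before the running-sum extremum
        le = _leading_edge(stats, mask, weight=weight)
        rows.append(
            {
                "gene_set": name,
                "size": k,
                "es": es,
                "nes": nes,
                "p": p,
                "leading_edge": ",".join(genes[le]),
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out.sort_values("p", kind="stable").reset_index(drop=True)


def _leading_edge(stats, mask, *, weight):
    n = len(stats)
    w = np.maximum(np.abs(stats.astype(float)) ** weight, _WEIGHT_EPS)
    hit = np.cumsum(mask * w) / (mask * w).sum()
    miss = np.cumsum(~mask) / (n - mask.sum())
    run = hit - miss
    i = int(np.argmax(np.abs(run)))
    if run[i] >= 0:
        return np.where(mask[: i + 1])[0]
    return np.where(mask[i:])[0] + i


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    return out
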