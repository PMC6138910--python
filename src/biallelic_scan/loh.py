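"""Allelic imbalance and loss-of-heterozygosity calling.

At every heterozygous germline site with paired normal/tumor read counts, a
one-sided Fisher's exact test asks whether the germline (alternate) allele
fraction increased in the tumor. Significant sites are "allelic imbalance"
(AI); an AI site is upgraded to LOH when it falls inside a same-sample
copy-number segment consistent with a deletion (fold change <= 0.9, the
value expected for a single-copy loss in 20% of tumor cells).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

ALPHA = 0.05
DELETION_FC = 0.9

ALLELE_COUNT_COLUMNS = [
    "sample",
    "variant",
    "chrom",
    "pos",
    "normal_ref",
    "normal_alt",
    "tumor_ref",
    "tumor_alt",
]


def fisher_imbalance_p(
    normal_ref: np.ndarray,
    normal_alt: np.ndarray,
    tumor_ref: np.ndarray,
    tumor_alt: np.ndarray,
) -> np.ndarray:
    """Vectorized one-sided Fisher exact p for increased tumor alt fraction.

    Conditioning on all four margins of the 2x2 table
    ``[[normal_ref, normal_alt], [tumor_ref, tumor_alt]]``, a higher tumor
    alternate fraction corresponds to a higher ``normal_ref`` count, so the
    p-value is the upper hypergeometric tail P(X >= normal_ref) with
    population size the grand total, ``normal_ref + tumor_ref`` successes,
    and ``normal_ref + normal_alt`` draws.
    """
    nr = np.asarray(normal_ref, dtype=np.int64)
    na = np.asarray(normal_alt, dtype=np.int64)
    tr = np.asarray(tumor_ref, dtype=np.int64)
    ta = np.asarray(tumor_alt, dtype=np.int64)
    if np.any(nr < 0) or np.any(na < 0) or np.any(tr < 0) or np.any(ta < 0):
        raise ValueError("allele counts must be nonnegative")
    total = nr + na + tr + ta
    return stats.hypergeom.sf(nr - 1, total, nr + tr, nr + na)


def test_allelic_imbalance(
    counts: pd.DataFrame, *, alpha: float = ALPHA
) -> pd.DataFrame:
    """Test each heterozygous site for somatic allelic imbalance.

    Returns the input with ``p``, ``imbalance`` and ``status`` columns.
    Sites where the germline allele was not observed in the tumor
    (``tumor_alt == 0``, including zero tumor coverage) are ``excluded``.
    Duplicate (sample, variant) keys — multi-allelic sites — are dropped
    with a warning. ``imbalance`` requires p <= alpha (the one-sided test
    already encodes the increased-alt-fraction direction; a decreased
    fraction yields p near 1).
    """
    out = counts.copy()
    if out.duplicated(subset=["sample", "variant"], keep=False).any():
        dup = out.duplicated(subset=["sample", "variant"], keep=False)
        warnings.warn(
            f"dropping {int(dup.sum())} rows at multi-allelic (duplicated) sites",
            stacklevel=2,
        )
        out = out.loc[~dup].copy()
    if (out["normal_ref"] + out["normal_alt"] <= 0).any():
        raise ValueError("sites with zero normal coverage are not testable")
    p = fisher_imbalance_p(
        out["normal_ref"], out["normal_alt"], out["tumor_ref"], out["tumor_alt"]
    )
    excluded = (out["tumor_alt"] == 0).to_numpy()
    out["p"] = np.where(excluded, np.nan, p)
    out["imbalance"] = (~excluded) & (out["p"].to_numpy() <= alpha)
    out["status"] = np.where(
        excluded, "excluded", np.where(out["imbalance"], "AI", "none")
    )
    return out


def expected_fold_change(loss_fraction: float) -> float:
    """Expected copy-ratio fold change for a clonal-fraction single-copy loss.

    With a diploid baseline, a fraction ``f`` of tumor cells carrying a
    single-chromosome loss gives mean copy number f*1 + (1-f)*2, i.e. a fold
    change of 1 - f/2. f = 0.20 gives the 0.9 deletion threshold.
    """
    f = float(loss_fraction)
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"loss fraction must be in [0, 1], got {f}")
    return 1.0 - f / 2.0


def read_seg(path) -> pd.DataFrame:
    """Read a SEG file into 0-based half-open segment coordinates.

    SEG input is 1-based inclusive; ``seg_mean`` carries the copy-ratio fold
    change. Segments with end <= start are rejected.
    """
    seg = pd.read_csv(path, sep="\t")
    required = {"sample", "chrom", "start", "end", "fold_change"}
    missing = required - set(seg.columns)
    if missing:
        raise ValueError(f"SEG file missing column(s): {sorted(missing)}")
    if (seg["end"] <= seg["start"]).any():
        bad = seg.loc[seg["end"] <= seg["start"]].iloc[0]
        raise ValueError(
            f"SEG segment with end <= start: {bad['chrom']}:{bad['start']}-{bad['end']}"
        )
    out = seg.copy()
    out["start"] = out["start"].astype(np.int64) - 1  # to 0-based half-open
    out["end"] = out["end"].astype(np.int64)
    if (out["fold_change"] <= 0).any():
        raise ValueError("fold_change must be positive")
    return out


def call_loh(
    ai_calls: pd.DataFrame,
    segments: pd.DataFrame,
    *,
    deletion_threshold: float = DELETION_FC,
) -> pd.DataFrame:
    """Upgrade AI calls to LOH when backed by a same-sample deletion segment.

    ``segments`` uses 0-based half-open coordinates (see :func:`read_seg`).
    A 1-bp variant at 1-based position ``pos`` lies in a segment iff
    ``start <= pos - 1 < end`` on the same chromosome. Any overlapping
    segment with fold change <= ``deletion_threshold`` (inclusive) counts.
    Variants on chromosomes absent from the segment table stay AI.
    """
    out = ai_calls.copy()
    dels = segments.loc[segments["fold_change"] <= deletion_threshold]
    by_sample_chrom: dict[tuple, np.ndarray] = {}
    for (smp, chrom), grp in dels.groupby(["sample", "chrom"]):
        by_sample_chrom[(smp, chrom)] = grp[["start", "end"]].to_numpy()
    is_loh = np.zeros(len(out), dtype=bool)
    for i, row in enumerate(out.itertuples(index=False)):
        if row.status != "AI":
            continue
        ivals = by_sample_chrom.get((row.sample, row.chrom))
        if ivals is None:
            continue
        p0 = row.pos - 1  # 1-based variant position -> 0-based
        if np.any((ivals[:, 0] <= p0) & (p0 < ivals[:, 1])):
            is_loh[i] = True
    out.loc[is_loh, "status"] = "LOH"
    return out
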