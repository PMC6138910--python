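"""96-channel mutation spectra, NNLS signature deconvolution, permutation test.

Single-base substitutions are tallied into the standard 96 trinucleotide
channels (six pyrimidine-strand substitution types x 16 flanking-base
contexts; purine-reference mutations are reverse-complemented). Per-sample
exposures to a column-stochastic signature matrix are estimated by
non-negative least squares on the normalized spectrum, with small weights
pruned and the remainder renormalized. Association between carrier status
and exposures uses a Wilcoxon rank-sum statistic with a label-shuffling
permutation null.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

PRUNE_THRESHOLD = 0.06
NPERM = 10_000

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
BASES = "ACGT"

#: Channel labels in COSMIC order: A[C>A]A, A[C>A]C, ... T[T>G]T.
CHANNELS = tuple(
    f"{five}[{sub}]{three}" for sub in SUBSTITUTIONS for five in BASES for three in BASES
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def channel_of(ref: str, alt: str, context: str) -> str:
    """Map an SNV with odd-length reference context onto its 96-channel label.

    ``context`` is the local reference sequence centered on the variant
    (at minimum the trinucleotide). Purine references are folded onto the
    pyrimidine strand by reverse complement.
    """
    ref, alt = ref.upper(), alt.upper()
    context = context.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not an SNV: {ref}>{alt}")
    if len(context) < 3 or len(context) % 2 != 1:
        raise ValueError(f"context must be odd-length >= 3, got {context!r}")
    if any(b not in _COMPLEMENT for b in context):
        raise ValueError(f"non-ACGT base in context {context!r}")
    mid = len(context) // 2
    if context[mid] != ref:
        raise ValueError(f"context center {context[mid]!r} != ref {ref!r}")
    five, three = context[mid - 1], context[mid + 1]
    if ref in "GA":
        five, three = _revcomp(three), _revcomp(five)
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return f"{five}[{ref}>{alt}]{three}"


def tally_spectra(mutations: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Tally per-sample 96-channel spectra from a MAF-like mutation table.

    Expects columns ``Tumor_Sample_Barcode``, ``Reference_Allele``,
    ``Tumor_Seq_Allele2`` and ``ref_context``. Non-SNVs and records with
    unusable contexts are skipped; returns (samples x 96 count frame,
    number skipped).
    """
    samples = pd.unique(mutations["Tumor_Sample_Barcode"])
    mat = pd.DataFrame(
        np.zeros((len(samples), 96), dtype=np.int64), index=samples, columns=CHANNELS
    )
    skipped = 0
    for row in mutations.itertuples(index=False):
        ref = str(row.Reference_Allele)
        alt = str(row.Tumor_Seq_Allele2)
        if len(ref) != 1 or len(alt) != 1 or "-" in (ref, alt):
            skipped += 1
            continue
        try:
            ch = channel_of(ref, alt, str(row.ref_context))
        except ValueError as exc:
            warnings.warn(f"skipping mutation: {exc}", stacklevel=2)
            skipped += 1
            continue
        mat.loc[row.Tumor_Sample_Barcode, ch] += 1
    return mat, skipped


def synthetic_signature_matrix(
    n_signatures: int = 30, seed: int = 20180914, concentration: float = 0.08
) -> pd.DataFrame:
    """Generate a synthetic column-stochastic 96 x n signature matrix.

    Stand-in for a reference signature catalog: sparse Dirichlet draws give
    each signature a few dominant trinucleotide channels, so the columns are
    mutually distinguishable and NNLS recovery is well-posed. Columns are
    labeled ``Signature.1`` ... ``Signature.N`` (the mismatch-repair-like
    component used by the cohort generator is ``Signature.6``).
    """
    rng = np.random.default_rng(seed)
    cols = rng.dirichlet(np.full(96, concentration), size=n_signatures).T
    return pd.DataFrame(
        cols,
        index=CHANNELS,
        columns=[f"Signature.{i + 1}" for i in range(n_signatures)],
    )


@dataclass
class SignatureExposure:
    """NNLS exposure estimate for one sample."""

    weights: pd.Series
    residual: float
    all_zero: bool = False


def estimate_exposures(
    spectrum: pd.Series | np.ndarray,
    signature_matrix: pd.DataFrame,
    *,
    prune_threshold: float = PRUNE_THRESHOLD,
) -> SignatureExposure:
    """Estimate relative signature contributions for one spectrum.

    The 96-vector of counts is normalized to proportions; exposures solve
    min ||S w - x||_2 subject to w >= 0. Relative weights below
    ``prune_threshold`` are zeroed and the remainder renormalized to sum 1.
    The reported residual is the unpruned fit's ||S w - x||_2. Exposure
    estimates are invariant to rescaling the input spectrum.
    """
    S = signature_matrix.to_numpy(dtype=float)
    colsums = S.sum(axis=0)
    if np.any(np.abs(colsums - 1.0) > 1e-6):
        raise ValueError("signature matrix columns must each sum to 1 (tol 1e-6)")
    x = np.asarray(spectrum, dtype=float)
    if x.shape[0] != S.shape[0]:
        raise ValueError(f"spectrum length {x.shape[0]} != {S.shape[0]} channels")
    total = x.sum()
    if total <= 0:
        raise ValueError("zero spectrum: no substitutions to deconvolve")
    x = x / total
    w, rnorm = optimize.nnls(S, x)
    wsum = w.sum()
    names = signature_matrix.columns
    if wsum <= 0:
        return SignatureExposure(pd.Series(0.0, index=names), float(rnorm), True)
    rel = w / wsum
    rel[rel < prune_threshold] = 0.0
    if rel.sum() <= 0:
        return SignatureExposure(pd.Series(0.0, index=names), float(rnorm), True)
    rel = rel / rel.sum()
    return SignatureExposure(pd.Series(rel, index=names), float(rnorm), False)


def estimate_exposures_matrix(
    spectra: pd.DataFrame,
    signature_matrix: pd.DataFrame,
    *,
    prune_threshold: float = PRUNE_THRESHOLD,
) -> pd.DataFrame:
    """Per-sample exposures for a samples x 96 spectra frame.

    Samples with empty spectra get all-zero rows.
    """
    rows = {}
    for smp in spectra.index:
        vec = spectra.loc[smp]
        if vec.sum() <= 0:
            rows[smp] = pd.Series(0.0, index=signature_matrix.columns)
        else:
            rows[smp] = estimate_exposures(
                vec, signature_matrix, prune_threshold=prune_threshold
            ).weights
    return pd.DataFrame.from_dict(rows, orient="index")


def permutation_exposure_test(
    exposures: pd.DataFrame,
    carrier: pd.Series,
    *,
    nperm: int = NPERM,
    seed: int | None = None,
    alternative: str = "greater",
    chunk: int = 2000,
) -> pd.DataFrame:
    """Permutation Wilcoxon rank-sum test of exposures vs carrier status.

    For each signature, the observed statistic is the carrier-group rank sum
    (midranks for ties). The null shuffles the carrier labels ``nperm``
    times; one-sided p = (#{permuted stat >= observed} + 1) / (nperm + 1).
    ``alternative='two-sided'`` doubles the smaller tail (capped at 1).
    Constant exposures are reported with p = 1 and a degeneracy flag.
    Benjamini-Hochberg q-values are computed across signatures.
    """
    from biallelic_scan.enrichment import bh_adjust

    carrier = carrier.reindex(exposures.index).astype(bool)
    n = len(carrier)
    k = int(carrier.sum())
    if k < 2 or n - k < 2:
        raise ValueError("need at least 2 carriers and 2 non-carriers")
    rng = np.random.default_rng(seed)
    ranks = np.apply_along_axis(stats.rankdata, 0, exposures.to_numpy(dtype=float))
    obs = ranks[carrier.to_numpy()].sum(axis=0)

    ge = np.zeros(exposures.shape[1], dtype=np.int64)
    le = np.zeros(exposures.shape[1], dtype=np.int64)
    done = 0
    while done < nperm:
        b = min(chunk, nperm - done)
        # b random k-subsets of the n samples (label shuffles)
        draws = np.argsort(rng.random((b, n)), axis=1)[:, :k]
        perm = ranks[draws].sum(axis=1)  # (b, n_signatures)
        ge += (perm >= obs[None, :]).sum(axis=0)
        le += (perm <= obs[None, :]).sum(axis=0)
        done += b
    p_hi = (ge + 1) / (nperm + 1)
    p_lo = (le + 1) / (nperm + 1)
    if alternative == "greater":
        p = p_hi
    elif alternative == "two-sided":
        p = np.minimum(np.minimum(p_hi, p_lo) * 2, 1.0)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    degenerate = exposures.nunique(axis=0).to_numpy() <= 1
    p = np.where(degenerate, 1.0, p)
    out = pd.DataFrame(
        {
            "signature": exposures.columns,
            "stat": obs,
            "p": p,
            "degenerate": degenerate,
        }
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    return out
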