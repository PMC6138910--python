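"""Germline and somatic variant filtering and damage classification.

Variants arrive pre-annotated (VQSR pass flag, LOF confidence class, CADD,
per-ancestry population frequencies, ClinVar ratings); this module only
applies the filtering and classification rules, it never recomputes the
annotations.
"""

from __future__ import annotations

import re
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# Default thresholds; every one is overridable at the call site or via RunConfig.
AF_MAX = 0.05  # max population allele frequency, any ancestry group, LOF set
AF_MAX_VUS = 0.005  # stricter cutoff for rare-missense VUS candidates
CADD_GERMLINE = 30.0  # predicted-pathogenic germline missense
CADD_SOMATIC = 20.0  # damaging somatic missense (sensitivity analysis)
QD_MIN = 1.0  # quality-by-depth floor for homopolymer indels
HOMOPOLYMER_LEN = 4  # minimum run of identical bases

#: Ancestry groups with population allele-frequency columns (``af_`` prefix).
ANCESTRY_GROUPS = ("afr", "amr", "eas", "fin", "nfe", "sas", "oth")

AF_COLUMNS = tuple(f"af_{g}" for g in ANCESTRY_GROUPS)

CLINVAR_PATHOGENIC = {"Pathogenic", "Likely Pathogenic"}
CLINVAR_KNOWN = CLINVAR_PATHOGENIC | {
    "Benign",
    "Likely Benign",
    "Uncertain Significance",
    "Conflicting",
    "Not Provided",
}


def _max_homopolymer_run(context: str) -> int:
    best = 0
    for match in re.finditer(r"(.)\1*", context):
        best = max(best, len(match.group(0)))
    return best


def is_homopolymer_indel_artifact(
    ref: str,
    alt: str,
    ref_context: str,
    qd: float,
    *,
    min_run: int = HOMOPOLYMER_LEN,
    qd_min: float = QD_MIN,
    variant_id: str | None = None,
) -> bool:
    """Flag an indel as a likely homopolymer sequencing artifact.

    True iff the local reference context contains a run of ``min_run`` or more
    identical bases (i.e. the indel lies in or adjacent to a homopolymer) AND
    the call's quality-by-depth score is below ``qd_min``. SNVs are never
    flagged. ``ref_context`` must cover at least ``min_run`` bases on each
    flank of the variant so a run can be detected on either side.
    """
    if len(ref) == len(alt) == 1:
        return False
    # context = left flank + ref + right flank
    flank = (len(ref_context) - len(ref)) // 2
    if flank < min_run:
        name = variant_id or f"{ref}>{alt}"
        raise ValueError(
            f"ref_context for indel {name!r} covers only {flank} flanking bases; "
            f"need at least {min_run} on each side"
        )
    return _max_homopolymer_run(ref_context) >= min_run and qd < qd_min


def _af_ok(row: pd.Series, af_max: float) -> bool:
    # Groups without a recorded frequency do not count against the variant;
    # a variant absent from the resource entirely is treated as novel (AF 0).
    for col in AF_COLUMNS:
        if col in row.index:
            af = row[col]
            if pd.notna(af) and af >= af_max:
                return False
    return True


def filter_germline_lof(
    variants: pd.DataFrame,
    *,
    af_max: float = AF_MAX,
    qd_min: float = QD_MIN,
    homopolymer_len: int = HOMOPOLYMER_LEN,
) -> pd.DataFrame:
    """Retain putative damaging germline LOF variants.

    Keeps rows that (1) pass VQSR, (2) carry a high-confidence LOF
    consequence (``LOF_HC``), (3) have allele frequency strictly below
    ``af_max`` in every ancestry group with a recorded frequency, and
    (4) are not homopolymer indel artifacts (run >= ``homopolymer_len``
    with QD < ``qd_min``).

    The result is always a subset of the input and the operation is
    idempotent.
    """
    if variants.empty:
        return variants.copy()
    keep = np.ones(len(variants), dtype=bool)
    keep &= variants["vqsr_pass"].astype(bool).to_numpy()
    keep &= (variants["consequence"] == "LOF_HC").to_numpy()
    af_mask = variants.apply(_af_ok, axis=1, af_max=af_max).to_numpy()
    keep &= af_mask
    for i, (_, row) in enumerate(variants.iterrows()):
        if not keep[i]:
            continue
        ref, alt = str(row["ref"]), str(row["alt"])
        if len(ref) != len(alt):  # indel
            keep[i] = not is_homopolymer_indel_artifact(
                ref,
                alt,
                str(row["ref_context"]),
                float(row["qd"]),
                min_run=homopolymer_len,
                qd_min=qd_min,
                variant_id=f"{row.get('chrom', '?')}:{row.get('pos', '?')}",
            )
    return variants.loc[keep]


def classify_clinvar_pathogenic(ratings: Sequence[str] | Iterable[str]) -> bool:
    """Majority-rule ClinVar pathogenicity.

    True iff at least half of the contributing sources rated the variant
    Pathogenic or Likely Pathogenic. An empty rating list (no contributing
    sources) is not pathogenic. Unknown rating labels raise ``ValueError``.
    """
    ratings = [r for r in ratings if r]
    if not ratings:
        return False
    unknown = set(ratings) - CLINVAR_KNOWN
    if unknown:
        raise ValueError(f"unknown ClinVar rating label(s): {sorted(unknown)}")
    n_path = sum(r in CLINVAR_PATHOGENIC for r in ratings)
    return n_path / len(ratings) >= 0.5


def classify_damaging(
    *,
    mode: str,
    consequence: str | None = None,
    cadd: float | None = None,
    clinvar_ratings: Sequence[str] | None = None,
    cadd_germline: float = CADD_GERMLINE,
    cadd_somatic: float = CADD_SOMATIC,
) -> bool:
    """Classify a variant/mutation as damaging under one of four rules.

    modes:
      ``germline_known``      — ClinVar majority Pathogenic/Likely Pathogenic
      ``germline_predicted``  — CADD >= 30 (predicted pathogenic missense)
      ``somatic_lof``         — any LOF consequence
      ``somatic_cadd20``      — CADD >= 20 (damaging somatic missense)
    """
    if mode == "germline_known":
        return classify_clinvar_pathogenic(clinvar_ratings or [])
    if mode == "germline_predicted":
        if cadd is None or (isinstance(cadd, float) and np.isnan(cadd)):
            raise ValueError("CADD score required for mode 'germline_predicted'")
        return float(cadd) >= cadd_germline
    if mode == "somatic_lof":
        return consequence in ("LOF", "LOF_HC")
    if mode == "somatic_cadd20":
        if cadd is None or (isinstance(cadd, float) and np.isnan(cadd)):
            raise ValueError("CADD score required for mode 'somatic_cadd20'")
        return float(cadd) >= cadd_somatic
    raise ValueError(f"unknown mode {mode!r}")


GERMLINE_COLUMNS = [
    "sample",
    "gene",
    "chrom",
    "pos",
    "ref",
    "alt",
    "vqsr_pass",
    "qd",
    "consequence",
    "cadd",
    *AF_COLUMNS,
    "clinvar",
    "ref_context",
]


def parse_clinvar_field(field: str | float) -> list[str]:
    """Split a serialized ClinVar ratings field (``|``-joined) into labels."""
    if field is None or (isinstance(field, float) and np.isnan(field)) or field == "":
        return []
    return [part.strip() for part in str(field).split("|") if part.strip()]
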