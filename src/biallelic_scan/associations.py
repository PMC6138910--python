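"""Phenotype association models.

Linear models for somatic microsatellite-instability burden
(log10 MSI ~ germline + somatic + methylation indicators + cancer type +
ancestry PCs) and age of diagnosis (age ~ germline indicator + covariates),
per-gene scans over DNA-damage-repair genes with Bonferroni control,
one-sided co-occurrence tests, age Z-scores, and the noncentral-F sample
size / power computation for a single regression coefficient.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

MAX_MUTATIONS = 5000  # hypermutator exclusion for co-occurrence tests
ALPHA = 0.05

#: Cancer-type spectrum expected for each predisposition gene set.
EXPECTED_CANCER_TYPES: dict[str, tuple[str, ...]] = {
    "MMR": ("colon", "uterine", "stomach"),
    "BRCA1/2": ("breast",),
    "TP53": ("ACC", "glioma", "GBM", "breast", "sarcoma"),
    "SDHB/RET": ("PCPG",),
}


def _design(
    profiles: pd.DataFrame, indicators: pd.DataFrame | None
) -> tuple[pd.DataFrame, list[str]]:
    ct = pd.get_dummies(profiles["cancer_type"], prefix="ct", drop_first=True, dtype=float)
    parts = [ct]
    for col in ("pc1", "pc2"):
        if col in profiles.columns:
            parts.append(profiles[col].astype(float))
    names: list[str] = []
    if indicators is not None:
        ind = indicators.astype(float)
        ind.index = profiles.index
        parts.append(ind)
        names = list(ind.columns)
    X = pd.concat(parts, axis=1)
    X = sm.add_constant(X, has_constant="add")
    return X, names


def _check_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # name columns involved in the deficiency via QR pivoting
        _, r = np.linalg.qr(A)
        diag = np.abs(np.diag(r))
        bad = [X.columns[i] for i in np.where(diag < 1e-8 * diag.max())[0]]
        raise ValueError(f"rank-deficient design; confounded column(s): {bad}")


def log10_msi(msi_burden: pd.Series) -> pd.Series:
    """log10 MSI burden with half-minimum pseudocount for exact zeros."""
    m = msi_burden.astype(float).copy()
    if (m < 0).any():
        raise ValueError("MSI burden must be nonnegative")
    if (m == 0).any():
        positive_min = m[m > 0].min()
        m[m == 0] = positive_min / 2.0
    return np.log10(m)


def fit_msi_model(
    profiles: pd.DataFrame, indicators: pd.DataFrame
) -> pd.DataFrame:
    """OLS of log10 MSI burden on alteration indicators + covariates.

    ``indicators``: samples x indicator columns (e.g. G, S, Me), binary,
    aligned to ``profiles``. Covariates: cancer-type dummies, PC1, PC2.
    Returns one row per indicator: coef (log10 scale), se, p (two-sided),
    fold (10**coef), flag for all-zero/all-one indicators.
    """
    y = log10_msi(profiles["msi_burden"]).to_numpy()
    degenerate = [c for c in indicators.columns if indicators[c].nunique() <= 1]
    live = indicators.drop(columns=degenerate)
    rows = []
    if live.shape[1]:
        X, names = _design(profiles, live)
        _check_rank(X)
        fit = sm.OLS(y, X).fit()
        for name in names:
            coef = float(fit.params[name])
            rows.append(
                {
                    "indicator": name,
                    "coef": coef,
                    "se": float(fit.bse[name]),
                    "p": float(fit.pvalues[name]),
                    "fold": 10.0**coef,
                    "flag": "",
                }
            )
    for name in degenerate:
        rows.append(
            {"indicator": name, "coef": np.nan, "se": np.nan, "p": np.nan,
             "fold": np.nan, "flag": "degenerate indicator (constant)"}
        )
    return pd.DataFrame(rows)


def fit_age_model(profiles: pd.DataFrame, indicators: pd.DataFrame) -> pd.DataFrame:
    """OLS of raw age of diagnosis on germline indicators + covariates.

    Coefficients are in years.
    """
    y = profiles["age"].astype(float).to_numpy()
    degenerate = [c for c in indicators.columns if indicators[c].nunique() <= 1]
    live = indicators.drop(columns=degenerate)
    rows = []
    if live.shape[1]:
        X, names = _design(profiles, live)
        _check_rank(X)
        fit = sm.OLS(y, X).fit()
        for name in names:
            rows.append(
                {
                    "indicator": name,
                    "coef": float(fit.params[name]),
                    "se": float(fit.bse[name]),
                    "p": float(fit.pvalues[name]),
                    "flag": "",
                }
            )
    for name in degenerate:
        rows.append(
            {"indicator": name, "coef": np.nan, "se": np.nan, "p": np.nan,
             "flag": "degenerate indicator (constant)"}
        )
    return pd.DataFrame(rows)


def age_zscore(profiles: pd.DataFrame) -> pd.Series:
    """Within-cancer-type Z-score of age of diagnosis.

    Uses each cancer type's mean and (n-1) standard deviation; types with
    fewer than 2 samples or zero variance raise.
    """
    out = pd.Series(np.nan, index=profiles.index, dtype=float)
    for ctype, grp in profiles.groupby("cancer_type"):
        if len(grp) < 2:
            raise ValueError(f"cancer type {ctype!r} has fewer than 2 samples")
        sd = grp["age"].std(ddof=1)
        if sd == 0:
            raise ValueError(f"cancer type {ctype!r} has zero age variance")
        out.loc[grp.index] = (grp["age"] - grp["age"].mean()) / sd
    return out


def ddr_scan(
    profiles: pd.DataFrame,
    layer_indicators: dict[str, pd.DataFrame],
    *,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Per-gene, per-layer MSI association scan with Bonferroni control.

    ``layer_indicators`` maps layer name (germline / somatic / methylation)
    to a samples x genes binary indicator frame. Each gene is fitted
    separately (its indicator + covariates); Bonferroni significance is
    assessed within layer across the genes actually tested (those with at
    least one carrier and one non-carrier). Upstream exclusions (e.g.
    microsatellite-overlapping frameshifts removed from the somatic layer,
    bi-allelic MMR carriers dropped from the cohort) are the caller's
    responsibility.
    """
    rows = []
    for layer, ind in layer_indicators.items():
        testable = [g for g in ind.columns if ind[g].nunique() > 1]
        n_tests = len(testable)
        for gene in ind.columns:
            if gene not in testable:
                rows.append(
                    {"gene": gene, "layer": layer, "coef": np.nan, "p": np.nan,
                     "n_carriers": int(ind[gene].sum()),
                     "bonferroni_significant": False, "flag": "untestable"}
                )
                continue
            res = fit_msi_model(profiles, ind[[gene]])
            coef, p = float(res["coef"].iloc[0]), float(res["p"].iloc[0])
            rows.append(
                {"gene": gene, "layer": layer, "coef": coef, "p": p,
                 "n_carriers": int(ind[gene].sum()),
                 "bonferroni_significant": bool(p <= alpha / n_tests), "flag": ""}
            )
    return pd.DataFrame(rows)


def cooccurrence_test(
    status_a: pd.Series,
    status_b: pd.Series,
    total_mutations: pd.Series,
    *,
    max_mutations: int = MAX_MUTATIONS,
) -> tuple[float, str]:
    """One-sided Fisher test for enrichment of B among A-positive samples.

    Samples with more than ``max_mutations`` somatic mutations
    (hypermutators) are excluded first. Returns (p, flag); degenerate
    margins give p = 1 with a flag.
    """
    keep = total_mutations.astype(float) <= max_mutations
    if not keep.any():
        raise ValueError("no samples after hypermutator exclusion")
    a = status_a.loc[keep].astype(bool)
    b = status_b.loc[keep].astype(bool)
    table = np.array(
        [
            [int((a & b).sum()), int((a & ~b).sum())],
            [int((~a & b).sum()), int((~a & ~b).sum())],
        ]
    )
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        return 1.0, "degenerate margins"
    _, p = stats.fisher_exact(table, alternative="greater")
    return float(p), ""


def power_single_coefficient(
    n: int, f2: float, *, n_predictors: int = 20, alpha: float = ALPHA
) -> float:
    """Power to detect one coefficient in a multiple linear regression.

    Noncentral-F convention: df1 = 1, df2 = n - n_predictors - 1,
    noncentrality lambda = n * f2, critical value at level alpha.
    """
    df2 = n - n_predictors - 1
    if df2 <= 0:
        return 0.0
    fcrit = stats.f.isf(alpha, 1, df2)
    return float(stats.ncf.sf(fcrit, 1, df2, n * f2))


def required_sample_size(
    f2: float,
    *,
    alpha: float = ALPHA,
    power: float = 0.80,
    n_predictors: int = 20,
) -> tuple[int, str]:
    """Smallest N reaching the target power for a single-coefficient test.

    Returns (N, flag). For effect sizes so large that the minimum
    estimable design already exceeds the target, returns
    n_predictors + 2 with a flag.
    """
    if f2 <= 0:
        raise ValueError("f2 must be positive")
    n_min = n_predictors + 2
    if power_single_coefficient(n_min, f2, n_predictors=n_predictors, alpha=alpha) >= power:
        return n_min, "effect size saturates minimal design"
    lo, hi = n_min, n_min
    while power_single_coefficient(hi, f2, n_predictors=n_predictors, alpha=alpha) < power:
        hi *= 2
        if hi > 10**9:
            raise ValueError("required sample size exceeds 1e9")
    while lo < hi:
        mid = (lo + hi) // 2
        if power_single_coefficient(mid, f2, n_predictors=n_predictors, alpha=alpha) >= power:
            hi = mid
        else:
            lo = mid + 1
    return lo, ""
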