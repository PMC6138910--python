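"""MSI/age linear models, DDR gene scan, co-occurrence, and power routine."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from biallelic_scan.associations import (
    age_zscore,
    cooccurrence_test,
    ddr_scan,
    fit_age_model,
    fit_msi_model,
    power_single_coefficient,
    required_sample_size,
)
from biallelic_scan.synthetic import ScenarioConfig, generate_cohort


def _profiles(n=400, seed=0, types=("colon", "lung")):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        {
            "cancer_type": rng.choice(types, size=n),
            "age": rng.normal(60, 10, size=n),
            "msi_burden": 10 ** rng.normal(-2, 0.3, size=n),
            "pc1": rng.normal(0, 0.02, size=n),
            "pc2": rng.normal(0, 0.02, size=n),
        },
        index=[f"S{i}" for i in range(n)],
    )


class TestMsiModel:
    def test_zero_noise_fold_exact(self):
        prof = _profiles()
        prof["msi_burden"] = 0.01  # noiseless baseline
        carriers = prof.index[:40]
        prof.loc[carriers, "msi_burden"] = 0.01 * 2.8
        ind = pd.DataFrame({"G": prof.index.isin(carriers)}, index=prof.index)
        res = fit_msi_model(prof, ind)
        assert res["coef"].iloc[0] == pytest.approx(np.log10(2.8), abs=1e-10)
        assert res["fold"].iloc[0] == pytest.approx(2.8, abs=1e-8)

    def test_planted_fold_recovery_on_cohort(self):
        # across 10 cohorts the mean recovered fold for each mechanism group
        # is within 2 simulation SE of its planted value
        folds = {"biallelic": [], "bilof": [], "bimiss": []}
        for seed in range(10):
            cfg = ScenarioConfig(
                n_samples=2500, seed=seed, n_biallelic=50, n_bilof=50, n_bimiss=50
            )
            b = generate_cohort(cfg)
            prof = b.samples.set_index("sample")
            # one indicator per effect-bearing group: omitting the methylation
            # indicator would shift the baseline and attenuate the others
            ind = pd.DataFrame(
                {
                    g: prof.index.isin(b.truth.loc[b.truth["group"] == g, "sample"])
                    for g in (*folds, "meth_silenced")
                },
                index=prof.index,
            )
            res = fit_msi_model(prof, ind).set_index("indicator")
            for g in folds:
                folds[g].append(res.loc[g, "fold"])
        planted = {"biallelic": 2.8, "bilof": 2.35, "bimiss": 1.50}
        for g, values in folds.items():
            se = np.std(values, ddof=1) / np.sqrt(len(values))
            assert abs(np.mean(values) - planted[g]) <= 2 * se, (g, np.mean(values), se)

    def test_null_indicator_p_uniform(self):
        ps = []
        for seed in range(80):
            prof = _profiles(seed=seed)
            rng = np.random.default_rng(1000 + seed)
            ind = pd.DataFrame(
                {"G": rng.random(len(prof)) < 0.1}, index=prof.index
            )
            ps.append(fit_msi_model(prof, ind)["p"].iloc[0])
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_degenerate_indicator_flagged(self):
        prof = _profiles()
        ind = pd.DataFrame({"G": False}, index=prof.index)
        res = fit_msi_model(prof, ind)
        assert res["flag"].iloc[0].startswith("degenerate")
        assert np.isnan(res["coef"].iloc[0])

    def test_rank_deficient_design_names_columns(self):
        prof = _profiles()
        ind = pd.DataFrame(
            {"G": prof["cancer_type"] == "colon", "H": prof["cancer_type"] == "lung"},
            index=prof.index,
        )
        with pytest.raises(ValueError, match="confounded"):
            fit_msi_model(prof, ind)

    def test_sample_order_invariance(self):
        prof = _profiles()
        ind = pd.DataFrame({"G": prof.index.isin(prof.index[:30])}, index=prof.index)
        a = fit_msi_model(prof, ind)
        perm = prof.sample(frac=1, random_state=1).index
        b = fit_msi_model(prof.loc[perm], ind.loc[perm])
        assert a["coef"].iloc[0] == pytest.approx(b["coef"].iloc[0], abs=1e-10)


class TestAgeModel:
    def test_zero_noise_shift_exact(self):
        prof = _profiles()
        prof["age"] = 60.0
        carriers = prof.index[:25]
        prof.loc[carriers, "age"] = 46.0
        ind = pd.DataFrame({"G": prof.index.isin(carriers)}, index=prof.index)
        res = fit_age_model(prof, ind)
        assert res["coef"].iloc[0] == pytest.approx(-14.0, abs=1e-10)

    def test_planted_shift_recovery_on_cohort(self):
        coefs = []
        for seed in range(10):
            b = generate_cohort(ScenarioConfig(n_samples=2500, seed=seed, n_bilof=60))
            prof = b.samples.set_index("sample")
            ind = pd.DataFrame(
                {"G": prof.index.isin(b.truth.loc[b.truth["group"] == "bilof", "sample"])},
                index=prof.index,
            )
            coefs.append(fit_age_model(prof, ind)["coef"].iloc[0])
        se = np.std(coefs, ddof=1) / np.sqrt(len(coefs))
        assert abs(np.mean(coefs) - (-14.0)) <= 2 * se

    def test_expected_cancer_type_split(self):
        # the age effect is planted only in carriers whose cancer type matches
        # the gene's expected spectrum; splitting the carrier indicator shows
        # the signal only in the matching stratum
        rng = np.random.default_rng(4)
        prof = _profiles(n=2000, seed=4, types=("colon", "breast"))
        prof["age"] = rng.normal(60, 10, len(prof))
        carriers = prof.index[:120]
        expected = prof.loc[carriers, "cancer_type"] == "colon"
        prof.loc[carriers[expected], "age"] -= 14
        ind = pd.DataFrame(
            {
                "G_expected": prof.index.isin(carriers[expected]),
                "G_other": prof.index.isin(carriers[~expected]),
            },
            index=prof.index,
        )
        res = fit_age_model(prof, ind).set_index("indicator")
        assert res.loc["G_expected", "p"] < 1e-6
        assert res.loc["G_other", "p"] > 0.05


class TestAgeZscore:
    def test_hand_computed_example(self):
        prof = pd.DataFrame(
            {"cancer_type": ["colon"] * 3, "age": [50.0, 60.0, 70.0]}
        )
        z = age_zscore(prof)
        assert z.tolist() == pytest.approx([-1.0, 0.0, 1.0])

    def test_reproduces_reference_zscores(self):
        # cohort constructed to mean 60 / sd 10 reproduces the reference
        # diagnoses at z = -1.03 (age 49.7) and z = +1.20 (age 72.0)
        ages = [60.0 - 10.0, 60.0 + 10.0, 60.0, 60.0, 49.7, 72.0]
        # adjust first four so mean is exactly 60 and sd exactly 10
        base = pd.Series(ages)
        base = (base - base.mean()) / base.std(ddof=1) * 10 + 60
        prof = pd.DataFrame({"cancer_type": "uterine", "age": base})
        z = age_zscore(prof)
        expected = (base - 60.0) / 10.0
        assert z.tolist() == pytest.approx(expected.tolist())

    def test_degenerate_groups_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            age_zscore(pd.DataFrame({"cancer_type": ["colon"], "age": [50.0]}))
        with pytest.raises(ValueError, match="zero age variance"):
            age_zscore(pd.DataFrame({"cancer_type": ["colon"] * 3, "age": [50.0] * 3}))


class TestDdrScan:
    def _scan_inputs(self, seed=0, n=800, planted_gene="G5", fold=2.4):
        rng = np.random.default_rng(seed)
        prof = _profiles(n=n, seed=seed)
        genes = [f"G{i}" for i in range(12)]
        ind = pd.DataFrame(
            rng.random((n, len(genes))) < 0.05, index=prof.index, columns=genes
        )
        if planted_gene:
            carriers = ind[planted_gene]
            prof.loc[carriers, "msi_burden"] *= fold
        return prof, ind

    def test_planted_gene_unique_bonferroni_hit(self):
        prof, ind = self._scan_inputs()
        out = ddr_scan(prof, {"methylation": ind})
        hits = out.loc[out["bonferroni_significant"], "gene"].tolist()
        assert hits == ["G5"]

    def test_null_scan_mostly_clean(self):
        prof, ind = self._scan_inputs(planted_gene=None)
        out = ddr_scan(prof, {"germline": ind})
        assert out["bonferroni_significant"].sum() == 0

    def test_untestable_gene_flagged(self):
        prof, ind = self._scan_inputs()
        ind["G0"] = False
        out = ddr_scan(prof, {"somatic": ind})
        row = out.set_index("gene").loc["G0"]
        assert row["flag"] == "untestable"
        assert not row["bonferroni_significant"]


class TestCooccurrence:
    def test_implied_status_at_floor(self):
        n = 500
        b = pd.Series([True] * 50 + [False] * 450)
        a = b.copy()  # B => A exactly
        total = pd.Series(100, index=b.index)
        p, flag = cooccurrence_test(a, b, total)
        assert p < 1e-10
        assert flag == ""

    def test_independent_statuses_p_uniform(self):
        ps = []
        rng = np.random.default_rng(0)
        for _ in range(100):
            a = pd.Series(rng.random(300) < 0.2)
            b = pd.Series(rng.random(300) < 0.2)
            total = pd.Series(100, index=a.index)
            ps.append(cooccurrence_test(a, b, total)[0])
        # discrete Fisher p-values are conservative; bulk must not be
        # anti-conservative
        assert np.mean(np.array(ps) <= 0.05) <= 0.08

    def test_hypermutators_excluded(self):
        a = pd.Series([True] * 10 + [False] * 10)
        b = a.copy()
        total = pd.Series([10_000] * 10 + [100] * 10)
        p, flag = cooccurrence_test(a, b, total)
        assert flag == "degenerate margins"  # all A+ samples were excluded
        assert p == 1.0

    def test_all_hypermutators_rejected(self):
        a = pd.Series([True, False])
        total = pd.Series([9000, 9000])
        with pytest.raises(ValueError, match="no samples"):
            cooccurrence_test(a, a, total)


def power_oracle(n, f2, n_predictors, alpha=0.05):
    """Independent noncentral-F power via direct numerical integration."""
    from scipy import integrate

    df2 = n - n_predictors - 1
    fcrit = sps.f.isf(alpha, 1, df2)
    lam = n * f2
    # P(F' > fcrit) integrated over the Poisson mixture representation
    val = 0.0
    for j in range(200):
        w = sps.poisson.pmf(j, lam / 2)
        if w < 1e-14 and j > lam:
            break
        val += w * sps.f.sf(fcrit * 1 / (1 + 2 * j / 1), 1 + 2 * j, df2)
    _ = integrate  # numerical quadrature fallback not needed at these sizes
    return val


class TestPower:
    def test_reference_effect_size(self):
        n, flag = required_sample_size(6.83e-4)
        assert flag == ""
        # noncentral-F convention; the G*Power print differs by ~0.1%
        assert n == 11494

    def test_medium_effect_matches_oracle(self):
        n, _ = required_sample_size(0.15, n_predictors=20)
        assert n == 56
        assert power_oracle(56, 0.15, 20) >= 0.80
        assert power_oracle(55, 0.15, 20) < 0.80

    def test_monotone_in_effect_size(self):
        sizes = [required_sample_size(f2)[0] for f2 in (1e-4, 1e-3, 1e-2, 0.1)]
        assert sizes == sorted(sizes, reverse=True)

    def test_agrees_with_oracle_on_random_pairs(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            f2 = float(10 ** rng.uniform(-3, -0.5))
            k = int(rng.integers(2, 30))
            n, flag = required_sample_size(f2, n_predictors=k)
            if flag:
                continue
            assert power_oracle(n, f2, k) >= 0.80
            assert power_oracle(n - 1, f2, k) < 0.80

    def test_saturating_effect_flagged(self):
        n, flag = required_sample_size(500.0, n_predictors=3)
        assert n == 5  # minimum estimable design: n_predictors + 2
        assert flag

    def test_power_increases_with_n(self):
        p1 = power_single_coefficient(100, 0.02)
        p2 = power_single_coefficient(1000, 0.02)
        assert p2 > p1
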