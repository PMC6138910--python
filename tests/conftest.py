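import pandas as pd
import pytest

from biallelic_scan.synthetic import ScenarioConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-sample cohort with default planted carriers (seed 7)."""
    return generate_cohort(ScenarioConfig(n_samples=400, seed=7))


@pytest.fixture(scope="session")
def clean_cohort():
    """A cohort with planted carriers but zero background event rates.

    Every bi-allelic record found downstream must be a planted one.
    """
    cfg = ScenarioConfig(
        n_samples=300,
        seed=11,
        n_somatic_only=50,
        n_meth_silenced=30,
        background_germline_lof_rate=0.0,
        background_somatic_lof_rate=0.0,
        background_somatic_missense_rate=0.0,
        ms_frameshift_scale=0.0,
        hypermutator_fraction=0.0,
    )
    return generate_cohort(cfg)


@pytest.fixture()
def germline_row():
    def make(**overrides):
        row = {
            "sample": "S1",
            "gene": "MSH2",
            "chrom": "chr2",
            "pos": 1000,
            "ref": "C",
            "alt": "T",
            "vqsr_pass": True,
            "qd": 10.0,
            "consequence": "LOF_HC",
            "cadd": 35.0,
            "af_afr": 0.01,
            "af_amr": 0.01,
            "af_eas": 0.01,
            "af_fin": 0.01,
            "af_nfe": 0.01,
            "af_sas": 0.01,
            "af_oth": 0.01,
            "clinvar": "",
            "ref_context": "ACGTACGTACG",
        }
        row.update(overrides)
        return row

    return make


@pytest.fixture()
def germline_table(germline_row):
    def make(rows):
        return pd.DataFrame([germline_row(**r) for r in rows])

    return make
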