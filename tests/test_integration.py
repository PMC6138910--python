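"""Mechanism/subtype assignment and gene-set category logic."""

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from biallelic_scan.integration import (
    CATEGORIES,
    build_records,
    categorize_genesets,
    count_mechanisms,
    integrate_gene,
)


class TestIntegrateGene:
    def test_dual_lof_is_bilof(self):
        rec = integrate_gene("S1", "MSH2", germline_class="LOF", somatic_class="LOF")
        assert rec.mechanism == "germline:somatic"
        assert rec.subtype == "Bi-LOF"

    def test_pathogenic_missense_plus_somatic_lof_is_bimiss(self):
        rec = integrate_gene(
            "S1", "MSH2", germline_class="pathogenic_missense", somatic_class="LOF"
        )
        assert rec.mechanism == "germline:somatic"
        assert rec.subtype == "Bi-Miss"

    def test_somatic_missense_second_hit_is_bimiss(self):
        rec = integrate_gene(
            "S1", "PMS2", germline_class="LOF", somatic_class="damaging_missense"
        )
        assert rec.subtype == "Bi-Miss"

    def test_methylation_second_hit(self):
        rec = integrate_gene("S1", "MLH1", germline_class="LOF", methylated=True)
        assert rec.mechanism == "germline:methylation"
        assert rec.subtype == "n/a"

    def test_mechanism_priority_somatic_over_methylation_over_loh(self):
        rec = integrate_gene(
            "S1", "MLH1", germline_class="LOF", somatic_class="LOF",
            methylated=True, loh=True,
        )
        assert rec.mechanism == "germline:somatic"
        rec = integrate_gene(
            "S1", "MLH1", germline_class="LOF", methylated=True, loh=True
        )
        assert rec.mechanism == "germline:methylation"

    def test_no_germline_never_biallelic(self):
        rec = integrate_gene("S1", "MLH1", somatic_class="LOF", methylated=True, loh=True)
        assert rec.mechanism == "none"

    def test_bad_class_rejected(self):
        with pytest.raises(ValueError):
            integrate_gene("S1", "G", germline_class="weird")


def _records(rows):
    cols = [
        "sample", "gene", "germline_class", "somatic_class",
        "methylated", "loh", "mechanism", "subtype",
    ]
    recs = [
        integrate_gene(
            r["sample"], r["gene"],
            germline_class=r.get("germline_class", "none"),
            somatic_class=r.get("somatic_class", "none"),
            methylated=r.get("methylated", False),
            loh=r.get("loh", False),
        ).__dict__
        for r in rows
    ]
    return pd.DataFrame(recs, columns=cols)


class TestGenesetCategories:
    SETS = {"MMR": ["MLH1", "MSH2", "MSH6"]}

    def test_mixed_different_genes(self):
        recs = _records(
            [
                {"sample": "S1", "gene": "MSH2", "germline_class": "LOF"},
                {"sample": "S1", "gene": "MLH1", "somatic_class": "LOF"},
            ]
        )
        out = categorize_genesets(recs, self.SETS, ["S1"])
        assert out["category"].tolist() == ["Mixed"]

    def test_methylation_only_is_som(self):
        recs = _records([{"sample": "S1", "gene": "MLH1", "methylated": True}])
        out = categorize_genesets(recs, self.SETS, ["S1"])
        assert out["category"].tolist() == ["Som"]

    def test_no_events_is_none(self):
        out = categorize_genesets(_records([]), self.SETS, ["S1"])
        assert out["category"].tolist() == ["None"]

    def test_biallelic_dominates(self):
        recs = _records(
            [
                {"sample": "S1", "gene": "MSH2", "germline_class": "LOF",
                 "somatic_class": "LOF"},
                {"sample": "S1", "gene": "MLH1", "somatic_class": "LOF"},
            ]
        )
        out = categorize_genesets(recs, self.SETS, ["S1"])
        assert out["category"].tolist() == ["Bi-allelic"]

    def test_germline_only_is_germ(self):
        recs = _records([{"sample": "S1", "gene": "MSH6", "germline_class": "LOF"}])
        out = categorize_genesets(recs, self.SETS, ["S1"])
        assert out["category"].tolist() == ["Germ"]

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            categorize_genesets(_records([]), {"X": []}, ["S1"])

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(["S1", "S2"]),
                st.sampled_from(["MLH1", "MSH2", "MSH6"]),
                st.sampled_from(["none", "LOF"]),
                st.sampled_from(["none", "LOF"]),
                st.booleans(),
                st.booleans(),
            ),
            max_size=6,
            unique_by=lambda t: (t[0], t[1]),
        )
    )
    @settings(max_examples=80, deadline=None)
    def test_exactly_one_category_per_sample_set(self, events):
        recs = _records(
            [
                {"sample": s, "gene": g, "germline_class": gc,
                 "somatic_class": sc, "methylated": m, "loh": l}
                for s, g, gc, sc, m, l in events
            ]
        )
        out = categorize_genesets(recs, self.SETS, ["S1", "S2"])
        assert len(out) == 2
        assert out["category"].isin(CATEGORIES).all()

    def test_removing_somatic_layers_never_creates_biallelic(self):
        rows = [
            {"sample": "S1", "gene": "MSH2", "germline_class": "LOF",
             "somatic_class": "LOF"},
            {"sample": "S2", "gene": "MLH1", "germline_class": "LOF",
             "methylated": True},
        ]
        full = categorize_genesets(_records(rows), self.SETS, ["S1", "S2"])
        stripped_rows = [
            {**r, "somatic_class": "none", "methylated": False, "loh": False}
            for r in rows
        ]
        stripped = categorize_genesets(_records(stripped_rows), self.SETS, ["S1", "S2"])
        assert (full["category"] == "Bi-allelic").sum() == 2
        assert set(stripped["category"]) <= {"Germ", "None"}


class TestBuildRecords:
    def _germline(self, rows):
        return pd.DataFrame(
            rows, columns=["sample", "gene", "consequence", "pathogenic"]
        )

    def _somatic(self, rows):
        return pd.DataFrame(
            rows, columns=["sample", "gene", "consequence", "damaging_missense"]
        )

    EMPTY_METH = pd.DataFrame(columns=["sample", "gene", "called"])
    EMPTY_LOH = pd.DataFrame(columns=["sample", "gene", "status"])

    def test_lof_only_by_default(self):
        germ = self._germline(
            [("S1", "MSH2", "LOF_HC", False), ("S2", "MSH2", "missense", True)]
        )
        som = self._somatic([("S1", "MSH2", "LOF", False), ("S2", "MSH2", "LOF", False)])
        recs = build_records(germ, som, self.EMPTY_METH, self.EMPTY_LOH)
        by_sample = recs.set_index("sample")["mechanism"]
        assert by_sample["S1"] == "germline:somatic"
        assert by_sample["S2"] == "none"  # missense germline ignored by default

    def test_pathogenic_missense_switch(self):
        germ = self._germline([("S2", "MSH2", "missense", True)])
        som = self._somatic([("S2", "MSH2", "LOF", False)])
        recs = build_records(
            germ, som, self.EMPTY_METH, self.EMPTY_LOH,
            include_pathogenic_missense=True,
        )
        assert recs["subtype"].tolist() == ["Bi-Miss"]

    def test_ai_mode_superset_of_strict_loh(self, small_cohort):
        from biallelic_scan.loh import call_loh, test_allelic_imbalance

        germ = small_cohort.germline.assign(pathogenic=False)
        ai = test_allelic_imbalance(small_cohort.allele_counts)
        seg = small_cohort.segments.copy()
        seg["start"] -= 1
        loh_calls = call_loh(ai, seg).merge(
            germ.assign(
                variant=lambda d: d["chrom"].astype(str) + ":" + d["pos"].astype(str)
                + ":" + d["ref"] + ":" + d["alt"]
            )[["sample", "variant", "gene"]],
            on=["sample", "variant"],
        )
        som = small_cohort.somatic.rename(
            columns={"Tumor_Sample_Barcode": "sample", "Hugo_Symbol": "gene"}
        ).assign(consequence="LOF", damaging_missense=False)
        strict = build_records(germ, som.iloc[:0], self.EMPTY_METH, loh_calls)
        loose = build_records(
            germ, som.iloc[:0], self.EMPTY_METH, loh_calls, use_ai_as_loh=True
        )
        strict_bi = set(
            map(tuple, strict.loc[strict["mechanism"] != "none", ["sample", "gene"]].values)
        )
        loose_bi = set(
            map(tuple, loose.loc[loose["mechanism"] != "none", ["sample", "gene"]].values)
        )
        assert strict_bi <= loose_bi


class TestCountMechanisms:
    def test_null_scenario_all_zero(self):
        out = count_mechanisms(_records([]))
        assert out.empty

    def test_counts_match_truth(self, clean_cohort):
        from biallelic_scan.loh import call_loh, test_allelic_imbalance
        from biallelic_scan.methylation import call_hypermethylation
        from biallelic_scan.synthetic import somatic_events

        b = clean_cohort
        labels = b.samples.set_index("sample")["cancer_type"]
        meth = call_hypermethylation(b.beta, labels)
        ai = test_allelic_imbalance(b.allele_counts)
        seg = b.segments.copy()
        seg["start"] -= 1
        loh_calls = call_loh(ai, seg).merge(
            b.germline.assign(
                variant=lambda d: d["chrom"].astype(str) + ":" + d["pos"].astype(str)
                + ":" + d["ref"] + ":" + d["alt"]
            )[["sample", "variant", "gene"]],
            on=["sample", "variant"],
        )
        recs = build_records(
            b.germline.assign(pathogenic=False),
            somatic_events(b.somatic),
            meth.loc[meth["called"]],
            loh_calls,
            include_somatic_cadd20=True,
        )
        counts = count_mechanisms(recs).groupby("mechanism")["n"].sum()
        truth_counts = (
            b.truth.loc[b.truth["mechanism"] != "none"]
            .groupby("mechanism")
            .size()
        )
        # germline:somatic planted carriers are recovered exactly (background
        # rates are zero). LOH recovery is bounded by Fisher-test power, and
        # methylation recovery by Z >= 3 outlier calling, which loses power as
        # the planted fraction within a small cancer-type group grows.
        assert counts["germline:somatic"] == truth_counts["germline:somatic"]
        assert counts["germline:methylation"] >= 0.5 * truth_counts["germline:methylation"]
        assert counts["germline:LOH"] >= 0.9 * truth_counts["germline:LOH"]

    def test_order_invariance(self, small_cohort):
        recs = _records(
            [
                {"sample": "S1", "gene": "MSH2", "germline_class": "LOF",
                 "somatic_class": "LOF"},
                {"sample": "S2", "gene": "MLH1", "germline_class": "LOF",
                 "methylated": True},
            ]
        )
        a = count_mechanisms(recs)
        b = count_mechanisms(recs.iloc[::-1].reset_index(drop=True))
        pd.testing.assert_frame_equal(a, b)
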