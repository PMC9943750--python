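"""QC filters, genomic control, IVW pooling, allele harmonization, loci."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prometa import (
    BlockSpec,
    align_alleles,
    define_loci,
    genomic_control,
    ivw_meta,
    post_meta_filter,
    qc_filter,
    simulate_ld_panel,
    variance_explained,
)
from prometa.meta import CHI2_1_MEDIAN, MetaResult

from conftest import make_sumstats


class TestQCFilter:
    def test_low_maf_excluded_with_reason(self):
        df = make_sumstats(["v1"], 0.1, 0.02, eaf=0.004)
        kept, log = qc_filter(df)
        assert kept.empty
        assert list(log["reason"]) == ["MAF"]

    def test_se_boundary_exactly_ten_is_kept(self):
        df = make_sumstats(["v1"], 0.1, 10.0)
        kept, log = qc_filter(df)
        assert len(kept) == 1 and log.empty

    def test_clean_table_passes_unchanged(self):
        df = make_sumstats([f"v{i}" for i in range(5)], 0.1, 0.02)
        kept, log = qc_filter(df)
        assert kept.equals(df) and log.empty

    def test_first_failing_rule_wins(self):
        # fails MAC, MAF, and INFO; MAC is first in precedence
        df = make_sumstats(["v1"], 0.1, 0.02, eaf=0.0001, n=1000)
        df["INFO"] = 0.1
        _, log = qc_filter(df)
        assert list(log["reason"]) == ["MAC"]

    @pytest.mark.parametrize(
        "column,bad,reason",
        [("CALLRATE", 0.90, "CALLRATE"), ("HWE_P", 1e-6, "HWE"),
         ("INFO", 0.2, "INFO"), ("SE", 10.5, "SE")],
    )
    def test_each_rule_fires(self, column, bad, reason):
        df = make_sumstats(["v1"], 0.1, 0.02)
        df[column] = bad
        _, log = qc_filter(df)
        assert list(log["reason"]) == [reason]

    def test_missing_column_is_hard_error(self):
        df = make_sumstats(["v1"], 0.1, 0.02).drop(columns=["HWE_P"])
        with pytest.raises(ValueError, match="HWE_P"):
            qc_filter(df)


class TestGenomicControl:
    def test_lambda_definition_at_unity(self, rng):
        z = rng.normal(size=501)
        z = z * np.sqrt(CHI2_1_MEDIAN / np.median(z**2))  # force median
        df = make_sumstats([f"v{i}" for i in range(501)], z * 0.01, 0.01)
        out, lam = genomic_control(df)
        assert lam == pytest.approx(1.0)
        assert np.allclose(out["SE"], df["SE"])

    def test_doubling_z_quadruples_lambda_and_cancels(self, rng):
        z = rng.normal(size=1000) * 1.4  # inflated so correction applies
        df1 = make_sumstats([f"v{i}" for i in range(1000)], z * 0.01, 0.01)
        df2 = df1.assign(BETA=df1["BETA"] * 2)
        out1, lam1 = genomic_control(df1)
        out2, lam2 = genomic_control(df2)
        assert lam2 == pytest.approx(4 * lam1, rel=1e-12)
        z1 = out1["BETA"] / out1["SE"]
        z2 = out2["BETA"] / out2["SE"]
        assert np.allclose(z1, z2)

    def test_deflation_never_applied(self, rng):
        z = rng.normal(size=1000) * 0.5
        df = make_sumstats([f"v{i}" for i in range(1000)], z * 0.01, 0.01)
        out, lam = genomic_control(df)
        assert lam < 1
        assert out["SE"].equals(df["SE"])

    def test_all_missing_z_errors(self):
        df = make_sumstats(["v1", "v2"], np.nan, 0.01)
        with pytest.raises(ValueError):
            genomic_control(df)


class TestIVWMeta:
    def test_two_point_oracle(self):
        s1 = make_sumstats(["v1"], 0.1, 0.1)
        s2 = make_sumstats(["v1"], 0.3, 0.2)
        res = ivw_meta([s1, s2], apply_meta_gc=False)
        assert res.table["BETA"].iloc[0] == pytest.approx(0.14, abs=1e-12)
        assert res.table["SE"].iloc[0] == pytest.approx(0.0894427, abs=1e-6)

    def test_single_study_identity(self):
        s1 = make_sumstats(["v1", "v2"], [0.1, -0.2], [0.05, 0.04])
        res = ivw_meta([s1], apply_meta_gc=False)
        assert np.allclose(res.table["BETA"], s1["BETA"])
        assert np.allclose(res.table["SE"], s1["SE"])

    def test_equal_se_symmetry(self):
        s1 = make_sumstats(["v1"], 0.1, 0.07)
        s2 = make_sumstats(["v1"], 0.5, 0.07)
        res = ivw_meta([s1, s2], apply_meta_gc=False)
        assert res.table["BETA"].iloc[0] == pytest.approx(0.3)
        assert res.table["SE"].iloc[0] == pytest.approx(0.07 / np.sqrt(2))

    def test_pooled_se_never_exceeds_min_study_se(self, rng):
        studies = [
            make_sumstats([f"v{i}" for i in range(50)],
                          rng.normal(0, 0.1, 50), rng.uniform(0.02, 0.2, 50))
            for _ in range(4)
        ]
        res = ivw_meta(studies, apply_meta_gc=False)
        min_se = pd.concat(studies).groupby("MARKER")["SE"].min()
        merged = res.table.set_index("MARKER")["SE"]
        assert (merged <= min_se.loc[merged.index] + 1e-12).all()

    def test_matches_wls_oracle(self, rng):
        import statsmodels.api as sm

        for _ in range(25):
            k = rng.integers(2, 8)
            betas = rng.normal(0, 0.2, k)
            ses = rng.uniform(0.01, 0.3, k)
            studies = [make_sumstats(["v"], b, s) for b, s in zip(betas, ses)]
            res = ivw_meta(studies, apply_meta_gc=False)
            w = 1 / ses**2
            fit = sm.WLS(betas, np.ones(k), weights=w).fit()
            assert res.table["BETA"].iloc[0] == pytest.approx(fit.params[0], abs=1e-10)
            se_fixed = float(fit.bse[0] / np.sqrt(fit.scale))
            assert res.table["SE"].iloc[0] == pytest.approx(se_fixed, abs=1e-10)


class TestAlignAlleles:
    REF = {"v1": ("A", "G")}

    def test_swapped_alleles_flip_beta_and_eaf(self):
        df = make_sumstats(["v1"], 0.05, 0.01, eaf=0.3)
        df["EA"], df["NEA"] = "G", "A"
        out, log = align_alleles(df, self.REF)
        assert out["BETA"].iloc[0] == pytest.approx(-0.05)
        assert out["EAF"].iloc[0] == pytest.approx(0.7)
        assert log.empty

    def test_ambiguous_common_variant_dropped(self):
        df = make_sumstats(["v1"], 0.05, 0.01, eaf=0.45)
        df["EA"], df["NEA"] = "A", "T"
        out, log = align_alleles(df, {"v1": ("A", "T")})
        assert out.empty
        assert list(log["reason"]) == ["strand-ambiguous"]

    def test_aligned_record_unchanged(self):
        df = make_sumstats(["v1"], 0.05, 0.01, eaf=0.3)
        out, log = align_alleles(df, self.REF)
        assert out["BETA"].iloc[0] == 0.05 and out["EAF"].iloc[0] == 0.3
        assert log.empty

    def test_irreconcilable_pair_dropped(self):
        df = make_sumstats(["v1"], 0.05, 0.01)
        df["EA"], df["NEA"] = "A", "C"
        out, log = align_alleles(df, self.REF)
        assert out.empty
        assert list(log["reason"]) == ["irreconcilable alleles"]

    def test_strand_flip_resolved(self):
        df = make_sumstats(["v1"], 0.05, 0.01, eaf=0.3)
        df["EA"], df["NEA"] = "T", "C"  # complement of A/G
        out, log = align_alleles(df, self.REF)
        assert out["BETA"].iloc[0] == 0.05
        assert (out["EA"].iloc[0], out["NEA"].iloc[0]) == ("A", "G")


class TestPostMetaFilter:
    def _meta(self, n, studies, eaf):
        t = make_sumstats(["v1"], 0.1, 0.01, eaf=eaf, n=n)
        t["N_STUDIES"] = studies
        return MetaResult(table=t, lambda_meta=1.0)

    def test_single_study_excluded(self):
        res = post_meta_filter(self._meta(40_000, 1, 0.3), max_n=40_000)
        assert res.table.empty

    def test_quarter_sample_boundary_kept(self):
        res = post_meta_filter(self._meta(10_000, 3, 0.3), max_n=40_000)
        assert len(res.table) == 1

    def test_maf_boundary_excluded(self):
        res = post_meta_filter(self._meta(40_000, 3, 0.005), max_n=40_000)
        assert res.table.empty


class TestLoci:
    def test_no_significant_variants_gives_empty(self):
        t = make_sumstats([f"v{i}" for i in range(10)], 0.01, 0.01)
        assert define_loci(t) == []

    def test_nearby_leads_in_ld_merge(self):
        panel = simulate_ld_panel(2000, [BlockSpec(2, (0.3, 0.3), 0.99)], seed=1)
        m = panel.markers
        assert panel.r2(m[0], m[1]) > 0.4
        t = make_sumstats(m, [0.2, 0.19], 0.01)
        t["POS"] = [1_000_000, 1_600_000]  # two greedy loci, then LD merge
        t["CHR"] = "1"
        loci = define_loci(t, panel=panel)
        assert len(loci) == 1
        assert set(loci[0].merged_from) == set(m)
        assert loci[0].start == 500_000 and loci[0].end == 2_100_000

    def test_distant_uncorrelated_leads_stay_separate(self, two_block_panel):
        m = [two_block_panel.markers[0], two_block_panel.markers[30]]
        t = make_sumstats(m, 0.2, 0.01)
        t.loc[0, ["CHR", "POS"]] = ["1", 1_000_000]
        t.loc[1, ["CHR", "POS"]] = ["1", 3_000_000]
        loci = define_loci(t, panel=two_block_panel)
        assert len(loci) == 2

    def test_order_invariance(self, rng):
        markers = [f"v{i}" for i in range(200)]
        beta = rng.normal(0, 0.02, 200)
        beta[[10, 150]] = 0.3
        t = make_sumstats(markers, beta, 0.01)
        t["POS"] = 1_000_000 + 10_000 * np.arange(200)
        a = define_loci(t)
        b = define_loci(t.sample(frac=1, random_state=0).reset_index(drop=True))
        assert [(l.lead, l.start, l.end) for l in a] == [
            (l.lead, l.start, l.end) for l in b
        ]
        # lead has the smallest p among members
        tt = t.set_index("MARKER")
        for locus in a:
            assert tt.loc[locus.lead, "P"] <= tt.loc[locus.members, "P"].min() + 1e-300


class TestVarianceExplained:
    def test_closed_form(self):
        assert variance_explained(0.1, 0.5) == pytest.approx(0.005)
        assert variance_explained(0.0, 0.2) == 0.0

    def test_monomorphic_rejected(self):
        with pytest.raises(ValueError, match="monomorphic"):
            variance_explained(0.1, 1.0)
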