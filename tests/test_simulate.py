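"""Generator statistics: determinism, planted frequencies, LD structure,
two-step adjustment, and summary-statistic calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from prometa import (
    BlockSpec,
    CausalEffect,
    EnrichmentConfig,
    SimulationScenario,
    inverse_normal_transform,
    simulate_annotations,
    simulate_cohort_sumstats,
    simulate_ld_panel,
    simulate_phenotype,
    two_step_adjust,
)
from prometa.simulate import marginal_ols


class TestLDPanelSimulation:
    def test_same_seed_is_byte_identical(self):
        a = simulate_ld_panel(200, [BlockSpec(20, (0.1, 0.5), 0.8)], seed=5)
        b = simulate_ld_panel(200, [BlockSpec(20, (0.1, 0.5), 0.8)], seed=5)
        assert np.array_equal(a.dosages, b.dosages)
        assert a.variant_meta.equals(b.variant_meta)

    def test_empirical_maf_tracks_planted_maf(self):
        panel = simulate_ld_panel(
            10_000, [BlockSpec(30, (0.19, 0.19), 0.0)], seed=6
        )
        # 2n haplotypes, binomial sampling error around the planted value
        tol = 3 * np.sqrt(0.19 * 0.81 / 20_000)
        assert np.all(np.abs(panel.freqs() - 0.19) < tol + 1e-12)

    def test_zero_decay_gives_independent_variants(self):
        panel = simulate_ld_panel(
            10_000, [BlockSpec(25, (0.2, 0.5), 0.0)], seed=7
        )
        r2 = panel.corr() ** 2
        off = r2[np.triu_indices_from(r2, k=1)]
        assert off.mean() < 0.01

    def test_cross_block_correlation_vanishes(self):
        panel = simulate_ld_panel(
            8000,
            [BlockSpec(10, (0.2, 0.5), 0.9, "1"), BlockSpec(10, (0.2, 0.5), 0.9, "1")],
            seed=8,
        )
        r = panel.corr()
        cross = np.abs(r[:10, 10:])
        assert cross.mean() < 0.02

    def test_degenerate_block_rejected(self):
        with pytest.raises(ValueError, match="block"):
            simulate_ld_panel(100, [BlockSpec(0, (0.1, 0.5), 0.5)], seed=1)

    def test_dosages_in_range_and_resample_matches_meta(self, small_panel):
        assert set(np.unique(small_panel.dosages)) <= {0, 1, 2}
        re = small_panel.resample(150, seed=3)
        assert re.n_samples == 150
        assert list(re.variant_meta["marker"]) == small_panel.markers


class TestPhenotype:
    def test_null_trait_variance_matches_noise(self):
        panel = simulate_ld_panel(10_000, [BlockSpec(5, (0.2, 0.5), 0.0)], seed=9)
        sc = SimulationScenario(
            n_cohorts=1, cohort_sizes=[10_000], causal_config=(),
            covariate_effects={}, noise_sd=1.3, seed=1,
        )
        y, _ = simulate_phenotype(panel, sc, "t")
        assert abs(y.var() / 1.3**2 - 1) < 0.05

    def test_doubling_beta_doubles_marginal_slope(self, small_panel):
        m = small_panel.markers[10]
        slopes = []
        for beta in (0.3, 0.6):
            sc = SimulationScenario(
                n_cohorts=1, cohort_sizes=[300],
                causal_config=(CausalEffect(m, "t", beta),),
                covariate_effects={}, noise_sd=1e-6, seed=4,
            )
            y, _ = simulate_phenotype(panel=small_panel, scenario=sc, trait="t")
            g = small_panel.dosages[:, small_panel.idx(m)[0]].astype(float)
            slopes.append(np.polyfit(g, y, 1)[0])
        assert slopes[1] / slopes[0] == pytest.approx(2.0, rel=1e-3)

    def test_missing_causal_variant_raises(self, small_panel):
        sc = SimulationScenario(
            n_cohorts=1, cohort_sizes=[300],
            causal_config=(CausalEffect("rs_none", "t", 0.1),), seed=1,
        )
        with pytest.raises(ValueError, match="absent"):
            simulate_phenotype(small_panel, sc, "t")


class TestTwoStepAdjust:
    def test_residuals_orthogonal_to_covariates(self, rng):
        n = 2000
        cov = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        y = rng.normal(size=n) + cov["a"] * 0.5
        res = two_step_adjust(y, cov)
        for c in cov:
            assert abs(np.corrcoef(res, cov[c])[0, 1]) < 1e-10

    def test_rank_preserving_when_covariates_orthogonal(self, rng):
        n = 500
        y = rng.normal(size=n)
        cov = pd.DataFrame({"c": np.zeros(n) + rng.normal(size=n)})
        res = two_step_adjust(y, cov)
        step1 = y - np.polyval(np.polyfit(cov["c"], y, 1), cov["c"])
        assert stats.spearmanr(res, step1).statistic > 0.999

    def test_transformed_variance_near_one(self, rng):
        x = rng.exponential(size=5000)
        t = inverse_normal_transform(x)
        assert abs(t.var() - 1.0) < 0.02

    def test_constant_covariate_dropped_with_warning(self, rng):
        cov = pd.DataFrame({"k": np.ones(100), "x": rng.normal(size=100)})
        with pytest.warns(UserWarning, match="constant covariate"):
            two_step_adjust(rng.normal(size=100), cov)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_blom_transform_is_monotone(self, seed):
        x = np.random.default_rng(seed).normal(size=50)
        t = inverse_normal_transform(x)
        assert np.array_equal(np.argsort(x, kind="stable"),
                              np.argsort(t, kind="stable"))


class TestCohortSumstats:
    def test_null_pvalues_are_uniform(self):
        panel = simulate_ld_panel(1500, [BlockSpec(400, (0.1, 0.5), 0.0)], seed=13)
        sc = SimulationScenario(
            n_cohorts=1, cohort_sizes=[1500], causal_config=(), seed=5,
        )
        ss = simulate_cohort_sumstats(panel, sc, "t", resample=False)
        frac = (ss["P"] < 0.05).mean()
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / 400)
        assert (ss["P"] < 5e-8).sum() == 0

    def test_planted_effect_estimates_are_unbiased(self, small_panel):
        # planted beta is on the adjusted-residual scale: balance the noise
        # so the total trait variance is 1 and the rank-based inverse-normal
        # transform leaves the scale alone
        m = small_panel.markers[5]
        f = float(small_panel.variant_meta["planted_maf"].iloc[5])
        beta = 0.26
        noise = np.sqrt(1.0 - beta**2 * 2 * f * (1 - f))
        sc = SimulationScenario(
            n_cohorts=2, cohort_sizes=[800, 800],
            causal_config=(CausalEffect(m, "t", beta),), noise_sd=noise,
            covariate_effects={}, seed=6,
        )
        est = []
        for rep in range(200):
            ss = simulate_cohort_sumstats(
                small_panel, sc, "t", cohort=rep % 2, n_samples=800,
                seed=1000 + rep,
            )
            est.append(float(ss.set_index("MARKER").loc[m, "BETA"]))
        mc_se = np.std(est, ddof=1) / np.sqrt(len(est))
        assert abs(np.mean(est) - beta) < 2 * mc_se

    def test_monomorphic_variant_flagged_missing(self):
        panel = simulate_ld_panel(80, [BlockSpec(10, (0.005, 0.01), 0.0)], seed=3)
        sc = SimulationScenario(n_cohorts=1, cohort_sizes=[80], seed=2)
        ss = simulate_cohort_sumstats(panel, sc, "t", resample=False)
        mono = panel.dosage_var() == 0
        if mono.any():
            assert ss.loc[mono, "BETA"].isna().all()
            assert (ss.loc[mono, "P"] == 1.0).all()

    def test_marginal_ols_matches_linregress(self, small_panel, rng):
        y = rng.normal(size=small_panel.n_samples)
        beta, se, p = marginal_ols(y, small_panel.dosages)
        j = 7
        ref = stats.linregress(small_panel.dosages[:, j].astype(float), y)
        assert beta[j] == pytest.approx(ref.slope, rel=1e-10)
        assert se[j] == pytest.approx(ref.stderr, rel=1e-10)


class TestAnnotations:
    def test_full_coverage_overlaps_everything(self, small_panel):
        cfg = EnrichmentConfig(fold=1.0, background_fraction=1.0)
        bed, bg = simulate_annotations(small_panel, cfg, seed=1)
        assert bg == 1.0
        from prometa import AnnotationTrack

        track = AnnotationTrack(bed)
        meta = small_panel.variant_meta
        hits = track.contains_many(meta["chr"].to_numpy(), meta["pos"].to_numpy())
        assert hits.all()

    def test_fold_one_covers_causals_at_background_rate(self):
        panel = simulate_ld_panel(400, [BlockSpec(300, (0.1, 0.5), 0.0)], seed=4)
        causal = tuple(panel.markers[::10])
        hit = 0
        for rep in range(40):
            cfg = EnrichmentConfig(fold=1.0, background_fraction=0.2,
                                   causal_markers=causal)
            bed, _ = simulate_annotations(panel, cfg, seed=rep)
            from prometa import AnnotationTrack

            track = AnnotationTrack(bed)
            meta = panel.variant_meta.set_index("marker")
            hit += np.mean(
                [track.contains(meta.loc[m, "chr"], int(meta.loc[m, "pos"]))
                 for m in causal]
            )
        rate = hit / 40
        assert abs(rate - 0.2) < 0.04

    def test_fold_below_one_rejected(self, small_panel):
        with pytest.raises(ValueError, match="fold"):
            simulate_annotations(
                small_panel, EnrichmentConfig(fold=0.5), seed=1
            )
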