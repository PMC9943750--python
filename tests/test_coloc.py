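"""Colocalization engines, sensitivity scoring, decisions, and directions."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prometa import (
    classify_direction,
    coloc_decision,
    coloc_p12_grid,
    coloc_pair,
    hyprcoloc_grid,
    multi_coloc,
    sensitivity_score,
    trait_abf,
)


def ztable(z, se=0.02):
    z = np.asarray(z, float)
    return pd.DataFrame(
        {"MARKER": [f"v{i}" for i in range(len(z))], "BETA": z * se, "SE": se}
    )


def brute_force_pairwise(dfA, dfB, p1=1e-4, p2=1e-4, p12=1e-5, prior_sd=0.15):
    """Naive O(n^2) direct summation over all causal-variant assignments."""
    bfA = np.exp(trait_abf(dfA["BETA"].to_numpy(), dfA["SE"].to_numpy(), prior_sd))
    bfB = np.exp(trait_abf(dfB["BETA"].to_numpy(), dfB["SE"].to_numpy(), prior_sd))
    n = len(bfA)
    h = np.zeros(5)
    h[0] = 1.0
    h[1] = p1 * bfA.sum()
    h[2] = p2 * bfB.sum()
    for i in range(n):
        for j in range(n):
            if i != j:
                h[3] += bfA[i] * bfB[j]
    h[3] *= p1 * p2
    h[4] = p12 * float(bfA @ bfB)
    return h / h.sum()


class TestTraitABF:
    def test_null_variant_is_disfavored(self):
        labf = trait_abf(np.array([0.0]), np.array([0.05]))
        assert labf[0] == pytest.approx(0.5 * np.log(0.05**2 / (0.05**2 + 0.15**2)))
        assert labf[0] < 0

    def test_degenerate_prior_gives_zero_evidence(self):
        labf = trait_abf(np.array([0.3, -0.1]), np.array([0.05, 0.02]), prior_sd=0.0)
        assert np.allclose(labf, 0.0)

    def test_matches_direct_formula_evaluation(self):
        beta, se, W = 0.1, 0.02, 0.15**2
        z2 = (beta / se) ** 2
        expected = 0.5 * (np.log(se**2 / (se**2 + W)) + W * z2 / (se**2 + W))
        got = trait_abf(np.array([beta]), np.array([se]), prior_sd=0.15)[0]
        assert got == pytest.approx(expected, rel=1e-14)


class TestColocPair:
    def test_double_null_gives_pp0(self, rng):
        a, b = ztable(rng.normal(0, 1, 200)), ztable(rng.normal(0, 1, 200))
        res = coloc_pair(a, b)
        assert res.posteriors["PP0"] > 0.9

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 60))
            zA = rng.normal(0, 2, n)
            zB = rng.normal(0, 2, n)
            a, b = ztable(zA), ztable(zB)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = coloc_pair(a, b)
            exp = brute_force_pairwise(a, b)
            got = np.array([res.posteriors[f"PP{i}"] for i in range(5)])
            assert np.abs(got - exp).max() < 1e-10

    def test_posteriors_sum_to_one(self, rng):
        res = coloc_pair(ztable(rng.normal(0, 3, 120)), ztable(rng.normal(0, 3, 120)))
        assert sum(res.posteriors.values()) == pytest.approx(1.0, abs=1e-10)

    def test_pp4_monotone_in_p12(self, rng):
        z = rng.normal(0, 1, 100)
        z[40] = 6.0
        a, b = ztable(z), ztable(z + rng.normal(0, 0.3, 100))
        pp4 = [
            coloc_pair(a, b, p12=g["p12"]).pp4 for g in coloc_p12_grid(n=100)
        ]
        assert all(x2 >= x1 - 1e-12 for x1, x2 in zip(pp4, pp4[1:]))

    def test_zero_shared_variants_is_error(self):
        a = ztable([1.0])
        b = ztable([1.0]).assign(MARKER=["other"])
        with pytest.raises(ValueError, match="shared"):
            coloc_pair(a, b)

    def test_shared_candidate_is_joint_peak(self):
        z = np.zeros(60)
        z[33] = 9.0
        res = coloc_pair(ztable(z), ztable(z))
        assert res.candidate == "v33"
        assert res.pp4 > 0.95


class TestMultiColoc:
    def test_three_traits_sharing_variant_cluster_together(self, rng):
        z = rng.normal(0, 1, (3, 80))
        z[:, 25] = [9.0, 8.0, 10.0]
        block = {t: ztable(z[i]) for i, t in enumerate(("pi", "fg", "t2d"))}
        res = multi_coloc(block)
        assert res.clusters == [("pi", "fg", "t2d")]
        assert res.ppfc > 0.6
        assert res.candidate == "v25"

    def test_distinct_causals_do_not_colocalize(self, rng):
        zA = rng.normal(0, 1, 80)
        zB = rng.normal(0, 1, 80)
        zA[10], zB[70] = 9.0, 9.0
        res = multi_coloc({"a": ztable(zA), "b": ztable(zB)})
        assert res.clusters == []
        assert res.ppfc < 0.1

    def test_divisive_clustering_drops_discordant_trait(self, rng):
        z = rng.normal(0, 1, (3, 80))
        z[0, 25] = 9.0
        z[1, 25] = 8.0
        z[2, 60] = 9.0  # third trait has its own causal variant
        block = {t: ztable(z[i]) for i, t in enumerate(("pi", "fg", "t2d"))}
        res = multi_coloc(block)
        assert ("pi", "fg") in res.clusters

    def test_single_trait_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            multi_coloc({"pi": ztable([1.0, 2.0])})

    def test_two_trait_calls_concord_with_pairwise(self, rng):
        agree = 0
        total = 60
        for rep in range(total):
            kind = rep % 3
            zA = rng.normal(0, 1, 60)
            zB = rng.normal(0, 1, 60)
            if kind == 0:  # shared
                zA[20] = zB[20] = 8.0
            elif kind == 1:  # distinct
                zA[10], zB[50] = 8.0, 8.0
            a, b = ztable(zA), ztable(zB)
            pair_call = coloc_pair(a, b).pp4 > 0.6
            multi_call = bool(multi_coloc({"a": a, "b": b}).clusters)
            agree += pair_call == multi_call
        assert agree / total >= 0.95


class TestSensitivityAndDecision:
    def test_sensitivity_score_is_pass_fraction(self):
        grid = [{"x": i} for i in range(10)]
        assert sensitivity_score(lambda x: x < 4, grid) == pytest.approx(0.4)
        assert sensitivity_score(lambda x: True, grid) == 1.0
        assert sensitivity_score(lambda x: False, grid) == 0.0

    def test_default_grids_have_documented_sizes(self):
        assert len(coloc_p12_grid()) == 100
        assert len(hyprcoloc_grid()) == 4 * 4 * 4

    @pytest.mark.parametrize(
        "pp,sens,r2,expected",
        [
            (0.7, 0.5, 0.3, True),   # posterior + sensitivity branch
            (0.5, 1.0, 0.95, False), # posterior gate fails
            (0.9, 0.2, 0.85, True),  # posterior + LD branch
            (0.9, 0.2, 0.5, False),  # neither branch
            (0.61, 0.41, 0.0, True), # strict inequalities just above
            (0.6, 1.0, 1.0, False),  # pp boundary is strict
        ],
    )
    def test_composite_rule(self, pp, sens, r2, expected):
        assert coloc_decision(pp, sens, r2) is expected

    def test_missing_r2_treated_as_zero_with_warning(self):
        with pytest.warns(UserWarning, match="r\\^2"):
            assert coloc_decision(0.9, 0.2, None) is False


class TestDirectionConsensus:
    def test_t2d_primary_rule(self):
        call = classify_direction({"T2D": (0.1, 1e-6), "FG": (0.0, 0.5)})
        assert (call.direction, call.rule) == (1, "primary")

    def test_all_weak_unclassified(self):
        call = classify_direction({t: (0.1, 0.2) for t in ("T2D", "FG", "FI")})
        assert call.direction is None and call.rule is None

    def test_fallback_two_consistent_outcomes(self):
        call = classify_direction(
            {"FI": (0.2, 0.005), "HbA1c": (0.1, 0.008), "T2D": (0.0, 0.9)}
        )
        assert (call.direction, call.rule) == (1, "fallback")

    def test_conflicting_primary_signs_flagged(self):
        call = classify_direction({"T2D": (0.1, 1e-6), "FG": (-0.2, 1e-6)})
        assert call.direction is None and call.conflict

    def test_negative_fallback(self):
        call = classify_direction({"FI": (-0.2, 0.005), "2hGlu": (-0.1, 0.003)})
        assert call.direction == -1
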