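"""Outlier rules, mixed-model BIC comparison, JZS Bayes factors, power."""

import math
import pathlib

import numpy as np
import pandas as pd
import pytest

from spherenav.stats import (
    ModelFit,
    attach_ideal_predictors,
    bf_from_bic,
    bfda_power,
    compare_geometries,
    filter_outliers_position,
    filter_outliers_triangle,
    fit_geometry_lmm,
    interaction_ttest,
    jzs_bf10,
    per_participant_r2,
    radius_sweep_analysis,
    split_short_long,
)
from spherenav.synthetic import (
    default_cohort_params,
    gen_triangle_cohort,
    trials_to_frame,
)
from spherenav.triangle import pool_turn

DATA = pathlib.Path(__file__).parent / "data"


def make_pooled_frame(design, **overrides):
    params = default_cohort_params(**overrides)
    df = trials_to_frame(gen_triangle_cohort(design, params))
    df["response_turn_deg"] = df["response_turn_deg"].map(pool_turn)
    return attach_ideal_predictors(df, design, scales=(1.5, 2.0, 3.0))


class TestOutlierFilters:
    def test_identical_values_keep_everything(self):
        df = pd.DataFrame(
            {
                "shape_id": ["A"] * 6,
                "response_turn_deg": [120.0] * 6,
                "response_distance_deg": [60.0] * 6,
            }
        )
        kept, removed = filter_outliers_triangle(df)
        assert len(kept) == 6 and len(removed) == 0

    def test_gross_outlier_removed_by_quartile_rule(self):
        # hand computation: sorted turns 10,11,12,13,100 -> Q1=11, Q3=13,
        # fences [8, 16], so only 100 is outside
        df = pd.DataFrame(
            {
                "shape_id": ["A"] * 5,
                "response_turn_deg": [10.0, 11.0, 12.0, 13.0, 100.0],
                "response_distance_deg": [50.0] * 5,
            }
        )
        kept, removed = filter_outliers_triangle(df)
        assert list(removed["response_turn_deg"]) == [100.0]
        assert len(kept) == 4

    def test_either_variable_triggers_removal(self):
        df = pd.DataFrame(
            {
                "shape_id": ["A"] * 5,
                "response_turn_deg": [10.0, 11.0, 12.0, 13.0, 12.0],
                "response_distance_deg": [50.0, 51.0, 52.0, 53.0, 400.0],
            }
        )
        kept, removed = filter_outliers_triangle(df)
        assert len(removed) == 1
        assert removed.iloc[0]["response_distance_deg"] == 400.0

    def test_order_invariance(self, rng):
        turns = np.r_[rng.normal(100, 10, 40), [250.0]]
        df = pd.DataFrame(
            {
                "shape_id": ["A"] * 41,
                "response_turn_deg": turns,
                "response_distance_deg": np.full(41, 60.0),
            }
        )
        perm = rng.permutation(41)
        kept1, _ = filter_outliers_triangle(df)
        kept2, _ = filter_outliers_triangle(df.iloc[perm])
        assert sorted(kept1["response_turn_deg"]) == \
            sorted(kept2["response_turn_deg"])

    def test_small_groups_skipped_with_warning(self):
        df = pd.DataFrame(
            {
                "shape_id": ["A"] * 3,
                "response_turn_deg": [1.0, 2.0, 300.0],
                "response_distance_deg": [1.0, 2.0, 3.0],
            }
        )
        with pytest.warns(UserWarning):
            kept, removed = filter_outliers_triangle(df)
        assert len(kept) == 3

    def test_position_filter_within_participant(self):
        df = pd.DataFrame(
            {
                "participant_id": ["P1"] * 5 + ["P2"] * 5,
                "position_error_deg": [10, 11, 12, 13, 90, 50, 51, 52, 53, 54.0],
            }
        )
        kept = filter_outliers_position(df)
        assert len(kept) == 9
        assert 90 not in kept["position_error_deg"].values

    def test_filters_keep_majority_on_normal_data(self, rng):
        df = pd.DataFrame(
            {
                "shape_id": np.repeat(list("ABCD"), 50),
                "response_turn_deg": rng.normal(120, 15, 200),
                "response_distance_deg": rng.normal(70, 12, 200),
            }
        )
        kept, removed = filter_outliers_triangle(df)
        assert len(kept) > len(removed)
        assert len(removed) < 0.1 * len(df)


class TestMixedModels:
    def test_noiseless_recovery_exact_slope(self, design):
        df = make_pooled_frame(
            design, seed=0, turn_noise_sd=0.0, distance_noise_sd=0.0,
            intercept_sd=0.0, slope_sd=0.0,
        )
        fit = fit_geometry_lmm(df[df.environment == "plane"], "planar", "turn")
        assert fit.fe_params["ideal_turn_planar"] == pytest.approx(1.0,
                                                                   abs=1e-6)
        assert fit.resid_var < 1e-9

    def test_loglik_matches_reference_implementation(self):
        # frozen oracle: lme4 ML fit of y ~ x + (x | participant) on the
        # fixture, logLik = -672.799016
        df = pd.read_csv(DATA / "lmm_fixture.csv")
        df = df.rename(columns={"y": "response_turn_deg"})
        df["ideal_turn_planar"] = df["x"]
        df["shape_id"] = df["x"].astype(str)
        fit = fit_geometry_lmm(df, "planar", "turn")
        assert fit.loglik == pytest.approx(-672.799016, abs=1e-4)
        assert fit.fe_params["ideal_turn_planar"] == pytest.approx(
            0.950992, abs=1e-4
        )

    def test_bic_bookkeeping(self, design):
        df = make_pooled_frame(design, seed=8)
        fit = fit_geometry_lmm(df[df.environment == "sphere"], "planar", "turn")
        # 2 fixed effects + random (co)variances (3 unstructured, 2 when
        # the singular fallback reduced to diagonal) + residual variance
        expected_recov = 2 if fit.singular else 3
        assert fit.k_params == 2 + expected_recov + 1
        assert fit.bic == pytest.approx(
            fit.k_params * math.log(fit.n_obs) - 2 * fit.loglik
        )

    def test_combined_model_has_more_parameters(self, design):
        df = make_pooled_frame(design, seed=8)
        sphere = df[df.environment == "sphere"]
        f1 = fit_geometry_lmm(sphere, "planar", "turn")
        f2 = fit_geometry_lmm(sphere, "combined", "turn")
        assert f2.k_params > f1.k_params
        # nesting up to numerical optimizer tolerance on the larger model
        assert f2.loglik >= f1.loglik - 0.5


class TestBayesFactorFromBIC:
    def _fit(self, bic, n=100):
        return ModelFit("m", "turn", 0.0, n, 5, bic, {}, None, 1.0)

    def test_equal_bics_give_one(self):
        assert bf_from_bic(self._fit(10.0), self._fit(10.0)) == 1.0

    def test_threshold_correspondence(self):
        # BIC difference of 2 ln 3 is exactly the BF = 3 evidence bound
        delta = 2 * math.log(3.0)
        assert bf_from_bic(self._fit(0.0), self._fit(delta)) == \
            pytest.approx(3.0)

    def test_difference_of_ten(self):
        assert bf_from_bic(self._fit(0.0), self._fit(10.0)) == \
            pytest.approx(math.exp(5.0))

    def test_reciprocal_identity(self):
        a, b = self._fit(12.3), self._fit(17.9)
        assert bf_from_bic(a, b) * bf_from_bic(b, a) == pytest.approx(1.0)

    def test_mismatched_n_rejected(self):
        with pytest.raises(ValueError):
            bf_from_bic(self._fit(1.0, n=10), self._fit(1.0, n=11))


class TestPerParticipantR2:
    def test_noiseless_r2_is_one(self, design):
        df = make_pooled_frame(
            design, seed=0, turn_noise_sd=0.0, distance_noise_sd=0.0,
            intercept_sd=0.0, slope_sd=0.0,
        )
        r2, mean, sd = per_participant_r2(
            df[df.environment == "plane"], "planar", "turn")
        assert mean == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_on_toy_table(self):
        x = np.array([1.0, 2, 3, 4, 5, 6])
        y = np.array([2.0, 2.5, 4.0, 4.5, 5.5, 7.0])
        df = pd.DataFrame(
            {"participant_id": "P1", "response_turn_deg": y,
             "ideal_turn_planar": x}
        )
        r2map, mean, _ = per_participant_r2(df, "planar", "turn")
        # brute force 1 - SSE/SST
        beta, alpha = np.polyfit(x, y, 1)
        sse = np.sum((y - alpha - beta * x) ** 2)
        sst = np.sum((y - y.mean()) ** 2)
        assert r2map["P1"] == pytest.approx(1 - sse / sst, abs=1e-12)

    def test_independent_dv_gives_near_zero(self, rng):
        x = np.tile([60.0, 90.0, 120.0, 150.0], 100)
        y = rng.normal(100, 20, 400)
        df = pd.DataFrame(
            {"participant_id": "P1", "response_turn_deg": y,
             "ideal_turn_planar": x}
        )
        r2map, _, _ = per_participant_r2(df, "planar", "turn")
        assert r2map["P1"] < 0.05


class TestRadiusSweep:
    def test_planar_responder_prefers_larger_radii(self, design):
        df = make_pooled_frame(design, seed=21)
        sphere = df[df.environment == "sphere"]
        kept, _ = filter_outliers_triangle(sphere)
        table, best = radius_sweep_analysis(kept, (1.0, 1.5, 2.0, 3.0), "turn")
        assert len(table) == 4
        assert (table["n_obs"] == table["n_obs"].iloc[0]).all()
        bics = table.sort_values("radius_scale")["bic"].to_numpy()
        assert bics[-1] < bics[0]  # larger radius fits planar data better
        # the planar model clearly beats clearly-spherical radii; at the
        # largest radius the predictors are near-collinear and BF ~ 1
        srt = table.sort_values("radius_scale")
        assert (srt["bf_planar_over_sphere"].iloc[:-1] > 1).all()
        assert srt["bf_planar_over_sphere"].iloc[-1] > 0.1

    def test_spherical_responder_recovers_scale_one(self, design):
        df = make_pooled_frame(design, seed=22,
                               responder_geometry="spherical")
        sphere = df[df.environment == "sphere"]
        kept, _ = filter_outliers_triangle(sphere)
        table, best = radius_sweep_analysis(kept, (1.0, 1.5, 2.0, 3.0), "turn")
        bics = table.sort_values("radius_scale")["bic"].to_numpy()
        assert bics[0] == min(bics)
        assert (best == 1.0).mean() > 0.6

    def test_requires_scale_one(self, design):
        df = make_pooled_frame(design, seed=23)
        with pytest.raises(ValueError):
            radius_sweep_analysis(df, (1.5, 2.0), "turn")


class TestSplitShortLong:
    @pytest.mark.parametrize(
        "distance,expected",
        [(63.0, "short"), (134.0, "long"), (110.0, "short"), (110.1, "long")],
    )
    def test_threshold_rule(self, distance, expected):
        df = pd.DataFrame({"distance_deg": [distance]})
        assert split_short_long(df)["condition"].iloc[0] == expected


class TestJZS:
    def test_agrees_with_independent_oracle(self):
        # oracle: pingouin's closed-form JZS integral (same prior)
        pingouin = pytest.importorskip("pingouin")
        for t, n in [(0.0, 20), (1.3, 15), (2.561, 20), (4.2, 25), (7.7, 20)]:
            ours = jzs_bf10(t, n)
            ref = float(
                pingouin.bayesfactor_ttest(t, n, paired=True,
                                           r=math.sqrt(2) / 2)
            )
            assert ours == pytest.approx(ref, rel=0.01)

    def test_null_favoring_at_t_zero(self):
        assert jzs_bf10(0.0, 20) < 1.0

    def test_monotone_in_t(self):
        bfs = [jzs_bf10(t, 20) for t in (0.0, 1.0, 2.0, 4.0)]
        assert bfs == sorted(bfs)


class TestInteractionTTest:
    @staticmethod
    def frame(diffs_sphere, diffs_plane=None, base=20.0):
        rows = []
        for i, d in enumerate(diffs_sphere):
            dp = 0.0 if diffs_plane is None else diffs_plane[i]
            for env, gap in (("sphere", d), ("plane", dp)):
                rows.append([f"P{i}", env, "short", base])
                rows.append([f"P{i}", env, "long", base + gap])
        return pd.DataFrame(
            rows, columns=["participant_id", "environment", "condition",
                           "direction_error_deg"]
        )

    def test_all_zero_differences(self):
        df = self.frame([0.0] * 10)
        res = interaction_ttest(df)
        assert res.t_statistic == 0.0
        assert res.bf10 < 1.0

    def test_constant_shift_invariance(self):
        diffs = [8.0, 12.0, 15.0, 9.0, 11.0, 14.0]
        a = interaction_ttest(self.frame(diffs, base=0.0))
        b = interaction_ttest(self.frame(diffs, base=57.0))
        assert a.bf10 == pytest.approx(b.bf10, rel=1e-9)
        assert a.t_statistic == pytest.approx(b.t_statistic)

    def test_missing_cells_dropped_with_warning(self):
        df = self.frame([10.0] * 5)
        df = df[~((df.participant_id == "P0") & (df.condition == "long")
                  & (df.environment == "sphere"))]
        with pytest.warns(UserWarning):
            res = interaction_ttest(df)
        assert res.n == 4

    def test_plane_only_effect_gives_negative_t(self):
        res = interaction_ttest(
            self.frame([0.0] * 8, diffs_plane=[10.0 + i for i in range(8)])
        )
        assert res.t_statistic < 0


class TestBFDAPower:
    def test_large_effect_reaches_threshold_always(self):
        hit, fp = bfda_power(1.9, n=20, iterations=200, threshold=3.0, seed=1)
        assert hit == 100.0
        assert fp < 5.0

    def test_huge_threshold_kills_hit_rate(self):
        hit, _ = bfda_power(0.2, n=10, iterations=100, threshold=1e9, seed=2)
        assert hit == 0.0

    def test_seed_determinism(self):
        assert bfda_power(0.5, 10, 50, 3.0, seed=3) == \
            bfda_power(0.5, 10, 50, 3.0, seed=3)


class TestGeometryComparisonRecovery:
    def test_true_geometry_wins_both_directions(self, design):
        # planar responder -> planar model; spherical responder -> spherical
        dfp = make_pooled_frame(design, seed=31)
        dfs = make_pooled_frame(design, seed=32,
                                responder_geometry="spherical")
        for df, expected in ((dfp, "planar"), (dfs, "spherical")):
            sphere = df[df.environment == "sphere"]
            kept, _ = filter_outliers_triangle(sphere)
            res = compare_geometries(kept, "turn")
            assert res.winner == expected
            bf = res.bf if expected == "planar" else 1.0 / res.bf
            assert bf > 10.0
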