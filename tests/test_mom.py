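"""MoM conversion, sequential adjustment and longitudinal statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pp13screen as p
from pp13screen import mom as mom_engine


def _samples(weeks, concs, sid=None):
    return pd.DataFrame(
        {
            "subject_id": sid or [f"S{i}" for i in range(len(weeks))],
            "ga_week": weeks,
            "concentration_pg_ml": concs,
        }
    )


class TestMedianCurve:
    def test_singleton_and_odd_count_medians(self):
        curve = p.fit_median_curve(_samples([8], [100.0]))
        assert curve[8] == 100.0
        curve = p.fit_median_curve(_samples([9, 9, 9], [80.0, 100.0, 120.0]))
        assert curve[9] == 100.0

    def test_even_count_uses_midpoint(self):
        curve = p.fit_median_curve(_samples([8, 8], [90.0, 110.0]))
        assert curve[8] == 100.0

    def test_simulated_week8_median_near_baseline(self):
        """500 unaffected week-8 samples recover the 119 pg/ml baseline
        within 5%, cross-checked against an independent sort-based median."""
        cfg = p.CohortConfig(n_subjects=1, seed=21)
        rng = np.random.default_rng(21)
        conc = 119.0 * np.exp(rng.normal(0, cfg.log_sd, 500))
        curve = p.fit_median_curve(_samples([8] * 500, conc))
        srt = np.sort(conc)
        oracle = 0.5 * (srt[249] + srt[250])
        assert curve[8] == oracle
        assert curve[8] == pytest.approx(119.0, rel=0.05)

    def test_small_bins_merge_with_nearest(self):
        df = _samples([8, 8, 8, 9], [90.0, 100.0, 110.0, 500.0])
        curve = p.fit_median_curve(df, min_bin_count=2)
        # week 9 pooled into week 8's bin
        assert curve[9] == curve[8] == 105.0

    def test_lookup_and_fitting_errors(self):
        with pytest.raises(mom_engine.FittingError):
            p.fit_median_curve(_samples([], []))
        curve = p.fit_median_curve(_samples([8], [100.0]))
        with pytest.raises(KeyError, match="12"):
            curve[12]
        assert curve.value(12, fallback="nearest") == 100.0


class TestToMom:
    def test_identity_and_hand_arithmetic(self):
        curve = mom_engine.MedianCurve(medians={8: 119.0}, counts={8: 1})
        moms = p.to_mom(_samples([8, 8], [119.0, 42.0]), curve)
        assert moms["mom"].tolist() == pytest.approx([1.0, 42.0 / 119.0])
        assert moms["trimester"].tolist() == [1, 1]

    @given(scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(deadline=None, derandomize=True, max_examples=25)
    def test_scale_equivariance(self, scale):
        """Multiplying all concentrations by c > 0 leaves every MoM unchanged."""
        rng = np.random.default_rng(5)
        conc = rng.lognormal(np.log(119), 0.5, 31)
        base = p.to_mom(_samples([8] * 31, conc), p.fit_median_curve(_samples([8] * 31, conc)))
        scaled_samples = _samples([8] * 31, conc * scale)
        scaled = p.to_mom(scaled_samples, p.fit_median_curve(scaled_samples))
        np.testing.assert_allclose(scaled["mom"], base["mom"], rtol=1e-9)

    def test_unaffected_median_mom_is_one_per_stratum(self, scored_cohort):
        _, subjects, _, moms = scored_cohort
        unaff = moms[moms["outcome"] == "unaffected"]
        for week, sub in unaff.groupby("ga_week"):
            assert np.median(sub["mom"]) == pytest.approx(1.0, abs=1e-12)


class TestCovariateAdjustment:
    def test_null_effects_recover_near_zero_coefficients(self):
        cfg = p.CohortConfig(n_subjects=1000, covariate_effects={}, seed=31)
        subjects, samples = p.generate_cohort(cfg)
        moms = p.score_cohort(subjects, samples)
        fit_set = moms[moms["outcome"] == "unaffected"]
        model = p.fit_covariate_adjustment(fit_set, fit_set)
        kind, mean, slope = model.terms["bmi"]
        assert abs(slope) < 3 * cfg.log_sd / (
            np.sqrt(len(fit_set)) * fit_set["bmi"].std()
        )

    def test_bmi_coefficient_recovery(self):
        """A generated log-BMI effect of 0.02 is recovered within 25%."""
        cfg = p.CohortConfig(
            n_subjects=2000, covariate_effects={"bmi": 0.02}, log_sd=0.4, seed=37
        )
        subjects, samples = p.generate_cohort(cfg)
        moms = p.score_cohort(subjects, samples)
        fit_set = moms[moms["outcome"] == "unaffected"]
        model = p.fit_covariate_adjustment(fit_set, fit_set)
        _, _, slope = model.terms["bmi"]
        assert slope == pytest.approx(0.02, rel=0.25)

    def test_adjustment_preserves_geometric_mean(self, scored_cohort):
        _, _, _, moms = scored_cohort
        fit_set = moms[moms["outcome"] == "unaffected"]
        model = p.fit_covariate_adjustment(fit_set, fit_set)
        adj = p.apply_covariate_adjustment(fit_set, fit_set, model)
        gm_raw = np.exp(np.log(fit_set["mom"]).mean())
        gm_adj = np.exp(np.log(adj["mom_cov_adj"]).mean())
        assert gm_adj == pytest.approx(gm_raw, rel=1e-9)

    def test_constant_covariate_warns_not_raises(self, caplog):
        df = pd.DataFrame(
            {
                "mom": [0.9, 1.0, 1.1, 1.2],
                "bmi": [24.0, 24.0, 24.0, 24.0],
                "subject_id": list("abcd"),
            }
        )
        model = p.fit_covariate_adjustment(df, df, order=("bmi",))
        assert model.terms["bmi"][2] == 0.0

    def test_missing_covariate_values_error_names_subjects(self):
        df = pd.DataFrame(
            {"mom": [1.0, 1.1], "bmi": [24.0, np.nan], "subject_id": ["a", "b"]}
        )
        with pytest.raises(mom_engine.FittingError, match="b"):
            p.fit_covariate_adjustment(df, df, order=("bmi",))

    def test_joint_mode_close_to_sequential_on_orthogonal_design(self):
        cfg = p.CohortConfig(n_subjects=1500, covariate_effects={"bmi": 0.02}, log_sd=0.3, seed=41)
        subjects, samples = p.generate_cohort(cfg)
        moms = p.score_cohort(subjects, samples)
        fit_set = moms[moms["outcome"] == "unaffected"]
        seq = p.fit_covariate_adjustment(fit_set, fit_set)
        joint = p.fit_covariate_adjustment(fit_set, fit_set, joint=True)
        assert joint.terms["bmi"][2] == pytest.approx(seq.terms["bmi"][2], abs=0.005)


class TestBloodGroupFactors:
    def test_symmetric_groups_give_unit_factors(self):
        rng = np.random.default_rng(3)
        n = 400
        df = pd.DataFrame(
            {
                "blood_group": rng.choice(p.BLOOD_GROUPS, n),
                "trimester": rng.choice([1, 2, 3], n),
                "mom_cov_adj": rng.lognormal(0, 0.3, n),
            }
        )
        factors = p.fit_blood_group_factors(df, per_trimester=False)
        for g in p.BLOOD_GROUPS:
            assert factors[g] == pytest.approx(1.0, abs=0.15)

    def test_factor_recovery_and_ordering(self):
        """First-trimester factors recover the configured multiplier ratios
        (B highest, AB lowest), within 10% at n = 2000."""
        cfg = p.CohortConfig(n_subjects=2000, seed=43)
        subjects, samples = p.generate_cohort(cfg)
        moms = p.score_cohort(subjects, samples)
        fit_set = moms[(moms["outcome"] == "unaffected")]
        factors = p.fit_blood_group_factors(fit_set, per_trimester=True)
        t1 = {g: factors[(g, 1)] for g in p.BLOOD_GROUPS}
        assert max(t1, key=t1.get) == "B"
        assert min(t1, key=t1.get) == "AB"
        for g in p.BLOOD_GROUPS:
            truth = cfg.group_serum_multipliers[g][0] / cfg.group_serum_multipliers["A"][0]
            assert t1[g] / t1["A"] == pytest.approx(truth, rel=0.10)

    def test_small_stratum_falls_back_to_unity(self, caplog):
        df = pd.DataFrame(
            {
                "blood_group": ["O"] * 10 + ["AB"] * 2,
                "trimester": [1] * 12,
                "mom_cov_adj": [2.0] * 12,
            }
        )
        factors = p.fit_blood_group_factors(df, per_trimester=False, min_count=5)
        assert factors["AB"] == 1.0
        assert factors["O"] == 2.0

    def test_adjustment_self_normalizes_each_group(self, scored_cohort):
        """After ABO adjustment the unaffected per-group median is 1."""
        _, _, _, moms = scored_cohort
        unaff = moms[moms["outcome"] == "unaffected"]
        for (g, t), sub in unaff.groupby(["blood_group", "trimester"]):
            if len(sub) >= 5:
                assert np.median(sub["mom_abo_adj"]) == pytest.approx(1.0, abs=1e-12)

    def test_unknown_group_label_raises(self, scored_cohort):
        _, _, _, moms = scored_cohort
        bad = moms.head(3).copy()
        bad["blood_group"] = "X"
        factors = {(g, t): 1.0 for g in p.BLOOD_GROUPS for t in (1, 2, 3)}
        with pytest.raises(KeyError, match="X"):
            p.adjust_for_blood_group(bad, factors)


class TestLongitudinal:
    def test_change_rate_exact_arithmetic(self):
        assert p.change_rate(119, 8, 212, 26) == pytest.approx(93 / 18, abs=1e-15)
        assert p.change_rate(5.0, 8, 5.0, 26) == 0.0
        assert p.change_rate(212, 8, 119, 26) == -p.change_rate(119, 8, 212, 26)
        with pytest.raises(ZeroDivisionError):
            p.change_rate(1.0, 8, 2.0, 8)

    def test_median_slope_matches_change_rate_on_two_points(self):
        slope, intercept = p.median_slope([(8, 119.0), (26, 212.0)])
        assert slope == pytest.approx(p.change_rate(119, 8, 212, 26), abs=1e-12)
        assert intercept == pytest.approx(119.0 - slope * 8, abs=1e-9)

    def test_collinear_points_have_zero_residuals(self):
        pts = [(8.0, 10.0), (18.0, 30.0), (26.0, 46.0)]
        slope, intercept = p.median_slope(pts)
        for x, y in pts:
            assert slope * x + intercept == pytest.approx(y, abs=1e-9)

    def test_group_B_has_steepest_concentration_slope(self):
        """When the generator gives group B the steepest rising trend
        (multipliers growing with trimester), the regression through the
        per-window medians is steeper for B than for A and O."""
        cfg = p.CohortConfig(
            n_subjects=800,
            group_serum_multipliers={
                "O": (0.94, 0.97, 1.00),
                "A": (1.01, 1.00, 1.00),
                "B": (1.10, 1.30, 1.60),
                "AB": (0.58, 0.85, 1.00),
            },
            seed=11,
        )
        subjects, samples = p.generate_cohort(cfg)
        merged = samples.merge(subjects, on="subject_id")
        unaff = merged[merged["outcome"] == "unaffected"]
        slopes = {}
        for g in ("O", "A", "B"):
            pts = []
            for t, (lo, hi) in ((1, (6, 10)), (2, (16, 20)), (3, (24, 28))):
                sub = unaff[
                    (unaff["blood_group"] == g)
                    & unaff["ga_week"].between(lo, hi)
                ]
                pts.append((cfg.window_midweeks[t - 1], float(np.median(sub["concentration_pg_ml"]))))
            slopes[g] = p.median_slope(pts)[0]
        assert slopes["B"] > slopes["A"]
        assert slopes["B"] > slopes["O"]

    def test_median_slope_input_validation(self):
        with pytest.raises(mom_engine.FittingError):
            p.median_slope([(8, 119.0)])
        with pytest.raises(mom_engine.FittingError):
            p.median_slope([(8, 119.0), (8, 121.0)])
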