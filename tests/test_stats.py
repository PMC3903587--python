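"""Baseline imputation, site pooling, MMRM contrasts and associations."""

import warnings

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from plinet import (
    TrajectoryMMRM,
    association_mixed,
    association_per_timepoint,
    fit_mmrm,
    impute_baseline_site_mean,
    pool_small_sites,
    simulate_trial_outcomes,
)
from plinet.types import TrialSimConfig

warnings.filterwarnings("ignore", module="statsmodels")


def _frame(rows):
    return pd.DataFrame(rows)


class TestBaselineImputation:
    def test_site_mean_fills_gap(self):
        df = _frame([
            dict(subject_id="a", site_id="s1", group="control",
                 visit="wk12", outcome=1.0, baseline_value=1.02),
            dict(subject_id="b", site_id="s1", group="control",
                 visit="wk12", outcome=1.0, baseline_value=1.04),
            dict(subject_id="c", site_id="s1", group="active",
                 visit="wk12", outcome=1.0, baseline_value=np.nan),
        ])
        out = impute_baseline_site_mean(df)
        assert out.loc[2, "baseline_value"] == pytest.approx(1.03)
        assert list(out["baseline_imputed"]) == [False, False, True]

    def test_no_missing_is_identity(self):
        df = _frame([
            dict(subject_id="a", site_id="s1", group="control",
                 visit="wk12", outcome=1.0, baseline_value=1.02),
        ])
        out = impute_baseline_site_mean(df)
        np.testing.assert_array_equal(out["baseline_value"],
                                      df["baseline_value"])

    def test_empty_site_falls_back_to_grand_mean(self):
        df = _frame([
            dict(subject_id="a", site_id="s1", group="control",
                 visit="wk12", outcome=1.0, baseline_value=1.00),
            dict(subject_id="b", site_id="s2", group="control",
                 visit="wk12", outcome=1.0, baseline_value=np.nan),
        ])
        with pytest.warns(UserWarning, match="grand mean"):
            out = impute_baseline_site_mean(df)
        assert out.loc[1, "baseline_value"] == pytest.approx(1.00)


class TestSitePooling:
    @staticmethod
    def _sites(sizes):
        rows = []
        s = 0
        for name, n in sizes.items():
            for _ in range(n):
                rows.append(dict(subject_id=f"p{s}", site_id=name,
                                 group="control", visit="wk12", outcome=1.0,
                                 baseline_value=1.0))
                s += 1
        return _frame(rows)

    def test_greedy_merge_smallest_first(self):
        df = self._sites({"s1": 3, "s2": 5, "s3": 9, "s4": 20})
        out = pool_small_sites(df, min_n=16)
        mapping = out.attrs["site_pooling"]
        # 3+5 -> 8, then 8+9 -> 17; the size-20 site stays alone
        assert mapping["s1"] == mapping["s2"] == mapping["s3"]
        assert mapping["s4"] == "s4"
        sizes = out.drop_duplicates("subject_id").groupby("site_id").size()
        assert (sizes >= 16).all()

    def test_all_large_is_identity(self):
        df = self._sites({"s1": 20, "s2": 18})
        out = pool_small_sites(df, min_n=16)
        assert set(out["site_id"]) == {"s1", "s2"}

    def test_single_site_is_identity(self):
        df = self._sites({"only": 3})
        out = pool_small_sites(df, min_n=16)
        assert set(out["site_id"]) == {"only"}


def _balanced_trial(effect_wk24=0.0, noise=0.02, nsub=40, seed=3,
                    baseline_slope=0.5):
    """Balanced complete two-arm frame with matched baselines, no
    site/subject random effects."""
    rng = np.random.default_rng(seed)
    base = rng.normal(1.0, 0.05, nsub // 2)
    rows = []
    for g in ("control", "active"):
        for k in range(nsub // 2):
            b = base[k]
            y24 = (1.0 + (effect_wk24 if g == "active" else 0.0)
                   + baseline_slope * b + rng.normal(0, noise))
            y12 = 0.9 + baseline_slope * b + rng.normal(0, noise)
            for v, y in (("wk12", y12), ("wk24", y24)):
                rows.append(dict(subject_id=f"{g}{k}", site_id="s1",
                                 group=g, visit=v, outcome=y,
                                 baseline_value=b, sample_rate_hz=200.0))
    return _frame(rows)


class TestMMRM:
    def test_exact_null_gives_zero_contrast(self):
        """Identical outcome patterns across arms: estimates 0, p = 1."""
        rng = np.random.default_rng(17)
        noise = rng.normal(0, 0.02, size=(12, 2))  # shared across arms
        rows = []
        for g in ("control", "active"):
            for k in range(12):
                for j, (v, mu) in enumerate((("wk12", 1.02),
                                             ("wk24", 1.01))):
                    rows.append(dict(
                        subject_id=f"{g}{k}", site_id=f"s{k % 2}", group=g,
                        visit=v, outcome=mu + 0.01 * k + noise[k, j],
                        baseline_value=1.0 + 0.005 * k,
                        sample_rate_hz=200.0))
        r = fit_mmrm(_frame(rows))
        assert abs(r.endpoint_estimate) < 1e-8
        assert r.trajectory_p > 0.999

    def test_endpoint_matches_ancova_oracle(self):
        df = _balanced_trial(effect_wk24=0.1)
        r = fit_mmrm(df)
        w24 = df[df["visit"] == "wk24"]
        X = sm.add_constant(pd.DataFrame({
            "g": (w24["group"] == "active").astype(float),
            "b": w24["baseline_value"],
        }))
        ancova = sm.OLS(w24["outcome"], X).fit()
        assert r.endpoint_estimate == pytest.approx(ancova.params["g"],
                                                    abs=1e-6)

    def test_row_order_and_site_label_invariance(self):
        cfg = TrialSimConfig(seed=21)
        df = simulate_trial_outcomes(cfg)
        r1 = fit_mmrm(df)
        shuffled = df.sample(frac=1.0, random_state=9).reset_index(drop=True)
        shuffled["site_id"] = shuffled["site_id"].map(
            lambda s: f"renamed_{s}")
        r2 = fit_mmrm(shuffled)
        assert r2.trajectory_F == pytest.approx(r1.trajectory_F, rel=1e-6)
        assert r2.endpoint_t == pytest.approx(r1.endpoint_t, rel=1e-6)

    def test_constant_shift_moves_only_intercept(self):
        df = _balanced_trial(effect_wk24=0.05)
        r1 = fit_mmrm(df)
        df2 = df.copy()
        df2["outcome"] = df2["outcome"] + 5.0
        r2 = fit_mmrm(df2)
        assert r2.endpoint_estimate == pytest.approx(r1.endpoint_estimate,
                                                     abs=1e-6)
        assert r2.trajectory_F == pytest.approx(r1.trajectory_F, rel=1e-4)

    def test_icc_bounds_and_zero_variance_limit(self):
        # ICC is consistent, not unbiased: at trial size its sampling
        # noise is ~0.1, so the zero-variance limit is checked at a
        # larger n where it must collapse toward 0.
        cfg = TrialSimConfig(sd_site=0.0, sd_subject=0.0,
                             n_control=600, n_active=600, seed=5)
        r = fit_mmrm(simulate_trial_outcomes(cfg))
        assert 0.0 <= r.icc <= 1.0
        assert r.icc < 0.06
        # strong grouping structure -> clearly positive ICC (the baseline
        # covariate absorbs part of the subject-level variance)
        cfg2 = TrialSimConfig(sd_site=0.015, sd_subject=0.03, seed=6)
        r2 = fit_mmrm(simulate_trial_outcomes(cfg2))
        assert r2.icc > 0.15

    def test_effect_generator_detected_with_decline(self):
        r = fit_mmrm(simulate_trial_outcomes(TrialSimConfig(seed=1)))
        assert r.trajectory_p < 0.05
        assert r.endpoint_estimate > 0  # active preserved vs control decline

    def test_estimator_wrapper(self):
        est = TrajectoryMMRM().fit(
            simulate_trial_outcomes(TrialSimConfig(seed=1)))
        assert est.trajectory_p_ == est.result_.trajectory_p
        assert est.get_params()["df_method"] == "between_within"

    def test_unknown_df_method_rejected(self):
        with pytest.raises(ValueError, match="df_method"):
            fit_mmrm(_balanced_trial(), df_method="satterthwaite")


class TestAssociations:
    @staticmethod
    def _assoc_frame(link, n=120, seed=0, noise=0.3):
        rng = np.random.default_rng(seed)
        gamma = rng.normal(1.02, 0.03, n)
        if link == "quadratic":
            mem = -300.0 * (gamma - 1.02) ** 2 + rng.normal(0, noise, n)
        elif link == "linear":
            mem = 10.0 * (gamma - 1.02) + rng.normal(0, noise, n)
        else:
            mem = rng.normal(0, 1, n)
        return _frame([
            dict(subject_id=f"p{i}", site_id="s1", group="active",
                 visit="wk12", outcome=gamma[i], memory_z=mem[i])
            for i in range(n)])

    def test_quadratic_link_recovered(self):
        r = association_per_timepoint(self._assoc_frame("quadratic"),
                                      "wk12", group="active")
        assert r.p_value < 0.01
        assert r.quadratic_coef < 0

    def test_linear_link_not_misread_as_quadratic(self):
        ps = [association_per_timepoint(
            self._assoc_frame("linear", seed=s), "wk12",
            group="active").p_value for s in range(30)]
        assert np.median(ps) > 0.2

    def test_null_type_one_error(self):
        ps = [association_per_timepoint(
            self._assoc_frame("none", seed=s), "wk12",
            group="active").p_value for s in range(300)]
        rate = np.mean(np.asarray(ps) < 0.05)
        assert 0.02 <= rate <= 0.09

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError, match=">= 10"):
            association_per_timepoint(self._assoc_frame("none", n=5),
                                      "wk12", group="active")

    def test_mixed_model_recovers_shared_quadratic(self):
        cfg = TrialSimConfig(memory_link="quadratic", memory_noise_sd=0.2,
                             seed=8)
        df = simulate_trial_outcomes(cfg)
        r = association_mixed(df, "control")
        assert r.p_value < 0.01
        assert r.quadratic_coef < 0
        assert not r.degenerate_random_effect

    def test_single_visit_subjects_fall_back_to_ols(self):
        df = self._assoc_frame("quadratic")
        r = association_mixed(df, "active")
        assert r.degenerate_random_effect
        assert r.p_value < 0.01
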