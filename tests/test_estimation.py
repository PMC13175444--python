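import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pxmode import (
    PropensityFit,
    fit_response_propensity,
    impute_outcomes,
    ipw_difference,
    mi_difference,
    rubin_pool,
    unadjusted_difference,
)
from pxmode.errors import EstimationError
from pxmode.estimation import _propensity_design
from pxmode.scoring import outcome_series, score_dataset
from pxmode.synthetic import MOBILE_WEB, TELEPHONE, generate_trial

from conftest import hand_frame, ipw_fixture, simple_config


def unit_fit(df):
    """Propensity fit with all probabilities 1 (weights 1, no coefficients)."""
    pi = pd.Series(1.0, index=df.index)
    r = df["responded"].astype(bool)
    return PropensityFit(
        params=pd.Series(dtype=float), pi=pi, weights=(1.0 / pi)[r],
        exog=np.zeros((len(df), 0)), exog_names=[], index=df.index, factors=(),
    )


class TestUnadjusted:
    def test_exact_symmetry(self):
        vals = [60.0, 70.0, 80.0, 90.0]
        rows = [dict(arm=a, responded=True) for a in ["telephone"] * 4 + ["mobile_web"] * 4]
        df = hand_frame(rows)
        y = pd.Series(vals * 2, index=df.index)
        res = unadjusted_difference(df, y)
        assert res.difference == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_six_respondent_fixture(self):
        rows = [dict(arm="telephone", responded=True)] * 2 + [
            dict(arm="mobile_web", responded=True)
        ] * 4
        df = hand_frame(rows)
        y = pd.Series([80.0, 90.0, 60.0, 70.0, 80.0, 90.0], index=df.index)
        res = unadjusted_difference(df, y)
        assert res.difference == pytest.approx(75.0 - 85.0)
        assert res.n_analyzed == 6
        # Welch inference matches scipy's reference implementation
        t, p = stats.ttest_ind([60, 70, 80, 90], [80, 90], equal_var=False)
        assert res.p_value == pytest.approx(p)

    def test_nonrespondents_excluded(self):
        rows = [dict(arm=a, responded=i < 2) for a in ("telephone", "mobile_web") for i in range(4)]
        df = hand_frame(rows)
        y = pd.Series([10.0, 20.0, 99.0, 99.0, 30.0, 40.0, 99.0, 99.0], index=df.index)
        y[~df["responded"]] = np.nan
        assert unadjusted_difference(df, y).difference == pytest.approx(35.0 - 15.0)

    def test_requires_two_per_arm(self):
        rows = [dict(arm="telephone", responded=True)] + [
            dict(arm="mobile_web", responded=True)
        ] * 3
        df = hand_frame(rows)
        with pytest.raises(EstimationError):
            unadjusted_difference(df, pd.Series([80.0, 60, 70, 80], index=df.index))


class TestPropensity:
    def test_uniform_half_response(self):
        rows = []
        for arm in ("telephone", "mobile_web"):
            for sex in ("female", "male"):
                for i in range(4):
                    rows.append(dict(arm=arm, sex=sex, responded=i < 2))
        df = hand_frame(rows)
        fit = fit_response_propensity(df, factors=("arm", "sex"))
        np.testing.assert_allclose(fit.pi.to_numpy(), 0.5, atol=1e-8)
        np.testing.assert_allclose(fit.weights.to_numpy(), 2.0, atol=1e-7)

    def test_coefficient_recovery_on_synthetic_data(self):
        cfg = simple_config(n_per_arm=4000, seed=21)
        ds = generate_trial(cfg)
        fit = fit_response_propensity(ds)
        import statsmodels.api as sm

        X = fit.exog
        res = sm.GLM(
            ds.responded.to_numpy(dtype=float), X, family=sm.families.Binomial()
        ).fit()
        truth = {
            "Intercept": 0.2,
            "C(arm)[T.telephone]": -0.5,
            "C(age_group)[T.70+]": -0.6,
            "C(hospital)[T.D]": -0.3,
        }
        for name, true_val in truth.items():
            i = fit.exog_names.index(name)
            assert abs(fit.params.iloc[i] - true_val) < 3.0 * res.bse[i]

    def test_score_equation_property(self, calibrated_trial):
        fit = fit_response_propensity(calibrated_trial)
        assert fit.pi.sum() == pytest.approx(
            float(calibrated_trial.responded.sum()), rel=1e-6
        )

    def test_separation_raises_naming_factor(self):
        rows = []
        for arm in ("telephone", "mobile_web"):
            for hosp in ("A", "B"):
                for i in range(4):
                    responded = (i < 2) and hosp == "A"
                    rows.append(dict(arm=arm, hospital=hosp, responded=responded))
        df = hand_frame(rows)
        with pytest.raises(EstimationError, match="hospital"):
            fit_response_propensity(df, factors=("arm", "hospital"))

    def test_constant_response_rejected(self):
        df = hand_frame([dict(arm="telephone", responded=True)] * 4
                        + [dict(arm="mobile_web", responded=True)] * 4)
        with pytest.raises(EstimationError):
            fit_response_propensity(df, factors=("arm",))


class TestIPW:
    def test_full_response_equals_unadjusted(self):
        rows = [dict(arm=a, responded=True) for a in ["telephone"] * 3 + ["mobile_web"] * 3]
        df = hand_frame(rows)
        y = pd.Series([70.0, 80.0, 90.0, 60.0, 75.0, 90.0], index=df.index)
        res = ipw_difference(df, y, unit_fit(df))
        assert res.difference == pytest.approx(unadjusted_difference(df, y).difference)

    def test_hajek_invariant_to_constant_weights(self):
        df, y = ipw_fixture()
        r = df["responded"].astype(bool)
        pi = pd.Series(0.25, index=df.index)  # constant, hence Hajek-neutral
        fit = PropensityFit(
            params=pd.Series(dtype=float), pi=pi, weights=(1.0 / pi)[r],
            exog=np.zeros((len(df), 0)), exog_names=[], index=df.index, factors=(),
        )
        res = ipw_difference(df, y, fit)
        assert res.difference == pytest.approx(unadjusted_difference(df, y).difference)

    def test_hand_computed_hajek_contrast(self):
        df, y = ipw_fixture()
        fit = fit_response_propensity(df, factors=("arm", "care_field"))
        np.testing.assert_allclose(
            np.sort(np.unique(fit.pi.round(10))), [0.25, 0.5], atol=1e-8
        )
        res = ipw_difference(df, y, fit)
        # telephone: (2*80 + 2*90 + 4*70)/8 = 77.5; mobile: (2*60+2*70+4*60)/8 = 62.5
        assert res.difference == pytest.approx(62.5 - 77.5)

    def test_sandwich_close_to_jackknife(self):
        # replicate the hand fixture 5x: the sandwich is asymptotic, and at
        # n=16 it legitimately disagrees with the jackknife; at n=80 the two
        # agree within 15% (and converge further as n grows)
        df0, y0 = ipw_fixture()
        df = pd.concat([df0] * 5, ignore_index=True)
        y = pd.Series(np.tile(y0.to_numpy(), 5), index=df.index)
        fit = fit_response_propensity(df, factors=("arm", "care_field"))
        res = ipw_difference(df, y, fit)
        thetas = []
        for i in df.index:
            sub = df.drop(index=i)
            suby = y.drop(index=i)
            f = fit_response_propensity(sub, factors=("arm", "care_field"))
            thetas.append(ipw_difference(sub, suby, f).difference)
        thetas = np.asarray(thetas)
        n = len(thetas)
        jk_se = np.sqrt((n - 1) / n * np.sum((thetas - thetas.mean()) ** 2))
        assert abs(res.se - jk_se) / jk_se < 0.15

    def test_mar_consistency_on_synthetic_data(self):
        from pxmode.synthetic import true_estimand

        cfg = simple_config(n_per_arm=4000, residual_sd=8.0, seed=33)
        ds = generate_trial(cfg)
        y = outcome_series(ds, score_dataset(ds), "total")
        res = ipw_difference(ds, y)
        assert abs(res.difference - true_estimand(cfg)) < 3.0 * res.se


class TestImputation:
    def test_zero_missing_copies_identical(self):
        cfg = simple_config(n_per_arm=60, response_coefs={"intercept": 40.0}, seed=41)
        ds = generate_trial(cfg)
        y = outcome_series(ds, score_dataset(ds), "total")
        imp = impute_outcomes(ds, y, m=4, delta=(3.0, -3.0), seed=5)
        for j in range(1, 4):
            np.testing.assert_array_equal(imp.completed[0], imp.completed[j])
        np.testing.assert_array_equal(imp.completed[0], y.to_numpy())

    def test_delta_shift_additive_under_common_draws(self):
        ds = generate_trial(simple_config(n_per_arm=300, seed=42))
        y = outcome_series(ds, score_dataset(ds), "total")
        base = impute_outcomes(ds, y, m=3, delta=(0.0, 0.0), seed=9)
        shifted = impute_outcomes(ds, y, m=3, delta=(0.0, -2.5), seed=9)
        mob_missing = base.missing & (ds.df["arm"] == MOBILE_WEB).to_numpy()
        tel_missing = base.missing & (ds.df["arm"] == TELEPHONE).to_numpy()
        np.testing.assert_allclose(
            shifted.completed[:, mob_missing] - base.completed[:, mob_missing], -2.5
        )
        np.testing.assert_array_equal(
            shifted.completed[:, tel_missing], base.completed[:, tel_missing]
        )
        observed = ~base.missing
        np.testing.assert_array_equal(
            shifted.completed[:, observed], base.completed[:, observed]
        )

    def test_mar_pooled_means_match_latent_truth(self):
        cfg = simple_config(n_per_arm=2000, residual_sd=8.0, seed=43)
        ds = generate_trial(cfg)
        y = outcome_series(ds, score_dataset(ds), "total")
        imp = impute_outcomes(ds, y, m=20, seed=6)
        for arm in (TELEPHONE, MOBILE_WEB):
            a = (ds.df["arm"] == arm).to_numpy()
            pooled = imp.completed[:, a].mean()
            truth = ds.truth.y_true[a].mean()
            se = ds.truth.y_true[a].std() / np.sqrt(a.sum())
            assert abs(pooled - truth) < 4.0 * se

    def test_too_few_respondents_rejected(self):
        ds = generate_trial(simple_config(n_per_arm=12, seed=44))
        y = pd.Series(50.0, index=ds.df.index)
        y[~ds.responded] = np.nan
        with pytest.raises(EstimationError):
            impute_outcomes(ds, y, m=3, seed=1)


class TestRubinPool:
    def test_two_copy_closed_form(self):
        res = rubin_pool([1.0, 3.0], [1.0, 1.0])
        assert res.difference == pytest.approx(2.0)
        assert res.se == pytest.approx(2.0)  # T = 1 + (3/2)*2 = 4
        assert res.df == pytest.approx(16.0 / 9.0)
        crit = stats.t.ppf(0.975, 16.0 / 9.0)
        assert res.ci_low == pytest.approx(2.0 - 2.0 * crit)
        assert res.ci_high == pytest.approx(2.0 + 2.0 * crit)

    def test_identical_copies_collapse(self):
        res = rubin_pool([1.5] * 5, [0.04] * 5)
        assert res.difference == 1.5
        assert res.se == pytest.approx(0.2)
        assert res.df is None  # normal reference when B = 0

    def test_degenerate_rejected(self):
        with pytest.raises(EstimationError):
            rubin_pool([2.0, 2.0], [0.0, 0.0])
        with pytest.raises(EstimationError):
            rubin_pool([1.0], [1.0])

    def test_permutation_invariant(self):
        a = rubin_pool([1.0, 2.0, 4.0], [0.5, 0.7, 0.6])
        b = rubin_pool([4.0, 1.0, 2.0], [0.6, 0.5, 0.7])
        assert a.difference == b.difference
        assert a.se == pytest.approx(b.se)


class TestMIDifference:
    def test_zero_missing_equals_unadjusted_on_all(self):
        cfg = simple_config(n_per_arm=80, response_coefs={"intercept": 40.0}, seed=51)
        ds = generate_trial(cfg)
        y = outcome_series(ds, score_dataset(ds), "total")
        mi = mi_difference(ds, y, m=3, seed=2)
        un = unadjusted_difference(ds, y)
        assert mi.difference == pytest.approx(un.difference)
        assert mi.se == pytest.approx(un.se, rel=1e-9)

    def test_seed_stability_within_one_se(self):
        ds = generate_trial(simple_config(n_per_arm=2000, seed=52))
        y = outcome_series(ds, score_dataset(ds), "total")
        a = mi_difference(ds, y, m=50, seed=1)
        b = mi_difference(ds, y, m=50, seed=2)
        assert abs(a.difference - b.difference) < a.se

    def test_mar_recovery(self):
        from pxmode.synthetic import true_estimand

        cfg = simple_config(n_per_arm=4000, residual_sd=8.0, seed=53)
        ds = generate_trial(cfg)
        y = outcome_series(ds, score_dataset(ds), "total")
        res = mi_difference(ds, y, m=20, seed=3)
        assert abs(res.difference - true_estimand(cfg)) < 3.0 * res.se


class TestDesign:
    def test_reference_coding_first_level(self, calibrated_trial):
        X, names = _propensity_design(
            calibrated_trial.df, ("arm", "sex", "age_group", "care_field", "hospital")
        )
        assert names[0] == "Intercept"
        # alphabetical first levels are the dropped references
        assert not any("mobile_web" in n for n in names)
        assert not any("female" in n for n in names)
        assert not any("19-39" in n for n in names)
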