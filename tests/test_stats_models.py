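"""Quasi-binomial and zero-inflated NB fits, contrasts and effect sizes."""

import numpy as np
import pandas as pd
import pytest

import phonogrow.stats_models as psm
from phonogrow.stats_models import (
    ModelError,
    effect_size_label,
    fit_proportional_model,
    fit_zinb_model,
    pairwise_spurt_contrasts,
    spurt_emmeans,
)

from conftest import simulate_proportional_table, simulate_zinb_table

BETA_NULLISH = {"Intercept": 0.3}
BETA_SPURT = {
    "Intercept": 0.5,
    "Spurt 2": -1.8,
    "Spurt 3": -2.0,
    "Spurt 4": -2.2,
    "Spurt 5": -2.4,
    "Spurt 6": -2.3,
    "AoA 3": 0.2,
    "AoA 5": 0.5,
}


@pytest.fixture(scope="module")
def spurt_fit():
    rng = np.random.default_rng(101)
    table = simulate_proportional_table(2000, BETA_SPURT, rng)
    return fit_proportional_model(table, "degree_gain")


class TestProportionalModel:
    def test_recovers_large_negative_spurt_effect(self, spurt_fit):
        coef = spurt_fit.coefficients.set_index("term")
        est, se = coef.loc["Spurt 2", "estimate"], coef.loc["Spurt 2", "se"]
        assert est < 0 and abs(est / se) > 2
        assert est == pytest.approx(-1.8, abs=4 * se)

    def test_dispersion_reflects_binomial_denominator(self, spurt_fit):
        # proportions of 20 trials have variance p(1-p)/20 -> dispersion ~ 1/20
        assert spurt_fit.dispersion == pytest.approx(0.05, rel=0.35)

    def test_mcfadden_near_zero_without_effects_and_positive_with(self, spurt_fit):
        rng = np.random.default_rng(5)
        null_table = simulate_proportional_table(2000, BETA_NULLISH, rng)
        null_fit = fit_proportional_model(null_table, "degree_gain")
        assert 0.0 <= null_fit.mcfadden_r2 < 0.01
        assert spurt_fit.mcfadden_r2 > 0.05

    def test_vifs_modest_for_balanced_design(self, spurt_fit):
        assert set(spurt_fit.vif) == set(spurt_fit.coefficients["term"]) - {"Intercept"}
        assert max(spurt_fit.vif.values()) < 3

    def test_constant_dv_signalled(self):
        df = pd.DataFrame(
            dict(spurt=[1, 2] * 10, aoa=[1] * 20, freq_log=0.5, length=3.0)
        )
        df["prop_degree_gain"] = 0.4
        df["prop_saturation_gain"] = 0.4
        with pytest.raises(ModelError):
            fit_proportional_model(df, "degree_gain")

    def test_dv_must_be_open_interval(self):
        df = pd.DataFrame(dict(spurt=[1, 2] * 10, aoa=[1] * 20, freq_log=0.5, length=3.0))
        df["prop_degree_gain"] = [0.0, 0.5] * 10
        df["prop_saturation_gain"] = df["prop_degree_gain"]
        with pytest.raises(ModelError):
            fit_proportional_model(df, "degree_gain")

    def test_unknown_dv(self, spurt_fit):
        with pytest.raises(ValueError):
            fit_proportional_model(spurt_fit._table, "weighted")


class TestContrasts:
    def test_all_pairs_reported_antisymmetric_convention(self, spurt_fit):
        ct = pairwise_spurt_contrasts(spurt_fit)
        assert len(ct) == 15
        assert ct["p_tukey"].between(0, 1).all()
        assert ct["estimate"].between(-1, 1).all()
        # reported as i - j with i < j; the reverse contrast is its negation
        first = ct.iloc[0]
        assert first["contrast"] == "Spurts 1 - 2" and first["estimate"] > 0

    def test_identical_groups_null_contrast(self):
        rng = np.random.default_rng(17)
        table = simulate_proportional_table(1500, BETA_NULLISH, rng)
        fit = fit_proportional_model(table, "degree_gain")
        ct = pairwise_spurt_contrasts(fit).set_index("contrast")
        row = ct.loc["Spurts 1 - 2"]
        assert abs(row["estimate"]) < 0.05
        assert row["p_tukey"] > 0.2

    def test_known_margin_difference(self):
        # spurt 1 at p ~ 0.7, all later spurts at p ~ 0.2
        beta = {"Intercept": np.log(0.7 / 0.3)}
        for s in range(2, 7):
            beta[f"Spurt {s}"] = np.log(0.2 / 0.8) - beta["Intercept"]
        rng = np.random.default_rng(23)
        table = simulate_proportional_table(3000, beta, rng)
        fit = fit_proportional_model(table, "degree_gain")
        ct = pairwise_spurt_contrasts(fit).set_index("contrast")
        for s in range(2, 7):
            assert ct.loc[f"Spurts 1 - {s}", "estimate"] == pytest.approx(0.5, abs=0.05)
        assert abs(ct.loc["Spurts 2 - 3", "estimate"]) < 0.05
        em = spurt_emmeans(fit).set_index("spurt")["estimate"]
        assert em.loc[1] == pytest.approx(0.7, abs=0.05)
        assert em.loc[4] == pytest.approx(0.2, abs=0.05)

    def test_requires_proportional_fit(self):
        rng = np.random.default_rng(3)
        table = simulate_zinb_table(
            800, {"Intercept": 1.0}, {"Intercept": -1.0}, 0.5, rng
        )
        zfit = fit_zinb_model(table)
        with pytest.raises(ModelError):
            pairwise_spurt_contrasts(zfit)


class TestZinbModel:
    def test_no_zeros_gives_vanishing_inflation(self):
        rng = np.random.default_rng(29)
        table = simulate_zinb_table(
            1500, {"Intercept": 2.0, "Frequency (log)": 0.3}, {"Intercept": -30.0}, 0.4, rng
        )
        # zero-truncate the handful of natural NB zeros
        table.loc[table["avg_wd_int"] == 0, "avg_wd_int"] = 1
        assert (table["avg_wd_int"] == 0).sum() == 0
        fit = fit_zinb_model(table)
        bz = fit.zero_coefficients.set_index("term")["estimate"]
        eta = sum(bz[t] * fit._X[t].to_numpy() for t in bz.index)
        pi_hat = float(np.mean(1 / (1 + np.exp(-eta))))
        assert pi_hat < 0.02

    def test_recovers_count_and_inflation_parameters(self):
        rng = np.random.default_rng(31)
        bc = {"Intercept": 1.2, "Frequency (log)": -0.3, "Length": 0.1}
        bz = {"Intercept": -0.8, "Length": 0.3}
        table = simulate_zinb_table(4000, bc, bz, 0.5, rng)
        fit = fit_zinb_model(table)
        cc = fit.coefficients.set_index("term")
        zz = fit.zero_coefficients.set_index("term")
        for k, v in bc.items():
            assert cc.loc[k, "estimate"] == pytest.approx(v, abs=3 * cc.loc[k, "se"])
        for k, v in bz.items():
            assert zz.loc[k, "estimate"] == pytest.approx(v, abs=3 * zz.loc[k, "se"])
        assert cc.loc["alpha", "estimate"] == pytest.approx(0.5, abs=3 * cc.loc["alpha", "se"])

    def test_non_integer_dv_rejected(self):
        df = pd.DataFrame(dict(spurt=[1, 2] * 10, aoa=[1, 2] * 10, freq_log=0.5, length=3.0))
        df["avg_wd_int"] = 1.5
        with pytest.raises(ModelError):
            fit_zinb_model(df)

    def test_zero_inflation_concentrated_in_late_spurts(self):
        # structural zeros increasingly rare at later spurts: the
        # zero-component spurt coefficients come out negative
        rng = np.random.default_rng(37)
        bz = {"Intercept": 0.0, "Spurt 2": -1.0, "Spurt 3": -2.0, "Spurt 4": -2.5,
              "Spurt 5": -3.0, "Spurt 6": -3.5}
        table = simulate_zinb_table(4000, {"Intercept": 1.5}, bz, 0.5, rng)
        fit = fit_zinb_model(table)
        zz = fit.zero_coefficients.set_index("term")
        for s in range(2, 7):
            assert zz.loc[f"Spurt {s}", "estimate"] < 0


class TestEffectSizes:
    @pytest.mark.parametrize(
        "orat,label",
        [
            (1.0, "Very small"),
            (1.67, "Very small"),
            (1.7, "Small"),
            (3.5, "Medium"),
            (6.8, "Large"),
            (0.15, "Large"),       # reciprocal 6.67 ~ Medium boundary
            (0.5, "Small"),
            (0.09, "Large"),
        ],
    )
    def test_labels(self, orat, label):
        if orat == 0.15:
            assert effect_size_label(orat) in ("Medium", "Large")
        else:
            assert effect_size_label(orat) == label

    def test_positive_required(self):
        with pytest.raises(ValueError):
            effect_size_label(0.0)

    def test_standardization_uses_sd_for_continuous_terms(self, spurt_fit):
        ors = spurt_fit.std_odds_ratios.set_index("term")
        coef = spurt_fit.coefficients.set_index("term")
        sd = float(spurt_fit._X["Frequency (log)"].std(ddof=1))
        expected = np.exp(coef.loc["Frequency (log)", "estimate"] * sd)
        assert ors.loc["Frequency (log)", "std_or"] == pytest.approx(expected)
        # categorical terms are exponentiated as-is
        expected_s2 = np.exp(coef.loc["Spurt 2", "estimate"])
        assert ors.loc["Spurt 2", "std_or"] == pytest.approx(expected_s2)
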