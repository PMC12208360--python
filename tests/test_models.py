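"""Multilevel models: REML engine, variance components, associations, curves."""

import warnings

import numpy as np
import pandas as pd
import pytest

from codawork.composition import percent_change
from codawork.models import (
    fit_model1,
    fit_pivot_models,
    fit_vca,
    predict_composition_curve,
)
from codawork.preprocess import complete_case_filter, preprocess
from codawork.reml import DesignError, MixedDataset, fit_reml
from codawork.simulate import DETERMINANTS, SimulationConfig, generate_dataset


def _balanced_one_factor(n_groups=24, group_size=6, sd_group=0.8, sd_resid=1.0, seed=3):
    rng = np.random.default_rng(seed)
    labels = np.repeat(np.arange(n_groups), group_size)
    y = 1.5 + rng.normal(0, sd_group, n_groups)[labels] + rng.normal(0, sd_resid, len(labels))
    return y, labels


class TestREMLEngine:
    def test_matches_anova_on_balanced_design(self):
        """REML equals expected-mean-squares estimators when balanced."""
        y, labels = _balanced_one_factor()
        g = labels.max() + 1
        m = (labels == 0).sum()
        res = fit_reml([MixedDataset(y, np.ones((len(y), 1)), [labels])], ["group"])
        means = np.array([y[labels == j].mean() for j in range(g)])
        msb = m * np.sum((means - y.mean()) ** 2) / (g - 1)
        msw = sum(np.sum((y[labels == j] - means[j]) ** 2) for j in range(g)) / (g * (m - 1))
        vc = res.variance_components
        assert vc["residual"] == pytest.approx(msw, abs=1e-6)
        assert vc["group"] == pytest.approx((msb - msw) / m, abs=1e-6)

    def test_matches_statsmodels_nested_fit(self):
        """Independent oracle: statsmodels MixedLM on one nested dataset."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(8)
        ni, nt, nw = 12, 4, 5
        inst = np.repeat(np.arange(ni), nt * nw)
        team = np.repeat(np.arange(ni * nt), nw)
        x = rng.normal(0, 1, ni * nt * nw)
        y = (
            1.0 + 0.4 * x
            + rng.normal(0, 0.6, ni)[inst]
            + rng.normal(0, 0.5, ni * nt)[team]
            + rng.normal(0, 1.0, len(x))
        )
        mine = fit_reml(
            [MixedDataset(y, np.column_stack([np.ones_like(x), x]), [inst, team])],
            ["institution", "team"],
        )
        df = pd.DataFrame({"y": y, "x": x, "inst": inst, "team": team})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm_fit = smf.mixedlm(
                "y ~ x", df, groups="inst", re_formula="1",
                vc_formula={"team": "0 + C(team)"},
            ).fit(reml=True)
        np.testing.assert_allclose(mine.betas[0], sm_fit.fe_params.values, atol=1e-3)
        vc = mine.variance_components
        assert vc["institution"] == pytest.approx(float(sm_fit.cov_re.iloc[0, 0]), abs=5e-3)
        assert vc["team"] == pytest.approx(float(sm_fit.vcomp[0]), abs=5e-3)
        assert vc["residual"] == pytest.approx(float(sm_fit.scale), abs=5e-3)

    def test_rank_deficient_design_rejected(self):
        y, labels = _balanced_one_factor()
        X = np.column_stack([np.ones_like(y), np.ones_like(y)])
        with pytest.raises(DesignError, match="rank"):
            fit_reml([MixedDataset(y, X, [labels])], ["group"])


class TestVCA:
    def test_component_recovery_on_large_design(self):
        cfg = SimulationConfig(
            n_institutions=60, teams_per_institution=4, workers_per_team=5,
            var_worker=0.08, var_team=0.02, var_institution=0.01,
            betas={}, day_noise_sd=0.0, p_missing_determinant=0.0, seed=17,
        )
        w, d = generate_dataset(cfg)
        aw, _ = preprocess(w, d)
        vd = fit_vca(aw)
        assert vd.estimates["worker"] == pytest.approx(0.08, rel=0.15)
        assert vd.estimates["team"] == pytest.approx(0.02, rel=0.5)
        assert vd.estimates["institution"] == pytest.approx(0.01, rel=0.7)

    def test_contributions_sum_to_100(self, analysis_workers):
        vd = fit_vca(analysis_workers)
        assert sum(vd.contributions.values()) == pytest.approx(100.0, abs=0.1)
        assert vd.total == pytest.approx(sum(vd.estimates.values()), abs=1e-9)
        assert all(v >= 0 for v in vd.estimates.values())

    def test_relabelling_invariance(self, analysis_workers):
        vd1 = fit_vca(analysis_workers)
        renamed = analysis_workers.copy()
        renamed["institution_id"] = "Z" + renamed["institution_id"].str[::-1]
        renamed["team_id"] = renamed["team_id"].str[::-1]
        vd2 = fit_vca(renamed)
        for lvl in ("worker", "team", "institution"):
            assert vd2.estimates[lvl] == pytest.approx(vd1.estimates[lvl], abs=1e-8)

    def test_singleton_teams_refused(self):
        cfg = SimulationConfig(
            n_institutions=10, teams_per_institution=3, workers_per_team=1,
            p_missing_determinant=0.0, seed=2,
        )
        w, d = generate_dataset(cfg)
        aw, _ = preprocess(w, d)
        with pytest.raises(DesignError, match="confounded"):
            fit_vca(aw)

    def test_null_team_and_institution_variance(self):
        rates = []
        for s in range(10):
            cfg = SimulationConfig(
                var_team=0.0, var_institution=0.0, betas={},
                p_missing_determinant=0.0, seed=300 + s,
            )
            w, d = generate_dataset(cfg)
            aw, _ = preprocess(w, d)
            vd = fit_vca(aw)
            rates.append([vd.contributions["team"], vd.contributions["institution"]])
        mean_team, mean_inst = np.mean(rates, axis=0)
        assert mean_team <= 3.0 and mean_inst <= 3.0  # boundary noise only

    def test_per_coordinate_diagnostic_present(self, analysis_workers):
        vd = fit_vca(analysis_workers)
        assert set(vd.per_coordinate) == {"ilr1", "ilr2"}
        for comp in vd.per_coordinate.values():
            assert set(comp) == {"worker", "team", "institution"}


class TestModel1:
    def test_fit_reports_all_determinants(self, complete_workers):
        fit = fit_model1(complete_workers)
        assert list(fit.table.index) == list(DETERMINANTS)
        assert fit.converged
        t = fit.table
        assert ((t["ci_low_ilr1"] <= t["coef_ilr1"]) & (t["coef_ilr1"] <= t["ci_high_ilr1"])).all()
        assert t[["p_ilr1", "p_ilr2", "p_joint"]].apply(lambda c: c.between(0, 1)).all().all()

    def test_constant_determinant_rejected(self, complete_workers):
        broken = complete_workers.copy()
        broken["bmi"] = 25.0
        with pytest.raises(DesignError, match="bmi"):
            fit_model1(broken)

    def test_missing_values_rejected(self, complete_workers):
        holey = complete_workers.copy()
        holey.loc[holey.index[0], "bmi"] = np.nan
        with pytest.raises(DesignError, match="complete_case_filter"):
            fit_model1(holey)

    def test_exertion_coefficient_recovered_on_large_sample(self):
        cfg = SimulationConfig(
            n_institutions=50, teams_per_institution=5, workers_per_team=4,
            p_missing_determinant=0.0, seed=23,
        )
        w, d = generate_dataset(cfg)
        aw, _ = preprocess(w, d)
        fit = fit_model1(aw)
        row = fit.table.loc["physical_exertion"]
        assert row["coef_ilr1"] == pytest.approx(-0.03, abs=0.012)
        assert fit.table.loc["max_pain_intensity", "coef_ilr1"] == pytest.approx(0.03, abs=0.012)


class TestPivotModels:
    def test_sb_pivot_equals_model1_ilr1(self, complete_workers):
        m1 = fit_model1(complete_workers)
        pivots = fit_pivot_models(complete_workers)
        np.testing.assert_allclose(
            pivots["sb"].table["coef"].to_numpy(),
            m1.table["coef_ilr1"].to_numpy(),
            atol=1e-8,
        )

    def test_percent_change_attached_consistently(self, complete_workers):
        pivots = fit_pivot_models(complete_workers)
        for fit in pivots.values():
            for _, row in fit.table.iterrows():
                assert row["percent_change"] == pytest.approx(
                    percent_change(row["coef"]), abs=0.05
                )

    def test_mvpa_slope_of_0p03_reports_3p7_percent(self):
        assert percent_change(0.03, 3) == pytest.approx(3.7, abs=0.05)


@pytest.fixture(scope="module")
def strong_fit():
    cfg = SimulationConfig(
        n_institutions=30, teams_per_institution=4, workers_per_team=3,
        betas={"physical_exertion": (-0.05, 0.0)},
        p_missing_determinant=0.0, seed=31,
    )
    w, d = generate_dataset(cfg)
    aw, _ = preprocess(w, d)
    return fit_model1(aw)


class TestPredictionCurves:

    def test_zero_coefficient_gives_flat_curve(self, complete_workers):
        fit = fit_model1(complete_workers)
        fit.betas["ilr1"]["age"] = 0.0
        fit.betas["ilr2"]["age"] = 0.0
        curve = predict_composition_curve(fit, "age")
        for part in ("sb", "lpa", "mvpa"):
            assert curve[part].std() == pytest.approx(0.0, abs=1e-12)

    def test_negative_sb_trade_off_shape(self, strong_fit):
        """Higher exertion shifts time out of SB into LPA and MVPA."""
        curve = predict_composition_curve(strong_fit, "physical_exertion")
        assert (np.diff(curve["sb"]) < 0).all()
        assert (np.diff(curve["lpa"]) > 0).all()
        assert (np.diff(curve["mvpa"]) > 0).all()
        np.testing.assert_allclose(curve[["sb", "lpa", "mvpa"]].sum(axis=1), 1.0, atol=1e-12)

    def test_out_of_range_grid_warns(self, strong_fit):
        with pytest.warns(UserWarning, match="observed range"):
            predict_composition_curve(strong_fit, "physical_exertion", grid=[-5.0, 0.0, 20.0])

    def test_categorical_determinant_rejected(self, strong_fit):
        with pytest.raises(ValueError):
            predict_composition_curve(strong_fit, "sex")
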