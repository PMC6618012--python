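"""Calibration, Rd and Vcmax fitting, and held-out validation."""

import numpy as np
import pandas as pd
import pytest

from leafrd.datasets import GasExchangeTable
from leafrd.estimation import (
    fit_calibration_s,
    fit_rd,
    fit_vcmax,
    validate,
)
from leafrd.kinetics import KineticParams


def light_curve_from_line(slope, intercept, iinc=(50, 75, 100, 125, 150), phi2=0.78):
    iinc = np.asarray(iinc, dtype=float)
    x = iinc * phi2 / 4.0
    return GasExchangeTable(
        pd.DataFrame(
            {
                "dataset_id": "d",
                "leaf_id": "l",
                "curve_type": "AI",
                "regime": "NPR",
                "iinc": iinc,
                "ca": 100.0,
                "ci": 90.0,
                "o": 2.0,
                "an": slope * x + intercept,
                "phi2": phi2,
                "gs": 1.0,
            }
        )
    )


class TestCalibration:
    def test_noiseless_line_recovery(self):
        t = light_curve_from_line(0.85, -1.2)
        fit = fit_calibration_s(t)
        assert fit.slope == pytest.approx(0.85, abs=1e-12)
        assert fit.intercept == pytest.approx(-1.2, abs=1e-10)

    def test_noisy_slope_within_three_se(self):
        rng = np.random.default_rng(5)
        iinc = np.linspace(50, 150, 11)
        t = light_curve_from_line(0.85, -1.2, iinc=iinc)
        t.df["an"] += rng.normal(0, 0.1, len(iinc))
        fit = fit_calibration_s(t)
        assert abs(fit.slope - 0.85) < 3 * fit.slope_se

    def test_degenerate_regressor_errors(self):
        t = light_curve_from_line(0.85, -1.2, iinc=(100, 100, 100))
        with pytest.raises(ValueError, match="variance"):
            fit_calibration_s(t)


class TestFitRd:
    def test_noiseless_self_consistency(self, noiseless_table, runner_inner, truth, true_kinetics):
        fit = fit_rd(noiseless_table, runner_inner, true_kinetics, regime="PR")
        assert fit.estimate == pytest.approx(truth.rd_pr, abs=1e-3)
        assert not fit.at_bound

    def test_regime_separation_and_ordering(self, noiseless_table, runner_inner, truth, true_kinetics):
        pr = fit_rd(noiseless_table, runner_inner, true_kinetics, regime="PR", starts=(1.5,))
        npr = fit_rd(noiseless_table, runner_inner, true_kinetics, regime="NPR", starts=(1.5,))
        assert npr.estimate == pytest.approx(truth.rd_npr, abs=1e-3)
        assert pr.estimate > npr.estimate  # generated with Rd_PR > Rd_NPR
        assert pr.subset != npr.subset

    def test_irradiance_filter_enters_n_obs(self, noiseless_table, runner_inner, true_kinetics):
        ai_pr = noiseless_table.subset(curve_type="AI", regime="PR").df
        n_low = int((ai_pr["iinc"] <= 150).sum())
        assert (ai_pr["iinc"] > 150).any()  # records above the window exist
        fit = fit_rd(noiseless_table, runner_inner, true_kinetics, regime="PR", starts=(1.5,))
        assert fit.n_obs == n_low

    def test_rss_at_estimate_not_above_truth(self, noiseless_table, runner_inner, truth, true_kinetics):
        ai = noiseless_table.subset(curve_type="AI", regime="PR").df
        df = ai[ai["iinc"] <= 150].reset_index(drop=True)
        obs = df["an"].to_numpy()
        fit = fit_rd(noiseless_table, runner_inner, true_kinetics, regime="PR", starts=(1.5,))

        def rss_at(rd):
            pred = runner_inner.predict_an(df, true_kinetics.with_(rd=rd))
            return float(np.sum((pred - obs) ** 2))

        assert fit.rss <= rss_at(truth.rd_pr) + 1e-12

    def test_too_few_records_error(self, runner_inner, true_kinetics):
        t = light_curve_from_line(0.85, -1.2, iinc=(50, 100))
        with pytest.raises(ValueError, match="3"):
            fit_rd(t, runner_inner, true_kinetics, regime="NPR")


class TestFitVcmax:
    def test_noiseless_self_consistency(self, noiseless_table, runner_inner, truth, true_kinetics):
        fit = fit_vcmax(
            noiseless_table, runner_inner, true_kinetics, starts=(100.0,)
        )
        assert fit.estimate == pytest.approx(truth.vcmax, rel=5e-3)

    def test_ca_filter_applied(self, noiseless_table, runner_inner, true_kinetics):
        aca = noiseless_table.subset(curve_type="ACa", regime="PR").df
        n_low = int((aca["ca"] < 30).sum())
        assert (aca["ca"] >= 30).any()
        fit = fit_vcmax(noiseless_table, runner_inner, true_kinetics, starts=(100.0,))
        assert fit.n_obs == n_low

    def test_misspecified_scenario_inflates_uncertainty(
        self, noiseless_table, runners, true_kinetics
    ):
        """Fitting Vcmax with outer-cytosol release against data generated
        with inner release is a misspecified model: its standard error
        (relative to the estimate) exceeds the matched fit's."""
        matched = fit_vcmax(noiseless_table, runners["inner"], true_kinetics, starts=(100.0,))
        wrong = fit_vcmax(noiseless_table, runners["outer"], true_kinetics, starts=(100.0,))
        assert wrong.rss > matched.rss
        assert wrong.se / wrong.estimate > matched.se / matched.estimate

    def test_no_low_ca_records_error(self, runner_inner, true_kinetics):
        t = light_curve_from_line(0.85, -1.2)
        t.df["curve_type"] = "ACa"
        t.df["regime"] = "PR"
        t.df["ca"] = 60.0
        with pytest.raises(ValueError, match="Ca"):
            fit_vcmax(t, runner_inner, true_kinetics)


class TestValidate:
    def test_degenerate_holdout_matches_fit_rmse(self, noiseless_table, runner_inner, truth, true_kinetics):
        fit = fit_rd(noiseless_table, runner_inner, true_kinetics, regime="PR", starts=(1.5,))
        ai = noiseless_table.subset(curve_type="AI", regime="PR").df
        subset = GasExchangeTable(ai[ai["iinc"] <= 150].reset_index(drop=True))
        report = validate(subset, runner_inner, true_kinetics.with_(rd=fit.estimate))
        assert report.attrs["rmse"] == pytest.approx(
            np.sqrt(fit.rss / fit.n_obs), abs=1e-6
        )

    def test_noiseless_matched_scenario_rmse_small(self, noiseless_table, runner_inner, truth, true_kinetics):
        held = noiseless_table.subset(curve_type="AI", regime="PR")
        report = validate(held, runner_inner, true_kinetics)
        assert report.attrs["rmse"] < 1e-3

    def test_empty_holdout_errors(self, runner_inner, true_kinetics):
        empty = GasExchangeTable(light_curve_from_line(0.8, -1).df.iloc[:0])
        with pytest.raises(ValueError, match="empty"):
            validate(empty, runner_inner, true_kinetics)
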