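"""Kok/Yin/Laisk estimators, Laisk simulation, sweeps and AIC."""

import numpy as np
import pandas as pd
import pytest

from leafrd.datasets import GasExchangeTable
from leafrd.methods import (
    aic,
    compare_scenarios,
    delta_aic,
    kok_method,
    laisk_method,
    yin_method,
)


def light_curve(an, iinc, phi2=None, regime="PR"):
    n = len(iinc)
    return GasExchangeTable(
        pd.DataFrame(
            {
                "dataset_id": "d",
                "leaf_id": "l",
                "curve_type": "AI",
                "regime": regime,
                "iinc": np.asarray(iinc, float),
                "ca": 40.0,
                "ci": 30.0,
                "o": 21.0,
                "an": np.asarray(an, float),
                "phi2": np.full(n, 0.78) if phi2 is None else np.asarray(phi2, float),
                "gs": 1.0,
            }
        )
    )


def aci_lines(lines, ci=(1.0, 2.0, 4.0, 6.0, 8.0)):
    """Build a Laisk table from exact lines {label: (slope, intercept)}."""
    rows = []
    for label, (a, b) in lines.items():
        for c in ci:
            rows.append(
                {
                    "dataset_id": "d",
                    "leaf_id": "l",
                    "curve_type": "ACi",
                    "regime": "PR",
                    "iinc": float(label),
                    "ca": np.nan,
                    "ci": float(c),
                    "o": 21.0,
                    "an": a * c + b,
                    "phi2": np.nan,
                    "gs": np.nan,
                }
            )
    return GasExchangeTable(pd.DataFrame(rows))


class TestKok:
    def test_exact_line(self):
        iinc = np.array([50.0, 100.0, 150.0])
        rd, se, fit = kok_method(light_curve(0.05 * iinc - 1.0, iinc))
        assert rd == pytest.approx(1.0, abs=1e-12)
        assert fit.n_obs == 3

    def test_window_excludes_low_light(self):
        iinc = np.array([25.0, 50.0, 100.0, 150.0])
        _, _, fit = kok_method(light_curve(0.05 * iinc - 1.0, iinc))
        assert fit.n_obs == 3

    def test_empty_window_errors(self):
        iinc = np.array([500.0, 1000.0, 1500.0])
        with pytest.raises(ValueError):
            kok_method(light_curve(0.05 * iinc - 1.0, iinc))


class TestYin:
    def test_exact_construction(self):
        iinc = np.array([50.0, 75.0, 100.0, 125.0, 150.0])
        phi2 = 0.8 - 1e-4 * iinc
        an = 0.85 * iinc * phi2 / 4.0 - 1.2
        rd, se, _ = yin_method(light_curve(an, iinc, phi2))
        assert rd == pytest.approx(1.2, abs=1e-10)

    def test_missing_phi2_errors(self):
        iinc = np.array([50.0, 100.0, 150.0])
        t = light_curve(0.05 * iinc - 1.0, iinc)
        t.df["phi2"] = np.nan
        with pytest.raises(ValueError, match="Phi2"):
            yin_method(t)


class TestLaisk:
    def test_exact_concurrent_lines_recovered(self):
        # lines through a common point (Ci* = 2.1, A* = -1.3)
        slopes = {150: 0.62, 100: 0.47, 50: 0.28, 25: 0.15}
        lines = {lab: (a, -1.3 - a * 2.1) for lab, a in slopes.items()}
        fit = laisk_method(aci_lines(lines))
        assert fit.ci_star == pytest.approx(2.1, abs=1e-8)
        assert fit.a_star == pytest.approx(-1.3, abs=1e-8)
        assert fit.rd_laisk == pytest.approx(1.3, abs=1e-8)
        assert fit.pairwise_ci_spread == pytest.approx(0.0, abs=1e-8)
        assert len(fit.pairwise) == 6  # C(4,2)

    def test_pairwise_intersection_algebra(self):
        fit = laisk_method(aci_lines({1: (0.5, -2.0), 2: (0.3, -1.0)}))
        assert len(fit.pairwise) == 1
        assert fit.pairwise["ci"].iloc[0] == pytest.approx(5.0)
        assert fit.pairwise["an"].iloc[0] == pytest.approx(0.5)

    def test_non_concurrent_lines_leave_residual(self):
        lines = {1: (0.5, -2.0), 2: (0.3, -1.0), 3: (0.2, -0.2)}
        fit = laisk_method(aci_lines(lines))
        assert fit.rss > 1e-6
        assert fit.pairwise["ci"].nunique() == 3

    def test_parallel_lines_error(self):
        lines = {1: (0.4, -2.0), 2: (0.4, -1.0)}
        with pytest.raises(ValueError, match="parallel"):
            laisk_method(aci_lines(lines))

    def test_low_ci_window_filters_records(self):
        lines = {1: (0.5, -2.0), 2: (0.3, -1.0)}
        t = aci_lines(lines, ci=(1, 2, 4, 6, 8, 12, 20))
        fit = laisk_method(t, ci_window=10.0)
        assert fit.n_obs == 10  # 5 records per curve below 10 Pa


class TestAic:
    def test_least_squares_formula(self):
        assert aic(5.0, 20, 3) == pytest.approx(20 * np.log(0.25) + 6, abs=1e-10)
        assert aic(5.0, 20, 3) == pytest.approx(-21.726, abs=1e-3)

    def test_extra_parameter_costs_two(self):
        assert aic(5.0, 20, 4) - aic(5.0, 20, 3) == pytest.approx(2.0)

    def test_degenerate_rss_errors(self):
        with pytest.raises(ValueError):
            aic(0.0, 20, 3)

    def test_aicc_small_sample_penalty(self):
        assert aic(5.0, 10, 3, corrected=True) > aic(5.0, 10, 3)


class TestDeltaAic:
    def test_support_flags(self):
        table = delta_aic({"a": -21.7, "b": -20.0, "c": -10.0})
        assert table["delta_aic"].tolist() == pytest.approx([0.0, 1.7, 11.7])
        assert table["support"].tolist() == [True, True, False]

    def test_threshold_inclusive_at_two(self):
        table = delta_aic({"a": 0.0, "b": 2.0})
        assert bool(table.loc[table["model"] == "b", "support"].item()) is True

    def test_ties_all_supported(self):
        table = delta_aic({"a": 3.3, "b": 3.3})
        assert table["support"].all()

    def test_single_model_rejected(self):
        with pytest.raises(ValueError):
            delta_aic({"a": 1.0})


class TestCompareScenarios:
    def test_table_from_fitlike_objects(self):
        class F:
            def __init__(self, rss, n_obs, n_params):
                self.rss, self.n_obs, self.n_params = rss, n_obs, n_params

        table = compare_scenarios(
            {"inner": F(1.0, 20, 2), "gaps": F(1.2, 20, 2), "outer": F(4.0, 20, 2)}
        )
        assert table["model"].iloc[0] == "inner"
        assert table["delta_aic"].iloc[0] == 0.0
        assert not table[table["model"] == "outer"]["support"].item()
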