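"""Model/Results facade over the fitting pipeline.

:class:`MesophyllModel` binds a gas-exchange + fluorescence dataset to
one unit-cell configuration (anatomy, transport constants, release
scenario); ``fit()`` runs the full estimation pipeline — calibration
factor s, day respiration Rd per oxygen regime, the TPU rate Tp, and
Vcmax — and returns a :class:`MesophyllResults` carrying the estimates,
their standard errors, residual diagnostics, a ``summary()`` table, and
simulation helpers (Laisk-protocol curves, gm/freass response sweeps,
held-out validation).  ``compare_release_scenarios`` refits the model
under each release scenario and ranks them by AIC.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .datasets import GasExchangeTable
from .estimation import (
    FitResult,
    ForwardRunner,
    RegressionFit,
    fit_calibration_s,
    fit_rd,
    fit_vcmax,
    validate,
)
from .geometry import LeafAnatomy, Scenario
from .kinetics import KineticParams, tp_from_ap
from .methods import (
    compare_scenarios,
    kok_method,
    laisk_method,
    response_sweep,
    simulate_laisk_family,
    yin_method,
)
from .solver import SolverOptions, TransportParams

__all__ = ["MesophyllModel", "MesophyllResults", "compare_release_scenarios"]


class MesophyllModel:
    """Reaction-diffusion gas-exchange model bound to one dataset.

    Parameters
    ----------
    data : GasExchangeTable or pandas.DataFrame
        Records of (curve_type, regime, Iinc, Ca, Ci, O, AN, Phi2, gs).
    anatomy : LeafAnatomy
        Mesophyll microstructure (defaults to the standard tomato set).
    scenario : {'inner', 'gaps', 'outer'}
        Assumed location of (photo)respired CO2 release.
    transport : TransportParams, optional
    resolution : (nx, ny)
        Unit-cell mesh resolution.
    kinetics : KineticParams, optional
        Starting values and Rubisco constants (KmC, KmO, Sc/o).
    boundary_mode : {'ci_driven', 'ca_driven'}
        Whether fitting drives the model with measured Ci (default) or
        with measured Ca and gs.
    """

    def __init__(
        self,
        data: GasExchangeTable | pd.DataFrame,
        anatomy: LeafAnatomy | None = None,
        scenario: Scenario | str = Scenario.INNER,
        transport: TransportParams | None = None,
        resolution: tuple[int, int] = (12, 40),
        kinetics: KineticParams | None = None,
        options: SolverOptions | None = None,
        boundary_mode: str = "ci_driven",
    ):
        self.data = data if isinstance(data, GasExchangeTable) else GasExchangeTable(data)
        self.anatomy = anatomy or LeafAnatomy()
        self.kinetics0 = kinetics or KineticParams()
        self.boundary_mode = boundary_mode
        self.runner = ForwardRunner(
            self.anatomy,
            scenario=scenario,
            transport=transport,
            resolution=resolution,
            options=options,
        )

    @classmethod
    def from_csv(cls, path, **kwargs) -> "MesophyllModel":
        from .datasets import read_gas_exchange

        return cls(read_gas_exchange(path), **kwargs)

    @property
    def scenario(self) -> Scenario:
        return self.runner.scenario

    def fit(self, regimes=("PR", "NPR"), iinc_max: float = 150.0, ca_max: float = 30.0) -> "MesophyllResults":
        """Run the full estimation pipeline.

        Order: s (NPR fluorescence regression), Rd per regime
        (reaction-diffusion least squares on Iinc <= ``iinc_max``), Tp
        (high-Ca plateau), Vcmax (PR CO2 response below ``ca_max`` Pa).
        """
        s_fit = fit_calibration_s(self.data.subset(curve_type="AI", regime="NPR"))
        kin = self.kinetics0.with_(s_cal=s_fit.slope)

        rd_fits: dict[str, FitResult] = {}
        for regime in regimes:
            rd_fits[regime] = fit_rd(
                self.data,
                self.runner,
                kin,
                regime=regime,
                iinc_max=iinc_max,
                boundary_mode=self.boundary_mode,
            )
        rd_pr = rd_fits.get("PR", next(iter(rd_fits.values()))).estimate

        aca_pr = self.data.subset(curve_type="ACa", regime="PR").df
        tp = None
        vcmax_fit = None
        if len(aca_pr):
            ap = float(aca_pr.loc[aca_pr["ca"] == aca_pr["ca"].max(), "an"].mean())
            tp = tp_from_ap(ap, rd_pr)
            vcmax_fit = fit_vcmax(
                self.data,
                self.runner,
                kin.with_(rd=rd_pr, tp=tp),
                ca_max=ca_max,
                boundary_mode=self.boundary_mode,
            )

        kin_final = kin.with_(
            rd=rd_pr,
            tp=tp,
            vcmax=vcmax_fit.estimate if vcmax_fit else kin.vcmax,
        )
        return MesophyllResults(
            model=self,
            s_fit=s_fit,
            rd_fits=rd_fits,
            tp=tp,
            vcmax_fit=vcmax_fit,
            kinetics=kin_final,
            fit_windows={"iinc_max": iinc_max, "ca_max": ca_max},
        )


@dataclass
class MesophyllResults:
    """Fitted parameters, uncertainties and diagnostics."""

    model: MesophyllModel
    s_fit: RegressionFit
    rd_fits: dict[str, FitResult]
    tp: float | None
    vcmax_fit: FitResult | None
    kinetics: KineticParams
    fit_windows: dict = dc_field(default_factory=dict)

    @property
    def params(self) -> dict[str, float]:
        out = {"s_cal": self.s_fit.slope}
        for regime, fit in self.rd_fits.items():
            out[f"rd_{regime.lower()}"] = fit.estimate
        if self.tp is not None:
            out["tp"] = self.tp
        if self.vcmax_fit is not None:
            out["vcmax"] = self.vcmax_fit.estimate
        return out

    @property
    def bse(self) -> dict[str, float]:
        out = {"s_cal": self.s_fit.slope_se}
        for regime, fit in self.rd_fits.items():
            out[f"rd_{regime.lower()}"] = fit.se
        if self.vcmax_fit is not None:
            out["vcmax"] = self.vcmax_fit.se
        return out

    @property
    def rss(self) -> float:
        """Pooled residual sum of squares of the reaction-diffusion fits."""
        rss = sum(f.rss for f in self.rd_fits.values())
        if self.vcmax_fit is not None:
            rss += self.vcmax_fit.rss
        return rss

    @property
    def n_obs(self) -> int:
        n = sum(f.n_obs for f in self.rd_fits.values())
        if self.vcmax_fit is not None:
            n += self.vcmax_fit.n_obs
        return n

    @property
    def n_params(self) -> int:
        n = len(self.rd_fits)
        if self.vcmax_fit is not None:
            n += 1
        return n

    def classical_rd(self, regime: str = "PR", window=(50.0, 150.0)) -> pd.DataFrame:
        """Kok and Yin Rd estimates on the same light-response records,
        alongside the reaction-diffusion estimate."""
        curve = self.model.data.subset(curve_type="AI", regime=regime)
        rd_kok, se_kok, _ = kok_method(curve, window)
        rd_yin, se_yin, _ = yin_method(curve, window)
        rd_fit = self.rd_fits.get(regime)
        rows = [
            {"method": "kok", "rd": rd_kok, "se": se_kok},
            {"method": "yin", "rd": rd_yin, "se": se_yin},
        ]
        if rd_fit is not None:
            rows.append(
                {"method": "reaction_diffusion", "rd": rd_fit.estimate, "se": rd_fit.se}
            )
        return pd.DataFrame(rows)

    def validate(self, held_out: GasExchangeTable | None = None) -> pd.DataFrame:
        """Predict AN on records not used in any fit (or a supplied set)."""
        if held_out is None:
            df = self.model.data.df
            used = (
                (df["curve_type"] == "AI")
                & (df["iinc"] <= self.fit_windows.get("iinc_max", 150.0))
            ) | (
                (df["curve_type"] == "ACa")
                & (df["regime"] == "PR")
                & (df["ca"] < self.fit_windows.get("ca_max", 30.0))
            )
            held_out = GasExchangeTable(df[~used].reset_index(drop=True))
        return validate(
            held_out, self.model.runner, self.kinetics, self.model.boundary_mode
        )

    def simulate_laisk(self, j_list=None, o: float = 21.0, **kw):
        """Laisk-protocol simulation with this fit's Rd (PR regime)."""
        from .methods import LAISK_J_DEFAULT

        rd = self.rd_fits.get("PR", next(iter(self.rd_fits.values()))).estimate
        return simulate_laisk_family(
            self.model.runner,
            rd=rd,
            j_list=j_list or LAISK_J_DEFAULT,
            o=o,
            sco=self.kinetics.sco,
            **kw,
        )

    def response_sweep(self, sweep: str = "Ca", o: float = 21.0, **kw) -> pd.DataFrame:
        return response_sweep(self.model.runner, self.kinetics, sweep, o=o, **kw)

    def summary(self) -> str:
        """Human-readable fit summary table."""
        lines = [
            "Mesophyll reaction-diffusion gas-exchange fit",
            "=" * 61,
            f"release scenario: {self.model.scenario.value:<12}  boundary: {self.model.boundary_mode}",
            f"mesh: {self.model.runner.mesh.nx} x {self.model.runner.mesh.ny}"
            f"  records: {len(self.model.data)}",
            "-" * 61,
            f"{'parameter':<14}{'estimate':>12}{'std err':>12}  subset",
            f"{'s (J=s*I*Phi2)':<14}{self.s_fit.slope:>12.4f}{self.s_fit.slope_se:>12.4f}"
            f"  AI NPR regression",
        ]
        for regime, fit in self.rd_fits.items():
            lines.append(
                f"{'Rd ' + regime:<14}{fit.estimate:>12.4f}{fit.se:>12.4f}  {fit.subset}"
            )
        if self.tp is not None:
            lines.append(f"{'Tp':<14}{self.tp:>12.4f}{'--':>12}  ACa PR plateau")
        if self.vcmax_fit is not None:
            f = self.vcmax_fit
            lines.append(f"{'Vcmax':<14}{f.estimate:>12.4f}{f.se:>12.4f}  {f.subset}")
        lines.append("-" * 61)
        lines.append(
            f"pooled RSS {self.rss:.4f} on {self.n_obs} obs, {self.n_params} fitted parameters"
        )
        units = "rates in umol m-2 s-1 (leaf area); pressures in Pa"
        lines.append(units)
        return "\n".join(lines)


def compare_release_scenarios(
    data: GasExchangeTable | pd.DataFrame,
    scenarios=("inner", "gaps", "outer"),
    corrected: bool = False,
    **model_kwargs,
) -> tuple[pd.DataFrame, dict[str, MesophyllResults]]:
    """Fit the model under each release scenario and rank by AIC.

    Returns the AIC table (delta AIC, inclusive <= 2 support flag) and
    the per-scenario results.
    """
    results: dict[str, MesophyllResults] = {}
    for scen in scenarios:
        results[scen] = MesophyllModel(data, scenario=scen, **model_kwargs).fit()

    @dataclass
    class _Pooled:
        rss: float
        n_obs: int
        n_params: int

    fits = {
        name: _Pooled(res.rss, res.n_obs, res.n_params) for name, res in results.items()
    }
    return compare_scenarios(fits, corrected=corrected), results
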