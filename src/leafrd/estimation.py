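"""Parameter estimation against the forward reaction-diffusion model.

The fitting pipeline mirrors standard gas-exchange practice:

1. the calibration factor ``s`` linking fluorescence to electron
   transport (J = s * Iinc * Phi2) comes from the ordinary
   least-squares slope of AN on Iinc*Phi2/4 under nonphotorespiratory
   conditions (its intercept is the Yin-method -Rd);
2. day respiration ``Rd`` is a one-dimensional least-squares fit of the
   forward model to light-response records at Iinc <= 150
   umol m-2 s-1, run separately per release scenario and per oxygen
   regime;
3. the TPU rate ``Tp`` follows from the high-Ca assimilation plateau;
4. ``Vcmax`` is a one-dimensional least-squares fit to the
   photorespiratory CO2-response records below Ca = 30 Pa with Rd held
   fixed.

Standard errors come from Gaussian linearisation at the optimum
(residual variance times inverse Gauss-Newton curvature).  By default
the forward model is driven by the measured Ci (ci_driven), avoiding
compounding stomatal-model error; ca_driven with measured gs is
available by flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datasets import GasExchangeTable
from .geometry import LeafAnatomy, Scenario, build_unit_cell, generate_mesh
from .kinetics import KineticParams, electron_transport
from .solver import (
    BoundaryCondition,
    FVOperator,
    SolverOptions,
    TransportParams,
    solve_steady_state,
)

__all__ = [
    "ForwardRunner",
    "FitResult",
    "RegressionFit",
    "fit_calibration_s",
    "fit_rd",
    "fit_vcmax",
    "validate",
]

log = logging.getLogger(__name__)

IINC_MAX_DEFAULT = 150.0  # umol m-2 s-1, light-response fitting window
CA_MAX_VCMAX_DEFAULT = 30.0  # Pa, CO2-response fitting window
RD_BOUNDS = (0.0, 10.0)
VCMAX_BOUNDS = (10.0, 500.0)
RD_STARTS = (0.5, 1.5, 3.0)


@dataclass
class RegressionFit:
    """OLS slope/intercept fit with standard errors."""

    slope: float
    slope_se: float
    intercept: float
    intercept_se: float
    n_obs: int
    rss: float


@dataclass
class FitResult:
    """Nonlinear least-squares estimate of a single model parameter."""

    name: str
    estimate: float
    se: float
    rss: float
    n_obs: int
    n_params: int
    residuals: np.ndarray = dc_field(repr=False)
    scenario: str | None = None
    regime: str | None = None
    subset: str = ""
    at_bound: bool = False

    def __post_init__(self) -> None:
        if self.n_obs <= self.n_params:
            raise ValueError("need more observations than parameters")


class ForwardRunner:
    """Forward model bound to one anatomy/scenario/transport/mesh.

    Builds the unit cell, mesh and finite-volume operator once and
    exposes per-record predictions for gas-exchange tables.
    """

    def __init__(
        self,
        anatomy: LeafAnatomy,
        scenario: Scenario | str = Scenario.INNER,
        transport: TransportParams | None = None,
        resolution: tuple[int, int] = (12, 40),
        options: SolverOptions | None = None,
    ):
        self.anatomy = anatomy
        self.scenario = Scenario(scenario)
        self.transport = transport or TransportParams()
        self.geometry = build_unit_cell(anatomy, self.scenario)
        self.mesh = generate_mesh(self.geometry, resolution)
        self.operator = FVOperator(self.mesh, self.transport)
        self.options = options or SolverOptions()

    def solve(self, boundary: BoundaryCondition, kinetics: KineticParams, j=None, **kw):
        return solve_steady_state(
            self.mesh,
            kinetics,
            self.transport,
            boundary,
            j=j,
            options=self.options,
            operator=self.operator,
            **kw,
        )

    def predict_an(
        self,
        records: pd.DataFrame,
        kinetics: KineticParams,
        boundary_mode: str = "ci_driven",
    ) -> np.ndarray:
        """Predicted AN for each record (ci_driven uses the measured Ci,
        ca_driven the measured Ca and gs); J = s_cal * Iinc * Phi2."""
        out = np.empty(len(records))
        warm = None
        for pos, (_, rec) in enumerate(records.iterrows()):
            j = float(electron_transport(kinetics.s_cal, rec["iinc"], rec["phi2"]))
            if boundary_mode == "ci_driven":
                bc = BoundaryCondition.ci_driven(float(rec["ci"]), float(rec["o"]))
            else:
                bc = BoundaryCondition.ca_driven(
                    float(rec["ca"]), float(rec["gs"]), float(rec["o"])
                )
            res = self.solve(bc, kinetics, j=j, c_init=warm)
            warm = res.field.ravel()
            out[pos] = res.an
        return out


def fit_calibration_s(
    npr_light_curve: GasExchangeTable,
    window: tuple[float, float] = (50.0, IINC_MAX_DEFAULT),
) -> RegressionFit:
    """Calibration factor s: OLS slope of AN on Iinc*Phi2/4 (NPR data).

    The intercept is retained: its negative is the Yin-method Rd
    estimate for the same data.
    """
    df = npr_light_curve.df
    df = df[(df["iinc"] >= window[0]) & (df["iinc"] <= window[1])]
    if len(df) < 3:
        raise ValueError("need >= 3 records inside the irradiance window")
    if "phi2" not in df or df["phi2"].isna().any():
        raise ValueError("Phi2 required to fit the calibration factor")
    x = df["iinc"].to_numpy() * df["phi2"].to_numpy() / 4.0
    y = df["an"].to_numpy()
    if np.ptp(x) < 1e-12:
        raise ValueError("zero variance in Iinc*Phi2/4: cannot regress")
    reg = stats.linregress(x, y)
    rss = float(np.sum((y - reg.slope * x - reg.intercept) ** 2))
    return RegressionFit(
        slope=float(reg.slope),
        slope_se=float(reg.stderr),
        intercept=float(reg.intercept),
        intercept_se=float(reg.intercept_stderr),
        n_obs=len(df),
        rss=rss,
    )


def _scalar_least_squares(
    predict,  # theta -> predicted AN vector
    observed: np.ndarray,
    bounds: tuple[float, float],
    starts,
    name: str,
    scenario,
    regime,
    subset: str,
) -> FitResult:
    """Bounded 1-D nonlinear least squares with multistart and
    Gauss-Newton standard errors."""

    def residuals(theta):
        return predict(float(theta[0])) - observed

    best = None
    for x0 in starts:
        x0 = float(np.clip(x0, *bounds))
        sol = optimize.least_squares(
            residuals,
            x0=[x0],
            bounds=([bounds[0]], [bounds[1]]),
            diff_step=1e-4,
            xtol=1e-10,
            ftol=1e-12,
            gtol=1e-12,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    theta = float(best.x[0])
    res = best.fun
    rss = float(res @ res)
    n = len(observed)
    dof = max(n - 1, 1)
    sigma2 = rss / dof
    jtj = float(np.sum(best.jac**2))
    se = float(np.sqrt(sigma2 / jtj)) if jtj > 0 else np.inf
    span = bounds[1] - bounds[0]
    at_bound = min(theta - bounds[0], bounds[1] - theta) < 1e-6 * span
    if at_bound:
        log.warning("%s estimate %.4g sits at a bound of %s", name, theta, bounds)
    return FitResult(
        name=name,
        estimate=theta,
        se=se,
        rss=rss,
        n_obs=n,
        n_params=1,
        residuals=res,
        scenario=str(scenario),
        regime=regime,
        subset=subset,
        at_bound=at_bound,
    )


def fit_rd(
    light_curve: GasExchangeTable,
    runner: ForwardRunner,
    kinetics: KineticParams,
    regime: str = "PR",
    iinc_max: float = IINC_MAX_DEFAULT,
    boundary_mode: str = "ci_driven",
    bounds: tuple[float, float] = RD_BOUNDS,
    starts=RD_STARTS,
) -> FitResult:
    """Estimate Rd from low-light records of one regime.

    Only records with Iinc <= ``iinc_max`` (default 150 umol m-2 s-1)
    enter the objective; per-record J = s_cal * Iinc * Phi2 with the
    measured Phi2.  ``kinetics`` supplies s_cal, Vcmax and the Rubisco
    constants; its rd is ignored.
    """
    df = light_curve.subset(curve_type="AI", regime=regime).df
    df = df[df["iinc"] <= iinc_max].reset_index(drop=True)
    if len(df) < 3:
        raise ValueError(f"need >= 3 usable records at Iinc <= {iinc_max}")
    observed = df["an"].to_numpy()

    def predict(rd):
        return runner.predict_an(df, kinetics.with_(rd=rd), boundary_mode)

    return _scalar_least_squares(
        predict,
        observed,
        bounds,
        starts,
        name="rd",
        scenario=runner.scenario.value,
        regime=regime,
        subset=f"AI {regime}, Iinc <= {iinc_max:g}",
    )


def fit_vcmax(
    co2_curve: GasExchangeTable,
    runner: ForwardRunner,
    kinetics: KineticParams,
    ca_max: float = CA_MAX_VCMAX_DEFAULT,
    boundary_mode: str = "ci_driven",
    bounds: tuple[float, float] = VCMAX_BOUNDS,
    starts=(60.0, 120.0, 240.0),
) -> FitResult:
    """Estimate Vcmax from photorespiratory CO2-response records with
    Ca < ``ca_max`` (default 30 Pa); Rd (and Tp) fixed in ``kinetics``."""
    df = co2_curve.subset(curve_type="ACa", regime="PR").df
    df = df[df["ca"] < ca_max].reset_index(drop=True)
    if len(df) < 2:
        raise ValueError(f"no usable records below Ca = {ca_max} Pa")
    observed = df["an"].to_numpy()

    def predict(vcmax):
        return runner.predict_an(df, kinetics.with_(vcmax=vcmax), boundary_mode)

    return _scalar_least_squares(
        predict,
        observed,
        bounds,
        starts,
        name="vcmax",
        scenario=runner.scenario.value,
        regime="PR",
        subset=f"ACa PR, Ca < {ca_max:g} Pa",
    )


def validate(
    held_out: GasExchangeTable,
    runner: ForwardRunner,
    kinetics: KineticParams,
    boundary_mode: str = "ci_driven",
) -> pd.DataFrame:
    """Predict AN on held-out records and report residual diagnostics.

    Returns a copy of the held-out records with ``an_pred`` and
    ``residual`` columns; the frame's ``attrs`` carry ``rmse`` and
    ``bias`` (mean residual).
    """
    df = held_out.df.reset_index(drop=True)
    if len(df) == 0:
        raise ValueError("held-out set is empty")
    pred = runner.predict_an(df, kinetics, boundary_mode)
    out = df.copy()
    out["an_pred"] = pred
    out["residual"] = out["an"] - pred
    out.attrs["rmse"] = float(np.sqrt(np.mean(out["residual"] ** 2)))
    out.attrs["bias"] = float(np.mean(out["residual"]))
    return out
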