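"""Classical day-respiration estimators, scenario simulations and AIC.

The three regression-based Rd estimators compared against the
reaction-diffusion fit:

* **Kok**: Rd is minus the intercept of the OLS line of AN on Iinc over
  a low-irradiance window (above the Kok-effect breakpoint).
* **Yin**: Rd is minus the intercept of the OLS line of AN on
  Iinc*Phi2/4, which corrects the Kok method for the declining PSII
  quantum yield.
* **Laisk**: several AN-Ci curves measured at different irradiances are
  fitted by straight lines at low Ci; Rd is minus the AN value at their
  common intersection.

``simulate_laisk_family`` reproduces the Laisk measurement protocol
with the forward model (Ci-driven boundary, electron-transport-limited
kinetics) to show how the release scenario shapes the intersection
pattern, and ``response_sweep`` maps apparent mesophyll conductance and
the reassimilated fraction over Ca or Iinc.  Scenario ranking uses the
least-squares Akaike information criterion with the inclusive
``delta AIC <= 2`` substantial-support rule.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datasets import GasExchangeTable, gs_response, phi2_response
from .estimation import ForwardRunner, RegressionFit
from .kinetics import KineticParams, electron_transport
from .solver import (
    BoundaryCondition,
    apparent_gm,
    reassimilation_fraction,
)

__all__ = [
    "kok_method",
    "yin_method",
    "laisk_method",
    "LaiskFit",
    "simulate_laisk_family",
    "response_sweep",
    "aic",
    "delta_aic",
    "compare_scenarios",
]

log = logging.getLogger(__name__)

KOK_WINDOW = (50.0, 150.0)  # umol m-2 s-1, above the Kok-effect breakpoint
LAISK_CI_MAX = 10.0  # Pa, low-Ci linear window
LAISK_J_DEFAULT = (52.0, 36.3, 19.3, 9.1)  # umol m-2 s-1 at Iinc 150/100/50/25


def _intercept_regression(x: np.ndarray, y: np.ndarray) -> RegressionFit:
    if len(x) < 3:
        raise ValueError("need >= 3 records inside the window")
    if np.ptp(x) < 1e-12:
        raise ValueError("zero variance in the regressor")
    reg = stats.linregress(x, y)
    rss = float(np.sum((y - reg.slope * x - reg.intercept) ** 2))
    return RegressionFit(
        slope=float(reg.slope),
        slope_se=float(reg.stderr),
        intercept=float(reg.intercept),
        intercept_se=float(reg.intercept_stderr),
        n_obs=len(x),
        rss=rss,
    )


def kok_method(
    light_curve: GasExchangeTable, window: tuple[float, float] = KOK_WINDOW
) -> tuple[float, float, RegressionFit]:
    """Kok Rd estimate: minus the intercept of AN on Iinc.

    Returns ``(rd, se, fit)``.  The default window [50, 150]
    umol m-2 s-1 stays above the Kok-effect breakpoint region.
    """
    df = light_curve.df
    df = df[(df["iinc"] >= window[0]) & (df["iinc"] <= window[1])]
    fit = _intercept_regression(df["iinc"].to_numpy(), df["an"].to_numpy())
    return -fit.intercept, fit.intercept_se, fit


def yin_method(
    light_curve: GasExchangeTable, window: tuple[float, float] = KOK_WINDOW
) -> tuple[float, float, RegressionFit]:
    """Yin Rd estimate: minus the intercept of AN on Iinc*Phi2/4."""
    df = light_curve.df
    if "phi2" not in df.columns or df["phi2"].isna().any():
        raise ValueError("Yin method requires Phi2")
    df = df[(df["iinc"] >= window[0]) & (df["iinc"] <= window[1])]
    x = df["iinc"].to_numpy() * df["phi2"].to_numpy() / 4.0
    fit = _intercept_regression(x, df["an"].to_numpy())
    return -fit.intercept, fit.intercept_se, fit


@dataclass
class LaiskFit:
    """Common-intersection fit of a family of low-Ci AN-Ci lines.

    ``lines`` is a DataFrame (one row per curve: label, slope,
    intercept, n); ``ci_star``/``a_star`` the shared intersection from
    the joint least squares AN_j = slope_j * (Ci - ci_star) + a_star;
    ``pairwise`` lists the C(n,2) individual line-pair intersections
    for concurrency diagnostics.
    """

    lines: pd.DataFrame
    ci_star: float
    a_star: float
    ci_star_se: float
    a_star_se: float
    rss: float
    n_obs: int
    pairwise: pd.DataFrame = dc_field(repr=False)

    @property
    def rd_laisk(self) -> float:
        return -self.a_star

    @property
    def pairwise_ci_spread(self) -> float:
        return float(self.pairwise["ci"].max() - self.pairwise["ci"].min())


def laisk_method(
    curves: GasExchangeTable,
    ci_window: float = LAISK_CI_MAX,
    curve_key: str = "iinc",
) -> LaiskFit:
    """Laisk common-intersection fit over several AN-Ci curves.

    ``curves`` must contain >= 2 curves distinguished by ``curve_key``
    (by default the irradiance), each with >= 3 records at
    Ci <= ``ci_window`` Pa.  Per-curve OLS lines give the pairwise
    intersections; the common intersection minimises the total squared
    AN residual of the family AN_j = a_j * (Ci - Ci*) + A* with free
    slopes and shared (Ci*, A*).
    """
    df = curves.df
    df = df[df["ci"] <= ci_window]
    groups = [(label, g) for label, g in df.groupby(curve_key) if len(g) >= 3]
    if len(groups) < 2:
        raise ValueError("need >= 2 curves with >= 3 low-Ci records each")

    lines = []
    for label, g in groups:
        fit = _intercept_regression(g["ci"].to_numpy(), g["an"].to_numpy())
        lines.append(
            {"label": label, "slope": fit.slope, "intercept": fit.intercept, "n": fit.n_obs}
        )
    lines = pd.DataFrame(lines)
    if np.ptp(lines["slope"].to_numpy()) < 1e-6:
        raise ValueError("curves are parallel: no intersection")

    pairs = []
    for (_, l1), (_, l2) in itertools.combinations(lines.iterrows(), 2):
        x = (l2["intercept"] - l1["intercept"]) / (l1["slope"] - l2["slope"])
        pairs.append(
            {
                "label_a": l1["label"],
                "label_b": l2["label"],
                "ci": x,
                "an": l1["slope"] * x + l1["intercept"],
            }
        )
    pairwise = pd.DataFrame(pairs)

    xs = [g["ci"].to_numpy() for _, g in groups]
    ys = [g["an"].to_numpy() for _, g in groups]
    slopes0 = lines["slope"].to_numpy()
    x0 = np.concatenate([[pairwise["ci"].mean(), pairwise["an"].mean()], slopes0])

    def residuals(p):
        ci_star, a_star = p[0], p[1]
        sl = p[2:]
        return np.concatenate(
            [y - (s * (x - ci_star) + a_star) for x, y, s in zip(xs, ys, sl)]
        )

    sol = optimize.least_squares(residuals, x0, method="lm", xtol=1e-12, ftol=1e-12)
    n_obs = sum(len(y) for y in ys)
    n_par = len(x0)
    rss = float(sol.fun @ sol.fun)
    dof = max(n_obs - n_par, 1)
    sigma2 = rss / dof
    try:
        cov = sigma2 * np.linalg.inv(sol.jac.T @ sol.jac)
        se = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        se = np.full(n_par, np.nan)
    return LaiskFit(
        lines=lines,
        ci_star=float(sol.x[0]),
        a_star=float(sol.x[1]),
        ci_star_se=float(se[0]),
        a_star_se=float(se[1]),
        rss=rss,
        n_obs=n_obs,
        pairwise=pairwise,
    )


def simulate_laisk_family(
    runner: ForwardRunner,
    rd: float,
    j_list=LAISK_J_DEFAULT,
    o: float = 21.0,
    ci_grid=None,
    sco: float = 2.6,
    ci_window: float = LAISK_CI_MAX,
) -> tuple[GasExchangeTable, LaiskFit]:
    """Simulate AN-Ci curves under the Laisk protocol and fit them.

    The boundary is Ci-driven and the stroma electron-transport-limited
    (Vcmax plays no role), one curve per prescribed J.  Returns the
    simulated curves (labelled by J) and their :class:`LaiskFit`.
    """
    kin = KineticParams(rd=rd, sco=sco)
    if ci_grid is None:
        ci_grid = np.arange(0.5, 7.01, 0.5)
    rows = []
    for j in j_list:
        warm = None
        for ci in ci_grid:
            res = runner.solve(
                BoundaryCondition.ci_driven(float(ci), o),
                kin,
                j=float(j),
                limitation="electron_transport",
                c_init=warm,
            )
            warm = res.field.ravel()
            rows.append(
                {
                    "dataset_id": "laisk_sim",
                    "leaf_id": runner.scenario.value,
                    "curve_type": "ACi",
                    "regime": "PR" if o > 10 else "NPR",
                    "iinc": float(j),  # label: curves indexed by J here
                    "ca": np.nan,
                    "ci": float(ci),
                    "o": o,
                    "an": res.an,
                    "phi2": np.nan,
                    "gs": np.nan,
                    "j": float(j),
                }
            )
    curves = GasExchangeTable(pd.DataFrame(rows))
    fit = laisk_method(curves, ci_window=ci_window, curve_key="j")
    return curves, fit


def response_sweep(
    runner: ForwardRunner,
    kinetics: KineticParams,
    sweep: str,
    values=None,
    o: float = 21.0,
    iinc_fixed: float = 1500.0,
    ca_fixed: float = 40.0,
    phi2_fn=phi2_response,
    gs_fn=gs_response,
) -> pd.DataFrame:
    """Map gm, freass, AN and Cc along a Ca or Iinc sweep.

    The protocol follows the response-curve conventions: the Ca sweep
    runs at saturating light (``iinc_fixed``), the Iinc sweep at fixed
    ambient CO2 (``ca_fixed``); stomatal conductance and Phi2 follow
    their irradiance sub-models.
    """
    if sweep not in ("Ca", "Iinc"):
        raise ValueError("sweep must be 'Ca' or 'Iinc'")
    if values is None:
        values = (
            np.array([5.0, 10.0, 15.0, 20.0, 30.0, 40.0, 60.0, 80.0, 100.0])
            if sweep == "Ca"
            else np.array([25.0, 50.0, 100.0, 150.0, 250.0, 500.0, 1000.0, 1500.0])
        )
    rows = []
    warm = None
    for v in np.asarray(values, dtype=float):
        ca = v if sweep == "Ca" else ca_fixed
        iinc = iinc_fixed if sweep == "Ca" else v
        phi2 = float(phi2_fn(iinc))
        gs = float(gs_fn(iinc))
        j = float(electron_transport(kinetics.s_cal, iinc, phi2))
        res = runner.solve(
            BoundaryCondition.ca_driven(ca, gs, o), kinetics, j=j, c_init=warm
        )
        warm = res.field.ravel()
        freass = reassimilation_fraction(res)
        try:
            gm = apparent_gm(res)
        except ValueError:
            gm = np.nan
        rows.append(
            {
                "sweep": sweep,
                "value": v,
                "ca": ca,
                "iinc": iinc,
                "o": o,
                "an": res.an,
                "ci": res.ci,
                "cc": res.cc,
                "gm": gm,
                "freass": freass,
            }
        )
    return pd.DataFrame(rows)


def aic(rss: float, n: int, k: int, corrected: bool = False) -> float:
    """Least-squares Akaike information criterion.

    AIC = n * ln(rss/n) + 2k, with ``k`` the number of fitted
    parameters plus one (the residual variance).  ``corrected`` adds
    the small-sample term 2k(k+1)/(n-k-1) (AICc).
    """
    if not n > k >= 1:
        raise ValueError("need n > k >= 1")
    if rss <= 0:
        raise ValueError("rss must be > 0 (degenerate fit)")
    out = n * np.log(rss / n) + 2 * k
    if corrected:
        if n - k - 1 <= 0:
            raise ValueError("AICc undefined for n <= k + 1")
        out += 2 * k * (k + 1) / (n - k - 1)
    return float(out)


def delta_aic(aic_by_model: dict[str, float]) -> pd.DataFrame:
    """AIC table with delta AIC and the inclusive <= 2 support flag."""
    if len(aic_by_model) < 2:
        raise ValueError("need >= 2 models to compare")
    df = pd.DataFrame(
        {"model": list(aic_by_model), "aic": list(aic_by_model.values())}
    )
    df["delta_aic"] = df["aic"] - df["aic"].min()
    df["support"] = df["delta_aic"] <= 2.0
    return df.sort_values("delta_aic").reset_index(drop=True)


def compare_scenarios(fits: dict[str, "object"], corrected: bool = False) -> pd.DataFrame:
    """Scenario AIC table from per-scenario fit results.

    ``fits`` maps scenario name to any object with ``rss``, ``n_obs``
    and ``n_params`` attributes (e.g. :class:`~leafrd.estimation.FitResult`).
    K counts the fitted parameters plus the residual variance.
    """
    aics = {}
    meta = {}
    for name, fit in fits.items():
        k = fit.n_params + 1
        aics[name] = aic(fit.rss, fit.n_obs, k, corrected=corrected)
        meta[name] = (fit.rss, fit.n_obs, k)
    table = delta_aic(aics)
    table["rss"] = [meta[m][0] for m in table["model"]]
    table["n"] = [meta[m][1] for m in table["model"]]
    table["k"] = [meta[m][2] for m in table["model"]]
    return table
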