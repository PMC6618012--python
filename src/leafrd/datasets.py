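"""Gas-exchange table I/O, fixture anatomies and synthetic-data generation.

Measurement tables hold combined gas-exchange and chlorophyll-
fluorescence records: CO2-response (A-Ca) and light-response (A-Iinc)
curves, each measured under photorespiratory (PR, O = 21 kPa) and
nonphotorespiratory (NPR, O = 2 kPa) regimes.  The standard designs are

====== ========== ================== ==========
curve  regime     fixed condition    grid
====== ========== ================== ==========
ACa    PR         Iinc = 1500, O=21  Ca 5..100 Pa
ACa    NPR        Iinc = 1500, O=2   Ca 5..100 Pa
AI     PR         Ca = 40 Pa, O=21   Iinc 25..1500
AI     NPR        Ca = 100 Pa, O=2   Iinc 25..1500
====== ========== ================== ==========

The synthetic generator runs the forward reaction-diffusion model over
a design with known true parameters, a declining PSII quantum-yield
sub-model Phi2(Iinc) = phi2_max / (1 + Iinc/i_half), and a saturating
stomatal-conductance sub-model
gs(Iinc) = gs_min + (gs_max - gs_min) * Iinc / (Iinc + i_g), then adds
seeded Gaussian measurement noise to AN and Phi2.  The declining Phi2
and the low gs at low irradiance are exactly the features that bias the
Kok and Yin intercept methods, so the generator reproduces the
measurement designs *and* the physiological structure the estimators
are confronted with.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import pandas as pd

from .geometry import LeafAnatomy, Scenario, build_unit_cell, generate_mesh
from .kinetics import KineticParams, electron_transport
from .solver import (
    BoundaryCondition,
    ConvergenceError,
    FVOperator,
    SolverOptions,
    TransportParams,
    solve_steady_state,
)

__all__ = [
    "GasExchangeTable",
    "SynthTruth",
    "read_gas_exchange",
    "write_gas_exchange",
    "synth_gas_exchange",
    "fixture_anatomy",
    "phi2_response",
    "gs_response",
    "DESIGNS",
]

log = logging.getLogger(__name__)

#: bit-exact CSV header (mandatory columns, in order)
CSV_HEADER = [
    "dataset_id",
    "leaf_id",
    "curve_type",
    "regime",
    "Iinc_umol_m2_s",
    "Ca_Pa",
    "Ci_Pa",
    "O_kPa",
    "AN_umol_m2_s",
    "Phi2",
    "gs_umol_m2_s_Pa",
]

_CSV_TO_SHORT = {
    "Iinc_umol_m2_s": "iinc",
    "Ca_Pa": "ca",
    "Ci_Pa": "ci",
    "O_kPa": "o",
    "AN_umol_m2_s": "an",
    "Phi2": "phi2",
    "gs_umol_m2_s_Pa": "gs",
}
_SHORT_TO_CSV = {v: k for k, v in _CSV_TO_SHORT.items()}
_NUMERIC = list(_CSV_TO_SHORT.values())

#: default measurement grids (Pa and umol m-2 s-1)
CA_GRID = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 40.0, 60.0, 80.0, 100.0)
IINC_GRID = (25.0, 50.0, 75.0, 100.0, 125.0, 150.0, 200.0, 350.0, 500.0, 1000.0, 1500.0)

#: the four standard measurement designs: (curve_type, regime, fixed, grid)
DESIGNS = {
    "aca_pr": ("ACa", "PR", {"iinc": 1500.0, "o": 21.0}, ("ca", CA_GRID)),
    "aca_npr": ("ACa", "NPR", {"iinc": 1500.0, "o": 2.0}, ("ca", CA_GRID)),
    "ai_pr": ("AI", "PR", {"ca": 40.0, "o": 21.0}, ("iinc", IINC_GRID)),
    "ai_npr": ("AI", "NPR", {"ca": 100.0, "o": 2.0}, ("iinc", IINC_GRID)),
}


@dataclass
class GasExchangeTable:
    """Tabular gas-exchange + fluorescence records.

    Wraps a :class:`pandas.DataFrame` with short column names
    (``iinc, ca, ci, o, an, phi2, gs`` plus identifiers); the CSV
    serialisation uses the unit-suffixed header of :data:`CSV_HEADER`.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in ("curve_type", "regime", *_NUMERIC) if c not in self.df.columns]
        if missing:
            raise ValueError(f"gas-exchange table missing columns: {missing}")

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, curve_type: str | None = None, regime: str | None = None) -> "GasExchangeTable":
        df = self.df
        if curve_type is not None:
            df = df[df["curve_type"] == curve_type]
        if regime is not None:
            df = df[df["regime"] == regime]
        return GasExchangeTable(df.reset_index(drop=True))

    def concat(self, other: "GasExchangeTable") -> "GasExchangeTable":
        return GasExchangeTable(pd.concat([self.df, other.df], ignore_index=True))


def read_gas_exchange(path) -> GasExchangeTable:
    """Read a gas-exchange CSV; validates header and numeric cells.

    Raises ``ValueError`` naming any missing mandatory column, or the
    first non-numeric cell with its row index.  Non-standard oxygen
    regimes (O not in {21, 2} kPa) are accepted with a warning.
    """
    raw = pd.read_csv(path, dtype=str).fillna("")
    missing = [c for c in CSV_HEADER if c not in raw.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")
    df = raw.rename(columns=_CSV_TO_SHORT)
    for col in _NUMERIC:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & (df[col].str.strip() != "")
        if bad.any() or converted.isna().any():
            row = int(np.argmax((converted.isna()).to_numpy()))
            raise ValueError(
                f"non-numeric value {df[col].iloc[row]!r} in column "
                f"{_SHORT_TO_CSV[col]} at row {row}"
            )
        df[col] = converted
    nonstandard = ~df["o"].isin((21.0, 2.0))
    if nonstandard.any():
        warnings.warn(
            f"{int(nonstandard.sum())} record(s) with non-standard O regime "
            "(expected 21 or 2 kPa)",
            stacklevel=2,
        )
    return GasExchangeTable(df)


def write_gas_exchange(table: GasExchangeTable, path) -> None:
    """Write the table with the canonical unit-suffixed header;
    unknown extra columns are appended after the standard ones."""
    df = table.df.rename(columns=_SHORT_TO_CSV)
    extra = [c for c in df.columns if c not in CSV_HEADER]
    df[CSV_HEADER + extra].to_csv(path, index=False)


def phi2_response(iinc, phi2_max: float = 0.8, i_half: float = 1000.0):
    """Declining PSII quantum yield Phi2(Iinc) = phi2_max/(1 + Iinc/i_half)."""
    return phi2_max / (1.0 + np.asarray(iinc, dtype=float) / i_half)


def gs_response(iinc, gs_min: float = 0.3, gs_max: float = 3.0, i_g: float = 200.0):
    """Saturating stomatal conductance (umol m-2 s-1 Pa-1) vs irradiance."""
    iinc = np.asarray(iinc, dtype=float)
    return gs_min + (gs_max - gs_min) * iinc / (iinc + i_g)


@dataclass(frozen=True)
class SynthTruth:
    """Known-truth parameter set behind a synthetic dataset.

    Day respiration may differ between regimes (``rd_pr >= rd_npr`` in
    the default, reflecting the higher respiratory release observed
    under photorespiratory conditions).  ``seed`` fixes the generated
    table bit-exactly (PCG64 generator).
    """

    rd_pr: float = 1.5
    rd_npr: float = 1.1
    vcmax: float = 120.0
    tp: float | None = 12.0
    s_cal: float = 0.45
    anatomy: LeafAnatomy = dc_field(default_factory=LeafAnatomy)
    transport: TransportParams = dc_field(default_factory=TransportParams)
    scenario: Scenario = Scenario.INNER
    kmc: float = 26.7
    kmo: float = 16.4
    sco: float = 2.6
    phi2_max: float = 0.8
    i_half: float = 1000.0
    gs_min: float = 0.3
    gs_max: float = 3.0
    i_g: float = 200.0
    noise_an: float = 0.15
    noise_phi2: float = 0.005
    seed: int = 0
    resolution: tuple[int, int] = (12, 40)

    def __post_init__(self) -> None:
        if self.noise_an < 0 or self.noise_phi2 < 0:
            raise ValueError("noise standard deviations must be >= 0")

    def rd(self, regime: str) -> float:
        return {"PR": self.rd_pr, "NPR": self.rd_npr}[regime]

    def kinetics(self, regime: str) -> KineticParams:
        return KineticParams(
            vcmax=self.vcmax,
            rd=self.rd(regime),
            tp=self.tp,
            s_cal=self.s_cal,
            kmc=self.kmc,
            kmo=self.kmo,
            sco=self.sco,
        )

    def with_(self, **kwargs) -> "SynthTruth":
        return replace(self, **kwargs)


def synth_gas_exchange(
    truth: SynthTruth,
    design: str = "all",
    dataset_id: str = "synth",
    leaf_id: str = "leaf1",
    grid=None,
    options: SolverOptions | None = None,
) -> GasExchangeTable:
    """Generate a synthetic gas-exchange table for a measurement design.

    ``design`` is one of ``aca_pr, aca_npr, ai_pr, ai_npr, all``.  For
    each grid point the forward solver runs ca_driven with the sub-model
    Phi2 and gs; the table records the noisy AN and Phi2 alongside the
    noiseless design variables.  Grid points where the solver fails are
    dropped with a warning; at least 80% of the grid must survive.
    """
    if design == "all":
        tables = [
            synth_gas_exchange(truth, d, dataset_id, leaf_id, options=options)
            for d in DESIGNS
        ]
        return GasExchangeTable(pd.concat([t.df for t in tables], ignore_index=True))
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; choose from {sorted(DESIGNS)} or 'all'")

    curve_type, regime, fixed, (grid_var, default_grid) = DESIGNS[design]
    grid = np.asarray(default_grid if grid is None else grid, dtype=float)
    # one independent noise stream per design so 'all' is reproducible
    rng = np.random.default_rng([truth.seed, sorted(DESIGNS).index(design)])

    geom = build_unit_cell(truth.anatomy, truth.scenario)
    mesh = generate_mesh(geom, truth.resolution)
    op = FVOperator(mesh, truth.transport)
    kin = truth.kinetics(regime)

    rows = []
    warm = None
    for value in grid:
        cond = dict(fixed)
        cond[grid_var] = value
        iinc, ca, o = cond["iinc"], cond["ca"], cond["o"]
        phi2 = float(phi2_response(iinc, truth.phi2_max, truth.i_half))
        gs = float(gs_response(iinc, truth.gs_min, truth.gs_max, truth.i_g))
        j = float(electron_transport(truth.s_cal, iinc, phi2))
        try:
            res = solve_steady_state(
                mesh,
                kin,
                truth.transport,
                BoundaryCondition.ca_driven(ca, gs, o),
                j=j,
                options=options,
                operator=op,
                c_init=warm,
            )
        except (ConvergenceError, ValueError) as exc:
            log.warning("dropping %s grid point %s=%.3g: %s", design, grid_var, value, exc)
            continue
        warm = res.field.ravel()
        rows.append(
            {
                "dataset_id": dataset_id,
                "leaf_id": leaf_id,
                "curve_type": curve_type,
                "regime": regime,
                "iinc": iinc,
                "ca": ca,
                "ci": res.ci,
                "o": o,
                "an": res.an,
                "phi2": phi2,
                "gs": gs,
                "an_true": res.an,
                "phi2_true": phi2,
            }
        )
    if len(rows) < 0.8 * len(grid):
        raise RuntimeError(
            f"design {design}: only {len(rows)}/{len(grid)} grid points converged"
        )
    df = pd.DataFrame(rows)
    df["an"] = df["an"] + rng.normal(0.0, truth.noise_an, len(df))
    df["phi2"] = np.clip(
        df["phi2"] + rng.normal(0.0, truth.noise_phi2, len(df)), 1e-6, 1.0
    )
    return GasExchangeTable(df)


_FIXTURES = {
    # tomato mesophyll defaults: twall 120 nm, tcyt 250 nm, tstr 2.5 um,
    # Sc/Sm = 0.90, Sm/S = 16
    "ho_default": dict(
        twall=120e-9, tcyt=250e-9, tstr=2.5e-6, sc_sm=0.90, sm_s=16.0
    ),
}


def fixture_anatomy(name: str = "ho_default", **custom) -> LeafAnatomy:
    """Named fixture anatomies.

    ``ho_default`` is the standard tomato mesophyll parameter set;
    ``custom`` builds an anatomy from explicit keyword fields (all of
    twall, tcyt, tstr, sc_sm, sm_s required).
    """
    if name == "custom":
        required = {"twall", "tcyt", "tstr", "sc_sm", "sm_s"}
        missing = required - custom.keys()
        if missing:
            raise ValueError(f"custom anatomy missing fields: {sorted(missing)}")
        return LeafAnatomy(**custom)
    if name not in _FIXTURES:
        raise ValueError(
            f"unknown anatomy {name!r}; options: {sorted(_FIXTURES) + ['custom']}"
        )
    return LeafAnatomy(**_FIXTURES[name])
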