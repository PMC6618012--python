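"""Steady-state CO2 reaction-diffusion solver on the mesophyll unit cell.

The solver computes the steady CO2 field C(x, y) (stored as liquid-phase
partial-pressure equivalents, Pa) satisfying

    div(D_eff grad C) - sink(C) + source = 0

on the structured unit-cell mesh.  D_eff is the layer's relative
diffusivity times the diffusivity of CO2 in water; membranes (plasma
membrane, chloroplast envelope) act as explicit interface conductances
flux = P * (C_left - C_right).  Carboxylation consumes CO2 in the
stroma following Michaelis-Menten kinetics (the smaller of the Rubisco-
and electron-transport-limited branches); day respiration Rd and
photorespiratory release Rp = Gamma* * integral(w/C) dV are re-injected
uniformly in the scenario's cytosolic source region.

Discretisation is cell-centred finite volume with harmonic face
averaging; the Michaelis-Menten sink is linearised as w = k(C_prev) * C
(a Picard iteration, damped 0.5 together with the Rp source) which keeps
the system an M-matrix and the field positive.  The airspace boundary is
either a prescribed intercellular pressure Ci (ci_driven) or an ambient
pressure Ca with stomatal conductance gs (ca_driven), in which case the
scalar compatibility condition AN = gs * (Ca - Ci) is solved by
bisection on Ci.

Flux bookkeeping is exact by construction: at every converged solve the
boundary influx equals total carboxylation minus total release to the
linear-solver tolerance, which the :func:`flux_report` audit exposes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .geometry import (
    CYT_GAP,
    CYT_INNER,
    CYT_OUTER,
    LAYERS,
    STROMA,
    WALL,
    Mesh,
    area_scaling,
)
from .kinetics import KineticParams, VolumetricKinetics, local_sink_coefficient

__all__ = [
    "TransportParams",
    "BoundaryCondition",
    "SolverOptions",
    "SolveResult",
    "solve_steady_state",
    "flux_report",
    "reassimilation_fraction",
    "apparent_gm",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TransportParams:
    """Diffusive and membrane transport constants.

    ``d_water`` is the diffusivity of CO2 in water at 25 degC (m2 s-1);
    ``f_wall``, ``f_cyt``, ``f_str`` are the relative effective
    diffusivities of cell wall, cytosol and stroma; ``p_pm`` and
    ``p_env`` the plasma-membrane and chloroplast-envelope
    permeabilities (m s-1); ``henry`` the CO2 solubility
    (mol m-3 Pa-1) closing the gas/liquid unit conversion.
    """

    d_water: float = 1.79e-9
    f_wall: float = 1.0
    f_cyt: float = 0.3
    f_str: float = 0.3
    p_pm: float = 3.5e-3
    p_env: float = 3.5e-3
    henry: float = 3.3e-4
    temperature: float = 298.15

    def __post_init__(self) -> None:
        for name in ("d_water", "f_wall", "f_cyt", "f_str", "p_pm", "p_env", "henry"):
            if getattr(self, name) <= 0:
                raise ValueError(f"transport parameter {name!r} must be > 0")
        for name in ("f_wall", "f_cyt", "f_str"):
            if getattr(self, name) > 1:
                raise ValueError(f"relative diffusivity {name!r} must be <= 1")

    def layer_diffusivity(self, layer_name: str) -> float:
        f = {
            WALL: self.f_wall,
            CYT_OUTER: self.f_cyt,
            CYT_GAP: self.f_cyt,
            CYT_INNER: self.f_cyt,
            STROMA: self.f_str,
        }[layer_name]
        return f * self.d_water

    def scaled(self, factor: float) -> "TransportParams":
        """All diffusivities and permeabilities multiplied by ``factor``
        (relative diffusivities untouched)."""
        return replace(
            self,
            d_water=self.d_water * factor,
            p_pm=self.p_pm * factor,
            p_env=self.p_env * factor,
        )


# membrane located on faces separating these layer pairs
_MEMBRANE_PAIRS = {
    frozenset({WALL, CYT_OUTER}): "p_pm",
    frozenset({CYT_OUTER, STROMA}): "p_env",
    frozenset({STROMA, CYT_INNER}): "p_env",
    frozenset({STROMA, CYT_GAP}): "p_env",
}


@dataclass(frozen=True)
class BoundaryCondition:
    """Airspace boundary: ca_driven (Ca, gs) or ci_driven (Ci); O in kPa."""

    mode: str
    o: float
    ca: float | None = None
    gs: float | None = None
    ci: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("ca_driven", "ci_driven"):
            raise ValueError("mode must be 'ca_driven' or 'ci_driven'")
        if self.o < 0:
            raise ValueError("O must be >= 0")
        if self.mode == "ca_driven":
            if self.ca is None or self.gs is None:
                raise ValueError("ca_driven needs ca and gs")
            if self.ca < 0 or self.gs <= 0:
                raise ValueError("need ca >= 0 and gs > 0")
        else:
            if self.ci is None:
                raise ValueError("ci_driven needs ci")
            if self.ci < 0:
                raise ValueError("need ci >= 0")

    @classmethod
    def ci_driven(cls, ci: float, o: float) -> "BoundaryCondition":
        return cls(mode="ci_driven", o=o, ci=ci)

    @classmethod
    def ca_driven(cls, ca: float, gs: float, o: float) -> "BoundaryCondition":
        return cls(mode="ca_driven", o=o, ca=ca, gs=gs)


@dataclass(frozen=True)
class SolverOptions:
    tol_an: float = 1e-6  # umol m-2 s-1 (leaf), Picard convergence
    max_iter: int = 200
    damping: float = 0.5
    bisect_rtol: float = 1e-6  # on Ci, relative to the bracket size
    max_bisect: int = 80


class FVOperator:
    """Finite-volume diffusion operator for a mesh + transport pair.

    Holds the constant part of the linear system: internal face
    conductances (umol s-1 Pa-1 per metre of out-of-plane depth),
    airspace boundary conductances, and cell volumes.  The per-iteration
    solve adds the linearised sink diagonal and the source vector.
    """

    def __init__(self, mesh: Mesh, transport: TransportParams):
        self.mesh = mesh
        self.transport = transport
        nx, ny = mesh.nx, mesh.ny
        self.n = nx * ny
        dx, dy = mesh.dx, mesh.dy
        henry_u = transport.henry * 1e6  # umol m-3 Pa-1

        d_layer = np.array([transport.layer_diffusivity(name) for name in LAYERS])
        perm = {"p_pm": transport.p_pm, "p_env": transport.p_env}
        d_cell = d_layer[mesh.layer]  # (nx, ny)

        idx = np.arange(self.n).reshape(nx, ny)
        rows, cols, gvals = [], [], []

        def add_faces(a_idx, b_idx, resistance, face_area):
            g = henry_u * face_area / resistance
            rows.append(a_idx.ravel())
            cols.append(b_idx.ravel())
            gvals.append(g.ravel())

        # vertical internal faces (between x-neighbours i, i+1)
        if nx > 1:
            la, lb = mesh.layer[:-1, :], mesh.layer[1:, :]
            r = 0.5 * dx[:-1, None] / d_cell[:-1, :] + 0.5 * dx[1:, None] / d_cell[1:, :]
            r = r + self._membrane_resistance(la, lb, perm)
            area = np.broadcast_to(dy[None, :], r.shape)
            add_faces(idx[:-1, :], idx[1:, :], r, area)

        # horizontal internal faces (between y-neighbours j, j+1)
        if ny > 1:
            la, lb = mesh.layer[:, :-1], mesh.layer[:, 1:]
            r = 0.5 * dy[None, :-1] / d_cell[:, :-1] + 0.5 * dy[None, 1:] / d_cell[:, 1:]
            r = r + self._membrane_resistance(la, lb, perm)
            area = np.broadcast_to(dx[:, None], r.shape)
            add_faces(idx[:, :-1], idx[:, 1:], r, area)

        self.face_a = np.concatenate([r for r in rows]) if rows else np.empty(0, int)
        self.face_b = np.concatenate([c for c in cols]) if cols else np.empty(0, int)
        self.face_g = np.concatenate(gvals) if gvals else np.empty(0)

        # airspace boundary: half-cell of wall between air interface and
        # the first cell row's centres
        self.top_cells = idx[:, 0]
        self.g_top = henry_u * dx / (0.5 * dy[0] / d_cell[:, 0])

        self.volumes = mesh.volumes.ravel()

        diag = np.zeros(self.n)
        np.add.at(diag, self.face_a, self.face_g)
        np.add.at(diag, self.face_b, self.face_g)
        np.add.at(diag, self.top_cells, self.g_top)
        self._laplacian = sp.coo_matrix(
            (
                np.concatenate([diag, -self.face_g, -self.face_g]),
                (
                    np.concatenate([np.arange(self.n), self.face_a, self.face_b]),
                    np.concatenate([np.arange(self.n), self.face_b, self.face_a]),
                ),
            ),
            shape=(self.n, self.n),
        ).tocsc()

    @staticmethod
    def _membrane_resistance(la, lb, perm):
        r = np.zeros(la.shape)
        codes = {name: LAYERS.index(name) for name in LAYERS}
        for pair, key in _MEMBRANE_PAIRS.items():
            n1, n2 = tuple(pair)
            c1, c2 = codes[n1], codes[n2]
            mask = ((la == c1) & (lb == c2)) | ((la == c2) & (lb == c1))
            r[mask] += 1.0 / perm[key]
        return r

    def solve(self, k_vol: np.ndarray, source_vol: np.ndarray, c_top: float) -> np.ndarray:
        """Solve (L + diag(k V)) C = g_top c_top + source V.

        ``k_vol`` is the linearised sink coefficient per cell
        (umol m-3 s-1 Pa-1) and ``source_vol`` the volumetric source
        (umol m-3 s-1); both flattened (n,).
        """
        a = self._laplacian + sp.diags(k_vol * self.volumes)
        b = source_vol * self.volumes
        b = b.copy()
        np.add.at(b, self.top_cells, self.g_top * c_top)
        return spla.spsolve(a.tocsc(), b)

    def boundary_influx(self, c: np.ndarray, c_top: float) -> float:
        """Net CO2 influx across the airspace interface
        (umol s-1 per metre depth); positive into the cell."""
        return float(np.sum(self.g_top * (c_top - c[self.top_cells])))


@dataclass
class SolveResult:
    """Converged steady-state solve summary (leaf-area rate units)."""

    an: float  # net assimilation, TPU-capped (umol m-2 s-1 leaf)
    an_uncapped: float
    ci: float  # Pa
    cc: float  # stroma volume-mean CO2 pressure (Pa)
    vc_tot: float  # gross carboxylation (umol m-2 s-1 leaf)
    vo_tot: float  # oxygenation = 2 Rp (umol m-2 s-1 leaf)
    rp_tot: float  # photorespiratory release (umol m-2 s-1 leaf)
    rd: float
    iterations: int
    residual: float
    tpu_limited: bool
    field: np.ndarray = dc_field(repr=False)  # (nx, ny) Pa
    freass: float | None = None
    gm_apparent: float | None = None
    # solver context for tracer/audit reuse
    _op: FVOperator = dc_field(repr=False, default=None)
    _k_vol: np.ndarray = dc_field(repr=False, default=None)
    _source_vol: np.ndarray = dc_field(repr=False, default=None)
    _rp_injected: float = 0.0  # umol s-1 per metre depth (cell units)
    _rd_injected: float = 0.0
    _leaf_scale: float = 1.0  # multiply cell totals -> leaf-area rates


class ConvergenceError(RuntimeError):
    def __init__(self, message: str, history: list[float]):
        super().__init__(message)
        self.residual_history = history


def _stroma_kinetics(
    kinetics: KineticParams,
    o: float,
    j: float | None,
    limitation: str,
    scaling,
) -> VolumetricKinetics:
    gamma = kinetics.gamma_star(o)
    vmax_vol = scaling.leaf_to_stroma_volumetric(kinetics.vcmax)
    j_vol = scaling.leaf_to_stroma_volumetric(j) if j is not None else np.inf
    if limitation == "electron_transport":
        if j is None:
            raise ValueError("electron_transport limitation requires j")
        vmax_vol = np.inf
    elif limitation == "rubisco":
        j_vol = np.inf
    elif limitation != "min":
        raise ValueError("limitation must be 'min', 'rubisco' or 'electron_transport'")
    return VolumetricKinetics(
        vmax_vol=vmax_vol,
        j_vol=j_vol,
        kmm=kinetics.kmm_effective(o),
        gamma=gamma,
    )


def _solve_ci(
    op: FVOperator,
    mesh: Mesh,
    vol: VolumetricKinetics,
    kinetics: KineticParams,
    ci: float,
    options: SolverOptions,
    c_init: np.ndarray | None,
) -> SolveResult:
    """Inner nonlinear solve at prescribed intercellular pressure Ci."""
    geom = mesh.geometry
    scaling = area_scaling(geom.anatomy)
    half_width = geom.half_width
    leaf_scale = scaling.sm_s / half_width  # cell totals -> leaf-area rates

    stroma = mesh.layer_mask(STROMA).ravel()
    source = mesh.source_mask.ravel()
    v = op.volumes
    v_source = float(v[source].sum())
    if v_source <= 0:
        raise ValueError("source region has zero volume")

    rd_cell = kinetics.rd / scaling.sm_s * half_width  # umol s-1 per m depth

    c = np.full(op.n, max(ci, 1e-3)) if c_init is None else c_init.copy()
    c = np.maximum(c, 1e-9)

    k_vol = np.zeros(op.n)
    k_vol[stroma] = local_sink_coefficient(c[stroma], vol)
    rp_cell = vol.gamma * float(np.sum(k_vol[stroma] * v[stroma]))

    theta = options.damping
    an_prev = np.inf
    history: list[float] = []
    an = np.nan
    for it in range(1, options.max_iter + 1):
        source_vol = np.zeros(op.n)
        source_vol[source] = (rd_cell + rp_cell) / v_source
        c_new = op.solve(k_vol, source_vol, ci)
        halvings = 0
        while c_new.min() < 0 and halvings < 30:
            c_new = 0.5 * (c + c_new)
            halvings += 1
        if c_new.min() < 0:
            raise ConvergenceError("negative concentrations persist after step halving", history)
        c = c_new

        influx = op.boundary_influx(c, ci)
        an = influx * leaf_scale
        k_new = np.zeros(op.n)
        k_new[stroma] = local_sink_coefficient(np.maximum(c[stroma], 1e-12), vol)
        rp_new = vol.gamma * float(np.sum(k_new[stroma] * v[stroma]))

        delta = abs(an - an_prev)
        delta_rp = abs(rp_new - rp_cell) * leaf_scale
        history.append(max(delta, delta_rp))
        log.debug("picard %d: AN=%.8f dAN=%.3e dRp=%.3e", it, an, delta, delta_rp)
        if delta < options.tol_an and delta_rp < options.tol_an:
            # keep k_vol as used in the final linear system so that the
            # reported totals close the flux balance exactly
            break
        an_prev = an
        k_vol = (1 - theta) * k_vol + theta * k_new
        rp_cell = (1 - theta) * rp_cell + theta * rp_new
    else:
        raise ConvergenceError(
            f"no convergence in {options.max_iter} Picard iterations "
            f"(last |dAN|={history[-1]:.3e})",
            history,
        )

    vc_cell = float(np.sum(k_vol[stroma] * v[stroma] * c[stroma]))
    rp_injected = rp_cell  # source actually present in the final system
    cc = float(np.average(c[stroma], weights=v[stroma]))

    an_uncapped = an
    tpu_limited = False
    if kinetics.tp is not None:
        cap = 3.0 * kinetics.tp - kinetics.rd
        if an > cap:
            an = cap
            tpu_limited = True

    return SolveResult(
        an=an,
        an_uncapped=an_uncapped,
        ci=ci,
        cc=cc,
        vc_tot=vc_cell * leaf_scale,
        rp_tot=rp_injected * leaf_scale,
        vo_tot=2.0 * rp_injected * leaf_scale,
        rd=kinetics.rd,
        iterations=it,
        residual=history[-1],
        tpu_limited=tpu_limited,
        field=c.reshape(mesh.nx, mesh.ny),
        _op=op,
        _k_vol=k_vol,
        _source_vol=source_vol,
        _rp_injected=rp_injected,
        _rd_injected=rd_cell,
        _leaf_scale=leaf_scale,
    )


def solve_steady_state(
    mesh: Mesh,
    kinetics: KineticParams,
    transport: TransportParams,
    boundary: BoundaryCondition,
    j: float | None = None,
    limitation: str = "min",
    options: SolverOptions | None = None,
    operator: FVOperator | None = None,
    c_init: np.ndarray | None = None,
) -> SolveResult:
    """Solve the steady CO2 field and return leaf-level rates.

    Parameters
    ----------
    mesh : Mesh
        Unit-cell mesh (defines geometry and release scenario).
    kinetics : KineticParams
        Leaf-area FvCB parameters; ``rd`` drives the respiratory source.
    transport : TransportParams
        Diffusivities, permeabilities, solubility.
    boundary : BoundaryCondition
        ci_driven or ca_driven airspace condition, with O (kPa).
    j : float, optional
        Electron transport rate (umol m-2 s-1 leaf).  When omitted the
        stroma kinetics are Rubisco-limited only.
    limitation : {'min', 'rubisco', 'electron_transport'}
        Local limitation rule inside the stroma.
    operator : FVOperator, optional
        Reusable prebuilt operator for this (mesh, transport) pair.
    c_init : ndarray, optional
        Warm-start field (flattened, Pa).
    """
    options = options or SolverOptions()
    op = operator if operator is not None else FVOperator(mesh, transport)
    if j is None and limitation == "min":
        limitation = "rubisco"
    scaling = area_scaling(mesh.geometry.anatomy)
    vol = _stroma_kinetics(kinetics, boundary.o, j, limitation, scaling)

    if boundary.mode == "ci_driven":
        return _solve_ci(op, mesh, vol, kinetics, boundary.ci, options, c_init)

    # ca_driven: bisection on Ci for AN(Ci) = gs * (Ca - Ci)
    ca, gs = boundary.ca, boundary.gs
    warm = {"c": c_init}

    def f(ci: float) -> tuple[float, SolveResult]:
        res = _solve_ci(op, mesh, vol, kinetics, max(ci, 1e-9), options, warm["c"])
        warm["c"] = res.field.ravel()
        return res.an_uncapped - gs * (ca - ci), res

    lo, hi = 0.0, ca
    f_hi, res_hi = f(hi)
    n_extend = 0
    while f_hi < 0 and n_extend < 6:
        # leaf is a net CO2 source: steady Ci exceeds Ca
        lo, hi = hi, hi * 2 + 1.0
        f_hi, res_hi = f(hi)
        n_extend += 1
    if f_hi < 0:
        raise ConvergenceError("could not bracket the ca_driven boundary", [])
    res = res_hi
    f_lo = None
    for _ in range(options.max_bisect):
        if hi - lo <= options.bisect_rtol * max(ca, 1.0):
            break
        mid = 0.5 * (lo + hi)
        f_mid, res = f(mid)
        if f_mid >= 0:
            hi, f_hi = mid, f_mid
        else:
            lo, f_lo = mid, f_mid
    ci = 0.5 * (lo + hi)
    _, res = f(ci)
    return res


def flux_report(result: SolveResult, rd: float | None = None) -> dict[str, float]:
    """Conservation audit of a converged solve (leaf-area rate units).

    Returns boundary influx, total carboxylation, total release
    (Rp + Rd) and the relative closure error
    |influx - (Vc - Rp - Rd)| / max(|AN|, 1).
    """
    rd = result.rd if rd is None else rd
    op = result._op
    influx = op.boundary_influx(result.field.ravel(), result.ci) * result._leaf_scale
    vc = result.vc_tot
    release = result.rp_tot + rd
    closure = abs(influx - (vc - release)) / max(abs(result.an_uncapped), 1.0)
    return {
        "influx": influx,
        "vc_tot": vc,
        "release_tot": release,
        "rp_tot": result.rp_tot,
        "rd": rd,
        "an": result.an_uncapped,
        "closure_error": closure,
    }


def reassimilation_fraction(result: SolveResult, rd: float | None = None) -> float:
    """Fraction of (photo)respired CO2 refixed before escaping the cell.

    Runs a linear tracer solve on the frozen first-order sink
    coefficients of the converged field, with the tracer released only
    in the scenario's source region at rate Rp + Rd; freass is one minus
    the tracer efflux across the airspace interface over the release.
    """
    rd_cell = result._rd_injected
    rp_cell = result._rp_injected
    total = rd_cell + rp_cell
    if total <= 0:
        raise ValueError("freass undefined: no respiratory release (Rp + Rd = 0)")
    op = result._op
    source_vol = result._source_vol  # already (rd + rp)/V_source in region
    c_tr = op.solve(result._k_vol, source_vol, 0.0)
    efflux = -op.boundary_influx(c_tr, 0.0)
    consumed = float(np.sum(result._k_vol * op.volumes * c_tr))
    balance = abs(total - (efflux + consumed)) / total
    if balance > 1e-8:
        raise RuntimeError(f"tracer conservation violated: {balance:.2e}")
    freass = 1.0 - efflux / total
    result.freass = float(np.clip(freass, 0.0, 1.0))
    return result.freass


def apparent_gm(result: SolveResult) -> float:
    """Apparent mesophyll conductance gm = AN / (Ci - Cc)
    (umol m-2 s-1 Pa-1), with Cc the stroma volume-mean pressure."""
    dc = result.ci - result.cc
    if abs(dc) < 1e-9:
        raise ValueError("gm undefined: |Ci - Cc| below 1e-9 Pa")
    result.gm_apparent = result.an_uncapped / dc
    return result.gm_apparent
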