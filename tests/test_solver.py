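"""Finite-volume solver verification: analytic oracles, conservation,
limits, tracer and apparent-gm behaviour."""

import numpy as np
import pytest

from leafrd.geometry import (
    LAYERS,
    STROMA,
    LeafAnatomy,
    Mesh,
    build_unit_cell,
    generate_mesh,
)
from leafrd.kinetics import KineticParams, LimitationState, fvcb_assimilation
from leafrd.solver import (
    BoundaryCondition,
    FVOperator,
    TransportParams,
    apparent_gm,
    flux_report,
    reassimilation_fraction,
    solve_steady_state,
)

RES = (10, 28)


def slab_mesh(n: int, depth: float) -> Mesh:
    """Single-layer 1D slab (unit width) for analytic verification."""
    return Mesh(
        geometry=None,
        x_edges=np.array([0.0, 1.0]),
        y_edges=np.linspace(0.0, depth, n + 1),
        layer=np.full((1, n), LAYERS.index(STROMA)),
    )


def make(scenario="inner", resolution=RES, anatomy=None, transport=None):
    anatomy = anatomy or LeafAnatomy()
    transport = transport or TransportParams()
    mesh = generate_mesh(build_unit_cell(anatomy, scenario), resolution)
    return mesh, transport


class TestLinearSlabOracle:
    @pytest.mark.parametrize("n, tol", [(40, 1e-3), (80, 1e-4)])
    def test_first_order_sink_cosh_profile(self, n, tol):
        d, k, depth, c0 = 5e-10, 50.0, 3e-6, 20.0
        mesh = slab_mesh(n, depth)
        tr = TransportParams(d_water=d, f_str=1.0)
        op = FVOperator(mesh, tr)
        henry_u = tr.henry * 1e6
        c = op.solve(np.full(op.n, k * henry_u), np.zeros(op.n), c0)
        q = np.sqrt(k / d)
        exact = c0 * np.cosh(q * (depth - mesh.y_centers)) / np.cosh(q * depth)
        assert np.max(np.abs(c - exact) / exact) < tol


class TestSteadyState:
    def test_equilibrium_without_sources_or_sinks(self):
        mesh, tr = make()
        kin = KineticParams(vcmax=1e-12, rd=0.0)
        res = solve_steady_state(
            mesh, kin, tr, BoundaryCondition.ci_driven(30.0, 0.0)
        )
        assert np.allclose(res.field, 30.0, rtol=1e-10)
        assert res.an == pytest.approx(0.0, abs=1e-8)

    def test_well_mixed_limit_matches_leaf_fvcb(self):
        mesh, _ = make(resolution=(12, 40))
        tr = TransportParams().scaled(1e6)
        kin = KineticParams(vcmax=120.0, rd=1.2)
        o, ci, j = 21.0, 20.0, 150.0
        res = solve_steady_state(
            mesh, kin, tr, BoundaryCondition.ci_driven(ci, o), j=j
        )
        gamma = kin.gamma_star(o)
        an_ref = min(
            fvcb_assimilation(ci, kin, LimitationState.rubisco(kin, o), o),
            fvcb_assimilation(ci, kin, LimitationState.electron_transport(j, gamma), o),
        )
        assert res.an == pytest.approx(an_ref, rel=5e-3)

    def test_flux_balance_closure(self):
        mesh, tr = make()
        kin = KineticParams(vcmax=150.0, rd=2.0)
        res = solve_steady_state(
            mesh, kin, tr, BoundaryCondition.ci_driven(18.0, 21.0), j=120.0
        )
        rep = flux_report(res)
        assert rep["closure_error"] <= 1e-6
        assert res.rp_tot == pytest.approx(0.5 * res.vo_tot, rel=1e-12)

    def test_mesh_refinement_changes_an_little(self):
        kin = KineticParams(vcmax=120.0, rd=1.5)
        ans = []
        for resolution in [(12, 40), (24, 80)]:
            mesh, tr = make(resolution=resolution)
            res = solve_steady_state(
                mesh, kin, tr, BoundaryCondition.ci_driven(25.0, 21.0), j=150.0
            )
            ans.append(res.an)
        assert abs(ans[1] - ans[0]) / abs(ans[0]) < 5e-3

    def test_determinism_bit_identical(self):
        mesh, tr = make()
        kin = KineticParams(vcmax=120.0, rd=1.5)
        bc = BoundaryCondition.ci_driven(25.0, 21.0)
        r1 = solve_steady_state(mesh, kin, tr, bc, j=150.0)
        r2 = solve_steady_state(mesh, kin, tr, bc, j=150.0)
        assert np.array_equal(r1.field, r2.field)
        assert r1.an == r2.an

    def test_ca_driven_satisfies_stomatal_supply(self):
        mesh, tr = make()
        kin = KineticParams(vcmax=120.0, rd=1.5)
        res = solve_steady_state(
            mesh, kin, tr, BoundaryCondition.ca_driven(40.0, 1.2, 21.0), j=180.0
        )
        assert 0.0 < res.ci < 40.0
        assert res.an == pytest.approx(1.2 * (40.0 - res.ci), abs=1e-3)

    def test_scenario_gm_and_freass_ordering(self):
        kin = KineticParams(vcmax=120.0, rd=1.5)
        gm, fr = {}, {}
        for scen in ("inner", "gaps", "outer"):
            mesh, tr = make(scen)
            res = solve_steady_state(
                mesh, kin, tr, BoundaryCondition.ci_driven(25.0, 21.0), j=150.0
            )
            gm[scen] = apparent_gm(res)
            fr[scen] = reassimilation_fraction(res)
        assert gm["inner"] > gm["gaps"] > gm["outer"]
        assert fr["inner"] >= fr["outer"]

    def test_tpu_cap_applied_to_reported_an(self):
        mesh, tr = make()
        kin = KineticParams(vcmax=120.0, rd=1.0, tp=5.0)  # cap at 14
        res = solve_steady_state(
            mesh, kin, tr, BoundaryCondition.ci_driven(40.0, 2.0), j=300.0
        )
        assert res.tpu_limited
        assert res.an == pytest.approx(3 * 5.0 - 1.0)
        assert res.an_uncapped > res.an


class TestReassimilationTracer:
    def test_no_sink_means_no_reassimilation(self):
        mesh, tr = make()
        kin = KineticParams(vcmax=1e-9, rd=1.5)
        res = solve_steady_state(mesh, kin, tr, BoundaryCondition.ci_driven(25.0, 21.0))
        assert reassimilation_fraction(res) == pytest.approx(0.0, abs=1e-9)

    def test_sealed_plasma_membrane_traps_tracer(self):
        mesh, _ = make()
        tr = TransportParams(p_pm=1e-9)
        kin = KineticParams(vcmax=120.0, rd=1.5)
        res = solve_steady_state(mesh, kin, tr, BoundaryCondition.ci_driven(25.0, 21.0))
        assert reassimilation_fraction(res) > 0.999

    def test_undefined_without_release(self):
        mesh, tr = make()
        kin = KineticParams(vcmax=1e-9, rd=0.0)
        res = solve_steady_state(mesh, kin, tr, BoundaryCondition.ci_driven(25.0, 0.0))
        with pytest.raises(ValueError, match="freass"):
            reassimilation_fraction(res)

    def test_fraction_in_unit_interval(self):
        for scen in ("inner", "gaps", "outer"):
            mesh, tr = make(scen)
            kin = KineticParams(vcmax=90.0, rd=0.8)
            res = solve_steady_state(
                mesh, kin, tr, BoundaryCondition.ci_driven(12.0, 21.0), j=80.0
            )
            assert 0.0 <= reassimilation_fraction(res) <= 1.0


class TestApparentGm:
    def test_arithmetic(self):
        mesh, tr = make()
        kin = KineticParams(vcmax=120.0, rd=1.5)
        res = solve_steady_state(
            mesh, kin, tr, BoundaryCondition.ci_driven(30.0, 21.0), j=200.0
        )
        gm = apparent_gm(res)
        assert gm == pytest.approx(res.an_uncapped / (res.ci - res.cc), rel=1e-12)

    def test_well_mixed_limit_guard(self):
        mesh, _ = make()
        tr = TransportParams().scaled(1e8)
        kin = KineticParams(vcmax=1e-10, rd=0.0)
        res = solve_steady_state(mesh, kin, tr, BoundaryCondition.ci_driven(30.0, 0.0))
        with pytest.raises(ValueError, match="gm"):
            apparent_gm(res)
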