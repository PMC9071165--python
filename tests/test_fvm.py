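"""Finite-volume discretization and implicit stepping."""

import numpy as np
import pytest

from spinesim import kinetics
from spinesim.fvm import (
    FieldState, ImplicitSolver, StepFailure, assemble_residual,
    build_dual_mesh, equilibrium_state, simulate, step,
)
from spinesim.mesh import CYTOSOL, ER_LUMEN, HEAD, TetMesh
from spinesim.parameters import InfluxSpec, ModelParameters, SimulationConfig


@pytest.fixture(scope="module")
def unit_tet_mesh():
    """One right tetrahedron labeled as cytosolic head tissue."""
    verts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    mesh = TetMesh(vertices=verts, tets=np.array([[0, 1, 2, 3]]),
                   volume_subset=np.array([CYTOSOL]),
                   zone=np.array([HEAD]), meta={})
    mesh.label_surfaces()
    return mesh


# stiffness of the reference right tet (P1, unit diffusivity):
# gradients (-1,-1,-1), e_x, e_y, e_z over volume 1/6
_K_REF = np.array([
    [0.5, -1 / 6, -1 / 6, -1 / 6],
    [-1 / 6, 1 / 6, 0, 0],
    [-1 / 6, 0, 1 / 6, 0],
    [-1 / 6, 0, 0, 1 / 6],
])


class TestDualMesh:
    def test_single_tet_control_volumes(self, unit_tet_mesh):
        dual = build_dual_mesh(unit_tet_mesh)
        assert dual.n_c == 4
        np.testing.assert_allclose(dual.Vc, np.full(4, 1 / 24), rtol=1e-12)

    def test_single_tet_stiffness_matches_hand_assembly(self, unit_tet_mesh):
        dual = build_dual_mesh(unit_tet_mesh)
        np.testing.assert_allclose(dual.Kc.toarray(), _K_REF, atol=1e-12)

    def test_volume_conservation(self, tiny_mesh):
        dual = build_dual_mesh(tiny_mesh)
        assert dual.Vc.sum() == pytest.approx(
            tiny_mesh.subdomain_volume(CYTOSOL), rel=1e-9)
        assert dual.Ve.sum() == pytest.approx(
            tiny_mesh.subdomain_volume(ER_LUMEN), rel=1e-9)

    def test_transmissibilities_symmetric(self, tiny_mesh):
        dual = build_dual_mesh(tiny_mesh)
        T = dual.interior_face_transmissibilities()
        assert abs(T - T.T).max() < 1e-12

    def test_erm_vertices_shared(self, tiny_mesh):
        dual = build_dual_mesh(tiny_mesh)
        assert dual.n_m > 0
        assert len(dual.erm_c) == len(dual.erm_e) == len(dual.A_erm)
        np.testing.assert_array_equal(
            dual.cyt_verts[dual.erm_c], dual.er_verts[dual.erm_e])

    def test_degenerate_tet_rejected(self):
        verts = np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0.5, 0.5, 0]])
        mesh = TetMesh(vertices=verts, tets=np.array([[0, 1, 2, 3]]),
                       volume_subset=np.array([CYTOSOL]),
                       zone=np.array([HEAD]), meta={})
        with pytest.raises(ValueError, match="tet 0"):
            build_dual_mesh(mesh)


class TestResidual:
    def test_equilibrium_residual_vanishes(self, unit_tet_mesh, params):
        dual = build_dual_mesh(unit_tet_mesh)
        st = equilibrium_state(dual, params)
        F = assemble_residual(st, st, 1e-5, dual, params,
                              membranes_enabled=False)
        scale = np.linalg.norm(st.to_vector()) / 1e-5
        assert np.linalg.norm(F) < 1e-10 * scale

    def test_pure_diffusion_matches_hand_assembly(self, unit_tet_mesh, params):
        dual = build_dual_mesh(unit_tet_mesh)
        b_eq = kinetics.equilibrium_free_buffer(params)
        cc = np.array([1.0, 2.0, 0.5, 3.0])
        prev_cc = np.array([1.0, 1.0, 1.0, 1.0])
        dt = 1e-5
        st = FieldState(c_c=cc, b=np.full(4, b_eq), c_e=np.empty(0),
                        c1=np.empty(0), o2=np.empty(0), c2=np.empty(0), t=dt)
        prev = FieldState(c_c=prev_cc, b=np.full(4, b_eq), c_e=np.empty(0),
                          c1=np.empty(0), o2=np.empty(0), c2=np.empty(0))
        F = assemble_residual(st, prev, dt, dual, params,
                              membranes_enabled=False)
        # buffer is at equilibrium with c=c_c0, not with this cc field, so
        # subtract the reaction term it contributes
        R = params.kb_minus * (params.b_tot - b_eq) - params.kb_plus * b_eq * cc
        expected = (1 / 24) * (cc - prev_cc) / dt + params.D_c * (_K_REF @ cc) \
            - (1 / 24) * R
        np.testing.assert_allclose(F[:4], expected, rtol=1e-12)

    def test_sum_of_diffusion_residual_is_storage_only(self, tiny_mesh, params):
        """Interior diffusive fluxes cancel in the control-volume sum."""
        dual = build_dual_mesh(tiny_mesh)
        rng = np.random.default_rng(3)
        st = equilibrium_state(dual, params)
        st.c_c = st.c_c + rng.uniform(0, 1, dual.n_c)
        prev = equilibrium_state(dual, params)
        dt = 1e-5
        F = assemble_residual(st, prev, dt, dual, params,
                              membranes_enabled=False)
        # remove the (local) reaction part, leaving storage + diffusion
        R = params.kb_minus * (params.b_tot - st.b) \
            - params.kb_plus * st.b * st.c_c
        storage = dual.Vc * (st.c_c - prev.c_c) / dt
        total_flux = np.sum(F[:dual.n_c] + dual.Vc * R - storage)
        assert abs(total_flux) < 1e-8 * np.abs(storage).sum()

    def test_nan_state_rejected(self, unit_tet_mesh, params):
        dual = build_dual_mesh(unit_tet_mesh)
        st = equilibrium_state(dual, params)
        st.c_c[0] = np.nan
        with pytest.raises(StepFailure):
            assemble_residual(st, st, 1e-5, dual, params)


class TestStep:
    def test_equilibrium_is_stationary(self, tiny_mesh, params):
        """With balanced leak coefficients the rest state does not move."""
        balanced = params.replace(v_lp=kinetics.calibrate_pm_leak(params),
                                  v_le=0.0)
        dual = build_dual_mesh(tiny_mesh)
        st = equilibrium_state(dual, balanced)
        cfg = SimulationConfig(t_end=1e-3, tau_sim=1e-4)
        out = step(st, 1e-4, dual, balanced, cfg)
        np.testing.assert_allclose(out.c_c, st.c_c, rtol=1e-9)
        np.testing.assert_allclose(out.c_e, st.c_e, rtol=1e-9)

    def test_linear_diffusion_step_matches_direct_solve(self, unit_tet_mesh,
                                                        params):
        """Pure diffusion is linear: one backward-Euler step equals the
        direct solve of (M/dt + D K) u = M uprev / dt."""
        p = params.replace(kb_plus=0.0, kb_minus=0.0)
        dual = build_dual_mesh(unit_tet_mesh)
        cc0 = np.array([1.0, 0.2, 0.4, 2.0])
        st = FieldState(c_c=cc0, b=np.full(4, p.b_tot), c_e=np.empty(0),
                        c1=np.empty(0), o2=np.empty(0), c2=np.empty(0))
        dt = 1e-5
        cfg = SimulationConfig(t_end=1e-3, tau_sim=dt)
        out = step(st, dt, dual, p, cfg, membranes_enabled=False)
        M = np.diag(dual.Vc)
        A = M / dt + p.D_c * _K_REF
        expected = np.linalg.solve(A, M @ cc0 / dt)
        np.testing.assert_allclose(out.c_c, expected, rtol=1e-8)

    def test_positivity_enforced(self, tiny_mesh, params):
        """A sharp spike relaxes without going negative."""
        dual = build_dual_mesh(tiny_mesh)
        st = equilibrium_state(dual, params)
        st.c_c = st.c_c.copy()
        st.c_c[0] = 500.0
        cfg = SimulationConfig(t_end=1e-3, tau_sim=2e-5)
        tr = simulate(tiny_mesh, params, cfg, membranes_enabled=False,
                      dual=dual, initial=st)
        for z, v in tr.zone_mean.items():
            assert np.all(v >= 0)


class TestSimulate:
    def test_mass_conserved_closed_system(self, tiny_mesh, params):
        dual = build_dual_mesh(tiny_mesh)
        st = equilibrium_state(dual, params)
        st.c_c = st.c_c + np.linspace(0, 2.0, dual.n_c)  # off equilibrium
        cfg = SimulationConfig(t_end=2e-3, tau_sim=10e-6)
        tr = simulate(tiny_mesh, params, cfg, membranes_enabled=False,
                      dual=dual, initial=st)
        c = tr.meta["conservation"]
        rel = abs(c["total_final_uM_um3"] - c["total_initial_uM_um3"]) \
            / c["total_initial_uM_um3"]
        assert rel < 1e-8

    def test_trace_bookkeeping(self, tiny_mesh, params, quick_config):
        influx = InfluxSpec(j_peak=8.6e-18, tau=0.010)
        tr = simulate(tiny_mesh, params, quick_config, influx=influx)
        assert len(tr.times) == len(tr.zone_mean["head"])
        assert tr.peak("head") == np.max(tr.zone_mean["head"])
        assert tr.peaks["head"] > tr.peaks["dendrite"]
        df = tr.to_dataframe()
        assert {"time_s", "head_uM", "neck_uM", "dendrite_uM"} <= set(df)

    def test_determinism(self, tiny_mesh, params, quick_config):
        influx = InfluxSpec(j_peak=8.6e-18, tau=0.010)
        t1 = simulate(tiny_mesh, params, quick_config, influx=influx)
        t2 = simulate(tiny_mesh, params, quick_config, influx=influx)
        np.testing.assert_array_equal(t1.zone_mean["head"],
                                      t2.zone_mean["head"])
        np.testing.assert_array_equal(t1.zone_mean["dendrite"],
                                      t2.zone_mean["dendrite"])

    def test_dt_underflow_aborts(self, unit_tet_mesh, params):
        from spinesim.fvm import SimulationError

        dual = build_dual_mesh(unit_tet_mesh)
        st = equilibrium_state(dual, params)
        st.c_c[0] = np.inf
        cfg = SimulationConfig(t_end=1e-3, tau_sim=1e-4)
        with pytest.raises(SimulationError, match="tau_min"):
            simulate(unit_tet_mesh, params, cfg, membranes_enabled=False,
                     dual=dual, initial=st)
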