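"""Coupled FE solver: fixed points, patch tests, Darcy post-fields, consistency."""

import numpy as np
import pytest

from gliomech.mesh import TetMesh
from gliomech.params import GrowthParams, ModelParams
from gliomech.solver import BiphasicProblem, SimulationConfig, run_simulation

ZERO_SOURCE = ModelParams(growth=GrowthParams(gamma=0.0, zeta=0.0, S_n=0.0))


def single_tet_mesh():
    pts = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0],
                    [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
    return TetMesh(points=pts, cells=np.array([[0, 1, 2, 3]]))


class TestFixedPoint:
    def test_zero_sources_preserve_initial_state(self, small_inputs):
        """With gamma = zeta = S_n = 0 the natural state is an exact fixed point."""
        mesh, chi, D0 = small_inputs
        cfg = SimulationConfig(dt=0.1, t_end=5.0, output_every=5.0,
                               params=ZERO_SOURCE)
        res = run_simulation(mesh, chi, D0, cfg)
        assert len(res.diagnostics) == 50
        fs = res.final_state
        assert np.abs(fs.u).max() < 1e-10
        assert np.abs(fs.p).max() < 1e-10
        assert np.abs(fs.c - 1.0).max() < 1e-10
        assert np.abs(fs.g - 1.0).max() == 0.0
        assert np.abs(fs.phi_s - 0.3).max() < 1e-12
        assert all(d.newton_iters == 0 for d in res.diagnostics)


class TestFreeGrowthPatch:
    def test_uniform_growth_is_stress_free(self):
        """Prescribed uniform g with traction-free boundary: J_s = g^3, T_s = 0.

        Isotropic growth F_g = g I is a compatible deformation, so the elastic
        accommodation vanishes and u = (g - 1) X solves the momentum balance.
        """
        mesh = single_tet_mesh()
        g0 = 1.2
        cfg = SimulationConfig(dt=0.1, t_end=0.1, bc_u="pin321", bc_p="zero_flux",
                               params=ZERO_SOURCE)
        prob = BiphasicProblem(mesh, np.ones(4), np.eye(3)[None], cfg)
        st = prob.initial_state()
        st.g[:] = g0
        st.J[:] = g0**3  # fluid content consistent with completed free growth
        u, p, c, ctx, iters, _ = prob.solve_level(st)
        kin = prob._kinematics(u, st.g)
        assert kin.J_s[0] == pytest.approx(g0**3, rel=1e-8)
        from gliomech.mechanics import cauchy_stress

        T = cauchy_stress(kin, prob.params.material, prob.chi_cell).T_s
        assert np.abs(T).max() < 1e-10
        assert np.allclose(u, (g0 - 1.0) * mesh.points, atol=1e-8)
        assert np.abs(p).max() < 1e-10


class TestNutrientPlateau:
    def test_interior_balance_concentration(self, small_inputs):
        """Uniform chi = 1, no growth: interior c_n -> S_n/(S_n + zeta phi_sn)."""
        mesh, _, D0 = small_inputs
        params = ModelParams(growth=GrowthParams(gamma=0.0))
        cfg = SimulationConfig(dt=0.1, t_end=0.5, params=params)
        res = run_simulation(mesh, np.ones(mesh.n_points), D0, cfg)
        gp = params.growth
        c_star = gp.S_n / (gp.S_n + gp.zeta * gp.phi_sn)
        d = np.linalg.norm(mesh.points, axis=1)
        interior = d < 12.0
        c_int = res.final_state.c[interior]
        assert np.abs(c_int - c_star).max() / c_star < 0.02


class TestDarcyVelocity:
    @pytest.fixture()
    def problem(self, small_inputs):
        mesh, chi, D0 = small_inputs
        return BiphasicProblem(mesh, chi, D0, SimulationConfig(params=ZERO_SOURCE))

    def test_uniform_pressure_gives_solid_velocity(self, problem):
        st0 = problem.initial_state()
        st1 = st0.copy()
        v0 = np.array([0.3, -0.2, 0.1])
        st1.u = st0.u + problem.config.dt * v0  # uniform translation
        st1.p = np.full(problem.N, 0.7)
        v = problem.darcy_velocity(st0, st1)
        assert np.allclose(v, v0, atol=1e-12)

    def test_linear_pressure_ramp_scalar_darcy(self, problem, small_inputs):
        mesh, _, _ = small_inputs
        st0 = problem.initial_state()
        st1 = st0.copy()
        a = np.array([1e-6, 0.0, 0.0])  # MPa/mm
        st1.p = mesh.points @ a
        v = problem.darcy_velocity(st0, st1)
        k0 = problem.params.permeability.k0
        phi_l = 0.7
        expected = -(k0 / phi_l) * a  # A = I for the isotropic phantom
        assert np.allclose(v, expected, rtol=1e-9)

    def test_anisotropic_mobility_tilts_flow(self, small_spec, small_mesh):
        from gliomech import phantom as ph
        from gliomech import tensors as ts

        spec = ph.PhantomSpec(**{**small_spec.__dict__, "dti_mode": "uniform_axis",
                                 "eigenvalues": (20.0, 2.0, 2.0)})
        D0 = ts.voxel_to_cell(ph.make_synthetic_dti(spec), small_mesh)
        chi = np.zeros(small_mesh.n_points)
        prob = BiphasicProblem(small_mesh, chi, D0, SimulationConfig(params=ZERO_SOURCE))
        st0 = prob.initial_state()
        st1 = st0.copy()
        grad = np.array([1e-6, 1e-6, 0.0]) / np.sqrt(2.0)
        st1.p = small_mesh.points @ grad
        v = prob.darcy_velocity(st0, st1)
        # independent dense-algebra oracle
        A = 3.0 * np.diag([20.0, 2.0, 2.0]) / 24.0
        expected = -(prob.params.permeability.k0 / 0.7) * A @ grad
        assert np.allclose(v, expected, rtol=1e-9)
        angle = np.degrees(np.arccos(
            v[0] @ (-grad) / np.linalg.norm(v[0]) / np.linalg.norm(grad)))
        assert angle > 30.0  # flow strongly deflected towards the fibre axis


class TestCFL:
    def test_zero_velocity(self, small_inputs):
        mesh, chi, D0 = small_inputs
        prob = BiphasicProblem(mesh, chi, D0, SimulationConfig(params=ZERO_SOURCE))
        st = prob.initial_state()
        assert prob.cfl_check(st, st.copy()) == 0.0

    def test_matches_brute_force_cell_maximum(self, small_inputs):
        mesh, chi, D0 = small_inputs
        prob = BiphasicProblem(mesh, chi, D0, SimulationConfig(params=ZERO_SOURCE))
        st0 = prob.initial_state()
        st1 = st0.copy()
        st1.p = 1e-6 * mesh.points[:, 0] ** 2 / 40.0
        v = prob.darcy_velocity(st0, st1)
        brute = max(np.linalg.norm(v[m]) * prob.config.dt / mesh.cell_sizes[m]
                    for m in range(mesh.n_cells))
        assert prob.cfl_check(st0, st1) == pytest.approx(brute, rel=1e-12)


@pytest.fixture(scope="module")
def short_run(small_inputs):
    mesh, chi, D0 = small_inputs
    cfg = SimulationConfig(dt=0.1, t_end=2.0, output_every=1.0)
    return run_simulation(mesh, chi, D0, cfg), mesh, chi


class TestGrowthRun:
    def test_g_monotone_and_localized(self, short_run):
        res, mesh, chi = short_run
        gs = np.stack([s.g for s in res.states])
        assert np.all(np.diff(gs, axis=0) >= -1e-15)
        healthy = res.problem.chi_cell == 0.0
        assert np.all(gs[:, healthy] == 1.0)

    def test_volume_strictly_increasing(self, short_run):
        res, _, _ = short_run
        assert np.all(np.diff(res.volumes) > 0.0)

    def test_saturation_identity(self, short_run):
        res, _, _ = short_run
        for s in res.states:
            assert np.all((s.phi_s > 0.0) & (s.phi_s < 1.0))

    def test_restart_equals_continuous_run(self, small_inputs, short_run):
        res, mesh, chi = short_run
        _, _, D0 = small_inputs
        cfg = SimulationConfig(dt=0.1, t_end=2.0, output_every=1.0)
        prob = BiphasicProblem(mesh, chi, D0, cfg)
        st = res.states[1].copy()  # checkpoint at t = 1
        for _ in range(10):
            st, _ = prob.advance_step(st)
        fs = res.final_state
        assert st.t == pytest.approx(fs.t)
        assert np.allclose(st.u, fs.u, atol=1e-8)
        assert np.allclose(st.c, fs.c, atol=1e-8)
        assert np.allclose(st.g, fs.g, atol=1e-10)

    def test_time_step_consistency(self, small_inputs, short_run):
        """Halving dt changes the day-2 tumour volume by well under 1%."""
        res, mesh, chi = short_run
        _, _, D0 = small_inputs
        cfg2 = SimulationConfig(dt=0.05, t_end=2.0, output_every=2.0)
        res2 = run_simulation(mesh, chi, D0, cfg2)
        assert abs(res2.volumes[-1] - res.volumes[-1]) / res.volumes[-1] < 0.01


class TestPressureStabilization:
    def test_toggle_preserves_fixed_point_and_runs(self, small_inputs):
        mesh, chi, D0 = small_inputs
        cfg = SimulationConfig(dt=0.1, t_end=0.3, pressure_stabilization=1e-3)
        res = run_simulation(mesh, chi, D0, cfg)
        assert np.all(np.isfinite(res.final_state.p))
        cfg0 = SimulationConfig(dt=0.1, t_end=0.3, pressure_stabilization=1e-3,
                                params=ZERO_SOURCE)
        res0 = run_simulation(mesh, chi, D0, cfg0)
        assert np.abs(res0.final_state.u).max() < 1e-10
        assert np.abs(res0.final_state.p).max() < 1e-10


class TestValidation:
    def test_chi_range_checked(self, small_inputs):
        mesh, chi, D0 = small_inputs
        bad = chi.copy()
        bad[0] = 1.5
        with pytest.raises(ValueError):
            BiphasicProblem(mesh, bad, D0, SimulationConfig())

    def test_d0_spd_checked(self, small_inputs):
        mesh, chi, D0 = small_inputs
        bad = D0.copy()
        bad[0] = -np.eye(3)
        with pytest.raises(ValueError):
            BiphasicProblem(mesh, chi, bad, SimulationConfig())

    def test_config_guards(self):
        with pytest.raises(ValueError):
            SimulationConfig(dt=-0.1)
        with pytest.raises(ValueError):
            SimulationConfig(growth_law="exponential")
        with pytest.raises(ValueError):
            SimulationConfig(bc_p="periodic")
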