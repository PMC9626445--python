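"""Coupled Lagrangian finite-element solver for biphasic tumour growth.

Each time step solves, on the fixed reference mesh with P1 elements, the
monolithic nonlinear system for (u_s, p, c_n):

  * fluid mass balance / Darcy:  (J_s, w) + dt (Grad w, K* Grad p) = (J_s^k, w)
  * mixture momentum:            (P(u, p), Grad v) = 0,
                                 P = -J_s p F_s^-T + P_s
  * nutrient transport:          (J_s c, q) - dt (K*/phi_l Grad p . Grad c, q)
                                 + dt (Grad q, D* Grad c)
                                 = (J_s c^k, q) + dt (J_s G_n(c) chi / phi_l, q)

with the growth stretch g, solid fraction phi_s, indicator chi and the
compression Sigma frozen at the previous level (semi-implicit Euler), then
updates g by explicit Euler and phi_s by mass conservation.  K* and D* are
the Lagrangian pullbacks of the deformation-reoriented permeability and
diffusion tensors; they follow the current Newton iterate of u, so the
converged residual is exact.  The Newton matrix drops the (weak)
derivatives of K*, D* and of the nutrient residual with respect to u; all
other couplings, including the finite-difference tangent of P with respect
to F, are kept.

Units: mm, day, MPa.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import growth as growth_mod
from . import mechanics
from .mesh import TetMesh
from .params import ModelParams
from .tensors import spectral, anisotropy_weights

_ONE20 = (np.ones((4, 4)) + np.eye(4)) / 20.0  # exact P1 tet mass matrix / V

GROWTH_LAWS = ("plain", "stress_inhibited")
BC_MODES = ("dirichlet", "zero_flux")


class NewtonError(RuntimeError):
    """Newton's method failed to converge; carries per-iteration diagnostics."""


@dataclass(frozen=True)
class SimulationConfig:
    """Time stepping, growth-law and solver settings."""

    dt: float = 0.1                  # day
    t_end: float = 10.0              # day
    growth_law: str = "plain"        # plain | stress_inhibited
    r: float = 1.0                   # anisotropy enhancement of A0
    bc_u: str = "clamped"            # clamped | pin321 (traction-free patch tests)
    bc_p: str = "dirichlet"          # dirichlet | zero_flux
    bc_c: str = "dirichlet"
    pressure_stabilization: float = 0.0  # Brezzi-Pitkaranta coefficient
    newton_rtol: float = 1e-8
    newton_atol: float = 1e-10
    newton_max_iter: int = 25
    output_every: float = 1.0        # day, checkpoint/metric cadence
    params: ModelParams = field(default_factory=ModelParams)

    def __post_init__(self) -> None:
        if self.dt <= 0.0 or self.t_end < self.dt:
            raise ValueError("need dt > 0 and t_end >= dt")
        if self.growth_law not in GROWTH_LAWS:
            raise ValueError(f"growth_law must be one of {GROWTH_LAWS}")
        if self.bc_p not in BC_MODES or self.bc_c not in BC_MODES:
            raise ValueError(f"BC modes must be one of {BC_MODES}")
        if self.bc_u not in ("clamped", "pin321"):
            raise ValueError("bc_u must be 'clamped' or 'pin321'")


@dataclass
class State:
    """Discrete state at one time level: nodal (u, p, c), cellwise (g, phi_s)."""

    t: float
    u: np.ndarray       # (N, 3) mm
    p: np.ndarray       # (N,) MPa
    c: np.ndarray       # (N,) dimensionless
    g: np.ndarray       # (M,) growth stretch
    phi_s: np.ndarray   # (M,) solid fraction
    J: np.ndarray       # (M,) det F_s, cached
    Sigma: np.ndarray   # (M,) MPa, compression of the converged stress

    def copy(self) -> "State":
        return State(t=self.t, u=self.u.copy(), p=self.p.copy(), c=self.c.copy(),
                     g=self.g.copy(), phi_s=self.phi_s.copy(), J=self.J.copy(),
                     Sigma=self.Sigma.copy())


@dataclass
class StepDiagnostics:
    t: float
    newton_iters: int
    residual_norms: tuple[float, float, float]
    cfl: float


@dataclass
class SimulationResult:
    times: np.ndarray
    volumes: np.ndarray          # tumour volume series, cm^3
    states: list[State]          # checkpoints at the output cadence
    diagnostics: list[StepDiagnostics]
    final_state: State
    problem: "BiphasicProblem"

    @property
    def wall_time(self) -> float:
        return self._wall_time

    _wall_time: float = 0.0


class BiphasicProblem:
    """Assembled problem on one mesh: geometry caches, tensors, BC sets."""

    def __init__(self, mesh: TetMesh, chi: np.ndarray, D0_cells: np.ndarray,
                 config: SimulationConfig):
        mesh.validate()
        chi = np.asarray(chi, dtype=float)
        if chi.shape != (mesh.n_points,):
            raise ValueError("chi must be a nodal field on the mesh")
        if np.any(chi < -1e-12) or np.any(chi > 1.0 + 1e-12):
            raise ValueError("tumour indicator chi must lie in [0, 1]")
        D0_cells = np.asarray(D0_cells, dtype=float)
        if D0_cells.shape != (mesh.n_cells, 3, 3):
            raise ValueError("D0 must be a (n_cells, 3, 3) cell tensor field")
        if not np.allclose(D0_cells, np.swapaxes(D0_cells, -1, -2), atol=1e-9):
            raise ValueError("D0 must be symmetric")

        self.mesh = mesh
        self.config = config
        self.params = config.params
        self.chi = np.clip(chi, 0.0, 1.0)
        self.chi_cell = mesh.cell_mean(self.chi)

        lams, vecs = spectral(D0_cells)
        if np.any(lams[:, 2] <= 0.0):
            raise ValueError("D0 must be positive-definite on every cell")
        self.D0_lams = lams
        self.D0_vecs = vecs
        a1, a2 = anisotropy_weights(config.r, lams[:, 0], lams[:, 1], lams[:, 2])
        self.A_weights = np.stack([a1, a2, np.ones_like(a1)], axis=1)  # (M, 3)

        N, M = mesh.n_points, mesh.n_cells
        self.N, self.M = N, M
        self.ndof = 5 * N
        cells = mesh.cells
        edof_u = (3 * cells[:, :, None] + np.arange(3)).reshape(M, 12)
        edof_p = 3 * N + cells
        edof_c = 4 * N + cells
        self.edof = np.concatenate([edof_u, edof_p, edof_c], axis=1)  # (M, 20)
        self._rows = np.repeat(self.edof, 20, axis=1).ravel()
        self._cols = np.tile(self.edof, (1, 20)).ravel()

        if config.bc_u == "clamped":
            fixed = [3 * mesh.boundary_nodes + i for i in range(3)]
        else:
            # 3-2-1 pinning of the first cell's nodes: blocks rigid modes only,
            # leaving the boundary traction-free (free-growth patch tests)
            n0, n1, n2 = mesh.cells[0, :3]
            fixed = [np.array([3 * n0, 3 * n0 + 1, 3 * n0 + 2,
                               3 * n1 + 1, 3 * n1 + 2, 3 * n2 + 2])]
        if config.bc_p == "dirichlet":
            fixed.append(3 * N + mesh.boundary_nodes)
        else:
            fixed.append(np.array([3 * N + mesh.boundary_nodes[0]]))  # pin gauge
        if config.bc_c == "dirichlet":
            fixed.append(4 * N + mesh.boundary_nodes)
        self.fixed_dofs = np.unique(np.concatenate(fixed))
        free_mask = np.ones(self.ndof, dtype=bool)
        free_mask[self.fixed_dofs] = False
        self._free_diag = sp.diags(free_mask.astype(float))
        self._fixed_diag = sp.diags((~free_mask).astype(float))
        self._lu = None  # cached Jacobian factorization (quasi-Newton reuse)

    # ------------------------------------------------------------------ state

    def initial_state(self) -> State:
        N, M = self.N, self.M
        phi_sn = self.params.growth.phi_sn
        st = State(t=0.0, u=np.zeros((N, 3)), p=np.zeros(N),
                   c=np.ones(N) if self.config.bc_c == "dirichlet" else np.ones(N),
                   g=np.ones(M), phi_s=np.full(M, phi_sn),
                   J=np.ones(M), Sigma=np.zeros(M))
        return st

    # ------------------------------------------------- pointwise cell fields

    def _kinematics(self, u: np.ndarray, g: np.ndarray) -> mechanics.Kinematics:
        grad_u = self.mesh.point_gradient(u)  # (M, 3, 3)
        return mechanics.compute_kinematics(grad_u, g)

    def _piola(self, kin: mechanics.Kinematics, p_cell: np.ndarray) -> np.ndarray:
        return mechanics.total_first_piola(kin, self.params.material,
                                           self.chi_cell, p_cell)

    def _transport_tensors(self, kin: mechanics.Kinematics):
        """Pullback mobility K* (per unit viscosity) and diffusion D* per cell."""
        F = kin.F_s
        Fe = F @ self.D0_vecs                      # columns F e_i
        nrm2 = np.sum(Fe**2, axis=1)               # (M, 3)
        D = np.einsum("mi,mji,mki->mjk", self.D0_lams / nrm2, Fe, Fe)
        Ahat = np.einsum("mi,mji,mki->mjk",
                         self.A_weights * self.D0_lams / nrm2, Fe, Fe)
        trA = np.trace(Ahat, axis1=-2, axis2=-1)
        A = Ahat * (3.0 / trA)[:, None, None]
        Finv = np.linalg.inv(F)
        J = kin.J_s[:, None, None]
        FinvT = np.swapaxes(Finv, -1, -2)
        Dstar = J * (Finv @ D @ FinvT)
        khat = mechanics.holmes_mow_k(kin.J_e, self.params.permeability)
        Kstar = khat[:, None, None] * J * (Finv @ A @ FinvT)
        return Kstar, Dstar, D, A

    # ------------------------------------------------------------- residual

    def _residual_blocks(self, u, p, c, frozen):
        """Exact residual; returns (R, cell context dict for the Jacobian)."""
        mesh, cfg = self.mesh, self.config
        dt = cfg.dt
        V = mesh.volumes
        B = mesh.grad_phi
        kin = self._kinematics(u, frozen["g"])
        p_cell = mesh.cell_mean(p)
        P = self._piola(kin, p_cell)
        Kstar, Dstar, _, _ = self._transport_tensors(kin)
        # equal-order P1-P1 pairing can oscillate; optional element-size-scaled
        # pressure-gradient stabilization of the Darcy block (off by default)
        Kp = Kstar
        if cfg.pressure_stabilization > 0.0:
            stab = (cfg.pressure_stabilization * self.params.permeability.k0
                    * mesh.cell_sizes**2)
            Kp = Kstar + stab[:, None, None] * np.eye(3)
        grad_p = mesh.point_gradient(p)
        grad_c = mesh.point_gradient(c)
        c_e = c[mesh.cells]
        ck_e = frozen["c_k"][mesh.cells]
        phi_l = 1.0 - frozen["phi_s"]
        gp = self.params.growth
        J = kin.J_s

        R = np.zeros(self.ndof)
        # momentum
        Ru = V[:, None, None] * np.einsum("mij,maj->mai", P, B)
        # fluid mass / Darcy
        Kgp = np.einsum("mij,mj->mi", Kstar, grad_p)
        Rp = (V / 4.0 * (J - frozen["J_k"]))[:, None] \
            + dt * V[:, None] * np.einsum("maj,mij,mi->ma", B, Kp, grad_p)
        # nutrients; the reaction G_n/phi_l = S_n - (zeta phi_s + S_n) c is very
        # stiff, so it is mass-lumped (nodal quadrature): keeps the nodal
        # equilibrium exact and avoids the oscillations a consistent reaction
        # matrix produces across the unresolved boundary layer
        react = gp.zeta * frozen["phi_s"] + gp.S_n
        adv = np.einsum("mi,mi->m", Kgp, grad_c) / phi_l
        Rc = (V * J)[:, None] * np.einsum("ab,mb->ma", _ONE20, c_e - ck_e) \
            - dt * (V / 4.0 * adv)[:, None] \
            + dt * V[:, None] * np.einsum("maj,mij,mi->ma", B, Dstar, grad_c) \
            - dt * (V / 4.0 * J * self.chi_cell)[:, None] * (
                gp.S_n - react[:, None] * c_e)

        np.add.at(R, self.edof[:, :12].ravel(), Ru.reshape(self.M, 12).ravel())
        np.add.at(R, self.edof[:, 12:16].ravel(), Rp.ravel())
        np.add.at(R, self.edof[:, 16:20].ravel(), Rc.ravel())
        R[self.fixed_dofs] = 0.0
        ctx = dict(kin=kin, p_cell=p_cell, Kstar=Kstar, Kp=Kp, Dstar=Dstar,
                   Kgp=Kgp, grad_c=grad_c, phi_l=phi_l, J=J)
        return R, ctx

    def _tangent_PF(self, kin, p_cell, h: float = 1e-7) -> np.ndarray:
        """dP/dF per cell by central differences (holding p and g fixed)."""
        grad_u0 = kin.F_s - np.eye(3)
        C4 = np.empty((self.M, 3, 3, 3, 3))
        for k in range(3):
            for l in range(3):
                dG = np.zeros((3, 3))
                dG[k, l] = h
                kp = mechanics.compute_kinematics(grad_u0 + dG, kin.g)
                km = mechanics.compute_kinematics(grad_u0 - dG, kin.g)
                C4[:, :, :, k, l] = (self._piola(kp, p_cell)
                                     - self._piola(km, p_cell)) / (2.0 * h)
        return C4

    def _jacobian(self, ctx, frozen) -> sp.csr_matrix:
        mesh, cfg = self.mesh, self.config
        dt = cfg.dt
        V = mesh.volumes
        B = mesh.grad_phi
        kin = ctx["kin"]
        J = ctx["J"]
        gp = self.params.growth
        FinvT = np.swapaxes(np.linalg.inv(kin.F_s), -1, -2)
        FB = np.einsum("mij,maj->mai", FinvT, B)           # (M, 4, 3)

        L = np.zeros((self.M, 20, 20))
        # momentum wrt u: FD elasticity tangent (includes the -J p F^-T part)
        C4 = self._tangent_PF(kin, ctx["p_cell"])
        Luu = V[:, None, None, None, None] * np.einsum(
            "miqjl,maq,mbl->maibj", C4, B, B)
        L[:, :12, :12] = Luu.reshape(self.M, 12, 12)
        # momentum wrt p and mass wrt u (exact geometric couplings)
        VJ4 = (V * J / 4.0)
        L[:, :12, 12:16] = (-VJ4[:, None, None] * FB.reshape(self.M, 12)[
            :, :, None]) * np.ones((1, 1, 4))
        L[:, 12:16, :12] = (VJ4[:, None, None]
                            * FB.reshape(self.M, 12)[:, None, :]) * np.ones((1, 4, 1))
        # Darcy stiffness (incl. optional stabilization)
        L[:, 12:16, 12:16] = dt * V[:, None, None] * np.einsum(
            "mai,mij,mbj->mab", B, ctx["Kp"], B)
        # nutrients
        Mcc = (V * J)[:, None, None] * _ONE20 \
            + dt * V[:, None, None] * np.einsum("mai,mij,mbj->mab", B, ctx["Dstar"], B) \
            - dt * (V / 4.0 / ctx["phi_l"])[:, None, None] * np.einsum(
                "mi,mbi->mb", ctx["Kgp"], B)[:, None, :] \
            + dt * (V / 4.0 * J * self.chi_cell
                    * (gp.zeta * frozen["phi_s"] + gp.S_n))[:, None, None] * np.eye(4)
        L[:, 16:20, 16:20] = Mcc
        L[:, 16:20, 12:16] = -dt * (V / 4.0 / ctx["phi_l"])[:, None, None] * np.einsum(
            "mij,mbj,mi->mb", ctx["Kstar"], B, ctx["grad_c"])[:, None, :]

        A = sp.coo_matrix((L.ravel(), (self._rows, self._cols)),
                          shape=(self.ndof, self.ndof)).tocsr()
        A = self._free_diag @ A @ self._free_diag + self._fixed_diag
        return A

    # ------------------------------------------------------------------ step

    def _block_norms(self, R):
        N = self.N
        return (np.linalg.norm(R[:3 * N]), np.linalg.norm(R[3 * N:4 * N]),
                np.linalg.norm(R[4 * N:]))

    def _factorize(self, ctx, frozen) -> None:
        A = self._jacobian(ctx, frozen).tocsc()
        self._lu = spla.splu(A, permc_spec="COLAMD")

    def solve_level(self, state: State):
        """Newton solve of the (u, p, c) system with growth frozen at ``state``.

        The residual is always exact; the Jacobian factorization is reused
        across iterations (and across steps) and refreshed whenever the
        residual stops contracting, so converged solutions are unaffected.
        """
        cfg = self.config
        frozen = dict(g=state.g, phi_s=state.phi_s, c_k=state.c, J_k=state.J)
        u = state.u.copy()
        p = state.p.copy()
        c = state.c.copy()
        r0 = None
        prev_total = None
        history = []
        for it in range(cfg.newton_max_iter + 1):
            R, ctx = self._residual_blocks(u, p, c, frozen)
            norms = self._block_norms(R)
            history.append(norms)
            total = float(np.linalg.norm(R))
            if r0 is None:
                r0 = tuple(max(n, cfg.newton_atol) for n in norms)
            if all(n <= cfg.newton_rtol * n0 + cfg.newton_atol
                   for n, n0 in zip(norms, r0)):
                return u, p, c, ctx, it, norms
            if it == cfg.newton_max_iter:
                break
            # refresh the factorization whenever the residual stops contracting
            stalled = prev_total is not None and total > 0.5 * prev_total
            if self._lu is None or stalled:
                self._factorize(ctx, frozen)
            prev_total = total
            delta = self._lu.solve(-R)
            if not np.all(np.isfinite(delta)):
                raise NewtonError(f"singular Newton system at t={state.t:.3f} d")
            u += delta[:3 * self.N].reshape(self.N, 3)
            p += delta[3 * self.N:4 * self.N]
            c += delta[4 * self.N:]
            # stagnation at machine precision counts as converged
            scale = max(np.abs(u).max(), np.abs(p).max(), np.abs(c).max(), 1.0)
            if np.abs(delta).max() < 1e-14 * scale:
                R, ctx = self._residual_blocks(u, p, c, frozen)
                return u, p, c, ctx, it + 1, self._block_norms(R)
        raise NewtonError(
            f"Newton did not converge at t={state.t:.3f} d; residual history {history}")

    def advance_step(self, state: State) -> tuple[State, StepDiagnostics]:
        """One semi-implicit Euler step: monolithic solve, then g and phi_s updates."""
        cfg = self.config
        gp = self.params.growth
        u, p, c, ctx, iters, final_norms = self.solve_level(state)
        # growth update from level-k quantities (Eq-(41) structure)
        Sigma_k = state.Sigma if cfg.growth_law == "stress_inhibited" else None
        c_k_cell = self.mesh.cell_mean(state.c)
        Gamma_k = growth_mod.growth_rate(state.phi_s, c_k_cell, gp, Sigma=Sigma_k)
        g_new = growth_mod.update_g(state.g, Gamma_k, state.phi_s,
                                    self.chi_cell, cfg.dt)
        J_new = ctx["J"]
        phi_s_new = growth_mod.update_phi_s(J_new, g_new, gp.phi_sn)
        kin_new = self._kinematics(u, g_new)
        stress = mechanics.cauchy_stress(kin_new, self.params.material, self.chi_cell)
        new = State(t=state.t + cfg.dt, u=u, p=p, c=c, g=g_new,
                    phi_s=phi_s_new, J=kin_new.J_s, Sigma=stress.Sigma)
        cfl = self.cfl_check(state, new)
        return new, StepDiagnostics(t=new.t, newton_iters=iters,
                                    residual_norms=tuple(final_norms), cfl=cfl)

    # ----------------------------------------------------------- post fields

    def darcy_velocity(self, state_prev: State, state_new: State) -> np.ndarray:
        """Spatial fluid velocity per cell: v_l = v_s - (k A / phi_l) grad_x p."""
        dt = self.config.dt
        kin = self._kinematics(state_new.u, state_new.g)
        _, _, _, A = self._transport_tensors(kin)
        khat = mechanics.holmes_mow_k(kin.J_e, self.params.permeability)
        phi_l = 1.0 - state_new.phi_s
        if np.any(phi_l <= 1e-9):
            raise ValueError("phi_l vanished: Darcy velocity undefined")
        FinvT = np.swapaxes(np.linalg.inv(kin.F_s), -1, -2)
        grad_x_p = np.einsum("mij,mj->mi", FinvT,
                             self.mesh.point_gradient(state_new.p))
        v_s = self.mesh.cell_mean((state_new.u - state_prev.u) / dt)
        return v_s - (khat / phi_l)[:, None] * np.einsum("mij,mj->mi", A, grad_x_p)

    def cfl_check(self, state_prev: State, state_new: State) -> float:
        """Max over cells of |v_l| dt / h_cell (advective CFL number)."""
        v = self.darcy_velocity(state_prev, state_new)
        return float(np.max(np.linalg.norm(v, axis=1) * self.config.dt
                            / self.mesh.cell_sizes))

    def tumour_volume(self, state: State) -> float:
        """Current tumour volume [cm^3]: deformed image of the chi > 0.1 cells."""
        mask = self.chi_cell > 0.1
        return float(np.sum(state.J[mask] * self.mesh.volumes[mask]) / 1e3)

    def reoriented_diffusion(self, state: State) -> np.ndarray:
        """Spatial diffusion tensor D per cell at the given state."""
        kin = self._kinematics(state.u, state.g)
        _, _, D, _ = self._transport_tensors(kin)
        return D


def run_simulation(mesh: TetMesh, chi: np.ndarray, D0_cells: np.ndarray,
                   config: SimulationConfig,
                   callback=None) -> SimulationResult:
    """Run the coupled problem from the natural initial state to t_end.

    ``callback(state, problem)`` is invoked at every output checkpoint.  The
    solve itself contains no randomness: results are deterministic for fixed
    inputs.
    """
    t0 = time.perf_counter()
    problem = BiphasicProblem(mesh, chi, D0_cells, config)
    state = problem.initial_state()
    n_steps = int(round(config.t_end / config.dt))
    every = max(1, int(round(config.output_every / config.dt)))

    times = [0.0]
    volumes = [problem.tumour_volume(state)]
    states = [state.copy()]
    diagnostics: list[StepDiagnostics] = []
    if callback is not None:
        callback(state, problem)
    for k in range(n_steps):
        state, diag = problem.advance_step(state)
        diagnostics.append(diag)
        if (k + 1) % every == 0 or k == n_steps - 1:
            times.append(state.t)
            volumes.append(problem.tumour_volume(state))
            states.append(state.copy())
            if callback is not None:
                callback(state, problem)
    result = SimulationResult(times=np.array(times), volumes=np.array(volumes),
                              states=states, diagnostics=diagnostics,
                              final_state=state, problem=problem)
    result._wall_time = time.perf_counter() - t0
    return result
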