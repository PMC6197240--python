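"""Quasi-static biphasic (u-p) finite elements for the explant cross-section.

Total-Lagrangian formulation on 4-node quadrilaterals with equal-order
bilinear displacement and pressure interpolation.  The pressure unknown is
the chemical potential of water (ambient value zero), so Donnan swelling
enters through the constitutive stress and a drained boundary simply has
p = 0.  Equal-order interpolation is stabilized with a local
polynomial-pressure-projection term acting on the pressure increment.

Mass balance (saturated, incompressible constituents), backward Euler:

    int w (J - J_n)/dt dV0 + int grad_x(w) . k grad_x(p) J dV0 + stab = 0

Element tangents are computed by batched finite differences of the element
residual, which keeps the constitutive code in one place.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import materials as mat
from .geometry import GAUSS_PTS, GAUSS_WTS, CompositionField, ExplantMesh, shape_functions

__all__ = [
    "LoadingProtocol",
    "SolutionHistory",
    "BiphasicFE",
    "NewtonError",
    "strain_invariants",
    "converge_mesh",
]


class NewtonError(RuntimeError):
    """Raised when the Newton loop fails to converge; carries the residual."""

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


@dataclass(frozen=True)
class LoadingProtocol:
    """Displacement-controlled cyclic unconfined-compression protocol."""

    amplitude: float = 0.15      #: strain amplitude, fraction of thickness
    frequency: float = 1.0       #: Hz
    waveform: str = "haversine"  #: amplitude * sin^2(pi f t)
    pre_strain: float = 0.0      #: static offset strain applied with the cycles
    n_cycles: int = 3            #: cycles simulated per adaptive iteration
    dt: float = 0.025            #: implicit time step [s]
    precondition: bool = False   #: consolidate at the mean strain before cycling
    precondition_time: float = 300.0  #: [s] duration of the consolidation stage

    def __post_init__(self) -> None:
        if not 0.0 <= self.amplitude < 0.5:
            raise ValueError("amplitude must lie in [0, 0.5)")
        if self.dt > 1.0 / (20.0 * self.frequency) + 1e-12:
            raise ValueError("dt must resolve the cycle with >= 20 steps")
        if self.waveform != "haversine":
            raise ValueError("only the haversine waveform is supported")

    def strain(self, t: float) -> float:
        """Compressive axial strain fraction at time t.

        Without preconditioning this is the textbook haversine starting from
        zero strain; with preconditioning the same waveform is phase-shifted
        to start at its mean, where the consolidation stage ends.
        """
        if self.precondition:
            s = 0.5 * (1.0 - np.sin(2.0 * np.pi * self.frequency * t))
        else:
            s = np.sin(np.pi * self.frequency * t) ** 2
        return self.pre_strain + self.amplitude * s


@dataclass
class SolutionHistory:
    """Time series and per-integration-point cycle maxima of a dynamic solve."""

    times: np.ndarray
    platen_force: np.ndarray       #: axial platen reaction (compression > 0)
    eps_dev_max: np.ndarray        #: (E, 4) max deviatoric strain, final cycle
    eps_shr_max: np.ndarray        #: (E, 4) max shear strain, final cycle
    v_fl_max: np.ndarray           #: (E, 4) max |fluid velocity| [mm/s], final cycle
    U: np.ndarray = None           #: final nodal displacements (n_nodes, 2)
    P: np.ndarray = None           #: final nodal pressures (n_nodes,)
    peak_drift: float = 0.0        #: relative change of the last two force peaks
    lift_off: bool = False         #: net tensile platen reaction occurred (flagged, not solved)


def strain_invariants(eps: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Principal strains, deviatoric strain and maximum shear strain.

    eps must be a symmetric 3x3 strain tensor.  Returns
    (principal_strains descending, eps_dev, eps_shr) with

        eps_dev = (1/3) sqrt((e1-e2)^2 + (e1-e3)^2 + (e2-e3)^2)
        eps_shr = e_max - e_min
    """
    eps = np.asarray(eps, dtype=float)
    if eps.shape != (3, 3) or not np.allclose(eps, eps.T, atol=1e-10):
        raise ValueError("strain tensor must be symmetric 3x3")
    e = np.sort(np.linalg.eigvalsh(eps))[::-1]
    e1, e2, e3 = e
    eps_dev = np.sqrt((e1 - e2) ** 2 + (e1 - e3) ** 2 + (e2 - e3) ** 2) / 3.0
    eps_shr = e1 - e3
    return e, float(eps_dev), float(eps_shr)


def _principal_invariants(l1sq, l2sq, l3sq):
    """Vectorized eps_dev / eps_shr from squared principal stretches."""
    e1 = 0.5 * np.log(l1sq)
    e2 = 0.5 * np.log(l2sq)
    e3 = 0.5 * np.log(l3sq)
    eps_dev = np.sqrt((e1 - e2) ** 2 + (e1 - e3) ** 2 + (e2 - e3) ** 2) / 3.0
    eps_shr = np.maximum(np.maximum(e1, e2), e3) - np.minimum(np.minimum(e1, e2), e3)
    return eps_dev, eps_shr


class BiphasicFE:
    """Assembler/solver bound to one mesh, composition field and parameter set."""

    def __init__(
        self,
        mesh: ExplantMesh,
        composition: CompositionField,
        params: mat.MaterialParams,
        stab_alpha: float = 0.1,
        fibril_smoothing: float = 2e-4,
    ):
        self.mesh = mesh
        self.comp = composition
        self.params = params
        self.K_nf, self.G_nf = mat.bulk_shear_moduli(params.E_nf, params.nu_nf)
        self.axisym = mesh.formulation == "axisymmetric"
        self.fib_smooth = fibril_smoothing

        Xe = mesh.nodes[mesh.elems]  # (E, 4, 2)
        self.N, dN = shape_functions(GAUSS_PTS)  # (4g, 4a), (4g, 4a, 2)
        Jmat = np.einsum("gai,eaj->egij", dN, Xe)  # (E, g, 2, 2)
        detJ = np.linalg.det(Jmat)
        if np.any(detJ <= 0):
            raise ValueError("mesh contains inverted elements")
        Jinv = np.linalg.inv(Jmat)
        self.dNdX = np.einsum("gaj,egji->egai", dN, Jinv)  # (E, g, a, 2)
        self.r0 = np.einsum("ga,eai->egi", self.N, Xe)[..., 0]  # (E, g) radius
        w = detJ * GAUSS_WTS[None, :]
        if self.axisym:
            w = w * 2.0 * np.pi * self.r0
        self.w = w  # (E, g) integration weights incl. geometry

        # composition at Gauss points
        self.c0 = composition.c_FCD
        self.nfl0 = composition.n_fl
        self.dirs = composition.fibril_dirs  # (E, g, nd, 3)
        self.wfib = composition.fibril_weights(params.C)  # (E, g, nd)

        # polynomial-pressure-projection stabilization matrix per element
        wsum = self.w.sum(axis=1)
        Nbar = (self.w @ self.N) / wsum[:, None]  # (E, a)
        dNp = self.N[None, :, :] - Nbar[:, None, :]  # (E, g, a)
        self.S = np.einsum("eg,ega,egb->eab", self.w, dNp, dNp)
        self.tau = stab_alpha / (2.0 * self.G_nf)

        self.n_nodes = mesh.n_nodes
        self.ndof = 3 * self.n_nodes
        e = mesh.elems
        edofs_u = (2 * e[:, :, None] + np.array([0, 1])[None, None, :]).reshape(e.shape[0], 8)
        self.edofs = np.concatenate([edofs_u, 2 * self.n_nodes + e], axis=1)  # (E, 12)

    # ------------------------------------------------------------------ kinematics

    def _kin(self, Ue):
        """Kinematics for batched element displacements Ue (B, E, 4, 2)."""
        gradU = np.einsum("beai,egaj->begij", Ue, self.dNdX)  # (B, E, g, 2, 2)
        F2 = gradU + np.eye(2)
        detF2 = F2[..., 0, 0] * F2[..., 1, 1] - F2[..., 0, 1] * F2[..., 1, 0]
        if self.axisym:
            ur = np.einsum("bea,ga->beg", Ue[..., 0], self.N)
            F33 = 1.0 + ur / self.r0
        else:
            F33 = np.ones_like(detF2)
        J = detF2 * F33
        Finv2 = np.empty_like(F2)
        Finv2[..., 0, 0] = F2[..., 1, 1]
        Finv2[..., 1, 1] = F2[..., 0, 0]
        Finv2[..., 0, 1] = -F2[..., 0, 1]
        Finv2[..., 1, 0] = -F2[..., 1, 0]
        Finv2 = Finv2 / detF2[..., None, None]
        return F2, F33, J, Finv2

    def gauss_J(self, U: np.ndarray) -> np.ndarray:
        _, _, J, _ = self._kin(U[self.mesh.elems][None])
        return J[0]

    def _cauchy(self, F2, F33, J, p_gp, swelling_scale):
        """Total Cauchy stress (..., E, g, 3, 3) at the Gauss points."""
        F3 = np.zeros(F2.shape[:-2] + (3, 3))
        F3[..., :2, :2] = F2
        F3[..., 2, 2] = F33
        B = F3 @ np.swapaxes(F3, -1, -2)
        I = np.eye(3)
        J_ = J[..., None, None]
        sig = self.K_nf * np.log(J_) / J_ * I + self.G_nf / J_ * (B - J_ ** (2.0 / 3.0) * I)
        if np.any(self.wfib):
            sig = sig + mat.fibril_network_stress_batch(
                F3, self.dirs, self.wfib, self.params.E_f, self.fib_smooth
            )
        c = mat.current_fcd(self.c0 * swelling_scale, self.nfl0, J)
        dpi = mat.donnan_pressure(c, self.params)
        tc = mat.chemical_expansion_stress(c, self.params)
        sig = sig - (dpi + tc + p_gp)[..., None, None] * I
        return sig

    # ------------------------------------------------------------------ residual

    def _element_residuals(self, Ue, Pe, Jn, dPe, dt, swelling_scale, transient):
        """Batched residuals: Ue (B, E, 4, 2), Pe/dPe (B, E, 4) -> (B, E, 12)."""
        F2, F33, J, Finv2 = self._kin(Ue)
        if np.any(J <= 0):
            raise FloatingPointError("element inversion during iteration")
        p_gp = np.einsum("bea,ga->beg", Pe, self.N)
        sig = self._cauchy(F2, F33, J, p_gp, swelling_scale)
        dNdx = np.einsum("egaj,begji->begai", self.dNdX, Finv2)
        wJ = self.w * J
        ru = np.einsum("begai,begij,beg->beaj", dNdx, sig[..., :2, :2], wJ)
        if self.axisym:
            ur = np.einsum("bea,ga->beg", Ue[..., 0], self.N)
            rcur = self.r0 + ur
            ru[..., 0] += np.einsum("ga,beg->bea", self.N, sig[..., 2, 2] * wJ / rcur)
        nB, nE = Ue.shape[:2]
        if not transient:
            return np.concatenate([ru.reshape(nB, nE, 8), np.zeros((nB, nE, 4))], axis=2)
        gradP = np.einsum("bea,egaj->begj", Pe, self.dNdX)
        gradp = np.einsum("begji,begj->begi", Finv2, gradP)
        rp = np.einsum("ga,beg->bea", self.N, (J - Jn) / dt * self.w)
        rp += self.params.k * np.einsum("begai,begi,beg->bea", dNdx, gradp, wJ)
        rp += (self.tau / dt) * np.einsum("eac,bec->bea", self.S, dPe)
        return np.concatenate([ru.reshape(nB, nE, 8), rp], axis=2)

    def _residual_only(self, U, P, Jn, Pn, dt, swelling_scale, transient):
        elems = self.mesh.elems
        base = self._element_residuals(
            U[elems][None], P[elems][None], Jn, (P - Pn)[elems][None],
            dt, swelling_scale, transient,
        )[0]
        r = np.zeros(self.ndof)
        np.add.at(r, self.edofs.ravel(), base.ravel())
        return r

    def _assemble(self, U, P, Jn, Pn, dt, swelling_scale, transient):
        """Global residual vector and FD tangent matrix (one batched call)."""
        elems = self.mesh.elems
        nE = elems.shape[0]
        Ue = U[elems]
        Pe = P[elems]
        dPe = Pe - Pn[elems]
        eps = 1e-7

        UeB = np.broadcast_to(Ue, (13,) + Ue.shape).copy()
        PeB = np.broadcast_to(Pe, (13,) + Pe.shape).copy()
        dPeB = np.broadcast_to(dPe, (13,) + dPe.shape).copy()
        for d in range(8):
            UeB.reshape(13, nE, 8)[1 + d, :, d] += eps
        for d in range(4):
            PeB[9 + d, :, d] += eps
            dPeB[9 + d, :, d] += eps
        res = self._element_residuals(UeB, PeB, Jn, dPeB, dt, swelling_scale, transient)
        base = res[0]
        Ke = np.transpose((res[1:] - base[None]) / eps, (1, 2, 0))  # (E, 12, 12)

        rows = np.repeat(self.edofs, 12, axis=1).ravel()
        cols = np.tile(self.edofs, (1, 12)).ravel()
        K = sp.coo_matrix((Ke.ravel(), (rows, cols)), shape=(self.ndof, self.ndof)).tocsr()
        r = np.zeros(self.ndof)
        np.add.at(r, self.edofs.ravel(), base.ravel())
        # force "activity" scale per dof: assembled absolute contributions,
        # used for an Abaqus-style relative convergence measure
        s = np.zeros(self.ndof)
        np.add.at(s, self.edofs.ravel(), np.abs(base).ravel())
        return r, K, s

    # ------------------------------------------------------------------ newton

    def _newton(
        self, U, P, fixed, fvals, Jn, Pn, dt, transient, swelling_scale,
        fext=None, rtol=1e-6, atol=1e-14, maxit=30,
    ):
        U = U.copy()
        P = P.copy()
        x = np.concatenate([U.ravel(), P])
        free = np.ones(self.ndof, bool)
        free[fixed] = False
        if not transient:
            free[2 * self.n_nodes:] = False  # static solve: pressure pinned
        nu = 2 * self.n_nodes
        for it in range(maxit):
            U = x[:nu].reshape(-1, 2)
            P = x[nu:]
            r, K, scale = self._assemble(U, P, Jn, Pn, dt, swelling_scale, transient)
            if fext is not None:
                r = r - fext
                scale = scale + np.abs(fext)
            # prescribed-value mismatch is driven to zero together with the
            # residual, so the line search can damp stiff Dirichlet increments
            dc = np.zeros(self.ndof)
            dc[fixed] = fvals - x[fixed]
            bc_gap = np.linalg.norm(dc[fixed]) if fixed.size else 0.0
            # per-field residual check against the internal-force activity
            fu = free.copy()
            fu[nu:] = False
            fp = free.copy()
            fp[:nu] = False
            rn_u = np.linalg.norm(r[fu])
            rn_p = np.linalg.norm(r[fp])
            su = np.linalg.norm(scale[fu])
            sp_ = np.linalg.norm(scale[fp])
            rn = np.hypot(rn_u, rn_p)
            if (
                rn_u <= rtol * su + atol
                and rn_p <= rtol * sp_ + atol
                and bc_gap <= 1e-10
            ):
                return U, P, r, it
            dx = dc.copy()
            Kll = K[free][:, free]
            rhs = -(r[free] + (K[:, ~free] @ dc[~free])[free])
            dx[free] = spla.spsolve(Kll.tocsc(), rhs)
            # backtracking line search on the residual norm; never accept a
            # trial state with inverted elements
            alpha, chosen, fallback = 1.0, None, None
            for _ in range(8):
                xt = x + alpha * dx
                Ut = xt[: 2 * self.n_nodes].reshape(-1, 2)
                Pt = xt[2 * self.n_nodes:]
                try:
                    rt = self._residual_only(Ut, Pt, Jn, Pn, dt, swelling_scale, transient)
                    if fext is not None:
                        rt = rt - fext
                    # while a Dirichlet gap remains, any valid state advances it
                    if np.linalg.norm(rt[free]) < rn or bc_gap > 1e-10 or alpha < 0.2:
                        chosen = alpha
                        break
                    fallback = alpha  # valid but not decreasing
                except FloatingPointError:
                    pass
                alpha *= 0.5
            if chosen is None:
                chosen = fallback
            if chosen is None:
                raise NewtonError("line search could not find a non-inverted state", rn)
            x = x + chosen * dx
        raise NewtonError(f"Newton failed after {maxit} iterations (residual {rn:.3e})", rn)

    # ------------------------------------------------------------------ solves

    def solve_free_swelling(self, n_ramp: int = 5, rtol: float = 1e-6) -> np.ndarray:
        """Static zero-traction swelling equilibrium; returns nodal displacements.

        The pressure field is identically zero at free-swelling equilibrium
        (the unknown is the water chemical potential), so only the momentum
        balance is solved, with the FCD ramped up for robustness.
        """
        m = self.mesh
        fixed = np.concatenate([
            2 * m.boundary_nodes("symmetry_axis"),      # u_x = 0
            2 * m.boundary_nodes("bottom") + 1,          # u_y = 0
        ])
        fvals = np.zeros(fixed.size)
        U = np.zeros((self.n_nodes, 2))
        P = np.zeros(self.n_nodes)
        if np.all(self.c0 == 0.0) and self.params.a0 == 0.0:
            return U

        def advance(U, s0, s1, depth):
            try:
                Unew, _, _, _ = self._newton(
                    U, P, fixed, fvals, None, P, None,
                    transient=False, swelling_scale=s1, rtol=rtol,
                )
                return Unew
            except NewtonError:
                if depth >= 4:
                    raise
                sm = 0.5 * (s0 + s1)  # bisect the swelling ramp and retry
                U = advance(U, s0, sm, depth + 1)
                return advance(U, sm, s1, depth + 1)

        s_prev = 0.0
        for s in np.linspace(1.0 / n_ramp, 1.0, n_ramp):
            U = advance(U, s_prev, s, 0)
            s_prev = s
        return U

    def platen_force(self, r: np.ndarray) -> float:
        """Axial platen reaction from an assembled residual (compression > 0)."""
        top = self.mesh.boundary_nodes("platen_top")
        return float(-np.sum(r[2 * top + 1]))

    def solve_transient(
        self,
        U0: np.ndarray,
        P0: np.ndarray,
        times: np.ndarray,
        bc_fn: Callable[[float], tuple[np.ndarray, np.ndarray]],
        fext: np.ndarray | None = None,
        on_step: Callable | None = None,
        swelling_scale: float = 1.0,
        rtol: float = 1e-6,
    ):
        """March the coupled u-p system through `times` with backward Euler.

        ``bc_fn(t)`` returns (fixed dof ids, prescribed values) for each step;
        pressure Dirichlet values belong to dofs ``2*n_nodes + node``.
        """
        U, P = U0.copy(), P0.copy()

        def advance(U, P, t0, t1, depth):
            Jn = self.gauss_J(U)
            fixed, fvals = bc_fn(t1)
            try:
                return self._newton(
                    U, P, fixed, fvals, Jn, P, t1 - t0,
                    transient=True, swelling_scale=swelling_scale, fext=fext, rtol=rtol,
                )
            except NewtonError:
                if depth >= 4:
                    raise
                tm = 0.5 * (t0 + t1)  # bisect the time step and retry
                U, P, _, _ = advance(U, P, t0, tm, depth + 1)
                return advance(U, P, tm, t1, depth + 1)

        t_prev = 0.0
        for t in times:
            if t - t_prev <= 0:
                raise ValueError("times must be strictly increasing from 0")
            U, P, r, nit = advance(U, P, t_prev, t, 0)
            if on_step is not None:
                on_step(t, U, P, r, nit)
            t_prev = t
        return U, P

    def gauss_fields(self, U: np.ndarray, P: np.ndarray) -> dict:
        """Derived fields at Gauss points: strains, fluid speed, FCD, J."""
        Ue = U[self.mesh.elems]
        Pe = P[self.mesh.elems]
        F2, F33, J, Finv2 = (a[0] for a in self._kin(Ue[None]))
        # principal squared stretches from the in-plane right Cauchy-Green tensor
        C11 = F2[..., 0, 0] ** 2 + F2[..., 1, 0] ** 2
        C22 = F2[..., 0, 1] ** 2 + F2[..., 1, 1] ** 2
        C12 = F2[..., 0, 0] * F2[..., 0, 1] + F2[..., 1, 0] * F2[..., 1, 1]
        mean = 0.5 * (C11 + C22)
        radp = np.sqrt(np.maximum(0.25 * (C11 - C22) ** 2 + C12**2, 0.0))
        l1sq = np.maximum(mean + radp, 1e-12)
        l2sq = np.maximum(mean - radp, 1e-12)
        l3sq = F33**2
        eps_dev, eps_shr = _principal_invariants(l1sq, l2sq, l3sq)
        gradP = np.einsum("ea,egaj->egj", Pe, self.dNdX)
        gradp = np.einsum("egji,egj->egi", Finv2, gradP)
        e_cur = np.maximum((J - 1.0 + self.nfl0) / (1.0 - self.nfl0), 1e-6)
        q = self.params.k * np.linalg.norm(gradp, axis=-1)
        v_fl = q * (e_cur + 1.0) / e_cur
        c = mat.current_fcd(self.c0, self.nfl0, J)
        return {
            "eps_dev": eps_dev, "eps_shr": eps_shr, "v_fl": v_fl,
            "J": J, "c_fcd": c, "p": np.einsum("ea,ga->eg", Pe, self.N),
        }

    def solve_dynamic_cycles(
        self, U_sw: np.ndarray, protocol: LoadingProtocol, rtol: float = 1e-6
    ) -> SolutionHistory:
        """Cyclic unconfined compression from the swollen state.

        The platen prescribes a uniform additional axial displacement on the
        top surface (frictionless, impermeable); the bottom is axially fixed
        and frictionless; the water chemical potential is ambient (zero) on
        the free lateral and lesion surfaces.
        """
        m = self.mesh
        top = m.boundary_nodes("platen_top")
        drain = m.boundary_nodes("free_lateral", "lesion_surface")
        fixed = np.concatenate([
            2 * m.boundary_nodes("symmetry_axis"),
            2 * m.boundary_nodes("bottom") + 1,
            2 * top + 1,
            2 * self.n_nodes + drain,
        ])
        n_fix_base = fixed.size - top.size - drain.size
        H_sw = m.thickness + float(np.mean(U_sw[top, 1]))
        top_y_sw = U_sw[top, 1]

        def bc_fn(t):
            delta = -protocol.strain(t) * H_sw
            vals = np.concatenate([
                np.zeros(n_fix_base),
                top_y_sw + delta,
                np.zeros(drain.size),
            ])
            return fixed, vals

        U_start, P_start = U_sw, np.zeros(self.n_nodes)
        if protocol.precondition and protocol.amplitude > 0:
            # drain the mean-strain consolidation transient with a few large
            # implicit steps so the cycles start near the periodic regime
            mean = protocol.pre_strain + 0.5 * protocol.amplitude
            pre_times = np.geomspace(1.0, protocol.precondition_time, 8)

            def bc_pre(t):
                vals = np.concatenate([
                    np.zeros(n_fix_base),
                    top_y_sw - mean * H_sw,
                    np.zeros(drain.size),
                ])
                return fixed, vals

            U_start, P_start = self.solve_transient(
                U_sw, P_start, pre_times, bc_pre, rtol=rtol
            )

        n_per_cycle = max(int(round(1.0 / (protocol.frequency * protocol.dt))), 20)
        dt = 1.0 / (protocol.frequency * n_per_cycle)
        n_steps = n_per_cycle * protocol.n_cycles
        times = dt * np.arange(1, n_steps + 1)
        last_cycle = times > (protocol.n_cycles - 1) / protocol.frequency - 1e-12

        nE = m.n_elems
        dev_max = np.zeros((nE, 4))
        shr_max = np.zeros((nE, 4))
        vfl_max = np.zeros((nE, 4))
        forces = np.zeros(n_steps)
        idx = {round(t, 9): i for i, t in enumerate(times)}

        def on_step(t, U, P, r, nit):
            i = idx[round(t, 9)]
            forces[i] = self.platen_force(r)
            if last_cycle[i]:
                f = self.gauss_fields(U, P)
                np.maximum(dev_max, f["eps_dev"], out=dev_max)
                np.maximum(shr_max, f["eps_shr"], out=shr_max)
                np.maximum(vfl_max, f["v_fl"], out=vfl_max)

        U, P = self.solve_transient(
            U_start, P_start, times, bc_fn, on_step=on_step, rtol=rtol
        )
        # cycle-to-cycle periodicity check on the force peaks
        peaks = [
            forces[i * n_per_cycle:(i + 1) * n_per_cycle].max()
            for i in range(protocol.n_cycles)
        ]
        drift = abs(peaks[-1] - peaks[-2]) / max(abs(peaks[-1]), 1e-12) if len(peaks) > 1 else 0.0
        return SolutionHistory(
            times=times, platen_force=forces,
            eps_dev_max=dev_max, eps_shr_max=shr_max, v_fl_max=vfl_max,
            U=U, P=P, peak_drift=float(drift),
            lift_off=bool(forces.min() < -1e-9),
        )


def edge_traction_forces(mesh: ExplantMesh, tag: str, traction: np.ndarray) -> np.ndarray:
    """Consistent nodal forces for a constant traction [MPa] on tagged edges.

    Evaluated on the reference geometry (adequate for the small-strain
    benchmark loads this supports); returns a global (3*n_nodes,) vector.
    """
    traction = np.asarray(traction, dtype=float)
    fext = np.zeros(3 * mesh.n_nodes)
    for n1, n2 in mesh.edges_with_tag(tag):
        L = np.linalg.norm(mesh.nodes[n2] - mesh.nodes[n1])
        for n in (n1, n2):
            fext[2 * n:2 * n + 2] += 0.5 * L * traction
    return fext


def converge_mesh(
    make_mesh: Callable[[float], ExplantMesh],
    metric: Callable[[ExplantMesh], float],
    target_h0: float,
    rtol: float = 0.02,
    max_levels: int = 3,
) -> tuple[ExplantMesh, float, list[float]]:
    """Refine ``target_h`` by halving until the probe metric changes < rtol.

    Returns the last mesh, its metric value, and the metric history.
    """
    h = target_h0
    mesh = make_mesh(h)
    values = [metric(mesh)]
    for _ in range(max_levels):
        h /= 2.0
        fine = make_mesh(h)
        values.append(metric(fine))
        if abs(values[-1] - values[-2]) <= rtol * max(abs(values[-1]), 1e-12):
            return fine, values[-1], values
        mesh = fine
    return mesh, values[-1], values
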