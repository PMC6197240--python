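"""Inverse identification of E_f, E_nf and k from stress-relaxation force data.

The observed quantity is the axial platen force of an unconfined
compression-stress-relaxation test (10% pre-strain with long relaxation,
then two 2.5% steps).  The three parameters are fitted by Nelder-Mead
simplex minimization of the normalized mean squared error

    NMSE = sum((f_num - f_obs)^2) / sum(f_obs^2)

evaluated on a deliberately coarse explant mesh so a single forward solve
stays around a second; everything else is pinned to the reference set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .fem import BiphasicFE
from .geometry import CompositionField, ExplantMesh, build_composition, build_explant_mesh
from .materials import MaterialParams

__all__ = [
    "StressRelaxationProtocol",
    "ForceRecord",
    "FitResult",
    "calibration_mesh",
    "simulate_stress_relaxation",
    "fit_parameters",
    "generate_synthetic_record",
]


@dataclass(frozen=True)
class StressRelaxationProtocol:
    """Stepped unconfined compression-stress-relaxation protocol."""

    pre_strain: float = 0.10
    pre_ramp: float = 200.0     #: [s]
    pre_hold: float = 600.0     #: [s]
    step_strain: float = 0.025
    n_steps: int = 2
    step_ramp: float = 30.0     #: [s]
    step_hold: float = 300.0    #: [s]

    def __post_init__(self) -> None:
        for name in ("pre_ramp", "pre_hold", "step_ramp", "step_hold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.total_strain >= 0.20:
            raise ValueError("cumulative strain must stay below 20%")

    @property
    def total_strain(self) -> float:
        return self.pre_strain + self.n_steps * self.step_strain

    @property
    def duration(self) -> float:
        return self.pre_ramp + self.pre_hold + self.n_steps * (self.step_ramp + self.step_hold)

    def strain(self, t) -> np.ndarray:
        """Compressive strain fraction at time t (piecewise-linear ramps)."""
        t = np.asarray(t, dtype=float)
        s = np.clip(t / self.pre_ramp, 0.0, 1.0) * self.pre_strain
        t0 = self.pre_ramp + self.pre_hold
        for _ in range(self.n_steps):
            s = s + np.clip((t - t0) / self.step_ramp, 0.0, 1.0) * self.step_strain
            t0 += self.step_ramp + self.step_hold
        out = np.asarray(s)
        return float(out) if out.ndim == 0 else out

    def time_grid(self, n_ramp: int = 6, n_hold: int = 12) -> np.ndarray:
        """Nonuniform solver time grid: linear in ramps, geometric in holds."""
        times = []
        t0 = 0.0
        segments = [(self.pre_ramp, self.pre_hold)]
        segments += [(self.step_ramp, self.step_hold)] * self.n_steps
        for ramp, hold in segments:
            times.append(t0 + np.linspace(ramp / n_ramp, ramp, n_ramp))
            t0 += ramp
            times.append(t0 + np.geomspace(hold / 60.0, hold, n_hold))
            t0 += hold
        return np.concatenate(times)


@dataclass
class ForceRecord:
    """Axial reaction force time series of a mechanical test."""

    time: np.ndarray   #: [s], strictly increasing
    force: np.ndarray  #: [N]

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.time.size != self.force.size:
            raise ValueError("time and force must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not np.all(np.isfinite(self.force)):
            raise ValueError("forces must be finite")

    def to_csv(self, path) -> None:
        pd.DataFrame({"time_s": self.time, "force_N": self.force}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ForceRecord":
        df = pd.read_csv(path)
        return cls(time=df.iloc[:, 0].to_numpy(), force=df.iloc[:, 1].to_numpy())


@dataclass
class FitResult:
    E_f: float
    E_nf: float
    k: float
    nmse: float
    n_evaluations: int
    converged: bool
    message: str = ""

    def as_dict(self) -> dict:
        return {
            "E_f_MPa": self.E_f, "E_nf_MPa": self.E_nf, "k_mm4_per_Ns": self.k,
            "nmse": self.nmse, "n_evaluations": self.n_evaluations,
            "converged": self.converged, "message": self.message,
        }


def calibration_mesh(target_h: float = 0.3, formulation: str = "axisymmetric") -> ExplantMesh:
    """Coarse intact explant mesh used inside the fitting objective."""
    return build_explant_mesh(
        radius=1.5, thickness=1.0, target_h=target_h, formulation=formulation
    )


def simulate_stress_relaxation(
    params: MaterialParams,
    mesh: ExplantMesh | None = None,
    protocol: StressRelaxationProtocol | None = None,
    composition: CompositionField | None = None,
    times: np.ndarray | None = None,
) -> ForceRecord:
    """Axial force response of the explant under the stepped protocol."""
    protocol = protocol or StressRelaxationProtocol()
    mesh = mesh if mesh is not None else calibration_mesh()
    comp = composition if composition is not None else build_composition(mesh)
    times = times if times is not None else protocol.time_grid()
    fe = BiphasicFE(mesh, comp, params)
    U_sw = fe.solve_free_swelling(n_ramp=3)

    top = mesh.boundary_nodes("platen_top")
    drain = mesh.boundary_nodes("free_lateral", "lesion_surface")
    fixed = np.concatenate([
        2 * mesh.boundary_nodes("symmetry_axis"),
        2 * mesh.boundary_nodes("bottom") + 1,
        2 * top + 1,
        2 * fe.n_nodes + drain,
    ])
    n_base = fixed.size - top.size - drain.size
    H_sw = mesh.thickness + float(np.mean(U_sw[top, 1]))
    top_y_sw = U_sw[top, 1]

    def bc_fn(t):
        vals = np.concatenate([
            np.zeros(n_base),
            top_y_sw - protocol.strain(t) * H_sw,
            np.zeros(drain.size),
        ])
        return fixed, vals

    forces = np.zeros(times.size)
    ti = {round(t, 9): i for i, t in enumerate(times)}

    def on_step(t, U, P, r, nit):
        forces[ti[round(t, 9)]] = fe.platen_force(r)

    fe.solve_transient(U_sw, np.zeros(fe.n_nodes), times, bc_fn, on_step=on_step)
    return ForceRecord(time=times, force=forces)


def nmse(f_num: np.ndarray, f_obs: np.ndarray) -> float:
    """Normalized mean squared error; invariant to joint force rescaling."""
    denom = float(np.sum(np.asarray(f_obs) ** 2))
    if denom == 0:
        raise ValueError("observed record has zero norm")
    return float(np.sum((np.asarray(f_num) - np.asarray(f_obs)) ** 2) / denom)


def fit_parameters(
    observed: ForceRecord,
    initial_guess: tuple[float, float, float] | None = None,
    bounds: tuple | None = None,
    base_params: MaterialParams | None = None,
    mesh: ExplantMesh | None = None,
    protocol: StressRelaxationProtocol | None = None,
    maxfev: int = 200,
    xatol: float = 1e-3,
    fatol: float = 1e-10,
) -> FitResult:
    """Fit (E_f, E_nf, k) to an observed force record by Nelder-Mead NMSE.

    The search runs in log-parameter space (the three parameters span
    orders of magnitude); bounds default to [0.1x, 10x] of the reference
    values and are enforced by penalty.
    """
    base = base_params or MaterialParams()
    ref = np.array([base.E_f, base.E_nf, base.k])
    if bounds is None:
        bounds = tuple((0.1 * v, 10.0 * v) for v in ref)
    lo = np.log(np.array([b[0] for b in bounds]))
    hi = np.log(np.array([b[1] for b in bounds]))
    x0 = np.log(np.asarray(initial_guess, dtype=float)) if initial_guess is not None else np.log(ref)
    if np.any(x0 < lo) or np.any(x0 > hi):
        raise ValueError("initial guess violates bounds")
    mesh = mesh if mesh is not None else calibration_mesh()
    protocol = protocol or StressRelaxationProtocol()
    comp = build_composition(mesh)
    n_eval = 0

    def objective(x):
        nonlocal n_eval
        if np.any(x < lo) or np.any(x > hi):
            return 1e6 + float(np.sum(np.maximum(lo - x, 0) + np.maximum(x - hi, 0)))
        E_f, E_nf, k = np.exp(x)
        n_eval += 1
        try:
            rec = simulate_stress_relaxation(
                base.with_(E_f=E_f, E_nf=E_nf, k=k), mesh=mesh,
                protocol=protocol, composition=comp, times=observed.time,
            )
        except Exception:
            return 1e6
        val = nmse(rec.force, observed.force)
        return val if np.isfinite(val) else 1e6

    res = minimize(
        objective, x0, method="Nelder-Mead",
        options={"maxfev": maxfev, "xatol": xatol, "fatol": fatol, "adaptive": True},
    )
    E_f, E_nf, k = np.exp(res.x)
    return FitResult(
        E_f=float(E_f), E_nf=float(E_nf), k=float(k),
        nmse=float(res.fun), n_evaluations=n_eval,
        converged=bool(res.success or res.fun < 1e-6), message=str(res.message),
    )


def generate_synthetic_record(
    true_params: MaterialParams,
    noise_sd: float = 0.0,
    seed: int | None = None,
    mesh: ExplantMesh | None = None,
    protocol: StressRelaxationProtocol | None = None,
) -> ForceRecord:
    """Simulated force record with multiplicative Gaussian noise (seeded)."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rec = simulate_stress_relaxation(true_params, mesh=mesh, protocol=protocol)
    force = rec.force
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        force = force * (1.0 + noise_sd * rng.standard_normal(force.size))
    return ForceRecord(time=rec.time, force=force)
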