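"""Material-point kernels for the fibril-reinforced porohyperelastic swelling law.

The solid skeleton is split into a compressible neo-Hookean ground substance
and a tension-only fibril network (primary arcade fibrils plus an isotropic
secondary set).  Osmotic (Donnan) swelling and chemical expansion act as
hydrostatic pre-stresses controlled by the fixed charge density (FCD).

Unit system: mm, N, s, MPa; concentrations in mEq/ml.  The single osmotic
conversion constant is ``OSMOTIC_MPA``: R*T*c with R in J/(mol K), T in K and
c in mEq/ml gives pressure in MPa after multiplying by 1e-3
(1 mEq/ml = 1e3 mol/m^3 and 1 Pa = 1e-6 MPa).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "OSMOTIC_MPA",
    "M4_PER_NS_TO_MM4_PER_NS",
    "MaterialParams",
    "MaterialPointState",
    "bulk_shear_moduli",
    "nonfibrillar_stress",
    "fibril_stress",
    "log_fibril_strain",
    "fibril_network_stress",
    "fibril_network_stress_batch",
    "mobile_anion_concentration",
    "donnan_pressure",
    "chemical_expansion_stress",
    "total_stress",
    "darcy_velocity",
    "void_ratio",
    "current_fcd",
]

#: converts R*T*c (J/(mol K) * K * mEq/ml) into MPa
OSMOTIC_MPA = 1e-3

#: converts hydraulic permeability from m^4/(N s) to mm^4/(N s)
M4_PER_NS_TO_MM4_PER_NS = 1e12


@dataclass(frozen=True)
class MaterialParams:
    """Constitutive constants of the cartilage model.

    Defaults are the reference parameter set: fitted moduli/permeability,
    literature Poisson ratio and fibril density ratio, physiological bath.
    Osmotic and activity coefficients default to the ideal-Donnan values and
    chemical expansion is off (``a0 = kappa = 0``); both are overridable.
    """

    E_f: float = 20.0          #: fibril network modulus [MPa]
    E_nf: float = 0.16         #: non-fibrillar matrix modulus [MPa]
    nu_nf: float = 0.42        #: Poisson ratio of the non-fibrillar matrix [-]
    k: float = 1.3e-3          #: hydraulic permeability [mm^4/(N s)]
    C: float = 3.009           #: primary-to-secondary fibril density ratio [-]
    c_ext: float = 0.15        #: external salt concentration [mEq/ml]
    R: float = 8.3145          #: molar gas constant [J/(mol K)]
    T: float = 293.0           #: absolute temperature [K]
    phi_int: float = 1.0       #: internal osmotic coefficient [-]
    phi_ext: float = 1.0       #: external osmotic coefficient [-]
    gamma_int: float = 1.0     #: internal activity coefficient [-]
    gamma_ext: float = 1.0     #: external activity coefficient [-]
    a0: float = 0.0            #: chemical expansion constant [MPa ml/mEq]
    kappa: float = 0.0         #: chemical expansion exponent constant [ml/mEq]

    def __post_init__(self) -> None:
        if self.E_f <= 0 or self.E_nf <= 0:
            raise ValueError("moduli must be positive")
        if not 0.0 <= self.nu_nf < 0.5:
            raise ValueError("nu_nf must lie in [0, 0.5); 0.5 is incompressible")
        if self.k <= 0:
            raise ValueError("permeability must be positive")
        if self.C <= 0 or self.c_ext <= 0:
            raise ValueError("C and c_ext must be positive")
        for name in ("R", "T", "phi_int", "phi_ext", "gamma_int", "gamma_ext"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.a0 < 0 or self.kappa < 0:
            raise ValueError("a0 and kappa must be non-negative")

    @property
    def RT(self) -> float:
        """R*T expressed in MPa per (mEq/ml)."""
        return self.R * self.T * OSMOTIC_MPA

    def with_(self, **kwargs) -> "MaterialParams":
        return replace(self, **kwargs)


@dataclass
class MaterialPointState:
    """Kinematic and compositional state at one integration point.

    ``F`` is the full 3x3 deformation gradient (in-plane block plus the
    out-of-plane stretch on the (2,2) slot).  ``c_FCD`` is the fixed charge
    density per unit *current* fluid volume.  ``p`` is the chemical potential
    of water carried by the FE pressure field.
    """

    F: np.ndarray = field(default_factory=lambda: np.eye(3))
    c_FCD: float = 0.0
    n_fl: float = 0.85
    rho_z: float = 1.0
    fibril_dirs: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    fibril_primary: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=bool))
    p: float = 0.0

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.shape == (2, 2):
            F3 = np.eye(3)
            F3[:2, :2] = self.F
            self.F = F3
        if np.linalg.det(self.F) <= 0:
            raise ValueError("deformation gradient must have positive determinant")
        if not 0.0 < self.n_fl < 1.0:
            raise ValueError("fluid fraction must lie in (0, 1)")
        if self.c_FCD < 0:
            raise ValueError("fixed charge density must be non-negative")
        self.fibril_dirs = np.atleast_2d(np.asarray(self.fibril_dirs, dtype=float))
        if self.fibril_dirs.size:
            norms = np.linalg.norm(self.fibril_dirs, axis=1)
            if np.any(norms < 1e-12):
                raise ValueError("zero-norm fibril direction")
            self.fibril_dirs = self.fibril_dirs / norms[:, None]
        self.fibril_primary = np.asarray(self.fibril_primary, dtype=bool)

    @property
    def n_s(self) -> float:
        return 1.0 - self.n_fl

    @property
    def void_ratio(self) -> float:
        return void_ratio(self.n_fl)


def bulk_shear_moduli(E_nf: float, nu_nf: float) -> tuple[float, float]:
    """Bulk and shear modulus of the neo-Hookean ground substance."""
    E_nf = np.asarray(E_nf, dtype=float)
    if np.any(E_nf <= 0):
        raise ValueError("E_nf must be positive")
    if np.any(np.asarray(nu_nf) >= 0.5) or np.any(np.asarray(nu_nf) < 0):
        raise ValueError("nu_nf must lie in [0, 0.5)")
    K_nf = E_nf / (3.0 * (1.0 - 2.0 * nu_nf))
    G_nf = E_nf / (2.0 * (1.0 + nu_nf))
    return float(K_nf) if K_nf.ndim == 0 else K_nf, float(G_nf) if G_nf.ndim == 0 else G_nf


def _as_F3(F: np.ndarray) -> np.ndarray:
    F = np.asarray(F, dtype=float)
    if F.shape[-2:] == (2, 2):
        F3 = np.zeros(F.shape[:-2] + (3, 3))
        F3[..., :2, :2] = F
        F3[..., 2, 2] = 1.0
        return F3
    return F


def nonfibrillar_stress(F: np.ndarray, K_nf: float, G_nf: float) -> np.ndarray:
    """Cauchy stress of the compressible neo-Hookean ground substance."""
    F = _as_F3(F)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("inverted element: det(F) <= 0")
    B = F @ np.swapaxes(F, -1, -2)
    I = np.broadcast_to(np.eye(3), F.shape)
    J_ = J[..., None, None]
    K_ = np.asarray(K_nf)[..., None, None] if np.ndim(K_nf) else K_nf
    G_ = np.asarray(G_nf)[..., None, None] if np.ndim(G_nf) else G_nf
    return K_ * np.log(J_) / J_ * I + G_ / J_ * (B - J_ ** (2.0 / 3.0) * I)


def fibril_stress(eps_f, E_f, smoothing: float = 0.0):
    """Tension-only fibril law: ``E_f * eps_f`` for positive strain, else 0.

    ``smoothing`` > 0 blends the tension branch in with a C1 quadratic over
    the strain interval (0, smoothing); compressive strains still give
    exactly zero.  The FE solver uses a small smoothing so Newton does not
    chatter across the kink; the constitutive law itself defaults to exact.
    """
    eps_f = np.asarray(eps_f, dtype=float)
    if smoothing > 0.0:
        quad = E_f * eps_f**2 / (2.0 * smoothing)
        lin = E_f * (eps_f - 0.5 * smoothing)
        out = np.where(eps_f <= 0.0, 0.0, np.where(eps_f < smoothing, quad, lin))
    else:
        out = np.where(eps_f > 0.0, E_f * eps_f, 0.0)
    return float(out) if out.ndim == 0 else out


def log_fibril_strain(F: np.ndarray, direction: np.ndarray) -> float:
    """Logarithmic fibril strain ln|F e| for a unit reference direction.

    Isolated so the strain measure can be swapped (e.g. for Green strain)
    without touching the network assembly.
    """
    m = _as_F3(F) @ np.asarray(direction, dtype=float)
    lam = np.linalg.norm(m, axis=-1)
    return np.log(lam)


def fibril_network_stress_batch(
    F: np.ndarray, dirs: np.ndarray, weights: np.ndarray, E_f: float,
    smoothing: float = 0.0,
) -> np.ndarray:
    """Summed fibril Cauchy stress for batches of points.

    Parameters
    ----------
    F : (..., 3, 3) deformation gradients.
    dirs : (..., nd, 3) unit reference directions.
    weights : (..., nd) density weights (rho_z*C for primary, rho_z secondary).
    """
    F = _as_F3(F)
    dirs = np.asarray(dirs, dtype=float)
    norms = np.linalg.norm(dirs, axis=-1)
    if np.any(norms < 1e-12):
        raise ValueError("zero-norm fibril direction")
    dirs = dirs / norms[..., None]
    m = np.einsum("...ij,...dj->...di", F, dirs)
    lam = np.linalg.norm(m, axis=-1)
    eps = np.log(lam)
    s = fibril_stress(eps, E_f, smoothing) * np.asarray(weights, dtype=float)
    n = m / lam[..., None]
    return np.einsum("...d,...di,...dj->...ij", s, n, n)


def fibril_network_stress(state: MaterialPointState, params: MaterialParams) -> np.ndarray:
    """Total fibril network Cauchy stress at a single material point."""
    if state.fibril_dirs.shape[0] == 0:
        return np.zeros((3, 3))
    weights = np.where(state.fibril_primary, state.rho_z * params.C, state.rho_z)
    return fibril_network_stress_batch(state.F, state.fibril_dirs, weights, params.E_f)


def mobile_anion_concentration(c_fcd, params: MaterialParams):
    """Mobile anion concentration from ideal Donnan equilibrium [mEq/ml]."""
    c_fcd = np.asarray(c_fcd, dtype=float)
    r = params.gamma_ext / params.gamma_int
    out = 0.5 * (np.sqrt(c_fcd**2 + 4.0 * r**2 * params.c_ext**2) - c_fcd)
    return float(out) if out.ndim == 0 else out


def donnan_pressure(c_fcd, params: MaterialParams):
    """Donnan osmotic swelling pressure [MPa]."""
    c_fcd = np.asarray(c_fcd, dtype=float)
    if np.any(c_fcd < 0):
        raise ValueError("fixed charge density must be non-negative")
    r = params.gamma_ext / params.gamma_int
    RT = params.RT
    out = params.phi_int * RT * np.sqrt(
        c_fcd**2 + 4.0 * r**2 * params.c_ext**2
    ) - 2.0 * params.phi_ext * RT * params.c_ext
    return float(out) if out.ndim == 0 else out


def chemical_expansion_stress(c_fcd, params: MaterialParams):
    """Chemical expansion stress T_c [MPa] (zero when a0 = 0)."""
    c_fcd = np.asarray(c_fcd, dtype=float)
    if params.a0 == 0.0:
        out = np.zeros_like(c_fcd)
        return float(out) if out.ndim == 0 else out
    c_minus = mobile_anion_concentration(c_fcd, params)
    r = params.gamma_ext / params.gamma_int
    out = params.a0 * c_fcd * np.exp(-params.kappa * r * np.sqrt(c_minus * (c_minus + c_fcd)))
    return float(out) if out.ndim == 0 else out


def total_stress(state: MaterialPointState, params: MaterialParams) -> np.ndarray:
    """Total Cauchy stress: fibrillar + non-fibrillar - (dpi + mu_f + T_c) I.

    The FE pressure unknown ``state.p`` is the chemical potential of water;
    the full pore pressure is p = dpi + mu_f and both enter hydrostatically.
    """
    K_nf, G_nf = bulk_shear_moduli(params.E_nf, params.nu_nf)
    sig = nonfibrillar_stress(state.F, K_nf, G_nf)
    sig = sig + fibril_network_stress(state, params)
    dpi = donnan_pressure(state.c_FCD, params)
    tc = chemical_expansion_stress(state.c_FCD, params)
    return sig - (dpi + state.p + tc) * np.eye(3)


def darcy_velocity(grad_p: np.ndarray, k: float, e: float):
    """Darcy flux q = -k grad(p) and interstitial fluid velocity q (e+1)/e."""
    if np.any(np.asarray(e) <= 0):
        raise ValueError("void ratio must be positive")
    q = -k * np.asarray(grad_p, dtype=float)
    v_fl = q * (np.asarray(e) + 1.0) / np.asarray(e)
    return q, v_fl


def void_ratio(n_fl):
    """Void ratio e = n_fl / n_s of a saturated mixture."""
    n_fl = np.asarray(n_fl, dtype=float)
    if np.any(n_fl <= 0) or np.any(n_fl >= 1):
        raise ValueError("fluid fraction must lie in (0, 1)")
    out = n_fl / (1.0 - n_fl)
    return float(out) if out.ndim == 0 else out


def current_fcd(c_fcd_ref, n_fl_ref, J):
    """FCD per current fluid volume after volumetric deformation J.

    Solid volume is conserved, so current fluid volume per reference volume
    is ``J - (1 - n_fl_ref)`` and the charge content is conserved.
    """
    c_fcd_ref = np.asarray(c_fcd_ref, dtype=float)
    fluid = np.asarray(J, dtype=float) - 1.0 + np.asarray(n_fl_ref, dtype=float)
    fluid = np.maximum(fluid, 1e-6)
    out = c_fcd_ref * np.asarray(n_fl_ref, dtype=float) / fluid
    return float(out) if out.ndim == 0 else out
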