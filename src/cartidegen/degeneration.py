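"""Iterative fixed-charge-density depletion driven by mechanical fields.

Each adaptive iteration re-solves free swelling plus the cyclic compression
protocol, extracts per-integration-point maxima of the driving field over
the final loading cycle, maps them through a piecewise-constant degeneration
rate factor, and depletes the FCD field multiplicatively:

    c_new = (1 - D_r) * c_old

The rate factor is 0 below the initiation threshold and 0.6 between the
threshold and the failure value.  Above the failure value the ground
substance fails completely and the local FCD is zeroed (the printed
piecewise rule is read with ">=" in its final branch; set
``above_failure="literal_zero"`` for the verbatim reading, which makes the
branch unreachable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fem import BiphasicFE, LoadingProtocol, NewtonError, SolutionHistory
from .geometry import CompositionField, ExplantMesh
from .materials import MaterialParams

__all__ = [
    "MECHANISMS",
    "DegenerationConfig",
    "DegenerationHistory",
    "degeneration_rate",
    "update_fcd",
    "run_degeneration_loop",
    "distance_to_lesion",
]

log = logging.getLogger(__name__)

MECHANISMS = ("fluid_velocity", "deviatoric_strain", "max_shear_strain")


@dataclass(frozen=True)
class DegenerationConfig:
    """Thresholds, failure limits and rate factor of the adaptive algorithm."""

    mechanism: str = "fluid_velocity"
    eps_dev_thres: float = 0.20   #: deviatoric-strain initiation threshold [-]
    eps_shr_thres: float = 0.50   #: maximum-shear-strain threshold [-]
    v_fl_thres: float = 0.04      #: fluid-velocity threshold [mm/s]
    eps_failure: float = 1.0      #: complete-failure strain [-]
    v_fl_failure: float = 1.5     #: complete-failure fluid velocity [mm/s]
    D_r: float = 0.6              #: degeneration rate factor [-]
    n_iterations: int = 50
    above_failure: str = "total_loss"  #: "total_loss" | "literal_zero"

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if not 0.0 < self.D_r <= 1.0:
            raise ValueError("D_r must lie in (0, 1]")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        for thres, failure in (
            (self.eps_dev_thres, self.eps_failure),
            (self.eps_shr_thres, self.eps_failure),
            (self.v_fl_thres, self.v_fl_failure),
        ):
            if not 0.0 < thres < failure:
                raise ValueError("thresholds must satisfy 0 < threshold < failure")
        if self.above_failure not in ("total_loss", "literal_zero"):
            raise ValueError("above_failure must be 'total_loss' or 'literal_zero'")

    def limits(self, mechanism: str | None = None) -> tuple[float, float]:
        mech = mechanism or self.mechanism
        if mech == "fluid_velocity":
            return self.v_fl_thres, self.v_fl_failure
        if mech == "deviatoric_strain":
            return self.eps_dev_thres, self.eps_failure
        if mech == "max_shear_strain":
            return self.eps_shr_thres, self.eps_failure
        raise ValueError(f"unknown mechanism {mech!r}")


def degeneration_rate(value, mechanism: str, config: DegenerationConfig):
    """Piecewise-constant rate factor for a field value (scalar or array)."""
    thres, failure = config.limits(mechanism)
    value = np.asarray(value, dtype=float)
    if np.any(value < 0):
        raise ValueError("strain/velocity magnitudes must be non-negative")
    rate = np.where((value >= thres) & (value <= failure), config.D_r, 0.0)
    if config.above_failure == "total_loss":
        rate = np.where(value > failure, 1.0, rate)
    return float(rate) if rate.ndim == 0 else rate


def update_fcd(c_fcd: np.ndarray, rate: np.ndarray) -> np.ndarray:
    """Multiplicative FCD depletion, floored at zero."""
    c_fcd = np.asarray(c_fcd, dtype=float)
    rate = np.asarray(rate, dtype=float)
    if np.any(c_fcd < 0) or np.any(rate < 0) or np.any(rate > 1):
        raise ValueError("c_FCD must be >= 0 and rates in [0, 1]")
    return np.maximum((1.0 - rate) * c_fcd, 0.0)


@dataclass
class DegenerationHistory:
    """Per-iteration record of the adaptive loop."""

    c_fcd: list = field(default_factory=list)        #: snapshots incl. initial, (E, 4)
    triggered: list = field(default_factory=list)    #: points with D_r > 0 per iteration
    mean_fcd: list = field(default_factory=list)
    min_fcd: list = field(default_factory=list)
    n_iterations: int = 0            #: iterations actually solved
    fixed_point_at: int | None = None  #: iteration after which nothing triggers
    failure: str | None = None       #: FE diagnostic if the loop died early
    last_solution: SolutionHistory | None = None

    @property
    def initial(self) -> np.ndarray:
        return self.c_fcd[0]

    @property
    def final(self) -> np.ndarray:
        return self.c_fcd[-1]

    def relative_decrease(self) -> np.ndarray:
        """1 - c_final / c_initial, zero where the initial FCD is zero."""
        c0 = self.initial
        out = np.zeros_like(c0)
        m = c0 > 0
        out[m] = 1.0 - self.final[m] / c0[m]
        return out


def run_degeneration_loop(
    mesh: ExplantMesh,
    composition: CompositionField,
    params: MaterialParams,
    protocol: LoadingProtocol,
    config: DegenerationConfig,
    stab_alpha: float = 0.1,
    on_iteration=None,
) -> DegenerationHistory:
    """Run the adaptive degeneration loop.

    Stops early once an iteration triggers no points: the fields are then
    reproduced identically by every later iteration, so the loop has reached
    its fixed point and the remaining iterations are no-ops.  On an FE
    failure mid-loop the history collected so far is returned with a
    diagnostic in ``history.failure``.
    """
    comp = composition.copy()
    hist = DegenerationHistory()
    hist.c_fcd.append(comp.c_FCD.copy())
    field_key = {
        "fluid_velocity": "v_fl_max",
        "deviatoric_strain": "eps_dev_max",
        "max_shear_strain": "eps_shr_max",
    }[config.mechanism]

    for it in range(1, config.n_iterations + 1):
        fe = BiphasicFE(mesh, comp, params, stab_alpha=stab_alpha)
        try:
            U_sw = fe.solve_free_swelling()
            sol = fe.solve_dynamic_cycles(U_sw, protocol)
        except NewtonError as err:
            hist.failure = f"iteration {it}: {err}"
            log.error("degeneration loop aborted: %s", hist.failure)
            break
        value = getattr(sol, field_key)
        rate = degeneration_rate(value, config.mechanism, config)
        n_trig = int(np.count_nonzero(rate))
        comp.c_FCD = update_fcd(comp.c_FCD, rate)
        hist.c_fcd.append(comp.c_FCD.copy())
        hist.triggered.append(n_trig)
        hist.mean_fcd.append(float(comp.c_FCD.mean()))
        hist.min_fcd.append(float(comp.c_FCD.min()))
        hist.n_iterations = it
        hist.last_solution = sol
        log.info(
            "iteration %d/%d: %d points triggered, mean FCD %.4f, min FCD %.4f",
            it, config.n_iterations, n_trig, hist.mean_fcd[-1], hist.min_fcd[-1],
        )
        if on_iteration is not None:
            on_iteration(it, comp, sol, rate)
        if n_trig == 0:
            hist.fixed_point_at = it
            log.info("fixed point reached at iteration %d; stopping early", it)
            break
    return hist


def distance_to_lesion(mesh: ExplantMesh) -> np.ndarray:
    """Distance from each Gauss point to the nearest lesion-surface edge.

    Returns (E, 4) distances [mm]; infinite when the mesh has no lesion.
    """
    gp = mesh.gauss_coords()  # (E, 4, 2)
    edges = mesh.edges_with_tag("lesion_surface")
    if edges.shape[0] == 0:
        return np.full(gp.shape[:2], np.inf)
    a = mesh.nodes[edges[:, 0]]  # (L, 2)
    b = mesh.nodes[edges[:, 1]]
    ab = b - a
    denom = np.maximum(np.einsum("li,li->l", ab, ab), 1e-30)
    ap = gp[:, :, None, :] - a  # (E, 4, L, 2)
    t = np.clip(np.einsum("egli,li->egl", ap, ab) / denom, 0.0, 1.0)
    closest = a + t[..., None] * ab
    d = np.linalg.norm(gp[:, :, None, :] - closest, axis=-1)
    return d.min(axis=2)
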