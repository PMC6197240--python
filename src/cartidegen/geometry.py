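"""Explant cross-section meshing and depth-wise tissue composition.

The explant is the half cross-section of a cylindrical disk: ``x`` runs from
the symmetry axis (x = 0) to the outer radius, ``y`` from the bottom (y = 0)
to the articular surface (y = thickness).  Normalized depth ``h`` is measured
from the surface (surface = 0, bottom = 1).

Surface-breaking cracks are inserted as conforming seams: the grid column
nearest the crack mouth is duplicated down to the crack depth and the two
copies are offset to form an open notch whose faces carry the
``lesion_surface`` tag.
"""

from __future__ import annotations

import math
from typing import Sequence
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CrackSpec",
    "ExplantMesh",
    "CompositionField",
    "depth_profiles",
    "build_explant_mesh",
    "fibril_architecture",
    "build_composition",
    "od_profile_to_fcd",
    "N_FL_COEFFS",
    "C_FCD_COEFFS",
    "RHO_Z_COEFFS",
]

# depth-wise composition polynomials (descending powers of h)
N_FL_COEFFS = np.array([-0.15, 0.85])
C_FCD_COEFFS = np.array([-4.4, 15.2, -21.0, 14.9, -5.8, 1.1, 0.03])
RHO_Z_COEFFS = np.array([20.6, -64.4, 78.1, -45.9, 13.4, -1.6, 0.96])

# 2x2 Gauss rule on the bi-unit square, shared with the FE solver
_g = 1.0 / math.sqrt(3.0)
GAUSS_PTS = np.array([[-_g, -_g], [_g, -_g], [_g, _g], [-_g, _g]])
GAUSS_WTS = np.ones(4)

BOUNDARY_TAGS = ("platen_top", "bottom", "free_lateral", "lesion_surface", "symmetry_axis")


def shape_functions(xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear quad shape functions and derivatives at points xi (n, 2).

    Returns (N (n, 4), dN (n, 4, 2)); node order is counter-clockwise from
    the (-1, -1) corner.
    """
    xi = np.atleast_2d(xi)
    r, s = xi[:, 0], xi[:, 1]
    N = 0.25 * np.stack(
        [(1 - r) * (1 - s), (1 + r) * (1 - s), (1 + r) * (1 + s), (1 - r) * (1 + s)], axis=1
    )
    dN = np.empty((xi.shape[0], 4, 2))
    dN[:, 0, 0] = -0.25 * (1 - s)
    dN[:, 1, 0] = 0.25 * (1 - s)
    dN[:, 2, 0] = 0.25 * (1 + s)
    dN[:, 3, 0] = -0.25 * (1 + s)
    dN[:, 0, 1] = -0.25 * (1 - r)
    dN[:, 1, 1] = -0.25 * (1 + r)
    dN[:, 2, 1] = 0.25 * (1 + r)
    dN[:, 3, 1] = 0.25 * (1 - r)
    return N, dN


@dataclass(frozen=True)
class CrackSpec:
    """Parametric surface-breaking crack in the explant cross-section."""

    mouth_position: float  #: mm from the symmetry axis
    depth: float  #: mm below the articular surface
    opening_width: float = 0.05  #: mm at the mouth
    inclination: float = 0.0  #: degrees from vertical
    profile: str = "v-notch"  #: "v-notch" or "parallel-walled"

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("crack depth must be positive")
        if self.opening_width <= 0:
            raise ValueError("crack opening width must be positive")
        if self.profile not in ("v-notch", "parallel-walled"):
            raise ValueError(f"unknown crack profile {self.profile!r}")


@dataclass
class ExplantMesh:
    """Conforming quad mesh of the explant cross-section with tagged boundary."""

    nodes: np.ndarray  #: (n_nodes, 2) coordinates [mm]
    elems: np.ndarray  #: (n_elems, 4) CCW connectivity
    edge_nodes: np.ndarray  #: (n_bedges, 2) boundary edge endpoints
    edge_tags: np.ndarray  #: (n_bedges,) tag strings
    radius: float
    thickness: float
    formulation: str = "plane_strain"
    cracks: tuple = ()
    target_h: float = 0.2

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_elems(self) -> int:
        return self.elems.shape[0]

    def boundary_nodes(self, *tags: str) -> np.ndarray:
        """Sorted unique node ids on boundary edges carrying any given tag."""
        mask = np.isin(self.edge_tags, tags)
        return np.unique(self.edge_nodes[mask])

    def edges_with_tag(self, tag: str) -> np.ndarray:
        return self.edge_nodes[self.edge_tags == tag]

    def gauss_coords(self) -> np.ndarray:
        """Reference coordinates of the 2x2 Gauss points, shape (E, 4, 2)."""
        N, _ = shape_functions(GAUSS_PTS)
        return np.einsum("ga,eai->egi", N, self.nodes[self.elems])

    def gauss_depth(self) -> np.ndarray:
        """Normalized depth h at each Gauss point (surface = 0, bottom = 1)."""
        y = self.gauss_coords()[..., 1]
        return np.clip(1.0 - y / self.thickness, 0.0, 1.0)

    def gauss_weights(self) -> np.ndarray:
        """Integration weights at Gauss points (E, 4), incl. axisymmetric 2*pi*r."""
        _, dN = shape_functions(GAUSS_PTS)
        Jmat = np.einsum("gai,eaj->egij", dN, self.nodes[self.elems])
        w = np.linalg.det(Jmat) * GAUSS_WTS[None, :]
        if self.formulation == "axisymmetric":
            w = w * 2.0 * np.pi * self.gauss_coords()[..., 0]
        return w

    def min_jacobian(self) -> float:
        _, dN = shape_functions(GAUSS_PTS)
        Jmat = np.einsum("gai,eaj->egij", dN, self.nodes[self.elems])
        return float(np.min(np.linalg.det(Jmat)))

    def area(self) -> float:
        x = self.nodes[self.elems][..., 0]
        y = self.nodes[self.elems][..., 1]
        x2, y2 = np.roll(x, -1, axis=1), np.roll(y, -1, axis=1)
        return float(np.sum(0.5 * np.abs(np.sum(x * y2 - x2 * y, axis=1))))


def depth_profiles(h):
    """Evaluate the depth-wise composition profiles at normalized depth h.

    Returns ``(n_fl, c_FCD, rho_z)``; h may be scalar or array in [0, 1].
    """
    h = np.asarray(h, dtype=float)
    if np.any(h < 0) or np.any(h > 1):
        raise ValueError("normalized depth must lie in [0, 1]")
    n_fl = np.polyval(N_FL_COEFFS, h)
    c_fcd = np.polyval(C_FCD_COEFFS, h)
    rho_z = np.polyval(RHO_Z_COEFFS, h)
    if h.ndim == 0:
        return float(n_fl), float(c_fcd), float(rho_z)
    return n_fl, c_fcd, rho_z


def _boundary_edges(nodes: np.ndarray, elems: np.ndarray, radius: float, thickness: float):
    """Extract exterior edges by connectivity and tag them geometrically."""
    edges: dict[tuple[int, int], tuple[int, int]] = {}
    counts: dict[tuple[int, int], int] = {}
    for el in elems:
        for a in range(4):
            n1, n2 = int(el[a]), int(el[(a + 1) % 4])
            key = (min(n1, n2), max(n1, n2))
            counts[key] = counts.get(key, 0) + 1
            edges[key] = (n1, n2)
    tol = 1e-9 * max(radius, thickness)
    enodes, etags = [], []
    for key, cnt in counts.items():
        if cnt != 1:
            continue
        n1, n2 = edges[key]
        y1, y2 = nodes[n1, 1], nodes[n2, 1]
        x1, x2 = nodes[n1, 0], nodes[n2, 0]
        if abs(y1) < tol and abs(y2) < tol:
            tag = "bottom"
        elif abs(y1 - thickness) < tol and abs(y2 - thickness) < tol:
            tag = "platen_top"
        elif abs(x1) < tol and abs(x2) < tol:
            tag = "symmetry_axis"
        elif abs(x1 - radius) < tol and abs(x2 - radius) < tol:
            tag = "free_lateral"
        else:
            tag = "lesion_surface"
        enodes.append((n1, n2))
        etags.append(tag)
    return np.array(enodes, dtype=int), np.array(etags, dtype=object)


def _side_steps(L: float, h_fine: float, h_coarse: float, growth: float) -> np.ndarray:
    """Geometrically growing steps from a refined end, rescaled to sum to L."""
    steps = []
    h, s = h_fine, 0.0
    while s < L - 1e-12:
        steps.append(h)
        s += h
        h = min(h * growth, h_coarse)
    steps = np.asarray(steps)
    return steps * (L / steps.sum())


def _feature_coords(
    length: float, features: Sequence[float], h_coarse: float,
    h_fine: float | None, growth: float = 1.4,
) -> np.ndarray:
    """1D node coordinates on [0, length], refined around feature positions.

    Feature positions become nodes; spacing grows geometrically from
    ``h_fine`` at a feature to ``h_coarse`` away from it.  Without features
    (or without ``h_fine``) the spacing is uniform.
    """
    feats_all = set(features)
    interior = sorted({f for f in feats_all if 0.0 < f < length})
    if h_fine is None or (not interior and not feats_all & {0.0, length}):
        n = max(4, int(round(length / h_coarse)))
        return np.linspace(0.0, length, n + 1)
    anchors = np.array([0.0] + interior + [length])
    refined = [a in feats_all for a in anchors]
    coords = [0.0]
    for a, b, ra, rb in zip(anchors[:-1], anchors[1:], refined[:-1], refined[1:]):
        L = b - a
        if ra and rb:
            left = _side_steps(L / 2, h_fine, h_coarse, growth)
            steps = np.concatenate([left, left[::-1]])
        elif ra:
            steps = _side_steps(L, h_fine, h_coarse, growth)
        elif rb:
            steps = _side_steps(L, h_fine, h_coarse, growth)[::-1]
        else:
            n = max(2, int(round(L / h_coarse)))
            steps = np.full(n, L / n)
        coords.extend(a + np.cumsum(steps))
        coords[-1] = b  # guard cumulative rounding
    return np.asarray(coords)


def build_explant_mesh(
    radius: float = 1.5,
    thickness: float = 1.0,
    cracks: list[CrackSpec] | tuple = (),
    target_h: float = 0.15,
    formulation: str = "axisymmetric",
    refine_h: float | None = None,
    growth: float = 1.4,
    refine_lateral: bool = False,
) -> ExplantMesh:
    """Structured quad mesh of the explant half cross-section with crack seams.

    With ``refine_h`` set, columns are clustered around each crack mouth (and
    the free lateral edge if ``refine_lateral``) and rows toward the
    articular surface, to resolve the fluid-exudation boundary layers.
    """
    if formulation not in ("plane_strain", "axisymmetric"):
        raise ValueError(f"unknown formulation {formulation!r}")
    for ck in cracks:
        if ck.depth >= thickness:
            raise ValueError("crack deeper than explant thickness")
        if not 0 < ck.mouth_position < radius:
            raise ValueError("crack mouth must lie strictly inside the section")
    xfeat = [ck.mouth_position for ck in cracks]
    if refine_lateral:
        xfeat.append(radius)
    xs = _feature_coords(radius, xfeat, target_h, refine_h, growth)
    yfeat = [thickness] if (cracks or refine_lateral) else []
    ys = _feature_coords(thickness, yfeat, target_h, refine_h, growth)
    nx, ny = xs.size - 1, ys.size - 1

    nid = lambda i, j: j * (nx + 1) + i
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    nodes = np.column_stack([X.T.ravel(), Y.T.ravel()])  # row-major in j
    elems = np.array(
        [
            [nid(i, j), nid(i + 1, j), nid(i + 1, j + 1), nid(i, j + 1)]
            for j in range(ny)
            for i in range(nx)
        ],
        dtype=int,
    )
    nodes = nodes.copy()
    elems = elems.copy()

    used_cols: set[int] = set()
    for ck in cracks:
        ic = int(np.argmin(np.abs(xs - ck.mouth_position)))
        ic = min(max(ic, 1), nx - 1)
        if ic in used_cols:
            raise ValueError("two cracks snap to the same mesh column; refine the mesh")
        used_cols.add(ic)
        # snap tip to the nearest grid row
        y_tip_target = thickness - ck.depth
        jt = int(np.argmin(np.abs(ys - y_tip_target)))
        jt = min(max(jt, 1), ny - 1)
        dup_rows = list(range(jt + 1, ny + 1))  # duplicated node rows (tip stays single)
        new_ids = {}
        for j in dup_rows:
            new_ids[j] = nodes.shape[0]
            nodes = np.vstack([nodes, nodes[nid(ic, j)]])
        # reconnect elements right of the seam to the duplicates
        for j in range(jt, ny):
            e = j * nx + ic
            if (j + 1) in new_ids:
                elems[e, 3] = new_ids[j + 1]
            if j in new_ids:
                elems[e, 0] = new_ids[j]
        # open the notch: seam copies take the full half-opening, surrounding
        # nodes follow with a shift decaying to zero over a support width so
        # locally refined columns are not inverted
        tanq = math.tan(math.radians(ck.inclination))
        y_tip = ys[jt]
        xc = xs[ic]

        def taper(y):
            if ck.profile == "v-notch":
                return np.clip((y - y_tip) / max(thickness - y_tip, 1e-12), 0.0, 1.0)
            return np.where(y >= y_tip - 1e-12, 1.0, 0.0)

        others = [c.mouth_position for c in cracks if c is not ck]
        gap = min([abs(c - xc) / 2.0 for c in others], default=np.inf)
        ws_l = min(0.3, xc, gap)
        ws_r = min(0.3, radius - xc, gap)
        seam = {nid(ic, j) for j in dup_rows} | set(new_ids.values()) | {nid(ic, jt)}
        for n in range(nodes.shape[0]):
            if n in seam:
                continue
            d = nodes[n, 0] - xc
            if d == 0.0:
                continue
            ws = ws_l if d < 0 else ws_r
            fall = max(0.0, 1.0 - abs(d) / ws) if ws > 0 else 0.0
            nodes[n, 0] += np.sign(d) * 0.5 * ck.opening_width * float(taper(nodes[n, 1])) * fall
        for j in dup_rows:
            y = ys[j]
            half = 0.5 * ck.opening_width * float(taper(y))
            shift = tanq * (thickness - y)
            nodes[nid(ic, j), 0] = xc - half - shift
            nodes[new_ids[j], 0] = xc + half - shift
        nodes[nid(ic, jt), 0] = xc - tanq * (thickness - y_tip)

    edge_nodes, edge_tags = _boundary_edges(nodes, elems, radius, thickness)
    mesh = ExplantMesh(
        nodes=nodes,
        elems=elems,
        edge_nodes=edge_nodes,
        edge_tags=edge_tags,
        radius=radius,
        thickness=thickness,
        formulation=formulation,
        cracks=tuple(cracks),
        target_h=target_h,
    )
    if mesh.min_jacobian() <= 0.0:
        raise ValueError("meshing produced an inverted element (degenerate CrackSpec?)")
    return mesh


def fibril_architecture(
    mesh: ExplantMesh, arrangement: str = "arcade",
    superficial: float = 0.15, deep: float = 0.40, n_secondary: int = 8,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fibril direction sets per integration point.

    Returns ``(dirs, primary, n_primary)`` with ``dirs`` of shape
    (E, 4, nd, 3) unit vectors and ``primary`` a (nd,) bool mask.  The
    primary family follows the requested arrangement; the secondary family is
    a fixed isotropic fan of ``n_secondary`` in-plane directions plus the
    out-of-plane axis.  For ``isotropic`` the primary family is spread over
    the same fan.
    """
    h = mesh.gauss_depth()  # (E, 4)
    fan_angles = np.pi * (np.arange(n_secondary) + 0.5) / n_secondary
    fan = np.zeros((n_secondary + 1, 3))
    fan[:n_secondary, 0] = np.cos(fan_angles)
    fan[:n_secondary, 1] = np.sin(fan_angles)
    fan[n_secondary, 2] = 1.0

    if arrangement == "arcade":
        t = np.clip((h - superficial) / (deep - superficial), 0.0, 1.0)
        alpha = t * (np.pi / 2.0)  # 0 = parallel to surface, pi/2 = depth-normal
        prim = np.stack([np.cos(alpha), -np.sin(alpha), np.zeros_like(alpha)], axis=-1)
    elif arrangement == "parallel_to_surface":
        prim = np.broadcast_to(np.array([1.0, 0.0, 0.0]), h.shape + (3,))
    elif arrangement == "perpendicular":
        prim = np.broadcast_to(np.array([0.0, 1.0, 0.0]), h.shape + (3,))
    elif arrangement == "isotropic":
        # primary weight spread over the same fan as the secondary family
        nd = n_secondary + 1
        both = np.concatenate([fan, fan], axis=0)
        dirs = np.ascontiguousarray(np.broadcast_to(both, h.shape + (2 * nd, 3)))
        primary = np.zeros(2 * nd, dtype=bool)
        primary[:nd] = True
        return dirs, primary, nd
    else:
        raise ValueError(f"unknown fibril arrangement {arrangement!r}")

    nd = 1 + n_secondary + 1
    dirs = np.empty(h.shape + (nd, 3))
    dirs[..., 0, :] = prim
    dirs[..., 1:, :] = fan
    primary = np.zeros(nd, dtype=bool)
    primary[0] = True
    return dirs, primary, 1


@dataclass
class CompositionField:
    """Per-integration-point tissue composition; the degeneration loop rewrites c_FCD."""

    n_fl: np.ndarray  #: (E, 4) reference fluid fraction
    c_FCD: np.ndarray  #: (E, 4) reference FCD [mEq/ml]
    rho_z: np.ndarray  #: (E, 4) relative collagen density
    fibril_dirs: np.ndarray  #: (E, 4, nd, 3)
    fibril_primary: np.ndarray  #: (nd,) bool mask
    n_primary_family: int = 1  #: directions the primary weight is spread over
    arrangement: str = "arcade"

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.c_FCD)) or np.any(self.c_FCD < 0):
            raise ValueError("c_FCD must be finite and non-negative")
        if np.any(self.n_fl <= 0) or np.any(self.n_fl >= 1):
            raise ValueError("n_fl must lie in (0, 1)")

    def fibril_weights(self, C: float) -> np.ndarray:
        """Density weights per direction, shape (E, 4, nd).

        Each primary direction carries rho_z*C and each secondary direction
        rho_z.  When the primary family is spread over several directions
        (isotropic arrangement) its weight is divided among them.
        """
        w = np.where(self.fibril_primary, C / self.n_primary_family, 1.0)
        return self.rho_z[..., None] * w

    def copy(self) -> "CompositionField":
        return CompositionField(
            n_fl=self.n_fl.copy(),
            c_FCD=self.c_FCD.copy(),
            rho_z=self.rho_z.copy(),
            fibril_dirs=self.fibril_dirs,
            fibril_primary=self.fibril_primary,
            n_primary_family=self.n_primary_family,
            arrangement=self.arrangement,
        )


def build_composition(
    mesh: ExplantMesh,
    arrangement: str = "arcade",
    fcd_coeffs: np.ndarray | None = None,
    fcd_scale: float = 1.0,
    rho_z_scale: float = 1.0,
    rho_z_uniform: bool = False,
    n_secondary: int = 8,
) -> CompositionField:
    """Populate composition fields from the depth-wise profiles."""
    h = mesh.gauss_depth()
    n_fl, c_fcd, rho_z = depth_profiles(h)
    if fcd_coeffs is not None:
        c_fcd = np.polyval(np.asarray(fcd_coeffs, dtype=float), h)
    c_fcd = np.clip(c_fcd * fcd_scale, 0.0, None)
    if rho_z_uniform:
        rho_z = np.ones_like(rho_z)
    rho_z = rho_z * rho_z_scale
    dirs, primary, n_prim = fibril_architecture(mesh, arrangement, n_secondary=n_secondary)
    return CompositionField(
        n_fl=n_fl, c_FCD=c_fcd, rho_z=rho_z,
        fibril_dirs=dirs, fibril_primary=primary,
        n_primary_family=n_prim, arrangement=arrangement,
    )


def od_profile_to_fcd(
    depth: np.ndarray, optical_density: np.ndarray, target_mean_fcd: float
) -> np.ndarray:
    """Convert a depth-wise optical-density profile to FCD polynomial coefficients.

    A degree-6 polynomial is least-squares fitted to the profile and scaled
    uniformly so its depth average over h in [0, 1] equals
    ``target_mean_fcd``.  Returns coefficients in descending powers.
    """
    depth = np.asarray(depth, dtype=float)
    od = np.asarray(optical_density, dtype=float)
    if depth.size < 7:
        raise ValueError("need at least 7 depth samples for a degree-6 fit")
    coeffs = np.polyfit(depth, od, deg=6)
    mean = float(np.polyval(np.polyint(coeffs), 1.0) - np.polyval(np.polyint(coeffs), 0.0))
    if abs(mean) < 1e-15:
        raise ValueError("fitted profile has zero mean; cannot scale to target FCD")
    return coeffs * (target_mean_fcd / mean)
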