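"""Solver tests: strain invariants, swelling equilibria, consolidation oracles,
and the cyclic compression protocol."""

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from cartidegen.fem import (
    BiphasicFE,
    LoadingProtocol,
    converge_mesh,
    edge_traction_forces,
    strain_invariants,
)
from cartidegen.geometry import (
    CompositionField,
    build_composition,
    build_explant_mesh,
    fibril_architecture,
)
from cartidegen.materials import (
    MaterialParams,
    bulk_shear_moduli,
    current_fcd,
    donnan_pressure,
)


def uniform_composition(mesh, c_fcd, n_fl=0.8, rho_z=0.0):
    """Spatially uniform composition for closed-form comparisons."""
    E = mesh.n_elems
    dirs, primary, npf = fibril_architecture(mesh, "arcade")
    return CompositionField(
        n_fl=np.full((E, 4), n_fl), c_FCD=np.full((E, 4), c_fcd),
        rho_z=np.full((E, 4), rho_z), fibril_dirs=dirs,
        fibril_primary=primary, n_primary_family=npf,
    )


class TestStrainInvariants:
    def test_hydrostatic_gives_zero(self):
        _, dev, shr = strain_invariants(0.3 * np.eye(3))
        assert dev == pytest.approx(0.0, abs=1e-14)
        assert shr == pytest.approx(0.0, abs=1e-14)

    def test_uniaxial_evaluation(self):
        eps = np.diag([0.3, 0.0, 0.0])
        principal, dev, shr = strain_invariants(eps)
        assert dev == pytest.approx(np.sqrt(0.09 + 0.09) / 3.0, rel=1e-12)
        assert dev == pytest.approx(0.1414, abs=1e-4)
        assert shr == pytest.approx(0.3, rel=1e-12)
        assert principal[0] == pytest.approx(0.3)

    def test_rotation_invariance(self, rng):
        for _ in range(20):
            A = rng.standard_normal((3, 3))
            eps = 0.5 * (A + A.T) * 0.1
            R = Rotation.random(random_state=int(rng.integers(1 << 30))).as_matrix()
            eps_rot = R @ eps @ R.T
            _, d1, s1 = strain_invariants(eps)
            _, d2, s2 = strain_invariants(eps_rot)
            assert d1 == pytest.approx(d2, rel=1e-9, abs=1e-12)
            assert s1 == pytest.approx(s2, rel=1e-9, abs=1e-12)

    def test_non_symmetric_rejected(self):
        bad = np.eye(3)
        bad[0, 1] = 0.1
        with pytest.raises(ValueError):
            strain_invariants(bad)


class TestLoadingProtocol:
    def test_haversine_zero_and_peak(self):
        p = LoadingProtocol(amplitude=0.15, frequency=1.0)
        assert p.strain(0.0) == pytest.approx(0.0, abs=1e-14)
        assert p.strain(0.5) == pytest.approx(0.15, rel=1e-12)
        assert p.strain(1.0) == pytest.approx(0.0, abs=1e-12)

    def test_dt_resolution_enforced(self):
        with pytest.raises(ValueError):
            LoadingProtocol(dt=0.1, frequency=1.0)

    def test_amplitude_bounds(self):
        with pytest.raises(ValueError):
            LoadingProtocol(amplitude=0.6)


class TestFreeSwelling:
    def test_zero_fcd_identity_solution(self, ref_params):
        mesh = build_explant_mesh(target_h=0.3)
        comp = build_composition(mesh, fcd_scale=0.0)
        fe = BiphasicFE(mesh, comp, ref_params)
        U = fe.solve_free_swelling()
        assert np.allclose(U, 0.0, atol=1e-12)

    def test_uniform_swelling_matches_scalar_root(self, ref_params):
        # plane-strain block, uniform FCD, no fibrils: the equilibrium is a
        # uniform biaxial stretch solved independently by a 1-point root find
        K, G = bulk_shear_moduli(ref_params.E_nf, ref_params.nu_nf)
        mesh = build_explant_mesh(
            radius=1.0, thickness=1.0, target_h=0.25, formulation="plane_strain"
        )
        c0, n0 = 0.2, 0.8
        fe = BiphasicFE(mesh, uniform_composition(mesh, c0, n_fl=n0), ref_params)
        U = fe.solve_free_swelling()
        J = fe.gauss_J(U)

        def residual(lam):
            Jv = lam * lam
            sxx = K * np.log(Jv) / Jv + G / Jv * (lam * lam - Jv ** (2 / 3))
            return sxx - donnan_pressure(current_fcd(c0, n0, Jv), ref_params)

        J_star = brentq(residual, 1.0, 1.5) ** 2
        assert J.max() - J.min() < 1e-6
        assert J.mean() == pytest.approx(J_star, rel=1e-5)

    def test_swelling_monotone_in_fcd(self, ref_params):
        mesh = build_explant_mesh(radius=1.0, thickness=1.0, target_h=0.25,
                                  formulation="plane_strain")
        heights = []
        for c in (0.1, 0.2):
            fe = BiphasicFE(mesh, uniform_composition(mesh, c), ref_params)
            U = fe.solve_free_swelling()
            heights.append(U[mesh.boundary_nodes("platen_top"), 1].mean())
        assert heights[1] > heights[0] > 0

    def test_explant_swells_upward(self, intact_dynamic, intact_mesh):
        U_sw = intact_dynamic["U_sw"]
        assert U_sw[intact_mesh.boundary_nodes("platen_top"), 1].mean() > 0


def terzaghi_pressure(y, t, L, cv, sig0, nterm=400):
    """Series solution for a step-loaded column drained at y = L."""
    z = (L - y) / L
    p = np.zeros_like(y, dtype=float)
    for m in range(nterm):
        M = np.pi * (2 * m + 1) / 2
        p += (2.0 / M) * np.sin(M * z) * np.exp(-M * M * cv * t / L**2)
    return sig0 * p


@pytest.fixture(scope="module")
def terzaghi_run(ref_params):
    """Step-loaded confined column, linear regime, shared across assertions."""
    K, G = bulk_shear_moduli(ref_params.E_nf, ref_params.nu_nf)
    cv = ref_params.k * (K + 4 * G / 3)
    L, sig0 = 1.0, 1e-4
    mesh = build_explant_mesh(radius=0.2, thickness=L, target_h=0.05,
                              formulation="plane_strain")
    comp = build_composition(mesh, fcd_scale=0.0, rho_z_scale=0.0)
    fe = BiphasicFE(mesh, comp, ref_params)
    fixed = np.concatenate([
        2 * mesh.boundary_nodes("symmetry_axis"),
        2 * mesh.boundary_nodes("free_lateral"),
        2 * mesh.boundary_nodes("bottom") + 1,
        2 * fe.n_nodes + mesh.boundary_nodes("platen_top"),
    ])
    fvals = np.zeros(fixed.size)
    fext = edge_traction_forces(mesh, "platen_top", [0.0, -sig0])
    Tend = 0.5 * L * L / cv
    times = np.concatenate([np.geomspace(Tend / 400, Tend, 70), [1e5, 1e6, 2e6]])
    samples, settlements = {}, []

    def on_step(t, U, P, r, nit):
        samples[t] = P.copy()
        settlements.append((t, U[mesh.boundary_nodes("platen_top"), 1].mean()))

    fe.solve_transient(
        np.zeros((fe.n_nodes, 2)), np.zeros(fe.n_nodes), times,
        lambda t: (fixed, fvals), fext=fext, on_step=on_step, rtol=1e-8,
    )
    return {
        "mesh": mesh, "samples": samples, "settle": settlements,
        "cv": cv, "L": L, "sig0": sig0, "times": times, "Tend": Tend,
        "K": K, "G": G,
    }


class TestTerzaghiOracle:
    def test_pressure_profiles_within_2_percent(self, terzaghi_run):
        r = terzaghi_run
        for frac in (0.1, 0.4, 1.0):
            t = r["times"][np.argmin(np.abs(r["times"][:-2] - frac * r["Tend"]))]
            p_fe = r["samples"][t]
            p_ex = terzaghi_pressure(r["mesh"].nodes[:, 1], t, r["L"], r["cv"], r["sig0"])
            assert np.abs(p_fe - p_ex).max() < 0.02 * r["sig0"]

    def test_drained_boundary_at_ambient_pressure(self, terzaghi_run):
        top = terzaghi_run["mesh"].boundary_nodes("platen_top")
        for P in terzaghi_run["samples"].values():
            assert np.allclose(P[top], 0.0, atol=1e-12)

    def test_final_drained_settlement(self, terzaghi_run):
        r = terzaghi_run
        M = r["K"] + 4 * r["G"] / 3
        assert r["settle"][-1][1] == pytest.approx(-r["sig0"] * r["L"] / M, rel=1e-3)

    def test_flux_vanishes_at_equilibrium(self, terzaghi_run):
        # settlement rate equals the net boundary outflow per unit area
        s = terzaghi_run["settle"]
        rates = [
            abs((s[i][1] - s[i - 1][1]) / (s[i][0] - s[i - 1][0]))
            for i in range(1, len(s))
        ]
        assert rates[-1] < 1e-8 * max(rates)


class TestUnconfinedStripOracle:
    def test_centerline_pressure_matches_series(self, ref_params):
        # plane-strain strip under a step axial strain, drained laterally;
        # the lateral-strain diffusion has an exact cosine-series solution
        K, G = bulk_shear_moduli(ref_params.E_nf, ref_params.nu_nf)
        lam = K - 2 * G / 3
        M = lam + 2 * G
        cp = ref_params.k * M
        a = H = 1.0
        eps0 = 1e-3
        mesh = build_explant_mesh(radius=a, thickness=H, target_h=0.1,
                                  formulation="plane_strain")
        comp = build_composition(mesh, fcd_scale=0.0, rho_z_scale=0.0)
        fe = BiphasicFE(mesh, comp, ref_params)
        top = mesh.boundary_nodes("platen_top")
        lat = mesh.boundary_nodes("free_lateral")
        fixed = np.concatenate([
            2 * mesh.boundary_nodes("symmetry_axis"),
            2 * mesh.boundary_nodes("bottom") + 1,
            2 * top + 1,
            2 * fe.n_nodes + lat,
        ])
        nb = fixed.size - top.size - lat.size
        vals = np.concatenate(
            [np.zeros(nb), -eps0 * H * np.ones(top.size), np.zeros(lat.size)]
        )
        tstar = 0.05 * a * a / cp
        times = np.concatenate([np.geomspace(tstar / 100, tstar, 30), [4 * tstar]])
        rec = {}
        fe.solve_transient(
            np.zeros((fe.n_nodes, 2)), np.zeros(fe.n_nodes), times,
            lambda t: (fixed, vals), on_step=lambda t, U, P, r, n: rec.update({t: P.copy()}),
        )

        def series_p(t, nterm=200):
            s = 0.0
            for n in range(nterm):
                Mn = (2 * n + 1) * np.pi / (2 * a)
                s += (4 * (-1) ** n / ((2 * n + 1) * np.pi)) * np.exp(-Mn * Mn * cp * t)
            e_inf = lam / M * eps0
            ex = e_inf + (eps0 - e_inf) * s
            return M * ex - lam * eps0

        centerline = np.where(np.isclose(mesh.nodes[:, 0], 0.0))[0]
        for t in (tstar, 4 * tstar):
            p_fe = rec[t][centerline].mean()
            assert p_fe == pytest.approx(series_p(t), rel=0.05)
        # peak centerline pressure approximates the undrained value 2*G*eps0
        peak = max(P[centerline].mean() for P in rec.values())
        assert peak == pytest.approx(2 * G * eps0, rel=0.05)


class TestDynamicCycles:
    def test_zero_amplitude_static_hold(self, ref_params):
        mesh = build_explant_mesh(target_h=0.3)
        comp = build_composition(mesh)
        fe = BiphasicFE(mesh, comp, ref_params)
        U_sw = fe.solve_free_swelling()
        hist = fe.solve_dynamic_cycles(
            U_sw, LoadingProtocol(amplitude=0.0, n_cycles=2, dt=0.05)
        )
        assert hist.v_fl_max.max() < 1e-6
        assert hist.eps_shr_max.max() < 0.05  # only the residual swelling strain

    def test_force_is_compressive_and_periodic_peaks_decay(self, intact_dynamic):
        hist = intact_dynamic["hist"]
        n = 20
        peaks = [hist.platen_force[i * n:(i + 1) * n].max() for i in range(2)]
        assert peaks[0] > 0
        assert peaks[1] < peaks[0]
        # consolidation makes peaks drift a few percent per early cycle; the
        # drift must already be moderate by the second cycle
        assert hist.peak_drift < 0.06

    def test_cycle_maxima_nonnegative(self, intact_dynamic):
        hist = intact_dynamic["hist"]
        assert np.all(hist.eps_dev_max >= 0)
        assert np.all(hist.eps_shr_max >= 0)
        assert np.all(hist.v_fl_max >= 0)

    def test_intact_peak_fluid_velocity_on_free_lateral_boundary(
        self, intact_dynamic, intact_mesh
    ):
        v = intact_dynamic["hist"].v_fl_max
        gc = intact_mesh.gauss_coords()
        i = np.unravel_index(np.argmax(v), v.shape)
        assert gc[i][0] > 0.8 * intact_mesh.radius

    def test_crack_creates_local_fluid_velocity_maximum(
        self, cracked_dynamic, cracked_mesh
    ):
        from cartidegen.degeneration import distance_to_lesion

        v = cracked_dynamic["hist"].v_fl_max
        d = distance_to_lesion(cracked_mesh)
        near = v[d < 0.15]
        far = v[d > 0.5]
        assert near.max() > far.max()

    def test_pressure_ambient_on_draining_boundaries(self, cracked_dynamic, cracked_mesh):
        P = cracked_dynamic["hist"].P
        drain = cracked_mesh.boundary_nodes("free_lateral", "lesion_surface")
        assert np.allclose(P[drain], 0.0, atol=1e-12)


class TestSpatialConvergence:
    def test_probe_eps_dev_stable_under_refinement(self, ref_params):
        # interior probe point at mid-radius, mid-depth
        protocol = LoadingProtocol(n_cycles=1, dt=0.05)

        def metric(mesh):
            comp = build_composition(mesh)
            fe = BiphasicFE(mesh, comp, ref_params)
            hist = fe.solve_dynamic_cycles(fe.solve_free_swelling(), protocol)
            gc = mesh.gauss_coords().reshape(-1, 2)
            i = np.argmin(np.linalg.norm(gc - np.array([0.75, 0.5]), axis=1))
            return hist.eps_dev_max.ravel()[i]

        mesh, value, history = converge_mesh(
            lambda h: build_explant_mesh(target_h=h), metric,
            target_h0=0.25, rtol=0.02, max_levels=2,
        )
        assert abs(history[-1] - history[-2]) <= 0.02 * abs(history[-1])


class TestHelpers:
    def test_edge_traction_total_force(self, intact_mesh):
        f = edge_traction_forces(intact_mesh, "platen_top", [0.0, -2.0])
        top = intact_mesh.boundary_nodes("platen_top")
        total = f[2 * top + 1].sum()
        assert total == pytest.approx(-2.0 * intact_mesh.radius, rel=1e-12)

    def test_converge_mesh_returns_on_constant_metric(self):
        mesh, value, history = converge_mesh(
            lambda h: build_explant_mesh(target_h=h),
            lambda m: 1.0, target_h0=0.3,
        )
        assert value == 1.0
        assert len(history) == 2
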