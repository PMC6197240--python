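"""Shared fixtures; the expensive FE solves are session-scoped and reused."""

from __future__ import annotations

import numpy as np
import pytest

from cartidegen.degeneration import DegenerationConfig, run_degeneration_loop
from cartidegen.fem import BiphasicFE, LoadingProtocol
from cartidegen.geometry import CrackSpec, build_composition, build_explant_mesh
from cartidegen.materials import MaterialParams


@pytest.fixture(scope="session")
def ref_params() -> MaterialParams:
    return MaterialParams()


@pytest.fixture(scope="session")
def fast_protocol() -> LoadingProtocol:
    """2 cycles at 20 steps/cycle: the workhorse protocol for the test suite."""
    return LoadingProtocol(n_cycles=2, dt=0.05)


@pytest.fixture(scope="session")
def intact_mesh():
    return build_explant_mesh(radius=1.5, thickness=1.0, target_h=0.15)


@pytest.fixture(scope="session")
def cracked_mesh():
    return build_explant_mesh(
        radius=1.5, thickness=1.0,
        cracks=[CrackSpec(mouth_position=0.75, depth=0.4, opening_width=0.06)],
        target_h=0.15, refine_h=0.03,
    )


@pytest.fixture(scope="session")
def intact_dynamic(intact_mesh, ref_params, fast_protocol):
    """Swelling + cyclic compression of the intact explant (shared solve)."""
    comp = build_composition(intact_mesh)
    fe = BiphasicFE(intact_mesh, comp, ref_params)
    U_sw = fe.solve_free_swelling()
    hist = fe.solve_dynamic_cycles(U_sw, fast_protocol)
    return {"fe": fe, "U_sw": U_sw, "hist": hist, "comp": comp}


@pytest.fixture(scope="session")
def cracked_dynamic(cracked_mesh, ref_params, fast_protocol):
    """Swelling + cyclic compression of the cracked explant (shared solve)."""
    comp = build_composition(cracked_mesh)
    fe = BiphasicFE(cracked_mesh, comp, ref_params)
    U_sw = fe.solve_free_swelling()
    hist = fe.solve_dynamic_cycles(U_sw, fast_protocol)
    return {"fe": fe, "U_sw": U_sw, "hist": hist, "comp": comp}


@pytest.fixture(scope="session")
def cracked_loop(cracked_mesh, ref_params, fast_protocol):
    """Five fluid-velocity degeneration iterations on the cracked explant."""
    comp = build_composition(cracked_mesh)
    cfg = DegenerationConfig(mechanism="fluid_velocity", n_iterations=5)
    hist = run_degeneration_loop(cracked_mesh, comp, ref_params, fast_protocol, cfg)
    assert hist.failure is None, hist.failure
    return {"hist": hist, "config": cfg}


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
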