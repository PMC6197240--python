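# cartidegen

A mechanobiological simulator of proteoglycan (fixed charge density, FCD)
loss around cartilage lesions under cyclic compression.

The package combines

* a **fibril-reinforced porohyperelastic swelling material**: compressible
  neo-Hookean ground substance, tension-only primary/secondary collagen
  fibrils, Donnan osmotic swelling and optional chemical expansion stress;
* a small **2D biphasic (u–p) finite-element solver** (4-node quads,
  equal-order displacement/pressure with polynomial-pressure-projection
  stabilization, total-Lagrangian Newton with finite-difference element
  tangents), in axisymmetric (default) or plane-strain form;
* a parametric **explant geometry** (3-mm-diameter, 1-mm-thick disk half
  cross-section) with surface-breaking crack seams and depth-wise
  composition profiles (fluid fraction, FCD, collagen density, arcade
  fibril architecture);
* an **adaptive degeneration loop**: free swelling → cyclic unconfined
  compression (haversine, 15 %, 1 Hz) → per-point cycle maxima of
  deviatoric strain, maximum shear strain and fluid velocity → a
  piecewise-constant degeneration rate (0 below threshold, 0.6 up to the
  failure value) → multiplicative FCD depletion, iterated up to 50 times;
* **calibration** of (E_f, E_nf, k) to unconfined stress-relaxation force
  records by Nelder–Mead minimization of the normalized mean squared error,
  plus a synthetic-record generator for recovery testing.

Units: mm, N, s, MPa; concentrations in mEq/ml.

## CLI

The console script `cartidegen` has five subcommands:

```bash
cartidegen mesh --config run.yaml --out mesh.vtk     # geometry + composition
cartidegen run --config run.yaml                     # full degeneration study
cartidegen sweep sweep.yaml --config run.yaml        # parametric analysis
cartidegen calibrate record.csv --out fit.json       # inverse fit of E_f, E_nf, k
cartidegen fixtures --out-dir fixtures --seed 0      # synthetic input data
```

A run writes, under `output_dir`: `iteration_log.csv`, `force_history.csv`
(platen reaction of the final iteration), `summary.json` (with a provenance
block: config hash, code version, formulation, seed), `config_used.yaml`,
legacy-VTK field snapshots and a PNG map of the relative FCD decrease.

Minimal configuration for a cracked explant (YAML, all keys optional):

```yaml
geometry:
  target_h: 0.15
  refine_h: 0.03           # cluster elements at crack mouths and surface
  cracks:
    - {mouth_position: 0.75, depth: 0.4, opening_width: 0.06}
degeneration:
  mechanism: fluid_velocity   # or deviatoric_strain / max_shear_strain
  n_iterations: 50
output_dir: out/cracked
```

## Library entry points

```python
from cartidegen import (
    MaterialParams, build_explant_mesh, build_composition,
    BiphasicFE, LoadingProtocol, DegenerationConfig, run_degeneration_loop,
)

mesh = build_explant_mesh(cracks=[], target_h=0.15)
comp = build_composition(mesh)
fe = BiphasicFE(mesh, comp, MaterialParams())
U = fe.solve_free_swelling()
history = fe.solve_dynamic_cycles(U, LoadingProtocol(n_cycles=2, dt=0.05))
```
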