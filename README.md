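# cardionet

An orientation-weighted **network model of cardiac electrical conduction**
on structured grids, with a matched finite-difference monodomain reference
solver and activation-map analysis tools.

## The problem

Cardiac arrhythmias are driven to a large degree by *structural*
remodelling: fibrosis, fatty infiltration and heterogeneous connexin
expression interrupt the electrical coupling between myocytes, slow
conduction locally, and create the substrate for conduction block and
re-entry. Standard tissue-scale solvers (finite differences / finite
elements) discretise a *continuous* reaction–diffusion description, which
makes it awkward to represent the loss of *individual* intercellular
connections. This package is for computational electrophysiologists who
want to simulate excitation on image-based structured-grid geometries
while manipulating inter-nodal connections directly — removing a given
fraction of along-fibre (axial) vs cross-fibre (transverse) connections,
scaling individual junction conductances, or both.

## The model

Tissue is a square/cuboid lattice of excitable nodes. Each node *i*
evolves as

    dV_i/dt = Σ_n I_gap^(i,n) − I_ion_i,

where the sum runs over the node's gap junctions (up to 8 in 2D, 26 in
3D), the junction current is ohmic, `I_gap^n = g_gap^n (V+ − V−)`, and all
currents are per-capacitance (mV/ms; conductances in nS/pF). The junction
conductance is the mean of the two nodal directional conductances, e.g.
along x in 2D:

    g_xx^node = (1/Δx) (g_a · W_xx + g_t · W_xx^t),     g_gap = (g_xx^i + g_xx^j)/2.

The weights `W` distribute each node's axial conductance `g_a` (along the
local myocyte orientation) and transverse conductance `g_t` (orthogonal to
it) over the 4 (2D) / 13 (3D) independent lattice directions. The
weighting is linear in the in-plane angles: an orientation exactly along
an axis or diagonal puts all its weight there (`W_axis = |(θ−π/4)/(π/4)|`,
`W_diag = 1 − W_axis`), and binary *pointing parameters* (`P_x = 1` iff
`x² ≥ y²`, `P_xy+ = 1` iff `xy ≥ 0`, …) select the segment/quadrant that
contains the vector. Per vector, at most 2 (2D) / 4 (3D) directions get
non-zero weight and the weights sum to 1.

Key consequences:

- **No-flux boundaries for free** — junctions only form between tissue
  nodes, so there are no boundary terms to special-case.
- **Exact current conservation** — junction currents enter their two
  endpoint nodes antisymmetrically.
- **Direct substrate manipulation** — junctions are classified axial /
  transverse / mixed and can be removed per class with chosen
  probabilities, or scaled by sampled factors, without making any node
  unexcitable.
- **FDM interoperability** — `g_a = D1/Δx`, `g_t = D2/Δx` matches the
  conduction velocities of a monodomain finite-difference solver with
  diffusion coefficients `D1, D2`, so existing FDM parameterisations
  carry over.

Membrane kinetics are pluggable; the bundled default is a Mitchell–
Schaeffer two-variable model mapped to a physiological voltage range
(rest −85 mV, peak ≈ +15 mV, APD90 ≈ 230 ms). The integration scheme is
forward Euler throughout.

## Worked example

An anisotropic wave from a focal stimulus on a 25 × 25 mm sheet with
fibres along x, parameters converted from monodomain diffusion
coefficients:

```python
import numpy as np
from cardionet import (StructuredGrid, generate_idealised_field,
                       CouplingParameters, diffusion_to_conductance,
                       focal_stimulus, run_simulation)
from cardionet.analysis import conduction_velocity

grid = StructuredGrid((101, 101), (0.25, 0.25))        # 25 x 25 mm sheet
fld = generate_idealised_field(grid, (1, 0))           # fibres along x
g_a, g_t = diffusion_to_conductance(D1=0.4, D2=0.1, dx=0.25)
res = run_simulation(grid=grid, fld=fld,
                     params=CouplingParameters(g_a=g_a, g_t1=g_t),
                     protocol=focal_stimulus(grid, radius=3, amplitude=40.0),
                     dt=0.02, duration=60.0)

along = np.arange(62, 91)
fixed = np.full_like(along, 50)
tr_x = grid.full_to_tissue[grid.linear_index(along, fixed)]
tr_y = grid.full_to_tissue[grid.linear_index(fixed, along)]
cv_x = conduction_velocity(res.activation, tr_x)
cv_y = conduction_velocity(res.activation, tr_y)
print(f"g_a = {g_a:.1f} nS/pF, g_t = {g_t:.1f} nS/pF")
print(f"axial CV      = {cv_x:.3f} mm/ms")
print(f"transverse CV = {cv_y:.3f} mm/ms")
print(f"CV ratio      = {cv_x / cv_y:.2f}  (sqrt(g_a/g_t) = 2.00)")
print(f"total activation time = {res.activation.total_activation_time:.1f} ms")
```

Output:

```
g_a = 1.6 nS/pF, g_t = 0.4 nS/pF
axial CV      = 0.624 mm/ms
transverse CV = 0.320 mm/ms
CV ratio      = 1.95  (sqrt(g_a/g_t) = 2.00)
total activation time = 42.4 ms
```

The elliptical wavefront's axis ratio tracks `sqrt(g_a/g_t)` — a 4:1
conductance anisotropy gives ~2:1 conduction-velocity anisotropy. To
remodel the substrate, pass a `HeterogeneitySpec` (e.g.
`HeterogeneitySpec(p_remove_axial=0.2, p_remove_transverse=0.8, seed=5)`)
to `run_simulation`; with heavy transverse removal the wavefront becomes
ragged and conduction block appears, which a *global* conductance
reduction does not reproduce.

## Command line

A thin CLI mirrors the library for config-driven runs:

```bash
cardionet build-network --config run.yaml --out-dir net/   # junction table + VTK maps
cardionet simulate      --config run.yaml --out-dir sim/   # voltage snapshots + activation map
cardionet simulate      --config run.yaml --method fdm --out-dir sim_fdm/
cardionet analyse       --config run.yaml --activation sim/activation.txt
```

See `tests/test_cli.py` for a complete YAML config.

## Acceptance script

`scripts/acceptance.py` recomputes the time-step convergence of the
planar-wave conduction velocity from scratch: it simulates a paced planar
wave on a homogeneous 100×100 sheet (Δx = 0.25 mm, g_a = 1.6, g_t = 0.4
nS/pF) at Δt = 0.05, 0.01, 0.005 and 0.001 ms, measures CV along an
interior axial transect, and writes the relative CV differences (percent)
between the coarse and the fine Δt pairs to JSON:

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

| module | contents |
| --- | --- |
| `cardionet.grid` | `StructuredGrid`, `OrientationField`, synthetic field generators, text/HDF5 I/O |
| `cardionet.weights` | angle weights, pointing parameters, 2D/3D direction weights, transverse-triad construction |
| `cardionet.network` | nodal conductances, junction assembly, classification, D→g conversion |
| `cardionet.heterogeneity` | per-class removal, junction scaling, nodal scale maps |
| `cardionet.cells` | cell-model interface, Mitchell–Schaeffer and passive membranes |
| `cardionet.simulate` | junction currents, tissue stepping, full simulation driver |
| `cardionet.fdm` | anisotropic monodomain FDM reference and solver comparison |
| `cardionet.analysis` | activation maps, conduction velocity, map differences |
| `cardionet.protocols` | planar-wave CV benchmark / convergence study |
| `cardionet.vtkio`, `cardionet.config`, `cardionet.cli` | VTK export, YAML config, CLI |

See `docs/methods.md` for the modelling assumptions, parameter defaults
and known numerical artifacts.
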