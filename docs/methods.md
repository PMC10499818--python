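# Methods

This note documents the model, the numerical choices, the defaults and
their rationale, and the known limitations of the implementation. It
states nothing the test suite or the acceptance script does not itself
compute.

## 1. The network formulation

The monodomain reaction–diffusion equation is replaced by an explicitly
discrete statement: every tissue node is an excitable unit, and spatial
coupling is a sum of ohmic currents over explicit inter-nodal junctions,

    dV_i/dt = Σ_n I_gap^(i,n) − I_ion_i,
    I_gap^n = g_gap^n (V^{+} − V^{−}),

with the positive/negative endpoint of each junction fixed at build time
(positive = lower linear node index; the choice is arbitrary and tested
to be immaterial, since the two endpoint contributions are `−I` and
`+I`). Membrane capacitance is absorbed into the conductance units
(nS/pF), so all currents are in mV/ms. An alternative absolute-conductance
convention (nS with an explicit 1/C_m) would only rescale `g`.

Junctions exist only between pairs of *tissue* nodes adjacent in one of
the independent lattice directions — 4 in 2D (x, y, two diagonals), 13 in
3D (3 axes, 6 plane diagonals, 4 corners). Because non-tissue nodes never
acquire junctions, no-flux boundary conditions hold by construction and
the solver contains no boundary-specific code; this is verified by
simulating disconnected tissue regions (no leakage, isolated regions
require their own stimulus).

### Orientation weighting

Each node carries a unit myocyte-orientation vector (plus sheet and
sheet-normal vectors in 3D, given or constructed). Its axial conductance
`g_a` is distributed over the lattice directions by weights that are
linear in the in-plane angles:

- angle to the nearer axis in a coordinate plane: `θ = arcsin(|b|/√(a²+b²))`;
- axis weight `W_axis = |(θ − π/4)/(π/4)|`, diagonal weight `1 − W_axis`;
- binary pointing parameters (`P_x = 1` iff `x² ≥ y²` [and `≥ z²` in 3D],
  `P_xy+ = 1` iff `xy ≥ 0`, …) select which axis/diagonal (2D segment) or
  axis/two-diagonals/corner (3D quadrant) receives the weight. In 3D the
  quadrant weights are products of two plane-angle weights, with the
  convention that when the vector points primarily toward z the xz
  diagonal counts as "in-plane" and yz as "elevation".

Per vector the weights are a partition of unity with at most 2 (2D) / 4
(3D) non-zero entries (property-tested to 1e-12 over 1e5 random unit
vectors, plus invariance under all 8 / 48 signed axis permutations). The
transverse conductance(s) are distributed the same way using the
transverse vector(s): in 2D this reduces to the axial formulae with all
pointing parameters swapped; in 3D, if only the primary orientation is
available, transverse vector 1 is the primary rotated π/2 toward +z in
the (vector, z) plane and transverse vector 2 is their cross product
(always in the x–y plane). For a vector parallel to z the rotation plane
is degenerate and t1 = (1,0,0) by convention — immaterial when
g_t1 = g_t2, which is also the default when no sheet data distinguish the
two transverse directions.

Tie-breaking: all pointing inequalities follow "≥" exactly with no
tolerance band (the competing weights vanish at ties, so the branch taken
does not affect conductances). In 3D, exactly one of P_x/P_y/P_z must be
1; ties use the fixed priority x > y > z. Degenerate plane angles (both
components zero) are defined as 0; the pointing parameters zero out any
term this could wrongly enable.

### Nodal and junctional conductances

Per direction, the nodal conductance is

    g_e^node = pref(e) · (g_a·W_e + g_t1·W_e^t1 + g_t2·W_e^t2),

with geometric prefactors `1/Δx` (axes), `1/√(Δx²+Δy²)` (plane
diagonals), `1/√(Δx²+Δy²+Δz²)` (corners), supporting anisotropic spacing.
A spacing-free mode replaces these by 1, 1/√2, 1/√3 — the relative
diagonal factors must be kept for geometric consistency. The junction
conductance is the plain mean of its two nodal values regardless of
connection class (the fully-axial / fully-transverse alternatives for
mixed junctions are a recognised open modelling choice; only the average
is implemented). A junction with one zero-contributing side still forms,
carrying half the other side's conductance.

Coupling parameters can be specified directly or converted from
monodomain diffusion coefficients, `g_a = D1/Δx`, `g_t = D2/Δx` (or
`g_t = g_a/AR`). With this conversion the network model and the FDM
reference produce the *same* conduction velocity for homogeneous
axis-aligned fibres — along a lattice axis the two discretisations are
algebraically identical.

## 2. Heterogeneous media

Junctions are classified at build time: **axial** if every non-zero
contribution (both sides) comes from the primary vector, **transverse**
if every one comes from a transverse vector, **mixed** otherwise (for
example at an abrupt fibre rotation, where one node's axial conductance
couples to its neighbour's transverse). A side contributing nothing
defers to the other side; contributions below 1e-9 of the largest nodal
conductance are treated as zero (arcsin rounding leaves O(1e-16) residues
at exact diagonals).

Remodelling operations:

- **Removal** — each junction is deactivated independently with the
  probability assigned to its class. Mixed junctions get their own
  probability (default: mean of the axial and transverse ones, since no
  canonical value exists). Removal toggles an `active` flag — tissue
  nodes remain excitable, maps can be exported and toggled, and inactive
  junctions carry exactly zero current.
- **Continuous scaling** — per-junction factors drawn i.i.d. from a named
  distribution (constant, uniform, lognormal, gamma); parameterisations
  that could produce negative factors are rejected at validation.
- **Nodal scale maps** — per-node factors applied to the directional
  conductances *before* junction averaging, reproducing the FDM-style
  "scale local g_a/g_t" workflow.

Random-number contract: one uniform per junction, consumed in junction-id
order, from numpy's counter-based Philox generator keyed by the user seed
(removal and scaling use separate sub-streams). Connection maps are
therefore bit-reproducible from (network, spec, seed).

## 3. Cell model

The solvers only require a small interface (resting state, I_ion,
forward-Euler step over arrays), so detailed ionic models can be dropped
in. The bundled model is the Mitchell–Schaeffer two-variable excitable
model on a physical voltage scale:

| parameter | value | meaning |
| --- | --- | --- |
| τ_in | 0.3 ms | upstroke time scale (sets CV with the coupling) |
| τ_out | 6 ms | early repolarisation |
| τ_open | 120 ms | gate recovery (refractoriness) |
| τ_close | 120 ms | gate inactivation; APD90 ≈ 230 ms |
| u_gate | 0.13 | gate switching threshold |
| V_rest, amplitude | −85 mV, 105 mV | voltage scale (peak ≈ +15 mV) |

All parameters are the model's standard set except τ_close, shortened
from 150 ms so the APD falls in the ventricular 150–250 ms range.
Measured behaviour (test suite): diastolic threshold ≈ 2.9 mV/ms for a
2 ms pulse in an isolated cell and ≈ 10.6 mV/ms for a 3-node edge slab in
well-coupled tissue; the default stimulus is 22 mV/ms for 2 ms (≈ 2×
tissue threshold). Default planar CV with g_a = 1.6 nS/pF at Δx = 0.25 mm
is ≈ 0.68 mm/ms.

This model is a *stand-in* with the qualitative features tissue dynamics
need (threshold, upstroke, plateau, refractoriness); it is not a
biophysical ionic model, so all kinetics-dependent verification is
phrased as self-convergence or relative comparison, never as absolute CV
or APD targets.

## 4. Numerics

- **Integration**: forward Euler for voltage and gates, chosen for
  comparability between the two solvers and with the convergence claims;
  no Rush–Larsen or operator splitting.
- **Convergence**: planar-wave CV error is first order in Δt. Measured on
  the homogeneous 100×100 sheet: 1.13% relative CV change between
  Δt = 0.05 and 0.01 ms, 0.115% between 0.005 and 0.001 ms — the ratio of
  the two equals the ratio of the Δt intervals (10×), as first-order
  theory requires. Note a *pair* of bands like "<1% and <0.01%" for these
  two Δt intervals cannot both hold for any first-order scheme unless the
  CV readout quantises below the finer difference; our activation times
  are interpolated between steps, so the measurement resolves it.
- **Stability**: the bundled model integrates stably at Δt ≤ 0.05 ms for
  the default coupling; the explicit FDM solver additionally requires
  Δt ≲ Δx²/(2·trace(D)).
- **Activation maps**: first upward crossing of −20 mV (≈ mid-upstroke),
  linearly interpolated between consecutive steps (or snapshot samples);
  never-activated nodes carry NaN. The threshold is configurable.
- **CV measurement**: endpoint activation-time difference along interior
  transects, excluding ≥10 nodes nearest stimulus and boundary to avoid
  wave-foot curvature and boundary effects.
- **Conservation**: coupling currents cancel pairwise; with I_ion = 0 the
  total voltage drifts by < 1e-9 (relative) over 1e4 steps on a randomly
  remodelled network (the residual is float summation noise, not a
  scheme error).
- **Precision**: all state is float64; snapshots are stored float32.

### FDM reference

The comparison solver discretises `∂V/∂t = ∇·(D∇V) − I_ion` with a
flux-form central-difference stencil (9-point in 2D, 19-point in 3D):
face fluxes use arithmetically averaged tensor entries and exact face
differences for the diagonal terms, with mask-aware (one-sided at tissue
edges) central derivatives for the cross terms; fluxes across faces
touching non-tissue are zero. `D = D2·I + (D1−D2)ffᵀ` from the fibre
field (plus a sheet term when sheet data and D3 are given). The tensor is
positive semidefinite by construction for D1 ≥ D2 ≥ D3 ≥ 0. Both solvers
share the grid, cell-model, stimulus and activation-recording code, so a
comparison isolates the spatial coupling scheme. Comparison metrics are
total activation time and CV along transects, not pointwise pattern
identity.

## 5. Synthetic data

The package generates all of its own inputs:

- **Idealised fields** — a global orientation (axis, diagonal, arbitrary).
- **Ramp** — fibre angle linear across one axis (start/end configurable).
- **Circular** — rotor-like tangential field about a centre.
- **Smoothed random** — i.i.d. Gaussian components smoothed with a
  Gaussian kernel (σ = 4 nodes by default) and renormalised; this is the
  stand-in for realistic spatially varying fibre maps whenever a
  disordered field is needed (the heterogeneous-conduction experiments),
  since no specific measured field is distributed with the package.

What these emulate — smooth orientation variation at a correlation length
of a few nodes — and what they do not: real DTI-derived fields have
laminar sheet structure, transmural rotation statistics and imaging
noise; a green test on synthetic fields establishes the discretisation
behaves correctly, not that any specific physiological conduction pattern
is reproduced. Likewise the removal probabilities used in demonstrations
(e.g. 20% axial / 80% transverse) demonstrate the mechanism and are not
physiologically validated disease parameterisations.

## 6. Known artifacts and limitations

- **Lattice diagonal anisotropy**: with the geometric 1/√2 factor, a wave
  along a diagonally oriented fibre field propagates node-to-node more
  slowly than along an axis-aligned one (measured hop-time ratio ≈ 1.25,
  physical CV ratio ≈ 1.13 under default parameters). Exact-diagonal
  conduction patterns are therefore *not* rotated copies of axis-aligned
  ones. This is inherent to weighting a fixed lattice neighbourhood and
  is shared in kind (not detail) by FDM cross-term stencils.
- **Junction conductance is static**: no voltage- or time-dependent
  gap-junction gating (the interface exposes per-junction conductance, so
  such models can be layered on).
- **Coupling strength is resolution-dependent**: as in any tissue-scale
  discretisation, `g` must be re-derived when Δx changes (the D/Δx
  conversion does this for CV matching).
- **Mixed-junction averaging** is one of several defensible choices; only
  the average is implemented.
- **Node ≠ myocyte**: a node aggregates many cells, so "connection
  removal" models meso-scale conduction barriers, not individual cell
  uncoupling.
- The FDM cross-derivative treatment at irregular tissue boundaries is
  first-order accurate; comparisons in strongly irregular geometries
  should weigh both solvers' errors.
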