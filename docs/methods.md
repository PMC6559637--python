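# Methods

## Model

The package computes steady-state soluble oxygen in the outer retina as a
diffusion problem with zero-order consumption confined to the photoreceptor
inner segments (IS). The modeling assumptions are:

1. oxygen consumption occurs only in the IS, at a constant volumetric rate
   Q (dark-adapted, the worst case) wherever oxygen is available;
2. transport in tissue is Fickian diffusion with a single diffusivity D for
   every domain — BrM, drusen, RPE, outer segments, IS, ONL+OPL — since no
   measured druse-specific diffusivity exists;
3. the choriocapillaris is a fixed-concentration boundary at the basal BrM
   face (it is perfused fast enough that its oxygen drop is ~1%);
4. the deep retinal capillary plexus delivers a constant areal influx J_ret
   at the apical OPL face (flow-regulated);
5. retinal curvature is negligible at the ~100 μm length scale of oxygen
   diffusion, so geometry is flat or gently undulating.

Only soluble oxygen is modeled (no hemoglobin/neuroglobin binding) and the
concentration↔pO₂ conversion is linear (Henry's law), anchored at
0.1107 mol/m³ ↔ 80 mmHg; no temperature dependence.

Zero-order consumption makes the unconstrained steady state negative
wherever demand exceeds supply, which is unphysical. Non-negativity is
enforced as the obstacle-problem complementarity condition: either c > 0
and the full sink Q applies, or c = 0 and the effective sink equals the
local diffusive supply (between 0 and Q). The solver realizes this with a
primal–dual active-set loop: solve, clamp cells driven negative (removing
their sink), reactivate clamped cells whose supply exceeds their
consumption capacity, repeat until both sets are stable (typically 2–5
iterations; an iteration cap of 50 guards against cycling).

## Parameters

| symbol | default | units | meaning |
|---|---|---|---|
| D | 1.97e-9 | m²/s | oxygen diffusivity, all tissue |
| Q | 0.148 | mol/(m³·s) | dark-adapted IS consumption |
| c_chor | 0.1107 | mol/m³ | choroid boundary concentration (80 mmHg) |
| J_ret | 5.05e-7 | mol/(m²·s) | deep-plexus influx at the OPL face |
| h_sub-IS | 55 | μm | BrM + RPE + OS combined thickness |
| h_IS | 25 | μm | IS thickness (also the pipeline IS maximum) |
| h_ONL+OPL | 45 | μm | combined ONL + OPL thickness |
| α | 0.1107/80 | mol/(m³·mmHg) | solubility constant |

J_ret deserves comment: it is not directly measurable and published values
are calibrations. With the default above, the deep plexus supplies
J_ret/(Q·h_IS) = 13.65% of IS demand — inside the physiological 10–15%
range — and the druse-free laminar minimum is 2.89 mmHg, at the low end of
dark-adapted outer-retina minima (experimental microelectrode profiles in
cat are commonly quoted as a few mmHg, with ~4 mmHg a typical figure).
Every anoxia threshold below depends sensitively on this reserve: raising
J_ret by 8% (to 5.45e-7) raises the laminar minimum to 4.0 mmHg and roughly
doubles some onset diameters. The package deliberately ships the literature
default unmodified and reports what it computes; users calibrating against
their own oximetry should override `retinal_flux` in the config.

## Discretization and solvers

Cell-centered finite volumes on structured grids, which make the discrete
flux audit exact: every converged solve balances choroid influx + retinal
influx against total consumption to roundoff (`mass_balance`).

* **Axisymmetric (r, z)** for generic single-druse studies (a hemisphere or
  on-axis cylinder is rotationally symmetric). Default spacing 1 μm in z
  and r. The full rectangular grid (identity rows outside tissue) keeps the
  matrix uniformly banded and SPD; it is solved with LAPACK's banded
  Cholesky, ordering the smaller dimension innermost. For very wide probe
  geometries the radial spacing coarsens as dr = max(dz, d/300), so
  diameters under 300 μm — the whole threshold regime — always run at 1 μm.
  Lateral extent is max(5 × diameter, 300 μm) with a zero-flux wall;
  far-field flatness makes results insensitive to further widening.
* **3D** for surface-stack geometry: 10–50 μm lateral spacing (set by the
  raster), 2 μm axial default. The cell aspect ratio makes vertical
  conductance ~100× lateral, so the SPD system is solved by conjugate
  gradients preconditioned with a z-line (tridiagonal) solve — essentially
  exact for this anisotropy (relative residuals ~1e-12, deterministic).

Dirichlet values are imposed on the basal face of each column's bottom
cell (half-cell distance); the Neumann influx on the apical face of each
column's top tissue cell, i.e. per area of the actual (possibly deformed)
apical surface. Convergence: halving the grid reduces the error against
the 1D closed form consistent with the scheme's second order (0.24% →
0.06% maximum relative error at 1 → 0.5 μm).

The druse-free laminar case has a piecewise closed form (linear in passive
slabs, quadratic in the IS) used as an independent oracle, including an
extra-passive-path variant that bounds what an infinitely wide druse can
do.

## Druse studies

Drusen are inserted on top of BrM; every boundary above is displaced
vertically by the local druse height, preserving layer thicknesses (the
simplest kinematics consistent with cross-sectional imaging; rim smoothing
is not modeled and could shift thresholds by a few μm). The generic model
books the merged 55 μm BrM+RPE+OS slab as a 4 μm BrM band plus a 51 μm
RPE+OS band so the druse has a defined seat; all passive domains share D,
so this is bookkeeping only.

Anoxia criterion: minimum pO₂ in IS cells on the druse axis ≤ 0.5 mmHg.
The clamp attains exactly zero only on the deactivated set, and a small
positive floor makes thresholds robust to grid resolution; the phase-map
output reports approximate thresholds at alternative floors (0.1 and
1 mmHg) read off the probes collected during each search. Threshold
searches bisect on diameter to 1 μm, maintaining the bracket invariant
(lower endpoint non-anoxic, upper anoxic); monotone severity in diameter,
which underwrites bisection, is verified by sampling in the test suite.
Search bound: 2000 μm for cylinders; 256 μm for hemispheres (whose height
is diameter/2 — a 2000 μm hemisphere would be a 1 mm dome, far outside the
hard-druse regime, and the bound only needs to exceed the onset).

With the default parameters the computed onsets are: hemisphere 40 μm;
cylinders 109/48/37/35 μm at heights 5/10/15/20 μm; and no cylinder below
3 μm height can induce anoxia at any diameter up to 2000 μm (at 2 μm the
infinite-width limit is 0.54 mmHg, just above the floor). These values are
grid-converged; their absolute scale tracks the oxygen reserve set by
J_ret (see Parameters), while their ordering and the height–diameter
trade-off (lateral diffusion compensates narrow but not wide path
extensions) are robust.

## Patient-style pipeline

Inputs are six ordered boundary surfaces (BrM base, BrM top, druse top,
RPE+OS top, IS top, ONL+OPL top) per eye and time point, as ESRI ASCII
rasters plus a JSON manifest. Processing steps, in order:

1. **Registration**: exhaustive search (rotation ±3° in 0.25° steps about
   the window center; translation ±300 μm in whole pixels) maximizing the
   Pearson correlation of the two time points' BrM+druse thickness maps
   over ≥50% overlap; ties break toward the smallest rotation then
   translation. Optima with r < 0.5 are flagged low-confidence.
2. **Cropping**: 3000 × 3000 μm half-open window centered at the deepest
   foveal spot, defined as the unmasked minimum of the 5×5-median-smoothed
   total retinal thickness (robust to segmentation speckle).
3. **Flattening**: all surfaces re-based to the basal surface (z₀ ≡ 0);
   tissue above the 400 μm Z window is truncated (rare, logged).
4. **IS reconstruction**: OCT cannot resolve the IS boundary, so IS
   thickness is set to 25 μm × T/max(T) where T is the overlying ONL+OPL
   thickness.
5. **Solve and reduce**: 3D solve on the baseline geometry; pO₂ sampled at
   20 evenly spaced heights through each tissue column, area-averaged onto
   150 × 150 pixels, minimized over the samples. The per-column minimum is
   expected in the IS; violations are logged, not assumed away.
6. **Thinning**: Δ(ONL+OPL) = T₁ − T₀ on the registered grid, resampled to
   150 × 150 (negative = thinning).

Statistics: pooled Pearson r across eyes' 22,500-point maps (p from the t
transform, always carrying a non-independence caveat — within-eye points
are spatially autocorrelated and no correction is attempted); binned means
with SEM over oxygen classes with edges {10, 20, 30, 40} mmHg (only the
outer "<10" and ">40" classes are conventionally quoted; the interior
edges interpolate) or five equal-width drusen-height bins; one-way ANOVA
with Tukey HSD across bins (scipy/statsmodels).

## Synthetic cohort

The generator emulates segmented two-time-point eyes: a gently tilted,
undulating basal surface; spherical-cap drusen (height and diameter
independent, so the soft-druse regime is reachable) with log-normal
diameters (median 150 μm, σ = 0.4, height ratio 0.15), Poisson count
(mean 8) and bounded-overlap rejection sampling; a Gaussian foveal pit
(20 μm deep, 300 μm radius) carved from the ONL+OPL; IS set by the same
linear rule the pipeline uses; 6000 μm extent at 40 μm spacing. Follow-up
thinning is generated from the model's own minimum-pO₂ map:

Δ(x, y) = base − β·max(0, 10 mmHg − minO₂) + γ·h_druse + N(0, σ²)

with defaults β = 0.2 μm/mmHg, γ = 0 (no direct mechanical effect — the
hypothesis under test made generative), σ = 2 μm, followed by a known
misregistration (80, −40) μm and 0.5°. A solver-independent surrogate
(1D minimum with the druse height added to the passive path, laterally
smoothed) exists for pipeline tests that must not depend on the solver.
All draws descend from `default_rng([seed, eye_index])`, so cohorts are
bit-reproducible and partially regenerable.

What the generator does **not** emulate: OCT speckle and segmentation
error, eye-specific layer curvature statistics, wet-AMD conversion events,
drusen growth between time points. Passing pipeline tests therefore
demonstrate algorithmic fidelity (registration recovery, map co-location,
correlation recovery against generator truth), not clinical performance.

One subtlety: applying the misregistration rotation interpolates the
noisy follow-up surfaces, slightly smoothing the noise; the correlation
actually present in the generated stacks is therefore a little higher than
the one computed from the raw pre-misregistration Δ field. Pipeline
fidelity is accordingly judged against the thinning measured under exact
(generator-stored) alignment, which isolates registration and resampling
error.

## Problem sizes and determinism

Generic solves use 1 μm cells (≈40k–200k unknowns; fractions of a second
to a few seconds each); a full threshold search is ~10–15 solves. Cohort
runs use the default 40 μm rasters with 2 μm axial cells (≈300k unknowns
per eye, ~2 s). All solvers are deterministic: identical inputs and
settings give bit-identical fields and maps.

## Known limitations

* Zero-order consumption with a clamp, not Michaelis–Menten; dark-adapted
  only (light adaptation roughly halves Q and would shift every threshold).
* The choroid is a boundary condition, not a perfused domain; choroidal
  thinning or dropout is outside the model.
* Druse diffusivity equals tissue diffusivity; calcified or lipid-rich
  drusen likely differ.
* Absolute anoxia thresholds inherit the uncertainty of J_ret (see
  Parameters); relative and qualitative results are robust.
* Registration is rigid in-plane only; no deformable component.
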