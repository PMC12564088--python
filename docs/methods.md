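# Methods

## The model

Two volume-fraction fields evolve on a 3-D voxel grid covering a brain
domain: tumor cells N_t(x, t) and vasculature N_v(x, t). Both obey
reaction-diffusion dynamics with nonlinear cross-diffusion:

    dN_t/dt = div[ D_t ( (1 - N_v/θ) ∇N_t + (N_t/θ) ∇N_v ) ] + k_t N_t (1 - N_t/θ)
    dN_v/dt = div[ D_v ( (1 - N_t/θ) ∇N_v + (N_v/θ) ∇N_t ) ]
              + k_v N_v (1 - N_v/θ) d(x) - k_dv N_v (1 - d(x))

The shared carrying capacity θ(x, t) rises linearly with the local
vasculature from θ_min = 0.1 (no vascular support) to θ_max = 0.9716, which
is reached once N_v ≥ N_v,thresh = 0.022. Angiogenesis is gated to the
tumor rim and vessel regression to the core by the normalized
distance-to-periphery map d(x) ∈ [0, 1] (1 at the rim, 0 at the deepest
tumor voxel); the regression rate is k_dv = 0.125 /day. The interplay of
capacity, rim angiogenesis and core regression produces the necrotic-core
morphology: central vasculature dies, the local capacity collapses to
θ_min, and the tumor core decays while the rim keeps expanding.

Mechanical coupling: the tumor-cell gradient exerts a body force on the
tissue, which responds as a linear elastic isotropic material in
quasi-static equilibrium, div σ = λ_f ∇N_t, with Hooke's law
σ = λ tr(ε) I + 2 G ε. White matter is stiffer (G = 800 Pa) than gray
matter (466 Pa). The resulting von Mises stress suppresses both diffusion
coefficients exponentially, D = D_0 exp(-γ σ_vm).

Four parameters are global and calibrated: D_t0, D_v0 (mm²/day) and k_t,
k_v (1/day). The central virtual tumor carries (0.0263, 0.0100, 0.45,
0.25); twelve variants offset the proliferation pair and the diffusion pair
jointly by ±25/50/75%, labeled by quadrant (1: +/+, 2: +/-, 3: -/+,
4: -/-) and magnitude digit.

### Parameters not fixed by the model's sources

* **λ_f (force coupling): 2000 Pa per unit tumor fraction.** Chosen so the
  peak von Mises stress over the reference lesion is of order 10²–10³ Pa,
  comparable to the tissue shear moduli; with γ = 0.25 per kPa this
  modulates diffusion by roughly 10–25% in the stressed rim, a noticeable
  but not dominant coupling. Config-exposed.
* **γ units: per kPa.** With stress of order hundreds of Pa this keeps the
  exponent of order one; interpreting γ = 0.25 per Pa would shut diffusion
  off entirely at any realistic stress.
* **Poisson ratio ν = 0.45**: nearly incompressible soft tissue.
* **Periphery/detection threshold 0.05·θ_max** (≈ 0.049): used for the
  d(x) tumor mask, Dice binarization and the CCC detection set. One voxel
  fraction scale is used for both species; at early days the vasculature
  rarely exceeds it, so early-day vasculature CCC can be undefined and is
  reported as missing rather than zero.

## Synthetic data

The generator replaces animal MRI and an atlas with parametric equivalents
that preserve what the model consumes:

* **Brain domain**: an ellipsoidal mask (semi-axes 1.85 × 1.85 × 2.6 mm in
  the study configuration) containing a white-matter shell between 45% and
  75% of the brain radii, with a seeded smooth angular wobble; gray matter
  elsewhere. This supplies the two-tissue mechanical heterogeneity; it does
  not reproduce real anatomy.
* **Initial conditions**: a radially symmetric tumor plateau with a sigmoid
  edge (radius 1.0 mm, peak θ_max, edge width radius/6) and a co-localized
  Gaussian vascular bed (peak 0.05, width = radius), emulating
  ADC-derived cellularity and DCE-derived blood-volume maps of a C6
  glioma seeded at the brain center. Far from the lesion the vasculature
  field is negligible, so vascular dynamics stay tumor-localized.
* **Converters**: the ADC→N_t mapping (affine between the free-water ADC
  3×10⁻³ mm²/s and the field minimum) and the DCE→N_v mapping (ratio of
  the 60-s concentration integral to the AIF integral) are implemented and
  exercised against synthetic ADC/DCE emulators that invert them exactly.

What the generator does not emulate: anatomical asymmetry, infiltrative
(non-mass-forming) growth, imaging point-spread functions, Rician noise
statistics, partial-volume effects at tissue interfaces. Passing the
scaled-down replication therefore demonstrates the *pipeline's* behavior
under the stated noise/resolution model, not performance on real scanner
data.

## Numerics

* **Spatial discretization**: regular voxel grid, divergence-form fluxes
  with face-centered coefficients (arithmetic means), which conserves the
  discrete mass of each species exactly under pure diffusion; verified to
  drift < 10⁻⁶ over ten days. Zero-flux at the brain-mask surface.
* **Time integration**: explicit forward Euler. The library default is
  dt = 0.01 day; the scaled study runs dt = 0.02 day, inside the stability
  bound dt ≤ 1/(2 (D_t + D_v) Σ 1/h²) for the bounded calibration region
  (D ≤ 0.08 mm²/day) on the finest study grid, and within the first-order
  convergence envelope (halving dt changes day-10 fields by < 10⁻³
  relative L2). A pre-run stability audit raises on violation; the
  calibrator treats mid-run instability as a large-penalty residual.
* **Carrying capacity and clipping**: θ is recomputed every step; fields
  are clipped voxelwise to [0, θ] after each update (cross-diffusion can
  produce small negatives at steep fronts).
* **Distance map d(x)**: tumor mask N_t > 0.05 θ_max; periphery voxels are
  mask voxels adjacent to non-mask voxels inside the box (the box edge is
  not periphery, mirroring zero flux); depth is the Euclidean distance to
  the nearest periphery voxel (scipy EDT with physical sampling),
  normalized by the maximum depth. Recomputed every step by default, every
  0.2 day in the study configuration (the front moves ~0.01 voxel per
  update at that cadence).
* **Mechanics**: second-order central differences; conservative stencils
  for same-direction terms, four-point cross stencils for mixed terms;
  normal displacement pinned to zero on box faces, tangential components
  free (even reflection). The operator depends only on the domain, so its
  sparse LU factorization is cached and reused across all solves.
  Equilibrium is re-solved once per simulated day by default (every 2 days
  in the study configuration; σ_vm evolves on the growth timescale). For
  grids above ~6000 voxels the solve runs on a block-homogenized
  factor-of-two coarsened domain and the smooth von Mises field is
  interpolated back — direct 3-D factorization cost grows super-linearly,
  while the stress varies on the lesion scale, not the voxel scale.
* **Calibration**: Levenberg-Marquardt (damped Gauss-Newton), forward
  finite-difference Jacobian (relative step 10⁻³), bounds enforced by
  projection: D ∈ [10⁻⁶, 0.1] mm²/day (0.08 in the study configuration,
  see above), k ∈ [10⁻³, 5] /day. The diffusivity cap exists because an
  explicit solver must bound the stability region; it sits ~4× above the
  central value and ~1.7× above the largest cohort value. Residuals are
  voxelwise model-minus-observed differences for both species at every
  observed day after day 1, equally weighted (a species weighting is
  exposed; with equal weights the objective is dominated by the
  larger-magnitude tumor term, and the vasculature parameters — D_v in
  particular — are correspondingly less constrained). The initial guess in
  experiment mode perturbs the true parameters by a seeded uniform ±50%
  per parameter. Convergence: relative objective change < 10⁻⁶ (10⁻⁵ in
  the study configuration) or step norm < 10⁻⁸, at most 50 iterations (20
  in the study configuration, with the Jacobian refreshed every second
  accepted step — the Gauss-Newton model changes slowly near the optimum).

## The in silico experiment

Ground truth at each spatial resolution is simulated *on that
resolution's grid* (initial conditions synthesized at the finest grid and
resampled down), so coarse data are coarse simulations rather than smoothed
fine ones. Degradation draws one independent Normal(1, 1/SNR) factor per
voxel, day and species (clipped to [0, θ_max]), and keeps only the
scheduled imaging days (1&5; 1,3,5; or 1–5). Calibration starts from the
*degraded* day-1 fields; prediction runs to day 10 with the estimated
parameters from those same fields; scoring compares against the same-SR
noiseless ground truth at days 6 and 10, within the brain mask. Per-row
seeds fan out from the master seed via `SeedSequence(master,
spawn_key=(tumor, condition, replicate))`, so any row is re-runnable in
isolation.

### Problem sizes

The full reference experiment (128×128×16 grid, 54 conditions, 13 tumors,
up to 50 replicates) is beyond a single-CPU desk run. The study
configuration fixes the finest resolution (0.008 mm³: 0.125 × 0.125 ×
0.5 mm voxels) on a 32×32×16 grid spanning a 4 × 4 × 8 mm box; the 0.063
and 0.50 mm³ resolutions follow by factor-2 per-axis degradation (16×16×8
and 8×8×4). The replication runs the central tumor plus the two 75% corner
variants (ids 13 and 43 — the high- and low-proliferation extremes) over
all 54 conditions with n = 5 noise replicates, i.e. 810 independent
calibrations. The lesion radius (1.0 mm) keeps the tumor front resolved by
≥ 4 in-plane voxels at the coarsest resolution, preserving the
information structure of the reference geometry.

## Known limitations

* The study commits the usual in silico "inverse crime": the calibrator
  uses the same forward model and discretization that generated the data,
  so parameter errors reflect noise/resolution propagation only, not model
  misspecification. This mirrors the design intent (isolating parameter
  uncertainty from structural uncertainty) but bounds what the numbers say
  about real data.
* At the coarsest resolution the brain contains only ~10² voxels, so
  noise averaging during calibration is far weaker than in the reference
  experiment; parameter-error medians at SNR 5 are correspondingly more
  volatile at this scale.
* The vasculature fields are an order of magnitude smaller than the tumor
  fields; with the shared detection threshold the early-day vasculature
  CCC is frequently undefined, and D_v percent error can reach hundreds of
  percent (it is reported, never gated) — the model output is insensitive
  to D_v.
* The ten-day growth length (2.5–3.4 mm for the high-proliferation
  variants) does not shrink with the domain, so fast cohort members fill
  the scaled brain and sit at carrying capacity well before day 10. A
  saturated field has almost no spatial variance, and the CCC of a
  near-constant field is dominated by noise-seeded ripples even when the
  absolute agreement is excellent (differences < 0.07 everywhere). Day-10
  CCC values for high-proliferation tumors at the coarsest resolution are
  therefore not comparable to the full-scale experiment, where the brain
  is large enough that tumors never saturate it.
* The elasticity solve on the coarsened domain introduces a smooth O(h²)
  error in σ_vm relative to a same-grid solve; since σ_vm enters only
  through a ~10–25% exponential modulation of D, the effect on the fields
  is well below the noise floor of the experiments.
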