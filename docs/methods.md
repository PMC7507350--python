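# Methods

This note documents the models, estimators, numerical choices and known
limitations of `microperm`, in the order data flows through the package.

## 1. Acquisition model and containers

Stacks live on a `VoxelGrid` with axis order (z, y, x), physical spacing in
μm (anisotropic by default: confocal z-steps are coarser than the in-plane
pixel pitch), and half-open integer ROI boxes. The defaults used in tests
emulate a 20× confocal acquisition of a ~50 μm-deep hydrogel channel at
reduced lateral extent — 24×96×96 voxels at (1.0, 0.62, 0.62) μm — so the
whole chain runs in seconds on one CPU; results are stated per physical
unit and are not tied to that size.

## 2. Synthetic vessel phantoms

A phantom is a union of flat-capped cylindrical segments: a trunk roughly
along the channel axis plus random child branches, all kept at least one
radius inside the grid. Rasterisation is voxel-centre membership — a voxel
is vascular iff its centre lies inside a segment — which makes geometry
tolerances well defined (no partial-volume convention to argue about).

Two oracles are computed independently of the raster:

* **Volume** — membership quadrature at ≥ 5 sample points per voxel per
  axis; accuracy follows from the sampling density, not from the raster.
* **Surface area** — per-segment surface quadrature (lateral sheet plus end
  caps, with exact area weights: lateral weights sum to 2πrL, cap weights to
  πr² at any resolution), discarding points strictly interior to another
  segment. Resolution only affects occlusion detection at segment joints.

Flat caps rather than hemispherical ones keep the single-cylinder closed
form (2πrL + 2πr²) exact and the union area well defined; branch joints are
covered because child segments root on the parent axis.

## 3. Tracer kinetics

The assay is modelled as two compartments: the vascular lumen at a constant
plateau `Iv0` (continuous luminal supply from the media channels — the
package assumes the lumen equilibrates instantaneously on perfusion, a
modelling choice, and measures `I_v` at the first timepoint only), and the
matrix filling through the vessel wall with rate constant

```
k = P · SA / V_m        [1/s]
```

* **well_mixed** (default): the matrix is one compartment,
  `I_m(t) = Iv0·(1 − e^(−kt))` with t from tracer addition (`t1 = 0` by
  default, so the first stack has a dark matrix; `t1 > 0` is supported).
* **spatial**: explicit finite-difference diffusion in the matrix
  (coefficient `D_m`, μm²/s) with a membrane-limited flux
  `J = P·(Iv0 − I_m,wall)` across vessel–matrix voxel faces. The explicit
  step must satisfy `dt ≤ 1/max(Σ D_m/h² + Σ P/h)`; a user step above the
  bound raises an error naming it, and the default step is half the bound.
  As `D_m` grows the matrix homogenises and the mean converges to the
  well-mixed closed form (verified monotonically in the tests). The
  discrete flux acts on voxel faces, so the consistent `SA` basis for this
  mode is the face-area estimator, not the mesh.

**Self-consistency of ground truth.** A simulated experiment's `k` must be
built on the same discrete geometry the estimator later measures, otherwise
rasterisation error (a few %) contaminates what should be a pure test of
the estimator. `ground_truth_for_labels` / `ground_truth_for_kdt` therefore
compute `k` from the rasterised label volume with a selectable SA method
(mesh by default, faces for spatial mode); the analytic quadrature oracle
remains the reference for geometry accuracy itself. Phantoms are far
smaller than a real device, so their SA/V_m is orders of magnitude larger;
simulations are parameterised by the dimensionless fill fraction `k·Δt`
(matched to realistic fill levels) rather than by a literature P.

**Two-timepoint bias.** Estimating the initial slope from two timepoints of
an exponential fill-in under-estimates P by exactly
`(1 − e^(−kΔt))/(kΔt)` — about −0.05% at `k·Δt = 10⁻³`, −5% at `10⁻¹`.
Noiseless recovery tests assert equality with this factor to 1e-6 relative;
the package does not fit multi-timepoint exponentials (two timepoints is
the assay's design).

**Imaging noise** is Poisson shot noise (parameterised as photons per
intensity unit; `NoiseSpec.for_snr` sets the level giving a requested SNR at
the vessel plateau) plus optional additive Gaussian read noise; negative
values are clipped at zero (the clip is the only mean distortion and is
negligible except for near-zero signal with large read noise). An optional
Gaussian PSF blur is off by default.

## 4. Segmentation and geometry

Segmentation is a deterministic global threshold — Otsu on a 256-bin
histogram of the full stack, or a user-fixed value — followed by
morphological closing with a physically specified radius (converted
per-axis into an anisotropic ellipsoid element) and removal of 26-connected
components below a physical volume. A constant stack or an empty post-filter
mask raises a "no vasculature detected" error, never a silent zero. The
interactive machine-learning segmentation used in practice is deliberately
replaced by this auditable, training-free pipeline; its adequacy is gated by
a Dice ≥ 0.95 requirement against ground-truth phantoms at SNR 10.

Volumes are voxel counts times the voxel volume, so `V_v + V_m` partitions
the ROI volume exactly. Surface area has two estimators:

* **mesh** (default): marching cubes at level 0.5 on the physically spaced
  lattice, after padding by one voxel (closes surfaces at the ROI boundary)
  and a Gaussian pre-smooth of **0.75 voxels per axis**. The smooth is the
  key numerical choice: the staircase isosurface of a raw binary tube
  over-estimates area by 6–9%, while 0.7–0.8 voxel smoothing brings
  cylinders and spheres within ~2% of closed forms across the anisotropies
  tested (0.5–1 voxel was probed; larger sigmas start eroding thin vessels).
* **voxel_faces**: exposed-face summation, an over-estimate on smooth
  surfaces (up to the Manhattan factor); kept as an independent cross-check
  and as the SA basis consistent with face-flux simulation.

An optional perivascular **border shell** (matrix within a given distance of
the wall, computed by an anisotropy-aware distance transform) can be
excluded from `V_m` and from matrix intensity averaging to avoid PSF /
partial-volume bleed. It defaults to **0 μm** so that the volume partition
identity holds exactly; when enabled it is recorded in `method_tags`.

Adherent-cell counting thresholds the cell channel, labels 26-connected
components, discards those below a physical volume, and counts components
whose minimum distance to the vessel mask is within `max_gap_um`
(equivalent to a physical dilation test).

## 5. Permeability estimation

`P = (V_m/(SA·ΔI))·(ΔI_m/Δt)` with `ΔI = I_v,1 − I_m,1` measured at the
first timepoint. Contracts:

* `ΔI ≤ 0` (tracer equilibrated or inverted contrast) is an error — no
  number is returned;
* `ΔI_m < 0` (photobleaching or noise) is allowed: P is reported negative
  with a warning tag rather than clamped, so bleaching artefacts stay
  visible;
* every result stores all intermediates and is internally consistent to
  1e-12 relative (checked at construction).

The estimator is invariant to intensity rescaling but **not** to a constant
offset: background raises `ΔI` without changing `ΔI_m` and biases P
downward (asserted as a directional test). Hence the optional constant
background subtraction; none is applied by default.

ROIs are uniform-random axis-aligned boxes (3 by default, emulating
unbiased sampling along the gel channel), deterministic per seed; overlaps
are allowed but logged. Aggregation is the arithmetic mean with the sample
SD (reported as absent for a single ROI, never 0), flagging ROIs more than
3 SD from the mean. Note that in well-mixed simulations the matrix fills
uniformly with the *global* rate, so sub-volume ROIs whose local SA/V_m
deviates from the global ratio show a systematic spread that real,
locally-fed extravasation would not — use the spatial mode or full-volume
ROIs when testing ROI-level accuracy.

## 6. Cytokine analysis

The 5PL standard curve is `y = d + (a − d)/(1 + (x/c)^b)^g` (lower
asymptote a, slope b, inflection c, upper asymptote d, asymmetry g; strictly
monotone for b, g > 0, a ≠ d), inverted in closed form. Fitting uses
least squares with slope/asymmetry in log-parameters, a 3×3 multi-start over
(b, g) initial guesses, asymptote starts from the data range and the
inflection start at the geometric mean of the calibrator levels; ≥ 6
strictly monotone calibrator levels are required. Noiseless calibrators are
recovered to ~1e-14. Under realistic response noise the inflection `c` is
poorly identified — b, c and g trade off along a near-degenerate ridge —
while the midpoint `EC50 = c·(2^(1/g) − 1)^(1/b)` is stable (median ~7%
error at 5% CV with 8 levels); `StandardCurve.ec50_pg_ml` exposes it and the
noisy-recovery test asserts it rather than `c`.

Censoring: responses at or outside the response range spanned by
[LLOQ, ULOQ] are imputed at the bound (LLOQ/2 available as an option);
no pseudo-counts anywhere — zero control means are errors and zero
spheroid-only means make D `undefined`, never silently adjusted.

Fold changes are `log2(mean_treatment/mean_control)` on (imputed) condition
means, flagged when either side contains censored values. The cooperativity
index `D = (c_co − c_MVN)/c_Sph` uses condition means by default (replicate
handling is not dictated by the assay; a per-replicate mode is provided and
the mode is recorded in the output). Classification uses a tolerance band
`|D − 1| ≤ τ` (default τ = 0.05) for calling additivity under noise;
exact D examples (1 → additive, 0 → antagonistic, 3 → supra-additive)
hold with τ = 0 semantics as well since the band only widens "additive".
D is scale-invariant and exactly affine in the co-culture value
(`ΔD = δ/c_Sph`), both asserted as properties. No multiplicity correction is
applied: D is descriptive, and significance testing is outside this
package's scope.

The synthetic table generator applies mean-preserving multiplicative
lognormal noise (σ² = ln(1 + CV²), μ = −σ²/2) per measurement, with 4
replicates per condition by default (matching common practice for
conditioned-media panels from 3-D devices), and flags LLOQ/ULOQ censoring
while retaining the raw value for test oracles.

## 7. What the generators do and do not emulate

They emulate: branched tubular networks in a gel volume at confocal-like
anisotropy; constant-lumen tracer fill-in with Poisson–Gaussian imaging
noise; three-condition cytokine panels with lognormal noise and quantitation
limits. They do **not** emulate: hemodynamic flow or pressure gradients,
vessel wall thickness or heterogeneous (focal) leakage, PSF anisotropy
(blur is optional, isotropic in physical units, and off by default),
spheroid growth, gel mechanics, bead-level assay artefacts (cross-talk,
hook effects), or plate-to-plate batch effects. Passing tests therefore
demonstrate correctness of the estimators under the stated models, not
robustness to every real-world artefact.

## 8. Reproducibility

All randomness flows from integer seeds through `numpy.random.default_rng`;
the pipeline derives per-stage seeds deterministically (CRC32 of the stage
name mixed into a `SeedSequence`). Reports are JSON with sorted keys and no
timestamps, so identical configs and inputs reproduce byte-identical
reports; fixtures are bit-reproducible per seed. Stack I/O writes 32-bit
TIFF with ImageJ-style spacing metadata plus a JSON sidecar, and loading
requires a voxel size from metadata, sidecar or explicit override — isotropy
is never assumed silently.
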