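# Methods

## Scope and intent

`bnctshift` models the *relative* dosimetric consequences of rigid
positioning errors in single posterior-field epithermal-beam BNCT. The
neutron/photon transport stage is deliberately an analytic stand-in: a
separable parametric kernel calibrated to the beam characteristics a
treatment planner would quote (aperture diameter, current-to-flux ratio,
advantage depth), not a transport solution. Absolute Gy-Eq values
therefore carry no metrological meaning. Everything downstream of the
kernel — biological weighting, prescription normalization, DVHs, ROI
metrics, directional aggregation and statistics — is exact arithmetic on
whatever dose grid is supplied, and the package's quantitative claims are
confined to prescription-normalized and percent-change quantities.

## Phantoms

Two families, both generated on a voxel grid with voxel-centre membership
tests (a voxel belongs to a primitive iff its centre satisfies the
inequality — chosen so a brute-force per-voxel oracle reproduces every
mask bit-for-bit).

* **Cylinder**: homogeneous PMMA (ρ = 1.19 g/cm³), 16 cm diameter,
  20 cm long, axis on the beam axis, flat entry face on the aperture
  plane. The length is a package choice: it covers both tumor depths
  plus margin. Air margins (4 cm lateral/distal) keep tissue inside the
  grid for every shift in the battery.
* **Head**: ellipsoid with semi-axes 9.5 × 12 × 8 cm (anteroposterior ×
  superoinferior × left-right), a 0.4 cm soft-tissue scalp shell around
  a brain interior, posterior pole touching the aperture plane. Organ
  set: tumor, normal brain (brain minus tumor), brainstem, circle of
  Willis, and anterior eyes/lenses/optic nerves placed far beyond the
  tumor along the beam.

The **tumor** is a cylinder, 3 cm diameter and 5 cm long, with its long
axis along the left-right direction and its central axis at a configured
depth (2.5 or 6.5 cm) from the entry surface. Depth is always measured
along the beam (+y) from the phantom entry surface. The shallow tumor's
proximal corners legitimately graze the scalp shell, so the containment
check uses the outer head surface, not the brain ellipsoid.

Phantoms round-trip through 8-bit grayscale TIFF stacks (one file per
axial slice, per-ROI mask stacks, plain-text manifest carrying spacing,
dims, origin and the label→gray map: air at 0, materials spread over
1–255 in density order). A planning-grid downsampler block-averages
density and snaps to the nearest source-material density (uniform
density binning only engages when the source palette exceeds the
material budget); ROI masks downsample by majority vote (fraction ≥ 0.5)
with a single-nearest-voxel fallback for sub-voxel structures, and
normal brain is re-disjointed from the tumor after voting.

What the generator does *not* emulate: CT-derived heterogeneity (bone,
sinuses, Hounsfield calibration), anatomically realistic shapes, and the
56-material tissue library of a clinical planning system. Passing tests
therefore demonstrate the correctness of the analysis chain and the
qualitative beam physics, not patient-specific accuracy.

## Dose kernel

Per voxel and channel: `D = A_c · f_gap(g) · P(r, d, g) · k_c(d)` with

* `d` — tissue path length along +y from the ray's entry surface
  (interior air contributes no depth; air voxels get zero dose);
* `g` — per-ray air gap between the aperture plane and the first tissue
  voxel, so outward shifts and surface curvature engage automatically;
* `k_c` — depth curves: thermal and boron share the buildup difference
  `A(e^(−d/λ₁) − e^(−d/λ₂))` (zero at the surface, single interior
  maximum at `λ₁λ₂/(λ₁−λ₂)·ln(λ₁/λ₂)`); fast is a decaying exponential
  (attenuation 1.6 cm); photon is an exponential (6 cm) with a buildup
  deficit near the surface;
* `f_gap` — inverse-square-like `1/(1+g/z₀)²` with `z₀ = 40 cm`, sized
  so a 3 cm air gap costs the deep tumor 10–17 % of its mean dose
  (≈ 5 % per cm, the scale reported for forward-peaked epithermal
  beams);
* `P` — lateral profile, the product of (i) a centre-peaked fluence
  term `exp(−r²/2ρ(d)²)` with `ρ = 3.2 + 1.0·d` cm, and (ii) a field-edge
  sigmoid at effective radius `R(d) = max(7 − 0.38·d, 2)` cm with
  penumbra width `w = 0.6 + 0.15·(1 − j/φ)·(d+g)` cm, normalized to 1 on
  axis (`j/φ` = current-to-flux ratio, so forward-peaked beams diverge
  less).

The two-factor profile is the package's key structural choice. Measured
epithermal fields show two behaviours that a single broadening penumbra
cannot reproduce simultaneously: normalized profiles are *flatter over
the central few cm* at depth (in-phantom scatter washes out the
forward-peaked fluence), yet *deep targets lose more dose* under lateral
shifts. Splitting the profile into a flattening centre term and an
inward-pulling edge reproduces both: at 6.5 cm the profile is flatter
than at 2.5 cm inside r ≈ 2 cm but falls more steeply across the field
shoulder (r ≈ 3–6 cm), which is exactly where a shifted tumor ends up.

### Calibration

`calibrate_engine` has one degree of freedom: the thermal/boron decay
length λ₁, solved by Brent's method so the on-axis advantage depth (AD,
the depth where the tumor Gy-Eq rate falls to the maximum normal-tissue
Gy-Eq rate, located on a 0.01 cm grid and refined by bisection) equals
8.5 cm ± 0.2 (hard constraint; the calibration raises if infeasible).
Two soft envelopes are then evaluated on the default cylinder and
recorded in the calibration report: deep-tumor mean-dose loss of 10–17 %
at a 3 cm air gap, and < 3 % at a 1 cm lateral shift. The remaining
constants were fixed once, by a scan against those same published beam
descriptors plus the qualitative orderings above, and are not runtime
degrees of freedom. The calibration is fully deterministic; its SHA-256
digest is the calibration id recorded in every run manifest.

## Biological weighting

Gy-Eq per voxel = `0.64·3.2·D_th + 1.39·3.2·D_fast + 0.96·0.5·D_ph +
0.65·CBE(v)·C(v)·D_B_per_ppm`. DRSF values (0.64/1.39/0.96/0.65)
normalize each computed channel to measured depth-dose-rate data; 3.2 is
the high-LET RBE (thermal nitrogen-capture products and fast neutrons),
0.5 the photon RBE as published for this beam (1.0 is the textbook
convention; a config override exists). Boron: CBE 3.8 and concentration
T/N × 25 ppm in tumor, CBE 1.3 and 25 ppm in normal tissue, T/N = 3.5.
The 25 ppm normal-tissue level is configurable and cancels out of every
prescription-normalized quantity. Voxels outside every mask are treated
as normal tissue. DRSF and RBE are commuting multiplications, so their
order is irrelevant to the result.

## Positioning perturbations

The phantom moves; the beam stays fixed. Left/right translate along ∓x,
superior/inferior along ±z, outward along +y (away from the aperture —
the translation direction that actually opens an air gap). Rotation is
about the beam central axis. Tilt is about the left-right axis through
the *tumor centroid*: rotational setup errors are conventionally defined
about the treatment isocenter, which planning places at the target
centre; a head-centroid pivot would conflate a tilt with a ~2 cm bulk
translation of a shallow tumor, which the shift battery already covers
separately. Resampling is inverse-mapping nearest-neighbour
(`scipy.ndimage.affine_transform`, order 0) so labels and masks stay
categorical; exact voxel-pitch translations are snapped to pure index
shifts to avoid boundary jitter, out-of-domain voxels become air, and
dose is always recomputed *after* the transform (no dose interpolation).

## Plans, DVHs and metrics

Cumulative DVHs use 512 uniform bins from zero to the masked maximum;
`D_q` is the smallest dose with ≥ q % coverage, linearly interpolated
between bracketing samples (agreement with a sort-based quantile is
within one bin by construction). Beam-on time = prescription dose /
`D_80%` of the baseline rate grid; by linearity the accumulated baseline
`D_80%` equals the prescription to floating round-off, independent of
binning. ROI metrics (D_mean, D_max, D_q) are volume-weighted voxel
statistics on the study grid; empty ROIs report as absent, never zero.

## Study and statistics

The default battery per (family, depth): baseline; left/right/superior/
inferior × {1, 2, 3} cm; outward × {1, 2, 3} cm; rotation and tilt ×
{±5°, ±10°, ±15°}. The baseline defines the beam-on time reused by all
sibling cases. Lateral directions aggregate as mean ± sample SD (n = 4),
angular senses as n = 2, with a two-sided one-sample t-test against the
deterministic baseline (df = n−1); zero sample SD makes the p-value
undefined and it is flagged as such. Percent changes are
`100·(baseline − shifted)/baseline` rounded half-away-from-zero to two
decimals; the percent-change table is recomputed from the dose tables of
the same report, never stored independently. Doses and percent changes
are rounded to two decimals in the CSV tables; machine-readable exports
keep full precision. The pipeline contains no randomness: a fixed seed
is recorded in the manifest alongside the config hash and calibration
id purely for provenance.

## Numerical choices and problem sizes

The study grid is 0.5 cm isotropic (cylinder 48×48×48, head 48×54×64
voxels). This resolves 1 cm shifts as exact two-voxel index shifts
(making left/right mirror symmetry exact) and 5° rotations without the
heavy quantization a 1 cm planning grid would impose;
`voxelize_to_planning_grid` still provides coarse-grid (e.g. 21×21×25)
metrics when a planning-system-scale grid is wanted. Material
quantization ties break toward the lower label; density bins snap to
source materials whenever the palette fits the budget. The full default
study (4 family/depth combinations × 28 cases) runs in well under a
minute on one CPU.

## Known limitations

* The kernel has no scatter transport: penumbra, buildup and divergence
  are parametric shapes constrained by beam descriptors, so absolute
  doses, beam times and normal-tissue values are indicative only.
* Single posterior field only; multi-field plans, fractionation and BED
  are out of scope, as are boron pharmacokinetics beyond the static
  T/N model.
* Nearest-neighbour resampling limits rotation fidelity to the voxel
  scale; round-trips differ at boundary voxels (≤ 2 % observed for the
  battery's magnitudes).
* The head phantom is geometric, not anatomical; organ doses should be
  read as relative robustness indicators, not clinical estimates.
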