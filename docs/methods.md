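# Methods

This note records the models implemented in `castct`, the choices made
where the design was genuinely open, and what the simulated validations
do and do not demonstrate.

## Measurement model

Detector readings are flat-field corrected, `Iffc = (I − dark)/(white −
dark)`, clipped into `(1e−6, 1]`, and log-transformed, `P0 = −ln Iffc ≥
0`. The clip at 1 discards super-white readings (scatter on unattenuated
rays, noise); the floor keeps dead pixels finite with a bias bounded by
`−ln 1e−6 ≈ 13.8` only on pixels that carried no signal. The dark field
is optional and defaults to zero. Angles are degrees, counterclockwise,
over `[0, 360)`; detector pixel centers sit at `(index + 0.5)·pitch`,
row 0 / column 0 top-left, and the sampling pitch at the isocenter is
`pitch / magnification`.

## Scatter correction

The scatter estimate is `Psc = [K · Iε^p · P0^q] ∗ G_σ`, subtracted from
the log projections. Implementation choices:

* **Kernel normalisation.** The discrete kernel uses the exponential
  profile `exp(−(x²+y²)/2σ²)`, truncated at `4σ` (<1e−4 mass lost) and
  renormalised to unit sum. Whatever amplitude constant the continuous
  form carries is thereby absorbed into `K`, which keeps a flat field a
  fixed point of the convolution and leaves `K` as the single strength
  knob.
* **Boundary handling.** Edge-replicate padding before the FFT
  convolution; zero padding would carve a dark halo into the estimate at
  the detector border.
* **Threshold semantics.** `Iε` keeps `Iffc < ε` and zeroes the rest;
  values exactly 1 are zeroed for every `ε` because a fully
  unattenuated ray contributes no object scatter. `ε = 1` (the
  homogeneous-cast mode) is the default.
* **Kernel width across grids.** The reference width `σ = 70` was tuned
  for a 628-pixel detector; on a grid of `n` columns covering the same
  field of view the package uses `σ·n/628`.
* **Negative projections.** `K` should be chosen so `Pc = P0 − Psc ≥ 0`.
  With clamping (default) negatives are zeroed and counted; without it
  they raise, reporting the negative fraction. `auto_cap_K` computes
  the literal cap `min P0/B` over pixels with positive unit response
  `B`; note that on data with genuine air pixels (`P0 = 0` next to the
  object) the literal cap is 0, so practical use pairs a finite `K`
  with clamping.
* **Strength calibration.** `p` and `q` are per-setup adjustment
  parameters; the package keeps the reference values (1.7, 0.9) and
  calibrates strength per setup. In simulation studies the strength can
  be fit in closed form against the known injected scatter (a
  least-squares scale); on real data it is tuned on a homogeneous
  calibration object (see Calibration below).

## Beam-hardening correction

`P_DSC = sinh(λ·P0)/λ`, computed exactly, with `λ = 0` an exact identity
(not a 0/0) and an overflow guard at `λ·max(P0) > 700`. The map is odd,
strictly increasing, convex for positive input and never below the
identity — it amplifies long paths, inverting the concavity that
polychromatic absorption imposes on the log projection.

In the combined pipeline the order is flat-field → log → DSC → SAC. The
scatter basis then needs an intensity factor: by default SAC runs
self-contained on its input, using the pseudo-intensity `exp(−P_DSC)`;
a `sac_intensity="measured"` switch feeds the original `Iffc` instead
(the literal reading of the separate equations). The default keeps one
code path and makes the combined operator a composition of the two
stand-alone ones.

## Reconstruction

Primary path: 2-D slice filtered backprojection from parallel-beam data;
fan-beam data are rebinned to parallel (`θ = β + γ`, `s = SOD·sin γ`)
with bilinear interpolation; multi-row stacks reconstruct slice by slice
(adequate for the small cone angles of the target geometry; a full FDK
cone reconstruction is out of scope). The ramp filter is built from its
band-limited space-domain form (sampling `|f|` directly in the DFT
mis-weights DC and biases the reconstruction low by several percent),
optionally apodised (Shepp-Logan, Hann), applied with zero-padding to
the next power of two; backprojection uses linear interpolation on a
grid centered on the rotation axis with voxel size `pitch/magnification`
by default. Full-circle scans are averaged over opposing rays; coverage
below 180° raises. Hounsfield calibration uses a configurable
`mu_water` (default 0.0227 /mm, the packaged spectrum's effective water
attenuation near 50 keV).

## Adaptive non-local means

No reference parameters exist for the denoiser, so standard
adaptive-NLM practice is used: patch radius 1, search radius 5, and
bandwidth `h = β·σ_local` with `β = 1`. The local noise level is
estimated per 48-voxel block (overlapping by the window size) as the
median absolute deviation of a discrete-Laplacian residual divided by
`0.6745·√20` — robust to structure and edges. The weighted averaging is
delegated to scikit-image's non-local means (exact, non-fast mode in
2-D). 3-D volumes are filtered slice-wise by default, matching the
slice-wise reconstruction; a `volumetric` switch enables true 3-D
windows. Output is a convex combination of input voxels, hence bounded
by the input range, and `β = 0` returns the input exactly.

## QA metrics

Sample (n−1) standard deviations throughout. Contrast is
`mean(feature) − mean(background)`; CNR divides by the background
standard deviation; homogeneity is CNR divided by the maximum pairwise
difference of five ROI means normalised by the mean of those means
(transcribed literally). MTF comes from a perpendicular-averaged edge
spread function across an axis-aligned edge, finite-differenced to a
line spread function and Fourier-transformed with 8× zero-padding;
`f10`/`f50` are the first linearly-interpolated crossings, in lp/mm
(slanted-edge super-resolution is out of scope; simulated edges are
axis-aligned). The cupping index of a profile across an object interior
is `100·(mean(edge bands) − mean(central band))/mean(edge bands)` with
20% bands; it is deliberately a relative measure and therefore not
offset-invariant.

## Surface pipeline

Segmentation takes the minimum of a smoothed 256-bin histogram between
the two dominant peaks (prominence ≥ 5% of the tallest), falling back to
an inter-class-variance split with a warning when no interior minimum
exists; unimodal volumes raise. Isosurfaces come from marching cubes
with vertices in mm on the reconstruction's centered frame. Ground-truth
phantom surfaces are contoured from the voxel mask after a 0.7-voxel
Gaussian pre-smoothing so the isosurface interpolates sub-voxel instead
of tracing voxel faces (which would inflate areas ~10%). STL I/O
(binary written; binary/ASCII sniffed on read) is delegated to trimesh.

Deviation maps are directional: sampled vertices of the *test* mesh to
the nearest point of the *reference* surface, unsigned, exact
point-to-triangle distances (plane projection with barycentric check,
else clamped edge candidates). The accelerated query prunes with a k-d
tree over triangle centroids: after a k=8 candidate pass giving distance
`d`, every triangle whose centroid lies within `d + max circumradius` is
checked, which guarantees exactness — only speed differs from the
brute-force scan, and tests assert agreement to 1e−9. RMS is computed on
the magnitudes. Registration between surfaces is assumed (the simulator
emits both meshes in one frame); mesh cropping is a bounding-box option,
not interactive editing.

## Simulator and study conditions

The simulator emulates the target system: 628×628 detector, 720 views,
magnification 1.7 as geometry defaults, with desk-scale grids (96–128
pixels, 180 views) for the packaged studies. The spectrum is a
Kramers-shaped 80 kVp bremsstrahlung with 2 mm aluminum filtration on a
10-keV grid; attenuation tables are NIST-anchored per-mm values for set
dental stone (gypsum, bulk density ≈1.7 g/cm³), aluminum, PMMA, PVC,
water and air. Forward projection ray-marches per-material path lengths
(step voxel/2, ≤1% line-integral error; the Beer-Lambert oracle is
checked against the rasterised chord, which absorbs up to one voxel of
rasterisation). Scatter is injected in the intensity domain — where
scatter physically adds — as `S = spr·G_σ∗(white − I)`: the attenuated
signal redistributed by the same kernel family the correction assumes,
so correction is a genuine inverse problem rather than a tautology.
Poisson noise uses 2·10⁴ incident photons per pixel by default.

Phantom defaults: the uniform plaster disk is 26 mm across (a cast-base
slab thickness); the dental arch is a U-slab with limbs ≈10 mm wide and
nine tooth-like protrusions (seeded jitter), optionally extruded to 3-D
over a solid base; the QA phantom is a PMMA body with a PVC rod in a
central air bore; the gear is aluminum with 32 teeth. The packaged
artifact studies use a scatter fraction `spr = 0.1`, a modest level
consistent with a 1.7:1-magnification micro-CT of a small cast, where
artifacts are strong but not signal-destroying; the scatter-recovery
study uses the heavier `spr = 0.3`. At much higher scatter the shadow
signal saturates (`I ≈ S`) and *no* projection-domain remap can recover
the lost contrast — a genuine limitation of this correction family, not
of the implementation.

## Calibration

`calibrate_correction` automates the per-setup trial-and-error tuning:
it scans a uniform plaster disk under the setup's spectrum and scatter
conditions and grid-searches `λ ∈ [0.1, 1]` (10 points) ×
`K ∈ {0.05, 0.1, 0.2, 0.3, 0.5}` for the flattest combined-correction
profile (smallest |cupping index|). The calibrated pair is then held
fixed for every object scanned on that setup, which is how the packaged
end-to-end study sets its parameters.

## What the simulations show — and what they do not

Passing tests show the implementation is internally consistent (exact
identities, closed forms, convolution and reconstruction oracles) and
that under the simulator's physics the corrections behave as designed:
cupping is removed on homogeneous objects, the injected scatter field is
recovered up to the model's smooth-field bandwidth, CNR/homogeneity
improve, and surface models move closer to ground truth by ~50% RMS.
They do not calibrate real scanners: the spectrum and attenuation tables
are toy (qualitatively correct hardening, not spectroscopic), detector
blur/lag/gain structure is absent, the scatter injection matches the
correction's kernel family by construction, and registration between
surfaces is assumed. Quantitative parameters (λ, K, σ) for a physical
system must be re-tuned on that system's calibration scans.

## Numerical details

* FFT convolution after edge padding; tiny negative FFT round-off in the
  scatter estimate is clipped to zero.
* FBP angular weight `Δθ` (or `Δθ/2` for full-circle data), detected
  from the angle list; interpolated backprojection outside the detector
  reads zero.
* Grid searches break ties toward the smaller parameter by evaluation
  order; calibration is deterministic.
* Mesh sampling at a `sampling_ratio < 1` uses a seeded generator;
  reports carry every parameter and seed, so a run is reproducible from
  its report alone.
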