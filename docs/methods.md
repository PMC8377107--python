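# Methods

`spectquant` implements a closed quantitative-SPECT loop for I-123 (LEHR and
ME collimators) and I-131 (HE collimator): digital phantoms, an analytic
acquisition simulator, OS-EM reconstruction with attenuation / scatter /
collimator-detector-response (CDR) compensation, and the clinical
quantification chain of calibration factors (CF), recovery coefficients (RC)
and percentage quantification error.  The design is a deliberate
*matched-model closure*: the reconstruction compensates exactly the physics
the simulator models (the classic "inverse crime").  That is intentional —
the quantity under test is the consistency of the whole pipeline (projector,
EM update, calibration, partial-volume correction), not the fidelity of a
photon-transport code, which is out of scope.

## Acquisition model

The projector is a rotate-and-blur operator.  For each view the volume is
rotated into the detector frame, each plane parallel to the detector is
weighted by the attenuation survival `exp(-∫ mu dl)` along the ray to the
detector (half-voxel self-term convention), blurred with the
distance-dependent CDR, and the planes are summed.

* **Rotation** is a cached sparse bilinear *splat* matrix per view; the
  backprojector uses its transpose (a bilinear gather).  The pair is an
  exact matrix adjoint and the forward rotation conserves activity exactly
  — both properties are asserted to machine precision in the test suite.
* **CDR**: system FWHM(d) = sqrt(FWHM_int² + (c₀ + c₁·d)²), realised as a
  two-component kernel: `(1-p)·Gaussian(FWHM) + p·Gaussian(FWHM·w)`, where
  `p` is the septal-penetration fraction and `w > 1` the tail width factor.
  In the projector the blur is applied per plane as the DFT of a *sampled,
  unit-sum, circularly wrapped* spatial Gaussian.  Sampling the analytic
  Gaussian transfer function instead (truncated at Nyquist) rings negative
  for sub-voxel sigmas and loses ~2% of the counts of a point source; the
  sampled-kernel spectrum is exactly mass-conserving, non-negative and
  self-adjoint.  `build_psf_kernel` exposes the equivalent spatial kernel
  (truncated at ±4σ of the broad component).
* **Scatter** is a stationary convolution compartment: the primary view is
  smoothed with a broad Gaussian (FWHM 80 mm) and added with gain
  `sf/(1-sf)`.  The preset `sensitivity` (cps/MBq) is the *all-in*
  photopeak-window sensitivity; the primary component carries `(1-sf)` of
  it, so with every flag enabled a point source in air yields exactly
  `sensitivity × A × t` total counts.
* **Noise**: independent Poisson draws per detector bin from the noise-free
  expectation, `numpy` Generator seeded per acquisition; identical seeds
  reproduce counts bit-for-bit.

Energy windows, spectra, dead time and the body-contour orbit are not
modelled; their net effect is absorbed into the preset fractions and the
circular orbit (radius 25 cm).  The three presets are emulation parameters
anchored to measurable quantities: point-source sensitivities 84.1 / 115.5 /
27.8 cps/MBq, system FWHM at the orbit radius ≈ 9.3 / 10.7 / 13.2 mm
(the HE value matches the 1.3 cm planar-resolution anchor), penetration
fractions 0.25 / 0.05 / 0.12, scatter fraction 0.30 (water geometry).
Attenuation uses water photopeak values 0.148 cm⁻¹ (159 keV) and
0.110 cm⁻¹ (364 keV), lung = 0.3 × water.

## Reconstruction

Ordered-subsets EM with 6 interleaved angular subsets (subset k takes views
k, k+6, …), uniform initial estimate inside the inscribed-cylinder support,
ratio floor 1e-12, sensitivity-image mask at 1e-8 of maximum.  The additive
scatter term is estimated once from the measured data by solving the
convolution model `y = p + g·G(p)` for the primary `p` with four fixed-point
iterations (the common one-pass estimate `sf·G(y)` is only first-order
consistent and leaves a percent-level bias in recovered counts); the
estimate is held fixed during iterations.  The system matrix carries
`(1-sf)/n_views`, so reconstructed voxel values are in *total-acquisition
counts*: for a source in air the image counts integrate to the total
photopeak counts, and the measured CF of a point source closes on the preset
sensitivity (measured closure: within ~1.5%).

With one subset the loop is exactly ML-EM; the suite asserts the monotone
likelihood, non-negativity, fixed-point and count-consistency properties,
plus a two-voxel/two-bin toy system against its analytic ML maximiser.

## Quantification chain

* `SD_rel = 100·SD/mean` over VOI voxels, sample (n-1) SD.
* `CF = Cnt/(A·t)` in cps/MBq.  The selected geometry is the point source in
  air with a VOI of the physical size plus a 3.0 cm radial margin.
* `RC = [A]_recovered/[A]_true`, fitted against sphere diameter with
  `RC(x) = a - b·e^(-cx)` (non-linear least squares, `a∈(0,1.5]`,
  `b,c ≥ 0`, initialisation `a=max RC, b=a-min RC, c=0.5`).
* Quantification: VOI counts → activity via CF → concentration via the VOI
  volume → divided by RC at the VOI diameter; error = `100·(rec-true)/true`.
  Non-spherical targets (liver) use the equivalent-sphere diameter
  `(6V/π)^(1/3)`; for the default liver this extrapolates slightly beyond
  the fitted 2.5–10 cm range (logged, and benign because the curve is at its
  asymptote there).

**VOI convention.**  VOIs are weighted by the fractional sub-voxel inclusion
of the geometric shape (supersampled occupancy), the behaviour of clinical
VOI tools; volumes are `Σw·voxel volume`.  On coarse grids a binary
voxel-centre mask produces deterministic lattice aliasing — the noiseless
ideal-reconstruction RC curve acquires inversions of ~0.1 and cannot exceed
monoexponential R² ≈ 0.87 at 9.6 mm voxels regardless of reconstruction
quality — while the fractional measure varies smoothly with diameter.
Binary masks remain available (`VOI(weighting="binary")`).

**Placement lattice.**  Sphere centres snap to a quarter-voxel-offset
lattice (voxel centre + voxel/4 per axis).  Centres on voxel centres or
corners produce coherent parity artefacts in voxelised volumes versus
diameter (ideal-bound monoexp R² 0.89–0.93); the quarter offset — the same
idea as quarter-offset detector sampling in CT — raises the ideal bound to
R² ≥ 0.998.  All studies share this lattice, so VOI masks are
translation-identical between the RC study and the quantification studies.

## Study recipes and scales

Two co-dimensioned profiles share identical physical geometry (61.44 cm
field of view, 40 s per view, 360° circular orbit):

| profile | grid | voxel | views | used for |
|---|---|---|---|---|
| `full` | 128³ | 4.8 mm | 60 | overnight runs, mirrors the clinical protocol |
| `reduced` | 64³ | 9.6 mm | 30 | default desk scale; all shipped studies |
| `tiny` | 32³ | 19.2 mm | 12 | fast unit tests only |

Phantoms: water cylinder 20.3/21.6/31.7 cm; hot spheres at 0.7 MBq/mL
(I-123) or 1.1 MBq/mL (I-131); warm cylinder at 100:1; parametric ellipsoid
torso with lungs (0.3 × water), liver and two spheres, with sphere:organ
concentration ratios of 100:1 (background), 100:7.5 (liver) and 100:2.8
(lung).  The eight RC-study spheres (2.5–10 cm) cannot coexist
in one 31.7 cm cylinder, so they are simulated in four similar-size axial
pairs with ≥ 5 cm surface gaps; mixing small spheres with large ones was
measured to inflate the small sphere's RC above its noiseless bound via
penetration-tail spill-in.  One derived child seed per (study, phantom,
preset), all reproducible from a single experiment seed.

OS-EM uses 60 updates (6 subsets × 10 iterations) everywhere — the update
count at which clinical-scale recovery gains become marginal; the sweep
grid is multiples of 6 from 18 to 168.

## What desk scale does and does not show

The reduced profile preserves the physical phantoms, camera physics and
count levels, but halves the resolution-to-voxel ratio (FWHM ≈ 1–1.4
voxels instead of 2–2.7).  Consequences observed and documented:

* EM converges faster in voxel space: large spheres reach ≥ 95% of their
  sweep maximum by 18 updates, the gain beyond 60 updates is ≤ 1.5
  percentage points, and the flagged "optimal" update count lands below 60
  (60 is nevertheless retained as the default).
* The absolute RC level at d ≥ 5 cm is capped by the voxelisation bound
  `Σocc²/Σocc` ≈ 0.81–0.90 at 9.6 mm (≈ 0.91–0.95 at 4.8 mm), so RC
  thresholds quoted for the clinical voxel size (≥ 0.9) are not reachable
  at desk scale even by a perfect reconstruction; the closure bounds
  (quantification errors), which are the pipeline's real figure of merit,
  are unaffected because CF and RC absorb the same deficit.
* At these count levels (10⁵–10⁹ per study) the VOI SD_relative is
  dominated by the systematic edge profile, not Poisson noise: it falls
  with sphere size, but its growth with update
  count is only visible for the noisiest preset, not universally.
* The RC ordering between presets (HE below ME) is a ~1% resolution effect
  at this scale, comparable to the CF measurement spread (~±1%); the
  ordering test therefore carries a 0.02 allowance.

Passing tests demonstrate internal consistency of the matched-model
pipeline at realistic count levels; they do not validate the camera model
against measured data, photon transport, energy spectra, or mismatched
forward/reconstruction models — all explicitly out of scope.

## Numerical choices

Ratio floor 1e-12; sensitivity mask 1e-8 of max; occupancy supersampling 4³
(boundary voxels only); PSF support ±4σ of the broad component; RC fit via
`scipy.optimize.curve_fit` with analytic R²; FFT blurs clipped at zero only
at the physical-projection boundary (ring amplitude ~1e-16 of maximum).
Degenerate inputs (zero activity, empty VOIs, zero expectations with
observed counts, non-divisible subset counts, out-of-grid placements) raise
or flag rather than propagate.

## Known limitations

Inverse-crime closure (by design); no energy-window or spectral modelling;
circular orbit; single parametric patient anatomy; RC curves from spheres
applied to the liver via the equivalent-sphere assumption; fractional-VOI
convention differs from a strict voxel-membership mask on coarse grids
(both are provided, the default is documented above).
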