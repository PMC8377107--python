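# spectquant

Quantitative SPECT emulation for iodine imaging: how accurately can the
activity concentration in a lesion be recovered from reconstructed SPECT
images of **¹²³I** (LEHR or ME collimator) and **¹³¹I** (HE collimator)?

Answering that in a clinic requires a camera, phantoms and days of
acquisition time.  `spectquant` closes the same loop on a desk: voxel
phantoms → an analytic acquisition simulator (attenuated rotate-and-blur
projector with distance-dependent collimator response, septal-penetration
tails, convolution scatter and Poisson noise) → OS-EM reconstruction with
attenuation/scatter/CDR compensation → the clinical quantification chain.
It is aimed at medical-physics researchers who want a reproducible,
fully-tested reference pipeline for quantification methodology —
calibration geometry choices, partial-volume corrections, update-count
optimisation — rather than a photon-transport code.

## The quantification chain

With VOI voxel values x_i and weights w_i:

* reconstruction noise:  SD_rel = 100 · SD / mean  (%)
* calibration factor:    CF = Cnt / (A · t)  (cps/MBq), from a point source
  in air with a VOI of the physical size + 3.0 cm radial margin
* recovery coefficient:  RC = [A]_recovered / [A]_true, fitted over sphere
  diameter x with RC(x) = a − b·e^(−cx)
* quantification error:  100 · ([A]_recovered − [A]_true) / [A]_true  (%)

Reconstruction is ordered-subsets EM (6 interleaved subsets, 60 updates),
x ← x · BPₛ(y / (FPₛ(x) + ŝ + ε)) / BPₛ(1), with a fixed data-driven
convolution scatter estimate ŝ in the denominator.  The forward/back
projector pair is an exact matrix adjoint by construction (sparse bilinear
splat/gather rotation, self-adjoint spectral blur), so EM's monotonicity
and count-conservation guarantees hold to machine precision.

## Worked example

Recover the concentration of a 6 cm sphere (0.7 MBq/mL ¹²³I, ME collimator)
in the warm water cylinder, at the desk scale (64³ voxels at 9.6 mm,
30 views × 40 s):

```python
from spectquant.experiments import (
    ExperimentConfig, point_calibration_factors,
    run_recovery_study, run_quantification_study,
)

cfg = ExperimentConfig(scale="reduced", presets=("I123_ME",), seed=1)
cfs = point_calibration_factors(cfg)          # CF_point per preset
rc = run_recovery_study(cfg, cfs)             # 8 cold spheres + fit
errors = run_quantification_study(
    cfg, "cylinder", cfs, rc.extras["curves"]).tables["errors"]
row = errors[errors.diameter_cm == 6.0].iloc[0]
print(f"CF_point = {cfs['I123_ME'].value:.1f} cps/MBq")
print(f"RC fit: a={rc.extras['curves']['I123_ME'].a:.3f}, "
      f"R^2={rc.extras['curves']['I123_ME'].r_squared:.4f}")
print(f"6 cm sphere: RC applied {row.rc_applied:.3f}, "
      f"error {row.error_percent:+.2f}%")
```

prints

```
CF_point = 116.6 cps/MBq
RC fit: a=0.905, R^2=0.9962
6 cm sphere: RC applied 0.835, error -0.06%
```

CF_point lands within ~1% of the camera's 115.5 cps/MBq system sensitivity
(count conservation through simulation and reconstruction); the recovery
curve fits the eight measured RCs with R² ≈ 0.996; and after CF + RC
correction the recovered concentration of the 6 cm sphere is accurate to a
fraction of a percent.  Across all eight spheres (2.5–10 cm), three
presets and Poisson noise, the maximum absolute error stays near 2%, and
below 2–3% for the two-sphere patient torso phantom including the liver.

The same studies are scriptable from the shell:

```sh
spectquant recovery --scale reduced --seed 1 --out runs/rc
spectquant quantify --target patient --seed 1 --out runs/patient
spectquant sweep-updates --seed 1 --out runs/sweep
```

plus `phantom` / `simulate` / `reconstruct` subcommands for working with
individual NIfTI volumes.

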