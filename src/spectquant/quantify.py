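"""VOI statistics, calibration factors, recovery curves and quantification error.

The activity-quantification chain measured here is the standard clinical one:

* VOI count statistics, with reconstruction noise summarised as the relative
  standard deviation ``SD_rel = 100 * SD / mean`` over the VOI voxels;
* a camera calibration factor ``CF = Cnt / (A * t)`` in cps/MBq converting
  reconstructed image counts to activity;
* recovery coefficients ``RC = [A]_recovered / [A]_true`` fitted against
  sphere diameter with the mono-exponential ``RC(x) = a - b exp(-c x)``,
  used to correct the residual partial-volume effect;
* the quantification error ``100 * ([A]_rec - [A]_true) / [A]_true``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .phantoms import VoxelGrid
from .recon import ReconSettings, ReconVolume, osem_reconstruct

log = logging.getLogger(__name__)

__all__ = [
    "VOI",
    "CountStats",
    "CalibrationFactor",
    "RecoveryCurve",
    "QuantResult",
    "count_stats",
    "compute_cf",
    "compute_rc",
    "fit_recovery_curve",
    "quantify_activity",
    "update_sweep",
]

#: Supported VOI diameter rules.
VOI_RULES = ("physical", "physical_minus", "physical_plus_3cm", "detector")


@dataclass(frozen=True)
class VOI:
    """A volume of interest: sphere or cylinder around a centre, or a raw mask.

    ``diameter`` is the physical object diameter in cm; the realised VOI
    diameter follows ``rule``: the physical size, the physical size minus two
    voxels, the physical size plus a 3.0 cm radial margin, or the physical
    detector size.  Cylindrical VOIs apply the radial margin to the radius
    and to each end of the length.
    """

    shape: str = "sphere"
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    diameter: float = 1.0
    rule: str = "physical"
    length: float | None = None
    mask: np.ndarray | None = None
    name: str = ""
    weighting: str = "fractional"

    def __post_init__(self) -> None:
        if self.shape not in ("sphere", "cylinder", "mask"):
            raise ValueError(f"unknown VOI shape {self.shape!r}")
        if self.rule not in VOI_RULES:
            raise ValueError(f"unknown VOI rule {self.rule!r}")
        if self.shape == "cylinder" and self.length is None:
            raise ValueError("cylindrical VOI needs a length")
        if self.shape == "mask" and self.mask is None:
            raise ValueError("mask VOI needs a mask")
        if self.weighting not in ("binary", "fractional"):
            raise ValueError(f"unknown VOI weighting {self.weighting!r}")

    def realised_diameter(self, grid: VoxelGrid) -> float:
        """VOI diameter in cm after applying the rule on ``grid``."""
        vox_cm = grid.voxel_size / 10.0
        if self.rule == "physical":
            return self.diameter
        if self.rule == "physical_minus":
            return max(self.diameter - 2.0 * vox_cm, vox_cm)
        if self.rule == "physical_plus_3cm":
            return self.diameter + 6.0
        # detector: transverse detector size
        return grid.shape[1] * vox_cm

    def mask_for(self, grid: VoxelGrid) -> np.ndarray:
        """Boolean voxel mask of the VOI (voxel-centre inclusion)."""
        if self.shape == "mask":
            if self.mask.shape != grid.shape:
                raise ValueError("mask VOI shape does not match grid")
            m = self.mask.astype(bool)
        else:
            if self.rule == "detector":
                m = np.ones(grid.shape, dtype=bool)
            else:
                r_mm = self.realised_diameter(grid) * 10.0 / 2.0
                dx = grid.axis_centers(0)[:, None, None] - self.center[0]
                dy = grid.axis_centers(1)[None, :, None] - self.center[1]
                dz = grid.axis_centers(2)[None, None, :] - self.center[2]
                if self.shape == "sphere":
                    m = dx**2 + dy**2 + dz**2 <= r_mm**2
                else:
                    margin = (self.realised_diameter(grid) - self.diameter) * 10.0 / 2.0
                    half_len = self.length * 10.0 / 2.0 + margin
                    m = (np.hypot(dx, dy) <= r_mm) & (np.abs(dz) <= half_len)
        if not m.any():
            raise ValueError("VOI mask is empty on this grid")
        return m

    def weights_for(self, grid: VoxelGrid, supersample: int = 4) -> np.ndarray:
        """Per-voxel VOI inclusion weights in [0, 1].

        With ``fractional`` weighting (default) boundary voxels carry their
        sub-voxel inclusion fraction, emulating the partial-voxel handling of
        clinical VOI tools; lattice-alignment artefacts of a binary mask
        largely cancel.  With ``binary`` weighting this is the 0/1 mask.
        A float-valued ``mask`` VOI supplies its own weights.
        """
        if self.shape == "mask":
            w = np.clip(self.mask.astype(float), 0.0, 1.0)
        elif self.weighting == "binary" or self.rule == "detector":
            w = self.mask_for(grid).astype(float)
        else:
            from .phantoms import _disc_occupancy, _interval_occupancy, _sphere_occupancy

            r_mm = self.realised_diameter(grid) * 10.0 / 2.0
            if self.shape == "sphere":
                w = _sphere_occupancy(grid, self.center, r_mm, supersample)
            else:
                margin = (self.realised_diameter(grid) - self.diameter) * 10.0 / 2.0
                half_len = self.length * 10.0 / 2.0 + margin
                disc = _disc_occupancy(grid, self.center[:2], r_mm, supersample)
                axial = _interval_occupancy(grid, 2, self.center[2], half_len, supersample)
                w = disc[:, :, None] * axial[None, None, :]
        if w.sum() <= 0:
            raise ValueError("VOI weights are empty on this grid")
        return w


@dataclass(frozen=True)
class CountStats:
    """Total/mean/SD counts over a VOI; ``sd_relative`` is 100*SD/mean (%)."""

    total: float
    mean: float
    sd: float
    sd_relative: float
    n_voxels: int


@dataclass(frozen=True)
class CalibrationFactor:
    """Camera calibration factor in cps/MBq for one geometry and VOI rule."""

    value: float
    geometry: str
    voi_rule: str
    camera: str
    suspect: bool = False


@dataclass(frozen=True)
class RecoveryCurve:
    """Fitted mono-exponential recovery curve ``RC(x) = a - b exp(-c x)``."""

    a: float
    b: float
    c: float
    r_squared: float
    diameters: tuple[float, ...]
    rcs: tuple[float, ...]

    def predict(self, diameter: float, warn_extrapolation: bool = True) -> float:
        """RC at a diameter (cm); warns when outside the fitted range."""
        lo, hi = min(self.diameters), max(self.diameters)
        if warn_extrapolation and not lo <= diameter <= hi:
            log.warning(
                "RC requested at %.2f cm, outside fitted range [%.2f, %.2f] cm",
                diameter, lo, hi,
            )
        return float(self.a - self.b * np.exp(-self.c * diameter))


@dataclass(frozen=True)
class QuantResult:
    """Recovered vs. true activity concentration for one VOI."""

    recovered_concentration: float
    true_concentration: float
    error_percent: float
    rc_applied: float
    voi: VOI


def _values(volume) -> tuple[np.ndarray, VoxelGrid]:
    if isinstance(volume, ReconVolume):
        return volume.values, volume.grid
    raise TypeError("expected a ReconVolume")


def count_stats(volume: ReconVolume, voi: VOI) -> CountStats:
    """Count statistics over the VOI; SD is the sample (n-1) standard deviation.

    With fractional VOI weighting the statistics are inclusion-weighted:
    ``total = sum(w x)``, ``mean = total / sum(w)`` and the weighted sample
    variance; ``n_voxels`` reports the effective voxel count ``sum(w)``
    rounded to the nearest integer.  Full-weight VOIs reduce to the plain
    per-voxel statistics.
    """
    vals, grid = _values(volume)
    w = voi.weights_for(grid)
    nz = w > 0
    x = vals[nz]
    wv = w[nz]
    wsum = float(wv.sum())
    total = float((wv * x).sum())
    mean = total / wsum
    if wsum > 1:
        sd = float(np.sqrt((wv * (x - mean) ** 2).sum() / (wsum - 1.0)))
    else:
        sd = 0.0
    if mean > 0:
        sd_rel = 100.0 * sd / mean
    else:
        sd_rel = float("nan")
        log.warning("VOI mean is zero; SD_relative undefined")
    return CountStats(total=total, mean=mean, sd=sd,
                      sd_relative=sd_rel, n_voxels=int(round(wsum)))


def compute_cf(volume: ReconVolume, voi: VOI, activity: float, time: float,
               geometry: str = "point") -> CalibrationFactor:
    """Calibration factor CF = Cnt / (A * t) in cps/MBq.

    ``activity`` in MBq, ``time`` the total acquisition time in seconds.
    """
    if activity <= 0 or time <= 0:
        raise ValueError("activity and time must be positive")
    total = count_stats(volume, voi).total
    suspect = total == 0
    if suspect:
        log.warning("zero VOI counts; calibration factor is suspect")
    return CalibrationFactor(value=total / (activity * time), geometry=geometry,
                             voi_rule=voi.rule, camera=volume.camera.name,
                             suspect=suspect)


def compute_rc(recovered: float, true: float) -> float:
    """Recovery coefficient RC = [A]_recovered / [A]_true."""
    if true <= 0:
        raise ValueError("true concentration must be positive")
    return recovered / true


def _rc_model(x, a, b, c):
    return a - b * np.exp(-c * x)


def fit_recovery_curve(diameters, rcs) -> RecoveryCurve:
    """Nonlinear least-squares fit of RC(x) = a - b exp(-c x).

    Requires at least four distinct diameters.  Initialisation
    ``a = max(RC), b = a - min(RC), c = 0.5``; bounds ``a in (0, 1.5],
    b >= 0, c >= 0`` keep the curve non-decreasing on the fitted range.
    """
    d = np.asarray(diameters, dtype=float)
    r = np.asarray(rcs, dtype=float)
    if d.size < 4 or np.unique(d).size < d.size:
        raise ValueError("need >= 4 points with distinct diameters")
    p0 = (r.max(), r.max() - r.min() + 1e-6, 0.5)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(
                _rc_model, d, r, p0=p0,
                bounds=([1e-9, 0.0, 0.0], [1.5, np.inf, np.inf]),
                maxfev=20000,
            )
    except RuntimeError as exc:  # pragma: no cover - diagnostics path
        raise RuntimeError(
            f"recovery-curve fit failed for diameters {d.tolist()} "
            f"and RCs {r.tolist()}: {exc}"
        ) from exc
    resid = r - _rc_model(d, *popt)
    ss_tot = float(((r - r.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else 1.0
    return RecoveryCurve(a=float(popt[0]), b=float(popt[1]), c=float(popt[2]),
                         r_squared=r2, diameters=tuple(d), rcs=tuple(r))


def quantify_activity(volume: ReconVolume, voi: VOI, cf: CalibrationFactor,
                      curve: RecoveryCurve, acq_time: float,
                      true_concentration: float,
                      equivalent_diameter: float | None = None) -> QuantResult:
    """Recover the VOI activity concentration and its quantification error.

    The VOI total counts are converted to activity with the calibration
    factor, divided by the voxelised VOI volume, and corrected for the
    partial-volume effect with the recovery curve evaluated at the VOI's
    (equivalent-sphere) diameter.
    """
    if voi.rule != "physical" and voi.shape != "mask":
        log.warning("quantification VOIs normally use the physical-size rule")
    stats = count_stats(volume, voi)
    vol_ml = float(voi.weights_for(volume.grid).sum()) * volume.grid.voxel_volume_ml
    d_eff = equivalent_diameter if equivalent_diameter is not None else voi.diameter
    rc = curve.predict(d_eff)
    measured = stats.total / (cf.value * acq_time) / vol_ml
    recovered = measured / rc
    err = 100.0 * (recovered - true_concentration) / true_concentration
    return QuantResult(recovered_concentration=recovered,
                       true_concentration=true_concentration,
                       error_percent=err, rc_applied=rc, voi=voi)


def update_sweep(projections, mu_map, camera, voi_list, updates_grid,
                 settings: ReconSettings | None = None) -> pd.DataFrame:
    """VOI recovery and noise as a function of OS-EM updates.

    Runs a single reconstruction out to ``max(updates_grid)`` and snapshots
    the VOI statistics at every grid point (each must be a multiple of the
    subset count).  Returns one row per (VOI, update count) with the total
    counts, SD_relative, and the total normalised to that VOI's maximum over
    the sweep (so the sweep maximum is 1 by construction).
    """
    grid_pts = sorted(int(u) for u in updates_grid)
    base = settings or ReconSettings()
    if any(u % base.n_subsets for u in grid_pts):
        raise ValueError("every sweep point must be divisible by n_subsets")
    settings_full = ReconSettings(
        n_subsets=base.n_subsets, n_updates=grid_pts[-1], flags=base.flags,
        initial_value=base.initial_value, epsilon=base.epsilon,
        sensitivity_mask_rel=base.sensitivity_mask_rel,
    )
    rows = []
    want = set(grid_pts)

    def snapshot(update, x):
        if update in want:
            vol = ReconVolume(values=x, grid=_sweep_grid[0], settings=settings_full,
                              camera=camera, protocol=projections.protocol)
            for voi in voi_list:
                st = count_stats(vol, voi)
                rows.append({
                    "voi": voi.name or f"d{voi.diameter:g}",
                    "diameter_cm": voi.diameter,
                    "updates": update,
                    "total": st.total,
                    "mean": st.mean,
                    "sd_relative": st.sd_relative,
                })

    # osem_reconstruct derives the grid; capture it via a mutable cell
    _sweep_grid = [None]

    def cb(update, x):
        if _sweep_grid[0] is None:
            _sweep_grid[0] = VoxelGrid(x.shape, projections.protocol.bin_size)
        snapshot(update, x)

    osem_reconstruct(projections, mu_map, camera, settings_full, callback=cb)
    df = pd.DataFrame(rows)
    df["normalised"] = df.groupby("voi")["total"].transform(lambda t: t / t.max())
    return df
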