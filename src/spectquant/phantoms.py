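"""Voxel-based digital phantoms: activity and attenuation map builders.

A phantom is a pair of co-registered 3-D fields on a :class:`VoxelGrid`:
activity concentration in MBq/mL and linear attenuation in cm^-1 at the
imaging photopeak energy.  Builders compose geometric primitives (cylinder,
spheres, a parametric ellipsoid torso) with sub-voxel supersampling so that
boundary voxels carry fractional fills and voxelised volumes converge to the
analytic ones.

Conventions: array axes are (x, y, z); the tomographic rotation axis and all
cylinder/body axes run along z; world coordinates are in mm with the origin
at the geometric centre of the grid.  Object diameters and lengths are
quoted in cm, as is usual for phantom hardware.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "VoxelGrid",
    "TissueMaps",
    "SphereSpec",
    "CylinderSpec",
    "PatientSpec",
    "make_cylinder_phantom",
    "add_sphere",
    "make_point_source",
    "make_patient_phantom",
    "patient_masks",
    "snap_to_voxel_center",
    "snap_to_placement_lattice",
]


@dataclass(frozen=True)
class VoxelGrid:
    """Isotropic voxel grid: ``shape`` (nx, ny, nz) and ``voxel_size`` in mm."""

    shape: tuple[int, int, int]
    voxel_size: float

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if len(self.shape) != 3 or any(int(n) < 8 for n in self.shape):
            raise ValueError("grid shape must be a triple with components >= 8")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in mL (= cm^3)."""
        return (self.voxel_size / 10.0) ** 3

    @property
    def extent_mm(self) -> tuple[float, float, float]:
        """Physical edge lengths of the grid in mm."""
        return tuple(n * self.voxel_size for n in self.shape)

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-centre world coordinates (mm) along one axis."""
        n = self.shape[axis]
        return (np.arange(n) - (n - 1) / 2.0) * self.voxel_size

    def zeros(self) -> np.ndarray:
        return np.zeros(self.shape, dtype=np.float64)


@dataclass
class TissueMaps:
    """Paired activity (MBq/mL) and attenuation (cm^-1) maps on one grid."""

    grid: VoxelGrid
    activity: np.ndarray
    mu: np.ndarray

    def __post_init__(self) -> None:
        for name in ("activity", "mu"):
            arr = getattr(self, name)
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} map shape {arr.shape} != grid {self.grid.shape}")
            if np.any(arr < 0):
                raise ValueError(f"{name} map must be non-negative")

    def copy(self) -> "TissueMaps":
        return TissueMaps(self.grid, self.activity.copy(), self.mu.copy())

    @property
    def total_activity_mbq(self) -> float:
        """Total activity in MBq (concentration integral over the grid)."""
        return float(self.activity.sum() * self.grid.voxel_volume_ml)


@dataclass(frozen=True)
class SphereSpec:
    """A hot sphere: ``center`` in world mm, ``diameter`` cm, fill in MBq/mL."""

    center: tuple[float, float, float]
    diameter: float
    concentration: float

    def __post_init__(self) -> None:
        if self.diameter <= 0:
            raise ValueError("sphere diameter must be positive")
        if self.concentration < 0:
            raise ValueError("sphere concentration must be non-negative")

    @property
    def volume_ml(self) -> float:
        return np.pi / 6.0 * self.diameter**3


@dataclass(frozen=True)
class CylinderSpec:
    """Water-fillable cylinder with a solid wall, axis along z."""

    inner_diameter: float = 20.3
    outer_diameter: float = 21.6
    length: float = 31.7
    fill_concentration: float = 0.0
    wall_is_water_equivalent: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.inner_diameter < self.outer_diameter:
            raise ValueError("need 0 < inner_diameter < outer_diameter")
        if self.length <= 0:
            raise ValueError("length must be positive")
        if self.fill_concentration < 0:
            raise ValueError("fill_concentration must be non-negative")


def _subvoxel_offsets(supersample: int, ndim: int, voxel_size: float) -> np.ndarray:
    """Centres of the supersample^ndim sub-voxels, relative to voxel centre (mm)."""
    s = int(supersample)
    step = voxel_size / s
    off1 = (np.arange(s) - (s - 1) / 2.0) * step
    grids = np.meshgrid(*([off1] * ndim), indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=-1)


def _disc_occupancy(grid: VoxelGrid, center_xy: tuple[float, float], radius_mm: float,
                    supersample: int) -> np.ndarray:
    """Fractional in-plane occupancy of a disc (2-D, axes x and y)."""
    x = grid.axis_centers(0)[:, None] - center_xy[0]
    y = grid.axis_centers(1)[None, :] - center_xy[1]
    r = np.hypot(x, y)
    half_diag = grid.voxel_size * np.sqrt(2.0) / 2.0
    frac = np.zeros(r.shape)
    frac[r <= radius_mm - half_diag] = 1.0
    band = (r > radius_mm - half_diag) & (r < radius_mm + half_diag)
    if np.any(band):
        offs = _subvoxel_offsets(supersample, 2, grid.voxel_size)
        px = (x + np.zeros_like(y))[band][:, None] + offs[None, :, 0]
        py = (np.zeros_like(x) + y)[band][:, None] + offs[None, :, 1]
        frac[band] = np.mean(px**2 + py**2 <= radius_mm**2, axis=1)
    return frac


def _interval_occupancy(grid: VoxelGrid, axis: int, center: float, half_len: float,
                        supersample: int) -> np.ndarray:
    """Fractional occupancy of the 1-D interval [center-half_len, center+half_len]."""
    z = grid.axis_centers(axis) - center
    lo, hi = -half_len, half_len
    h = grid.voxel_size / 2.0
    overlap = np.clip(np.minimum(hi, z + h) - np.maximum(lo, z - h), 0.0, None)
    return overlap / grid.voxel_size


def _ellipsoid_occupancy(grid: VoxelGrid, center_mm, semi_axes_mm, supersample: int) -> np.ndarray:
    """Fractional occupancy of an axis-aligned ellipsoid."""
    axes = [grid.axis_centers(i) - center_mm[i] for i in range(3)]
    a = np.asarray(semi_axes_mm, dtype=float)
    rho2 = (
        (axes[0][:, None, None] / a[0]) ** 2
        + (axes[1][None, :, None] / a[1]) ** 2
        + (axes[2][None, None, :] / a[2]) ** 2
    )
    # conservative boundary band in normalised-radius units
    margin = grid.voxel_size * np.sqrt(3.0) / 2.0 / a.min()
    rho = np.sqrt(rho2)
    frac = np.zeros(grid.shape)
    frac[rho <= 1.0 - margin] = 1.0
    band = (rho > 1.0 - margin) & (rho < 1.0 + margin)
    idx = np.argwhere(band)
    if idx.size:
        offs = _subvoxel_offsets(supersample, 3, grid.voxel_size)
        pts = np.stack([axes[i][idx[:, i]] for i in range(3)], axis=-1)
        sub = pts[:, None, :] + offs[None, :, :]
        inside = ((sub / a) ** 2).sum(axis=-1) <= 1.0
        frac[band] = inside.mean(axis=1)
    return frac


def _sphere_occupancy(grid: VoxelGrid, center_mm, radius_mm: float, supersample: int) -> np.ndarray:
    return _ellipsoid_occupancy(grid, center_mm, (radius_mm,) * 3, supersample)


def snap_to_voxel_center(grid: VoxelGrid, point_mm) -> tuple[float, float, float]:
    """Return the world coordinates of the voxel centre nearest to ``point_mm``."""
    out = []
    for ax in range(3):
        c = grid.axis_centers(ax)
        out.append(float(c[np.argmin(np.abs(c - point_mm[ax]))]))
    return tuple(out)


def snap_to_placement_lattice(grid: VoxelGrid, point_mm) -> tuple[float, float, float]:
    """Snap to the quarter-voxel placement lattice (voxel centre + voxel/4).

    Spheres centred exactly on voxel centres (or corners) produce coherent
    lattice-parity artefacts in voxelised volumes and VOI measures: the
    partial-volume deficit then jumps irregularly with diameter.  A
    quarter-voxel offset along every axis breaks the alignment symmetry --
    the same trick as the quarter-offset sampling used in CT detector design
    -- and makes voxelised measures vary smoothly with object size.  All
    study recipes place spheres on this common lattice so VOI masks are
    translation-consistent between the recovery and quantification studies.
    """
    q = grid.voxel_size / 4.0
    snapped = snap_to_voxel_center(grid, tuple(p - q for p in point_mm))
    return tuple(s + q for s in snapped)


def make_cylinder_phantom(spec: CylinderSpec, grid: VoxelGrid, mu_water: float,
                          supersample: int = 2) -> TissueMaps:
    """Build the water cylinder: interior fill + water-equivalent wall, air outside.

    Raises a dimension error if the cylinder does not fit inside the grid.
    """
    ex, ey, ez = grid.extent_mm
    if spec.outer_diameter * 10 > min(ex, ey) or spec.length * 10 > ez:
        raise ValueError("cylinder exceeds grid extent")
    r_in = spec.inner_diameter * 10 / 2.0
    r_out = spec.outer_diameter * 10 / 2.0
    axial = _interval_occupancy(grid, 2, 0.0, spec.length * 10 / 2.0, supersample)
    disc_in = _disc_occupancy(grid, (0.0, 0.0), r_in, supersample)
    disc_out = _disc_occupancy(grid, (0.0, 0.0), r_out, supersample)
    inner = disc_in[:, :, None] * axial[None, None, :]
    outer = disc_out[:, :, None] * axial[None, None, :]
    activity = spec.fill_concentration * inner
    mu = mu_water * (outer if spec.wall_is_water_equivalent else inner)
    return TissueMaps(grid, activity, mu)


def add_sphere(maps: TissueMaps, sphere: SphereSpec, supersample: int = 4,
               mu_value: float | None = None) -> TissueMaps:
    """Return a copy of ``maps`` with a sphere painted in.

    Boundary voxels blend the sphere concentration with the existing
    background according to sub-voxel occupancy; interior voxels are replaced.
    ``mu_value``, if given, paints the sphere's attenuation the same way
    (used for spheres surrounded by air).
    """
    if supersample < 1:
        raise ValueError("supersample must be >= 1")
    grid = maps.grid
    r = sphere.diameter * 10 / 2.0
    for ax in range(3):
        half = grid.extent_mm[ax] / 2.0
        if abs(sphere.center[ax]) + r > half:
            raise ValueError("sphere crosses the grid boundary")
    frac = _sphere_occupancy(grid, sphere.center, r, supersample)
    out = maps.copy()
    out.activity = (1.0 - frac) * out.activity + frac * sphere.concentration
    if mu_value is not None:
        out.mu = (1.0 - frac) * out.mu + frac * mu_value
    return out


def make_point_source(grid: VoxelGrid, activity: float,
                      center: tuple[float, float, float] | None = None) -> TissueMaps:
    """A point-like source in air: all activity (MBq) in one voxel, mu = 0."""
    if activity <= 0:
        raise ValueError("point-source activity must be positive")
    act = grid.zeros()
    if center is None:
        idx = tuple(n // 2 for n in grid.shape)
    else:
        idx = tuple(
            int(np.argmin(np.abs(grid.axis_centers(ax) - center[ax]))) for ax in range(3)
        )
    act[idx] = activity / grid.voxel_volume_ml
    return TissueMaps(grid, act, grid.zeros())


@dataclass(frozen=True)
class PatientSpec:
    """Parametric torso: body/lung/liver ellipsoids plus two hot spheres.

    All geometry in cm (centres in world cm, semi-axes in cm).  Organ
    concentrations are expressed relative to the spheres at 100: background 1,
    liver 7.5, lung 2.8.  Scenario 1 places the large sphere at the upper
    anchor (above the liver, between the lungs) and the small one at the
    lower anchor (below the liver); scenario 2 swaps them.
    """

    body_center: tuple[float, float, float] = (0.0, 0.0, 0.0)
    body_axes: tuple[float, float, float] = (15.5, 10.5, 24.0)
    lung_centers: tuple[tuple[float, float, float], ...] = (
        (-7.0, -1.0, 12.0),
        (7.0, -1.0, 12.0),
    )
    lung_axes: tuple[float, float, float] = (3.5, 4.5, 7.0)
    liver_center: tuple[float, float, float] = (-4.5, 0.5, -0.5)
    liver_axes: tuple[float, float, float] = (7.5, 5.5, 5.0)
    upper_anchor: tuple[float, float, float] = (0.0, 0.0, 10.0)
    lower_anchor: tuple[float, float, float] = (0.0, 0.0, -9.5)
    sphere_diameters: tuple[float, float] = (5.0, 3.0)
    sphere_concentration: float = 0.7
    ratio_background: float = 1.0
    ratio_liver: float = 7.5
    ratio_lung: float = 2.8

    @property
    def liver_volume_ml(self) -> float:
        a, b, c = self.liver_axes
        return 4.0 / 3.0 * np.pi * a * b * c


def _patient_sphere_specs(spec: PatientSpec, grid: VoxelGrid, scenario: int):
    if scenario not in (1, 2):
        raise ValueError("scenario must be 1 or 2")
    big, small = spec.sphere_diameters
    upper = snap_to_placement_lattice(grid, tuple(10 * v for v in spec.upper_anchor))
    lower = snap_to_placement_lattice(grid, tuple(10 * v for v in spec.lower_anchor))
    if scenario == 1:
        placed = [(big, upper), (small, lower)]
    else:
        placed = [(small, upper), (big, lower)]
    return [
        SphereSpec(center=c, diameter=d, concentration=spec.sphere_concentration)
        for d, c in placed
    ]


def patient_masks(spec: PatientSpec, grid: VoxelGrid, scenario: int,
                  supersample: int = 4) -> dict:
    """Binary organ masks and sphere metadata for one scenario.

    Returns a dict with ``body``, ``lungs``, ``liver`` boolean masks and a
    ``spheres`` list of (diameter_cm, center_mm, mask) in placement order.
    """
    to_mm = lambda t: tuple(10.0 * v for v in t)
    body = _ellipsoid_occupancy(grid, to_mm(spec.body_center),
                                to_mm(spec.body_axes), supersample)
    lungs = np.zeros(grid.shape)
    for c in spec.lung_centers:
        lungs += _ellipsoid_occupancy(grid, to_mm(c), to_mm(spec.lung_axes), supersample)
    liver = _ellipsoid_occupancy(grid, to_mm(spec.liver_center),
                                 to_mm(spec.liver_axes), supersample)
    spheres = []
    for s in _patient_sphere_specs(spec, grid, scenario):
        frac = _sphere_occupancy(grid, s.center, s.diameter * 10 / 2.0, supersample)
        spheres.append((s.diameter, s.center, frac))
    return {
        "body": body > 0.5,
        "lungs": lungs > 0.5,
        "liver": liver > 0.5,
        "spheres": spheres,
        "occupancy": {"body": body, "lungs": lungs, "liver": liver},
    }


def make_patient_phantom(spec: PatientSpec, grid: VoxelGrid, scenario: int,
                         mu_water: float, supersample: int = 4) -> TissueMaps:
    """Build the torso phantom for one sphere-placement scenario.

    Organs are painted in order body -> lungs -> liver -> spheres; a sphere
    overlapping the lungs or liver raises a placement error.
    """
    m = patient_masks(spec, grid, scenario, supersample)
    body, lungs, liver = m["occupancy"]["body"], m["occupancy"]["lungs"], m["occupancy"]["liver"]
    c_sphere = spec.sphere_concentration
    c_bg = c_sphere * spec.ratio_background / 100.0
    c_liver = c_sphere * spec.ratio_liver / 100.0
    c_lung = c_sphere * spec.ratio_lung / 100.0

    from .presets import LUNG_MU_FACTOR  # local import avoids cycle at module load

    activity = c_bg * body
    mu = mu_water * body
    activity = (1 - lungs) * activity + lungs * c_lung
    mu = (1 - lungs) * mu + lungs * LUNG_MU_FACTOR * mu_water
    activity = (1 - liver) * activity + liver * c_liver
    mu = (1 - liver) * mu + liver * mu_water

    organ = m["lungs"] | m["liver"]
    maps = TissueMaps(grid, activity, mu)
    for d, center, frac in m["spheres"]:
        if np.any((frac > 0.5) & organ):
            raise ValueError("sphere placement overlaps an organ")
        maps.activity = (1 - frac) * maps.activity + frac * c_sphere
    return maps
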