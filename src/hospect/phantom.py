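"""Digital Jaszczak-style phantoms and radioactive-decay bookkeeping.

The phantom is a water-filled cylinder (inner diameter 206 mm, inner height
186 mm, 7 mm PMMA wall) carrying up to six fillable hot spheres (2 mm PMMA
walls) in a ring at mid-height.  Voxelization is by voxel-center membership:
a voxel belongs to the innermost region whose analytic boundary contains its
center.  Activity arrays store concentration in MBq/ml; totals are always
derived from concentration times voxel volume.

Label convention: 0 = air, 1 = background (water), 2..7 = sphere interiors
(in the order the spheres are given), 8 = PMMA wall (cylinder and sphere
shells).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GridSpec",
    "SphereSpec",
    "VoxelPhantom",
    "DecayParams",
    "GeometryError",
    "build_jaszczak",
    "decay",
    "attenuation_map",
    "jaszczak_sphere_set",
    "default_grid",
    "CYLINDER_INNER_DIAMETER_MM",
    "CYLINDER_INNER_HEIGHT_MM",
    "CYLINDER_WALL_MM",
    "SPHERE_INNER_DIAMETERS_MM",
    "SPHERE_WALL_MM",
    "HO166_HALF_LIFE_H",
    "LABEL_AIR",
    "LABEL_BACKGROUND",
    "LABEL_WALL",
]

# Jaszczak Pro-NM geometry (mm) and the fillable-sphere insert set.
CYLINDER_INNER_DIAMETER_MM = 206.0
CYLINDER_INNER_HEIGHT_MM = 186.0
CYLINDER_WALL_MM = 7.0
SPHERE_INNER_DIAMETERS_MM = (9.9, 12.4, 15.4, 19.8, 24.8, 31.3)
SPHERE_WALL_MM = 2.0

HO166_HALF_LIFE_H = 26.8

LABEL_AIR = 0
LABEL_BACKGROUND = 1
LABEL_WALL = 8
_FIRST_SPHERE_LABEL = 2
_MAX_SPHERES = 6


class GeometryError(ValueError):
    """Raised when phantom geometry is inconsistent (overlaps, out of bounds)."""


@dataclass(frozen=True)
class GridSpec:
    """A 3D voxel grid.

    Axes are ordered (z, y, x); ``voxel_size`` is mm per axis in the same
    order; ``origin`` is the mm position of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise ValueError("grid shape must be three integers >= 1")
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel sizes must be positive")

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in ml (1 ml = 1000 mm^3)."""
        return float(np.prod(self.voxel_size)) / 1000.0

    def axis_centers(self, axis: int) -> np.ndarray:
        """Voxel-center coordinates (mm) along one axis."""
        n = self.shape[axis]
        return self.origin[axis] + self.voxel_size[axis] * np.arange(n)

    def center_mesh(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Broadcastable (z, y, x) voxel-center coordinate arrays in mm."""
        z = self.axis_centers(0)[:, None, None]
        y = self.axis_centers(1)[None, :, None]
        x = self.axis_centers(2)[None, None, :]
        return z, y, x


def default_grid(n: int = 128, voxel_mm: float = 4.0) -> GridSpec:
    """Isotropic n^3 grid centered on the phantom axis at (0, 0, 0)."""
    half = voxel_mm * (n - 1) / 2.0
    return GridSpec(
        shape=(n, n, n),
        voxel_size=(voxel_mm, voxel_mm, voxel_mm),
        origin=(-half, -half, -half),
    )


@dataclass(frozen=True)
class SphereSpec:
    """A fillable hot sphere: center (mm, z/y/x), diameters in mm."""

    center: tuple[float, float, float]
    inner_diameter: float
    wall_thickness: float = SPHERE_WALL_MM
    activity_conc: float = 0.0  # MBq/ml

    def __post_init__(self) -> None:
        if self.inner_diameter <= 0:
            raise ValueError("inner_diameter must be positive")
        if self.wall_thickness < 0:
            raise ValueError("wall_thickness must be non-negative")
        if self.activity_conc < 0:
            raise ValueError("activity_conc must be non-negative")

    @property
    def outer_radius(self) -> float:
        return self.inner_diameter / 2.0 + self.wall_thickness

    @property
    def inner_volume_ml(self) -> float:
        return (np.pi / 6.0) * self.inner_diameter**3 / 1000.0

    @property
    def outer_volume_ml(self) -> float:
        return (4.0 / 3.0) * np.pi * self.outer_radius**3 / 1000.0


@dataclass(frozen=True)
class DecayParams:
    """Radioactive-decay parameters; default is the 166Ho half-life."""

    half_life: float = HO166_HALF_LIFE_H  # hours

    def __post_init__(self) -> None:
        if self.half_life <= 0:
            raise ValueError("half_life must be positive")


@dataclass
class VoxelPhantom:
    """Voxelized phantom: activity (MBq/ml), attenuation (1/cm), labels."""

    grid: GridSpec
    activity: np.ndarray
    mu: np.ndarray
    labels: np.ndarray
    analytic_volumes: dict[str, float] = field(default_factory=dict)  # ml
    region_conc: dict[int, float] = field(default_factory=dict)  # MBq/ml per label
    sphere_plane_z: float = 0.0  # mm, plane containing sphere centers

    def __post_init__(self) -> None:
        for name in ("activity", "mu", "labels"):
            arr = getattr(self, name)
            if arr.shape != tuple(self.grid.shape):
                raise ValueError(f"{name} shape {arr.shape} != grid {self.grid.shape}")
        if np.any(self.activity < 0):
            raise ValueError("activity must be non-negative")
        if np.any(self.mu < 0):
            raise ValueError("mu must be non-negative")

    @property
    def total_activity_MBq(self) -> float:
        return float(self.activity.sum()) * self.grid.voxel_volume_ml

    def voxel_volume_ml(self) -> float:
        return self.grid.voxel_volume_ml


def decay(activity_MBq: float, elapsed_hours: float, p: DecayParams = DecayParams()) -> float:
    """Exponential decay: activity * 2^(-elapsed/half_life)."""
    if elapsed_hours < 0:
        raise ValueError("elapsed time must be non-negative")
    return activity_MBq * 2.0 ** (-elapsed_hours / p.half_life)


# Photon mass attenuation coefficients mu/rho (cm^2/g), standard published
# tables for liquid water and PMMA, 50-150 keV.  Log-log interpolated.
_MU_TABLE_KEV = np.array([50.0, 60.0, 80.0, 100.0, 150.0])
_MU_RHO_WATER = np.array([0.2269, 0.2059, 0.1837, 0.1707, 0.1505])
_MU_RHO_PMMA = np.array([0.2074, 0.1924, 0.1751, 0.1641, 0.1456])
_DENSITY_WATER = 1.0  # g/cm^3
_DENSITY_PMMA = 1.19


def _mu_interp(energy_kev: float, mu_rho: np.ndarray, density: float) -> float:
    if not (_MU_TABLE_KEV[0] <= energy_kev <= _MU_TABLE_KEV[-1]):
        raise ValueError(
            f"energy {energy_kev} keV outside tabulated range "
            f"[{_MU_TABLE_KEV[0]}, {_MU_TABLE_KEV[-1]}]"
        )
    logmu = np.interp(np.log(energy_kev), np.log(_MU_TABLE_KEV), np.log(mu_rho))
    return float(np.exp(logmu)) * density


def attenuation_map(phantom: VoxelPhantom, energy_kev: float = 80.6) -> np.ndarray:
    """Linear attenuation map (1/cm) from the phantom labels.

    Water for background and sphere interiors, PMMA for walls, zero for air.
    """
    mu_water = _mu_interp(energy_kev, _MU_RHO_WATER, _DENSITY_WATER)
    mu_pmma = _mu_interp(energy_kev, _MU_RHO_PMMA, _DENSITY_PMMA)
    mu = np.zeros(phantom.labels.shape, dtype=float)
    mu[phantom.labels == LABEL_BACKGROUND] = mu_water
    sphere = (phantom.labels >= _FIRST_SPHERE_LABEL) & (phantom.labels < LABEL_WALL)
    mu[sphere] = mu_water
    mu[phantom.labels == LABEL_WALL] = mu_pmma
    return mu


def jaszczak_sphere_set(
    sphere_conc: float = 29.0 / 31.53,
    ring_radius_mm: float = 55.0,
    plane_z_mm: float = 0.0,
) -> list[SphereSpec]:
    """The six standard fillable spheres on a ring at the given axial plane.

    Default concentration fills the 31.53 ml total inner volume with 29 MBq,
    the study's hot-sphere loading (about 18x the background concentration).
    """
    angles = np.deg2rad(90.0 - 60.0 * np.arange(6))
    spheres = []
    for d, a in zip(SPHERE_INNER_DIAMETERS_MM, angles):
        center = (plane_z_mm, ring_radius_mm * np.sin(a), ring_radius_mm * np.cos(a))
        spheres.append(
            SphereSpec(
                center=tuple(float(c) for c in center),
                inner_diameter=d,
                activity_conc=sphere_conc,
            )
        )
    return spheres


def build_jaszczak(
    grid: GridSpec,
    spheres: list[SphereSpec] | None = None,
    background_conc: float = 312.0 / 6200.0,
    cylinder_inner_diameter: float = CYLINDER_INNER_DIAMETER_MM,
    cylinder_inner_height: float = CYLINDER_INNER_HEIGHT_MM,
    cylinder_wall: float = CYLINDER_WALL_MM,
    mu_energy_kev: float = 80.6,
) -> VoxelPhantom:
    """Voxelize a Jaszczak-style cylinder with hot-sphere inserts.

    The cylinder axis is z through (y, x) = (0, 0), axially centered on z=0.
    Default background concentration is 312 MBq in the 6200 ml background.
    Raises :class:`GeometryError` for spheres outside the inner cylinder or
    overlapping each other.
    """
    if spheres is None:
        spheres = []
    if len(spheres) > _MAX_SPHERES:
        raise GeometryError(f"at most {_MAX_SPHERES} spheres supported")
    if background_conc < 0:
        raise ValueError("background_conc must be non-negative")

    r_in = cylinder_inner_diameter / 2.0
    h_in = cylinder_inner_height

    # Geometry validation against the inner cylinder.
    for i, s in enumerate(spheres):
        zc, yc, xc = s.center
        radial = np.hypot(yc, xc)
        if radial + s.outer_radius > r_in or abs(zc) + s.outer_radius > h_in / 2.0:
            raise GeometryError(f"sphere {i} (d={s.inner_diameter} mm) outside inner cylinder")
    for i in range(len(spheres)):
        for j in range(i + 1, len(spheres)):
            si, sj = spheres[i], spheres[j]
            dist = np.linalg.norm(np.subtract(si.center, sj.center))
            if dist < si.outer_radius + sj.outer_radius:
                raise GeometryError(f"spheres {i} and {j} overlap")

    z, y, x = grid.center_mesh()
    rho2 = y**2 + x**2
    in_z = np.abs(z) <= h_in / 2.0
    in_z_outer = np.abs(z) <= h_in / 2.0 + cylinder_wall

    labels = np.full(grid.shape, LABEL_AIR, dtype=np.int16)
    outer_cyl = (rho2 <= (r_in + cylinder_wall) ** 2) & in_z_outer
    inner_cyl = (rho2 <= r_in**2) & in_z
    labels[outer_cyl] = LABEL_WALL
    labels[inner_cyl] = LABEL_BACKGROUND

    region_conc: dict[int, float] = {LABEL_BACKGROUND: background_conc}
    for i, s in enumerate(spheres):
        zc, yc, xc = s.center
        d2 = (z - zc) ** 2 + (y - yc) ** 2 + (x - xc) ** 2
        shell = d2 <= s.outer_radius**2
        interior = d2 <= (s.inner_diameter / 2.0) ** 2
        labels[shell] = LABEL_WALL
        label = _FIRST_SPHERE_LABEL + i
        labels[interior] = label
        region_conc[label] = s.activity_conc

    activity = np.zeros(grid.shape, dtype=float)
    activity[labels == LABEL_BACKGROUND] = background_conc
    for i, s in enumerate(spheres):
        activity[labels == _FIRST_SPHERE_LABEL + i] = s.activity_conc

    volumes: dict[str, float] = {
        "cylinder_inner_ml": np.pi * r_in**2 * h_in / 1000.0,
    }
    sphere_inner_total = 0.0
    sphere_outer_total = 0.0
    for i, s in enumerate(spheres):
        volumes[f"sphere_{i}_inner_ml"] = s.inner_volume_ml
        sphere_inner_total += s.inner_volume_ml
        sphere_outer_total += s.outer_volume_ml
    volumes["spheres_inner_total_ml"] = sphere_inner_total
    volumes["background_ml"] = volumes["cylinder_inner_ml"] - sphere_outer_total

    phantom = VoxelPhantom(
        grid=grid,
        activity=activity,
        mu=np.zeros(grid.shape),
        labels=labels,
        analytic_volumes=volumes,
        region_conc=region_conc,
        sphere_plane_z=float(spheres[0].center[0]) if spheres else 0.0,
    )
    phantom.mu = attenuation_map(phantom, mu_energy_kev)
    return phantom
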