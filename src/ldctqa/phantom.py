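"""Synthetic chest-CT phantoms with exact ground truth.

The generator builds a voxelized chest on a configurable grid in the
package's canonical orientation (axis 0 right, axis 1 posterior, axis 2
cranial): two elliptic-cylinder lungs partitioned into five lobes, a
"candy-cane" aorta — descending limb, arch, ascending limb — with a lumen
of configurable radius wrapped in a wall of configurable thickness, soft
tissue elsewhere inside a body ellipse, and air outside.  Empty cranial and
caudal scan margins (slices without lung) emulate over-/underscanning with
exactly known distances, and additive Gaussian noise of known standard
deviation is injected on top of the piecewise-constant HU geometry.

Every mask the pipeline consumes or should reproduce is returned as ground
truth: lobe masks, the aorta (lumen + wall), the lumen alone, the wall, and
labels for the descending and ascending limbs.  The truth masks are the
noise-free geometry; determinism is guaranteed by the spec's seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage as ndi

from .segmentation import LOBE_LABELS, BinaryMask3D
from .volume_io import AcquisitionMeta, CTVolume

__all__ = [
    "PhantomSpec",
    "PhantomTruth",
    "InfeasibleGeometryError",
    "generate_phantom",
    "generate_cohort",
]


class InfeasibleGeometryError(ValueError):
    """The requested phantom geometry does not fit the grid."""


@dataclass
class PhantomSpec:
    """Parameters of one synthetic chest volume.

    Defaults describe a modest screening-like chest at 1.2 × 1.2 × 2.0 mm
    voxels.  The caudal gap default (16 slices = 32 mm) mirrors typical
    caudal overscanning in screening cohorts; the cranial gap must also host
    the aortic arch, which this phantom places above the lung apex, so its
    default (20 slices = 40 mm) is geometry-driven.  ``noise_sigma`` is the
    SD of the additive Gaussian HU noise (default 25 HU ≈ a normalized noise
    in the mid-30s at the default voxel volume of 2.88 mm³).
    """

    shape: tuple[int, int, int] = (96, 96, 110)
    spacing: tuple[float, float, float] = (1.2, 1.2, 2.0)
    caudal_gap_slices: int = 16
    cranial_gap_slices: int = 20
    # lung geometry (mm): elliptic cylinders mirrored about the midline
    lung_semiaxis_x_mm: float = 22.0
    lung_semiaxis_y_mm: float = 34.0
    lung_offset_x_mm: float = 26.0
    lung_center_y_mm: float = -4.0
    # aorta geometry (mm)
    arch_enabled: bool = True
    lumen_radius_mm: float = 9.0
    wall_thickness_mm: float = 1.9
    arch_radius_mm: float = 22.0
    descending_y_mm: float = 24.0
    arch_clearance_mm: float = 2.0
    # tissue HU values
    lung_hu: float = -800.0
    blood_hu: float = 40.0
    wall_hu: float = 50.0
    soft_tissue_hu: float = 30.0
    air_hu: float = -1000.0
    noise_sigma: float = 25.0
    seed: int = 0

    def validate(self) -> None:
        nx, ny, nz = self.shape
        dx, dy, dz = self.spacing
        if min(self.shape) < 8:
            raise InfeasibleGeometryError(f"grid {self.shape} too small")
        if any(s <= 0 for s in self.spacing):
            raise InfeasibleGeometryError(f"spacing must be positive: {self.spacing}")
        if self.caudal_gap_slices < 0 or self.cranial_gap_slices < 0:
            raise InfeasibleGeometryError("scan gaps must be >= 0")
        if self.caudal_gap_slices + self.cranial_gap_slices >= nz - 4:
            raise InfeasibleGeometryError("scan gaps leave too few slices for the lungs")
        if self.wall_thickness_mm < 0 or self.lumen_radius_mm <= self.wall_thickness_mm:
            raise InfeasibleGeometryError("need lumen radius > wall thickness >= 0")
        if self.noise_sigma < 0:
            raise InfeasibleGeometryError("noise_sigma must be >= 0")
        outer = self.lumen_radius_mm + self.wall_thickness_mm
        if self.lung_offset_x_mm + self.lung_semiaxis_x_mm > (nx - 1) * dx / 2:
            raise InfeasibleGeometryError("lungs exceed the grid in x")
        if abs(self.lung_center_y_mm) + self.lung_semiaxis_y_mm > (ny - 1) * dy / 2:
            raise InfeasibleGeometryError("lungs exceed the grid in y")
        if self.descending_y_mm + outer > (ny - 1) * dy / 2:
            raise InfeasibleGeometryError("descending aorta exceeds the grid in y")
        if self.arch_enabled:
            # arch apex (outer surface) must fit below the scan top
            apex = self._lung_top_mm + self.arch_clearance_mm + self.arch_radius_mm + outer
            if apex > (nz - 1) * dz:
                raise InfeasibleGeometryError(
                    "aortic arch does not fit in the cranial gap; enlarge "
                    "cranial_gap_slices or disable the arch")
            asc_y = self.descending_y_mm - 2 * self.arch_radius_mm
            if abs(asc_y) + outer > (ny - 1) * dy / 2:
                raise InfeasibleGeometryError("ascending aorta exceeds the grid in y")

    @property
    def _lung_top_mm(self) -> float:
        nz = self.shape[2]
        return (nz - 1 - self.cranial_gap_slices) * self.spacing[2]

    @property
    def _lung_bottom_mm(self) -> float:
        return self.caudal_gap_slices * self.spacing[2]


@dataclass
class PhantomTruth:
    """Exact ground truth of a generated phantom."""

    lobes: dict[str, BinaryMask3D]
    aorta: BinaryMask3D            #: lumen + wall
    lumen: BinaryMask3D            #: blood only
    wall: BinaryMask3D
    descending_lumen: BinaryMask3D  #: lumen restricted to the descending limb
    ascending_lumen: BinaryMask3D
    margins_mm: tuple[float, float]  #: (caudal, cranial) empty-margin distance
    caudal_gap_slices: int
    cranial_gap_slices: int
    underscan_caudal: bool
    underscan_cranial: bool
    noise_sigma: float
    spec: PhantomSpec

    @property
    def lung(self) -> BinaryMask3D:
        out = np.zeros(self.aorta.shape, dtype=bool)
        for m in self.lobes.values():
            out |= m.voxels
        return BinaryMask3D(out, self.aorta.spacing)


# ---------------------------------------------------------------------------
# geometry rasterization
# ---------------------------------------------------------------------------

def _grids_mm(spec: PhantomSpec):
    nx, ny, nz = spec.shape
    dx, dy, dz = spec.spacing
    x = (np.arange(nx) - (nx - 1) / 2) * dx
    y = (np.arange(ny) - (ny - 1) / 2) * dy
    z = np.arange(nz) * dz
    return x[:, None, None], y[None, :, None], z[None, None, :]


def _centerline_points(spec: PhantomSpec) -> np.ndarray:
    """Sampled aorta centerline in mm, as an (n, 3) array of (x, y, z)."""
    step = min(spec.spacing) / 2.0
    desc_y = spec.descending_y_mm
    z_low = max(0.0, spec._lung_bottom_mm - 20.0)
    z_arch = spec._lung_top_mm + spec.arch_clearance_mm
    pts = []
    # descending limb (present in all phantoms)
    for z in np.arange(z_low, z_arch + step, step):
        pts.append((0.0, desc_y, z))
    if spec.arch_enabled:
        rho = spec.arch_radius_mm
        asc_y = desc_y - 2 * rho
        yc = desc_y - rho
        # semicircular arch in the y-z plane, apex above the lung top
        for phi in np.arange(0.0, np.pi + step / rho, step / rho):
            pts.append((0.0, yc + rho * np.cos(phi), z_arch + rho * np.sin(phi)))
        # ascending limb down to mid-lung (aortic valve level)
        z_valve = 0.5 * (spec._lung_bottom_mm + spec._lung_top_mm)
        for z in np.arange(z_valve, z_arch + step, step):
            pts.append((0.0, asc_y, z))
    return np.asarray(pts)


def _distance_to_centerline(spec: PhantomSpec, pts: np.ndarray) -> np.ndarray:
    """Per-voxel Euclidean distance (mm) to the rasterized centerline."""
    nx, ny, nz = spec.shape
    dx, dy, dz = spec.spacing
    seed = np.zeros(spec.shape, dtype=bool)
    ix = np.clip(np.round(pts[:, 0] / dx + (nx - 1) / 2).astype(int), 0, nx - 1)
    iy = np.clip(np.round(pts[:, 1] / dy + (ny - 1) / 2).astype(int), 0, ny - 1)
    iz = np.clip(np.round(pts[:, 2] / dz).astype(int), 0, nz - 1)
    seed[ix, iy, iz] = True
    return ndi.distance_transform_edt(~seed, sampling=spec.spacing)


def _build_lobes(spec: PhantomSpec, aorta_outer: np.ndarray) -> dict[str, np.ndarray]:
    """Two elliptic-cylinder lungs, partitioned into 3 right + 2 left z-bands."""
    x, y, z = _grids_mm(spec)
    nz = spec.shape[2]
    z0, z1 = spec.caudal_gap_slices, nz - 1 - spec.cranial_gap_slices
    zi = np.arange(nz)[None, None, :]
    in_z = (zi >= z0) & (zi <= z1)

    def ellipse(cx: float) -> np.ndarray:
        return (((x - cx) / spec.lung_semiaxis_x_mm) ** 2
                + ((y - spec.lung_center_y_mm) / spec.lung_semiaxis_y_mm) ** 2) <= 1.0

    # keep lungs clear of the aorta (and one voxel of separation)
    keep_out = ndi.binary_dilation(aorta_outer, iterations=1)
    right = ellipse(+spec.lung_offset_x_mm) & in_z & ~keep_out
    left = ellipse(-spec.lung_offset_x_mm) & in_z & ~keep_out

    # planar partition into lobes along z; no anatomical fidelity claimed
    n_lung = z1 - z0 + 1
    r_cuts = (z0 + n_lung // 3, z0 + 2 * n_lung // 3)
    l_cut = z0 + n_lung // 2
    lobes = {
        "right_lower": right & (zi < r_cuts[0]),
        "right_middle": right & (zi >= r_cuts[0]) & (zi < r_cuts[1]),
        "right_upper": right & (zi >= r_cuts[1]),
        "left_lower": left & (zi < l_cut),
        "left_upper": left & (zi >= l_cut),
    }
    return lobes


def generate_phantom(spec: Optional[PhantomSpec] = None) -> tuple[CTVolume, PhantomTruth]:
    """Generate one phantom volume and its ground truth.

    Deterministic given ``spec.seed``: the HU volume is the piecewise
    constant tissue geometry plus i.i.d. Gaussian(0, ``noise_sigma``) noise;
    truth masks are the noise-free geometry.
    """
    spec = spec or PhantomSpec()
    spec.validate()
    x, y, _z = _grids_mm(spec)
    dx, dy, _dz = spec.spacing
    nx, ny, _nz = spec.shape

    pts = _centerline_points(spec)
    dist = _distance_to_centerline(spec, pts)
    outer_r = spec.lumen_radius_mm + spec.wall_thickness_mm
    aorta = dist <= outer_r
    lumen = dist <= spec.lumen_radius_mm
    wall = aorta & ~lumen

    lobes = _build_lobes(spec, aorta)
    lung = np.zeros(spec.shape, dtype=bool)
    for m in lobes.values():
        lung |= m

    # limb labels: vertical cylinders below the arch take-off
    z_arch = spec._lung_top_mm + spec.arch_clearance_mm
    _xg, yg, zg = _grids_mm(spec)
    below_arch = zg <= z_arch
    desc_lumen = lumen & (np.abs(yg - spec.descending_y_mm) <= outer_r) & below_arch
    if spec.arch_enabled:
        asc_y = spec.descending_y_mm - 2 * spec.arch_radius_mm
        asc_lumen = lumen & (np.abs(yg - asc_y) <= outer_r) & below_arch
    else:
        asc_lumen = np.zeros(spec.shape, dtype=bool)

    # body: elliptic cylinder of soft tissue containing everything, air outside
    body = ((x / ((nx - 1) * dx / 2 - 1.0)) ** 2
            + (y / ((ny - 1) * dy / 2 - 1.0)) ** 2) <= 1.0
    body = np.broadcast_to(body, spec.shape) | aorta | lung

    hu = np.full(spec.shape, spec.air_hu, dtype=np.float64)
    hu[body] = spec.soft_tissue_hu
    hu[lung] = spec.lung_hu
    hu[wall] = spec.wall_hu
    hu[lumen] = spec.blood_hu

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sigma > 0:
        hu = hu + rng.normal(0.0, spec.noise_sigma, size=spec.shape)

    vol = CTVolume(voxels=hu, spacing=spec.spacing,
                   acquisition=AcquisitionMeta(source_format="NIfTI"))
    sp = spec.spacing
    truth = PhantomTruth(
        lobes={k: BinaryMask3D(v, sp) for k, v in lobes.items()},
        aorta=BinaryMask3D(aorta, sp),
        lumen=BinaryMask3D(lumen, sp),
        wall=BinaryMask3D(wall, sp),
        descending_lumen=BinaryMask3D(desc_lumen, sp),
        ascending_lumen=BinaryMask3D(asc_lumen, sp),
        margins_mm=(spec.caudal_gap_slices * sp[2], spec.cranial_gap_slices * sp[2]),
        caudal_gap_slices=spec.caudal_gap_slices,
        cranial_gap_slices=spec.cranial_gap_slices,
        underscan_caudal=spec.caudal_gap_slices == 0,
        underscan_cranial=spec.cranial_gap_slices == 0,
        noise_sigma=spec.noise_sigma,
        spec=spec,
    )
    assert all(truth.lobes[l].shape == spec.shape for l in LOBE_LABELS)
    return vol, truth


# ---------------------------------------------------------------------------
# randomized cohorts
# ---------------------------------------------------------------------------

def generate_cohort(n: int, seed: int = 0, underscan_fraction: float = 0.0,
                    caudal_gap_range: tuple[int, int] = (4, 24),
                    cranial_gap_range: tuple[int, int] = (18, 26),
                    noise_sigma_range: tuple[float, float] = (10.0, 60.0),
                    base_spec: Optional[PhantomSpec] = None,
                    ) -> list[tuple[CTVolume, PhantomTruth]]:
    """Generate ``n`` reproducibly randomized phantoms.

    Gaps, noise level, lung size and lumen radius are drawn uniformly from
    their ranges.  ``round(underscan_fraction * n)`` phantoms are forced to
    touch the caudal scan edge (caudal gap 0) so the underscan flag is
    exercised; which phantoms are forced is drawn from the same seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    base = base_spec or PhantomSpec()
    rng = np.random.default_rng(seed)
    n_forced = int(round(underscan_fraction * n))
    forced = set(rng.choice(n, size=n_forced, replace=False).tolist()) if n_forced else set()
    out = []
    for i in range(n):
        spec = replace(
            base,
            caudal_gap_slices=0 if i in forced else int(rng.integers(*caudal_gap_range)),
            cranial_gap_slices=int(rng.integers(*cranial_gap_range)),
            noise_sigma=float(rng.uniform(*noise_sigma_range)),
            lung_semiaxis_x_mm=base.lung_semiaxis_x_mm + float(rng.uniform(-3, 3)),
            lung_semiaxis_y_mm=base.lung_semiaxis_y_mm + float(rng.uniform(-3, 3)),
            lumen_radius_mm=float(rng.uniform(8.0, 10.0)),
            seed=int(rng.integers(2 ** 31)),
        )
        out.append(generate_phantom(spec))
    return out
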