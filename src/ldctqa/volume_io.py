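"""Reading CT volumes, orientation canonicalization and pre-flight integrity checks.

Internally every volume is stored in a fixed "RPS" convention: array axis 0
increases toward the patient's right, axis 1 toward the back (posterior) and
axis 2 toward the head (cranial).  All downstream geometry — cranial/caudal
coverage accounting and the dorsal-component selection in the aortic-lumen
extraction — relies on these fixed axes, so reorientation happens exactly
once, at load time, driven by the NIfTI affine or the DICOM geometry tags.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import nibabel as nib
from nibabel import orientations as nibo

__all__ = [
    "AcquisitionMeta",
    "CTVolume",
    "IntegrityFlag",
    "VolumeLoadError",
    "CANONICAL_AXCODES",
    "load_volume",
    "save_volume",
    "save_mask",
    "check_integrity",
]

#: canonical axis codes: Right, Posterior, Superior
CANONICAL_AXCODES = ("R", "P", "S")

#: default floor below which HU values are considered corrupted
DEFAULT_HU_FLOOR = -19_000.0


class VolumeLoadError(RuntimeError):
    """Raised when a volume cannot be read (corrupt, inconsistent or unsupported)."""


@dataclass
class AcquisitionMeta:
    """Acquisition metadata relevant to dose/noise interpretation.

    All fields are optional because NIfTI files and anonymized exports
    frequently lack them; ``effective_mas`` (noise module) requires ``mas``
    and ``pitch``.
    """

    mas: Optional[float] = None
    pitch: Optional[float] = None
    kvp: Optional[float] = None
    source_format: str = "NIfTI"
    rescale_present: bool = True

    def __post_init__(self) -> None:
        if self.mas is not None and self.mas <= 0:
            raise ValueError(f"mAs must be > 0, got {self.mas}")
        if self.pitch is not None and self.pitch <= 0:
            raise ValueError(f"pitch must be > 0, got {self.pitch}")


@dataclass
class CTVolume:
    """A HU-calibrated CT volume in canonical (R, P, S) orientation.

    Parameters
    ----------
    voxels:
        3-D float array of Hounsfield units.
    spacing:
        ``(dx, dy, dz)`` voxel spacing in mm along the three array axes.
        ``dz`` is the cranio-caudal step: slice count × dz converts slice
        accounting into millimetres.
    acquisition:
        Scanner metadata, see :class:`AcquisitionMeta`.
    axis_convention:
        Marker string; ``"RPS"`` after successful canonicalization.
    slice_positions:
        Optional per-slice coordinates (mm) along the cranio-caudal axis, in
        array order.  Present for DICOM series (from image positions); used
        by :func:`check_integrity` to detect inconsistent slice spacing.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    acquisition: AcquisitionMeta = field(default_factory=AcquisitionMeta)
    axis_convention: str = "RPS"
    slice_positions: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or self.voxels.size == 0:
            raise ValueError("voxels must be a non-empty 3-D array")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be three positive values, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass(frozen=True)
class IntegrityFlag:
    """A single pre-flight finding; ``code`` is from a closed vocabulary."""

    code: str
    detail: str

    CODES = ("HU_IMPLAUSIBLE", "SPACING_INCONSISTENT", "ORIENTATION_UNRESOLVED", "RESCALE_MISSING")

    def __post_init__(self) -> None:
        if self.code not in self.CODES:
            raise ValueError(f"unknown integrity code {self.code!r}")


# ---------------------------------------------------------------------------
# orientation helpers
# ---------------------------------------------------------------------------

def _reorient_to_canonical(data: np.ndarray, affine: np.ndarray,
                           zooms: Sequence[float]) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Reorder/flip ``data`` so its axes follow :data:`CANONICAL_AXCODES`.

    Returns the reoriented array and the correspondingly permuted spacing.
    Raises :class:`VolumeLoadError` when the affine does not resolve to a
    definite orientation.
    """
    try:
        src_ornt = nibo.io_orientation(affine)
    except Exception as exc:  # pragma: no cover - defensive
        raise VolumeLoadError(f"orientation could not be determined: {exc}") from exc
    if np.any(np.isnan(src_ornt)):
        raise VolumeLoadError("orientation could not be determined from the affine")
    dst_ornt = nibo.axcodes2ornt(CANONICAL_AXCODES)
    transform = nibo.ornt_transform(src_ornt, dst_ornt)
    out = nibo.apply_orientation(data, transform)
    spacing = [0.0, 0.0, 0.0]
    for src_axis, (dst_axis, _flip) in enumerate(transform):
        spacing[int(dst_axis)] = float(zooms[src_axis])
    return np.ascontiguousarray(out), (spacing[0], spacing[1], spacing[2])


def _canonical_affine(spacing: Sequence[float]) -> np.ndarray:
    """RAS affine of a canonical (R,P,S) array: y is flipped (P = -A)."""
    dx, dy, dz = spacing
    return np.diag([dx, -dy, dz, 1.0])


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_volume(path: str | os.PathLike, format_hint: Optional[str] = None) -> CTVolume:
    """Load a CT volume from a NIfTI file or a DICOM series directory.

    The result is HU-calibrated (DICOM rescale slope/intercept applied when
    present) and canonically oriented.  ``format_hint`` may be ``"nifti"`` or
    ``"dicom"``; otherwise the format is inferred from the path.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"volume path does not exist: {p}")
    fmt = format_hint
    if fmt is None:
        fmt = "dicom" if p.is_dir() else "nifti"
    fmt = fmt.lower()
    if fmt == "nifti":
        return _load_nifti(p)
    if fmt == "dicom":
        return _load_dicom_series(p)
    raise ValueError(f"unknown format hint {format_hint!r}")


def _load_nifti(path: Path) -> CTVolume:
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(dtype=np.float64))
    except FileNotFoundError:
        raise
    except Exception as exc:
        raise VolumeLoadError(f"corrupt or unreadable NIfTI file {path}: {exc}") from exc
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeLoadError(f"expected a 3-D NIfTI volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    data, spacing = _reorient_to_canonical(data, img.affine, zooms)
    meta = AcquisitionMeta(source_format="NIfTI")
    return CTVolume(voxels=data, spacing=spacing, acquisition=meta)


def _load_dicom_series(path: Path) -> CTVolume:
    import pydicom

    files = sorted(f for f in path.iterdir() if f.is_file())
    datasets = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue  # non-DICOM clutter in the directory
        if hasattr(ds, "PixelData"):
            datasets.append(ds)
    if not datasets:
        raise VolumeLoadError(f"no readable DICOM images found in {path}")

    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) != 1:
        raise VolumeLoadError(f"directory mixes {len(uids)} DICOM series; expected one")

    try:
        iops = np.array([np.asarray(ds.ImageOrientationPatient, dtype=float) for ds in datasets])
        ipps = np.array([np.asarray(ds.ImagePositionPatient, dtype=float) for ds in datasets])
    except Exception as exc:
        raise VolumeLoadError(f"missing DICOM geometry tags: {exc}") from exc
    if not np.allclose(iops, iops[0], atol=1e-4):
        raise VolumeLoadError("mixed image orientations within the series")

    row_cos = iops[0, :3]   # direction of increasing column index
    col_cos = iops[0, 3:]   # direction of increasing row index
    normal = np.cross(row_cos, col_cos)
    z_proj = ipps @ normal
    order = np.argsort(z_proj)
    datasets = [datasets[i] for i in order]
    ipps = ipps[order]
    z_proj = z_proj[order]

    rescale_present = all(
        hasattr(ds, "RescaleSlope") and hasattr(ds, "RescaleIntercept") for ds in datasets
    )
    slices = []
    for ds in datasets:
        arr = ds.pixel_array.astype(np.float64)
        if rescale_present:
            arr = arr * float(ds.RescaleSlope) + float(ds.RescaleIntercept)
        slices.append(arr)
    shapes = {s.shape for s in slices}
    if len(shapes) != 1:
        raise VolumeLoadError("inconsistent slice shapes within the series")
    vol = np.stack(slices, axis=-1)  # (row, col, slice)

    ps = np.asarray(datasets[0].PixelSpacing, dtype=float)  # (row spacing, col spacing)
    if len(datasets) > 1:
        dz = _modal_spacing(np.diff(z_proj))
    else:
        dz = float(getattr(datasets[0], "SliceThickness", 1.0) or 1.0)
    if dz <= 0:
        raise VolumeLoadError("non-positive inter-slice spacing")

    # LPS affine for array axes (row, col, slice), then LPS -> RAS (negate x, y).
    affine = np.eye(4)
    affine[:3, 0] = col_cos * ps[0]
    affine[:3, 1] = row_cos * ps[1]
    affine[:3, 2] = normal * dz
    affine[:3, 3] = ipps[0]
    affine[:2, :] *= -1.0

    zooms = (ps[0], ps[1], dz)
    data, spacing = _reorient_to_canonical(vol, affine, zooms)

    ds0 = datasets[0]
    meta = AcquisitionMeta(
        mas=_optional_float(getattr(ds0, "Exposure", None)),
        pitch=_optional_float(getattr(ds0, "SpiralPitchFactor", None)),
        kvp=_optional_float(getattr(ds0, "KVP", None)),
        source_format="DICOM-series",
        rescale_present=rescale_present,
    )
    # slice positions along the canonical cranio-caudal axis, ascending
    positions = np.sort(z_proj.copy())
    return CTVolume(voxels=data, spacing=spacing, acquisition=meta, slice_positions=positions)


def _optional_float(value) -> Optional[float]:
    if value in (None, ""):
        return None
    try:
        v = float(value)
    except (TypeError, ValueError):
        return None
    return v if v > 0 else None


def _modal_spacing(diffs: np.ndarray, decimals: int = 3) -> float:
    """Most frequent inter-slice distance, robust to a few gapped slices."""
    rounded = np.round(np.abs(diffs), decimals)
    values, counts = np.unique(rounded, return_counts=True)
    return float(values[np.argmax(counts)])


# ---------------------------------------------------------------------------
# saving (canonical arrays -> NIfTI)
# ---------------------------------------------------------------------------

def save_volume(vol: CTVolume, path: str | os.PathLike) -> None:
    """Write a canonical volume to NIfTI (float64, no scaling: lossless)."""
    img = nib.Nifti1Image(np.asarray(vol.voxels, dtype=np.float64),
                          _canonical_affine(vol.spacing))
    img.header.set_data_dtype(np.float64)
    nib.save(img, str(path))


def save_mask(mask_voxels: np.ndarray, spacing: Sequence[float], path: str | os.PathLike) -> None:
    """Write a boolean mask on a canonical grid to NIfTI (uint8 labels 0/1)."""
    img = nib.Nifti1Image(np.asarray(mask_voxels, dtype=np.uint8),
                          _canonical_affine(spacing))
    img.header.set_data_dtype(np.uint8)
    nib.save(img, str(path))


# ---------------------------------------------------------------------------
# integrity checks
# ---------------------------------------------------------------------------

def check_integrity(vol: CTVolume, hu_floor: float = DEFAULT_HU_FLOOR,
                    spacing_tolerance: float = 0.10) -> list[IntegrityFlag]:
    """Pure pre-flight checks; returns a possibly-empty list of flags.

    * ``HU_IMPLAUSIBLE`` — minimum HU below ``hu_floor`` (default −19,000),
      the signature of corrupted rescale data.
    * ``SPACING_INCONSISTENT`` — any inter-slice distance deviating from the
      modal distance by more than ``spacing_tolerance`` (relative).
    * ``RESCALE_MISSING`` — DICOM series lacked rescale slope/intercept.
    * ``ORIENTATION_UNRESOLVED`` — the volume is not in canonical form.
    """
    flags: list[IntegrityFlag] = []
    vmin = float(np.min(vol.voxels))
    if vmin < hu_floor:
        flags.append(IntegrityFlag(
            "HU_IMPLAUSIBLE", f"minimum HU {vmin:.0f} below plausibility floor {hu_floor:.0f}"))
    if vol.slice_positions is not None and len(vol.slice_positions) >= 3:
        diffs = np.abs(np.diff(np.asarray(vol.slice_positions, dtype=float)))
        mode = _modal_spacing(diffs)
        if mode > 0 and np.any(np.abs(diffs - mode) / mode > spacing_tolerance):
            worst = float(np.max(np.abs(diffs - mode)))
            flags.append(IntegrityFlag(
                "SPACING_INCONSISTENT",
                f"inter-slice distances deviate from modal {mode:.3f} mm by up to {worst:.3f} mm"))
    if not vol.acquisition.rescale_present:
        flags.append(IntegrityFlag(
            "RESCALE_MISSING", "DICOM rescale slope/intercept absent; HU calibration unverified"))
    if vol.axis_convention != "RPS":
        flags.append(IntegrityFlag(
            "ORIENTATION_UNRESOLVED", f"axis convention {vol.axis_convention!r} is not canonical"))
    return flags
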