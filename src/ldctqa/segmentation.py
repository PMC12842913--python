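"""Segmentation adapter: one interface over external segmenters and mask files.

The pipeline needs six organ masks on the exact grid of the CT volume: the
five lung lobes and the aorta.  They may come from an external neural
segmenter (TotalSegmentator, a soft dependency), from precomputed NIfTI
label files, or — in tests — straight from phantom ground truth.  Masks are
never resampled: a grid mismatch is an error, because silent interpolation
would corrupt both the boundary slices that coverage depends on and the
partial-volume voxels that would bias the noise estimate.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional

import numpy as np
import nibabel as nib

from .volume_io import CTVolume, VolumeLoadError, _reorient_to_canonical

__all__ = [
    "LOBE_LABELS",
    "BinaryMask3D",
    "SegmentationSet",
    "SegmentationError",
    "SegmenterUnavailableError",
    "load_masks",
    "segment",
    "register_backend",
]

#: canonical lobe label order: right upper/middle/lower, left upper/lower
LOBE_LABELS = ("right_upper", "right_middle", "right_lower", "left_upper", "left_lower")


class SegmentationError(RuntimeError):
    """Invalid, missing or grid-incompatible segmentation input."""


class SegmenterUnavailableError(SegmentationError):
    """The requested segmentation backend is not installed."""


@dataclass
class BinaryMask3D:
    """A boolean mask aligned to a canonical CT grid."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if self.voxels.ndim != 3:
            raise ValueError("mask must be 3-D")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(np.count_nonzero(self.voxels))

    def copy(self) -> "BinaryMask3D":
        return BinaryMask3D(self.voxels.copy(), self.spacing)

    def check_grid(self, vol: CTVolume, what: str = "mask") -> None:
        """Assert shape and spacing agreement with a reference volume."""
        if self.shape != vol.shape:
            raise SegmentationError(
                f"{what} shape {self.shape} does not match volume shape {vol.shape}")
        if not np.allclose(self.spacing, vol.spacing, rtol=1e-4, atol=1e-4):
            raise SegmentationError(
                f"{what} spacing {self.spacing} does not match volume spacing {vol.spacing}")


@dataclass
class SegmentationSet:
    """Five lobe masks plus the aorta mask, all on one shared grid."""

    lobes: dict[str, BinaryMask3D]
    aorta: BinaryMask3D
    backend: str = "unspecified"
    backend_version: Optional[str] = None
    grid_shape: tuple[int, int, int] = field(init=False)

    def __post_init__(self) -> None:
        missing = [l for l in LOBE_LABELS if l not in self.lobes]
        if missing:
            raise SegmentationError(f"missing lobe masks: {', '.join(missing)}")
        shapes = {m.shape for m in self.lobes.values()} | {self.aorta.shape}
        if len(shapes) != 1:
            raise SegmentationError(f"masks disagree on grid shape: {sorted(shapes)}")
        spacings = {m.spacing for m in self.lobes.values()} | {self.aorta.spacing}
        if len(spacings) != 1:
            raise SegmentationError(f"masks disagree on spacing: {sorted(spacings)}")
        self.grid_shape = self.aorta.shape

    def check_grid(self, vol: CTVolume) -> None:
        self.aorta.check_grid(vol, "aorta mask")
        for label, m in self.lobes.items():
            m.check_grid(vol, f"{label} mask")


# ---------------------------------------------------------------------------
# file-based masks
# ---------------------------------------------------------------------------

def _load_mask_file(path: Path, vol: CTVolume, label: str) -> BinaryMask3D:
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata())
    except FileNotFoundError:
        raise SegmentationError(f"mask file for {label!r} not found: {path}")
    except Exception as exc:
        raise SegmentationError(f"unreadable mask file for {label!r} ({path}): {exc}") from exc
    try:
        data, spacing = _reorient_to_canonical(data, img.affine, img.header.get_zooms()[:3])
    except VolumeLoadError as exc:
        raise SegmentationError(f"mask {label!r}: {exc}") from exc
    values = np.unique(data)
    if not np.all(np.isin(values, (0, 1))):
        raise SegmentationError(
            f"mask {label!r} is not binary: found values {values[:10].tolist()}")
    mask = BinaryMask3D(data.astype(bool), spacing)
    mask.check_grid(vol, f"{label} mask")
    return mask


def load_masks(paths: Mapping[str, str | os.PathLike], vol: CTVolume,
               backend: str = "precomputed") -> SegmentationSet:
    """Build a :class:`SegmentationSet` from NIfTI label files.

    ``paths`` must map every label in :data:`LOBE_LABELS` plus ``"aorta"`` to
    a readable binary NIfTI file on the volume's grid.  Shapes must match
    exactly — there is deliberately no resampling.
    """
    required = set(LOBE_LABELS) | {"aorta"}
    missing = sorted(required - set(paths))
    if missing:
        raise SegmentationError(f"missing mask labels: {', '.join(missing)}")
    lobes = {l: _load_mask_file(Path(paths[l]), vol, l) for l in LOBE_LABELS}
    aorta = _load_mask_file(Path(paths["aorta"]), vol, "aorta")
    return SegmentationSet(lobes=lobes, aorta=aorta, backend=backend)


# ---------------------------------------------------------------------------
# backend registry
# ---------------------------------------------------------------------------

_BACKENDS: dict[str, Callable[..., SegmentationSet]] = {}


def register_backend(name: str, fn: Callable[..., SegmentationSet]) -> None:
    _BACKENDS[name] = fn


def segment(vol: CTVolume, backend: str = "totalsegmentator", **kwargs) -> SegmentationSet:
    """Produce lobe + aorta masks for ``vol`` using the named backend.

    Built-in backends:

    * ``"precomputed"`` — requires ``paths=`` mapping labels to NIfTI files.
    * ``"phantom-truth"`` — requires ``truth=`` (a :class:`~ldctqa.phantom.PhantomTruth`).
    * ``"totalsegmentator"`` — external neural segmenter, optional at
      install time; raises :class:`SegmenterUnavailableError` when absent.
    """
    if backend not in _BACKENDS:
        raise SegmentationError(
            f"unknown backend {backend!r}; available: {sorted(_BACKENDS)}")
    result = _BACKENDS[backend](vol, **kwargs)
    result.check_grid(vol)
    return result


def _backend_precomputed(vol: CTVolume, paths: Mapping[str, str | os.PathLike] | None = None,
                         **_ignored) -> SegmentationSet:
    if paths is None:
        raise SegmentationError("backend 'precomputed' requires paths= mapping label -> file")
    return load_masks(paths, vol, backend="precomputed")


def _backend_phantom_truth(vol: CTVolume, truth=None, **_ignored) -> SegmentationSet:
    if truth is None:
        raise SegmentationError("backend 'phantom-truth' requires truth= (PhantomTruth)")
    lobes = {label: mask.copy() for label, mask in truth.lobes.items()}
    return SegmentationSet(lobes=lobes, aorta=truth.aorta.copy(), backend="phantom-truth")


def _backend_totalsegmentator(vol: CTVolume, **_ignored) -> SegmentationSet:
    try:
        import totalsegmentator  # noqa: F401
    except ImportError as exc:
        raise SegmenterUnavailableError(
            "the 'totalsegmentator' backend is not installed; install the "
            "totalsegmentator package, or supply precomputed masks via "
            "backend='precomputed' with paths={label: nifti_file}") from exc
    raise SegmenterUnavailableError(
        "totalsegmentator execution is not wired in this environment; "
        "run it externally and pass its masks via backend='precomputed'")


register_backend("precomputed", _backend_precomputed)
register_backend("phantom-truth", _backend_phantom_truth)
register_backend("totalsegmentator", _backend_totalsegmentator)
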