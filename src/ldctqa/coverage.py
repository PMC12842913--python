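"""Cranial/caudal scan-range coverage from the merged lung mask.

Overscanning is the scanned z-range extending beyond the lung parenchyma:
the number of slices strictly caudal (or cranial) to the lung mask times the
z-increment, with a zero-margin convention — no tolerance band is
subtracted, so the value is a continuous, maximally sensitive measure of
excess scan range.  Underscanning is flagged when lung tissue reaches the
first or last slice, meaning the lungs may be truncated; in that direction
the overscan distance is 0 by construction.  Operational alerting thresholds
are site configuration (see :mod:`ldctqa.report`), never hard-coded here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mask_ops import EmptyMaskError
from .segmentation import BinaryMask3D

__all__ = ["CoverageResult", "measure_coverage", "fraction_nonlung_slices"]


@dataclass
class CoverageResult:
    """Per-scan coverage accounting along the cranio-caudal axis.

    ``lung_slice_range`` holds 0-based inclusive indices (caudal-most,
    cranial-most) of slices containing lung; slice index increases cranially.
    """

    caudal_overscan_mm: float
    cranial_overscan_mm: float
    underscan_caudal: bool
    underscan_cranial: bool
    lung_slice_range: tuple[int, int]
    n_slices_total: int
    fraction_nonlung_slices: float

    def __post_init__(self) -> None:
        if self.underscan_caudal and self.caudal_overscan_mm != 0:
            raise ValueError("caudal underscan implies zero caudal overscan")
        if self.underscan_cranial and self.cranial_overscan_mm != 0:
            raise ValueError("cranial underscan implies zero cranial overscan")

    @property
    def total_overscan_mm(self) -> float:
        return self.caudal_overscan_mm + self.cranial_overscan_mm


def measure_coverage(lung: BinaryMask3D) -> CoverageResult:
    """Measure over-/underscanning from a merged lung mask in canonical orientation."""
    per_slice = lung.voxels.any(axis=(0, 1))
    n_total = int(per_slice.size)
    if not per_slice.any():
        raise EmptyMaskError("measure_coverage: lung mask is empty")
    dz = lung.spacing[2]
    first = int(np.argmax(per_slice))                    # caudal-most lung slice
    last = n_total - 1 - int(np.argmax(per_slice[::-1]))  # cranial-most lung slice
    underscan_caudal = first == 0
    underscan_cranial = last == n_total - 1
    return CoverageResult(
        caudal_overscan_mm=first * dz,
        cranial_overscan_mm=(n_total - 1 - last) * dz,
        underscan_caudal=underscan_caudal,
        underscan_cranial=underscan_cranial,
        lung_slice_range=(first, last),
        n_slices_total=n_total,
        fraction_nonlung_slices=fraction_nonlung_slices(lung),
    )


def fraction_nonlung_slices(lung: BinaryMask3D) -> float:
    """Proportion of slices containing no lung voxels at all."""
    per_slice = lung.voxels.any(axis=(0, 1))
    return float(np.count_nonzero(~per_slice)) / per_slice.size
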