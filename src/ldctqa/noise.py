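"""Image-noise estimation from aortic blood, normalized for voxel size.

The raw standard deviation of HU inside the lumen depends on resolution:
averaging voxels together reduces noise roughly with the square root of the
number of photons contributing.  The normalized value

    sigma_norm = sigma_raw * sqrt(v_raw / v_norm),      v_norm = 1 mm^3

reports how much noise would theoretically occur at a 1 mm^3 voxel, making
scans with different reconstruction grids comparable (within one
reconstruction kernel).  ``effective_mas = mAs / pitch`` is the
dose-relevant exposure per z-position for helical acquisitions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .segmentation import BinaryMask3D
from .volume_io import CTVolume

__all__ = ["NoiseResult", "NoiseUnavailableError", "compute_noise", "effective_mas", "V_NORM_MM3"]

#: reference voxel volume for normalization, mm^3
V_NORM_MM3 = 1.0


class NoiseUnavailableError(RuntimeError):
    """The lumen sample is too small for a reliable noise estimate."""


@dataclass
class NoiseResult:
    mu_raw: float        #: mean HU of lumen voxels
    sigma_raw: float     #: sample SD (n-1 denominator) of lumen HU
    v_raw: float         #: voxel volume dx*dy*dz in mm^3
    sigma_norm: float    #: sigma_raw * sqrt(v_raw / 1 mm^3)
    n_voxels: int        #: number of lumen voxels used

    def __post_init__(self) -> None:
        if self.sigma_raw < 0 or self.v_raw <= 0:
            raise ValueError("sigma_raw must be >= 0 and v_raw > 0")


def compute_noise(vol: CTVolume, lumen: BinaryMask3D, min_voxels: int = 100) -> NoiseResult:
    """Mean and SD of HU over the lumen voxels, plus the normalized SD.

    The SD uses the n−1 denominator (sample SD); at realistic lumen sizes
    the difference from the population SD is negligible, but the choice is
    fixed for reproducibility.  ``v_raw`` comes from the volume's spacing
    metadata.  Fewer than ``min_voxels`` lumen voxels raises
    :class:`NoiseUnavailableError` — callers report noise as unavailable
    rather than returning an unstable number.
    """
    if lumen.shape != vol.shape:
        raise ValueError(f"lumen shape {lumen.shape} does not match volume {vol.shape}")
    values = vol.voxels[lumen.voxels]
    n = int(values.size)
    if n < min_voxels:
        raise NoiseUnavailableError(
            f"only {n} lumen voxels; at least {min_voxels} required")
    v_raw = vol.voxel_volume_mm3
    sigma_raw = float(np.std(values, ddof=1))
    return NoiseResult(
        mu_raw=float(np.mean(values)),
        sigma_raw=sigma_raw,
        v_raw=v_raw,
        sigma_norm=sigma_raw * math.sqrt(v_raw / V_NORM_MM3),
        n_voxels=n,
    )


def effective_mas(mas: float, pitch: float) -> float:
    """Effective tube charge: mAs divided by helical pitch."""
    if mas <= 0:
        raise ValueError(f"mAs must be > 0, got {mas}")
    if pitch <= 0:
        raise ValueError(f"pitch must be > 0, got {pitch}")
    return mas / pitch
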