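"""Per-scan QA orchestration, JSON reports, exception flagging and PDF rendering.

``run_scan`` wires the full pipeline — load, integrity check, masks, lobe
merge, coverage, lumen extraction, noise — with soft-fail semantics: a
failure in a late stage (e.g. an unusable lumen) is recorded in the report
instead of aborting, so batch runs survive individual degenerate scans.
JSON is the primary artifact; the single-page PDF is derived and optional.
"""

from __future__ import annotations

import dataclasses
import datetime
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import yaml

from . import __version__
from .aorta import LumenExtractionError, extract_lumen
from .coverage import CoverageResult, measure_coverage
from .mask_ops import merge_lobes
from .noise import NoiseResult, NoiseUnavailableError, compute_noise
from .segmentation import SegmentationError, SegmentationSet, load_masks, segment
from .volume_io import CTVolume, IntegrityFlag, check_integrity, load_volume

__all__ = ["QAConfig", "QAReport", "run_scan", "flag_exceptions", "render_pdf"]


@dataclass
class QAConfig:
    """Runtime configuration; every threshold is site configuration, not a constant.

    ``max_*`` thresholds drive :func:`flag_exceptions`; ``None`` disables
    that particular check.
    """

    margin_mm: float = 3.0
    hu_floor: float = -19_000.0
    min_voxels: int = 100
    connectivity: int = 26
    spacing_tolerance: float = 0.10
    max_caudal_overscan_mm: Optional[float] = None
    max_cranial_overscan_mm: Optional[float] = None
    max_sigma_norm: Optional[float] = None

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "QAConfig":
        """Load from a plain key/value text file (YAML subset)."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class QAReport:
    """Everything a reviewer needs about one scan, JSON-serializable losslessly."""

    scan_id: str
    integrity_flags: list[IntegrityFlag] = field(default_factory=list)
    coverage: Optional[CoverageResult] = None
    noise: Optional[NoiseResult] = None
    noise_unavailable_reason: Optional[str] = None
    lumen_provenance: list[str] = field(default_factory=list)
    lumen_n_voxels: Optional[int] = None
    split_found: Optional[bool] = None
    backend: str = "unspecified"
    backend_version: Optional[str] = None
    config: dict = field(default_factory=dict)
    tool_version: str = __version__
    timestamp: str = ""
    stage_errors: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: Mapping) -> "QAReport":
        d = dict(d)
        d["integrity_flags"] = [IntegrityFlag(**f) for f in d.get("integrity_flags", [])]
        if d.get("coverage") is not None:
            cov = dict(d["coverage"])
            cov["lung_slice_range"] = tuple(cov["lung_slice_range"])
            d["coverage"] = CoverageResult(**cov)
        if d.get("noise") is not None:
            d["noise"] = NoiseResult(**d["noise"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "QAReport":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_record(self) -> dict:
        """Flat record for :func:`ldctqa.cohort.summarize_cohort`."""
        rec: dict = {"scan_id": self.scan_id}
        if self.coverage is not None:
            rec.update(
                caudal_overscan_mm=self.coverage.caudal_overscan_mm,
                cranial_overscan_mm=self.coverage.cranial_overscan_mm,
                underscan_caudal=self.coverage.underscan_caudal,
                underscan_cranial=self.coverage.underscan_cranial,
                fraction_nonlung_slices=self.coverage.fraction_nonlung_slices,
            )
        rec["sigma_norm"] = self.noise.sigma_norm if self.noise is not None else None
        return rec


def run_scan(vol_path: str | os.PathLike | CTVolume,
             masks: Optional[Mapping[str, str | os.PathLike]] = None,
             backend: Optional[str] = None,
             segmentation: Optional[SegmentationSet] = None,
             config: Optional[QAConfig] = None,
             scan_id: Optional[str] = None,
             **backend_kwargs) -> QAReport:
    """Run the full per-scan QA pipeline and return a :class:`QAReport`.

    ``vol_path`` may be a path (NIfTI file or DICOM directory) or an
    in-memory :class:`CTVolume`.  Masks come from one of ``masks`` (label →
    NIfTI path), ``segmentation`` (pre-built set) or ``backend`` (+ kwargs).
    An unreadable volume raises; later-stage failures are recorded in
    ``stage_errors`` and the report is still returned.
    """
    config = config or QAConfig()
    if isinstance(vol_path, CTVolume):
        vol = vol_path
        scan_id = scan_id or "in-memory"
    else:
        vol = load_volume(vol_path)  # hard error on unreadable input
        scan_id = scan_id or Path(vol_path).name

    report = QAReport(
        scan_id=scan_id,
        config=config.to_dict(),
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    report.integrity_flags = check_integrity(
        vol, hu_floor=config.hu_floor, spacing_tolerance=config.spacing_tolerance)

    try:
        if segmentation is not None:
            seg = segmentation
            seg.check_grid(vol)
        elif masks is not None:
            seg = load_masks(masks, vol)
        elif backend is not None:
            seg = segment(vol, backend=backend, **backend_kwargs)
        else:
            raise SegmentationError("no masks, segmentation or backend given")
        report.backend = seg.backend
        report.backend_version = seg.backend_version
    except SegmentationError as exc:
        report.stage_errors.append({"stage": "segmentation", "message": str(exc)})
        return report

    try:
        lung = merge_lobes(seg.lobes, connectivity=config.connectivity)
        report.coverage = measure_coverage(lung)
    except Exception as exc:
        report.stage_errors.append({"stage": "coverage", "message": str(exc)})
        return report

    try:
        extraction = extract_lumen(seg.aorta, lung, margin_mm=config.margin_mm,
                                   connectivity=config.connectivity)
        report.lumen_provenance = extraction.provenance
        report.lumen_n_voxels = extraction.n_voxels
        report.split_found = extraction.split_found
        report.noise = compute_noise(vol, extraction.lumen, min_voxels=config.min_voxels)
    except (LumenExtractionError, NoiseUnavailableError) as exc:
        report.noise = None
        report.noise_unavailable_reason = str(exc)
        report.stage_errors.append({"stage": "noise", "message": str(exc)})
    return report


def flag_exceptions(report: QAReport, config: Optional[QAConfig] = None) -> str:
    """Return ``"review"`` when anything warrants a human look, else ``"pass"``.

    Review triggers: any underscan flag, any integrity flag, any stage
    error, overscan beyond a configured threshold, or sigma_norm beyond a
    configured threshold.
    """
    if config is None:
        config = QAConfig(**report.config) if report.config else QAConfig()
    if report.integrity_flags or report.stage_errors:
        return "review"
    cov = report.coverage
    if cov is None or cov.underscan_caudal or cov.underscan_cranial:
        return "review"
    if (config.max_caudal_overscan_mm is not None
            and cov.caudal_overscan_mm > config.max_caudal_overscan_mm):
        return "review"
    if (config.max_cranial_overscan_mm is not None
            and cov.cranial_overscan_mm > config.max_cranial_overscan_mm):
        return "review"
    if (config.max_sigma_norm is not None and report.noise is not None
            and report.noise.sigma_norm > config.max_sigma_norm):
        return "review"
    return "pass"


def render_pdf(report: QAReport, out_path: str | os.PathLike,
               vol: Optional[CTVolume] = None,
               lung=None, lumen=None) -> None:
    """Render a minimal single-page PDF summary of one QA report.

    When ``vol`` (and optionally ``lung``/``lumen`` masks) are provided, a
    mid-coronal thumbnail with mask overlays is included for visual review.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(8.27, 11.69))  # A4 portrait
    lines = [f"LDCT quality-assurance report — {report.scan_id}",
             f"tool version {report.tool_version}   backend {report.backend}",
             f"generated {report.timestamp}", ""]
    disposition = flag_exceptions(report)
    lines.append(f"Disposition: {disposition.upper()}")
    if report.integrity_flags:
        for f in report.integrity_flags:
            lines.append(f"  integrity: {f.code} — {f.detail}")
    cov = report.coverage
    if cov is not None:
        lines += [
            "",
            f"Caudal overscan:  {cov.caudal_overscan_mm:.1f} mm"
            + ("  [UNDERSCAN]" if cov.underscan_caudal else ""),
            f"Cranial overscan: {cov.cranial_overscan_mm:.1f} mm"
            + ("  [UNDERSCAN]" if cov.underscan_cranial else ""),
            f"Lung slices {cov.lung_slice_range[0]}–{cov.lung_slice_range[1]} "
            f"of {cov.n_slices_total}; "
            f"{100 * cov.fraction_nonlung_slices:.2f}% of slices without lung",
        ]
    lines.append("")
    if report.noise is not None:
        nz = report.noise
        lines += [
            f"Aortic-blood noise: sigma_raw {nz.sigma_raw:.2f} HU, "
            f"sigma_norm {nz.sigma_norm:.2f} HU (v_raw {nz.v_raw:.3f} mm3, "
            f"{nz.n_voxels} voxels, mean {nz.mu_raw:.1f} HU)",
        ]
    else:
        lines.append(f"Aortic-blood noise: unavailable "
                     f"({report.noise_unavailable_reason or 'not computed'})")
    for err in report.stage_errors:
        lines.append(f"stage error [{err['stage']}]: {err['message']}")

    fig.text(0.07, 0.95, "\n".join(lines), va="top", family="monospace", fontsize=9)

    if vol is not None:
        ax = fig.add_axes([0.15, 0.08, 0.7, 0.45])
        j = vol.shape[1] // 2 if lumen is None else int(
            round(np.mean(np.nonzero(lumen.voxels)[1]))) if lumen.n_voxels else vol.shape[1] // 2
        sl = vol.voxels[:, j, :].T  # coronal-ish view, z vertical
        ax.imshow(sl, cmap="gray", origin="lower", aspect=vol.spacing[2] / vol.spacing[0])
        for mask, color in ((lung, "tab:blue"), (lumen, "tab:red")):
            if mask is not None and mask.n_voxels:
                ax.contour(mask.voxels[:, j, :].T, levels=[0.5], colors=color,
                           linewidths=0.8, origin="lower")
        ax.set_xticks([]), ax.set_yticks([])
        ax.set_title("mid-coronal view (lung blue, lumen red)", fontsize=8)

    fig.savefig(out_path, format="pdf")
    plt.close(fig)
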