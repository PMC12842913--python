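"""Cohort aggregation: rating tallies, exact binomial CIs, summary statistics.

Reader-study ratings (1 = Insufficient … 6 = Perfect) are tallied into
cumulative at-least proportions with exact Clopper–Pearson 95% confidence
intervals.  Per-scan QA records aggregate into cohort summaries: conditional
mean ± SD overscan distances (over scans where that overscan occurred),
underscan rates, and normalized-noise statistics with scans lacking a noise
value excluded and counted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.stats import beta

__all__ = [
    "RATING_LABELS",
    "RatingTally",
    "CohortSummary",
    "tally_ratings",
    "exact_binomial_ci",
    "summarize_cohort",
]

#: rating labels ordered best (6) to worst (1)
RATING_LABELS = ("Perfect", "Nearly Perfect", "Good", "Acceptable", "Poor", "Insufficient")


def exact_binomial_ci(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Clopper–Pearson exact confidence interval for a binomial proportion.

    Returns ``(lower, upper)`` as proportions in [0, 1].  Boundary cases are
    closed-form: k = 0 gives lower = 0 and upper = 1 − (α/2)^(1/n);
    k = n gives upper = 1 and lower = (α/2)^(1/n).
    """
    if not (isinstance(k, (int, np.integer)) and isinstance(n, (int, np.integer))):
        raise ValueError("k and n must be integers")
    if n < 1 or not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    if not (0 < conf < 1):
        raise ValueError(f"conf must be in (0, 1), got {conf}")
    alpha = 1.0 - conf
    lower = 0.0 if k == 0 else float(beta.ppf(alpha / 2, k, n - k + 1))
    upper = 1.0 if k == n else float(beta.ppf(1 - alpha / 2, k + 1, n - k))
    return lower, upper


@dataclass
class RatingTally:
    """Counts and cumulative at-least proportions for a 6-point rating scale.

    ``counts`` is ordered Perfect(6) → Insufficient(1).  For each label,
    ``cumulative_percent`` holds the full-precision percentage of ratings at
    least that good, and ``ci_per_label`` its 95% Clopper–Pearson interval
    (proportions).  Display rounding to one decimal happens in
    :meth:`formatted_rows`, never in the stored values.
    """

    counts: tuple[int, ...]
    n: int
    cumulative_percent: tuple[float, ...]
    ci_per_label: tuple[tuple[float, float], ...]
    conf: float = 0.95

    def __post_init__(self) -> None:
        if sum(self.counts) != self.n:
            raise ValueError("counts must sum to n")
        for pct, (lo, hi) in zip(self.cumulative_percent, self.ci_per_label):
            p = pct / 100.0
            if not (lo - 1e-12 <= p <= hi + 1e-12):
                raise ValueError("CI must contain its point estimate")

    def formatted_rows(self) -> list[str]:
        rows = []
        for label, c, pct, (lo, hi) in zip(RATING_LABELS, self.counts,
                                           self.cumulative_percent, self.ci_per_label):
            rows.append(f"{label}\t{c}\t{pct:.1f}% [CI: {lo * 100:.1f}-{hi * 100:.1f}%]")
        return rows


def tally_ratings(ratings: Sequence[int], conf: float = 0.95) -> RatingTally:
    """Tally a list of ratings in 1–6 into a :class:`RatingTally`."""
    if len(ratings) < 1:
        raise ValueError("need at least one rating")
    arr = np.asarray(ratings)
    if not np.issubdtype(arr.dtype, np.integer) or arr.min() < 1 or arr.max() > 6:
        raise ValueError("ratings must be integers in 1..6")
    n = len(ratings)
    counts = tuple(int(np.count_nonzero(arr == r)) for r in range(6, 0, -1))
    cum_counts = np.cumsum(counts)
    cum_pct = tuple(100.0 * c / n for c in cum_counts)
    cis = tuple(exact_binomial_ci(int(c), n, conf) for c in cum_counts)
    return RatingTally(counts=counts, n=n, cumulative_percent=cum_pct,
                       ci_per_label=cis, conf=conf)


@dataclass
class CohortSummary:
    """Aggregate coverage and noise statistics over a cohort of QA records.

    Directional overscan means are conditional: computed only over scans
    where that overscan was > 0 (so they are not additive with rates).
    Rates are proportions in [0, 1]; percentage display is the caller's
    concern (two decimals conventionally).
    """

    n_scans: int
    caudal_overscan_mean_mm: Optional[float]
    caudal_overscan_sd_mm: Optional[float]
    n_caudal_overscanned: int
    cranial_overscan_mean_mm: Optional[float]
    cranial_overscan_sd_mm: Optional[float]
    n_cranial_overscanned: int
    underscan_caudal_rate: float
    underscan_cranial_rate: float
    underscan_both_rate: float
    sigma_norm_mean: Optional[float]
    sigma_norm_sd: Optional[float]
    n_noise_excluded: int
    mean_fraction_nonlung_slices: Optional[float]

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def _mean_sd(values: np.ndarray) -> tuple[Optional[float], Optional[float]]:
    if values.size == 0:
        return None, None
    mean = float(np.mean(values))
    sd = 0.0 if values.size == 1 else float(np.std(values, ddof=1))
    return mean, sd


def summarize_cohort(records: Sequence[Mapping]) -> CohortSummary:
    """Aggregate per-scan QA records (see :meth:`ldctqa.report.QAReport.to_record`).

    Each record is a mapping with keys ``caudal_overscan_mm``,
    ``cranial_overscan_mm``, ``underscan_caudal``, ``underscan_cranial``,
    ``fraction_nonlung_slices`` (all optional — scans whose coverage failed
    contribute nothing) and ``sigma_norm`` (``None`` when noise was
    unavailable; such scans are excluded from the noise statistics and
    counted in ``n_noise_excluded``).
    """
    if len(records) == 0:
        raise ValueError("empty record list")
    n = len(records)

    def collect(key):
        return np.asarray([r[key] for r in records
                           if r.get(key) is not None], dtype=float)

    caudal = collect("caudal_overscan_mm")
    cranial = collect("cranial_overscan_mm")
    caudal_pos = caudal[caudal > 0]
    cranial_pos = cranial[cranial > 0]
    us_caudal = np.asarray([bool(r.get("underscan_caudal")) for r in records])
    us_cranial = np.asarray([bool(r.get("underscan_cranial")) for r in records])
    sigma = collect("sigma_norm")
    frac = collect("fraction_nonlung_slices")

    ca_mean, ca_sd = _mean_sd(caudal_pos)
    cr_mean, cr_sd = _mean_sd(cranial_pos)
    sg_mean, sg_sd = _mean_sd(sigma)
    return CohortSummary(
        n_scans=n,
        caudal_overscan_mean_mm=ca_mean,
        caudal_overscan_sd_mm=ca_sd,
        n_caudal_overscanned=int(caudal_pos.size),
        cranial_overscan_mean_mm=cr_mean,
        cranial_overscan_sd_mm=cr_sd,
        n_cranial_overscanned=int(cranial_pos.size),
        underscan_caudal_rate=float(np.count_nonzero(us_caudal)) / n,
        underscan_cranial_rate=float(np.count_nonzero(us_cranial)) / n,
        underscan_both_rate=float(np.count_nonzero(us_caudal & us_cranial)) / n,
        sigma_norm_mean=sg_mean,
        sigma_norm_sd=sg_sd,
        n_noise_excluded=n - int(sigma.size),
        mean_fraction_nonlung_slices=float(np.mean(frac)) if frac.size else None,
    )
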