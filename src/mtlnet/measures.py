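"""Scalar endpoints: network indexes, masked means, amyloid status, volumes.

The network connectivity index is the mean of the strictly positive
Fisher-z values inside a participant-specific mask, extracted from
*unsmoothed* maps — a smoothed input is a contract violation, not a
warning, because smoothing mixes out-of-mask signal into the index.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np

from .grids import ConnMap

log = logging.getLogger(__name__)

__all__ = [
    "positive_mean", "masked_mean", "abeta_threshold", "abeta_status",
    "normalize_volume", "SubjectVisitMeasures",
]


@dataclass
class SubjectVisitMeasures:
    subject_id: str
    visit_index: int
    at_index: Optional[float] = None
    pm_index: Optional[float] = None
    roi_indexes: Dict[int, float] = field(default_factory=dict)
    amyloid_suvr: Optional[float] = None
    fdg_suvr: Optional[float] = None
    hippo_volume_norm: Optional[float] = None
    abeta_status: str = "undetermined"


class SmoothedInputError(ValueError):
    """An extraction that requires unsmoothed maps received a smoothed one."""


def positive_mean(conn: ConnMap, mask: np.ndarray) -> float:
    """Mean of strictly positive in-mask values; NaN when none exist.

    Requires an unsmoothed map (``smoothed_fwhm_mm is None``).
    """
    if conn.smoothed_fwhm_mm is not None:
        raise SmoothedInputError(
            f"index extraction requires an unsmoothed map; got "
            f"fwhm = {conn.smoothed_fwhm_mm} mm"
        )
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != conn.data.shape:
        raise ValueError("mask and map must share a grid")
    vals = conn.data[mask]
    pos = vals[np.isfinite(vals) & (vals > 0)]
    if pos.size == 0:
        log.info("positive_mean: no positive voxels among %d in-mask values",
                 int(mask.sum()))
        return float("nan")
    return float(pos.mean())


def masked_mean(image: np.ndarray, mask: np.ndarray) -> float:
    """Plain mean over the mask (signed values retained; for PET images)."""
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if image.shape != mask.shape:
        raise ValueError("image and mask must share a grid")
    if not mask.any():
        raise ValueError("mask is empty")
    return float(image[mask].mean())


def abeta_threshold(young_suvrs: Sequence[float], percentile: float = 99.9) -> float:
    """Amyloid-positivity cut-off: percentile of a young-adult SUVR sample.

    Uses the linear-interpolation (closest-ranks) percentile convention.
    """
    vals = np.asarray(list(young_suvrs), dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 SUVR values to form a threshold")
    if not 0 <= percentile <= 100:
        raise ValueError("percentile must be in [0, 100]")
    return float(np.percentile(vals, percentile, method="linear"))


def abeta_status(
    suvrs: Sequence[float],
    visit_times_months: Sequence[float],
    threshold: float,
    baseline_month: float = 0.0,
) -> str:
    """Baseline amyloid status from per-visit SUVR scans.

    A baseline scan (visit time == ``baseline_month``) decides directly:
    positive iff SUVR >= threshold.  With no baseline scan, the subject is
    negative when *all* later scans fall below threshold, and undetermined
    when any later scan is supra-threshold (the rule does not extrapolate
    positivity backwards in time).
    """
    suvrs = list(suvrs)
    times = list(visit_times_months)
    if len(suvrs) != len(times) or not suvrs:
        raise ValueError("need equal, non-empty SUVR and visit-time lists")
    pairs = [(t, s) for t, s in zip(times, suvrs)
             if s is not None and not (isinstance(s, float) and math.isnan(s))]
    if not pairs:
        return "undetermined"
    baseline = [s for t, s in pairs if t == baseline_month]
    if baseline:
        return "positive" if baseline[0] >= threshold else "negative"
    later = [s for _, s in pairs]
    if all(s < threshold for s in later):
        return "negative"
    return "undetermined"


def normalize_volume(raw_mm3: float, tiv_mm3: float) -> float:
    """Head-size normalised volume: raw / (TIV x 1000)."""
    if not raw_mm3 > 0:
        raise ValueError(f"raw volume must be positive, got {raw_mm3}")
    if not tiv_mm3 > 0:
        raise ValueError(f"TIV must be positive, got {tiv_mm3}")
    return raw_mm3 / (tiv_mm3 * 1000.0)
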