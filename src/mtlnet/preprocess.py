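"""Temporal filtering, confound regression and motion-based exclusion.

The processing order is fixed: (optional spatial smoothing) -> bandpass ->
confound extraction from the filtered run -> nuisance regression, with
confound columns bandpassed identically before regression so that the
regression cannot re-introduce out-of-band power.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import signal

from .grids import BoldRun, SegmentationSet, check_same_grid

log = logging.getLogger(__name__)

__all__ = [
    "framewise_displacement",
    "motion_qc",
    "bandpass",
    "bandpass_series",
    "extract_confounds",
    "nuisance_regression",
    "ConfoundSet",
    "QCDecision",
]

#: Fixed column order of the confound design (documented contract).
CONFOUND_ORDER = [
    "wm_mean", "csf_mean", "global_mean",
    "wm_mean_diff", "csf_mean_diff", "global_mean_diff",
    "trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z",
]


@dataclass
class ConfoundSet:
    """Named nuisance series plus framewise-displacement summaries."""

    columns: pd.DataFrame
    fd_series: np.ndarray
    mean_fd: float

    def __post_init__(self) -> None:
        n = len(self.columns)
        if len(self.fd_series) != n:
            raise ValueError("fd_series length must match confound columns")
        if self.mean_fd < 0:
            raise ValueError("mean_fd must be non-negative")


@dataclass
class QCDecision:
    retain: bool
    reasons: List[str] = field(default_factory=list)
    max_translation_mm: float = 0.0
    mean_abs_rotation_deg: float = 0.0


def framewise_displacement(
    motion: np.ndarray, sphere_radius_mm: float = 50.0
) -> Tuple[np.ndarray, float]:
    """Per-volume framewise displacement (Power convention).

    ``FD_t = sum_i |delta p_i(t)|`` over the six rigid-body parameters,
    with the three rotations (degrees) converted to arc length on a sphere
    of ``sphere_radius_mm`` (radians x radius).  ``FD_1 = 0``.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6 or motion.shape[0] < 1:
        raise ValueError("motion must be a non-empty (t, 6) array")
    if not np.all(np.isfinite(motion)):
        raise ValueError("motion parameters contain non-finite values")
    scaled = motion.copy()
    scaled[:, 3:] = np.deg2rad(scaled[:, 3:]) * sphere_radius_mm
    fd = np.zeros(motion.shape[0])
    fd[1:] = np.abs(np.diff(scaled, axis=0)).sum(axis=1)
    return fd, float(fd.mean())


def motion_qc(
    motion: np.ndarray,
    max_translation_mm: float = 3.0,
    max_mean_abs_rotation_deg: float = 1.5,
) -> QCDecision:
    """Retain/exclude decision from the scan-level motion rule.

    Excludes when the maximum absolute translation exceeds 3 mm or the
    mean absolute Euler rotation angle exceeds 1.5 degrees.
    """
    motion = np.asarray(motion, dtype=float)
    if motion.ndim != 2 or motion.shape[1] != 6 or motion.shape[0] < 1:
        raise ValueError("motion must be a non-empty (t, 6) array")
    if not np.all(np.isfinite(motion)):
        raise ValueError("motion parameters contain non-finite values")
    max_trans = float(np.abs(motion[:, :3]).max())
    # Euler angle magnitude per volume: norm of the three rotation angles.
    mean_rot = float(np.linalg.norm(motion[:, 3:], axis=1).mean())
    reasons = []
    if max_trans > max_translation_mm:
        reasons.append("translation")
    if mean_rot > max_mean_abs_rotation_deg:
        reasons.append("rotation")
    return QCDecision(retain=not reasons, reasons=reasons,
                      max_translation_mm=max_trans,
                      mean_abs_rotation_deg=mean_rot)


def _bandpass_array(x: np.ndarray, tr_s: float, low_hz: float, high_hz: float) -> np.ndarray:
    """Linear detrend then frequency-domain masking along the last axis."""
    x = signal.detrend(x, axis=-1, type="linear")
    n = x.shape[-1]
    freqs = np.fft.rfftfreq(n, d=tr_s)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(x, axis=-1)
    spec[..., ~keep] = 0.0
    return np.fft.irfft(spec, n=n, axis=-1)


def _check_band(tr_s: float, low_hz: float, high_hz: float) -> None:
    nyquist = 1.0 / (2.0 * tr_s)
    if not 0 <= low_hz < high_hz:
        raise ValueError(f"need 0 <= low < high, got [{low_hz}, {high_hz}]")
    if high_hz >= nyquist:
        raise ValueError(
            f"high cutoff {high_hz} Hz must be below the Nyquist frequency "
            f"{nyquist:.4f} Hz for TR {tr_s} s"
        )


def bandpass(run: BoldRun, low_hz: float = 0.01, high_hz: float = 0.08) -> BoldRun:
    """Voxelwise detrend + FFT band mask retaining [low, high] Hz."""
    _check_band(run.tr_s, low_hz, high_hz)
    data = _bandpass_array(run.data, run.tr_s, low_hz, high_hz)
    return BoldRun(data=data, grid=run.grid, tr_s=run.tr_s,
                   subject_id=run.subject_id, visit_index=run.visit_index,
                   sequence_variant=run.sequence_variant)


def bandpass_series(series: np.ndarray, tr_s: float,
                    low_hz: float = 0.01, high_hz: float = 0.08) -> np.ndarray:
    """Bandpass 1D/2D confound series with the same filter as the data."""
    _check_band(tr_s, low_hz, high_hz)
    return _bandpass_array(np.asarray(series, dtype=float), tr_s, low_hz, high_hz)


def extract_confounds(
    run: BoldRun,
    seg: SegmentationSet,
    motion: np.ndarray,
    tissue_threshold: float = 0.9,
) -> ConfoundSet:
    """Mean WM/CSF/global series, their first differences, and motion.

    Tissue means are taken over voxels with probability >= ``tissue_threshold``
    (default 0.9 to avoid partial-volume contamination); the global mean is
    taken over the brain mask.  First differences carry a leading zero.
    """
    check_same_grid(run.grid, seg.grid)
    motion = np.asarray(motion, dtype=float)
    if motion.shape != (run.n_volumes, 6):
        raise ValueError(
            f"motion shape {motion.shape} does not match (n_volumes, 6) = "
            f"({run.n_volumes}, 6)"
        )
    cols = {}
    for name, prob in (("wm_mean", seg.wm), ("csf_mean", seg.csf)):
        mask = prob >= tissue_threshold
        if not mask.any():
            raise ValueError(
                f"no voxels reach {name.split('_')[0].upper()} probability "
                f">= {tissue_threshold}; lower tissue_threshold"
            )
        cols[name] = run.data[mask].mean(axis=0)
    if not seg.brain_mask.any():
        raise ValueError("brain mask is empty")
    cols["global_mean"] = run.data[seg.brain_mask].mean(axis=0)
    for name in ("wm_mean", "csf_mean", "global_mean"):
        diff = np.zeros_like(cols[name])
        diff[1:] = np.diff(cols[name])
        cols[name + "_diff"] = diff
    for i, name in enumerate(("trans_x", "trans_y", "trans_z",
                              "rot_x", "rot_y", "rot_z")):
        cols[name] = motion[:, i]
    fd, mean_fd = framewise_displacement(motion)
    frame = pd.DataFrame({name: cols[name] for name in CONFOUND_ORDER})
    return ConfoundSet(columns=frame, fd_series=fd, mean_fd=mean_fd)


def _prune_collinear(design: np.ndarray, names: List[str], tol: float = 1e-10):
    """Drop exactly-collinear columns, keeping the first occurrence."""
    keep: List[int] = []
    dropped: List[str] = []
    for j in range(design.shape[1]):
        trial = design[:, keep + [j]]
        if np.linalg.matrix_rank(trial, tol=tol * max(1.0, np.abs(trial).max())) > len(keep):
            keep.append(j)
        else:
            dropped.append(names[j])
    if dropped:
        log.warning("dropped exactly-collinear confound columns: %s", dropped)
    return keep, dropped


def nuisance_regression(run: BoldRun, confounds: ConfoundSet) -> BoldRun:
    """Per-voxel OLS residuals after regressing out intercept + confounds.

    Exactly-collinear columns are pruned (first occurrence kept, with a
    logged warning).  Raises if the pruned design is still rank-deficient.
    """
    t = run.n_volumes
    cols = confounds.columns
    if len(cols) != t:
        raise ValueError("confound length does not match run length")
    names = ["intercept"] + list(cols.columns)
    design = np.column_stack([np.ones(t)] + [cols[c].to_numpy(float) for c in cols.columns])
    keep, dropped = _prune_collinear(design, names)
    design = design[:, keep]
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            f"design still rank-deficient after pruning (dropped: {dropped})"
        )
    flat = run.data.reshape(-1, t).T  # (t, voxels)
    beta, *_ = np.linalg.lstsq(design, flat, rcond=None)
    resid = flat - design @ beta
    out = resid.T.reshape(run.data.shape)
    return BoldRun(data=out, grid=run.grid, tr_s=run.tr_s,
                   subject_id=run.subject_id, visit_index=run.visit_index,
                   sequence_variant=run.sequence_variant)
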