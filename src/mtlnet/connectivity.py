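"""Seed-to-voxel correlation maps, Fisher z, smoothing, dropout masking.

Group-level inference uses maps smoothed at 6.3 mm FWHM; index extraction
always uses unsmoothed maps (the :class:`~mtlnet.grids.ConnMap` carries its
smoothing state so the extraction stage can enforce this).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .grids import BoldRun, ConnMap, SeedRoi, VolumeGrid, check_same_grid, check_volume

log = logging.getLogger(__name__)

__all__ = ["dropout_mask", "seed_correlation_map", "fisher_z", "gaussian_smooth",
           "FWHM_TO_SIGMA"]

#: FWHM = 2 * sqrt(2 ln 2) * sigma
FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def dropout_mask(
    gm_t1: np.ndarray,
    gm_t2star: np.ndarray,
    threshold: float = 0.25,
    combine: str = "intersection",
) -> np.ndarray:
    """Signal-dropout analysis mask from T1 and non-EPI T2* GM segmentations.

    Each probability map is thresholded at ``threshold`` (inclusive) and the
    results combined.  The default combination is the intersection: the
    mask exists to *exclude* dropout voxels, and a union would re-admit
    them; ``combine="union"`` is available for sensitivity checks.
    """
    gm_t1 = np.asarray(gm_t1, dtype=float)
    gm_t2star = np.asarray(gm_t2star, dtype=float)
    if gm_t1.shape != gm_t2star.shape:
        raise ValueError("gm_t1 and gm_t2star must share a grid")
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    a, b = gm_t1 >= threshold, gm_t2star >= threshold
    if combine == "intersection":
        mask = a & b
    elif combine == "union":
        mask = a | b
    else:
        raise ValueError(f"combine must be 'intersection' or 'union', got {combine!r}")
    if not mask.any():
        log.warning("dropout mask is empty at threshold %.2f", threshold)
    return mask


def seed_correlation_map(
    run: BoldRun,
    seed: SeedRoi,
    analysis_mask: np.ndarray,
) -> ConnMap:
    """Pearson correlation between the seed-mean series and every voxel.

    Voxels outside ``analysis_mask`` are set to NaN (the missing marker);
    zero-variance voxels inside the mask get r = 0 with a logged count.
    The run is expected to be residualized (nuisance regressed) already.
    """
    analysis_mask = check_volume(np.asarray(analysis_mask, dtype=bool),
                                 run.grid, "analysis mask")
    if run.n_volumes < 3:
        raise ValueError("need at least 3 time points for correlation")
    seed_vox = check_volume(seed.voxels, run.grid, f"seed {seed.label}")
    if not seed_vox.any():
        raise ValueError(f"seed {seed.label!r} has no voxels on the run grid")

    seed_series = run.data[seed_vox].mean(axis=0)
    s = seed_series - seed_series.mean()
    s_norm = np.sqrt((s**2).sum())
    if s_norm == 0:
        raise ValueError(f"seed {seed.label!r} mean series has zero variance")

    flat = run.data[analysis_mask]  # (n_mask_vox, t)
    x = flat - flat.mean(axis=1, keepdims=True)
    x_norm = np.sqrt((x**2).sum(axis=1))
    zero_var = x_norm == 0
    if zero_var.any():
        log.info("seed %s: %d zero-variance voxels set to r = 0",
                 seed.label, int(zero_var.sum()))
    denom = np.where(zero_var, 1.0, x_norm * s_norm)
    r = np.clip((x @ s) / denom, -1.0, 1.0)
    r[zero_var] = 0.0

    out = np.full(run.grid.shape, np.nan)
    out[analysis_mask] = r
    return ConnMap(data=out, grid=run.grid, seed_label=seed.label,
                   scale="pearson_r", smoothed_fwhm_mm=None,
                   subject_id=run.subject_id, visit_index=run.visit_index)


def fisher_z(conn: ConnMap, clip: float = 0.999999) -> ConnMap:
    """Variance-stabilising z = atanh(r), with |r| clipped below 1.

    NaN missing markers propagate unchanged.
    """
    if conn.scale != "pearson_r":
        raise ValueError(f"fisher_z expects a pearson_r map, got {conn.scale!r}")
    z = np.arctanh(np.clip(conn.data, -clip, clip))
    return ConnMap(data=z, grid=conn.grid, seed_label=conn.seed_label,
                   scale="fisher_z", smoothed_fwhm_mm=conn.smoothed_fwhm_mm,
                   subject_id=conn.subject_id, visit_index=conn.visit_index)


def gaussian_smooth(volume: np.ndarray, fwhm_mm: float, grid: VolumeGrid) -> np.ndarray:
    """Separable Gaussian smoothing specified by FWHM in millimetres.

    sigma_mm = fwhm / (2 sqrt(2 ln 2)) per axis, converted to voxel units by
    each voxel size; the kernel is truncated at 4 sigma, with reflective
    boundaries (conserves flux on small grids).  NaNs are treated as missing:
    the smoothed value is renormalised by the smoothed validity mask.
    """
    if not fwhm_mm > 0:
        raise ValueError(f"fwhm_mm must be positive, got {fwhm_mm}")
    volume = check_volume(np.asarray(volume, dtype=float), grid, "volume")
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / vs for vs in grid.voxel_size_mm]
    nan_mask = np.isnan(volume)
    if nan_mask.any():
        filled = np.where(nan_mask, 0.0, volume)
        sm = ndimage.gaussian_filter(filled, sigma=sigma_vox, mode="reflect", truncate=4.0)
        weight = ndimage.gaussian_filter((~nan_mask).astype(float),
                                         sigma=sigma_vox, mode="reflect", truncate=4.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = sm / weight
        out[nan_mask] = np.nan
        return out
    return ndimage.gaussian_filter(volume, sigma=sigma_vox, mode="reflect", truncate=4.0)


def smooth_map(conn: ConnMap, fwhm_mm: float) -> ConnMap:
    """Smooth a connectivity map, recording the smoothing state."""
    data = gaussian_smooth(conn.data, fwhm_mm, conn.grid)
    return ConnMap(data=data, grid=conn.grid, seed_label=conn.seed_label,
                   scale=conn.scale, smoothed_fwhm_mm=fwhm_mm,
                   subject_id=conn.subject_id, visit_index=conn.visit_index)
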