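"""Orchestration: reproducible end-to-end runs in image or table mode.

``run_all`` executes the staged pipeline:

* table mode: synthgen -> stats (fast; used for coefficient-recovery runs);
* image mode: synthgen -> preprocess -> connectivity -> netmask ->
  measures, reporting the Dice overlap between recovered and planted
  network masks in the run manifest.

Every stochastic stage derives its seed from the config seed, and the
config is serialised verbatim into the run directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import connectivity, measures, netmask, preprocess, synthgen
from .grids import VolumeGrid
from .io import load_table, load_volume, save_json, save_table, save_volume
from .stats import SuiteConfig, run_analysis_suite

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all", "validate_inputs", "image_mode_masks"]


@dataclass
class RunConfig:
    """Serialisable configuration of a full pipeline run."""

    mode: str = "table"                      # "table" | "image"
    seed: int = 0
    out_dir: str = "results/run"
    # image-mode settings
    grid_shape: tuple = (20, 20, 12)
    voxel_size_mm: tuple = (3.0, 3.0, 3.0)
    n_subjects: int = 20
    n_volumes: int = 120
    tr_s: float = 2.382
    loadings: Dict[str, float] = field(default_factory=lambda: {"AT": 0.7, "PM": 0.7})
    nuisance_scale: float = 1.0
    n_perm: int = 500
    alpha: float = 0.05
    tfce_E: float = 0.5
    tfce_H: float = 2.0
    tfce_connectivity: int = 26
    mask_source: str = "young"               # "young" | "older-negative"
    group_smooth_fwhm_mm: float = 6.3
    run_smooth_fwhm_mm: float = 4.0
    # table-mode settings
    cohort: synthgen.CohortConfig = field(default_factory=synthgen.CohortConfig)
    suite: SuiteConfig = field(default_factory=SuiteConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort = raw.pop("cohort", None)
        suite = raw.pop("suite", None)
        cfg = cls(**raw)
        if cohort:
            cfg.cohort = synthgen.CohortConfig(**cohort)
        if suite:
            cfg.suite = SuiteConfig(**suite)
        return cfg


def _derive_seed(seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31 - 1)


def image_mode_masks(config: RunConfig):
    """Image-mode core: simulate, preprocess, map, and infer group masks.

    Returns ``(mask_set, per_subject_maps, truth, cohort_rows)`` where
    ``per_subject_maps`` holds unsmoothed Fisher-z PRC/PHC maps per subject.
    """
    grid = VolumeGrid(tuple(config.grid_shape), tuple(config.voxel_size_mm))
    runs, truth = synthgen.generate_image_dataset(
        config.n_subjects, config.loadings, grid=grid,
        n_volumes=config.n_volumes, tr_s=config.tr_s,
        seed=_derive_seed(config.seed, "synthgen"),
        nuisance_scale=config.nuisance_scale,
    )
    smoothed = {"PRC": [], "PHC": []}
    unsmoothed: List[Dict[str, object]] = []
    qc_log = []
    analysis_mask = None
    for sr in runs:
        qc = preprocess.motion_qc(sr.motion)
        qc_log.append(dict(subject_id=sr.run.subject_id, retain=qc.retain,
                           reasons=qc.reasons))
        if not qc.retain:
            continue
        run = sr.run
        if config.run_smooth_fwhm_mm:
            from scipy import ndimage

            sigma_vox = [config.run_smooth_fwhm_mm * connectivity.FWHM_TO_SIGMA / v
                         for v in grid.voxel_size_mm] + [0.0]
            data = ndimage.gaussian_filter(run.data, sigma=sigma_vox,
                                           mode="reflect", truncate=4.0)
            run = dataclasses.replace(run, data=data)
        run = preprocess.bandpass(run)
        confounds = preprocess.extract_confounds(run, sr.seg, sr.motion)
        filtered_cols = confounds.columns.apply(
            lambda c: preprocess.bandpass_series(c.to_numpy(), run.tr_s))
        confounds = preprocess.ConfoundSet(columns=filtered_cols,
                                           fd_series=confounds.fd_series,
                                           mean_fd=confounds.mean_fd)
        resid = preprocess.nuisance_regression(run, confounds)
        mask = connectivity.dropout_mask(sr.seg.gm_t1, sr.seg.gm_t2star)
        if analysis_mask is None:
            analysis_mask = mask
        entry: Dict[str, object] = dict(subject_id=run.subject_id,
                                        mean_fd=confounds.mean_fd, seg=sr.seg)
        for seed_roi in sr.seed_rois:
            cmap = connectivity.seed_correlation_map(resid, seed_roi, mask)
            zmap = connectivity.fisher_z(cmap)
            entry[seed_roi.label] = zmap
            smoothed[seed_roi.label].append(
                connectivity.smooth_map(zmap, config.group_smooth_fwhm_mm))
        unsmoothed.append(entry)
    if len(unsmoothed) < 5:
        raise RuntimeError("fewer than 5 retained subjects; cannot build masks")

    perm_kwargs = dict(n_perm=config.n_perm, alpha=config.alpha,
                       E=config.tfce_E, H=config.tfce_H,
                       connectivity=config.tfce_connectivity)
    prc = [m.data for m in smoothed["PRC"]]
    phc = [m.data for m in smoothed["PHC"]]
    prc_os = netmask.one_sample_perm_test(
        prc, analysis_mask, seed=_derive_seed(config.seed, "prc_os"), **perm_kwargs)
    phc_os = netmask.one_sample_perm_test(
        phc, analysis_mask, seed=_derive_seed(config.seed, "phc_os"), **perm_kwargs)
    prc_gt = netmask.paired_perm_test(
        prc, phc, analysis_mask, seed=_derive_seed(config.seed, "prc_gt"), **perm_kwargs)
    phc_gt = netmask.paired_perm_test(
        phc, prc, analysis_mask, seed=_derive_seed(config.seed, "phc_gt"), **perm_kwargs)
    mask_set = netmask.build_network_masks(prc_os, phc_os, prc_gt, phc_gt)
    layout = runs[0].layout
    mask_set.dice_vs = {
        "planted_AT": netmask.dice(
            netmask.participant_mask(mask_set.at_mask, runs[0].seg.gm_t1,
                                     seeds=runs[0].seed_rois),
            layout.at_net),
        "planted_PM": netmask.dice(
            netmask.participant_mask(mask_set.pm_mask, runs[0].seg.gm_t1,
                                     seeds=runs[0].seed_rois),
            layout.pm_net),
    }

    rows = []
    for entry in unsmoothed:
        seg: synthgen.SegmentationSet = entry["seg"]  # type: ignore[assignment]
        seeds = runs[0].seed_rois
        p_at = netmask.participant_mask(mask_set.at_mask, seg.gm_t1, seeds=seeds)
        p_pm = netmask.participant_mask(mask_set.pm_mask, seg.gm_t1, seeds=seeds)
        at_idx = measures.positive_mean(entry["PRC"], p_at) if p_at.any() else np.nan
        pm_idx = measures.positive_mean(entry["PHC"], p_pm) if p_pm.any() else np.nan
        rows.append(dict(subject_id=entry["subject_id"], visit_index=1,
                         at_index=at_idx, pm_index=pm_idx,
                         mean_fd=entry["mean_fd"]))
    return mask_set, unsmoothed, truth, pd.DataFrame(rows), qc_log


def run_all(config: RunConfig) -> Path:
    """Execute the configured pipeline and write a reproducible run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = dict(config=config.to_dict(), config_hash=config.config_hash(),
                    mode=config.mode, stages={})
    try:
        if config.mode == "table":
            cfg = config.cohort
            table, truth = synthgen.generate_cohort(
                cfg, seed=_derive_seed(config.seed, "cohort"))
            save_table(table, out / "cohort.tsv")
            truth.to_json(out / "groundtruth.json")
            manifest["stages"]["synthgen"] = dict(n_rows=len(table))
            fits, results = run_analysis_suite(table, config.suite)
            save_table(results, out / "results.tsv")
            manifest["stages"]["stats"] = dict(n_designs=len(fits))
        elif config.mode == "image":
            mask_set, maps, truth, table, qc_log = image_mode_masks(config)
            grid = VolumeGrid(tuple(config.grid_shape), tuple(config.voxel_size_mm))
            save_volume(mask_set.at_mask.astype(float), grid, out / "at_mask.nii.gz",
                        sidecar=mask_set.provenance)
            save_volume(mask_set.pm_mask.astype(float), grid, out / "pm_mask.nii.gz",
                        sidecar=mask_set.provenance)
            save_table(table, out / "cohort.tsv")
            save_table(pd.DataFrame(qc_log).assign(
                reasons=lambda d: d["reasons"].astype(str)), out / "qc_log.tsv")
            truth.to_json(out / "groundtruth.json")
            manifest["stages"]["netmask"] = dict(
                dice=mask_set.dice_vs, provenance=mask_set.provenance)
        else:
            raise ValueError(f"unknown mode {config.mode!r}")
    except Exception as exc:  # preserve partial artefacts, name the stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        save_json(manifest, out / "manifest.json")
        raise
    save_json(manifest, out / "manifest.json")
    return out


def validate_inputs(volume_paths: List = (), table_paths: List = (),
                    motion_paths: Optional[Dict] = None) -> List[str]:
    """Cross-file consistency report; empty list means all checks passed.

    Checks that all NIfTI volumes share one grid, tables contain the cohort
    schema columns, and motion TSVs have one row per BOLD volume
    (``motion_paths`` maps motion TSV path -> its 4D volume path).
    """
    problems: List[str] = []
    grids = {}
    for p in volume_paths:
        try:
            _, grid = load_volume(p)
            grids[str(p)] = grid
        except Exception as exc:
            problems.append(f"{p}: unreadable volume ({exc})")
    if len({g for g in grids.values()}) > 1:
        shapes = {p: g.shape for p, g in grids.items()}
        problems.append(f"mixed grids across volumes: {shapes}")
    required = {"subject_id", "visit_index", "group", "age_years"}
    for p in table_paths:
        try:
            tab = load_table(p)
        except Exception as exc:
            problems.append(f"{p}: unreadable table ({exc})")
            continue
        missing = sorted(required - set(tab.columns))
        if missing:
            problems.append(f"{p}: missing columns {missing}")
    for mpath, vpath in (motion_paths or {}).items():
        try:
            motion = pd.read_csv(mpath, sep="\t")
            data, _ = load_volume(vpath)
        except Exception as exc:
            problems.append(f"{mpath}: unreadable ({exc})")
            continue
        n_vol = data.shape[3] if data.ndim == 4 else 1
        if len(motion) != n_vol:
            problems.append(
                f"{mpath}: {len(motion)} motion rows but {vpath} has "
                f"{n_vol} volumes"
            )
    return problems
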