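"""Synthetic cohort and BOLD-run generation with known ground truth.

Two generator modes mirror the two ways the downstream pipeline is
exercised:

* **table mode** (:func:`generate_cohort`): per-visit network connectivity
  indexes are emitted directly as ``planted linear predictor + Gaussian
  noise``, so the statistics stage can be tested for exact coefficient
  recovery at desk scale.
* **image mode** (:func:`generate_run` / :func:`generate_image_dataset`):
  full 4D BOLD volumes are synthesised in which two seed regions (PRC,
  PHC) are coupled to two disjoint networks (AT, PM) through shared latent
  time courses, plus drift / global / tissue / motion nuisance.  The
  population correlation between the seed mean series and each network
  voxel equals the requested loading.

The planted effect sizes default to the coefficients this pipeline is
designed to recover: an AT age slope of +0.0003 and PM age slope of
-0.0007 Fisher-z/year, amyloid +0.1601 z/SUVR, FDG -0.1013 z/SUVR,
hippocampal volume -0.0694 z per standardized normalized volume,
MMSE -0.0047 and MDRS -0.0018 z/point, and -0.0136 z per month of delay
to dementia onset in MCI converters, with stage offsets of +0.0416 (MCI)
and +0.0375 (AD) on the AT index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from .grids import BoldRun, SegmentationSet, SeedRoi, VolumeGrid

__all__ = [
    "DEFAULT_EFFECTS",
    "CohortConfig",
    "GroundTruth",
    "SyntheticRun",
    "generate_cohort",
    "plant_effects",
    "generate_run",
    "generate_image_dataset",
    "layout_rois",
]


class LayoutError(ValueError):
    """The grid is too small to hold the four disjoint ROIs."""


# ---------------------------------------------------------------------------
# Planted effects (generator defaults = the stated world)
# ---------------------------------------------------------------------------

#: Default planted effects, in Fisher-z units per unit of the (centred)
#: predictor.  Keys ending in ``_at`` act on the AT index, ``_pm`` on PM.
DEFAULT_EFFECTS: Dict[str, float] = {
    "intercept_at": 0.20,
    "intercept_pm": 0.35,
    "age_at": 0.0003,       # z per year
    "age_pm": -0.0007,      # z per year
    "group_mci_at": 0.0416,  # stage offset vs older controls
    "group_ad_at": 0.0375,
    "amyloid_at": 0.1601,   # z per SUVR
    "fdg_at": -0.1013,      # z per SUVR
    "hippo_at": -0.0694,    # z per standardized normalized volume
    "mmse_at": -0.0047,     # z per point
    "mdrs_at": -0.0018,     # z per point
    "delay_at": -0.0136,    # z per month to dementia onset
}

# Fixed centring references so that effect planting is exactly linear and
# invertible independent of the realised sample.
AMYLOID_REF = 1.31
FDG_REF = 1.0
MMSE_REF = 29.0
MDRS_REF = 140.0
HIPPO_NORM_MEAN = 4.4e-6   # raw_mm3 / (tiv_mm3 * 1000), cohort-scale centre
HIPPO_NORM_SD = 5.0e-7

GROUPS = ("CU-young", "CU-middle", "CU-oldneg", "CU-oldpos", "MCI", "AD")

_COHORT_COLUMNS = [
    "subject_id", "visit_index", "group", "age_years", "sex",
    "education_years", "months_from_baseline", "sequence_variant",
    "amyloid_suvr", "fdg_suvr", "hippo_volume_raw", "tiv", "mmse", "mdrs",
    "months_to_dementia", "mean_fd", "at_index", "pm_index",
]


@dataclass
class GroundTruth:
    """Planted network voxel sets, loadings and effect parameters."""

    at_voxels: Optional[np.ndarray] = None
    pm_voxels: Optional[np.ndarray] = None
    seed_prc: Optional[np.ndarray] = None
    seed_phc: Optional[np.ndarray] = None
    loading_per_subject: Dict[str, Dict[str, float]] = field(default_factory=dict)
    effect_params: Dict[str, float] = field(default_factory=dict)
    noise_sd: float = 0.05
    rng_seed: int = 0

    def to_json(self, path) -> None:
        payload = {
            "effect_params": self.effect_params,
            "noise_sd": self.noise_sd,
            "rng_seed": self.rng_seed,
            "loading_per_subject": self.loading_per_subject,
            "at_voxels": _mask_to_indices(self.at_voxels),
            "pm_voxels": _mask_to_indices(self.pm_voxels),
            "seed_prc": _mask_to_indices(self.seed_prc),
            "seed_phc": _mask_to_indices(self.seed_phc),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _mask_to_indices(mask):
    if mask is None:
        return None
    return np.argwhere(mask).tolist()


# ---------------------------------------------------------------------------
# Cohort (table mode)
# ---------------------------------------------------------------------------

# Group-level demographics: (age mean, sd, lo, hi), female fraction,
# (education mean, sd, lo, hi), visit-count probabilities for 1/2/3 visits.
_GROUP_DEMOGRAPHICS = {
    "CU-young":  dict(age=(30.0, 6.0, 19.5, 40.0), female=0.52,
                      edu=(13.9, 2.9, 9, 20), visits=(0.2, 0.8, 0.0)),
    "CU-middle": dict(age=(49.0, 5.5, 40.0, 59.6), female=0.52,
                      edu=(13.9, 2.9, 9, 20), visits=(0.2, 0.8, 0.0)),
    "CU-oldneg": dict(age=(69.8, 6.56, 60.0, 84.6), female=0.56,
                      edu=(12.1, 3.7, 7, 20), visits=(0.15, 0.40, 0.45)),
    "CU-oldpos": dict(age=(69.8, 6.56, 60.0, 84.6), female=0.56,
                      edu=(12.1, 3.7, 7, 20), visits=(0.15, 0.40, 0.45)),
    "MCI":       dict(age=(74.5, 6.7, 60.7, 85.0), female=0.31,
                      edu=(11.8, 4.3, 6, 20), visits=(0.3, 0.5, 0.2)),
    "AD":        dict(age=(67.2, 9.8, 51.7, 84.1), female=0.42,
                      edu=(11.5, 3.6, 7, 20), visits=(0.4, 0.6, 0.0)),
}

_MMSE_BY_GROUP = {
    "CU-young": (29.4, 0.7, 27, 30), "CU-middle": (29.4, 0.7, 27, 30),
    "CU-oldneg": (28.8, 1.2, 26, 30), "CU-oldpos": (28.8, 1.2, 26, 30),
    "MCI": (26.6, 1.7, 22, 30), "AD": (20.6, 4.9, 12, 29),
}
_MDRS_BY_GROUP = {
    "CU-young": (142.2, 2.4, 132, 144), "CU-middle": (142.2, 2.4, 132, 144),
    "CU-oldneg": (141.2, 2.7, 130, 144), "CU-oldpos": (141.2, 2.7, 130, 144),
    "MCI": (132.3, 5.6, 122, 142), "AD": (118.2, 10.8, 101, 139),
}
_AMYLOID_BY_GROUP = {
    "CU-young": (1.12, 0.06, 0.95, 1.30), "CU-middle": (1.14, 0.06, 0.95, 1.30),
    "CU-oldneg": (1.13, 0.07, 0.95, 1.30), "CU-oldpos": (1.45, 0.10, 1.31, 1.85),
    "MCI": (1.58, 0.18, 1.31, 2.20), "AD": (1.65, 0.20, 1.31, 2.30),
}
_FDG_BY_GROUP = {
    "CU-young": (1.08, 0.07), "CU-middle": (1.06, 0.07),
    "CU-oldneg": (1.04, 0.07), "CU-oldpos": (1.02, 0.08),
    "MCI": (0.95, 0.08), "AD": (0.85, 0.09),
}
_HIPPO_SHIFT = {  # mm^3 deficit vs healthy mean
    "CU-young": 0.0, "CU-middle": -100.0, "CU-oldneg": -300.0,
    "CU-oldpos": -400.0, "MCI": -900.0, "AD": -1300.0,
}
_FD_SHIFT = {
    "CU-young": 0.0, "CU-middle": 0.01, "CU-oldneg": 0.04,
    "CU-oldpos": 0.05, "MCI": 0.08, "AD": 0.10,
}


@dataclass
class CohortConfig:
    """Settings for :func:`generate_cohort`.

    Defaults reproduce the reference cohort structure: 261 participants in
    six groups (the pooled 145 unimpaired young/middle-aged adults are split
    90/55), one to three visits spaced ~18 months apart, and all default
    effects planted.
    """

    group_sizes: Dict[str, int] = field(default_factory=lambda: {
        "CU-young": 90, "CU-middle": 55, "CU-oldneg": 56,
        "CU-oldpos": 8, "MCI": 26, "AD": 26,
    })
    n_converters: int = 18
    visit_spacing_months: float = 18.0
    visit_jitter_sd_months: float = 4.0
    effects: Dict[str, float] = field(default_factory=lambda: dict(DEFAULT_EFFECTS))
    noise_sd: float = 0.05
    fd_base: float = 0.12
    fd_sd: float = 0.04
    fd_group_shift: Dict[str, float] = field(default_factory=lambda: dict(_FD_SHIFT))
    sequence_variant_prob: float = 0.075  # young/middle subjects only
    age_ranges: Dict[str, tuple] = field(default_factory=lambda: {
        g: (_GROUP_DEMOGRAPHICS[g]["age"][2], _GROUP_DEMOGRAPHICS[g]["age"][3])
        for g in GROUPS
    })

    def validate(self) -> None:
        if not self.group_sizes:
            raise ValueError("empty cohort config: no group sizes given")
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}; expected one of {GROUPS}")
            if n < 0:
                raise ValueError(f"negative group size for {g}: {n}")
        for g, (lo, hi) in self.age_ranges.items():
            if not lo < hi:
                raise ValueError(f"invalid age range for {g}: [{lo}, {hi}]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def _truncnorm(rng, mean, sd, lo, hi, size=None):
    x = rng.normal(mean, sd, size=size)
    return np.clip(x, lo, hi)


def generate_cohort(config: Optional[CohortConfig] = None, seed: int = 0):
    """Generate a long-format cohort table plus its ground truth.

    Returns ``(table, truth)`` where ``table`` is a pandas DataFrame with
    one row per subject-visit (columns fixed by the cohort schema) and
    ``truth`` records the planted effects and noise level.  The ``at_index``
    and ``pm_index`` columns equal the planted linear predictor plus
    ``N(0, noise_sd)`` noise (table mode).
    """
    config = config or CohortConfig()
    config.validate()
    rng = np.random.default_rng(seed)

    rows = []
    subject_counter = 0
    for group in GROUPS:
        n = int(config.group_sizes.get(group, 0))
        demo = _GROUP_DEMOGRAPHICS[group]
        lo, hi = config.age_ranges[group]
        mci_converter_ids = set()
        if group == "MCI":
            mci_converter_ids = set(range(min(config.n_converters, n)))
        for i in range(n):
            subject_counter += 1
            sid = f"sub-{subject_counter:03d}"
            age0 = float(_truncnorm(rng, demo["age"][0], demo["age"][1], lo, hi))
            sex = "F" if rng.random() < demo["female"] else "M"
            edu = int(round(_truncnorm(rng, *demo["edu"])))
            seq = int(
                group in ("CU-young", "CU-middle")
                and rng.random() < config.sequence_variant_prob
            )
            n_visits = int(rng.choice([1, 2, 3], p=demo["visits"]))
            tiv = float(rng.normal(1.45e6, 1.2e5))
            hippo0 = float(rng.normal(6500.0 + _HIPPO_SHIFT[group], 500.0))
            suvr0 = float(_truncnorm(rng, *_AMYLOID_BY_GROUP[group]))
            fdg0 = float(rng.normal(*_FDG_BY_GROUP[group]))
            mmse0 = float(_truncnorm(rng, *_MMSE_BY_GROUP[group]))
            mdrs0 = float(_truncnorm(rng, *_MDRS_BY_GROUP[group]))
            onset = (
                float(rng.uniform(6.0, 85.4))
                if group == "MCI" and i in mci_converter_ids else None
            )
            months = 0.0
            for v in range(1, n_visits + 1):
                if v > 1:
                    months += max(
                        1.0,
                        config.visit_spacing_months
                        + rng.normal(0.0, config.visit_jitter_sd_months),
                    )
                years = months / 12.0
                decline = {"MCI": 0.8, "AD": 2.0}.get(group, 0.05) * years
                mmse_b = _MMSE_BY_GROUP[group]
                mdrs_b = _MDRS_BY_GROUP[group]
                mmse = int(round(np.clip(mmse0 - decline, mmse_b[2], mmse_b[3])))
                mdrs = int(round(np.clip(mdrs0 - 3.0 * decline, mdrs_b[2], mdrs_b[3])))
                delay = None
                if onset is not None and months < onset:
                    delay = onset - months
                rows.append(dict(
                    subject_id=sid, visit_index=v, group=group,
                    age_years=age0 + years, sex=sex, education_years=edu,
                    months_from_baseline=months, sequence_variant=seq,
                    amyloid_suvr=suvr0 + 0.01 * years,
                    fdg_suvr=fdg0 - 0.005 * years,
                    hippo_volume_raw=max(hippo0 - 40.0 * years, 2000.0),
                    tiv=tiv, mmse=mmse, mdrs=mdrs,
                    months_to_dementia=delay,
                    mean_fd=float(max(
                        0.02,
                        rng.normal(
                            config.fd_base + config.fd_group_shift.get(group, 0.0),
                            config.fd_sd,
                        ),
                    )),
                ))

    table = pd.DataFrame(rows, columns=[c for c in _COHORT_COLUMNS
                                        if c not in ("at_index", "pm_index")])
    truth = GroundTruth(effect_params=dict(config.effects),
                        noise_sd=config.noise_sd, rng_seed=int(seed))
    if table.empty:
        table = pd.DataFrame(columns=_COHORT_COLUMNS)
        return table, truth

    table = plant_effects(table, config.effects)
    noise_at = rng.normal(0.0, config.noise_sd, size=len(table))
    noise_pm = rng.normal(0.0, config.noise_sd, size=len(table))
    table["at_index"] = table["at_true"] + noise_at
    table["pm_index"] = table["pm_true"] + noise_pm
    return table, truth


def hippo_standardized(table: pd.DataFrame) -> pd.Series:
    """Standardized normalized hippocampal volume (fixed reference scale)."""
    norm = table["hippo_volume_raw"] / (table["tiv"] * 1000.0)
    return (norm - HIPPO_NORM_MEAN) / HIPPO_NORM_SD


def plant_effects(cohort: pd.DataFrame, effects: Dict[str, float]) -> pd.DataFrame:
    """Write ``at_true`` / ``pm_true`` columns from a linear effect model.

    The mapping is exactly linear and invertible given ``effects``:

    ``pm_true = intercept_pm + age_pm * age``

    ``at_true = intercept_at + age_at * age + group offsets
    + amyloid_at * (SUVR - 1.31) + fdg_at * (FDG - 1.0)
    + hippo_at * hippo_z + mmse_at * (MMSE - 29) + mdrs_at * (MDRS - 140)
    + delay_at * months_to_dementia`` (converters only; the delay term is
    zero for non-converters).

    Only the keys present in ``effects`` contribute; an unknown key raises.
    """
    unknown = set(effects) - set(DEFAULT_EFFECTS)
    if unknown:
        raise ValueError(f"unknown effect name(s): {sorted(unknown)}")
    required = {
        "age_at": "age_years", "age_pm": "age_years",
        "amyloid_at": "amyloid_suvr", "fdg_at": "fdg_suvr",
        "mmse_at": "mmse", "mdrs_at": "mdrs",
        "delay_at": "months_to_dementia",
        "group_mci_at": "group", "group_ad_at": "group",
    }
    for name in effects:
        col = required.get(name)
        if col is not None and col not in cohort.columns:
            raise ValueError(f"effect {name!r} needs cohort column {col!r}")

    out = cohort.copy()
    e = effects
    at = np.full(len(out), e.get("intercept_at", 0.0), dtype=float)
    pm = np.full(len(out), e.get("intercept_pm", 0.0), dtype=float)
    if "age_at" in e:
        at += e["age_at"] * out["age_years"].to_numpy(float)
    if "age_pm" in e:
        pm += e["age_pm"] * out["age_years"].to_numpy(float)
    if "group_mci_at" in e:
        at += e["group_mci_at"] * (out["group"] == "MCI").to_numpy(float)
    if "group_ad_at" in e:
        at += e["group_ad_at"] * (out["group"] == "AD").to_numpy(float)
    if "amyloid_at" in e:
        at += e["amyloid_at"] * (out["amyloid_suvr"].to_numpy(float) - AMYLOID_REF)
    if "fdg_at" in e:
        at += e["fdg_at"] * (out["fdg_suvr"].to_numpy(float) - FDG_REF)
    if "hippo_at" in e:
        at += e["hippo_at"] * hippo_standardized(out).to_numpy(float)
    if "mmse_at" in e:
        at += e["mmse_at"] * (out["mmse"].to_numpy(float) - MMSE_REF)
    if "mdrs_at" in e:
        at += e["mdrs_at"] * (out["mdrs"].to_numpy(float) - MDRS_REF)
    if "delay_at" in e:
        delay = out["months_to_dementia"].to_numpy(float)
        at += e["delay_at"] * np.nan_to_num(delay, nan=0.0)
    out["at_true"] = at
    out["pm_true"] = pm
    return out


# ---------------------------------------------------------------------------
# Image mode
# ---------------------------------------------------------------------------

@dataclass
class RoiLayout:
    """Deterministic placement of the four disjoint cuboid ROIs."""

    grid: VolumeGrid
    seed_prc: np.ndarray
    seed_phc: np.ndarray
    at_net: np.ndarray
    pm_net: np.ndarray
    brain: np.ndarray
    wm_box: np.ndarray
    csf_box: np.ndarray
    labels: np.ndarray


def layout_rois(grid: VolumeGrid) -> RoiLayout:
    """Place PRC/PHC seeds and AT/PM network cuboids on ``grid``.

    Seeds sit anteriorly (low y), networks posteriorly; WM and CSF boxes in
    between provide nuisance sources.  Raises :class:`LayoutError` when the
    grid cannot hold four disjoint ROIs plus a one-voxel brain margin.
    """
    nx, ny, nz = grid.shape
    if nx < 14 or ny < 12 or nz < 8:
        raise LayoutError(
            f"grid {grid.shape} too small for the four disjoint ROIs "
            "(need at least 14 x 12 x 8 voxels)"
        )
    shape = grid.shape

    def box(xs, ys, zs):
        m = np.zeros(shape, dtype=bool)
        m[xs[0]:xs[1], ys[0]:ys[1], zs[0]:zs[1]] = True
        return m

    brain = box((1, nx - 1), (1, ny - 1), (1, nz - 1))
    z0, z1 = max(1, nz // 3), max(1, nz // 3) + min(4, nz - 2 - nz // 3)
    seed_prc = box((2, 4), (2, 4), (z0, z1))
    seed_phc = box((nx - 4, nx - 2), (2, 4), (z0, z1))
    wx = max(3, (nx - 6) // 3)
    ys = (6, ny - 2)
    zs = (2, nz - 2)
    at_net = box((2, 2 + wx), ys, zs)
    pm_net = box((nx - 2 - wx, nx - 2), ys, zs)
    # nuisance tissue boxes between seeds
    mid = nx // 2
    wm_box = box((mid - 2, mid), (2, 4), (z0, z1))
    csf_box = box((mid, mid + 2), (2, 4), (z0, z1))

    masks = [seed_prc, seed_phc, at_net, pm_net, wm_box, csf_box]
    if any(not m.any() for m in masks):
        raise LayoutError(f"grid {grid.shape} too small: an ROI came out empty")
    total = sum(m.astype(int) for m in masks)
    if total.max() > 1:
        raise LayoutError("ROI layout overlap; grid too small")

    labels = np.zeros(shape, dtype=int)
    zmid = (zs[0] + zs[1]) // 2
    labels[at_net] = 1
    at_hi = at_net.copy()
    at_hi[:, :, :zmid] = False
    labels[at_hi] = 2
    labels[pm_net] = 3
    pm_hi = pm_net.copy()
    pm_hi[:, :, :zmid] = False
    labels[pm_hi] = 4
    return RoiLayout(grid, seed_prc, seed_phc, at_net, pm_net, brain,
                     wm_box, csf_box, labels)


@dataclass
class SyntheticRun:
    """One synthetic scan: BOLD + motion + segmentations + ROI layout."""

    run: BoldRun
    motion: np.ndarray          # (t, 6): 3 translations mm, 3 rotations deg
    seg: SegmentationSet
    layout: RoiLayout

    @property
    def seed_rois(self):
        return (
            SeedRoi("PRC", self.layout.seed_prc, self.run.grid),
            SeedRoi("PHC", self.layout.seed_phc, self.run.grid),
        )


DEFAULT_GRID = VolumeGrid((20, 20, 12), (3.0, 3.0, 3.0))


def generate_run(
    loadings: Dict[str, float],
    grid: VolumeGrid = DEFAULT_GRID,
    n_volumes: int = 120,
    tr_s: float = 2.382,
    seed: int = 0,
    nuisance_scale: float = 1.0,
    subject_id: str = "sub-00",
    visit_index: int = 1,
    sequence_variant: int = 0,
) -> SyntheticRun:
    """Synthesise a single BOLD run with planted seed-network coupling.

    ``loadings`` maps ``"AT"`` / ``"PM"`` to the population correlation
    between the corresponding seed-mean series and each network voxel
    (each in [0, 0.999]).  Nuisance structure (linear drift, global, WM and
    CSF signals, motion-coupled terms) is scaled by ``nuisance_scale``; at
    0 the run contains only latent signal + white noise, so the loading
    contract holds for raw correlations.
    """
    if n_volumes < 20:
        raise ValueError(f"n_volumes must be >= 20, got {n_volumes}")
    lam = {"AT": float(loadings.get("AT", 0.0)), "PM": float(loadings.get("PM", 0.0))}
    for k, v in lam.items():
        if not 0.0 <= v < 1.0:
            raise ValueError(f"loading for {k} must be in [0, 1), got {v}")
    layout = layout_rois(grid)
    rng = np.random.default_rng(seed)
    t = n_volumes
    shape = grid.shape

    amp = 10.0
    latent_at = rng.standard_normal(t)
    latent_pm = rng.standard_normal(t)
    data = 1000.0 + amp * rng.standard_normal(shape + (t,))
    data[~layout.brain] = 0.0

    # seeds carry the latent series exactly; networks mix latent + noise so
    # corr(seed mean, voxel) = loading in the population
    data[layout.seed_prc] = 1000.0 + amp * latent_at
    data[layout.seed_phc] = 1000.0 + amp * latent_pm
    for net_mask, latent, key in (
        (layout.at_net, latent_at, "AT"),
        (layout.pm_net, latent_pm, "PM"),
    ):
        n_vox = int(net_mask.sum())
        eps = rng.standard_normal((n_vox, t))
        lam_k = lam[key]
        data[net_mask] = 1000.0 + amp * (
            lam_k * latent + np.sqrt(1.0 - lam_k**2) * eps
        )

    # motion: slow random walk, translations in mm, rotations in degrees
    motion = np.cumsum(
        rng.normal(0.0, [0.02, 0.02, 0.02, 0.01, 0.01, 0.01], size=(t, 6)), axis=0
    )

    if nuisance_scale > 0:
        s = nuisance_scale
        tt = np.linspace(-0.5, 0.5, t)
        global_sig = rng.standard_normal(t)
        wm_sig = rng.standard_normal(t)
        csf_sig = rng.standard_normal(t)
        drift_coef = rng.normal(0.0, 2.0, size=shape)
        data[layout.brain] += s * amp * (
            drift_coef[layout.brain, None] * tt[None, :]
            + 0.3 * global_sig[None, :]
        )
        data[layout.wm_box] += s * amp * 0.5 * wm_sig
        data[layout.csf_box] += s * amp * 0.5 * csf_sig
        mot_std = (motion - motion.mean(0)) / (motion.std(0) + 1e-12)
        mot_w = rng.normal(0.0, 0.2, size=(int(layout.brain.sum()), 6))
        data[layout.brain] += s * amp * (mot_w @ mot_std.T)

    run = BoldRun(data=data, grid=grid, tr_s=tr_s, subject_id=subject_id,
                  visit_index=visit_index, sequence_variant=sequence_variant)

    gm = np.zeros(shape)
    gm[layout.brain] = 0.95
    gm[layout.wm_box] = 0.05
    gm[layout.csf_box] = 0.05
    wm = np.zeros(shape)
    wm[layout.wm_box] = 0.95
    csf = np.zeros(shape)
    csf[layout.csf_box] = 0.95
    gm_t2 = gm.copy()
    # susceptibility dropout pocket in a corner away from the networks
    gm_t2[1:3, 1:3, 1:3] = np.minimum(gm_t2[1:3, 1:3, 1:3], 0.1)
    seg = SegmentationSet(gm_t1=gm, wm=wm, csf=csf, gm_t2star=gm_t2,
                          brain_mask=layout.brain, grid=grid)
    return SyntheticRun(run=run, motion=motion, seg=seg, layout=layout)


def generate_image_dataset(
    n_subjects: int,
    loadings: Dict[str, float],
    grid: VolumeGrid = DEFAULT_GRID,
    n_volumes: int = 120,
    tr_s: float = 2.382,
    seed: int = 0,
    nuisance_scale: float = 1.0,
) -> tuple[list[SyntheticRun], GroundTruth]:
    """Generate one run per subject, all with the same planted layout."""
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    rng = np.random.default_rng(seed)
    runs = []
    per_subject = {}
    for i in range(n_subjects):
        sid = f"sub-{i + 1:03d}"
        sub_seed = int(rng.integers(0, 2**31 - 1))
        runs.append(generate_run(loadings, grid=grid, n_volumes=n_volumes,
                                 tr_s=tr_s, seed=sub_seed,
                                 nuisance_scale=nuisance_scale,
                                 subject_id=sid))
        per_subject[sid] = dict(loadings)
    lay = runs[0].layout
    truth = GroundTruth(at_voxels=lay.at_net, pm_voxels=lay.pm_net,
                        seed_prc=lay.seed_prc, seed_phc=lay.seed_phc,
                        loading_per_subject=per_subject,
                        effect_params={}, noise_sd=0.0, rng_seed=int(seed))
    return runs, truth
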