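"""Permutation inference with TFCE and max-statistic FWE; network masks.

The mask-building procedure mirrors the seed pipeline: one-sample sign-flip
permutation t-tests retain voxels positively connected to each seed; paired
permutation t-tests on difference maps highlight voxels *more* strongly
connected to one seed than the other; the AT mask is the intersection of
the perirhinal one-sample and perirhinal>parahippocampal paired results,
and the PM mask the intersection of the parahippocampal one-sample and the
opposite paired contrast.  All tests are one-sided ('greater').

TFCE(v) = sum_h e(h, v)^E * h^H * dh over thresholds h = dh, 2dh, ... <= max,
where e(h, v) is the size of the connected component containing v in the
suprathreshold (>= h) set.  Defaults E = 0.5, H = 2, 26-connectivity,
100 integration steps (dh = max/100) follow the standard convention.

Two equivalent TFCE code paths exist: an incremental union-find (numba,
~20x faster, used when numba imports) and a per-threshold scipy labelling
loop.  Tests assert their exact agreement and check both against an
independent brute-force oracle.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .grids import ConnMap, SeedRoi

log = logging.getLogger(__name__)

__all__ = [
    "tfce", "one_sample_perm_test", "paired_perm_test",
    "build_network_masks", "participant_mask", "split_by_parcellation",
    "dice", "PermResult", "GroupMaskSet",
]


def _neighbour_offsets(connectivity: int) -> np.ndarray:
    if connectivity not in (6, 18, 26):
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}")
    offs = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                nz_count = (dx != 0) + (dy != 0) + (dz != 0)
                if nz_count == 0:
                    continue
                if connectivity == 6 and nz_count > 1:
                    continue
                if connectivity == 18 and nz_count > 2:
                    continue
                offs.append((dx, dy, dz))
    return np.asarray(offs, dtype=np.int64)


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(3, {6: 1, 18: 2, 26: 3}[connectivity])


# ---------------------------------------------------------------------------
# TFCE
# ---------------------------------------------------------------------------

def _tfce_scipy(stat: np.ndarray, E: float, H: float, dh: float,
                n_steps: int, connectivity: int) -> np.ndarray:
    struct = _structure(connectivity)
    out = np.zeros_like(stat, dtype=float)
    for k in range(1, n_steps + 1):
        h = dh * k
        supra = stat >= h
        if not supra.any():
            break
        labels, nlab = ndimage.label(supra, structure=struct)
        sizes = np.bincount(labels.ravel())
        out[supra] += (sizes[labels[supra]].astype(float) ** E) * (h ** H) * dh
    return out


try:  # optional fast path
    from numba import njit

    @njit(fastmath=False)
    def _tfce_uf(values, nx, ny, nz, dh, n_steps, E, H, offs):  # pragma: no cover
        V = nx * ny * nz
        parent = np.full(V, -1, np.int64)
        size = np.zeros(V, np.int64)
        out = np.zeros(V)
        order = np.argsort(-values)
        active = np.empty(V, np.int64)
        n_active = 0
        ptr = 0
        n_off = offs.shape[0]
        for k in range(n_steps, 0, -1):
            h = dh * k
            while ptr < V and values[order[ptr]] >= h:
                v = order[ptr]
                ptr += 1
                parent[v] = v
                size[v] = 1
                active[n_active] = v
                n_active += 1
                x = v // (ny * nz)
                rem = v % (ny * nz)
                y = rem // nz
                z = rem % nz
                for o in range(n_off):
                    xx = x + offs[o, 0]
                    yy = y + offs[o, 1]
                    zz = z + offs[o, 2]
                    if xx < 0 or xx >= nx or yy < 0 or yy >= ny or zz < 0 or zz >= nz:
                        continue
                    w = (xx * ny + yy) * nz + zz
                    if parent[w] == -1:
                        continue
                    # union(v, w) by size
                    rv = v
                    while parent[rv] != rv:
                        parent[rv] = parent[parent[rv]]
                        rv = parent[rv]
                    rw = w
                    while parent[rw] != rw:
                        parent[rw] = parent[parent[rw]]
                        rw = parent[rw]
                    if rv != rw:
                        if size[rv] < size[rw]:
                            rv, rw = rw, rv
                        parent[rw] = rv
                        size[rv] += size[rw]
            inc = (h ** H) * dh
            for i in range(n_active):
                v = active[i]
                r = v
                while parent[r] != r:
                    parent[r] = parent[parent[r]]
                    r = parent[r]
                out[v] += (size[r] ** E) * inc
        return out

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


def tfce(
    stat_map: np.ndarray,
    E: float = 0.5,
    H: float = 2.0,
    dh: Optional[float] = None,
    connectivity: int = 26,
    n_steps: int = 100,
) -> np.ndarray:
    """Threshold-free cluster enhancement of a 3D statistic map.

    Negative and zero voxels receive 0; an entirely non-positive map yields
    an all-zero output.  When ``dh`` is None it is set to ``max(stat)/n_steps``.
    """
    stat = np.nan_to_num(np.asarray(stat_map, dtype=float), nan=0.0)
    if stat.ndim != 3:
        raise ValueError("stat_map must be 3D")
    peak = stat.max()
    if peak <= 0:
        return np.zeros_like(stat)
    if dh is None:
        dh = peak / n_steps
        steps = n_steps
    else:
        if dh <= 0:
            raise ValueError("dh must be positive")
        steps = int(np.floor(peak / dh + 1e-9))
        if steps < 1:
            return np.zeros_like(stat)
    if _HAVE_NUMBA:
        nx, ny, nz = stat.shape
        offs = _neighbour_offsets(connectivity)
        flat = _tfce_uf(np.ascontiguousarray(stat.ravel()), nx, ny, nz,
                        float(dh), steps, float(E), float(H), offs)
        return flat.reshape(stat.shape)
    return _tfce_scipy(stat, E, H, float(dh), steps, connectivity)


# ---------------------------------------------------------------------------
# Permutation tests
# ---------------------------------------------------------------------------

@dataclass
class PermResult:
    """Result of a (one-sample or paired) sign-flip permutation test."""

    t_map: np.ndarray
    tfce_map: np.ndarray
    p_fwe_map: np.ndarray
    sig_mask: np.ndarray
    null_max: np.ndarray
    n_perm_used: int
    alpha: float
    side: str = "greater"


def _as_arrays(maps: Sequence) -> np.ndarray:
    arrs = [m.data if isinstance(m, ConnMap) else np.asarray(m, dtype=float)
            for m in maps]
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise ValueError(f"maps are not on one grid: shapes {sorted(shapes)}")
    return np.stack([np.nan_to_num(a, nan=0.0) for a in arrs])


def _sign_matrix(n: int, n_perm: int, rng: np.random.Generator):
    """Sign-flip design: exhaustive when affordable within n_perm draws."""
    if n <= 30 and 2 ** n <= n_perm:
        total = 2 ** n
        bits = (np.arange(total)[:, None] >> np.arange(n)[None, :]) & 1
        return (2 * bits - 1).astype(np.float64), total
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    return signs, n_perm


def one_sample_perm_test(
    maps: Sequence,
    analysis_mask: np.ndarray,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    E: float = 0.5,
    H: float = 2.0,
    connectivity: int = 26,
    dh: Optional[float] = None,
) -> PermResult:
    """One-sample sign-flip permutation t-test with TFCE + max-stat FWE.

    The permutation statistic is the image-wide maximum of TFCE(t-map);
    ``p_fwe(v) = (1 + #{null_max >= TFCE_obs(v)}) / (n_perm_used + 1)``,
    one-sided (greater).  Sign flips are enumerated exhaustively when
    ``2^n <= n_perm``.
    """
    data = _as_arrays(maps)
    n = data.shape[0]
    if n < 5:
        raise ValueError(f"need at least 5 maps, got {n}")
    if n_perm < 100:
        warnings.warn(f"n_perm = {n_perm} is small; p-value floor is high")
    mask = np.asarray(analysis_mask, dtype=bool)
    if mask.shape != data.shape[1:]:
        raise ValueError("analysis_mask shape does not match maps")
    shape = mask.shape
    X = data[:, mask]  # (n, V)
    nv = X.shape[1]
    rng = np.random.default_rng(seed)
    signs, n_used = _sign_matrix(n, n_perm, rng)

    ssq = (X ** 2).sum(axis=0)
    # a voxel whose values are exactly constant and positive is infinitely
    # significant; represent it with a large finite t so TFCE stays finite
    _BIG_T = 1e6
    zero_scale = 1e-24 * (ssq / n + 1e-300)

    def t_from_mean(mean):
        var = (ssq - n * mean ** 2) / (n - 1)
        var = np.maximum(var, 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = mean / np.sqrt(var / n)
        zv = var <= zero_scale
        t[zv] = np.where(mean[zv] > 0, _BIG_T, 0.0)
        t[~np.isfinite(t)] = 0.0
        return t

    obs_t_flat = t_from_mean(X.mean(axis=0))
    obs_t = np.zeros(shape)
    obs_t[mask] = obs_t_flat
    obs_tfce = tfce(obs_t, E=E, H=H, dh=dh, connectivity=connectivity)

    null_max = np.empty(n_used)
    scratch = np.zeros(shape)
    chunk = 256
    for start in range(0, n_used, chunk):
        S = signs[start:start + chunk]
        means = (S @ X) / n
        for i in range(S.shape[0]):
            scratch[mask] = t_from_mean(means[i])
            null_max[start + i] = tfce(scratch, E=E, H=H, dh=dh,
                                       connectivity=connectivity).max()

    sorted_null = np.sort(null_max)
    obs_vals = obs_tfce[mask]
    exceed = n_used - np.searchsorted(sorted_null, obs_vals, side="left")
    p_flat = (1.0 + exceed) / (n_used + 1.0)
    p_map = np.ones(shape)
    p_map[mask] = p_flat
    sig = np.zeros(shape, dtype=bool)
    sig[mask] = p_flat < alpha
    return PermResult(t_map=obs_t, tfce_map=obs_tfce, p_fwe_map=p_map,
                      sig_mask=sig, null_max=null_max, n_perm_used=n_used,
                      alpha=alpha)


def paired_perm_test(
    maps_a: Sequence,
    maps_b: Sequence,
    analysis_mask: np.ndarray,
    **kwargs,
) -> PermResult:
    """Paired test of a > b via a one-sample test on difference maps."""
    a = _as_arrays(maps_a)
    b = _as_arrays(maps_b)
    if a.shape[0] != b.shape[0]:
        raise ValueError(
            f"paired lists differ in length: {a.shape[0]} vs {b.shape[0]}"
        )
    diffs = a - b
    return one_sample_perm_test(list(diffs), analysis_mask, **kwargs)


# ---------------------------------------------------------------------------
# Mask construction
# ---------------------------------------------------------------------------

@dataclass
class GroupMaskSet:
    """Binary AT and PM network masks plus build provenance."""

    at_mask: np.ndarray
    pm_mask: np.ndarray
    provenance: Dict = field(default_factory=dict)
    dice_vs: Dict[str, float] = field(default_factory=dict)


def build_network_masks(
    prc_onesample: PermResult,
    phc_onesample: PermResult,
    prc_gt_phc: PermResult,
    phc_gt_prc: PermResult,
    at_combine: str = "intersection",
) -> GroupMaskSet:
    """Combine one-sample and paired significance masks into AT/PM masks.

    ``AT = sig(PRC one-sample) ∩ sig(PRC > PHC)`` and
    ``PM = sig(PHC one-sample) ∩ sig(PHC > PRC)``.  The AT rule is read as
    an intersection by symmetry with PM's stated overlap; ``at_combine=
    "union"`` exposes the alternative reading.  The two paired contrasts
    are opposite one-sided tests, so (with the default rule) AT and PM are
    disjoint by construction.
    """
    shapes = {r.sig_mask.shape for r in
              (prc_onesample, phc_onesample, prc_gt_phc, phc_gt_prc)}
    if len(shapes) != 1:
        raise ValueError(f"PermResults are not on one grid: {sorted(shapes)}")
    if at_combine == "intersection":
        at = prc_onesample.sig_mask & prc_gt_phc.sig_mask
    elif at_combine == "union":
        at = prc_onesample.sig_mask | prc_gt_phc.sig_mask
    else:
        raise ValueError(f"at_combine must be 'intersection' or 'union'")
    pm = phc_onesample.sig_mask & phc_gt_prc.sig_mask
    for name, m in (("AT", at), ("PM", pm)):
        if not m.any():
            log.warning("%s mask is empty (one-sample and paired results "
                        "do not overlap)", name)
    prov = dict(
        rule={"AT": at_combine, "PM": "intersection"},
        alpha=prc_onesample.alpha,
        n_perm_used={"prc_onesample": prc_onesample.n_perm_used,
                     "phc_onesample": phc_onesample.n_perm_used,
                     "prc_gt_phc": prc_gt_phc.n_perm_used,
                     "phc_gt_prc": phc_gt_prc.n_perm_used},
        n_voxels={"AT": int(at.sum()), "PM": int(pm.sum())},
    )
    return GroupMaskSet(at_mask=at, pm_mask=pm, provenance=prov)


def participant_mask(
    group_mask: np.ndarray,
    gm_prob: np.ndarray,
    gm_threshold: float = 0.5,
    seeds: Sequence[SeedRoi] = (),
) -> np.ndarray:
    """Participant-specific mask: group mask ∧ (GM >= 0.5) minus seeds."""
    group_mask = np.asarray(group_mask, dtype=bool)
    gm_prob = np.asarray(gm_prob, dtype=float)
    if gm_prob.shape != group_mask.shape:
        raise ValueError("gm_prob and group_mask must share a grid")
    out = group_mask & (gm_prob >= gm_threshold)
    for s in seeds:
        if s.voxels.shape != group_mask.shape:
            raise ValueError(f"seed {s.label} not on the group-mask grid")
        out &= ~s.voxels
    if not out.any():
        log.warning("participant mask is empty; downstream extraction will "
                    "return missing")
    return out


def split_by_parcellation(
    network_mask: np.ndarray,
    labels: np.ndarray,
    min_voxels: int = 100,
) -> List[Tuple[int, np.ndarray]]:
    """Split a network mask by an integer parcellation (0 = background).

    Keeps label intersections with >= ``min_voxels`` voxels (inclusive),
    ordered by label id.
    """
    network_mask = np.asarray(network_mask, dtype=bool)
    labels = np.asarray(labels)
    if labels.shape != network_mask.shape:
        raise ValueError("labels and network_mask must share a grid")
    if labels.min() < 0:
        raise ValueError("labels must be >= 0 (0 = background)")
    out = []
    for lab in np.unique(labels[network_mask & (labels > 0)]):
        roi = network_mask & (labels == lab)
        if int(roi.sum()) >= min_voxels:
            out.append((int(lab), roi))
    return out


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|a∩b| / (|a| + |b|); two empty masks give 1.0."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        log.warning("dice of two empty masks defined as 1.0")
        return 1.0
    return 2.0 * int((a & b).sum()) / denom
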