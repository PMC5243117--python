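"""Whole-brain searchlight maps and cluster-mass family-wise-error inference.

A cubic searchlight of odd side length moves through the brain mask; the
statistic returned by ``stat_fn`` on the cube's in-mask voxels is written to
the centre voxel. Group inference thresholds the voxelwise one-sample t map
at a cluster-forming threshold, labels supra-threshold voxels with
26-connectivity, and compares each cluster's mass (summed t) against the
permutation distribution of the maximum cluster mass under sign-flipping of
the per-participant (or per-interval) maps — the standard exchangeability
argument for one-sample designs. With few maps the sign-flip space is
enumerated exhaustively, making the corrected p deterministic.
"""

from __future__ import annotations

from itertools import product

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import label as cc_label

from .datatypes import ClusterResult, StatMap

__all__ = [
    "run_searchlight",
    "stack_maps",
    "cluster_mass_fwe",
    "encoding_accuracy_map",
]

#: 26-neighbourhood connectivity structure for cluster labelling
_CONN26 = np.ones((3, 3, 3), dtype=bool)


def run_searchlight(
    coords: np.ndarray,
    mask_shape: tuple[int, int, int],
    stat_fn,
    side: int = 3,
    min_voxels: int = 1,
    strict_interior: bool | None = None,
) -> StatMap:
    """Evaluate ``stat_fn(voxel_indices)`` in a cubic searchlight.

    Parameters
    ----------
    coords : (n_voxels, 3) int array
        Grid coordinates of the in-mask voxels; ``stat_fn`` receives indices
        into this array (i.e. row numbers of the voxel x time matrix).
    mask_shape : tuple
        Shape of the 3D grid the coordinates live in.
    side : int
        Cube side (odd). The side-3 variant uses the strict-interior edge
        rule (centres whose full cube fits in the grid); the side-5 variant
        intersects the cube with the mask and applies ``min_voxels``
        (25 in the group analysis).
    strict_interior : bool, optional
        Override the edge rule; defaults to ``side == 3``.
    """
    if side % 2 != 1:
        raise ValueError("searchlight side must be odd")
    coords = np.asarray(coords, dtype=int)
    if coords.size == 0:
        raise ValueError("empty mask")
    if strict_interior is None:
        strict_interior = side == 3
    half = side // 2

    in_mask = np.zeros(mask_shape, dtype=bool)
    vox_index = -np.ones(mask_shape, dtype=int)
    in_mask[tuple(coords.T)] = True
    vox_index[tuple(coords.T)] = np.arange(len(coords))

    values = np.full(mask_shape, np.nan)
    offsets = np.array(list(product(range(-half, half + 1), repeat=3)))
    dims = np.array(mask_shape)
    for idx, c in enumerate(coords):
        if strict_interior and (np.any(c - half < 0) or np.any(c + half >= dims)):
            continue
        neigh = c + offsets
        ok = np.all((neigh >= 0) & (neigh < dims), axis=1)
        neigh = neigh[ok]
        members = vox_index[tuple(neigh.T)]
        members = members[members >= 0]
        if members.size < min_voxels:
            continue
        values[tuple(c)] = stat_fn(members)
    return StatMap(values=values, mask=in_mask)


def stack_maps(maps: list[StatMap], min_participants: int = 5) -> np.ndarray:
    """Stack StatMaps into (n_maps, *grid), masking voxels evaluated in fewer
    than ``min_participants`` maps to NaN everywhere."""
    arr = np.stack([m.values for m in maps])
    counts = np.sum(np.isfinite(arr), axis=0)
    arr[:, counts < min_participants] = np.nan
    return arr


def _max_cluster_mass(tmap: np.ndarray, thresh_t: np.ndarray | float) -> float:
    supra = tmap > thresh_t
    if not supra.any():
        return 0.0
    labels, n = cc_label(supra, structure=_CONN26)
    if n == 0:
        return 0.0
    masses = np.array([tmap[labels == i].sum() for i in range(1, n + 1)])
    return float(masses.max())


def _tmap(arr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Voxelwise one-sample t over axis 0, ignoring all-NaN voxels."""
    if not np.isnan(arr).any():  # fast path for dense maps
        n = np.full(arr.shape[1:], arr.shape[0])
        mean = arr.mean(axis=0)
        sd = arr.std(axis=0, ddof=1)
    else:
        n = np.sum(np.isfinite(arr), axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean = np.nanmean(arr, axis=0)
            sd = np.nanstd(arr, axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = mean / (sd / np.sqrt(n))
    t[~np.isfinite(t)] = np.nan
    return t, n


def cluster_mass_fwe(
    maps: list[StatMap] | np.ndarray,
    cluster_p: float = 0.01,
    n_perm: int = 10000,
    seed: int = 0,
) -> ClusterResult:
    """Cluster-mass FWE inference over per-participant/per-interval maps.

    Voxelwise right-tailed one-sample t across maps; voxels with
    uncorrected p < ``cluster_p`` form clusters under 26-connectivity.
    Each cluster's mass (sum of supra-threshold t) is compared with the
    sign-flip permutation distribution of the maximum cluster mass:
    corrected p = (1 + #{perm max >= observed}) / (1 + n_perm), or the
    exact enumeration fraction when 2^n_maps <= n_perm.
    """
    arr = maps if isinstance(maps, np.ndarray) else stack_maps(maps,
                                                               min_participants=0)
    n_maps = arr.shape[0]
    if n_maps < 8:
        raise ValueError("need at least 8 maps for permutation resolution")
    t, n = _tmap(arr)
    # per-voxel t threshold for the cluster-forming p (df varies with n)
    df = np.where(n > 1, n - 1, 1)
    thresh = stats.t.ppf(1.0 - cluster_p, df)
    finite = np.isfinite(t)
    supra = finite & (t > thresh)

    labels = np.zeros(arr.shape[1:], dtype=int)
    table_rows = []
    if supra.any():
        labels, n_clusters = cc_label(supra, structure=_CONN26)
        obs_masses = [
            float(t[labels == i].sum()) for i in range(1, n_clusters + 1)
        ]
    else:
        obs_masses = []

    if obs_masses:
        exact = 2**n_maps <= n_perm
        if exact:
            signs_iter = (np.array(s) for s in product((1.0, -1.0), repeat=n_maps))
            total = 2**n_maps
        else:
            rng = np.random.default_rng(seed)
            signs_iter = (rng.choice((1.0, -1.0), size=n_maps)
                          for _ in range(n_perm))
            total = n_perm
        max_obs = max(obs_masses)
        perm_max = np.empty(total)
        for i, signs in enumerate(signs_iter):
            flipped = arr * signs[:, None, None, None]
            tp, _ = _tmap(flipped)
            tp[~np.isfinite(tp)] = -np.inf
            perm_max[i] = _max_cluster_mass(tp, thresh)
        for cid, mass in enumerate(obs_masses, start=1):
            exceed = int(np.sum(perm_max >= mass))
            p = exceed / total if exact else (1 + exceed) / (1 + total)
            size = int(np.sum(labels == cid))
            cog = np.array(np.nonzero(labels == cid)).mean(axis=1)
            table_rows.append((cid, mass, size, p, *cog))

    table = pd.DataFrame(
        table_rows,
        columns=["cluster_id", "mass", "size", "p_fwe", "cog_x", "cog_y", "cog_z"],
    )
    return ClusterResult(labels=labels, table=table)


def encoding_accuracy_map(
    run,
    clip_windows: np.ndarray,
    accuracy: np.ndarray,
) -> np.ndarray:
    """Per-voxel Fisher-z correlation between clip-evoked activity and
    timeline-placement accuracy across clips.

    ``clip_windows`` is (n_clips, 2) start/stop TR bounds of each clip's
    5-TR window; ``accuracy`` is the per-clip negative absolute residual of
    the timeline regression. Raises if accuracy has zero variance (perfect
    placements).
    """
    accuracy = np.asarray(accuracy, dtype=float)
    if accuracy.size < 3:
        raise ValueError("need at least 3 clips")
    if np.ptp(accuracy) == 0:
        raise ValueError("accuracy has zero variance (perfect placements)")
    data = run.data
    evoked = np.stack(
        [data[:, start:stop].mean(axis=1) for start, stop in clip_windows],
        axis=1,
    )  # voxels x clips
    ec = evoked - evoked.mean(axis=1, keepdims=True)
    ac = accuracy - accuracy.mean()
    denom = np.sqrt((ec**2).sum(axis=1) * (ac**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (ec * ac).sum(axis=1) / denom
    r = np.clip(r, -1 + 1e-7, 1 - 1e-7)
    return np.arctanh(r)
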