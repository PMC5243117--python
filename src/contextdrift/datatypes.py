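"""Shared data containers for the context-drift analysis pipeline.

Conventions used throughout the package:

* time is in seconds internally; minutes appear only at presentation,
* TR indices are 0-based internally; logs and docstrings that quote a
  "TR number" use the 1-based convention common in the fMRI literature
  (conversion happens in exactly one place, :func:`contextdrift.drift.clip_middle_tr`),
* voxel-by-time matrices are ``(n_voxels, n_trs)`` float arrays.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: compartment labels a voxel can carry
GREY, WHITE, CSF = "grey", "white", "csf"


@dataclass
class BoldRun:
    """One participant's voxel x time BOLD matrix with voxel metadata.

    Parameters
    ----------
    participant_id : str
    data : ndarray, shape (n_voxels, n_trs)
        BOLD signal; must be free of NaNs after loading.
    tr : float
        Repetition time in seconds (1.5 s for the study design emulated here).
    coords : ndarray, shape (n_voxels, 3)
        Integer voxel grid coordinates.
    compartments : ndarray of str, shape (n_voxels,)
        One of ``grey``/``white``/``csf`` per voxel.
    roi_labels : ndarray of str, shape (n_voxels,)
        Region label per voxel (ROIs tile the grey compartment; white/CSF
        voxels carry their compartment name).
    """

    participant_id: str
    data: np.ndarray
    tr: float
    coords: np.ndarray
    compartments: np.ndarray
    roi_labels: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("BOLD data must be a (n_voxels, n_trs) matrix")
        if np.isnan(self.data).any():
            raise ValueError("BOLD data contains NaNs")
        if self.tr <= 0:
            raise ValueError("TR must be positive")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_trs(self) -> int:
        return self.data.shape[1]

    def voxel_indices(self, roi: str) -> np.ndarray:
        """Indices of voxels belonging to ROI (or compartment) `roi`."""
        idx = np.flatnonzero(self.roi_labels == roi)
        if idx.size == 0:
            idx = np.flatnonzero(self.compartments == roi)
        return idx

    def roi_matrix(self, roi: str) -> np.ndarray:
        idx = self.voxel_indices(roi)
        if idx.size == 0:
            raise KeyError(f"no voxels labelled {roi!r}")
        return self.data[idx]

    def copy_with(self, data: np.ndarray) -> "BoldRun":
        return BoldRun(
            participant_id=self.participant_id,
            data=np.asarray(data, dtype=float),
            tr=self.tr,
            coords=self.coords,
            compartments=self.compartments,
            roi_labels=self.roi_labels,
        )


@dataclass
class ClipSchedule:
    """Clip onsets/durations plus the interval pairs built from them.

    ``clips`` columns: clip_id, onset_s, duration_s.
    ``intervals`` columns: interval_id, clip_a, clip_b, true_gap_s, position_s
    where position_s is the interval's chronological "position in story"
    (midpoint between the two delimiting clips).
    """

    clips: pd.DataFrame
    intervals: pd.DataFrame

    def __post_init__(self) -> None:
        onsets = self.clips.set_index("clip_id")["onset_s"]
        a = onsets.loc[self.intervals["clip_a"]].to_numpy()
        b = onsets.loc[self.intervals["clip_b"]].to_numpy()
        if not (b > a).all():
            raise ValueError("clip_b must start after clip_a in every interval")

    @property
    def n_intervals(self) -> int:
        return len(self.intervals)

    def clip(self, clip_id) -> pd.Series:
        row = self.clips.loc[self.clips["clip_id"] == clip_id]
        if len(row) != 1:
            raise KeyError(f"clip {clip_id!r} not in schedule")
        return row.iloc[0]

    def intervals_with_gap(self, gap_s: float) -> pd.DataFrame:
        return self.intervals.loc[np.isclose(self.intervals["true_gap_s"], gap_s)]


@dataclass
class DurationReport:
    """Per-participant duration estimates and per-clip confidence ratings.

    ``estimates`` maps interval_id -> estimate in seconds (>= 0);
    ``clip_confidence`` maps clip_id -> ordinal 1-5 or binary 0/1 rating.
    """

    participant_id: str
    estimates: pd.Series
    clip_confidence: pd.Series
    group: str = "original"

    def __post_init__(self) -> None:
        if (self.estimates < 0).any():
            raise ValueError("duration estimates must be non-negative")

    def estimate_vector(self, interval_ids) -> np.ndarray:
        return self.estimates.loc[list(interval_ids)].to_numpy(dtype=float)


@dataclass
class FilterSpec:
    """High-pass filter specification following the FSL convention.

    The filter is parameterised by its cut-off period; the Gaussian scale of
    the running-line fit is half the cut-off (sigma_s = cutoff_s / 2), which
    reconciles a reported sigma of 240 s with a selected 480 s cut-off.
    """

    cutoff_s: float

    def __post_init__(self) -> None:
        if self.cutoff_s <= 0:
            raise ValueError("cutoff must be positive")

    @property
    def sigma_s(self) -> float:
        return self.cutoff_s / 2.0


@dataclass
class DistanceSeries:
    """Lagged pattern-dissimilarity time course for one ROI.

    ``values[i]`` is the dissimilarity (1 - Pearson r) between the
    window-averaged pattern whose window is centred on TR ``start_trs[i]``
    and the window-averaged pattern ``lag_trs`` later.
    """

    values: np.ndarray
    start_trs: np.ndarray
    lag_trs: int = 80
    window_trs: int = 5

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.start_trs = np.asarray(self.start_trs, dtype=int)

    def index_for_tr(self, center_tr: int) -> int:
        """Series index whose first window is centred on `center_tr` (0-based)."""
        hits = np.flatnonzero(self.start_trs == center_tr)
        if hits.size != 1:
            raise IndexError(f"TR {center_tr} outside the valid series range")
        return int(hits[0])


@dataclass
class NullEnsemble:
    """An empirical statistic with its surrogate/permutation null distribution.

    ``z = (empirical - mean(nulls)) / sd(nulls)`` with the sample (n-1)
    standard deviation. All quantities are Fisher-transformed correlations.
    """

    empirical: float
    nulls: np.ndarray

    def __post_init__(self) -> None:
        self.nulls = np.asarray(self.nulls, dtype=float)

    @property
    def z(self) -> float:
        sd = float(np.std(self.nulls, ddof=1))
        if sd == 0:
            raise ZeroDivisionError("null distribution has zero spread")
        return (self.empirical - float(np.mean(self.nulls))) / sd


@dataclass
class CorrDiffCI:
    """Difference between two correlations with its combined CI (Zou)."""

    rdiff: float
    lldiff: float
    uldiff: float

    def __post_init__(self) -> None:
        if not (self.lldiff <= self.rdiff <= self.uldiff):
            raise ValueError("CI bounds must bracket the difference")


@dataclass
class AcfProfile:
    """Lagwise autocorrelation of a region's signal and its FWHM.

    ``lags`` are signed TR offsets (symmetric about 0); ``fwhm_trs`` counts
    the lags in that range whose mean autocorrelation is at or above half
    the maximum (the maximum is 1 at lag 0).
    """

    lags: np.ndarray
    mean_acf: np.ndarray
    method: str

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=int)
        self.mean_acf = np.asarray(self.mean_acf, dtype=float)
        if self.lags.shape != self.mean_acf.shape:
            raise ValueError("lags and acf must align")

    @property
    def fwhm_trs(self) -> int:
        half_max = 0.5 * float(np.nanmax(self.mean_acf))
        return int(np.sum(self.mean_acf >= half_max))


@dataclass
class StatMap:
    """3D statistic map (searchlight output) with its brain mask."""

    values: np.ndarray
    mask: np.ndarray
    voxel_size_mm: float = 3.0
    space: str = "native"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("map and mask shapes differ")
        if np.isfinite(self.values[~self.mask]).any():
            raise ValueError("values outside the mask must be NaN")


@dataclass
class ClusterResult:
    """Supra-threshold clusters with mass, size and FWE-corrected p."""

    labels: np.ndarray
    table: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["cluster_id", "mass", "size", "p_fwe", "cog_x", "cog_y", "cog_z"]))
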