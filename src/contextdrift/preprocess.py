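"""Algorithmic preprocessing: despiking, gentle high-pass filtering,
nuisance residualization, the ISC-based filter-cutoff diagnostic and
temporal smoothing.

The high-pass filter is a Gaussian-weighted running-line fit (the FSL
algorithm), implemented directly rather than through a Butterworth
substitute so its pass-band behaviour matches the named procedure. The
filter is parameterised by the cut-off period; the Gaussian scale is
sigma = cutoff / 2.
"""

from __future__ import annotations

import warnings
from functools import lru_cache

import numpy as np
from scipy import stats
from scipy.interpolate import interp1d

from .datatypes import CSF, GREY, WHITE, BoldRun, FilterSpec

__all__ = [
    "despike",
    "highpass",
    "highpass_matrix",
    "nuisance_residualize",
    "isc",
    "select_cutoff",
    "smooth_window",
    "DEFAULT_CUTOFFS",
]

#: candidate high-pass cut-off periods (seconds) scanned by the diagnostic
DEFAULT_CUTOFFS = (140.0, 240.0, 300.0, 400.0, 480.0, 600.0, 720.0)


def despike(series: np.ndarray) -> np.ndarray:
    """Replace points deviating from the mean by more than 5x the IQR.

    Flagged points are replaced by cubic interpolation over the surviving
    points; flagged points at the edges take the nearest surviving value.
    A constant series (IQR = 0, all deviations 0) passes through unchanged.
    Raises if more than half the points are flagged (pathological series).
    """
    x = np.asarray(series, dtype=float)
    if x.size < 4:
        raise ValueError("series too short to despike")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    dev = np.abs(x - x.mean())
    bad = dev > 5.0 * iqr
    if not bad.any():
        return x.copy()
    if bad.mean() > 0.5:
        raise ValueError("more than 50% of points flagged as spikes")
    good = ~bad
    t = np.arange(x.size)
    kind = "cubic" if good.sum() >= 4 else "linear"
    f = interp1d(t[good], x[good], kind=kind, bounds_error=False,
                 fill_value=(x[good][0], x[good][-1]))
    out = x.copy()
    out[bad] = f(t[bad])
    return out


def highpass_matrix(n_trs: int, tr: float, spec: FilterSpec) -> np.ndarray:
    """The (T, T) linear smoother of the Gaussian-weighted running-line fit.

    Row t holds the weights that produce the local line's value at t;
    subtracting ``S @ y`` from ``y`` (and re-adding the mean) implements the
    high-pass filter. Computing S once lets a whole voxel matrix be filtered
    with a single matmul; the matrix is cached per (T, TR, sigma).
    """
    return _highpass_matrix_cached(n_trs, float(tr), float(spec.sigma_s))


@lru_cache(maxsize=16)
def _highpass_matrix_cached(n_trs: int, tr: float, sigma_s: float) -> np.ndarray:
    sigma_trs = sigma_s / tr
    if sigma_trs <= 0:
        raise ValueError("sigma must be positive")
    t = np.arange(n_trs, dtype=float)
    d = t[None, :] - t[:, None]
    w = np.exp(-0.5 * (d / sigma_trs) ** 2)
    s0 = w.sum(axis=1)
    s1 = (w * d).sum(axis=1)
    s2 = (w * d * d).sum(axis=1)
    denom = s0 * s2 - s1**2
    # local weighted line evaluated at its centre: standard local-linear
    # smoother weights (s2 - d*s1) * w / (s0*s2 - s1^2)
    smoother = (s2[:, None] - d * s1[:, None]) * w / denom[:, None]
    return smoother


def highpass(series: np.ndarray, spec: FilterSpec, tr: float) -> np.ndarray:
    """Gaussian-weighted running-line high-pass of one series or a voxel matrix.

    The local line fit is subtracted at every time point and the original
    mean re-added, so the output mean equals the input mean.
    """
    x = np.atleast_2d(np.asarray(series, dtype=float))
    n_trs = x.shape[1]
    if spec.cutoff_s >= n_trs * tr:
        raise ValueError("cutoff must be shorter than the run duration")
    smoother = highpass_matrix(n_trs, tr, spec)
    resid = x - x @ smoother.T
    resid -= resid.mean(axis=1, keepdims=True)
    out = resid + x.mean(axis=1, keepdims=True)
    return out[0] if np.ndim(series) == 1 else out


def highpass_run(run: BoldRun, spec: FilterSpec) -> BoldRun:
    return run.copy_with(highpass(run.data, spec, run.tr))


def nuisance_residualize(run: BoldRun, top_sd_frac: float = 0.01) -> BoldRun:
    """Project three nuisance time courses out of every voxel.

    Regressors: the mean of the top ``top_sd_frac`` highest-SD in-brain
    voxels, the mean CSF signal and the mean white-matter signal (plus an
    intercept, which is added back so voxel means are preserved). Intended
    to run on data that has already been high-pass filtered.
    """
    for comp in (CSF, WHITE):
        if not (run.compartments == comp).any():
            raise ValueError(f"empty {comp!r} compartment mask")
    data = run.data
    sds = data.std(axis=1)
    n_top = max(1, int(np.ceil(top_sd_frac * run.n_voxels)))
    top = np.argsort(sds)[-n_top:]
    regressors = np.column_stack(
        [
            data[top].mean(axis=0),
            data[run.compartments == CSF].mean(axis=0),
            data[run.compartments == WHITE].mean(axis=0),
            np.ones(run.n_trs),
        ]
    )
    beta, *_ = np.linalg.lstsq(regressors, data.T, rcond=None)
    fitted = regressors @ beta
    resid = data.T - fitted
    intercept = np.outer(np.ones(run.n_trs), beta[-1])
    return run.copy_with((resid + intercept).T)


def isc(runs: list[BoldRun], roi: str) -> np.ndarray:
    """Leave-one-out inter-subject correlation of an ROI's mean time course.

    For each participant: Pearson r between their ROI-mean time course and
    the average ROI-mean time course of all the other participants. A
    participant with a constant time course gets NaN (flagged undefined).
    """
    if len(runs) < 3:
        raise ValueError("need at least 3 participants for ISC")
    courses = np.stack([r.roi_matrix(roi).mean(axis=0) for r in runs])
    n = courses.shape[0]
    total = courses.sum(axis=0)
    out = np.empty(n)
    for j in range(n):
        own = courses[j]
        others = (total - own) / (n - 1)
        if np.ptp(own) == 0 or np.ptp(others) == 0:
            out[j] = np.nan
            continue
        out[j] = stats.pearsonr(own, others)[0]
    return out


def select_cutoff(
    runs: list[BoldRun],
    grey_rois: list[str],
    csf_roi: str = CSF,
    candidate_cutoffs: tuple[float, ...] = DEFAULT_CUTOFFS,
    alpha: float = 0.05,
) -> tuple[FilterSpec, dict]:
    """Pick the gentlest (longest) cut-off whose filtered+residualized data
    show every grey ROI's ISC significantly above the CSF ISC.

    Significance is a paired one-tailed t-test across participants at
    ``alpha``. If no candidate qualifies the shortest one is returned with a
    warning. Also returns a diagnostics dict with the per-cutoff ISC tables.
    """
    cutoffs = sorted(candidate_cutoffs)
    diagnostics: dict = {"isc": {}, "qualifies": {}}
    qualifying = []
    for cutoff in cutoffs:
        spec = FilterSpec(cutoff_s=cutoff)
        processed = [nuisance_residualize(highpass_run(r, spec)) for r in runs]
        csf_isc = isc(processed, csf_roi)
        table = {csf_roi: csf_isc}
        ok = True
        for roi in grey_rois:
            grey_isc = isc(processed, roi)
            table[roi] = grey_isc
            valid = ~np.isnan(grey_isc) & ~np.isnan(csf_isc)
            t, p = stats.ttest_rel(grey_isc[valid], csf_isc[valid],
                                   alternative="greater")
            if not p < alpha:
                ok = False
        diagnostics["isc"][cutoff] = table
        diagnostics["qualifies"][cutoff] = ok
        if ok:
            qualifying.append(cutoff)
    if qualifying:
        return FilterSpec(cutoff_s=max(qualifying)), diagnostics
    warnings.warn(
        "no cut-off separated grey ISC from CSF ISC; falling back to the "
        f"shortest candidate ({cutoffs[0]:.0f} s)",
        stacklevel=2,
    )
    return FilterSpec(cutoff_s=cutoffs[0]), diagnostics


def smooth_window(series: np.ndarray, width: int = 5) -> np.ndarray:
    """Centred moving average; edges use shrinking (one-sided truncated) windows."""
    if width % 2 != 1:
        raise ValueError("width must be odd")
    x = np.atleast_2d(np.asarray(series, dtype=float))
    n = x.shape[1]
    if width > n:
        raise ValueError("window wider than the series")
    half = width // 2
    csum = np.cumsum(np.pad(x, ((0, 0), (1, 0))), axis=1)
    starts = np.maximum(np.arange(n) - half, 0)
    stops = np.minimum(np.arange(n) + half + 1, n)
    out = (csum[:, stops] - csum[:, starts]) / (stops - starts)
    return out[0] if np.ndim(series) == 1 else out
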