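"""Slowness of signal change per region, quantified as the full width at
half maximum (FWHM) of the autocorrelation function.

Three variants mirror the region-comparison procedure: a multivariate ACF
(pattern at each TR correlated with the pattern at every lag, averaged over
reference TRs), the same after regressing ROI size out of the FWHM vector,
and a univariate ACF (per-voxel lagged autocorrelation averaged over the
ROI). The FWHM counts the lags, over a symmetric evaluated range, whose
mean autocorrelation is at or above half the maximum (the maximum is 1 at
lag 0), so a boxcar-smoothed white-noise signal with a 5-TR window gives
FWHM = 5 and an AR(1) voxel with rho = 0.9 gives FWHM = 13.

The evaluated lag range is capped at +/- T/4 to bound edge noise; the mean
ACF at each lag uses the shrinking sample of available pairs (no padding).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import AcfProfile, BoldRun
from .preprocess import smooth_window

__all__ = [
    "pattern_acf",
    "voxel_acf",
    "regress_out_size",
    "compare_regions",
    "region_fwhm_table",
]

MIN_ROI_VOXELS = 10


def _symmetric_profile(acf_pos: np.ndarray, method: str) -> AcfProfile:
    """Mirror non-negative-lag values onto the signed lag axis."""
    max_lag = acf_pos.size - 1
    lags = np.arange(-max_lag, max_lag + 1)
    vals = np.concatenate([acf_pos[:0:-1], acf_pos])
    return AcfProfile(lags=lags, mean_acf=vals, method=method)


def pattern_acf(
    run: BoldRun, roi: str, smooth: int = 5, max_lag: int | None = None
) -> AcfProfile:
    """Multivariate ACF: correlation of the multivoxel pattern at each TR
    with the pattern every lag away, averaged over reference TRs.

    Voxel time courses are smoothed with a 5-TR moving average first (a
    denoising step; pass ``smooth=0`` to skip). ROIs under 10 voxels are
    skipped (ValueError).
    """
    mat = run.roi_matrix(roi)
    if mat.shape[0] < MIN_ROI_VOXELS:
        raise ValueError(f"ROI {roi!r} has fewer than {MIN_ROI_VOXELS} voxels")
    if smooth:
        mat = smooth_window(mat, smooth)
    n_trs = mat.shape[1]
    if max_lag is None:
        max_lag = n_trs // 4
    # z-score each TR's pattern across voxels so corr(t, t+k) is a dot product
    z = mat - mat.mean(axis=0)
    norms = np.linalg.norm(z, axis=0)
    norms[norms == 0] = np.nan
    z = z / norms
    acf = np.empty(max_lag + 1)
    acf[0] = 1.0
    for k in range(1, max_lag + 1):
        acf[k] = np.nanmean(np.sum(z[:, :-k] * z[:, k:], axis=0))
    return _symmetric_profile(acf, method="multivariate")


def voxel_acf(
    run: BoldRun, roi: str, smooth: int = 0, max_lag: int | None = None
) -> AcfProfile:
    """Univariate ACF: per-voxel lagged autocorrelation, averaged over the
    ROI's voxels. Constant voxels are excluded from the average.

    Each voxel's lag-k value is the Pearson correlation between the series
    and itself shifted by k, computed on the shrinking overlap (no padding).
    """
    mat = run.roi_matrix(roi)
    if mat.shape[0] < MIN_ROI_VOXELS:
        raise ValueError(f"ROI {roi!r} has fewer than {MIN_ROI_VOXELS} voxels")
    if smooth:
        mat = smooth_window(mat, smooth)
    keep = mat.std(axis=1) > 0
    mat = mat[keep]
    n_trs = mat.shape[1]
    if max_lag is None:
        max_lag = n_trs // 4
    acf = np.empty(max_lag + 1)
    acf[0] = 1.0
    for k in range(1, max_lag + 1):
        a = mat[:, :-k]
        b = mat[:, k:]
        ac = a - a.mean(axis=1, keepdims=True)
        bc = b - b.mean(axis=1, keepdims=True)
        denom = np.sqrt((ac**2).sum(axis=1) * (bc**2).sum(axis=1))
        ok = denom > 0
        acf[k] = np.mean((ac[ok] * bc[ok]).sum(axis=1) / denom[ok])
    return _symmetric_profile(acf, method="univariate")


def regress_out_size(fwhm: pd.DataFrame, sizes: pd.Series) -> pd.DataFrame:
    """Residual FWHM after OLS of FWHM on ROI size, per participant.

    ``fwhm`` is participants x ROIs; ``sizes`` gives each ROI's voxel count.
    With constant sizes the residuals reduce to the centred FWHM.
    """
    if fwhm.shape[1] < 3:
        raise ValueError("need at least 3 ROIs to regress out size")
    x = sizes.loc[fwhm.columns].to_numpy(dtype=float)
    out = {}
    for participant, row in fwhm.iterrows():
        y = row.to_numpy(dtype=float)
        if np.ptp(x) == 0:
            out[participant] = y - y.mean()
            continue
        slope, intercept = np.polyfit(x, y, 1)
        out[participant] = y - (slope * x + intercept)
    return pd.DataFrame(out, index=fwhm.columns).T


def compare_regions(
    fwhm_a: np.ndarray, fwhm_b: np.ndarray, alternative: str = "greater"
) -> float:
    """Paired Wilcoxon signed-rank p for FWHM(a) vs FWHM(b) across participants."""
    a = np.asarray(fwhm_a, dtype=float)
    b = np.asarray(fwhm_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("FWHM vectors must be paired across participants")
    diff = a - b
    if np.all(diff == 0):
        raise ValueError("all ties: signed-rank test undefined")
    return float(stats.wilcoxon(a, b, alternative=alternative,
                                zero_method="wilcox").pvalue)


def region_fwhm_table(
    runs: list[BoldRun],
    rois: list[str],
    method: str = "multivariate",
    smooth: int = 5,
    max_lag: int | None = None,
) -> pd.DataFrame:
    """Participants x ROIs table of FWHM values, plus per-ROI mean ranking.

    ``method`` selects :func:`pattern_acf` ("multivariate") or
    :func:`voxel_acf` ("univariate", unsmoothed by default per procedure 3).
    """
    fn = pattern_acf if method == "multivariate" else voxel_acf
    rows = {}
    for run in runs:
        vals = {}
        for roi in rois:
            try:
                prof = fn(run, roi, smooth=smooth if method == "multivariate" else 0,
                          max_lag=max_lag)
            except ValueError:
                vals[roi] = np.nan
                continue
            vals[roi] = prof.fwhm_trs
        rows[run.participant_id] = vals
    return pd.DataFrame(rows).T


def rank_regions(fwhm: pd.DataFrame) -> pd.Series:
    """Rank ROIs by mean FWHM, 1 = slowest (largest FWHM)."""
    means = fwhm.mean(axis=0, skipna=True)
    return means.rank(ascending=False).astype(int)
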