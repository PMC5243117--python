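"""The central computation: clip-pattern extraction, pattern dissimilarity,
surrogate-tested within-participant correlation with duration estimates,
the within-interval (across-participant) permutation analysis, FDR over
ROIs and effect sizes.

Statistical logic
-----------------
BOLD has long-range temporal autocorrelation, so the chance level of a
correlation between pattern change and behaviour cannot be read off a
standard r distribution. For the within-participant analysis the null is
built from phase-randomized surrogates of the lagged pattern-distance time
course: surrogates share the empirical amplitude spectrum (hence
autocorrelation) but have random phases. Each surrogate is sampled at the
retained intervals' positions and correlated with the duration estimates;
the empirical Fisher-z correlation is standardised against the null set

    z = (empirical - mean(nulls)) / sd(nulls)        (sample sd, n-1).

For the within-interval analysis the exchangeable unit is the participant,
so the null scrambles the estimate-to-participant assignment instead.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import BoldRun, ClipSchedule, DistanceSeries, NullEnsemble

__all__ = [
    "clip_middle_tr",
    "clip_pattern",
    "pattern_distance",
    "interval_distances",
    "drift_behavior_corr",
    "distance_timecourse",
    "phase_surrogates",
    "surrogate_z",
    "group_roi_test",
    "within_interval_analysis",
    "cohens_d",
    "story_position_drift",
]

MIN_ROI_VOXELS = 10
FISHER_CLAMP = 1.0 - 1e-7


def clip_middle_tr(onset_s: float, duration_s: float, tr: float) -> int:
    """0-based index of the TR at the middle of a clip.

    The field convention is 1-based: middle TR = round((onset + dur/2)/TR).
    This is the single place where that convention is converted to the
    package's 0-based indexing.
    """
    one_based = int(np.rint((onset_s + duration_s / 2.0) / tr))
    return one_based - 1


def _window_bounds(center: int, window: int, n_trs: int) -> tuple[int, int]:
    """Start/stop (exclusive) of a `window`-TR window centred on `center`,
    shifted to stay inside the run."""
    if window > n_trs:
        raise ValueError("window longer than the run")
    half = window // 2
    start = center - half
    start = min(max(start, 0), n_trs - window)
    return start, start + window


def clip_pattern(
    run: BoldRun, roi: str, onset_s: float, duration_s: float, window: int = 5
) -> np.ndarray:
    """Mean voxel pattern over the `window` TRs centred on the clip's middle TR.

    ROIs with fewer than 10 voxels are treated as missing (returns NaNs so
    callers can record the missing value); a clip whose middle TR falls
    outside the run is an error.
    """
    mat = run.roi_matrix(roi)
    if mat.shape[0] < MIN_ROI_VOXELS:
        return np.full(mat.shape[0], np.nan)
    center = clip_middle_tr(onset_s, duration_s, run.tr)
    if not 0 <= center < run.n_trs:
        raise ValueError(f"clip middle TR {center} outside run of {run.n_trs} TRs")
    start, stop = _window_bounds(center, window, run.n_trs)
    return mat[:, start:stop].mean(axis=1)


def pattern_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Dissimilarity 1 - Pearson r between two voxel patterns; range [0, 2]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.size < 2:
        raise ValueError("patterns must have equal length >= 2")
    if np.ptp(p) == 0 or np.ptp(q) == 0:
        raise ValueError("pattern distance undefined for a constant pattern")
    return float(1.0 - np.corrcoef(p, q)[0, 1])


def interval_distances(
    run: BoldRun,
    roi: str,
    schedule: ClipSchedule,
    interval_ids=None,
    window: int = 5,
) -> pd.Series:
    """Pattern distance between the two clip patterns of each interval."""
    iv = schedule.intervals
    if interval_ids is not None:
        iv = iv.loc[iv["interval_id"].isin(interval_ids)]
    clips = schedule.clips.set_index("clip_id")
    out = {}
    for _, row in iv.iterrows():
        a = clips.loc[row["clip_a"]]
        b = clips.loc[row["clip_b"]]
        pa = clip_pattern(run, roi, a["onset_s"], a["duration_s"], window)
        pb = clip_pattern(run, roi, b["onset_s"], b["duration_s"], window)
        if np.isnan(pa).any() or np.isnan(pb).any():
            out[row["interval_id"]] = np.nan
        else:
            out[row["interval_id"]] = pattern_distance(pa, pb)
    return pd.Series(out)


def _fisher(r: float | np.ndarray) -> float | np.ndarray:
    clamped = np.clip(r, -FISHER_CLAMP, FISHER_CLAMP)
    if np.any(np.abs(np.asarray(r)) >= 1.0):
        warnings.warn("correlation at +/-1 clamped before Fisher transform",
                      stacklevel=3)
    return np.arctanh(clamped)


def drift_behavior_corr(
    run: BoldRun,
    roi: str,
    schedule: ClipSchedule,
    estimates: pd.Series,
    retained_intervals,
) -> float:
    """Fisher-z Pearson correlation between per-interval pattern distance
    and the participant's duration estimates over the retained intervals."""
    ids = [i for i in retained_intervals]
    if len(ids) < 3:
        raise ValueError("need at least 3 retained intervals")
    d = interval_distances(run, roi, schedule, ids)
    y = estimates.loc[d.index].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant duration estimates")
    r = stats.pearsonr(d.to_numpy(), y)[0]
    return float(_fisher(r))


def distance_timecourse(
    run: BoldRun, roi: str, lag: int = 80, window: int = 5
) -> DistanceSeries:
    """Dissimilarity between each window-averaged pattern and the pattern
    `lag` TRs later; length T - lag - (window - 1).

    Entry i corresponds to a first window centred on TR ``i + window//2``
    (0-based), the earliest centre whose window fits in the run.
    """
    mat = run.roi_matrix(roi)
    n_trs = mat.shape[1]
    if n_trs <= lag + window:
        raise ValueError("run too short for the requested lag/window")
    half = window // 2
    # window-averaged patterns for every valid centre
    kernel = np.ones(window) / window
    padded = np.apply_along_axis(
        lambda v: np.convolve(v, kernel, mode="valid"), 1, mat
    )  # (voxels, T - window + 1), column c = window centred on TR c + half
    first = padded[:, : n_trs - lag - window + 1]
    second = padded[:, lag:]
    fc = first - first.mean(axis=0)
    sc = second - second.mean(axis=0)
    denom = np.sqrt((fc**2).sum(axis=0) * (sc**2).sum(axis=0))
    r = (fc * sc).sum(axis=0) / denom
    centers = np.arange(first.shape[1]) + half
    return DistanceSeries(values=1.0 - r, start_trs=centers, lag_trs=lag,
                          window_trs=window)


def phase_surrogates(series: np.ndarray, n: int = 10000, seed: int = 0) -> np.ndarray:
    """Phase-randomized surrogates preserving the amplitude spectrum.

    Each positive frequency's phase is rotated by an independent uniform
    draw on [0, 2pi); negative frequencies take the conjugate-symmetric
    phases so the inverse transform is real. The DC component (and the
    Nyquist bin for even length) is left untouched. Returns (n, len(series)).
    """
    x = np.asarray(series, dtype=float)
    if x.size < 8:
        raise ValueError("series too short for phase randomization")
    rng = np.random.default_rng(seed)
    spec = np.fft.rfft(x)
    n_bins = spec.size
    # indices of freely rotatable bins: exclude DC, and Nyquist if present
    hi = n_bins - 1 if x.size % 2 == 0 else n_bins
    phases = rng.uniform(0.0, 2.0 * np.pi, size=(n, hi - 1))
    rotated = np.tile(spec, (n, 1))
    rotated[:, 1:hi] = spec[1:hi] * np.exp(1j * phases)
    return np.fft.irfft(rotated, n=x.size, axis=1)


def surrogate_z(
    run: BoldRun,
    roi: str,
    schedule: ClipSchedule,
    estimates: pd.Series,
    retained_intervals,
    n: int = 10000,
    seed: int = 0,
    lag: int = 80,
    window: int = 5,
) -> NullEnsemble:
    """Surrogate-tested correlation between pattern change and estimates.

    The empirical statistic is :func:`drift_behavior_corr`. Nulls replace
    the lagged distance time course by phase-randomized surrogates, sampled
    for each retained interval at the series index whose first window is
    centred on clip_a's middle TR. All correlations are Fisher-transformed
    before the z-value is formed.
    """
    ids = list(retained_intervals)
    empirical = drift_behavior_corr(run, roi, schedule, estimates, ids)
    series = distance_timecourse(run, roi, lag=lag, window=window)
    clips = schedule.clips.set_index("clip_id")
    iv = schedule.intervals.set_index("interval_id").loc[ids]
    centers = [
        clip_middle_tr(clips.loc[c, "onset_s"], clips.loc[c, "duration_s"], run.tr)
        for c in iv["clip_a"]
    ]
    # map each clip_a centre to the series index whose first window is centred
    # there; centres too close to the run edges (where no full window exists)
    # clamp to the nearest valid series entry
    half = window // 2
    indices = np.clip(np.asarray(centers) - half, 0, series.values.size - 1)
    y = estimates.loc[ids].to_numpy(dtype=float)

    surr = phase_surrogates(series.values, n=n, seed=seed)[:, indices]
    sc = surr - surr.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    denom = np.sqrt((sc**2).sum(axis=1) * (yc**2).sum())
    null_r = (sc * yc).sum(axis=1) / denom
    return NullEnsemble(empirical=empirical, nulls=_fisher(null_r))


def group_roi_test(
    z_table: pd.DataFrame, q_level: float = 0.05
) -> pd.DataFrame:
    """Right-tailed one-sample t per ROI with two-stage FDR over ROIs.

    ``z_table`` is participants x ROIs (NaN = missing). ROIs with fewer than
    3 non-missing values are excluded (logged in the output as NaN rows).
    Returns a DataFrame indexed by ROI with t, p, q and a boolean
    ``significant`` column at ``q_level``; q-values come from the two-stage
    Benjamini-Krieger-Yekutieli procedure.
    """
    rows = {}
    for roi in z_table.columns:
        vals = z_table[roi].dropna().to_numpy(dtype=float)
        if vals.size < 3:
            rows[roi] = (np.nan, np.nan, vals.size)
            continue
        if np.ptp(vals) == 0:  # degenerate: no spread across participants
            m = vals.mean()
            t = 0.0 if m == 0 else np.copysign(np.inf, m)
            p = 0.5 if m == 0 else (0.0 if m > 0 else 1.0)
        else:
            t, p = stats.ttest_1samp(vals, 0.0, alternative="greater")
        rows[roi] = (float(t), float(p), vals.size)
    out = pd.DataFrame(rows, index=["t", "p", "n"]).T
    tested = out["p"].notna()
    qvals = np.full(len(out), np.nan)
    if tested.any():
        rej, q, *_ = multipletests(out.loc[tested, "p"], alpha=q_level,
                                   method="fdr_tsbky")
        qvals[tested.to_numpy()] = q
    out["q"] = qvals
    out["significant"] = out["q"] < q_level
    return out


def _zscore_within(values: pd.Series) -> pd.Series:
    sd = values.std(ddof=1)
    if sd == 0 or np.isnan(sd):
        return values - values.mean()
    return (values - values.mean()) / sd


def within_interval_analysis(
    distances: pd.DataFrame,
    estimates: pd.DataFrame,
    n_perm: int = 10000,
    seed: int = 0,
    min_participants: int = 3,
):
    """Across-participant correlation between pattern distance and estimates,
    per interval, with a scrambling permutation null.

    ``distances`` and ``estimates`` are interval x participant frames holding
    only each participant's retained intervals (NaN elsewhere). Both are
    z-scored within participant (across that participant's retained
    intervals) so they are comparable across participants; a per-participant
    affine rescaling of estimates therefore leaves the result unchanged.

    Returns ``(per_interval, t, p)`` where per_interval is a DataFrame with
    the empirical r, z and participant count per interval, and (t, p) is the
    right-tailed one-sample t-test on the z-values across intervals.
    """
    rng = np.random.default_rng(seed)
    dz = distances.apply(_zscore_within, axis=0)
    ez = estimates.apply(_zscore_within, axis=0)

    rows = {}
    for interval in distances.index:
        d = dz.loc[interval]
        e = ez.loc[interval]
        ok = d.notna() & e.notna()
        if ok.sum() < min_participants:
            continue
        dv = d[ok].to_numpy(dtype=float)
        ev = e[ok].to_numpy(dtype=float)
        if np.ptp(dv) == 0 or np.ptp(ev) == 0:
            continue
        emp = _fisher(stats.pearsonr(dv, ev)[0])
        perms = np.stack([rng.permutation(ev) for _ in range(n_perm)])
        pc = perms - perms.mean(axis=1, keepdims=True)
        dc = dv - dv.mean()
        denom = np.sqrt((pc**2).sum(axis=1) * (dc**2).sum())
        null_r = (pc * dc).sum(axis=1) / denom
        ens = NullEnsemble(empirical=float(emp), nulls=_fisher(null_r))
        rows[interval] = (float(np.tanh(emp)), ens.z, int(ok.sum()))
    per_interval = pd.DataFrame(rows, index=["r", "z", "n"]).T
    if len(per_interval) < 2:
        raise ValueError("fewer than 2 intervals with enough participants")
    t, p = stats.ttest_1samp(per_interval["z"], 0.0, alternative="greater")
    return per_interval, float(t), float(p)


def cohens_d(r_values: np.ndarray) -> float:
    """mean(r) / sd(r) across participants or intervals."""
    r = np.asarray(r_values, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 values")
    sd = r.std(ddof=1)
    if sd == 0:
        raise ValueError("zero standard deviation")
    return float(r.mean() / sd)


def story_position_drift(
    distances: pd.DataFrame,
    estimates: pd.DataFrame,
    positions: pd.Series,
):
    """Per-participant correlations of pattern distance and of estimates with
    the interval's position in the story, plus group one-sample t-tests.

    Returns a dict with per-participant r arrays and (t, p) for each of the
    two correlations.
    """
    pos = positions.loc[distances.index].to_numpy(dtype=float)
    r_dist, r_est = [], []
    for col in distances.columns:
        d = distances[col]
        e = estimates[col]
        ok = d.notna() & e.notna()
        if ok.sum() < 3:
            continue
        r_dist.append(stats.pearsonr(pos[ok.to_numpy()], d[ok])[0])
        r_est.append(stats.pearsonr(pos[ok.to_numpy()], e[ok])[0])
    r_dist, r_est = np.asarray(r_dist), np.asarray(r_est)
    t_d, p_d = stats.ttest_1samp(r_dist, 0.0)
    t_e, p_e = stats.ttest_1samp(r_est, 0.0)
    return {
        "r_position_distance": r_dist,
        "r_position_estimate": r_est,
        "t_distance": (float(t_d), float(p_d)),
        "t_estimate": (float(t_e), float(p_e)),
    }
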