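"""Behavioral analyses of retrospective duration estimates.

Covers group means and paired tests across the two true interval durations,
confidence-based interval filtering, bootstrap confidence intervals for
correlations with event-boundary counts, the Zou combined CI for a
difference between two correlations, inter-subject correlation (ISC) of
duration estimates within and between groups with a label-scrambling
permutation test, split-half reliability, the time-order effect, and
timeline-placement accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ClipSchedule, CorrDiffCI, DurationReport

__all__ = [
    "interval_confidence",
    "confidence_filter",
    "gap_means_and_ttest",
    "difference_score_contrast",
    "bootstrap_corr_ci",
    "zou_difference_ci",
    "isc_within_between",
    "split_half_reliability",
    "time_order_effect",
    "timeline_accuracy",
]


def _estimates_frame(reports: list[DurationReport]) -> pd.DataFrame:
    """interval x participant matrix of estimates (seconds)."""
    return pd.DataFrame(
        {r.participant_id: r.estimates for r in reports}
    )


def interval_confidence(report: DurationReport, schedule: ClipSchedule) -> pd.Series:
    """Per-interval confidence = the smaller of the two clip ratings.

    Missing clip ratings propagate as NaN (flagged missing interval).
    """
    iv = schedule.intervals
    conf = report.clip_confidence
    a = conf.reindex(iv["clip_a"]).to_numpy(dtype=float)
    b = conf.reindex(iv["clip_b"]).to_numpy(dtype=float)
    return pd.Series(np.minimum(a, b), index=iv["interval_id"].to_numpy())


def confidence_filter(
    report: DurationReport, schedule: ClipSchedule
) -> pd.Index:
    """Retained (high-confidence) interval ids for one participant.

    The participant-specific threshold c drops intervals with confidence < c
    such that at least a third of the intervals are dropped AND at least a
    third retained. Among feasible thresholds the one giving the retained
    fraction closest to 1/2 is used. If no threshold is feasible (e.g. all
    ratings equal) every interval is retained and a warning is emitted.
    """
    conf = interval_confidence(report, schedule).dropna()
    n = len(conf)
    levels = np.unique(conf.to_numpy())
    best, best_gap = None, np.inf
    for c in levels[1:]:  # dropping nothing is never feasible
        retained = (conf >= c).sum()
        dropped = n - retained
        if dropped / n >= 1 / 3 and retained / n >= 1 / 3:
            gap = abs(retained / n - 0.5)
            if gap < best_gap - 1e-12:
                best, best_gap = c, gap
    if best is None:
        warnings.warn(
            f"{report.participant_id}: no feasible confidence threshold; "
            "retaining all intervals",
            stacklevel=2,
        )
        return pd.Index(conf.index)
    return pd.Index(conf.index[conf >= best])


def _per_gap_means(
    report: DurationReport, schedule: ClipSchedule, subset: pd.Index | None
) -> dict[float, float]:
    iv = schedule.intervals
    ids = iv["interval_id"] if subset is None else iv["interval_id"][
        iv["interval_id"].isin(subset)
    ]
    out = {}
    for gap in sorted(iv["true_gap_s"].unique()):
        gap_ids = iv.loc[iv["true_gap_s"] == gap, "interval_id"]
        keep = gap_ids[gap_ids.isin(ids)]
        if len(keep):
            out[float(gap)] = float(report.estimates.loc[keep].mean())
    return out


def gap_means_and_ttest(
    reports: list[DurationReport],
    schedule: ClipSchedule,
    subsets: dict[str, pd.Index] | None = None,
):
    """Grand mean estimate per true gap plus a paired t-test on the per-
    participant (long gap - short gap) difference.

    Returns ``(mean_short_s, mean_long_s, t, df, p)``. Participants missing a
    retained interval at either gap are excluded from the pair.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 participants")
    gaps = sorted(schedule.intervals["true_gap_s"].unique())
    if len(gaps) != 2:
        raise ValueError("paired gap contrast needs exactly two true gaps")
    short, long_ = gaps
    pairs = []
    for r in reports:
        subset = subsets.get(r.participant_id) if subsets else None
        means = _per_gap_means(r, schedule, subset)
        if short in means and long_ in means:
            pairs.append((means[short], means[long_]))
    arr = np.asarray(pairs)
    diffs = arr[:, 1] - arr[:, 0]
    if np.all(diffs == 0):  # degenerate: no difference anywhere
        return (float(arr[:, 0].mean()), float(arr[:, 1].mean()), 0.0,
                len(arr) - 1, 1.0)
    t, p = stats.ttest_rel(arr[:, 1], arr[:, 0])
    return (
        float(arr[:, 0].mean()),
        float(arr[:, 1].mean()),
        float(t),
        len(arr) - 1,
        float(p),
    )


def difference_score_contrast(
    reports: list[DurationReport],
    schedule: ClipSchedule,
    subsets_a: dict[str, pd.Index] | None,
    subsets_b: dict[str, pd.Index] | None,
):
    """Paired contrast of the (long - short) difference score under two
    interval subsets (e.g. high-confidence vs all intervals).

    Returns ``(mean_a_s, mean_b_s, t, df, p)``.
    """
    gaps = sorted(schedule.intervals["true_gap_s"].unique())
    short, long_ = gaps
    diffs = []
    for r in reports:
        row = []
        for subsets in (subsets_a, subsets_b):
            subset = subsets.get(r.participant_id) if subsets else None
            means = _per_gap_means(r, schedule, subset)
            if short not in means or long_ not in means:
                row = None
                break
            row.append(means[long_] - means[short])
        if row is not None:
            diffs.append(row)
    arr = np.asarray(diffs)
    if np.allclose(arr[:, 0], arr[:, 1]):
        raise ValueError("identical difference scores under both subsets: "
                         "paired t-test undefined (zero variance)")
    t, p = stats.ttest_rel(arr[:, 0], arr[:, 1])
    return (
        float(arr[:, 0].mean()),
        float(arr[:, 1].mean()),
        float(t),
        len(arr) - 1,
        float(p),
    )


def bootstrap_corr_ci(
    reports: list[DurationReport],
    covariate: pd.Series,
    n_boot: int = 1000,
    level: float = 0.95,
    seed: int = 0,
):
    """Pearson r between participant-averaged estimates and an interval
    covariate, with a percentile bootstrap CI over participants.

    Resamples participants with replacement ``n_boot`` times; the interval
    means are recomputed per sample. Bounds are the standard percentile
    limits ((1-level)/2 and 1-(1-level)/2 of the bootstrap distribution).
    Returns ``(r, ll, ul)``.
    """
    ids = covariate.index
    if len(ids) < 3:
        raise ValueError("need at least 3 intervals")
    cov = covariate.to_numpy(dtype=float)
    if np.ptp(cov) == 0:
        raise ValueError("covariate is constant; correlation undefined")
    est = _estimates_frame(reports).loc[ids]  # intervals x participants
    mat = est.to_numpy(dtype=float)
    r = float(stats.pearsonr(mat.mean(axis=1), cov)[0])
    rng = np.random.default_rng(seed)
    n = mat.shape[1]
    boots = np.empty(n_boot)
    for b in range(n_boot):
        pick = rng.integers(0, n, size=n)
        boots[b] = stats.pearsonr(mat[:, pick].mean(axis=1), cov)[0]
    alpha = (1 - level) / 2
    ll, ul = np.quantile(boots, [alpha, 1 - alpha])
    return r, float(ll), float(ul)


def zou_difference_ci(
    r1: float, ll1: float, ul1: float, r2: float, ll2: float, ul2: float
) -> CorrDiffCI:
    """Combined CI for the difference between two bootstrapped correlations.

    rdiff = r1 - r2,
    lldiff = rdiff - sqrt((r1-ll1)^2 + (ul2-r2)^2),
    uldiff = rdiff + sqrt((ul1-r1)^2 + (r2-ll2)^2).
    """
    for r, ll, ul in ((r1, ll1, ul1), (r2, ll2, ul2)):
        if not ll <= r <= ul:
            raise ValueError(f"CI [{ll}, {ul}] does not bracket r={r}")
    rdiff = r1 - r2
    lldiff = rdiff - np.sqrt((r1 - ll1) ** 2 + (ul2 - r2) ** 2)
    uldiff = rdiff + np.sqrt((ul1 - r1) ** 2 + (r2 - ll2) ** 2)
    return CorrDiffCI(rdiff=float(rdiff), lldiff=float(lldiff), uldiff=float(uldiff))


def _colcorr(mat: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Pearson r of every column of `mat` with `ref` (vectorised)."""
    mc = mat - mat.mean(axis=0)
    rc = ref - ref.mean()
    denom = np.sqrt((mc**2).sum(axis=0) * (rc**2).sum())
    return (mc * rc[:, None]).sum(axis=0) / denom


def _loo_isc(mat: np.ndarray) -> np.ndarray:
    """Per-column r(own vector, mean of the other columns)."""
    n = mat.shape[1]
    total = mat.sum(axis=1, keepdims=True)
    others = (total - mat) / (n - 1)
    mc = mat - mat.mean(axis=0)
    oc = others - others.mean(axis=0)
    denom = np.sqrt((mc**2).sum(axis=0) * (oc**2).sum(axis=0))
    return (mc * oc).sum(axis=0) / denom


def _between_isc(mat_a: np.ndarray, mat_b: np.ndarray) -> float:
    """Mean over participants of r(own estimates, other group's mean)."""
    rs_a = _colcorr(mat_a, mat_b.mean(axis=1))
    rs_b = _colcorr(mat_b, mat_a.mean(axis=1))
    return float(np.concatenate([rs_a, rs_b]).mean())


def isc_within_between(
    group_a: list[DurationReport],
    group_b: list[DurationReport],
    n_perm: int = 10000,
    seed: int = 0,
):
    """Within- and between-group ISC of duration estimates, plus a
    label-scrambling permutation p for (mean within - between) > 0.

    Group sizes must match: the within/between comparison is only
    interpretable when the two groups are equally sized.
    Returns ``(isc_a, isc_b, isc_between, p)`` where isc_a/isc_b are the
    mean leave-one-out ISCs.
    """
    if len(group_a) != len(group_b):
        raise ValueError(
            "groups must be the same size for the within/between ISC "
            "comparison to be meaningful"
        )
    ids = group_a[0].estimates.index
    mat_a = np.column_stack([r.estimates.loc[ids].to_numpy() for r in group_a])
    mat_b = np.column_stack([r.estimates.loc[ids].to_numpy() for r in group_b])
    isc_a = float(_loo_isc(mat_a).mean())
    isc_b = float(_loo_isc(mat_b).mean())
    isc_between = _between_isc(mat_a, mat_b)
    emp = (isc_a + isc_b) / 2 - isc_between

    both = np.concatenate([mat_a, mat_b], axis=1)
    n = mat_a.shape[1]
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(both.shape[1])
        pa, pb = both[:, perm[:n]], both[:, perm[n:]]
        w = (_loo_isc(pa).mean() + _loo_isc(pb).mean()) / 2
        b = _between_isc(pa, pb)
        if w - b >= emp:
            count += 1
    return isc_a, isc_b, isc_between, (count + 1) / (n_perm + 1)


def split_half_reliability(
    reports: list[DurationReport],
    interval_ids: pd.Index | None = None,
    n_splits: int = 1000,
    seed: int = 0,
):
    """Mean and SD over random half-splits of r between the two halves'
    per-interval mean estimates. Odd n gives halves differing by one.
    """
    if len(reports) < 4:
        raise ValueError("need at least 4 participants")
    mat = _estimates_frame(reports)
    if interval_ids is not None:
        mat = mat.loc[interval_ids]
    if len(mat) < 2:
        raise ValueError("need at least 2 intervals")
    vals = mat.to_numpy(dtype=float)
    n = vals.shape[1]
    rng = np.random.default_rng(seed)
    rs = np.empty(n_splits)
    for s in range(n_splits):
        perm = rng.permutation(n)
        half = n // 2
        m1 = vals[:, perm[:half]].mean(axis=1)
        m2 = vals[:, perm[half:]].mean(axis=1)
        rs[s] = stats.pearsonr(m1, m2)[0]
    return float(rs.mean()), float(rs.std(ddof=1))


def time_order_effect(
    reports: list[DurationReport],
    schedule: ClipSchedule,
    gap_s: float | None = 120.0,
):
    """Per-participant r between duration estimates and interval position in
    the story, with a two-sided one-sample t-test across participants.

    Returns ``(mean_r, sd_r, t, df, p)``. By default only the 2-minute
    intervals are used; pass ``gap_s=None`` for all intervals.
    """
    iv = schedule.intervals
    if gap_s is not None:
        iv = iv.loc[np.isclose(iv["true_gap_s"], gap_s)]
    pos = iv["position_s"].to_numpy(dtype=float)
    if np.ptp(pos) == 0:
        raise ValueError("interval positions are constant")
    ids = iv["interval_id"].to_numpy()
    rs = []
    for r in reports:
        est = r.estimates.loc[ids].to_numpy(dtype=float)
        if np.ptp(est) == 0:
            continue
        rs.append(stats.pearsonr(est, pos)[0])
    rs = np.asarray(rs)
    t, p = stats.ttest_1samp(rs, 0.0)
    return float(rs.mean()), float(rs.std(ddof=1)), float(t), len(rs) - 1, float(p)


@dataclass
class TimelineAccuracy:
    """Per-clip placement error and per-participant timeline fidelity."""

    errors: pd.DataFrame       # clips x participants |residual|
    per_participant_r: pd.Series

    @property
    def accuracy(self) -> pd.DataFrame:
        return -self.errors


def timeline_accuracy(
    placements: pd.DataFrame, actual_positions: pd.Series
) -> TimelineAccuracy:
    """Regress estimated timeline position on actual position, per participant.

    ``placements`` is clips x participants. The per-clip error is the
    absolute residual of the within-participant regression (so any affine
    distortion of a participant's timeline is absorbed); accuracy is the
    negative error.
    """
    if len(actual_positions) < 3:
        raise ValueError("need at least 3 clips")
    x = actual_positions.to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("actual positions have zero variance")
    errors = {}
    rs = {}
    for col in placements.columns:
        y = placements[col].loc[actual_positions.index].to_numpy(dtype=float)
        slope, intercept = np.polyfit(x, y, 1)
        resid = y - (slope * x + intercept)
        errors[col] = np.abs(resid)
        rs[col] = stats.pearsonr(x, y)[0]
    return TimelineAccuracy(
        errors=pd.DataFrame(errors, index=actual_positions.index),
        per_participant_r=pd.Series(rs),
    )
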