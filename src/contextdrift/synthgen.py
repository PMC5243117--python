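"""Seeded synthetic datasets with a known embedded context-drift signal.

The generator emulates the statistical structure the analysis assumes: a
group of participants listening to the same ~26-minute narrative while a
slow, high-dimensional "mental context" signal drifts in designated grey
matter regions. The per-interval displacement of that latent signal drives
simulated retrospective duration estimates, so every stage of the pipeline
(pattern distance, surrogate inference, group tests, mixed models) can be
verified against a known ground truth.

Model sketch, per region r and participant p:

    voxel pattern(t) = W_rp @ c_rp(t)            (latent context drift)
                     + u_rp * s_r(t)             (shared stimulus-locked signal,
                                                  grey compartment only)
                     + v_rp * a(t)               (global low-frequency artifact,
                                                  ALL compartments incl. CSF/WM)
                     + AR(1) voxel noise

with c_rp a k-dimensional Gaussian random walk whose increments are smoothed
over ~20 TRs (slow drift with controllable displacement), partly shared
across participants (the story drives some context change in everyone) and
partly idiosyncratic. The ground-truth "displacement" of an interval is the
Euclidean distance of c_rp between the two clip middle TRs — recomputable
from the seed alone.

Behavioral estimates follow

    estimate = base + slope * true_gap
             + effect_size   * z(drift displacement in the effect region)
             + content_effect * z(clip-content dissimilarity)
             + participant offset + noise,   floored at 0, 1-s resolution,

naive estimates depend only on the content term, and event-boundary raters
press with rate proportional to the shared latent step size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .datatypes import CSF, GREY, WHITE, BoldRun, ClipSchedule, DurationReport

__all__ = [
    "RoiSpec",
    "SynthConfig",
    "SynthDataset",
    "generate_schedule",
    "generate_bold",
    "generate_behavior",
    "generate_dataset",
    "latent_walk",
    "truth_displacements",
]

# named RNG sub-streams: every random draw comes from a SeedSequence keyed by
# (master seed, stream id, participant index, region index) so that parallel
# or partial regeneration is bit-identical
_STREAMS = {
    "schedule": 0,
    "walk_shared": 1,
    "walk_idio": 2,
    "loadings": 3,
    "noise": 4,
    "artifact": 5,
    "stimulus": 6,
    "stim_loadings": 7,
    "behavior": 8,
    "confidence": 9,
    "boundaries": 10,
    "content": 11,
    "artifact_loadings": 12,
    "high_sd": 13,
    "naive": 14,
}


def _rng(seed: int, stream: str, *key: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(_STREAMS[stream], *key))
    )


@dataclass(frozen=True)
class RoiSpec:
    """One synthetic region: label, size, drift rate, noise level, compartment."""

    label: str
    n_voxels: int
    drift_rate: float
    noise_sd: float
    compartment: str = GREY

    def __post_init__(self) -> None:
        if self.n_voxels < 10:
            raise ValueError("regions must have at least 10 voxels")
        if self.compartment not in (GREY, WHITE, CSF):
            raise ValueError(f"unknown compartment {self.compartment!r}")


def _default_rois() -> tuple[RoiSpec, ...]:
    return (
        RoiSpec("drift_roi", 40, drift_rate=1.0, noise_sd=1.0, compartment=GREY),
        RoiSpec("null_roi", 40, drift_rate=0.0, noise_sd=1.0, compartment=GREY),
        RoiSpec("wm", 60, drift_rate=0.0, noise_sd=1.0, compartment=WHITE),
        RoiSpec("csf", 40, drift_rate=0.0, noise_sd=1.0, compartment=CSF),
        # a ventricle sub-region, distinct from the whole-CSF nuisance mask:
        # the ISC diagnostic needs a CSF ROI that is not exactly the mean
        # used as a regressor (which is annihilated by the projection)
        RoiSpec("ventricle", 20, drift_rate=0.0, noise_sd=0.5, compartment=CSF),
    )


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition defaults: 18 participants, 1040 TRs at TR=1.5 s,
    24 two-minute and 19 six-minute intervals delimited by 5-10 s clips.

    ``effect_size`` and ``content_effect`` are slopes of the duration
    estimate (seconds) on the standardised drift displacement and
    clip-content dissimilarity; ``global_drift_amplitude`` scales a
    low-frequency artifact shared across participants and compartments.
    """

    n_participants: int = 18
    n_trs: int = 1040
    tr_seconds: float = 1.5
    n_intervals_2min: int = 24
    n_intervals_6min: int = 19
    clip_duration_range_s: tuple[float, float] = (5.0, 10.0)
    roi_specs: tuple[RoiSpec, ...] = field(default_factory=_default_rois)
    effect_roi: str = "drift_roi"
    effect_size: float = 45.0
    content_effect: float = 30.0
    confidence_noise: float = 0.5
    global_drift_amplitude: float = 1.0
    seed: int = 0

    # generator internals (documented in docs/methods.md)
    latent_dim: int = 12
    latent_smooth_trs: float = 8.0      # Gaussian sigma; ~20-TR kernel width
    shared_drift_frac: float = 0.5      # fraction of drift variance shared
    signal_amplitude: float = 1.2       # latent signal scale relative to noise
    stimulus_amplitude: float = 0.8     # shared stimulus-locked component
    stimulus_smooth_trs: float = 3.0
    artifact_period_s: float = 600.0
    ar1_phi: float = 0.3
    high_sd_frac: float = 0.02
    base_offset_s: float = 160.0
    gap_slope: float = 0.5
    estimate_noise_sd: float = 60.0
    participant_offset_sd: float = 40.0
    low_conf_extra_noise: float = 0.6
    naive_base_s: float = 300.0
    naive_gap_slope: float = 0.15
    content_decay_s: float = 180.0
    n_boundary_raters: int = 9
    boundary_rate_per_min: float = 1.5

    def __post_init__(self) -> None:
        for name in ("n_participants", "n_trs", "n_intervals_2min"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_intervals_6min < 0:
            raise ValueError("n_intervals_6min must be non-negative")
        lo, hi = self.clip_duration_range_s
        if not 0 < lo <= hi:
            raise ValueError("invalid clip duration range")
        if self.tr_seconds <= 0:
            raise ValueError("TR must be positive")
        labels = [r.label for r in self.roi_specs]
        if len(set(labels)) != len(labels):
            raise ValueError("ROI labels must be unique")
        if self.effect_roi not in labels:
            raise ValueError(f"effect_roi {self.effect_roi!r} not among ROIs")

    @property
    def run_duration_s(self) -> float:
        return self.n_trs * self.tr_seconds

    @property
    def region_labels(self) -> list[str]:
        return [r.label for r in self.roi_specs]


@dataclass
class SynthDataset:
    """Everything one simulated experiment produces, plus its ground truth."""

    config: SynthConfig
    schedule: ClipSchedule
    runs: list[BoldRun]
    reports: list[DurationReport]
    naive_reports: list[DurationReport]
    boundaries: list[np.ndarray]
    truth: pd.DataFrame  # columns: region, participant_id, interval_id, displacement


class ScheduleError(ValueError):
    """Requested intervals cannot be packed into the run duration."""


# ---------------------------------------------------------------------------
# schedule


def generate_schedule(cfg: SynthConfig) -> ClipSchedule:
    """Place 2 x n_intervals distinct clips delimiting the requested intervals.

    Each interval is delimited by two non-overlapping clips whose onsets are
    ``true_gap_s`` apart (24 gaps of exactly 120 s, 19 of exactly 360 s under
    the default config). Interval start times are stratified over the run so
    positions cover the whole story.
    """
    rng = _rng(cfg.seed, "schedule")
    lo, hi = cfg.clip_duration_range_s
    gaps = np.concatenate(
        [np.full(cfg.n_intervals_2min, 120.0), np.full(cfg.n_intervals_6min, 360.0)]
    )
    max_gap = float(gaps.max())
    slack = cfg.run_duration_s - max_gap - hi
    if slack <= 0:
        raise ScheduleError(
            f"cannot fit a {max_gap:.0f}s interval plus clip into a "
            f"{cfg.run_duration_s:.0f}s run"
        )

    clips, intervals = [], []
    for i, gap in enumerate(gaps):
        # stratified start so interval midpoints spread across the story
        usable = cfg.run_duration_s - gap - hi
        if usable <= 0:
            raise ScheduleError("run too short for requested intervals")
        n_of_kind = int(np.sum(gaps == gap))
        rank = int(np.sum(gaps[:i] == gap))
        cell = usable / n_of_kind
        onset_a = rank * cell + rng.uniform(0, cell)
        dur_a = rng.uniform(lo, hi)
        dur_b = rng.uniform(lo, hi)
        onset_b = onset_a + gap
        if onset_b < onset_a + dur_a:  # non-overlap of the two clips
            raise ScheduleError("clips within an interval overlap")
        clip_a, clip_b = f"clip_{2 * i:03d}", f"clip_{2 * i + 1:03d}"
        clips.append((clip_a, onset_a, dur_a))
        clips.append((clip_b, onset_b, dur_b))
        mid_a = onset_a + dur_a / 2
        mid_b = onset_b + dur_b / 2
        intervals.append(
            (f"interval_{i:03d}", clip_a, clip_b, gap, (mid_a + mid_b) / 2)
        )

    return ClipSchedule(
        clips=pd.DataFrame(clips, columns=["clip_id", "onset_s", "duration_s"]),
        intervals=pd.DataFrame(
            intervals,
            columns=["interval_id", "clip_a", "clip_b", "true_gap_s", "position_s"],
        ),
    )


# ---------------------------------------------------------------------------
# latent context walks and ground truth


def _smoothed_walk(rng: np.random.Generator, k: int, n_trs: int, sigma: float) -> np.ndarray:
    """k-dimensional Gaussian random walk with increments smoothed over ~2.5 sigma TRs."""
    steps = rng.standard_normal((k, n_trs))
    if sigma > 0:
        steps = gaussian_filter1d(steps, sigma=sigma, axis=1, mode="reflect")
        # keep unit increment variance after smoothing
        steps /= np.sqrt(1.0 / (2.0 * np.sqrt(np.pi) * sigma))
    return np.cumsum(steps, axis=1)


def latent_walk(cfg: SynthConfig, participant: int, region: str) -> np.ndarray:
    """The (latent_dim, n_trs) context walk for one participant and region.

    Deterministic in (seed, participant, region): the shared story-driven
    component is common to all participants, the idiosyncratic component is
    participant-specific, and both scale with the region's drift rate.
    """
    r_idx = cfg.region_labels.index(region)
    spec = cfg.roi_specs[r_idx]
    if spec.drift_rate == 0:
        return np.zeros((cfg.latent_dim, cfg.n_trs))
    shared = _smoothed_walk(
        _rng(cfg.seed, "walk_shared", r_idx), cfg.latent_dim, cfg.n_trs,
        cfg.latent_smooth_trs,
    )
    idio = _smoothed_walk(
        _rng(cfg.seed, "walk_idio", participant, r_idx), cfg.latent_dim, cfg.n_trs,
        cfg.latent_smooth_trs,
    )
    f = cfg.shared_drift_frac
    walk = np.sqrt(f) * shared + np.sqrt(1.0 - f) * idio
    return spec.drift_rate * walk


def _clip_middle_trs(cfg: SynthConfig, schedule: ClipSchedule) -> pd.Series:
    mid = schedule.clips["onset_s"] + schedule.clips["duration_s"] / 2
    trs = np.clip(np.rint(mid / cfg.tr_seconds).astype(int), 0, cfg.n_trs - 1)
    return pd.Series(trs.to_numpy(), index=schedule.clips["clip_id"])


def truth_displacements(cfg: SynthConfig, schedule: ClipSchedule) -> pd.DataFrame:
    """Ground-truth per-interval latent displacement for every region/participant.

    The displacement of an interval is the Euclidean distance of the latent
    walk between the middle TRs of its two clips; it is recomputable from the
    seed without generating any voxel data.
    """
    mids = _clip_middle_trs(cfg, schedule)
    t_a = mids.loc[schedule.intervals["clip_a"]].to_numpy()
    t_b = mids.loc[schedule.intervals["clip_b"]].to_numpy()
    rows = []
    for region in cfg.region_labels:
        for p in range(cfg.n_participants):
            walk = latent_walk(cfg, p, region)
            disp = np.linalg.norm(walk[:, t_b] - walk[:, t_a], axis=0)
            rows.append(
                pd.DataFrame(
                    {
                        "region": region,
                        "participant_id": f"sub-{p:02d}",
                        "interval_id": schedule.intervals["interval_id"],
                        "displacement": disp,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# BOLD generation


def _region_coords(cfg: SynthConfig) -> dict[str, np.ndarray]:
    """Pack each region into its own small cube, regions spaced along x."""
    coords = {}
    x0 = 0
    for spec in cfg.roi_specs:
        side = int(np.ceil(spec.n_voxels ** (1 / 3)))
        grid = np.stack(
            np.meshgrid(np.arange(side), np.arange(side), np.arange(side),
                        indexing="ij"),
            axis=-1,
        ).reshape(-1, 3)[: spec.n_voxels]
        grid = grid + np.array([x0, 0, 0])
        coords[spec.label] = grid
        x0 += side + 2
    return coords


N_ARTIFACT_COMPONENTS = 8


def _global_artifact(cfg: SynthConfig) -> np.ndarray:
    """Dataset-level low-frequency artifact, a few independent slow courses.

    Power is concentrated at periods around/above ``artifact_period_s``; the
    growing step size reproduces the observation that, without filtering,
    patterns everywhere (including CSF) drift apart as the story progresses.
    More components than there are nuisance regressors (three) mean the
    regression can only partially project the artifact out of individual
    voxels — the reason the ISC-based cutoff diagnostic is needed at all.
    Returns (N_ARTIFACT_COMPONENTS, n_trs).
    """
    rng = _rng(cfg.seed, "artifact")
    sigma_trs = cfg.artifact_period_s / (4.0 * cfg.tr_seconds)
    steps = rng.standard_normal((N_ARTIFACT_COMPONENTS, cfg.n_trs))
    steps *= np.linspace(0.3, 1.7, cfg.n_trs)  # accelerating drift
    art = np.cumsum(
        gaussian_filter1d(steps, sigma=sigma_trs, axis=1, mode="reflect"),
        axis=1,
    )
    art -= art.mean(axis=1, keepdims=True)
    sd = art.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return art / sd


def _stimulus_course(cfg: SynthConfig, r_idx: int) -> np.ndarray:
    rng = _rng(cfg.seed, "stimulus", r_idx)
    s = gaussian_filter1d(rng.standard_normal(cfg.n_trs),
                          sigma=cfg.stimulus_smooth_trs, mode="reflect")
    s -= s.mean()
    return s / s.std()


def generate_bold(cfg: SynthConfig, schedule: ClipSchedule) -> list[BoldRun]:
    """One BoldRun per participant with the structure described in the module docstring."""
    coords_by_region = _region_coords(cfg)
    artifact = _global_artifact(cfg)
    runs = []
    for p in range(cfg.n_participants):
        blocks, coord_blocks, comp_blocks, label_blocks = [], [], [], []
        for r_idx, spec in enumerate(cfg.roi_specs):
            n_vox = spec.n_voxels
            load_rng = _rng(cfg.seed, "loadings", p, r_idx)
            noise_rng = _rng(cfg.seed, "noise", p, r_idx)
            # artifact loadings are shared across participants (the spatial
            # footprint of scanner/physiological drift is anatomy-linked),
            # which is what lets spurious CSF ISC survive nuisance regression
            art_rng = _rng(cfg.seed, "artifact_loadings", r_idx)

            data = np.zeros((n_vox, cfg.n_trs))

            if spec.drift_rate != 0:
                walk = latent_walk(cfg, p, spec.label)
                loadings = load_rng.standard_normal((n_vox, cfg.latent_dim))
                loadings /= np.sqrt(cfg.latent_dim)
                # scale so voxel-wise signal sd over the run ~ signal_amplitude
                sig = loadings @ walk
                scale = cfg.signal_amplitude / max(sig.std(), 1e-12)
                data += sig * scale

            if spec.compartment == GREY and cfg.stimulus_amplitude > 0:
                stim = _stimulus_course(cfg, r_idx)
                u = load_rng.normal(1.0, 0.3, size=n_vox)
                data += cfg.stimulus_amplitude * np.outer(u, stim)

            if cfg.global_drift_amplitude > 0:
                v = art_rng.normal(1.0, 0.5,
                                   size=(n_vox, N_ARTIFACT_COMPONENTS))
                data += cfg.global_drift_amplitude / np.sqrt(
                    N_ARTIFACT_COMPONENTS) * (v @ artifact)

            # AR(1) voxel noise
            eps = noise_rng.standard_normal((n_vox, cfg.n_trs))
            noise = np.empty_like(eps)
            noise[:, 0] = eps[:, 0]
            phi = cfg.ar1_phi
            for t in range(1, cfg.n_trs):
                noise[:, t] = phi * noise[:, t - 1] + np.sqrt(1 - phi**2) * eps[:, t]
            sd = np.full(n_vox, spec.noise_sd)
            if spec.compartment == GREY and cfg.high_sd_frac > 0:
                n_hi = max(1, int(round(cfg.high_sd_frac * n_vox)))
                hi = _rng(cfg.seed, "high_sd", p, r_idx).choice(
                    n_vox, size=n_hi, replace=False
                )
                sd[hi] *= 4.0
                if cfg.global_drift_amplitude > 0:
                    v_hi = art_rng.normal(1.0, 0.5,
                                          size=(n_hi, N_ARTIFACT_COMPONENTS))
                    data[hi] += 2.0 * cfg.global_drift_amplitude / np.sqrt(
                        N_ARTIFACT_COMPONENTS) * (v_hi @ artifact)
            data += noise * sd[:, None]

            blocks.append(data)
            coord_blocks.append(coords_by_region[spec.label])
            comp_blocks.append(np.full(n_vox, spec.compartment, dtype=object))
            label_blocks.append(np.full(n_vox, spec.label, dtype=object))

        runs.append(
            BoldRun(
                participant_id=f"sub-{p:02d}",
                data=np.vstack(blocks),
                tr=cfg.tr_seconds,
                coords=np.vstack(coord_blocks),
                compartments=np.concatenate(comp_blocks),
                roi_labels=np.concatenate(label_blocks),
            )
        )
    return runs


# ---------------------------------------------------------------------------
# behavior


def _content_features(cfg: SynthConfig, schedule: ClipSchedule) -> pd.DataFrame:
    """Per-clip feature vectors from a smooth story-time process.

    Similarity between two clips' features decays with their separation in
    story time (timescale ``content_decay_s``), giving naive estimates
    stimulus-only structure.
    """
    rng = _rng(cfg.seed, "content")
    k = 8
    sigma_trs = cfg.content_decay_s / cfg.tr_seconds / 2.355  # FWHM -> sigma
    course = gaussian_filter1d(rng.standard_normal((k, cfg.n_trs)),
                               sigma=sigma_trs, axis=1, mode="reflect")
    course /= course.std(axis=1, keepdims=True)
    mids = _clip_middle_trs(cfg, schedule)
    feats = course[:, mids.to_numpy()].T  # (n_clips, k)
    return pd.DataFrame(feats, index=mids.index)


def content_dissimilarity(cfg: SynthConfig, schedule: ClipSchedule) -> pd.Series:
    """1 - Pearson r between the two clips' content features, per interval."""
    feats = _content_features(cfg, schedule)
    vals = []
    for _, iv in schedule.intervals.iterrows():
        a = feats.loc[iv["clip_a"]].to_numpy()
        b = feats.loc[iv["clip_b"]].to_numpy()
        vals.append(1.0 - np.corrcoef(a, b)[0, 1])
    return pd.Series(vals, index=schedule.intervals["interval_id"].to_numpy())


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def _zscore_within_gap(x: np.ndarray, gaps: np.ndarray) -> np.ndarray:
    """z-score separately inside each true-gap group so the drift/content
    terms carry within-gap variation only; the objective-time effect is the
    gap_slope term's job."""
    out = np.empty_like(x, dtype=float)
    for g in np.unique(gaps):
        sel = gaps == g
        out[sel] = _zscore(x[sel])
    return out


def _confidence_ratings(
    cfg: SynthConfig, p: int, clip_ids: pd.Index
) -> tuple[pd.Series, pd.Series]:
    """Latent per-clip memory strength and its ordinal 1-5 rating."""
    rng = _rng(cfg.seed, "confidence", p)
    strength = rng.standard_normal(len(clip_ids))
    noisy = strength + cfg.confidence_noise * rng.standard_normal(len(clip_ids))
    edges = np.quantile(noisy, [0.2, 0.4, 0.6, 0.8])
    rating = np.digitize(noisy, edges) + 1  # 1..5
    return (
        pd.Series(strength, index=clip_ids),
        pd.Series(rating.astype(int), index=clip_ids),
    )


def generate_behavior(
    cfg: SynthConfig, schedule: ClipSchedule, truth: pd.DataFrame
) -> tuple[list[DurationReport], list[DurationReport], list[np.ndarray]]:
    """Simulated duration reports, naive reports and boundary press times."""
    iv = schedule.intervals
    interval_ids = iv["interval_id"].to_numpy()
    gaps = iv["true_gap_s"].to_numpy(dtype=float)
    content = content_dissimilarity(cfg, schedule)
    z_content = _zscore_within_gap(content.loc[interval_ids].to_numpy(), gaps)
    clip_ids = pd.Index(schedule.clips["clip_id"])

    eff = truth.loc[truth["region"] == cfg.effect_roi]
    eff = eff.pivot(index="participant_id", columns="interval_id",
                    values="displacement")

    reports = []
    for p in range(cfg.n_participants):
        rng = _rng(cfg.seed, "behavior", p)
        disp = eff.loc[f"sub-{p:02d}", interval_ids].to_numpy(dtype=float)
        z_disp = _zscore_within_gap(disp, gaps)
        strength, rating = _confidence_ratings(cfg, p, clip_ids)
        s_a = strength.loc[iv["clip_a"]].to_numpy()
        s_b = strength.loc[iv["clip_b"]].to_numpy()
        min_strength = np.minimum(s_a, s_b)
        noise_sd = cfg.estimate_noise_sd * np.where(
            min_strength < 0, 1.0 + cfg.low_conf_extra_noise, 1.0
        )
        offset = rng.normal(0.0, cfg.participant_offset_sd)
        est = (
            cfg.base_offset_s
            + cfg.gap_slope * gaps
            + cfg.effect_size * z_disp
            + cfg.content_effect * z_content
            + offset
            + rng.normal(0.0, noise_sd)
        )
        est = np.round(np.maximum(est, 0.0))  # floored at 0, 1-s resolution
        reports.append(
            DurationReport(
                participant_id=f"sub-{p:02d}",
                estimates=pd.Series(est, index=interval_ids),
                clip_confidence=rating,
                group="original",
            )
        )

    naive_reports = []
    for p in range(cfg.n_participants):
        rng = _rng(cfg.seed, "naive", p)
        offset = rng.normal(0.0, cfg.participant_offset_sd)
        est = (
            cfg.naive_base_s
            + cfg.naive_gap_slope * gaps
            + cfg.content_effect * z_content
            + offset
            + rng.normal(0.0, cfg.estimate_noise_sd, size=len(interval_ids))
        )
        est = np.round(np.maximum(est, 0.0))
        _, rating = _confidence_ratings(cfg, cfg.n_participants + p, clip_ids)
        naive_reports.append(
            DurationReport(
                participant_id=f"naive-{p:02d}",
                estimates=pd.Series(est, index=interval_ids),
                clip_confidence=rating,
                group="naive",
            )
        )

    boundaries = _generate_boundaries(cfg)
    return reports, naive_reports, boundaries


def _generate_boundaries(cfg: SynthConfig) -> list[np.ndarray]:
    """Button-press times per rater, rate proportional to shared latent step size."""
    walk = None
    for r_idx, spec in enumerate(cfg.roi_specs):
        if spec.label == cfg.effect_roi:
            shared = _smoothed_walk(
                _rng(cfg.seed, "walk_shared", r_idx), cfg.latent_dim, cfg.n_trs,
                cfg.latent_smooth_trs,
            )
            walk = np.sqrt(cfg.shared_drift_frac) * shared * spec.drift_rate
    step = np.linalg.norm(np.diff(walk, axis=1), axis=0) if walk is not None \
        and walk.any() else np.ones(cfg.n_trs - 1)
    rate = step / max(step.mean(), 1e-12)
    rate *= cfg.boundary_rate_per_min / 60.0  # presses per second
    presses = []
    for rater in range(cfg.n_boundary_raters):
        rng = _rng(cfg.seed, "boundaries", rater)
        p_tr = np.clip(rate * cfg.tr_seconds, 0, 1)
        hit = rng.random(cfg.n_trs - 1) < p_tr
        times = (np.flatnonzero(hit) + 0.5) * cfg.tr_seconds
        presses.append(times)
    return presses


def boundary_counts(
    schedule: ClipSchedule, boundaries: list[np.ndarray]
) -> pd.Series:
    """Mean number of button presses inside each interval, averaged over raters."""
    onsets = schedule.clips.set_index("clip_id")["onset_s"]
    iv = schedule.intervals
    start = onsets.loc[iv["clip_a"]].to_numpy()
    stop = onsets.loc[iv["clip_b"]].to_numpy()
    counts = np.zeros(len(iv))
    for times in boundaries:
        counts += (
            (times[None, :] >= start[:, None]) & (times[None, :] < stop[:, None])
        ).sum(axis=1)
    counts /= len(boundaries)
    return pd.Series(counts, index=iv["interval_id"].to_numpy())


# ---------------------------------------------------------------------------


def generate_dataset(cfg: SynthConfig, include_bold: bool = True) -> SynthDataset:
    """Full seeded dataset; ``include_bold=False`` skips the voxel data
    (schedule, ground truth and behavior only), useful for behavioral
    simulations at scale."""
    schedule = generate_schedule(cfg)
    truth = truth_displacements(cfg, schedule)
    runs = generate_bold(cfg, schedule) if include_bold else []
    reports, naive_reports, boundaries = generate_behavior(cfg, schedule, truth)
    return SynthDataset(
        config=cfg,
        schedule=schedule,
        runs=runs,
        reports=reports,
        naive_reports=naive_reports,
        boundaries=boundaries,
        truth=truth,
    )
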