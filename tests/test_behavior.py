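"""Behavioral statistics: confidence handling, gap contrasts, bootstrap and
Zou confidence intervals, ISC reliability, split-half, time-order and
timeline accuracy."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from contextdrift import behavior as bh
from contextdrift.datatypes import CorrDiffCI, DurationReport

from conftest import make_report


def report_with_conf(conf_by_interval, schedule, pid="p0", estimates=None):
    """Build a report whose per-clip ratings produce the wanted per-interval
    minima (both clips get the interval's value)."""
    iv = schedule.intervals
    clip_conf = {}
    for _, row in iv.iterrows():
        c = conf_by_interval[row.interval_id]
        clip_conf[row.clip_a] = c
        clip_conf[row.clip_b] = c
    est = estimates if estimates is not None else np.full(len(iv), 100.0)
    return DurationReport(
        participant_id=pid,
        estimates=pd.Series(est, index=iv["interval_id"].to_numpy()),
        clip_confidence=pd.Series(clip_conf, dtype=float),
    )


class TestConfidence:
    def test_interval_confidence_is_min_of_clips(self, simple_schedule):
        rep = report_with_conf(
            {"i0": 5, "i1": 3, "i2": 1, "i3": 4}, simple_schedule
        )
        rep.clip_confidence.loc["c0"] = 5
        rep.clip_confidence.loc["c1"] = 3  # (5, 3) -> 3
        conf = bh.interval_confidence(rep, simple_schedule)
        assert conf.loc["i0"] == 3
        assert conf.loc["i2"] == 1

    def test_binary_ratings(self, simple_schedule):
        rep = report_with_conf({"i0": 1, "i1": 0, "i2": 1, "i3": 0},
                               simple_schedule)
        rep.clip_confidence.loc["c0"] = 1
        rep.clip_confidence.loc["c1"] = 0  # (1, 0) -> 0
        assert bh.interval_confidence(rep, simple_schedule).loc["i0"] == 0

    def _filter_schedule(self, n):
        from conftest import small_config
        from contextdrift.synthgen import generate_schedule

        return generate_schedule(
            small_config(seed=0, n_intervals_2min=n, n_intervals_6min=0)
        )

    def test_balanced_binary_keeps_high_half(self):
        sch = self._filter_schedule(24)
        ids = sch.intervals["interval_id"].to_numpy()
        conf = {i: (1 if k < 12 else 0) for k, i in enumerate(ids)}
        rep = report_with_conf(conf, sch)
        retained = bh.confidence_filter(rep, sch)
        assert set(retained) == {i for i in ids[:12]}

    def test_all_equal_retains_all_with_warning(self):
        sch = self._filter_schedule(24)
        ids = sch.intervals["interval_id"].to_numpy()
        rep = report_with_conf({i: 3 for i in ids}, sch)
        with pytest.warns(UserWarning):
            retained = bh.confidence_filter(rep, sch)
        assert len(retained) == 24

    def test_three_level_example_retains_sixteen(self):
        # {1 x8, 3 x8, 5 x8}: dropping only the 8 at conf 1 satisfies both
        # one-third constraints and is closest to an even split
        sch = self._filter_schedule(24)
        ids = sch.intervals["interval_id"].to_numpy()
        conf = {i: [1, 3, 5][k // 8] for k, i in enumerate(ids)}
        rep = report_with_conf(conf, sch)
        retained = bh.confidence_filter(rep, sch)
        assert len(retained) == 16

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.integers(min_value=1, max_value=5), min_size=43,
                    max_size=43))
    def test_filter_respects_thirds_whenever_feasible(self, ratings):
        sch = self._filter_schedule(43)
        ids = sch.intervals["interval_id"].to_numpy()
        rep = report_with_conf(dict(zip(ids, ratings)), sch)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            retained = bh.confidence_filter(rep, sch)
        n = len(ids)
        feasible = any(
            (np.sum(np.array(ratings) < c) / n >= 1 / 3)
            and (np.sum(np.array(ratings) >= c) / n >= 1 / 3)
            for c in set(ratings)
        )
        if feasible:
            assert len(retained) / n >= 1 / 3
            assert (n - len(retained)) / n >= 1 / 3
        else:
            assert len(retained) == n


class TestGapContrasts:
    def test_pure_gap_generation_recovers_slope(self, simple_schedule):
        a = 0.6
        gaps = simple_schedule.intervals.set_index("interval_id")["true_gap_s"]
        reports = [
            make_report(f"p{k}", gaps.index, a * gaps.to_numpy())
            for k in range(4)
        ]
        m2, m6, t, df, p = bh.gap_means_and_ttest(reports, simple_schedule)
        assert m6 - m2 == pytest.approx(a * 240.0)

    def test_identical_estimates_give_zero_difference(self, simple_schedule):
        reports = [
            make_report(f"p{k}", simple_schedule.intervals["interval_id"],
                        np.full(4, 200.0))
            for k in range(3)
        ]
        m2, m6, t, df, p = bh.gap_means_and_ttest(reports, simple_schedule)
        assert m6 - m2 == 0 and t == 0

    def test_identical_subsets_rejected(self, simple_schedule):
        ids = simple_schedule.intervals["interval_id"]
        reports = [make_report(f"p{k}", ids, [100, 150, 400, 120])
                   for k in range(3)]
        subset = {f"p{k}": pd.Index(ids) for k in range(3)}
        with pytest.raises(ValueError, match="zero variance"):
            bh.difference_score_contrast(reports, simple_schedule, subset,
                                         subset)


class TestBootstrapAndZou:
    def test_printed_zou_interval(self):
        ci = bh.zou_difference_ci(0.49, 0.27, 0.57, 0.09, -0.05, 0.21)
        assert round(ci.rdiff, 2) == 0.40
        assert round(ci.lldiff, 2) == 0.15
        assert round(ci.uldiff, 2) == 0.56

    def test_identical_inputs_symmetric_about_zero(self):
        ci = bh.zou_difference_ci(0.3, 0.1, 0.5, 0.3, 0.1, 0.5)
        assert ci.rdiff == 0
        assert ci.lldiff == pytest.approx(-ci.uldiff)

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_bound_ordering_invariant(self, data):
        def ci_triplet():
            r = data.draw(st.floats(-0.95, 0.95))
            lo = data.draw(st.floats(0.0, 0.5))
            hi = data.draw(st.floats(0.0, 0.5))
            return r, max(r - lo, -1), min(r + hi, 1)
        r1, ll1, ul1 = ci_triplet()
        r2, ll2, ul2 = ci_triplet()
        ci = bh.zou_difference_ci(r1, ll1, ul1, r2, ll2, ul2)
        assert ci.lldiff <= ci.rdiff <= ci.uldiff

    def test_constant_covariate_rejected(self, simple_schedule):
        ids = simple_schedule.intervals["interval_id"]
        reports = [make_report(f"p{k}", ids, np.random.default_rng(k)
                               .uniform(50, 300, 4)) for k in range(5)]
        with pytest.raises(ValueError, match="constant"):
            bh.bootstrap_corr_ci(reports, pd.Series(1.0, index=list(ids)))

    def test_bootstrap_ci_covers_generative_r(self):
        """Percentile CI over participant resamples covers the generative
        correlation within 5 points of nominal over 500 replicates.

        The population-mean estimate vector has a fixed correlation ~0.45
        with the covariate; each participant adds independent noise that is
        small relative to the shared signal, so the participant-mean r is an
        approximately unbiased estimate of the generative r. (When
        participant noise dominates, the participant-mean correlation -- and
        hence the percentile interval -- is biased toward zero; that is a
        property of the published procedure, not of this implementation.)
        """
        rng = np.random.default_rng(7)
        n_iv, n_part, amp, sigma, rho = 24, 17, 60.0, 40.0, 0.6
        cov = pd.Series(rng.standard_normal(n_iv),
                        index=[f"i{k}" for k in range(n_iv)])
        w0 = rng.standard_normal(n_iv)
        mu = amp * (rho * cov.to_numpy() + np.sqrt(1 - rho**2) * w0)
        target = np.corrcoef(mu, cov)[0, 1]
        hits = 0
        n_rep = 500
        for rep_i in range(n_rep):
            mats = mu[:, None] + rng.normal(0, sigma, (n_iv, n_part))
            reports = [
                make_report(f"p{j}", cov.index,
                            np.maximum(600 + mats[:, j], 0.0))
                for j in range(n_part)
            ]
            _, ll, ul = bh.bootstrap_corr_ci(reports, cov, n_boot=200,
                                             seed=rep_i)
            hits += ll <= target <= ul
        assert 0.90 <= hits / n_rep <= 1.0


class TestISCAndReliability:
    def _noise_reports(self, rng, n_part, prefix, signal=None, noise=60.0):
        ids = [f"i{k}" for k in range(24)]
        sig = signal if signal is not None else np.zeros(24)
        return [
            make_report(f"{prefix}{j}", ids,
                        np.maximum(200 + sig + rng.normal(0, noise, 24), 0))
            for j in range(n_part)
        ]

    def test_copy_group_gives_p_near_one(self):
        rng = np.random.default_rng(0)
        group_a = self._noise_reports(rng, 6, "a",
                                      signal=rng.normal(0, 80, 24))
        group_b = [
            make_report(f"b{j}", r.estimates.index, r.estimates.to_numpy())
            for j, r in enumerate(group_a)
        ]
        isc_a, isc_b, between, p = bh.isc_within_between(
            group_a, group_b, n_perm=300, seed=1
        )
        assert isc_a == pytest.approx(isc_b)
        assert p > 0.5

    def test_disjoint_strategies_detected(self):
        rng = np.random.default_rng(3)
        sig_a = rng.normal(0, 80, 24)
        sig_b = rng.normal(0, 80, 24)
        group_a = self._noise_reports(rng, 8, "a", signal=sig_a, noise=40)
        group_b = self._noise_reports(rng, 8, "b", signal=sig_b, noise=40)
        *_, p = bh.isc_within_between(group_a, group_b, n_perm=500, seed=2)
        assert p < 0.05

    def test_unequal_sizes_rejected(self):
        rng = np.random.default_rng(1)
        with pytest.raises(ValueError, match="same size"):
            bh.isc_within_between(self._noise_reports(rng, 5, "a"),
                                  self._noise_reports(rng, 4, "b"))

    def test_permutation_p_uniform_under_null(self):
        """Both groups drawn from the same generator: the permutation p is
        approximately uniform (checked via its mean and 10th percentile)."""
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(120):
            shared = rng.normal(0, 50, 24)
            a = self._noise_reports(rng, 5, "a", signal=shared)
            b = self._noise_reports(rng, 5, "b", signal=shared)
            *_, p = bh.isc_within_between(a, b, n_perm=99, seed=int(rng.integers(2**31)))
            ps.append(p)
        ps = np.asarray(ps)
        assert abs(ps.mean() - 0.5) < 0.1
        assert abs(np.mean(ps < 0.1) - 0.1) < 0.08

    def test_identical_participants_split_half_r_one(self):
        ids = [f"i{k}" for k in range(10)]
        base = np.linspace(100, 400, 10)
        reports = [make_report(f"p{j}", ids, base) for j in range(6)]
        mean_r, sd_r = bh.split_half_reliability(reports, n_splits=50, seed=0)
        assert mean_r == pytest.approx(1.0)
        assert sd_r == pytest.approx(0.0)

    def test_independent_noise_split_half_near_zero(self):
        rng = np.random.default_rng(5)
        ids = [f"i{k}" for k in range(24)]
        reports = [make_report(f"p{j}", ids, rng.uniform(60, 600, 24))
                   for j in range(10)]
        mean_r, _ = bh.split_half_reliability(reports, n_splits=300, seed=1)
        assert abs(mean_r) < 0.25


class TestTimeOrderAndTimeline:
    def test_monotone_decreasing_estimates(self, simple_schedule):
        ids = simple_schedule.intervals["interval_id"]
        reports = [make_report(f"p{k}", ids, [400, 300, 250, 100])
                   for k in range(5)]
        mean_r, sd_r, t, df, p = bh.time_order_effect(
            reports, simple_schedule, gap_s=None
        )
        assert mean_r < 0 and t < 0

    def test_constant_positions_rejected(self, simple_schedule):
        sch = simple_schedule
        sch.intervals["position_s"] = 100.0
        reports = [make_report(f"p{k}", sch.intervals["interval_id"],
                               [1, 2, 3, 4]) for k in range(3)]
        with pytest.raises(ValueError, match="constant"):
            bh.time_order_effect(reports, sch, gap_s=None)

    def test_perfect_and_affine_placements(self):
        actual = pd.Series(np.linspace(0, 1500, 20),
                           index=[f"c{k}" for k in range(20)])
        placements = pd.DataFrame(
            {"p0": actual, "p1": 2.0 * actual + 5.0}
        )
        res = bh.timeline_accuracy(placements, actual)
        assert np.allclose(res.errors, 0.0, atol=1e-9)
        assert np.allclose(res.per_participant_r, 1.0)

    def test_random_placements_uncorrelated(self):
        rng = np.random.default_rng(0)
        actual = pd.Series(np.linspace(0, 1500, 86),
                           index=[f"c{k}" for k in range(86)])
        rs = []
        for j in range(40):
            placements = pd.DataFrame(
                {"p": rng.uniform(0, 1500, 86)}, index=actual.index
            )
            rs.append(bh.timeline_accuracy(placements, actual)
                      .per_participant_r.iloc[0])
        assert abs(np.mean(rs)) < 0.1
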