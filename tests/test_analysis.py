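import numpy as np
import pytest

from shhtrack.activity import ActivityTrace
from shhtrack.analysis import (
    average_by_fate,
    cluster_tracks,
    compute_position_metrics,
    compute_response_metrics,
    cross_cell_sd,
    realign_by_onset,
)
from shhtrack.tracks import Cohort

from conftest import make_track


class TestAverageByFate:
    def test_single_track_mean_is_track(self):
        tr = make_track("a", response=np.arange(10) + 1.0, fate="LFP")
        avg = average_by_fate(Cohort([tr]))["LFP"]
        np.testing.assert_allclose(avg["mean"], tr.intensity["response"])
        np.testing.assert_allclose(avg["sd"], 0.0)
        assert (avg["n"] == 1).all()

    def test_identical_tracks_zero_sd(self):
        trs = [make_track(c, response=np.arange(10) + 1.0, fate="pMN") for c in "ab"]
        avg = average_by_fate(Cohort(trs))["pMN"]
        np.testing.assert_allclose(avg["sd"], 0.0)

    def test_constant_offset_pair(self):
        """Offset k: mean is the midline, SD = k/sqrt(2) with divisor n-1."""
        k = 3.0
        base = np.arange(10) + 1.0
        trs = [
            make_track("a", response=base, fate="LFP"),
            make_track("b", response=base + k, fate="LFP"),
        ]
        avg = average_by_fate(Cohort(trs))["LFP"]
        np.testing.assert_allclose(avg["mean"], base + k / 2)
        np.testing.assert_allclose(avg["sd"], k / np.sqrt(2))

    def test_n_counts_sum_to_contributing_tracks(self):
        trs = [
            make_track("a", t=10 + 0.1 * np.arange(10), fate="LFP"),
            make_track("b", t=10.5 + 0.1 * np.arange(10), fate="LFP"),
        ]
        avg = average_by_fate(Cohort(trs))["LFP"]
        assert avg["n"].sum() == 20


class TestRealign:
    def _trace(self, cid, onset, n=30):
        t = 10 + 0.1 * np.arange(n)
        x = np.where(t >= onset, 1.0, 0.0)
        return ActivityTrace(cid, t, x, x_norm=x, onset_time=onset)

    def test_identical_shapes_align_pointwise(self):
        a, b = self._trace("a", 11.0), self._trace("b", 12.0)
        ra, rb = realign_by_onset([a, b])
        common = np.intersect1d(np.round(ra.t, 6), np.round(rb.t, 6))
        xa = ra.x_raw[np.isin(np.round(ra.t, 6), common)]
        xb = rb.x_raw[np.isin(np.round(rb.t, 6), common)]
        np.testing.assert_allclose(xa, xb)

    def test_no_onset_excluded(self):
        a = self._trace("a", 11.0)
        b = self._trace("b", 12.0)
        b.onset_time = None
        out = realign_by_onset([a, b])
        assert [tr.cell_id for tr in out] == ["a"]

    def test_alignment_reduces_cross_cell_variance(self):
        """Shared post-onset shape with jittered onsets: SD at matched
        coverage drops after re-alignment."""
        rng = np.random.default_rng(5)
        # onsets land on the sampling grid, as detect_onset returns grid times
        traces = [
            self._trace(f"c{i}", 11.5 + 0.1 * round(8 * rng.standard_normal()), n=50)
            for i in range(15)
        ]
        unaligned = cross_cell_sd(traces, use_norm=False)
        aligned = cross_cell_sd(realign_by_onset(traces), use_norm=False)
        assert aligned < unaligned


class TestClusterTracks:
    def _constant_cohort(self, levels, n_each=5, n_t=20):
        trs = []
        for li, lv in enumerate(levels):
            for i in range(n_each):
                trs.append(
                    make_track(f"g{li}-{i}", t=10 + 0.1 * np.arange(n_t),
                               response=np.full(n_t, float(lv)),
                               fate="LFP" if li == 0 else "dorsal")
                )
        return Cohort(trs)

    def test_two_well_separated_groups(self):
        res = cluster_tracks(self._constant_cohort([0.0, 10.0]), k_override=2,
                             k_range=range(2, 3))
        labels = {cid: cl for cid, cl in res.assignments.items()}
        g0 = {labels[c] for c in labels if c.startswith("g0")}
        g1 = {labels[c] for c in labels if c.startswith("g1")}
        assert len(g0) == 1 and len(g1) == 1 and g0 != g1
        assert res.wcss_curve[2] == pytest.approx(0.0, abs=1e-12)

    def test_coverage_bookkeeping_exact(self):
        """10 of 50 tracks engineered below the 80% coverage rule are the
        exact set excluded."""
        n_t = 51
        t_full = 10 + 0.1 * np.arange(n_t)
        trs = []
        for i in range(40):
            trs.append(make_track(f"full-{i:02d}", t=t_full,
                                  response=np.ones(n_t)))
        for i in range(10):
            missing = {(i + 3 * j) % n_t for j in range(15)}  # 36/51 = 70.6%
            keep = np.array([k for k in range(n_t) if k not in missing])
            trs.append(make_track(f"short-{i:02d}", t=t_full[keep],
                                  response=np.ones(keep.size)))
        res = cluster_tracks(Cohort(trs), k_override=2, k_range=range(2, 3))
        assert len(res.included) == 40
        assert all(c.startswith("full") for c in res.included)
        assert set(res.excluded) == {f"short-{i:02d}" for i in range(10)}

    def test_permutation_invariance(self):
        cohort = self._constant_cohort([0.0, 5.0, 10.0], n_each=4)
        res1 = cluster_tracks(cohort, k_override=3, k_range=range(3, 4), seed=1)
        shuffled = Cohort(list(reversed(cohort.tracks)), cohort.sampling_interval)
        res2 = cluster_tracks(shuffled, k_override=3, k_range=range(3, 4), seed=1)
        assert res1.assignments == res2.assignments

    def test_separated_fates_share_no_cluster(self, anterior_zero_noise):
        """With well-separated programs, no cluster contributes to both the
        most ventral and the dorsal fate."""
        from shhtrack.preprocess import PreprocessParams, preprocess_cohort

        cohort, _ = anterior_zero_noise
        proc = preprocess_cohort(cohort, PreprocessParams(bleed_ratio=0.0))
        res = cluster_tracks(proc, k_override=6, k_range=range(6, 7), seed=0)
        fc = res.fate_contribution
        both = (fc.loc["LFP"] > 0) & (fc.loc["dorsal"] > 0)
        assert not both.any()

    def test_k_exceeding_tracks_rejected(self):
        with pytest.raises(ValueError):
            cluster_tracks(self._constant_cohort([1.0]), k_override=10,
                           k_range=range(10, 11))

    def test_elbow_picks_plateau_knee(self):
        cohort = self._constant_cohort([0.0, 5.0, 10.0], n_each=6)
        res = cluster_tracks(cohort, k_range=range(2, 7), seed=0)
        assert res.k == 3  # WCSS drops to ~0 at the true group count


class TestResponseMetrics:
    def _trace(self, x, t0=10.0):
        x = np.asarray(x, dtype=float)
        return ActivityTrace("a", t0 + 0.1 * np.arange(x.size), x)

    def test_zero_activity_gives_zeros(self):
        m = compute_response_metrics(self._trace(np.zeros(50)))
        assert (m.max_response, m.avg_response, m.response_time) == (0.0, 0.0, 0.0)

    def test_boxcar_closed_form(self):
        """Height h for 2 of 5 hr: max = h, avg = 0.4h, time = 2 hr."""
        h = 0.8
        x = np.zeros(50)
        x[10:30] = h  # 20 of 50 points
        m = compute_response_metrics(self._trace(x))
        assert m.max_response == pytest.approx(h)
        assert m.avg_response == pytest.approx(0.4 * h)
        assert m.response_time == pytest.approx(2.0)

    def test_disjoint_runs_all_count(self):
        x = np.zeros(50)
        x[5:15] = 1.0
        x[30:40] = 1.0  # two disjoint 1-hr runs
        m = compute_response_metrics(self._trace(x))
        assert m.response_time == pytest.approx(2.0)

    def test_avg_not_above_max_for_nonnegative(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            m = compute_response_metrics(self._trace(rng.uniform(0, 1, 50)))
            assert m.avg_response <= m.max_response

    def test_response_time_monotone_in_threshold(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 1, 50)
        times = [
            compute_response_metrics(self._trace(x), on_threshold=th).response_time
            for th in (0.01, 0.1, 0.5, 0.9)
        ]
        assert all(b <= a for a, b in zip(times, times[1:]))

    def test_insufficient_coverage_leaves_missing(self):
        m = compute_response_metrics(self._trace(np.ones(3)))
        assert m.max_response is None


class TestPositionMetrics:
    def test_stationary_cell_zero_speed(self):
        t = 10 + 0.1 * np.arange(60)
        tr = make_track("a", t=t, response=np.ones(60), lmdv=np.full(60, 5.0),
                        ap=np.full(60, 50.0))
        m = compute_position_metrics(tr)
        assert m.speed_early == pytest.approx(0.0)
        assert m.lmdv_early == 5.0 and m.ap_late == 50.0

    def test_straight_line_speed(self):
        t = 10 + 0.1 * np.arange(60)
        ap = 5.0 * (t - 10)  # 10 um over any 2-hr window
        tr = make_track("a", t=t, response=np.ones(60), ap=ap)
        m = compute_position_metrics(tr)
        assert m.speed_early == pytest.approx(5.0)
        assert m.speed_net_early == pytest.approx(5.0)

    def test_zigzag_path_speed_at_least_net(self):
        t = 10 + 0.1 * np.arange(60)
        ap = np.where(np.arange(60) % 2 == 0, 0.0, 2.0)
        tr = make_track("a", t=t, response=np.ones(60), ap=ap)
        m = compute_position_metrics(tr)
        assert m.speed_early >= m.speed_net_early
        assert m.speed_early > 0

    def test_uncovered_window_leaves_missing(self):
        t = 10 + 0.1 * np.arange(10)  # ends at 10.9, far from 11.5/14.5
        m = compute_position_metrics(make_track("a", t=t))
        assert m.speed_early is None and m.lmdv_late is None
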