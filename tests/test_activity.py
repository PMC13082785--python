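import math

import numpy as np
import pytest

from shhtrack.activity import (
    ActivityTrace,
    FitError,
    InsufficientDataError,
    ParameterError,
    detect_onset,
    fit_halflife_heatshock,
    infer_activity,
    normalize_activity,
)
from shhtrack.simulate import (
    Program,
    forward_simulate_reporter,
    generate_cohort,
    generate_heatshock_dataset,
)
from shhtrack.tracks import Cohort

from conftest import make_track

LN2 = math.log(2.0)


class TestInferActivity:
    def test_constant_intensity_gives_zero(self):
        tr = make_track("a", t=10 + 0.1 * np.arange(20), response=np.full(20, 4.0))
        at = infer_activity(tr)
        np.testing.assert_allclose(at.x_raw, 0.0, atol=1e-10)

    @pytest.mark.parametrize("t_half", [1.0, 3.0])
    def test_linear_intensity_gives_constant(self, t_half):
        t = 10 + 0.1 * np.arange(20)
        b = 2.5
        tr = make_track("a", t=t, response=1.0 + b * (t - 10))
        at = infer_activity(tr, t_half=t_half)
        np.testing.assert_allclose(at.x_raw, b * LN2 / t_half, atol=1e-8)

    def test_interior_grid_excludes_run_endpoints(self):
        tr = make_track("a", t=10 + 0.1 * np.arange(20), response=np.arange(20) + 1.0)
        at = infer_activity(tr)
        assert at.n == 18
        np.testing.assert_allclose(at.t, tr.t[1:-1])

    @pytest.mark.parametrize("t_half", [1.0, 3.0, 5.0])
    def test_forward_inverse_boxcar_recovery(self, t_half):
        """Noise-free round trip: inferred activity matches the program (up
        to c) within 5% relative RMSE on interior points."""
        grid = 10 + 0.1 * np.arange(51)
        prog = Program.boxcar(11.55, 2.0, 1.0)
        _, I = forward_simulate_reporter(prog, t_half, 1.0, grid)
        tr = make_track("a", t=grid, response=I)
        at = infer_activity(tr, t_half=t_half)
        x_true = prog(at.t)
        rel = np.sqrt(np.mean((at.x_raw - x_true) ** 2)) / x_true.max()
        assert rel < 0.05

    def test_longest_unmasked_run_used(self):
        tr = make_track("a", t=10 + 0.1 * np.arange(20), response=np.arange(20) + 1.0)
        tr.mask["response"][5] = True  # splits 0-4 (5 pts) and 6-19 (14 pts)
        at = infer_activity(tr)
        assert at.t[0] >= tr.t[7] - 1e-9

    def test_too_few_points_rejected(self):
        tr = make_track("a", t=10 + 0.1 * np.arange(6))
        tr.mask["response"][3] = True
        with pytest.raises(InsufficientDataError):
            infer_activity(tr)

    def test_non_uniform_sampling_rejected(self):
        t = np.array([10.0, 10.1, 10.2, 10.5, 10.6, 10.7])
        with pytest.raises(ParameterError, match="resample"):
            infer_activity(make_track("a", t=t))

    def test_bad_t_half_rejected(self):
        with pytest.raises(ParameterError):
            infer_activity(make_track("a"), t_half=0.0)


class TestNormalize:
    def _trace(self, cid, peak):
        t = 10 + 0.1 * np.arange(10)
        x = np.linspace(0, peak, 10)
        return ActivityTrace(cid, t, x)

    def test_single_trace_peak_one(self):
        out = normalize_activity([self._trace("a", 4.0)])
        assert out[0].x_norm.max() == pytest.approx(1.0)

    def test_dataset_wide_scaling(self):
        out = normalize_activity([self._trace("a", 2.0), self._trace("b", 4.0)])
        assert out[0].x_norm.max() == pytest.approx(0.5)
        assert out[1].x_norm.max() == pytest.approx(1.0)

    def test_all_nonpositive_rejected(self):
        tr = ActivityTrace("a", np.arange(5.0), -np.ones(5))
        with pytest.raises(FitError):
            normalize_activity([tr])

    def test_peak_ordering_tracks_amplitudes(self, anterior_zero_noise):
        """Per-cell normalized peaks rank like the true program amplitudes."""
        from scipy.stats import spearmanr

        from shhtrack.preprocess import PreprocessParams, preprocess_cohort

        cohort, truth = anterior_zero_noise
        proc = preprocess_cohort(cohort, PreprocessParams(bleed_ratio=0.0, smooth_window=1))
        traces = normalize_activity([infer_activity(tr) for tr in proc])
        peaks = [tr.x_norm.max() for tr in traces]
        amps = [truth.cells[tr.cell_id].program.values.max() for tr in traces]
        rho, _ = spearmanr(peaks, amps)
        assert rho > 0.95


class TestDetectOnset:
    def _norm_trace(self, x_norm, t0=10.0):
        t = t0 + 0.1 * np.arange(len(x_norm))
        x = np.asarray(x_norm, dtype=float)
        return ActivityTrace("a", t, x, x_norm=x)

    def test_flat_zero_has_no_onset(self):
        assert detect_onset(self._norm_trace(np.zeros(10))) is None

    def test_two_point_excursion_rejected_by_persistence(self):
        x = np.zeros(10)
        x[4:6] = 0.5  # only 2 consecutive points above threshold
        assert detect_onset(self._norm_trace(x)) is None

    def test_step_onset_detected_at_first_point_of_run(self):
        x = np.zeros(30)
        x[20:] = 0.5  # t = 12.0 onward
        assert detect_onset(self._norm_trace(x)) == pytest.approx(12.0)

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            x = np.abs(rng.normal(0.02, 0.05, size=40))
            tr = self._norm_trace(x)
            onsets = [detect_onset(tr, threshold=th) for th in (0.01, 0.025, 0.05, 0.1)]
            times = [o for o in onsets if o is not None]
            # raising the threshold never yields an earlier onset
            assert all(b >= a for a, b in zip(times, times[1:]))
            # and once the onset disappears it stays absent
            seen_none = False
            for o in onsets:
                if o is None:
                    seen_none = True
                assert not (seen_none and o is not None)

    def test_requires_normalization(self):
        tr = ActivityTrace("a", np.arange(5.0), np.ones(5))
        with pytest.raises(ParameterError):
            detect_onset(tr)


class TestHalfLifeFit:
    def test_exact_exponential_recovers_printed_value(self):
        """A track with -ln(1-I/Imax) slope 0.4/hr gives t_half = 1.7 hr."""
        t = 0.1 * np.arange(201)  # 0-20 hr
        I = 10.0 * (1 - np.exp(-0.4 * t))
        coh = Cohort([make_track("a", t=t, response=I)])
        fit = fit_halflife_heatshock(coh, pulse_end=0.0)
        assert fit.slope == pytest.approx(0.4, rel=0.01)
        assert round(fit.t_half, 1) == 1.7

    def test_slope_ln2_means_one_hour(self):
        t = 0.1 * np.arange(151)
        I = 5.0 * (1 - np.exp(-LN2 * t))
        fit = fit_halflife_heatshock(Cohort([make_track("a", t=t, response=I)]), pulse_end=0.0)
        assert fit.t_half == pytest.approx(1.0, rel=0.01)

    def test_noiseless_generator_half_life(self):
        coh = generate_heatshock_dataset(t_half=1.7, n_cells=3, noise_cv=0.0,
                                         amplitude_cv=0.0, seed=0)
        fit = fit_halflife_heatshock(coh)
        assert fit.slope == pytest.approx(LN2 / 1.7, rel=0.02)
        assert fit.r_squared > 0.999

    def test_noisy_parameter_recovery(self):
        coh = generate_heatshock_dataset(t_half=3.0, n_cells=20, noise_cv=0.02, seed=1)
        fit = fit_halflife_heatshock(coh)
        assert fit.t_half == pytest.approx(3.0, rel=0.10)

    def test_decaying_intensity_rejected(self):
        t = 0.1 * np.arange(100)
        I = 10.0 * np.exp(-0.3 * t) + 1.0
        with pytest.raises((FitError, InsufficientDataError)):
            fit_halflife_heatshock(Cohort([make_track("a", t=t, response=I)]), pulse_end=0.0)

    def test_too_short_track_rejected(self):
        t = 0.1 * np.arange(5)
        I = np.array([0, 1, 2, 2.5, 2.6])
        with pytest.raises(InsufficientDataError):
            fit_halflife_heatshock(Cohort([make_track("a", t=t, response=I)]), pulse_end=0.0)


def test_forward_inverse_consistency_on_generator_output(anterior_zero_noise):
    """Cohort-level check: pooled relative RMSE of the reconstructed programs
    stays below 5% of each cell's peak on noise-free data."""
    from shhtrack.preprocess import PreprocessParams, preprocess_cohort

    cohort, truth = anterior_zero_noise
    proc = preprocess_cohort(cohort, PreprocessParams(bleed_ratio=0.0, smooth_window=1))
    sq, n = 0.0, 0
    for tr in proc:
        if truth.cells[tr.cell_id].fate == "dorsal":
            continue  # near-basal programs have no meaningful peak scale
        at = infer_activity(tr)
        x_true = truth.cells[tr.cell_id].program(at.t)
        peak = x_true.max()
        sq += float(np.sum(((at.x_raw - x_true) / peak) ** 2))
        n += at.n
    assert math.sqrt(sq / n) < 0.05
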