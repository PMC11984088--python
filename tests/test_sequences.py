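"""Theta cycle segmentation, trajectory fitting, shuffle significance."""

import numpy as np
import pytest

from placeseq import AnalysisConfig, LfpChannel
from placeseq.circular import circ_dist_deg
from placeseq.decoder import DecodedPosterior
from placeseq.sequences import (fit_decoded_trajectory, longest_contiguous_run,
                                segment_theta_cycles, shuffle_test)
from placeseq.theta import theta_filter_phase

FS = 2000.0
SLOPE_BOUNDS = (-3000.0, 3000.0)


def delta_posterior(angles_deg, step_s=0.01, win_s=0.04, n_bins=90):
    """Near-delta posteriors whose circular COM equals each given angle.

    Mass is split between the two bins flanking the target angle so the
    posterior-weighted circular mean reproduces it (up to a negligible
    chord-vs-arc correction for 4-deg bins)."""
    angles_deg = np.asarray(angles_deg, float)
    W = angles_deg.size
    width = 360.0 / n_bins
    post = np.zeros((W, n_bins))
    centers = (np.arange(n_bins) + 0.5) * width
    for w, a in enumerate(angles_deg):
        pos = (a % 360.0) / width - 0.5
        lo = int(np.floor(pos)) % n_bins
        frac = pos - np.floor(pos)
        post[w, lo] = 1.0 - frac
        post[w, (lo + 1) % n_bins] = frac
    starts = np.arange(W) * step_s
    wins = np.column_stack([starts, starts + win_s])
    return DecodedPosterior(wins.mean(axis=1), wins, post, np.ones(W),
                            np.ones(W), centers)


class TestCycleSegmentation:
    def test_pure_8hz_yields_125ms_cycles(self):
        t = np.arange(int(10 * FS)) / FS
        lfp = LfpChannel(FS, np.cos(2 * np.pi * 8.0 * t))
        phases = theta_filter_phase(lfp)
        spikes = np.arange(0.5, 9.5, 0.0625)  # spread over phases
        cycles, _ = segment_theta_cycles(phases, spikes)
        assert 70 <= len(cycles) <= 82
        durs = np.array([c.duration_s for c in cycles])
        np.testing.assert_allclose(durs, 0.125, atol=0.01)

    def test_cut_avoids_spike_phase(self):
        """Spikes clustered at one phase: the cut lands elsewhere, so every
        cycle keeps its spike cluster intact."""
        t = np.arange(int(10 * FS)) / FS
        lfp = LfpChannel(FS, np.cos(2 * np.pi * 8.0 * t))
        phases = theta_filter_phase(lfp)
        # spikes at phase ~180 deg: t = (k + 0.5) * 0.125
        spikes = (np.arange(8, 72) + 0.5) * 0.125
        cycles, cut = segment_theta_cycles(phases, spikes)
        assert circ_dist_deg(cut, 180.0) > 60.0
        for c in cycles:
            inside = spikes[(spikes >= c.start_s) & (spikes < c.end_s)]
            assert inside.size <= 1  # never splits the single per-cycle burst

    def test_cut_phase_matches_histogram_argmin_oracle(self, cfg):
        rng = np.random.default_rng(0)
        t = np.arange(int(20 * FS)) / FS
        lfp = LfpChannel(FS, np.cos(2 * np.pi * 8.0 * t))
        phases = theta_filter_phase(lfp)
        # nonuniform spike phases
        spikes = np.sort(rng.uniform(0.5, 19.5, 3000))
        keep = rng.uniform(0, 1, 3000) < 0.5 * (
            1 + np.cos(np.deg2rad(phases.at(spikes) - 200.0)))
        spikes = spikes[keep]
        _, cut = segment_theta_cycles(phases, spikes, cfg=cfg)
        hist, edges = np.histogram(phases.at(spikes),
                                   bins=np.linspace(0, 360, 19))
        oracle = edges[np.argmin(hist)] + 10.0
        assert cut == pytest.approx(oracle)


class TestContiguity:
    def test_broken_at_two_consecutive_empty_windows(self):
        counts = [2, 1, 0, 0, 3, 2, 1, 4, 0, 2]
        idx = longest_contiguous_run(counts, gap_bins=2)
        np.testing.assert_array_equal(idx, np.arange(4, 10))

    def test_single_empty_window_does_not_break(self):
        counts = [2, 0, 1, 0, 3]
        np.testing.assert_array_equal(longest_contiguous_run(counts, 2),
                                      np.arange(5))

    def test_edges_trimmed_to_spiking_windows(self):
        counts = [0, 2, 1, 0, 0, 1]
        idx = longest_contiguous_run(counts, 2)
        np.testing.assert_array_equal(idx, np.array([1, 2]))


class TestTrajectoryFit:
    def test_exact_linear_deltas(self):
        # 5 deg per 10 ms window step -> 500 deg/s, r^2 = 1
        angles = 100.0 + 5.0 * np.arange(8)
        fit = fit_decoded_trajectory(delta_posterior(angles), SLOPE_BOUNDS)
        assert fit.slope_deg_per_s == pytest.approx(500.0, abs=2.0)
        assert fit.r2 == pytest.approx(1.0, abs=1e-6)
        assert fit.x_span_deg == pytest.approx(abs(fit.slope_deg_per_s)
                                               * fit.t_span_s, abs=1e-9)
        assert fit.t_span_s == pytest.approx(0.07)

    def test_constant_angles_zero_slope_and_span(self):
        fit = fit_decoded_trajectory(delta_posterior(np.full(8, 200.0)),
                                     SLOPE_BOUNDS)
        assert fit.slope_deg_per_s == pytest.approx(0.0, abs=1e-6)
        assert fit.x_span_deg == pytest.approx(0.0, abs=1e-6)

    def test_com_uses_circular_mean(self):
        post = np.zeros((3, 90))
        for w in range(3):
            post[w, 87] = 0.5  # 350 deg bin
            post[w, 2] = 0.5   # 10 deg bin
        dp = delta_posterior(np.zeros(3))
        dp.posterior = post
        com = dp.com_deg()
        assert np.max(circ_dist_deg(com, 0.0)) < 1e-9

    def test_fit_wraps_across_zero(self):
        angles = (340.0 + 5.0 * np.arange(10)) % 360.0  # passes through 0
        fit = fit_decoded_trajectory(delta_posterior(angles), SLOPE_BOUNDS)
        assert fit.slope_deg_per_s == pytest.approx(500.0, abs=2.0)
        assert fit.r2 > 0.999

    def test_time_reversal_negates_slope_preserves_r2(self):
        rng = np.random.default_rng(1)
        angles = (50.0 + 40.0 * np.arange(9) + rng.normal(0, 5, 9)) % 360.0
        fwd = fit_decoded_trajectory(delta_posterior(angles), SLOPE_BOUNDS)
        rev = fit_decoded_trajectory(delta_posterior(angles[::-1]), SLOPE_BOUNDS)
        assert rev.slope_deg_per_s == pytest.approx(-fwd.slope_deg_per_s,
                                                    abs=1.0)
        assert rev.r2 == pytest.approx(fwd.r2, abs=1e-6)

    def test_global_rotation_leaves_fit_statistics_unchanged(self):
        rng = np.random.default_rng(2)
        angles = (50.0 + 30.0 * np.arange(9) + rng.normal(0, 8, 9)) % 360.0
        base = fit_decoded_trajectory(delta_posterior(angles), SLOPE_BOUNDS)
        rot = fit_decoded_trajectory(delta_posterior((angles + 120.0) % 360.0),
                                     SLOPE_BOUNDS)
        assert rot.slope_deg_per_s == pytest.approx(base.slope_deg_per_s, abs=1.0)
        assert rot.r2 == pytest.approx(base.r2, abs=1e-6)
        assert rot.x_span_deg == pytest.approx(base.x_span_deg, abs=1.0)


class TestShuffle:
    def test_perfect_sequence_is_significant(self):
        angles = 100.0 + 5.0 * np.arange(8)
        dp = delta_posterior(angles)
        fit = fit_decoded_trajectory(dp, SLOPE_BOUNDS)
        p = shuffle_test(dp, fit, n=1000, seed=0, slope_bounds=SLOPE_BOUNDS)
        assert p <= 0.05

    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(3)
        angles = rng.uniform(0, 360, 9)
        dp = delta_posterior(angles)
        fit = fit_decoded_trajectory(dp, SLOPE_BOUNDS)
        p1 = shuffle_test(dp, fit, n=200, seed=42, slope_bounds=SLOPE_BOUNDS)
        p2 = shuffle_test(dp, fit, n=200, seed=42, slope_bounds=SLOPE_BOUNDS)
        assert p1 == p2

    def test_null_rate_on_independent_rows_near_alpha(self):
        """Structureless, per-window-independent posteriors pass the shuffle
        test at ~the nominal rate (exchangeable null)."""
        rng = np.random.default_rng(5)
        n_sig, N = 0, 250
        for i in range(N):
            raw = rng.dirichlet(np.ones(90) * 0.1, size=9)
            dp = delta_posterior(np.zeros(9))
            dp.posterior = raw
            fit = fit_decoded_trajectory(dp, SLOPE_BOUNDS)
            if shuffle_test(dp, fit, n=200, seed=i,
                            slope_bounds=SLOPE_BOUNDS) < 0.05:
                n_sig += 1
        assert n_sig / N == pytest.approx(0.05, abs=0.035)
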