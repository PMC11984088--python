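"""Rate maps, spatial information, stability measures, place fields."""

import numpy as np
import pytest

from placeseq import (AnalysisConfig, EpochSpec, PositionTrace, SpikeTrain,
                      compute_rate_map, compute_speed, day_average_map,
                      detect_place_fields, rate_overlap, spatial_correlation,
                      spatial_information)
from placeseq.ratemaps import RateMap, circular_gaussian_kernel
from placeseq.session import DEFAULT_CIRCUMFERENCE_CM


def _run_trace(duration_s=90.0, deg_per_s=40.0, fs=100.0):
    t = np.arange(int(duration_s * fs)) / fs
    return compute_speed(PositionTrace(t, (deg_per_s * t) % 360.0))


def _map_from_arrays(rate_hz, occupancy_s=None, unit_id="u"):
    n = len(rate_hz)
    occ = np.ones(n) if occupancy_s is None else np.asarray(occupancy_s, float)
    rate = np.asarray(rate_hz, float)
    return RateMap(np.linspace(0, 360, n + 1), occ, rate, rate,
                   np.zeros(n), unit_id=unit_id)


class TestComputeRateMap:
    def test_zero_spikes_gives_zero_map(self, cfg):
        trace = _run_trace()
        unit = SpikeTrain("u0", np.empty(0))
        m = compute_rate_map(unit, trace, EpochSpec("run1", 0.0, 90.0), cfg)
        np.testing.assert_allclose(m.rate_hz, 0.0)
        assert m.occupancy_s.sum() == pytest.approx(90.0, rel=0.01)

    def test_single_spike_map_is_wrapped_gaussian(self, cfg):
        """One spike in bin 0 under uniform occupancy smooths to the wrapped
        Gaussian kernel itself, checked against a direct convolution."""
        trace = _run_trace(duration_s=90.0, deg_per_s=4.0 * 100.0, fs=1000.0)
        # speed here is huge (fast sweep) so the gate passes everywhere
        spike_t = np.array([90.0 * 0.25e-4])  # angle ~ 0.9 deg -> bin 0
        m = compute_rate_map(SpikeTrain("u", spike_t), trace,
                             EpochSpec("run1", 0.0, 90.0), cfg)
        kern = circular_gaussian_kernel(cfg.smooth_deg / cfg.bin_deg, 90)
        raw = np.zeros(90)
        raw[0] = m.raw_rate_hz[0]
        oracle = np.array([
            sum(kern[(i - j) % 90] * raw[j] for j in range(90))
            for i in range(90)])
        np.testing.assert_allclose(m.rate_hz, oracle, atol=1e-12)
        # total rate mass is conserved by the normalized kernel
        assert m.rate_hz.sum() == pytest.approx(raw.sum(), rel=1e-9)

    def test_smoothing_preserves_constant_maps(self, cfg):
        trace = _run_trace()
        # one spike per sample -> near-uniform rate; exact constancy checked
        # on the kernel instead
        kern = circular_gaussian_kernel(2.0, 90)
        assert kern.sum() == pytest.approx(1.0, abs=1e-12)

    def test_zero_occupancy_errors(self, cfg):
        t = np.arange(600) / 29.97
        trace = compute_speed(PositionTrace(t, np.full(600, 5.0)))  # stationary
        with pytest.raises(ValueError, match="no qualifying samples"):
            compute_rate_map(SpikeTrain("u", np.empty(0)), trace,
                             EpochSpec("run1", 0.0, 20.0), cfg)

    def test_rotation_equivariance(self, cfg):
        """Rotating trajectory and spikes by k bins rotates the map by k."""
        k = 7
        shift = k * cfg.bin_deg
        duration, fs = 90.0, 100.0
        t = np.arange(int(duration * fs)) / fs
        base = PositionTrace(t, (40.0 * t) % 360.0)
        rot = PositionTrace(t, (40.0 * t + shift) % 360.0)
        rng = np.random.default_rng(0)
        spikes = np.sort(rng.uniform(0, duration, 200))
        ep = EpochSpec("run1", 0.0, duration)
        m0 = compute_rate_map(SpikeTrain("u", spikes), compute_speed(base), ep, cfg)
        m1 = compute_rate_map(SpikeTrain("u", spikes), compute_speed(rot), ep, cfg)
        np.testing.assert_allclose(np.roll(m0.rate_hz, k), m1.rate_hz,
                                   atol=1e-9)


class TestDayAverage:
    def test_identical_sessions_equal_day_map(self, cfg):
        trace = _run_trace()
        unit = SpikeTrain("u", np.sort(np.random.default_rng(1).uniform(0, 90, 300)))
        ep = EpochSpec("run1", 0.0, 90.0)
        m = compute_rate_map(unit, trace, ep, cfg)
        day = day_average_map([m, m], cfg)
        np.testing.assert_allclose(day.rate_hz, m.rate_hz, atol=1e-12)

    def test_pooling_is_not_averaging(self, cfg):
        """Occupancies 1 s and 3 s with 1 and 9 spikes pool to 10/4 = 2.5 Hz,
        not mean(1, 3) = 2."""
        n = 90
        a = _map_from_arrays(np.zeros(n), np.full(n, 1.0))
        b = _map_from_arrays(np.zeros(n), np.full(n, 3.0))
        a.n_spikes = np.full(n, 1.0)
        b.n_spikes = np.full(n, 9.0)
        day = day_average_map([a, b], cfg)
        np.testing.assert_allclose(day.raw_rate_hz, 2.5)
        np.testing.assert_allclose(day.rate_hz, 2.5)

    def test_inclusion_threshold_on_peak(self, cfg):
        n = 90
        weak = _map_from_arrays(np.zeros(n), np.full(n, 10.0))
        weak.n_spikes = np.zeros(n)
        weak.n_spikes[0] = 9.0  # raw peak 0.9 Hz
        day = day_average_map([weak], cfg)
        assert day.peak_rate_hz < 1.0
        assert not day.include_for_analysis

    def test_mismatched_binning_rejected(self, cfg):
        a = _map_from_arrays(np.zeros(90))
        b = _map_from_arrays(np.zeros(45))
        with pytest.raises(ValueError, match="binning"):
            day_average_map([a, b], cfg)


class TestStabilityMeasures:
    def test_self_correlation_is_one(self):
        m = _map_from_arrays(np.random.default_rng(0).uniform(0, 5, 90))
        assert spatial_correlation(m, m) == pytest.approx(1.0)

    def test_negated_contrast_is_minus_one(self):
        rates = np.random.default_rng(1).uniform(0, 5, 90)
        a = _map_from_arrays(rates)
        b = _map_from_arrays(6.0 - rates)
        assert spatial_correlation(a, b) == pytest.approx(-1.0)

    def test_rotated_bump_matches_pearson_oracle(self):
        kern = circular_gaussian_kernel(2.0, 90)
        bump = np.roll(kern, 10) * 100.0
        a = _map_from_arrays(bump)
        b = _map_from_arrays(np.roll(bump, 45))
        oracle = float(np.corrcoef(bump, np.roll(bump, 45))[0, 1])
        assert spatial_correlation(a, b) == pytest.approx(oracle, abs=1e-12)
        assert oracle < 0  # opposed bumps anticorrelate

    def test_zero_variance_map_returns_none(self):
        a = _map_from_arrays(np.full(90, 2.0))
        b = _map_from_arrays(np.random.default_rng(2).uniform(0, 5, 90))
        with pytest.warns(UserWarning):
            assert spatial_correlation(a, b) is None

    @pytest.mark.parametrize("ra,rb,expected", [
        (2.0, 2.0, 1.0), (2.0, 4.0, 0.5), (0.0, 3.0, 0.0)])
    def test_rate_overlap_ratio(self, ra, rb, expected):
        a = _map_from_arrays(np.full(90, ra))
        b = _map_from_arrays(np.full(90, rb))
        assert rate_overlap(a, b) == pytest.approx(expected)


class TestSpatialInformation:
    def test_constant_map_zero_bits(self):
        m = _map_from_arrays(np.full(90, 3.0))
        assert spatial_information(m) == pytest.approx(0.0, abs=1e-12)

    def test_single_bin_firing_log2_90_bits(self):
        rates = np.zeros(90)
        rates[17] = 5.0
        m = _map_from_arrays(rates)
        assert spatial_information(m) == pytest.approx(np.log2(90), abs=1e-12)

    def test_toy_map_matches_direct_sum(self):
        p = np.full(5, 0.2)
        lam_i = np.array([1.0, 2.0, 3.0, 2.0, 1.0])
        lam = float(np.sum(p * lam_i))
        oracle = float(sum(pi * (li / lam) * np.log2(li / lam)
                           for pi, li in zip(p, lam_i)))
        m = _map_from_arrays(lam_i, np.ones(5))
        assert spatial_information(m) == pytest.approx(oracle, abs=1e-14)

    def test_si_nonnegative_and_permutation_invariant(self):
        rng = np.random.default_rng(3)
        rates = rng.uniform(0, 10, 90)
        occ = rng.uniform(0.5, 2.0, 90)
        m = _map_from_arrays(rates, occ)
        si = spatial_information(m)
        perm = rng.permutation(90)
        m2 = _map_from_arrays(rates[perm], occ[perm])
        assert si >= 0
        assert spatial_information(m2) == pytest.approx(si, abs=1e-12)


class TestPlaceFields:
    def test_constant_map_has_no_fields(self, cfg):
        assert detect_place_fields(_map_from_arrays(np.full(90, 2.0)), cfg) == []

    def test_single_bump_boundaries_match_brute_force(self, cfg):
        kern = circular_gaussian_kernel(3.0, 90)
        rates = np.roll(kern / kern.max() * 5.0, 40)
        m = _map_from_arrays(rates)
        fields = detect_place_fields(m, cfg)
        assert len(fields) == 1
        # brute-force scan: grow from every z>=2 bin until z<0.5
        z = (rates - rates.mean()) / rates.std()
        member = set()
        for s in np.flatnonzero(z >= 2.0):
            member.add(s)
            i = s
            while z[(i + 1) % 90] >= 0.5:
                i = (i + 1) % 90
                member.add(i)
            i = s
            while z[(i - 1) % 90] >= 0.5:
                i = (i - 1) % 90
                member.add(i)
        assert set(fields[0].bins.tolist()) == member

    def test_wrapping_bump_detected_once(self, cfg):
        kern = circular_gaussian_kernel(3.0, 90)
        rates = kern / kern.max() * 5.0  # peak at bin 0, wraps across 0 deg
        fields = detect_place_fields(_map_from_arrays(rates), cfg)
        assert len(fields) == 1
        assert fields[0].contains(0.5) and fields[0].contains(359.5)

    def test_narrow_bump_rejected_by_size_rule(self, cfg):
        rates = np.zeros(90)
        rates[40:43] = [3.0, 5.0, 3.0]  # 12 deg wide region
        fields = detect_place_fields(_map_from_arrays(rates), cfg)
        assert fields == []

    def test_low_peak_rejected_by_rate_rule(self, cfg):
        kern = circular_gaussian_kernel(3.0, 90)
        rates = np.roll(kern / kern.max() * 0.8, 40)  # peak 0.8 Hz
        assert detect_place_fields(_map_from_arrays(rates), cfg) == []
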