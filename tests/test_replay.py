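"""Candidate-event detection, replay classification, PSTH, and ISIs."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

from placeseq import (AnalysisConfig, EpochSpec, PositionTrace, Session,
                      SpikeTrain, TuningModel, classify_replay,
                      detect_candidates, event_isis, replay_psth)
from placeseq.replay import CandidateEvent
from placeseq.session import compute_speed


def _rest_session(unit_spikes: dict, duration=60.0, label="rest2"):
    t = np.arange(int(duration * 29.97)) / 29.97
    trace = compute_speed(PositionTrace(t, np.zeros(t.size)))
    units = [SpikeTrain(uid, np.sort(np.asarray(st, float)))
             for uid, st in unit_spikes.items()]
    return Session(trace, units, [], [EpochSpec(label, 0.0, duration)])


def _burst(t0, n_units, per_unit=3, spacing=0.008, prefix="u"):
    """n_units cells firing per_unit spikes each in a tight ramp from t0."""
    out = {}
    for j in range(n_units):
        base = t0 + j * spacing
        out[f"{prefix}{j}"] = [base + k * 0.001 for k in range(per_unit)]
    return out


def _merge_spikes(*dicts):
    out = {}
    for d in dicts:
        for k, v in d.items():
            out.setdefault(k, []).extend(v)
    return out


class TestCandidateDetection:
    def _detect(self, unit_spikes, duration=60.0, cfg=None):
        cfg = cfg or AnalysisConfig()
        s = _rest_session(unit_spikes, duration)
        return detect_candidates(s, list(unit_spikes), s.schedule[0], cfg), s

    def test_nearby_bursts_merge_distant_bursts_split(self, cfg):
        base = {f"u{j}": [] for j in range(8)}
        close = _merge_spikes(_burst(10.0, 8), _burst(10.09, 8))   # ~30 ms gap
        far = _merge_spikes(_burst(30.0, 8), _burst(30.16, 8))     # ~100 ms gap
        events, _ = self._detect(_merge_spikes(base, close, far))
        starts = sorted(e.start_s for e in events)
        near_10 = [s for s in starts if 9.5 < s < 11]
        near_30 = [s for s in starts if 29.5 < s < 31]
        assert len(near_10) == 1
        assert len(near_30) == 2

    def test_four_cell_burst_excluded(self, cfg):
        events, _ = self._detect(_merge_spikes(
            {f"u{j}": [] for j in range(10)}, _burst(10.0, 4, per_unit=6)))
        assert all(not (9.5 < e.start_s < 10.5) for e in events)

    def test_bounds_trimmed_to_spikes(self, cfg):
        spikes = _merge_spikes({f"u{j}": [] for j in range(8)}, _burst(20.0, 8))
        events, _ = self._detect(spikes)
        ev = next(e for e in events if 19.5 < e.start_s < 20.5)
        pooled = np.sort(np.concatenate(
            [np.asarray(v) for v in spikes.values() if len(v)]))
        assert ev.start_s == pytest.approx(pooled[0])
        assert ev.end_s == pytest.approx(pooled[-1])

    def test_translation_invariance(self, cfg):
        spikes = _merge_spikes({f"u{j}": [] for j in range(8)},
                               _burst(15.0, 8), _burst(40.0, 8, spacing=0.006))
        ev_a, _ = self._detect(spikes)
        delta = 7.0
        shifted = {k: [t + delta for t in v] for k, v in spikes.items()}
        ev_b, _ = self._detect(shifted)
        assert len(ev_a) == len(ev_b)
        for a, b in zip(sorted(ev_a, key=lambda e: e.start_s),
                        sorted(ev_b, key=lambda e: e.start_s)):
            assert b.start_s - a.start_s == pytest.approx(delta, abs=2e-3)
            assert b.end_s - a.end_s == pytest.approx(delta, abs=2e-3)

    def test_poisson_false_positive_count_matches_oracle(self, cfg):
        """Detection on homogeneous Poisson trains matches an independently
        coded implementation of the threshold/merge/trim rules."""
        rng = np.random.default_rng(9)
        duration = 120.0
        unit_spikes = {f"u{j}": rng.uniform(0, duration, rng.poisson(2.0 * duration))
                       for j in range(10)}
        events, _ = self._detect(unit_spikes, duration)

        # --- independent oracle ---
        pooled = np.sort(np.concatenate(list(unit_spikes.values())))
        bins = np.arange(0, duration + 1e-9, 0.001)
        counts, _ = np.histogram(pooled, bins)
        rate = gaussian_filter1d(counts.astype(float), 10.0, mode="nearest") / 0.001
        mu, sd = rate.mean(), rate.std()
        regions = []
        i = 0
        n = rate.size
        while i < n:
            if rate[i] > mu + 3 * sd:
                a = i
                while a > 0 and rate[a - 1] >= mu:
                    a -= 1
                b = i
                while b < n - 1 and rate[b + 1] >= mu:
                    b += 1
                regions.append([a * 0.001, (b + 1) * 0.001])
                i = b + 1
            else:
                i += 1
        merged = []
        for r in regions:
            if merged and r[0] - merged[-1][1] <= 0.04:
                merged[-1][1] = max(merged[-1][1], r[1])
            else:
                merged.append(list(r))
        oracle = []
        for a, b in merged:
            inside = pooled[(pooled >= a) & (pooled <= b)]
            if inside.size == 0:
                continue
            t0, t1 = inside[0], inside[-1]
            if not (0.05 <= t1 - t0 <= 2.0):
                continue
            cells = sum(np.any((np.asarray(v) >= t0) & (np.asarray(v) <= t1))
                        for v in unit_spikes.values())
            if cells >= 5:
                oracle.append((t0, t1))
        assert len(events) == len(oracle)
        for ev, (t0, t1) in zip(sorted(events, key=lambda e: e.start_s),
                                sorted(oracle)):
            assert ev.start_s == pytest.approx(t0, abs=1e-6)
            assert ev.end_s == pytest.approx(t1, abs=1e-6)


class TestClassification:
    def _model(self):
        # 18 units with one-bin fields every 20 deg
        tuning = np.zeros((18, 90))
        for j in range(18):
            tuning[j, j * 5] = 20.0
        centers = (np.arange(90) + 0.5) * 4.0
        return TuningModel([f"u{j}" for j in range(18)], tuning, centers)

    def _event_spikes(self, order, t0=0.0, dt=0.02):
        """One spike pair per unit in the given field order, dt apart."""
        spikes = {f"u{j}": np.empty(0) for j in range(18)}
        for k, j in enumerate(order):
            t = t0 + k * dt
            spikes[f"u{j}"] = np.array([t, t + 0.004])
        return spikes

    def test_sequential_event_classified_with_scripted_slope(self, cfg):
        # fields 20 deg apart crossed every 20 ms -> 1000 deg/s... use 2 bins
        order = list(range(10))  # 20 deg per 20 ms = 1000 deg/s
        spikes = self._event_spikes(order)
        ev = CandidateEvent(0.0, 0.184, [f"u{j}" for j in order], "rest2")
        res = classify_replay(ev, self._model(), spikes, cfg)
        assert res.is_replay
        assert res.abs_slope_deg_per_s == pytest.approx(1000.0, rel=0.15)
        assert res.fit.r2 > 0.8
        assert res.path_distance_deg == pytest.approx(180.0, abs=25.0)

    def test_reverse_event_same_abs_slope(self, cfg):
        fwd = self._event_spikes(list(range(10)))
        rev = self._event_spikes(list(range(9, -1, -1)))
        ev = CandidateEvent(0.0, 0.184, [f"u{j}" for j in range(10)], "rest2")
        a = classify_replay(ev, self._model(), fwd, cfg)
        b = classify_replay(ev, self._model(), rev, cfg)
        assert a.fit.slope_deg_per_s == pytest.approx(-b.fit.slope_deg_per_s,
                                                      rel=0.1)
        assert a.abs_slope_deg_per_s == pytest.approx(b.abs_slope_deg_per_s,
                                                      rel=0.1)

    def test_teleporting_trajectory_rejected_by_jump_rule(self, cfg):
        # first half sweeps 0..80 deg, then teleports to 200 deg
        order = [0, 1, 2, 3, 4, 13, 14, 15, 16, 17]
        spikes = self._event_spikes(order)
        ev = CandidateEvent(0.0, 0.184, [f"u{j}" for j in order], "rest2")
        res = classify_replay(ev, self._model(), spikes, cfg)
        assert res.max_jump_frac > 0.25
        assert not res.is_replay
        assert "jump" in res.reason

    def test_rest1_event_never_replay(self, cfg):
        spikes = self._event_spikes(list(range(10)))
        ev = CandidateEvent(0.0, 0.184, [f"u{j}" for j in range(10)], "rest1")
        res = classify_replay(ev, self._model(), spikes, cfg)
        assert not res.is_replay
        assert "rest" in res.reason


class TestIsis:
    def test_population_isi_worked_example(self):
        ev = CandidateEvent(0.0, 0.05, ["a", "b"])
        trains = {"a": np.array([0.0, 0.020]), "b": np.array([0.010, 0.030])}
        out = event_isis(ev, trains)
        assert out["population_isi_ms"] == pytest.approx(10.0)

    def test_first_spike_isi_worked_example(self):
        ev = CandidateEvent(0.0, 0.05, ["a", "b", "c"])
        trains = {"a": np.array([0.0, 0.005]), "b": np.array([0.003]),
                  "c": np.array([0.009])}
        out = event_isis(ev, trains)
        assert out["first_spike_isi_ms"] == pytest.approx(4.5)

    def test_population_isi_telescoping_identity(self):
        rng = np.random.default_rng(4)
        ts = np.sort(rng.uniform(0, 0.2, 23))
        ev = CandidateEvent(0.0, 0.2, ["a"])
        out = event_isis(ev, {"a": ts})
        assert out["population_isi_ms"] == pytest.approx(
            (ts[-1] - ts[0]) / (ts.size - 1) * 1000.0)

    def test_insufficient_spikes_yield_none_with_reason(self):
        ev = CandidateEvent(0.0, 0.05, ["a"])
        out = event_isis(ev, {"a": np.array([0.01])})
        assert out["population_isi_ms"] is None
        assert out["reason"]


class TestPsth:
    def test_spike_count_and_rate_arithmetic(self, cfg):
        # unit fires exactly 3 spikes in each 150 ms event it joins
        events = [CandidateEvent(10.0, 10.15, ["a"], "rest2"),
                  CandidateEvent(20.0, 20.15, ["a"], "rest2")]
        spikes = {"a": [10.01, 10.05, 10.10, 20.02, 20.06, 20.11],
                  "b": [5.0]}
        s = _rest_session(spikes)
        out = replay_psth(s, events, cfg)
        ua = out["units"]["a"]
        assert ua["spikes_per_event"] == pytest.approx(3.0)
        assert ua["in_event_rate_hz"] == pytest.approx(20.0)
        assert ua["n_events"] == 2

    def test_nonparticipant_excluded_with_reason(self, cfg):
        events = [CandidateEvent(10.0, 10.15, ["a"], "rest2")]
        spikes = {"a": [10.01, 10.05], "b": [5.0]}
        out = replay_psth(_rest_session(spikes), events, cfg)
        assert out["units"]["b"]["psth_hz"] is None
        assert out["units"]["b"]["reason"]
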