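"""Synthetic circular-track sessions with known ground truth.

The generator emulates the statistical structure the analyses assume:

* run epochs — a rat running unidirectionally at ~34 cm/s on a 1-m-diameter
  track, units with Gaussian place tuning, a 6-10 Hz theta LFP, and spiking
  from an inhomogeneous Poisson process that is theta-modulated with either
  (a) an explicit phase-precession model (preferred phase advancing linearly
  with normalized position through the field) or (b) a within-cycle "sweep"
  model in which the represented position runs ahead of/behind the rat at a
  scripted speed, producing compressed theta sequences of known slope;
* rest epochs — sparse baseline firing plus scripted replay events in which
  units fire in field-center order along a scripted trajectory at a
  controllable speed, with 150-250 Hz ripple bursts enveloped onto the LFP.

All randomness derives from a single seed through ``numpy.random.SeedSequence``
so a day is bit-identical under a fixed seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.special import i0

from .circular import circ_dist_deg, signed_delta_deg, wrap_deg
from .session import (
    DEFAULT_CIRCUMFERENCE_CM,
    EpochSpec,
    LfpChannel,
    PositionTrace,
    Session,
    SpikeTrain,
    compute_speed,
)

__all__ = [
    "GroundTruth",
    "ReplayEventSpec",
    "preset",
    "simulate_run_epoch",
    "simulate_rest_epoch",
    "make_day",
    "run_intensity",
]


@dataclass
class ReplayEventSpec:
    """One scripted rest-period replay event (times relative to epoch start)."""

    start_s: float
    duration_s: float
    start_angle_deg: float
    speed_deg_per_s: float
    direction: int = 1  # +1 forward (running direction), -1 reverse

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s

    @property
    def path_deg(self) -> float:
        return self.speed_deg_per_s * self.duration_s


@dataclass
class GroundTruth:
    """Scripted parameters of a synthetic day.

    Defaults describe a wild-type-like animal: four 10-min unidirectional run
    sessions at ~34 cm/s interleaved with five 10-min rests, 60 place cells
    with ~36-deg fields and 15 Hz peak rates, 8 Hz theta with one full cycle
    of phase precession per field, and 200 Hz ripples during replay.
    """

    n_units: int = 60
    field_center_deg: np.ndarray | None = None  # default: evenly spaced
    field_width_deg: float = 36.0               # ~31 cm fields
    peak_rate_hz: float = 15.0
    baseline_run_hz: float = 0.1
    baseline_rest_hz: float = 0.2
    run_speed_cm_s: float = 34.0
    speed_mod_frac: float = 0.1                 # slow sinusoidal speed jitter
    tracker_noise_deg: float = 0.25
    theta_f_hz: float = 8.0
    theta_amp_uv: float = 300.0
    noise_amp_uv: float = 60.0                  # 1/f LFP noise SD
    # phase-precession model (used when seq_sweep_deg_per_s is None)
    precession_phi0_deg: float = 360.0
    precession_slope_deg_per_field: float = -360.0
    precession_kappa: float = 2.0
    # scripted-sequence ("sweep") model
    seq_sweep_deg_per_s: float | None = None
    seq_envelope_kappa: float = 0.5
    # rest / replay
    replay_events_per_rest: int = 12
    replay_speed_mean_deg_s: float = 600.0
    replay_speed_sd_deg_s: float = 80.0
    replay_duration_s: float = 0.2
    spikes_per_crossing: float = 3.0
    replay_jitter_ms: float = 3.0
    event_guard_s: float = 0.05   # baseline quiescence flanking each burst
    ripple_f_hz: float = 200.0
    ripple_amp_uv: float = 150.0
    # sampling / geometry
    lfp_fs_hz: float = 2000.0
    pos_fs_hz: float = 29.97
    track_circumference_cm: float = DEFAULT_CIRCUMFERENCE_CM
    run_duration_s: float = 600.0
    rest_duration_s: float = 600.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.field_width_deg <= 0:
            raise ValueError("field_width_deg must be positive")
        if self.field_center_deg is None:
            self.field_center_deg = wrap_deg(
                np.arange(self.n_units) * 360.0 / self.n_units)
        else:
            self.field_center_deg = wrap_deg(np.asarray(self.field_center_deg, float))
            self.n_units = self.field_center_deg.size

    @property
    def run_speed_deg_s(self) -> float:
        return self.run_speed_cm_s * 360.0 / self.track_circumference_cm

    @property
    def seq_compression(self) -> float | None:
        """Decoded cm/s per real cm/s under the sweep model (None otherwise)."""
        if self.seq_sweep_deg_per_s is None:
            return None
        return self.seq_sweep_deg_per_s / self.run_speed_deg_s

    def unit_ids(self):
        return [f"u{j:03d}" for j in range(self.n_units)]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["field_center_deg"] = [float(v) for v in self.field_center_deg]
        return {k: (float(v) if isinstance(v, (np.floating,)) else v)
                for k, v in d.items()}


def preset(name: str, seed: int = 0, **overrides) -> GroundTruth:
    """Named parameter sets.

    ``"wt"`` — fast scripted dynamics: theta sweeps at 600 deg/s, replay at
    ~600 deg/s lasting ~0.2 s, 200 Hz ripples.
    ``"fxs"`` — slowed dynamics: sweeps at 350 deg/s, replay at ~330 deg/s
    lasting ~0.42 s, 175 Hz ripples. Spike count per event is unchanged, so
    in-event rates drop and interspike intervals stretch.
    """
    base = dict(rng_seed=seed)
    if name == "wt":
        base.update(seq_sweep_deg_per_s=600.0, replay_speed_mean_deg_s=600.0,
                    replay_speed_sd_deg_s=80.0, replay_duration_s=0.2,
                    ripple_f_hz=200.0)
    elif name == "fxs":
        base.update(seq_sweep_deg_per_s=350.0, replay_speed_mean_deg_s=330.0,
                    replay_speed_sd_deg_s=50.0, replay_duration_s=0.42,
                    ripple_f_hz=175.0)
    else:
        raise ValueError(f"unknown preset {name!r}; use 'wt' or 'fxs'")
    base.update(overrides)
    return GroundTruth(**base)


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _pink_noise(n, fs, amp, rng):
    """Gaussian 1/f ("pink") noise with standard deviation ``amp``."""
    if n == 0:
        return np.zeros(0)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    x = np.fft.irfft(spec * scale, n=n)
    sd = x.std()
    return x * (amp / sd) if sd > 0 else x


def _norm_field_pos(angle_deg, center_deg, width_deg):
    """Normalized position through the field, clipped to [0, 1]."""
    d = signed_delta_deg(angle_deg, center_deg) / width_deg + 0.5
    return np.clip(d, 0.0, 1.0)


def run_intensity(gt: GroundTruth, t, angle_unwrapped_deg):
    """Scripted firing intensity (Hz) of every unit along a run trajectory.

    Returns an (n_units, len(t)) matrix; the same function drives spike
    generation, so integrating it over time gives the expected spike counts.
    """
    t = np.asarray(t, float)
    phase = (360.0 * gt.theta_f_hz * t) % 360.0
    sigma = gt.field_width_deg / 4.0
    rates = np.empty((gt.n_units, t.size))
    if gt.seq_sweep_deg_per_s is not None:
        # represented position sweeps ahead within each theta cycle,
        # resetting at phase 0 (cycle center at phase 180)
        period = 1.0 / gt.theta_f_hz
        t_in_cycle = (t % period) - period / 2.0
        rep = angle_unwrapped_deg + gt.seq_sweep_deg_per_s * t_in_cycle
        kap = gt.seq_envelope_kappa
        env = np.exp(kap * np.cos(np.deg2rad(phase - 180.0))) / i0(kap)
        for j in range(gt.n_units):
            dist = circ_dist_deg(rep, gt.field_center_deg[j])
            g = np.exp(-(dist**2) / (2.0 * sigma**2))
            rates[j] = gt.peak_rate_hz * g * env + gt.baseline_run_hz
    else:
        kap = gt.precession_kappa
        for j in range(gt.n_units):
            dist = circ_dist_deg(angle_unwrapped_deg, gt.field_center_deg[j])
            g = np.exp(-(dist**2) / (2.0 * sigma**2))
            d = _norm_field_pos(angle_unwrapped_deg, gt.field_center_deg[j],
                                gt.field_width_deg)
            pref = gt.precession_phi0_deg + gt.precession_slope_deg_per_field * d
            mod = np.exp(kap * np.cos(np.deg2rad(phase - pref))) / i0(kap)
            rates[j] = gt.peak_rate_hz * g * mod + gt.baseline_run_hz
    return rates


def _max_intensity(gt: GroundTruth) -> float:
    kap = (gt.seq_envelope_kappa if gt.seq_sweep_deg_per_s is not None
           else gt.precession_kappa)
    return gt.peak_rate_hz * np.exp(kap) / i0(kap) + gt.baseline_run_hz


@dataclass
class EpochData:
    """Raw products of one simulated epoch, in epoch-local time."""

    trace: PositionTrace
    spikes: dict                    # unit_id -> spike times (s)
    lfp: np.ndarray
    events: list = dc_field(default_factory=list)           # ReplayEventSpec
    ripple_intervals: list = dc_field(default_factory=list)  # (start, end) s


# ---------------------------------------------------------------------------
# epoch simulators
# ---------------------------------------------------------------------------

def simulate_run_epoch(gt: GroundTruth, duration_s: float | None = None,
                       seed=None) -> EpochData:
    """One unidirectional running epoch with theta LFP and place-tuned spikes.

    Spikes are drawn by thinning a homogeneous Poisson process at the
    intensity ceiling, which is exact for the scripted intensity.
    """
    duration_s = gt.run_duration_s if duration_s is None else float(duration_s)
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(gt.rng_seed if seed is None else seed)

    # ideal trajectory: constant speed with a slow sinusoidal modulation
    n_pos = int(np.floor(duration_s * gt.pos_fs_hz))
    t_pos = np.arange(n_pos) / gt.pos_fs_hz
    v0 = gt.run_speed_deg_s
    mod_f = 0.05  # Hz
    mod_phi = rng.uniform(0, 2 * np.pi)
    x0 = rng.uniform(0, 360.0)
    # angle(t) = x0 + v0*t - (v0*mod/(2 pi f)) * (cos(2 pi f t + phi) - cos(phi))
    def ideal_angle(ts):
        ts = np.asarray(ts, float)
        return (x0 + v0 * ts
                - v0 * gt.speed_mod_frac / (2 * np.pi * mod_f)
                * (np.cos(2 * np.pi * mod_f * ts + mod_phi) - np.cos(mod_phi)))

    angle_ideal = ideal_angle(t_pos)
    observed = wrap_deg(angle_ideal + rng.normal(0, gt.tracker_noise_deg, n_pos))
    trace = PositionTrace(t_pos, observed)

    # spikes by Poisson thinning
    lam_max = _max_intensity(gt)
    spikes = {}
    for j, uid in enumerate(gt.unit_ids()):
        n_cand = rng.poisson(lam_max * duration_s)
        t_cand = np.sort(rng.uniform(0, duration_s, n_cand))
        if n_cand == 0 or gt.peak_rate_hz + gt.baseline_run_hz == 0:
            spikes[uid] = np.empty(0)
            continue
        gt_j = dataclasses.replace(gt, field_center_deg=gt.field_center_deg[[j]])
        lam = run_intensity(gt_j, t_cand, ideal_angle(t_cand))[0]
        keep = rng.uniform(0, 1, n_cand) < lam / lam_max
        spikes[uid] = t_cand[keep]

    # LFP: theta sinusoid (phase 0 at peak) + 1/f noise
    n_lfp = int(np.floor(duration_s * gt.lfp_fs_hz))
    t_lfp = np.arange(n_lfp) / gt.lfp_fs_hz
    lfp = (gt.theta_amp_uv * np.cos(2 * np.pi * gt.theta_f_hz * t_lfp)
           + _pink_noise(n_lfp, gt.lfp_fs_hz, gt.noise_amp_uv, rng))
    return EpochData(trace, spikes, lfp)


def schedule_replay_events(gt: GroundTruth, duration_s: float, rng) -> list:
    """Draw non-overlapping replay events for one rest epoch."""
    n = gt.replay_events_per_rest
    events = []
    if n == 0:
        return events
    slot = duration_s / n
    for k in range(n):
        dur = gt.replay_duration_s * rng.uniform(0.8, 1.2)
        speed = max(50.0, rng.normal(gt.replay_speed_mean_deg_s,
                                     gt.replay_speed_sd_deg_s))
        lo = k * slot + 0.25 * slot
        start = lo + rng.uniform(0, max(slot * 0.5 - dur, 1e-3))
        events.append(ReplayEventSpec(
            start_s=start, duration_s=dur,
            start_angle_deg=rng.uniform(0, 360.0),
            speed_deg_per_s=speed,
            direction=1 if rng.uniform() < 0.7 else -1,
        ))
    return events


def simulate_rest_epoch(gt: GroundTruth, duration_s: float | None = None,
                        events: list | None = None, seed=None) -> EpochData:
    """One rest epoch: sparse baseline firing, scripted replay, ripple LFP.

    During each scripted event, units fire (Poisson-many spikes with a few ms
    of jitter) as the scripted trajectory crosses their field centers, and the
    LFP gains amplitude-enveloped ripple bursts.
    """
    duration_s = gt.rest_duration_s if duration_s is None else float(duration_s)
    rng = np.random.default_rng(gt.rng_seed if seed is None else seed)
    if events is None:
        events = schedule_replay_events(gt, duration_s, rng)
    events = sorted(events, key=lambda e: e.start_s)
    for a, b in zip(events, events[1:]):
        if b.start_s < a.end_s:
            raise ValueError("scripted replay events overlap")
    for e in events:
        if e.start_s < 0 or e.end_s > duration_s:
            raise ValueError("scripted replay event outside the epoch")

    # stationary position (rat in the flowerpot off the track)
    n_pos = int(np.floor(duration_s * gt.pos_fs_hz))
    t_pos = np.arange(n_pos) / gt.pos_fs_hz
    trace = PositionTrace(
        t_pos, wrap_deg(rng.normal(0.0, 0.05, n_pos)))

    # baseline firing, silenced in a guard interval around each scripted
    # event (population bursts are flanked by network quiescence)
    spikes = {}
    for uid in gt.unit_ids():
        base = rng.uniform(0, duration_s, rng.poisson(
            gt.baseline_rest_hz * duration_s))
        for e in events:
            base = base[(base < e.start_s - gt.event_guard_s)
                        | (base > e.end_s + gt.event_guard_s)]
        spikes[uid] = [base]
    for e in events:
        for j, uid in enumerate(gt.unit_ids()):
            # times at which the scripted trajectory crosses this field center
            delta = (e.direction * (gt.field_center_deg[j] - e.start_angle_deg)) % 360.0
            k = 0
            while True:
                t_cross = e.start_s + (delta + 360.0 * k) / e.speed_deg_per_s
                if t_cross > e.end_s:
                    break
                n_spk = rng.poisson(gt.spikes_per_crossing)
                if n_spk:
                    ts = t_cross + rng.normal(0, gt.replay_jitter_ms / 1000.0, n_spk)
                    spikes[uid].append(np.clip(ts, e.start_s, e.end_s))
                k += 1
    spikes = {uid: np.sort(np.concatenate(parts)) for uid, parts in spikes.items()}

    # LFP: 1/f noise with ripple bursts enveloped onto each event
    n_lfp = int(np.floor(duration_s * gt.lfp_fs_hz))
    t_lfp = np.arange(n_lfp) / gt.lfp_fs_hz
    lfp = _pink_noise(n_lfp, gt.lfp_fs_hz, gt.noise_amp_uv, rng)
    ripple_intervals = []
    burst_len, burst_period = 0.08, 0.12
    for e in events:
        n_burst = max(1, int(np.floor(e.duration_s / burst_period)))
        for b in range(n_burst):
            b0 = e.start_s + b * burst_period
            b1 = min(b0 + burst_len, e.end_s)
            if b1 - b0 < 0.02:
                continue
            i0_, i1_ = int(b0 * gt.lfp_fs_hz), int(b1 * gt.lfp_fs_hz)
            seg_t = t_lfp[i0_:i1_]
            env = np.hanning(seg_t.size)
            lfp[i0_:i1_] += (gt.ripple_amp_uv * env
                             * np.cos(2 * np.pi * gt.ripple_f_hz * seg_t))
            ripple_intervals.append((b0, b1))
    return EpochData(trace, spikes, lfp, events=events,
                     ripple_intervals=ripple_intervals)


# ---------------------------------------------------------------------------
# day assembly
# ---------------------------------------------------------------------------

def make_day(gt: GroundTruth, run_duration_s: float | None = None,
             rest_duration_s: float | None = None) -> Session:
    """Assemble a full day: rest1, run1, rest2, ..., run4, rest5.

    Epochs are contiguous from t = 0. The scripted ground truth (field
    centers, sweep/replay parameters, absolute event and ripple times) is
    attached to ``Session.ground_truth``.
    """
    run_dur = gt.run_duration_s if run_duration_s is None else float(run_duration_s)
    rest_dur = gt.rest_duration_s if rest_duration_s is None else float(rest_duration_s)
    ss = np.random.SeedSequence(gt.rng_seed)
    child = ss.spawn(9)

    labels, durations = [], []
    for i in range(4):
        labels += [f"rest{i + 1}", f"run{i + 1}"]
        durations += [rest_dur, run_dur]
    labels.append("rest5")
    durations.append(rest_dur)

    t_cursor = 0.0
    schedule, traces_t, traces_a = [], [], []
    spike_parts = {uid: [] for uid in gt.unit_ids()}
    lfp_parts = []
    abs_events, abs_ripples = [], []
    for i, (label, dur) in enumerate(zip(labels, durations)):
        if label.startswith("run"):
            ep = simulate_run_epoch(gt, dur, seed=child[i])
        else:
            ep = simulate_rest_epoch(gt, dur, seed=child[i])
            for e in ep.events:
                abs_events.append({
                    "rest_label": label,
                    "start_s": float(t_cursor + e.start_s),
                    "duration_s": float(e.duration_s),
                    "start_angle_deg": float(e.start_angle_deg),
                    "speed_deg_per_s": float(e.speed_deg_per_s),
                    "direction": int(e.direction),
                })
            abs_ripples += [(float(t_cursor + a), float(t_cursor + b))
                            for a, b in ep.ripple_intervals]
        schedule.append(EpochSpec(label, t_cursor, t_cursor + dur))
        traces_t.append(ep.trace.t + t_cursor)
        traces_a.append(ep.trace.angle_deg)
        for uid, ts in ep.spikes.items():
            spike_parts[uid].append(ts + t_cursor)
        lfp_parts.append(ep.lfp)
        t_cursor += dur

    trace = PositionTrace(np.concatenate(traces_t), np.concatenate(traces_a))
    trace = compute_speed(trace, gt.track_circumference_cm)
    units = []
    total = t_cursor
    for uid in gt.unit_ids():
        st = np.sort(np.concatenate(spike_parts[uid]))
        units.append(SpikeTrain(uid, st, mean_rate_hz=st.size / total,
                                is_interneuron=st.size / total > 5.0))
    lfp = [LfpChannel(gt.lfp_fs_hz, np.concatenate(lfp_parts), t0=0.0)]

    gt_dict = gt.to_dict()
    gt_dict["replay_events"] = abs_events
    gt_dict["ripple_intervals"] = [list(r) for r in abs_ripples]
    return Session(trace, units, lfp, schedule,
                   track_circumference_cm=gt.track_circumference_cm,
                   ground_truth=gt_dict)
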