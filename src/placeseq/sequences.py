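"""Theta-sequence detection: cycle segmentation, within-cycle decoding,
circular-linear trajectory fits, and a circular-shuffle significance test.

Individual theta cycles are cut at the theta phase carrying the fewest
place-cell spikes (so bursts are never split). Qualifying cycles (>= 3 active
place cells, speed at or above the gate) are decoded in 40 ms windows stepped
by 10 ms; the longest stretch of windows uninterrupted by two consecutive
spikeless windows is fit with a circular-linear regression of the posterior
center of mass against time. Significance requires the fit's r^2 to exceed
95% of 1,000 circular shuffles of the posterior, 60% of posterior mass within
20 deg of the line, and the line to pass within 20 deg of the actual position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .circular import (best_slope_batch, circ_dist_deg, r2_batch)
from .config import AnalysisConfig
from .decoder import DecodedPosterior, TuningModel, decode, make_windows
from .session import DEFAULT_CIRCUMFERENCE_CM, Session
from .theta import PhaseSeries, theta_filter_phase

__all__ = [
    "ThetaCycle",
    "SequenceFit",
    "segment_theta_cycles",
    "fit_decoded_trajectory",
    "shuffle_test",
    "detect_theta_sequences",
    "longest_contiguous_run",
]


@dataclass
class ThetaCycle:
    start_s: float
    end_s: float
    n_active_cells: int = 0
    mean_speed_cm_s: float = np.nan

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class SequenceFit:
    """Circular-linear fit of decoded positions against time.

    Houses both theta-sequence and replay fits. Spatial quantities are kept
    in degrees with cm twins via the track circumference.
    """

    slope_deg_per_s: float
    slope_cm_per_s: float
    x_span_deg: float
    x_span_cm: float
    t_span_s: float
    r2: float
    intercept_deg: float
    n_windows: int
    window_centers_s: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    com_deg: np.ndarray = dc_field(default_factory=lambda: np.empty(0))
    shuffle_p: float = np.nan
    prob_near_line_frac: float = np.nan
    min_dist_to_actual_deg: float = np.nan
    significant: bool = False
    start_s: float = np.nan
    end_s: float = np.nan
    reason: str = ""

    def line_deg(self, times=None) -> np.ndarray:
        t = self.window_centers_s if times is None else np.asarray(times, float)
        t0 = self.window_centers_s[0] if self.window_centers_s.size else 0.0
        return (self.intercept_deg + self.slope_deg_per_s * (t - t0)) % 360.0


def segment_theta_cycles(phases: PhaseSeries, spike_times, trace=None,
                         cfg: AnalysisConfig | None = None,
                         t_range=None) -> tuple:
    """Cut theta cycles at the phase with the fewest spikes.

    ``spike_times`` — pooled place-cell spike times used to build the
    spike-phase histogram (20-deg bins; ties broken toward the smallest
    phase). Cycle boundaries are the times at which the unwrapped theta phase
    crosses the cutting phase.

    Returns (cycles, cutting_phase_deg).
    """
    cfg = cfg or AnalysisConfig()
    spike_times = np.asarray(spike_times, float)
    if t_range is not None:
        spike_times = spike_times[(spike_times >= t_range[0])
                                  & (spike_times <= t_range[1])]
    if spike_times.size == 0:
        raise ValueError("no spikes available to locate the cutting phase")
    sp_phase = phases.at(spike_times)
    n_ph_bins = int(round(360.0 / cfg.cycle_phase_bin_deg))
    hist, edges = np.histogram(sp_phase, bins=np.linspace(0, 360, n_ph_bins + 1))
    cut_phase = edges[int(np.argmin(hist))] + cfg.cycle_phase_bin_deg / 2.0

    unw = np.maximum.accumulate(phases.unwrapped_deg)
    t = phases.t
    if t_range is not None:
        m = (t >= t_range[0]) & (t <= t_range[1])
        t, unw = t[m], unw[m]
    if t.size < 2:
        return [], cut_phase
    k0 = int(np.ceil((unw[0] - cut_phase) / 360.0))
    k1 = int(np.floor((unw[-1] - cut_phase) / 360.0))
    targets = cut_phase + 360.0 * np.arange(k0, k1 + 1)
    if targets.size < 2:
        return [], cut_phase
    bounds = np.interp(targets, unw, t)
    cycles = [ThetaCycle(float(a), float(b)) for a, b in zip(bounds, bounds[1:])]
    return cycles, float(cut_phase)


def longest_contiguous_run(n_spikes_per_window, gap_bins: int = 2) -> np.ndarray:
    """Indices of the longest stretch of windows not containing ``gap_bins``
    consecutive spikeless windows. Spikeless windows shorter than the gap are
    retained inside a stretch but trimmed from its edges."""
    z = np.asarray(n_spikes_per_window) == 0
    n = z.size
    segments, seg_start, zero_run = [], 0, 0
    for i in range(n):
        if z[i]:
            zero_run += 1
            if zero_run == gap_bins:
                end = i - gap_bins + 1
                if end > seg_start:
                    segments.append((seg_start, end))
                seg_start = i + 1
        else:
            if zero_run >= gap_bins:
                seg_start = i
            zero_run = 0
    if seg_start < n and not (zero_run >= gap_bins and seg_start >= n):
        segments.append((seg_start, n))
    best = np.empty(0, dtype=int)
    for a, b in segments:
        idx = np.arange(a, b)
        idx = idx[~z[idx]] if idx.size else idx
        if idx.size:
            idx = np.arange(idx[0], idx[-1] + 1)  # keep interior zeros
        if idx.size > best.size:
            best = idx
    return best


def fit_decoded_trajectory(posterior: DecodedPosterior,
                           slope_bounds=(-3000.0, 3000.0),
                           circumference_cm: float = DEFAULT_CIRCUMFERENCE_CM,
                           weights=None) -> SequenceFit:
    """Circular-linear regression of per-window posterior COM against time.

    x-span is |slope| * t-span (the regression line's own extent), reported
    in degrees and cm; t-span is center-to-center.
    """
    com = posterior.com_deg()
    centers = posterior.window_centers_s
    ok = np.isfinite(com)
    if not ok.all():
        warnings.warn("dropping degenerate decoding windows")
        com, centers = com[ok], centers[ok]
    if com.size < 2:
        raise ValueError("need at least 2 usable windows to fit a trajectory")
    t_rel = centers - centers[0]
    slope = best_slope_batch(com[None, :], t_rel, slope_bounds, weights=weights)[0]
    r2, intercept = r2_batch(com[None, :], t_rel, np.array([slope]), weights=weights)
    t_span = float(t_rel[-1])
    x_span = abs(slope) * t_span
    deg2cm = circumference_cm / 360.0
    return SequenceFit(
        slope_deg_per_s=float(slope),
        slope_cm_per_s=float(slope) * deg2cm,
        x_span_deg=float(x_span),
        x_span_cm=float(x_span) * deg2cm,
        t_span_s=t_span,
        r2=float(r2[0]),
        intercept_deg=float(intercept[0]),
        n_windows=int(com.size),
        window_centers_s=centers,
        com_deg=com,
        start_s=float(posterior.windows[0, 0]),
        end_s=float(posterior.windows[-1, 1]),
    )


def shuffle_test(posterior: DecodedPosterior, fit: SequenceFit,
                 n: int = 1000, seed=0,
                 slope_bounds=(-3000.0, 3000.0)) -> float:
    """Circular-shuffle significance of a trajectory fit.

    Each of ``n`` shuffles rotates every window's posterior circularly by an
    independent uniform number of bins and refits. Rotating a posterior by k
    bins rotates its circular center of mass by exactly k bin widths, so the
    refit operates on offset COM angles; the two-stage slope grid matches the
    observed fit. Returns the fraction of shuffles with r^2 >= observed.
    """
    rng = np.random.default_rng(seed)
    com = fit.com_deg
    t_rel = fit.window_centers_s - fit.window_centers_s[0]
    n_bins = posterior.posterior.shape[1]
    bin_deg = 360.0 / n_bins
    offsets = rng.integers(0, n_bins, size=(n, com.size)) * bin_deg
    shuffled = (com[None, :] + offsets) % 360.0
    slopes = best_slope_batch(shuffled, t_rel, slope_bounds)
    r2s, _ = r2_batch(shuffled, t_rel, slopes)
    return float(np.mean(r2s >= fit.r2))


def _mass_near_line(posterior: DecodedPosterior, fit: SequenceFit,
                    dist_deg: float) -> float:
    """Fraction of total posterior probability within dist_deg of the line."""
    line = fit.line_deg()
    d = circ_dist_deg(posterior.bin_centers_deg[None, :], line[:, None])
    mass = posterior.posterior * (d <= dist_deg)
    return float(mass.sum() / posterior.posterior.sum())


def null_calibration(model: TuningModel, n_cycles: int = 300,
                     n_shuffle: int = 200, seed: int = 0,
                     cfg: AnalysisConfig | None = None,
                     cycle_s: float = 0.125, rate_hz: float = 4.0) -> dict:
    """False-positive rates of the significance procedure on structureless
    cycles.

    Each synthetic cycle holds independent uniform spike times (every unit a
    homogeneous Poisson at ``rate_hz``), so the decoded posterior carries no
    trajectory. Returns ``{"full_rate", "shuffle_rate", "n_cycles"}``:
    the fraction of cycles passing the complete criterion stack (shuffle test
    on r^2 + posterior-mass concentration + proximity to a random "actual"
    position), and the fraction passing the circular-shuffle test alone,
    which should sit at the nominal alpha up to binomial noise.
    """
    cfg = cfg or AnalysisConfig()
    rng = np.random.default_rng(seed)
    n_sig = n_shuf_sig = n_done = 0
    while n_done < n_cycles:
        trains = [np.sort(rng.uniform(0, cycle_s, rng.poisson(rate_hz * cycle_s)))
                  for _ in model.unit_ids]
        active = sum(1 for t in trains if t.size)
        if active < cfg.seq_min_cells:
            continue
        windows = make_windows(0.0, cycle_s, cfg.seq_win_s, cfg.seq_step_s)
        post = decode(model, trains, windows, cfg)
        idx = longest_contiguous_run(post.n_spikes_per_window, cfg.seq_gap_bins)
        if idx.size < 3:
            continue
        sub = DecodedPosterior(
            post.window_centers_s[idx], post.windows[idx],
            post.posterior[idx], post.n_active_per_window[idx],
            post.n_spikes_per_window[idx], post.bin_centers_deg)
        fit = fit_decoded_trajectory(sub, cfg.seq_slope_bounds)
        p = shuffle_test(sub, fit, n=n_shuffle,
                         seed=rng.integers(0, 2**31 - 1),
                         slope_bounds=cfg.seq_slope_bounds)
        frac = _mass_near_line(sub, fit, cfg.seq_prob_dist_deg)
        actual = rng.uniform(0, 360.0)
        min_dist = float(np.min(circ_dist_deg(fit.line_deg(), actual)))
        if p < cfg.seq_alpha:
            n_shuf_sig += 1
            if frac >= cfg.seq_prob_frac and min_dist < cfg.seq_actual_dist_deg:
                n_sig += 1
        n_done += 1
    return {"full_rate": n_sig / n_cycles,
            "shuffle_rate": n_shuf_sig / n_cycles,
            "n_cycles": n_cycles}


def detect_theta_sequences(session: Session, model: TuningModel,
                           cfg: AnalysisConfig | None = None,
                           lfp_channel: int = 0,
                           n_shuffle: int | None = None,
                           progress: bool = False) -> list:
    """Detect and score theta sequences across the day's run epochs.

    Runs the full pipeline: theta phase, cycle segmentation per run epoch,
    activity and speed gating, within-cycle decoding, trajectory fits,
    circular-shuffle significance plus the posterior-concentration and
    actual-position-proximity criteria. Cycles failing gates are skipped.
    """
    cfg = cfg or AnalysisConfig()
    n_shuffle = cfg.seq_n_shuffle if n_shuffle is None else n_shuffle
    phases = theta_filter_phase(session.lfp[lfp_channel], cfg.theta_band, cfg)
    trace = session.position
    unwrapped_angle = np.rad2deg(np.unwrap(np.deg2rad(trace.angle_deg)))
    spikes = {u.unit_id: u.spike_t for u in session.units}
    trains = [spikes[uid] for uid in model.unit_ids]

    # pooled place-cell spikes at gated speeds, for the cutting phase
    pooled = []
    for ep in session.epochs("run"):
        for st in trains:
            s = st[(st >= ep.start_s) & (st <= ep.end_s)]
            if s.size:
                sp = np.interp(s, trace.t, trace.speed_cm_s)
                pooled.append(s[~(sp < cfg.speed_min)])
    if not pooled:
        return []
    pooled = np.sort(np.concatenate(pooled))

    results = []
    rng = np.random.default_rng(cfg.rng_seed)
    for ep in session.epochs("run"):
        cycles, _ = segment_theta_cycles(
            phases, pooled, cfg=cfg, t_range=(ep.start_s, ep.end_s))
        for cyc in cycles:
            active = sum(1 for st in trains
                         if np.any((st >= cyc.start_s) & (st < cyc.end_s)))
            cyc.n_active_cells = active
            m = (trace.t >= cyc.start_s) & (trace.t <= cyc.end_s)
            cyc.mean_speed_cm_s = (float(trace.speed_cm_s[m].mean())
                                   if m.any() else
                                   float(np.interp(cyc.start_s, trace.t,
                                                   trace.speed_cm_s)))
            if active < cfg.seq_min_cells or cyc.mean_speed_cm_s < cfg.speed_min:
                continue
            windows = make_windows(cyc.start_s, cyc.end_s,
                                   cfg.seq_win_s, cfg.seq_step_s)
            if windows.shape[0] < 3:
                continue
            post = decode(model, trains, windows, cfg)
            idx = longest_contiguous_run(post.n_spikes_per_window, cfg.seq_gap_bins)
            if idx.size < 3:
                continue
            sub = DecodedPosterior(
                post.window_centers_s[idx], post.windows[idx],
                post.posterior[idx], post.n_active_per_window[idx],
                post.n_spikes_per_window[idx], post.bin_centers_deg)
            fit = fit_decoded_trajectory(
                sub, cfg.seq_slope_bounds, session.track_circumference_cm)
            fit.shuffle_p = shuffle_test(
                sub, fit, n=n_shuffle,
                seed=rng.integers(0, 2**31 - 1),
                slope_bounds=cfg.seq_slope_bounds)
            fit.prob_near_line_frac = _mass_near_line(sub, fit, cfg.seq_prob_dist_deg)
            actual = np.interp(sub.window_centers_s, trace.t, unwrapped_angle) % 360.0
            fit.min_dist_to_actual_deg = float(
                np.min(circ_dist_deg(fit.line_deg(), actual)))
            fit.significant = bool(
                fit.shuffle_p < cfg.seq_alpha
                and fit.prob_near_line_frac >= cfg.seq_prob_frac
                and fit.min_dist_to_actual_deg < cfg.seq_actual_dist_deg)
            results.append(fit)
    return results
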