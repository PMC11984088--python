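"""Rest-period replay: candidate population bursts, Bayesian classification,
per-cell firing around events, and interspike-interval measures.

Candidate events are excursions of the smoothed population firing rate
(1 ms bins, Gaussian sigma = 10 ms) above mean + 3 SD, bounded where the rate
crosses back through the mean, merged across gaps <= 40 ms, trimmed inward to
the first/last spike, and kept when lasting 50-2,000 ms with >= 5 cells
firing. Each candidate is decoded in 20 ms windows stepped by 10 ms, a
circular-linear line is fit to the per-window posterior center of mass, and
an event counts as replay when r^2 >= 0.5, no adjacent-window jump exceeds
25% of the track, and the event lies in rest sessions 2-5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .circular import circ_dist_deg
from .config import AnalysisConfig
from .decoder import DecodedPosterior, TuningModel, decode, make_windows
from .sequences import SequenceFit, fit_decoded_trajectory
from .session import DEFAULT_CIRCUMFERENCE_CM, EpochSpec, Session

__all__ = [
    "CandidateEvent",
    "ReplayResult",
    "detect_candidates",
    "classify_replay",
    "detect_replay",
    "replay_psth",
    "event_isis",
]

REPLAY_REST_LABELS = ("rest2", "rest3", "rest4", "rest5")


@dataclass
class CandidateEvent:
    start_s: float                 # trimmed inward to the first spike
    end_s: float                   # trimmed inward to the last spike
    participant_units: list
    rest_label: str = ""

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    @property
    def n_cells(self) -> int:
        return len(self.participant_units)


@dataclass
class ReplayResult:
    event: CandidateEvent
    fit: SequenceFit | None
    abs_slope_deg_per_s: float = np.nan
    abs_slope_cm_per_s: float = np.nan
    path_distance_deg: float = np.nan
    max_jump_frac: float = np.nan
    is_replay: bool = False
    reason: str = ""


def detect_candidates(session: Session, unit_ids, rest_epoch: EpochSpec,
                      cfg: AnalysisConfig | None = None) -> list:
    """Candidate population-burst events within one rest epoch.

    ``unit_ids`` — the units counted toward the population rate and the
    cell-participation rule (the cells active on the track). The rate mean
    and SD are computed over this rest epoch. No speed gate is applied:
    the rat rests off the track.
    """
    cfg = cfg or AnalysisConfig()
    by_id = {u.unit_id: u for u in session.units}
    trains = [by_id[uid].in_window(rest_epoch.start_s, rest_epoch.end_s)
              for uid in unit_ids]
    pooled = np.sort(np.concatenate([t for t in trains if t.size] or
                                    [np.empty(0)]))
    if pooled.size == 0:
        return []

    bin_s = cfg.psth_bin_s
    n_bins = int(np.ceil(rest_epoch.duration_s / bin_s))
    edges = rest_epoch.start_s + np.arange(n_bins + 1) * bin_s
    counts, _ = np.histogram(pooled, bins=edges)
    rate = gaussian_filter1d(counts.astype(float), cfg.psth_smooth_s / bin_s,
                             mode="nearest") / bin_s
    mu, sd = rate.mean(), rate.std()
    if sd == 0:
        return []
    above = rate > mu + cfg.replay_z * sd
    if not above.any():
        return []
    below_mean = rate < mu

    # boundary index of the nearest below-mean bin on each side
    idx = np.arange(n_bins)
    prev_below = np.where(below_mean, idx, -1)
    prev_below = np.maximum.accumulate(prev_below)
    next_below = np.where(below_mean, idx, n_bins)
    next_below = np.minimum.accumulate(next_below[::-1])[::-1]

    # contiguous above-threshold regions
    d = np.diff(above.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, n_bins]

    raw = []
    for s, e in zip(starts, ends):
        lo = prev_below[s] + 1
        hi = next_below[e - 1]  # exclusive
        raw.append((edges[lo], edges[min(hi, n_bins)]))
    # merge events separated by <= the merge gap
    merged = [list(raw[0])]
    for s, e in raw[1:]:
        if s - merged[-1][1] <= cfg.replay_merge_s:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    events = []
    lo_dur, hi_dur = cfg.replay_dur_s
    for s, e in merged:
        inside = pooled[(pooled >= s) & (pooled <= e)]
        if inside.size == 0:
            continue
        t0, t1 = float(inside[0]), float(inside[-1])  # trim inward to spikes
        if not (lo_dur <= t1 - t0 <= hi_dur):
            continue
        participants = [uid for uid, st in zip(unit_ids, trains)
                        if np.any((st >= t0) & (st <= t1))]
        if len(participants) < cfg.replay_min_cells:
            continue
        events.append(CandidateEvent(t0, t1, participants,
                                     rest_label=rest_epoch.label))
    return events


def classify_replay(event: CandidateEvent, model: TuningModel, spike_trains,
                    cfg: AnalysisConfig | None = None,
                    circumference_cm: float = DEFAULT_CIRCUMFERENCE_CM) -> ReplayResult:
    """Decode one candidate event and apply the replay criteria.

    ``spike_trains`` — dict unit_id -> spike times (model unit order applies).
    """
    cfg = cfg or AnalysisConfig()
    windows = make_windows(event.start_s, event.end_s,
                           cfg.replay_win_s, cfg.replay_step_s)
    if windows.shape[0] < 2:
        return ReplayResult(event, None, reason="fewer than 2 decoding windows")
    post = decode(model, spike_trains, windows, cfg)
    # activity gate: a window with no spikes decodes to the fixed
    # minimum of the summed tuning, not a represented position; drop it
    keep = post.n_spikes_per_window > 0
    if keep.sum() < 2:
        return ReplayResult(event, None, reason="fewer than 2 active windows")
    post = DecodedPosterior(
        post.window_centers_s[keep], post.windows[keep], post.posterior[keep],
        post.n_active_per_window[keep], post.n_spikes_per_window[keep],
        post.bin_centers_deg)
    fit = fit_decoded_trajectory(post, cfg.replay_slope_bounds, circumference_cm)
    com = fit.com_deg
    jumps = circ_dist_deg(com[1:], com[:-1])
    max_jump_frac = float(jumps.max() / 360.0) if jumps.size else 0.0
    path = float(circ_dist_deg(com[-1], com[0]))
    ok_rest = event.rest_label in REPLAY_REST_LABELS
    is_replay = bool(fit.r2 >= cfg.replay_r2_min
                     and max_jump_frac <= cfg.replay_jump_frac
                     and ok_rest)
    reasons = []
    if fit.r2 < cfg.replay_r2_min:
        reasons.append(f"r2 {fit.r2:.2f} < {cfg.replay_r2_min}")
    if max_jump_frac > cfg.replay_jump_frac:
        reasons.append(f"jump {max_jump_frac:.2f} > {cfg.replay_jump_frac}")
    if not ok_rest:
        reasons.append(f"{event.rest_label or 'unknown epoch'} outside rest 2-5")
    return ReplayResult(
        event=event, fit=fit,
        abs_slope_deg_per_s=abs(fit.slope_deg_per_s),
        abs_slope_cm_per_s=abs(fit.slope_cm_per_s),
        path_distance_deg=path,
        max_jump_frac=max_jump_frac,
        is_replay=is_replay,
        reason="; ".join(reasons),
    )


def detect_replay(session: Session, model: TuningModel,
                  cfg: AnalysisConfig | None = None) -> list:
    """Candidates from every rest epoch, classified. Convenience wrapper."""
    cfg = cfg or AnalysisConfig()
    spikes = {u.unit_id: u.spike_t for u in session.units}
    results = []
    for ep in session.epochs("rest"):
        for ev in detect_candidates(session, model.unit_ids, ep, cfg):
            results.append(classify_replay(ev, model, spikes, cfg,
                                           session.track_circumference_cm))
    return results


def replay_psth(session: Session, events: list,
                cfg: AnalysisConfig | None = None,
                t_before_s: float = 0.25, t_after_s: float = 0.5) -> dict:
    """Per-unit firing around replay-event onset, participation-matched.

    For each unit, only the events in which it fired are averaged: a 1 ms
    binned rate vector around onset smoothed with a 10 ms Gaussian, plus the
    mean in-event firing rate and mean spikes per participated event. Units
    participating in no event are reported with None entries.
    """
    cfg = cfg or AnalysisConfig()
    bin_s = cfg.psth_bin_s
    n_before = int(round(t_before_s / bin_s))
    n_after = int(round(t_after_s / bin_s))
    t_axis = (np.arange(-n_before, n_after) + 0.5) * bin_s
    out = {"time_s": t_axis, "units": {}}
    for u in session.units:
        rows, in_rates, counts = [], [], []
        for ev in events:
            spk = u.in_window(ev.start_s, ev.end_s)
            if spk.size == 0:
                continue
            rel = u.spike_t - ev.start_s
            hist, _ = np.histogram(
                rel, bins=np.arange(-n_before, n_after + 1) * bin_s)
            rows.append(hist / bin_s)
            in_rates.append(spk.size / ev.duration_s)
            counts.append(spk.size)
        if not rows:
            out["units"][u.unit_id] = {
                "psth_hz": None, "in_event_rate_hz": None,
                "spikes_per_event": None, "n_events": 0,
                "reason": "participated in no replay event"}
            continue
        mean_rate = np.mean(rows, axis=0)
        smoothed = gaussian_filter1d(mean_rate, cfg.psth_smooth_s / bin_s,
                                     mode="nearest")
        out["units"][u.unit_id] = {
            "psth_hz": smoothed,
            "in_event_rate_hz": float(np.mean(in_rates)),
            "spikes_per_event": float(np.mean(counts)),
            "n_events": len(rows),
            "reason": "",
        }
    return out


def event_isis(event: CandidateEvent, spike_trains: dict) -> dict:
    """Population and first-spike interspike intervals of one event (ms).

    population_isi — mean interval between consecutive pooled spikes of all
    participating cells; equals (last - first)/(n - 1) by telescoping.
    first_spike_isi — mean interval between consecutive per-cell first-spike
    times. Insufficient spikes yield None with a reason.
    """
    per_cell = [np.asarray(spike_trains[uid], float) for uid in event.participant_units]
    per_cell = [st[(st >= event.start_s) & (st <= event.end_s)] for st in per_cell]
    per_cell = [st for st in per_cell if st.size]
    pooled = np.sort(np.concatenate(per_cell)) if per_cell else np.empty(0)
    out = {"population_isi_ms": None, "first_spike_isi_ms": None, "reason": ""}
    if pooled.size >= 2:
        out["population_isi_ms"] = float(np.mean(np.diff(pooled)) * 1000.0)
    else:
        out["reason"] = "fewer than 2 spikes in event"
    firsts = np.sort([st[0] for st in per_cell])
    if firsts.size >= 2:
        out["first_spike_isi_ms"] = float(np.mean(np.diff(firsts)) * 1000.0)
    elif not out["reason"]:
        out["reason"] = "fewer than 2 participating cells"
    return out
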