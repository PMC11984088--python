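"""Day-level orchestration: run every analysis stage in order with gating,
collect tidy result tables, and compare two days metric by metric.

Stage order mirrors the acquisition-to-replay logic: behavior -> rate maps ->
place fields / stability / information -> phase precession -> decoding gate ->
theta sequences -> replay -> replay-associated LFP. Theta sequences and
replay are analyzed only on days whose decoding accuracy passes the gate
(median error < 20 deg), and replay statistics are restricted to rest
sessions 2-5.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field as dc_field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import ranksums

from .config import AnalysisConfig
from .decoder import TuningModel, decoding_accuracy
from .lfp import count_ripples_per_event, detect_ripples, event_band_metrics
from .ratemaps import (compute_rate_map, day_average_map, detect_place_fields,
                       rate_overlap, spatial_correlation, spatial_information)
from .replay import classify_replay, detect_candidates, event_isis, replay_psth
from .sequences import detect_theta_sequences
from .session import Session, behavior_metrics, load_session
from .theta import circular_linear_fit, spike_phases_in_field, theta_filter_phase

__all__ = ["DayReport", "run_day", "compare_presets"]


@dataclass
class DayReport:
    behavior: pd.DataFrame
    cells: pd.DataFrame            # per-unit SI, peak rate, fields
    stability: pd.DataFrame        # per unit x session pair
    precession: pd.DataFrame
    decoding: dict
    sequences: pd.DataFrame
    replay: pd.DataFrame
    psth: pd.DataFrame
    lfp: pd.DataFrame
    n_place_cells: int = 0
    config: dict = dc_field(default_factory=dict)
    seed: int = 0
    exclusions: list = dc_field(default_factory=list)

    def save(self, out_dir):
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("behavior", "cells", "stability", "precession",
                     "sequences", "replay", "psth", "lfp"):
            getattr(self, name).to_csv(out / f"{name}.csv", index=False)
        summary = {
            "n_place_cells": int(self.n_place_cells),
            "decoding_median_error_deg": float(self.decoding["median_error_deg"]),
            "decoding_passes_criterion": bool(self.decoding["passes_criterion"]),
            "n_theta_sequences": int(len(self.sequences)),
            "n_significant_sequences": int(self.sequences["significant"].sum())
            if len(self.sequences) else 0,
            "n_replay_events": int(self.replay["is_replay"].sum())
            if len(self.replay) else 0,
            "seed": int(self.seed),
            "exclusions": list(self.exclusions),
            "config": self.config,
        }
        (out / "summary.yaml").write_text(yaml.safe_dump(summary, sort_keys=False))
        return out


def run_day(session_or_dir, cfg: AnalysisConfig | None = None,
            n_shuffle: int | None = None, lfp_channel: int = 0) -> DayReport:
    """Run the full analysis on one recorded or synthetic day."""
    cfg = cfg or AnalysisConfig()
    session = (session_or_dir if isinstance(session_or_dir, Session)
               else load_session(session_or_dir, cfg))
    exclusions = []

    behavior = behavior_metrics(session, cfg)

    run_epochs = session.epochs("run")
    trace = session.position
    per_session_maps, day_maps = {}, {}
    for u in session.units:
        if u.is_interneuron:
            exclusions.append(f"{u.unit_id}: mean rate {u.mean_rate_hz:.2f} Hz "
                              f"> {cfg.interneuron_hz} Hz (putative interneuron)")
            continue
        maps = [compute_rate_map(u, trace, ep, cfg, session_label=ep.label)
                for ep in run_epochs]
        per_session_maps[u.unit_id] = maps
        day_maps[u.unit_id] = day_average_map(maps, cfg)

    included = {uid: m for uid, m in day_maps.items() if m.include_for_analysis}
    for uid, m in day_maps.items():
        if not m.include_for_analysis:
            exclusions.append(f"{uid}: day-map peak {m.peak_rate_hz:.2f} Hz < "
                              f"{cfg.peak_min_hz} Hz")

    cell_rows, stab_rows = [], []
    fields_by_unit = {}
    for uid, dmap in included.items():
        flds = detect_place_fields(dmap, cfg)
        fields_by_unit[uid] = flds
        si = spatial_information(dmap)
        cell_rows.append({
            "unit_id": uid,
            "mean_rate_hz": dmap.mean_rate_hz,
            "peak_rate_hz": dmap.peak_rate_hz,
            "spatial_information_bits": si,
            "n_fields": len(flds),
            "largest_field_deg": max((f.size_deg for f in flds), default=np.nan),
        })
        maps = per_session_maps[uid]
        for a, b in combinations(range(len(maps)), 2):
            stab_rows.append({
                "unit_id": uid,
                "pair": f"{maps[a].session_label}-{maps[b].session_label}",
                "spatial_correlation": spatial_correlation(maps[a], maps[b]),
                "rate_overlap": rate_overlap(maps[a], maps[b]),
            })
    cells = pd.DataFrame(cell_rows)
    stability = pd.DataFrame(stab_rows)

    # phase precession on the largest field of each included unit
    prec_rows = []
    if session.lfp:
        phases = theta_filter_phase(session.lfp[lfp_channel], cfg.theta_band, cfg)
        by_id = {u.unit_id: u for u in session.units}
        for uid, flds in fields_by_unit.items():
            if not flds:
                continue
            fld = max(flds, key=lambda f: f.size_deg)
            pos, ph = spike_phases_in_field(by_id[uid], fld, trace, phases,
                                            cfg, epochs=run_epochs)
            res = circular_linear_fit(pos, ph, unit_id=uid, cfg=cfg)
            prec_rows.append({
                "unit_id": uid, "n_spikes": res.n_spikes,
                "slope_deg_per_field": res.slope_deg_per_unit_pos,
                "r": res.r, "p_value": res.p_value,
                "included": res.included, "reason": res.reason,
            })
    precession = pd.DataFrame(prec_rows)

    empty_seq = pd.DataFrame(columns=[
        "start_s", "slope_deg_per_s", "slope_cm_per_s", "x_span_deg",
        "x_span_cm", "t_span_s", "r2", "shuffle_p", "prob_near_line_frac",
        "min_dist_to_actual_deg", "significant"])
    empty_rep = pd.DataFrame(columns=[
        "rest_label", "start_s", "duration_s", "n_cells", "r2",
        "abs_slope_deg_per_s", "abs_slope_cm_per_s", "path_distance_deg",
        "max_jump_frac", "is_replay", "population_isi_ms",
        "first_spike_isi_ms", "reason"])
    empty_psth = pd.DataFrame(columns=[
        "unit_id", "n_events", "in_event_rate_hz", "spikes_per_event",
        "psth_peak_hz"])
    empty_lfp = pd.DataFrame(columns=[
        "onset_s", "peak_ripple_hz", "slow_gamma_z", "n_ripples"])

    model = TuningModel.from_day_maps(included, cfg) if included else None
    if model is None:
        decoding = {"median_error_deg": np.nan, "passes_criterion": False}
        exclusions.append("no included place cells; decoding skipped")
        return DayReport(behavior, cells, stability, precession, decoding,
                         empty_seq, empty_rep, empty_psth, empty_lfp,
                         n_place_cells=0, config=asdict(cfg),
                         seed=cfg.rng_seed, exclusions=exclusions)

    decoding = decoding_accuracy(session, model, cfg)
    if not decoding["passes_criterion"]:
        exclusions.append(
            f"decoding gate failed (median error "
            f"{decoding['median_error_deg']:.1f} deg >= {cfg.acc_criterion[1]}); "
            "theta-sequence and replay stages skipped")
        return DayReport(behavior, cells, stability, precession, decoding,
                         empty_seq, empty_rep, empty_psth, empty_lfp,
                         n_place_cells=len(included), config=asdict(cfg),
                         seed=cfg.rng_seed, exclusions=exclusions)

    seqs = detect_theta_sequences(session, model, cfg, lfp_channel=lfp_channel,
                                  n_shuffle=n_shuffle)
    sequences = pd.DataFrame([{
        "start_s": f.start_s, "slope_deg_per_s": f.slope_deg_per_s,
        "slope_cm_per_s": f.slope_cm_per_s, "x_span_deg": f.x_span_deg,
        "x_span_cm": f.x_span_cm, "t_span_s": f.t_span_s, "r2": f.r2,
        "shuffle_p": f.shuffle_p, "prob_near_line_frac": f.prob_near_line_frac,
        "min_dist_to_actual_deg": f.min_dist_to_actual_deg,
        "significant": f.significant} for f in seqs]) if seqs else empty_seq

    spikes = {u.unit_id: u.spike_t for u in session.units}
    replay_rows, replay_events = [], []
    for ep in session.epochs("rest"):
        for ev in detect_candidates(session, model.unit_ids, ep, cfg):
            res = classify_replay(ev, model, spikes, cfg,
                                  session.track_circumference_cm)
            isis = event_isis(ev, spikes)
            replay_rows.append({
                "rest_label": ev.rest_label, "start_s": ev.start_s,
                "duration_s": ev.duration_s, "n_cells": ev.n_cells,
                "r2": res.fit.r2 if res.fit else np.nan,
                "abs_slope_deg_per_s": res.abs_slope_deg_per_s,
                "abs_slope_cm_per_s": res.abs_slope_cm_per_s,
                "path_distance_deg": res.path_distance_deg,
                "max_jump_frac": res.max_jump_frac,
                "is_replay": res.is_replay,
                "population_isi_ms": isis["population_isi_ms"],
                "first_spike_isi_ms": isis["first_spike_isi_ms"],
                "reason": res.reason,
            })
            if res.is_replay:
                replay_events.append(ev)
    replay = pd.DataFrame(replay_rows) if replay_rows else empty_rep

    if replay_events:
        psth_res = replay_psth(session, replay_events, cfg)
        psth_rows = []
        for uid, r in psth_res["units"].items():
            psth_rows.append({
                "unit_id": uid, "n_events": r["n_events"],
                "in_event_rate_hz": r["in_event_rate_hz"],
                "spikes_per_event": r["spikes_per_event"],
                "psth_peak_hz": (float(np.max(r["psth_hz"]))
                                 if r["psth_hz"] is not None else np.nan),
            })
        psth = pd.DataFrame(psth_rows)
        band = event_band_metrics(session.lfp[lfp_channel], replay_events, cfg)
        ripples = detect_ripples(session.lfp[lfp_channel], cfg)
        n_rip = count_ripples_per_event(replay_events, ripples)
        lfp_tab = pd.DataFrame([{
            "onset_s": b["onset_s"], "peak_ripple_hz": b["peak_ripple_hz"],
            "slow_gamma_z": b["slow_gamma_z"], "n_ripples": int(k)}
            for b, k in zip(band, n_rip)])
    else:
        psth, lfp_tab = empty_psth, empty_lfp
        exclusions.append("no significant replay events; PSTH/LFP stages empty")

    return DayReport(behavior, cells, stability, precession, decoding,
                     sequences, replay, psth, lfp_tab,
                     n_place_cells=len(included), config=asdict(cfg),
                     seed=cfg.rng_seed, exclusions=exclusions)


_COMPARISON_METRICS = [
    # (report table, column, row filter column)
    ("sequences", "slope_cm_per_s", "significant", "theta sequence slope (cm/s)"),
    ("sequences", "x_span_cm", "significant", "theta sequence x-span (cm)"),
    ("sequences", "t_span_s", "significant", "theta sequence t-span (s)"),
    ("replay", "duration_s", "is_replay", "replay duration (s)"),
    ("replay", "abs_slope_deg_per_s", "is_replay", "replay slope (deg/s)"),
    ("replay", "path_distance_deg", "is_replay", "replay path distance (deg)"),
    ("replay", "population_isi_ms", "is_replay", "population ISI (ms)"),
    ("replay", "first_spike_isi_ms", "is_replay", "first-spike ISI (ms)"),
    ("psth", "in_event_rate_hz", None, "in-event firing rate (Hz)"),
    ("psth", "spikes_per_event", None, "spikes per event"),
    ("lfp", "peak_ripple_hz", None, "peak ripple frequency (Hz)"),
    ("lfp", "slow_gamma_z", None, "slow gamma power (z)"),
]


def _metric_values(report: DayReport, table, column, filt):
    df = getattr(report, table)
    if len(df) == 0 or column not in df:
        return np.empty(0)
    if filt is not None and filt in df:
        df = df[df[filt].astype(bool)]
    vals = pd.to_numeric(df[column], errors="coerce").to_numpy(dtype=float)
    if table == "sequences" and column.startswith("slope"):
        vals = np.abs(vals)
    return vals[np.isfinite(vals)]


def compare_presets(report_a: DayReport, report_b: DayReport) -> pd.DataFrame:
    """Direction-of-effect summary between two day reports.

    Per metric: medians, the Wilcoxon rank-sum statistic and p-value, and the
    direction of a relative to b ("higher", "lower", or "none" for equal
    medians or an empty metric). Swapping the arguments negates directions.
    """
    rows = []
    for table, column, filt, label in _COMPARISON_METRICS:
        va = _metric_values(report_a, table, column, filt)
        vb = _metric_values(report_b, table, column, filt)
        if va.size == 0 or vb.size == 0:
            continue
        med_a, med_b = float(np.median(va)), float(np.median(vb))
        stat, p = ranksums(va, vb)
        direction = ("none" if med_a == med_b
                     else "higher" if med_a > med_b else "lower")
        rows.append({"metric": label, "median_a": med_a, "median_b": med_b,
                     "n_a": va.size, "n_b": vb.size,
                     "ranksum_z": float(stat), "p_value": float(p),
                     "direction_a_vs_b": direction})
    return pd.DataFrame(rows)
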