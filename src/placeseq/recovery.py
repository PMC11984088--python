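"""Parameter-recovery studies on synthetic sessions.

These functions exercise the full pipeline against the generator's scripted
ground truth: decoding accuracy at a known population size, theta-sequence
slope recovery across scripted compression speeds, replay detection and
slope recovery with fast/slow preset contrasts, and ripple-injection checks.
They are the package's own benchmark suite; every number they return is
recomputed from freshly generated sessions.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr

from .config import AnalysisConfig
from .decoder import TuningModel, decoding_accuracy
from .ratemaps import compute_rate_map, day_average_map
from .replay import classify_replay, detect_candidates, event_isis, replay_psth
from .sequences import detect_theta_sequences
from .synthetic import make_day, preset

__all__ = [
    "build_day_model",
    "decoding_study",
    "sequence_slope_recovery",
    "replay_recovery",
]


def build_day_model(session, cfg: AnalysisConfig):
    """Day-averaged maps for all non-interneuron units plus a tuning model."""
    maps = {}
    for u in session.place_cell_units():
        ms = [compute_rate_map(u, session.position, ep, cfg,
                               session_label=ep.label)
              for ep in session.epochs("run")]
        maps[u.unit_id] = day_average_map(ms, cfg)
    included = {uid: m for uid, m in maps.items() if m.include_for_analysis}
    return maps, TuningModel.from_day_maps(included, cfg)


def decoding_study(seed: int, laps: int = 20,
                   cfg: AnalysisConfig | None = None) -> dict:
    """Decoding error of a 60-unit day holding ~``laps`` laps of running."""
    cfg = cfg or AnalysisConfig(rng_seed=seed)
    gt = preset("wt", seed=seed)
    lap_s = gt.track_circumference_cm / gt.run_speed_cm_s
    run_dur = laps * lap_s / 4.0  # laps spread over the four run sessions
    session = make_day(gt, run_duration_s=run_dur, rest_duration_s=5.0)
    _, model = build_day_model(session, cfg)
    acc = decoding_accuracy(session, model, cfg)
    return {
        "median_error_deg": acc["median_error_deg"],
        "passes_criterion": acc["passes_criterion"],
        "n_windows": int(acc["errors_deg"].size),
        "n_units": model.n_units,
    }


def sequence_slope_recovery(seed: int,
                            sweeps=(300.0, 450.0, 600.0, 750.0, 900.0),
                            run_duration_s: float = 45.0,
                            n_shuffle: int = 50,
                            cfg: AnalysisConfig | None = None) -> dict:
    """Fit theta sequences on days scripted at each compression speed.

    Returns the Spearman rank correlation between scripted and fitted |slope|
    across significant sequences, the median absolute relative slope error,
    and per-sweep medians.
    """
    cfg = cfg or AnalysisConfig(rng_seed=seed)
    scripted, fitted, per_sweep = [], [], {}
    for k, sweep in enumerate(sweeps):
        gt = preset("wt", seed=seed + 101 * k, seq_sweep_deg_per_s=float(sweep))
        session = make_day(gt, run_duration_s=run_duration_s, rest_duration_s=5.0)
        _, model = build_day_model(session, cfg)
        seqs = detect_theta_sequences(session, model, cfg, n_shuffle=n_shuffle)
        sig = [abs(s.slope_deg_per_s) for s in seqs if s.significant]
        per_sweep[float(sweep)] = {
            "n": len(sig),
            "median_abs_slope_deg_s": float(np.median(sig)) if sig else np.nan,
        }
        scripted += [float(sweep)] * len(sig)
        fitted += sig
    scripted = np.asarray(scripted)
    fitted = np.asarray(fitted)
    rho = float(spearmanr(scripted, fitted).statistic)
    med_err = float(np.median(np.abs(fitted - scripted) / scripted))
    medians = [per_sweep[s]["median_abs_slope_deg_s"] for s in sweeps]
    rho_medians = float(spearmanr(list(sweeps), medians).statistic)
    return {
        "rank_corr_events": rho,
        "rank_corr_medians": rho_medians,
        "median_abs_rel_error": med_err,
        "per_sweep": per_sweep,
        "n_events": int(fitted.size),
    }


def _analyze_replay_day(session, cfg):
    """Classify every rest-epoch candidate; returns (results, spikes dict)."""
    _, model = build_day_model(session, cfg)
    spikes = {u.unit_id: u.spike_t for u in session.units}
    results = []
    for ep in session.epochs("rest"):
        for ev in detect_candidates(session, model.unit_ids, ep, cfg):
            results.append(classify_replay(ev, model, spikes, cfg,
                                           session.track_circumference_cm))
    return results, spikes


def replay_recovery(seed: int, run_duration_s: float = 60.0,
                    rest_duration_s: float = 60.0,
                    cfg: AnalysisConfig | None = None) -> dict:
    """Scripted-replay recovery plus the fast/slow preset contrasts.

    A "fast" (wild-type-like) and a "slow" (knockout-like) day are generated;
    scripted rest-2..5 events are matched to classified replay events by
    interval overlap. Returns the recovery fraction and fitted-vs-scripted
    slope rank correlation on the fast day, and the slow-vs-fast medians for
    duration, |slope|, in-event rate, and both interspike-interval measures.
    """
    cfg = cfg or AnalysisConfig(rng_seed=seed)
    out = {}
    for name in ("wt", "fxs"):
        gt = preset(name, seed=seed + (0 if name == "wt" else 1))
        session = make_day(gt, run_duration_s=run_duration_s,
                           rest_duration_s=rest_duration_s)
        results, spikes = _analyze_replay_day(session, cfg)
        classified = [r for r in results if r.is_replay]
        scripted = [e for e in session.ground_truth["replay_events"]
                    if e["rest_label"] != "rest1"]
        matches = []
        for e in scripted:
            s0, s1 = e["start_s"], e["start_s"] + e["duration_s"]
            hit = next((r for r in classified
                        if r.event.start_s <= s1 and r.event.end_s >= s0), None)
            if hit is not None:
                matches.append((e["speed_deg_per_s"], hit))
        durations = [r.event.duration_s for r in classified]
        isis = [event_isis(r.event, spikes) for r in classified]
        psth = replay_psth(session, [r.event for r in classified], cfg)
        rates = [u["in_event_rate_hz"] for u in psth["units"].values()
                 if u["in_event_rate_hz"] is not None]
        out[name] = {
            "n_scripted": len(scripted),
            "n_classified": len(classified),
            "recovery_frac": len(matches) / len(scripted) if scripted else np.nan,
            "scripted_speeds": [m[0] for m in matches],
            "fitted_slopes": [m[1].abs_slope_deg_per_s for m in matches],
            "median_duration_s": float(np.median(durations)) if durations else np.nan,
            "median_abs_slope_deg_s": float(np.median(
                [r.abs_slope_deg_per_s for r in classified])) if classified else np.nan,
            "median_in_event_rate_hz": float(np.median(rates)) if rates else np.nan,
            "median_population_isi_ms": float(np.median(
                [i["population_isi_ms"] for i in isis
                 if i["population_isi_ms"] is not None])) if isis else np.nan,
            "median_first_spike_isi_ms": float(np.median(
                [i["first_spike_isi_ms"] for i in isis
                 if i["first_spike_isi_ms"] is not None])) if isis else np.nan,
        }
    speeds = np.concatenate([out[n]["scripted_speeds"] for n in ("wt", "fxs")])
    slopes = np.concatenate([out[n]["fitted_slopes"] for n in ("wt", "fxs")])
    out["slope_rank_corr"] = float(spearmanr(speeds, slopes).statistic)
    out["recovery_frac"] = float(np.mean([out["wt"]["recovery_frac"],
                                          out["fxs"]["recovery_frac"]]))
    out["directions_slow_vs_fast"] = {
        "duration_longer": out["fxs"]["median_duration_s"]
        > out["wt"]["median_duration_s"],
        "slope_lower": out["fxs"]["median_abs_slope_deg_s"]
        < out["wt"]["median_abs_slope_deg_s"],
        "in_event_rate_lower": out["fxs"]["median_in_event_rate_hz"]
        < out["wt"]["median_in_event_rate_hz"],
        "population_isi_longer": out["fxs"]["median_population_isi_ms"]
        > out["wt"]["median_population_isi_ms"],
        "first_spike_isi_longer": out["fxs"]["median_first_spike_isi_ms"]
        > out["wt"]["median_first_spike_isi_ms"],
    }
    return out
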