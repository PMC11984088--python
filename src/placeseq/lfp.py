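"""Time-frequency power around replay events, ripple metrics, and ripple
detection.

Power is computed with a complex Morlet wavelet transform at 1 Hz steps from
2 to 250 Hz, aligned to event onsets, averaged across events, and z-scored
within each frequency row. Per-event summaries (peak ripple frequency in
150-250 Hz; mean slow-gamma z in 25-55 Hz) use per-frequency statistics
pooled over the day's peri-event segments. Ripples are intervals where the
z-scored, smoothed (sigma = 8 ms) Hilbert envelope of the 150-250 Hz filtered
LFP reaches z >= 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.ndimage import gaussian_filter1d
from scipy.signal import hilbert

from .config import AnalysisConfig
from .session import LfpChannel
from .theta import bandpass

__all__ = [
    "PowerMap",
    "RippleInterval",
    "wavelet_power",
    "event_power",
    "peak_ripple_frequency",
    "slow_gamma_power",
    "detect_ripples",
    "count_ripples_per_event",
]


@dataclass
class PowerMap:
    freqs_hz: np.ndarray
    times_s: np.ndarray            # relative to event onset
    z_power: np.ndarray            # (n_freqs, n_times), z-scored per row


@dataclass
class RippleInterval:
    start_s: float
    end_s: float
    peak_z: float

    def overlaps(self, start_s, end_s) -> bool:
        return self.start_s <= end_s and self.end_s >= start_s


def _morlet_name(cycles: float) -> str:
    # cmorB-C: time SD at center frequency C=1 is sqrt(B/2) periods, so the
    # +-3 sigma support holds 6*sqrt(B/2) cycles
    bandwidth = 2.0 * (cycles / 6.0) ** 2
    return f"cmor{bandwidth:.4f}-1.0"


def wavelet_power(samples, fs, freqs_hz, cycles: float = 7.0) -> np.ndarray:
    """|CWT|^2 of a signal at the requested frequencies; (n_freqs, n_samples).

    Rows are rescaled to an L1 wavelet normalization (power multiplied by
    frequency), so a pure tone produces its peak response in its own
    frequency row rather than being skewed low by the default L2 scaling.
    """
    freqs_hz = np.asarray(freqs_hz, float)
    name = _morlet_name(cycles)
    scales = pywt.frequency2scale(name, freqs_hz / fs)
    coeffs, _ = pywt.cwt(np.asarray(samples, float), scales, name,
                         sampling_period=1.0 / fs, method="fft")
    return np.abs(coeffs) ** 2 * freqs_hz[:, None]


def _event_power_stack(lfp: LfpChannel, onsets, cfg: AnalysisConfig):
    """Per-event peri-onset power, (n_events, n_freqs, n_times)."""
    freqs = np.arange(cfg.wavelet_band[0], cfg.wavelet_band[1] + 1.0, 1.0)
    half = int(round(cfg.peri_event_s * lfp.fs_hz))
    pad = int(round(0.5 * lfp.fs_hz))  # absorbs wavelet edge effects
    times = np.arange(-half, half + 1) / lfp.fs_hz
    stack, kept = [], []
    for onset in onsets:
        c = int(round((onset - lfp.t0) * lfp.fs_hz))
        i0, i1 = c - half - pad, c + half + pad + 1
        if i0 < 0 or i1 > lfp.samples.size:
            import warnings
            warnings.warn(f"event at {onset:.2f}s exceeds the LFP extent; dropped")
            continue
        p = wavelet_power(lfp.samples[i0:i1], lfp.fs_hz, freqs, cfg.wavelet_cycles)
        stack.append(p[:, pad:pad + 2 * half + 1])
        kept.append(onset)
    if not stack:
        raise ValueError("no events within the LFP extent")
    return freqs, times, np.stack(stack), kept


def event_power(lfp: LfpChannel, onsets, cfg: AnalysisConfig | None = None) -> PowerMap:
    """Event-averaged peri-onset power map, z-scored within each frequency."""
    cfg = cfg or AnalysisConfig()
    freqs, times, stack, _ = _event_power_stack(lfp, onsets, cfg)
    mean_p = stack.mean(axis=0)
    mu = mean_p.mean(axis=1, keepdims=True)
    sd = mean_p.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return PowerMap(freqs, times, (mean_p - mu) / sd)


def event_band_metrics(lfp: LfpChannel, events, cfg: AnalysisConfig | None = None):
    """Per-event peak ripple frequency and mean slow-gamma z.

    ``events`` — objects with start_s/end_s (onset = start). z statistics are
    pooled over the day's peri-event segments, then each event's power within
    its own time extent is summarized.
    """
    cfg = cfg or AnalysisConfig()
    onsets = [ev.start_s for ev in events]
    freqs, times, stack, kept = _event_power_stack(lfp, onsets, cfg)
    pooled = stack.transpose(1, 0, 2).reshape(stack.shape[1], -1)
    mu = pooled.mean(axis=1)[:, None]
    sd = pooled.std(axis=1)[:, None]
    sd[sd == 0] = 1.0
    out = []
    ev_by_onset = {ev.start_s: ev for ev in events}
    for p, onset in zip(stack, kept):
        ev = ev_by_onset[onset]
        dur = min(ev.end_s - ev.start_s, cfg.peri_event_s)
        in_event = (times >= 0) & (times <= dur)
        out.append({
            "onset_s": onset,
            "peak_ripple_hz": peak_ripple_frequency(p[:, in_event], freqs, cfg),
            "slow_gamma_z": slow_gamma_power(((p - mu) / sd)[:, in_event], freqs, cfg),
        })
    return out


def peak_ripple_frequency(power, freqs_hz, cfg: AnalysisConfig | None = None) -> float:
    """Frequency with the highest time-averaged power in the ripple band.

    Ties resolve to the lowest frequency (np.argmax takes the first maximum
    over ascending frequencies).
    """
    cfg = cfg or AnalysisConfig()
    freqs_hz = np.asarray(freqs_hz, float)
    band = (freqs_hz >= cfg.ripple_band[0]) & (freqs_hz <= cfg.ripple_band[1])
    mean_p = np.asarray(power, float)[band].mean(axis=1)
    return float(freqs_hz[band][np.argmax(mean_p)])


def slow_gamma_power(z_power, freqs_hz, cfg: AnalysisConfig | None = None) -> float:
    """Mean z-scored power across the slow-gamma band and across time."""
    cfg = cfg or AnalysisConfig()
    freqs_hz = np.asarray(freqs_hz, float)
    band = (freqs_hz >= cfg.slowgamma_band[0]) & (freqs_hz <= cfg.slowgamma_band[1])
    return float(np.asarray(z_power, float)[band].mean())


def detect_ripples(lfp: LfpChannel, cfg: AnalysisConfig | None = None,
                   t_range=None) -> list:
    """Ripple intervals from the z-scored 150-250 Hz Hilbert envelope."""
    cfg = cfg or AnalysisConfig()
    t, x = (lfp.segment(*t_range) if t_range is not None
            else (lfp.t, lfp.samples))
    filtered = bandpass(x, lfp.fs_hz, cfg.ripple_band)
    env = np.abs(hilbert(filtered))
    env = gaussian_filter1d(env, cfg.ripple_smooth_s * lfp.fs_hz, mode="nearest")
    mu, sd = env.mean(), env.std()
    if sd == 0:
        return []
    z = (env - mu) / sd
    above = z >= cfg.ripple_z
    if not above.any():
        return []
    d = np.diff(above.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    return [RippleInterval(float(t[s]), float(t[e - 1]), float(z[s:e].max()))
            for s, e in zip(starts, ends)]


def count_ripples_per_event(events, ripples) -> np.ndarray:
    """Number of ripple intervals overlapping each event's bounds."""
    return np.array([sum(r.overlaps(ev.start_s, ev.end_s) for r in ripples)
                     for ev in events])
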