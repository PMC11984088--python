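"""Theta-band phase extraction and single-cell phase precession.

The LFP is bandpass filtered in the theta range (6-10 Hz) with a 4th-order
Butterworth applied forward-backward (zero phase), and instantaneous phase
is taken from the Hilbert analytic signal. Phase convention: 0 deg at the
filtered-waveform peak, 180 deg at the trough.

Phase precession is quantified per cell by circular-linear regression of
spike theta phase against normalized position through the place field
(0 at entry, 1 at exit), with the correlation magnitude r computed as the
standard circular-linear correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .circular import circ_lin_corr, fit_circular_linear
from .config import AnalysisConfig
from .ratemaps import PlaceField
from .session import LfpChannel, PositionTrace, SpikeTrain

__all__ = [
    "PhaseSeries",
    "PrecessionResult",
    "bandpass",
    "theta_filter_phase",
    "spike_phases_in_field",
    "circular_linear_fit",
]


@dataclass
class PhaseSeries:
    t: np.ndarray
    phase_deg: np.ndarray         # [0, 360)
    unwrapped_deg: np.ndarray     # monotone-ish, for interpolation
    source_channel: str = ""

    def at(self, times) -> np.ndarray:
        """Phase at arbitrary times, linear interpolation on unwrapped phase."""
        return np.interp(np.asarray(times, float), self.t, self.unwrapped_deg) % 360.0


@dataclass
class PrecessionResult:
    unit_id: str
    n_spikes: int
    slope_deg_per_unit_pos: float
    r: float
    p_value: float
    included: bool = True
    reason: str = ""


def bandpass(x, fs, band, order=4):
    """Zero-phase Butterworth bandpass (second-order sections for stability
    at narrow normalized bands)."""
    lo, hi = band
    sos = butter(order, [lo / (fs / 2), hi / (fs / 2)], btype="band", output="sos")
    return sosfiltfilt(sos, x)


def theta_filter_phase(lfp: LfpChannel, band=None,
                       cfg: AnalysisConfig | None = None) -> PhaseSeries:
    """Instantaneous theta phase of an LFP channel."""
    cfg = cfg or AnalysisConfig()
    band = band or cfg.theta_band
    if lfp.fs_hz < 4 * band[1]:
        raise ValueError("sampling rate too low for the requested band")
    min_len = int(3 * lfp.fs_hz / band[0])
    if lfp.samples.size < min_len:
        raise ValueError(
            f"segment too short for theta filtering (need >= {min_len} samples)")
    filtered = bandpass(lfp.samples, lfp.fs_hz, band)
    analytic = hilbert(filtered)
    phase = np.angle(analytic)                       # 0 at peak for a cosine
    unwrapped = np.rad2deg(np.unwrap(phase))
    return PhaseSeries(lfp.t, unwrapped % 360.0, unwrapped,
                       source_channel=lfp.channel_id)


def spike_phases_in_field(unit: SpikeTrain, field: PlaceField,
                          trace: PositionTrace, phases: PhaseSeries,
                          cfg: AnalysisConfig | None = None,
                          epochs=None):
    """(normalized position, theta phase) pairs for in-field spikes.

    Takes every spike across the given run epochs (default: the whole trace
    extent) that falls inside the field while the animal moves at or above
    the speed gate. Positions are normalized circular distances from the
    field start, so fields wrapping 360 -> 0 are handled transparently.
    """
    cfg = cfg or AnalysisConfig()
    if trace.speed_cm_s is None:
        raise ValueError("speed must be computed")
    windows = ([(e.start_s, e.end_s) for e in epochs] if epochs is not None
               else [(trace.t[0], trace.t[-1])])
    unwrapped_angle = np.rad2deg(np.unwrap(np.deg2rad(trace.angle_deg)))
    pos_list, phase_list = [], []
    for start, end in windows:
        spikes = unit.in_window(max(start, phases.t[0]), min(end, phases.t[-1]))
        if spikes.size == 0:
            continue
        ang = np.interp(spikes, trace.t, unwrapped_angle) % 360.0
        speed = np.interp(spikes, trace.t, trace.speed_cm_s)
        keep = ~(speed < cfg.speed_min) & field.contains(ang)
        if not keep.any():
            continue
        pos_list.append(field.norm_pos(ang[keep]))
        phase_list.append(phases.at(spikes[keep]))
    if not pos_list:
        return np.empty(0), np.empty(0)
    return np.concatenate(pos_list), np.concatenate(phase_list)


def circular_linear_fit(norm_pos, phase_deg, unit_id: str = "",
                        cfg: AnalysisConfig | None = None) -> PrecessionResult:
    """Phase-precession fit: slope (deg per field traversal), r, p.

    Units with fewer than the minimum in-field spike count are returned as
    excluded records rather than raising.
    """
    cfg = cfg or AnalysisConfig()
    norm_pos = np.asarray(norm_pos, float)
    phase_deg = np.asarray(phase_deg, float)
    n = norm_pos.size
    if n < cfg.precession_min_spikes:
        return PrecessionResult(unit_id, n, np.nan, np.nan, np.nan,
                                included=False,
                                reason=f"fewer than {cfg.precession_min_spikes} in-field spikes")
    fit = fit_circular_linear(norm_pos, phase_deg, cfg.precession_slope_bounds)
    r, p = circ_lin_corr(norm_pos, phase_deg)
    return PrecessionResult(unit_id, n, fit.slope, r, p)
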