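"""Occupancy-normalized firing-rate maps and place-field properties.

The track is divided into 90 bins of 4 deg. Per bin, the spike count of a
unit is divided by the speed-gated time spent there, and the raw map is then
smoothed with a wrap-around Gaussian kernel (sigma = 8 deg, i.e. 2 bins).
Bins never visited above the speed gate get a raw rate of 0 before smoothing
(rare on a circular track with many laps). Spatial information is the Skaggs
formula, sum_i P_i (lambda_i/lambda) log2(lambda_i/lambda).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .config import AnalysisConfig
from .session import PositionTrace, SpikeTrain

__all__ = [
    "RateMap",
    "PlaceField",
    "compute_rate_map",
    "day_average_map",
    "spatial_correlation",
    "rate_overlap",
    "spatial_information",
    "detect_place_fields",
    "circular_gaussian_kernel",
]


@dataclass
class RateMap:
    bin_edges_deg: np.ndarray     # 91 edges for 90 bins
    occupancy_s: np.ndarray       # gated time per bin
    rate_hz: np.ndarray           # smoothed rates
    raw_rate_hz: np.ndarray       # before smoothing
    n_spikes: np.ndarray          # gated spike counts per bin
    unit_id: str = ""
    session_label: str = ""
    include_for_analysis: bool = True

    @property
    def n_bins(self) -> int:
        return self.rate_hz.size

    @property
    def bin_centers_deg(self) -> np.ndarray:
        return (self.bin_edges_deg[:-1] + self.bin_edges_deg[1:]) / 2.0

    @property
    def mean_rate_hz(self) -> float:
        """Occupancy-weighted overall mean rate (lambda)."""
        tot = self.occupancy_s.sum()
        if tot == 0:
            return 0.0
        return float(np.sum(self.rate_hz * self.occupancy_s) / tot)

    @property
    def peak_rate_hz(self) -> float:
        return float(self.rate_hz.max())


@dataclass
class PlaceField:
    start_deg: float          # circular interval [start, end) in run direction
    end_deg: float
    peak_rate_hz: float
    size_deg: float
    bins: np.ndarray = dc_field(default_factory=lambda: np.empty(0, int))

    @property
    def center_deg(self) -> float:
        half = self.size_deg / 2.0
        return (self.start_deg + half) % 360.0

    def contains(self, angle_deg) -> np.ndarray:
        off = (np.asarray(angle_deg, float) - self.start_deg) % 360.0
        return off <= self.size_deg

    def norm_pos(self, angle_deg) -> np.ndarray:
        """Normalized position through the field in [0, 1] (wrap-safe)."""
        off = (np.asarray(angle_deg, float) - self.start_deg) % 360.0
        return np.clip(off / self.size_deg, 0.0, 1.0)


def circular_gaussian_kernel(sigma_bins: float, n_bins: int) -> np.ndarray:
    """Gaussian kernel truncated at 4 sigma, renormalized, length n_bins,
    centered at index 0 for circular convolution via np.roll-style wrap."""
    half = int(np.ceil(4 * sigma_bins))
    offsets = np.arange(-half, half + 1)
    k = np.exp(-(offsets**2) / (2.0 * sigma_bins**2))
    k /= k.sum()
    kern = np.zeros(n_bins)
    np.add.at(kern, offsets % n_bins, k)
    return kern


def _circular_smooth(x: np.ndarray, sigma_bins: float) -> np.ndarray:
    kern = circular_gaussian_kernel(sigma_bins, x.size)
    # circular convolution via FFT would be fine; direct roll-sum is exact
    n = x.size
    idx = np.arange(n)
    out = np.zeros(n)
    for off, w in enumerate(kern):
        if w:
            out += w * x[(idx - off) % n]
    return out


def _gated_samples(trace: PositionTrace, start_s: float, end_s: float,
                   speed_min: float):
    sub = trace.slice(start_s, end_s)
    if sub.speed_cm_s is None:
        raise ValueError("speed must be computed before building rate maps")
    keep = ~(sub.speed_cm_s < speed_min)  # exclude samples slower than the gate
    return sub.t[keep], sub.angle_deg[keep]


def compute_rate_map(unit: SpikeTrain, trace: PositionTrace, epoch,
                     cfg: AnalysisConfig | None = None,
                     session_label: str = "") -> RateMap:
    """Rate map of one unit over one epoch (speed-gated, smoothed).

    ``epoch`` is anything with ``start_s``/``end_s``. Spikes and occupancy at
    speeds below the gate are excluded before binning.
    """
    cfg = cfg or AnalysisConfig()
    n_bins = cfg.n_bins
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    t_ok, ang_ok = _gated_samples(trace, epoch.start_s, epoch.end_s, cfg.speed_min)
    if t_ok.size == 0:
        raise ValueError("no qualifying samples (zero gated occupancy)")

    # occupancy: each retained sample contributes its frame interval
    dt = np.median(np.diff(trace.t)) if trace.t.size > 1 else 0.0
    occupancy, _ = np.histogram(ang_ok, bins=edges)
    occupancy = occupancy * dt

    spikes = unit.in_window(epoch.start_s, epoch.end_s)
    if spikes.size:
        sp_angle = np.interp(spikes, trace.t,
                             np.rad2deg(np.unwrap(np.deg2rad(trace.angle_deg)))) % 360.0
        sp_speed = np.interp(spikes, trace.t, trace.speed_cm_s)
        sp_angle = sp_angle[~(sp_speed < cfg.speed_min)]
    else:
        sp_angle = np.empty(0)
    counts, _ = np.histogram(sp_angle, bins=edges)

    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(occupancy > 0, counts / np.where(occupancy > 0, occupancy, 1.0), 0.0)
    smoothed = _circular_smooth(raw, cfg.smooth_deg / cfg.bin_deg)
    return RateMap(edges, occupancy, smoothed, raw, counts,
                   unit_id=unit.unit_id, session_label=session_label)


def day_average_map(maps: list, cfg: AnalysisConfig | None = None) -> RateMap:
    """Day map from pooled spikes and pooled occupancy across sessions.

    Pooling (not averaging the per-session maps) equals the rate definition
    applied to the whole day. Sets ``include_for_analysis`` by the 1 Hz
    minimum peak rate rule.
    """
    cfg = cfg or AnalysisConfig()
    if not maps:
        raise ValueError("no maps to pool")
    edges = maps[0].bin_edges_deg
    for m in maps[1:]:
        if m.n_bins != maps[0].n_bins or not np.allclose(m.bin_edges_deg, edges):
            raise ValueError("mismatched binning across session maps")
        if m.unit_id != maps[0].unit_id:
            raise ValueError("day_average_map pools maps of a single unit")
    occupancy = np.sum([m.occupancy_s for m in maps], axis=0)
    counts = np.sum([m.n_spikes for m in maps], axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = np.where(occupancy > 0, counts / np.where(occupancy > 0, occupancy, 1.0), 0.0)
    smoothed = _circular_smooth(raw, cfg.smooth_deg / cfg.bin_deg)
    rm = RateMap(edges, occupancy, smoothed, raw, counts,
                 unit_id=maps[0].unit_id, session_label="day")
    rm.include_for_analysis = rm.peak_rate_hz >= cfg.peak_min_hz
    return rm


def spatial_correlation(a: RateMap, b: RateMap):
    """Pearson correlation of two rate maps; None if either has no variance."""
    if a.n_bins != b.n_bins:
        raise ValueError("mismatched binning")
    x, y = a.rate_hz, b.rate_hz
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero-variance rate map; spatial correlation undefined")
        return None
    return float(np.corrcoef(x, y)[0, 1])


def rate_overlap(a: RateMap, b: RateMap):
    """min(mean_a, mean_b) / max(mean_a, mean_b); None for 0/0."""
    ra, rb = a.mean_rate_hz, b.mean_rate_hz
    hi = max(ra, rb)
    if hi == 0:
        warnings.warn("both maps silent; rate overlap undefined")
        return None
    return float(min(ra, rb) / hi)


def spatial_information(m: RateMap):
    """Skaggs spatial information in bits per spike.

    SI = sum_i P_i (lambda_i / lambda) log2(lambda_i / lambda), summed over
    bins with positive rate; P_i is the occupancy distribution. None (with a
    warning) for a silent map.
    """
    tot_occ = m.occupancy_s.sum()
    if tot_occ == 0:
        raise ValueError("zero total occupancy")
    p = m.occupancy_s / tot_occ
    lam_i = m.rate_hz
    lam = np.sum(p * lam_i)
    if lam == 0:
        warnings.warn("silent map; spatial information undefined")
        return None
    ratio = lam_i / lam
    mask = lam_i > 0
    return float(np.sum(p[mask] * ratio[mask] * np.log2(ratio[mask])))


def detect_place_fields(m: RateMap, cfg: AnalysisConfig | None = None) -> list:
    """Place fields by z-scored thresholding with circular growth.

    Bins with z >= 2 seed candidate fields, grown circularly in both
    directions until z < 0.5; regions touching are merged. Fields must reach
    1 Hz peak rate and span at least 18 deg. A zero-variance map yields no
    fields.
    """
    cfg = cfg or AnalysisConfig()
    rates = m.rate_hz
    sd = np.std(rates)
    if sd == 0:
        return []
    z = (rates - np.mean(rates)) / sd
    n = rates.size
    above_exit = z >= cfg.field_z_exit
    member = np.zeros(n, dtype=bool)
    for seed in np.flatnonzero(z >= cfg.field_z_enter):
        if member[seed]:
            continue
        member[seed] = True
        i = seed
        while True:
            j = (i + 1) % n
            if j == seed or not above_exit[j]:
                break
            member[j] = True
            i = j
        i = seed
        while True:
            j = (i - 1) % n
            if j == seed or not above_exit[j]:
                break
            member[j] = True
            i = j

    if member.all():
        runs = [np.arange(n)]
    else:
        # circular runs of True: rotate so index 0 is False, then split
        start = int(np.flatnonzero(~member)[0])
        rolled = np.roll(member, -start)
        runs = []
        idx = np.flatnonzero(rolled)
        if idx.size:
            breaks = np.flatnonzero(np.diff(idx) > 1)
            for seg in np.split(idx, breaks + 1):
                runs.append((seg + start) % n)

    fields = []
    for bins in runs:
        size = bins.size * cfg.bin_deg
        peak = float(rates[bins].max())
        if size < cfg.field_min_deg or peak < cfg.peak_min_hz:
            continue
        start_deg = float(m.bin_edges_deg[bins[0]])
        end_deg = float((start_deg + size) % 360.0)
        fields.append(PlaceField(start_deg, end_deg, peak, size, bins=bins))
    fields.sort(key=lambda f: f.start_deg)
    return fields
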