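"""Analysis configuration: every threshold of the pipeline as a named field.

Defaults reproduce the published CA1 circular-track methods exactly; change a
field only to run a deliberate sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml


@dataclass
class AnalysisConfig:
    # --- rate maps / place fields ---
    bin_deg: float = 4.0              # track divided into 4 deg bins (90 bins)
    smooth_deg: float = 8.0           # Gaussian smoothing sigma, deg
    speed_min: float = 5.0            # cm/s locomotion gate
    peak_min_hz: float = 1.0          # day-map inclusion: minimum peak rate
    interneuron_hz: float = 5.0       # mean-rate cutoff for putative interneurons
    field_z_enter: float = 2.0        # place-field seed threshold (z)
    field_z_exit: float = 0.5         # place-field boundary threshold (z)
    field_min_deg: float = 18.0       # minimum place-field length (~15 cm)
    # --- phase precession ---
    precession_min_spikes: int = 50   # in-field spikes required per cell
    theta_band: tuple = (6.0, 10.0)   # Hz
    precession_slope_bounds: tuple = (-1080.0, 1080.0)  # deg per field
    # --- decoding accuracy gate ---
    acc_win_s: float = 0.5
    acc_step_s: float = 0.1
    acc_criterion: tuple = (0.5, 20.0)  # cumulative error reaches 50% below 20 deg
    rate_floor_hz: float = 0.01         # tuning-curve floor inside the log
    # --- theta sequences ---
    seq_win_s: float = 0.04
    seq_step_s: float = 0.01
    seq_min_cells: int = 3
    seq_gap_bins: int = 2             # contiguity broken at this many empty bins
    seq_n_shuffle: int = 1000
    seq_alpha: float = 0.05
    seq_prob_frac: float = 0.6        # posterior mass required near the line
    seq_prob_dist_deg: float = 20.0   # ...within this arc of the line
    seq_actual_dist_deg: float = 20.0 # line must approach the actual position
    seq_slope_bounds: tuple = (-3000.0, 3000.0)  # deg/s
    cycle_phase_bin_deg: float = 20.0 # spike-phase histogram bin for cycle cutting
    # --- replay ---
    replay_z: float = 3.0
    replay_merge_s: float = 0.04
    replay_dur_s: tuple = (0.05, 2.0)
    replay_min_cells: int = 5
    replay_win_s: float = 0.02
    replay_step_s: float = 0.01
    replay_r2_min: float = 0.5
    replay_jump_frac: float = 0.25
    replay_slope_bounds: tuple = (-5000.0, 5000.0)  # deg/s
    psth_bin_s: float = 0.001
    psth_smooth_s: float = 0.01
    # --- LFP ---
    wavelet_band: tuple = (2.0, 250.0)
    ripple_band: tuple = (150.0, 250.0)
    slowgamma_band: tuple = (25.0, 55.0)
    ripple_smooth_s: float = 0.008
    ripple_z: float = 3.0
    peri_event_s: float = 0.5         # window around event onset for power maps
    wavelet_cycles: float = 7.0       # Morlet cycles per frequency
    # --- misc ---
    rng_seed: int = 0

    def __post_init__(self):
        for name in ("acc_win_s", "acc_step_s", "seq_win_s", "seq_step_s",
                     "replay_win_s", "replay_step_s", "psth_bin_s", "bin_deg"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("theta_band", "ripple_band", "slowgamma_band", "wavelet_band"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"{name} must satisfy low < high")

    @property
    def n_bins(self) -> int:
        return int(round(360.0 / self.bin_deg))

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        # YAML round-trips tuples as lists
        for f_ in fields(cls):
            if f_.name in data and isinstance(data[f_.name], list):
                data[f_.name] = tuple(data[f_.name])
        return cls(**data)
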