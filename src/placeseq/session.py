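"""Session container, on-disk layout, and behavioral metrics.

A recording day is a directory holding a position trace, per-unit spike
times, one or more LFP channels, and a metadata file with the run/rest
schedule:

    session_dir/
      metadata.yaml   track circumference, schedule, LFP channel registry
      position.csv    columns t, angle_deg
      spikes.csv      columns unit_id, t
      lfp0.npz ...    one file per channel (samples array)

The schedule interleaves four run sessions with five rest sessions
(rest1, run1, rest2, ..., run4, rest5). Angles are degrees in [0, 360),
increasing in the running direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.ndimage import uniform_filter1d

from .config import AnalysisConfig

RUN_LABELS = ("run1", "run2", "run3", "run4")
REST_LABELS = ("rest1", "rest2", "rest3", "rest4", "rest5")

DEFAULT_CIRCUMFERENCE_CM = 100.0 * np.pi  # 1-m-diameter circular track


class SessionValidationError(ValueError):
    """A session violated a structural invariant."""


@dataclass
class EpochSpec:
    label: str
    start_s: float
    end_s: float

    def __post_init__(self):
        if self.end_s <= self.start_s:
            raise SessionValidationError(
                f"epoch {self.label}: end {self.end_s} <= start {self.start_s}"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class PositionTrace:
    t: np.ndarray                 # seconds, strictly increasing (~29.97 Hz)
    angle_deg: np.ndarray         # [0, 360)
    speed_cm_s: np.ndarray | None = None

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.angle_deg = np.asarray(self.angle_deg, dtype=float) % 360.0
        if self.t.ndim != 1 or self.t.shape != self.angle_deg.shape:
            raise SessionValidationError("t and angle_deg must be equal-length 1-D")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            idx = int(np.argmax(dt <= 0))
            raise SessionValidationError(
                f"position timestamps not strictly increasing at index {idx + 1}"
            )

    def slice(self, start_s, end_s) -> "PositionTrace":
        m = (self.t >= start_s) & (self.t <= end_s)
        sp = self.speed_cm_s[m] if self.speed_cm_s is not None else None
        return PositionTrace(self.t[m], self.angle_deg[m], sp)


@dataclass
class SpikeTrain:
    unit_id: str
    spike_t: np.ndarray           # seconds, sorted ascending
    mean_rate_hz: float = 0.0
    is_interneuron: bool = False  # flagged, never deleted

    def __post_init__(self):
        self.spike_t = np.asarray(self.spike_t, dtype=float)
        if np.any(np.diff(self.spike_t) < 0):
            raise SessionValidationError(f"unit {self.unit_id}: spike times not sorted")

    def in_window(self, start_s, end_s) -> np.ndarray:
        lo = np.searchsorted(self.spike_t, start_s, side="left")
        hi = np.searchsorted(self.spike_t, end_s, side="right")
        return self.spike_t[lo:hi]


@dataclass
class LfpChannel:
    fs_hz: float
    samples: np.ndarray           # microvolts
    t0: float = 0.0
    channel_id: str = "lfp0"

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0:
            raise SessionValidationError("fs_hz must be positive")

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs_hz

    def segment(self, start_s, end_s) -> tuple[np.ndarray, np.ndarray]:
        """(times, samples) covering [start_s, end_s]."""
        i0 = max(0, int(np.ceil((start_s - self.t0) * self.fs_hz)))
        i1 = min(self.samples.size, int(np.floor((end_s - self.t0) * self.fs_hz)) + 1)
        idx = np.arange(i0, i1)
        return self.t0 + idx / self.fs_hz, self.samples[i0:i1]


@dataclass
class Session:
    position: PositionTrace
    units: list
    lfp: list
    schedule: list
    track_circumference_cm: float = DEFAULT_CIRCUMFERENCE_CM
    ground_truth: dict | None = None   # attached by the synthetic generator

    def __post_init__(self):
        if self.track_circumference_cm <= 0:
            raise SessionValidationError("track_circumference_cm must be > 0")
        self.validate()

    # -- schedule helpers ------------------------------------------------
    def epochs(self, kind=None):
        if kind is None:
            return list(self.schedule)
        prefix = {"run": "run", "rest": "rest"}[kind]
        return [e for e in self.schedule if e.label.startswith(prefix)]

    def epoch(self, label) -> EpochSpec:
        for e in self.schedule:
            if e.label == label:
                return e
        raise KeyError(label)

    @property
    def t_start(self) -> float:
        return self.schedule[0].start_s

    @property
    def t_end(self) -> float:
        return self.schedule[-1].end_s

    def place_cell_units(self, cfg: AnalysisConfig | None = None):
        """Units not flagged as putative interneurons."""
        return [u for u in self.units if not u.is_interneuron]

    def validate(self):
        if not self.schedule:
            raise SessionValidationError("empty schedule")
        for a, b in zip(self.schedule, self.schedule[1:]):
            if b.start_s < a.end_s:
                raise SessionValidationError(
                    f"epochs {a.label} and {b.label} overlap or are out of order"
                )
        lo, hi = self.t_start, self.t_end
        for u in self.units:
            if u.spike_t.size and (u.spike_t[0] < lo or u.spike_t[-1] > hi):
                bad = u.spike_t[(u.spike_t < lo) | (u.spike_t > hi)][0]
                raise SessionValidationError(
                    f"unit {u.unit_id}: spike at {bad:.4f}s outside schedule [{lo}, {hi}]"
                )


# ---------------------------------------------------------------------------
# speed and behavior
# ---------------------------------------------------------------------------

def compute_speed(trace: PositionTrace, circumference_cm: float = DEFAULT_CIRCUMFERENCE_CM,
                  smooth_samples: int = 5) -> PositionTrace:
    """Attach linear speed (cm/s) derived from the circular angle trace.

    Central difference on the unwrapped angle (shortest-arc steps, so a
    358 -> 2 deg crossing counts as +4 deg), converted to cm via
    circumference/360, then boxcar-smoothed over ``smooth_samples`` frames
    (~167 ms at 29.97 Hz) to suppress tracker jitter around the 5 cm/s gate.
    """
    t, ang = trace.t, trace.angle_deg
    if t.size < 2:
        raise SessionValidationError("need at least 2 position samples")
    if np.any(np.diff(t) == 0):
        raise SessionValidationError("duplicate position timestamps")
    unwrapped = np.rad2deg(np.unwrap(np.deg2rad(ang)))
    speed_deg = np.gradient(unwrapped, t)          # central difference
    speed = np.abs(speed_deg) * circumference_cm / 360.0
    if smooth_samples and smooth_samples > 1 and speed.size >= 2:
        speed = uniform_filter1d(speed, size=smooth_samples, mode="nearest")
    return PositionTrace(t, ang, speed)


def count_laps(trace: PositionTrace) -> int:
    """Completed laps: full 360-deg passes of the unwrapped angle in the
    running direction. Invariant to rotating the angular origin."""
    if trace.t.size < 2:
        return 0
    unwrapped = np.rad2deg(np.unwrap(np.deg2rad(trace.angle_deg)))
    net = unwrapped[-1] - unwrapped[0]
    return int(np.floor(abs(net) / 360.0)) if abs(net) >= 360.0 else 0


def behavior_metrics(session: Session, cfg: AnalysisConfig | None = None) -> pd.DataFrame:
    """Per run-session mean run speed (samples > speed gate only) and laps.

    Stationary sessions produce a null mean speed with a warning column.
    """
    import warnings

    cfg = cfg or AnalysisConfig()
    trace = session.position
    if trace.speed_cm_s is None:
        trace = compute_speed(trace, session.track_circumference_cm)
    rows = []
    for ep in session.epochs("run"):
        sub = trace.slice(ep.start_s, ep.end_s)
        if sub.t.size == 0:
            warnings.warn(f"empty run epoch {ep.label}")
            rows.append({"session": ep.label, "mean_run_speed_cm_s": np.nan, "n_laps": 0})
            continue
        moving = sub.speed_cm_s > cfg.speed_min
        mean_speed = float(np.mean(sub.speed_cm_s[moving])) if moving.any() else np.nan
        if not moving.any():
            warnings.warn(f"no samples above the speed gate in {ep.label}")
        rows.append({
            "session": ep.label,
            "mean_run_speed_cm_s": mean_speed,
            "n_laps": count_laps(sub),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------------

def save_session(session: Session, path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"t": session.position.t, "angle_deg": session.position.angle_deg}
                 ).to_csv(path / "position.csv", index=False)
    frames = []
    for u in session.units:
        frames.append(pd.DataFrame({"unit_id": u.unit_id, "t": u.spike_t}))
    spikes = (pd.concat(frames, ignore_index=True) if frames
              else pd.DataFrame(columns=["unit_id", "t"]))
    spikes.to_csv(path / "spikes.csv", index=False)
    lfp_meta = []
    for i, ch in enumerate(session.lfp):
        fname = f"lfp{i}.npz"
        np.savez_compressed(path / fname, samples=ch.samples)
        lfp_meta.append({"file": fname, "fs_hz": float(ch.fs_hz),
                         "t0": float(ch.t0), "channel_id": ch.channel_id})
    meta = {
        "track_circumference_cm": float(session.track_circumference_cm),
        "schedule": [{"label": e.label, "start_s": float(e.start_s),
                      "end_s": float(e.end_s)} for e in session.schedule],
        "lfp_channels": lfp_meta,
        "unit_ids": [u.unit_id for u in session.units],
    }
    (path / "metadata.yaml").write_text(yaml.safe_dump(meta, sort_keys=False))
    if session.ground_truth is not None:
        (path / "ground_truth.yaml").write_text(
            yaml.safe_dump(session.ground_truth, sort_keys=False))
    return path


def load_session(path, cfg: AnalysisConfig | None = None) -> Session:
    """Load a session directory, validate it, and flag putative interneurons.

    Units with whole-day mean firing rates above the interneuron cutoff
    (default 5 Hz) are flagged ``is_interneuron`` but kept.
    """
    cfg = cfg or AnalysisConfig()
    path = Path(path)
    for required in ("metadata.yaml", "position.csv", "spikes.csv"):
        if not (path / required).exists():
            raise FileNotFoundError(f"missing session file: {path / required}")
    meta = yaml.safe_load((path / "metadata.yaml").read_text())
    schedule = [EpochSpec(e["label"], e["start_s"], e["end_s"]) for e in meta["schedule"]]
    pos = pd.read_csv(path / "position.csv")
    trace = PositionTrace(pos["t"].to_numpy(), pos["angle_deg"].to_numpy())
    circumference = float(meta.get("track_circumference_cm", DEFAULT_CIRCUMFERENCE_CM))
    trace = compute_speed(trace, circumference)

    spikes = pd.read_csv(path / "spikes.csv")
    total_dur = schedule[-1].end_s - schedule[0].start_s
    units = []
    unit_ids = meta.get("unit_ids")
    if unit_ids is None:
        unit_ids = sorted(spikes["unit_id"].astype(str).unique())
    grouped = {str(k): g["t"].to_numpy() for k, g in spikes.groupby("unit_id")}
    for uid in unit_ids:
        st = np.sort(grouped.get(str(uid), np.empty(0)))
        rate = st.size / total_dur if total_dur > 0 else 0.0
        units.append(SpikeTrain(str(uid), st, mean_rate_hz=rate,
                                is_interneuron=rate > cfg.interneuron_hz))

    lfp = []
    for chm in meta.get("lfp_channels", []):
        f = path / chm["file"]
        if not f.exists():
            raise FileNotFoundError(f"missing LFP file: {f}")
        if f.suffix == ".npz":
            samples = np.load(f)["samples"]
        else:
            samples = pd.read_csv(f)["samples"].to_numpy()
        lfp.append(LfpChannel(chm["fs_hz"], samples, chm.get("t0", 0.0),
                              chm.get("channel_id", f.stem)))

    gt = None
    if (path / "ground_truth.yaml").exists():
        gt = yaml.safe_load((path / "ground_truth.yaml").read_text())
    return Session(trace, units, lfp, schedule,
                   track_circumference_cm=circumference, ground_truth=gt)
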