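"""Memoryless Bayesian position decoding from population spike counts.

Per decoding window, the posterior over track angle x follows Bayes' rule
with a flat spatial prior and an independent-Poisson likelihood built from
each unit's day-averaged tuning curve lambda_j(x):

    log P(n|x) = sum_j [ n_j log(tau lambda_j(x)) - tau lambda_j(x) ]

(constant terms dropped), normalized so each window's posterior sums to 1.
Tuning curves are floored at a small rate inside the log to avoid -inf.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circular import circ_dist_deg
from .config import AnalysisConfig
from .session import Session

__all__ = ["TuningModel", "DecodedPosterior", "make_windows", "decode",
           "decoding_accuracy"]


@dataclass
class TuningModel:
    unit_ids: list
    tuning_hz: np.ndarray          # (n_units, n_bins) day-averaged rates
    bin_centers_deg: np.ndarray
    tau_s: float = 0.5

    def __post_init__(self):
        self.tuning_hz = np.atleast_2d(np.asarray(self.tuning_hz, float))
        if np.any(self.tuning_hz < 0):
            raise ValueError("tuning rates must be >= 0")
        if not np.any(self.tuning_hz > 0):
            raise ValueError("all-zero tuning model cannot decode")

    @classmethod
    def from_day_maps(cls, maps: dict, cfg: AnalysisConfig | None = None,
                      included_only: bool = True) -> "TuningModel":
        """Build from {unit_id: day RateMap}, keeping included place cells."""
        cfg = cfg or AnalysisConfig()
        items = [(uid, m) for uid, m in maps.items()
                 if (m.include_for_analysis or not included_only)]
        if not items:
            raise ValueError("no included units")
        ids = [uid for uid, _ in items]
        tuning = np.vstack([m.rate_hz for _, m in items])
        centers = items[0][1].bin_centers_deg
        return cls(ids, tuning, centers, tau_s=cfg.acc_win_s)

    @property
    def n_units(self) -> int:
        return self.tuning_hz.shape[0]

    @property
    def n_bins(self) -> int:
        return self.tuning_hz.shape[1]


@dataclass
class DecodedPosterior:
    window_centers_s: np.ndarray
    windows: np.ndarray            # (W, 2) start/end
    posterior: np.ndarray          # (W, n_bins), rows sum to 1
    n_active_per_window: np.ndarray
    n_spikes_per_window: np.ndarray
    bin_centers_deg: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.posterior.shape[0]

    def com_deg(self) -> np.ndarray:
        """Per-window posterior-weighted circular mean angle."""
        z = self.posterior @ np.exp(1j * np.deg2rad(self.bin_centers_deg))
        return np.angle(z) % (2 * np.pi) * 180.0 / np.pi

    def argmax_deg(self) -> np.ndarray:
        return self.bin_centers_deg[np.argmax(self.posterior, axis=1)]


def make_windows(start_s: float, end_s: float, win_s: float, step_s: float) -> np.ndarray:
    """Partially overlapping windows; the last must end at or before end_s."""
    starts = []
    s = start_s
    while s + win_s <= end_s + 1e-12:
        starts.append(s)
        s += step_s
    if not starts:
        return np.empty((0, 2))
    starts = np.asarray(starts)
    return np.column_stack([starts, starts + win_s])


def _count_matrix(spike_trains, windows) -> np.ndarray:
    """(W, J) spike counts; spike_trains is a list of time arrays ordered as
    the tuning model's units."""
    W = windows.shape[0]
    counts = np.zeros((W, len(spike_trains)))
    for j, st in enumerate(spike_trains):
        st = np.asarray(st, float)
        lo = np.searchsorted(st, windows[:, 0], side="left")
        hi = np.searchsorted(st, windows[:, 1], side="right")
        counts[:, j] = hi - lo
    return counts


def decode(model: TuningModel, spike_trains, windows,
           cfg: AnalysisConfig | None = None) -> DecodedPosterior:
    """Decode posteriors for a window schedule.

    ``spike_trains`` — list of spike-time arrays in the model's unit order
    (or a dict unit_id -> times).
    ``windows`` — (W, 2) start/end array, e.g. from :func:`make_windows`.
    """
    cfg = cfg or AnalysisConfig()
    windows = np.atleast_2d(np.asarray(windows, float))
    if windows.size == 0:
        raise ValueError("no decoding windows")
    if isinstance(spike_trains, dict):
        spike_trains = [spike_trains[uid] for uid in model.unit_ids]
    counts = _count_matrix(spike_trains, windows)          # (W, J)
    tau = windows[:, 1] - windows[:, 0]                    # (W,)
    lam = np.maximum(model.tuning_hz, cfg.rate_floor_hz)   # (J, X)
    log_lam = np.log(lam)
    sum_lam = lam.sum(axis=0)                              # (X,)
    # log P(n|x) up to terms constant in x
    logpost = counts @ log_lam - tau[:, None] * sum_lam[None, :]
    logpost += counts.sum(axis=1, keepdims=True) * np.log(tau)[:, None]
    logpost -= logpost.max(axis=1, keepdims=True)
    post = np.exp(logpost)
    post /= post.sum(axis=1, keepdims=True)
    return DecodedPosterior(
        window_centers_s=windows.mean(axis=1),
        windows=windows,
        posterior=post,
        n_active_per_window=(counts > 0).sum(axis=1),
        n_spikes_per_window=counts.sum(axis=1),
        bin_centers_deg=model.bin_centers_deg,
    )


def decoding_accuracy(session: Session, model: TuningModel,
                      cfg: AnalysisConfig | None = None) -> dict:
    """Decoding-error gate over the day's run epochs.

    Positions are decoded in 500 ms windows advanced by 100 ms, restricted to
    windows in which the rat moved above the speed gate. The error is the
    shortest-arc distance between the actual angle at the window center and
    the maximum-posterior bin. A day passes when the cumulative error
    distribution reaches 50% below 20 deg — i.e. the median error is < 20 deg.

    Returns a dict with per-window errors, the cumulative error curve
    evaluated at 1-deg steps, the confusion matrix (rows: actual-position
    bins; values: mean posterior), and ``passes_criterion``.
    """
    cfg = cfg or AnalysisConfig()
    trace = session.position
    if trace.speed_cm_s is None:
        raise ValueError("speed must be computed")
    unwrapped = np.rad2deg(np.unwrap(np.deg2rad(trace.angle_deg)))
    spikes = {u.unit_id: u.spike_t for u in session.units}
    trains = [spikes[uid] for uid in model.unit_ids]

    all_err, all_post, all_actual, all_centers = [], [], [], []
    for ep in session.epochs("run"):
        windows = make_windows(ep.start_s, ep.end_s, cfg.acc_win_s, cfg.acc_step_s)
        if windows.size == 0:
            continue
        centers = windows.mean(axis=1)
        speed = np.interp(centers, trace.t, trace.speed_cm_s)
        keep = speed > cfg.speed_min
        if not keep.any():
            continue
        windows = windows[keep]
        post = decode(model, trains, windows, cfg)
        actual = np.interp(post.window_centers_s, trace.t, unwrapped) % 360.0
        err = circ_dist_deg(actual, post.argmax_deg())
        all_err.append(err)
        all_post.append(post.posterior)
        all_actual.append(actual)
        all_centers.append(post.window_centers_s)
    if not all_err:
        raise ValueError("no qualifying windows for decoding accuracy")

    errors = np.concatenate(all_err)
    posteriors = np.vstack(all_post)
    actuals = np.concatenate(all_actual)

    edges = np.linspace(0, 360.0, model.n_bins + 1)
    which = np.clip(np.digitize(actuals, edges) - 1, 0, model.n_bins - 1)
    confusion = np.zeros((model.n_bins, model.n_bins))
    for b in range(model.n_bins):
        m = which == b
        if m.any():
            confusion[b] = posteriors[m].mean(axis=0)

    grid = np.arange(0.0, 181.0)
    cumulative = np.array([(errors <= g).mean() for g in grid])
    frac, lim = cfg.acc_criterion
    median_err = float(np.median(errors))
    return {
        "errors_deg": errors,
        "window_centers_s": np.concatenate(all_centers),
        "cumulative_error_deg": grid,
        "cumulative_error_frac": cumulative,
        "confusion_matrix": confusion,
        "median_error_deg": median_err,
        "passes_criterion": bool(median_err < lim),
    }
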