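"""Circular statistics shared across the analysis stages.

All public functions work in degrees, matching the track coordinate system
(angles in [0, 360)) and the theta-phase convention used throughout the
package. Internally angles are converted to radians for trigonometry.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

__all__ = [
    "wrap_deg",
    "signed_delta_deg",
    "circ_dist_deg",
    "circ_mean_deg",
    "resultant_length",
    "circ_var",
    "circ_lin_corr",
    "CircularLinearFit",
    "fit_circular_linear",
    "best_slope_batch",
    "r2_batch",
]


def wrap_deg(a):
    """Wrap angles into [0, 360)."""
    return np.asarray(a, dtype=float) % 360.0


def signed_delta_deg(a, b):
    """Signed shortest-arc difference a - b in (-180, 180]."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % 360.0
    return np.where(d > 180.0, d - 360.0, d)


def circ_dist_deg(a, b):
    """Unsigned shortest-arc distance between angles, in [0, 180]."""
    return np.abs(signed_delta_deg(a, b))


def _to_complex(a_deg, w=None):
    z = np.exp(1j * np.deg2rad(np.asarray(a_deg, dtype=float)))
    if w is not None:
        w = np.asarray(w, dtype=float)
        return z * w, np.sum(w)
    return z, z.size


def circ_mean_deg(a_deg, w=None, axis=None):
    """(Weighted) circular mean direction in degrees, in [0, 360)."""
    z = np.exp(1j * np.deg2rad(np.asarray(a_deg, dtype=float)))
    if w is not None:
        z = z * np.asarray(w, dtype=float)
    return np.angle(np.sum(z, axis=axis)) % (2 * np.pi) * 180.0 / np.pi


def resultant_length(a_deg, w=None, axis=None):
    """Mean resultant length R in [0, 1] of a set of angles."""
    z = np.exp(1j * np.deg2rad(np.asarray(a_deg, dtype=float)))
    if w is not None:
        w = np.asarray(w, dtype=float)
        return np.abs(np.sum(z * w, axis=axis)) / np.sum(w, axis=axis)
    n = np.shape(z)[axis] if axis is not None else np.size(z)
    return np.abs(np.sum(z, axis=axis)) / n


def circ_var(a_deg, w=None, axis=None):
    """Circular variance 1 - R, in [0, 1]."""
    return 1.0 - resultant_length(a_deg, w=w, axis=axis)


def circ_lin_corr(x, phase_deg):
    """Circular-linear correlation between a linear and a circular variable.

    The standard construction: Pearson correlations of x with cos(phase) and
    sin(phase) are combined into

        r = sqrt((rxc^2 + rxs^2 - 2 rxc rxs rcs) / (1 - rcs^2))

    with rcs the correlation between the cosine and sine components. The
    p-value uses the chi-squared approximation n*r^2 ~ chi2(2).

    Returns
    -------
    (r, p) : magnitude of association in [0, 1] and its approximate p-value.
    """
    x = np.asarray(x, dtype=float)
    phi = np.deg2rad(np.asarray(phase_deg, dtype=float))
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    c, s = np.cos(phi), np.sin(phi)
    # degenerate cases: no variation in x or in phase -> no association
    if np.ptp(x) == 0 or (np.std(c) == 0 and np.std(s) == 0):
        return 0.0, 1.0

    def _corr(u, v):
        su, sv = np.std(u), np.std(v)
        if su == 0 or sv == 0:
            return 0.0
        return float(np.corrcoef(u, v)[0, 1])

    rxc, rxs, rcs = _corr(x, c), _corr(x, s), _corr(c, s)
    denom = 1.0 - rcs**2
    if denom <= 0:
        return 0.0, 1.0
    r2 = (rxc**2 + rxs**2 - 2.0 * rxc * rxs * rcs) / denom
    r = float(np.sqrt(max(r2, 0.0)))
    p = float(stats.chi2.sf(n * r * r, df=2))
    return r, p


def best_slope_batch(phases_deg, x, bounds, n_coarse=241, n_fine=41, weights=None):
    """Best circular-linear slope for each row of ``phases_deg``.

    For each candidate slope ``a`` the mean resultant length of the residual
    angles ``phase - a*x`` is evaluated; the slope maximizing it is refined on
    a second, finer grid centered on the coarse optimum. The two-stage grid is
    deterministic and is used identically for observed and shuffled fits.

    Parameters
    ----------
    phases_deg : (m, n) array — m independent angle series over the same x.
    x : (n,) array — the linear covariate (normalized position, or time in s).
    bounds : (lo, hi) slope search interval, in deg per unit of x.

    Returns
    -------
    slopes : (m,) best slope per row.
    """
    phi = np.deg2rad(np.atleast_2d(np.asarray(phases_deg, dtype=float)))
    x = np.asarray(x, dtype=float)
    lo, hi = bounds
    coarse = np.linspace(lo, hi, n_coarse)

    def _resultant(slopes_grid):
        # slopes_grid: (m, k) or (k,) broadcastable; returns (m, k) R values
        a = np.deg2rad(np.atleast_2d(slopes_grid))
        # residual phase: (m, k, n)
        resid = phi[:, None, :] - a[..., None] * x[None, None, :]
        z = np.exp(1j * resid)
        if weights is not None:
            w = np.asarray(weights, dtype=float)
            return np.abs(np.sum(z * w, axis=-1)) / np.sum(w)
        return np.abs(np.mean(z, axis=-1))

    R = _resultant(coarse)  # (m, n_coarse) via broadcast of (1, k)
    best = coarse[np.argmax(R, axis=1)]  # (m,)
    step = coarse[1] - coarse[0] if n_coarse > 1 else (hi - lo)
    offsets = np.linspace(-step, step, n_fine)
    fine = best[:, None] + offsets[None, :]
    fine = np.clip(fine, lo, hi)
    Rf = _resultant(fine)
    rows = np.arange(fine.shape[0])
    return fine[rows, np.argmax(Rf, axis=1)]


def r2_batch(phases_deg, x, slopes, weights=None):
    """Goodness of fit for circular-linear regression lines.

    Defined as 1 - V_resid / V_total, where V is circular variance, the
    residual is the shortest arc between each angle and the fitted line
    ``intercept + slope*x`` (intercept = circular mean of phase - slope*x),
    clipped into [0, 1]. Reduces to the ordinary coefficient of determination
    in the small-angle limit. A zero total variance (all angles equal) yields
    r^2 = 1 with a zero-residual line.
    """
    phi = np.atleast_2d(np.asarray(phases_deg, dtype=float))
    x = np.asarray(x, dtype=float)
    slopes = np.atleast_1d(np.asarray(slopes, dtype=float))
    detr = phi - slopes[:, None] * x[None, :]  # phase - a*x, rows
    z = np.exp(1j * np.deg2rad(detr))
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        inter = np.angle(np.sum(z * w, axis=1))
        R_resid = np.abs(np.sum(z * np.exp(-1j * inter[:, None]) * w, axis=1)) / np.sum(w)
        zt = np.exp(1j * np.deg2rad(phi)) * w
        R_tot = np.abs(np.sum(zt, axis=1)) / np.sum(w)
    else:
        inter = np.angle(np.mean(z, axis=1))
        R_resid = np.abs(np.mean(z * np.exp(-1j * inter[:, None]), axis=1))
        R_tot = np.abs(np.mean(np.exp(1j * np.deg2rad(phi)), axis=1))
    v_resid = 1.0 - R_resid
    v_tot = 1.0 - R_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = 1.0 - v_resid / v_tot
    r2 = np.where(v_tot <= 1e-15, 1.0, r2)
    intercept = np.rad2deg(inter) % 360.0
    return np.clip(r2, 0.0, 1.0), intercept


class CircularLinearFit:
    """Result of a circular-linear regression of angle on a linear covariate.

    Attributes
    ----------
    slope : deg per unit x (signed).
    intercept_deg : fitted angle at x = 0, in [0, 360).
    r2 : circular coefficient of determination in [0, 1].
    r : circular-linear correlation magnitude in [0, 1].
    p_value : chi-squared approximation for r.
    """

    def __init__(self, slope, intercept_deg, r2, r, p_value, n):
        self.slope = float(slope)
        self.intercept_deg = float(intercept_deg)
        self.r2 = float(r2)
        self.r = float(r)
        self.p_value = float(p_value)
        self.n = int(n)

    def predict(self, x):
        """Line angle at x, wrapped to [0, 360)."""
        return wrap_deg(self.intercept_deg + self.slope * np.asarray(x, dtype=float))

    def __repr__(self):  # pragma: no cover
        return (
            f"CircularLinearFit(slope={self.slope:.3g}, r2={self.r2:.3f}, "
            f"r={self.r:.3f}, n={self.n})"
        )


def fit_circular_linear(x, phase_deg, bounds, weights=None):
    """Fit angle ~ intercept + slope*x by maximizing the residual resultant.

    ``bounds`` is the (lo, hi) slope search interval. Returns a
    :class:`CircularLinearFit`.
    """
    x = np.asarray(x, dtype=float)
    phase_deg = np.asarray(phase_deg, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations to fit a slope")
    slope = best_slope_batch(phase_deg[None, :], x, bounds, weights=weights)[0]
    r2, intercept = r2_batch(phase_deg[None, :], x, np.array([slope]), weights=weights)
    if x.size >= 3:
        r, p = circ_lin_corr(x, phase_deg)
    else:
        r, p = 0.0, 1.0
    return CircularLinearFit(slope, intercept[0], r2[0], r, p, x.size)
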