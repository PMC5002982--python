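"""Hue tuning curves: preprocessing, smoothing, model fitting.

The tuning model is a truncated raised-cosine ("sine-squared") curve on
the hue circle,

    r(theta) = fmin + fmax * cos^2( pi * (theta - alpha) / (2 w) )   if |theta - alpha| < w
    r(theta) = fmin                                                  otherwise

with the angular difference wrapped circularly to (-180, 180]. ``w`` is
the full width at half maximum in degrees: at |theta - alpha| = w/2 the
curve sits exactly halfway between fmin and fmin + fmax. A linear
(cosine) cell corresponds to w = 180; smaller w means narrower,
more nonlinear tuning.

Fitting is bounded multi-start nonlinear least squares with a
deterministic start grid (an alpha start at every sampled angle), so the
fit involves no random numbers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from ._angles import circ_diff, wrap360

W_MIN = 36.0   # two inter-stimulus gaps on the 21-hue grid; guards delta-like overfits
W_MAX = 360.0


@dataclass
class TuningFit:
    """Fitted tuning parameters for one neuron in one luminance class."""

    fmin: float
    fmax: float
    width_w: float
    peak_alpha: float
    r2: float
    luminance_class: str | None = None
    reliable: bool = True


class NoResponseError(ValueError):
    """The PSTH never crosses the response threshold."""


def integrate_window(psth, bin_ms, baseline_mean, baseline_sd, stim_duration):
    """Latency-anchored response window and its mean rate.

    ``psth`` is a vector of firing rates in consecutive ``bin_ms`` bins
    starting at stimulus onset. The visual latency is the first bin whose
    rate exceeds baseline_mean + 2.5 * baseline_sd. The window ends when
    the rate falls back below that threshold, or at
    stim_duration - latency/4 (which avoids integrating OFF responses),
    whichever comes first.

    Returns (latency_ms, window_ms, mean_rate).
    """
    psth = np.asarray(psth, dtype=float)
    thresh = baseline_mean + 2.5 * baseline_sd
    above = psth > thresh
    if not np.any(above):
        raise NoResponseError("response never exceeds baseline + 2.5 SD")
    i0 = int(np.argmax(above))
    latency = i0 * bin_ms
    cap = stim_duration - latency / 4.0
    end = i0
    while end < len(psth) and psth[end] > thresh and (end + 1) * bin_ms <= cap:
        end += 1
    end = max(end, i0 + 1)
    window = (end - i0) * bin_ms
    return latency, window, float(np.mean(psth[i0:end]))


def boxcar_smooth(responses, half_width: int = 1):
    """Circular moving average over a window of 2*half_width + 1 stimuli.

    Responses must be ordered by ascending hue angle; the window wraps
    around the hue circle.
    """
    r = np.asarray(responses, dtype=float)
    if half_width == 0:
        return r.copy()
    n = len(r)
    idx = (np.arange(n)[:, None] + np.arange(-half_width, half_width + 1)[None, :]) % n
    return r[idx].mean(axis=1)


def ss_curve(theta, fmin, fmax, w, alpha):
    """Evaluate the truncated raised-cosine tuning curve (rates, Hz)."""
    d = np.abs(circ_diff(theta, alpha))
    out = np.full_like(np.asarray(d, dtype=float), fmin, dtype=float)
    inside = d < w
    out[inside] = fmin + fmax * np.cos(np.pi * d[inside] / (2.0 * w)) ** 2
    return out


def _curve_from_fit(theta, fit: TuningFit):
    return ss_curve(theta, fit.fmin, fit.fmax, fit.width_w, fit.peak_alpha)


def peak_angle(responses, angles):
    """Angle of the maximal response; ties go to the first angle in
    ascending-angle order."""
    responses = np.asarray(responses, dtype=float)
    angles = np.asarray(angles, dtype=float)
    if responses.size == 0:
        raise ValueError("empty response vector")
    order = np.argsort(angles, kind="stable")
    r_sorted = responses[order]
    return float(angles[order][int(np.argmax(r_sorted))])


def fit_tuning(
    responses,
    angles,
    smoothing: bool = True,
    luminance_class: str | None = None,
) -> TuningFit:
    """Least-squares fit of the truncated raised-cosine model.

    Responses are first ordered by hue angle and optionally boxcar
    smoothed (+/- one stimulus). The optimizer runs bounded local least
    squares from a deterministic grid of starts: every sampled angle as
    an alpha start, crossed with a few width starts. R^2 is computed
    against the (smoothed) responses actually fit.
    """
    responses = np.asarray(responses, dtype=float)
    angles = np.asarray(angles, dtype=float)
    if len(np.unique(np.round(angles, 6))) < 8:
        raise ValueError("need at least 8 distinct angles")
    if not np.all(np.isfinite(responses)):
        raise ValueError("responses must be finite")
    order = np.argsort(angles, kind="stable")
    ang = angles[order]
    y = responses[order]
    if smoothing:
        y = boxcar_smooth(y, half_width=1)

    y_min, y_max = float(np.min(y)), float(np.max(y))
    span = y_max - y_min
    if span <= 1e-12:
        # flat cell: fmax ~ 0, any alpha; flag as unreliable
        return TuningFit(
            fmin=y_min, fmax=0.0, width_w=W_MAX, peak_alpha=float(ang[0]),
            r2=0.0, luminance_class=luminance_class, reliable=False,
        )

    def resid(p):
        fmin, fmax, w, alpha = p
        return ss_curve(ang, fmin, fmax, w, alpha) - y

    lb = [y_min - span, 0.0, W_MIN, -360.0]
    ub = [y_max + span, 4.0 * span, W_MAX, 720.0]
    best = None
    alpha0 = ang[int(np.argmax(y))]
    w_starts = (60.0, 100.0, 180.0, 300.0)
    starts = [(alpha0, w0) for w0 in w_starts]
    starts += [(a, 120.0) for a in ang]
    for a0, w0 in starts:
        p0 = np.array([y_min, span, w0, a0])
        try:
            sol = least_squares(resid, p0, bounds=(lb, ub), method="trf")
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or sol.cost < best.cost - 1e-15:
            best = sol
    fmin, fmax, w, alpha = best.x
    ss_res = 2.0 * best.cost
    ss_tot = float(np.sum((y - np.mean(y)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return TuningFit(
        fmin=float(fmin),
        fmax=float(fmax),
        width_w=float(w),
        peak_alpha=float(wrap360(alpha)),
        r2=float(r2),
        luminance_class=luminance_class,
        reliable=True,
    )


def fit_population(rates, angles, smoothing: bool = True, luminance_class=None):
    """Fit every row of a neurons x stimuli rate matrix; returns a list."""
    return [
        fit_tuning(row, angles, smoothing=smoothing, luminance_class=luminance_class)
        for row in np.asarray(rates, dtype=float)
    ]
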