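"""Photocurrent and synaptic-current quantification from voltage-clamp traces.

Covers the four scalar readouts of channel function used throughout the
analyses:

* stationary photocurrent — baseline-subtracted current at the end of a 1 s
  light pulse (mean over the final 10 ms by default);
* peak photocurrent — baseline-subtracted extremum within the light epoch;
* channel closing kinetics — mono-exponential fit
  ``I(t) = I0 * exp(-t / tau_off) + C`` to the post-offset decay;
* light sensitivity — saturation fit ``I(LPD) = I_max * LPD / (EPD50 + LPD)``
  of stationary photocurrent against light power density, with the
  effective LPD for half-maximal photocurrent (EPD50) as free parameter;
* EPSC amplitude — maximal deviation of the Welch-weighted Savitzky-Golay
  smoothed current from its pre-light baseline within 20 ms of light
  delivery.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit


@dataclass
class CurrentTrace:
    """Uniformly sampled holding-current trace.

    ``light_epochs`` is a list of ``(on_s, off_s, lpd_mw_mm2, wavelength_nm)``.
    """

    t: np.ndarray  # s
    i: np.ndarray  # pA
    sample_rate: float  # Hz
    v_hold: float = -35.0  # mV
    light_epochs: list = field(default_factory=list)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.i = np.asarray(self.i, dtype=float)
        if self.t.shape != self.i.shape or self.t.ndim != 1:
            raise ValueError("t and i must be 1-D arrays of equal length")
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be positive")
        for on, off, *_ in self.light_epochs:
            if not (self.t[0] <= on < off <= self.t[-1] + 1.0 / self.sample_rate):
                raise ValueError("light epoch outside trace")

    def window_mean(self, t0: float, t1: float) -> float:
        m = (self.t >= t0) & (self.t < t1)
        if not m.any():
            raise ValueError(f"no samples in [{t0}, {t1}] s")
        return float(self.i[m].mean())


@dataclass
class KineticsFit:
    """Mono-exponential closing-kinetics fit result."""

    i0_pa: float
    tau_off_s: float
    c_pa: float
    residual_norm: float
    converged: bool


@dataclass
class SaturationFit:
    """Light-sensitivity saturation fit result."""

    i_max_pa: float
    epd50_mw_mm2: float
    residual_norm: float
    converged: bool

    def predict(self, lpd):
        lpd = np.asarray(lpd, dtype=float)
        return self.i_max_pa * lpd / (self.epd50_mw_mm2 + lpd)


def _baseline(trace: CurrentTrace, epoch_on: float,
              baseline_s: float = 0.05) -> float:
    t0 = max(trace.t[0], epoch_on - baseline_s)
    if t0 >= epoch_on:
        raise ValueError("no pre-pulse samples available for baseline")
    return trace.window_mean(t0, epoch_on)


def stationary_current(trace: CurrentTrace, epoch=0,
                       avg_window_s: float = 0.010,
                       baseline_s: float = 0.05) -> float:
    """Baseline-subtracted photocurrent at the end of a light pulse.

    The stationary photocurrent is the mean current over the final
    ``avg_window_s`` of the pulse minus the mean over the ``baseline_s``
    immediately preceding light onset.  Invariant under additive baseline
    shifts.
    """
    on, off = _epoch_bounds(trace, epoch)
    if off - on < avg_window_s:
        raise ValueError("light epoch shorter than the averaging window")
    plateau = trace.window_mean(off - avg_window_s, off)
    return plateau - _baseline(trace, on, baseline_s)


def peak_current(trace: CurrentTrace, epoch=0,
                 baseline_s: float = 0.05) -> float:
    """Baseline-subtracted extremum of the current within the light epoch
    (signed; the sign reflects the conductance direction at V_hold)."""
    on, off = _epoch_bounds(trace, epoch)
    base = _baseline(trace, on, baseline_s)
    m = (trace.t >= on) & (trace.t < off)
    if not m.any():
        raise ValueError("no samples inside the light epoch")
    dev = trace.i[m] - base
    return float(dev[np.argmax(np.abs(dev))])


def _epoch_bounds(trace: CurrentTrace, epoch):
    if isinstance(epoch, int):
        if not trace.light_epochs:
            raise ValueError("trace carries no light epochs")
        on, off = trace.light_epochs[epoch][:2]
    else:
        on, off = epoch[:2]
    return float(on), float(off)


def fit_tau_off(trace: CurrentTrace, offset_t: float,
                fit_window_s: float | None = None) -> KineticsFit:
    """Mono-exponential fit of the post-offset current decay.

    Fits ``I(t) = I0 * exp(-(t - offset) / tau_off) + C`` on the samples
    after ``offset_t`` by nonlinear least squares.  Initialization: ``I0``
    from the offset-minus-end current, ``C`` from the trace end, ``tau``
    from the time at which the decay first crosses 1/e of its span.  Never
    raises on noisy data; non-decaying input yields ``converged=False``.
    """
    m = trace.t >= offset_t
    if fit_window_s is not None:
        m &= trace.t < offset_t + fit_window_s
    t = trace.t[m] - offset_t
    y = trace.i[m]
    if t.size < 4:
        return KineticsFit(np.nan, np.nan, np.nan, np.nan, False)

    c0 = float(np.mean(y[-max(3, y.size // 20):]))
    i0 = float(y[0] - c0)
    if abs(i0) < 1e-12:
        # flat input: amplitude zero, tau unidentifiable
        return KineticsFit(0.0, np.nan, c0, float(np.linalg.norm(y - c0)),
                           False)
    span = np.abs(y - c0)
    below = np.flatnonzero(span <= abs(i0) / np.e)
    tau0 = float(t[below[0]]) if below.size and t[below[0]] > 0 else \
        float(t[-1]) / 5.0

    def model(tt, i0_, tau_, c_):
        return i0_ * np.exp(-tt / tau_) + c_

    try:
        popt, _ = curve_fit(model, t, y, p0=[i0, tau0, c0],
                            bounds=([-np.inf, 1e-9, -np.inf],
                                    [np.inf, np.inf, np.inf]),
                            maxfev=10000)
    except (RuntimeError, ValueError):
        return KineticsFit(np.nan, np.nan, np.nan, np.nan, False)
    resid = float(np.linalg.norm(y - model(t, *popt)))
    i0_hat, tau_hat, c_hat = map(float, popt)
    # reject fits of non-decaying data: amplitude sign opposite to the
    # offset-to-end excursion, or a time constant far beyond the data span
    # (a ramp fits an exponential arbitrarily well in that limit)
    converged = np.isfinite(tau_hat) and 1e-9 < tau_hat <= (t[-1] - t[0]) \
        and np.sign(i0_hat) == np.sign(i0)
    return KineticsFit(i0_hat, tau_hat, c_hat, resid, bool(converged))


def fit_epd50(points) -> SaturationFit:
    """Saturation fit of stationary photocurrent vs light power density.

    ``points`` is a sequence of ``(lpd_mw_mm2, stationary_pa)``; at least 3
    distinct LPDs are required.  Model: ``I = I_max * LPD / (EPD50 + LPD)``,
    so the fitted curve evaluates to ``I_max / 2`` at ``LPD = EPD50``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be (lpd, current) pairs")
    lpd, cur = pts[:, 0], pts[:, 1]
    if np.unique(lpd).size < 3:
        raise ValueError("need >= 3 distinct light power densities")

    def model(x, imax, epd50):
        return imax * x / (epd50 + x)

    i_max0 = float(np.max(np.abs(cur))) or 1.0
    sign = np.sign(cur[np.argmax(np.abs(cur))]) or 1.0
    p0 = [sign * i_max0, float(np.median(lpd))]
    try:
        popt, _ = curve_fit(model, lpd, cur, p0=p0,
                            bounds=([-np.inf, 1e-12], [np.inf, np.inf]),
                            maxfev=10000)
    except (RuntimeError, ValueError):
        return SaturationFit(np.nan, np.nan, np.nan, False)
    resid = float(np.linalg.norm(cur - model(lpd, *popt)))
    scale = float(np.linalg.norm(cur)) or 1.0
    return SaturationFit(float(popt[0]), float(popt[1]), resid,
                         converged=resid / scale < 0.5)


def welch_savgol(y, window: int = 11, order: int = 2) -> np.ndarray:
    """Savitzky-Golay smoothing with Welch (parabolic) window weights.

    Each output sample is the value at the window center of a local
    polynomial of degree ``order`` fitted by weighted least squares over
    ``window`` samples, with weights ``w_k = 1 - (k / ((m+1)/2))^2`` for
    offsets k in [-(m-1)/2, (m-1)/2].  Reproduces polynomials up to
    ``order`` exactly.  Edge samples use truncated windows with the same
    weight law.
    """
    y = np.asarray(y, dtype=float)
    if window % 2 != 1 or window < order + 2:
        raise ValueError("window must be odd and > order + 1")
    half = (window - 1) // 2
    n = y.size
    if n < window:
        raise ValueError("input shorter than the smoothing window")

    def center_coeffs(ks):
        w = 1.0 - (ks / ((window + 1) / 2.0)) ** 2
        X = np.vander(ks, order + 1, increasing=True)
        xtw = X.T * w
        return np.linalg.solve(xtw @ X, xtw)[0]  # row evaluating at k=0

    interior = center_coeffs(np.arange(-half, half + 1, dtype=float))
    out = np.empty(n)
    # interior via correlation with the fixed coefficient vector
    out[half:n - half] = np.correlate(y, interior[::-1], mode="valid")
    for i in range(half):
        ks = np.arange(-i, half + 1, dtype=float)
        out[i] = center_coeffs(ks) @ y[0:i + half + 1]
        ks = np.arange(-half, i + 1, dtype=float)
        out[n - 1 - i] = center_coeffs(ks) @ y[n - 1 - i - half:n]
    return out


def epsc_amplitude(trace: CurrentTrace, light_t: float,
                   window_s: float = 0.020,
                   baseline_s: float = 0.05,
                   sg_window: int = 11) -> float:
    """Light-evoked EPSC amplitude (pA, magnitude).

    The trace is smoothed with the Welch-weighted Savitzky-Golay filter
    (11 points, order 2); the amplitude is the maximal absolute deviation of
    the smoothed current from the pre-light smoothed baseline within
    ``window_s`` after light delivery.
    """
    if light_t + window_s > trace.t[-1] + 1.0 / trace.sample_rate:
        raise ValueError("response window exceeds the trace")
    smoothed = welch_savgol(trace.i, window=sg_window, order=2)
    pre = (trace.t >= max(trace.t[0], light_t - baseline_s)) & \
        (trace.t < light_t)
    if not pre.any():
        raise ValueError("no pre-light samples for the baseline")
    base = smoothed[pre].mean()
    m = (trace.t >= light_t) & (trace.t < light_t + window_s)
    return float(np.max(np.abs(smoothed[m] - base)))
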