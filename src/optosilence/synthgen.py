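"""Synthetic inputs with the statistical structure each analysis assumes.

Every generator is deterministic under its seed (sub-streams are spawned
per unit/trial from one ``numpy.random.SeedSequence``) and returns ground
truth alongside the data, so downstream classifiers can be scored.

What is emulated
----------------
* **Spike trains** — inhomogeneous-Poisson units whose rate drops by a
  suppression fraction during a light pulse and optionally rebounds
  transiently after offset; short-latency antidromic spikes can be injected
  at light onset with per-trial probability.  Default protocol: 5 s pulses,
  5 s pre/post, 10 trials per light power density.
* **Pixel-change traces** — per-frame changed-pixel counts, high during
  motion and near zero inside scheduled freezing bouts, with optional
  patch-cord artifact; 25 frames per second.
* **Frame stacks** — a bright random-walk blob ("mouse") on a dark arena,
  stationary during bouts, plus an optional moving cord line, for
  end-to-end testing of the pixel-change stage.
* **Current traces** — photocurrents rising to the saturation-law
  stationary level and decaying mono-exponentially at offset, or delayed
  difference-of-exponentials EPSCs; 20 kHz sampling, additive Gaussian
  noise.
* **Region-count tables** — per-region Poisson nuclei counts with an
  ipsilateral suppression factor applied in expressing regions only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .biophys import CurrentTrace
from .ephys import DEFAULT_LPDS, LightProtocol, SpikeDataset
from .freezing import DEFAULT_FPS, PixelChangeTrace


@dataclass
class SimConfig:
    """Parameters of the synthetic recording session.

    Rates in Hz, durations in s, probabilities in [0, 1].  With
    ``rate_cv > 0`` per-unit baseline rates are drawn from a gamma
    distribution with mean ``baseline_rate_hz`` and that coefficient of
    variation; the default 0 keeps all units at the stated rate so analytic
    expectations stay closed-form.
    """

    seed: int = 0
    n_units: int = 50
    baseline_rate_hz: float = 5.0
    rate_cv: float = 0.0
    suppression_fraction: float = 0.8
    rebound_gain: float = 0.0
    rebound_tau_s: float = 0.5
    antidromic_prob: float = 0.0
    antidromic_latency_ms: float = 4.0
    antidromic_jitter_ms: float = 1.0
    n_trials: int = 10
    pre_s: float = 5.0
    light_s: float = 5.0
    post_s: float = 5.0
    lpds: tuple = DEFAULT_LPDS
    # behavior
    fps: float = DEFAULT_FPS
    frame_shape: tuple = (96, 128)
    session_s: float = 300.0
    bout_schedule: tuple = ((60.0, 75.0), (130.0, 150.0), (220.0, 230.0))
    motion_px_mean: float = 3000.0
    motion_px_sd: float = 500.0
    freezing_px_mean: float = 20.0
    freezing_px_sd: float = 10.0
    cord_px_mean: float = 0.0  # additive patch-cord artifact (global mode)
    # traces
    current_noise_sd_pa: float = 5.0
    sample_rate_hz: float = 20_000.0

    def __post_init__(self):
        if self.baseline_rate_hz <= 0:
            raise ValueError("baseline rate must be positive")
        for name in ("suppression_fraction", "antidromic_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.rebound_gain < 0:
            raise ValueError("rebound gain must be >= 0")
        for name in ("pre_s", "light_s", "post_s", "fps", "session_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        bouts = sorted(self.bout_schedule)
        for (a0, a1), (b0, b1) in zip(bouts, bouts[1:]):
            if b0 < a1:
                raise ValueError("overlapping freezing bouts")
        for b0, b1 in bouts:
            if not (0 <= b0 < b1 <= self.session_s):
                raise ValueError("bout outside session")

    def with_(self, **kw) -> "SimConfig":
        return replace(self, **kw)


def _rate_profile(cfg: SimConfig, r0: float):
    """Piecewise rate function r(t) and its maximum over the trial."""
    s = cfg.suppression_fraction
    g = cfg.rebound_gain
    t_off = cfg.light_s

    def r(t):
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, r0)
        out[(t >= 0) & (t < t_off)] = r0 * (1.0 - s)
        post = t >= t_off
        out[post] = r0 * (1.0 + g * np.exp(-(t[post] - t_off) / cfg.rebound_tau_s))
        return out

    return r, r0 * max(1.0, 1.0 + g)


def expected_relative_fr(cfg: SimConfig) -> float:
    """Closed-form light-window / pre-window rate ratio of the generator."""
    return 1.0 - cfg.suppression_fraction


def gen_spike_dataset(cfg: SimConfig,
                      protocol: LightProtocol | None = None) -> SpikeDataset:
    """Simulate an extracellular recording session.

    Each (unit, LPD, trial) is an inhomogeneous Poisson process on
    [-pre, light + post) s sampled by thinning against the max-rate bound
    ``r0 * (1 + rebound_gain)``; antidromic spikes are extra events at
    onset + truncated-Gaussian latency with per-trial probability.

    Ground truth in ``dataset.truth``: per-unit baseline rate, the
    suppression fraction, and which units carry antidromic spikes.
    """
    if protocol is None:
        protocol = LightProtocol(pulse_s=cfg.light_s, pre_s=cfg.pre_s,
                                 post_s=cfg.post_s, n_trials=cfg.n_trials,
                                 lpds=cfg.lpds)
    ss = np.random.SeedSequence(cfg.seed)
    unit_streams = ss.spawn(cfg.n_units)
    col_unit, col_trial, col_t, col_lpd = [], [], [], []
    unit_rates = {}
    for u, child in enumerate(unit_streams):
        rng = np.random.default_rng(child)
        if cfg.rate_cv > 0:
            shape = 1.0 / cfg.rate_cv ** 2
            r0 = float(rng.gamma(shape, cfg.baseline_rate_hz / shape))
        else:
            r0 = cfg.baseline_rate_hz
        unit_rates[u] = r0
        rate, rmax = _rate_profile(cfg, r0)
        t0, t1 = -cfg.pre_s, cfg.light_s + cfg.post_s
        span = t1 - t0
        for lpd in cfg.lpds:
            for trial in range(cfg.n_trials):
                n = rng.poisson(rmax * span)
                t = rng.uniform(t0, t1, size=n)
                keep = rng.uniform(0, 1, size=n) < rate(t) / rmax
                spikes = t[keep]
                if cfg.antidromic_prob > 0 and \
                        rng.uniform() < cfg.antidromic_prob:
                    lat = -1.0
                    while lat < 0:
                        lat = rng.normal(cfg.antidromic_latency_ms,
                                         cfg.antidromic_jitter_ms)
                    spikes = np.append(spikes, lat / 1000.0)
                spikes.sort()
                col_t.append(spikes)
                col_unit.append(np.full(spikes.size, u, dtype=np.int64))
                col_trial.append(np.full(spikes.size, trial, dtype=np.int64))
                col_lpd.append(np.full(spikes.size, lpd))
    events = pd.DataFrame({
        "unit": np.concatenate(col_unit) if col_unit else np.array([], int),
        "trial": np.concatenate(col_trial) if col_trial else np.array([], int),
        "t_s": np.concatenate(col_t) if col_t else np.array([]),
        "lpd": np.concatenate(col_lpd) if col_lpd else np.array([]),
    })
    truth = {"unit_rates_hz": unit_rates,
             "suppression_fraction": cfg.suppression_fraction,
             "rebound_gain": cfg.rebound_gain,
             "antidromic_prob": cfg.antidromic_prob,
             "antidromic_latency_ms": cfg.antidromic_latency_ms}
    return SpikeDataset(events=events, protocol=protocol, truth=truth)


def bout_labels(cfg: SimConfig) -> np.ndarray:
    """Ground-truth boolean freezing label per frame from the schedule."""
    n_frames = int(round(cfg.session_s * cfg.fps))
    labels = np.zeros(n_frames, dtype=bool)
    for b0, b1 in cfg.bout_schedule:
        labels[int(round(b0 * cfg.fps)):int(round(b1 * cfg.fps))] = True
    return labels


def gen_pixel_trace(cfg: SimConfig):
    """Simulate a changed-pixel-count trace with scheduled freezing bouts.

    Outside bouts the count fluctuates around ``motion_px_mean``; inside
    bouts around ``freezing_px_mean`` (respiration-scale residual motion);
    ``cord_px_mean`` adds patch-cord artifact counts everywhere.  Counts are
    clipped at zero; frame 0 is zero by convention.

    Returns ``(trace, labels)`` with ground-truth boolean labels per frame.
    """
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    labels = bout_labels(cfg)
    n = labels.size
    values = np.where(
        labels,
        rng.normal(cfg.freezing_px_mean, cfg.freezing_px_sd, size=n),
        rng.normal(cfg.motion_px_mean, cfg.motion_px_sd, size=n))
    if cfg.cord_px_mean > 0:
        values += rng.poisson(cfg.cord_px_mean, size=n)
    values = np.clip(values, 0, None)
    values[0] = 0.0
    h, w = cfg.frame_shape
    trace = PixelChangeTrace(values=values, fps=cfg.fps,
                             frame_pixels=196_608, roi_mode="global")
    return trace, labels


def gen_frame_stack(cfg: SimConfig, n_frames: int | None = None,
                    blob_radius: int = 6, step_px: int = 2,
                    with_cord: bool = False):
    """Render a synthetic grayscale video: a bright disk ("mouse") random-
    walking on a dark arena, stationary during scheduled bouts; optionally
    a bright moving line ("patch cord") confined to the top rows, away from
    the animal.

    Returns ``(frames, truth)`` where frames is (n, h, w) uint8 and truth
    holds per-frame bout labels and the mouse-region mask.
    """
    h, w = cfg.frame_shape
    if min(h, w) < 64:
        raise ValueError("frame shape must be >= 64x64")
    if 2 * blob_radius >= min(h, w):
        raise ValueError("blob diameter must be smaller than the frame")
    labels = bout_labels(cfg)
    if n_frames is None:
        n_frames = labels.size
    labels = labels[:n_frames]
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(2)[1])

    yy, xx = np.mgrid[0:h, 0:w]
    cord_band = h // 6  # cord stays in the top band, mouse below it
    cy, cx = float(h // 2), float(w // 2)
    frames = np.zeros((n_frames, h, w), dtype=np.uint8)
    mouse_mask = np.zeros((h, w), dtype=bool)
    for f in range(n_frames):
        if f > 0 and not labels[f]:
            cy += rng.integers(-step_px, step_px + 1)
            cx += rng.integers(-step_px, step_px + 1)
            cy = float(np.clip(cy, cord_band + blob_radius + 2, h - blob_radius - 1))
            cx = float(np.clip(cx, blob_radius, w - blob_radius - 1))
        frame = np.full((h, w), 20, dtype=np.uint8)
        disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= blob_radius ** 2
        frame[disk] = 200
        mouse_mask |= disk
        if with_cord:
            col = int((f * 3) % (w - 2)) + 1
            frame[0:cord_band, col] = 180
        frames[f] = frame
    truth = {"labels": labels, "mouse_mask": mouse_mask,
             "cord_rows": (0, cord_band) if with_cord else None}
    return frames, truth


def gen_current_trace(kind: str, *, seed: int = 0,
                      sample_rate_hz: float = 20_000.0,
                      noise_sd_pa: float = 0.0,
                      v_hold_mv: float = -35.0,
                      baseline_pa: float = 0.0,
                      # photocurrent parameters
                      i_max_pa: float = 1000.0,
                      epd50_mw_mm2: float = 0.05,
                      lpd_mw_mm2: float = 1.0,
                      wavelength_nm: float = 470.0,
                      tau_on_s: float = 0.003,
                      tau_off_s: float = 0.010,
                      peak_factor: float = 1.0,
                      desens_tau_s: float = 0.2,
                      pre_s: float = 0.1,
                      light_s: float = 1.0,
                      post_s: float = 0.3,
                      # EPSC parameters
                      epsc_pa: float = 150.0,
                      epsc_latency_s: float = 0.008,
                      epsc_tau_rise_s: float = 0.001,
                      epsc_tau_decay_s: float = 0.005) -> CurrentTrace:
    """Simulate a voltage-clamp current trace.

    ``kind='photocurrent'``: mono-exponential rise (tau_on) to the
    stationary level given by the saturation law
    ``I_ss = i_max * LPD / (EPD50 + LPD)`` (times an optional transient
    peak), then mono-exponential decay (tau_off) after light offset.
    ``kind='epsc'``: light pulse at t = pre_s followed, after a synaptic
    latency, by a difference-of-exponentials deflection of amplitude
    ``epsc_pa``.  Additive Gaussian noise of ``noise_sd_pa``.  The
    ground-truth parameters are attached as ``trace.truth``.
    """
    if sample_rate_hz <= 0:
        raise ValueError("sample rate must be positive")
    if min(tau_on_s, tau_off_s, epsc_tau_rise_s, epsc_tau_decay_s) <= 0:
        raise ValueError("time constants must be positive")
    rng = np.random.default_rng(seed)
    total = pre_s + light_s + post_s
    n = int(round(total * sample_rate_hz))
    t = np.arange(n) / sample_rate_hz
    i = np.full(n, baseline_pa, dtype=float)
    on, off = pre_s, pre_s + light_s

    if kind == "photocurrent":
        i_ss = i_max_pa * lpd_mw_mm2 / (epd50_mw_mm2 + lpd_mw_mm2)
        i_peak = peak_factor * i_ss
        during = (t >= on) & (t < off)
        td = t[during] - on
        envelope = i_ss + (i_peak - i_ss) * np.exp(-td / desens_tau_s)
        i[during] += (1.0 - np.exp(-td / tau_on_s)) * envelope
        i_at_off = (1.0 - math.exp(-light_s / tau_on_s)) * \
            (i_ss + (i_peak - i_ss) * math.exp(-light_s / desens_tau_s))
        post = t >= off
        i[post] += i_at_off * np.exp(-(t[post] - off) / tau_off_s)
        truth = {"i_ss_pa": i_ss, "i_peak_pa": i_peak,
                 "tau_off_s": tau_off_s, "i_max_pa": i_max_pa,
                 "epd50_mw_mm2": epd50_mw_mm2}
        epochs = [(on, off, lpd_mw_mm2, wavelength_nm)]
    elif kind == "epsc":
        t0 = on + epsc_latency_s
        m = t >= t0
        td = t[m] - t0
        shape = np.exp(-td / epsc_tau_decay_s) - np.exp(-td / epsc_tau_rise_s)
        # peak of the difference of exponentials, for amplitude normalization
        tp = (epsc_tau_decay_s * epsc_tau_rise_s
              / (epsc_tau_decay_s - epsc_tau_rise_s)
              * math.log(epsc_tau_decay_s / epsc_tau_rise_s))
        peak = math.exp(-tp / epsc_tau_decay_s) - math.exp(-tp / epsc_tau_rise_s)
        i[m] += epsc_pa * shape / peak
        truth = {"epsc_pa": epsc_pa, "latency_s": epsc_latency_s}
        epochs = [(on, min(on + 0.005, off), lpd_mw_mm2, wavelength_nm)]
    else:
        raise ValueError(f"unknown trace kind {kind!r}")

    if noise_sd_pa > 0:
        i += rng.normal(0.0, noise_sd_pa, size=n)
    trace = CurrentTrace(t=t, i=i, sample_rate=sample_rate_hz,
                         v_hold=v_hold_mv, light_epochs=epochs)
    trace.truth = truth
    return trace


def gen_region_counts(*, seed: int = 0, n_expressing: int = 10,
                      n_non_expressing: int = 10,
                      mean_count: float = 200.0,
                      ipsi_suppression_factor: float = 1.0,
                      dapi_mean: float = 1000.0) -> pd.DataFrame:
    """Simulate per-region nuclei counts for lateralization analysis.

    c-Fos counts are Poisson with mean ``mean_count`` everywhere except
    ipsilateral expressing regions, whose mean is multiplied by
    ``ipsi_suppression_factor`` (1 = no effect, 0 = complete silencing).
    DAPI counts are symmetric Poisson with mean ``dapi_mean`` (nuclear
    density is unaffected by silencing).
    """
    if mean_count < 0 or dapi_mean < 0 or ipsi_suppression_factor < 0:
        raise ValueError("means and factors must be non-negative")
    rng = np.random.default_rng(seed)
    rows = []
    for cls, n_regions in (("expressing", n_expressing),
                           ("non-expressing", n_non_expressing)):
        for r in range(n_regions):
            region = f"{cls[:4]}_{r}"
            for hemi in ("ipsi", "contra"):
                mu = mean_count
                if cls == "expressing" and hemi == "ipsi":
                    mu = mean_count * ipsi_suppression_factor
                rows.append({"region": region, "region_class": cls,
                             "hemisphere": hemi,
                             "count": int(rng.poisson(mu)), "stain": "cfos"})
                rows.append({"region": region, "region_class": cls,
                             "hemisphere": hemi,
                             "count": int(rng.poisson(dapi_mean)),
                             "stain": "dapi"})
    return pd.DataFrame(rows)
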