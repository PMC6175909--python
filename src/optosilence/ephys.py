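"""Per-unit and population analysis of optogenetic silencing from sorted
spike times.

The substrate is a :class:`SpikeDataset`: trial-aligned spike timestamps
(light onset at t = 0) per unit and light power density (LPD), plus the
light protocol.  Two classification procedures operate on it:

* *silencing* (long pulses, default 5 s, 10 trials per LPD): a paired
  two-tailed t-test compares per-trial spike counts between the 5 s
  pre-light and the 5 s light windows; a unit is suppressed when p < alpha
  *and* the mean light-window count is below the mean pre-light count.
* *antidromic spiking* (short pulses, default 5 ms, 20 trials): the same
  paired test on 20 ms pre-light vs 20 ms from-light-onset windows, flagged
  when spiking is *elevated*; the mean first-spike latency within the 20 ms
  response window characterizes the evoked spike.

Population summaries report the fraction of significant units per LPD and
compare constructs with a 2x2 chi-square (no zero cells) or Fisher's exact
test (zero cells present).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stats as osstats

logger = logging.getLogger(__name__)

DEFAULT_LPDS = (0.125, 0.25, 0.5, 1.0)  # mW mm^-2


@dataclass
class LightProtocol:
    """Stimulation protocol of a recording session."""

    pulse_s: float = 5.0
    pre_s: float = 5.0
    post_s: float = 5.0
    n_trials: int = 10
    lpds: tuple = DEFAULT_LPDS
    site: str = "local"  # illumination site: 'local' | 'distal'

    def __post_init__(self):
        if min(self.pulse_s, self.pre_s, self.post_s) <= 0:
            raise ValueError("durations must be positive")

    @classmethod
    def long_pulse(cls, **kw):
        kw.setdefault("n_trials", 10)
        return cls(pulse_s=5.0, **kw)

    @classmethod
    def short_pulse(cls, **kw):
        kw.setdefault("pre_s", 0.5)
        kw.setdefault("post_s", 0.5)
        kw.setdefault("n_trials", 20)
        return cls(pulse_s=0.005, **kw)


@dataclass
class SpikeDataset:
    """Trial-aligned sorted spike times with their light protocol.

    ``events`` columns: unit, trial, t_s (trial-aligned, light onset at 0)
    and lpd; optional animal / site columns ride along.
    """

    events: pd.DataFrame
    protocol: LightProtocol
    truth: dict = field(default_factory=dict)

    def __post_init__(self):
        required = {"unit", "trial", "t_s", "lpd"}
        missing = required - set(self.events.columns)
        if missing:
            raise ValueError(f"events missing columns: {sorted(missing)}")

    @property
    def units(self):
        return sorted(self.events["unit"].unique())

    def _sel(self, unit, lpd) -> pd.DataFrame:
        """Events of one (unit, lpd), via a lazily built groupby cache."""
        if not hasattr(self, "_group_cache") or self._group_cache is None:
            self._group_cache = {
                key: grp for key, grp in self.events.groupby(["unit", "lpd"])}
        return self._group_cache.get(
            (unit, lpd), self.events.iloc[0:0])

    def trial_counts(self, unit, lpd, t0: float, t1: float) -> np.ndarray:
        """Spike count in [t0, t1) per trial (length = protocol.n_trials;
        trials without spikes anywhere count as zero)."""
        sel = self._sel(unit, lpd)
        counts = np.zeros(self.protocol.n_trials)
        inwin = sel[(sel["t_s"] >= t0) & (sel["t_s"] < t1)]
        for trial, n in inwin.groupby("trial").size().items():
            counts[int(trial)] = n
        return counts

    def to_csv(self, path):
        self.events.to_csv(path, index=False)


def classify_suppressed(ds: SpikeDataset, unit, lpd,
                        window_s: float = 5.0,
                        alpha: float = 0.05):
    """Paired-count test for light suppression of one unit at one LPD.

    Compares per-trial spike counts between [-window, 0) and [0, window) s
    with a paired two-tailed t-test.  Returns ``(flag, p)``; the flag
    additionally requires the mean light count to be *below* the mean
    pre-light count, so opposite-direction (activated) units are not
    counted as suppressed.  Zero-variance identical counts give p = 1.
    """
    pre = ds.trial_counts(unit, lpd, -window_s, 0.0)
    light = ds.trial_counts(unit, lpd, 0.0, window_s)
    if pre.size < 2:
        raise ValueError("need >= 2 trials")
    res = osstats.paired_t(light, pre)
    flag = (res.p_value < alpha) and (light.mean() < pre.mean())
    return bool(flag), res.p_value


def relative_fr(ds: SpikeDataset, unit, lpd,
                window_s: float | None = None) -> float:
    """Relative firing rate: FR during light / pre-light FR, pooled over
    trials.  NaN (undefined, excluded from means) when the pre-light FR is
    zero."""
    if window_s is None:
        window_s = min(ds.protocol.pulse_s, ds.protocol.pre_s)
    pre = ds.trial_counts(unit, lpd, -window_s, 0.0).sum()
    light = ds.trial_counts(unit, lpd, 0.0, ds.protocol.pulse_s).sum()
    pre_fr = pre / (window_s * ds.protocol.n_trials)
    light_fr = light / (ds.protocol.pulse_s * ds.protocol.n_trials)
    if pre_fr == 0:
        return float("nan")
    return float(light_fr / pre_fr)


def psth_relative(ds: SpikeDataset, units=None, lpd=None,
                  bin_s: float = 0.1):
    """Population PSTH of relative firing rate.

    Per unit, spike rate in ``bin_s`` bins tiling [-pre, pulse+post) is
    divided by that unit's mean pre-light rate; the normalized curves are
    averaged across units.  Units with zero pre-light rate are excluded
    (their number is logged).

    Returns ``(bin_edges_s, mean_curve)``.
    """
    if bin_s <= 0:
        raise ValueError("bin width must be positive")
    p = ds.protocol
    if units is None:
        units = ds.units
    if lpd is None:
        lpd = p.lpds[0]
    edges = np.arange(-p.pre_s, p.pulse_s + p.post_s + bin_s / 2, bin_s)
    curves = []
    n_excluded = 0
    for unit in units:
        sel = ds._sel(unit, lpd)
        hist, _ = np.histogram(sel["t_s"], bins=edges)
        rate = hist / (p.n_trials * bin_s)
        pre_mask = edges[:-1] < 0
        pre_rate = rate[pre_mask].mean()
        if pre_rate == 0:
            n_excluded += 1
            continue
        curves.append(rate / pre_rate)
    if n_excluded:
        logger.info("psth_relative: excluded %d units with zero pre-light rate",
                    n_excluded)
    if not curves:
        raise ValueError("no units with nonzero pre-light rate")
    return edges, np.mean(curves, axis=0)


def classify_antidromic(ds: SpikeDataset, unit, lpd,
                        window_ms: float = 20.0,
                        alpha: float = 0.05):
    """Paired-count test for light-evoked (antidromic) spiking at light
    onset of a short pulse.

    Compares spike counts in the ``window_ms`` pre-light window against the
    ``window_ms`` window starting at light onset, across trials.  Returns
    ``(flag, p, mean_first_spike_latency_ms)``; the flag requires p < alpha
    *and* elevated spiking during the response window.  Latency is the mean
    over trials that contain at least one spike in [0, window) ms; NaN when
    no trial responds.
    """
    w = window_ms / 1000.0
    pre = ds.trial_counts(unit, lpd, -w, 0.0)
    light = ds.trial_counts(unit, lpd, 0.0, w)
    res = osstats.paired_t(light, pre)
    flag = (res.p_value < alpha) and (light.mean() > pre.mean())

    ev = ds._sel(unit, lpd)
    sel = ev[(ev["t_s"] >= 0) & (ev["t_s"] < w)]
    if sel.empty:
        return bool(flag), res.p_value, float("nan")
    first = sel.groupby("trial")["t_s"].min()
    return bool(flag), res.p_value, float(first.mean() * 1000.0)


def latency_order(latencies: pd.DataFrame) -> pd.DataFrame:
    """Order units by ascending mean first-spike latency (ties broken by
    unit id).  Input needs columns 'unit' and 'latency_ms'."""
    defined = latencies.dropna(subset=["latency_ms"])
    return (defined.sort_values(["latency_ms", "unit"], kind="stable")
            .reset_index(drop=True))


def classify_all(ds: SpikeDataset, kind: str = "suppressed",
                 alpha: float = 0.05) -> pd.DataFrame:
    """Run the per-unit classifier over every unit x LPD.

    ``kind``: 'suppressed' (long-pulse silencing test + relative FR) or
    'antidromic' (short-pulse onset test + first-spike latency).
    """
    rows = []
    for unit in ds.units:
        for lpd in ds.protocol.lpds:
            if kind == "suppressed":
                flag, p = classify_suppressed(ds, unit, lpd, alpha=alpha)
                rows.append({"unit": unit, "lpd": lpd, "suppressed": flag,
                             "p": p, "relative_fr": relative_fr(ds, unit, lpd)})
            elif kind == "antidromic":
                flag, p, lat = classify_antidromic(ds, unit, lpd, alpha=alpha)
                rows.append({"unit": unit, "lpd": lpd, "antidromic": flag,
                             "p": p, "latency_ms": lat})
            else:
                raise ValueError(f"unknown kind {kind!r}")
    return pd.DataFrame(rows)


def compare_proportions(k1: int, n1: int, k2: int, n2: int):
    """Compare two proportions (k of n significant units per construct)
    with a 2x2 chi-square when no cell is zero, Fisher's exact test
    otherwise."""
    a, b, c, d = k1, n1 - k1, k2, n2 - k2
    if min(a, b, c, d) > 0:
        return osstats.chi2_2x2(a, b, c, d)
    return osstats.fisher_exact_2x2(a, b, c, d)


def population_summary(classifications: dict, flag_col: str = "suppressed"
                       ) -> pd.DataFrame:
    """Fraction of flagged units per LPD per construct, with pairwise
    construct comparisons.

    ``classifications`` maps construct name -> the DataFrame returned by
    :func:`classify_all`.  The output has one row per (LPD, construct) with
    n, n_flagged and fraction; pairwise test results are attached in
    ``df.attrs['comparisons']`` as (lpd, construct_a, construct_b,
    TestResult) tuples.
    """
    if not classifications:
        raise ValueError("no groups given")
    rows = []
    comparisons = []
    constructs = list(classifications)
    lpds = sorted({lpd for df in classifications.values()
                   for lpd in df["lpd"].unique()})
    for lpd in lpds:
        for name in constructs:
            df = classifications[name]
            sub = df[df["lpd"] == lpd]
            if sub.empty:
                raise ValueError(f"construct {name!r} has no units at lpd {lpd}")
            rows.append({"lpd": lpd, "construct": name, "n": len(sub),
                         "n_flagged": int(sub[flag_col].sum()),
                         "fraction": float(sub[flag_col].mean())})
        for i, na in enumerate(constructs):
            for nb in constructs[i + 1:]:
                sa = classifications[na][classifications[na]["lpd"] == lpd]
                sb = classifications[nb][classifications[nb]["lpd"] == lpd]
                res = compare_proportions(int(sa[flag_col].sum()), len(sa),
                                          int(sb[flag_col].sum()), len(sb))
                comparisons.append((lpd, na, nb, res))
    out = pd.DataFrame(rows)
    out.attrs["comparisons"] = comparisons
    return out
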