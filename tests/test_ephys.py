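"""Tests of per-unit suppression / antidromic classification and
population summaries."""

import numpy as np
import pandas as pd
import pytest

from optosilence import ephys, synthgen
from optosilence.ephys import LightProtocol, SpikeDataset


def dataset_from_counts(pre_counts, light_counts, lpd=1.0,
                        protocol=None):
    """Build a single-unit dataset realizing given per-trial window counts
    (spikes placed deterministically inside each window)."""
    if protocol is None:
        protocol = LightProtocol(n_trials=len(pre_counts), lpds=(lpd,))
    rows = []
    for trial, (np_, nl) in enumerate(zip(pre_counts, light_counts)):
        for k in range(np_):
            rows.append({"unit": 0, "trial": trial, "lpd": lpd,
                         "t_s": -protocol.pre_s + 0.01 * (k + 1)})
        for k in range(nl):
            rows.append({"unit": 0, "trial": trial, "lpd": lpd,
                         "t_s": 0.01 * (k + 1)})
    events = pd.DataFrame(rows, columns=["unit", "trial", "lpd", "t_s"])
    return SpikeDataset(events=events, protocol=protocol)


class TestClassifySuppressed:
    def test_maximal_effect_flagged(self):
        ds = dataset_from_counts([10] * 10, [0] * 10)
        flag, p = ephys.classify_suppressed(ds, 0, 1.0)
        assert flag
        assert p == 0.0  # zero-variance nonzero-mean differences

    def test_identical_counts_not_flagged(self):
        ds = dataset_from_counts([7] * 10, [7] * 10)
        flag, p = ephys.classify_suppressed(ds, 0, 1.0)
        assert not flag
        assert p == 1.0

    def test_elevated_units_not_flagged_as_suppressed(self):
        ds = dataset_from_counts([2, 3, 2, 3, 2, 3, 2, 3, 2, 3],
                                 [20, 21, 20, 21, 20, 21, 20, 21, 20, 21])
        flag, p = ephys.classify_suppressed(ds, 0, 1.0)
        assert p < 0.05 and not flag

    def test_strong_suppression_detected_in_simulation(self):
        cfg = synthgen.SimConfig(seed=21, n_units=20, n_trials=10,
                                 baseline_rate_hz=5.0,
                                 suppression_fraction=0.9, lpds=(1.0,))
        ds = synthgen.gen_spike_dataset(cfg)
        flags = [ephys.classify_suppressed(ds, u, 1.0)[0] for u in ds.units]
        assert np.mean(flags) >= 0.9


class TestRelativeFr:
    def test_complete_suppression(self):
        ds = dataset_from_counts([5] * 10, [0] * 10)
        assert ephys.relative_fr(ds, 0, 1.0) == 0.0

    def test_no_modulation_near_one(self):
        ds = dataset_from_counts([6] * 10, [6] * 10)
        assert ephys.relative_fr(ds, 0, 1.0) == pytest.approx(1.0)

    def test_zero_pre_rate_undefined(self):
        ds = dataset_from_counts([0] * 10, [3] * 10)
        assert np.isnan(ephys.relative_fr(ds, 0, 1.0))

    def test_generator_ground_truth_recovered(self):
        cfg = synthgen.SimConfig(seed=1, n_units=50, n_trials=10,
                                 baseline_rate_hz=5.0,
                                 suppression_fraction=0.8, lpds=(1.0,))
        ds = synthgen.gen_spike_dataset(cfg)
        rfr = np.array([ephys.relative_fr(ds, u, 1.0) for u in ds.units])
        assert np.nanmean(rfr) == pytest.approx(0.2, abs=0.02)


class TestPsth:
    def test_null_units_flat_near_one(self):
        cfg = synthgen.SimConfig(seed=4, n_units=30, n_trials=10,
                                 baseline_rate_hz=8.0,
                                 suppression_fraction=0.0, lpds=(1.0,))
        ds = synthgen.gen_spike_dataset(cfg)
        edges, curve = ephys.psth_relative(ds, lpd=1.0)
        assert curve.shape[0] == edges.size - 1
        assert np.all(np.abs(curve - 1.0) < 0.35)
        assert np.abs(curve.mean() - 1.0) < 0.05

    def test_complete_suppression_zeroes_light_bins(self):
        cfg = synthgen.SimConfig(seed=5, n_units=10, n_trials=10,
                                 baseline_rate_hz=10.0,
                                 suppression_fraction=1.0, lpds=(1.0,))
        ds = synthgen.gen_spike_dataset(cfg)
        edges, curve = ephys.psth_relative(ds, lpd=1.0)
        centers = (edges[:-1] + edges[1:]) / 2
        light = (centers > 0) & (centers < cfg.light_s)
        assert np.allclose(curve[light], 0.0)

    def test_rebound_elevates_post_offset_bins(self):
        cfg = synthgen.SimConfig(seed=6, n_units=40, n_trials=20,
                                 baseline_rate_hz=10.0,
                                 suppression_fraction=0.5,
                                 rebound_gain=2.0, rebound_tau_s=0.5,
                                 lpds=(1.0,))
        ds = synthgen.gen_spike_dataset(cfg)
        edges, curve = ephys.psth_relative(ds, lpd=1.0)
        centers = (edges[:-1] + edges[1:]) / 2
        first_rebound = (centers > cfg.light_s) & \
            (centers < cfg.light_s + 0.3)
        # analytic profile: 1 + g*exp(-(t-off)/tau) averaged over the bin
        expected = 1.0 + 2.0 * np.exp(-(centers[first_rebound]
                                        - cfg.light_s) / 0.5)
        assert np.all(curve[first_rebound] > 1.5)
        assert np.allclose(curve[first_rebound], expected, rtol=0.15)


class TestAntidromic:
    def _short_ds(self, **kw):
        defaults = dict(seed=13, n_units=1, n_trials=20,
                        baseline_rate_hz=2.0, antidromic_prob=0.9,
                        antidromic_latency_ms=4.0, antidromic_jitter_ms=1.0,
                        light_s=0.005, pre_s=0.5, post_s=0.5, lpds=(0.25,))
        defaults.update(kw)
        cfg = synthgen.SimConfig(**defaults)
        proto = LightProtocol.short_pulse(lpds=cfg.lpds)
        proto.n_trials = cfg.n_trials
        return synthgen.gen_spike_dataset(cfg, protocol=proto)

    def test_deterministic_spike_flagged_with_latency(self):
        rows = [{"unit": 0, "trial": t, "lpd": 0.25, "t_s": 0.003}
                for t in range(20)]
        ds = SpikeDataset(events=pd.DataFrame(rows),
                          protocol=LightProtocol.short_pulse(lpds=(0.25,),
                                                             n_trials=20))
        flag, p, lat = ephys.classify_antidromic(ds, 0, 0.25)
        assert flag
        assert lat == pytest.approx(3.0)

    def test_silent_unit_not_flagged(self):
        ds = SpikeDataset(events=pd.DataFrame(
            columns=["unit", "trial", "lpd", "t_s"]),
            protocol=LightProtocol.short_pulse(lpds=(0.25,), n_trials=20))
        flag, p, lat = ephys.classify_antidromic(ds, 0, 0.25)
        assert not flag
        assert np.isnan(lat)

    def test_generator_truth_recovered(self):
        ds = self._short_ds()
        flag, p, lat = ephys.classify_antidromic(ds, 0, 0.25)
        assert flag
        assert lat == pytest.approx(4.0, abs=0.8)


class TestLatencyOrder:
    def test_sorted_ascending(self):
        df = pd.DataFrame({"unit": [1, 2, 3], "latency_ms": [5.0, 2.0, 9.0]})
        out = ephys.latency_order(df)
        assert list(out["latency_ms"]) == [2.0, 5.0, 9.0]

    def test_ties_broken_by_unit_id(self):
        df = pd.DataFrame({"unit": [9, 3, 7], "latency_ms": [4.0, 4.0, 4.0]})
        out = ephys.latency_order(df)
        assert list(out["unit"]) == [3, 7, 9]

    def test_matches_sort_oracle(self, rng):
        lat = rng.uniform(1, 20, size=30)
        df = pd.DataFrame({"unit": np.arange(30), "latency_ms": lat})
        out = ephys.latency_order(df)
        assert np.array_equal(out["latency_ms"].to_numpy(), np.sort(lat))

    def test_nan_latencies_dropped(self):
        df = pd.DataFrame({"unit": [1, 2], "latency_ms": [np.nan, 3.0]})
        assert len(ephys.latency_order(df)) == 1


class TestPopulationSummary:
    def _cls(self, flags, lpd=1.0):
        return pd.DataFrame({"unit": np.arange(len(flags)), "lpd": lpd,
                             "suppressed": flags})

    def test_published_chi2_from_fractions(self):
        a = self._cls([True] * 21 + [False] * 79)
        b = self._cls([True] * 51 + [False] * 47)
        out = ephys.population_summary({"GtACR2": a, "stGtACR2": b})
        assert out["fraction"].tolist() == [0.21, pytest.approx(51 / 98)]
        (lpd, na, nb, res), = out.attrs["comparisons"]
        assert res.statistic == pytest.approx(20.61, abs=0.005)
        assert res.method == "chi2_2x2"

    def test_identical_groups_chi2_zero(self):
        a = self._cls([True] * 10 + [False] * 10)
        out = ephys.population_summary({"x": a, "y": a.copy()})
        (_, _, _, res), = out.attrs["comparisons"]
        assert res.statistic == pytest.approx(0.0)

    def test_zero_cell_delegates_to_fisher(self):
        a = self._cls([False] * 10)
        b = self._cls([True] * 3 + [False] * 7)
        out = ephys.population_summary({"x": a, "y": b})
        (_, _, _, res), = out.attrs["comparisons"]
        assert res.method == "fisher_exact_2x2"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            ephys.population_summary({})
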