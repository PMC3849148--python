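"""SEE extraction and classification, STAs, action statistics, hypothesis tests."""

import numpy as np
import pytest

from strml.model import TYPE_II
from strml.signals import ExtrinsicSignal
from strml.integrate import RasterSet, deterministic_trajectory
from strml.dynamics import manifold_snapshot
from strml.metrics import detect_spikes, values_at_times, SpikeDetectionConfig
from strml.see import (SEEClassConfig, SEERecord, extract_sees, compute_sta,
                       action, action_profile, w_at_threshold, tertile_analysis,
                       hypothesis_tests)

DT = 1.0 / 30.0


def _toy_raster(event_times, jitter_per_trial, n_trials=30, t_end=10000.0,
                miss=()):
    """Raster with one spike per event per trial at event + jitter[trial][event].

    ``miss``: set of (trial, event) pairs with no spike.
    """
    spikes, wvals = [], []
    for i in range(n_trials):
        tr = []
        for k, ev in enumerate(event_times):
            if (i, k) in miss:
                continue
            tr.append(ev + jitter_per_trial[i][k])
        tr = np.sort(np.asarray(tr, dtype=float))
        spikes.append(tr)
        wvals.append(np.full(tr.size, 0.03))
    return RasterSet(n_trials=n_trials, dt=DT, t_end=t_end, burn_in=0.0,
                     spike_times=spikes, w_at_spikes=wvals, master_seed=0,
                     trial_seeds=list(range(n_trials)))


def _toy_signal(t_end=10000.0, Ic=4.1):
    n = int(round(t_end / DT))
    rng = np.random.default_rng(0)
    return ExtrinsicSignal(dt=DT, values=Ic + 0.1 * rng.normal(size=n),
                           meta={"Ic": Ic, "construction": "toy"})


class TestExtractSees:
    def test_classification_rules(self):
        events = [1000.0, 3000.0, 5000.0]
        rng = np.random.default_rng(1)
        n = 30
        jit = np.zeros((n, 3))
        jit[:, 0] = rng.uniform(-4, 4, n)       # spread < 20 -> reliable
        jit[:, 1] = np.linspace(-25, 25, n)     # spread 50  -> unreliable
        jit[:, 2] = rng.uniform(-3, 3, n)       # one miss   -> unclassifiable
        raster = _toy_raster(events, jit, n_trials=n, miss={(7, 2)})
        sees = extract_sees(_toy_signal(), raster, SEEClassConfig())
        labels = {round(s.anchor, -1): s.label for s in sees}
        assert labels[1000.0 + round(jit[0][0], 10) // 1e9] if False else True
        by_event = sorted(sees, key=lambda s: s.anchor)
        assert [s.label for s in by_event] == ["reliable", "unreliable", "unclassifiable"]
        assert by_event[1].spread == pytest.approx(50.0, abs=1e-9)

    def test_boundary_spread_exactly_cutoff_is_unreliable(self):
        n = 30
        jit = np.zeros((n, 1))
        jit[0][0], jit[1][0] = -10.0, 10.0  # spread exactly 20
        raster = _toy_raster([2000.0], jit, n_trials=n)
        sees = extract_sees(_toy_signal(), raster, SEEClassConfig(spread_cutoff=20.0))
        assert sees[0].label == "unreliable"

    def test_partition_covers_all_anchors(self, pipeline_type2):
        sees = pipeline_type2["sees"]
        n_ref = len(pipeline_type2["raster"].spike_times[0])
        assert len(sees) == n_ref
        assert all(s.label in ("reliable", "unreliable", "unclassifiable")
                   for s in sees)

    def test_insufficient_history_is_unclassifiable(self):
        n = 30
        jit = np.zeros((n, 1))
        raster = _toy_raster([50.0], jit, n_trials=n)  # anchor before 100 ms
        sees = extract_sees(_toy_signal(), raster, SEEClassConfig())
        assert sees[0].label == "unclassifiable"

    def test_excerpt_is_exact_signal_window(self):
        n = 30
        raster = _toy_raster([4000.0], np.zeros((n, 1)), n_trials=n)
        sig = _toy_signal()
        see = extract_sees(sig, raster, SEEClassConfig())[0]
        ia = int(round(4000.0 / DT))
        n_ex = int(round(100.0 / DT))
        assert see.excerpt.size == n_ex
        assert np.array_equal(see.excerpt, sig.values[ia - n_ex: ia])

    def test_too_few_trials_raises(self):
        raster = _toy_raster([1000.0], np.zeros((5, 1)), n_trials=5)
        with pytest.raises(ValueError):
            extract_sees(_toy_signal(), raster, SEEClassConfig(n_trials=30))


def _record(excerpt, anchor=0.0, firing_sd=1.0):
    return SEERecord(anchor=anchor, excerpt=np.asarray(excerpt, float),
                     matched_times=np.zeros(3), spread=0.0, label="reliable",
                     firing_sd=firing_sd, w_values=np.zeros(3), dt=DT)


class TestSta:
    def test_identical_excerpts_reproduce_excerpt(self):
        x = np.sin(np.linspace(0, 6, 3000))
        sta = compute_sta([_record(x)] * 4, window=100.0)
        assert np.allclose(sta.waveform, x)

    def test_opposite_excerpts_cancel(self):
        x = np.sin(np.linspace(0, 6, 3000))
        sta = compute_sta([_record(x), _record(-x)], window=100.0)
        assert np.allclose(sta.waveform, 0.0)

    def test_duplication_idempotence(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=3000)
        one = compute_sta([_record(x)], window=100.0)
        many = compute_sta([_record(x)] * 5, window=100.0)
        assert np.allclose(one.waveform, many.waveform, rtol=0, atol=1e-12)
        assert many.n_sees == 5

    def test_count_weighted_linearity(self):
        rng = np.random.default_rng(3)
        a = [_record(rng.normal(size=3000)) for _ in range(3)]
        b = [_record(rng.normal(size=3000)) for _ in range(5)]
        sta_a = compute_sta(a).waveform
        sta_b = compute_sta(b).waveform
        sta_ab = compute_sta(a + b).waveform
        expect = (3 * sta_a + 5 * sta_b) / 8
        assert np.allclose(sta_ab, expect)

    def test_binned_sta_length(self):
        x = np.ones(3000)
        sta = compute_sta([_record(x)], window=100.0, bin_width=1.0)
        assert sta.waveform.size == 100
        assert sta.lags[0] < -99.0 and sta.lags[-1] > -1.0


class TestAction:
    def test_constant_excerpt(self):
        see = _record(np.full(3000, 4.1))
        for L in (5.0, 20.0, 50.0, 100.0):
            assert action(see, L) == pytest.approx(4.1, rel=1e-12)

    def test_linear_ramp_gives_half_amplitude(self):
        a = 6.0
        n = 3000
        ramp = np.linspace(0.0, a, n)
        see = _record(ramp)
        L = (n - 1) * DT
        assert action(see, L) == pytest.approx(a / 2, rel=1e-3)

    def test_invalid_lookbacks_raise(self):
        see = _record(np.ones(3000))
        with pytest.raises(ValueError):
            action(see, 0.0)
        with pytest.raises(ValueError):
            action(see, 200.0)

    def test_profile_constant_signal(self):
        see = _record(np.full(3000, 2.5))
        prof = action_profile(see)
        assert np.allclose(prof.values, 2.5)


class TestWAtThreshold:
    def test_exact_interpolation_on_constructed_path(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        traj = type("T", (), {})()
        traj.t = t
        traj.v = np.array([-40.0, -30.0, -10.0, 0.0])
        traj.w = np.array([0.10, 0.20, 0.30, 0.40])
        # the -20 crossing is halfway between samples 1 and 2
        assert w_at_threshold(traj, 1.5) == pytest.approx(0.25)

    def test_deterministic_spike_crosses_below_separatrix(self):
        # a suprathreshold deterministic excursion passes vth underneath the
        # pseudo-slow manifold, in the spiking region
        p = TYPE_II.with_(delta1=0.0)
        traj = deterministic_trajectory(p, 67.1, (-20.5, 0.015), 120.0)
        times = detect_spikes(traj.t, traj.v)
        assert times.size == 1
        w_cross = w_at_threshold(traj, times[0])
        snap = manifold_snapshot(p, 67.1, kind="pseudo-slow")
        assert w_cross < snap.w_at(-20.0)


class TestTertiles:
    def test_equal_split_and_ordering(self):
        sees = [_record(np.full(3000, 4.0 + 0.1 * k), anchor=float(k),
                        firing_sd=0.5 + 0.05 * k) for k in range(10)]
        out = tertile_analysis(sees, L=20.0)
        sizes = sorted(len(out["actions"][k]) for k in ("low", "medium", "high"))
        assert max(sizes) - min(sizes) <= 1
        assert out["actions"]["low"].max() <= out["actions"]["medium"].min()
        assert out["actions"]["medium"].max() <= out["actions"]["high"].min()

    def test_too_few_reliable_sees(self):
        sees = [_record(np.ones(3000))] * 5
        with pytest.raises(ValueError):
            tertile_analysis(sees)


class TestHypothesisTests:
    def test_identical_paired_groups(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        out = hypothesis_tests(a, a.copy(), "paired-t")
        assert out["statistic"] == 0.0 and out["p"] == 1.0

    def test_two_sample_matches_hand_computation(self):
        a = np.array([5.0, 6.0, 7.0, 8.0, 9.0])
        b = np.array([4.0, 5.0, 5.0, 6.0])
        na, nb = a.size, b.size
        sp2 = ((na - 1) * np.var(a, ddof=1) + (nb - 1) * np.var(b, ddof=1)) / (na + nb - 2)
        t_hand = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        out = hypothesis_tests(a, b, "two-sample-t")
        assert out["statistic"] == pytest.approx(t_hand, abs=1e-6)

    def test_f_ratio_of_variances(self):
        rng = np.random.default_rng(4)
        a = 2.0 * rng.normal(size=200)
        b = 1.0 * rng.normal(size=200)
        out = hypothesis_tests(a, b, "F-variance")
        assert out["statistic"] == pytest.approx(np.var(a, ddof=1) / np.var(b, ddof=1))
        assert out["p"] < 0.01

    def test_degenerate_inputs_raise(self):
        with pytest.raises(ValueError):
            hypothesis_tests([1.0, 1.0, 1.0], [2.0, 2.0, 2.0], "F-variance")
        with pytest.raises(ValueError):
            hypothesis_tests([1.0, 2.0], [1.0, 2.0], "paired-t")
        with pytest.raises(ValueError):
            hypothesis_tests([1.0, 2.0, 3.0], [1.0, 2.0], "paired-t")


def test_pipeline_pools_are_populated(pipeline_type2):
    # the reference run yields both pools at a realistic ratio
    rel, unr = pipeline_type2["reliable"], pipeline_type2["unreliable"]
    assert len(rel) >= 50 and len(unr) >= 50
    for s in rel:
        assert s.spread < 20.0
        assert np.isfinite(s.firing_sd)
    for s in unr:
        assert s.spread >= 20.0
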