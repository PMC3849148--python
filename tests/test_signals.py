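"""Signal synthesis: alpha kernel, filtered noise, splicing, spectra, persistence."""

import numpy as np
import pytest

from strml.model import TYPE_II
from strml.signals import (ExtrinsicSignal, EpochLibrary, alpha_kernel,
                           filtered_noise, build_signal, splice_signal,
                           insert_sta_copies, power_spectrum)

DT = 1.0 / 30.0


class TestAlphaKernel:
    @pytest.mark.parametrize("tau", [1.0, 3.0, 7.0])
    def test_unit_area_and_peak(self, tau):
        k = alpha_kernel(tau, DT)
        t = np.arange(k.size) * DT
        assert np.trapezoid(k, dx=DT) == pytest.approx(1.0, abs=1e-4)
        # maximum at t = tau with value 1/(tau e)
        i = int(np.argmax(k))
        assert t[i] == pytest.approx(tau, abs=DT)
        assert k[i] == pytest.approx(1.0 / (tau * np.e), rel=1e-3)

    def test_energy_integral(self):
        # integral of alpha^2 over [0, inf) is 1/(4 tau)
        tau = 3.0
        k = alpha_kernel(tau, DT)
        assert np.trapezoid(k**2, dx=DT) == pytest.approx(1.0 / (4 * tau), rel=1e-4)

    def test_under_resolved_kernel_rejected(self):
        with pytest.raises(ValueError):
            alpha_kernel(tau=0.02, dt=DT)
        with pytest.raises(ValueError):
            alpha_kernel(tau=3.0, dt=DT, cutoff=20.0)


class TestFilteredNoise:
    def test_stationary_sd_matches_closed_form(self):
        # Var eta2 = integral alpha^2 = 1/(4 tau) for unit white intensity
        tau = 2.0
        eta = filtered_noise(tau, DT, duration=1e5 * tau, seed=0)
        assert np.std(eta) == pytest.approx(1.0 / (2 * np.sqrt(tau)), rel=0.03)

    def test_autocorrelation_decays_within_five_tau(self):
        tau = 3.0
        eta = filtered_noise(tau, DT, duration=60000.0, seed=1)
        eta = eta - eta.mean()
        lag = int(round(5 * tau / DT))
        rho = np.dot(eta[:-lag], eta[lag:]) / np.dot(eta, eta)
        assert rho < 0.1

    def test_frozen_noise_contract(self):
        a = filtered_noise(3.0, DT, 1000.0, seed=7)
        b = filtered_noise(3.0, DT, 1000.0, seed=7)
        c = filtered_noise(3.0, DT, 1000.0, seed=8)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)


class TestBuildSignal:
    def test_zero_coefficient_gives_constant(self):
        p = TYPE_II.with_(delta2=0.0)
        sig = build_signal(p, 1000.0, seed=0)
        assert np.all(sig.values == p.Ic)

    def test_normalized_sd_equals_delta2(self):
        sig = build_signal(TYPE_II, 120000.0, seed=2)
        assert sig.empirical_sd() == pytest.approx(TYPE_II.delta2, rel=0.03)

    def test_raw_sd_follows_kernel_energy(self):
        sig = build_signal(TYPE_II, 120000.0, seed=2, normalize=False)
        expect = TYPE_II.delta2 / (2 * np.sqrt(TYPE_II.tau))
        assert sig.empirical_sd() == pytest.approx(expect, rel=0.03)

    def test_seed_determinism(self):
        a = build_signal(TYPE_II, 2000.0, seed=5)
        b = build_signal(TYPE_II, 2000.0, seed=5)
        c = build_signal(TYPE_II, 2000.0, seed=6)
        assert np.array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_white_construction_sd(self):
        sig = build_signal(TYPE_II, 60000.0, seed=3, construction="white",
                           target_sd=2.5)
        assert sig.empirical_sd() == pytest.approx(2.5, rel=0.02)

    def test_csv_round_trip_is_bit_identical(self, tmp_path):
        sig = build_signal(TYPE_II, 500.0, seed=9)
        path = tmp_path / "sig.csv"
        sig.to_csv(path)
        back = ExtrinsicSignal.from_csv(path)
        assert back.dt == sig.dt
        assert np.array_equal(back.values, sig.values)
        assert back.meta["seed"] == 9


def _toy_library(Ic=4.1, pulse_ms=30.0, quiet_ms=60.0):
    """Synthetic library: identical rectangular 'trigger' pulses and quiet pieces
    straddling Ic so the mean constraint is satisfiable."""
    n_p = int(round(pulse_ms / DT))
    n_q = int(round(quiet_ms / DT))
    sees = [np.full(n_p, Ic + 2.0) for _ in range(4)]
    quiet = ([np.full(n_q, Ic - 1.2), np.full(n_q, Ic - 0.6)]
             + [np.full(n_q, Ic + 0.4), np.full(n_q, Ic - 0.1)])
    return EpochLibrary(dt=DT, Ic=Ic, sees=sees, nonspiking=quiet)


class TestSplicing:
    def test_single_epoch_schedule_returns_epoch(self):
        lib = _toy_library()
        sig = splice_signal(lib, [(1, 0.0)], mean_tol=1.0)
        assert np.array_equal(sig.values, lib.sees[1])

    def test_epoch_interiors_never_altered(self):
        lib = _toy_library()
        sched = [(0, 100.0), (2, 130.0), (3, 90.0)]
        sig = splice_signal(lib, sched, seed=1)
        n_p = lib.sees[0].size
        for onset, (idx, _) in zip(sig.meta["onsets"], sched):
            i0 = int(round(onset / DT))
            assert np.array_equal(sig.values[i0:i0 + n_p], lib.sees[idx])

    def test_mean_preserved_and_duration_additive(self):
        lib = _toy_library()
        sched = [(i % 4, 100.0) for i in range(10)]
        sig = splice_signal(lib, sched, seed=2)
        assert abs(np.mean(sig.values) - lib.Ic) <= 0.01 * lib.Ic
        expect_n = 10 * (lib.sees[0].size + int(round(100.0 / DT)))
        assert sig.n == expect_n

    def test_regular_spacing_puts_spectral_line_at_one_over_period(self):
        lib = _toy_library(pulse_ms=30.0)
        period = 156.0
        gap = period - 30.0
        sig = splice_signal(lib, [(i % 4, gap) for i in range(40)], seed=3)
        f, p = power_spectrum(sig)
        sel = (f > 1e-4) & (f < 0.02)
        f_peak = f[sel][np.argmax(p[sel])]
        assert f_peak == pytest.approx(1.0 / period, rel=0.05)

    def test_infeasible_mean_raises_with_deficit(self):
        lib = _toy_library()
        lib.nonspiking = [np.full(1800, lib.Ic - 3.0)]  # only strongly low material
        with pytest.raises(ValueError, match="mean preservation"):
            splice_signal(lib, [(0, 400.0), (1, 400.0), (2, 400.0)], seed=0)


class TestStaInsertion:
    def test_onsets_and_exact_copies(self):
        lib = _toy_library()
        wave = np.sin(np.linspace(0, 3 * np.pi, 3000)) * 0.5 + lib.Ic
        sig = insert_sta_copies(wave, lib, n_copies=5, gaps=(80.0, 120.0), seed=4)
        onsets = sig.meta["onsets"]
        assert len(onsets) == 5
        for onset in onsets:
            i0 = int(round(onset / DT))
            assert np.array_equal(sig.values[i0:i0 + wave.size], wave)
        assert abs(np.mean(sig.values) - lib.Ic) <= 0.01 * lib.Ic


class TestPowerSpectrum:
    def test_sinusoid_peak(self):
        f0 = 0.01  # kHz
        t = np.arange(0, 20000.0, DT)
        x = 2.0 + np.sin(2 * np.pi * f0 * t)
        f, p = power_spectrum(x, dt=DT)
        assert f[np.argmax(p)] == pytest.approx(f0, rel=0.01)

    def test_parseval(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30000)
        f, p = power_spectrum(x, dt=DT)
        df = f[1] - f[0]
        assert np.sum(p) * df == pytest.approx(np.var(x), rel=0.01)

    def test_white_noise_block_averaged_spectrum_is_flat(self):
        # averaging over seeds and coarse frequency blocks tames periodogram noise
        acc = None
        for seed in range(8):
            x = np.random.default_rng(seed).normal(size=2**15)
            _, p = power_spectrum(x, dt=DT)
            acc = p if acc is None else acc + p
        block = acc[1:1 + (acc.size - 1) // 128 * 128].reshape(-1, 128).mean(axis=1)
        assert block.max() < 5.0 * np.median(block)


def test_epoch_library_round_trip(tmp_path, epoch_library_type2):
    lib = epoch_library_type2
    lib.save(tmp_path / "lib")
    back = EpochLibrary.load(tmp_path / "lib")
    assert back.dt == lib.dt and back.Ic == lib.Ic
    assert len(back.sees) == len(lib.sees)
    for a, b in zip(lib.sees + lib.nonspiking, back.sees + back.nonspiking):
        assert np.array_equal(a, b)
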