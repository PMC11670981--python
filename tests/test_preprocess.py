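"""Band splitting, envelope, trial averaging, and spike-rate estimation."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sp_signal

import laminarpa as lp
from laminarpa.containers import RecordingMatrix, SignalKind


def _tone(freq_hz: float, fs_hz: float = 10_000.0, dur_s: float = 1.0, n_ch: int = 3):
    t = np.arange(int(dur_s * fs_hz)) / fs_hz
    values = np.tile(np.sin(2 * np.pi * freq_hz * t), (n_ch, 1))
    return RecordingMatrix(values, dt=1000.0 / fs_hz, kind=SignalKind.ECP)


class TestSplitBands:
    def test_low_tone_passes_to_lfp(self):
        ecp = _tone(10.0)
        lfp, mua = lp.split_bands(ecp, cutoff_hz=300.0)
        ratio = lfp.values.std() / ecp.values.std()
        assert ratio > 0.99
        assert mua.values.std() < 0.01 * ecp.values.std()

    def test_high_tone_passes_to_mua(self):
        ecp = _tone(1000.0)
        lfp, mua = lp.split_bands(ecp, cutoff_hz=300.0)
        assert mua.values.std() / ecp.values.std() > 0.99
        # stopband attenuation of the low-pass exceeds 20 dB at 1 kHz
        assert lfp.values.std() < 0.1 * ecp.values.std()

    def test_band_powers_partition_total(self, rng):
        values = rng.standard_normal((2, 20_000))
        ecp = RecordingMatrix(values, dt=0.1, kind=SignalKind.ECP)
        lfp, mua = lp.split_bands(ecp, cutoff_hz=300.0)
        total = np.sum(values**2)
        split = np.sum(lfp.values**2) + np.sum(mua.values**2)
        assert abs(split - total) / total < 0.05

    def test_zero_phase(self):
        # band-limited input: smoothed noise; filtered output must not lag
        rng = np.random.default_rng(0)
        x = sp_signal.sosfiltfilt(
            sp_signal.butter(4, 50.0, fs=10_000.0, output="sos"),
            rng.standard_normal(20_000),
        )
        ecp = RecordingMatrix(np.tile(x, (1, 1)), dt=0.1, kind=SignalKind.ECP)
        lfp, _ = lp.split_bands(ecp, cutoff_hz=300.0)
        xc = sp_signal.correlate(lfp.values[0], x, mode="full")
        lag = xc.argmax() - (len(x) - 1)
        assert lag == 0

    def test_cutoff_at_nyquist_rejected(self):
        ecp = _tone(10.0, fs_hz=500.0)
        with pytest.raises(ValueError, match="Nyquist"):
            lp.split_bands(ecp, cutoff_hz=300.0)

    def test_requires_ecp_kind(self):
        mat = RecordingMatrix(np.zeros((2, 100)) + np.arange(100), dt=1.0, kind=SignalKind.LFP)
        with pytest.raises(ValueError, match="ECP"):
            lp.split_bands(mat)


class TestMuaEnvelope:
    def _mua(self, values):
        return RecordingMatrix(values, dt=1.0, kind=SignalKind.MUA)

    def test_zero_in_zero_out(self):
        env = lp.mua_envelope(self._mua(np.zeros((4, 100))))
        assert np.all(env.values == 0)

    def test_constant_rectification_identity(self):
        env = lp.mua_envelope(self._mua(np.full((2, 200), 3.5)))
        assert np.allclose(env.values, 3.5)

    def test_square_wave_mean_abs(self):
        # alternating +-A with smoothing much longer than the period -> ~A
        a = 2.0
        wave = a * np.tile([1.0, -1.0], 500)
        env = lp.mua_envelope(self._mua(wave[None, :]), smooth_ms=50.0)
        interior = env.values[0, 100:-100]
        assert np.allclose(interior, a, rtol=1e-3)

    def test_invalid_smoothing(self):
        with pytest.raises(ValueError, match="smooth_ms"):
            lp.mua_envelope(self._mua(np.ones((1, 10))), smooth_ms=0.0)


class TestTrialAverage:
    def test_identical_trials(self, rng):
        m = RecordingMatrix(rng.standard_normal((4, 50)), dt=1.0)
        avg = lp.trial_average([m, m, m])
        assert np.allclose(avg.values, m.values, rtol=1e-14)

    def test_antisymmetric_pair_cancels(self, rng):
        x = rng.standard_normal((4, 50))
        avg = lp.trial_average(
            [RecordingMatrix(x, dt=1.0), RecordingMatrix(-x, dt=1.0)]
        )
        assert np.allclose(avg.values, 0.0)

    def test_noise_reduction_sqrt_n(self):
        # Monte-Carlo oracle: averaging 10 noisy copies shrinks sd ~ sqrt(10)
        rng = np.random.default_rng(42)
        template = np.sin(np.linspace(0, 6 * np.pi, 4000))[None, :]
        sigma = 1.0
        trials = [
            RecordingMatrix(template + sigma * rng.standard_normal(template.shape), dt=1.0)
            for _ in range(10)
        ]
        resid = lp.trial_average(trials).values - template
        assert resid.std() == pytest.approx(sigma / np.sqrt(10), rel=0.1)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            lp.trial_average([])


class TestFiringRates:
    def test_no_spikes_gives_zero(self):
        events = pd.DataFrame(columns=["population_id", "trial", "time_ms"])
        rates = lp.firing_rate_from_spikes(events, ["a", "b"], t0_ms=0.0, n_bins=100)
        assert rates.values.shape == (2, 100)
        assert np.all(rates.values == 0)

    def test_homogeneous_poisson_mean_rate(self):
        # 10 Hz, 1 cell, 100 trials of 1 s -> mean rate 10 +- sampling error
        rng = np.random.default_rng(7)
        rows = []
        for trial in range(100):
            n = rng.poisson(10.0)
            for t in rng.uniform(0.0, 1000.0, n):
                rows.append(("p", trial, t))
        events = pd.DataFrame(rows, columns=["population_id", "trial", "time_ms"])
        rates = lp.firing_rate_from_spikes(
            events, ["p"], t0_ms=0.0, n_bins=1000, n_trials=100,
            cells_per_population={"p": 1},
        )
        assert rates.values.mean() == pytest.approx(10.0, rel=0.05)

    def test_single_spike_mass_conserved(self):
        events = pd.DataFrame(
            [("p", 0, 100.3)], columns=["population_id", "trial", "time_ms"]
        )
        rates = lp.firing_rate_from_spikes(
            events, ["p"], t0_ms=0.0, n_bins=500, n_trials=1,
            cells_per_population={"p": 1},
        )
        # smoothing conserves mass: integral (spikes/s * s) = 1 spike
        total = rates.values.sum() * (rates.dt / 1000.0)
        assert total == pytest.approx(1.0, abs=1e-9)
        assert rates.values.argmax() == 100

    def test_spike_count_conservation_many(self, rng):
        times = rng.uniform(10.0, 490.0, 200)
        events = pd.DataFrame(
            {"population_id": "p", "trial": rng.integers(0, 5, 200), "time_ms": times}
        )
        rates = lp.firing_rate_from_spikes(
            events, ["p"], t0_ms=0.0, n_bins=500, n_trials=5,
            cells_per_population={"p": 3},
        )
        total = rates.values.sum() * (rates.dt / 1000.0) * 5 * 3
        assert total == pytest.approx(200.0, rel=1e-6)

    def test_unknown_population_rejected(self):
        events = pd.DataFrame(
            [("ghost", 0, 5.0)], columns=["population_id", "trial", "time_ms"]
        )
        with pytest.raises(ValueError, match="unknown population"):
            lp.firing_rate_from_spikes(events, ["p"], t0_ms=0.0, n_bins=10)
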