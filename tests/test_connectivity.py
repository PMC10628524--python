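"""Filtering, epoching, phase extraction and the PLI formula."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from megsw import (
    BandDefinition,
    PhaseEpoch,
    RoiTimeSeries,
    ValidationError,
    average_connectivity,
    band_by_name,
    band_connectivity,
    bandpass_epoch,
    instantaneous_phase,
    pli_epoch,
    pli_from_phases,
    preprocess,
    segment_epochs,
)
from megsw.simulate import OscillatorSpec, generate_coupled_oscillators


def _sine_ts(freq: float, fs: float = 500.0, duration: float = 4.0, n_ch: int = 1) -> RoiTimeSeries:
    t = np.arange(int(duration * fs)) / fs
    data = np.tile(np.sin(2 * np.pi * freq * t)[:, None], (1, n_ch))
    return RoiTimeSeries(data=data, fs=fs, labels=[f"ch{i}" for i in range(n_ch)])


class TestPreprocess:
    def test_notch_removes_line_frequency(self):
        ts = _sine_ts(60.0)
        out = preprocess(ts, target_fs=500.0, notch_freqs=(60.0,), broadband=None)
        interior = slice(200, -200)  # skip filter edge transients
        assert np.sqrt(np.mean(out.data[interior] ** 2)) < 0.01 * np.sqrt(
            np.mean(ts.data[interior] ** 2)
        )

    def test_identity_path_is_exact(self):
        ts = _sine_ts(10.0)
        out = preprocess(ts, target_fs=500.0, notch_freqs=(), broadband=None)
        assert np.max(np.abs(out.data - ts.data)) < 1e-6

    def test_downsample_quarters_sample_count(self):
        ts = _sine_ts(10.0, fs=2000.0, duration=2.0)
        out = preprocess(ts, target_fs=500.0, notch_freqs=(), broadband=None)
        assert out.n_samples == ts.n_samples // 4
        assert out.fs == 500.0

    def test_notch_at_nyquist_rejected(self):
        with pytest.raises(ValidationError, match="notch"):
            preprocess(_sine_ts(10.0), target_fs=500.0, notch_freqs=(250.0,), broadband=None)


class TestEpoching:
    def test_two_minutes_gives_24_epochs(self):
        ts = RoiTimeSeries(np.random.default_rng(0).standard_normal((60000, 2)), 500.0, ["a", "b"])
        epochs = segment_epochs(ts, 5.0)
        assert len(epochs) == 24
        assert all(e.n_samples == 2500 for e in epochs)

    def test_remainder_discarded(self):
        ts = RoiTimeSeries(np.zeros((int(12.5 * 500), 1)), 500.0, ["a"])
        assert len(segment_epochs(ts, 5.0)) == 2

    def test_exact_single_epoch(self):
        ts = RoiTimeSeries(np.zeros((2500, 1)), 500.0, ["a"])
        assert len(segment_epochs(ts, 5.0)) == 1

    def test_too_short_raises(self):
        ts = RoiTimeSeries(np.zeros((2000, 1)), 500.0, ["a"])
        with pytest.raises(ValidationError, match="shorter"):
            segment_epochs(ts, 5.0)


class TestBandpass:
    def test_in_band_tone_passes(self):
        ts = _sine_ts(10.0)
        out = bandpass_epoch(ts, band_by_name("alpha"))
        interior = slice(300, -300)
        ratio = np.abs(out.data[interior]).max() / np.abs(ts.data[interior]).max()
        assert ratio > 0.95

    def test_out_of_band_tone_blocked(self):
        ts = _sine_ts(10.0)
        out = bandpass_epoch(ts, band_by_name("gamma"))
        assert np.sqrt(np.mean(out.data**2)) < 0.05 * np.sqrt(np.mean(ts.data**2))

    def test_zero_signal_maps_to_zero(self):
        ts = RoiTimeSeries(np.zeros((2500, 2)), 500.0, ["a", "b"])
        out = bandpass_epoch(ts, band_by_name("alpha"))
        assert np.allclose(out.data, 0.0)

    def test_band_above_nyquist_rejected(self):
        ts = RoiTimeSeries(np.zeros((100, 1)), 100.0, ["a"])
        with pytest.raises(ValidationError, match="Nyquist"):
            bandpass_epoch(ts, band_by_name("gamma"))


class TestInstantaneousPhase:
    def test_cosine_phase_slope(self):
        fs, f = 500.0, 10.0
        t = np.arange(2500) / fs
        ts = RoiTimeSeries(np.cos(2 * np.pi * f * t)[:, None], fs, ["a"])
        ph = instantaneous_phase(ts, band_by_name("alpha")).phases[:, 0]
        interior = slice(250, 2250)
        slope = np.polyfit(t[interior], np.unwrap(ph)[interior], 1)[0]
        assert slope == pytest.approx(2 * np.pi * f, rel=0.01)

    def test_known_phase_offset_recovered(self):
        fs = 500.0
        t = np.arange(2500) / fs
        theta = 2 * np.pi * 10.0 * t
        data = np.column_stack([np.cos(theta), np.cos(theta - 0.5)])
        ts = RoiTimeSeries(data, fs, ["a", "b"])
        ph = instantaneous_phase(ts, band_by_name("alpha")).phases
        diff = np.angle(np.exp(1j * (ph[:, 0] - ph[:, 1])))
        interior = slice(250, 2250)
        assert np.max(np.abs(diff[interior] - 0.5)) < 0.02

    def test_sign_flip_shifts_phase_by_pi(self):
        fs = 500.0
        t = np.arange(2500) / fs
        x = np.cos(2 * np.pi * 10.0 * t)
        ts = RoiTimeSeries(np.column_stack([x, -x]), fs, ["a", "b"])
        ph = instantaneous_phase(ts, band_by_name("alpha")).phases
        diff = np.abs(np.angle(np.exp(1j * (ph[:, 0] - ph[:, 1]))))
        assert np.allclose(diff[250:-250], np.pi, atol=1e-6)

    def test_constant_channel_rejected_by_name(self):
        data = np.column_stack([np.sin(np.linspace(0, 10, 500)), np.ones(500)])
        ts = RoiTimeSeries(data, 500.0, ["good", "flatline"])
        with pytest.raises(ValidationError, match="flatline"):
            instantaneous_phase(ts, band_by_name("alpha"))


class TestPli:
    def test_constant_difference_gives_one(self):
        phases = np.column_stack([np.full(10, 0.3), np.zeros(10)])
        assert pli_from_phases(phases, edge_trim=0)[0, 1] == 1.0

    def test_three_plus_one_minus_gives_half(self):
        phases = np.column_stack([np.array([0.3, 0.3, 0.3, -0.3]), np.zeros(4)])
        assert pli_from_phases(phases, edge_trim=0)[0, 1] == 0.5

    def test_balanced_signs_give_zero(self):
        phases = np.column_stack([np.array([0.3, -0.3, 0.3, -0.3]), np.zeros(4)])
        assert pli_from_phases(phases, edge_trim=0)[0, 1] == 0.0

    def test_zero_difference_counts_as_zero(self):
        phases = np.column_stack([np.zeros(8), np.zeros(8)])
        assert pli_from_phases(phases, edge_trim=0)[0, 1] == 0.0

    @settings(deadline=None, max_examples=25)
    @given(st.integers(min_value=0, max_value=2**31 - 1))
    def test_symmetric_bounded_zero_diagonal(self, seed):
        rng = np.random.default_rng(seed)
        phases = rng.uniform(-np.pi, np.pi, size=(50, 5))
        m = pli_from_phases(phases, edge_trim=0)
        assert np.allclose(m, m.T)
        assert np.all(np.diag(m) == 0)
        assert np.all((m >= 0) & (m <= 1))

    def test_amplitude_scaling_invariance(self):
        # PLI depends only on phases: per-channel rescaling leaves it unchanged
        spec = OscillatorSpec(
            n_channels=3, band=(8.0, 13.0),
            coupling=np.array([[1, 0.7, 0.0], [0.7, 1, 0.0], [0.0, 0.0, 1.0]]),
            lag=np.array([[0, 0.4, 0], [-0.4, 0, 0], [0, 0, 0.0]]),
            noise_sd=0.0, duration_s=10.0, fs=500.0, seed=4,
        )
        ts = generate_coupled_oscillators(spec)
        scaled = RoiTimeSeries(ts.data * np.array([1.0, 7.0, 0.01]), ts.fs, ts.labels)
        band = band_by_name("alpha")
        a = band_connectivity(ts, [band], epoch_s=5.0)["alpha"].weights
        b = band_connectivity(scaled, [band], epoch_s=5.0)["alpha"].weights
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_pli_nonincreasing_in_noise(self):
        # seed-averaged PLI of a lagged coupled pair decays with noise level
        band = band_by_name("alpha")
        means = []
        for noise in (0.0, 0.5, 2.0):
            vals = []
            for seed in range(5):
                spec = OscillatorSpec(
                    n_channels=2, band=(8.0, 13.0),
                    coupling=np.array([[1.0, 1.0], [1.0, 1.0]]),
                    lag=np.array([[0.0, 0.6], [-0.6, 0.0]]),
                    noise_sd=noise, duration_s=20.0, fs=500.0, seed=seed,
                )
                ts = generate_coupled_oscillators(spec)
                vals.append(band_connectivity(ts, [band], epoch_s=5.0)["alpha"].weights[0, 1])
            means.append(np.mean(vals))
        assert means[0] >= means[1] >= means[2]

    def test_zero_lag_full_coupling_suppressed(self):
        # identical signals: wrapped difference exactly zero -> PLI 0
        spec = OscillatorSpec(
            n_channels=2, band=(8.0, 13.0),
            coupling=np.array([[1.0, 1.0], [1.0, 1.0]]),
            lag=np.zeros((2, 2)), noise_sd=0.0, duration_s=10.0, fs=500.0, seed=3,
        )
        ts = generate_coupled_oscillators(spec)
        m = band_connectivity(ts, [band_by_name("alpha")], epoch_s=5.0)["alpha"]
        assert m.weights[0, 1] < 0.05


class TestAverageConnectivity:
    def _cm(self, val, band="alpha", n=1):
        w = np.array([[0.0, val], [val, 0.0]])
        from megsw import ConnectivityMatrix

        return ConnectivityMatrix(w, band_by_name(band), "s1", "EO", n_epochs_averaged=n)

    def test_single_matrix_identity(self):
        m = self._cm(0.4)
        out = average_connectivity([m])
        np.testing.assert_array_equal(out.weights, m.weights)
        assert out.n_epochs_averaged == 1

    def test_two_matrix_mean(self):
        out = average_connectivity([self._cm(0.2), self._cm(0.4)])
        assert out.weights[0, 1] == pytest.approx(0.3)
        assert out.n_epochs_averaged == 2

    def test_mixed_bands_rejected(self):
        with pytest.raises(ValidationError, match="band"):
            average_connectivity([self._cm(0.2, "alpha"), self._cm(0.2, "beta")])

    def test_epoch_mean_of_perfect_coupling_is_one(self):
        spec = OscillatorSpec(
            n_channels=2, band=(8.0, 13.0),
            coupling=np.array([[1.0, 1.0], [1.0, 1.0]]),
            lag=np.array([[0.0, 0.5], [-0.5, 0.0]]),
            noise_sd=0.0, duration_s=15.0, fs=500.0, seed=0,
        )
        ts = generate_coupled_oscillators(spec)
        m = band_connectivity(ts, [band_by_name("alpha")], epoch_s=5.0)["alpha"]
        assert m.n_epochs_averaged == 3
        assert m.weights[0, 1] == pytest.approx(1.0)
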