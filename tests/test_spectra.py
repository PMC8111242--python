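"""State-weighted multitaper estimator: identities, recovery, band maps."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps
from scipy.signal import windows

from gammastates.preprocess import ConcatenatedData
from gammastates.simulate import (
    Oscillator,
    StateSpec,
    default_transition,
    generate_state_sequence,
    render_recording,
)
from gammastates.spectra import (
    BANDS,
    band_maps,
    compute_rho,
    mean_coupling,
    weighted_multitaper,
)

FS = 250.0


def make_concat(data, fs=FS, label="rest"):
    index = pd.DataFrame(
        [{"subject_id": "A", "segment_id": 0, "label": label, "start": 0, "stop": len(data)}]
    )
    return ConcatenatedData(np.asarray(data, dtype=float), fs, index)


def reference_multitaper(x, fs, window_s, overlap, n_tapers, freq_range):
    """Plain multitaper PSD written independently of the implementation."""
    win = int(round(window_s * fs))
    hop = int(round(win * (1 - overlap)))
    tapers = windows.dpss(win, (n_tapers + 1) / 2, Kmax=n_tapers)
    freqs = np.fft.rfftfreq(win, 1 / fs)
    sel = (freqs >= freq_range[0]) & (freqs <= freq_range[1])
    acc, n = 0.0, 0
    for start in range(0, len(x) - win + 1, hop):
        seg = x[start : start + win]
        p = np.mean(
            np.abs(np.fft.rfft(tapers * seg[None, :], axis=1)) ** 2, axis=0
        )
        acc = acc + p[sel]
        n += 1
    return freqs[sel], acc / n


class TestRho:
    def test_uniform_posterior_gives_unit_weights(self):
        g = np.full((50, 4), 0.25)
        rho = compute_rho(g).rho
        assert np.allclose(rho, 1.0)

    def test_one_hot_column_formula(self):
        g = np.array([[1.0, 0.0], [0.0, 1.0], [0.0, 1.0], [0.0, 1.0]])
        rho = compute_rho(g).rho
        assert np.allclose(rho[:, 0], [4.0, 0.0, 0.0, 0.0])

    def test_column_means_are_one(self, rng):
        g = rng.random((100, 3))
        g /= g.sum(axis=1, keepdims=True)
        rho = compute_rho(g).rho
        assert np.allclose(rho.mean(axis=0), 1.0, atol=1e-10)
        assert np.all(rho >= 0)

    def test_zero_mass_state_raises(self):
        g = np.column_stack([np.ones(10), np.zeros(10)])
        with pytest.raises(ValueError, match="zero total posterior mass"):
            compute_rho(g)


class TestWeightedMultitaper:
    def test_unit_weights_reduce_to_ordinary_spectrum(self, rng):
        x = rng.standard_normal((4000, 2))
        concat = make_concat(x)
        rho = np.ones((4000, 2))  # two states, both always "on"
        spec = weighted_multitaper(
            concat, rho, window_s=1.0, n_tapers=3, freq_range=(1.0, 45.0)
        )
        f_ref, p_ref = reference_multitaper(x[:, 0], FS, 1.0, 0.5, 3, (1.0, 45.0))
        assert np.allclose(spec.freqs, f_ref)
        for k in range(2):
            assert np.allclose(spec.power[k, 0], p_ref, rtol=1e-10)

    def test_fo_weighted_mean_reproduces_unweighted(self, rng):
        g = rng.random((6000, 3))
        g /= g.sum(axis=1, keepdims=True)
        x = rng.standard_normal((6000, 2))
        concat = make_concat(x)
        spec = weighted_multitaper(
            concat, compute_rho(g), window_s=1.0, n_tapers=3, freq_range=(1.0, 45.0)
        )
        fo = g.mean(axis=0)
        mixed = np.einsum("k,kpf->pf", fo, spec.power)
        _, p_ref = reference_multitaper(x[:, 0], FS, 1.0, 0.5, 3, (1.0, 45.0))
        assert np.allclose(mixed[0], p_ref, rtol=0.01)

    def test_planted_states_recover_band_peaks(self):
        """With ground-truth one-hot weights, each state's spectrum peaks in
        its planted band (conditioned-epoch Welch as the sign oracle)."""
        specs = (
            StateSpec(0, (Oscillator((0,), 10.0, 2.0),)),
            StateSpec(1, (Oscillator((0,), 2.0, 2.0, bandwidth=1.0),)),
        )
        states = generate_state_sequence(default_transition(2, 0.995), 60000, seed=3)
        ts = render_recording(states, specs, FS, seed=3, n_parcels=2)
        concat = make_concat(ts.data)
        onehot = np.zeros((60000, 2))
        onehot[np.arange(60000), states] = 1.0
        spec = weighted_multitaper(
            concat, compute_rho(onehot), window_s=2.0, n_tapers=3, freq_range=(1.0, 45.0)
        )
        alpha = (spec.freqs >= 8) & (spec.freqs <= 12)
        delta = (spec.freqs >= 1) & (spec.freqs <= 3)
        assert spec.power[0, 0, alpha].mean() > spec.power[1, 0, alpha].mean()
        assert spec.power[1, 0, delta].mean() > spec.power[0, 0, delta].mean()

    def test_identical_parcels_fully_coherent(self, rng):
        x = rng.standard_normal(3000)
        concat = make_concat(np.column_stack([x, x]))
        g = rng.random((3000, 2))
        g /= g.sum(axis=1, keepdims=True)
        spec = weighted_multitaper(
            concat, compute_rho(g), window_s=1.0, freq_range=(1.0, 45.0)
        )
        assert np.allclose(spec.coherence[:, 0, 1], 1.0, atol=1e-10)

    def test_coherence_symmetric_and_self_unity(self, rng):
        concat = make_concat(rng.standard_normal((3000, 3)))
        rho = np.ones((3000, 1))
        spec = weighted_multitaper(concat, rho, window_s=1.0, freq_range=(1.0, 45.0))
        assert np.allclose(spec.coherence, np.swapaxes(spec.coherence, 1, 2))
        for p in range(3):
            assert np.allclose(spec.coherence[0, p, p], 1.0, atol=1e-10)

    def test_window_longer_than_segments_raises(self, rng):
        concat = make_concat(rng.standard_normal((100, 2)))
        with pytest.raises(ValueError, match="longer than every segment"):
            weighted_multitaper(concat, np.ones((100, 1)), window_s=2.0, freq_range=(1, 45))

    def test_freq_range_above_nyquist_raises(self, rng):
        concat = make_concat(rng.standard_normal((1000, 2)))
        with pytest.raises(ValueError, match="Nyquist"):
            weighted_multitaper(concat, np.ones((1000, 1)), freq_range=(1, 200))


class TestBandMaps:
    def fake_spectra(self, power, freqs):
        from gammastates.spectra import StateSpectra

        return StateSpectra(power, None, freqs, 3, 2.0, 0.5)

    def test_equal_power_gives_zero_relative_map(self):
        freqs = np.linspace(1, 90, 90)
        power = np.ones((3, 2, 90))
        _, rel = band_maps(self.fake_spectra(power, freqs))
        assert np.allclose(rel.values, 0.0)

    def test_two_state_closed_form(self):
        freqs = np.array([10.0])
        power = np.array([[[3.0]], [[1.0]]])
        bands = {"alpha": (8.0, 12.0)}
        absm, rel = band_maps(self.fake_spectra(power, freqs), bands)
        assert np.allclose(absm.values.ravel(), [3.0, 1.0])
        assert np.allclose(rel.values.ravel(), [0.5, -0.5])

    def test_relative_maps_average_to_zero(self, rng):
        freqs = np.linspace(1, 95, 190)
        power = rng.random((4, 5, 190)) + 0.1
        _, rel = band_maps(self.fake_spectra(power, freqs))
        assert np.allclose(rel.values.mean(axis=0), 0.0, atol=1e-8)
        # invariant as stated for (1 + map): mean over states of (1+m) == 1
        assert np.allclose((1 + rel.values).mean(axis=0), 1.0, atol=1e-8)

    def test_empty_band_raises(self):
        freqs = np.array([50.0])
        power = np.ones((2, 1, 1))
        with pytest.raises(ValueError, match="empty"):
            band_maps(self.fake_spectra(power, freqs), {"alpha": (8.0, 12.0)})

    def test_alpha_deficit_state_has_minimal_occipital_alpha(self):
        """The state rendered without the shared occipital alpha oscillator
        shows the lowest relative alpha power on the occipital parcels."""
        from gammastates.simulate import default_state_specs

        specs = default_state_specs(8, 4, roi_parcels=(6, 7), enhancing_state=1)
        states = generate_state_sequence(default_transition(4, 0.97), 80000, seed=5)
        ts = render_recording(states, specs, FS, seed=5, n_parcels=8)
        onehot = np.zeros((80000, 4))
        onehot[np.arange(80000), states] = 1.0
        spec = weighted_multitaper(
            make_concat(ts.data),
            compute_rho(onehot),
            window_s=2.0,
            freq_range=(1.0, 45.0),
            compute_coherence=False,
        )
        _, rel = band_maps(spec, {"alpha": (8.0, 12.0)})
        for roi in (6, 7):
            assert np.argmin(rel.values[:, roi, 0]) == 1


class TestMeanCoupling:
    def test_two_parcel_mean_equals_pairwise(self, rng):
        concat = make_concat(rng.standard_normal((4000, 2)))
        spec = weighted_multitaper(
            concat, np.ones((4000, 1)), window_s=1.0, freq_range=(1.0, 45.0)
        )
        mc = mean_coupling(spec, {"alpha": (8.0, 12.0)})
        sel = (spec.freqs >= 8) & (spec.freqs <= 12)
        pair = spec.coherence[0, 0, 1, sel].mean()
        assert np.allclose(mc[0, :, 0], pair)

    def test_duplicated_parcel_dominates(self, rng):
        x = rng.standard_normal(6000)
        data = np.column_stack([x, x, rng.standard_normal(6000)])
        spec = weighted_multitaper(
            make_concat(data), np.ones((6000, 1)), window_s=1.0, freq_range=(1.0, 45.0)
        )
        mc = mean_coupling(spec, {"broad": (1.0, 45.0)})
        assert mc[0, 0, 0] >= mc[0, 2, 0]

    def test_independent_noise_floor_uniform(self, rng):
        data = rng.standard_normal((30000, 3))
        spec = weighted_multitaper(
            make_concat(data), np.ones((30000, 1)), window_s=1.0, freq_range=(1.0, 45.0)
        )
        mc = mean_coupling(spec, {"broad": (1.0, 45.0)})[0, :, 0]
        assert mc.max() < 0.15  # near the multitaper bias floor
        assert mc.max() - mc.min() < 0.02
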