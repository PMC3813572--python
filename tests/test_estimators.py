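"""Connectivity estimators: DTF, SDTF, coherence, SL, band integration."""
import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dtfnet import (MVAR, ConnectivitySpectrum, MultichannelRecording,
                    SLParams, SimulationConfig, band_integrate, coherence,
                    default_frequency_grid, dtf, sdtf,
                    simulate_mvar_network, synchronization_likelihood)
from dtfnet.mvar import SpectralTransfer, companion_matrix


def _spectrum_from_H(H, freqs, labels):
    return dtf(SpectralTransfer(np.asarray(freqs), np.asarray(H, complex),
                                128.0, labels))


class TestDtf:
    def test_identity_transfer(self):
        freqs = np.arange(0.0, 64.5, 0.5)
        H = np.broadcast_to(np.eye(3), (len(freqs), 3, 3)).copy()
        spec = _spectrum_from_H(H, freqs, ["A", "B", "C"])
        assert np.all(spec.values[np.arange(3), np.arange(3)] == 1.0)
        off = spec.values[0, 1], spec.values[1, 0]
        assert np.all(off[0] == 0) and np.all(off[1] == 0)

    def test_no_transfer_gives_zero(self):
        """H_12 = 0 (no 2 -> 1 transfer) forces DTF[1, 2] = 0 at every f."""
        freqs = np.array([1.0, 10.0, 40.0])
        H = np.array([[[1.0, 0.0], [0.5, 1.2]]] * 3, dtype=complex)
        spec = _spectrum_from_H(H, freqs, ["A", "B"])
        assert np.all(spec.values[0, 1] == 0)
        assert np.all(spec.values[1, 0] > 0)

    def test_matches_adjugate_oracle(self):
        """2x2 closed form: H = adj(A(f)) / det(A(f)); DTF recomputed from it."""
        A = np.zeros((1, 2, 2))
        A[0] = [[0.5, 0.0], [0.4, 0.3]]       # unidirectional 1 -> 2
        fs = 128.0
        freqs = default_frequency_grid(fs)
        rec, _ = simulate_mvar_network(A, np.eye(2),
                                       SimulationConfig(1024, fs, seed=0))
        res = MVAR(rec, standardize=False).fit(1)
        res.coefficients[:] = A                 # evaluate at the exact system
        package = dtf(res.transfer_matrix(freqs)).values
        oracle = np.empty_like(package)
        for fi, f in enumerate(freqs):
            z = np.exp(-2j * np.pi * f / fs)
            Af = np.eye(2) - A[0] * z
            det = Af[0, 0] * Af[1, 1] - Af[0, 1] * Af[1, 0]
            Hf = np.array([[Af[1, 1], -Af[0, 1]], [-Af[1, 0], Af[0, 0]]]) / det
            p = np.abs(Hf) ** 2
            oracle[:, :, fi] = p / p.sum(axis=1, keepdims=True)
        np.testing.assert_allclose(package, oracle, atol=1e-12)

    def test_all_zero_row_raises(self):
        freqs = np.array([10.0])
        H = np.zeros((1, 2, 2), complex)
        H[0, 1, 1] = 1.0
        with pytest.raises(ValueError, match="all-zero"):
            _spectrum_from_H(H, freqs, ["A", "B"])

    @pytest.mark.parametrize("seed", range(5))
    def test_row_normalization_random_models(self, seed):
        """Rows of the DTF sum to 1 at every frequency for any stable fit."""
        rng = np.random.default_rng(seed)
        k, p = rng.integers(2, 5), rng.integers(1, 4)
        while True:
            A = rng.normal(scale=0.3, size=(p, k, k))
            if np.max(np.abs(np.linalg.eigvals(companion_matrix(A)))) < 0.95:
                break
        rec, _ = simulate_mvar_network(A, np.eye(k),
                                       SimulationConfig(1024, 128.0, seed=seed))
        spec = MVAR(rec).fit(p).dtf()
        sums = spec.values.sum(axis=1)
        np.testing.assert_allclose(sums, 1.0, atol=1e-9)


class TestCoherence:
    def test_self_coherence_is_one(self, white_recording):
        spec = coherence(white_recording)
        assert not spec.directed
        for c in range(3):
            assert np.all(spec.values[c, c] == 1.0)

    def test_independent_channels_bias_level(self):
        """Welch coherence bias for independent signals ~ 1/n_segments."""
        rng = np.random.default_rng(0)
        rec = MultichannelRecording(rng.standard_normal((2560, 2)), 128.0,
                                    ["A", "B"])
        spec = coherence(rec, segment_length=256, overlap=0.5)
        inner = (spec.frequencies > 2) & (spec.frequencies < 62)
        assert spec.values[0, 1, inner].mean() < 0.2

    def test_common_signal_closed_form(self):
        """x = s + n1, y = s + n2 with white s: coherence = (1/(1+1/snr^2))^2."""
        rng = np.random.default_rng(1)
        n, snr = 8192, 2.0
        s = rng.standard_normal(n)
        x = s + rng.standard_normal(n) / snr
        y = s + rng.standard_normal(n) / snr
        rec = MultichannelRecording(np.column_stack([x, y]), 128.0, ["A", "B"])
        spec = coherence(rec, segment_length=256)
        expected = (1 / (1 + snr ** -2)) ** 2
        inner = (spec.frequencies > 2) & (spec.frequencies < 62)
        assert abs(spec.values[0, 1, inner].mean() - expected) < 0.05

    def test_symmetry_and_range(self, white_recording):
        spec = coherence(white_recording)
        np.testing.assert_array_equal(spec.values,
                                      np.swapaxes(spec.values, 0, 1))
        assert spec.values.min() >= 0 and spec.values.max() <= 1

    def test_segment_validation(self, white_recording):
        with pytest.raises(ValueError, match="exceeds"):
            coherence(white_recording, segment_length=4096)
        with pytest.raises(ValueError, match="segments"):
            coherence(white_recording, segment_length=1024, overlap=0.0)


class TestSynchronizationLikelihood:
    def test_identical_channels_give_one(self):
        from dtfnet import gen_source_signal
        x = gen_source_signal(2048, 128.0, seed=9)
        rec = MultichannelRecording(np.column_stack([x, x]), 128.0, ["A", "B"])
        sl = synchronization_likelihood(rec, SLParams(delay=10, embedding_dim=10))
        assert sl.values[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_independent_noise_at_chance_level(self, seed):
        """For independent channels SL sits at the p_ref chance floor."""
        rng = np.random.default_rng(seed)
        rec = MultichannelRecording(rng.standard_normal((2560, 2)), 128.0,
                                    ["A", "B"])
        params = SLParams(delay=10, embedding_dim=10, p_ref=0.05)
        v = synchronization_likelihood(rec, params).values[0, 1]
        assert abs(v - params.p_ref) / params.p_ref < 0.5

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(7)
        rec = MultichannelRecording(rng.standard_normal((1500, 3)), 128.0,
                                    ["A", "B", "C"])
        sl = synchronization_likelihood(rec, SLParams(delay=5, embedding_dim=5))
        np.testing.assert_array_equal(sl.values, sl.values.T)
        np.testing.assert_array_equal(np.diag(sl.values), 1.0)
        assert sl.values.min() >= 0

    def test_embedding_too_long(self):
        rng = np.random.default_rng(0)
        rec = MultichannelRecording(rng.standard_normal((300, 2)), 128.0,
                                    ["A", "B"])
        with pytest.raises(ValueError):
            synchronization_likelihood(rec, SLParams(delay=40, embedding_dim=10))

    def test_param_validation(self):
        with pytest.raises(ValueError):
            SLParams(delay=0)
        with pytest.raises(ValueError):
            SLParams(p_ref=1.5)


class TestBandIntegrate:
    def _const_spectrum(self, c=0.25):
        freqs = default_frequency_grid(128.0)
        k = 2
        values = np.full((k, k, len(freqs)), c)
        return ConnectivitySpectrum("DTF", freqs, values, True, ["A", "B"])

    def test_constant_spectrum(self):
        integ = band_integrate(self._const_spectrum(0.25), 4.0, 60.0)
        np.testing.assert_allclose(integ.matrix, 0.25)

    def test_single_point_band(self):
        spec = self._const_spectrum()
        spec.values[0, 1, :] = np.linspace(0, 1, spec.values.shape[2])
        integ = band_integrate(spec, 10.0, 10.0 + 1e-9)
        fi = np.argmin(np.abs(spec.frequencies - 10.0))
        assert integ.matrix[0, 1] == pytest.approx(spec.values[0, 1, fi])

    @pytest.mark.parametrize("band", [(0.5, 40.0), (1.0, 45.0), (4.0, 60.0)])
    def test_standard_bands_populated(self, band):
        """The conventional EEG analysis bands align with the default grid."""
        integ = band_integrate(self._const_spectrum(), *band)
        assert integ.band == band
        n_pts = ((self._const_spectrum().frequencies >= band[0])
                 & (self._const_spectrum().frequencies <= band[1])).sum()
        assert n_pts == int(round((band[1] - band[0]) / 0.5)) + 1

    def test_empty_band(self):
        with pytest.raises(ValueError):
            band_integrate(self._const_spectrum(), 63.7, 63.9)
        with pytest.raises(ValueError):
            band_integrate(self._const_spectrum(), 40.0, 4.0)


def _coupled_trials(n_trials, n, coupling_on, seed, switch_at=None):
    """2-channel AR ensemble; 1 -> 2 coupling optionally switching on."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_trials):
        e = rng.standard_normal((n, 2))
        x = np.zeros((n, 2))
        for i in range(2, n):
            on = coupling_on and (switch_at is None or i >= switch_at)
            c = 0.8 if on else 0.0
            x[i, 0] = 1.2 * x[i - 1, 0] - 0.5 * x[i - 2, 0] + e[i, 0]
            x[i, 1] = 0.9 * x[i - 1, 1] - 0.3 * x[i - 2, 1] + c * x[i - 1, 0] + e[i, 1]
        out.append(MultichannelRecording(x, 128.0, ["S", "T"]))
    return out


class TestSdtf:
    def test_stationary_ensemble_constant(self):
        trials = _coupled_trials(20, 512, True, seed=0)
        tv = sdtf(trials, window_length=80, step=40, order=3)
        vals = np.array([band_integrate(s, 4, 60).matrix[1, 0]
                         for s in tv.spectra])
        assert vals.std() < 0.1
        assert vals.mean() > 0.1   # the coupling is visible in every window

    @pytest.mark.parametrize("seed", range(10))
    def test_detects_coupling_onset(self, seed):
        trials = _coupled_trials(20, 512, True, seed=seed, switch_at=256)
        tv = sdtf(trials, window_length=80, step=40, order=3)
        vals = np.array([band_integrate(s, 4, 60).matrix[1, 0]
                         for s in tv.spectra])
        mid = np.searchsorted(tv.window_starts, 256)
        assert vals[mid:].mean() > vals[:mid].mean()

    def test_window_times_match_epoching(self):
        """Windows cover a 0-3 s analysis epoch at 128 Hz."""
        trials = _coupled_trials(12, 384, False, seed=1)
        tv = sdtf(trials, window_length=64, step=64, order=2)
        assert tv.window_times[0] == 0.0
        assert tv.window_times[-1] + tv.window_length / 128.0 <= 3.0 + 1e-9

    def test_too_few_trials_warns(self):
        trials = _coupled_trials(4, 512, False, seed=2)
        with pytest.warns(UserWarning, match="trials"):
            sdtf(trials, window_length=128, step=64, order=2)

    def test_under_determined_raises(self):
        trials = _coupled_trials(2, 256, False, seed=3)
        with pytest.raises(ValueError, match="under-determined"):
            sdtf(trials, window_length=6, step=6, order=5)

    def test_mismatched_trials_rejected(self):
        t1 = _coupled_trials(1, 256, False, seed=4)[0]
        t2 = _coupled_trials(1, 300, False, seed=5)[0]
        with pytest.raises(ValueError, match="share"):
            sdtf([t1, t2], window_length=64, step=32, order=2)


@settings(max_examples=10, deadline=None, derandomize=True)
@given(seed=st.integers(0, 2 ** 16), order=st.integers(1, 3))
def test_dtf_rows_sum_to_one_property(seed, order):
    rng = np.random.default_rng(seed)
    rec = MultichannelRecording(rng.standard_normal((600, 3)), 128.0,
                                ["A", "B", "C"])
    spec = MVAR(rec).fit(order).dtf()
    np.testing.assert_allclose(spec.values.sum(axis=1), 1.0, atol=1e-9)
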