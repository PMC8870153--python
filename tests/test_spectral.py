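"""Morlet family, wavelet power, dB normalization, effect recovery."""

import numpy as np
import pandas as pd
import pytest

from sst_ersp import spectral as sp
from sst_ersp import synth as sy
from sst_ersp import task as tk


def _epochs_from_array(data, fs, t0=0.0):
    """Wrap a raw (trials, samples) array as a minimal epoch-like object."""

    class _E:
        pass

    e = _E()
    e.data = data
    e.fs = fs
    e.times = np.arange(data.shape[1]) * 1000.0 / fs + t0
    e.meta = pd.DataFrame({"trial": np.arange(data.shape[0])})
    e.lock_event = "motion_onset"
    return e


class TestWaveletFamily:
    def test_grid_of_95_frequencies(self, full_family):
        assert full_family.n_freqs == 95
        assert full_family.freqs[0] == 3.0 and full_family.freqs[-1] == 50.0
        assert np.allclose(np.diff(full_family.freqs), 0.5)
        # unit energy
        for k in full_family.kernels[::16]:
            assert np.isclose(np.sum(np.abs(k) ** 2), 1.0)

    def test_degenerate_single_wavelet(self):
        fam = sp.build_wavelets(3.0, 3.0, 0.5, fs=500.0)
        assert fam.n_freqs == 1

    def test_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            sp.build_wavelets(3.0, 260.0, 0.5, fs=500.0)

    def test_kernel_spectrum_peaks_at_nominal_frequency(self, full_family):
        nfft = 1 << 15
        grid = np.fft.fftfreq(nfft, 1.0 / full_family.fs)
        for i in (0, 40, 94):
            spec = np.abs(np.fft.fft(full_family.kernels[i], nfft))
            peak = grid[np.argmax(spec)]
            assert abs(peak - full_family.freqs[i]) <= full_family.fs / nfft + 1e-9

    def test_temporal_fwhm_closed_form(self):
        # FWHM of the Gaussian envelope: sigma_t * 2*sqrt(2 ln 2),
        # sigma_t = cycles / (2 pi f)
        fam = sp.build_wavelets(10.0, 10.0, 0.5, fs=1000.0, cycles=5.0)
        env = np.abs(fam.kernels[0])
        t = (np.arange(len(env)) - len(env) // 2) / fam.fs
        half = env >= env.max() / 2
        fwhm = t[half][-1] - t[half][0]
        expected = (5.0 / 10.0) * (2 * np.sqrt(2 * np.log(2)) / (2 * np.pi))
        assert abs(fwhm - expected) < 2.5 / fam.fs


class TestTFPower:
    def test_sinusoid_localizes_at_its_frequency(self, small_family):
        fs = small_family.fs
        t = np.arange(int(3 * fs)) / fs
        data = np.sin(2 * np.pi * 20.0 * t)[None, :]
        tf = sp.tf_power(_epochs_from_array(data, fs), small_family)
        mid = tf.power.shape[1] // 2
        assert small_family.freqs[np.argmax(tf.power[:, mid, 0])] == 20.0

    def test_power_scales_quadratically_with_amplitude(self, small_family):
        fs = small_family.fs
        t = np.arange(int(3 * fs)) / fs
        row = int(np.argmin(np.abs(small_family.freqs - 15.0)))
        mids = []
        for amp in (1.0, 2.0):
            data = amp * np.sin(2 * np.pi * 15.0 * t)[None, :]
            tf = sp.tf_power(_epochs_from_array(data, fs), small_family)
            mids.append(tf.power[row, tf.power.shape[1] // 2, 0])
        assert np.isclose(mids[1] / mids[0], 4.0, rtol=1e-4)

    def test_white_noise_expected_power_is_flat(self, small_family):
        """Unit-energy kernels make E[power] frequency-independent for white
        noise (matching the average FFT periodogram level)."""
        rng = np.random.default_rng(1)
        fs = small_family.fs
        data = rng.standard_normal((60, int(4 * fs)))
        tf = sp.tf_power(_epochs_from_array(data, fs), small_family, decim=4)
        valid = tf.edge_valid.all(axis=0)
        mean_by_freq = tf.power[:, valid, :].mean(axis=(1, 2))
        # expected level: noise variance = 1 (unit-energy kernels)
        assert abs(mean_by_freq.mean() - 1.0) < 0.05
        assert mean_by_freq.max() / mean_by_freq.min() < 1.15

    def test_edge_flagging(self, small_family):
        fs = small_family.fs
        data = np.zeros((1, int(fs)))  # 1 s epoch
        tf = sp.tf_power(_epochs_from_array(data, fs), small_family)
        half = small_family.half_lengths.max()
        assert not tf.edge_valid[:, 0].any()
        assert tf.edge_valid.all(axis=0)[half]
        with pytest.raises(ValueError):
            tf.require_valid(tf.times[0], tf.times[-1])

    def test_agrees_with_mne_morlet_on_db_change(self, small_family):
        """Independent oracle: mne's Morlet TFR measures the same dB step
        for an amplitude-modulated tone (scale factors cancel in ratios)."""
        mne = pytest.importorskip("mne")
        fs = small_family.fs
        n = int(4 * fs)
        t = np.arange(n) / fs
        amp = np.where(t >= 2.0, 2.0, 1.0)  # power step +6.02 dB at 2 s
        rng = np.random.default_rng(2)
        data = amp * np.sin(2 * np.pi * 18.0 * t)[None, :] \
            + 0.05 * rng.standard_normal((1, n))
        row = int(np.argmin(np.abs(small_family.freqs - 18.0)))
        seg1 = (t > 0.7) & (t < 1.7)
        seg2 = (t > 2.3) & (t < 3.3)

        tf = sp.tf_power(_epochs_from_array(data, fs), small_family)
        mine = 10 * np.log10(tf.power[row, seg2, 0].mean()
                             / tf.power[row, seg1, 0].mean())

        out = mne.time_frequency.tfr_array_morlet(
            data[None], sfreq=fs, freqs=small_family.freqs,
            n_cycles=small_family.cycles, output="power", zero_mean=False)
        theirs = 10 * np.log10(out[0, 0, row, seg2].mean()
                               / out[0, 0, row, seg1].mean())
        assert abs(mine - theirs) < 0.1
        assert abs(mine - 6.02) < 0.3


class TestDbNormalization:
    def test_closed_form_ratios(self):
        power = np.ones((1, 3, 1)) * np.array([1.0, 10.0, 0.5])[None, :, None]
        tf = sp.TFArray(power=power, freqs=np.array([10.0]),
                        times=np.array([0.0, 1.0, 2.0]),
                        edge_valid=np.ones((1, 3), bool),
                        meta=pd.DataFrame({"trial": [0]}))
        db = sp.db_normalize(tf, np.array([[1.0]]))
        assert np.allclose(db.power[0, :, 0], [0.0, 10.0, -3.010299956639812])

    def test_denormalize_inverts(self, small_family):
        rng = np.random.default_rng(3)
        data = rng.standard_normal((8, int(2 * small_family.fs)))
        tf = sp.tf_power(_epochs_from_array(data, small_family.fs), small_family)
        base = tf.power[:, 50:100, :].mean(axis=1)
        db = sp.db_normalize(tf, base)
        raw = sp.db_denormalize(db)
        np.testing.assert_allclose(raw.power, tf.power, rtol=1e-5)

    def test_nonpositive_baseline_rejected(self):
        power = np.ones((1, 2, 1))
        tf = sp.TFArray(power=power, freqs=np.array([10.0]),
                        times=np.array([0.0, 1.0]),
                        edge_valid=np.ones((1, 2), bool),
                        meta=pd.DataFrame({"trial": [0]}))
        with pytest.raises(ValueError):
            sp.db_normalize(tf, np.array([[0.0]]))


class TestErspMap:
    def _tf(self):
        rng = np.random.default_rng(4)
        power = rng.standard_normal((3, 4, 5))
        return sp.TFArray(power=power, freqs=np.arange(3.0),
                          times=np.arange(4.0), edge_valid=np.ones((3, 4), bool),
                          meta=pd.DataFrame({"trial": range(5)}), units="dB")

    def test_single_trial_subset_is_identity(self):
        tf = self._tf()
        np.testing.assert_allclose(sp.ersp_map(tf, [2]), tf.power[:, :, 2])

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            sp.ersp_map(self._tf(), [])


class TestEffectRecovery:
    """Injected dB changes recovered through the full wavelet pipeline with
    the leakage-corrected plateau estimator, across the reporting bands."""

    CASES = [  # (band, window ms, delta dB)
        ((4.0, 7.0), (0.0, 900.0), -4.0),
        ((8.0, 12.0), (0.0, 700.0), 3.0),
        ((13.0, 30.0), (0.0, 400.0), -4.0),
        ((30.0, 50.0), (0.0, 300.0), -6.0),
    ]

    @pytest.mark.parametrize("band, win, delta", CASES)
    def test_recovery_within_half_db(self, band, win, delta):
        eff = sy.ERSPEffect("RSFG", band, win, delta, group="A")
        cfg = sy.EEGGenConfig(rois=("RSFG",), oscillators=(), effects=(eff,))
        fam = sp.build_wavelets(fs=cfg.fs)
        seed = 50 + int(band[0])
        ep_a = sy.synthesize_epochs(cfg, 200, group="A", seed=seed)
        ep_b = sy.synthesize_epochs(cfg, 200, group="B", seed=seed + 1)
        tf_a = sp.tf_power(ep_a, fam, decim=5)
        tf_b = sp.tf_power(ep_b, fam, decim=5)
        rec = sp.recover_effect_db(tf_a, fam, band, win, tf_b=tf_b,
                                   psd=lambda f: sy.model_psd(cfg, f))
        assert abs(rec - delta) <= 0.5
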