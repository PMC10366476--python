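import numpy as np
import pytest

from sbpsnn.preprocess import (BAND_ORDER, EEGRecording, bandpass,
                               epoch_and_baseline, ersp, remove_artifacts_ica,
                               rereference_average, wavelet_band_power)


def _tone(freq, fs=250.0, dur=10.0, n_ch=2):
    t = np.arange(int(dur * fs)) / fs
    return EEGRecording(np.tile(np.sin(2 * np.pi * freq * t), (n_ch, 1)),
                        fs, tuple(f"ch{i}" for i in range(n_ch)))


class TestBandpass:
    def test_60hz_attenuated_20db(self):
        rec = bandpass(_tone(60.0))
        rms_out = rec.data[0][500:-500].std()
        assert 20 * np.log10(np.sqrt(0.5) / rms_out) >= 20

    def test_dc_offset_removed(self):
        rec = EEGRecording(np.full((2, 1000), 100.0), 250.0, ("a", "b"))
        out = bandpass(rec)
        assert np.abs(out.data.mean()) < 1.0

    def test_10hz_passband_unity_gain(self):
        out = bandpass(_tone(10.0))
        amp = np.sqrt(2.0) * out.data[0][500:-500].std()
        assert 0.95 <= amp <= 1.05

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError, match="too low"):
            bandpass(EEGRecording(np.zeros((2, 100)), 90.0, ("a", "b")))

    def test_bad_order_rejected(self):
        with pytest.raises(ValueError, match="order"):
            bandpass(_tone(10.0), order=0)


class TestRereference:
    def test_column_means_zero(self, rng):
        rec = EEGRecording(rng.standard_normal((5, 400)), 100.0,
                           tuple("abcde"))
        out = rereference_average(rec)
        assert np.abs(out.data.mean(axis=0)).max() < 1e-9

    def test_idempotent(self, rng):
        rec = EEGRecording(rng.standard_normal((4, 300)), 100.0,
                           tuple("abcd"))
        once = rereference_average(rec)
        twice = rereference_average(once)
        assert np.allclose(once.data, twice.data)

    def test_zero_mean_pair_unchanged(self):
        v = np.sin(np.linspace(0, 10, 200))
        rec = EEGRecording(np.vstack([v, -v]), 100.0, ("p", "n"))
        out = rereference_average(rec)
        assert np.allclose(out.data, rec.data, atol=1e-12)

    def test_single_channel_rejected(self):
        with pytest.raises(ValueError, match="2 channels"):
            rereference_average(EEGRecording(np.zeros((1, 10)), 10.0, ("a",)))


def test_filter_and_rereference_commute(rng):
    rec = EEGRecording(rng.standard_normal((6, 2000)), 250.0,
                       tuple("abcdef"))
    a = rereference_average(bandpass(rec))
    b = bandpass(rereference_average(rec))
    scale = np.abs(a.data).max()
    assert np.abs(a.data - b.data).max() / scale < 1e-6


class TestICA:
    def test_blink_rms_reduced(self, small_dataset):
        rec = next(r for r in small_dataset.recordings
                   if any(c == "blink" for _s, c in r.events))
        clean = remove_artifacts_ica(rec, corr_threshold=0.6, seed=0)
        assert clean.meta["ica_removed"] >= 1
        n = int(0.3 * rec.fs)
        fp1 = rec.labels.index("Fp1")
        before = after = 0.0
        for s, code in rec.events:
            if code == "blink":
                before += rec.data[fp1, s:s + n].std()
                after += clean.data[fp1, s:s + n].std()
        assert after <= 0.5 * before

    def test_blink_free_data_untouched(self, rng):
        data = rng.standard_normal((6, 3000))
        labels = ("Fp1", "Fp2", "Cz", "Pz", "O1", "O2")
        rec = EEGRecording(data, 250.0, labels)
        clean = remove_artifacts_ica(rec, corr_threshold=0.9, seed=0)
        assert clean.meta["ica_removed"] == 0
        assert np.allclose(clean.data, rec.data, atol=1e-6)

    def test_invalid_threshold(self, rng):
        rec = EEGRecording(rng.standard_normal((4, 500)), 100.0,
                           ("Fp1", "Fp2", "Cz", "Pz"))
        with pytest.raises(ValueError, match="corr_threshold"):
            remove_artifacts_ica(rec, corr_threshold=0.0)


class TestEpoching:
    def test_constant_channel_zeroed(self):
        rec = EEGRecording(np.full((1, 2000), 5.0), 1000.0, ("a",))
        eps = epoch_and_baseline(rec, [1000], duration_s=0.5)
        assert np.allclose(eps[0], 0.0)

    def test_baseline_window_mean_zero(self, rng):
        rec = EEGRecording(rng.standard_normal((2, 4000)), 1000.0, ("a", "b"))
        onset = 2000
        eps = epoch_and_baseline(rec, [onset], duration_s=1.0)
        base = rec.data[:, onset - 500:onset].mean(axis=1, keepdims=True)
        manual = rec.data[:, onset:onset + 1000] - base
        assert np.allclose(eps[0], manual)

    def test_onset_too_early_rejected(self):
        rec = EEGRecording(np.zeros((1, 5000)), 1000.0, ("a",))
        with pytest.raises(ValueError, match="baseline window"):
            epoch_and_baseline(rec, [10], duration_s=0.5)


class TestWaveletBandPower:
    def test_alpha_tone_dominates_alpha_band(self):
        bp = wavelet_band_power(_tone(10.0, n_ch=1), frame_hop=0.5)
        total = bp.power.sum()
        assert bp.band("alpha").sum() / total > 0.8

    def test_beta_tone_dominates_beta_band(self):
        bp = wavelet_band_power(_tone(20.0, n_ch=1), frame_hop=0.5)
        shares = {b: bp.band(b).sum() for b in BAND_ORDER}
        assert max(shares, key=shares.get) == "beta"

    def test_zero_signal_zero_power(self):
        rec = EEGRecording(np.zeros((1, 1000)), 250.0, ("a",))
        bp = wavelet_band_power(rec)
        assert np.allclose(bp.power, 0.0)

    def test_band_means_reconstruct_total_power(self, rng):
        # tiling completeness: band means weighted by their bin counts
        # reconstruct the total power over the analysis frequencies
        from sbpsnn.preprocess import BANDS, _cwt_power
        rec = EEGRecording(rng.standard_normal((1, 4000)), 250.0, ("a",))
        rec = bandpass(rec)
        bp = wavelet_band_power(rec, frame_hop=1.0)
        freqs = np.geomspace(0.5, 48.0, 40)
        counts = {b: int(((freqs >= lo) & (freqs < hi)).sum())
                  for b, (lo, hi) in BANDS.items()}
        recon = sum(bp.band(b).mean() * counts[b] for b in BAND_ORDER)
        total = _cwt_power(rec.data, rec.fs, freqs)[0].mean(axis=1).sum()
        assert recon == pytest.approx(total, rel=0.1)


class TestERSP:
    def test_identical_to_baseline_is_zero_db(self, rng):
        ep = rng.standard_normal((1, 500))
        from sbpsnn.preprocess import _cwt_power
        freqs = np.geomspace(0.5, 48.0, 20)
        hop = 25
        base = _cwt_power(ep, 250.0, freqs)[0]
        nf = base.shape[1] // hop
        base_frames = base[:, :nf * hop].reshape(len(freqs), nf, hop).mean(axis=2)
        out = ersp([ep], 250.0, base_frames.mean(axis=1), freqs=freqs,
                   frame_hop=0.1)
        assert np.abs(out).mean() < 3.0     # near 0 dB on average

    def test_doubled_power_is_3db(self):
        t = np.arange(2000) / 250.0
        ep = np.sin(2 * np.pi * 20 * t)[None, :]
        from sbpsnn.preprocess import _cwt_power
        freqs = np.array([20.0])
        base = _cwt_power(ep, 250.0, freqs)[0].mean()
        out = ersp([np.sqrt(2.0) * ep], 250.0, np.array([base]), freqs=freqs,
                   frame_hop=2.0)
        assert out.mean() == pytest.approx(3.0, abs=0.5)

    def test_zero_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline power"):
            ersp([np.zeros((1, 100))], 250.0, np.zeros(5))

    def test_no_epochs_rejected(self):
        with pytest.raises(ValueError, match="at least one epoch"):
            ersp([], 250.0, np.ones(5))
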