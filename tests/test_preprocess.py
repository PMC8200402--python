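"""Preprocessing chain: artifact scan, filter, resample, epoching, rejection."""

import numpy as np
import pytest
from scipy import signal as sps

from neobg.core import EPOCH_SAMPLES, Recording
from neobg.preprocess import (bandpass_filter, derive_bipolar,
                              detect_artifact_samples, preprocess_recording,
                              reject_channels_and_epochs, resample_to_64,
                              segment_epochs)


class TestArtifactScan:
    def test_amplitude_threshold_strict(self):
        x = np.array([0.0, 501.0, -600.0, 499.0])
        mask = detect_artifact_samples(x, fs=4)
        assert list(mask) == [False, True, True, False]

    def test_all_zero_signal_fully_masked_as_flat(self):
        mask = detect_artifact_samples(np.zeros(640), fs=64)
        assert mask.all()

    def test_clean_sine_unmasked(self):
        t = np.arange(640) / 64
        mask = detect_artifact_samples(100 * np.sin(2 * np.pi * 5 * t), fs=64)
        assert not mask.any()

    def test_flat_run_shorter_than_1s_not_masked(self):
        x = np.sin(np.arange(256) / 3.0) * 50
        x[10:40] = 7.0  # 30 samples at 64 Hz < 1 s
        mask = detect_artifact_samples(x, fs=64)
        assert not mask[10:40].any()

    def test_nan_masked_with_warning(self):
        x = np.zeros(10) + np.sin(np.arange(10))
        x[3] = np.nan
        with pytest.warns(UserWarning):
            mask = detect_artifact_samples(x, fs=4)
        assert mask[3]


class TestBandpass:
    def test_passband_sine_rms_preserved(self):
        fs = 256.0
        t = np.arange(int(30 * fs)) / fs
        x = np.sin(2 * np.pi * 10 * t)
        y = bandpass_filter(x, fs)
        mid = slice(int(5 * fs), int(25 * fs))  # avoid edge transients
        rms_in = np.sqrt(np.mean(x[mid] ** 2))
        rms_out = np.sqrt(np.mean(y[mid] ** 2))
        assert abs(rms_out - rms_in) / rms_in < 0.05

    def test_stopband_attenuation_matches_realized_response(self):
        fs = 256.0
        sos = sps.cheby2(5, 40, (0.25, 40.0), btype="bandpass", fs=fs,
                         output="sos")
        w, h = sps.sosfreqz(sos, worN=[50.0], fs=fs)
        design_att = np.abs(h[0]) ** 2  # forward-backward doubles attenuation
        t = np.arange(int(120 * fs)) / fs
        x = np.sin(2 * np.pi * 50 * t)
        y = bandpass_filter(x, fs)
        mid = slice(int(40 * fs), int(80 * fs))  # past the band-edge transients
        gain = np.sqrt(np.mean(y[mid] ** 2)) / np.sqrt(np.mean(x[mid] ** 2))
        assert gain <= design_att * 1.05
        assert gain < 10 ** (-40 / 20)  # at least the design stopband floor

    def test_zero_in_zero_out_and_length(self):
        y = bandpass_filter(np.zeros(1000), 200.0)
        assert y.shape == (1000,)
        assert np.allclose(y, 0)

    def test_low_fs_rejected(self):
        with pytest.raises(ValueError):
            bandpass_filter(np.zeros(100), fs=60.0)


class TestResample:
    @pytest.mark.parametrize("fs", [200.0, 250.0, 256.0])
    def test_300s_gives_19200_samples(self, fs):
        n_in = int(300 * fs)
        out = resample_to_64(np.zeros(n_in), fs)
        assert out.shape[-1] == EPOCH_SAMPLES

    @pytest.mark.parametrize("fs", [200.0, 250.0, 256.0])
    def test_5hz_sine_amplitude_within_2pct(self, fs):
        t = np.arange(int(60 * fs)) / fs
        x = np.sin(2 * np.pi * 5 * t)
        y = resample_to_64(x, fs)
        t64 = np.arange(len(y)) / 64.0
        ref = np.sin(2 * np.pi * 5 * t64)
        mid = slice(320, len(y) - 320)
        amp = np.sqrt(2 * np.mean(y[mid] ** 2))
        assert abs(amp - 1.0) < 0.02
        # cross-correlate against the analytic reference: same phase & shape
        c = np.corrcoef(y[mid], ref[mid])[0, 1]
        assert c > 0.999

    def test_unusual_rate_warns(self):
        with pytest.warns(UserWarning):
            resample_to_64(np.zeros(1000), 123.0)


class TestSegmentation:
    def _recording64(self, seconds):
        n = int(seconds * 64)
        data = np.random.default_rng(0).normal(size=(2, n))
        return data, np.zeros_like(data, dtype=bool)

    def test_1100s_gives_3_epochs(self):
        data, mask = self._recording64(1100)
        es = segment_epochs(data, mask, ["a", "b"])
        assert es.n_epochs == 3

    def test_exactly_300s_gives_one_epoch(self):
        data, mask = self._recording64(300)
        es = segment_epochs(data, mask, ["a", "b"])
        assert es.n_epochs == 1
        assert es.epochs.shape[-1] == EPOCH_SAMPLES

    def test_299s_gives_zero_epochs_with_warning(self):
        data, mask = self._recording64(299)
        with pytest.warns(UserWarning):
            es = segment_epochs(data, mask, ["a", "b"])
        assert es.n_epochs == 0


class TestRejection:
    def _epochset(self, n_ch=8, masked_fraction=None):
        from conftest import make_epochset

        epochs = np.zeros((1, n_ch, EPOCH_SAMPLES)) + 1.0
        mask = np.zeros_like(epochs, dtype=bool)
        if masked_fraction is not None:
            for c, frac in enumerate(masked_fraction):
                mask[0, c, : int(frac * EPOCH_SAMPLES)] = True
        return make_epochset(epochs, mask)

    def test_half_of_channels_rejected_rejects_epoch(self):
        es = self._epochset(8, [0.3, 0.3, 0.3, 0.3, 0.0, 0.0, 0.0, 0.0])
        reject_channels_and_epochs(es)
        assert es.channel_rejected[0].sum() == 4
        assert es.epoch_rejected[0]  # 4/8 = 50%, "at least"

    def test_exactly_25pct_masked_rejects_channel(self):
        es = self._epochset(2, [0.25, 0.0])
        reject_channels_and_epochs(es)
        assert es.channel_rejected[0, 0]
        assert not es.channel_rejected[0, 1]

    def test_clean_epoch_no_rejection(self):
        es = self._epochset(4)
        reject_channels_and_epochs(es)
        assert not es.channel_rejected.any()
        assert not es.epoch_rejected.any()

    def test_rejection_monotone_over_thresholds(self):
        rng = np.random.default_rng(3)
        es = self._epochset(8, rng.uniform(0, 0.6, size=8))
        counts = []
        for thr in (0.0, 0.10, 0.25, 0.50):
            reject_channels_and_epochs(es, channel_fraction=thr)
            counts.append(int(es.channel_rejected.sum()))
        assert counts == sorted(counts, reverse=True)


class TestBipolar:
    def _recording(self):
        rng = np.random.default_rng(0)
        data = rng.normal(size=(4, 1000))
        return Recording(data=data, fs=200.0,
                         channel_labels=["F3", "F4", "P3", "P4"])

    def test_bipolar_is_elementwise_difference(self):
        rec = self._recording()
        bp = derive_bipolar(rec)
        assert bp.channel_labels == ["F3-P3", "F4-P4", "P3-P4"]
        assert np.array_equal(bp.data[0], rec.data[0] - rec.data[2])
        assert np.array_equal(bp.data[2], rec.data[2] - rec.data[3])

    def test_identical_channels_cancel(self):
        rec = self._recording()
        rec.data[2] = rec.data[0]
        bp = derive_bipolar(rec, pairs=(("F3", "P3"),))
        assert np.all(bp.data[0] == 0)

    def test_missing_electrode_named_in_error(self):
        rec = self._recording()
        with pytest.raises(KeyError, match="O1"):
            derive_bipolar(rec, pairs=(("F3", "O1"),))

    def test_masks_or_combined(self):
        rec = self._recording()
        mask = np.zeros(rec.data.shape, dtype=bool)
        mask[0, :10] = True
        mask[2, 5:15] = True
        rec.artifact_mask = mask
        bp = derive_bipolar(rec, pairs=(("F3", "P3"),))
        assert bp.artifact_mask[0, :15].all()
        assert not bp.artifact_mask[0, 15:].any()


class TestFullChain:
    def test_pipeline_linearity_of_filter_and_resample(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=int(310 * 250))
        y1 = resample_to_64(bandpass_filter(3.0 * x, 250.0), 250.0)
        y2 = 3.0 * resample_to_64(bandpass_filter(x, 250.0), 250.0)
        assert np.allclose(y1, y2, atol=1e-9)

    def test_epoch_count_conserved_regardless_of_rejection(self):
        rng = np.random.default_rng(2)
        data = rng.normal(scale=30, size=(2, int(620 * 200)))
        data[0, : 200 * 400] = 700.0  # heavy artifact -> flat + amplitude
        rec = Recording(data=data, fs=200.0, channel_labels=["F3", "P3"])
        es = preprocess_recording(rec)
        assert es.n_epochs == 2  # floor(620/300), rejection notwithstanding
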