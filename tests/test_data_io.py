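"""Data preparation: window extraction arithmetic, the 'C'-channel rule,
anti-aliased downsampling, train-statistics standardization, and the HDF5
trial container round trip."""

import numpy as np
import pytest

from mbeeg import (
    ChannelStandardizer,
    ContinuousRecording,
    TrialDataset,
    downsample_half,
    extract_trial_window,
    load_trials,
    save_trials,
    select_motor_channels,
    standardize_per_channel,
)
from mbeeg.data_io import TrialFormatError


def _recording(n_ch=3, n_samp=4000, rate=250.0, onsets=(500, 1500, 2500),
               labels=None, names=None, rng=None):
    rng = rng or np.random.default_rng(0)
    labels = labels if labels is not None else [1, 2, 1][:len(onsets)]
    return ContinuousRecording(
        samples=rng.normal(size=(n_ch, n_samp)),
        channel_names=names or [f"C{i}" for i in range(n_ch)],
        sampling_rate=rate,
        event_onsets=np.array(onsets),
        event_labels=np.array(labels),
        class_names=["left_hand", "right_hand"],
    )


class TestExtractTrialWindow:
    def test_standard_window_is_1125_samples(self):
        rec = _recording()
        trials = extract_trial_window(rec, pre_cue_s=0.5, total_s=4.5)
        assert trials.n_samples == 1125
        assert trials.sampling_rate == 250.0

    def test_window_offsets_are_exact(self):
        rec = _recording()
        trials = extract_trial_window(rec, pre_cue_s=0.0, total_s=1.0)
        # onset 500, no pre-cue, 1 s at 250 Hz -> samples 500..749
        np.testing.assert_array_equal(trials.signals[0],
                                      rec.samples[:, 500:750])

    def test_shape_for_many_events(self, rng):
        onsets = np.arange(6) * 1500 + 200
        rec = _recording(n_ch=22, n_samp=10000, onsets=onsets,
                         labels=[1, 2, 1, 2, 1, 2], rng=rng)
        trials = extract_trial_window(rec, 0.5, 4.5)
        assert trials.signals.shape == (6, 22, 1125)

    def test_out_of_bounds_window_names_onset(self):
        rec = _recording(onsets=(50, 1500, 2500))
        with pytest.raises(ValueError, match=r"\[50\]"):
            extract_trial_window(rec, pre_cue_s=0.5, total_s=4.5)


class TestSelectMotorChannels:
    def test_substring_rule(self):
        rec = _recording(n_ch=5, names=["C3", "Cz", "FC1", "O1", "P4"])
        out = select_motor_channels(rec)
        assert out.channel_names == ["C3", "Cz", "FC1"]
        np.testing.assert_array_equal(out.samples, rec.samples[:3])

    def test_no_match_is_an_error(self):
        rec = _recording(n_ch=2, names=["O1", "P3"])
        with pytest.raises(ValueError, match="no channel"):
            select_motor_channels(rec)

    def test_high_density_montage_keeps_44(self):
        # synthetic 128-name montage in 10-20 style with exactly 44
        # motor-cortex ('C') sensors, mirroring the high-gamma layout
        c_row = (["C" + s for s in
                  ["z", "1", "2", "3", "4", "5", "6"]]
                 + ["FC" + s for s in ["z", "1", "2", "3", "4", "5", "6"]]
                 + ["CP" + s for s in ["z", "1", "2", "3", "4", "5", "6"]]
                 + ["FCC" + s for s in
                    ["1h", "2h", "3h", "4h", "5h", "6h", "7h", "8h"]]
                 + ["CCP" + s for s in
                    ["1h", "2h", "3h", "4h", "5h", "6h", "7h", "8h"]]
                 + ["CPP" + s for s in
                    ["1h", "2h", "3h", "4h", "5h", "6h", "7h"]])
        assert all("C" in n for n in c_row)
        assert len(c_row) == 44
        others = ([f"F{i}" for i in range(1, 11)]
                  + [f"P{i}" for i in range(1, 11)]
                  + [f"O{i}" for i in range(1, 11)]
                  + [f"AF{i}" for i in range(1, 11)]
                  + [f"PO{i}" for i in range(1, 11)]
                  + [f"T{i}" for i in range(1, 11)]
                  + [f"FT{i}" for i in range(1, 11)]
                  + [f"TP{i}" for i in range(1, 11)]
                  + [f"Fp{i}" for i in range(1, 5)])
        names = c_row + others[:128 - 44]
        assert len(names) == 128
        rec = _recording(n_ch=128, names=names)
        assert len(select_motor_channels(rec).channel_names) == 44


class TestDownsampleHalf:
    def test_length_and_rate(self, rng):
        rec = _recording(n_samp=2250, rate=500.0, onsets=(100, 900, 1800),
                         rng=rng)
        out = downsample_half(rec)
        assert out.samples.shape[1] == 1125
        assert out.sampling_rate == 250.0
        np.testing.assert_array_equal(out.event_onsets, [50, 450, 900])

    def test_dc_preserved(self):
        rec = _recording()
        rec.samples[:] = 3.7
        out = downsample_half(rec)
        np.testing.assert_allclose(out.samples, 3.7, atol=1e-6)

    def test_above_nyquist_tone_attenuated(self):
        # 200 Hz sine at 500 Hz sampling must die (> 20 dB) after decimation
        t = np.arange(5000) / 500.0
        rec = _recording(n_ch=1, n_samp=5000, rate=500.0,
                         onsets=(100,), labels=[1], names=["C3"])
        rec.samples = np.sin(2 * np.pi * 200.0 * t)[None, :]
        out = downsample_half(rec)
        spec = np.abs(np.fft.rfft(out.samples[0]))
        freqs = np.fft.rfftfreq(out.samples.shape[1], 1 / 250.0)
        # independent FFT check: power near the alias frequency (50 Hz)
        in_power = np.sum(np.abs(np.fft.rfft(rec.samples[0])) ** 2)
        out_power = np.sum(spec ** 2)
        assert 10 * np.log10(in_power / max(out_power, 1e-30)) > 20

    def test_naive_mode_drops_samples(self):
        rec = _recording(n_samp=1000, rate=500.0, onsets=(10, 20, 30))
        out = downsample_half(rec, anti_alias=False)
        np.testing.assert_array_equal(out.samples, rec.samples[:, :1000:2])

    def test_odd_rate_rejected(self):
        rec = _recording(rate=255.0)
        with pytest.raises(ValueError, match="not even"):
            downsample_half(rec)


class TestStandardizer:
    def _data(self, rng, shift=0.0, scale=1.0):
        x = scale * rng.normal(size=(10, 4, 100)) + shift
        return TrialDataset(signals=x, labels=np.tile([1, 2], 5),
                            sampling_rate=250.0, class_names=["a", "b"])

    def test_train_channels_become_zero_mean_unit_variance(self, rng):
        z = standardize_per_channel(self._data(rng, shift=5, scale=3))
        np.testing.assert_allclose(z.signals.mean(axis=(0, 2)), 0, atol=1e-10)
        np.testing.assert_allclose(z.signals.var(axis=(0, 2)), 1, atol=1e-6)

    def test_affine_invariance(self, rng):
        base = self._data(rng)
        affine = TrialDataset(signals=3 * base.signals + 5,
                              labels=base.labels, sampling_rate=250.0,
                              class_names=["a", "b"])
        za = standardize_per_channel(base)
        zb = standardize_per_channel(affine)
        np.testing.assert_allclose(za.signals, zb.signals, atol=1e-9)

    def test_test_set_uses_train_statistics(self, rng):
        train = self._data(rng)
        test = self._data(np.random.default_rng(99), shift=2.0)
        _, ztest = standardize_per_channel(train, test)
        # shifted test set must NOT be re-centered to zero
        assert np.all(np.abs(ztest.signals.mean(axis=(0, 2))) > 0.5)

    def test_zero_variance_channel_named(self, rng):
        data = self._data(rng)
        data.signals[:, 2, :] = 1.0
        data.channel_names = ["C1", "C2", "C3", "C4"]
        with pytest.raises(ValueError, match="C3"):
            ChannelStandardizer().fit(data)

    def test_transform_commutes_with_trial_permutation(self, rng):
        data = self._data(rng)
        scaler = ChannelStandardizer().fit(data)
        perm = rng.permutation(data.n_trials)
        a = scaler.transform(data.subset(perm)).signals
        b = scaler.transform(data).signals[perm]
        np.testing.assert_array_equal(a, b)


class TestTrialContainer:
    def test_round_trip_bit_identical(self, tmp_path, rng):
        data = TrialDataset(signals=rng.normal(size=(10, 22, 1125)),
                            labels=rng.integers(1, 5, size=10),
                            sampling_rate=250.0,
                            class_names=["lh", "rh", "f", "t"],
                            channel_names=[f"C{i}" for i in range(22)])
        path = tmp_path / "trials.h5"
        save_trials(data, path)
        back = load_trials(path)
        np.testing.assert_array_equal(back.signals, data.signals)
        np.testing.assert_array_equal(back.labels, data.labels)
        assert back.sampling_rate == 250.0
        assert back.class_names == data.class_names
        assert back.channel_names == data.channel_names

    def test_missing_labels_is_format_error(self, tmp_path, rng):
        import h5py

        path = tmp_path / "bad.h5"
        with h5py.File(path, "w") as fh:
            fh.create_dataset("signals", data=rng.normal(size=(2, 3, 4)))
            fh.attrs["sampling_rate"] = 250.0
        with pytest.raises(TrialFormatError, match="labels"):
            load_trials(path)

    def test_mismatched_label_length_is_format_error(self, tmp_path, rng):
        import h5py

        path = tmp_path / "bad.h5"
        with h5py.File(path, "w") as fh:
            fh.create_dataset("signals", data=rng.normal(size=(2, 3, 4)))
            fh.create_dataset("labels", data=[1, 2, 1])
            fh.attrs["sampling_rate"] = 250.0
        with pytest.raises(TrialFormatError, match="labels length"):
            load_trials(path)
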