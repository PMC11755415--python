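"""Simulator contracts: determinism, label consistency, learnability."""

import numpy as np
import pytest

from pulseguard.errors import ConfigurationError, InsufficientBeatsError
from pulseguard.signal_sim import (SimConfig, extract_sbp_dbp, make_dataset,
                                   read_record_csv, read_record_hdf5,
                                   simulate_record, write_record_csv,
                                   write_record_hdf5)


def fixed_bp_config(**kw):
    kw.setdefault("n_subjects", 1)
    kw.setdefault("duration_s", 10.0)
    kw.setdefault("fs", 125.0)
    kw.setdefault("hr_range", (60.0, 60.0))
    kw.setdefault("sbp_range", (120.0, 120.0))
    kw.setdefault("dbp_range", (80.0, 80.0))
    kw.setdefault("noise_sd", 0.0)
    kw.setdefault("coupling_strength", 0.0)
    kw.setdefault("seed", 5)
    return SimConfig(**kw)


class TestSimConfig:
    def test_systolic_below_diastolic_rejected(self):
        with pytest.raises(ConfigurationError, match="sbp_range"):
            SimConfig(sbp_range=(70.0, 90.0), dbp_range=(60.0, 95.0))

    @pytest.mark.parametrize("kw,name", [
        (dict(fs=0.0), "fs"),
        (dict(duration_s=-1.0), "duration_s"),
        (dict(coupling_strength=1.5), "coupling_strength"),
        (dict(noise_sd=-0.1), "noise_sd"),
    ])
    def test_violations_name_the_field(self, kw, name):
        with pytest.raises(ConfigurationError, match=name):
            SimConfig(**kw)


class TestSimulateRecord:
    def test_noiseless_template_bounds(self):
        rec = simulate_record(fixed_bp_config(), 0)
        assert rec.abp.min() >= 80.0 - 1e-9
        assert rec.abp.max() <= 120.0 + 1e-9
        s, d = extract_sbp_dbp(rec.abp, rec.beat_onsets)
        np.testing.assert_allclose(s, 120.0)
        np.testing.assert_allclose(d, 80.0)

    def test_determinism_bit_identical(self, small_config):
        a = simulate_record(small_config, 1)
        b = simulate_record(small_config, 1)
        np.testing.assert_array_equal(a.ppg, b.ppg)
        np.testing.assert_array_equal(a.ecg, b.ecg)
        np.testing.assert_array_equal(a.abp, b.abp)
        np.testing.assert_array_equal(a.sbp_per_beat, b.sbp_per_beat)

    def test_beat_count_matches_closed_form(self):
        # 60 bpm for 10 s at 125 Hz: exactly 10 beats, 125 samples apart
        rec = simulate_record(fixed_bp_config(), 0)
        assert rec.n_beats == 10
        assert np.all(np.abs(np.diff(rec.beat_onsets) - 125) <= 1)

    def test_label_consistency_on_noiseless_abp(self, small_config):
        from dataclasses import replace
        cfg = replace(small_config, noise_sd=0.0)
        for s in range(cfg.n_subjects):
            rec = simulate_record(cfg, s)
            sbp, dbp = extract_sbp_dbp(rec.abp, rec.beat_onsets)
            np.testing.assert_allclose(sbp, rec.sbp_per_beat[:-1], atol=0.5)
            np.testing.assert_allclose(dbp, rec.dbp_per_beat[:-1], atol=0.5)

    def test_ecg_r_peaks_precede_beats(self, small_config):
        rec = simulate_record(small_config, 0)
        # an R-peak hump should sit within 300 ms before each later onset
        lag = int(0.3 * rec.fs)
        for onset in rec.beat_onsets[1:]:
            assert rec.ecg[onset - lag:onset + 1].max() > 0.5

    def test_subject_index_out_of_range(self, small_config):
        with pytest.raises(ConfigurationError, match="subject_index"):
            simulate_record(small_config, small_config.n_subjects)


class TestExtractSbpDbp:
    def test_constant_waveform(self):
        s, d = extract_sbp_dbp(np.full(100, 100.0), [0, 50])
        assert s[0] == d[0] == 100.0

    def test_sampled_sine_cycle(self):
        t = np.arange(200)
        wave = 100 + 20 * np.sin(2 * np.pi * t / 100)
        s, d = extract_sbp_dbp(wave, [0, 100])
        # numerically evaluated extrema of the sampled sine
        assert s[0] == pytest.approx(wave[:100].max())
        assert d[0] == pytest.approx(wave[:100].min())
        assert s[0] == pytest.approx(120.0, abs=0.1)
        assert d[0] == pytest.approx(80.0, abs=0.1)

    def test_sbp_always_at_least_dbp(self, rng):
        wave = rng.standard_normal(500)
        s, d = extract_sbp_dbp(wave, [0, 100, 200, 300, 400])
        assert np.all(s >= d)

    def test_fewer_than_two_onsets_raises(self):
        with pytest.raises(InsufficientBeatsError):
            extract_sbp_dbp(np.ones(10), [0])


class TestMakeDataset:
    def test_window_counts(self, small_config):
        one = make_dataset(small_config, window_s=12.0, stride_s=12.0)
        assert one.n_windows == small_config.n_subjects
        two = make_dataset(small_config, window_s=6.0, stride_s=6.0)
        assert two.n_windows == 2 * small_config.n_subjects

    def test_window_shapes_uniform(self, small_dataset, small_config):
        expected = int(4.0 * small_config.fs)
        assert small_dataset.ppg.shape[1] == expected
        assert small_dataset.ecg.shape == small_dataset.ppg.shape
        assert small_dataset.abp.shape == small_dataset.ppg.shape

    def test_channel_stacking(self, small_dataset):
        x = small_dataset.inputs("ppg_ecg")
        assert x.shape[1] == 2
        np.testing.assert_array_equal(x[:, 0], small_dataset.ppg)

    def test_labels_bounded_by_config(self, small_dataset, small_config):
        assert np.all(small_dataset.sbp >= small_config.sbp_range[0])
        assert np.all(small_dataset.sbp <= small_config.sbp_range[1])
        assert np.all(small_dataset.sbp > small_dataset.dbp)

    def test_bad_stride_rejected(self, small_config):
        with pytest.raises(ConfigurationError, match="stride"):
            make_dataset(small_config, window_s=4.0, stride_s=0.0)

    def test_window_longer_than_record_rejected(self, small_config):
        with pytest.raises(ConfigurationError, match="window_s"):
            make_dataset(small_config, window_s=60.0, stride_s=5.0)

    def test_dataset_determinism_after_serialization(self, small_config,
                                                     tmp_path):
        rec_a = simulate_record(small_config, 2)
        rec_b = simulate_record(small_config, 2)
        pa, pb = tmp_path / "a.csv", tmp_path / "b.csv"
        write_record_csv(rec_a, pa)
        write_record_csv(rec_b, pb)
        assert pa.read_bytes() == pb.read_bytes()


class TestRecordIO:
    def test_csv_roundtrip(self, small_record, tmp_path):
        path = tmp_path / "rec.csv"
        write_record_csv(small_record, path)
        back = read_record_csv(path)
        assert back.subject_id == small_record.subject_id
        np.testing.assert_allclose(back.ppg, small_record.ppg, atol=1e-9)
        np.testing.assert_array_equal(back.beat_onsets,
                                      small_record.beat_onsets)

    def test_hdf5_roundtrip(self, small_record, tmp_path):
        path = tmp_path / "rec.h5"
        write_record_hdf5(small_record, path)
        back = read_record_hdf5(path, small_record.subject_id)
        np.testing.assert_array_equal(back.abp, small_record.abp)
        np.testing.assert_array_equal(back.sbp_per_beat,
                                      small_record.sbp_per_beat)


class TestLearnability:
    """Information content of the windows tracks the coupling dial."""

    @staticmethod
    def _nn_regress(train_x, train_y, test_x):
        preds = np.empty(len(test_x))
        for i, w in enumerate(test_x):
            d = np.sum((train_x - w) ** 2, axis=1)
            preds[i] = train_y[np.argmin(d)]
        return preds

    def _windows(self, coupling, noise, stride=2.5):
        cfg = SimConfig(n_subjects=30, duration_s=20.0, fs=50.0,
                        noise_sd=noise, coupling_strength=coupling, seed=11)
        ds = make_dataset(cfg, window_s=2.5, stride_s=stride)
        return ds

    def test_full_coupling_nearest_neighbour_beats_5mmhg(self):
        # held-out windows of seen subjects: morphology pins the BP level
        # (a dense stride supplies phase-matched neighbours)
        ds = self._windows(coupling=1.0, noise=0.0, stride=0.625)
        assert ds.n_windows >= 200
        test = np.arange(ds.n_windows) % 8 == 0
        preds = self._nn_regress(ds.ppg[~test], ds.sbp[~test], ds.ppg[test])
        err = np.mean(np.abs(preds - ds.sbp[test]))
        assert err < 5.0

    def test_zero_coupling_carries_no_bp_information(self):
        # across subjects: windows are uninformative, so a nearest
        # neighbour cannot beat predicting the training mean
        ds = self._windows(coupling=0.0, noise=0.02)
        assert ds.n_windows >= 200
        subjects = ds.subjects()
        test_mask = np.isin(ds.subject_ids, subjects[:10])
        preds = self._nn_regress(ds.ppg[~test_mask], ds.sbp[~test_mask],
                                 ds.ppg[test_mask])
        nn_err = np.mean(np.abs(preds - ds.sbp[test_mask]))
        mean_err = np.mean(np.abs(ds.sbp[~test_mask].mean()
                                  - ds.sbp[test_mask]))
        assert nn_err >= 0.9 * mean_err
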