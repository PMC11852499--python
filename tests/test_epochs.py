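"""Synthetic generator, preprocessing chain and container I/O."""

import numpy as np
import pytest
from scipy.signal import periodogram

from gdtil import (EEGEpochs, SyntheticConfig, average_reference,
                   butterworth_bandpass, downsample, generate_mi_epochs,
                   load_epochs, save_epochs, split_sessions)


def _sine_epochs(freq, fs=1000.0, n_samples=4000, n_channels=2, n_trials=3):
    t = np.arange(n_samples) / fs
    x = np.sin(2 * np.pi * freq * t)
    data = np.tile(x, (n_trials, n_channels, 1))
    return EEGEpochs(data, np.zeros(n_trials, dtype=int), fs)


class TestGenerator:
    def test_deterministic_under_seed(self):
        cfg = SyntheticConfig(seed=11)
        a = generate_mi_epochs(cfg)
        b = generate_mi_epochs(SyntheticConfig(seed=11))
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(a.labels, b.labels)

    def test_zero_trials_keeps_metadata(self):
        ep = generate_mi_epochs(SyntheticConfig(trials_per_class=0, n_channels=6, fs=200.0))
        assert ep.n_trials == 0
        assert ep.n_channels == 6
        assert ep.fs == 200.0

    def test_noise_free_power_concentrates_in_class_band(self):
        cfg = SyntheticConfig(n_classes=2, trials_per_class=4, snr=np.inf, seed=0,
                              class_band_hz=[(10.0, 12.0), (20.0, 24.0)])
        ep = generate_mi_epochs(cfg)
        gains = cfg.class_channel_pattern[0]
        ch = int(np.argmax(gains))
        for i in np.flatnonzero(ep.labels == 0):
            f, p = periodogram(ep.data[i, ch], fs=ep.fs)
            inband = p[(f >= 9) & (f <= 13)].sum()
            offband = p[(f < 9) | (f > 13)].sum()
            assert inband / (offband + 1e-30) > 10

    def test_variance_classifier_separates_default_classes(self):
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import train_test_split

        ep = generate_mi_epochs(SyntheticConfig(n_classes=2, trials_per_class=60,
                                                snr=1.0, seed=5))
        X = np.log(ep.data.var(axis=2) + 1e-12)
        xtr, xte, ytr, yte = train_test_split(X, ep.labels, test_size=0.25,
                                              random_state=0, stratify=ep.labels)
        acc = LogisticRegression(max_iter=2000).fit(xtr, ytr).score(xte, yte)
        assert acc >= 0.90

    def test_separability_monotone_in_snr(self):
        """Holdout accuracy of the variance baseline is non-decreasing in
        snr over {0, 0.5, 1, 2} (mean over 5 seeds, small slack)."""
        from sklearn.linear_model import LogisticRegression
        from sklearn.model_selection import train_test_split

        means = []
        for snr in (0.0, 0.5, 1.0, 2.0):
            accs = []
            for seed in range(5):
                ep = generate_mi_epochs(SyntheticConfig(n_classes=2, trials_per_class=40,
                                                        snr=snr, seed=seed))
                X = np.log(ep.data.var(axis=2) + 1e-12)
                xtr, xte, ytr, yte = train_test_split(X, ep.labels, test_size=0.25,
                                                      random_state=seed, stratify=ep.labels)
                accs.append(LogisticRegression(max_iter=2000).fit(xtr, ytr).score(xte, yte))
            means.append(np.mean(accs))
        for lo, hi in zip(means, means[1:]):
            assert hi >= lo - 0.05

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            SyntheticConfig(class_band_hz=[(4.0, 12.0), (20.0, 24.0)])
        with pytest.raises(ValueError):
            SyntheticConfig(class_channel_pattern=np.ones((3, 8)))


class TestBandpass:
    def test_in_band_sine_passes_through(self):
        ep = _sine_epochs(20.0)
        out = butterworth_bandpass(ep, 8.0, 32.0, order=8)
        core = slice(500, -500)  # trim filter transients
        rms_in = np.sqrt(np.mean(ep.data[0, 0, core] ** 2))
        rms_out = np.sqrt(np.mean(out.data[0, 0, core] ** 2))
        assert abs(rms_out - rms_in) / rms_in < 0.05

    def test_out_of_band_sine_attenuated_40db(self):
        ep = _sine_epochs(2.0, n_samples=8000)
        out = butterworth_bandpass(ep, 8.0, 32.0, order=8)
        core = slice(1000, -1000)
        rms_in = np.sqrt(np.mean(ep.data[0, 0, core] ** 2))
        rms_out = np.sqrt(np.mean(out.data[0, 0, core] ** 2))
        assert 20 * np.log10(rms_in / rms_out) >= 40

    def test_double_filtering_attenuates_band_edges(self):
        ep = _sine_epochs(8.0, n_samples=8000)
        once = butterworth_bandpass(ep, 8.0, 32.0, order=4)
        twice = butterworth_bandpass(once, 8.0, 32.0, order=4)
        core = slice(1000, -1000)
        p1 = np.mean(once.data[0, 0, core] ** 2)
        p2 = np.mean(twice.data[0, 0, core] ** 2)
        assert p2 <= p1 * (1 + 1e-9)

    def test_band_outside_nyquist_rejected(self):
        ep = _sine_epochs(20.0, fs=100.0, n_samples=500)
        with pytest.raises(ValueError):
            butterworth_bandpass(ep, 8.0, 60.0)


class TestDownsample:
    def test_factor_four_divides_sample_count(self):
        ep = _sine_epochs(20.0, fs=1000.0, n_samples=4000)
        out = downsample(ep, 250.0)
        assert out.n_samples == 1000
        assert out.fs == 250.0
        assert out.n_trials == ep.n_trials and out.n_channels == ep.n_channels

    def test_identity_when_rates_match(self):
        ep = _sine_epochs(20.0, fs=250.0, n_samples=1000)
        out = downsample(ep, 250.0)
        assert np.array_equal(out.data, ep.data)

    def test_tone_survives_decimation(self):
        ep = _sine_epochs(20.0, fs=1000.0, n_samples=4000)
        out = downsample(ep, 250.0)
        spec = np.abs(np.fft.rfft(out.data[0, 0]))
        freqs = np.fft.rfftfreq(out.n_samples, 1 / out.fs)
        assert abs(freqs[np.argmax(spec)] - 20.0) < 0.5

    def test_non_integer_factor_rejected(self):
        ep = _sine_epochs(20.0, fs=1000.0, n_samples=1000)
        with pytest.raises(ValueError):
            downsample(ep, 300.0)


class TestAverageReference:
    def test_channel_mean_is_zero(self, small_epochs):
        out = average_reference(small_epochs)
        assert np.allclose(out.data.mean(axis=1), 0.0, atol=1e-12)

    def test_idempotent(self, small_epochs):
        once = average_reference(small_epochs)
        twice = average_reference(once)
        assert np.allclose(once.data, twice.data)

    def test_hand_example(self):
        ep = EEGEpochs(np.array([[[1.0, 3.0], [3.0, 5.0]]]), [0], 100.0)
        out = average_reference(ep)
        assert np.allclose(out.data[0], [[-1.0, -1.0], [1.0, 1.0]])

    def test_single_channel_rejected(self):
        ep = EEGEpochs(np.ones((2, 1, 10)), [0, 1], 100.0)
        with pytest.raises(ValueError):
            average_reference(ep)


class TestSplit:
    def test_first_four_of_six_sessions_gives_two_to_one(self):
        n = 60
        sid = np.repeat(np.arange(6), 10)
        ep = EEGEpochs(np.zeros((n, 2, 8)), np.tile([0, 1], 30), 100.0, session_id=sid)
        tr, te = split_sessions(ep, train_sessions=4)
        assert tr.n_trials == 40 and te.n_trials == 20
        assert set(np.unique(tr.session_id)) == {0, 1, 2, 3}

    def test_one_to_one_by_session(self):
        sid = np.repeat([0, 1], 10)
        ep = EEGEpochs(np.zeros((20, 2, 8)), np.tile([0, 1], 10), 100.0, session_id=sid)
        tr, te = split_sessions(ep, train_sessions=1)
        assert tr.n_trials == te.n_trials == 10

    def test_fraction_split_is_disjoint_and_stratified(self, small_epochs):
        tr, te = split_sessions(small_epochs, train_fraction=0.75)
        assert tr.n_trials + te.n_trials == small_epochs.n_trials
        assert set(np.unique(tr.labels)) == set(np.unique(te.labels))

    def test_missing_spec_rejected(self, small_epochs):
        with pytest.raises(ValueError):
            split_sessions(small_epochs)
        ep = EEGEpochs(np.zeros((4, 2, 8)), [0, 1, 0, 1], 100.0)
        with pytest.raises(ValueError):
            split_sessions(ep, train_sessions=1)


@pytest.mark.parametrize("ext", ["npz", "h5"])
def test_container_roundtrip_bit_exact(tmp_path, small_epochs, ext):
    path = tmp_path / f"epochs.{ext}"
    save_epochs(small_epochs, str(path))
    back = load_epochs(str(path))
    assert np.array_equal(back.data, small_epochs.data)
    assert np.array_equal(back.labels, small_epochs.labels)
    assert back.fs == small_epochs.fs


def test_container_rejects_nonfinite():
    data = np.zeros((2, 2, 4))
    data[0, 0, 0] = np.nan
    with pytest.raises(ValueError):
        EEGEpochs(data, [0, 1], 100.0)
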