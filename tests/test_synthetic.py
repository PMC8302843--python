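"""Statistical structure of the synthetic sEMG generator."""

import numpy as np
import pytest

import emgface as ef
from emgface.signal_io import EXPRESSIONS, MOUTH_CORNER_CHANNELS


def channel_rms(rec):
    return np.sqrt(np.mean(rec.signals**2, axis=1))


class TestActivationProfile:
    def test_default_matrix_satisfies_invariants(self, profile):
        m = profile.matrix
        assert m.shape == (7, 10)
        assert ((m >= 0) & (m <= 1)).all()
        assert (m.max(axis=1) > 0.5).all()
        for i in range(7):
            for j in range(i + 1, 7):
                assert not np.array_equal(m[i], m[j])

    def test_happiness_peaks_on_mouth_corners(self, profile):
        happy = profile.row("happiness")
        corner = [c - 1 for c in MOUTH_CORNER_CHANNELS]
        assert int(np.argmax(happy)) in corner
        assert happy[corner].min() > np.delete(happy, corner).max()

    def test_invalid_profiles_rejected(self, profile):
        flat = np.full((7, 10), 0.6)
        with pytest.raises(ValueError):
            ef.ActivationProfile(flat)  # identical rows
        weak = profile.matrix * 0.4
        with pytest.raises(ValueError):
            ef.ActivationProfile(weak)  # no weight above 0.5


class TestEmgChannel:
    def test_rms_matches_requested_amplitude(self):
        x = ef.simulate_emg_channel(2.0, amplitude=10.0, seed=7)
        rms = np.sqrt(np.mean(x**2))
        assert 9.5 <= rms <= 10.5
        assert abs(np.mean(x)) < 0.5  # zero-mean

    def test_zero_amplitude_is_silent(self):
        x = ef.simulate_emg_channel(1.0, amplitude=0.0, seed=7)
        assert np.sqrt(np.mean(x**2)) < 1e-12

    def test_same_seed_identical(self):
        a = ef.simulate_emg_channel(1.0, amplitude=5.0, seed=42)
        b = ef.simulate_emg_channel(1.0, amplitude=5.0, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            ef.simulate_emg_channel(1.0, fs=1000, band=(20.0, 600.0), seed=0)

    def test_spectrum_confined_to_band(self):
        from scipy import signal as sp

        x = ef.simulate_emg_channel(4.0, amplitude=1.0, band=(20.0, 450.0), seed=3)
        f, p = sp.welch(x, fs=1000, nperseg=1024)
        in_band = p[(f > 30) & (f < 400)].mean()
        below = p[f < 10].mean()
        assert below < in_band / 100


class TestGenerateRecording:
    def test_happiness_rms_maximal_on_mouth_corner(self, profile):
        for intensity in (1, 3, 5):
            rec = ef.generate_recording("happiness", intensity, "B1", profile, seed=5)
            assert int(np.argmax(channel_rms(rec))) + 1 in MOUTH_CORNER_CHANNELS

    def test_intensity_monotone_on_activated_channels(self, profile):
        low = ef.generate_recording("anger", 1, "B1", profile, seed=9)
        high = ef.generate_recording("anger", 5, "B1", profile, seed=9)
        active = profile.row("anger") > 0.3
        assert (channel_rms(high)[active] > channel_rms(low)[active]).all()

    def test_batch_gain_is_exact_multiplicative_factor(self, profile):
        cfg = ef.GeneratorConfig(batch_gains={"B1": 1.0, "B2": 2.0})
        a = ef.generate_recording("fear", 4, "B1", profile, cfg, seed=2)
        b = ef.generate_recording("fear", 4, "B2", profile, cfg, seed=2)
        np.testing.assert_allclose(b.signals, 2.0 * a.signals, rtol=0, atol=0)

    def test_unknown_batch_rejected(self, profile):
        with pytest.raises(KeyError):
            ef.generate_recording("fear", 4, "B9", profile, seed=2)


class TestGenerateDataset:
    def test_balanced_and_sized(self, small_dataset):
        cfg, recs = small_dataset
        assert len(recs) == 7 * 5 * 2 * cfg.recordings_per_class
        from collections import Counter

        cells = Counter((r.label.expression, r.label.intensity, r.batch_id) for r in recs)
        assert set(cells.values()) == {cfg.recordings_per_class}

    def test_deterministic_given_seed(self, profile):
        cfg = ef.GeneratorConfig(recordings_per_class=1, duration_s=0.3, seed=77)
        a = ef.generate_dataset(cfg, profile)
        b = ef.generate_dataset(cfg, profile)
        assert len(a) == len(b) == 70
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.signals, rb.signals)
            assert ra.label == rb.label and ra.batch_id == rb.batch_id

    def test_separability_grows_as_noise_shrinks(self, profile):
        """Between/within expression-class distance ratio rises as baseline
        noise falls and activation rows separate (three settings, fixed
        seed, fixed intensity so noise drives the within-class spread)."""
        ratios = []
        base = profile.matrix
        for noise, row_sep in ((8.0, 0.7), (2.0, 0.85), (0.25, 1.0)):
            # Shrink rows toward their common mean to reduce separation.
            mixed = row_sep * base + (1 - row_sep) * base.mean(axis=0)
            cfg = ef.GeneratorConfig(
                recordings_per_class=3, duration_s=0.4, baseline_noise_sd=noise,
                batch_gains={"B1": 1.0}, seed=13,
            )
            recs = [r for r in ef.generate_dataset(cfg, ef.ActivationProfile(mixed))
                    if r.label.intensity == 3]
            fm = ef.extract_features_from_recordings(recs, window=200, hop=100)
            X = fm.values
            y = fm.expressions()
            centroids = {e: X[y == e].mean(axis=0) for e in EXPRESSIONS}
            within = np.mean(
                [np.linalg.norm(x - centroids[e]) for x, e in zip(X, y)]
            )
            cents = np.array(list(centroids.values()))
            between = np.mean(
                [np.linalg.norm(a - b) for i, a in enumerate(cents) for b in cents[i + 1:]]
            )
            ratios.append(between / within)
        assert ratios[0] < ratios[1] < ratios[2]
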