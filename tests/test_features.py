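"""RMS/IEMG features and the robust scaler."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import emgface as ef
from emgface.features import FEATURE_COLUMNS, ScalerParams
from emgface.signal_io import EmptyInputError, Frame


class TestScalarFeatures:
    @pytest.mark.parametrize(
        "window,expected",
        [
            (np.full(200, 3.0), 3.0),
            (np.tile([1.0, -1.0], 100), 1.0),
            (np.array([0.0, 3.0, 4.0]), np.sqrt(25 / 3)),
        ],
    )
    def test_rms_hand_values(self, window, expected):
        assert ef.rms(window) == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize(
        "window,expected",
        [(np.zeros(50), 0.0), (np.array([1.0, -2.0, 3.0]), 6.0)],
    )
    def test_iemg_hand_values(self, window, expected):
        assert ef.iemg(window) == pytest.approx(expected, abs=1e-12)

    def test_empty_window_rejected(self):
        with pytest.raises(EmptyInputError):
            ef.rms(np.array([]))
        with pytest.raises(EmptyInputError):
            ef.iemg(np.array([]))

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        scale=st.floats(-100, 100, allow_nan=False),
        seed=st.integers(0, 2**16),
    )
    def test_homogeneity_of_degree_one(self, scale, seed):
        x = np.random.default_rng(seed).standard_normal(64)
        assert ef.rms(scale * x) == pytest.approx(abs(scale) * ef.rms(x), abs=1e-9)
        assert ef.iemg(scale * x) == pytest.approx(abs(scale) * ef.iemg(x), rel=1e-12, abs=1e-9)


class TestExtractFeatures:
    def test_all_zero_frame_gives_zero_vector(self):
        fm = ef.extract_features([Frame(np.zeros((10, 200)), 0)])
        np.testing.assert_array_equal(fm.values, np.zeros((1, 20)))

    def test_single_channel_locality(self, rng):
        w = np.zeros((10, 200))
        w[5] = rng.standard_normal(200)  # CH6
        fm = ef.extract_features([Frame(w, 0)])
        nonzero = np.flatnonzero(fm.values[0])
        assert nonzero.tolist() == [5, 15]  # RMS_CH6 and IEMG_CH6

    def test_matches_naive_per_entry_oracle(self, rng):
        frames = [Frame(rng.standard_normal((10, 200)) * 30, i * 50) for i in range(8)]
        fm = ef.extract_features(frames)
        for r, frame in enumerate(frames):
            for c in range(10):
                assert fm.values[r, c] == ef.rms(frame.window[c])
                assert fm.values[r, 10 + c] == ef.iemg(frame.window[c])

    def test_column_order_rms_block_then_iemg_block(self):
        assert FEATURE_COLUMNS[0] == "RMS_CH1"
        assert FEATURE_COLUMNS[10] == "IEMG_CH1"
        assert len(FEATURE_COLUMNS) == 20


def _fm_from_array(values, batch_ids=None):
    df = pd.DataFrame(values, columns=list(FEATURE_COLUMNS))
    df["frame_index"] = range(len(df))
    df["expression"] = "happiness"
    df["intensity"] = 3
    df["subject_id"] = "S1"
    df["batch_id"] = batch_ids if batch_ids is not None else "B1"
    return ef.FeatureMatrix(df)


class TestRobustScaler:
    def test_fit_linear_interpolation_quantiles(self):
        col = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        values = np.tile(col[:, None], (1, 20))
        params = ef.fit_robust_scaler(_fm_from_array(values), scope="global")["global"]
        np.testing.assert_allclose(params.medians, 3.0)
        np.testing.assert_allclose(params.iqrs, 2.0)  # Q1=2, Q3=4

    def test_apply_centres_and_scales(self):
        col = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        fm = _fm_from_array(np.tile(col[:, None], (1, 20)))
        scaled = ef.apply_robust_scaler(fm, ef.fit_robust_scaler(fm, "global"))
        np.testing.assert_allclose(scaled.values[:, 0], [-1, -0.5, 0, 0.5, 1])
        # post-condition: median 0, IQR 1 per column
        np.testing.assert_allclose(np.median(scaled.values, axis=0), 0.0, atol=1e-12)
        q1, q3 = np.percentile(scaled.values, [25, 75], axis=0)
        np.testing.assert_allclose(q3 - q1, 1.0, atol=1e-12)

    def test_constant_column_is_centred_only(self):
        values = np.full((6, 20), 7.5)
        fm = _fm_from_array(values)
        scaled = ef.apply_robust_scaler(fm, ef.fit_robust_scaler(fm, "global"))
        np.testing.assert_allclose(scaled.values, 0.0)

    def test_group_smaller_than_four_rejected(self):
        with pytest.raises(ValueError):
            ef.fit_robust_scaler(_fm_from_array(np.zeros((3, 20))), "global")

    def test_fit_is_deterministic(self, small_features):
        a = ef.fit_robust_scaler(small_features, "per_batch")
        b = ef.fit_robust_scaler(small_features, "per_batch")
        for key in a:
            np.testing.assert_array_equal(a[key].medians, b[key].medians)
            np.testing.assert_array_equal(a[key].iqrs, b[key].iqrs)

    def test_matches_sklearn_robust_scaler(self, rng):
        """Independent cross-check against the reference implementation."""
        from sklearn.preprocessing import RobustScaler

        values = rng.standard_normal((40, 20)) * 12 + 3
        fm = _fm_from_array(values)
        ours = ef.apply_robust_scaler(fm, ef.fit_robust_scaler(fm, "global"))
        theirs = RobustScaler().fit_transform(values)
        np.testing.assert_allclose(ours.values, theirs, rtol=1e-12, atol=1e-12)

    def test_batch_gain_invariance_end_to_end(self, profile):
        """Scaling one batch's raw signal by any gain leaves the per-batch
        scaled features numerically identical."""
        cfg1 = ef.GeneratorConfig(
            recordings_per_class=1, duration_s=0.4, batch_gains={"B1": 1.0}, seed=3
        )
        cfg2 = ef.GeneratorConfig(
            recordings_per_class=1, duration_s=0.4, batch_gains={"B1": 3.7}, seed=3
        )
        fm1 = ef.extract_features_from_recordings(ef.generate_dataset(cfg1, profile))
        fm2 = ef.extract_features_from_recordings(ef.generate_dataset(cfg2, profile))
        s1 = ef.apply_robust_scaler(fm1, ef.fit_robust_scaler(fm1, "per_batch"))
        s2 = ef.apply_robust_scaler(fm2, ef.fit_robust_scaler(fm2, "per_batch"))
        np.testing.assert_allclose(s1.values, s2.values, rtol=1e-9, atol=1e-9)

    def test_outlier_breakdown_bounded(self, rng):
        """10% arbitrarily large corruption moves median/IQR only within the
        range of the clean data (robustness below the 25% breakdown point)."""
        clean = rng.standard_normal(100)
        corrupted = clean.copy()
        corrupted[:10] = 1e9
        med_shift = abs(np.median(corrupted) - np.median(clean))
        q1c, q3c = np.percentile(corrupted, [25, 75])
        q1, q3 = np.percentile(clean, [25, 75])
        iqr_shift = abs((q3c - q1c) - (q3 - q1))
        spread = clean.max() - clean.min()
        assert med_shift <= spread
        assert iqr_shift <= spread

    def test_dimension_mismatch_rejected(self):
        params = ScalerParams(np.zeros(10), np.ones(10))
        with pytest.raises(ValueError):
            ef.apply_robust_scaler(np.zeros((5, 20)), params)

    def test_scaler_params_json_round_trip(self, tmp_path):
        params = ScalerParams(np.arange(20.0), np.ones(20) * 2, "B1")
        back = ScalerParams.from_json(params.to_json(tmp_path / "scaler.json"))
        np.testing.assert_array_equal(back.medians, params.medians)
        np.testing.assert_array_equal(back.iqrs, params.iqrs)
        assert back.fitted_on == "B1"
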