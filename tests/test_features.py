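import numpy as np
import pandas as pd
import pytest

from helpers import make_annotations
from pacdetect import synth
from pacdetect.features import (
    DRR_CLIP_FEATURES,
    META_COLUMNS,
    RR_CLIP_FEATURES,
    RR_MAX_MS,
    RR_MIN_MS,
    ClipBounds,
    FeatureTransform,
    assemble_matrix,
    clip_features,
    feature_names,
    load_features,
    prune_features,
    save_features,
    zscore_apply,
    zscore_fit,
)


def test_feature_count_186():
    names = feature_names()
    assert len(names) == 42 + 72 + 72 == 186
    assert len(set(names)) == 186


class TestClipBounds:
    def test_rr_max_value(self):
        # twice the 35 bpm interval: 2 * (60/35) * 1000 ms
        assert RR_MAX_MS == pytest.approx(3428.6)
        assert ClipBounds().rr_max == RR_MAX_MS

    def test_rr_min(self):
        assert RR_MIN_MS == 250.0

    def test_drr_symmetric(self):
        b = ClipBounds()
        assert b.drr_max == -(b.drr_min) == b.rr_max - b.rr_min

    def test_invalid(self):
        with pytest.raises(ValueError):
            ClipBounds(rr_min=500, rr_max=400)


class TestClipFeatures:
    def _frame(self, **values):
        row = {name: 0.0 for name in feature_names()}
        row.update(values)
        return pd.DataFrame([row])

    def test_upper(self):
        out = clip_features(self._frame(hrv_rr_i=4000.0))
        assert out.loc[0, "hrv_rr_i"] == pytest.approx(3428.6)

    def test_lower(self):
        out = clip_features(self._frame(hrv_rr_i=100.0))
        assert out.loc[0, "hrv_rr_i"] == 250.0

    def test_in_range_identity(self):
        out = clip_features(self._frame(hrv_rr_i=800.0))
        assert out.loc[0, "hrv_rr_i"] == 800.0

    def test_drr_bounds(self):
        out = clip_features(self._frame(hrv_drr_i=-9000.0))
        assert out.loc[0, "hrv_drr_i"] == pytest.approx(-(3428.6 - 250.0))

    def test_non_rr_columns_untouched(self):
        frame = self._frame(morph_raw_qrs_t80_L1_xcorr=5.0, hrv_win1p_sdrr=9999.0)
        out = clip_features(frame)
        assert out.loc[0, "morph_raw_qrs_t80_L1_xcorr"] == 5.0
        assert out.loc[0, "hrv_win1p_sdrr"] == 9999.0

    def test_clip_column_lists(self):
        assert set(RR_CLIP_FEATURES) <= set(feature_names())
        assert set(DRR_CLIP_FEATURES) <= set(feature_names())


@pytest.fixture(scope="module")
def record_300():
    cfg = synth.SynthConfig(patient_id="a300", n_beats=300, pac_rate=0.06,
                            pvc_rate=0.04, seed=31)
    record, truth = synth.generate_record(cfg)
    return record, truth


class TestAssemble:
    def test_trim_counts(self, record_300):
        record, truth = record_300
        anns = synth.annotations_from_truth(truth)
        matrix = assemble_matrix(record, anns)
        assert len(matrix) == 300 - 2 * 40
        assert list(matrix.columns[:3]) == list(META_COLUMNS)
        assert matrix.shape[1] == 3 + 186
        assert not matrix[feature_names()].isna().any().any()
        assert set(matrix["label"]) <= {"N", "S", "V"}

    def test_excluded_beats_skipped_but_contribute(self, record_300):
        record, truth = record_300
        anns = synth.annotations_from_truth(truth)
        # relabel 2 interior beats as junctional -> excluded from output,
        # still present for RR timing and trim arithmetic
        from pacdetect.io import BeatAnnotation

        for j in (100, 200):
            anns[j] = BeatAnnotation(anns[j].sample, "J", "EXCLUDED")
        matrix = assemble_matrix(record, anns)
        assert len(matrix) == 300 - 2 * 40 - 2

    def test_short_record_empty(self):
        cfg = synth.SynthConfig(n_beats=80, seed=5)
        record, truth = synth.generate_record(cfg)
        with pytest.warns(UserWarning, match="trim"):
            matrix = assemble_matrix(record, synth.annotations_from_truth(truth))
        assert matrix.empty

    def test_roundtrip_csv(self, record_300, tmp_path):
        record, truth = record_300
        matrix = assemble_matrix(record, synth.annotations_from_truth(truth))
        save_features(matrix, tmp_path / "f.csv")
        loaded = load_features(tmp_path / "f.csv")
        pd.testing.assert_frame_equal(loaded, matrix)  # bit-exact reload


class TestPrune:
    def test_constant_dropped(self, rng):
        df = pd.DataFrame({"a": rng.normal(size=200), "b": np.full(200, 2.0)})
        assert prune_features(df) == ["a"]

    def test_duplicate_drops_later(self, rng):
        x = rng.normal(size=200)
        df = pd.DataFrame({"a": x, "b": x.copy(), "c": rng.normal(size=200)})
        assert prune_features(df) == ["a", "c"]

    def test_independent_noise_kept(self):
        rng = np.random.default_rng(42)
        df = pd.DataFrame({"a": rng.normal(size=1000), "b": rng.normal(size=1000)})
        assert prune_features(df) == ["a", "b"]

    def test_low_variance_dropped(self, rng):
        df = pd.DataFrame(
            {"a": rng.normal(size=500), "tiny": 0.01 * rng.normal(size=500)}
        )
        assert prune_features(df, var_min=0.05) == ["a"]

    def test_all_dropped_errors(self):
        df = pd.DataFrame({"a": np.ones(100), "b": np.full(100, 5.0)})
        with pytest.raises(ValueError):
            prune_features(df)


class TestZScore:
    def test_closed_form(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
        params = zscore_fit(df)
        out = zscore_apply(params, df)
        assert np.allclose(out["x"], [-1, 0, 1])

    def test_apply_to_same(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame({"x": rng.normal(3, 2, 100)})
        params = zscore_fit(df)
        out = zscore_apply(params, df)
        assert abs(out["x"].mean()) < 1e-9
        assert abs(out["x"].std(ddof=1) - 1) < 1e-9

    def test_constant_errors(self):
        with pytest.raises(ValueError, match="constant"):
            zscore_fit(pd.DataFrame({"x": np.ones(10)}))


def _toy_matrix(rng, n=120, patient="p0"):
    data = {"patient_id": patient, "beat_sample": np.arange(n) * 200,
            "label": rng.choice(["N", "S", "V"], size=n)}
    for j, name in enumerate(feature_names()):
        data[name] = rng.normal(loc=j % 7, scale=1.0 + (j % 3), size=n)
    return pd.DataFrame(data)


class TestFeatureTransform:
    def test_fit_transform_shapes(self, rng):
        train = _toy_matrix(rng)
        ft = FeatureTransform().fit(train)
        out = ft.transform(train)
        assert list(out.columns) == ft.kept
        assert np.allclose(out.mean(axis=0), 0, atol=1e-9)
        assert np.allclose(out.std(axis=0, ddof=1), 1, atol=1e-9)

    def test_no_leakage(self, rng):
        train = _toy_matrix(rng, patient="train")
        test_a = _toy_matrix(rng, n=30, patient="test")
        test_b = _toy_matrix(rng, n=30, patient="test")  # different content
        ft = FeatureTransform().fit(train)
        out_a1 = ft.transform(test_a)
        ft2 = FeatureTransform().fit(train)
        out_a2 = ft2.transform(pd.concat([test_a]))  # refit on same train
        pd.testing.assert_frame_equal(out_a1, out_a2)
        # transforming different test content does not change parameters
        ft.transform(test_b)
        pd.testing.assert_frame_equal(ft.transform(test_a), out_a1)

    def test_missing_imputed_with_train_means(self, rng):
        train = _toy_matrix(rng)
        name = "hrv_win10c_rmssd"
        train.loc[train.index[:10], name] = np.nan
        ft = FeatureTransform().fit(train)
        test = _toy_matrix(rng, n=5)
        test[name] = np.nan
        out = ft.transform(test)
        if name in ft.kept:
            expected = (ft.impute_means[name] - ft.mu[name]) / ft.sd[name]
            assert np.allclose(out[name], expected)

    def test_json_roundtrip(self, rng, tmp_path):
        train = _toy_matrix(rng)
        ft = FeatureTransform().fit(train)
        ft.to_json(tmp_path / "t.json")
        ft2 = FeatureTransform.from_json(tmp_path / "t.json")
        test = _toy_matrix(rng, n=20)
        pd.testing.assert_frame_equal(ft.transform(test), ft2.transform(test))

    def test_transform_before_fit(self):
        with pytest.raises(RuntimeError):
            FeatureTransform().transform(pd.DataFrame({"x": [1.0]}))
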