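import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from insole_weight import schema
from insole_weight.adaptive_bias import BiasMode
from insole_weight.moticon_io import RecordingKey
from insole_weight.windowed_features import (
    LABEL_COLUMN,
    build_feature_matrix,
    plan_windows,
    synthesize_features,
    trim_count,
    trimmed_mean,
)

from conftest import make_recording


def brute_force_trimmed_mean(values, alpha):
    """Independent oracle: explicit sort / slice / average."""
    xs = sorted(values)
    n = len(xs)
    k = int(alpha * n / 100)
    if 2 * k >= n:
        k = (n - 1) // 2
    kept = xs[k:n - k]
    return sum(kept) / len(kept)


class TestPlanWindows:
    def test_hand_example(self):
        # L=1000, l_samples=100, overlap 0.2:
        # win_init=10, olap_new=2, win_new=10.2 -> windows of 10, stride 8
        plan = plan_windows(1000, 100, 0.2)
        assert plan.win_init == pytest.approx(10.0)
        assert plan.olap_new == pytest.approx(2.0)
        assert plan.win_new == pytest.approx(10.2)
        assert plan.window_length == 10
        assert plan.stride == 8
        assert plan.n_windows == 124
        assert plan.bounds[0] == (0, 10)
        assert plan.bounds[-1][1] <= 1000

    def test_zero_overlap_tiles(self):
        plan = plan_windows(1000, 100, 0.0)
        assert plan.olap_new == 0.0
        assert plan.win_new == pytest.approx(plan.win_init)
        assert plan.stride == plan.window_length
        starts = [s for s, _ in plan.bounds]
        assert starts == list(range(0, 991, plan.stride))

    def test_larger_l_samples_means_smaller_more_windows(self):
        small = plan_windows(1000, 25, 0.2)
        large = plan_windows(1000, 100, 0.2)
        assert large.window_length < small.window_length
        assert large.n_windows > small.n_windows

    def test_window_count_non_decreasing_in_l_samples(self):
        counts = [plan_windows(1200, ls, 0.2).n_windows for ls in (10, 25, 50, 100, 200)]
        assert counts == sorted(counts)

    def test_short_sequence_single_window(self):
        with pytest.warns(UserWarning, match="shorter"):
            plan = plan_windows(50, 100, 0.2)
        assert plan.bounds == ((0, 50),)

    def test_bounds_within_sequence(self):
        for l_data, ls, ol in [(997, 40, 0.3), (505, 100, 0.0), (64, 7, 0.45)]:
            plan = plan_windows(l_data, ls, ol)
            for s, e in plan.bounds:
                assert 0 <= s < e <= l_data
                assert e - s == plan.window_length

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            plan_windows(100, 0, 0.2)
        with pytest.raises(ValueError):
            plan_windows(100, 10, 1.0)


class TestTrimmedMean:
    def test_hand_example(self):
        assert trimmed_mean([1, 2, 3, 4, 100], 20) == pytest.approx(3.0)

    def test_alpha_zero_is_mean(self):
        x = [3.2, 1.1, 9.9, 2.0]
        assert trimmed_mean(x, 0) == pytest.approx(np.mean(x))

    def test_alpha_fifty_is_median_odd(self):
        x = [5.0, 1.0, 9.0, 2.0, 7.0]
        assert trimmed_mean(x, 50) == pytest.approx(np.median(x))

    def test_alpha_fifty_is_median_even(self):
        x = [4.0, 1.0, 3.0, 2.0]
        assert trimmed_mean(x, 50) == pytest.approx(np.median(x))

    @settings(deadline=None, max_examples=200)
    @given(
        x=st.lists(st.floats(-1e6, 1e6, allow_nan=False), min_size=1, max_size=50),
        alpha=st.floats(0, 50),
    )
    def test_matches_brute_force_and_bounded(self, x, alpha):
        got = trimmed_mean(x, alpha)
        assert got == pytest.approx(brute_force_trimmed_mean(x, alpha), abs=1e-6)
        assert min(x) - 1e-9 <= got <= max(x) + 1e-9

    @given(x=st.lists(st.floats(-100, 100, allow_nan=False), min_size=2, max_size=30))
    def test_permutation_invariant(self, x):
        rng = np.random.default_rng(0)
        shuffled = list(rng.permutation(x))
        assert trimmed_mean(x, 15) == pytest.approx(trimmed_mean(shuffled, 15))

    def test_trim_count_caps(self):
        assert trim_count(5, 20) == 1
        assert trim_count(10, 50) == 4   # capped so >= 1 sample survives
        assert trim_count(11, 50) == 5
        assert trim_count(1, 50) == 0

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            trimmed_mean([1.0], 51)
        with pytest.raises(ValueError):
            trimmed_mean([], 10)


class TestSynthesizeFeatures:
    def test_uniform_left_pressures(self):
        row = pd.DataFrame(
            [{c: (1.0 if c.startswith("left_pressure") else 0.0)
              for c in schema.RAW_MODEL_COLUMNS}]
        )
        out = synthesize_features(row)
        assert out["left_pressure_sum"][0] == pytest.approx(16.0)
        assert out["right_pressure_sum"][0] == 0.0
        assert out["pressure_sum"][0] == pytest.approx(16.0)
        assert out["pressure_avg"][0] == pytest.approx(0.5)

    def test_force_sum_and_avg(self):
        row = pd.DataFrame([dict.fromkeys(schema.RAW_MODEL_COLUMNS, 0.0)])
        row["left_total_force"] = 400.0
        row["right_total_force"] = 420.0
        out = synthesize_features(row)
        assert out["force_sum"][0] == pytest.approx(820.0)
        assert out["force_avg"][0] == pytest.approx(410.0)

    def test_pressure_avg_identity(self):
        rng = np.random.default_rng(5)
        row = pd.DataFrame(
            [dict(zip(schema.RAW_MODEL_COLUMNS, rng.random(34) * 10))]
        )
        out = synthesize_features(row)
        assert out["pressure_avg"][0] * 32 == pytest.approx(out["pressure_sum"][0])

    def test_output_schema(self):
        row = pd.DataFrame([dict.fromkeys(schema.RAW_MODEL_COLUMNS, 1.0)])
        out = synthesize_features(row)
        assert list(out.columns) == list(schema.MODEL_COLUMNS)

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            synthesize_features(pd.DataFrame([{"left_total_force": 1.0}]))


class TestBuildFeatureMatrix:
    def _recordings(self, n=200, force=100.0):
        recs = []
        for w in (0, 2, 5):
            values = {c: force for c in schema.RAW_MODEL_COLUMNS}
            recs.append(
                make_recording(values, n=n, key=RecordingKey(w, "standing", 1))
            )
        return recs

    def test_row_count_matches_plan(self):
        from insole_weight.windowed_features import plan_windows
        recs = self._recordings(n=200)
        fm = build_feature_matrix(recs, None, BiasMode.NONE, 100, 0.2, 15.0,
                                  body_weight=150.0, participant_id="X")
        per_rec = plan_windows(200, 100, 0.2).n_windows
        assert len(fm) == 3 * per_rec

    def test_constant_stream_gives_exact_features_and_labels(self):
        fm = build_feature_matrix(self._recordings(force=10.0), None,
                                  BiasMode.NONE, 100, 0.2, 15.0,
                                  body_weight=150.0)
        assert (fm["left_total_force"] == 10.0).all()
        assert set(fm[LABEL_COLUMN]) == {150.0, 152.0, 155.0}

    def test_exactly_forty_features(self):
        fm = build_feature_matrix(self._recordings(), None, BiasMode.NONE,
                                  100, 0.2, 15.0, body_weight=150.0)
        assert len(schema.MODEL_COLUMNS) == 40
        assert not fm[list(schema.MODEL_COLUMNS)].isna().any().any()

    def test_trim_removes_single_sample_outliers(self):
        rng = np.random.default_rng(0)
        base = 100.0 + rng.normal(0, 0.5, 300)
        spiked = base.copy()
        spiked[::37] *= 10  # sparse single-sample outliers
        values = {c: spiked for c in schema.RAW_MODEL_COLUMNS}
        rec = make_recording(values, n=300, key=RecordingKey(0, "standing", 1))
        # l_samples=30 over 300 samples -> windows of 11 samples, so a 15%
        # trim removes one sample from each end (enough for lone spikes)
        fm0 = build_feature_matrix([rec], None, BiasMode.NONE, 30, 0.2, 0.0,
                                   body_weight=150.0)
        fm15 = build_feature_matrix([rec], None, BiasMode.NONE, 30, 0.2, 15.0,
                                    body_weight=150.0)
        err0 = (fm0["left_total_force"] - 100).abs().max()
        err15 = (fm15["left_total_force"] - 100).abs().max()
        assert err15 < 1.0 < err0

    def test_provenance_columns(self):
        fm = build_feature_matrix(self._recordings(), None, BiasMode.NONE,
                                  100, 0.2, 15.0, body_weight=150.0,
                                  participant_id="P09")
        assert set(fm["participant"]) == {"P09"}
        assert set(fm["carried_weight"]) == {0, 2, 5}
        assert set(fm["iteration"]) == {1}
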