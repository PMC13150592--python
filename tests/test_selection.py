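"""The feature-reduction cascade: filters, normalization, shadow
selection, RFE and knee detection — including leakage sentinels."""
import numpy as np
import pytest

import bcrpqsar as bq
from bcrpqsar.records import ValidationError
from bcrpqsar.selection import RfeCurve

SMALL_RF = {"max_depth": 5, "n_estimators": 40}


def table_from(matrix, prefix="f"):
    matrix = np.asarray(matrix, dtype=float)
    return bq.FeatureTable(
        compound_ids=[f"c{i}" for i in range(matrix.shape[0])],
        feature_names=[f"{prefix}:{j}" for j in range(matrix.shape[1])],
        matrix=matrix,
        provenance=["external_descriptor"] * matrix.shape[1])


class TestVarianceFilter:
    def test_constant_column_dropped(self):
        t = table_from(np.column_stack([np.ones(20),
                                        np.arange(20) % 2]))
        out, trace = bq.variance_filter(t)
        assert out.feature_names == ["f:1"]
        assert "f:0" in trace.dropped

    def test_balanced_binary_kept(self):
        col = np.zeros(870)
        col[:435] = 1            # variance 0.25
        out, _ = bq.variance_filter(table_from(col[:, None]))
        assert out.p == 1

    def test_rare_bit_dropped(self):
        col = np.zeros(870)
        col[:5] = 1              # p(1-p) ~ 0.0057 < 0.01
        out, trace = bq.variance_filter(table_from(col[:, None]))
        assert out.p == 0 and len(trace.dropped) == 1

    def test_trace_partition_invariant(self):
        rng = np.random.default_rng(0)
        t = table_from(rng.integers(0, 2, (50, 30)))
        out, trace = bq.variance_filter(t)
        assert sorted(trace.kept + list(trace.dropped)) == \
            sorted(t.feature_names)


class TestCorrelationFilter:
    def test_duplicate_column_kept_once(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=40)
        t = table_from(np.column_stack([col, col]))
        out, trace = bq.correlation_filter(t)
        assert out.p == 1 and len(trace.dropped) == 1

    def test_complement_dropped_by_absolute_r(self):
        rng = np.random.default_rng(2)
        bit = rng.integers(0, 2, 60).astype(float)
        t = table_from(np.column_stack([bit, 1 - bit]))
        out, trace = bq.correlation_filter(t)
        assert out.p == 1
        # the trace names the partner responsible for the drop
        reason = next(iter(trace.dropped.values()))
        assert "f:" in reason

    def test_independent_columns_both_kept(self):
        rng = np.random.default_rng(3)
        t = table_from(rng.normal(size=(200, 2)))
        out, _ = bq.correlation_filter(t)
        assert out.p == 2

    def test_higher_variance_member_survives(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=80)
        t = table_from(np.column_stack([base, 3.0 * base]))
        out, _ = bq.correlation_filter(t)
        assert out.feature_names == ["f:1"]


class TestZScaler:
    def test_hand_arithmetic_population_sd(self):
        t = table_from(np.array([[1.0], [2.0], [3.0]]))
        scaled = bq.ZScaler().fit_transform(t)
        np.testing.assert_allclose(
            scaled.matrix[:, 0], [-1.224744871, 0.0, 1.224744871],
            atol=1e-8)

    def test_test_value_at_train_mean_maps_to_zero(self):
        train = table_from(np.array([[1.0], [3.0]]))
        scaler = bq.ZScaler().fit(train)
        test = table_from(np.array([[2.0]]))
        assert scaler.transform(test).matrix[0, 0] == 0.0

    def test_double_application_guarded(self):
        t = table_from(np.array([[1.0], [2.0], [3.0]]))
        scaler = bq.ZScaler().fit(t)
        once = scaler.transform(t)
        with pytest.raises(ValidationError, match="not idempotent"):
            scaler.transform(once)

    def test_zero_sd_column_is_an_error(self):
        t = table_from(np.ones((5, 1)))
        with pytest.raises(ValidationError):
            bq.ZScaler().fit(t)

    def test_binary_fingerprint_bypass(self):
        mat = np.column_stack([np.arange(6) % 2, np.arange(6.0)])
        t = bq.FeatureTable(
            compound_ids=[f"c{i}" for i in range(6)],
            feature_names=["bit:0", "desc"],
            matrix=mat,
            provenance=["fingerprint", "external_descriptor"])
        out = bq.ZScaler(normalize_binary=False).fit_transform(t)
        np.testing.assert_array_equal(out.matrix[:, 0], mat[:, 0])
        assert abs(out.matrix[:, 1].mean()) < 1e-12


class TestShadowSelection:
    def test_planted_feature_confirmed_noise_mostly_rejected(self):
        table, y, causal = bq.generate_bits_dataset(
            n=250, p=40, n_causal=2, effect=0.8, seed=5)
        trace = bq.shadow_feature_select(table, y, max_iter=15, seed=5,
                                         rf_params=SMALL_RF,
                                         keep_tentative=False)
        assert all(c in trace.kept for c in causal)
        assert len(trace.kept) < 15

    def test_all_noise_yields_near_zero_confirmations(self):
        """Under a pure-noise target at most a small fraction of
        features is falsely confirmed (percentile-based shadow
        thresholds admit occasional chance in-sample associations)."""
        rng = np.random.default_rng(6)
        table = table_from(rng.integers(0, 2, (300, 30)), prefix="n")
        y = rng.normal(5, 0.5, 300)
        trace = bq.shadow_feature_select(table, y, max_iter=15, seed=6,
                                         rf_params=SMALL_RF,
                                         keep_tentative=False)
        assert trace.params["n_confirmed"] <= 3

    def test_duplicated_causal_feature_tolerated(self):
        table, y, causal = bq.generate_bits_dataset(
            n=250, p=30, n_causal=1, effect=0.8, seed=7)
        dup = np.column_stack([table.matrix, table.matrix[:, 0]])
        t2 = bq.FeatureTable(
            compound_ids=table.compound_ids,
            feature_names=table.feature_names + ["bit:dup"],
            matrix=dup)
        trace = bq.shadow_feature_select(t2, y, max_iter=15, seed=7,
                                         rf_params=SMALL_RF)
        assert ("bit:0" in trace.kept) or ("bit:dup" in trace.kept)

    def test_constant_target_is_an_error(self):
        table, _, _ = bq.generate_bits_dataset(n=50, p=5, seed=0)
        with pytest.raises(ValidationError):
            bq.shadow_feature_select(table, np.full(50, 5.0))


class TestRfe:
    def test_degenerate_single_point_grid(self):
        table, y, _ = bq.generate_bits_dataset(n=120, p=25, seed=8)
        curve = bq.rfe_curve(table, y, grid=[20],
                             estimator_params=SMALL_RF, cv_folds=3)
        assert len(curve.points) == 1
        assert curve.points[0]["k"] == 20
        assert len(curve.points[0]["features"]) == 20

    def test_determinism_under_seed(self):
        table, y, _ = bq.generate_bits_dataset(n=120, p=30, seed=9)
        kw = dict(grid=range(30, 4, -5), estimator_params=SMALL_RF,
                  seed=3, cv_folds=3)
        a = bq.rfe_curve(table, y, **kw)
        b = bq.rfe_curve(table, y, **kw)
        assert a.points == b.points

    def test_planted_signal_survives_to_small_k(self):
        table, y, causal = bq.generate_bits_dataset(
            n=250, p=60, n_causal=3, effect=0.7, seed=10)
        curve = bq.rfe_curve(table, y, grid=range(60, 4, -5),
                             estimator_params=SMALL_RF, seed=1,
                             cv_folds=3)
        # causal features are the last to be eliminated
        smallest = curve.points[-1]["features"]
        assert sum(c in smallest for c in causal) >= 2
        # r2 at moderate k beats r2 at the degenerate end
        r2 = {p["k"]: p["r2"] for p in curve.points}
        assert max(r2.values()) > 0.2


class TestKnee:
    def make_curve(self, ks, rmses):
        return RfeCurve(points=[{"k": k, "rmse": r, "r2": -r,
                                 "features": []}
                                for k, r in zip(ks, rmses)])

    def test_constructed_breakpoint_found(self):
        ks = list(range(700, 19, -10))
        rmses = [0.40 if k >= 170 else 0.40 + 0.004 * (170 - k)
                 for k in ks]
        curve = self.make_curve(ks, rmses)
        assert bq.find_knee(curve) == 170
        assert not curve.no_knee

    def test_linear_curve_flagged_no_knee(self):
        ks = [50, 40, 30, 20]
        curve = self.make_curve(ks, [0.4, 0.5, 0.6, 0.7])
        assert bq.find_knee(curve) == 20
        assert curve.no_knee

    def test_matches_brute_force_max_distance_scan(self):
        rng = np.random.default_rng(11)
        ks = list(range(100, 9, -10))
        rmses = np.sort(rng.random(len(ks))) + 0.3
        curve = self.make_curve(ks, list(rmses))
        got = bq.find_knee(curve)
        # independent scan over normalized points
        k = np.array(ks, float)
        r = np.array(rmses, float)
        x = (k - k.min()) / (k.max() - k.min())
        yv = (r - r.min()) / (r.max() - r.min())
        d = np.abs((yv[-1] - yv[0]) * x - (x[-1] - x[0]) * yv
                   + x[-1] * yv[0] - yv[-1] * x[0])
        assert got == ks[int(np.argmax(d))]

    def test_needs_three_points(self):
        with pytest.raises(ValidationError):
            bq.find_knee(self.make_curve([20, 10], [0.4, 0.5]))


class TestLeakage:
    def test_cascade_never_sees_test_rows(self):
        """Permuting or poisoning rows outside the training slice does
        not change any selection decision."""
        table, y, _ = bq.generate_bits_dataset(n=200, p=40, seed=12)
        train_rows = list(range(150))
        cfg = bq.PipelineConfig(shadow_max_iter=8,
                                selection_rf_params=SMALL_RF,
                                rfe_grid=range(30, 9, -5),
                                rfe_cv_folds=3)
        train = table.take_rows(train_rows)
        base = bq.run_cascade(train, y[:150], cfg, seed=0)
        poisoned = table.matrix.copy()
        poisoned[150:] = np.nan
        t2 = bq.FeatureTable(compound_ids=table.compound_ids,
                             feature_names=table.feature_names,
                             matrix=np.nan_to_num(poisoned, nan=0.0))
        t2.matrix[150:] = 12345.0     # arbitrary garbage, finite
        again = bq.run_cascade(t2.take_rows(train_rows), y[:150], cfg,
                               seed=0)
        assert base.selected == again.selected
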