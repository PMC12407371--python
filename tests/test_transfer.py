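"""Transfer-function fitting, voltage translation and hold-out evaluation."""

import dataclasses

import numpy as np
import pytest

from leafplp import cvae, synthetic, transfer
from leafplp.calibration import CharacteristicCurve
from leafplp.errors import (
    InvalidArgumentError,
    LeakageError,
    UnderdeterminedFitError,
)
from leafplp.morphometrics import LeafFeatures
from leafplp.transfer import TransferFunction, VoltageTrace


def _linear_tf(intercept=100.0, slope=-0.1, v_range=(50.0, 900.0)):
    return TransferFunction(
        poly=np.polynomial.Polynomial([intercept, slope]),
        degree=1,
        v_range=v_range,
    )


class TestFitTransfer:
    def test_recovers_a_known_cubic(self):
        coef = [120.0, -0.5, 8e-4, -4.5e-7]  # rwc = c0 + c1 v + c2 v^2 + c3 v^3
        v = np.linspace(100, 600, 10)
        rwc = np.clip(np.polynomial.polynomial.polyval(v, coef), 0, 100)
        keep = (rwc > 0) & (rwc < 100)  # stay off the clamp
        curve = CharacteristicCurve(v[keep], rwc[keep])
        tf = transfer.fit_transfer(curve, degree=3)
        assert tf.fit_residual < 1e-6
        assert np.allclose(tf.coefficients, coef, rtol=1e-5)

    def test_constant_curve_fits_a_constant(self):
        curve = CharacteristicCurve(np.linspace(100, 400, 10), np.full(10, 60.0))
        tf = transfer.fit_transfer(curve, degree=3)
        grid = np.linspace(*tf.v_range, 50)
        assert np.allclose(transfer.voltage_to_rwc(tf, grid), 60.0, atol=1e-8)

    def test_round_trip_on_monotone_synthetic_curves(self, honey_noiseless_spec):
        lib = synthetic.generate_library(honey_noiseless_spec, n=20, seed=31)
        for i in range(lib.n_leaves):
            curve = CharacteristicCurve(lib.v_matrix[i], lib.rwc_matrix[i])
            tf = transfer.fit_transfer(curve, degree=3)
            recovered = transfer.voltage_to_rwc(tf, curve.v_trx)
            assert np.all(np.abs(recovered - curve.rwc) < 2.0)

    def test_underdetermined_fit_rejected(self):
        curve = CharacteristicCurve(np.array([100.0, 200, 300]), np.array([90.0, 50, 10]))
        with pytest.raises(UnderdeterminedFitError):
            transfer.fit_transfer(curve, degree=3)

    def test_monotone_fits_dominate_on_synthetic_leaves(self, honey_noiseless_spec):
        # a strictly monotone 10-point curve should almost always give a
        # monotone cubic on its own V range
        lib = synthetic.generate_library(honey_noiseless_spec, n=100, seed=17)
        monotone = 0
        for i in range(lib.n_leaves):
            curve = CharacteristicCurve(lib.v_matrix[i], lib.rwc_matrix[i])
            monotone += transfer.fit_transfer(curve, degree=3).is_monotone()
        assert monotone >= 95


class TestVoltageToRwc:
    def test_linear_arithmetic(self):
        assert transfer.voltage_to_rwc(_linear_tf(), 300.0) == pytest.approx(70.0)

    def test_below_range_clamps_to_low_endpoint_value(self):
        tf = _linear_tf(v_range=(200.0, 900.0))
        assert transfer.voltage_to_rwc(tf, 10.0) == pytest.approx(
            transfer.voltage_to_rwc(tf, 200.0)
        )

    def test_output_always_within_unit_interval(self):
        tf = _linear_tf(intercept=150.0)  # would exceed 100% at low voltage
        v = np.linspace(1.0, 2000.0, 200)
        out = transfer.voltage_to_rwc(tf, v)
        assert np.all((out >= 0.0) & (out <= 100.0))


class TestTranslateTrace:
    def test_empty_trace_gives_empty_series(self):
        out = transfer.translate_trace(_linear_tf(), VoltageTrace([], []))
        assert len(out) == 0

    def test_constant_trace_gives_constant_rwc(self):
        trace = VoltageTrace(np.arange(5.0), np.full(5, 300.0))
        out = transfer.translate_trace(_linear_tf(), trace)
        assert np.allclose(out["rwc_pct"], 70.0)

    def test_sample_count_preserved_and_clamped(self):
        trace = VoltageTrace(np.arange(100.0), np.linspace(10, 5000, 100))
        out = transfer.translate_trace(_linear_tf(), trace)
        assert len(out) == 100
        assert out["rwc_pct"].between(0, 100).all()

    def test_end_to_end_drying_trace_recovery(self, honey_noiseless_spec):
        # a noiseless drying trace translated through the fit of its own
        # truth curve must recover RWC within 3 points
        feats = synthetic.sample_features(honey_noiseless_spec, 1, seed=55)[0]
        leaf = synthetic.make_leaf(honey_noiseless_spec, feats, seed=55)
        rwc_true = np.linspace(100, 8, 40)
        trace = VoltageTrace(np.linspace(0, 12, 40), leaf.truth(rwc_true))
        records = synthetic.simulate_drying_loop(leaf, 10)
        from leafplp.calibration import assemble_curve

        curve = assemble_curve(records, leaf.turgid_mass, leaf.dry_mass)
        tf = transfer.fit_transfer(curve, degree=3)
        out = transfer.translate_trace(tf, trace)
        assert np.max(np.abs(out["rwc_pct"].to_numpy() - rwc_true)) < 3.0

    def test_invalid_traces_rejected(self):
        with pytest.raises(InvalidArgumentError):
            VoltageTrace([0.0, 0.0], [100.0, 100.0])  # non-increasing time
        with pytest.raises(InvalidArgumentError):
            VoltageTrace([0.0, 1.0], [100.0, -5.0])  # non-positive voltage


class TestOneShot:
    def test_composition_equals_manual_steps(self, jsp_noiseless_generator):
        gen, _ = jsp_noiseless_generator
        f = LeafFeatures.from_measurements(30.0, 18.0, 250.0, 0.2)
        result = transfer.one_shot_rwc(gen, f, v=250.0)
        curve = cvae.predict_curve(gen, f, mode="deterministic")
        tf = transfer.fit_transfer(curve, degree=3)
        assert result.rwc == pytest.approx(transfer.voltage_to_rwc(tf, 250.0))
        assert np.array_equal(result.curve.v_trx, curve.v_trx)

    def test_output_in_unit_interval(self, jsp_noiseless_generator):
        gen, _ = jsp_noiseless_generator
        f = LeafFeatures.from_measurements(30.0, 18.0, 250.0, 0.2)
        for v in (50.0, 200.0, 400.0, 900.0):
            assert 0.0 <= transfer.one_shot_rwc(gen, f, v).rwc <= 100.0

    def test_recovers_truth_rwc_on_heldout_leaf(
        self, jsp_noiseless_generator, jsp_noiseless_spec
    ):
        gen, _ = jsp_noiseless_generator
        feats = synthetic.sample_features(jsp_noiseless_spec, 1, seed=88)[0]
        leaf = synthetic.make_leaf(jsp_noiseless_spec, feats, seed=88)
        for rwc_true in (80.0, 50.0, 20.0):
            v = float(leaf.truth(rwc_true))
            result = transfer.one_shot_rwc(gen, feats, v)
            assert result.rwc == pytest.approx(rwc_true, abs=3.0)


class TestRmse:
    def test_identical_series_is_zero(self):
        assert transfer.rmse([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == 0.0

    def test_constant_offset(self):
        assert transfer.rmse([1.0, 2.0], [4.0, 5.0]) == pytest.approx(3.0)

    def test_hand_computed_example(self):
        assert transfer.rmse([1, 2, 3], [1, 2, 5]) == pytest.approx(np.sqrt(4 / 3))

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            transfer.rmse([1.0], [1.0, 2.0])


class TestEvaluateHoldout:
    def test_single_leaf_best_equals_mean(
        self, jsp_noiseless_generator, jsp_noiseless_spec
    ):
        gen, _ = jsp_noiseless_generator
        hold = synthetic.generate_library(jsp_noiseless_spec, n=2, seed=123)
        report = transfer.evaluate_holdout(gen, hold, best_of=1)
        assert report.best_v_rmse == report.mean_v_rmse
        assert report.best_rwc_rmse == report.mean_rwc_rmse

    def test_best_never_exceeds_mean(self, trained_cultivars):
        for bundle in trained_cultivars.values():
            report = transfer.evaluate_holdout(bundle["generator"], bundle["holdout"])
            assert report.best_v_rmse <= report.mean_v_rmse
            assert report.best_rwc_rmse <= report.mean_rwc_rmse

    def test_leakage_detected_by_leaf_id(self, jsp_noiseless_generator, jsp_noiseless_library):
        gen, _ = jsp_noiseless_generator
        with pytest.raises(LeakageError):
            transfer.evaluate_holdout(gen, jsp_noiseless_library)

    def test_reports_are_deterministic(self, trained_cultivars):
        bundle = trained_cultivars["japanese"]
        r1 = transfer.evaluate_holdout(bundle["generator"], bundle["holdout"])
        r2 = transfer.evaluate_holdout(bundle["generator"], bundle["holdout"])
        assert r1.per_leaf.equals(r2.per_leaf)
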