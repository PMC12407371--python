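"""CVAE mechanics (encoder/decoder/ELBO/reparameterization) and training."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from leafplp import cvae, synthetic, transfer
from leafplp.cvae import CVAEConfig, LatentParams, SlaveVAE
from leafplp.errors import InvalidArgumentError, NotFittedError
from leafplp.morphometrics import LeafFeatures


class _FixedRng:
    """Stub rng whose standard_normal returns a constant."""

    def __init__(self, value):
        self.value = value

    def standard_normal(self, shape):
        return np.full(shape, self.value)


class TestEncode:
    def test_zero_network_gives_standard_normal_params(self):
        slave = SlaveVAE.zeros(x_dim=10, c_dim=5, latent_dim=2)
        params = cvae.encode(slave, np.zeros(10), np.zeros(5))
        assert np.array_equal(params.mu, np.zeros(2))
        assert np.array_equal(params.log_var, np.zeros(2))
        assert np.array_equal(params.sigma, np.ones(2))

    def test_deterministic_for_identical_inputs(self, rng):
        slave = SlaveVAE(10, 5, 2, (16,), rng=np.random.default_rng(0))
        x, c = rng.random(10), rng.random(5)
        p1, p2 = cvae.encode(slave, x, c), cvae.encode(slave, x, c)
        assert np.array_equal(p1.mu, p2.mu) and np.array_equal(p1.log_var, p2.log_var)

    def test_variance_strictly_positive(self, rng):
        slave = SlaveVAE(10, 5, 2, (16,), rng=np.random.default_rng(1))
        for _ in range(20):
            params = cvae.encode(slave, rng.random(10), rng.random(5))
            assert np.all(np.exp(params.log_var) > 0)

    def test_dimension_mismatch_rejected(self):
        slave = SlaveVAE.zeros(10, 5, 2)
        with pytest.raises(InvalidArgumentError):
            cvae.encode(slave, np.zeros(9), np.zeros(5))


class TestReparameterize:
    def test_zero_noise_returns_the_mean(self):
        params = LatentParams(np.array([1.5, -2.0]), np.array([0.3, 0.7]))
        z = cvae.reparameterize(params, _FixedRng(0.0))
        assert np.array_equal(z, params.mu)

    def test_unit_noise_arithmetic(self):
        # mu = 0, sigma^2 = 4 (log_var = ln 4), eps = 1  ->  z = 2
        params = LatentParams(np.array([0.0]), np.array([np.log(4.0)]))
        z = cvae.reparameterize(params, _FixedRng(1.0))
        assert z == pytest.approx([2.0])

    def test_monte_carlo_moments_match_the_gaussian(self):
        params = LatentParams(np.zeros(1), np.zeros(1))
        rng = np.random.default_rng(7)
        draws = np.array([cvae.reparameterize(params, rng)[0] for _ in range(100_000)])
        assert abs(draws.mean()) < 0.02
        assert abs(draws.var() - 1.0) < 0.05


class TestDecode:
    def test_zero_network_outputs_denormalized_bias(self):
        slave = SlaveVAE.zeros(10, 5, 2)
        scaler = cvae.ColumnScaler(mins=np.full(10, 50.0), ranges=np.full(10, 200.0))
        slave.x_scaler = scaler
        out = cvae.decode(slave, np.zeros(2), np.zeros(5))
        # zero weights and biases -> normalized output 0 -> column minima
        assert np.allclose(out, 50.0)

    def test_output_length_is_ten(self, jsp_noiseless_generator):
        gen, _ = jsp_noiseless_generator
        out = cvae.decode(gen.slave_v, np.zeros(2), np.zeros(5))
        assert out.shape == (10,)

    def test_deterministic(self, rng):
        slave = SlaveVAE(10, 5, 2, (16,), rng=np.random.default_rng(2))
        z, c = rng.random(2), rng.random(5)
        assert np.array_equal(cvae.decode(slave, z, c), cvae.decode(slave, z, c))


class TestElboLoss:
    def test_perfect_reconstruction_at_the_prior_is_zero(self):
        x = np.linspace(0, 1, 10)
        params = LatentParams(np.zeros(2), np.zeros(2))
        assert cvae.elbo_loss(x, x, params) == (0.0, 0.0, 0.0)

    def test_closed_form_kl_for_unit_shift(self):
        # KL(N(1,1) || N(0,1)) = 0.5
        params = LatentParams(np.array([1.0]), np.array([0.0]))
        _, kl, _ = cvae.elbo_loss(np.zeros(3), np.zeros(3), params)
        assert kl == pytest.approx(0.5)

    @given(
        mu=st.lists(st.floats(-3, 3), min_size=1, max_size=4),
        lv=st.lists(st.floats(-3, 3), min_size=1, max_size=4),
    )
    @settings(max_examples=100, deadline=None)
    def test_kl_non_negative(self, mu, lv):
        n = min(len(mu), len(lv))
        params = LatentParams(np.array(mu[:n]), np.array(lv[:n]))
        _, kl, _ = cvae.elbo_loss(np.zeros(2), np.zeros(2), params)
        assert kl >= 0.0


class TestTraining:
    def test_loss_decreases_and_stays_finite(self, trained_cultivars):
        for name, bundle in trained_cultivars.items():
            for slave, trace in bundle["traces"].items():
                assert np.all(np.isfinite(trace.total)), (name, slave)
                assert trace.total[-1] < trace.total[0], (name, slave)

    def test_seeded_training_is_reproducible(self, jsp_noiseless_spec):
        lib = synthetic.generate_library(jsp_noiseless_spec, n=12, seed=4)
        cfg = CVAEConfig(epochs=150, seed=9)
        gen1, tr1 = cvae.train(lib, cfg)
        gen2, tr2 = cvae.train(lib, cfg)
        for k in gen1.slave_v.params:
            assert np.array_equal(gen1.slave_v.params[k], gen2.slave_v.params[k])
        assert np.array_equal(tr1["rwc"].total, tr2["rwc"].total)

    def test_moving_average_trend_non_increasing_late_in_training(
        self, jsp_noiseless_generator
    ):
        _, traces = jsp_noiseless_generator
        for trace in traces.values():
            total = trace.total
            ma = np.convolve(total, np.ones(100) / 100, mode="valid")
            late = ma[len(ma) // 2 :]
            # 100-epoch moving average may wiggle by at most 1% upward
            assert np.all(np.diff(late) <= 0.01 * late[:-1] + 1e-12)

    def test_noiseless_holdout_recovery_below_2_rwc_points(
        self, jsp_noiseless_generator, jsp_noiseless_holdout
    ):
        gen, _ = jsp_noiseless_generator
        report = transfer.evaluate_holdout(gen, jsp_noiseless_holdout)
        assert report.best_rwc_rmse < 2.0
        assert report.mean_rwc_rmse < 2.0

    def test_denormalized_losses_have_physical_scale(self, trained_cultivars):
        traces = trained_cultivars["japanese"]["traces"]
        # voltage reconstruction is reported in mV^2, RWC in %^2
        assert traces["voltage"].recon_denorm[-1] < traces["voltage"].recon_denorm[0]
        assert traces["rwc"].recon_denorm[-1] < 25.0  # < (5%)^2 after training


class TestPredictCurve:
    def test_output_has_ten_points(self, jsp_noiseless_generator):
        gen, _ = jsp_noiseless_generator
        f = LeafFeatures.from_measurements(30.0, 18.0, 250.0, 0.2)
        assert len(cvae.predict_curve(gen, f)) == 10

    def test_deterministic_mode_is_repeatable(self, jsp_noiseless_generator):
        gen, _ = jsp_noiseless_generator
        f = LeafFeatures.from_measurements(30.0, 18.0, 250.0, 0.2)
        c1, c2 = cvae.predict_curve(gen, f), cvae.predict_curve(gen, f)
        assert np.array_equal(c1.v_trx, c2.v_trx)
        assert np.array_equal(c1.rwc, c2.rwc)

    def test_training_leaf_reconstruction_accuracy(
        self, jsp_noiseless_generator, jsp_noiseless_library
    ):
        gen, _ = jsp_noiseless_generator
        lib = jsp_noiseless_library
        for i in range(lib.n_leaves):
            pred = cvae.predict_curve(gen, LeafFeatures(*lib.features[i]))
            assert transfer.rmse(pred.v_trx, lib.v_matrix[i]) < 5.0
            assert transfer.rmse(pred.rwc, lib.rwc_matrix[i]) < 2.0

    def test_untrained_generator_rejected(self, jsp_noiseless_generator):
        import dataclasses

        gen, _ = jsp_noiseless_generator
        broken = dataclasses.replace(gen, fitted=False)
        f = LeafFeatures.from_measurements(30.0, 18.0, 250.0, 0.2)
        with pytest.raises(NotFittedError):
            cvae.predict_curve(broken, f)

    def test_conditioning_carries_the_signal(
        self, jsp_noiseless_generator, jsp_noiseless_holdout
    ):
        # destroying the feature conditioning must raise held-out error
        # substantially (features determine the synthetic curves)
        gen, _ = jsp_noiseless_generator
        hold = jsp_noiseless_holdout
        correct, shuffled = [], []
        perm = np.roll(np.arange(hold.n_leaves), 3)
        for i in range(hold.n_leaves):
            pred = cvae.predict_curve(gen, LeafFeatures(*hold.features[i]))
            correct.append(transfer.rmse(pred.v_trx, hold.v_matrix[i]))
            wrong = cvae.predict_curve(gen, LeafFeatures(*hold.features[perm[i]]))
            shuffled.append(transfer.rmse(wrong.v_trx, hold.v_matrix[i]))
        assert np.mean(shuffled) >= 1.5 * np.mean(correct)

    def test_sampled_mode_mean_matches_deterministic(self, jsp_noiseless_generator):
        gen, _ = jsp_noiseless_generator
        f = LeafFeatures.from_measurements(30.0, 18.0, 250.0, 0.2)
        det = cvae.predict_curve(gen, f)
        rng = np.random.default_rng(42)
        draws = np.stack(
            [cvae.predict_curve(gen, f, mode="sampled", rng=rng).v_trx for _ in range(200)]
        )
        se = draws.std(axis=0, ddof=1) / np.sqrt(draws.shape[0])
        # the sample mean of a nonlinear decoder carries an O(sigma_z^2)
        # curvature bias relative to decoding z = 0, so allow 0.1% of
        # the signal on top of the Monte-Carlo standard error
        tol = np.maximum(2 * se, 1e-3 * np.abs(det.v_trx))
        assert np.all(np.abs(draws.mean(axis=0) - det.v_trx) <= tol)


class TestSerialization:
    def test_json_round_trip_preserves_predictions(
        self, jsp_noiseless_generator, tmp_path
    ):
        gen, _ = jsp_noiseless_generator
        path = tmp_path / "model.json"
        cvae.save_generator(gen, path)
        back = cvae.load_generator(path)
        f = LeafFeatures.from_measurements(30.0, 18.0, 250.0, 0.2)
        a, b = cvae.predict_curve(gen, f), cvae.predict_curve(back, f)
        assert np.allclose(a.v_trx, b.v_trx)
        assert np.allclose(a.rwc, b.rwc)
        assert back.cultivar == gen.cultivar
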