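"""Oracle-backed tests of the shared-weight Gaussian-Bernoulli RBM."""

import numpy as np
import pytest
import scipy.stats

from ssvephybrid import mcrbm
from ssvephybrid.errors import ShapeError
from ssvephybrid.signal_io import TrialSample


@pytest.fixture
def small_params():
    p = mcrbm.MCRBMParams.init(3, 2, scale=0.5, seed=0)
    p.a[:] = [0.1, -0.2, 0.05]
    p.b[:] = [0.3, -0.1]
    return p


class _StubRng:
    """Deterministic rng stand-in: uniforms 0.5, Gaussian noise 0."""

    def random(self, shape):
        return np.full(shape, 0.5)

    def standard_normal(self, shape):
        return np.zeros(shape)


def _energy_bruteforce(params, v, h):
    nc, nv = v.shape
    nh = h.shape[1]
    e = 0.0
    for k in range(nc):
        for i in range(nv):
            e += 0.5 * v[k, i] ** 2 - params.a[i] * v[k, i]
            for j in range(nh):
                e -= v[k, i] * params.W[i, j] * h[k, j]
        for j in range(nh):
            e -= params.b[j] * h[k, j]
    return e


class TestEnergy:
    def test_zero_state_zero_energy(self, small_params):
        assert mcrbm.energy(small_params, np.zeros((2, 3)), np.zeros((2, 2))) == 0.0

    def test_hand_computed_scalar_instance(self):
        p = mcrbm.MCRBMParams(np.array([[0.5]]), np.array([0.1]), np.array([0.3]))
        # 0.5*4 - 2*0.5*1 - 0.3 - 0.1*2 = 0.5
        assert mcrbm.energy(p, np.array([[2.0]]), np.array([[1.0]])) == pytest.approx(0.5)

    def test_matches_direct_summation(self, small_params, rng):
        v = rng.standard_normal((4, 3))
        h = rng.integers(0, 2, (4, 2)).astype(float)
        assert mcrbm.energy(small_params, v, h) == pytest.approx(
            _energy_bruteforce(small_params, v, h), rel=1e-12
        )

    def test_channel_duplication_doubles_energy(self, small_params, rng):
        v = rng.standard_normal((2, 3))
        h = rng.integers(0, 2, (2, 2)).astype(float)
        e1 = mcrbm.energy(small_params, v, h)
        e2 = mcrbm.energy(small_params, np.vstack([v, v]), np.vstack([h, h]))
        assert e2 == pytest.approx(2 * e1, rel=1e-12)

    def test_shape_mismatch(self, small_params):
        with pytest.raises(ShapeError):
            mcrbm.energy(small_params, np.zeros((2, 4)), np.zeros((2, 2)))


class TestConditionals:
    def test_null_params_give_half(self):
        p = mcrbm.MCRBMParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        np.testing.assert_array_equal(mcrbm.hidden_conditional(p, np.ones((2, 3))), 0.5)

    def test_monotone_in_hidden_bias(self, small_params, rng):
        v = rng.standard_normal((1, 3))
        probs = []
        for shift in (0.0, 1.0, 5.0, 20.0):
            p = small_params.copy()
            p.b[0] += shift
            probs.append(mcrbm.hidden_conditional(p, v)[0, 0])
        assert np.all(np.diff(probs) > 0) and probs[-1] > 0.99

    def test_hidden_sampling_matches_probabilities(self, small_params, rng):
        """Monte-Carlo oracle: empirical Bernoulli frequencies of sample_hidden
        match the conditional within 3 standard errors."""
        v = rng.standard_normal((1, 3))
        p = mcrbm.hidden_conditional(small_params, v)[0]
        n = 100_000
        tiled = np.tile(v, (n, 1))  # channels are conditionally independent
        freq = mcrbm.sample_hidden(small_params, tiled, rng).mean(axis=0)
        se = np.sqrt(p * (1 - p) / n)
        assert np.all(np.abs(freq - p) < 3 * se)

    def test_visible_mean_null_and_bias(self, small_params):
        p0 = mcrbm.MCRBMParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        np.testing.assert_array_equal(mcrbm.visible_conditional_mean(p0, np.ones((1, 2))), 0.0)
        np.testing.assert_array_equal(
            mcrbm.visible_conditional_mean(small_params, np.zeros((1, 2)))[0], small_params.a
        )

    def test_visible_sampling_unit_variance(self, small_params, rng):
        h = np.array([[1.0, 0.0]])
        draws = np.stack([mcrbm.sample_visible(small_params, h, rng)[0] for _ in range(20_000)])
        np.testing.assert_allclose(draws.var(axis=0), 1.0, rtol=0.05)
        np.testing.assert_allclose(
            draws.mean(axis=0), mcrbm.visible_conditional_mean(small_params, h)[0], atol=0.05
        )


class TestCDUpdate:
    def test_zero_learning_rate_keeps_params(self, small_params, rng):
        cfg = mcrbm.CDConfig(learning_rate=0.0)
        new, _ = mcrbm.cd_update(small_params, rng.standard_normal((8, 2, 3)), cfg, rng)
        np.testing.assert_array_equal(new.W, small_params.W)
        np.testing.assert_array_equal(new.a, small_params.a)
        np.testing.assert_array_equal(new.b, small_params.b)

    def test_empty_batch_rejected(self, small_params, rng):
        with pytest.raises(ValueError, match="nonempty"):
            mcrbm.cd_update(small_params, np.zeros((0, 2, 3)), mcrbm.CDConfig(), rng)

    def test_update_shrinks_on_model_samples(self, small_params):
        """Data drawn from the model's own distribution: expected update is 0,
        so the realized update norm shrinks with batch size."""
        hs = ((np.arange(4)[:, None] >> np.arange(2)) & 1).astype(float)
        lw_p = np.exp(
            hs @ small_params.b
            + 0.5 * np.sum((hs @ small_params.W.T + small_params.a) ** 2, axis=1)
        )
        p_h = lw_p / lw_p.sum()
        rng = np.random.default_rng(0)
        norms = []
        for n in (10, 100, 1000):
            idx = rng.choice(4, size=n, p=p_h)
            v = hs[idx] @ small_params.W.T + small_params.a + rng.standard_normal((n, 3))
            batch = v[:, None, :]  # one channel
            cfg = mcrbm.CDConfig(k_steps=5, sample_visible=True)
            _, stats = mcrbm.cd_update(small_params, batch, cfg, np.random.default_rng(1))
            norms.append(stats["dW_norm"])
        assert norms[-1] < norms[0]

    def test_channel_permutation_invariance_exact(self, small_params, rng):
        """With channel-symmetric shared parameters, permuting the channel axis
        leaves the (deterministically sampled) update exactly unchanged."""
        batch = rng.standard_normal((6, 5, 3))
        perm = np.array([3, 0, 4, 1, 2])
        cfg = mcrbm.CDConfig()
        new_a, _ = mcrbm.cd_update(small_params, batch, cfg, _StubRng())
        new_b, _ = mcrbm.cd_update(small_params, batch[:, perm, :], cfg, _StubRng())
        np.testing.assert_array_equal(new_a.W, new_b.W)
        np.testing.assert_array_equal(new_a.a, new_b.a)
        np.testing.assert_array_equal(new_a.b, new_b.b)

    def test_pretraining_reduces_reconstruction_error(self, rng):
        data = mcrbm.standardize_channels(rng.standard_normal((60, 4, 20))
                                          + np.sin(np.linspace(0, 12, 20)))
        cfg = mcrbm.CDConfig(learning_rate=5e-3, epochs=30, batch_size=16, seed=1)
        _, history = mcrbm.pretrain(data, 8, cfg)
        smooth = np.convolve(history, np.ones(5) / 5, mode="valid")
        assert history[-1] < history[0]
        assert np.sum(np.diff(smooth) > 1e-3) < len(smooth) // 4  # decreasing trend


class TestExtractFeatures:
    def test_null_params_all_half(self):
        p = mcrbm.MCRBMParams(np.zeros((10, 4)), np.zeros(10), np.zeros(4))
        trial = TrialSample(np.random.default_rng(0).standard_normal((3, 10)), 0)
        np.testing.assert_array_equal(mcrbm.extract_features(p, trial), 0.5)

    def test_weight_sharing_identical_channels(self, rng):
        p = mcrbm.MCRBMParams.init(10, 4, scale=0.5, seed=1)
        row = rng.standard_normal(10)
        trial = TrialSample(np.tile(row, (3, 1)), 0)
        feats = mcrbm.extract_features(p, trial)
        assert feats.shape == (3, 4)
        np.testing.assert_array_equal(feats[0], feats[1])
        np.testing.assert_array_equal(feats[0], feats[2])

    def test_values_in_open_unit_interval_and_deterministic(self, rng):
        p = mcrbm.MCRBMParams.init(16, 6, scale=0.5, seed=2)
        trial = TrialSample(rng.standard_normal((4, 16)), 0)
        f1 = mcrbm.extract_features(p, trial)
        f2 = mcrbm.extract_features(p, trial)
        np.testing.assert_array_equal(f1, f2)
        assert np.all((f1 > 0) & (f1 < 1))

    def test_length_mismatch_names_both(self, rng):
        p = mcrbm.MCRBMParams.init(16, 6, seed=0)
        with pytest.raises(ShapeError, match="T=12.*Nv=16"):
            mcrbm.extract_features(p, TrialSample(rng.standard_normal((4, 12)), 0))

    def test_permutation_equivariance(self, rng):
        p = mcrbm.MCRBMParams.init(8, 3, scale=0.5, seed=3)
        sig = rng.standard_normal((5, 8))
        perm = np.array([4, 2, 0, 1, 3])
        f = mcrbm.extract_features(p, TrialSample(sig, 0))
        fp = mcrbm.extract_features(p, TrialSample(sig[perm], 0))
        np.testing.assert_array_equal(fp, f[perm])


class TestExactOracles:
    def test_null_params_standard_normal_density(self, rng):
        p = mcrbm.MCRBMParams(np.zeros((3, 2)), np.zeros(3), np.zeros(2))
        v = rng.standard_normal((2, 3))
        assert mcrbm.exact_log_likelihood(p, v) == pytest.approx(
            scipy.stats.norm.logpdf(v).sum(), rel=1e-12
        )

    def test_density_integrates_to_one(self):
        p = mcrbm.MCRBMParams(np.array([[0.7]]), np.array([0.2]), np.array([-0.4]))
        grid = np.linspace(-12, 12, 4001)
        dens = np.array([np.exp(mcrbm.exact_log_likelihood(p, np.array([[v]]))) for v in grid])
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=0.01)

    def test_partition_closed_form_at_zero_weights(self):
        a = np.array([0.3, -0.5])
        b = np.array([0.2, 0.9, -1.1])
        p = mcrbm.MCRBMParams(np.zeros((2, 3)), a, b)
        expected = (
            0.5 * 2 * np.log(2 * np.pi)
            + 0.5 * np.sum(a**2)
            + np.sum(np.log1p(np.exp(b)))
        )
        assert mcrbm.exact_log_partition(p) == pytest.approx(expected, rel=1e-12)
        # hidden-bias shift moves log Z exactly as the closed form predicts
        p2 = mcrbm.MCRBMParams(np.zeros((2, 3)), a, b + 1.5)
        predicted_shift = np.sum(np.log1p(np.exp(b + 1.5)) - np.log1p(np.exp(b)))
        assert mcrbm.exact_log_partition(p2) - mcrbm.exact_log_partition(p) == pytest.approx(
            predicted_shift, rel=1e-12
        )

    def test_exact_gradient_vanishes_at_optimum_direction(self, small_params):
        """At data == model samples in bulk, the exact gradient is near zero."""
        hs = ((np.arange(4)[:, None] >> np.arange(2)) & 1).astype(float)
        lw = np.exp(
            hs @ small_params.b
            + 0.5 * np.sum((hs @ small_params.W.T + small_params.a) ** 2, axis=1)
        )
        p_h = lw / lw.sum()
        rng = np.random.default_rng(5)
        idx = rng.choice(4, size=40_000, p=p_h)
        v = hs[idx] @ small_params.W.T + small_params.a + rng.standard_normal((40_000, 3))
        gw, ga, gb = mcrbm.exact_log_likelihood_grad(small_params, v[:, None, :])
        assert np.abs(gw).max() < 0.05
        assert np.abs(ga).max() < 0.05
        assert np.abs(gb).max() < 0.05

    def test_enumeration_cap(self):
        p = mcrbm.MCRBMParams.init(2, 13, seed=0)
        with pytest.raises(ValueError, match="Nh <= 12"):
            mcrbm.exact_log_likelihood(p, np.zeros((1, 2)))


def test_params_round_trip(tmp_path):
    p = mcrbm.MCRBMParams.init(6, 4, scale=0.3, seed=7)
    mcrbm.save_params(p, tmp_path / "params.npz")
    q = mcrbm.load_params(tmp_path / "params.npz")
    np.testing.assert_array_equal(p.W, q.W)
    np.testing.assert_array_equal(p.a, q.a)
    np.testing.assert_array_equal(p.b, q.b)
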