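import numpy as np
import pytest

from ssvephybrid import mcrbm, preprocessing, synthetic, training_pipeline as tp
from ssvephybrid.signal_io import TrialSample
from ssvephybrid.training_pipeline import (
    EvalReport,
    ModelBundle,
    RunConfig,
    evaluate,
    leave_one_block_out,
    stratified_holdout,
    train_subject,
)


def _toy_samples(rng, n_classes=3, n_blocks=4, c=2, t=30):
    out = []
    for b in range(n_blocks):
        for cls in range(n_classes):
            sig = rng.standard_normal((c, t)) + 3 * cls
            out.append(TrialSample(sig, cls, "S1", b))
    return out


class _OracleBundle(ModelBundle):
    """Stub predictor returning a fixed label or echoing the truth."""

    def __init__(self, n_classes, fixed=None, truth=None):
        super().__init__(mode="hybrid", n_classes=n_classes)
        self._fixed = fixed
        self._truth = iter(truth) if truth is not None else None

    def predict(self, signals):
        if self._truth is not None:
            return np.array([next(self._truth)])
        return np.array([self._fixed])


class TestSplits:
    def test_leave_one_block_out_partitions(self, rng):
        samples = _toy_samples(rng)
        seen = np.zeros(len(samples), dtype=int)
        for train, test, block in leave_one_block_out(samples):
            assert set(train) & set(test) == set()
            assert {samples[i].block_id for i in test} == {block}
            assert block not in {samples[i].block_id for i in train}
            seen[test] += 1
        np.testing.assert_array_equal(seen, 1)  # every trial tested exactly once

    def test_single_block_rejected(self, rng):
        samples = _toy_samples(rng, n_blocks=1)
        with pytest.raises(ValueError, match="2 blocks"):
            list(leave_one_block_out(samples))

    def test_stratified_holdout_covers_all_classes(self, rng):
        samples = _toy_samples(rng, n_classes=4, n_blocks=5)
        train, test = stratified_holdout(samples, 0.2, seed=0)
        assert set(train) | set(test) == set(range(len(samples)))
        assert set(train) & set(test) == set()
        assert {samples[i].label for i in test} == set(range(4))


class TestEvaluate:
    def test_perfect_predictor(self, rng):
        samples = _toy_samples(rng)
        truth = [s.label for s in samples]
        rep = evaluate(_OracleBundle(3, truth=truth), samples)
        assert rep.mean == 1.0 and rep.variance == 0.0
        np.testing.assert_array_equal(np.diag(rep.confusion), [4, 4, 4])

    def test_constant_predictor_hits_chance(self, rng):
        samples = _toy_samples(rng, n_classes=4, n_blocks=4)
        rep = evaluate(_OracleBundle(4, fixed=2), samples)
        assert rep.mean == pytest.approx(0.25)

    def test_mean_is_unweighted_over_subjects(self):
        rep = EvalReport.from_predictions(
            ["A", "A", "A", "B"], [0, 0, 0, 1], [0, 0, 1, 0], 2, 0.0
        )
        assert rep.per_subject_accuracy == {"A": pytest.approx(2 / 3), "B": 0.0}
        assert rep.mean == pytest.approx((2 / 3 + 0.0) / 2)
        accs = np.array([2 / 3, 0.0])
        assert rep.variance == pytest.approx(accs.var())

    def test_empty_fold_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate(_OracleBundle(2, fixed=0), [])


@pytest.fixture(scope="module")
def tiny_samples():
    rng = np.random.default_rng(0)
    out = []
    t = np.arange(64) / 64
    for b in range(4):
        for cls in range(3):
            sig = np.sin(2 * np.pi * (4 + 3 * cls) * t)[None, :] * np.ones((2, 1))
            out.append(TrialSample(sig + 0.3 * rng.standard_normal((2, 64)), cls, "S1", b))
    return out


class TestTrainSubject:

    def test_zero_finetune_epochs_leaves_pretrained_features(self, tiny_samples):
        cfg = RunConfig(mode="hybrid", epochs=0, n_hidden=12, seed=1,
                        cd=mcrbm.CDConfig(epochs=3))
        bundle = train_subject(tiny_samples, cfg)
        assert bundle.finetune_history == []
        # the feature layer still holds the unsupervised CD solution exactly
        np.testing.assert_array_equal(bundle.model.layers[0].W, bundle.rbm_params.W)
        np.testing.assert_array_equal(bundle.model.layers[0].b, bundle.rbm_params.b)

    def test_determinism_across_runs(self, tiny_samples):
        cfg = RunConfig(mode="hybrid", epochs=4, n_hidden=12, seed=7,
                        cd=mcrbm.CDConfig(epochs=3))
        x = np.stack([s.signal for s in tiny_samples])
        p1 = train_subject(tiny_samples, cfg).predict(x)
        p2 = train_subject(tiny_samples, cfg).predict(x)
        np.testing.assert_array_equal(p1, p2)

    def test_freeze_features_flag(self, tiny_samples):
        cfg = RunConfig(mode="hybrid", epochs=3, n_hidden=12, seed=2,
                        freeze_features=True, cd=mcrbm.CDConfig(epochs=2))
        bundle = train_subject(tiny_samples, cfg)
        np.testing.assert_array_equal(bundle.model.layers[0].W, bundle.rbm_params.W)

    def test_fbcca_mode_requires_plan(self, tiny_samples):
        with pytest.raises(ValueError, match="frequency plan"):
            train_subject(tiny_samples, RunConfig(mode="fbcca"))

    def test_mcrbm_only_head_has_no_convolutions(self, tiny_samples):
        from ssvephybrid import nn

        cfg = RunConfig(mode="mcrbm_only", epochs=2, n_hidden=12, seed=3,
                        cd=mcrbm.CDConfig(epochs=2))
        bundle = train_subject(tiny_samples, cfg)
        kinds = {type(l).__name__ for l in bundle.model.layers}
        assert "ChannelConv" not in kinds and "TemporalConv" not in kinds
        assert isinstance(bundle.model.layers[0], nn.SigmoidFeature)


class TestBundleIO:
    def test_nn_bundle_round_trip(self, rng, tmp_path):
        samples = _toy_samples(rng)
        cfg = RunConfig(mode="hybrid", epochs=2, n_hidden=12, seed=0,
                        cd=mcrbm.CDConfig(epochs=2))
        bundle = train_subject(samples, cfg)
        tp.save_bundle(bundle, tmp_path / "bundle.npz")
        loaded = tp.load_bundle(tmp_path / "bundle.npz")
        x = np.stack([s.signal for s in samples])
        np.testing.assert_array_equal(bundle.predict(x), loaded.predict(x))

    def test_fbcca_bundle_round_trip(self, rng, tmp_path):
        samples = _toy_samples(rng, t=250)
        cfg = RunConfig(mode="fbcca", frequencies=np.array([9.0, 11.0, 13.0]),
                        phases=np.zeros(3), fs=250.0)
        bundle = train_subject(samples, cfg)
        tp.save_bundle(bundle, tmp_path / "fb.npz")
        loaded = tp.load_bundle(tmp_path / "fb.npz")
        x = np.stack([s.signal for s in samples[:4]])
        np.testing.assert_array_equal(bundle.predict(x), loaded.predict(x))


class TestBenchmarkGrid:
    def test_grid_size_and_determinism(self, rng, tmp_path):
        freqs = np.array([8.0, 10.0, 12.0])
        phases = np.zeros(3)
        cfg = synthetic.SynthConfig(frequencies=freqs, phases=phases, snr_db=25.0,
                                    channel_gains=np.ones(3), fs=250.0, seed=5)
        rec = synthetic.synth_recording(cfg, "datasetII", 10, 1.5)

        def make(w):
            return preprocessing.preprocess_recording(rec, preprocessing.dataset_ii_config(w))

        base = RunConfig(split="stratified_holdout", epochs=5, n_hidden=16, seed=0,
                         frequencies=freqs, phases=phases,
                         cd=mcrbm.CDConfig(epochs=2))
        df1 = tp.run_benchmark({"S1": make}, [1.0, 0.5], ["hybrid", "fbcca"], base,
                               fs=250.0, out_csv=tmp_path / "bench.csv")
        assert len(df1) == 4  # 2 modes x 2 windows
        assert (tmp_path / "bench.csv").exists()
        df2 = tp.run_benchmark({"S1": make}, [1.0, 0.5], ["hybrid", "fbcca"], base, fs=250.0)
        np.testing.assert_array_equal(df1["mean_accuracy"].values, df2["mean_accuracy"].values)

    def test_fbcca_slower_per_sample_than_hybrid(self, four_class_samples, four_class_plan):
        """Template matching against every class at prediction time costs more
        than a single trained forward pass."""
        freqs, phases = four_class_plan
        samples = four_class_samples[:80]
        x = np.stack([s.signal for s in samples])
        fb = train_subject(samples, RunConfig(mode="fbcca", frequencies=freqs,
                                              phases=phases, fs=250.0))
        hy = train_subject(samples, RunConfig(mode="hybrid", epochs=2, n_hidden=16,
                                              seed=0, cd=mcrbm.CDConfig(epochs=1)))
        import time

        def per_sample(bundle):
            t0 = time.perf_counter()
            for xi in x:
                bundle.predict(xi)
            return (time.perf_counter() - t0) / len(x)

        assert per_sample(fb) > per_sample(hy)
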