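"""Model contract: output range, determinism, training behaviour, ablation
configurations, checkpoint round trip."""

import numpy as np
import pytest

from m6aduet.features import stack_features
from m6aduet.model import (
    DualResNet,
    ModelConfig,
    predict_read_level,
    train_model,
)

#: reduced architecture for fast training tests; the default-size network is
#: exercised by the end-to-end suite
SMALL = dict(
    block_channels=(4, 6, 8, 12),
    convs_per_block=2,
    stem_raw_channels=4,
    stem_error_channels=4,
    head_hidden=(8, 4),
)


def _random_batch(rng, n, separable=False):
    raw = rng.normal(size=(n, 5, 325)).astype(np.float32)
    err = rng.normal(size=(n, 8, 5)).astype(np.float32)
    y = rng.integers(0, 2, n).astype(np.float64)
    if separable:
        raw[y == 1, 4, :] += 3.0
        err[y == 1, 4, :] -= 1.5
    return raw, err, y


class TestBuild:
    def test_forward_scalar_probability_in_open_interval(self, rng):
        model = DualResNet(ModelConfig(**SMALL, seed=0))
        raw, err, _ = _random_batch(rng, 3)
        p = model.predict_proba(raw, err)
        assert p.shape == (3,)
        assert np.all((p > 0) & (p < 1))

    def test_zero_head_pre_activation_gives_half(self, rng):
        model = DualResNet(ModelConfig(**SMALL, seed=0))
        final = model.head.layers[-1]
        final.weight.value[...] = 0
        final.bias.value[...] = 0
        raw, err, _ = _random_batch(rng, 4)
        assert np.allclose(model.predict_proba(raw, err), 0.5)

    def test_build_is_deterministic(self):
        cfg = ModelConfig(seed=42)
        a, b = DualResNet(cfg), DualResNet(cfg)
        assert a.n_params == b.n_params
        for pa, pb in zip(a.params(), b.params()):
            assert np.array_equal(pa.value, pb.value)

    def test_invalid_configs_rejected_before_training(self):
        with pytest.raises(ValueError):
            ModelConfig(branch_enable=())
        with pytest.raises(ValueError):
            ModelConfig(block_channels=(64, 32, 128, 256))
        with pytest.raises(ValueError):
            ModelConfig(branch_enable=("raw_signal", "bogus"))


class TestPredict:
    def test_inference_is_deterministic(self, rng):
        model = DualResNet(ModelConfig(**SMALL, seed=1))
        raw, err, _ = _random_batch(rng, 10)
        assert np.array_equal(model.predict_proba(raw, err), model.predict_proba(raw, err))

    def test_permuting_inputs_permutes_outputs(self, rng):
        model = DualResNet(ModelConfig(**SMALL, seed=1))
        raw, err, _ = _random_batch(rng, 8)
        p = model.predict_proba(raw, err)
        perm = rng.permutation(8)
        assert np.allclose(model.predict_proba(raw[perm], err[perm]), p[perm])

    def test_shape_mismatch_is_an_error(self, rng):
        model = DualResNet(ModelConfig(**SMALL, seed=1))
        with pytest.raises(ValueError, match="raw-signal"):
            model.predict_proba(rng.normal(size=(2, 5, 100)), rng.normal(size=(2, 8, 5)))

    def test_predict_read_level_wraps_records(self, tiny_features):
        model = DualResNet(ModelConfig(**SMALL, seed=1))
        preds = predict_read_level(model, tiny_features[:6])
        assert len(preds) == 6
        assert all(0 <= p.pr <= 1 for p in preds)
        assert [p.read_id for p in preds] == [f.read_id for f in tiny_features[:6]]


class TestTrain:
    def _data(self, rng, n=96):
        tr = _random_batch(rng, n, separable=True)
        va = _random_batch(rng, n // 2, separable=True)
        return tr, va

    def test_loss_decreases_in_first_epoch(self, rng):
        tr, va = self._data(rng)
        model = DualResNet(ModelConfig(**SMALL, epochs=2, batch_size=32, seed=2))
        probs0 = model.predict_proba(tr[0], tr[1])
        eps = 1e-12
        initial = -np.mean(
            tr[2] * np.log(probs0 + eps) + (1 - tr[2]) * np.log(1 - probs0 + eps)
        )
        result = train_model(model, tr, va)
        assert result.log[0]["train_loss"] < initial

    def test_single_class_refused(self, rng):
        raw, err, _ = _random_batch(rng, 20)
        y = np.ones(20)
        model = DualResNet(ModelConfig(**SMALL, seed=2))
        with pytest.raises(ValueError, match="single class"):
            train_model(model, (raw, err, y), (raw, err, y))

    def test_seeded_training_reproducible(self, rng):
        tr, va = self._data(rng, n=64)
        logs = []
        for _ in range(2):
            model = DualResNet(ModelConfig(**SMALL, epochs=2, batch_size=32, seed=5))
            logs.append(train_model(model, tr, va).log)
        assert logs[0] == logs[1]

    def test_best_checkpoint_restored(self, rng):
        tr, va = self._data(rng)
        model = DualResNet(ModelConfig(**SMALL, epochs=3, batch_size=32, seed=3))
        result = train_model(model, tr, va)
        probs = model.predict_proba(va[0], va[1])
        eps = 1e-12
        val_loss = -np.mean(
            va[2] * np.log(probs + eps) + (1 - va[2]) * np.log(1 - probs + eps)
        )
        assert val_loss == pytest.approx(result.best_val_loss, abs=1e-6)

    @pytest.mark.parametrize("branch", ["raw_signal", "error"])
    def test_ablation_variants_accept_only_their_branch(self, rng, branch):
        tr, va = self._data(rng, n=64)
        cfg = ModelConfig(**SMALL, branch_enable=(branch,), epochs=1, batch_size=32, seed=4)
        model = DualResNet(cfg)
        data = (
            (tr[0], None, tr[2]) if branch == "raw_signal" else (None, tr[1], tr[2])
        )
        vdata = (
            (va[0], None, va[2]) if branch == "raw_signal" else (None, va[1], va[2])
        )
        result = train_model(model, data, vdata)
        assert len(result.log) == 1
        with pytest.raises(ValueError):
            model.forward_logits(None, None)


class TestCheckpoint:
    def test_save_load_round_trip(self, tmp_path, rng):
        model = DualResNet(ModelConfig(**SMALL, seed=9))
        raw, err, _ = _random_batch(rng, 5)
        path = tmp_path / "model.npz"
        model.save(path)
        back = DualResNet.load(path)
        assert back.cfg == model.cfg
        assert np.array_equal(back.predict_proba(raw, err), model.predict_proba(raw, err))
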