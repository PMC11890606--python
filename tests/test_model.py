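import numpy as np
import pytest

from tweetformer import ModelConfig, TextClassifier, lr_schedule
from tweetformer.tokenizer import encode

from conftest import debug_config, encode_corpus


@pytest.fixture(scope="module")
def data(request):
    tiny_corpus = request.getfixturevalue("tiny_corpus")
    tiny_vocab = request.getfixturevalue("tiny_vocab")
    return encode_corpus(tiny_corpus, tiny_vocab, 6), tiny_vocab


class TestForward:
    def test_multiclass_probabilities_sum_to_one(self, data):
        seqs, vocab = data
        cfg = debug_config(task_mode="multiclass", n_classes=3)
        model = TextClassifier(cfg, vocab)
        probs = model.predict_proba(seqs[:8])
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-12)

    def test_binary_output_in_unit_interval(self, data):
        seqs, vocab = data
        model = TextClassifier(debug_config(), vocab)
        probs = model.predict_proba(seqs[:8])
        assert probs.shape == (8, 1)
        assert np.all((probs > 0) & (probs < 1))

    def test_ablation_parameter_bookkeeping(self, data):
        _, vocab = data
        full = TextClassifier(debug_config(), vocab)
        no_bilstm = TextClassifier(debug_config(use_bilstm=False), vocab)
        no_pos = TextClassifier(debug_config(use_position_vector=False), vocab)
        lstm_names = {n for n, _ in full.param_items() if n.startswith("ctx.layer") or n == "ctx.fusion_logits"}
        assert lstm_names
        assert {n for n, _ in no_bilstm.param_items()} == {n for n, _ in full.param_items()} - lstm_names
        # dropping the position vector changes no trainable array (the table is frozen)
        assert no_pos.n_trainable_parameters() == full.n_trainable_parameters()
        assert full.n_trainable_parameters() > no_bilstm.n_trainable_parameters()


class TestSchedule:
    def test_peak_and_first_step(self):
        total, base = 100, 3e-5
        warmup = int(np.ceil(0.1 * total))
        assert abs(lr_schedule(warmup, total, base, 0.1) - base) < 1e-12
        assert abs(lr_schedule(1, total, base, 0.1) - base / warmup) < 1e-12

    def test_final_step_decays_to_zero(self):
        assert lr_schedule(100, 100, 3e-5, 0.1) == 0.0

    def test_trapezoid_area_conservation(self):
        total, base = 173, 3e-5
        warmup = int(np.ceil(0.1 * total))
        ratios = [lr_schedule(s, total, base, 0.1) / base for s in range(1, total + 1)]
        # sum over warmup ramp: (1+2+...+W)/W; decay: sum_{s>W} (T-s)/(T-W)
        expected = (warmup + 1) / 2 + sum((total - s) / (total - warmup) for s in range(warmup + 1, total + 1))
        assert abs(sum(ratios) - expected) < 1e-9


class TestTraining:
    def test_identical_seeds_identical_parameters(self, data):
        seqs, vocab = data
        results = []
        for _ in range(2):
            model = TextClassifier(debug_config(epochs=2, dropout=0.3), vocab)
            model.train(seqs)
            results.append({n: a.copy() for n, a in model.param_items()})
        for name in results[0]:
            np.testing.assert_array_equal(results[0][name], results[1][name])

    def test_loss_decreases_on_strong_signal(self, data):
        seqs, vocab = data
        cfg = debug_config(epochs=10, learning_rate=3e-3, batch_size=16)
        model = TextClassifier(cfg, vocab)
        history = model.train(seqs)
        assert history.losses[-1] < history.losses[0]

    def test_empty_training_set_rejected(self, data):
        _, vocab = data
        with pytest.raises(ValueError, match="empty"):
            TextClassifier(debug_config(), vocab).train([])

    def test_ewma_buffers_updated_when_enabled(self, data):
        seqs, vocab = data
        model = TextClassifier(debug_config(), vocab)
        model.train(seqs[:8])
        assert any(np.any(buf["wq"] != 0) for buf in model.ewma_buffers)

    def test_validation_metrics_recorded_per_epoch(self, data):
        seqs, vocab = data
        model = TextClassifier(debug_config(epochs=2), vocab)
        history = model.train(seqs[:16], val_seqs=seqs[16:32])
        assert len(history.val_metrics) == 2
        assert set(history.val_metrics[0]) == {"precision", "recall", "f1"}


class TestPredict:
    def test_probability_exactly_half_is_positive(self, data):
        _, vocab = data
        model = TextClassifier(debug_config(), vocab)
        model.head_W[:] = 0.0
        model.head_b[:] = 0.0  # logit 0 => probability exactly 0.5
        seqs, _ = data
        assert np.all(model.predict(seqs[:4]) == 1)

    def test_multiclass_argmax_with_tie_toward_lower_index(self, data):
        _, vocab = data
        model = TextClassifier(debug_config(task_mode="multiclass", n_classes=3), vocab)
        probs = np.array([[0.2, 0.5, 0.3], [0.4, 0.4, 0.2]])
        assert probs.argmax(axis=1).tolist() == [1, 0]
        model.head_W[:] = 0.0
        model.head_b[:] = 0.0  # uniform probabilities => class 0 by tie-break
        seqs, _ = data
        assert np.all(model.predict(seqs[:4]) == 0)

    def test_empty_input_gives_empty_output(self, data):
        _, vocab = data
        model = TextClassifier(debug_config(), vocab)
        assert model.predict([]).shape == (0,)


def test_checkpoint_roundtrip_bit_exact(tmp_path, data):
    seqs, vocab = data
    model = TextClassifier(debug_config(), vocab)
    model.train(seqs[:16])
    path = str(tmp_path / "model.npz")
    model.save(path)
    loaded = TextClassifier.load(path, vocab)
    for (n1, a1), (n2, a2) in zip(model.param_items(trainable_only=False), loaded.param_items(trainable_only=False)):
        assert n1 == n2
        np.testing.assert_array_equal(a1, a2)
    p1 = model.predict_proba(seqs[:8])
    p2 = loaded.predict_proba(seqs[:8])
    np.testing.assert_array_equal(p1, p2)


def test_full_model_gradients_match_finite_differences(data):
    """End-to-end gradient check through embeddings, BiLSTM, attention, head."""
    seqs, vocab = data
    cfg = debug_config(dropout=0.0)
    model = TextClassifier(cfg, vocab)
    batch = seqs[:6]
    ids, mask, oovs, labels = model.make_batch(batch)

    def loss():
        l, _, _ = model.loss_and_grads(ids, mask, oovs, labels, train=False)
        return l

    _, grads, _ = model.loss_and_grads(ids, mask, oovs, labels, train=False)
    rng = np.random.default_rng(0)
    eps = 1e-6
    arrays = dict(model.param_items())
    for name, arr in arrays.items():
        g = grads[name]
        for _ in range(2):
            idx = tuple(rng.integers(0, s) for s in arr.shape)
            if name == "emb.word" and idx[0] == 0:
                continue  # frozen padding row
            orig = arr[idx]
            arr[idx] = orig + eps
            lp = loss()
            arr[idx] = orig - eps
            lm = loss()
            arr[idx] = orig
            num = (lp - lm) / (2 * eps)
            denom = max(1e-3, abs(num), abs(g[idx]))
            assert abs(num - g[idx]) <= 1e-4 * denom, f"{name}[{idx}]: {num} vs {g[idx]}"
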