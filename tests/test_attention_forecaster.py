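import numpy as np
import pytest

from stresscast.attention_forecaster import (
    AttentionForecaster,
    ModelConfig,
    ablate,
    build_training_rows,
    classify,
    dimension_attend,
    encode_recurrent,
    pad_variants,
    temporal_attend,
    train,
)
from stresscast.errors import InsufficientDataError
from stresscast.sequence_io import StressSequence, two_label_scheme
from stresscast.synthetic_data import GeneratorSpec, generate_dataset


class TestPadVariants:
    def test_front_and_back_padding(self):
        front, back = pad_variants([1, 2, 3], max_len=5)
        np.testing.assert_array_equal(front, [0, 0, 1, 2, 3])
        np.testing.assert_array_equal(back, [1, 2, 3, 0, 0])

    def test_full_length_input_unchanged(self):
        front, back = pad_variants([1, 2, 3], max_len=3)
        np.testing.assert_array_equal(front, back)
        np.testing.assert_array_equal(front, [1, 2, 3])

    def test_empty_or_overlong_raises(self):
        with pytest.raises(InsufficientDataError):
            pad_variants([], max_len=4)
        with pytest.raises(InsufficientDataError):
            pad_variants([1] * 5, max_len=4)


class TestLayerPrimitives:
    def test_zero_attention_parameters_annihilate_input(self):
        # tanh(0) = 0: with zeroed parameters dimension attention wipes X
        X = np.arange(12.0).reshape(4, 3)
        Xp, DA = dimension_attend(X, np.zeros(4), 0.0)
        np.testing.assert_array_equal(DA, 0.0)
        np.testing.assert_array_equal(Xp, 0.0)

    def test_saturated_gate_passes_input_through(self):
        X = np.arange(12.0).reshape(4, 3)
        Xp, DA = dimension_attend(X, np.zeros(4), 50.0)
        np.testing.assert_allclose(DA, 1.0)
        np.testing.assert_allclose(Xp, X)

    def test_zero_column_stays_zero(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 3))
        X[:, 1] = 0.0
        Xp, _ = dimension_attend(X, rng.normal(size=5), 0.3)
        np.testing.assert_array_equal(Xp[:, 1], 0.0)

    def test_gate_values_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(1)
        _, DA = dimension_attend(rng.normal(size=(6, 4)), rng.normal(size=6), 0.0)
        assert np.all(np.abs(DA) < 1.0)

    def test_identical_hidden_states_give_uniform_attention(self):
        H = np.tile([1.0, -2.0, 0.5], (7, 1))
        I, TA = temporal_attend(H, np.array([0.3, -0.1, 0.8]), 0.2)
        np.testing.assert_allclose(TA, 1.0 / 7)
        np.testing.assert_allclose(I, H[0])

    def test_zero_attention_vector_means_mean_pooling(self):
        rng = np.random.default_rng(2)
        H = rng.normal(size=(9, 4))
        I, TA = temporal_attend(H, np.zeros(4), 0.0)
        np.testing.assert_allclose(TA, 1.0 / 9)
        np.testing.assert_allclose(I, H.mean(axis=0))

    def test_temporal_attention_sums_to_one(self):
        rng = np.random.default_rng(3)
        _, TA = temporal_attend(rng.normal(size=(11, 5)), rng.normal(size=5), -0.4)
        assert TA.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(TA >= 0)

    def test_dominating_logit_selects_its_state(self):
        H = np.vstack([np.ones((4, 2)), [[50.0, 50.0]]])
        I, TA = temporal_attend(H, np.array([1.0, 1.0]), 0.0)
        assert TA[-1] == pytest.approx(1.0, abs=1e-6)
        np.testing.assert_allclose(I, H[-1], rtol=1e-6)

    def test_classifier_uniform_with_zero_parameters(self):
        probs = classify(np.array([0.3, -0.7]), np.zeros((2, 3)), np.zeros(3))
        np.testing.assert_allclose(probs, 1.0 / 3)

    def test_classifier_probabilities_sum_to_one(self):
        rng = np.random.default_rng(4)
        probs = classify(rng.normal(size=8), rng.normal(size=(8, 2)), rng.normal(size=2))
        assert probs.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_input_zero_recurrence_stays_zero(self):
        h = 3
        Xp = np.zeros((6, 2))
        Wx, Wh, b = np.zeros((2, 4 * h)), np.zeros((h, 4 * h)), np.zeros(4 * h)
        H = encode_recurrent(Xp, Wx, Wh, b)
        np.testing.assert_array_equal(H, 0.0)

    def test_recurrent_batch_matches_per_sample_loop(self):
        rng = np.random.default_rng(5)
        h = 4
        Wx, Wh, b = rng.normal(size=(3, 4 * h)), rng.normal(size=(h, 4 * h)), rng.normal(size=4 * h)
        X = rng.normal(size=(6, 10, 3))
        batched = encode_recurrent(X, Wx, Wh, b)
        for i in range(6):
            np.testing.assert_allclose(batched[i], encode_recurrent(X[i], Wx, Wh, b))


class TestGradients:
    @pytest.mark.parametrize("use_da,use_ta", [(True, True), (False, True), (True, False)])
    def test_backprop_matches_finite_differences(self, use_da, use_ta):
        cfg = ModelConfig(
            num_class=3, hidden_size=3, max_len=8, tau=2, d=3,
            use_da=use_da, use_ta=use_ta, seed=11,
        )
        model = AttentionForecaster(cfg)
        rng = np.random.default_rng(0)
        for k in model.params:
            model.params[k] = rng.normal(scale=0.4, size=model.params[k].shape)
        X = rng.normal(size=(4, cfg.n_steps, cfg.input_dim))
        y = rng.integers(0, 3, size=4)
        _, grads = model.loss_and_grads(X, y)
        eps = 1e-6
        for k, v in model.params.items():
            flat = v.ravel()
            for idx in range(0, flat.size, max(1, flat.size // 4)):
                orig = flat[idx]
                flat[idx] = orig + eps
                lp = model.loss(X, y)
                flat[idx] = orig - eps
                lm = model.loss(X, y)
                flat[idx] = orig
                num = (lp - lm) / (2 * eps)
                assert grads[k].ravel()[idx] == pytest.approx(num, rel=1e-3, abs=1e-8)


@pytest.fixture(scope="module")
def separable_sequences():
    """Sequences whose next-day class is determined by their recent mean."""
    rng = np.random.default_rng(42)
    seqs = []
    for u in range(12):
        low = u % 2 == 0
        vals = rng.integers(1, 3, size=30) if low else rng.integers(3, 6, size=30)
        seqs.append(StressSequence(f"s{u}", tuple(int(v) for v in vals)))
    return seqs


class TestTraining:
    def test_loss_decreases_and_fits_separable_data(self, separable_sequences):
        cfg = ModelConfig(
            num_class=2, max_len=30, tau=1, d=3, seed=5,
            epochs=60, patience=60, batch_size=32, min_prefix=10,
        )
        model = train(separable_sequences, two_label_scheme(), cfg)
        hist = model.history
        assert hist["train_loss"][-1] < hist["train_loss"][0]
        assert hist["train_acc"][-1] >= 0.9

    def test_same_seed_reproduces_identical_loss(self, separable_sequences):
        cfg = ModelConfig(
            num_class=2, max_len=30, tau=1, d=3, seed=9,
            epochs=5, patience=5, min_prefix=10,
        )
        h1 = train(separable_sequences, two_label_scheme(), cfg).history
        h2 = train(separable_sequences, two_label_scheme(), cfg).history
        assert h1["train_loss"] == h2["train_loss"]

    def test_empty_training_set_raises(self):
        cfg = ModelConfig(num_class=2, max_len=30)
        all_unknown = [StressSequence("u", (0,) * 30)]
        with pytest.raises(InsufficientDataError):
            build_training_rows(all_unknown, two_label_scheme(), cfg)

    def test_unknown_next_day_labels_are_skipped(self):
        cfg = ModelConfig(num_class=2, max_len=12, tau=1, d=2, min_prefix=4)
        seq = StressSequence("u", (1, 2, 1, 2, 0, 2, 1, 0, 1, 2))
        X, y = build_training_rows([seq], two_label_scheme(), cfg)
        # prefixes 4..9, next days at indices 4 and 7 are unknown -> skipped
        assert len(y) == 2 * 4
        assert set(y) == {0}


class TestForecastAndAblation:
    def test_forecasts_bit_reproducible(self, separable_sequences):
        cfg = ModelConfig(
            num_class=2, max_len=30, tau=1, d=3, seed=2,
            epochs=8, patience=8, min_prefix=10,
        )
        scheme = two_label_scheme()
        m1 = train(separable_sequences, scheme, cfg)
        m2 = train(separable_sequences, scheme, cfg)
        seq = separable_sequences[1]
        f1 = m1.forecast_range(seq.prefix(20), 6, scheme)
        f2 = m2.forecast_range(seq.prefix(20), 6, scheme)
        assert f1.classes == f2.classes
        np.testing.assert_array_equal(f1.probabilities, f2.probabilities)

    def test_forecast_levels_are_class_representatives(self, separable_sequences):
        cfg = ModelConfig(
            num_class=2, max_len=30, tau=1, d=3, seed=2,
            epochs=3, patience=3, min_prefix=10,
        )
        scheme = two_label_scheme()
        model = train(separable_sequences, scheme, cfg)
        fc = model.forecast_range(separable_sequences[0].prefix(20), 5, scheme)
        assert all(
            lv == scheme.representative_level(c)
            for lv, c in zip(fc.levels, fc.classes)
        )

    def test_ablation_flags_compose(self):
        base = ModelConfig(num_class=2)
        assert not ablate(base, no_da=True).use_da
        assert not ablate(base, no_ta=True).use_ta
        both = ablate(base, no_da=True, no_ta=True)
        assert not both.use_da and not both.use_ta

    def test_no_ta_single_step_equals_full_model(self):
        # with one time step the temporal softmax is the identity pooling
        cfg_full = ModelConfig(
            num_class=2, max_len=1, use_phase_space=False, seed=3, use_ta=True
        )
        cfg_ablate = ablate(cfg_full, no_ta=True)
        m_full, m_ablate = AttentionForecaster(cfg_full), AttentionForecaster(cfg_ablate)
        m_ablate.params = {k: v.copy() for k, v in m_full.params.items()}
        X = np.array([[[2.0]]])
        p1, _ = m_full._forward(X)
        p2, _ = m_ablate._forward(X)
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_ablated_variants_train_without_error(self, separable_sequences):
        scheme = two_label_scheme()
        base = ModelConfig(
            num_class=2, max_len=30, tau=1, d=3, seed=1,
            epochs=2, patience=2, min_prefix=10,
        )
        for no_da, no_ta in [(True, False), (False, True), (True, True)]:
            model = train(separable_sequences, scheme, ablate(base, no_da, no_ta))
            assert np.isfinite(model.history["train_loss"][-1])

    def test_dl_only_path_uses_raw_sequence(self, separable_sequences):
        cfg = ModelConfig(
            num_class=2, max_len=30, use_phase_space=False, seed=1,
            epochs=2, patience=2, min_prefix=10,
        )
        model = train(separable_sequences, two_label_scheme(), cfg)
        assert model.config.input_dim == 1
        assert model.config.n_steps == 30

    def test_save_load_preserves_forecasts(self, tmp_path, separable_sequences):
        cfg = ModelConfig(
            num_class=2, max_len=30, tau=1, d=3, seed=4,
            epochs=3, patience=3, min_prefix=10,
        )
        scheme = two_label_scheme()
        model = train(separable_sequences, scheme, cfg)
        model.save(tmp_path / "model.json")
        loaded = AttentionForecaster.load(tmp_path / "model.json")
        seq = separable_sequences[3].prefix(18)
        np.testing.assert_array_equal(
            model.forecast_range(seq, 4, scheme).probabilities,
            loaded.forecast_range(seq, 4, scheme).probabilities,
        )
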