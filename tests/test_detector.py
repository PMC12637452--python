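"""Temporal embeddings, classification contracts, weight transfer, and a
short fine-tuning run on the synthetic cohort."""

import numpy as np
import pytest

from budcall.detector import (
    DivisionDetector,
    StackDataset,
    classify_stack,
    encode_frame,
    finetune,
    init_from_mae,
    load_detector_checkpoint,
    predict_movie,
    save_detector_checkpoint,
    temporal_embedding,
)
from budcall.errors import ValidationError
from budcall.events import timeline_from_probabilities
from budcall.preprocessing import TemporalStack, build_temporal_stack
from conftest import tiny_crop_config, tiny_detector_config


class TestTemporalEmbedding:
    def test_index_zero_alternates_zero_one(self):
        emb = temporal_embedding(0, 8)
        np.testing.assert_array_equal(emb, [0, 1, 0, 1, 0, 1, 0, 1])

    def test_pairwise_distinct_over_window(self):
        embs = np.stack([temporal_embedding(i, 16) for i in range(11)])
        assert len(np.unique(np.round(embs, 9), axis=0)) == 11

    def test_closed_form_components(self):
        d = 8
        idx = 3
        emb = temporal_embedding(idx, d)
        for i in range(d // 2):
            freq = idx / (10000.0 ** (2 * i / d))
            assert emb[2 * i] == pytest.approx(np.sin(freq))
            assert emb[2 * i + 1] == pytest.approx(np.cos(freq))

    def test_odd_dim_raises(self):
        with pytest.raises(ValidationError, match="even"):
            temporal_embedding(0, 7)


@pytest.fixture(scope="module")
def detector():
    return DivisionDetector(tiny_detector_config())


class TestClassifyContracts:
    def test_encode_frame_shape_and_determinism(self, detector):
        crop = np.random.default_rng(0).random((64, 64)).astype(np.float32)
        a = encode_frame(crop, detector)
        b = encode_frame(crop, detector)
        assert a.shape == (32,)
        np.testing.assert_array_equal(a, b)

    def test_encode_frame_wrong_size_raises(self, detector):
        with pytest.raises(ValidationError, match="64"):
            encode_frame(np.zeros((32, 32), dtype=np.float32), detector)

    def test_single_patch_perturbation_changes_embedding(self, detector):
        rng = np.random.default_rng(1)
        crop = rng.random((64, 64)).astype(np.float32)
        other = crop.copy()
        other[:16, :16] += 0.5  # one 16-px patch
        assert not np.allclose(encode_frame(crop, detector),
                               encode_frame(other, detector))

    def test_stack_logits_shape_and_softmax(self, detector):
        rng = np.random.default_rng(2)
        stack = TemporalStack("c", 5, rng.random((11, 64, 64)))
        logits = classify_stack(stack, detector)
        assert logits.shape == (11, 2)
        probs = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        np.testing.assert_allclose(probs.sum(axis=1), 1.0, atol=1e-6)

    def test_wrong_stack_length_raises(self, detector):
        stack = TemporalStack("c", 3, np.zeros((7, 64, 64)))
        with pytest.raises(ValidationError, match="stack length"):
            classify_stack(stack, detector)


class TestInitFromMae:
    def test_encoder_copied_exactly(self, tiny_mae_state):
        model = init_from_mae(tiny_mae_state, tiny_detector_config())
        enc = tiny_mae_state.encoder_state(use_ema=True)
        own = dict(model.named_parameters())
        for name, value in enc.items():
            np.testing.assert_array_equal(own[name].data, value, err_msg=name)

    def test_live_vs_ema_selectable(self, tiny_mae_state):
        live = init_from_mae(
            tiny_mae_state, tiny_detector_config(use_ema_weights=False)
        )
        expected = tiny_mae_state.encoder_state(use_ema=False)
        got = dict(live.named_parameters())["patch_embed.weight"].data
        np.testing.assert_array_equal(got, expected["patch_embed.weight"])

    def test_random_init_needs_no_checkpoint(self):
        model = DivisionDetector(tiny_detector_config(encoder_init="random"))
        assert model.cls_token.data.shape == (32,)

    def test_dimension_mismatch_named(self, tiny_mae_state):
        bad = tiny_detector_config(embed_dim=64, n_heads=4)
        with pytest.raises(ValidationError, match="patch_embed"):
            init_from_mae(tiny_mae_state, bad)


@pytest.fixture(scope="module")
def finetuned(small_cohort, tiny_mae_state):
    movies, truths = small_cohort
    dataset = StackDataset(movies, truths, tiny_crop_config())
    return finetune(dataset, tiny_detector_config(epochs=3),
                    mae_state=tiny_mae_state), dataset


class TestFinetune:
    def test_beats_majority_baseline(self, finetuned, small_cohort):
        """Held-out center-frame accuracy exceeds the all-negative rate."""
        state, dataset = finetuned
        movies, truths = small_cohort
        model = state.best_model()
        crop = tiny_crop_config()
        movie, truth = movies[-1], truths[-1]
        probs = predict_movie(movie, model, crop).probabilities
        calls = probs >= 0.5
        labels = np.zeros(movie.n_frames, dtype=bool)
        labels[truth.division_frames] = True
        acc = (calls == labels).mean()
        majority = 1.0 - labels.mean()
        assert acc > majority

    def test_training_loss_decreases(self, finetuned):
        state, _ = finetuned
        losses = [h["train_loss"] for h in state.history]
        assert losses[-1] < losses[0]

    def test_freeze_contract(self, small_cohort, tiny_mae_state):
        movies, truths = small_cohort
        dataset = StackDataset(movies[:4], truths[:4], tiny_crop_config())
        cfg = tiny_detector_config(epochs=1, freeze_encoder=True)
        state = finetune(dataset, cfg, mae_state=tiny_mae_state)
        enc_before = tiny_mae_state.encoder_state(use_ema=True)
        enc_after = {
            n: p.data for n, p in state.model.named_parameters()
            if n.startswith(("patch_embed.", "encoder."))
        }
        for name, val in enc_before.items():
            np.testing.assert_array_equal(enc_after[name], val, err_msg=name)

    def test_single_class_raises(self, small_cohort):
        movies, _ = small_cohort
        stacks = [
            build_temporal_stack(movies[0], f, tiny_crop_config(), label=0)
            for f in range(6)
        ]
        with pytest.raises(ValidationError, match="both classes"):
            finetune(stacks, tiny_detector_config(epochs=1))

    def test_deterministic_metric_trace(self, small_cohort, tiny_mae_state):
        movies, truths = small_cohort
        dataset = StackDataset(movies[:4], truths[:4], tiny_crop_config())
        cfg = tiny_detector_config(epochs=2)
        a = finetune(dataset, cfg, mae_state=tiny_mae_state)
        b = finetune(dataset, cfg, mae_state=tiny_mae_state)
        assert a.history == b.history


class TestPredictMovie:
    def test_probability_trace_shape_and_range(self, finetuned, small_cohort):
        state, _ = finetuned
        movies, _ = small_cohort
        probs = predict_movie(movies[0], state.best_model(), tiny_crop_config())
        assert probs.probabilities.shape == (movies[0].n_frames,)
        assert (probs.probabilities >= 0).all()
        assert (probs.probabilities <= 1).all()

    def test_deterministic_and_identical_movies_agree(self, finetuned,
                                                      small_cohort):
        state, _ = finetuned
        movies, _ = small_cohort
        model = state.best_model()
        a = predict_movie(movies[1], model, tiny_crop_config())
        b = predict_movie(movies[1], model, tiny_crop_config())
        np.testing.assert_array_equal(a.probabilities, b.probabilities)

    def test_matches_per_stack_classification(self, finetuned, small_cohort):
        """The cached-embedding sliding window equals stack-by-stack
        classification, including at the replicated boundaries."""
        state, _ = finetuned
        movies, _ = small_cohort
        model = state.best_model()
        crop = tiny_crop_config()
        movie = movies[2]
        probs = predict_movie(movie, model, crop).probabilities
        for t in [0, 1, 30, movie.n_frames - 1]:
            stack = build_temporal_stack(movie, t, crop)
            logits = classify_stack(stack, model)
            p = np.exp(logits[5]) / np.exp(logits[5]).sum()
            assert probs[t] == pytest.approx(p[1], abs=1e-5)

    def test_temporal_sensitivity_on_event_stack(self, finetuned,
                                                 small_cohort):
        """Shuffling the frames of a stack containing a bud emergence
        changes the trained model's center prediction."""
        state, _ = finetuned
        movies, truths = small_cohort
        model = state.best_model()
        crop = tiny_crop_config()
        movie, truth = movies[0], truths[0]
        event = truth.division_frames[2]
        stack = build_temporal_stack(movie, event, crop)
        base = classify_stack(stack, model)[5]
        rng = np.random.default_rng(0)
        changed = False
        for _ in range(5):
            perm = rng.permutation(11)
            shuffled = TemporalStack(stack.cell_id, event,
                                     stack.images[perm])
            out = classify_stack(shuffled, model)[5]
            if not np.allclose(out, base, atol=1e-6):
                changed = True
                break
        assert changed


class TestCheckpoint:
    def test_roundtrip_predictions_identical(self, finetuned, small_cohort,
                                             tmp_path):
        state, _ = finetuned
        movies, _ = small_cohort
        path = tmp_path / "det.npz"
        save_detector_checkpoint(state, path)
        back = load_detector_checkpoint(path)
        a = predict_movie(movies[0], state.best_model(), tiny_crop_config())
        b = predict_movie(movies[0], back.best_model(), tiny_crop_config())
        np.testing.assert_array_equal(a.probabilities, b.probabilities)


class TestEndToEndTimeline:
    def test_predicted_events_close_to_truth(self, finetuned, small_cohort):
        """On a training-distribution cell the predicted timeline recovers
        most scheduled divisions within one frame."""
        from budcall.evaluation import match_rate_at

        state, _ = finetuned
        movies, truths = small_cohort
        model = state.best_model()
        probs = predict_movie(movies[0], model, tiny_crop_config())
        timeline = timeline_from_probabilities(probs.probabilities,
                                               cell_id=movies[0].cell_id)
        rate = match_rate_at(timeline, truths[0], 1)
        assert rate >= 0.5
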