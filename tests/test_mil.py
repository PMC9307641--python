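"""Attention-MIL model: pooling algebra, training, folds and grid search."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from pathomil.backbones import make_backbone
from pathomil.mil import (
    AttentionMILClassifier,
    Bag,
    MILError,
    MILHead,
    TrainConfig,
    attention_pool,
    cross_validate,
    embed_bag,
    grid_search,
    make_folds,
    patch_predict,
    predict_wsi,
    train_fold,
)
from pathomil.schema import make_label


FEATURE_DIM = 12


def feature_bag(rng, label, patient="pt0", p=5, shift=0.0, slide="s0"):
    """Bag of raw feature vectors (no tiles) around a class-dependent center."""
    features = rng.standard_normal((p, FEATURE_DIM)) + shift
    return Bag(slide_id=slide, patient_id=patient, features=features, label=label)


def separable_bags(rng, n=20, p=5):
    """Two linearly separable classes: cancer bags vs normal bags."""
    bags = []
    for i in range(n):
        if i % 2 == 0:
            label, shift = make_label({"cancer"}), 2.0
        else:
            label, shift = make_label({"normal"}), -2.0
        bags.append(
            feature_bag(rng, label, patient=f"pt{i}", p=p, shift=shift, slide=f"s{i}")
        )
    return bags


@pytest.fixture()
def head(rng):
    head = MILHead(FEATURE_DIM, embed_dim=8, rng=rng)
    head.fit_standardizer(rng.standard_normal((100, FEATURE_DIM)))
    return head


class TestEmbedBag:
    def test_single_patch_shape(self, rng, head):
        bag = feature_bag(rng, make_label({"cancer"}), p=1)
        assert embed_bag(bag, None, head).shape == (1, 8)

    def test_duplicated_patches_embed_identically(self, rng, head):
        row = rng.standard_normal(FEATURE_DIM)
        bag = Bag(
            slide_id="s",
            patient_id="p",
            features=np.tile(row, (4, 1)),
            label=make_label({"normal"}),
        )
        emb = embed_bag(bag, None, head)
        assert np.allclose(emb, emb[0])

    def test_zero_weight_embedding_is_zero(self, rng, head):
        head.params["We"][:] = 0.0
        head.params["be"][:] = 0.0
        bag = feature_bag(rng, make_label({"cancer"}))
        assert np.all(embed_bag(bag, None, head) == 0.0)

    def test_dimension_mismatch_names_sizes(self, rng, head):
        bag = Bag(
            slide_id="s",
            patient_id="p",
            features=rng.standard_normal((3, FEATURE_DIM + 1)),
            label=make_label({"cancer"}),
        )
        with pytest.raises(MILError, match=f"{FEATURE_DIM}"):
            embed_bag(bag, None, head)


class TestPatchPredict:
    def test_uniform_softmax_for_zero_logits(self, head):
        head.params["Wc"][:] = 0.0
        head.params["bc"][:] = 0.0
        probs, hard = patch_predict(np.ones((3, 8)), head)
        assert np.allclose(probs, 0.2)
        assert np.all(hard == 0)  # ties break to the lowest class index

    def test_matches_brute_force_softmax(self, rng, head):
        emb = rng.standard_normal((7, 8))
        probs, hard = patch_predict(emb, head)
        logits = emb @ head.params["Wc"] + head.params["bc"]
        expected = np.exp(logits) / np.exp(logits).sum(axis=1, keepdims=True)
        assert np.allclose(probs, expected, atol=1e-9)
        assert np.array_equal(hard, expected.argmax(axis=1))
        assert np.allclose(probs.sum(axis=1), 1.0, atol=1e-6)


class TestAttentionPool:
    def test_single_patch_weight_is_one(self, rng, head):
        emb = rng.standard_normal((1, 8))
        logits = emb @ head.params["Wc"] + head.params["bc"]
        att, probs, wsi_logits = attention_pool(emb, logits, head)
        assert np.all(att == 1.0)
        assert np.allclose(wsi_logits, logits[0])

    def test_identical_embeddings_uniform_attention(self, rng, head):
        emb = np.tile(rng.standard_normal(8), (6, 1))
        logits = emb @ head.params["Wc"] + head.params["bc"]
        att, _, _ = attention_pool(emb, logits, head)
        assert np.allclose(att, 1 / 6)

    def test_three_patch_hand_oracle(self, head):
        emb = np.array(
            [[0.5, -1.0, 0.2, 0.0, 1.0, 0.3, -0.2, 0.8],
             [1.5, 0.0, -0.7, 0.4, 0.1, -0.3, 0.9, 0.2],
             [-0.2, 0.6, 0.3, -0.5, 0.7, 0.1, 0.0, -0.9]]
        )
        logits = emb @ head.params["Wc"] + head.params["bc"]
        scores = emb @ head.params["Wa"] + head.params["ba"]
        att, probs, wsi_logits = attention_pool(emb, logits, head)
        for c in range(5):
            e = np.exp(scores[:, c] - scores[:, c].max())
            weights = e / e.sum()
            expected_logit = float(np.sum(weights * logits[:, c]))
            assert att[c] == pytest.approx(weights, abs=1e-9)
            assert wsi_logits[c] == pytest.approx(expected_logit, abs=1e-9)
            assert probs[c] == pytest.approx(1 / (1 + np.exp(-expected_logit)), abs=1e-9)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=1, max_value=40), st.integers(min_value=0, max_value=2**31 - 1))
    def test_rows_sum_to_one(self, p, seed):
        rng = np.random.default_rng(seed)
        head = MILHead(FEATURE_DIM, embed_dim=8, rng=rng)
        emb = rng.standard_normal((p, 8))
        logits = rng.standard_normal((p, 5))
        att, _, _ = attention_pool(emb, logits, head)
        assert att.shape == (5, p)
        assert np.all(att >= 0)
        assert np.allclose(att.sum(axis=1), 1.0, atol=1e-6)

    def test_shared_attention_rows_identical(self, rng):
        head = MILHead(FEATURE_DIM, embed_dim=8, shared_attention=True, rng=rng)
        emb = rng.standard_normal((4, 8))
        att, _, _ = attention_pool(emb, rng.standard_normal((4, 5)), head)
        assert np.allclose(att, att[0])

    def test_permutation_equivariance(self, rng, head):
        emb = rng.standard_normal((6, 8))
        logits = emb @ head.params["Wc"] + head.params["bc"]
        att, probs, _ = attention_pool(emb, logits, head)
        perm = rng.permutation(6)
        att_p, probs_p, _ = attention_pool(emb[perm], logits[perm], head)
        assert np.allclose(att_p, att[:, perm])
        assert np.allclose(probs_p, probs)


class TestPredictWsi:
    def test_threshold_and_multilabel_and_fallback(self, rng, head):
        bag = feature_bag(rng, make_label({"cancer"}), p=4)
        label, probs, att = predict_wsi(bag, None, head, threshold=0.5)
        expected = (probs > 0.5).astype(int)
        if expected.any():
            assert np.array_equal(label, expected)
        else:
            assert label.sum() == 1 and label[np.argmax(probs)] == 1
        # force the fallback with an unreachable threshold
        label_hi, probs_hi, _ = predict_wsi(bag, None, head, threshold=0.999999)
        assert label_hi.sum() == 1
        assert label_hi[int(np.argmax(probs_hi))] == 1

    def test_probabilities_match_attention_pool(self, rng, head):
        bag = feature_bag(rng, make_label({"normal"}), p=5)
        _, probs, att = predict_wsi(bag, None, head)
        emb = embed_bag(bag, None, head)
        logits = emb @ head.params["Wc"] + head.params["bc"]
        att2, probs2, _ = attention_pool(emb, logits, head)
        assert np.allclose(probs, probs2)
        assert np.allclose(att, att2)


class TestTrainFold:
    def test_loss_decreases_on_separable_data(self, rng):
        bags = separable_bags(rng)
        head, history = train_fold(
            bags, [], None, TrainConfig(augment=False, epochs=5), seed=0
        )
        losses = history["train_loss"]
        assert losses[1] < losses[0]
        assert losses[2] < losses[0]

    def test_seeded_determinism(self, rng):
        bags = separable_bags(rng)
        val = separable_bags(np.random.default_rng(99))
        for v, tag in zip(val, "abcdefghijklmnopqrst"):
            v.patient_id = f"val-{tag}"
        _, h1 = train_fold(bags, val, None, TrainConfig(augment=False, epochs=4), seed=5)
        _, h2 = train_fold(bags, val, None, TrainConfig(augment=False, epochs=4), seed=5)
        assert h1["train_loss"] == h2["train_loss"]
        assert h1["val_loss"] == h2["val_loss"]

    def test_validation_contributes_no_gradients(self, rng):
        bags = separable_bags(rng)
        val_a = [feature_bag(np.random.default_rng(1), make_label({"cancer"}), patient="va", slide="va")]
        val_b = [feature_bag(np.random.default_rng(2), make_label({"normal"}), patient="vb", slide="vb")]
        config = TrainConfig(augment=False, epochs=1)  # single epoch: same checkpoint
        head_a, _ = train_fold(bags, val_a, None, config, seed=3)
        head_b, _ = train_fold(bags, val_b, None, config, seed=3)
        for key in head_a.params:
            assert np.array_equal(head_a.params[key], head_b.params[key])

    def test_patient_overlap_rejected(self, rng):
        bags = separable_bags(rng)
        with pytest.raises(MILError, match="patients"):
            train_fold(bags, bags[:1], None, TrainConfig(augment=False, epochs=1))

    def test_frozen_backbone_unchanged_by_training(self, rng):
        backbone = make_backbone("tiny")
        before = backbone.fingerprint()
        tiles = rng.integers(0, 255, (3, 224, 224, 3), dtype=np.uint8)
        bags = [
            Bag(slide_id=f"s{i}", patient_id=f"p{i}", tiles=tiles, label=make_label({"cancer"}))
            for i in range(3)
        ]
        train_fold(bags, [], backbone, TrainConfig(augment=True, epochs=2), seed=0)
        assert backbone.fingerprint() == before


class TestMakeFolds:
    def test_twenty_patients_ten_folds_of_two(self):
        plan = make_folds([f"p{i}" for i in range(20)], k=10, seed=1)
        sizes = [len(plan.patients(f)) for f in range(10)]
        assert sizes == [2] * 10

    def test_partition_properties(self, rng):
        patients = [f"p{i}" for i in range(47)]
        plan = make_folds(patients, k=10, seed=3)
        seen = [p for f in range(10) for p in plan.patients(f)]
        assert sorted(seen) == sorted(patients)  # coverage, no duplicates
        sizes = [len(plan.patients(f)) for f in range(10)]
        assert max(sizes) - min(sizes) <= 1

    def test_k_larger_than_patients_rejected(self):
        with pytest.raises(MILError):
            make_folds(["a", "b"], k=3)


class TestGridSearch:
    def test_singleton_space(self, rng):
        bags = separable_bags(rng, n=8)
        folds = make_folds([b.patient_id for b in bags], k=2, seed=0)
        base = TrainConfig(augment=False, epochs=2)
        best, trials = grid_search(
            [{"learning_rate": 1e-3}], bags, None, folds, seed=0, base_config=base
        )
        assert best.learning_rate == 1e-3
        assert len(trials) == 1

    def test_dominating_config_wins_and_order_invariant(self, rng):
        bags = separable_bags(rng, n=8)
        folds = make_folds([b.patient_id for b in bags], k=2, seed=0)
        base = TrainConfig(augment=False, epochs=3)
        good = {"learning_rate": 1e-2}
        bad = {"learning_rate": 1e-12}  # stays at initialization
        best_ab, _ = grid_search([good, bad], bags, None, folds, seed=0, base_config=base)
        best_ba, _ = grid_search([bad, good], bags, None, folds, seed=0, base_config=base)
        assert best_ab.learning_rate == best_ba.learning_rate == 1e-2


class TestCrossValidate:
    def test_mean_equals_arithmetic_mean_and_two_checkpoints(self, rng):
        bags = separable_bags(rng, n=12)
        result = cross_validate(
            bags, None, TrainConfig(augment=False, epochs=3), k=2, seed=0
        )
        assert len(result["heads"]) == 2
        per_fold = [m["micro_accuracy"] for m in result["folds"]]
        assert result["micro_accuracy"]["mean"] == pytest.approx(np.mean(per_fold))
        assert result["micro_accuracy"]["std"] == pytest.approx(np.std(per_fold, ddof=1))


class TestEstimator:
    def test_sklearn_protocol_and_fit_predict(self, rng):
        bags = separable_bags(rng, n=10)
        clf = AttentionMILClassifier(
            backbone="tiny", embed_dim=8, epochs=3, augment=False, random_state=0
        )
        assert clone(clf).get_params()["embed_dim"] == 8
        clf.fit(bags)
        assert clf.head_.embed_dim == 8
        pred = clf.predict(bags)
        probs = clf.predict_proba(bags)
        assert pred.shape == (10, 5) and probs.shape == (10, 5)
        assert np.all(pred.sum(axis=1) >= 1)
        att = clf.attention(bags[0])
        assert att.shape == (5, bags[0].n_patches)
        assert np.allclose(att.sum(axis=1), 1.0, atol=1e-6)

    def test_bag_validation(self):
        with pytest.raises(MILError):
            Bag(slide_id="s", patient_id="p")  # neither tiles nor features
        with pytest.raises(MILError):
            Bag(
                slide_id="s",
                patient_id="p",
                features=np.zeros((2, 4)),
                label=np.zeros(5, dtype=np.int8),  # not finalized
            )
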