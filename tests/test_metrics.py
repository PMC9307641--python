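"""Evaluation metrics against independent brute-force oracles."""

import itertools

import numpy as np
import pytest

from pathomil.metrics import (
    MetricsError,
    UndefinedMetricError,
    cohen_kappa,
    evaluate_predictions,
    exact_match_accuracy,
    find_mislabeled,
    micro_accuracy,
    per_class_prf,
    rank_sum_test,
    roc_auc,
    weighted_f1,
)
from pathomil.schema import labels_to_frame
from pathomil.visualize import VisualizeError, attention_raster, export_latent
from pathomil.preprocess import PatchRecord


# ---------------------------------------------------------------------------
# Brute-force oracles (deliberately naive, loop-based)


def oracle_micro_accuracy(gt, pred):
    correct = total = 0
    for row_gt, row_pred in zip(gt, pred):
        for a, b in zip(row_gt, row_pred):
            correct += int(a == b)
            total += 1
    return correct / total


def oracle_prf(gt, pred, c):
    tp = sum(1 for g, p in zip(gt[:, c], pred[:, c]) if g == 1 and p == 1)
    fp = sum(1 for g, p in zip(gt[:, c], pred[:, c]) if g == 0 and p == 1)
    fn = sum(1 for g, p in zip(gt[:, c], pred[:, c]) if g == 1 and p == 0)
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return precision, recall, f1, tp + fn


def oracle_weighted_f1(gt, pred):
    values, weights = [], []
    for c in range(5):
        _, _, f1, support = oracle_prf(gt, pred, c)
        values.append(f1)
        weights.append(support)
    return sum(v * w for v, w in zip(values, weights)) / sum(weights)


def oracle_kappa(gt, pred):
    n = len(gt)
    p_o = sum(1 for a, b in zip(gt, pred) if a == b) / n
    p_e = sum(
        (sum(1 for a in gt if a == k) / n) * (sum(1 for b in pred if b == k) / n)
        for k in range(5)
    )
    if p_e == 1.0:
        return 1.0
    return (p_o - p_e) / (1 - p_e)


def oracle_auc(labels, scores):
    """Concordance probability with tie correction."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def random_table(rng, n=20):
    gt = rng.integers(0, 2, size=(n, 5))
    pred = rng.integers(0, 2, size=(n, 5))
    return gt, pred


# ---------------------------------------------------------------------------


class TestMicroAccuracy:
    def test_perfect_and_flipped(self, rng):
        gt, _ = random_table(rng)
        assert micro_accuracy(gt, gt) == 1.0
        assert micro_accuracy(gt, 1 - gt) == 0.0

    def test_toy_counts(self):
        gt = np.array([[1, 0, 0, 0, 1], [0, 1, 0, 0, 0], [0, 0, 1, 1, 0]])
        pred = gt.copy()
        pred[0, 0] = 0
        pred[2, 3] = 0
        assert micro_accuracy(gt, pred) == pytest.approx(13 / 15)

    def test_matches_oracle_on_random_tables(self, rng):
        for _ in range(100):
            gt, pred = random_table(rng)
            assert micro_accuracy(gt, pred) == pytest.approx(
                oracle_micro_accuracy(gt, pred), abs=1e-12
            )

    def test_empty_rejected(self):
        with pytest.raises(MetricsError):
            micro_accuracy(np.empty((0, 5)), np.empty((0, 5)))


class TestWeightedF1:
    def test_perfect(self, rng):
        gt, _ = random_table(rng)
        gt[0] = 1  # ensure some support
        value, _ = weighted_f1(gt, gt)
        assert value == 1.0

    def test_half_recall_single_class(self):
        gt = np.zeros((4, 5), dtype=int)
        gt[:, 0] = [1, 1, 1, 1]
        pred = np.zeros((4, 5), dtype=int)
        pred[:, 0] = [1, 1, 0, 0]  # P = 1, R = 0.5
        _, per_class = weighted_f1(gt, pred)
        assert per_class["cancer"] == pytest.approx(2 / 3)

    def test_matches_oracle_on_random_tables(self, rng):
        for _ in range(100):
            gt, pred = random_table(rng, n=50)
            if gt.sum() == 0:
                continue
            value, _ = weighted_f1(gt, pred)
            assert value == pytest.approx(oracle_weighted_f1(gt, pred), abs=1e-12)

    def test_zero_support_class_excluded(self, rng):
        gt = np.zeros((6, 5), dtype=int)
        gt[:, 0] = 1  # only cancer has support
        pred = gt.copy()
        pred[:, 3] = 1  # false positives on an unsupported class
        value, _ = weighted_f1(gt, pred)
        assert value == 1.0  # hyperplastic F1=0 carries zero weight

    def test_all_supports_zero_rejected(self):
        with pytest.raises(UndefinedMetricError):
            weighted_f1(np.zeros((3, 5), dtype=int), np.zeros((3, 5), dtype=int))


class TestCohenKappa:
    def test_complete_agreement(self, rng):
        x = rng.integers(0, 5, size=30)
        assert cohen_kappa(x, x) == 1.0

    def test_independent_predictions_near_zero(self):
        rng = np.random.default_rng(7)
        marginal = [0.3, 0.1, 0.25, 0.15, 0.2]
        gt = rng.choice(5, size=20000, p=marginal)
        pred = rng.choice(5, size=20000, p=marginal)
        assert abs(cohen_kappa(gt, pred)) < 0.02

    def test_matches_formula_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(5, 60))
            gt = rng.integers(0, 5, size=n)
            pred = rng.integers(0, 5, size=n)
            assert cohen_kappa(gt, pred) == pytest.approx(oracle_kappa(gt, pred), abs=1e-12)

    def test_invariant_to_simultaneous_relabeling(self, rng):
        gt = rng.integers(0, 5, size=80)
        pred = rng.integers(0, 5, size=80)
        perm = rng.permutation(5)
        assert cohen_kappa(perm[gt], perm[pred]) == pytest.approx(
            cohen_kappa(gt, pred), abs=1e-12
        )


class TestRocAuc:
    def test_perfect_separation(self):
        gt = np.zeros((6, 5), dtype=int)
        gt[:3, 0] = 1
        scores = np.zeros((6, 5))
        scores[:, 0] = [0.9, 0.8, 0.7, 0.3, 0.2, 0.1]
        _, area = roc_auc(gt, scores, 0)
        assert area == 1.0

    def test_constant_scores_chance(self):
        gt = np.zeros((6, 5), dtype=int)
        gt[:3, 0] = 1
        scores = np.full((6, 5), 0.5)
        _, area = roc_auc(gt, scores, 0)
        assert area == pytest.approx(0.5)

    def test_matches_concordance_oracle(self, rng):
        for _ in range(100):
            labels = rng.integers(0, 2, size=25)
            if labels.min() == labels.max():
                continue
            scores = np.round(rng.random(25), 2)  # ties likely
            gt = np.zeros((25, 5), dtype=int)
            gt[:, 2] = labels
            table = np.zeros((25, 5))
            table[:, 2] = scores
            _, area = roc_auc(gt, table, 2)
            assert area == pytest.approx(oracle_auc(labels, scores), abs=1e-9)

    def test_invariant_to_monotone_transform(self, rng):
        labels = rng.integers(0, 2, size=30)
        labels[:2] = [0, 1]
        scores = rng.random(30)
        gt = np.zeros((30, 5), dtype=int)
        gt[:, 1] = labels
        t1 = np.zeros((30, 5)); t1[:, 1] = scores
        t2 = np.zeros((30, 5)); t2[:, 1] = np.exp(3 * scores)  # strictly monotone
        assert roc_auc(gt, t1, 1)[1] == pytest.approx(roc_auc(gt, t2, 1)[1], abs=1e-12)

    def test_degenerate_class_flagged(self):
        gt = np.zeros((4, 5), dtype=int)
        with pytest.raises(UndefinedMetricError):
            roc_auc(gt, np.random.default_rng(0).random((4, 5)), 0)


class TestRankSum:
    def test_identical_samples_p_one(self):
        _, p = rank_sum_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == 1.0

    def test_extreme_shift_exact_enumeration(self):
        w, p = rank_sum_test([1, 2, 3], [10, 11, 12])
        assert w == 6.0  # minimal possible rank sum
        # enumeration oracle over C(6,3)=20 equally likely assignments
        ranks = np.arange(1, 7)
        mean_w = 3 * 7 / 2
        observed = abs(6 - mean_w)
        count = sum(
            1
            for combo in itertools.combinations(range(6), 3)
            if abs(ranks[list(combo)].sum() - mean_w) >= observed - 1e-12
        )
        assert p == pytest.approx(count / 20) == pytest.approx(0.1)

    def test_exact_and_normal_agree_at_boundary(self, rng):
        for _ in range(50):
            a = rng.normal(size=6)
            b = rng.normal(loc=0.5, size=6)  # n = 12: the branch switch point
            _, p_exact = rank_sum_test(a, b, method="exact")
            _, p_norm = rank_sum_test(a, b, method="normal")
            assert abs(p_exact - p_norm) < 0.02

    def test_normal_branch_with_ties(self):
        a = [1.0] * 8 + [2.0] * 2
        b = [1.0] * 5 + [2.0] * 5
        _, p = rank_sum_test(a, b)
        assert 0.0 < p <= 1.0

    def test_empty_rejected(self):
        with pytest.raises(MetricsError):
            rank_sum_test([], [1.0])


class TestFindMislabeled:
    def _frames(self, labels_a, labels_b):
        ids = [f"c{i}" for i in range(len(labels_a))]
        return labels_to_frame(ids, np.array(labels_a)), labels_to_frame(ids, np.array(labels_b))

    def test_identical_tables_empty(self):
        auto, gt = self._frames([[1, 0, 0, 0, 0]] * 3, [[1, 0, 0, 0, 0]] * 3)
        assert find_mislabeled(auto, gt).case_ids == []

    def test_single_flip_found(self):
        auto, gt = self._frames(
            [[1, 0, 0, 0, 0], [0, 0, 1, 0, 0]], [[1, 0, 0, 0, 0], [0, 1, 1, 0, 0]]
        )
        result = find_mislabeled(auto, gt)
        assert result.case_ids == ["c1"]
        assert result.per_class_disagreement["high_grade_dysplasia"] == 1

    def test_id_mismatch_rejected(self):
        auto, gt = self._frames([[1, 0, 0, 0, 0]], [[1, 0, 0, 0, 0]])
        gt["case_id"] = ["other"]
        with pytest.raises(MetricsError):
            find_mislabeled(auto, gt)


class TestHeatmap:
    def _records(self, coords):
        return [PatchRecord("s", x, y, 10.0, 1.0, patch_size=4) for x, y in coords]

    def test_uniform_attention_constant_overlay(self):
        records = self._records([(0, 0), (4, 0), (0, 4)])
        att = np.full((5, 3), 1 / 3)
        canvas = attention_raster((8, 8), records, att, 0)
        inside = ~np.isnan(canvas)
        assert np.all(canvas[inside] == canvas[inside][0])
        assert np.isnan(canvas[4:, 4:]).all()  # background untouched

    def test_dominant_patch_is_unique_maximum(self):
        records = self._records([(0, 0), (4, 0), (0, 4)])
        att = np.array([[0.1, 0.8, 0.1]] * 5)
        canvas = attention_raster((8, 8), records, att, 0)
        assert canvas[0, 4] == 1.0
        assert np.nanmax(canvas[:4, :4]) < 1.0

    def test_normalization_preserves_ranking(self, rng):
        coords = [(4 * i, 0) for i in range(6)]
        records = self._records(coords)
        att = rng.random((5, 6))
        canvas = attention_raster((4, 24), records, att, 2)
        painted = [canvas[0, 4 * i] for i in range(6)]
        assert np.array_equal(np.argsort(painted), np.argsort(att[2]))

    def test_misaligned_lengths_rejected(self):
        with pytest.raises(VisualizeError):
            attention_raster((8, 8), self._records([(0, 0)]), np.ones((5, 2)) / 2, 0)


class TestExportLatent:
    def test_all_below_threshold_empty(self, rng):
        emb = rng.standard_normal((10, 8))
        probs = np.full((10, 5), 0.2)
        frame = export_latent(emb, probs)
        assert len(frame) == 0

    def test_retained_count_matches_filter(self, rng):
        emb = rng.standard_normal((40, 8))
        probs = rng.dirichlet(np.ones(5) * 0.3, size=40)
        frame = export_latent(emb, probs, seed=1)
        assert len(frame) == int((probs.max(axis=1) > 0.5).sum())

    def test_seeded_determinism(self, rng):
        emb = rng.standard_normal((30, 8))
        probs = rng.dirichlet(np.ones(5) * 0.2, size=30)
        f1 = export_latent(emb, probs, seed=3)
        f2 = export_latent(emb, probs, seed=3)
        assert np.allclose(f1[["x", "y"]].to_numpy(), f2[["x", "y"]].to_numpy())


class TestReport:
    def test_full_report_fields(self, rng):
        gt, pred = random_table(rng, n=30)
        gt[0] = 1
        scores = rng.random((30, 5))
        report = evaluate_predictions(gt, pred, scores)
        d = report.to_dict()
        assert 0 <= d["micro_accuracy"] <= 1
        assert 0 <= d["weighted_f1"] <= 1
        assert len(d["per_class"]) == 5
        assert d["exact_match_accuracy"] <= d["micro_accuracy"]

    def test_exact_match_stricter_than_micro(self, rng):
        for _ in range(20):
            gt, pred = random_table(rng)
            assert exact_match_accuracy(gt, pred) <= micro_accuracy(gt, pred)
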