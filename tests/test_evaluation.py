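"""Metric oracles, exact tests, and collective scoring."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from histmark.dataset import DEFAULT_MARKERS, EncodedBatch, SiteTable
from histmark.evaluation import (
    UndefinedMetricError,
    auprc,
    auroc,
    collective_predict,
    evaluate_predictions,
    one_vs_rest_labels,
    paired_sign_test,
    wilcoxon_rank_sum_one_sided,
)
from histmark.formats_io import GenomicInterval
from histmark.network import NetworkSpec, build_network


def concordance_auroc(scores, labels):
    """Exhaustive pairwise oracle with ties counted one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1
            elif p == q:
                ties += 1
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def enumeration_auprc(scores, labels):
    """Average precision by direct precision/recall enumeration."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    n_pos = labels.sum()
    ap = 0.0
    prev_recall = 0.0
    tp = fp = 0
    i = 0
    n = len(scores)
    while i < n:
        j = i
        while j < n and sorted_scores[j] == sorted_scores[i]:
            tp += sorted_labels[j]
            fp += 1 - sorted_labels[j]
            j += 1
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


def make_table(labels):
    labels = np.asarray(labels, dtype=np.uint8)
    windows = [
        GenomicInterval("chr1", i * 200, i * 200 + 200) for i in range(labels.shape[0])
    ]
    return SiteTable("E000", DEFAULT_MARKERS, windows, labels)


class TestOneVsRest:
    def test_multilabel_row_is_positive_for_each_of_its_markers(self):
        table = make_table([[1, 1, 0, 0, 0, 0, 0], [0, 1, 0, 0, 0, 0, 0]])
        assert one_vs_rest_labels(table, DEFAULT_MARKERS[1]).tolist() == [1, 1]
        assert one_vs_rest_labels(table, DEFAULT_MARKERS[0]).tolist() == [1, 0]

    def test_other_marker_sites_are_the_negatives(self):
        table = make_table([[0, 1, 0, 0, 0, 0, 0]])
        assert one_vs_rest_labels(table, DEFAULT_MARKERS[0]).tolist() == [0]

    def test_degenerate_marker_flagged_not_scored(self):
        table = make_table([[1, 1, 0, 0, 0, 0, 0], [1, 0, 0, 0, 0, 0, 0]])
        results = evaluate_predictions(table, np.full((2, 7), 0.5))
        by_marker = {r.marker: r for r in results}
        assert np.isnan(by_marker[DEFAULT_MARKERS[0]].auroc)  # no negatives
        assert np.isnan(by_marker[DEFAULT_MARKERS[2]].auroc)  # no positives


class TestAuroc:
    def test_perfect_and_inverted_ranking(self):
        assert auroc([0.9, 0.1], [1, 0]) == 1.0
        assert auroc([0.1, 0.9], [1, 0]) == 0.0

    def test_all_tied_scores_give_half(self):
        assert auroc([0.5, 0.5, 0.5, 0.5], [1, 1, 0, 0]) == pytest.approx(0.5)

    def test_single_class_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auroc([0.5, 0.6], [1, 1])

    @given(
        st.lists(st.integers(0, 1), min_size=2, max_size=60).filter(
            lambda ls: 0 < sum(ls) < len(ls)
        ),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_concordance_oracle(self, labels, pyrandom):
        scores = [pyrandom.choice([0.1, 0.3, 0.5, 0.7, 0.9]) for _ in labels]
        assert auroc(scores, labels) == pytest.approx(
            concordance_auroc(scores, labels), abs=1e-12
        )

    def test_score_negation_complements(self, rng):
        labels = (rng.random(50) < 0.4).astype(int)
        labels[:2] = [0, 1]
        scores = rng.permutation(50) / 50.0  # tie-free
        assert auroc(scores, labels) + auroc(-scores, labels) == pytest.approx(1.0)


class TestAuprc:
    def test_perfect_separation(self):
        assert auprc([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0]) == 1.0

    def test_three_point_enumeration(self):
        assert auprc([0.9, 0.8, 0.7], [1, 0, 1]) == pytest.approx(5 / 6)

    def test_single_positive_ranked_last(self):
        scores = np.linspace(1.0, 0.1, 10)
        labels = np.zeros(10, dtype=int)
        labels[-1] = 1
        assert auprc(scores, labels) == pytest.approx(0.1)

    def test_no_positive_undefined(self):
        with pytest.raises(UndefinedMetricError):
            auprc([0.1, 0.2], [0, 0])

    def test_matches_enumeration_oracle_random(self, rng):
        for _ in range(50):
            n = int(rng.integers(5, 120))
            labels = (rng.random(n) < 0.3).astype(int)
            labels[0] = 1
            scores = rng.random(n)
            assert auprc(scores, labels) == pytest.approx(
                enumeration_auprc(scores, labels), abs=1e-10
            )


class TestPairedSignTest:
    def test_clean_sweep_is_two_to_the_minus_fifteen(self):
        assert paired_sign_test(15, 15) == pytest.approx(2**-15)

    def test_even_split_is_exactly_half(self):
        assert paired_sign_test(8, 15) == pytest.approx(0.5)

    def test_zero_wins_is_certain(self):
        assert paired_sign_test(0, 15) == pytest.approx(1.0)

    def test_tail_complement_identity(self):
        from scipy.stats import binom

        for n in (7, 15, 24):
            for k in range(1, n + 1):
                # P(X >= k) + P(X <= k-1) = 1 under the exact null
                assert paired_sign_test(k, n) + binom.cdf(k - 1, n, 0.5) == pytest.approx(1.0)

    def test_empty_after_tie_removal_undefined(self):
        with pytest.raises(UndefinedMetricError):
            paired_sign_test(0, 0)


class TestWilcoxon:
    def test_extreme_ordering_exact(self):
        assert wilcoxon_rank_sum_one_sided([5, 6, 7], [1, 2, 3]) == pytest.approx(1 / 20)

    def test_opposite_extreme_is_full_tail(self):
        # inclusive exact tail: every arrangement is at least as favorable
        assert wilcoxon_rank_sum_one_sided([1, 2, 3], [5, 6, 7]) == pytest.approx(1.0)

    def test_identical_samples_are_symmetric(self):
        assert wilcoxon_rank_sum_one_sided([1, 2, 3], [1, 2, 3]) == pytest.approx(0.5)

    def test_five_on_five_extreme(self):
        assert wilcoxon_rank_sum_one_sided(
            [0.9, 0.91, 0.92, 0.93, 0.94], [0.1, 0.2, 0.3, 0.4, 0.5]
        ) == pytest.approx(1 / 252)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum_one_sided([], [1.0])


class TestCollectivePredict:
    @staticmethod
    def constant_model(spec, prob):
        model = build_network(spec, seed=0)
        model.out_layer.W.value[...] = 0.0
        model.out_layer.b.value[...] = np.log(prob / (1 - prob))
        return model

    @pytest.fixture
    def batch(self, tiny_spec, rng):
        n = 3
        seq = np.zeros((n, 4, tiny_spec.seq_len), dtype=np.float32)
        rows = rng.integers(0, 4, size=(n, tiny_spec.seq_len))
        seq[np.arange(n)[:, None], rows, np.arange(tiny_spec.seq_len)[None, :]] = 1.0
        openness = rng.random((n, 1, tiny_spec.seq_len)).astype(np.float32)
        return EncodedBatch(seq, openness, np.zeros((n, 7), np.float32))

    def test_single_epigenome_constant_models(self, tiny_spec, batch):
        models = [self.constant_model(tiny_spec, 0.8) for _ in range(5)]
        preds = collective_predict([models], batch)
        np.testing.assert_allclose(preds, 0.8, atol=1e-6)

    def test_two_epigenomes_average(self, tiny_spec, batch):
        e1 = [self.constant_model(tiny_spec, 0.2)]
        e2 = [self.constant_model(tiny_spec, 0.8)]
        np.testing.assert_allclose(collective_predict([e1, e2], batch), 0.5, atol=1e-6)

    def test_epigenome_order_invariance(self, tiny_spec, batch):
        e1 = [build_network(tiny_spec, seed=1), build_network(tiny_spec, seed=2)]
        e2 = [build_network(tiny_spec, seed=3)]
        np.testing.assert_allclose(
            collective_predict([e1, e2], batch), collective_predict([e2, e1], batch)
        )

    def test_bounded_by_contributing_models(self, tiny_spec, batch):
        ensembles = [[build_network(tiny_spec, seed=s)] for s in range(4)]
        preds = collective_predict(ensembles, batch)
        each = np.stack([collective_predict([e], batch) for e in ensembles])
        assert (preds <= each.max(axis=0) + 1e-12).all()
        assert (preds >= each.min(axis=0) - 1e-12).all()

    def test_empty_model_list_rejected(self, batch):
        with pytest.raises(ValueError):
            collective_predict([], batch)
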