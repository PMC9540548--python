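"""Metric implementations against brute-force oracles and hand examples."""

import numpy as np
import pytest
from sklearn.metrics import (
    jaccard_score,
    label_ranking_average_precision_score,
)

import rxncontext.evaluate as ev
from rxncontext.pipeline import assign_roles, build_context

from .conftest import CTX_A, CTX_B, species


# -- independent brute-force oracles (kept deliberately naive) ---------------

def brute_topk(scores, truth, k):
    hits = 0
    for s, t in zip(scores, truth):
        ranked = sorted(range(len(s)), key=lambda j: (-s[j], j))
        hits += int(list(t).index(1) in ranked[:k])
    return hits / len(scores)


def brute_rank_curve(scores, truth, k_max):
    effective = []
    for s, t in zip(scores, truth):
        ranked = sorted(range(len(s)), key=lambda j: (-s[j], j))
        worst = max(ranked.index(j) + 1 for j in range(len(s)) if t[j])
        effective.append(worst / sum(t))
    return {
        k: sum(e <= k for e in effective) / len(effective)
        for k in range(1, k_max + 1)
    }


def brute_lrap(scores, truth):
    total = 0.0
    for s, t in zip(scores, truth):
        true_labels = [j for j in range(len(s)) if t[j]]
        per_label = []
        for y in true_labels:
            geq = [j for j in range(len(s)) if s[j] >= s[y]]
            per_label.append(
                sum(1 for j in geq if t[j]) / len(geq)
            )
        total += sum(per_label) / len(per_label)
    return total / len(scores)


def brute_jaccard(pred, truth):
    total = 0.0
    for p, t in zip(pred, truth):
        P = {j for j in range(len(p)) if p[j]}
        T = {j for j in range(len(t)) if t[j]}
        total += 1.0 if not (P | T) else len(P & T) / len(P | T)
    return total / len(pred)


def random_instance(rng, n_rows=20, n_labels=5, multi=True):
    scores = rng.random((n_rows, n_labels))
    if multi:
        truth = (rng.random((n_rows, n_labels)) < 0.3).astype(int)
        empty = truth.sum(axis=1) == 0
        truth[empty, rng.integers(0, n_labels, int(empty.sum()))] = 1
    else:
        truth = np.zeros((n_rows, n_labels), dtype=int)
        truth[np.arange(n_rows), rng.integers(0, n_labels, n_rows)] = 1
    return scores, truth


class TestTopK:
    def test_argmax_truth_gives_perfect_top1(self):
        scores = np.array([[0.7, 0.2, 0.1], [0.1, 0.8, 0.1]])
        truth = np.array([[1, 0, 0], [0, 1, 0]])
        assert ev.topk_accuracy(scores, truth, 1) == 1.0

    def test_hand_example_top1_vs_top2(self):
        scores = np.array([[0.5, 0.3, 0.2]])
        truth = np.array([[0, 1, 0]])
        assert ev.topk_accuracy(scores, truth, 1) == 0.0
        assert ev.topk_accuracy(scores, truth, 2) == 1.0

    def test_k_equal_to_label_count_is_always_one(self):
        rng = np.random.default_rng(0)
        scores, truth = random_instance(rng, multi=False)
        assert ev.topk_accuracy(scores, truth, truth.shape[1]) == 1.0

    def test_ties_prefer_lower_label_index(self):
        scores = np.array([[0.5, 0.5, 0.0]])
        assert ev.topk_accuracy(scores, np.array([[1, 0, 0]]), 1) == 1.0
        assert ev.topk_accuracy(scores, np.array([[0, 1, 0]]), 1) == 0.0

    def test_out_of_range_k_raises(self):
        scores = np.array([[0.5, 0.5]])
        truth = np.array([[1, 0]])
        for k in (0, 3):
            with pytest.raises(ValueError, match="k="):
                ev.topk_accuracy(scores, truth, k)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            scores, truth = random_instance(rng, multi=False)
            for k in (1, 2, 3):
                assert ev.topk_accuracy(scores, truth, k) == pytest.approx(
                    brute_topk(scores, truth, k), abs=1e-12
                )


class TestLRAP:
    def test_perfect_ranking_is_one(self):
        scores = np.array([[0.9, 0.8, 0.1, 0.05]])
        truth = np.array([[1, 1, 0, 0]])
        assert ev.lrap(scores, truth) == 1.0

    def test_hand_example_on_three_labels(self):
        # row 1: truths {0, 2}, both have precision 1 at their own rank;
        # row 2: single truth ranked last of 3 -> 1/3
        scores = np.array([[0.75, 0.5, 1.0], [1.0, 0.2, 0.1]])
        truth = np.array([[1, 0, 1], [0, 0, 1]])
        assert ev.lrap(scores, truth) == pytest.approx(
            (1.0 + 1.0 / 3.0) / 2.0
        )

    def test_single_truth_ranked_last_gives_one_over_l(self):
        for L in (3, 5, 8):
            scores = np.linspace(1.0, 0.1, L)[None, :]
            truth = np.zeros((1, L), dtype=int)
            truth[0, -1] = 1
            assert ev.lrap(scores, truth) == pytest.approx(1.0 / L)

    def test_row_without_truth_raises(self):
        with pytest.raises(ValueError, match="at least one true label"):
            ev.lrap(np.array([[0.5, 0.5]]), np.array([[0, 0]]))

    def test_matches_brute_force_and_sklearn(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            scores, truth = random_instance(rng)
            ours = ev.lrap(scores, truth)
            assert ours == pytest.approx(brute_lrap(scores, truth), abs=1e-12)
            assert ours == pytest.approx(
                label_ranking_average_precision_score(truth, scores),
                abs=1e-12,
            )


class TestJaccard:
    def test_exact_match_is_one(self):
        m = np.array([[1, 0, 1], [0, 1, 0]])
        assert ev.jaccard_samples(m, m) == 1.0

    def test_half_overlap_is_half(self):
        pred = np.array([[1, 1, 0]])
        truth = np.array([[1, 0, 0]])
        assert ev.jaccard_samples(pred, truth) == 0.5

    def test_empty_prediction_scores_zero(self):
        assert ev.jaccard_samples(
            np.array([[0, 0, 0]]), np.array([[1, 0, 0]])
        ) == 0.0

    def test_both_empty_counts_as_agreement(self):
        z = np.zeros((1, 3), dtype=int)
        assert ev.jaccard_samples(z, z) == 1.0

    def test_matches_brute_force_and_sklearn(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            scores, truth = random_instance(rng)
            pred = ev.threshold_positives(scores)
            ours = ev.jaccard_samples(pred, truth)
            assert ours == pytest.approx(brute_jaccard(pred, truth),
                                         abs=1e-12)
            assert ours == pytest.approx(
                jaccard_score(truth, pred, average="samples",
                              zero_division=1.0),
                abs=1e-12,
            )


class TestRankCurve:
    def test_single_truth_ranked_second_contributes_from_k2(self):
        scores = np.array([[0.9, 0.8, 0.1]])
        truth = np.array([[0, 1, 0]])
        curve = ev.rank_curve(scores, truth, 3)
        assert curve == {1: 0.0, 2: 1.0, 3: 1.0}

    def test_two_truths_ranked_1_and_4_have_effective_rank_2(self):
        scores = np.array([[0.9, 0.5, 0.4, 0.3, 0.1]])
        truth = np.array([[1, 0, 0, 1, 0]])
        curve = ev.rank_curve(scores, truth, 5)
        assert curve[1] == 0.0
        assert curve[2] == 1.0

    def test_perfect_two_truths_have_effective_rank_one(self):
        scores = np.array([[0.9, 0.8, 0.1, 0.05]])
        truth = np.array([[1, 1, 0, 0]])
        assert ev.rank_curve(scores, truth, 2)[1] == 1.0

    def test_equals_topk_for_single_truth_rows(self):
        rng = np.random.default_rng(17)
        scores, truth = random_instance(rng, multi=False)
        curve = ev.rank_curve(scores, truth, truth.shape[1])
        for k in range(1, truth.shape[1] + 1):
            assert curve[k] == pytest.approx(
                ev.topk_accuracy(scores, truth, k)
            )

    def test_matches_brute_force(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            scores, truth = random_instance(rng)
            assert ev.rank_curve(scores, truth, 5) == pytest.approx(
                brute_rank_curve(scores, truth, 5)
            )

    def test_curve_is_non_decreasing(self):
        rng = np.random.default_rng(23)
        scores, truth = random_instance(rng)
        curve = ev.rank_curve(scores, truth, 5)
        values = [curve[k] for k in sorted(curve)]
        assert values == sorted(values)


class TestSensitivitySpecificity:
    def test_perfect_predictions_give_ones(self):
        truth = np.eye(3, dtype=int)[[0, 1, 2, 0]]
        rows = ev.sensitivity_specificity(truth.astype(float), truth, "top1")
        for row in rows:
            assert row["sensitivity"] == 1.0
            assert row["specificity"] == 1.0

    def test_constant_predictor_confuses_everything(self):
        truth = np.eye(3, dtype=int)[[0, 1, 2]]
        scores = np.tile([1.0, 0.0, 0.0], (3, 1))
        rows = ev.sensitivity_specificity(scores, truth, "top1")
        assert rows[0]["sensitivity"] == 1.0
        assert rows[0]["specificity"] == 0.0   # false positive on every row
        assert rows[1]["sensitivity"] == 0.0
        assert rows[2]["sensitivity"] == 0.0

    def test_zero_support_context_reports_missing(self):
        truth = np.array([[1, 0, 0], [1, 0, 0]])
        scores = np.array([[0.9, 0.1, 0.0], [0.8, 0.1, 0.1]])
        rows = ev.sensitivity_specificity(scores, truth, "top1")
        assert rows[1]["support"] == 0
        assert rows[1]["sensitivity"] is None


class TestConfusionLikelihood:
    def test_perfect_top1_gives_identity(self):
        truth = np.eye(4, dtype=int)[[0, 1, 2, 3, 0, 2]]
        matrix = ev.confusion_likelihood(truth.astype(float), truth, k=1)
        assert np.array_equal(matrix, np.eye(4))

    def test_top3_rows_sum_to_three_for_supported_truths(self):
        rng = np.random.default_rng(29)
        scores, truth = random_instance(rng, n_rows=40, multi=False)
        matrix = ev.confusion_likelihood(scores, truth, k=3)
        supported = truth.sum(axis=0) > 0
        assert np.allclose(matrix[supported].sum(axis=1), 3.0)

    def test_support_weighted_diagonal_equals_topk_accuracy(self):
        rng = np.random.default_rng(31)
        scores, truth = random_instance(rng, n_rows=60, multi=False)
        for k in (1, 3):
            matrix = ev.confusion_likelihood(scores, truth, k=k)
            support = truth.sum(axis=0)
            weighted = (np.diag(matrix) * support).sum() / support.sum()
            assert weighted == pytest.approx(
                ev.topk_accuracy(scores, truth, k)
            )


class TestPartialAgreement:
    @pytest.fixture()
    def contexts(self, curated):
        ctx_a = build_context(assign_roles(CTX_A, curated))
        ctx_b = build_context(assign_roles(CTX_B, curated))
        return ctx_a, ctx_b

    def test_identical_contexts_agree_fully(self, contexts):
        ctx_a, _ = contexts
        score, flags = ev.partial_agreement(ctx_a, ctx_a)
        assert score == 1.0
        assert all(flags.values())

    def test_sharing_only_the_base_scores_quarter(self, curated):
        ctx_a = build_context(assign_roles(CTX_A, curated))
        variant = [
            species("CC(=O)O[Pd]OC(C)=O"),
            species("CC(C)(C)P(C(C)(C)C)C(C)(C)C"),
            CTX_A[2],                      # same base
            species("C1COCCO1", role="solvent"),
        ]
        ctx_other = build_context(assign_roles(variant, curated))
        score, flags = ev.partial_agreement(ctx_a, ctx_other)
        assert score == 0.25
        assert flags == {"catalyst": False, "ligand": False,
                         "base": True, "solvent": False}

    def test_both_missing_ligand_counts_as_agreement(self, curated):
        no_ligand_1 = build_context(assign_roles(
            [CTX_A[0], CTX_A[2], CTX_A[3]], curated))
        no_ligand_2 = build_context(assign_roles(
            [CTX_B[0], CTX_B[2], CTX_B[3]], curated))
        score, flags = ev.partial_agreement(no_ligand_1, no_ligand_2)
        assert flags["ligand"] is True
        assert score == 0.25

    def test_analysis_filters_to_rows_outside_top3(self, contexts):
        ctx_a, ctx_b = contexts
        # 5 labels; row 0 truth ranked 5th (hard), row 1 truth ranked 1st
        scores = np.array(
            [[0.5, 0.2, 0.15, 0.1, 0.05], [0.05, 0.5, 0.2, 0.15, 0.1]]
        )
        truth = np.array([[0, 0, 0, 0, 1], [0, 1, 0, 0, 0]])
        by_index = [ctx_a, ctx_b, ctx_b, ctx_b, ctx_a]
        result = ev.partial_agreement_analysis(scores, truth, by_index, k=3)
        assert result["n_rows"] == 1
        assert result["mean_score"] == 1.0  # pred ctx_a vs truth ctx_a


class TestPopularityBaselines:
    def test_uniform_truth_over_four_contexts(self):
        truth = np.eye(4, dtype=int)[[0, 1, 2, 3]]
        top1, top3 = ev.popularity_baselines([40, 30, 20, 10], truth)
        assert top1 == 0.25
        assert top3 == 0.75

    def test_truth_always_most_popular(self):
        truth = np.tile([1, 0, 0], (5, 1))
        top1, top3 = ev.popularity_baselines([9, 5, 1], truth)
        assert top1 == 1.0

    def test_top3_never_below_top1(self):
        rng = np.random.default_rng(37)
        _, truth = random_instance(rng, multi=False)
        top1, top3 = ev.popularity_baselines(rng.integers(1, 50, 5), truth)
        assert top3 >= top1


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(deadline=None, derandomize=True, max_examples=30)
@given(seed=st.integers(0, 2**31 - 1), n_rows=st.integers(2, 15),
       n_labels=st.integers(2, 8))
def test_metric_outputs_are_bounded_and_monotone(seed, n_rows, n_labels):
    rng = np.random.default_rng(seed)
    scores, truth = random_instance(rng, n_rows=n_rows, n_labels=n_labels)
    assert 0.0 <= ev.lrap(scores, truth) <= 1.0
    pred = ev.threshold_positives(scores)
    assert 0.0 <= ev.jaccard_samples(pred, truth) <= 1.0
    curve = ev.rank_curve(scores, truth, n_labels)
    values = [curve[k] for k in sorted(curve)]
    assert values == sorted(values)
    assert values[-1] == 1.0


def test_metrics_invariant_under_label_permutation():
    rng = np.random.default_rng(41)
    scores, truth = random_instance(rng, n_rows=30)
    perm = rng.permutation(truth.shape[1])
    s_p, t_p = scores[:, perm], truth[:, perm]
    assert ev.lrap(scores, truth) == pytest.approx(ev.lrap(s_p, t_p))
    pred = ev.threshold_positives(scores)
    assert ev.jaccard_samples(pred, truth) == pytest.approx(
        ev.jaccard_samples(pred[:, perm], t_p)
    )
    assert ev.rank_curve(scores, truth, 5) == pytest.approx(
        ev.rank_curve(s_p, t_p, 5)
    )


def test_evaluate_report_assembles_consistent_fields():
    rng = np.random.default_rng(43)
    scores, truth = random_instance(rng, n_rows=30)
    report = ev.evaluate_report(scores, truth, mode="multi")
    assert 0.0 <= report.lrap <= 1.0
    assert 0.0 <= report.jaccard <= 1.0
    ks = sorted(report.topk)
    assert [report.topk[k] for k in ks] == sorted(
        report.topk[k] for k in ks
    )
    values = [report.rank_curve[k] for k in sorted(report.rank_curve)]
    assert values == sorted(values)
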