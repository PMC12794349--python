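"""Evaluation metrics against hand computations, brute force and sklearn."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import settings as hsettings
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score, precision_recall_fscore_support

from amide2d import (
    classification_metrics,
    cohens_kappa,
    confusion_from_labels,
    loo_report,
    rmse,
    s_pooled,
)


class TestCohensKappa:
    def test_perfect_agreement(self):
        assert cohens_kappa([[10, 0], [0, 7]]) == pytest.approx(1.0)

    def test_chance_agreement(self):
        assert cohens_kappa([[25, 25], [25, 25]]) == pytest.approx(0.0)

    def test_hand_computed_example(self):
        assert cohens_kappa([[20, 5], [10, 15]]) == pytest.approx(0.4)

    def test_degenerate_total_agreement_convention(self):
        # every row in one class -> p_e = 1 -> kappa defined as 0
        assert cohens_kappa([[8, 0], [0, 0]]) == 0.0

    def test_matches_sklearn_on_random_labels(self):
        rng = np.random.default_rng(5)
        y1 = rng.integers(0, 3, 200)
        y2 = rng.integers(0, 3, 200)
        confusion = confusion_from_labels(y1, y2, [0, 1, 2])
        assert cohens_kappa(confusion) == pytest.approx(cohen_kappa_score(y1, y2), rel=1e-12)

    def test_empty_matrix_invalid(self):
        with pytest.raises(ValueError):
            cohens_kappa([[0, 0], [0, 0]])


class TestClassificationMetrics:
    def test_perfect_diagonal(self):
        m = classification_metrics([[5, 0], [0, 5]])
        assert m["accuracy"] == 1.0 and m["macro_f1"] == 1.0

    def test_hand_counted_example(self):
        m = classification_metrics([[20, 5], [10, 15]])
        assert m["accuracy"] == pytest.approx(0.7)
        assert m["precision"][0] == pytest.approx(20 / 30)
        assert m["recall"][0] == pytest.approx(20 / 25)

    def test_absent_truth_class_flagged_with_zero_recall(self):
        m = classification_metrics([[4, 1], [0, 0]])
        assert m["recall"][1] == 0.0
        assert m["undefined_recall"] == [1]

    def test_matches_sklearn_on_random_labels(self):
        rng = np.random.default_rng(6)
        y1 = rng.integers(0, 3, 300)
        y2 = rng.integers(0, 3, 300)
        m = classification_metrics(confusion_from_labels(y1, y2, [0, 1, 2]))
        p, r, f, _ = precision_recall_fscore_support(y1, y2, labels=[0, 1, 2], zero_division=0)
        np.testing.assert_allclose(m["precision"], p, rtol=1e-12)
        np.testing.assert_allclose(m["recall"], r, rtol=1e-12)
        np.testing.assert_allclose(m["f1"], f, rtol=1e-12)

    def test_accuracy_equals_trace_over_total(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            c = rng.integers(0, 30, (3, 3))
            if c.sum() == 0:
                continue
            assert classification_metrics(c)["accuracy"] == pytest.approx(
                np.trace(c) / c.sum()
            )


class TestRmse:
    def test_identical_vectors(self):
        assert rmse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_arithmetic(self):
        assert rmse([10.0, 20.0], [20.0, 10.0]) == pytest.approx(10.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            rmse([1.0], [1.0, 2.0])

    @hsettings(max_examples=100)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        p, t = rng.normal(size=(2, 30))
        brute = np.sqrt(sum((a - b) ** 2 for a, b in zip(p, t)) / 30)
        assert rmse(p, t) == pytest.approx(brute, rel=1e-12)


class TestSPooled:
    def test_constant_groups(self):
        assert s_pooled([[3.0, 3.0, 3.0], [1.0, 1.0]]) == 0.0

    def test_single_group_reduces_to_sample_sd(self):
        g = [1.0, 4.0, 7.0]
        assert s_pooled([g]) == pytest.approx(np.std(g, ddof=1))

    def test_hand_computed_two_groups(self):
        # sample variances 2 and 8, one dof each -> sqrt(5)
        assert s_pooled([[0.0, 2.0], [10.0, 14.0]]) == pytest.approx(np.sqrt(5.0))

    def test_small_groups_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="excluded"):
            val = s_pooled([[5.0], [0.0, 2.0]])
        assert val == pytest.approx(np.sqrt(2.0))

    def test_all_groups_too_small_invalid(self):
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError):
                s_pooled([[1.0], [2.0]])

    @hsettings(max_examples=100)
    @given(seed=st.integers(0, 10_000))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        groups = [rng.normal(size=int(n)) for n in rng.integers(2, 8, 5)]
        num = sum((len(g) - 1) * np.var(g, ddof=1) for g in groups)
        den = sum(len(g) - 1 for g in groups)
        assert s_pooled(groups) == pytest.approx(np.sqrt(num / den), rel=1e-12)


class TestLooReport:
    def test_all_correct_classification(self):
        import pandas as pd

        folds = {
            pid: pd.DataFrame({"truth": ["a"] * 4, "pred": ["a"] * 4})
            for pid in ("p1", "p2")
        }
        folds["p3"] = pd.DataFrame({"truth": ["b"] * 4, "pred": ["b"] * 4})
        rep = loo_report(folds, "class", classes=["a", "b"])
        assert all(v["accuracy"] == 1.0 for v in rep.per_protein.values())
        assert rep.aggregate["mean_protein_accuracy"] == 1.0
        assert rep.aggregate["kappa"] == pytest.approx(1.0)

    def test_regression_constant_predictions_have_zero_spread(self):
        import pandas as pd

        folds = {
            "p1": pd.DataFrame({"truth_t": [50.0] * 3, "pred_t": [48.0] * 3}),
            "p2": pd.DataFrame({"truth_t": [20.0] * 3, "pred_t": [21.0] * 3}),
        }
        rep = loo_report(folds, "fractions", targets=["t"])
        assert all(v["t"]["prediction_sd"] == 0.0 for v in rep.per_protein.values())
        assert rep.aggregate["s_pooled"]["t"] == 0.0
        assert rep.aggregate["rmse"]["t"] == pytest.approx(np.sqrt((4 + 1) / 2))
        assert rep.aggregate["rmse_protein_mean"]["t"] == pytest.approx(np.sqrt((4 + 1) / 2))

    def test_report_lists_every_protein(self):
        import pandas as pd

        folds = {
            f"p{i}": pd.DataFrame({"truth": ["a"], "pred": ["a"]}) for i in range(35)
        }
        rep = loo_report(folds, "class", classes=["a"])
        assert len(rep.per_protein) == 35
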