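"""ROC construction, threshold selection and the two-step classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import roc_auc_score

from ecosig import (
    AbundanceProfile,
    OrfSubset,
    ProfileMatrix,
    ThresholdError,
    TwoStepModel,
    classify_matrix,
    evaluate_iterations,
    roc_curve,
    score_profiles,
    select_threshold,
    two_step_classify,
)
from ecosig.classifier import HUMAN_POLLUTED, NONHUMAN_POLLUTED, UNPOLLUTED
from ecosig.pollution import ENV_BOV, ENV_HGV, ENV_PORC, ENV_U, MonteCarloIteration


def rank_sum_auc(scores, positive):
    """Pairwise-comparison oracle: P(pos > neg) + 0.5 P(tie)."""
    pos = [s for s, p in zip(scores, positive) if p]
    neg = [s for s, p in zip(scores, positive) if not p]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestScoreProfiles:
    def test_subset_sums(self, tiny_matrix):
        subset = OrfSubset("s", ("ORF_1", "ORF_3"))
        scores = score_profiles(tiny_matrix, subset)
        assert list(scores) == [1.0, 1.0, 2.0]

    def test_singleton_subset(self, tiny_matrix):
        scores = score_profiles(tiny_matrix, OrfSubset("s", ("ORF_2",)))
        assert list(scores) == [1.0, 0.0, 0.0]

    def test_universe_mismatch(self, tiny_matrix):
        with pytest.raises(KeyError):
            score_profiles(tiny_matrix, OrfSubset("s", ("ORF_99",)))

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError):
            OrfSubset("s", ())

    def test_from_numbers(self):
        s = OrfSubset.from_numbers("s2", [16, 34, 56])
        assert s.orf_ids == ("ORF_16", "ORF_34", "ORF_56")


class TestRocCurve:
    def test_perfect_separation(self):
        roc = roc_curve([10, 9, 1, 2], [True, True, False, False])
        assert roc.auc == pytest.approx(1.0)

    def test_hand_value(self):
        roc = roc_curve([3, 5, 1, 4], [True, True, False, False])
        assert roc.auc == pytest.approx(0.75)

    def test_identical_scores_give_half(self):
        roc = roc_curve([2, 2, 2, 2], [True, False, True, False])
        assert roc.auc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_curve([1, 2], [True, True])

    def test_sensitivity_monotone_along_curve(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=40)
        labels = rng.uniform(size=40) < 0.5
        labels[0], labels[1] = True, False
        roc = roc_curve(scores, labels)
        assert (np.diff(roc.sensitivity) >= 0).all()
        assert (np.diff(roc.thresholds) <= 0).all()

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.lists(st.integers(0, 6), min_size=4, max_size=30))
    def test_auc_equals_rank_sum_oracle(self, raw):
        labels = [i % 2 == 0 for i in range(len(raw))]
        roc = roc_curve([float(x) for x in raw], labels)
        assert roc.auc == pytest.approx(rank_sum_auc(raw, labels), abs=1e-12)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=60).round(1)  # rounding forces ties
        labels = rng.uniform(size=60) < 0.4
        labels[:2] = [True, False]
        roc = roc_curve(scores, labels)
        assert roc.auc == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)


class TestSelectThreshold:
    def roc_from_points(self, pts):
        thr, sens, spec = map(np.array, zip(*pts))
        return type(roc_curve([1, 0], [True, False]))(
            thr, sens, spec, auc=0.9, positive_label=True
        )

    def test_max_specificity_under_constraint(self):
        roc = self.roc_from_points(
            [(1.0, 1.0, 0.2), (5.0, 0.95, 0.8), (9.0, 0.5, 0.99)]
        )
        assert select_threshold(roc, 0.91) == 5.0

    def test_unattainable_floor_errors_with_best(self):
        roc = self.roc_from_points([(1.0, 0.8, 0.2), (2.0, 0.6, 0.9)])
        with pytest.raises(ThresholdError, match="0.8"):
            select_threshold(roc, 0.91)

    def test_perfect_curve_picks_perfect_point(self):
        roc = roc_curve([10, 9, 1, 2], [True, True, False, False])
        thr = select_threshold(roc, 0.91)
        i = list(roc.thresholds).index(thr)
        assert roc.sensitivity[i] == 1.0 and roc.specificity[i] == 1.0

    def test_specificity_tie_breaks_to_higher_sensitivity(self):
        roc = self.roc_from_points(
            [(1.0, 1.0, 0.8), (5.0, 0.95, 0.8), (9.0, 0.92, 0.7)]
        )
        assert select_threshold(roc, 0.91) == 1.0


def profile_from(values):
    return AbundanceProfile("p", pd.Series(values, dtype=float))


class TestTwoStep:
    MODEL = TwoStepModel(
        OrfSubset("s1", ("ORF_1", "ORF_2")), 1.0,
        OrfSubset("s2", ("ORF_2",)), 0.5,
    )

    def test_all_zero_is_unpolluted(self):
        p = profile_from({"ORF_1": 0.0, "ORF_2": 0.0})
        assert two_step_classify(p, self.MODEL) == UNPOLLUTED

    def test_rule_table(self):
        human = profile_from({"ORF_1": 1.0, "ORF_2": 0.6})
        animal = profile_from({"ORF_1": 2.0, "ORF_2": 0.1})
        clean = profile_from({"ORF_1": 0.4, "ORF_2": 0.1})
        assert two_step_classify(human, self.MODEL) == HUMAN_POLLUTED
        assert two_step_classify(animal, self.MODEL) == NONHUMAN_POLLUTED
        assert two_step_classify(clean, self.MODEL) == UNPOLLUTED

    def test_vectorised_matches_scalar(self, tiny_matrix):
        model = TwoStepModel(
            OrfSubset("s1", ("ORF_1", "ORF_2")), 1.0,
            OrfSubset("s2", ("ORF_3",)), 1.0,
        )
        vec = classify_matrix(tiny_matrix, model)
        for ds in tiny_matrix.dataset_ids:
            assert vec[ds] == two_step_classify(tiny_matrix.profile(ds), model)

    def test_json_roundtrip(self, tmp_path):
        path = tmp_path / "model.json"
        self.MODEL.to_json(path)
        back = TwoStepModel.from_json(path)
        assert back == self.MODEL


def iteration_from(values_by_type, orfs):
    rows, ids, types = [], [], []
    for t, rows_t in values_by_type.items():
        for i, v in enumerate(rows_t):
            rows.append(v)
            ids.append(f"{t}_{i}")
            types.append(t)
    data = pd.DataFrame(rows, index=ids, columns=orfs, dtype=float)
    meta = pd.DataFrame({"true_type": types, "strength": np.nan}, index=ids)
    return MonteCarloIteration(1, ProfileMatrix(data, meta))


class TestEvaluateIterations:
    ORFS = ["ORF_1", "ORF_2"]

    def separable_iteration(self):
        return iteration_from(
            {
                ENV_U: [[0.1, 0.0], [0.2, 0.0]],
                ENV_HGV: [[5.0, 3.0], [6.0, 4.0]],
                ENV_BOV: [[5.0, 0.0], [7.0, 0.1]],
                ENV_PORC: [[6.0, 0.0], [5.0, 0.2]],
            },
            self.ORFS,
        )

    def test_perfectly_separable_cohort_scores_one(self):
        model = TwoStepModel(OrfSubset("s1", ("ORF_1",)), 1.0,
                             OrfSubset("s2", ("ORF_2",)), 1.0)
        summary = evaluate_iterations([self.separable_iteration()], model)
        assert (summary.per_type["accuracy_mean"] == 1.0).all()
        assert (summary.per_type["accuracy_sem"] == 0.0).all()
        assert summary.step1_sensitivity == 1.0
        assert summary.step2_sensitivity == 1.0

    def test_identical_iterations_have_zero_sem(self):
        model = TwoStepModel(OrfSubset("s1", ("ORF_1",)), 1.0,
                             OrfSubset("s2", ("ORF_2",)), 1.0)
        it = self.separable_iteration()
        summary = evaluate_iterations([it, it], model)
        assert (summary.per_type["accuracy_sem"] == 0.0).all()

    def test_degenerate_model_forces_nonhuman_calls(self):
        # thr1 = 0 catches everything; thr2 = inf rejects every human call
        model = TwoStepModel(OrfSubset("s1", ("ORF_1",)), 0.0,
                             OrfSubset("s2", ("ORF_2",)), np.inf)
        summary = evaluate_iterations([self.separable_iteration()], model)
        acc = summary.per_type["accuracy_mean"]
        assert acc[ENV_HGV] == 0.0
        assert acc[ENV_BOV] == 1.0 and acc[ENV_PORC] == 1.0
        assert acc[ENV_U] == 0.0  # nothing scores below zero

    def test_raising_thr1_never_raises_sensitivity(self):
        it = self.separable_iteration()
        sens = []
        for thr1 in [0.0, 1.0, 5.5, 100.0]:
            model = TwoStepModel(OrfSubset("s1", ("ORF_1",)), thr1,
                                 OrfSubset("s2", ("ORF_2",)), 1.0)
            sens.append(evaluate_iterations([it], model).step1_sensitivity)
        assert all(a >= b for a, b in zip(sens, sens[1:]))

    def test_order_invariance_within_iteration(self):
        it = self.separable_iteration()
        perm = list(it.profiles.data.index[::-1])
        shuffled = MonteCarloIteration(1, it.profiles.select(perm))
        model = TwoStepModel(OrfSubset("s1", ("ORF_1",)), 1.0,
                             OrfSubset("s2", ("ORF_2",)), 1.0)
        a = evaluate_iterations([it], model)
        b = evaluate_iterations([shuffled], model)
        pd.testing.assert_frame_equal(a.per_type, b.per_type)

    def test_empty_iteration_list_rejected(self):
        model = TwoStepModel(OrfSubset("s1", ("ORF_1",)), 1.0,
                             OrfSubset("s2", ("ORF_2",)), 1.0)
        with pytest.raises(ValueError):
            evaluate_iterations([], model)
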