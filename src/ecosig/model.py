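"""Model/Results interface for virome-based source tracking.

:class:`TwoStepSourceTracker` is constructed from Monte-Carlo simulation
iterations (or any equivalently labelled profile sets); :meth:`fit`
calibrates the two thresholds on a designated calibration iteration's ROC
curves and evaluates the resulting classifier on the remaining iterations,
returning a :class:`SourceTrackingResults` with the fitted thresholds, ROC
curves, AUCs, held-out performance and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .classifier import (
    OrfSubset,
    PerformanceSummary,
    RocCurve,
    TwoStepModel,
    default_subset1,
    default_subset2,
    evaluate_iterations,
    roc_curve,
    score_profiles,
    select_threshold,
)
from .pollution import ENV_BOV, ENV_HGV, ENV_PORC, ENV_U, MonteCarloIteration

__all__ = ["TwoStepSourceTracker", "SourceTrackingResults"]


def calibration_rocs(
    iteration: MonteCarloIteration,
    step1_subset: OrfSubset,
    step2_subset: OrfSubset,
) -> tuple[RocCurve, RocCurve]:
    """Step-1 and step-2 ROC curves from one iteration.

    Step 1: polluted of any type (positive) versus uncontaminated ENV_U,
    scored on the step-1 subset.  Step 2: human-polluted (positive) versus
    animal-polluted, among the truly polluted profiles, scored on the
    step-2 subset.
    """
    truth = iteration.true_types
    s1 = score_profiles(iteration.profiles, step1_subset)
    polluted = truth != ENV_U
    roc1 = roc_curve(s1.values, polluted.values, positive_label=True)

    polluted_ids = list(iteration.profiles.data.index[polluted.values])
    sub = iteration.profiles.select(polluted_ids)
    s2 = score_profiles(sub, step2_subset)
    human = (truth.loc[polluted_ids] == ENV_HGV).values
    roc2 = roc_curve(s2.values, human, positive_label=True)
    return roc1, roc2


class TwoStepSourceTracker:
    """Two-step pollution detection / human attribution model.

    Parameters
    ----------
    iterations
        Monte-Carlo iterations; one is used for calibration, the rest for
        evaluation.
    step1_subset, step2_subset
        ORF subsets scored in each step.  Defaults are the gut-affiliated
        detection set (15 ORFs) and the human-specific attribution set
        (ORFs 16, 34, 56).
    calibration_index
        Positional index of the calibration iteration (default 0, i.e.,
        the first).
    """

    def __init__(
        self,
        iterations: Sequence[MonteCarloIteration],
        step1_subset: OrfSubset | None = None,
        step2_subset: OrfSubset | None = None,
        calibration_index: int = 0,
    ):
        if not iterations:
            raise ValueError("need at least one iteration")
        if not 0 <= calibration_index < len(iterations):
            raise ValueError("calibration_index out of range")
        self.iterations = list(iterations)
        self.step1_subset = step1_subset or default_subset1()
        self.step2_subset = step2_subset or default_subset2()
        self.calibration_index = calibration_index

    @property
    def calibration_iteration(self) -> MonteCarloIteration:
        return self.iterations[self.calibration_index]

    @property
    def evaluation_iterations(self) -> list[MonteCarloIteration]:
        its = [
            it for i, it in enumerate(self.iterations)
            if i != self.calibration_index
        ]
        # with a single iteration, evaluate on the calibration data itself
        return its or [self.calibration_iteration]

    def fit(self, min_sensitivity: float = 0.91) -> "SourceTrackingResults":
        """Calibrate thresholds and evaluate on held-out iterations.

        Each threshold maximises specificity among ROC points with
        sensitivity >= ``min_sensitivity``.
        """
        roc1, roc2 = calibration_rocs(
            self.calibration_iteration, self.step1_subset, self.step2_subset
        )
        thr1 = select_threshold(roc1, min_sensitivity)
        thr2 = select_threshold(roc2, min_sensitivity)
        spec = TwoStepModel(self.step1_subset, thr1, self.step2_subset, thr2)
        performance = evaluate_iterations(self.evaluation_iterations, spec)
        return SourceTrackingResults(
            model=self,
            thresholds=spec,
            roc_step1=roc1,
            roc_step2=roc2,
            performance=performance,
            min_sensitivity=min_sensitivity,
        )


@dataclass
class SourceTrackingResults:
    """Fitted thresholds, calibration ROC curves and held-out performance."""

    model: TwoStepSourceTracker
    thresholds: TwoStepModel
    roc_step1: RocCurve
    roc_step2: RocCurve
    performance: PerformanceSummary
    min_sensitivity: float

    @property
    def auc(self) -> pd.Series:
        return pd.Series(
            {"step1": self.roc_step1.auc, "step2": self.roc_step2.auc}
        )

    def summary(self) -> str:
        m = self.model
        t = self.thresholds
        n_eval = len(m.evaluation_iterations)
        lines = [
            "Two-step ecogenomic source-tracking model",
            "=" * 57,
            f"Iterations: {len(m.iterations)} "
            f"(calibration: #{m.calibration_index + 1}, evaluation: {n_eval})",
            f"Sensitivity floor for threshold selection: {self.min_sensitivity}",
            "",
            f"Step 1 (pollution detection)  subset {t.step1_subset.name!r} "
            f"({len(t.step1_subset)} ORFs)",
            f"  AUC = {self.roc_step1.auc:.4f}   "
            f"threshold = {t.step1_threshold:.4f} hits/Mb",
            f"Step 2 (human attribution)    subset {t.step2_subset.name!r} "
            f"({len(t.step2_subset)} ORFs)",
            f"  AUC = {self.roc_step2.auc:.4f}   "
            f"threshold = {t.step2_threshold:.4f} hits/Mb",
            "",
            "Held-out accuracy by true type (mean +/- SEM over iterations):",
        ]
        for ttype, row in self.performance.per_type.iterrows():
            lines.append(
                f"  {ttype:<9s} {row['accuracy_mean']:.4f} "
                f"+/- {row['accuracy_sem']:.4f}"
            )
        p = self.performance
        lines += [
            "",
            f"Pooled step-1 sensitivity = {p.step1_sensitivity:.4f}, "
            f"specificity = {p.step1_specificity:.4f}",
            f"Pooled step-2 sensitivity = {p.step2_sensitivity:.4f}, "
            f"specificity = {p.step2_specificity:.4f}",
        ]
        return "\n".join(lines)

    def __str__(self) -> str:
        return self.summary()
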