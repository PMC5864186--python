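"""ROC-thresholded two-step detection and attribution of faecal pollution.

Profiles are scored by cumulative (raw, untransformed) relative abundance
over an ORF subset.  Step 1 bins a profile as polluted when its score over
the pollution-detection subset reaches a threshold; step 2 bins polluted
profiles as human- versus non-human-polluted with a second subset and
threshold.  Thresholds come from ROC curves built on a calibration
iteration, maximising specificity subject to a minimum sensitivity
(default 0.91).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .pollution import ENV_BOV, ENV_HGV, ENV_PORC, ENV_U, MonteCarloIteration
from .profiles import AbundanceProfile, ProfileMatrix, cumulative_abundance

__all__ = [
    "SUBSET1_ORF_NUMBERS",
    "SUBSET2_ORF_NUMBERS",
    "UNPOLLUTED",
    "HUMAN_POLLUTED",
    "NONHUMAN_POLLUTED",
    "OrfSubset",
    "RocCurve",
    "TwoStepModel",
    "PerformanceSummary",
    "ThresholdError",
    "score_profiles",
    "roc_curve",
    "select_threshold",
    "two_step_classify",
    "classify_matrix",
    "evaluate_iterations",
    "default_subset1",
    "default_subset2",
]

#: ORFs with significantly greater mean relative abundance in human gut
#: viromes than environmental viromes (pollution detection, step 1).
SUBSET1_ORF_NUMBERS = (5, 16, 18, 20, 21, 22, 23, 25, 34, 36, 43, 44, 59, 61, 67)
#: ORFs significantly enriched in human gut viromes versus *all* other
#: virome groups (human attribution, step 2).
SUBSET2_ORF_NUMBERS = (16, 34, 56)

UNPOLLUTED = "unpolluted"
HUMAN_POLLUTED = "human_polluted"
NONHUMAN_POLLUTED = "nonhuman_polluted"

#: Expected classification per true simulation label.
_CORRECT = {
    ENV_U: UNPOLLUTED,
    ENV_HGV: HUMAN_POLLUTED,
    ENV_BOV: NONHUMAN_POLLUTED,
    ENV_PORC: NONHUMAN_POLLUTED,
}


class ThresholdError(ValueError):
    """No ROC point satisfies the sensitivity constraint."""


@dataclass(frozen=True)
class OrfSubset:
    """A named set of ORF identifiers used for scoring."""

    name: str
    orf_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.orf_ids:
            raise ValueError("OrfSubset must be non-empty")

    @classmethod
    def from_numbers(
        cls, name: str, numbers: Iterable[int], prefix: str = "ORF_"
    ) -> "OrfSubset":
        return cls(name, tuple(f"{prefix}{n}" for n in numbers))

    def __len__(self) -> int:
        return len(self.orf_ids)


def default_subset1(prefix: str = "ORF_") -> OrfSubset:
    return OrfSubset.from_numbers("subset1", SUBSET1_ORF_NUMBERS, prefix)


def default_subset2(prefix: str = "ORF_") -> OrfSubset:
    return OrfSubset.from_numbers("subset2", SUBSET2_ORF_NUMBERS, prefix)


def score_profiles(matrix: ProfileMatrix, subset: OrfSubset) -> pd.Series:
    """Cumulative raw abundance over ``subset`` for every profile, in order."""
    return matrix.cumulative(subset.orf_ids)


@dataclass
class RocCurve:
    """ROC points (threshold, sensitivity, specificity) plus trapezoidal AUC.

    Points are ordered by decreasing threshold (so sensitivity is
    non-decreasing along the curve); prediction is positive iff
    score >= threshold.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    positive_label: object = True

    @property
    def points(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )

    def plot(self, ax=None, label: str | None = None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        lab = label or f"AUC = {self.auc:.3f}"
        ax.plot(1 - self.specificity, self.sensitivity, marker=".", label=lab)
        ax.plot([0, 1], [0, 1], ls="--", c="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.legend()
        return ax


def roc_curve(scores, labels, positive_label=True) -> RocCurve:
    """ROC over thresholds swept through the distinct scores plus +/- infinity.

    At threshold t a profile is predicted positive iff its score >= t.  AUC
    is the trapezoidal area over (1 - specificity, sensitivity), which
    equals the probability that a random positive outscores a random
    negative, counting ties as one half.
    """
    scores = np.asarray(scores, dtype=float)
    pos = np.asarray([l == positive_label for l in labels])
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    thresholds = np.concatenate(
        ([np.inf], np.unique(scores)[::-1], [-np.inf])
    )
    tp = np.array([(scores[pos] >= t).sum() for t in thresholds], dtype=float)
    fp = np.array([(scores[~pos] >= t).sum() for t in thresholds], dtype=float)
    sens = tp / n_pos
    spec = 1.0 - fp / n_neg
    auc = float(np.trapezoid(sens, 1.0 - spec))
    return RocCurve(thresholds, sens, spec, auc, positive_label)


def select_threshold(roc: RocCurve, min_sensitivity: float = 0.91) -> float:
    """Best threshold: maximum specificity subject to the sensitivity floor.

    Ties in specificity break toward higher sensitivity, then toward the
    higher threshold.  Raises :class:`ThresholdError` (naming the best
    attainable sensitivity) when no point meets the constraint.
    """
    eps = 1e-12
    ok = roc.sensitivity >= min_sensitivity - eps
    if not ok.any():
        raise ThresholdError(
            f"no ROC point reaches sensitivity {min_sensitivity}; "
            f"best attainable is {roc.sensitivity.max():.4f}"
        )
    cand = np.flatnonzero(ok)
    keys = [
        (roc.specificity[i], roc.sensitivity[i], roc.thresholds[i]) for i in cand
    ]
    best = cand[max(range(len(cand)), key=lambda j: keys[j])]
    return float(roc.thresholds[best])


@dataclass
class TwoStepModel:
    """Calibrated two-step classifier: (subset, threshold) per step."""

    step1_subset: OrfSubset
    step1_threshold: float
    step2_subset: OrfSubset
    step2_threshold: float

    def __post_init__(self) -> None:
        if self.step1_threshold < 0 or self.step2_threshold < 0:
            raise ValueError("thresholds must be >= 0")

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "step1": {
                "name": self.step1_subset.name,
                "orfs": list(self.step1_subset.orf_ids),
                "threshold": self.step1_threshold,
            },
            "step2": {
                "name": self.step2_subset.name,
                "orfs": list(self.step2_subset.orf_ids),
                "threshold": self.step2_threshold,
            },
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "TwoStepModel":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        payload = json.loads(text)
        return cls(
            OrfSubset(payload["step1"].get("name", "step1"),
                      tuple(payload["step1"]["orfs"])),
            float(payload["step1"]["threshold"]),
            OrfSubset(payload["step2"].get("name", "step2"),
                      tuple(payload["step2"]["orfs"])),
            float(payload["step2"]["threshold"]),
        )


def two_step_classify(profile: AbundanceProfile, model: TwoStepModel) -> str:
    """Classify one profile as unpolluted / human_polluted / nonhuman_polluted."""
    score1 = cumulative_abundance(profile, model.step1_subset.orf_ids)
    if score1 < model.step1_threshold:
        return UNPOLLUTED
    score2 = cumulative_abundance(profile, model.step2_subset.orf_ids)
    return HUMAN_POLLUTED if score2 >= model.step2_threshold else NONHUMAN_POLLUTED


def classify_matrix(matrix: ProfileMatrix, model: TwoStepModel) -> pd.Series:
    """Vectorised :func:`two_step_classify` over a profile matrix."""
    s1 = score_profiles(matrix, model.step1_subset)
    s2 = score_profiles(matrix, model.step2_subset)
    out = np.where(
        s1 < model.step1_threshold,
        UNPOLLUTED,
        np.where(s2 >= model.step2_threshold, HUMAN_POLLUTED, NONHUMAN_POLLUTED),
    )
    return pd.Series(out, index=matrix.data.index, name="classification")


@dataclass
class PerformanceSummary:
    """Per-type accuracy (mean and SEM over iterations) plus pooled step rates.

    ``per_iteration`` holds one row per iteration with one accuracy column
    per true type; ``per_type`` summarises mean and SEM across iterations.
    Pooled rates aggregate individual data sets over all iterations:
    step-1 sensitivity (truly polluted classified polluted), step-1
    specificity (ENV_U classified unpolluted), step-2 sensitivity (human
    pollution called human among correctly detected polluted sets) and
    step-2 specificity (animal pollution called non-human likewise).
    """

    per_iteration: pd.DataFrame
    per_type: pd.DataFrame
    step1_sensitivity: float
    step1_specificity: float
    step2_sensitivity: float
    step2_specificity: float

    def __str__(self) -> str:
        lines = ["Two-step classification performance", str(self.per_type.round(4))]
        lines.append(
            f"pooled step 1: sensitivity {self.step1_sensitivity:.4f}, "
            f"specificity {self.step1_specificity:.4f}"
        )
        lines.append(
            f"pooled step 2: sensitivity {self.step2_sensitivity:.4f}, "
            f"specificity {self.step2_specificity:.4f}"
        )
        return "\n".join(lines)


def evaluate_iterations(
    iterations: Sequence[MonteCarloIteration], model: TwoStepModel
) -> PerformanceSummary:
    """Accuracy of ``model`` per true type, per iteration, plus pooled rates."""
    if not iterations:
        raise ValueError("need at least one iteration")
    acc_rows = {}
    pooled = {"polluted_total": 0, "polluted_called": 0, "envu_total": 0,
              "envu_correct": 0, "hgv_detected": 0, "hgv_called_human": 0,
              "animal_detected": 0, "animal_called_nonhuman": 0}
    for it in iterations:
        pred = classify_matrix(it.profiles, model)
        truth = it.true_types
        row = {}
        for t in (ENV_U, ENV_HGV, ENV_BOV, ENV_PORC):
            mask = truth == t
            if not mask.any():
                continue
            row[t] = float((pred[mask.values] == _CORRECT[t]).mean())
        acc_rows[it.index] = row

        polluted = truth != ENV_U
        called_polluted = pred != UNPOLLUTED
        pooled["polluted_total"] += int(polluted.sum())
        pooled["polluted_called"] += int((polluted.values & called_polluted.values).sum())
        pooled["envu_total"] += int((~polluted).sum())
        pooled["envu_correct"] += int(((~polluted.values) & (~called_polluted.values)).sum())
        hgv_det = (truth == ENV_HGV).values & called_polluted.values
        pooled["hgv_detected"] += int(hgv_det.sum())
        pooled["hgv_called_human"] += int((hgv_det & (pred == HUMAN_POLLUTED).values).sum())
        animal_det = truth.isin([ENV_BOV, ENV_PORC]).values & called_polluted.values
        pooled["animal_detected"] += int(animal_det.sum())
        pooled["animal_called_nonhuman"] += int(
            (animal_det & (pred == NONHUMAN_POLLUTED).values).sum()
        )

    per_iteration = pd.DataFrame(acc_rows).T.sort_index()
    per_iteration.index.name = "iteration"
    mean = per_iteration.mean()
    n = len(per_iteration)
    sem = (per_iteration.std(ddof=1) / np.sqrt(n)) if n > 1 else mean * 0.0
    per_type = pd.DataFrame({"accuracy_mean": mean, "accuracy_sem": sem})
    per_type.index.name = "true_type"

    def _rate(num: int, den: int) -> float:
        return num / den if den else float("nan")

    return PerformanceSummary(
        per_iteration=per_iteration,
        per_type=per_type,
        step1_sensitivity=_rate(pooled["polluted_called"], pooled["polluted_total"]),
        step1_specificity=_rate(pooled["envu_correct"], pooled["envu_total"]),
        step2_sensitivity=_rate(pooled["hgv_called_human"], pooled["hgv_detected"]),
        step2_specificity=_rate(pooled["animal_called_nonhuman"], pooled["animal_detected"]),
    )
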