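"""Habitat-group comparison statistics for per-ORF gut affiliation.

Per ORF, relative abundances are compared across habitat groups with the
Kruskal-Wallis test followed by Dunn's post hoc z-tests with family-wise
multiplicity correction.  An ORF is a pollution-detection candidate when its
abundance in the focal group (human gut viromes) is significantly greater
than in environmental viromes, and a human-attribution candidate when it is
significantly greater than in every other group.  Reported group means use
the shifted log transform log10(y + 1e-5); the tests themselves are
rank-based and therefore identical on raw and log-transformed values.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .profiles import ProfileMatrix

__all__ = [
    "PSEUDO_COUNT",
    "OrfAffiliationTable",
    "log10_shift",
    "kruskal_wallis",
    "dunn_posthoc",
    "orf_affiliation",
]

#: Shift added before log10 so absent ORFs (0 hits/Mb) map to -5.
PSEUDO_COUNT = 1e-5


def log10_shift(x, epsilon: float = PSEUDO_COUNT):
    """log10(x + epsilon) for non-negative abundances (scalar or array)."""
    arr = np.asarray(x, dtype=float)
    if (arr < 0).any():
        raise ValueError("abundances must be >= 0")
    out = np.log10(arr + epsilon)
    if np.isscalar(x) or arr.ndim == 0:
        return float(out)
    if isinstance(x, pd.Series):
        return pd.Series(out, index=x.index)
    if isinstance(x, pd.DataFrame):
        return pd.DataFrame(out, index=x.index, columns=x.columns)
    return out


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and chi-square p over value groups.

    All-identical values return (H=0, p=1) with a warning instead of an
    error, so tie-degenerate ORFs do not abort a genome-wide scan.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group needs at least 1 value")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need at least 3 values in total")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical; Kruskal-Wallis H = 0, p = 1")
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def dunn_posthoc(
    groups,
    labels=None,
    method: str = "bonferroni",
) -> pd.DataFrame:
    """Dunn's pairwise z-tests on pooled ranks with tie correction.

    For each pair (i, j): z = (mean_rank_i - mean_rank_j) / sqrt(
    (N(N+1)/12 - T/(12(N-1))) (1/n_i + 1/n_j)) with T = sum(t^3 - t) over
    tie groups.  Two-sided normal p-values are adjusted family-wise:
    ``bonferroni`` multiplies by the number of comparisons (capped at 1,
    the convention of common GUI statistics software), ``holm`` applies the
    step-down variant, ``none`` leaves them unadjusted.

    Returns a frame with one row per pair: group_i, group_j, z,
    p_unadjusted, p_adjusted.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if labels is None:
        labels = list(range(k))
    labels = list(labels)
    if len(labels) != k:
        raise ValueError("labels length must match number of groups")

    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [
        ranks[bounds[i]: bounds[i + 1]].mean() for i in range(k)
    ]

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    base_var = n * (n + 1) / 12.0 - tie_term / (12.0 * (n - 1))

    rows = []
    for i, j in itertools.combinations(range(k), 2):
        var = base_var * (1.0 / sizes[i] + 1.0 / sizes[j])
        if var <= 0:
            z, p = 0.0, 1.0
            warnings.warn("degenerate (all-tied) data in Dunn comparison")
        else:
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var)
            p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group_i": labels[i], "group_j": labels[j],
                     "z": float(z), "p_unadjusted": float(min(p, 1.0))})
    out = pd.DataFrame(rows)

    if method == "none":
        out["p_adjusted"] = out["p_unadjusted"]
    elif method == "bonferroni":
        out["p_adjusted"] = np.minimum(out["p_unadjusted"] * len(out), 1.0)
    elif method == "holm":
        out["p_adjusted"] = multipletests(out["p_unadjusted"], method="holm")[1]
    else:
        raise ValueError(f"unknown adjustment method {method!r}")
    return out


@dataclass
class OrfAffiliationTable:
    """Per-ORF affiliation summary.

    ``table`` has one row per ORF: per-group mean log10(hits/Mb + 1e-5),
    overall representation fraction (share of data sets with abundance > 0),
    the Kruskal-Wallis p, the adjusted Dunn p of the focal group against
    each comparison group, and flags: ``cosmopolitan`` (representation >=
    ``min_representation``), ``gt_env`` (focal significantly greater than
    the environmental-virome group; pollution-detection candidate) and
    ``gt_all`` (focal significantly greater than every other group;
    human-attribution candidate).
    """

    table: pd.DataFrame
    focal_group: str
    env_group: str
    alpha: float
    min_representation: float

    @property
    def gt_env_orfs(self) -> list[str]:
        return list(self.table.index[self.table["gt_env"]])

    @property
    def gt_all_orfs(self) -> list[str]:
        return list(self.table.index[self.table["gt_all"]])

    def to_csv(self, path) -> None:
        out = self.table.copy()
        out.index.name = "orf_id"
        out.to_csv(path)


def orf_affiliation(
    matrix: ProfileMatrix,
    focal_group: str = "human_gut_virome",
    env_group: str = "env_virome",
    alpha: float = 0.05,
    min_representation: float = 0.5,
    adjust: str = "bonferroni",
    require_omnibus: bool = True,
) -> OrfAffiliationTable:
    """Per-ORF habitat-affiliation scan over a labelled profile matrix.

    Dunn's tests are run (and flags set) only for ORFs whose omnibus
    Kruskal-Wallis test is significant at ``alpha`` when
    ``require_omnibus`` is set, the usual post hoc convention.  Direction
    is taken from the Dunn z sign (focal mean rank greater), so flags are
    invariant to any strictly monotone transform of the abundances.
    """
    groups = matrix.groups
    group_names = list(pd.unique(groups))
    if focal_group not in group_names:
        raise ValueError(f"focal group {focal_group!r} absent from matrix")
    if env_group not in group_names:
        raise ValueError(f"environmental group {env_group!r} absent from matrix")
    others = [g for g in group_names if g != focal_group]

    rows = {}
    for orf in matrix.orf_ids:
        values = matrix.data[orf]
        by_group = [values[(groups == g).values].values for g in group_names]
        row: dict[str, float | bool] = {
            f"mean_log10_{g}": float(np.mean(log10_shift(v)))
            for g, v in zip(group_names, by_group)
        }
        row["representation"] = float((values > 0).mean())
        h, p_kw = kruskal_wallis(by_group)
        row["kw_H"], row["kw_p"] = h, p_kw

        gate_open = (p_kw <= alpha) or not require_omnibus
        sig_greater: dict[str, bool] = {g: False for g in others}
        for g in others:
            row[f"p_adj_vs_{g}"] = np.nan
        if gate_open:
            dunn = dunn_posthoc(by_group, labels=group_names, method=adjust)
            for g in others:
                pair = dunn[
                    ((dunn.group_i == focal_group) & (dunn.group_j == g))
                    | ((dunn.group_i == g) & (dunn.group_j == focal_group))
                ].iloc[0]
                # z is mean_rank(group_i) - mean_rank(group_j)
                focal_first = pair.group_i == focal_group
                z_focal = pair.z if focal_first else -pair.z
                row[f"p_adj_vs_{g}"] = float(pair.p_adjusted)
                sig_greater[g] = bool(pair.p_adjusted <= alpha and z_focal > 0)
        row["cosmopolitan"] = bool(row["representation"] >= min_representation)
        row["gt_env"] = sig_greater[env_group]
        row["gt_all"] = all(sig_greater[g] for g in others)
        rows[orf] = row

    table = pd.DataFrame(rows).T
    for col in ("cosmopolitan", "gt_env", "gt_all"):
        table[col] = table[col].astype(bool)
    return OrfAffiliationTable(
        table, focal_group, env_group, alpha, min_representation
    )
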