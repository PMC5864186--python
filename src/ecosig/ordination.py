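"""Unsupervised ordination of ecogenomic profiles: Bray-Curtis, nMDS, ANOSIM.

Abundance profiles are square-root transformed before Bray-Curtis
dissimilarities are computed; non-metric multidimensional scaling (nMDS)
embeds the dissimilarity matrix in few dimensions by minimising Kruskal
stress-1 over monotone-regressed disparities, taking the best of many random
starts; ANOSIM tests separation of a priori habitat groups by comparing
between- versus within-group distance ranks under label permutation.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from skbio import DistanceMatrix
from sklearn.isotonic import IsotonicRegression

from .profiles import ProfileMatrix

__all__ = [
    "OrdinationResult",
    "AnosimResult",
    "sqrt_transform",
    "bray_curtis",
    "nmds",
    "kruskal_stress",
    "anosim",
]


def sqrt_transform(matrix: ProfileMatrix | pd.DataFrame):
    """Elementwise square root of a non-negative abundance matrix.

    The transform damps the influence of dominant ORFs before distance
    computation, as is conventional for community dissimilarity analyses.
    """
    data = matrix.data if isinstance(matrix, ProfileMatrix) else matrix
    if (data.values < 0).any():
        raise ValueError("abundance values must be >= 0")
    out = np.sqrt(data)
    if isinstance(matrix, ProfileMatrix):
        return ProfileMatrix(out, matrix.meta)
    return out


def bray_curtis(matrix: ProfileMatrix | pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity matrix d(u,v) = sum|u-v| / sum(u+v).

    Pairs whose abundances sum to zero (two all-zero profiles) are assigned
    d = 0 by convention and flagged with a warning.
    """
    data = matrix.data if isinstance(matrix, ProfileMatrix) else matrix
    if len(data) < 2:
        raise ValueError("need at least 2 profiles")
    if (data.values < 0).any():
        raise ValueError("abundance values must be >= 0")
    x = data.values
    with np.errstate(invalid="ignore", divide="ignore"):
        condensed = pdist(x, metric="braycurtis")
    bad = ~np.isfinite(condensed)
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} profile pair(s) with zero total abundance; "
            "their Bray-Curtis distance is set to 0 by convention"
        )
        condensed[bad] = 0.0
    return DistanceMatrix(squareform(condensed), ids=[str(i) for i in data.index])


# ---------------------------------------------------------------------------
# non-metric MDS
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """Best nMDS configuration over random starts.

    ``coordinates`` is an n x k frame (rows = data sets) centred at the
    origin; ``stress`` is Kruskal stress-1 of that configuration.
    """

    coordinates: pd.DataFrame
    stress: float
    n_starts: int
    converged: bool

    def plot(self, groups: pd.Series | None = None, ax=None):
        """Scatter the first two ordination axes, optionally coloured by group."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        xy = self.coordinates.iloc[:, :2]
        if groups is None:
            ax.scatter(xy.iloc[:, 0], xy.iloc[:, 1], s=12)
        else:
            groups = groups.reindex(xy.index)
            for name, sub in xy.groupby(groups):
                ax.scatter(sub.iloc[:, 0], sub.iloc[:, 1], s=12, label=str(name))
            ax.legend(fontsize="small")
        ax.set_xlabel("nMDS1")
        ax.set_ylabel("nMDS2")
        ax.set_title(f"nMDS (stress = {self.stress:.3f})")
        return ax


def _stress_and_disparities(delta: np.ndarray, d: np.ndarray, iso: IsotonicRegression):
    """Kruskal stress-1 of configuration distances d against dissimilarities delta."""
    disparities = iso.fit_transform(delta, d)
    denom = float(np.sum(d**2))
    if denom == 0.0:
        return np.inf, disparities
    stress = float(np.sqrt(np.sum((d - disparities) ** 2) / denom))
    return stress, disparities


def kruskal_stress(dist: DistanceMatrix, coordinates: pd.DataFrame | np.ndarray) -> float:
    """Stress-1 of an arbitrary configuration against a dissimilarity matrix."""
    coords = np.asarray(coordinates, dtype=float)
    delta = dist.condensed_form()
    d = pdist(coords)
    stress, _ = _stress_and_disparities(delta, d, IsotonicRegression(increasing=True))
    return stress


def _single_start(
    delta: np.ndarray, n: int, k: int, rng: np.random.Generator,
    max_iter: int, tol: float,
):
    iso = IsotonicRegression(increasing=True)
    X = rng.uniform(-1.0, 1.0, size=(n, k))
    prev = np.inf
    converged = False
    stress = np.inf
    for _ in range(max_iter):
        d = pdist(X)
        stress, disparities = _stress_and_disparities(delta, d, iso)
        if not np.isfinite(stress):
            break
        if prev - stress < tol:
            converged = True
            break
        prev = stress
        # Guttman transform toward the monotone-regressed disparities
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, disparities / d, 0.0)
        B = -squareform(ratio)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = B.dot(X) / n
        X -= X.mean(axis=0)
    return stress, X - X.mean(axis=0), converged


def nmds(
    dist: DistanceMatrix,
    k: int = 2,
    n_starts: int = 1000,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int | np.random.Generator | None = None,
) -> OrdinationResult:
    """Non-metric MDS by SMACOF-style majorization with isotonic disparities.

    Runs ``n_starts`` random initialisations and returns the configuration
    with the lowest Kruskal stress-1; deterministic for a given seed.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if n_starts < 1:
        raise ValueError("n_starts must be >= 1")
    delta = dist.condensed_form()
    n = dist.shape[0]
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed

    best = (np.inf, None, False)
    for _ in range(n_starts):
        stress, X, converged = _single_start(delta, n, k, rng, max_iter, tol)
        if stress < best[0]:
            best = (stress, X, converged)
    stress, X, converged = best
    if X is None:  # every start degenerate (e.g. all-zero distances)
        X = np.zeros((n, k))
        stress = 0.0
        converged = True
    coords = pd.DataFrame(
        X, index=list(dist.ids), columns=[f"nMDS{i + 1}" for i in range(k)]
    )
    return OrdinationResult(coords, float(stress), n_starts, converged)


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

@dataclass
class AnosimResult:
    """ANOSIM R statistic and permutation significance.

    R approaches 1 as between-group distances increasingly exceed
    within-group distances; R near 0 indicates no separation.  ``p_value``
    is the permutation p; with ``n_permutations`` random permutations the
    smallest attainable p is 1/(n_permutations + 1).
    """

    r: float
    p_value: float
    n_permutations: int
    group_labels: tuple

    def __str__(self) -> str:
        return (
            f"ANOSIM R = {self.r:.4f}, p = {self.p_value:.4g} "
            f"({self.n_permutations} permutations; groups: "
            f"{', '.join(map(str, self.group_labels))})"
        )


def _anosim_r(ranks: np.ndarray, within: np.ndarray, denom: float) -> float:
    between_mean = ranks[~within].mean()
    within_mean = ranks[within].mean()
    return (between_mean - within_mean) / denom


def anosim(
    dist: DistanceMatrix,
    grouping,
    n_permutations: int | str = 999,
    seed: int | np.random.Generator | None = None,
) -> AnosimResult:
    """Analysis of similarities with mean-rank tie handling.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4) over
    the ranks of all pairwise distances.  Significance comes from random
    relabelling (p = (1 + #{R_perm >= R_obs}) / (1 + n_permutations)), or,
    with ``n_permutations="exact"``, from exhaustive enumeration of all
    distinct relabellings (p = proportion of relabellings, including the
    observed one, with R_perm >= R_obs).
    """
    labels = np.asarray(list(grouping))
    n = dist.shape[0]
    if labels.shape[0] != n:
        raise ValueError("grouping length must match distance matrix size")
    uniq, codes = np.unique(labels, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = [str(uniq[i]) for i in np.flatnonzero(sizes < 2)]
        raise ValueError(f"every group needs >= 2 members; too small: {small}")

    condensed = dist.condensed_form()
    iu = np.triu_indices(n, k=1)
    denom = n * (n - 1) / 4.0

    if np.allclose(condensed, condensed[0]):
        warnings.warn("all distances identical; ANOSIM R = 0 by convention")
        return AnosimResult(0.0, 1.0, 0, tuple(uniq))

    ranks = rankdata(condensed)  # mean ranks for ties
    within_obs = codes[iu[0]] == codes[iu[1]]
    r_obs = _anosim_r(ranks, within_obs, denom)

    eps = 1e-12
    if n_permutations == "exact":
        seen = set()
        count = total = 0
        for perm in itertools.permutations(codes):
            if perm in seen:
                continue
            seen.add(perm)
            total += 1
            p = np.asarray(perm)
            within = p[iu[0]] == p[iu[1]]
            if _anosim_r(ranks, within, denom) >= r_obs - eps:
                count += 1
        return AnosimResult(float(r_obs), count / total, total, tuple(uniq))

    n_permutations = int(n_permutations)
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    count = 0
    for _ in range(n_permutations):
        p = rng.permutation(codes)
        within = p[iu[0]] == p[iu[1]]
        if _anosim_r(ranks, within, denom) >= r_obs - eps:
            count += 1
    p_value = (1 + count) / (1 + n_permutations)
    return AnosimResult(float(r_obs), p_value, n_permutations, tuple(uniq))
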