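"""In silico faecal pollution of environmental virome profiles.

Contamination acts in abundance space: the mean source-habitat profile
(human, bovine or porcine gut) is added, gene by gene, to an environmental
profile at a chosen strength (fraction of the source mean; 100% == 1.0).
The Monte-Carlo simulation permutes environmental baselines by drawing each
ORF's abundance uniformly between 0 and the maximum observed for that ORF
across environmental viromes, then pollutes fresh baselines at strengths
drawn uniformly on [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .profiles import AbundanceProfile, MetagenomeMeta, ProfileMatrix

__all__ = [
    "ENV_U",
    "ENV_HGV",
    "ENV_BOV",
    "ENV_PORC",
    "POLLUTION_TYPES",
    "DEFAULT_STRENGTH_GRID",
    "ContaminationSpec",
    "MonteCarloConfig",
    "MonteCarloIteration",
    "mean_profile",
    "group_mean_profiles",
    "env_max_vector",
    "contaminate",
    "contamination_series",
    "permute_environmental_profile",
    "run_monte_carlo",
]

ENV_U = "ENV_U"
ENV_HGV = "ENV_HGV"
ENV_BOV = "ENV_BOV"
ENV_PORC = "ENV_PORC"

#: Pollution source label -> simulated-set label.
POLLUTION_TYPES = {"human": ENV_HGV, "bovine": ENV_BOV, "porcine": ENV_PORC}

#: Decade steps spanning the 100% .. 0.01% strength range, as fractions.
DEFAULT_STRENGTH_GRID = (1.0, 0.1, 0.01, 0.001, 0.0001)


@dataclass
class ContaminationSpec:
    """A pollution event: which source signature, and how strong."""

    source_mean: pd.Series
    strength: float
    source_label: str = "human"

    def __post_init__(self) -> None:
        self.source_mean = pd.Series(self.source_mean, dtype=float)
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("strength must be a fraction in [0, 1]")

    @classmethod
    def from_percent(
        cls, source_mean: pd.Series, percent: float, source_label: str = "human"
    ) -> "ContaminationSpec":
        return cls(source_mean, percent / 100.0, source_label)


def mean_profile(profiles: Sequence[AbundanceProfile]) -> AbundanceProfile:
    """Elementwise arithmetic mean of abundance profiles (shared universe)."""
    if not profiles:
        raise ValueError("need at least one profile")
    universe = profiles[0].orf_ids
    for p in profiles:
        if p.orf_ids != universe:
            raise ValueError("profiles must share the ORF universe")
    stacked = pd.concat([p.abundances for p in profiles], axis=1)
    return AbundanceProfile("mean", stacked.mean(axis=1))


def group_mean_profiles(matrix: ProfileMatrix) -> pd.DataFrame:
    """Mean abundance profile per habitat group (groups x ORFs)."""
    return matrix.data.groupby(matrix.groups).mean()


def env_max_vector(matrix: ProfileMatrix, env_group: str = "env_virome") -> pd.Series:
    """Per-ORF maximum abundance across the environmental virome group."""
    mask = matrix.groups == env_group
    if not mask.any():
        raise ValueError(f"no data sets in group {env_group!r}")
    return matrix.data.loc[mask.values].max(axis=0)


def contaminate(env: AbundanceProfile, spec: ContaminationSpec) -> AbundanceProfile:
    """Add ``strength x source_mean`` to an environmental profile, per ORF."""
    if list(spec.source_mean.index) != env.orf_ids:
        raise ValueError("source mean and environmental profile universes differ")
    out = env.abundances + spec.strength * spec.source_mean
    ds_id = f"{env.dataset_id}+{spec.source_label}@{spec.strength:g}"
    meta = None
    if env.meta is not None:
        meta = MetagenomeMeta(
            dataset_id=ds_id,
            habitat_group=f"polluted_{spec.source_label}",
            total_bp=env.meta.total_bp,
            assembled=env.meta.assembled,
        )
    return AbundanceProfile(ds_id, out, meta)


def contamination_series(
    env_profiles: Sequence[AbundanceProfile],
    source_mean: pd.Series | AbundanceProfile,
    strengths: Iterable[float] = DEFAULT_STRENGTH_GRID,
    source_label: str = "human",
) -> ProfileMatrix:
    """One contaminated copy per (environmental profile, strength) pair.

    Returns a matrix whose metadata carries ``strength`` (fraction) and
    ``source`` columns, mirroring the fixed-strength dilution experiment.
    """
    if isinstance(source_mean, AbundanceProfile):
        source_mean = source_mean.abundances
    strengths = list(strengths)
    if not strengths:
        raise ValueError("strengths must be non-empty")
    for s in strengths:
        if not 0.0 <= s <= 1.0:
            raise ValueError(f"strength {s} outside [0, 1]")
    rows, meta_rows = {}, {}
    for s in strengths:
        spec = ContaminationSpec(source_mean, s, source_label)
        for env in env_profiles:
            out = contaminate(env, spec)
            rows[out.dataset_id] = out.abundances
            meta_rows[out.dataset_id] = {
                "habitat_group": f"polluted_{source_label}",
                "strength": s,
                "source": source_label,
                "total_bp": env.meta.total_bp if env.meta else np.nan,
                "assembled": env.meta.assembled if env.meta else False,
            }
    data = pd.DataFrame(rows).T
    data = data[list(source_mean.index)]
    return ProfileMatrix(data, pd.DataFrame(meta_rows).T)


def permute_environmental_profile(
    env_max: pd.Series, rng: np.random.Generator, dataset_id: str = "ENVperm"
) -> AbundanceProfile:
    """Random environmental baseline: each ORF ~ Uniform[0, max observed]."""
    env_max = pd.Series(env_max, dtype=float)
    if (env_max < 0).any():
        raise ValueError("environmental maxima must be >= 0")
    values = rng.uniform(0.0, 1.0, size=len(env_max)) * env_max.values
    return AbundanceProfile(dataset_id, pd.Series(values, index=env_max.index))


@dataclass
class MonteCarloConfig:
    """Configuration of the permuted-and-polluted virome simulation."""

    env_max: pd.Series
    source_means: Mapping[str, pd.Series]
    n_iterations: int = 100
    n_env_per_iteration: int = 100
    n_polluted_per_type: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        self.env_max = pd.Series(self.env_max, dtype=float)
        if (self.env_max < 0).any():
            raise ValueError("env_max must be >= 0 elementwise")
        if min(self.n_iterations, self.n_env_per_iteration, self.n_polluted_per_type) < 1:
            raise ValueError("all counts must be >= 1")
        missing = set(POLLUTION_TYPES) - set(self.source_means)
        if missing:
            raise ValueError(f"missing source mean(s) for: {sorted(missing)}")
        self.source_means = {
            k: pd.Series(v, dtype=float).reindex(self.env_max.index)
            for k, v in self.source_means.items()
        }
        for k, v in self.source_means.items():
            if v.isna().any():
                raise ValueError(f"source mean {k!r} does not cover the ORF universe")

    @classmethod
    def from_cohort(
        cls,
        cohort: ProfileMatrix,
        env_group: str = "env_virome",
        source_groups: Mapping[str, str] | None = None,
        **kwargs,
    ) -> "MonteCarloConfig":
        """Derive env maxima and source means from a labelled profile matrix."""
        source_groups = source_groups or {
            "human": "human_gut_virome",
            "bovine": "bovine_virome",
            "porcine": "porcine_virome",
        }
        means = group_mean_profiles(cohort)
        absent = [g for g in source_groups.values() if g not in means.index]
        if absent:
            raise ValueError(f"cohort lacks habitat group(s): {absent}")
        return cls(
            env_max=env_max_vector(cohort, env_group),
            source_means={k: means.loc[g] for k, g in source_groups.items()},
            **kwargs,
        )


@dataclass
class MonteCarloIteration:
    """One iteration's uncontaminated and polluted profile sets.

    ``profiles.meta`` carries ``true_type`` (ENV_U / ENV_HGV / ENV_BOV /
    ENV_PORC) and, for polluted sets, the true ``strength`` in [0, 1]
    (NaN for ENV_U).
    """

    index: int
    profiles: ProfileMatrix

    @property
    def true_types(self) -> pd.Series:
        return self.profiles.meta["true_type"]

    @property
    def strengths(self) -> pd.Series:
        return self.profiles.meta["strength"]

    def subset(self, true_type: str) -> ProfileMatrix:
        keep = self.true_types == true_type
        return self.profiles.select(list(self.profiles.data.index[keep.values]))


def _iteration_frame(
    it: int,
    config: MonteCarloConfig,
    rng: np.random.Generator,
) -> MonteCarloIteration:
    orfs = list(config.env_max.index)
    maxima = config.env_max.values
    rows, ids, types, strengths = [], [], [], []

    base = rng.uniform(size=(config.n_env_per_iteration, len(orfs))) * maxima
    rows.append(base)
    ids += [f"it{it:03d}_ENVU_{j:03d}" for j in range(config.n_env_per_iteration)]
    types += [ENV_U] * config.n_env_per_iteration
    strengths += [np.nan] * config.n_env_per_iteration

    for source, label in POLLUTION_TYPES.items():
        # fresh baselines: polluted sets are independent of the ENV_U members
        baselines = rng.uniform(size=(config.n_polluted_per_type, len(orfs))) * maxima
        s = rng.uniform(size=config.n_polluted_per_type)
        rows.append(baselines + s[:, None] * config.source_means[source].values)
        ids += [
            f"it{it:03d}_{label.replace('ENV_', 'ENV')}_{j:03d}"
            for j in range(config.n_polluted_per_type)
        ]
        types += [label] * config.n_polluted_per_type
        strengths += list(s)

    data = pd.DataFrame(np.vstack(rows), index=ids, columns=orfs)
    meta = pd.DataFrame(
        {"true_type": types, "strength": strengths, "habitat_group": types},
        index=ids,
    )
    return MonteCarloIteration(it, ProfileMatrix(data, meta))


def run_monte_carlo(config: MonteCarloConfig) -> list[MonteCarloIteration]:
    """Run the permuted-and-polluted simulation; reproducible from the seed.

    Each iteration holds ``n_env_per_iteration`` uncontaminated permuted
    environmental profiles plus ``n_polluted_per_type`` profiles per source
    type, each built on a freshly permuted baseline and polluted at a
    Uniform[0, 1] strength.
    """
    root = np.random.default_rng(config.seed)
    children = root.spawn(config.n_iterations)
    return [
        _iteration_frame(i + 1, config, child) for i, child in enumerate(children)
    ]
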