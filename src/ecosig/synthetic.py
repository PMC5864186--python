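"""Synthetic habitat-structured cohorts and hit-table fixtures.

The cohort generator emulates the statistical structure the source-tracking
analysis assumes: a sparse environmental background, a set of gut-shared
ORFs elevated in all mammalian-gut viromes, a small set of human-gut-specific
ORFs, a handful of cosmopolitan ORFs present nearly everywhere, and high
inter-individual variability among human gut viromes.  Per data set and ORF,
abundance is a zero-inflated lognormal draw: zero with probability
1 - occurrence, otherwise exp(Normal(ln median, sigma)) hits/Mb.

The fixture generator does the reverse of profiling: given a target
abundance matrix it writes a 12-column hit table (plus lengths and metadata
tables) whose valid rows reproduce the target exactly through
``compute_profile``, with decoy rows that each violate exactly one validity
threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classifier import SUBSET1_ORF_NUMBERS, SUBSET2_ORF_NUMBERS
from .profiles import (
    HitTable,
    MetagenomeMeta,
    ProfileMatrix,
    compute_profile,
)

__all__ = [
    "ZILNParams",
    "CohortSpec",
    "FixtureBundle",
    "generate_cohort",
    "generate_hit_table_fixture",
    "DEFAULT_GROUP_SIZES",
    "DEFAULT_GROUP_CLASSES",
]

ARCHETYPES = ("human_gut_specific", "gut_shared", "cosmopolitan", "background")

#: Virome counts per habitat group (human gut mirrors the n = 12 used to
#: average the human gut signature; other groups are of the same order).
DEFAULT_GROUP_SIZES = {
    "human_gut_virome": 12,
    "bovine_virome": 8,
    "porcine_virome": 8,
    "env_virome": 20,
}

#: Habitat group -> generative class used to index archetype parameters.
DEFAULT_GROUP_CLASSES = {
    "human_gut_virome": "human_gut",
    "bovine_virome": "other_gut",
    "porcine_virome": "other_gut",
    "env_virome": "environmental",
}

#: Cosmopolitan ORF ids (broadly represented, moderate abundance); kept
#: disjoint from the gut-affiliated subsets.
DEFAULT_COSMOPOLITAN = (1, 2, 3, 10, 30, 40, 50, 57, 63, 70)


@dataclass(frozen=True)
class ZILNParams:
    """Zero-inflated lognormal parameters for one (archetype, group class).

    ``occurrence`` is the probability an ORF is detected at all in a data
    set; ``median`` the median of the nonzero abundance in hits/Mb;
    ``sigma`` the lognormal shape (natural-log SD).
    """

    occurrence: float
    median: float
    sigma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.occurrence <= 1.0:
            raise ValueError("occurrence must be in [0, 1]")
        if self.median < 0:
            raise ValueError("median must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def _default_params() -> dict[str, dict[str, ZILNParams]]:
    # Gut-enriched ORFs sit in the tens of hits/Mb in their home habitats,
    # against a sparse sub-1-hits/Mb environmental background; the human
    # gut group gets the largest dispersion (high inter-individual
    # variability of human gut viromes).
    P = ZILNParams
    return {
        "human_gut_specific": {
            "human_gut": P(0.95, 30.0, 1.0),
            "other_gut": P(0.30, 1.0, 0.8),
            "environmental": P(0.05, 0.05, 0.8),
        },
        "gut_shared": {
            "human_gut": P(0.90, 20.0, 1.0),
            "other_gut": P(0.85, 15.0, 0.8),
            "environmental": P(0.10, 0.10, 0.8),
        },
        "cosmopolitan": {
            "human_gut": P(0.90, 2.0, 1.0),
            "other_gut": P(0.90, 2.0, 0.8),
            "environmental": P(0.90, 2.0, 0.8),
        },
        "background": {
            "human_gut": P(0.12, 0.15, 0.8),
            "other_gut": P(0.12, 0.15, 0.8),
            "environmental": P(0.12, 0.15, 0.8),
        },
    }


def _default_archetypes(n_orfs: int) -> dict[int, str]:
    arch = {}
    human_specific = set(SUBSET2_ORF_NUMBERS)
    gut_shared = set(SUBSET1_ORF_NUMBERS) - human_specific
    cosmopolitan = set(DEFAULT_COSMOPOLITAN) - human_specific - gut_shared
    for i in range(1, n_orfs + 1):
        if i in human_specific:
            arch[i] = "human_gut_specific"
        elif i in gut_shared:
            arch[i] = "gut_shared"
        elif i in cosmopolitan:
            arch[i] = "cosmopolitan"
        else:
            arch[i] = "background"
    return arch


@dataclass
class CohortSpec:
    """Specification of a synthetic habitat-structured cohort.

    Defaults place the human-attribution analogues at ORFs {16, 34, 56}
    and the pollution-detection analogues at the 15-ORF gut-affiliated set,
    spanning ids 1..70.
    """

    n_orfs: int = 70
    group_sizes: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_SIZES)
    )
    group_classes: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_CLASSES)
    )
    archetypes: Mapping[int, str] | None = None
    params: Mapping[str, Mapping[str, ZILNParams]] | None = None
    orf_prefix: str = "ORF_"
    total_bp: float = 10_000_000.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_orfs < 1:
            raise ValueError("n_orfs must be >= 1")
        for g, size in self.group_sizes.items():
            if size < 1:
                raise ValueError(f"group {g!r} requested with size {size}")
            if g not in self.group_classes:
                raise ValueError(f"no generative class for group {g!r}")
        if self.archetypes is None:
            self.archetypes = _default_archetypes(self.n_orfs)
        if self.params is None:
            self.params = _default_params()
        for i in range(1, self.n_orfs + 1):
            if i not in self.archetypes:
                raise ValueError(f"no archetype for ORF {i}")

    @classmethod
    def null(
        cls,
        n_orfs: int = 20,
        group_sizes: Mapping[str, int] | None = None,
        seed: int | None = None,
    ) -> "CohortSpec":
        """A no-signal cohort: identical parameters in every habitat group."""
        flat = ZILNParams(occurrence=0.6, median=1.0, sigma=0.8)
        params = {a: {c: flat for c in ("human_gut", "other_gut", "environmental")}
                  for a in ARCHETYPES}
        return cls(
            n_orfs=n_orfs,
            group_sizes=dict(group_sizes or DEFAULT_GROUP_SIZES),
            params=params,
            seed=seed,
        )

    @property
    def orf_ids(self) -> list[str]:
        return [f"{self.orf_prefix}{i}" for i in range(1, self.n_orfs + 1)]


def generate_cohort(spec: CohortSpec) -> ProfileMatrix:
    """Draw a labelled cohort of abundance profiles from ``spec``.

    Deterministic for a given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    orf_ids = spec.orf_ids
    rows, meta_rows = {}, {}
    short = {
        "human_gut_virome": "HGV",
        "bovine_virome": "BOV",
        "porcine_virome": "PORC",
        "env_virome": "ENV",
    }
    for group, size in spec.group_sizes.items():
        gclass = spec.group_classes[group]
        occ = np.array(
            [spec.params[spec.archetypes[i]][gclass].occurrence
             for i in range(1, spec.n_orfs + 1)]
        )
        med = np.array(
            [spec.params[spec.archetypes[i]][gclass].median
             for i in range(1, spec.n_orfs + 1)]
        )
        sig = np.array(
            [spec.params[spec.archetypes[i]][gclass].sigma
             for i in range(1, spec.n_orfs + 1)]
        )
        present = rng.uniform(size=(size, spec.n_orfs)) < occ
        with np.errstate(divide="ignore"):
            log_med = np.where(med > 0, np.log(med), -np.inf)
        draws = np.exp(rng.normal(loc=log_med, scale=sig, size=(size, spec.n_orfs)))
        values = np.where(present & (med > 0), draws, 0.0)
        tag = short.get(group, group)
        for j in range(size):
            ds = f"{tag}_{j + 1:02d}"
            rows[ds] = pd.Series(values[j], index=orf_ids)
            meta_rows[ds] = {
                "habitat_group": group,
                "total_bp": spec.total_bp,
                "assembled": False,
            }
    data = pd.DataFrame(rows).T[orf_ids]
    return ProfileMatrix(data, pd.DataFrame(meta_rows).T)


# ---------------------------------------------------------------------------
# hit-table fixtures
# ---------------------------------------------------------------------------

#: Decoy recipes: each violates exactly one validity threshold.
_DECOYS = (
    {"identity": 34.9, "coverage": 0.90, "evalue": 1e-20},   # identity fails
    {"identity": 90.0, "coverage": 0.49, "evalue": 1e-20},   # coverage fails
    {"identity": 90.0, "coverage": 0.90, "evalue": 1.1e-5},  # e-value fails
)


@dataclass
class FixtureBundle:
    """A hit table plus lengths/metadata tables encoding a known matrix.

    ``compute_profile`` over the bundle reproduces ``target`` exactly; use
    :meth:`recompute` to round-trip it.
    """

    hit_tables: dict[str, HitTable]
    query_lengths: dict[str, int]
    metadata: pd.DataFrame
    target: ProfileMatrix

    def recompute(self, **kwargs) -> ProfileMatrix:
        from .profiles import AbundanceProfile

        profiles = []
        for ds in self.target.dataset_ids:
            m = self.metadata.loc[ds]
            meta = MetagenomeMeta(
                dataset_id=ds,
                habitat_group=str(m["habitat_group"]),
                total_bp=float(m["total_bp"]),
                assembled=bool(m["assembled"]),
            )
            profiles.append(
                compute_profile(
                    self.hit_tables[ds],
                    query_lengths=self.query_lengths,
                    orf_ids=self.target.orf_ids,
                    meta=meta,
                    **kwargs,
                )
            )
        return ProfileMatrix.from_profiles(profiles)

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        """Write hits/<ds>.tsv, lengths.tsv, metadata.csv and target.csv."""
        out_dir = Path(out_dir)
        (out_dir / "hits").mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        for ds, table in self.hit_tables.items():
            p = out_dir / "hits" / f"{ds}.tsv"
            with open(p, "w") as fh:
                fh.write("# synthetic hit-table fixture\n")
                for h in table:
                    fh.write(
                        "\t".join(
                            map(
                                str,
                                [
                                    h.query_id, h.subject_id, h.percent_identity,
                                    h.alignment_length, h.mismatches, h.gap_opens,
                                    h.query_start, h.query_end, h.subject_start,
                                    h.subject_end, h.evalue, h.bit_score,
                                ],
                            )
                        )
                        + "\n"
                    )
            paths[ds] = p
        with open(out_dir / "lengths.tsv", "w") as fh:
            for qid, length in self.query_lengths.items():
                fh.write(f"{qid}\t{length}\n")
        meta = self.metadata.copy()
        meta.index.name = "dataset_id"
        meta.to_csv(out_dir / "metadata.csv")
        self.target.to_csv(out_dir / "target.csv")
        paths["lengths"] = out_dir / "lengths.tsv"
        paths["metadata"] = out_dir / "metadata.csv"
        paths["target"] = out_dir / "target.csv"
        return paths


def generate_hit_table_fixture(
    target: ProfileMatrix,
    seed: int | None = None,
    n_decoys: int = 3,
    read_length: int = 100,
    atol: float = 1e-9,
) -> FixtureBundle:
    """Emit hit tables whose valid rows reproduce ``target`` exactly.

    Every target abundance must equal ``k / (total_bp / 1e6)`` for an
    integer ``k`` given each data set's ``total_bp`` (taken from the target
    metadata, default 1 Mb); otherwise a ValueError suggests a suitable
    ``total_bp``.  Valid rows sit safely inside the validity thresholds;
    ``n_decoys`` decoy rows per data set each violate exactly one threshold
    (identity 34.9, coverage 0.49 or e-value 1.1e-5).
    """
    rng = np.random.default_rng(seed)
    hit_tables: dict[str, HitTable] = {}
    lengths: dict[str, int] = {}
    meta_rows = {}

    for ds in target.dataset_ids:
        if target.meta is not None and "total_bp" in target.meta.columns:
            total_bp = float(target.meta.loc[ds, "total_bp"])
        else:
            total_bp = 1e6
        habitat = (
            str(target.meta.loc[ds, "habitat_group"])
            if target.meta is not None and "habitat_group" in target.meta.columns
            else "unknown"
        )
        mb = total_bp / 1e6
        rows = []
        read_no = 0
        for orf in target.orf_ids:
            value = float(target.data.loc[ds, orf])
            k = value * mb
            k_int = round(k)
            if abs(k - k_int) > atol:
                suggested = 1e6 / value if value > 0 else total_bp
                raise ValueError(
                    f"abundance {value} for {ds}/{orf} is not an integer hit "
                    f"count at total_bp={total_bp:g}; choose total_bp so that "
                    f"value*total_bp/1e6 is integral (e.g. a multiple of "
                    f"{suggested:g})"
                )
            for _ in range(int(k_int)):
                read_no += 1
                qid = f"{ds}_read{read_no:05d}"
                lengths[qid] = read_length
                rows.append(_valid_row(qid, orf, read_length, rng))
        for d in range(n_decoys):
            recipe = _DECOYS[d % len(_DECOYS)]
            read_no += 1
            qid = f"{ds}_decoy{read_no:05d}"
            lengths[qid] = read_length
            orf = target.orf_ids[int(rng.integers(len(target.orf_ids)))]
            rows.append(_decoy_row(qid, orf, read_length, recipe))
        hit_tables[ds] = HitTable(rows, "read_query")
        meta_rows[ds] = {
            "habitat_group": habitat,
            "total_bp": total_bp,
            "assembled": False,
        }

    metadata = pd.DataFrame(meta_rows).T
    return FixtureBundle(hit_tables, lengths, metadata, target)


def _valid_row(qid: str, orf: str, read_length: int, rng: np.random.Generator):
    from .profiles import HitRecord

    identity = round(float(rng.uniform(60.0, 99.0)), 1)
    return HitRecord(
        query_id=qid,
        subject_id=orf,
        percent_identity=identity,
        alignment_length=read_length,
        mismatches=int(round(read_length * (1 - identity / 100))),
        gap_opens=0,
        query_start=1,
        query_end=read_length,
        subject_start=1,
        subject_end=read_length,
        evalue=1e-20,
        bit_score=round(float(rng.uniform(80, 200)), 1),
    )


def _decoy_row(qid: str, orf: str, read_length: int, recipe: dict):
    from .profiles import HitRecord

    qend = max(1, int(round(recipe["coverage"] * read_length)))
    return HitRecord(
        query_id=qid,
        subject_id=orf,
        percent_identity=recipe["identity"],
        alignment_length=qend,
        mismatches=int(round(qend * (1 - recipe["identity"] / 100))),
        gap_opens=0,
        query_start=1,
        query_end=qend,
        subject_start=1,
        subject_end=qend,
        evalue=recipe["evalue"],
        bit_score=50.0,
    )
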