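"""Per-ORF relative-abundance profiling of metagenomes from homology-search hit tables.

A metagenome's "ecogenomic profile" with respect to a phage genome is the
relative abundance, in valid homology-search hits per megabase of sequence
data (hits/Mb), of each phage-encoded ORF in that data set.  Hit tables are
the standard 12-column tab-separated alignment format; a hit is *valid* when
it shows at least 35% identity over at least 50% of the query sequence with
an e-value of at most 1e-5 (all boundaries inclusive).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "HitRecord",
    "HitTable",
    "HitTableParseError",
    "MetagenomeMeta",
    "AbundanceProfile",
    "ProfileMatrix",
    "read_hit_table",
    "read_lengths",
    "read_metadata",
    "is_valid_hit",
    "compute_profile",
    "cumulative_abundance",
    "filter_min_orf_representation",
    "IDENTITY_THRESHOLD",
    "COVERAGE_THRESHOLD",
    "EVALUE_THRESHOLD",
]

#: Hit-validity thresholds (inclusive: >=, >=, <=).
IDENTITY_THRESHOLD = 35.0
COVERAGE_THRESHOLD = 0.5
EVALUE_THRESHOLD = 1e-5

ORIENTATIONS = ("read_query", "orf_query")


class HitTableParseError(ValueError):
    """Raised when a hit-table row cannot be parsed."""


@dataclass(frozen=True)
class HitRecord:
    """One alignment row of 12-column tabular homology-search output.

    Coordinates are 1-based inclusive residue positions on the respective
    sequences, following the tabular dialect's convention.
    """

    query_id: str
    subject_id: str
    percent_identity: float
    alignment_length: int
    mismatches: int
    gap_opens: int
    query_start: int
    query_end: int
    subject_start: int
    subject_end: int
    evalue: float
    bit_score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.percent_identity <= 100.0:
            raise ValueError(
                f"percent_identity must be in [0, 100], got {self.percent_identity}"
            )
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.query_start > self.query_end:
            raise ValueError("query_start must be <= query_end")


@dataclass
class HitTable:
    """Parsed hit rows plus the search orientation they came from.

    ``orientation`` records which side of the alignment is the phage ORF:
    ``read_query`` (reads searched against translated ORFs, e.g. BlastX on
    viral data sets) means the subject is the ORF; ``orf_query`` (ORF
    proteins searched against an assembled data set, e.g. tBlastn) means the
    query is the ORF.
    """

    hits: list[HitRecord]
    orientation: str

    def __post_init__(self) -> None:
        if self.orientation not in ORIENTATIONS:
            raise ValueError(
                f"orientation must be one of {ORIENTATIONS}, got {self.orientation!r}"
            )

    def __iter__(self) -> Iterator[HitRecord]:
        return iter(self.hits)

    def __len__(self) -> int:
        return len(self.hits)

    def orf_id(self, hit: HitRecord) -> str:
        """Identifier of the phage ORF side of *hit* under this orientation."""
        return hit.subject_id if self.orientation == "read_query" else hit.query_id

    def unit_id(self, hit: HitRecord) -> str:
        """Identifier of the counted (non-ORF) side of *hit*."""
        return hit.query_id if self.orientation == "read_query" else hit.subject_id


@dataclass(frozen=True)
class MetagenomeMeta:
    """Metadata for one metagenomic data set."""

    dataset_id: str
    habitat_group: str
    total_bp: float
    assembled: bool = False

    def __post_init__(self) -> None:
        if self.total_bp <= 0:
            raise ValueError("total_bp must be > 0")


@dataclass
class AbundanceProfile:
    """Per-ORF relative abundance (hits/Mb) of one metagenome.

    Absent ORFs are exactly 0; ``abundances`` is indexed by ORF id over the
    full shared ORF universe.
    """

    dataset_id: str
    abundances: pd.Series
    meta: MetagenomeMeta | None = None

    def __post_init__(self) -> None:
        self.abundances = pd.Series(self.abundances, dtype=float)
        if (self.abundances < 0).any():
            raise ValueError("abundances must be >= 0")

    @property
    def orf_ids(self) -> list[str]:
        return list(self.abundances.index)

    @property
    def cumulative(self) -> float:
        """Cumulative relative abundance: sum of all per-ORF values."""
        return float(self.abundances.sum())

    def cumulative_over(self, orf_subset: Iterable[str] | None = None) -> float:
        return cumulative_abundance(self, orf_subset)


class ProfileMatrix:
    """Ordered collection of abundance profiles over a shared ORF universe.

    Thin wrapper around a datasets x ORFs :class:`pandas.DataFrame` (``data``)
    plus an aligned per-dataset metadata frame (``meta`` with columns
    ``habitat_group``, ``total_bp``, ``assembled`` and, for simulated
    profiles, ``true_type``/``strength``).
    """

    META_COLUMNS = ("habitat_group", "total_bp", "assembled")

    def __init__(self, data: pd.DataFrame, meta: pd.DataFrame | None = None):
        data = data.astype(float)
        if (data.values < 0).any():
            raise ValueError("abundances must be >= 0")
        if not data.index.is_unique:
            raise ValueError("dataset ids must be unique")
        if meta is not None:
            meta = meta.reindex(data.index)
        self.data = data
        self.meta = meta

    # -- construction ---------------------------------------------------
    @classmethod
    def from_profiles(cls, profiles: Sequence[AbundanceProfile]) -> "ProfileMatrix":
        if not profiles:
            raise ValueError("need at least one profile")
        universe = profiles[0].orf_ids
        rows, meta_rows = {}, {}
        for p in profiles:
            if p.orf_ids != universe:
                raise ValueError(
                    f"profile {p.dataset_id!r} does not share the ORF universe"
                )
            rows[p.dataset_id] = p.abundances
            if p.meta is not None:
                meta_rows[p.dataset_id] = {
                    "habitat_group": p.meta.habitat_group,
                    "total_bp": p.meta.total_bp,
                    "assembled": p.meta.assembled,
                }
        data = pd.DataFrame(rows).T
        data = data.loc[[p.dataset_id for p in profiles], universe]
        meta = pd.DataFrame(meta_rows).T if meta_rows else None
        return cls(data, meta)

    @classmethod
    def read_csv(
        cls, path: str | Path, meta: pd.DataFrame | str | Path | None = None
    ) -> "ProfileMatrix":
        data = pd.read_csv(path, index_col=0)
        data.index = data.index.astype(str)
        if isinstance(meta, (str, Path)):
            meta = read_metadata(meta)
        return cls(data, meta)

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out.index.name = "dataset_id"
        out.to_csv(path)

    # -- basic accessors ------------------------------------------------
    @property
    def dataset_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def orf_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def groups(self) -> pd.Series:
        if self.meta is None or "habitat_group" not in self.meta:
            raise ValueError("matrix has no habitat_group metadata")
        return self.meta["habitat_group"]

    def __len__(self) -> int:
        return len(self.data)

    def profile(self, dataset_id: str) -> AbundanceProfile:
        row = self.data.loc[dataset_id]
        meta = None
        if self.meta is not None and dataset_id in self.meta.index:
            m = self.meta.loc[dataset_id]
            meta = MetagenomeMeta(
                dataset_id=dataset_id,
                habitat_group=str(m.get("habitat_group", "unknown")),
                total_bp=float(m.get("total_bp", 1.0)),
                assembled=bool(m.get("assembled", False)),
            )
        return AbundanceProfile(dataset_id, row.copy(), meta)

    def profiles(self) -> Iterator[AbundanceProfile]:
        for ds in self.dataset_ids:
            yield self.profile(ds)

    def cumulative(self, orf_subset: Iterable[str] | None = None) -> pd.Series:
        """Cumulative relative abundance per data set, optionally over a subset."""
        if orf_subset is None:
            return self.data.sum(axis=1)
        subset = list(orf_subset)
        missing = set(subset) - set(self.data.columns)
        if missing:
            raise KeyError(f"ORFs not in universe: {sorted(missing)}")
        return self.data[subset].sum(axis=1)

    def select(self, dataset_ids: Sequence[str]) -> "ProfileMatrix":
        meta = self.meta.loc[dataset_ids] if self.meta is not None else None
        return ProfileMatrix(self.data.loc[dataset_ids], meta)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_hit_table(path: str | Path, orientation: str) -> HitTable:
    """Parse a 12-column tab-separated alignment file into a :class:`HitTable`.

    Lines starting with ``#`` are skipped; an empty file yields an empty
    table.  A row with the wrong column count or non-numeric numeric fields
    raises :class:`HitTableParseError` naming the offending line.
    """
    if orientation not in ORIENTATIONS:
        raise ValueError(f"orientation must be one of {ORIENTATIONS}")
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise HitTableParseError(
                    f"{path}: line {lineno}: expected 12 tab-separated columns, "
                    f"got {len(fields)}"
                )
            try:
                hits.append(
                    HitRecord(
                        query_id=fields[0],
                        subject_id=fields[1],
                        percent_identity=float(fields[2]),
                        alignment_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        query_start=int(fields[6]),
                        query_end=int(fields[7]),
                        subject_start=int(fields[8]),
                        subject_end=int(fields[9]),
                        evalue=float(fields[10]),
                        bit_score=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise HitTableParseError(
                    f"{path}: line {lineno}: {exc}"
                ) from exc
    return HitTable(hits, orientation)


def read_lengths(path: str | Path) -> dict[str, int]:
    """Read sequence lengths from FASTA (lengths of records) or 2-column TSV."""
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip():
                first = line.lstrip()
                break
    if first.startswith(">"):
        from Bio import SeqIO

        return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"{path}: line {lineno}: expected 'id<TAB>length'")
            lengths[parts[0]] = int(parts[1])
    return lengths


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-dataset metadata CSV (dataset_id,habitat_group,total_bp,assembled)."""
    meta = pd.read_csv(path)
    required = {"dataset_id", "habitat_group", "total_bp"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    if "assembled" not in meta.columns:
        meta["assembled"] = False
    if meta["dataset_id"].duplicated().any():
        raise ValueError("dataset_id values must be unique")
    if (meta["total_bp"] <= 0).any():
        raise ValueError("total_bp must be > 0")
    return meta.set_index("dataset_id")


# ---------------------------------------------------------------------------
# Hit filtering and profile computation
# ---------------------------------------------------------------------------

def is_valid_hit(hit: HitRecord, query_length: float) -> bool:
    """Apply the hit-validity filter.

    Valid iff identity >= 35%, query coverage
    (query_end - query_start + 1) / query_length >= 0.5 and
    e-value <= 1e-5.  All three comparisons are inclusive at the boundary.
    """
    if query_length is None:
        raise ValueError(f"no length known for query {hit.query_id!r}")
    if query_length <= 0:
        raise ValueError("query_length must be > 0")
    coverage = (hit.query_end - hit.query_start + 1) / query_length
    return (
        hit.percent_identity >= IDENTITY_THRESHOLD
        and coverage >= COVERAGE_THRESHOLD
        and hit.evalue <= EVALUE_THRESHOLD
    )


def _best_hit(a: HitRecord, b: HitRecord) -> HitRecord:
    """Best of two HSPs: lowest e-value, ties broken by higher bit score."""
    if (a.evalue, -a.bit_score) <= (b.evalue, -b.bit_score):
        return a
    return b


def compute_profile(
    hits: HitTable | Iterable[HitRecord],
    query_lengths: Mapping[str, float],
    orf_ids: Sequence[str],
    meta: MetagenomeMeta,
    orientation: str | None = None,
    best_orf_only: bool = False,
) -> AbundanceProfile:
    """Convert hit rows into a per-ORF hits/Mb abundance profile.

    Multiple HSPs between the same (sequence unit, ORF) pair collapse to the
    single best alignment (lowest e-value, then highest bit score) before the
    validity filter is applied; each unit validly hitting ``k`` distinct ORFs
    contributes one count to each of the ``k`` ORFs (or, with
    ``best_orf_only``, only to its single best ORF).  Per-ORF abundance is
    ``valid hit count / (total_bp / 1e6)``.
    """
    if isinstance(hits, HitTable):
        table = hits
        if orientation is not None and orientation != table.orientation:
            raise ValueError("orientation conflicts with the hit table's own")
    else:
        if orientation is None:
            raise ValueError("orientation required when hits is a plain sequence")
        table = HitTable(list(hits), orientation)

    universe = set(orf_ids)
    best: dict[tuple[str, str], HitRecord] = {}
    for hit in table:
        orf = table.orf_id(hit)
        if orf not in universe:
            raise KeyError(
                f"hit references ORF {orf!r} outside the declared universe"
            )
        key = (table.unit_id(hit), orf)
        best[key] = hit if key not in best else _best_hit(best[key], hit)

    valid: dict[tuple[str, str], HitRecord] = {}
    for (unit, orf), hit in best.items():
        qlen = query_lengths.get(hit.query_id)
        if qlen is None:
            raise KeyError(f"no length entry for query {hit.query_id!r}")
        if is_valid_hit(hit, qlen):
            valid[(unit, orf)] = hit

    if best_orf_only:
        per_unit: dict[str, tuple[str, HitRecord]] = {}
        for (unit, orf), hit in valid.items():
            if unit not in per_unit or _best_hit(per_unit[unit][1], hit) is hit:
                per_unit[unit] = (orf, hit)
        valid = {(unit, orf): hit for unit, (orf, hit) in per_unit.items()}

    counts = pd.Series(0.0, index=list(orf_ids))
    for (_, orf) in valid:
        counts[orf] += 1.0
    abundances = counts / (meta.total_bp / 1e6)
    return AbundanceProfile(meta.dataset_id, abundances, meta)


def cumulative_abundance(
    profile: AbundanceProfile, orf_subset: Iterable[str] | None = None
) -> float:
    """Sum of per-ORF abundances over ``orf_subset`` (all ORFs if None)."""
    if orf_subset is None:
        return profile.cumulative
    subset = list(orf_subset)
    missing = set(subset) - set(profile.abundances.index)
    if missing:
        raise KeyError(f"ORFs not in universe: {sorted(missing)}")
    return float(profile.abundances[subset].sum())


def filter_min_orf_representation(
    matrix: ProfileMatrix, min_distinct: int = 2
) -> ProfileMatrix:
    """Keep only data sets with at least ``min_distinct`` ORFs at abundance > 0.

    The stringency filter applied before ordination: a data set must show
    similarity to at least two distinct phage ORFs to be included.
    """
    if min_distinct < 0:
        raise ValueError("min_distinct must be >= 0")
    keep = (matrix.data > 0).sum(axis=1) >= min_distinct
    return matrix.select(list(matrix.data.index[keep]))
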