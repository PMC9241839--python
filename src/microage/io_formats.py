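"""Tables, metadata, configuration and on-disk formats.

Count tables follow the dominant amplicon convention: taxa as rows,
samples as columns, integer cells, tab-separated with the taxon id in the
first column and sample ids in the header.  Metadata is a separate
QIIME-style mapping TSV keyed by ``sample_id``.  Distance matrices are
square TSVs with identical row and column sample ids.

The five murine life phases are carried as strings with the fixed
canonical ordering ``MR < MA < MD < OD < VO`` (maturing, mature, middle
age, old, very old).  Ages between phase windows are labelled
``intermediate`` and excluded from source selection.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PHASE_ORDER",
    "DEFAULT_PHASE_RANGES",
    "DEFAULT_PHASE_MIDPOINTS",
    "INTERMEDIATE",
    "phase_of_age",
    "CountTable",
    "SampleMetadata",
    "RunConfig",
    "read_count_table",
    "write_count_table",
    "read_metadata",
    "write_metadata",
    "read_distance_matrix_tsv",
    "write_distance_matrix_tsv",
    "join_metadata",
    "filter_low_prevalence",
    "ParseError",
]

#: Canonical life-phase ordering: maturing, mature, middle age, old, very old.
PHASE_ORDER: tuple[str, ...] = ("MR", "MA", "MD", "OD", "VO")

#: Label for sampling ages that fall between the phase windows.
INTERMEDIATE = "intermediate"

#: Age windows (weeks, inclusive) assigning sampling ages to life phases.
#: Interpolated from the phase midpoints and the study timeline; ages
#: outside every window are "intermediate".
DEFAULT_PHASE_RANGES: dict[str, tuple[float, float]] = {
    "MR": (9.0, 12.0),
    "MA": (17.0, 22.0),
    "MD": (47.0, 56.0),
    "OD": (86.0, 100.0),
    "VO": (108.0, 112.0),
}

#: Life-phase midpoints in weeks, the coefficients of the age formula.
DEFAULT_PHASE_MIDPOINTS: dict[str, float] = {
    "MR": 10.5,
    "MA": 19.5,
    "MD": 51.5,
    "OD": 93.0,
    "VO": 110.0,
}


def phase_of_age(age_weeks: float,
                 ranges: Mapping[str, tuple[float, float]] | None = None) -> str:
    """Map an age in weeks to its life phase, or ``"intermediate"``."""
    ranges = DEFAULT_PHASE_RANGES if ranges is None else ranges
    for phase, (lo, hi) in ranges.items():
        if lo <= age_weeks <= hi:
            return phase
    return INTERMEDIATE


class ParseError(ValueError):
    """Raised when an on-disk table violates the format contract."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class CountTable:
    """Integer taxa-by-samples count matrix with id lists.

    Invariants (checked in ``__post_init__``): counts are nonnegative
    integers, ids are unique, and matrix dimensions match the id lists.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_taxa, n_samples) integer

    def __post_init__(self) -> None:
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ParseError("counts must be a 2-D matrix")
        if counts.shape != (len(self.taxon_ids), len(self.sample_ids)):
            raise ParseError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded, atol=0, rtol=0):
                raise ParseError("counts must be integral")
            counts = rounded.astype(np.int64)
        if (counts < 0).any():
            raise ParseError("counts must be nonnegative")
        self.counts = counts.astype(np.int64, copy=False)
        for name, ids in (("taxon", self.taxon_ids), ("sample", self.sample_ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise ParseError(f"duplicate {name} id: {i!r}")
                seen.add(i)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id: {sample_id!r}") from None

    def select_samples(self, sample_ids: Sequence[str]) -> "CountTable":
        idx = [self.sample_index(s) for s in sample_ids]
        return CountTable(list(self.taxon_ids), [self.sample_ids[i] for i in idx],
                          self.counts[:, idx].copy())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.taxon_ids,
                            columns=self.sample_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return (self.taxon_ids == other.taxon_ids
                and self.sample_ids == other.sample_ids
                and np.array_equal(self.counts, other.counts))


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample record: host, age, life phase, diet and cage."""

    sample_id: str
    mouse_id: str
    age_weeks: float
    life_phase: str = INTERMEDIATE
    diet: str = "standard"
    cage: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.age_weeks <= 150.0:
            raise ValueError(
                f"age_weeks={self.age_weeks} outside [0, 150] "
                f"for sample {self.sample_id!r}")
        allowed = set(PHASE_ORDER) | {INTERMEDIATE}
        if self.life_phase not in allowed:
            raise ValueError(f"unknown life phase {self.life_phase!r}")
        if self.diet not in ("standard", "western"):
            raise ValueError(f"unknown diet {self.diet!r}")


@dataclass
class RunConfig:
    """Analysis parameters; the defaults replicate the study pipeline.

    rarefaction_depth
        Reads per sample after subsampling (2,733 for the longitudinal
        cohort; the dietary cohort used 9,778).
    min_prevalence
        Taxa observed in fewer samples than this are dropped.
    n_permutations / fdr_alpha
        Pairwise PERMANOVA permutations and the FDR significance level
        used when counting "significantly different pairs".
    burnins / restarts
        Gibbs sweeps discarded per chain, and independent chains whose
        retained draws are averaged.
    uncertainty_threshold
        Sinks whose "unknown" attribution exceeds this are excluded from
        age prediction.
    phase_midpoints
        Weeks assigned to each life phase in the age formula.
    """

    rarefaction_depth: int = 2733
    min_prevalence: int = 5
    n_permutations: int = 9999
    fdr_alpha: float = 0.01
    burnins: int = 100
    restarts: int = 10
    uncertainty_threshold: float = 0.30
    phase_midpoints: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PHASE_MIDPOINTS))
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("rarefaction_depth", "min_prevalence", "n_permutations",
                     "burnins", "restarts"):
            if int(getattr(self, name)) <= 0:
                raise ValueError(f"{name} must be a positive integer")
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError("fdr_alpha must lie in (0, 1)")
        if not 0.0 < self.uncertainty_threshold < 1.0:
            raise ValueError("uncertainty_threshold must lie in (0, 1)")
        mids = [self.phase_midpoints[p] for p in PHASE_ORDER]
        if not all(a < b for a, b in zip(mids, mids[1:])):
            raise ValueError("phase midpoints must increase in MR<MA<MD<OD<VO order")

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "RunConfig":
        """Read a flat ``key=value`` config file (``#`` comments allowed).

        Midpoints are given as ``midpoint_MR=10.5`` etc.
        """
        kwargs: dict = {}
        midpoints = dict(DEFAULT_PHASE_MIDPOINTS)
        fields = {f.name: f for f in dataclasses.fields(cls)}
        with open(path) as fh:
            for lineno, raw in enumerate(fh, 1):
                line = raw.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ParseError(f"{path}:{lineno}: expected key=value")
                key, value = (s.strip() for s in line.split("=", 1))
                if key.startswith("midpoint_"):
                    midpoints[key.removeprefix("midpoint_")] = float(value)
                elif key in ("fdr_alpha", "uncertainty_threshold"):
                    kwargs[key] = float(value)
                elif key in fields:
                    kwargs[key] = int(value)
                else:
                    raise ParseError(f"{path}:{lineno}: unknown key {key!r}")
        kwargs["phase_midpoints"] = midpoints
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_count_table(path: str | os.PathLike | io.TextIOBase,
                     transposed: bool = False) -> CountTable:
    """Read a taxa-by-samples TSV count table.

    First column holds taxon ids, header row holds sample ids.  With
    ``transposed=True`` the file is samples-by-taxa and is flipped on
    read.  Round-trips byte-identically with :func:`write_count_table`.
    """
    df = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str)
    if df.shape[1] == 0:
        raise ParseError("no samples: header row lists no sample columns")
    if df.shape[0] == 0:
        raise ParseError("no samples: data section is empty")
    try:
        values = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise ParseError(f"non-numeric cell in count table: {exc}") from exc
    bad = np.argwhere(values != np.rint(values))
    if bad.size:
        r, c = bad[0]
        raise ParseError(
            f"non-integer count at row {df.index[r]!r}, column {df.columns[c]!r}")
    row_ids = [str(i) for i in df.index]
    col_ids = [str(c) for c in df.columns]
    counts = values.astype(np.int64)
    if transposed:
        row_ids, col_ids = col_ids, row_ids
        counts = counts.T
    return CountTable(row_ids, col_ids, counts)


def write_count_table(table: CountTable, path: str | os.PathLike) -> None:
    """Write a CountTable as the canonical taxa-by-samples TSV."""
    with open(path, "w") as fh:
        fh.write("taxon_id\t" + "\t".join(table.sample_ids) + "\n")
        for i, taxon in enumerate(table.taxon_ids):
            fh.write(taxon + "\t" + "\t".join(str(int(c)) for c in table.counts[i])
                     + "\n")


_META_COLUMNS = ["sample_id", "mouse_id", "age_weeks", "life_phase", "diet", "cage"]


def read_metadata(path: str | os.PathLike) -> list[SampleMetadata]:
    """Read a QIIME-style mapping TSV into SampleMetadata records."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("sample_id", "mouse_id", "age_weeks") if c not in df.columns]
    if missing:
        raise ParseError(f"metadata lacks required columns: {missing}")
    records = []
    for _, row in df.iterrows():
        records.append(SampleMetadata(
            sample_id=str(row["sample_id"]),
            mouse_id=str(row["mouse_id"]),
            age_weeks=float(row["age_weeks"]),
            life_phase=str(row.get("life_phase", INTERMEDIATE)),
            diet=str(row.get("diet", "standard")),
            cage=str(row.get("cage", "")),
        ))
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ParseError(f"duplicate sample ids in metadata: {dupes}")
    return records


def write_metadata(metadata: Iterable[SampleMetadata], path: str | os.PathLike) -> None:
    rows = [dataclasses.asdict(m) for m in metadata]
    pd.DataFrame(rows, columns=_META_COLUMNS).to_csv(path, sep="\t", index=False)


def read_distance_matrix_tsv(path: str | os.PathLike):
    """Read a square TSV distance matrix into a skbio DistanceMatrix."""
    from skbio import DistanceMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ParseError("distance matrix row and column ids differ")
    return DistanceMatrix(df.to_numpy(dtype=float), ids=[str(i) for i in df.index])


def write_distance_matrix_tsv(dm, path: str | os.PathLike) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Table-level operations
# ---------------------------------------------------------------------------

def filter_low_prevalence(table: CountTable, min_samples: int) -> CountTable:
    """Drop taxa observed (count > 0) in fewer than ``min_samples`` samples.

    The study removed ASVs present in fewer than five samples to
    minimise spurious reads.  Retained counts are untouched; the sample
    set never changes.  Idempotent.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    prevalence = (table.counts > 0).sum(axis=1)
    keep = prevalence >= min_samples
    return CountTable([t for t, k in zip(table.taxon_ids, keep) if k],
                      list(table.sample_ids), table.counts[keep].copy())


@dataclass
class JoinedTable:
    """A CountTable joined with per-sample metadata, sample order preserved."""

    table: CountTable
    metadata: list[SampleMetadata]

    def __post_init__(self) -> None:
        by_id = {m.sample_id: m for m in self.metadata}
        orphans = [s for s in self.table.sample_ids if s not in by_id]
        if orphans:
            raise KeyError(f"samples without metadata: {orphans}")
        # keep only rows for table samples, in table order
        self.metadata = [by_id[s] for s in self.table.sample_ids]

    def column(self, attr: str) -> list:
        return [getattr(m, attr) for m in self.metadata]

    def group_samples(self, attr: str) -> dict:
        """Sample ids grouped by a metadata attribute (phase/age/diet/mouse)."""
        groups: dict = {}
        for m in self.metadata:
            groups.setdefault(getattr(m, attr), []).append(m.sample_id)
        return groups


def join_metadata(table: CountTable, metadata: Iterable[SampleMetadata]) -> JoinedTable:
    """Attach metadata to a count table; every sample must have a row."""
    return JoinedTable(table, list(metadata))
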