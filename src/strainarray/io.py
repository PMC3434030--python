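"""Data model and readers/writers for probe-level microarray tables.

The raw input is a pair of wide TSV tables of perfect-match (PM) and
mismatch (MM) probe intensities (rows = probes, columns = samples), a
sample-metadata table, and optional gene-category annotation.  Probe rows
are identified as ``<probeset_id>:<probe_index>``; quality-control probe
sets (identifier prefix ``AFFX-`` by default) are flagged at load so they
can be excluded from candidate gene lists while still flowing through
preprocessing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "MetadataError",
    "SampleInfo",
    "ProbeLevelDataset",
    "ExpressionMatrix",
    "AnnotationTable",
    "load_probe_level_dataset",
    "load_annotation_table",
    "write_result_table",
    "read_result_table",
]

DEFAULT_CONTROL_PREFIX = "AFFX-"
MIN_PROBES_PER_SET = 3


class FormatError(ValueError):
    """A table does not have the shape or columns the format requires."""


class MetadataError(ValueError):
    """Sample metadata violates the study design (e.g. inconsistent strain
    -> domestication mapping, duplicate sample ids)."""


@dataclass(frozen=True)
class SampleInfo:
    """One hybridized sample: a pool of same-sex, same-strain fish."""

    sample_id: str
    strain: str
    domestication: str  # "wild" | "domesticated"
    sex: str  # "M" | "F"
    pool_size: int

    def __post_init__(self) -> None:
        if self.domestication not in ("wild", "domesticated"):
            raise MetadataError(
                f"sample {self.sample_id}: domestication must be 'wild' or "
                f"'domesticated', got {self.domestication!r}"
            )
        if self.sex not in ("M", "F"):
            raise MetadataError(
                f"sample {self.sample_id}: sex must be 'M' or 'F', got {self.sex!r}"
            )
        if self.pool_size <= 0:
            raise MetadataError(
                f"sample {self.sample_id}: pool_size must be positive"
            )


def _validate_samples(samples: Sequence[SampleInfo]) -> None:
    ids = [s.sample_id for s in samples]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise MetadataError(f"duplicate sample ids: {dupes}")
    strain_dom: dict[str, str] = {}
    for s in samples:
        prev = strain_dom.setdefault(s.strain, s.domestication)
        if prev != s.domestication:
            raise MetadataError(
                f"strain {s.strain!r} mapped to both {prev!r} and "
                f"{s.domestication!r}"
            )


@dataclass
class ProbeLevelDataset:
    """PM/MM intensities with probe->probe-set mapping and sample metadata.

    ``pm`` and ``mm`` are probes x samples arrays with identical shape and
    row order; ``probe_map`` carries one row per probe with columns
    ``probeset_id`` and ``probe_index``.
    """

    pm: np.ndarray
    mm: np.ndarray
    probe_map: pd.DataFrame
    samples: list[SampleInfo]
    control_prefix: str = DEFAULT_CONTROL_PREFIX

    def __post_init__(self) -> None:
        self.pm = np.asarray(self.pm, dtype=float)
        self.mm = np.asarray(self.mm, dtype=float)
        if self.pm.shape != self.mm.shape:
            raise FormatError(
                f"PM shape {self.pm.shape} != MM shape {self.mm.shape}"
            )
        if self.pm.ndim != 2:
            raise FormatError("intensity matrices must be 2-D (probes x samples)")
        if len(self.probe_map) != self.pm.shape[0]:
            raise FormatError(
                f"probe_map has {len(self.probe_map)} rows but PM has "
                f"{self.pm.shape[0]}"
            )
        if self.pm.shape[1] != len(self.samples):
            raise FormatError(
                f"{self.pm.shape[1]} intensity columns but {len(self.samples)} samples"
            )
        if not (np.isfinite(self.pm).all() and np.isfinite(self.mm).all()):
            raise ValueError("non-finite intensity")
        if (self.pm <= 0).any() or (self.mm <= 0).any():
            raise ValueError("all intensities must be strictly positive")
        _validate_samples(self.samples)
        counts = self.probe_map.groupby("probeset_id", sort=False).size()
        too_small = counts[counts < MIN_PROBES_PER_SET]
        if len(too_small):
            raise FormatError(
                f"probe sets with < {MIN_PROBES_PER_SET} probe pairs: "
                f"{list(too_small.index[:5])}"
            )

    # -- convenience accessors -------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def probeset_ids(self) -> list[str]:
        return list(dict.fromkeys(self.probe_map["probeset_id"]))

    @property
    def n_probesets(self) -> int:
        return self.probe_map["probeset_id"].nunique()

    def control_flags(self) -> pd.Series:
        """Boolean Series over probe-set ids: True = quality-control feature."""
        ids = pd.Index(self.probeset_ids)
        return pd.Series(ids.str.startswith(self.control_prefix), index=ids)

    def strain_of(self) -> pd.Series:
        return pd.Series(
            [s.strain for s in self.samples], index=self.sample_ids
        )


@dataclass
class ExpressionMatrix:
    """Probe-set x sample matrix of log2 expression."""

    values: pd.DataFrame  # index = probeset_id, columns = sample_id

    def __post_init__(self) -> None:
        v = self.values
        if not np.isfinite(v.to_numpy()).all():
            raise ValueError("expression values must be finite")
        if v.index.has_duplicates:
            raise ValueError("duplicate probe-set ids")
        if v.columns.has_duplicates:
            raise ValueError("duplicate sample ids")

    @property
    def probeset_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset(self, probesets: Iterable[str]) -> "ExpressionMatrix":
        keep = [p for p in self.probeset_ids if p in set(probesets)]
        return ExpressionMatrix(self.values.loc[keep])


@dataclass
class AnnotationTable:
    """probeset_id -> set of category ids, with human-readable labels."""

    membership: dict[str, set[str]]
    labels: dict[str, str] = field(default_factory=dict)

    def categories(self) -> list[str]:
        cats: set[str] = set()
        for s in self.membership.values():
            cats |= s
        return sorted(cats)

    def members_of(self, category: str) -> set[str]:
        return {p for p, cats in self.membership.items() if category in cats}


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _read_intensity_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise FormatError(f"{path}: empty intensity table")
    return df


def _split_probe_ids(ids: pd.Index) -> pd.DataFrame:
    probesets, indices = [], []
    for rid in ids:
        probeset, _, idx = str(rid).rpartition(":")
        if not probeset or not idx.isdigit():
            raise FormatError(
                f"probe row id {rid!r} is not of the form 'probeset_id:probe_index'"
            )
        probesets.append(probeset)
        indices.append(int(idx))
    return pd.DataFrame({"probeset_id": probesets, "probe_index": indices})


def load_probe_level_dataset(
    pm_path: str | Path,
    mm_path: str | Path,
    samples_path: str | Path,
    control_prefix: str = DEFAULT_CONTROL_PREFIX,
) -> ProbeLevelDataset:
    """Load and validate a probe-level dataset from wide TSV tables.

    Raises
    ------
    FormatError
        If PM/MM shapes or row ids disagree, or required columns are missing.
    MetadataError
        If sample metadata is internally inconsistent.
    """
    pm = _read_intensity_table(pm_path)
    mm = _read_intensity_table(mm_path)
    if pm.shape != mm.shape or list(pm.index) != list(mm.index):
        raise FormatError(
            f"PM ({pm.shape}) and MM ({mm.shape}) tables do not share "
            "shape and row identifiers"
        )
    if list(pm.columns) != list(mm.columns):
        raise FormatError("PM and MM tables have different sample columns")

    meta = pd.read_csv(samples_path, sep="\t", dtype=str)
    required = {"sample_id", "strain", "domestication", "sex", "pool_size"}
    missing = required - set(meta.columns)
    if missing:
        raise FormatError(f"samples table missing columns: {sorted(missing)}")
    samples = [
        SampleInfo(
            sample_id=row.sample_id,
            strain=row.strain,
            domestication=row.domestication,
            sex=row.sex,
            pool_size=int(row.pool_size),
        )
        for row in meta.itertuples()
    ]
    order = {s.sample_id: s for s in samples}
    unknown = [c for c in pm.columns if c not in order]
    if unknown:
        raise MetadataError(f"intensity columns without metadata: {unknown}")
    samples = [order[c] for c in pm.columns]

    probe_map = _split_probe_ids(pm.index)
    return ProbeLevelDataset(
        pm=pm.to_numpy(dtype=float),
        mm=mm.to_numpy(dtype=float),
        probe_map=probe_map,
        samples=samples,
        control_prefix=control_prefix,
    )


def write_probe_level_dataset(dataset: ProbeLevelDataset, out_dir: str | Path) -> None:
    """Write pm.tsv, mm.tsv and samples.tsv for a dataset."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    row_ids = [
        f"{ps}:{ix}"
        for ps, ix in zip(dataset.probe_map["probeset_id"], dataset.probe_map["probe_index"])
    ]
    for name, mat in (("pm", dataset.pm), ("mm", dataset.mm)):
        df = pd.DataFrame(mat, index=row_ids, columns=dataset.sample_ids)
        df.index.name = "probe_id"
        df.to_csv(out / f"{name}.tsv", sep="\t", float_format="%.12g")
    meta = pd.DataFrame(
        [
            (s.sample_id, s.strain, s.domestication, s.sex, s.pool_size)
            for s in dataset.samples
        ],
        columns=["sample_id", "strain", "domestication", "sex", "pool_size"],
    )
    meta.to_csv(out / "samples.tsv", sep="\t", index=False)


def load_annotation_table(path: str | Path) -> AnnotationTable:
    """Read a probeset -> category TSV (columns probeset_id, category_id,
    category_label); duplicated memberships are dropped with a warning."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"probeset_id", "category_id", "category_label"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"annotation table missing columns: {sorted(missing)}")
    if df.empty:
        raise FormatError(f"{path}: annotation table has no rows")
    n_dup = df.duplicated(subset=["probeset_id", "category_id"]).sum()
    if n_dup:
        warnings.warn(f"{n_dup} duplicate annotation rows dropped", stacklevel=2)
        df = df.drop_duplicates(subset=["probeset_id", "category_id"])
    membership: dict[str, set[str]] = {}
    labels: dict[str, str] = {}
    for row in df.itertuples():
        membership.setdefault(row.probeset_id, set()).add(row.category_id)
        labels.setdefault(row.category_id, row.category_label)
    return AnnotationTable(membership=membership, labels=labels)


def write_result_table(
    result: pd.DataFrame,
    path: str | Path,
    id_column: str | None = None,
    p_column: str | None = None,
) -> None:
    """Write a result table as TSV with a deterministic row order.

    Rows are sorted by adjusted p-value (if a column named ``adj_p`` or the
    one passed as ``p_column`` exists) and identifier; floats are printed
    with 12 significant digits so load . write is the identity.
    """
    df = result.copy()
    if id_column is None:
        id_column = df.columns[0]
    sort_cols = []
    if p_column is None and "adj_p" in df.columns:
        p_column = "adj_p"
    if p_column is not None and p_column in df.columns:
        sort_cols.append(p_column)
    sort_cols.append(id_column)
    df = df.sort_values(sort_cols, kind="mergesort")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_result_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
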