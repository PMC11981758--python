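"""Core data containers and file I/O for genus-level abundance analysis.

The canonical in-memory layout is taxa x samples, held in a pandas DataFrame
(taxon ids on the index, sample ids on the columns).  Tables carry a ``kind``
flag distinguishing integer read counts from relative abundances (columns
summing to one).  Metadata rows pair each sample with a phenotype group and
optional TNM stage and survival information.  Phylogenies are scikit-bio
``TreeNode`` objects read from Newick.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import skbio

__all__ = [
    "AbundanceTable",
    "CohortMetadata",
    "FormatError",
    "read_abundance_table",
    "write_abundance_table",
    "to_relative_abundance",
    "rarefy_to_min_depth",
    "read_newick",
    "read_metadata",
    "write_metadata",
    "metadata_frame",
]

_REL_TOL = 1e-6  # column-sum tolerance when inferring relative tables


class FormatError(ValueError):
    """Raised when an input table or metadata file violates the format contract."""


@dataclass
class AbundanceTable:
    """A taxa x samples matrix of counts or relative abundances.

    Parameters
    ----------
    data:
        DataFrame with taxon ids as index and sample ids as columns; all
        entries non-negative.
    kind:
        ``"counts"`` or ``"relative"``.  Relative tables must have every
        column summing to 1 (within 1e-9 after normalisation, 1e-6 on read).
    """

    data: pd.DataFrame
    kind: str = "counts"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "relative"):
            raise FormatError(f"unknown table kind {self.kind!r}")
        if self.data.index.has_duplicates:
            raise FormatError("duplicate taxon identifiers")
        if self.data.columns.has_duplicates:
            raise FormatError("duplicate sample identifiers")
        values = self.data.to_numpy()
        if values.size == 0:
            raise FormatError("empty abundance table")
        if not np.issubdtype(values.dtype, np.number):
            raise FormatError("non-numeric entries in abundance table")
        if np.isnan(values).any():
            raise FormatError("missing values in abundance table")
        if (values < 0).any():
            raise FormatError("negative entries in abundance table")
        if self.kind == "relative":
            sums = values.sum(axis=0)
            if not np.allclose(sums, 1.0, atol=1e-6):
                bad = self.data.columns[np.abs(sums - 1.0) > 1e-6]
                raise FormatError(f"relative table columns not summing to 1: {list(bad)}")

    @property
    def taxon_ids(self) -> list[str]:
        return [str(t) for t in self.data.index]

    @property
    def sample_ids(self) -> list[str]:
        return [str(s) for s in self.data.columns]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def relative(self) -> "AbundanceTable":
        """Return this table as relative abundances (no-op if already relative)."""
        if self.kind == "relative":
            return self
        return to_relative_abundance(self)


@dataclass
class CohortMetadata:
    """Per-sample phenotype record.

    ``event`` must be present exactly when ``survival_time`` is (1 = death,
    0 = censored).  ``tnm_stage`` uses Roman numerals I-IV.
    """

    sample_id: str
    group: str
    tnm_stage: str | None = None
    survival_time: float | None = None
    event: int | None = None
    extra: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.survival_time is None) != (self.event is None):
            raise FormatError(
                f"sample {self.sample_id}: survival_time and event must be given together"
            )
        if self.survival_time is not None and self.survival_time <= 0:
            raise FormatError(f"sample {self.sample_id}: survival_time must be positive")
        if self.event is not None and self.event not in (0, 1):
            raise FormatError(f"sample {self.sample_id}: event must be 0 or 1")
        if self.tnm_stage is not None and self.tnm_stage not in ("I", "II", "III", "IV"):
            raise FormatError(f"sample {self.sample_id}: bad TNM stage {self.tnm_stage!r}")

    @property
    def advanced_stage(self) -> bool | None:
        """True for TNM III-IV, False for I-II, None when stage is missing."""
        if self.tnm_stage is None:
            return None
        return self.tnm_stage in ("III", "IV")


def read_abundance_table(path, orientation: str = "taxa_rows") -> AbundanceTable:
    """Read a TSV abundance table.

    The first column holds row identifiers and the header row column
    identifiers.  ``orientation`` says whether rows are taxa (``taxa_rows``)
    or samples (``samples_rows``); the returned table is always taxa x
    samples.  ``kind`` is inferred: if every sample column sums to ~1 the
    table is treated as relative abundances, otherwise as counts.
    """
    if orientation not in ("taxa_rows", "samples_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty abundance file: {path}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise FormatError(f"empty abundance table: {path}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            raise FormatError(f"non-numeric cell in column {col!r}")
    if orientation == "samples_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    sums = df.to_numpy().sum(axis=0)
    kind = "relative" if np.allclose(sums, 1.0, atol=_REL_TOL) else "counts"
    return AbundanceTable(df, kind=kind)


def write_abundance_table(table: AbundanceTable, path) -> None:
    """Write a table as TSV, taxa as rows; counts are written as integers."""
    df = table.data
    if table.kind == "counts" and np.allclose(df.to_numpy() % 1, 0):
        df = df.astype(np.int64)
    df.to_csv(path, sep="\t", index_label="taxon_id")


def to_relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Normalise each sample column to sum to one."""
    if table.kind != "counts":
        raise ValueError("table is already relative")
    totals = table.values.sum(axis=0)
    zero = np.asarray(table.sample_ids)[totals == 0]
    if zero.size:
        raise ValueError(f"zero-total sample(s): {list(zero)}")
    return AbundanceTable(table.data / totals, kind="relative")


def rarefy_to_min_depth(
    table: AbundanceTable,
    seed: int,
    min_depth_floor: int | None = None,
) -> AbundanceTable:
    """Subsample every sample, without replacement, to the minimum depth.

    Samples whose depth falls below ``min_depth_floor`` are dropped (with a
    warning naming them); the remaining samples are drawn down to the minimum
    retained depth using a multivariate hypergeometric draw, so each taxon's
    rarefied count never exceeds its original count.  Deterministic per seed.
    """
    if table.kind != "counts":
        raise ValueError("rarefaction requires a counts table")
    counts = np.rint(table.values).astype(np.int64)
    if not np.allclose(table.values, counts):
        raise ValueError("rarefaction requires integer counts")
    depths = counts.sum(axis=0)
    keep = np.ones(table.n_samples, dtype=bool)
    if min_depth_floor is not None:
        keep = depths >= int(min_depth_floor)
        dropped = [s for s, k in zip(table.sample_ids, keep) if not k]
        if dropped:
            warnings.warn(
                f"rarefaction dropped {len(dropped)} sample(s) below depth "
                f"{min_depth_floor}: {dropped}",
                stacklevel=2,
            )
    if not keep.any():
        raise ValueError("no samples at or above the rarefaction floor")
    counts = counts[:, keep]
    target = int(counts.sum(axis=0).min())
    if target == 0:
        raise ValueError("cannot rarefy: a retained sample has zero depth")
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts)
    for j in range(counts.shape[1]):
        out[:, j] = rng.multivariate_hypergeometric(counts[:, j], target)
    cols = [s for s, k in zip(table.sample_ids, keep) if k]
    return AbundanceTable(
        pd.DataFrame(out, index=table.data.index, columns=cols), kind="counts"
    )


def read_newick(path) -> skbio.TreeNode:
    """Read a rooted Newick tree, checking leaf-name uniqueness and branch lengths."""
    tree = skbio.TreeNode.read(str(path), format="newick")
    names = [t.name for t in tree.tips()]
    if len(names) == 0:
        raise FormatError("tree has no leaves")
    if any(n is None for n in names):
        raise FormatError("tree has unnamed leaves")
    if len(set(names)) != len(names):
        raise FormatError("duplicate leaf names in tree")
    for node in tree.traverse(include_self=False):
        if node.length is not None and node.length < 0:
            raise FormatError("negative branch length in tree")
    return tree


def read_metadata(path) -> list[CohortMetadata]:
    """Read a sample metadata TSV with required columns sample_id and group.

    Optional columns: tnm_stage, survival_time, event; any other column is
    kept in the record's ``extra`` map.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"empty metadata file: {path}") from exc
    if df.shape[0] == 0:
        raise FormatError(f"metadata file has no rows: {path}")
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise FormatError(f"metadata missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise FormatError(f"duplicate sample ids in metadata: {dups}")
    known = {"sample_id", "group", "tnm_stage", "survival_time", "event"}
    records = []
    for _, row in df.iterrows():
        stage = row.get("tnm_stage")
        stage = None if pd.isna(stage) or stage == "" else str(stage)
        stime = row.get("survival_time")
        stime = None if pd.isna(stime) or stime == "" else float(stime)
        event = row.get("event")
        event = None if pd.isna(event) or event == "" else int(float(event))
        extra = {
            c: str(row[c]) for c in df.columns if c not in known and not pd.isna(row[c])
        }
        records.append(
            CohortMetadata(
                sample_id=str(row["sample_id"]),
                group=str(row["group"]),
                tnm_stage=stage,
                survival_time=stime,
                event=event,
                extra=extra,
            )
        )
    return records


def write_metadata(records: list[CohortMetadata], path) -> None:
    metadata_frame(records).to_csv(path, sep="\t", index=False)


def metadata_frame(records: list[CohortMetadata]) -> pd.DataFrame:
    """Tabular view of a metadata list (one row per sample)."""
    extra_keys = sorted({k for r in records for k in r.extra})
    rows = []
    for r in records:
        row = {
            "sample_id": r.sample_id,
            "group": r.group,
            "tnm_stage": r.tnm_stage,
            "survival_time": r.survival_time,
            "event": r.event,
        }
        for k in extra_keys:
            row[k] = r.extra.get(k)
        rows.append(row)
    return pd.DataFrame(rows)


def check_alignment(table: AbundanceTable, records: list[CohortMetadata]) -> None:
    """Require the metadata sample set to equal the table's sample set."""
    t = set(table.sample_ids)
    m = {r.sample_id for r in records}
    if t != m:
        missing = sorted(t - m)
        extra = sorted(m - t)
        raise FormatError(
            f"metadata/table sample mismatch; missing from metadata: {missing}, "
            f"not in table: {extra}"
        )
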