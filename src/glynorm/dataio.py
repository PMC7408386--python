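"""Reading and writing abundance tables, metadata, pathways and rankings.

The canonical in-memory container is :class:`GlycomicsDataset`: a pandas
DataFrame of non-negative abundances with samples in rows and glycans in
columns, plus optional per-sample metadata (age) and per-glycan metadata
(subclass, composition string, mass key).  Before any normalization the
complete-case filter :func:`drop_incomplete_samples` removes every sample
with at least one missing value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .glycan_model import ReferencePathway

logger = logging.getLogger(__name__)

__all__ = [
    "GlycomicsDataset",
    "read_abundance_table",
    "drop_incomplete_samples",
    "read_pathway_edges",
    "write_results",
    "read_results",
]

PLATFORMS = ("lc-esi-ms", "uhplc-fld", "maldi-fticr-ms", "generic")

# accepted missing-value tokens (case-insensitive), common in exported
# spectral tables
NA_TOKENS = {"", "na", "nan"}


@dataclass
class GlycomicsDataset:
    """Samples x glycans abundance matrix with metadata.

    ``abundance`` is indexed by sample id with glycan ids as columns.
    ``sample_meta`` (indexed like rows) may carry ``age`` in years;
    ``glycan_meta`` (indexed like columns) may carry ``subclass``,
    ``composition`` and ``mass``.
    """

    abundance: pd.DataFrame
    sample_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    glycan_meta: pd.DataFrame = field(default_factory=pd.DataFrame)
    platform: str = "generic"

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValueError(f"unknown platform {self.platform!r}; expected one of {PLATFORMS}")
        if self.abundance.index.has_duplicates:
            dups = self.abundance.index[self.abundance.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if self.abundance.columns.has_duplicates:
            dups = self.abundance.columns[self.abundance.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate glycan ids: {dups}")
        if self.sample_meta.empty:
            self.sample_meta = pd.DataFrame(index=self.abundance.index)
        if self.glycan_meta.empty:
            self.glycan_meta = pd.DataFrame(index=self.abundance.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.abundance.index)

    @property
    def glycan_ids(self) -> list[str]:
        return list(self.abundance.columns)

    @property
    def n_samples(self) -> int:
        return self.abundance.shape[0]

    @property
    def n_glycans(self) -> int:
        return self.abundance.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.abundance.to_numpy(dtype=float)

    def with_values(self, values: np.ndarray) -> "GlycomicsDataset":
        """Same dataset with the abundance matrix replaced (shape preserved)."""
        if values.shape != self.abundance.shape:
            raise ValueError(f"shape mismatch: {values.shape} vs {self.abundance.shape}")
        df = pd.DataFrame(values, index=self.abundance.index, columns=self.abundance.columns)
        return replace(self, abundance=df)

    def subclasses(self) -> pd.Series:
        if "subclass" not in self.glycan_meta.columns:
            raise ValueError("glycan metadata carries no 'subclass' column")
        sub = self.glycan_meta["subclass"]
        if sub.isna().any():
            missing = sub.index[sub.isna()].tolist()
            raise ValueError(f"missing subclass label for glycans: {missing}")
        return sub


def _read_delimited(path, sep: str | None) -> pd.DataFrame:
    if sep is None:
        sep = "," if str(path).lower().endswith(".csv") else "\t"
    df = pd.read_csv(
        path, sep=sep, index_col=0, dtype=str, keep_default_na=False, na_values=[]
    )
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate row ids {dups}")
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate column ids {dups}")
    return df


def _to_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    out = np.empty(df.shape, dtype=float)
    arr = df.to_numpy(dtype=object)
    for i in range(arr.shape[0]):
        for j in range(arr.shape[1]):
            cell = str(arr[i, j]).strip()
            if cell.lower() in NA_TOKENS:
                out[i, j] = np.nan
                continue
            try:
                out[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at row {df.index[i]!r}, "
                    f"column {df.columns[j]!r}"
                ) from None
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def read_abundance_table(
    path,
    orientation: str = "samples_in_rows",
    sample_meta_path=None,
    glycan_meta_path=None,
    platform: str = "generic",
    sep: str | None = None,
) -> GlycomicsDataset:
    """Read a delimited abundance table into canonical samples x glycans form.

    Delimiter is sniffed from the extension (``.csv`` -> comma, else tab)
    unless ``sep`` is given.  Empty cells and the tokens NA/NaN (any case)
    are recorded as missing; any other non-numeric cell is an error naming
    its row and column.
    """
    if orientation not in ("samples_in_rows", "glycans_in_rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _to_numeric(_read_delimited(path, sep), path)
    if orientation == "glycans_in_rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None

    sample_meta = pd.DataFrame(index=df.index)
    if sample_meta_path is not None:
        meta = _read_delimited(sample_meta_path, sep)
        meta.index = meta.index.astype(str)
        sample_meta = meta.reindex(df.index)
        if "age" in sample_meta.columns:
            # plain float() is correctly rounded, unlike pandas' fast parser
            sample_meta["age"] = sample_meta["age"].map(
                lambda v: np.nan
                if v is None or str(v).strip().lower() in NA_TOKENS
                else float(v)
            )
    glycan_meta = pd.DataFrame(index=df.columns)
    if glycan_meta_path is not None:
        meta = _read_delimited(glycan_meta_path, sep)
        meta.index = meta.index.astype(str)
        glycan_meta = meta.reindex(df.columns)
        glycan_meta = glycan_meta.replace("", np.nan)

    return GlycomicsDataset(df, sample_meta, glycan_meta, platform)


def drop_incomplete_samples(d: GlycomicsDataset) -> tuple[GlycomicsDataset, int]:
    """Complete-case filter: remove every sample with >= 1 missing value.

    Sample order is preserved; the number of removed samples is returned
    and logged.  Idempotent.  Raises if no sample survives.
    """
    keep = ~d.abundance.isna().any(axis=1)
    n_removed = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError("all samples contain missing values; nothing left after filtering")
    filtered = GlycomicsDataset(
        d.abundance.loc[keep],
        d.sample_meta.loc[keep],
        d.glycan_meta,
        d.platform,
    )
    logger.info("complete-case filter: removed %d of %d samples", n_removed, d.n_samples)
    return filtered, n_removed


def read_pathway_edges(path, nodes, sep: str | None = None) -> ReferencePathway:
    """Read a two-column edge list into a pathway over ``nodes``.

    Every edge endpoint must resolve against ``nodes`` (typically the
    dataset's glycan ids); self-loops and unknown names are rejected.
    Duplicate edge lines collapse to a single canonical edge.
    """
    if sep is None:
        sep = "," if str(path).lower().endswith(".csv") else "\t"
    node_list = list(nodes)
    known = set(node_list)
    edges: set[tuple[str, str]] = set()
    with open(path) as fh:
        header_skipped = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = [p.strip() for p in line.split(sep)]
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected two columns, got {line!r}")
            a, b = parts[0], parts[1]
            if not header_skipped and (a not in known and b not in known):
                # tolerate a single header line such as "node1\tnode2"
                header_skipped = True
                continue
            header_skipped = True
            if a == b:
                raise ValueError(f"{path}:{lineno}: self-loop at {a!r}")
            for name in (a, b):
                if name not in known:
                    raise ValueError(f"{path}:{lineno}: unknown node {name!r}")
            edges.add(tuple(sorted((a, b))))
    return ReferencePathway(node_list, edges)


def write_results(evaluations, path, header_comment: str | None = None) -> None:
    """Write a strategy ranking TSV: label, median p, CI bounds, rank.

    Rows are ordered by ascending median p with ties broken by label;
    floats are written with 12 significant digits so a re-read reproduces
    them. An optional ``#``-prefixed provenance line is written first.
    """
    rows = sorted(evaluations, key=lambda e: (e.median_p, e.label))
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write("label\tmedian_p\tci_low\tci_high\trank\n")
        for rank, ev in enumerate(rows, start=1):
            fh.write(
                f"{ev.label}\t{ev.median_p:.12g}\t{ev.ci_low:.12g}\t"
                f"{ev.ci_high:.12g}\t{rank}\n"
            )


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
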