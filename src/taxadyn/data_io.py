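"""Validated I/O for count tables, resource series, sequences, and result tables.

This module contains no science: it reads and writes the tabular and
sequence formats the framework touches and enforces the structural
invariants downstream code relies on (integer non-negative counts, unique
identifiers, strictly increasing sampling days within a replicate).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

SCHEMA_VERSION = "taxadyn-schema-1"

__all__ = [
    "CountTable",
    "ResourceSeries",
    "SequenceSet",
    "read_count_table",
    "read_resource_series",
    "read_sequences",
    "write_results",
    "read_results",
]


class DataValidationError(ValueError):
    """Raised when an input file violates a structural invariant."""


def _sep_for(path: os.PathLike | str, sep: str | None) -> str:
    if sep is not None:
        return sep
    suffix = Path(path).suffix.lower()
    return "," if suffix == ".csv" else "\t"


@dataclass
class CountTable:
    """Taxa-by-samples read counts with per-sample metadata.

    ``counts`` is a non-negative integer matrix with one row per taxon
    and one column per sample.  ``metadata`` is indexed by sample id and
    carries ``replicate_id``, ``day`` (real-valued, days) and ``group``.
    Samples are kept sorted by ``(replicate_id, day)``.
    """

    taxon_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.validate()

    # -- structural checks -------------------------------------------------
    def validate(self) -> None:
        n_taxa, n_samples = self.counts.shape
        if len(self.taxon_ids) != n_taxa or len(self.sample_ids) != n_samples:
            raise DataValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.taxon_ids)} taxa x {len(self.sample_ids)} samples"
            )
        if len(set(self.taxon_ids)) != n_taxa:
            raise DataValidationError("duplicate taxon ids")
        if len(set(self.sample_ids)) != n_samples:
            raise DataValidationError("duplicate sample ids")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                bad = np.argwhere(self.counts != np.round(self.counts))[0]
                raise DataValidationError(
                    f"non-integer count at taxon {self.taxon_ids[bad[0]]}, "
                    f"sample {self.sample_ids[bad[1]]}"
                )
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            bad = np.argwhere(self.counts < 0)[0]
            raise DataValidationError(
                f"negative count at taxon {self.taxon_ids[bad[0]]}, "
                f"sample {self.sample_ids[bad[1]]}"
            )
        missing = [s for s in self.sample_ids if s not in self.metadata.index]
        if missing:
            raise DataValidationError(
                f"samples missing from metadata: {', '.join(missing)}"
            )
        for col in ("replicate_id", "day"):
            if col not in self.metadata.columns:
                raise DataValidationError(f"metadata lacks required column {col!r}")
        days = pd.to_numeric(self.metadata.loc[self.sample_ids, "day"], errors="coerce")
        if days.isna().any():
            bad = days.index[days.isna()][0]
            raise DataValidationError(f"sample {bad!r} has a non-finite day")
        meta = self.metadata.loc[self.sample_ids]
        for rep, sub in meta.groupby("replicate_id"):
            d = np.sort(sub["day"].to_numpy(dtype=float))
            if len(d) > 1 and (np.diff(d) <= 0).any():
                raise DataValidationError(
                    f"replicate {rep!r} has duplicated sampling days"
                )

    def sort_samples(self) -> "CountTable":
        """Return a copy with samples ordered by (replicate_id, day)."""
        meta = self.metadata.loc[self.sample_ids]
        order = meta.sort_values(["replicate_id", "day"]).index.tolist()
        idx = [self.sample_ids.index(s) for s in order]
        return CountTable(
            taxon_ids=list(self.taxon_ids),
            sample_ids=order,
            counts=self.counts[:, idx],
            metadata=self.metadata,
        )

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def replicates(self) -> list[str]:
        meta = self.metadata.loc[self.sample_ids]
        return sorted(meta["replicate_id"].unique().tolist())


@dataclass
class ResourceSeries:
    """Resource measurements for one replicate over time.

    ``values`` has one row per day and one column per resource, in the
    units supplied (e.g. g/L volatile solids).
    """

    replicate_id: str
    resource_names: list[str]
    days: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.days = np.asarray(self.days, dtype=float)
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[0] != len(self.days):
            self.values = self.values.reshape(len(self.days), -1)
        if not np.isfinite(self.values).all():
            raise DataValidationError(
                f"non-finite resource value in replicate {self.replicate_id!r}"
            )
        if not np.isfinite(self.days).all():
            raise DataValidationError("non-finite day in resource series")
        if len(np.unique(self.days)) != len(self.days):
            raise DataValidationError(
                f"duplicated (replicate, day) in resource series "
                f"for {self.replicate_id!r}"
            )
        order = np.argsort(self.days)
        self.days = self.days[order]
        self.values = self.values[order]

    def at(self, days: Iterable[float]) -> np.ndarray:
        """Resource values at the given days, linearly interpolated.

        Interpolation never extrapolates: requesting a day outside the
        measured range is an error.
        """
        days = np.asarray(list(days), dtype=float)
        if days.min() < self.days.min() - 1e-9 or days.max() > self.days.max() + 1e-9:
            raise DataValidationError(
                f"resource series for {self.replicate_id!r} covers days "
                f"[{self.days.min()}, {self.days.max()}], cannot supply "
                f"values outside this range"
            )
        out = np.empty((len(days), self.values.shape[1]))
        for j in range(self.values.shape[1]):
            out[:, j] = np.interp(days, self.days, self.values[:, j])
        return out


class SequenceSet(dict):
    """Mapping taxon_id -> nucleotide sequence (IUPAC DNA)."""

    def __setitem__(self, key: str, value: str) -> None:
        if not value:
            raise DataValidationError(f"empty sequence for {key!r}")
        super().__setitem__(key, str(value).upper())


# ---------------------------------------------------------------------------
# readers


def read_count_table(
    counts_path: os.PathLike | str,
    metadata_path: os.PathLike | str,
    *,
    sep: str | None = None,
    orientation: str = "auto",
) -> CountTable:
    """Read a taxa x samples count matrix plus sample metadata.

    The counts file has taxa in rows and samples in columns (or the
    transpose: orientation is detected by matching the metadata sample
    ids, and can be forced with ``orientation='taxa_rows'`` or
    ``'taxa_columns'``).  The metadata file needs columns ``sample_id``,
    ``replicate_id``, ``day`` and optionally ``group``.
    """
    counts = pd.read_csv(counts_path, sep=_sep_for(counts_path, sep), index_col=0)
    meta = pd.read_csv(metadata_path, sep=_sep_for(metadata_path, sep))
    required = {"sample_id", "replicate_id", "day"}
    if not required.issubset(meta.columns):
        raise DataValidationError(
            f"metadata must have columns {sorted(required)}; got {list(meta.columns)}"
        )
    if "group" not in meta.columns:
        meta["group"] = ""
    meta = meta.set_index("sample_id")

    if orientation == "auto":
        cols_match = sum(c in meta.index for c in counts.columns.astype(str))
        rows_match = sum(r in meta.index for r in counts.index.astype(str))
        orientation = "taxa_rows" if cols_match >= rows_match else "taxa_columns"
    if orientation == "taxa_columns":
        counts = counts.T
    elif orientation != "taxa_rows":
        raise ValueError(f"unknown orientation {orientation!r}")

    sample_ids = [str(c) for c in counts.columns]
    missing = [s for s in sample_ids if s not in meta.index]
    if missing:
        raise DataValidationError(
            f"samples missing from metadata: {', '.join(missing)}"
        )
    values = counts.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise DataValidationError("count matrix contains non-numeric entries")
    table = CountTable(
        taxon_ids=[str(t) for t in counts.index],
        sample_ids=sample_ids,
        counts=values,
        metadata=meta,
    )
    return table.sort_samples()


def read_resource_series(
    path: os.PathLike | str, *, sep: str | None = None
) -> list[ResourceSeries]:
    """Read a long-format resource table: replicate_id, day, one column per resource."""
    df = pd.read_csv(path, sep=_sep_for(path, sep))
    if df.empty:
        return []
    for col in ("replicate_id", "day"):
        if col not in df.columns:
            raise DataValidationError(f"resource table lacks column {col!r}")
    resource_names = [c for c in df.columns if c not in ("replicate_id", "day")]
    if not resource_names:
        raise DataValidationError("resource table has no resource columns")
    out = []
    for rep, sub in df.groupby("replicate_id", sort=True):
        vals = sub[resource_names].apply(pd.to_numeric, errors="coerce")
        if vals.isna().any().any():
            raise DataValidationError(
                f"non-numeric resource value in replicate {rep!r}"
            )
        out.append(
            ResourceSeries(
                replicate_id=str(rep),
                resource_names=resource_names,
                days=sub["day"].to_numpy(dtype=float),
                values=vals.to_numpy(dtype=float),
            )
        )
    return out


def read_sequences(path: os.PathLike | str) -> SequenceSet:
    """Read representative sequences from FASTA into a SequenceSet."""
    seqs = SequenceSet()
    for record in SeqIO.parse(str(path), "fasta"):
        seqs[record.id] = str(record.seq)
    return seqs


# ---------------------------------------------------------------------------
# writers


def write_results(
    tables: Mapping[str, pd.DataFrame], out_dir: os.PathLike | str
) -> dict[str, Path]:
    """Write result tables as CSV with a schema-version header comment.

    Returns a mapping table-name -> written path.  Floats are written at
    full precision so that re-reading reproduces values exactly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in tables.items():
        path = out_dir / f"{name}.csv"
        with open(path, "w") as fh:
            fh.write(f"# {SCHEMA_VERSION}\n")
            df.to_csv(fh, index=False, float_format="%.17g")
        paths[name] = path
    return paths


def read_results(path: os.PathLike | str) -> pd.DataFrame:
    """Read back a CSV written by :func:`write_results`."""
    return pd.read_csv(path, comment="#")
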