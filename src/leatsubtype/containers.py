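"""Core in-memory containers and TSV I/O.

The pipeline operates on log-scale expression matrices (genes as rows,
samples as columns) annotated with a per-sample batch label, plus a
per-sample clinical table.  Both are thin wrappers over pandas objects so
that every downstream module can rely on aligned, duplicate-free indices.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: canonical clinical table columns (synthetic cohorts and real tables alike)
CLINICAL_COLUMNS = [
    "sample_id",
    "histology",
    "age",
    "engel",
    "recurrence",
    "braf",
    "cluster",
    "pfs_time",
    "pfs_event",
]


@dataclass
class ExpressionMatrix:
    """Gene-by-sample matrix of log-scale expression values.

    Parameters
    ----------
    values
        DataFrame with unique gene IDs as the row index and unique sample
        IDs as columns.  Rows containing missing values are dropped (and
        logged) at construction.
    batch
        Per-sample batch / dataset label, aligned to ``values.columns``.
    """

    values: pd.DataFrame
    batch: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene IDs: {list(dup[:5])}")
        if self.values.columns.has_duplicates:
            dup = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample IDs: {list(dup[:5])}")
        if self.values.isna().any().any():
            bad = self.values.index[self.values.isna().any(axis=1)]
            logger.warning("dropping %d gene rows with missing values", len(bad))
            self.values = self.values.drop(index=bad)
        if self.batch is None:
            self.batch = pd.Series("batch0", index=self.values.columns, name="batch")
        else:
            self.batch = pd.Series(self.batch)
            missing = self.values.columns.difference(self.batch.index)
            if len(missing):
                raise ValueError(f"batch label missing for samples: {list(missing[:5])}")
            self.batch = self.batch.reindex(self.values.columns)
        self.values = self.values.astype(float)

    # -- convenience -------------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[genes], self.batch)

    def subset_samples(self, samples) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(samples)], self.batch.loc[list(samples)])

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), self.batch.copy())

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path, batch_path=None) -> None:
        """Write the matrix as TSV (first column gene ID, header = sample IDs)."""
        out = self.values.copy()
        out.index.name = "gene_id"
        out.to_csv(path, sep="\t")
        if batch_path is not None:
            b = self.batch.rename("batch").to_frame()
            b.index.name = "sample_id"
            b.to_csv(batch_path, sep="\t")

    @classmethod
    def from_tsv(cls, path, batch=None, batch_path=None) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        values.index.name = None
        values.columns.name = None
        if batch is None and batch_path is not None:
            meta = pd.read_csv(batch_path, sep="\t", index_col=0)
            batch = meta["batch"]
        return cls(values, batch)


def read_clinical_tsv(path) -> pd.DataFrame:
    """Read a per-sample clinical table (TSV with a ``sample_id`` column)."""
    table = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in table.columns:
        raise ValueError("clinical table must contain a 'sample_id' column")
    if table["sample_id"].duplicated().any():
        raise ValueError("duplicate sample IDs in clinical table")
    return table


def write_clinical_tsv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def check_survival_columns(table: pd.DataFrame) -> None:
    """Validate PFS columns: positive times, 0/1 event indicators."""
    times = pd.to_numeric(table["pfs_time"], errors="coerce")
    if (times.dropna() <= 0).any():
        raise ValueError("PFS times must be strictly positive")
    events = set(pd.unique(table["pfs_event"].dropna()))
    if not events <= {0, 1, 0.0, 1.0, True, False}:
        raise ValueError("PFS event indicator must be 0/1")


def as_float_array(x) -> np.ndarray:
    return np.asarray(x, dtype=float)
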