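"""Expression-matrix container shared by all pipeline stages.

Matrices are features-by-samples tables of FPKM-scale or log2-scale
expression values, tagged with the RNA class they carry (mRNA, lncRNA or
miRNA).  The scale flag tracks the transformation history so that stages
with scale preconditions (e.g. the median-FPKM filter) can refuse
already-transformed input.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

RNA_CLASSES = ("mRNA", "lncRNA", "miRNA")
SCALES = ("fpkm", "log2")


class MatrixError(ValueError):
    """Raised for malformed or empty expression matrices."""


@dataclass
class ExpressionMatrix:
    """Features x samples expression grid with class and scale metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature ID with sample IDs as columns.
    rna_class
        One of ``mRNA``, ``lncRNA``, ``miRNA``, or ``gene`` for a mixed
        (not yet biotype-partitioned) matrix.
    scale
        ``fpkm`` for non-negative linear-scale values, ``log2`` after the
        log transform.
    """

    values: pd.DataFrame
    rna_class: str
    scale: str = "fpkm"

    def __post_init__(self) -> None:
        if self.scale not in SCALES:
            raise MatrixError(f"unknown scale {self.scale!r}; expected one of {SCALES}")
        if self.rna_class not in RNA_CLASSES + ("gene",):
            raise MatrixError(
                f"unknown rna_class {self.rna_class!r}; expected one of {RNA_CLASSES + ('gene',)}"
            )
        if self.values.index.has_duplicates:
            raise MatrixError("duplicate feature IDs")
        if self.values.columns.has_duplicates:
            raise MatrixError("duplicate sample IDs")
        if self.scale == "fpkm" and self.values.size and (self.values.to_numpy() < 0).any():
            raise MatrixError("negative values on FPKM scale")

    # -- basic accessors -------------------------------------------------
    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset(
        self,
        features: Sequence[str] | None = None,
        samples: Sequence[str] | None = None,
    ) -> "ExpressionMatrix":
        """Return a copy restricted to the given features and/or samples."""
        values = self.values
        if features is not None:
            values = values.loc[list(features)]
        if samples is not None:
            values = values[list(samples)]
        return replace(self, values=values.copy())

    def with_values(self, values: pd.DataFrame, scale: str | None = None) -> "ExpressionMatrix":
        return replace(self, values=values, scale=scale or self.scale)

    # -- I/O -------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write as tab-separated text: feature rows, sample-ID header."""
        self.values.to_csv(path, sep="\t", index_label="feature")

    @classmethod
    def from_tsv(
        cls, path: str | Path, rna_class: str, scale: str = "fpkm"
    ) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        values.index = values.index.astype(str)
        values.columns = values.columns.astype(str)
        return cls(values=values, rna_class=rna_class, scale=scale)


def read_two_column_table(path: str | Path, value_name: str) -> pd.Series:
    """Read a two-column tab-separated table (ID, value) into a Series."""
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise MatrixError(f"{path}: expected two columns")
    ser = df.set_index(df.columns[0])[df.columns[1]]
    ser.name = value_name
    return ser
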