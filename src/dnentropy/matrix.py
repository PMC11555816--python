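"""Expression-matrix containers and TSV I/O.

The pipeline's in-memory currency is a genes x timepoints real matrix with a
missing-value mask (:class:`ExpressionMatrix`) and its three-state discretized
counterpart (:class:`DiscreteMatrix`).  Time stamps are minutes.

TSV dialect: first column gene id, header row of numeric times; empty cells or
``NA`` mean missing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "DiscreteMatrix", "read_expression_tsv"]


def _as_gene_list(gene_ids: Sequence[str]) -> list[str]:
    genes = [str(g) for g in gene_ids]
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene ids")
    return genes


@dataclass
class ExpressionMatrix:
    """Real-valued genes x timepoints matrix with missing-value mask.

    Parameters
    ----------
    gene_ids
        Ordered gene identifiers (rows).
    times
        Strictly increasing timestamps in minutes (columns).
    values
        Matrix of expression values; entries under the mask are ignored.
    missing_mask
        Boolean matrix, ``True`` where the measurement is missing.
    """

    gene_ids: list[str]
    times: np.ndarray
    values: np.ndarray
    missing_mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.gene_ids = _as_gene_list(self.gene_ids)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.missing_mask is None:
            self.missing_mask = ~np.isfinite(self.values)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("need >=2 timepoints")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.values.shape != (len(self.gene_ids), self.times.size):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {self.times.size} timepoints"
            )
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("mask shape mismatch")
        if not np.all(np.isfinite(self.values[~self.missing_mask])):
            raise ValueError("non-finite value outside missing mask")

    # -- basic views ---------------------------------------------------
    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_times(self) -> int:
        return int(self.times.size)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def row(self, gene: str) -> np.ndarray:
        return self.values[self.gene_index(gene)]

    def missing_rate(self) -> np.ndarray:
        """Per-gene fraction of masked entries."""
        return self.missing_mask.mean(axis=1)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.gene_ids),
            self.times.copy(),
            self.values.copy(),
            self.missing_mask.copy(),
        )

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        idx = [self.gene_index(g) for g in genes]
        return ExpressionMatrix(
            [self.gene_ids[i] for i in idx],
            self.times.copy(),
            self.values[idx].copy(),
            self.missing_mask[idx].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        vals = self.values.astype(object)
        vals = np.where(self.missing_mask, np.nan, self.values)
        return pd.DataFrame(vals, index=self.gene_ids, columns=self.times)

    def write_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "gene"
        df.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")


@dataclass
class DiscreteMatrix:
    """Three-state (1/2/3) discretization of an expression matrix."""

    gene_ids: list[str]
    times: np.ndarray
    states: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = _as_gene_list(self.gene_ids)
        self.times = np.asarray(self.times, dtype=float)
        self.states = np.asarray(self.states, dtype=int)
        if self.states.shape != (len(self.gene_ids), self.times.size):
            raise ValueError("states shape mismatch")
        if not np.isin(self.states, (1, 2, 3)).all():
            raise ValueError("states must be in {1, 2, 3}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_times(self) -> int:
        return int(self.times.size)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"unknown gene {gene!r}") from None

    def restrict_columns(self, col_idx: np.ndarray) -> np.ndarray:
        """States restricted to the given observation columns (genes x k)."""
        return self.states[:, np.asarray(col_idx, dtype=int)]

    def write_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.states, index=self.gene_ids, columns=self.times)
        df.index.name = "gene"
        df.to_csv(path, sep="\t")


def read_expression_tsv(path: str | Path) -> ExpressionMatrix:
    """Read the TSV dialect: gene-id column, numeric-time header, NA/empty missing."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    times = np.array([float(c) for c in df.columns])
    values = df.to_numpy(dtype=float)
    mask = ~np.isfinite(values)
    values = np.where(mask, 0.0, values)
    return ExpressionMatrix(list(df.index), times, values, mask)


def read_discrete_tsv(path: str | Path) -> DiscreteMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    times = np.array([float(c) for c in df.columns])
    return DiscreteMatrix(list(df.index), times, df.to_numpy(dtype=int))
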