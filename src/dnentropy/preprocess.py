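"""Filtering, imputation, normalization and three-state discretization.

The stages mirror standard microarray time-course preparation: drop genes
with too many missing observations, fill the remaining gaps by cubic-spline
interpolation over time, standardize each gene, and map each gene's values
onto three states (low / mid / high) relative to its own mean and spread.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import CubicSpline

from .matrix import DiscreteMatrix, ExpressionMatrix

__all__ = [
    "filter_by_missing_rate",
    "impute_missing",
    "normalize",
    "discretize",
]


def filter_by_missing_rate(m: ExpressionMatrix, max_rate: float) -> ExpressionMatrix:
    """Keep genes whose fraction of missing timepoints is <= ``max_rate``."""
    if not 0.0 <= max_rate <= 1.0:
        raise ValueError("max_rate must be in [0, 1]")
    keep = [g for g, r in zip(m.gene_ids, m.missing_rate()) if r <= max_rate]
    if not keep:
        raise ValueError("empty matrix: all genes exceed the missing-rate cap")
    return m.subset_genes(keep)


def impute_missing(m: ExpressionMatrix) -> ExpressionMatrix:
    """Fill masked entries by cubic-spline interpolation over time.

    The spline uses not-a-knot boundary conditions, so data lying exactly on
    a cubic polynomial are reproduced exactly.  Genes with fewer than 4
    observed points fall back to linear interpolation.  Masked points
    outside the observed time range take the nearest observed value
    (splines should not extrapolate).  Observed entries are never altered.
    """
    values = m.values.copy()
    for gi, gene in enumerate(m.gene_ids):
        miss = m.missing_mask[gi]
        if not miss.any():
            continue
        obs = ~miss
        n_obs = int(obs.sum())
        if n_obs < 2:
            raise ValueError(f"gene {gene!r} has {n_obs} observed points; need >=2")
        t_obs = m.times[obs]
        v_obs = values[gi, obs]
        t_fill = m.times[miss]
        if n_obs >= 4:
            spline = CubicSpline(t_obs, v_obs, bc_type="not-a-knot")
            filled = spline(np.clip(t_fill, t_obs[0], t_obs[-1]))
        else:
            filled = np.interp(t_fill, t_obs, v_obs)
        values[gi, miss] = filled
    return ExpressionMatrix(
        list(m.gene_ids), m.times.copy(), values, np.zeros_like(m.missing_mask)
    )


def normalize(m: ExpressionMatrix, mode: str = "zscore") -> ExpressionMatrix:
    """Per-gene standardization; ``zscore`` (default) or ``minmax``."""
    if m.missing_mask.any():
        raise ValueError("normalize requires a fully observed matrix; impute first")
    values = m.values.copy()
    for gi, gene in enumerate(m.gene_ids):
        row = values[gi]
        if mode == "zscore":
            sd = row.std(ddof=1)
            if sd == 0:
                raise ValueError(f"gene {gene!r} is constant; z-score undefined")
            values[gi] = (row - row.mean()) / sd
        elif mode == "minmax":
            span = row.max() - row.min()
            if span == 0:
                raise ValueError(f"gene {gene!r} is constant; min-max undefined")
            values[gi] = (row - row.min()) / span
        else:
            raise ValueError(f"unknown normalization mode {mode!r}")
    return ExpressionMatrix(
        list(m.gene_ids), m.times.copy(), values, np.zeros_like(m.missing_mask)
    )


def discretize(m: ExpressionMatrix, mode: str = "symmetric") -> DiscreteMatrix:
    """Map each gene onto states {1, 2, 3} relative to its mean and spread.

    ``symmetric`` (default): below mu - s -> 1, within [mu - s, mu + s] -> 2,
    above mu + s -> 3, where s is the per-gene sample standard deviation.

    ``literal``: above mu + s -> 3, exactly mu + s -> 2, below -> 1.  With
    continuous data state 2 then almost never occurs, so the code is
    effectively binary; kept for fidelity to the printed rule.
    """
    if m.missing_mask.any():
        raise ValueError("discretize requires a fully observed matrix; impute first")
    if mode not in ("symmetric", "literal"):
        raise ValueError(f"unknown discretization mode {mode!r}")
    mu = m.values.mean(axis=1, keepdims=True)
    s = m.values.std(axis=1, ddof=1, keepdims=True)
    states = np.empty(m.values.shape, dtype=int)
    if mode == "symmetric":
        states[:] = 2
        states[m.values > mu + s] = 3
        states[m.values < mu - s] = 1
    else:
        states[:] = 1
        states[m.values == mu + s] = 2
        states[m.values > mu + s] = 3
    return DiscreteMatrix(list(m.gene_ids), m.times.copy(), states)
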