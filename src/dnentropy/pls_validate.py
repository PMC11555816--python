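"""Partial-least-squares network validation by simulated prediction error.

Each gene is modeled as a contemporaneous linear combination of its network
parents, x_i(t) = sum_j beta_j x_j(t) + intercept, with beta_j = 0 for every
non-parent.  The coefficients are fitted by PLS regression on the observed
series.  Competing networks are compared by drawing expression vectors from
each gene's fitted normal distribution, pushing the draws through the fitted
models, and averaging the relative prediction error over draws and genes —
a network whose parent sets match the real dependency structure predicts
its targets with a smaller error.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats
from sklearn.cross_decomposition import PLSRegression

from .matrix import ExpressionMatrix
from .network import RegNetwork

__all__ = ["PLSModel", "ErrorReport", "fit_pls", "simulate_error", "normality_screen"]

REL_ERR_EPS = 1e-8  # guards the relative-error denominator near zero expression


@dataclass
class PLSModel:
    """Per-gene sparse linear model plus fitted marginal normal parameters."""

    genes: list[str]
    beta: np.ndarray          # genes x genes, beta[i, j] = weight of gene j for gene i
    intercept: np.ndarray     # per-gene
    mean: np.ndarray          # per-gene fitted normal mean
    sd: np.ndarray            # per-gene fitted normal sd (>0)
    parents: dict[str, list[str]]

    def predict(self, draws: np.ndarray) -> np.ndarray:
        """Predict every gene from the drawn values of its parents.

        ``draws`` is (n_draws, n_genes); parentless genes predict their
        training mean (their beta row is zero and intercept the mean).
        """
        return draws @ self.beta.T + self.intercept


@dataclass
class ErrorReport:
    """Mean relative prediction errors from a seeded simulation."""

    per_gene: dict[str, float]
    network_error: float
    n_draws: int
    seed: int

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "network_error": self.network_error,
                    "per_gene": self.per_gene,
                    "n_draws": self.n_draws,
                    "seed": self.seed,
                },
                indent=2,
            )
            + "\n"
        )


def fit_pls(
    expr: ExpressionMatrix, net: RegNetwork, n_components: int = 2
) -> PLSModel:
    """Fit per-gene PLS regressions restricted to each gene's network parents.

    Components are capped at the parent count.  Parentless genes get the
    constant (training-mean) model.  Also records each gene's marginal
    normal fit (mean, sample sd) used by the simulation.
    """
    if expr.missing_mask.any():
        raise ValueError("fit_pls requires a fully observed matrix; impute first")
    genes = list(expr.gene_ids)
    n = len(genes)
    beta = np.zeros((n, n))
    intercept = np.zeros(n)
    parents_map: dict[str, list[str]] = {}
    for i, gene in enumerate(genes):
        parents = [p for p in net.parents(gene) if p in genes]
        parents_map[gene] = parents
        y = expr.values[i]
        if not parents:
            intercept[i] = y.mean()
            continue
        if expr.n_times < len(parents) + 1:
            raise ValueError(
                f"gene {gene!r}: {expr.n_times} timepoints cannot fit "
                f"{len(parents)} parents"
            )
        for p in parents:
            if np.ptp(expr.row(p)) == 0:
                raise ValueError(f"parent {p!r} of {gene!r} is constant")
        X = expr.values[[expr.gene_index(p) for p in parents]].T
        pls = PLSRegression(n_components=min(n_components, len(parents)))
        pls.fit(X, y)
        coefs = np.ravel(pls.coef_)
        for p, b in zip(parents, coefs):
            beta[i, expr.gene_index(p)] = b
        # sklearn's intercept_ applies to internally centered X; recompute
        # the raw-scale intercept from the training means
        intercept[i] = float(y.mean() - X.mean(axis=0) @ coefs)
    sd = expr.values.std(axis=1, ddof=1)
    if np.any(sd <= 0):
        bad = genes[int(np.argmin(sd))]
        raise ValueError(f"gene {bad!r} is constant; normal fit undefined")
    return PLSModel(genes, beta, intercept, expr.values.mean(axis=1), sd, parents_map)


def simulate_error(
    model: PLSModel,
    net: RegNetwork,
    n_draws: int = 1000,
    seed: int = 0,
    *,
    joint: bool = False,
    expr: ExpressionMatrix | None = None,
) -> ErrorReport:
    """Score a fitted network model by mean relative error on simulated data.

    Draws ``n_draws`` expression vectors — each gene independent normal at
    its fitted (mean, sd), or multivariate normal with the empirical
    correlation matrix when ``joint=True`` (requires ``expr``) — predicts
    each gene from its parents, and averages
    |predicted - drawn| / (|drawn| + eps) per gene.  The network error is
    the mean over genes that have parents.  Fixed seed, fixed report.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(model.genes)
    if joint:
        if expr is None:
            raise ValueError("joint draws need the expression matrix")
        cov = np.corrcoef(expr.values) * np.outer(model.sd, model.sd)
        draws = rng.multivariate_normal(model.mean, cov, size=n_draws)
    else:
        draws = rng.normal(model.mean, model.sd, size=(n_draws, n))
    pred = model.predict(draws)
    rel = np.abs(pred - draws) / (np.abs(draws) + REL_ERR_EPS)
    per_gene = {g: float(rel[:, i].mean()) for i, g in enumerate(model.genes)}
    with_parents = [g for g in model.genes if model.parents.get(g)]
    if with_parents:
        network_error = float(np.mean([per_gene[g] for g in with_parents]))
    else:
        network_error = float("nan")
    return ErrorReport(per_gene, network_error, n_draws, seed)


def normality_screen(
    expr: ExpressionMatrix, alpha: float = 0.05
) -> dict[str, dict[str, float | bool]]:
    """Per-gene Shapiro-Wilk normality test; pass when p > alpha."""
    if expr.n_times < 3:
        raise ValueError("normality test needs >= 3 timepoints")
    out: dict[str, dict[str, float | bool]] = {}
    for i, gene in enumerate(expr.gene_ids):
        row = expr.values[i]
        if np.ptp(row) == 0:
            raise ValueError(f"gene {gene!r} is constant; normality test undefined")
        p = float(stats.shapiro(row).pvalue)
        out[gene] = {"pvalue": p, "normal": p > alpha}
    return out
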