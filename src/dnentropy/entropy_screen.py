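"""Correlation-based network entropy and combinatorial edge screening.

A node's entropy is the Shannon entropy of the normalized absolute
correlations between the node and its network neighbors (undirected view):

    H_i = - sum_j p_ij log p_ij,    p_ij = |corr(i, j)| / sum_m |corr(i, m)|

with m running over the neighbors of i.  Pearson correlation is used when
both series pass a normality test, Spearman otherwise.  Network entropy is
the sum of node entropies; smaller entropy marks a more stable network.

Screening: each unconfirmed edge is tried against every combination
("context") of the other unconfirmed edges in its group, on top of the
confirmed subnetwork.  A context is a *violation* when adding the edge
raises total entropy by more than the threshold ``a``; the edge is accepted
when its violation count stays below the threshold ``b``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
from scipy import stats

from .matrix import ExpressionMatrix
from .network import RegNetwork

__all__ = [
    "ScreenConfig",
    "corr_with_normality_switch",
    "correlation_matrix",
    "node_entropy",
    "network_entropy",
    "screen_edges",
]


def corr_with_normality_switch(
    x: np.ndarray, y: np.ndarray, alpha: float = 0.05
) -> tuple[float, str]:
    """Signed correlation with a normality-driven Pearson/Spearman switch.

    Shapiro-Wilk is applied to each series at ``alpha``; Pearson is used
    only when both pass, otherwise Spearman.  Returns ``(coefficient,
    kind)`` with kind in {"pearson", "spearman"}.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("series must have equal length >= 3")
    if np.ptp(x) == 0:
        raise ValueError("first series is constant; correlation undefined")
    if np.ptp(y) == 0:
        raise ValueError("second series is constant; correlation undefined")
    normal = (
        stats.shapiro(x).pvalue > alpha and stats.shapiro(y).pvalue > alpha
    )
    if normal:
        return float(stats.pearsonr(x, y).statistic), "pearson"
    return float(stats.spearmanr(x, y).statistic), "spearman"


def correlation_matrix(
    expr: ExpressionMatrix, alpha: float = 0.05
) -> tuple[np.ndarray, dict[tuple[str, str], str]]:
    """Pairwise switched correlations for all gene pairs.

    Returns the symmetric signed coefficient matrix and the per-pair kind.
    """
    n = expr.n_genes
    corr = np.eye(n)
    kinds: dict[tuple[str, str], str] = {}
    for i, j in combinations(range(n), 2):
        c, kind = corr_with_normality_switch(expr.values[i], expr.values[j], alpha)
        corr[i, j] = corr[j, i] = c
        kinds[(expr.gene_ids[i], expr.gene_ids[j])] = kind
    return corr, kinds


def _abs_corr(expr: ExpressionMatrix, corr: np.ndarray | None, alpha: float) -> np.ndarray:
    if corr is None:
        corr, _ = correlation_matrix(expr, alpha)
    return np.abs(np.asarray(corr, dtype=float))


def node_entropy(
    net: RegNetwork,
    expr: ExpressionMatrix,
    node: str,
    *,
    corr: np.ndarray | None = None,
    log_base: float = math.e,
    alpha: float = 0.05,
) -> float:
    """Entropy of one node's normalized neighbor correlations.

    Zero for isolated nodes and when all neighbor correlations vanish.
    """
    ac = _abs_corr(expr, corr, alpha)
    i = expr.gene_index(node)
    nbrs = [expr.gene_index(n) for n in net.neighbors(node)]
    if not nbrs:
        return 0.0
    weights = ac[i, nbrs]
    total = weights.sum()
    if total == 0:
        return 0.0
    p = weights / total
    p = p[p > 0]
    return float(-(p * np.log(p)).sum() / math.log(log_base))


def network_entropy(
    net: RegNetwork,
    expr: ExpressionMatrix,
    *,
    corr: np.ndarray | None = None,
    log_base: float = math.e,
    alpha: float = 0.05,
) -> float:
    """Total network entropy: sum of node entropies over all genes."""
    ac = _abs_corr(expr, corr, alpha)
    return sum(
        node_entropy(net, expr, g, corr=ac, log_base=log_base) for g in net.nodes
    )


@dataclass
class ScreenConfig:
    """Thresholds and grouping for the combinatorial edge screen.

    ``a`` is the entropy-increase tolerance; ``b`` the violation-count cap
    (an edge is accepted while its violations stay below b).  ``groups``
    optionally partitions the unconfirmed edges, each group with its own b;
    ungrouped screening treats all unconfirmed edges as one group.
    ``max_context_size`` caps the context (subset) size m; ``None`` means
    all sizes 1 .. group_size - 1, refused for groups above 20 edges.
    """

    a: float = 0.3
    b: int = 100
    max_context_size: int | None = None
    groups: list[tuple[list[tuple[str, str]], int]] | None = None
    semantics: str = "corrected"
    log_base: float = math.e

    def __post_init__(self) -> None:
        if self.a < 0 and self.a != -math.inf:
            pass  # negative a is allowed (boundary behavior: reject-all probe)
        if self.b < 1:
            raise ValueError("b must be >= 1")
        if self.semantics not in ("corrected", "literal"):
            raise ValueError("semantics must be 'corrected' or 'literal'")


def _edge_groups(
    net: RegNetwork, cfg: ScreenConfig
) -> list[tuple[list[tuple[str, str]], int]]:
    unconfirmed = net.edges_with_status("unconfirmed")
    if cfg.groups is None:
        return [(unconfirmed, cfg.b)]
    seen: set[tuple[str, str]] = set()
    groups = []
    for edges, b in cfg.groups:
        edges = [tuple(e) for e in edges]
        for e in edges:
            if e not in unconfirmed:
                raise ValueError(f"grouped edge {e} is not an unconfirmed edge")
            if e in seen:
                raise ValueError(f"edge {e} appears in two groups")
            seen.add(e)
        groups.append((edges, b))
    missing = [e for e in unconfirmed if e not in seen]
    if missing:
        raise ValueError(f"unconfirmed edges not covered by groups: {missing}")
    return groups


def screen_edges(
    net: RegNetwork,
    expr: ExpressionMatrix,
    cfg: ScreenConfig,
    *,
    corr: np.ndarray | None = None,
) -> tuple[RegNetwork, dict]:
    """Accept or reject each unconfirmed edge by contextual entropy increase.

    For every unconfirmed edge e, contexts are the subsets (size m = 1 ..
    group_size - 1, capped by ``max_context_size``) of the *other*
    unconfirmed edges in e's group, laid over the confirmed subnetwork.
    With c the entropy of confirmed + context and d the entropy after also
    adding e, a context counts as a violation when d - c > a.  The edge is
    accepted (status ``candidate-added``) iff its violation count < b.

    Returns the screened network (confirmed + accepted edges) and a report
    with per-edge context/violation counts and decisions.

    ``semantics="literal"`` reproduces the printed pseudocode, whose
    violation counter is never incremented, so every edge is accepted; it
    exists only for fidelity.
    """
    ac = _abs_corr(expr, corr, 0.05)
    confirmed = net.edges_with_status("confirmed")
    base = RegNetwork(
        list(net.nodes),
        {e: "confirmed" for e in confirmed},
        {e: net.provenance.get(e, frozenset()) for e in confirmed},
    )
    report: dict = {"edges": {}, "a": cfg.a, "semantics": cfg.semantics}
    accepted: list[tuple[str, str]] = []

    for edges, b in _edge_groups(net, cfg):
        if len(edges) > 20 and cfg.max_context_size is None:
            raise ValueError(
                f"group of {len(edges)} unconfirmed edges needs max_context_size "
                "(full context enumeration is combinatorially infeasible)"
            )
        max_m = len(edges) - 1
        if cfg.max_context_size is not None:
            max_m = min(max_m, cfg.max_context_size)
        for e in edges:
            others = [o for o in edges if o != e]
            violations = 0
            n_contexts = 0
            for m in range(1, max_m + 1):
                for ctx in combinations(others, m):
                    n_contexts += 1
                    g1 = base.copy()
                    for o in ctx:
                        g1.edges[o] = "unconfirmed"
                    g1 = RegNetwork(g1.nodes, g1.edges, g1.provenance)
                    c = network_entropy(g1, expr, corr=ac, log_base=cfg.log_base)
                    g2 = g1.with_edge(*e)
                    d = network_entropy(g2, expr, corr=ac, log_base=cfg.log_base)
                    if cfg.semantics == "corrected":
                        if d - c > cfg.a:
                            violations += 1
                    else:  # literal printed rule: counter is reset, never bumped
                        if c - d > cfg.a:
                            violations = 0
            accept = violations < b
            report["edges"]["->".join(e)] = {
                "contexts": n_contexts,
                "violations": violations,
                "b": b,
                "accepted": accept,
            }
            if accept:
                accepted.append(e)

    out = base
    for e in accepted:
        out = out.with_edge(*e, status="candidate-added")
        out.provenance[e] = net.provenance.get(e, frozenset())
    report["n_confirmed"] = len(confirmed)
    report["n_accepted"] = len(accepted)
    return out, report
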