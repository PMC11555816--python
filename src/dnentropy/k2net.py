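"""K2 structure learning per plateau interval and interval-network union.

The score of a node given a candidate parent set is the Cooper-Herskovits
Bayesian marginal likelihood under a uniform Dirichlet prior,

    score(i, pi_i) = prod_j  (r-1)! / (N_ij + r - 1)!  *  prod_k N_ijk!

where j runs over observed parent-state configurations, k over the r states
of the node, N_ijk is the number of observations with the node in state k
and the parents in configuration j, and N_ij = sum_k N_ijk.  All arithmetic
is in log space (log-gamma); raw factorials overflow at modest N.

The search is the classic greedy K2: nodes are visited in a fixed ordering,
and each node greedily adopts the predecessor that most increases its score
until no addition helps or the parent budget is exhausted.  The resulting
per-interval graphs are acyclic by construction; their union across
intervals (the summary network) may contain cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln

from .matrix import DiscreteMatrix
from .network import RegNetwork
from .segmentation import Segmentation

__all__ = [
    "K2Config",
    "k2_score",
    "k2_search",
    "learn_interval_networks",
    "union_network",
]


@dataclass
class K2Config:
    """Ordering, parent budget and state count for the K2 search.

    ``ordering`` lists genes upstream-first: a gene may only take parents
    that precede it.  ``states`` is the arity r of the discretized code
    (3 for the three-state discretization).
    """

    ordering: list[str]
    max_parents: int = 3
    states: int = 3

    def __post_init__(self) -> None:
        if len(set(self.ordering)) != len(self.ordering):
            raise ValueError("ordering contains duplicates")
        if self.max_parents < 1:
            raise ValueError("max_parents must be >= 1")
        if self.max_parents >= len(self.ordering):
            raise ValueError("max_parents must be < number of genes")
        if self.states not in (2, 3):
            raise ValueError("states must be 2 or 3")


def k2_score(
    target_states: np.ndarray,
    parent_states: np.ndarray | None,
    r: int,
) -> float:
    """Log Cooper-Herskovits score of a node given its parents' observations.

    Parameters
    ----------
    target_states
        1-D integer states of the node, one entry per observation.
    parent_states
        ``(n_parents, n_obs)`` integer states of the parents, or ``None`` /
        empty for a parentless node (a single configuration).
    r
        Number of states of the node (2 or 3).

    Returns
    -------
    float
        Natural log of the score.  Zero observations give log 1 = 0.
    """
    target_states = np.asarray(target_states, dtype=int)
    n_obs = target_states.size
    if n_obs == 0:
        return 0.0
    if parent_states is None or np.size(parent_states) == 0:
        configs = np.zeros(n_obs, dtype=int)
    else:
        parent_states = np.atleast_2d(np.asarray(parent_states, dtype=int))
        # encode each observation's parent configuration as a single integer
        _, configs = np.unique(parent_states.T, axis=0, return_inverse=True)

    total = 0.0
    for j in np.unique(configs):
        in_config = configs == j
        n_ij = int(in_config.sum())
        counts = np.bincount(target_states[in_config], minlength=r + 1)[1 : r + 1]
        total += gammaln(r) - gammaln(n_ij + r) + gammaln(counts + 1).sum()
    return float(total)


def k2_search(d: DiscreteMatrix, cols: np.ndarray | None, cfg: K2Config) -> RegNetwork:
    """Greedy K2 parent search over one interval's observations.

    ``cols`` selects the observation columns of the interval (``None`` for
    all).  For each gene in ``cfg.ordering``, the predecessor whose addition
    most increases the score is adopted repeatedly; ties break toward the
    lowest gene index in the matrix.  Stops when no addition increases the
    score or ``max_parents`` is reached.
    """
    if set(cfg.ordering) != set(d.gene_ids):
        raise ValueError("ordering must be a permutation of the matrix genes")
    states = d.states if cols is None else d.restrict_columns(cols)
    if states.shape[1] < 1:
        raise ValueError("interval has no observations")

    edges: dict[tuple[str, str], str] = {}
    for pos, gene in enumerate(cfg.ordering):
        gi = d.gene_index(gene)
        target = states[gi]
        candidates = cfg.ordering[:pos]
        parents: list[str] = []
        best = k2_score(target, None, cfg.states)
        while len(parents) < cfg.max_parents:
            gain_best, pick = 0.0, None
            # lowest matrix index wins ties -> iterate in matrix order
            for cand in sorted(candidates, key=d.gene_index):
                if cand in parents:
                    continue
                pmat = states[[d.gene_index(p) for p in parents + [cand]]]
                sc = k2_score(target, pmat, cfg.states)
                if sc - best > gain_best + 1e-12:
                    gain_best, pick = sc - best, cand
            if pick is None:
                break
            parents.append(pick)
            best += gain_best
        for p in parents:
            edges[(p, gene)] = "unconfirmed"
    return RegNetwork(list(d.gene_ids), edges)


def learn_interval_networks(
    d: DiscreteMatrix, seg: Segmentation, cfg: K2Config
) -> list[RegNetwork]:
    """One K2 network per plateau interval."""
    nets = []
    for k, cols in enumerate(seg.column_windows(d.times)):
        if cols.size < 1:
            raise ValueError(f"interval {k} has no observations")
        net = k2_search(d, cols, cfg)
        net.provenance = {e: frozenset({k}) for e in net.edges}
        nets.append(net)
    return nets


def union_network(
    nets: Sequence[RegNetwork],
    prior: Iterable[tuple[str, str]] | None = None,
) -> RegNetwork:
    """Union of interval networks with per-edge interval provenance.

    Edges present in ``prior`` (the literature-curated network) are marked
    ``confirmed``; all others ``unconfirmed``.  The union may be cyclic even
    though each interval graph is a DAG.
    """
    if not nets:
        raise ValueError("no networks to union")
    nodes = nets[0].nodes
    for net in nets[1:]:
        if net.nodes != nodes:
            raise ValueError("interval networks disagree on the node set")
    prior_set = {tuple(e) for e in prior} if prior is not None else set()
    for u, v in prior_set:
        if u not in nodes or v not in nodes:
            raise ValueError(f"prior edge {u}->{v} references unknown gene")

    edges: dict[tuple[str, str], str] = {}
    prov: dict[tuple[str, str], set[int]] = {}
    for k, net in enumerate(nets):
        for e in net.edges:
            intervals = net.provenance.get(e, frozenset({k}))
            prov.setdefault(e, set()).update(intervals)
            edges[e] = "confirmed" if e in prior_set else "unconfirmed"
    return RegNetwork(
        list(nodes), edges, {e: frozenset(v) for e, v in prov.items()}
    )
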