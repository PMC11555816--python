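"""Seeded synthetic expression data with known piecewise-stationary structure.

Each dataset is piecewise stationary: within a segment, parentless genes
draw independent standard normals around a per-segment baseline, and each
child gene is a fixed linear combination of its parents plus Gaussian
noise (a contemporaneous linear-Gaussian model, matching the assumptions of
the downstream PLS validation).  Segment changes shift baselines and may
swap the regulatory structure.  Missing entries are masked uniformly at
random.  The true per-segment networks are returned alongside the data, so
every pipeline stage can be scored against ground truth.

The default shape mimics a short microarray time course: 8 genes, 17
timepoints at 10-minute spacing (0-160 min).  Structure recovery from so
few points is unreliable by design; :func:`dense_two_segment_config` builds
the denser profile (200 points per segment) used for recovery benchmarks.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .matrix import ExpressionMatrix
from .network import RegNetwork

__all__ = ["SynthConfig", "generate", "recovery_report", "dense_two_segment_config"]


@dataclass
class SynthConfig:
    """Ground-truth description of a piecewise-stationary dataset.

    ``edges`` holds one weighted edge dict per segment, keyed by
    ``(source, target)`` gene names.  ``segment_boundaries`` are the
    interior change points (empty for a single stationary segment);
    ``segment_means`` is an optional per-segment baseline added to every
    gene (scalar per segment, or per-segment per-gene array).
    """

    n_genes: int = 8
    n_timepoints: int = 17
    spacing: float = 10.0
    start: float = 0.0
    segment_boundaries: list[float] = field(default_factory=list)
    edges: list[dict[tuple[str, str], float]] = field(default_factory=lambda: [{}])
    segment_means: list | None = None
    noise_sd: float = 0.1
    root_sd: float = 1.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if len(self.edges) != len(self.segment_boundaries) + 1:
            raise ValueError("need one edge dict per segment")
        end = self.start + self.spacing * (self.n_timepoints - 1)
        for b in self.segment_boundaries:
            if not self.start < b < end:
                raise ValueError(f"boundary {b} outside time range")

    @property
    def gene_ids(self) -> list[str]:
        return [f"G{i + 1}" for i in range(self.n_genes)]

    @property
    def times(self) -> np.ndarray:
        return self.start + self.spacing * np.arange(self.n_timepoints)

    def truth_networks(self) -> list[RegNetwork]:
        nets = []
        for k, ed in enumerate(self.edges):
            net = RegNetwork.from_edges(self.gene_ids, ed.keys())
            net.provenance = {e: frozenset({k}) for e in net.edges}
            if not net.is_acyclic():
                raise ValueError(f"segment {k} truth graph is cyclic")
            nets.append(net)
        return nets

    def segment_of(self, t: float) -> int:
        return int(np.searchsorted(self.segment_boundaries, t, side="right"))


def generate(cfg: SynthConfig) -> tuple[ExpressionMatrix, list[RegNetwork]]:
    """Draw one seeded dataset and return it with the true segment networks.

    Pure function of the config: the same seed yields byte-identical output.
    """
    truth = cfg.truth_networks()
    genes = cfg.gene_ids
    times = cfg.times
    rng = np.random.default_rng(cfg.seed)
    values = np.zeros((cfg.n_genes, cfg.n_timepoints))

    for col, t in enumerate(times):
        k = cfg.segment_of(t)
        net = truth[k]
        order = list(nx.topological_sort(net.to_digraph()))
        z = {}
        for g in order:
            parents = net.parents(g)
            if parents:
                z[g] = sum(
                    cfg.edges[k][(p, g)] * z[p] for p in parents
                ) + rng.normal(0.0, cfg.noise_sd)
            else:
                z[g] = rng.normal(0.0, cfg.root_sd)
        base = 0.0 if cfg.segment_means is None else np.asarray(cfg.segment_means[k])
        col_vals = np.array([z[g] for g in genes]) + base
        values[:, col] = col_vals

    mask = rng.random(values.shape) < cfg.missing_rate
    return ExpressionMatrix(genes, times, values, mask), truth


def dense_two_segment_config(
    seed: int = 0,
    n_genes: int = 8,
    points_per_segment: int = 200,
    edges_per_segment: int = 3,
    weight: float = 0.9,
    noise_sd: float = 0.3,
    mean_shift: float = 2.0,
    missing_rate: float = 0.0,
) -> SynthConfig:
    """Two-segment dense profile for structure-recovery benchmarks.

    Each segment plants ``edges_per_segment`` strong edges (weight 0.9 by
    default) drawn at random but consistent with the gene numbering (source
    index < target index), and the second segment's baseline is shifted so
    the change point is detectable.  One minute between observations.
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i + 1}" for i in range(n_genes)]
    seg_edges = []
    for _ in range(2):
        pairs: set[tuple[str, str]] = set()
        targets: set[str] = set()
        while len(pairs) < edges_per_segment:
            i, j = sorted(rng.choice(n_genes, size=2, replace=False))
            # one parent per child keeps the planted structure unambiguous
            if genes[j] in targets:
                continue
            pairs.add((genes[i], genes[j]))
            targets.add(genes[j])
        seg_edges.append({p: weight for p in pairs})
    n_points = 2 * points_per_segment
    return SynthConfig(
        n_genes=n_genes,
        n_timepoints=n_points,
        spacing=1.0,
        segment_boundaries=[float(points_per_segment)],
        edges=seg_edges,
        segment_means=[0.0, mean_shift],
        noise_sd=noise_sd,
        missing_rate=missing_rate,
        seed=seed,
    )


def recovery_report(
    cfg: SynthConfig,
    *,
    window: float = 50.0,
    alpha: float = 0.01,
    max_missing: float = 0.15,
    discretize_mode: str = "symmetric",
    max_parents: int = 3,
    states: int = 3,
    ordering: list[str] | None = None,
) -> dict:
    """Run generate -> preprocess -> segment -> learn and score edge recovery.

    Learned interval networks are assigned to the true segment containing
    the interval midpoint and unioned per segment; precision and recall are
    direction-sensitive.  Vacuous conventions: recall = 1 when a segment has
    no true edges, precision = 1 when nothing was predicted.
    """
    from . import preprocess
    from .k2net import K2Config, learn_interval_networks, union_network
    from .segmentation import segment as run_segment

    expr, truth = generate(cfg)
    m = preprocess.filter_by_missing_rate(expr, max_missing)
    m = preprocess.impute_missing(m)
    m = preprocess.normalize(m)
    disc = preprocess.discretize(m, mode=discretize_mode)
    seg = run_segment(m, window=window, alpha=alpha)
    k2cfg = K2Config(
        ordering=ordering or list(disc.gene_ids),
        max_parents=max_parents,
        states=states,
    )
    nets = learn_interval_networks(disc, seg, k2cfg)

    per_segment = []
    for k, true_net in enumerate(truth):
        members = [
            nets[i]
            for i, (lo, hi) in enumerate(seg.intervals)
            if cfg.segment_of((lo + hi) / 2.0) == k
        ]
        predicted = (
            set(union_network(members).edges) if members else set()
        )
        true_edges = set(true_net.edges)
        tp = len(predicted & true_edges)
        precision = tp / len(predicted) if predicted else 1.0
        recall = tp / len(true_edges) if true_edges else 1.0
        per_segment.append(
            {
                "precision": precision,
                "recall": recall,
                "n_predicted": len(predicted),
                "n_true": len(true_edges),
            }
        )
    return {
        "per_segment": per_segment,
        "precision": float(np.mean([s["precision"] for s in per_segment])),
        "recall": float(np.mean([s["recall"] for s in per_segment])),
        "n_intervals": seg.n_intervals,
        "boundaries": seg.boundaries,
    }
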