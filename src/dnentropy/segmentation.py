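"""Stationary-plateau segmentation of multivariate expression time series.

A series is cut into consecutive base windows; adjacent windows are merged
while every gene's values in the two windows are statistically
indistinguishable (two-sample distribution-equality test).  The surviving
boundaries delimit *plateau intervals* within which the network structure is
assumed fixed.

The per-interval fluctuation ratio RB — the mean absolute deviation inside
the interval over the mean absolute deviation of the whole series — is the
descriptive stationarity statistic: small RB marks a plateau.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import stats

from .matrix import ExpressionMatrix

__all__ = ["Segmentation", "rb_statistic", "segment"]


@dataclass
class Segmentation:
    """Ordered interval boundaries tiling the observed time span.

    ``boundaries`` are time values t_0 < t_1 < ... < t_m; interval k is
    [t_k, t_{k+1}), the last interval closed on the right.
    """

    boundaries: list[float]

    def __post_init__(self) -> None:
        b = [float(x) for x in self.boundaries]
        if len(b) < 2 or any(y <= x for x, y in zip(b, b[1:])):
            raise ValueError("boundaries must be strictly increasing, length >=2")
        self.boundaries = b

    @property
    def n_intervals(self) -> int:
        return len(self.boundaries) - 1

    @property
    def intervals(self) -> list[tuple[float, float]]:
        return list(zip(self.boundaries[:-1], self.boundaries[1:]))

    def column_windows(self, times: np.ndarray) -> list[np.ndarray]:
        """Observation-column indices per interval (half-open, last closed)."""
        times = np.asarray(times, dtype=float)
        out = []
        for k, (lo, hi) in enumerate(self.intervals):
            if k == self.n_intervals - 1:
                sel = (times >= lo) & (times <= hi)
            else:
                sel = (times >= lo) & (times < hi)
            out.append(np.flatnonzero(sel))
        return out

    def to_json(self, path: str | Path, **meta) -> None:
        payload = {"boundaries": self.boundaries, **meta}
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "Segmentation":
        return cls(json.loads(Path(path).read_text())["boundaries"])


def rb_statistic(values: np.ndarray, times: np.ndarray, s: float, t: float) -> float:
    """Fluctuation ratio of one gene over [s, t] against the whole series.

    RB = (mean absolute deviation of the gene within [s, t]) /
    (mean absolute deviation over the full series).  RB = 1 on the full
    interval, 0 on a constant sub-interval; values below 1 indicate a
    plateau.  Undefined (error) for a series constant overall.
    """
    values = np.asarray(values, dtype=float)
    times = np.asarray(times, dtype=float)
    if values.shape != times.shape:
        raise ValueError("values and times must align")
    whole_mad = np.abs(values - values.mean()).mean()
    if whole_mad == 0:
        raise ValueError("whole series constant; RB undefined")
    sel = (times >= s) & (times <= t)
    if sel.sum() < 1:
        raise ValueError(f"interval [{s}, {t}] contains no observations")
    window = values[sel]
    return float(np.abs(window - window.mean()).mean() / whole_mad)


def _base_boundaries(times: np.ndarray, window: float) -> list[float]:
    start, end = float(times[0]), float(times[-1])
    if end - start < window:
        raise ValueError("series shorter than one base window")
    bounds = list(np.arange(start, end, window))
    # the final window absorbs any remainder shorter than a full window
    if end - bounds[-1] < window and len(bounds) > 1:
        bounds.pop()
    bounds.append(end)
    return [float(b) for b in bounds]


def _windows_equal(a: np.ndarray, b: np.ndarray, thresh: float, test: str) -> bool:
    """True when no gene's two windows differ in distribution at ``thresh``."""
    for x, y in zip(a, b):
        if test == "ks":
            p = stats.ks_2samp(x, y, method="auto").pvalue
        elif test == "mw":
            p = stats.mannwhitneyu(x, y, alternative="two-sided").pvalue
        else:
            raise ValueError(f"unknown test {test!r}")
        if p < thresh:
            return False
    return True


def segment(
    m: ExpressionMatrix,
    window: float = 20.0,
    alpha: float = 0.01,
    test: str = "ks",
    correction: str = "sidak",
) -> Segmentation:
    """Merge consecutive base windows into stationary plateau intervals.

    Starting from windows of ``window`` minutes, adjacent intervals merge
    when for *every* gene the two-sample test (Kolmogorov-Smirnov by
    default, ``mw`` for Mann-Whitney) fails to reject equality of
    distributions.  Left-to-right passes repeat until no pair merges; the
    procedure is deterministic.

    ``alpha`` is the significance level of each *merge decision* (one
    decision per adjacent interval pair).  Because a decision aggregates
    one test per gene under an AND rule, the default ``correction="sidak"``
    tests each gene at 1 - (1 - alpha)^(1/n_genes) so the family-wise level
    of the decision is alpha; ``correction="none"`` tests every gene at
    alpha directly (decision level then approaches n_genes * alpha).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if correction == "sidak":
        thresh = 1.0 - (1.0 - alpha) ** (1.0 / m.n_genes)
    elif correction == "none":
        thresh = alpha
    else:
        raise ValueError(f"unknown correction {correction!r}")
    if m.missing_mask.any():
        raise ValueError("segment requires a fully observed matrix; impute first")
    bounds = _base_boundaries(m.times, window)
    seg = Segmentation(bounds)
    for cols in seg.column_windows(m.times):
        if cols.size < 2:
            raise ValueError("a base window contains fewer than 2 observations")

    changed = True
    while changed:
        changed = False
        bounds = list(seg.boundaries)
        i = 0
        while i < len(bounds) - 2:
            probe = Segmentation(bounds)
            wins = probe.column_windows(m.times)
            left = m.values[:, wins[i]]
            right = m.values[:, wins[i + 1]]
            if _windows_equal(left, right, thresh, test):
                del bounds[i + 1]
                changed = True
            else:
                i += 1
        seg = Segmentation(bounds)
    return seg
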