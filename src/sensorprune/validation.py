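"""Posterior validation of a pruned sensor layout.

Pools all readings of a sensor set over the whole recording into a
probability histogram on the device range, then compares cluster vs kept
subset by Jensen-Shannon divergence (base-2 logs, so the value is bounded by
[0, 1]) and by relative mean-pressure deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .consensus import ConsensusModel
from .io_framing import SensorRecording
from .selection import SelectionResult

__all__ = [
    "DEFAULT_N_BINS",
    "PressureHistogram",
    "ClusterValidation",
    "ValidationReport",
    "pooled_histogram",
    "jsd",
    "validate_selection",
]

DEFAULT_N_BINS = 64


@dataclass(frozen=True)
class PressureHistogram:
    """Normalized pressure histogram on fixed equal-width bins."""

    bin_edges: np.ndarray = field(repr=False)
    probabilities: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        probs = np.asarray(self.probabilities, dtype=float)
        if edges.ndim != 1 or probs.ndim != 1 or len(edges) != len(probs) + 1:
            raise ValueError("need len(bin_edges) == len(probabilities) + 1")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin_edges must be strictly ascending")
        if np.any(probs < 0) or abs(float(probs.sum()) - 1.0) > 1e-9:
            raise ValueError("probabilities must be non-negative and sum to 1")
        for name, arr in (("bin_edges", edges), ("probabilities", probs)):
            arr = arr.copy()
            arr.flags.writeable = False
            object.__setattr__(self, name, arr)

    @property
    def n_bins(self) -> int:
        return len(self.probabilities)


def pooled_histogram(
    rec: SensorRecording, members: Iterable[str], n_bins: int = DEFAULT_N_BINS
) -> PressureHistogram:
    """Histogram of all member-sensor readings pooled over the whole recording.

    Bins are equal-width over ``rec.reading_range``; the last bin is closed,
    so saturation values at the range ceiling land in the final bin.
    """
    labels = [str(m) for m in members]
    if not labels:
        raise ValueError("members must be non-empty")
    if n_bins < 1:
        raise ValueError(f"n_bins must be >= 1, got {n_bins}")
    lo, hi = rec.reading_range
    pooled = np.clip(rec.readings[:, rec.indices_of(labels)].ravel(), lo, hi)
    counts, edges = np.histogram(pooled, bins=n_bins, range=(lo, hi))
    return PressureHistogram(
        bin_edges=edges, probabilities=counts / counts.sum()
    )


def jsd(p: PressureHistogram, q: PressureHistogram) -> float:
    """Jensen-Shannon divergence between two histograms on identical bins.

    JSD(P||Q) = KL(P||M)/2 + KL(Q||M)/2 with M = (P+Q)/2, logarithms base 2
    (required for the [0, 1] bound); zero-probability terms contribute 0.
    Symmetric; 0 iff P == Q; 1 for disjoint supports.
    """
    if not np.array_equal(p.bin_edges, q.bin_edges):
        raise ValueError("histograms have mismatched binning")
    pp = p.probabilities
    qq = q.probabilities
    m = 0.5 * (pp + qq)

    def _kl(a: np.ndarray) -> float:
        mask = a > 0
        return float(np.sum(a[mask] * np.log2(a[mask] / m[mask])))

    val = 0.5 * _kl(pp) + 0.5 * _kl(qq)
    return min(1.0, max(0.0, val))


@dataclass(frozen=True)
class ClusterValidation:
    """Validation row for one cluster of the pruned layout."""

    cluster: tuple[str, ...]
    chosen: tuple[str, ...]
    jsd_chosen: float
    best_subset_by_jsd: tuple[str, ...]
    jsd_min: float
    mean_all: float
    mean_chosen: float
    variation_pct: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.jsd_min <= self.jsd_chosen <= 1.0:
            raise ValueError("need 0 <= jsd_min <= jsd_chosen <= 1")
        if self.variation_pct < 0:
            raise ValueError("variation_pct must be >= 0")

    def to_dict(self) -> dict:
        return {
            "cluster": list(self.cluster),
            "chosen": list(self.chosen),
            "jsd_chosen": self.jsd_chosen,
            "best_subset_by_jsd": list(self.best_subset_by_jsd),
            "jsd_min": self.jsd_min,
            "mean_all_kpa": self.mean_all,
            "mean_chosen_kpa": self.mean_chosen,
            "variation_pct": self.variation_pct,
        }


@dataclass(frozen=True)
class ValidationReport:
    """Per-cluster JSD and mean-pressure checks for a pruned layout."""

    rows: tuple[ClusterValidation, ...]
    n_bins: int = DEFAULT_N_BINS

    def to_dict(self) -> dict:
        return {"n_bins": self.n_bins, "clusters": [r.to_dict() for r in self.rows]}


def _pooled_mean(rec: SensorRecording, labels: Sequence[str]) -> float:
    lo, hi = rec.reading_range
    return float(np.clip(rec.readings[:, rec.indices_of(labels)], lo, hi).mean())


def validate_selection(
    rec: SensorRecording,
    model: ConsensusModel,
    selections: Sequence[SelectionResult],
    n_bins: int = DEFAULT_N_BINS,
) -> ValidationReport:
    """Validate each cluster's chosen subset against the full cluster.

    Per cluster: JSD between the pooled histograms of the whole cluster and
    of the chosen subset, the exhaustive minimum JSD over all C(m, k)
    subsets of the same size, and the relative deviation of the mean
    pressure in percent.
    """
    model_clusters = {frozenset(c): c for c in model.partition.clusters}
    rows: list[ClusterValidation] = []
    for sel in selections:
        key = frozenset(sel.cluster)
        if key not in model_clusters:
            raise ValueError(f"selection cluster {sel.cluster} not in the model")
        if not set(sel.chosen) <= key:
            raise ValueError(
                f"chosen subset {sel.chosen} not within cluster {sel.cluster}"
            )
        p = pooled_histogram(rec, sel.cluster, n_bins)
        jsd_chosen = jsd(p, pooled_histogram(rec, sel.chosen, n_bins))
        best_subset = sel.chosen
        jsd_min = jsd_chosen
        for subset in combinations(sel.cluster, sel.k):
            d = jsd(p, pooled_histogram(rec, subset, n_bins))
            if d < jsd_min:
                best_subset, jsd_min = subset, d
        mean_all = _pooled_mean(rec, sel.cluster)
        mean_chosen = _pooled_mean(rec, sel.chosen)
        variation = (
            100.0 * abs(mean_chosen - mean_all) / mean_all if mean_all else 0.0
        )
        rows.append(
            ClusterValidation(
                cluster=sel.cluster,
                chosen=sel.chosen,
                jsd_chosen=jsd_chosen,
                best_subset_by_jsd=tuple(best_subset),
                jsd_min=jsd_min,
                mean_all=mean_all,
                mean_chosen=mean_chosen,
                variation_pct=variation,
            )
        )
    return ValidationReport(rows=tuple(rows), n_bins=n_bins)
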