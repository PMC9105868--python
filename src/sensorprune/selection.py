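"""Choosing the sensors to keep inside one cluster.

For a cluster of ``m`` sensors and a kept count ``k``, every one of the
C(m, k) subsets is scored by the Pearson correlation between its centroid
(pointwise mean series) and the full-cluster centroid, averaged over frames;
the subset with the highest mean score wins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .clustering import _label_key
from .io_framing import Frame

__all__ = [
    "DegenerateSeriesError",
    "SelectionResult",
    "pcc",
    "cluster_centroid",
    "select_k",
    "n_combinations",
]


class DegenerateSeriesError(ValueError):
    """A zero-variance series makes the correlation undefined."""


def pcc(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson correlation coefficient of two equal-length series.

    Symmetric, invariant to positive affine transforms of either argument,
    and always within [-1, 1].  Raises :class:`DegenerateSeriesError` for a
    constant series instead of returning NaN.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.ndim != 1 or ya.ndim != 1 or xa.shape != ya.shape:
        raise ValueError(f"series shapes differ: {xa.shape} vs {ya.shape}")
    n = xa.size
    if n < 2:
        raise ValueError(f"need at least 2 points, got {n}")
    dx = xa - xa.mean()
    dy = ya - ya.mean()
    sxx = float(dx @ dx)
    syy = float(dy @ dy)
    if sxx == 0.0:
        raise DegenerateSeriesError("first series has zero variance")
    if syy == 0.0:
        raise DegenerateSeriesError("second series has zero variance")
    if np.array_equal(xa, ya):
        return 1.0
    r = float(dx @ dy) / math.sqrt(sxx * syy)
    return min(1.0, max(-1.0, r))


def cluster_centroid(frame: Frame, members: Iterable[str]) -> np.ndarray:
    """Pointwise mean pressure series over the member sensors of a frame."""
    labels = [str(m) for m in members]
    if not labels:
        raise ValueError("members must be non-empty")
    cols = np.stack([frame.column(l) for l in labels], axis=1)
    return cols.mean(axis=1)


def n_combinations(m: int, k: int) -> int:
    """Exact binomial coefficient C(m, k)."""
    if k < 0 or m < 0:
        raise ValueError("m and k must be non-negative")
    if k > m:
        raise ValueError(f"k={k} exceeds m={m}")
    return math.comb(m, k)


@dataclass(frozen=True)
class SelectionResult:
    """Exhaustive k-subset scoring for one cluster.

    ``scored`` holds every subset in canonical order with its mean PCC over
    frames (``None`` marks a subset that was unscorable in every frame).
    """

    cluster: tuple[str, ...]
    k: int
    scored: tuple[tuple[tuple[str, ...], float | None], ...]
    chosen: tuple[str, ...]

    def __post_init__(self) -> None:
        m = len(self.cluster)
        if len(self.scored) != math.comb(m, self.k):
            raise ValueError(
                f"expected {math.comb(m, self.k)} scored subsets, got"
                f" {len(self.scored)}"
            )
        subsets = [s for s, _ in self.scored]
        if self.chosen not in subsets:
            raise ValueError("chosen subset missing from scored list")
        for s, score in self.scored:
            if score is not None and not -1.0 <= score <= 1.0:
                raise ValueError(f"score {score} for subset {s} outside [-1, 1]")

    @property
    def n_combinations(self) -> int:
        return len(self.scored)

    @property
    def chosen_score(self) -> float:
        return dict(self.scored)[self.chosen]

    def to_dict(self) -> dict:
        return {
            "cluster": list(self.cluster),
            "k": self.k,
            "n_combinations": self.n_combinations,
            "chosen": list(self.chosen),
            "scored": [
                {"subset": list(s), "score": score} for s, score in self.scored
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SelectionResult":
        return cls(
            cluster=tuple(d["cluster"]),
            k=int(d["k"]),
            scored=tuple(
                (tuple(e["subset"]), e["score"]) for e in d["scored"]
            ),
            chosen=tuple(d["chosen"]),
        )


def select_k(
    frames: Sequence[Frame], cluster: Iterable[str], k: int
) -> SelectionResult:
    """Score every k-subset of the cluster and pick the best.

    score(S) = mean over frames of pcc(centroid(S), centroid(cluster)).
    A frame where either centroid has zero variance (e.g. fully saturated
    sensors) is excluded from that subset's mean with a warning; a subset
    excluded in every frame is marked unscorable (score ``None``) and never
    chosen.  Ties go to the lexicographically smallest canonical subset.
    """
    members = tuple(sorted({str(m) for m in cluster}, key=_label_key))
    m = len(members)
    if not 1 <= k <= m:
        raise ValueError(f"k must lie in [1, {m}], got {k}")
    if not frames:
        raise ValueError("at least one frame required")

    full_centroids = [cluster_centroid(f, members) for f in frames]
    scored: list[tuple[tuple[str, ...], float | None]] = []
    best: tuple[str, ...] | None = None
    best_score = -np.inf
    for subset in combinations(members, k):
        per_frame: list[float] = []
        for fi, frame in enumerate(frames):
            sub = cluster_centroid(frame, subset)
            try:
                per_frame.append(pcc(sub, full_centroids[fi]))
            except DegenerateSeriesError as exc:
                warnings.warn(
                    f"subset {subset} excluded on frame {fi}: {exc}",
                    stacklevel=2,
                )
        score = float(np.mean(per_frame)) if per_frame else None
        scored.append((subset, score))
        if score is not None and score > best_score:
            best, best_score = subset, score
    if best is None:
        raise DegenerateSeriesError(
            "every subset was unscorable on every frame (all centroids constant)"
        )
    return SelectionResult(
        cluster=members, k=k, scored=tuple(scored), chosen=best
    )
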