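"""Sensor clustering within one frame: a from-scratch SOM plus Lloyd K-means.

Each sensor's pressure series within the frame (one column, length ``n``) is
one input vector; sensors whose vectors map to the same output neuron (SOM)
or centroid (K-means) form a cluster.  Input vectors are the raw kPa series:
all sensors share one physical unit and range, so no standardization is
applied.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .io_framing import Frame

__all__ = ["SomConfig", "SomState", "Partition", "som_cluster", "kmeans_cluster"]


def _label_key(label: str) -> tuple:
    # Natural order for numeric labels ("2" before "10"), lexicographic otherwise.
    return (0, int(label), "") if label.isdigit() else (1, 0, label)


@dataclass(frozen=True)
class Partition:
    """Disjoint, covering, non-empty sensor clusters in canonical form.

    Canonical form: members sorted within each cluster, clusters sorted by
    their smallest member label; equality is therefore set-of-sets equality.
    """

    clusters: tuple[tuple[str, ...], ...]

    def __post_init__(self) -> None:
        if any(not tuple(c) for c in self.clusters):
            raise ValueError("empty cluster in partition")
        canon = tuple(
            tuple(sorted((str(m) for m in c), key=_label_key)) for c in self.clusters
        )
        canon = tuple(sorted(canon, key=lambda c: _label_key(c[0])))
        seen: set[str] = set()
        for c in canon:
            for m in c:
                if m in seen:
                    raise ValueError(f"sensor {m!r} appears in more than one cluster")
                seen.add(m)
        object.__setattr__(self, "clusters", canon)

    @classmethod
    def from_groups(cls, groups: Iterable[Iterable[str]]) -> "Partition":
        return cls(tuple(tuple(g) for g in groups))

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(sorted((m for c in self.clusters for m in c), key=_label_key))

    def as_sets(self) -> frozenset[frozenset[str]]:
        return frozenset(frozenset(c) for c in self.clusters)

    def to_lists(self) -> list[list[str]]:
        return [list(c) for c in self.clusters]


@dataclass(frozen=True)
class SomConfig:
    """SOM grid and learning-schedule parameters.

    Defaults follow the reference setup: 3x3 rectangular output grid,
    initial learning rate 0.2, 10 iterations (one iteration = one full epoch
    over all input vectors).  ``sigma0`` defaults to ``max(rows, cols) / 2``.
    """

    grid_rows: int = 3
    grid_cols: int = 3
    eta0: float = 0.2
    sigma0: float | None = None
    tau: int = 10
    seed: int = 0
    presentation_order: str = "fixed"

    def __post_init__(self) -> None:
        if self.grid_rows < 1 or self.grid_cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if not 0 < self.eta0 <= 1:
            raise ValueError(f"eta0 must lie in (0, 1], got {self.eta0}")
        if self.sigma0 is not None and not self.sigma0 > 0:
            raise ValueError(f"sigma0 must be > 0, got {self.sigma0}")
        if self.tau < 1:
            raise ValueError(f"tau must be >= 1, got {self.tau}")
        if self.presentation_order not in ("fixed", "shuffled"):
            raise ValueError("presentation_order must be 'fixed' or 'shuffled'")

    @property
    def n_neurons(self) -> int:
        return self.grid_rows * self.grid_cols

    @property
    def effective_sigma0(self) -> float:
        if self.sigma0 is not None:
            return float(self.sigma0)
        return max(self.grid_rows, self.grid_cols) / 2.0


@dataclass(frozen=True)
class SomState:
    """Trained SOM: weight vectors and grid coordinates, one per neuron."""

    weights: np.ndarray = field(repr=False)  # (k, n)
    neuron_coords: np.ndarray = field(repr=False)  # (k, 2)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        c = np.asarray(self.neuron_coords, dtype=float)
        if not np.all(np.isfinite(w)):
            raise ValueError("non-finite SOM weights")
        if c.shape != (w.shape[0], 2):
            raise ValueError("one (row, col) coordinate pair per neuron required")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "neuron_coords", c)

    def bmu(self, x: np.ndarray) -> int:
        """Index of the best matching unit (Euclidean; ties -> lowest index)."""
        d2 = np.sum((self.weights - x) ** 2, axis=1)
        return int(np.argmin(d2))


def _train_som(X: np.ndarray, cfg: SomConfig) -> SomState:
    n_inputs, n = X.shape
    k = cfg.n_neurons
    rng = np.random.default_rng(cfg.seed)
    coords = np.array(
        [(r, c) for r in range(cfg.grid_rows) for c in range(cfg.grid_cols)],
        dtype=float,
    )
    # Initialization: uniform within each input dimension's observed range.
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    weights = rng.uniform(size=(k, n)) * (hi - lo) + lo
    sigma0 = cfg.effective_sigma0
    for t in range(cfg.tau):
        sigma = sigma0 * math.exp(-t / cfg.tau)
        eta = cfg.eta0 * math.exp(-t / cfg.tau)
        order = np.arange(n_inputs)
        if cfg.presentation_order == "shuffled":
            order = rng.permutation(n_inputs)
        for idx in order:
            x = X[idx]
            bmu = int(np.argmin(np.sum((weights - x) ** 2, axis=1)))
            d2 = np.sum((coords - coords[bmu]) ** 2, axis=1)
            neigh = np.exp(-d2 / (2.0 * sigma * sigma))
            weights += eta * neigh[:, None] * (x - weights)
    return SomState(weights=weights, neuron_coords=coords)


def som_cluster(frame: Frame, cfg: SomConfig) -> Partition:
    """Cluster a frame's sensors by their SOM best matching units.

    Weights are seeded from ``cfg.seed``; the decay schedules are
    ``sigma(t) = sigma0 * exp(-t/tau)`` and ``eta(t) = eta0 * exp(-t/tau)``
    with the Gaussian neighborhood ``exp(-D^2 / (2 sigma(t)^2))`` over
    Euclidean grid distance ``D``.  Empty neurons yield no cluster.
    """
    X = np.ascontiguousarray(frame.data.T)  # (n_sensors, n)
    if X.shape[0] < 1:
        raise ValueError("frame has no sensors")
    if not np.all(np.isfinite(X)):
        raise ValueError("non-finite data in frame")
    state = _train_som(X, cfg)
    assignment: dict[int, list[str]] = {}
    for i, label in enumerate(frame.sensor_labels):
        assignment.setdefault(state.bmu(X[i]), []).append(label)
    return Partition.from_groups(assignment.values())


def kmeans_cluster(
    frame: Frame, K: int, iterations: int = 10, seed: int = 0
) -> Partition:
    """Lloyd's K-means over the frame's sensor vectors.

    Centroids are initialized as ``K`` distinct sensor vectors drawn
    uniformly without replacement from ``seed``; the loop runs ``iterations``
    assignment/update rounds or to convergence, whichever comes first.
    Empty K-means clusters are dropped from the returned partition.
    """
    X = np.ascontiguousarray(frame.data.T)
    n_sensors = X.shape[0]
    if not 1 <= K <= n_sensors:
        raise ValueError(f"K must lie in [1, {n_sensors}], got {K}")
    rng = np.random.default_rng(seed)
    centroids = X[rng.choice(n_sensors, size=K, replace=False)].astype(float)
    assign = np.full(n_sensors, -1)
    for _ in range(iterations):
        d2 = np.sum((X[:, None, :] - centroids[None, :, :]) ** 2, axis=2)
        new_assign = np.argmin(d2, axis=1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(K):
            members = X[assign == j]
            if len(members):
                centroids[j] = members.mean(axis=0)
    groups: dict[int, list[str]] = {}
    for label, j in zip(frame.sensor_labels, assign):
        groups.setdefault(int(j), []).append(label)
    return Partition.from_groups(groups.values())
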