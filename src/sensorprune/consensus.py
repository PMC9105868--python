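"""Consensus over per-frame clusterings: the redundancy-detection model.

Every frame is clustered independently; the partition that occurs most often
across frames becomes the model.  K-means re-clustering of the same frames
gives a cross-algorithm agreement count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace

from .clustering import Partition, SomConfig, kmeans_cluster, som_cluster
from .io_framing import Frame

__all__ = ["ConsensusModel", "detect_redundancy", "crosscheck_kmeans"]


@dataclass(frozen=True)
class ConsensusModel:
    """The modal partition across frames, with its provenance.

    ``crosscheck_support`` is the number of frames whose K-means partition
    reproduces the model exactly; ``None`` until the crosscheck runs.
    ``tied`` flags a modal tie broken by the documented rule.
    """

    partition: Partition
    support: int
    n_frames: int
    per_frame: tuple[tuple[int, Partition], ...]
    tied: bool = False
    crosscheck_support: int | None = None
    crosscheck_per_frame: tuple[tuple[int, Partition], ...] | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.support <= self.n_frames:
            raise ValueError("support must lie in [1, n_frames]")
        observed = sum(1 for _, p in self.per_frame if p == self.partition)
        if observed != self.support:
            raise ValueError(
                f"partition appears {observed} times in per_frame, support says"
                f" {self.support}"
            )

    def to_dict(self) -> dict:
        d = {
            "partition": self.partition.to_lists(),
            "support": self.support,
            "n_frames": self.n_frames,
            "tied": self.tied,
            "per_frame": [
                {"frame": i, "partition": p.to_lists()} for i, p in self.per_frame
            ],
        }
        if self.crosscheck_support is not None:
            d["crosscheck_support"] = self.crosscheck_support
            d["crosscheck_per_frame"] = [
                {"frame": i, "partition": p.to_lists()}
                for i, p in (self.crosscheck_per_frame or ())
            ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ConsensusModel":
        return cls(
            partition=Partition.from_groups(d["partition"]),
            support=int(d["support"]),
            n_frames=int(d["n_frames"]),
            per_frame=tuple(
                (int(e["frame"]), Partition.from_groups(e["partition"]))
                for e in d["per_frame"]
            ),
            tied=bool(d.get("tied", False)),
            crosscheck_support=d.get("crosscheck_support"),
            crosscheck_per_frame=tuple(
                (int(e["frame"]), Partition.from_groups(e["partition"]))
                for e in d["crosscheck_per_frame"]
            )
            if "crosscheck_per_frame" in d
            else None,
        )


def _modal_partition(partitions: list[Partition]) -> tuple[Partition, int, bool]:
    counts = Counter(partitions)
    best_support = max(counts.values())
    candidates = [p for p, c in counts.items() if c == best_support]
    # Tie-break: fewer clusters first (coarser model = more redundancy
    # detected), then lexicographically smallest canonical form.
    candidates.sort(key=lambda p: (p.n_clusters, p.clusters))
    return candidates[0], best_support, len(candidates) > 1


def detect_redundancy(frames: list[Frame], cfg: SomConfig) -> ConsensusModel:
    """SOM-cluster every frame and return the most common partition.

    Per-frame runs use ``seed = cfg.seed + frame_index`` so frames are
    independent yet reproducible.  All frames must share one sensor set.
    """
    if not frames:
        raise ValueError("at least one frame required")
    sensor_set = frames[0].sensor_labels
    for i, f in enumerate(frames):
        if f.sensor_labels != sensor_set:
            raise ValueError(
                f"frame {i} has sensor labels {f.sensor_labels}, expected"
                f" {sensor_set}"
            )
    per_frame = tuple(
        (i, som_cluster(f, replace(cfg, seed=cfg.seed + i)))
        for i, f in enumerate(frames)
    )
    partition, support, tied = _modal_partition([p for _, p in per_frame])
    return ConsensusModel(
        partition=partition,
        support=support,
        n_frames=len(frames),
        per_frame=per_frame,
        tied=tied,
    )


def crosscheck_kmeans(
    frames: list[Frame],
    model: ConsensusModel,
    iterations: int = 10,
    seed: int = 0,
) -> ConsensusModel:
    """Re-cluster every frame with K-means, K = the model's cluster count.

    Returns the model augmented with the number of frames whose K-means
    partition equals the model partition.
    """
    K = model.partition.n_clusters
    per_frame = tuple(
        (i, kmeans_cluster(f, K, iterations=iterations, seed=seed + i))
        for i, f in enumerate(frames)
    )
    agree = sum(1 for _, p in per_frame if p == model.partition)
    return replace(
        model, crosscheck_support=agree, crosscheck_per_frame=per_frame
    )
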