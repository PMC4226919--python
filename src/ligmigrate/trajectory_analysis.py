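"""Post-run analysis: pose clustering, receptor preference, traces, RMSD.

Clustering follows a greedy quality-threshold rule on ligand
centre-of-mass positions: take every ``stride``-th filtered frame, then
repeatedly extract the point with the most neighbours within ``cutoff``
(ties to the earliest frame) together with those neighbours, until
``max_clusters`` clusters exist or no points remain.  Clusters are ranked
by size and assigned to the receptor whose COM lies nearer their
centroid; the preference statistic is the percentage of clustered frames
that belong to receptor-b-assigned clusters.

Percentages are rounded by ceiling, the convention that reproduces the
reference per-state preferences from their per-cluster counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DomainError
from .mc_engine import Frame, Trajectory
from .protocols import FilterSpec, TrajectorySet
from .structures import CompetitiveSystem, superpose

__all__ = [
    "Cluster",
    "ClusterSet",
    "PreferenceResult",
    "cluster_frames",
    "assign_clusters",
    "preference",
    "preference_from_counts",
    "com_distance_trace",
    "rmsd_to_reference",
    "export_scatter",
]


@dataclass
class Cluster:
    member_frame_ids: list[int]
    centroid: np.ndarray
    receptor_assignment: str = "unassigned"  # 'a' | 'b' | 'unassigned'

    @property
    def size(self) -> int:
        return len(self.member_frame_ids)


@dataclass
class ClusterSet:
    """Ranked ligand-pose clusters (size-descending, ties by first frame)."""

    clusters: list[Cluster]
    stride: int
    cutoff: float
    max_clusters: int
    frame_points: np.ndarray | None = None  # strided COM points, analysis order

    def sizes(self) -> list[int]:
        return [c.size for c in self.clusters]


@dataclass(frozen=True)
class PreferenceResult:
    counts_a: int
    counts_b: int

    @property
    def total(self) -> int:
        return self.counts_a + self.counts_b

    @property
    def preference_b_percent(self) -> int:
        if self.total == 0:
            raise DomainError("no assigned clusters")
        return math.ceil(100.0 * self.counts_b / self.total - 1e-9)


def _frame_points(frames: Sequence[Frame], stride: int):
    strided = list(frames)[::stride]
    if not strided:
        raise DomainError("no frames left after striding")
    pts = [fr.coords.mean(axis=0) if fr.coords.ndim == 2 else fr.coords for fr in strided]
    return strided, np.asarray(pts, dtype=float)


def cluster_frames(
    frames: Sequence[Frame] | np.ndarray,
    stride: int = 10,
    cutoff: float = 5.0,
    max_clusters: int = 10,
) -> ClusterSet:
    """Greedy quality-threshold clustering of ligand COM positions.

    *frames* is either a flat sequence of :class:`Frame` (pooled over
    chains in chain order) or an (N, 3) array of points already strided.
    Member ids index into the strided point order.  Leftover points after
    ``max_clusters`` rounds stay unassigned.
    """
    if isinstance(frames, np.ndarray):
        points = np.asarray(frames, dtype=float)[::stride]
    else:
        _, points = _frame_points(frames, stride)
    if points.size == 0:
        raise DomainError("empty input to clustering")
    n = points.shape[0]
    d2 = ((points[:, None, :] - points[None, :, :]) ** 2).sum(-1)
    neighbors = d2 <= cutoff**2  # includes self
    remaining = np.ones(n, dtype=bool)
    clusters: list[Cluster] = []
    while remaining.any() and len(clusters) < max_clusters:
        counts = (neighbors & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        seed_idx = int(np.argmax(counts))  # argmax takes first occurrence on ties
        members = np.where(neighbors[seed_idx] & remaining)[0]
        clusters.append(
            Cluster(
                member_frame_ids=[int(i) for i in members],
                centroid=points[members].mean(axis=0),
            )
        )
        remaining[members] = False
    order = sorted(
        range(len(clusters)),
        key=lambda i: (-clusters[i].size, clusters[i].member_frame_ids[0]),
    )
    return ClusterSet(
        clusters=[clusters[i] for i in order],
        stride=stride,
        cutoff=cutoff,
        max_clusters=max_clusters,
        frame_points=points,
    )


def assign_clusters(clusters: ClusterSet, system: CompetitiveSystem) -> ClusterSet:
    """Assign each cluster to the receptor with the nearer COM.

    Centroids equidistant within 1e-6 Å stay unassigned; systems without
    a second receptor assign everything to receptor a.
    """
    com_a = system.com_a()
    com_b = system.com_b() if system.receptor_b is not None else None
    for cl in clusters.clusters:
        da = float(np.linalg.norm(cl.centroid - com_a))
        if com_b is None:
            cl.receptor_assignment = "a"
            continue
        db = float(np.linalg.norm(cl.centroid - com_b))
        if abs(da - db) <= 1e-6:
            cl.receptor_assignment = "unassigned"
        else:
            cl.receptor_assignment = "a" if da < db else "b"
    return clusters


def preference(clusters: ClusterSet) -> PreferenceResult:
    """Receptor-b preference from assigned cluster sizes."""
    counts_a = sum(c.size for c in clusters.clusters if c.receptor_assignment == "a")
    counts_b = sum(c.size for c in clusters.clusters if c.receptor_assignment == "b")
    if counts_a + counts_b == 0:
        raise DomainError("no assigned clusters to compute a preference from")
    return PreferenceResult(counts_a=counts_a, counts_b=counts_b)


def preference_from_counts(
    counts_a: Sequence[int], counts_b: Sequence[int]
) -> PreferenceResult:
    """Preference from per-cluster trajectory counts for each receptor."""
    if not counts_a and not counts_b:
        raise DomainError("no cluster counts supplied")
    return PreferenceResult(counts_a=int(sum(counts_a)), counts_b=int(sum(counts_b)))


def com_distance_trace(traj: Trajectory, receptor: str) -> np.ndarray:
    """Per-frame ligand-COM to receptor-COM distance, frame order preserved."""
    if receptor not in ("a", "b"):
        raise DomainError(f"unknown receptor token {receptor!r}")
    if not traj.frames:
        raise DomainError("empty trajectory")
    out = []
    for fr in traj.frames:
        d = fr.dist_to_a if receptor == "a" else fr.dist_to_b
        if d is None:
            raise DomainError("trajectory has no distances to receptor b")
        out.append(d)
    return np.asarray(out, dtype=float)


def rmsd_to_reference(
    coords: np.ndarray,
    reference: np.ndarray,
    superpose_first: bool = False,
) -> float:
    """Heavy-atom RMSD in Å, optionally after least-squares superposition."""
    coords = np.asarray(coords, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if coords.shape != reference.shape:
        raise DomainError("coordinate sets must have matching shapes")
    if superpose_first:
        R, t, rmsd = superpose(coords, reference)
        return rmsd
    return float(np.sqrt(((coords - reference) ** 2).sum(axis=1).mean()))


def export_scatter(
    frames: Sequence[Frame],
    receptor: str,
    path: str | Path,
    filters: FilterSpec | None = None,
) -> pd.DataFrame:
    """Write the per-frame (distance, energy) scatter table as CSV.

    Honors the scatter cleanup convention: rows beyond the COM-distance
    ceiling or with non-negative energy are dropped.  Returns the
    DataFrame that was written.
    """
    if receptor not in ("a", "b"):
        raise DomainError(f"unknown receptor token {receptor!r}")
    if not frames:
        raise DomainError("no frames to export")
    filters = filters or FilterSpec(burn_in=0)
    rows = []
    for fr in frames:
        d = fr.dist_to_a if receptor == "a" else fr.dist_to_b
        if d is None:
            raise DomainError("frames have no distances to receptor b")
        if d > filters.max_com_distance or fr.e_interaction >= filters.max_energy:
            continue
        rows.append(
            {
                "chain": fr.chain_id,
                "step": fr.step_index,
                "distance_A": d,
                "energy_kcal_mol": fr.e_interaction,
            }
        )
    df = pd.DataFrame(rows, columns=["chain", "step", "distance_A", "energy_kcal_mol"])
    df.to_csv(path, index=False)
    return df
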