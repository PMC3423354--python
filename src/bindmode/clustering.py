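"""Greedy RMSD clustering, interconversion tracking and docked-pose analysis.

The clustering is the Daura neighbour-count algorithm: compute all pairwise
RMSDs, repeatedly take the conformation with the most neighbours within the
cutoff as a cluster centre, remove it and its neighbours, and continue until
the pool is empty.  Clusters are renumbered by size (1 = largest).  On MD
snapshots pooled across replicates it yields metastable ligand conformations;
tracking which cluster each replicate occupies over time then shows whether
clusters interconvert on the simulated timescale — the practical test of
whether one starting structure suffices for equilibrium averages.

The same clustering applied to docked poses (2 A cutoff, mean docking score
per cluster) ranks candidate binding modes, and a simple axis comparison
classifies each pose as parallel, anti-parallel or perpendicular to the
reference helix it mimics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AnalysisError, GeometryError
from .geometry import kabsch_fit, rmsd

__all__ = [
    "ClusterAssignment",
    "OccupancyTimeline",
    "InterconversionMatrix",
    "DockedPose",
    "OrientationCall",
    "PARALLEL",
    "ANTI_PARALLEL",
    "PERPENDICULAR",
    "pairwise_rmsd_matrix",
    "daura_cluster",
    "occupancy_timeline",
    "interconversion_counts",
    "rank_pose_clusters",
    "classify_orientation",
]

PARALLEL = "parallel"
ANTI_PARALLEL = "anti_parallel"
PERPENDICULAR = "perpendicular"


@dataclass
class ClusterAssignment:
    """Partition of pooled conformations into greedy RMSD clusters.

    ``labels[i]`` is the 1-based cluster id of conformation i (1 = largest
    cluster); ``centers[k]`` is the pool index of the representative of
    cluster k+1 (the member with the most neighbours at extraction time).
    """

    labels: np.ndarray
    centers: np.ndarray
    cutoff: float

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        self.centers = np.asarray(self.centers, dtype=int)
        sizes = self.sizes()
        if np.any(np.diff(sizes) > 0):
            raise ValueError("cluster sizes must be non-increasing by rank")

    @property
    def n_clusters(self) -> int:
        return len(self.centers)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=self.n_clusters + 1)[1:]


@dataclass
class OccupancyTimeline:
    """Per-replicate, time-ordered cluster occupancy."""

    timelines: dict  # replicate label -> DataFrame(time_ps, cluster)

    def total_frames(self) -> int:
        return sum(len(df) for df in self.timelines.values())


@dataclass
class InterconversionMatrix:
    """Per-replicate K x K transition counts among the top-K clusters."""

    matrices: dict  # replicate label -> (K, K) int array
    top_k: int

    def interconverts(self, replicate) -> bool:
        m = self.matrices[replicate]
        return bool(m.sum() - np.trace(m) > 0)

    def total(self) -> np.ndarray:
        return sum(self.matrices.values())


@dataclass
class DockedPose:
    """One docked ligand pose: coordinates, optional score, free-form label."""

    coords: np.ndarray
    energy: float | None = None
    label: str = ""

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("pose coords must have shape (n_atoms, 3)")
        if self.energy is not None and not np.isfinite(self.energy):
            raise ValueError("pose energy must be finite when present")


@dataclass(frozen=True)
class OrientationCall:
    """Binding-mode orientation relative to the reference helix axis."""

    call: str
    cos_angle: float

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.cos_angle <= 1.0 + 1e-12:
            raise ValueError("cos_angle must lie in [-1, 1]")


def pairwise_rmsd_matrix(conformations, superpose: bool = True) -> np.ndarray:
    """Symmetric matrix of pairwise RMSDs between equal-size conformations.

    With ``superpose`` each pair is Kabsch-fitted first (internal-geometry
    RMSD); without it coordinates are compared in their common frame, which is
    appropriate when all conformations are already aligned to the same
    protein (pocket-frame RMSD).
    """
    try:
        coords = np.asarray(conformations, dtype=float)
    except ValueError as exc:
        raise AnalysisError(f"conformations do not stack: {exc}") from exc
    if coords.ndim != 3 or coords.shape[2] != 3:
        raise AnalysisError("conformations must stack to an (n, m, 3) array")
    n = coords.shape[0]
    mat = np.zeros((n, n))
    if superpose:
        for i in range(n):
            for j in range(i + 1, n):
                _, d = kabsch_fit(coords[i], coords[j])
                mat[i, j] = mat[j, i] = d
    else:
        # |x_i - x_j|^2 summed over atoms, via the Gram-matrix identity
        flat = coords.reshape(n, -1)
        sq = np.sum(flat**2, axis=1)
        g = flat @ flat.T
        d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * g, 0.0)
        mat = np.sqrt(d2 / coords.shape[1])
        np.fill_diagonal(mat, 0.0)
    return mat


def daura_cluster(matrix: np.ndarray, cutoff: float, rng=None) -> ClusterAssignment:
    """Greedy neighbour-count clustering of a pairwise RMSD matrix.

    Repeatedly extracts the pool member with the most remaining neighbours
    within ``cutoff`` (ties broken deterministically by lowest index, or
    uniformly at random when ``rng`` is given) together with those neighbours
    as one cluster, until the pool is empty.  Clusters are renumbered by
    decreasing size, ties by order of extraction.
    """
    matrix = np.asarray(matrix, dtype=float)
    n = matrix.shape[0]
    if matrix.shape != (n, n) or n == 0:
        raise AnalysisError("RMSD matrix must be square and non-empty")
    if not np.allclose(matrix, matrix.T, atol=1e-8):
        raise AnalysisError("RMSD matrix must be symmetric")
    if cutoff <= 0:
        raise AnalysisError("cutoff must be positive")
    adj = matrix <= cutoff
    np.fill_diagonal(adj, True)
    alive = np.ones(n, dtype=bool)
    labels = np.zeros(n, dtype=int)
    centers, sizes = [], []
    cluster_id = 0
    while alive.any():
        counts = np.where(alive, adj[:, alive].sum(axis=1), -1)
        best = int(counts.max())
        candidates = np.nonzero(counts == best)[0]
        center = (
            int(candidates[0])
            if rng is None
            else int(candidates[rng.integers(len(candidates))])
        )
        members = np.nonzero(adj[center] & alive)[0]
        cluster_id += 1
        labels[members] = cluster_id
        centers.append(center)
        sizes.append(len(members))
        alive[members] = False
    # renumber by decreasing size; stable sort keeps extraction order on ties
    order = np.argsort(-np.asarray(sizes), kind="stable")
    remap = np.empty(cluster_id + 1, dtype=int)
    for new_id, old in enumerate(order, start=1):
        remap[old + 1] = new_id
    return ClusterAssignment(
        labels=remap[labels],
        centers=np.asarray(centers)[order],
        cutoff=cutoff,
    )


def occupancy_timeline(
    assignment: ClusterAssignment, replicate_of, times
) -> OccupancyTimeline:
    """Split a pooled cluster assignment back into per-replicate timelines."""
    replicate_of = np.asarray(replicate_of)
    times = np.asarray(times, dtype=float)
    if not (len(replicate_of) == len(times) == len(assignment.labels)):
        raise AnalysisError("replicate labels, times and assignment must align")
    timelines = {}
    for rep in pd.unique(replicate_of):
        mask = replicate_of == rep
        df = pd.DataFrame(
            {"time_ps": times[mask], "cluster": assignment.labels[mask]}
        ).sort_values("time_ps", kind="stable", ignore_index=True)
        timelines[rep] = df
    return OccupancyTimeline(timelines=timelines)


def interconversion_counts(
    timeline: OccupancyTimeline, top_k: int = 4
) -> InterconversionMatrix:
    """Count consecutive-frame transitions among the top-``top_k`` clusters.

    A transition is recorded only when both frames sit in a top-k cluster; a
    replicate "interconverts" when any off-diagonal count is positive.
    """
    if top_k < 2:
        raise AnalysisError("top_k must be at least 2")
    matrices = {}
    for rep, df in timeline.timelines.items():
        m = np.zeros((top_k, top_k), dtype=int)
        ids = df["cluster"].to_numpy()
        for a, b in zip(ids[:-1], ids[1:]):
            if 1 <= a <= top_k and 1 <= b <= top_k:
                m[a - 1, b - 1] += 1
        matrices[rep] = m
    return InterconversionMatrix(matrices=matrices, top_k=top_k)


def rank_pose_clusters(
    poses,
    cutoff: float = 2.0,
    superpose: bool = False,
    indistinguishable_margin: float = 2.5,
) -> pd.DataFrame:
    """Cluster docked poses at an RMSD cutoff and rank clusters by mean score.

    Docked poses share the receptor frame, so pose RMSD is computed without
    superposition by default.  Returns one row per cluster with membership
    count, mean energy (kcal/mol), the lowest-energy representative, and an
    ``indistinguishable`` flag marking clusters whose mean energy lies within
    ``indistinguishable_margin`` kcal/mol of the best mean — docking scores
    cannot discriminate binding modes that close.
    """
    poses = list(poses)
    if not poses:
        raise AnalysisError("need at least one pose")
    coords = np.stack([p.coords for p in poses])
    assignment = daura_cluster(pairwise_rmsd_matrix(coords, superpose), cutoff)
    energies = [p.energy for p in poses]
    have_energy = all(e is not None for e in energies)
    if not have_energy:
        warnings.warn("poses lack energies: ranking by cluster size only", stacklevel=2)
    rows = []
    for k in range(1, assignment.n_clusters + 1):
        members = np.nonzero(assignment.labels == k)[0]
        if have_energy:
            e = np.array([energies[i] for i in members], dtype=float)
            mean_e = float(e.mean())
            rep = int(members[np.argmin(e)])
        else:
            mean_e = np.nan
            rep = int(assignment.centers[k - 1])
        rows.append(
            {
                "cluster": k,
                "size": len(members),
                "mean_energy": mean_e,
                "representative": poses[rep].label or str(rep),
            }
        )
    df = pd.DataFrame(rows)
    if have_energy:
        df = df.sort_values(
            ["mean_energy", "size"], ascending=[True, False], ignore_index=True
        )
        best = df["mean_energy"].iloc[0]
        df["indistinguishable"] = df["mean_energy"] <= best + indistinguishable_margin
    else:
        df = df.sort_values("size", ascending=False, ignore_index=True)
        df["indistinguishable"] = True
    return df


def classify_orientation(
    pose: DockedPose,
    n_anchor: int,
    c_anchor: int,
    helix_n,
    helix_c,
    threshold: float = 0.3,
) -> OrientationCall:
    """Compare a mimetic's N->C axis with the reference helix N->C axis.

    ``cos_angle`` is the cosine between the two axes: >= +threshold is
    parallel (mimetic C-terminus near the helix C-terminus), <= -threshold is
    anti-parallel, anything in between is perpendicular (roughly 90 deg to
    the helix — a distinct, non-helix-like binding mode).
    """
    if n_anchor == c_anchor:
        raise GeometryError("N and C anchors must be distinct atoms")
    axis = pose.coords[c_anchor] - pose.coords[n_anchor]
    helix = np.asarray(helix_c, dtype=float) - np.asarray(helix_n, dtype=float)
    na, nh = np.linalg.norm(axis), np.linalg.norm(helix)
    if na <= 1e-10:
        raise GeometryError("zero-length mimetic axis")
    if nh <= 1e-10:
        raise GeometryError("zero-length helix axis")
    cos_angle = float(np.dot(axis, helix) / (na * nh))
    cos_angle = float(np.clip(cos_angle, -1.0, 1.0))
    if cos_angle >= threshold:
        call = PARALLEL
    elif cos_angle <= -threshold:
        call = ANTI_PARALLEL
    else:
        call = PERPENDICULAR
    return OrientationCall(call=call, cos_angle=cos_angle)
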