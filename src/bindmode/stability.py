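"""Ligand-in-pocket stability measures: contact counts and COM drift.

Two complementary diagnostics of whether a docked ligand stays put over a
simulation: the number of intermolecular atom pairs within a distance cutoff
(default 3.5 A), and the change in the protein-ligand centre-of-mass distance
relative to the starting structure.  A rising contact count with a falling
COM distance indicates the ligand settling deeper into the pocket.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .errors import AnalysisError
from .trajio import Frame, Trajectory

__all__ = [
    "ContactSeries",
    "ComDistanceSeries",
    "contact_count_timeseries",
    "com_distance_delta_timeseries",
]


@dataclass(frozen=True)
class ContactSeries:
    """Per-frame count of intermolecular atom pairs within ``cutoff`` A."""

    times: np.ndarray
    counts: np.ndarray
    cutoff: float

    def __post_init__(self):
        if self.cutoff < 0:
            raise AnalysisError("contact cutoff must be non-negative")
        if np.any(self.counts < 0):
            raise AnalysisError("contact counts must be non-negative")


@dataclass(frozen=True)
class ComDistanceSeries:
    """Per-frame inter-group COM distance minus its reference value (A)."""

    times: np.ndarray
    delta: np.ndarray

    def __post_init__(self):
        if not np.all(np.isfinite(self.delta)):
            raise AnalysisError("COM delta series contains non-finite values")


def _check_groups(traj, group_a, group_b, disjoint):
    a = np.asarray(group_a, dtype=int)
    b = np.asarray(group_b, dtype=int)
    if a.size == 0 or b.size == 0:
        raise AnalysisError("both atom groups must be non-empty")
    n = traj.n_atoms
    for g, name in ((a, "A"), (b, "B")):
        if g.min() < 0 or g.max() >= n:
            raise AnalysisError(f"group {name} index out of range")
    if disjoint and np.intersect1d(a, b).size:
        raise AnalysisError("atom groups overlap")
    return a, b


def contact_count_timeseries(
    traj: Trajectory,
    group_a,
    group_b,
    cutoff: float = 3.5,
    heavy_only: bool = False,
) -> ContactSeries:
    """Count (a in A, b in B) pairs with ``|r_a - r_b| <= cutoff`` per frame.

    All atoms count by default (hydrogens included); ``heavy_only`` drops
    atoms whose element is H from both groups before counting.
    """
    a, b = _check_groups(traj, group_a, group_b, disjoint=True)
    if heavy_only:
        a = np.array([i for i in a if traj.atoms[i].element.upper() != "H"])
        b = np.array([i for i in b if traj.atoms[i].element.upper() != "H"])
        if a.size == 0 or b.size == 0:
            raise AnalysisError("heavy-atom filter left an empty group")
    counts = np.empty(traj.n_frames, dtype=int)
    for i, fr in enumerate(traj.frames):
        if cutoff <= 0:
            counts[i] = 0
            continue
        tree = cKDTree(fr.coords[a])
        counts[i] = sum(
            len(hits) for hits in tree.query_ball_point(fr.coords[b], r=cutoff)
        )
    return ContactSeries(times=traj.times, counts=counts, cutoff=cutoff)


def _com(coords, masses):
    if masses is None:
        return coords.mean(axis=0)
    w = masses / masses.sum()
    return w @ coords


def com_distance_delta_timeseries(
    traj: Trajectory,
    group_a,
    group_b,
    ref: Frame,
    masses=None,
) -> ComDistanceSeries:
    """Inter-group centre distance per frame, minus its value in ``ref``.

    The centre is the unweighted centroid unless per-atom ``masses`` (full
    atom-template length) are supplied.
    """
    a, b = _check_groups(traj, group_a, group_b, disjoint=False)
    if masses is not None:
        masses = np.asarray(masses, dtype=float)
        if masses.shape != (traj.n_atoms,):
            raise AnalysisError("masses must cover every template atom")
        if np.any(~np.isfinite(masses)) or np.any(masses <= 0):
            raise AnalysisError("masses must be finite and positive")
        m_a, m_b = masses[a], masses[b]
    else:
        m_a = m_b = None
    ref_dist = np.linalg.norm(_com(ref.coords[a], m_a) - _com(ref.coords[b], m_b))
    delta = np.empty(traj.n_frames)
    for i, fr in enumerate(traj.frames):
        d = np.linalg.norm(_com(fr.coords[a], m_a) - _com(fr.coords[b], m_b))
        delta[i] = d - ref_dist
    return ComDistanceSeries(times=traj.times, delta=delta)
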