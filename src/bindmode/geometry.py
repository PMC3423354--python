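"""Rigid superposition, deviation metrics and binding-site plane projection.

The plane projection summarises where a ligand probe atom sits above the
binding site: three pocket-rim Calpha atoms (in the hDM2/p53 system: Tyr 56,
Met 62 and Val 93) span a plane, and each probe position is carried along a
projection line onto that plane.  The in-plane coordinates (u, v) are
expressed in the oblique basis (p1 - p0, p2 - p0), so they are dimensionless
multiples of the two rim edges rather than Angstrom — convenient for
comparing spatial sampling between replicate simulations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GeometryError, NoIntersectionError
from .trajio import Frame, Trajectory

__all__ = [
    "RotationTranslation",
    "ProjectionPlane",
    "ProjectionResult",
    "kabsch_fit",
    "rmsd",
    "rmsd_timeseries",
    "rmsf_per_atom",
    "line_plane_intersection",
    "projection_timeseries",
]

_SINGULARITY_TOL = 1e-10


@dataclass(frozen=True)
class RotationTranslation:
    """A proper rigid transform: ``x -> rotation @ x + translation``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        t = np.asarray(self.translation, dtype=float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise GeometryError("rotation must be 3x3 and translation a 3-vector")
        if abs(np.linalg.det(R) - 1.0) > 1e-8:
            raise GeometryError("rotation determinant must be +1")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-8):
            raise GeometryError("rotation must be orthonormal")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass(frozen=True)
class ProjectionPlane:
    """Plane through three anchor points p0, p1, p2 (A)."""

    p0: np.ndarray
    p1: np.ndarray
    p2: np.ndarray

    def __post_init__(self):
        p0, p1, p2 = (np.asarray(p, dtype=float) for p in (self.p0, self.p1, self.p2))
        normal = np.cross(p1 - p0, p2 - p0)
        if np.linalg.norm(normal) <= 1e-8:
            raise GeometryError("plane anchor points are collinear")
        object.__setattr__(self, "p0", p0)
        object.__setattr__(self, "p1", p1)
        object.__setattr__(self, "p2", p2)

    @property
    def normal(self) -> np.ndarray:
        n = np.cross(self.p1 - self.p0, self.p2 - self.p0)
        return n / np.linalg.norm(n)


@dataclass(frozen=True)
class ProjectionResult:
    """Solution of the line-plane intersection.

    ``t`` parameterises the line ``l_a + (l_b - l_a) t``; ``(u, v)`` are the
    in-plane coordinates in the basis ``(p1 - p0, p2 - p0)``; ``point`` is the
    intersection in Cartesian A.
    """

    t: float
    u: float
    v: float
    point: np.ndarray


def _as_points(x, name):
    a = np.asarray(x, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise GeometryError(f"{name} must be an (M, 3) array")
    return a


def kabsch_fit(ref, mov, weights=None):
    """Optimal rigid superposition of ``mov`` onto ``ref`` (least-squares).

    Returns
    -------
    (RotationTranslation, float)
        The proper rigid transform and the fitted RMSD in A.

    Raises
    ------
    GeometryError
        For fewer than 3 points or (near-)collinear point sets, where the
        rotation is not uniquely determined.
    """
    ref = _as_points(ref, "ref")
    mov = _as_points(mov, "mov")
    if ref.shape != mov.shape:
        raise GeometryError("ref and mov must have equal shapes")
    m = ref.shape[0]
    if m < 3:
        raise GeometryError("kabsch_fit needs at least 3 points")
    if weights is None:
        w = np.full(m, 1.0 / m)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (m,) or np.any(w < 0) or w.sum() <= 0:
            raise GeometryError("weights must be non-negative with positive sum")
        w = w / w.sum()
    c_ref = w @ ref
    c_mov = w @ mov
    ref0 = ref - c_ref
    mov0 = mov - c_mov
    scale = max(np.linalg.norm(ref0), np.linalg.norm(mov0), 1e-30)
    # rank < 2 after centering means all points on one line: rotation ambiguous
    if (
        np.linalg.matrix_rank(ref0, tol=1e-8 * scale) < 2
        or np.linalg.matrix_rank(mov0, tol=1e-8 * scale) < 2
    ):
        raise GeometryError("degenerate (collinear) point set")
    H = (mov0 * w[:, None]).T @ ref0
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = c_ref - R @ c_mov
    fitted = mov @ R.T + t
    value = float(np.sqrt(np.sum(w * np.sum((fitted - ref) ** 2, axis=1))))
    return RotationTranslation(R, t), value


def rmsd(a, b, weights=None) -> float:
    """Plain (unfitted) RMSD between two equal-shape coordinate sets."""
    a = _as_points(a, "a")
    b = _as_points(b, "b")
    if a.shape != b.shape:
        raise GeometryError("coordinate sets must have equal shapes")
    if weights is None:
        return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    return float(np.sqrt(np.sum(w * np.sum((a - b) ** 2, axis=1))))


def _check_indices(sel, n, label):
    sel = np.asarray(sel, dtype=int)
    if sel.size == 0:
        raise GeometryError(f"{label} selection is empty")
    if sel.min() < 0 or sel.max() >= n:
        raise GeometryError(f"{label} selection index out of range (n_atoms={n})")
    return sel


def rmsd_timeseries(
    traj: Trajectory, ref: Frame, fit_sel, calc_sel, weights=None
) -> pd.Series:
    """Per-frame RMSD (A) from a reference after rigid superposition.

    Each frame is superposed onto ``ref`` using the ``fit_sel`` atoms, then the
    RMSD is evaluated over ``calc_sel``.  Unweighted by default.
    """
    fit_sel = _check_indices(fit_sel, traj.n_atoms, "fit")
    calc_sel = _check_indices(calc_sel, traj.n_atoms, "calc")
    out = np.empty(traj.n_frames)
    for i, fr in enumerate(traj.frames):
        rt, _ = kabsch_fit(ref.coords[fit_sel], fr.coords[fit_sel])
        fitted = rt.apply(fr.coords[calc_sel])
        out[i] = rmsd(ref.coords[calc_sel], fitted, weights=weights)
    return pd.Series(out, index=pd.Index(traj.times, name="time_ps"), name="rmsd_A")


def rmsf_per_atom(
    traj: Trajectory,
    ref: Frame,
    sel,
    fit_sel=None,
    mean_reference: bool = False,
) -> pd.Series:
    """Per-atom root-mean-square fluctuation (A) about a reference.

    Frames are first superposed on ``fit_sel`` (default: ``sel`` itself); the
    fluctuation of each selected atom is then measured against its position in
    ``ref``, or against the trajectory mean when ``mean_reference`` is set.
    """
    sel = _check_indices(sel, traj.n_atoms, "rmsf")
    fit = sel if fit_sel is None else _check_indices(fit_sel, traj.n_atoms, "fit")
    if traj.n_frames == 1:
        warnings.warn(
            "RMSF on a single-frame trajectory: returning per-atom deviation",
            stacklevel=2,
        )
    fitted = np.empty((traj.n_frames, sel.size, 3))
    for i, fr in enumerate(traj.frames):
        rt, _ = kabsch_fit(ref.coords[fit], fr.coords[fit])
        fitted[i] = rt.apply(fr.coords[sel])
    target = fitted.mean(axis=0) if mean_reference else ref.coords[sel]
    sq = np.sum((fitted - target) ** 2, axis=2)
    values = np.sqrt(sq.mean(axis=0))
    return pd.Series(values, index=pd.Index(sel, name="atom_index"), name="rmsf_A")


def line_plane_intersection(l_a, l_b, plane: ProjectionPlane) -> ProjectionResult:
    """Solve ``l_a + (l_b - l_a) t = p0 + (p1 - p0) u + (p2 - p0) v``.

    Raises
    ------
    NoIntersectionError
        When the line direction lies in the plane (singular 3x3 system);
        a parallel line never yields a NaN result.
    """
    l_a = np.asarray(l_a, dtype=float)
    l_b = np.asarray(l_b, dtype=float)
    if np.allclose(l_a, l_b):
        raise GeometryError("line endpoints coincide")
    # columns: -(l_b - l_a), p1 - p0, p2 - p0 ; unknowns (t, u, v)
    A = np.column_stack([-(l_b - l_a), plane.p1 - plane.p0, plane.p2 - plane.p0])
    row_norms = np.linalg.norm(A, axis=1)
    scaled = A / np.where(row_norms > 0, row_norms, 1.0)[:, None]
    if np.abs(np.linalg.det(scaled)) < _SINGULARITY_TOL:
        raise NoIntersectionError("projection line is parallel to the plane")
    try:
        t, u, v = np.linalg.solve(A, l_a - plane.p0)
    except np.linalg.LinAlgError:
        raise NoIntersectionError("projection line is parallel to the plane")
    point = l_a + (l_b - l_a) * t
    # both parametric forms must agree; cheap internal consistency guard
    plane_point = plane.p0 + (plane.p1 - plane.p0) * u + (plane.p2 - plane.p0) * v
    if not np.allclose(point, plane_point, atol=1e-8):
        raise GeometryError("inconsistent line/plane solution")  # pragma: no cover
    return ProjectionResult(float(t), float(u), float(v), point)


def projection_timeseries(
    traj: Trajectory,
    probe_sel,
    plane_sel,
    direction_sel=None,
    probe_labels=None,
):
    """Project probe atoms onto the pocket plane, frame by frame.

    ``plane_sel`` must resolve to exactly three atoms spanning the plane.  The
    projection line through each probe runs along the plane normal by default
    (orthogonal projection); passing three ``direction_sel`` atoms instead
    tilts the line along the normal of the plane those atoms span per frame
    (e.g. the ligand's aromatic plane).

    Returns
    -------
    (pandas.DataFrame, int)
        Columns ``replicate, time_ps, probe_label, u, v``; the second element
        counts frames/probes skipped because the line was parallel to the
        plane.
    """
    probe_sel = _check_indices(probe_sel, traj.n_atoms, "probe")
    plane_sel = _check_indices(plane_sel, traj.n_atoms, "plane")
    if plane_sel.size != 3:
        raise GeometryError("plane_sel must resolve to exactly 3 atoms")
    if direction_sel is not None:
        direction_sel = _check_indices(direction_sel, traj.n_atoms, "direction")
        if direction_sel.size != 3:
            raise GeometryError("direction_sel must resolve to exactly 3 atoms")
    if probe_labels is None:
        probe_labels = [traj.atoms[i].name for i in probe_sel]
    rows = []
    n_excluded = 0
    for fr in traj.frames:
        plane = ProjectionPlane(*fr.coords[plane_sel])
        if direction_sel is None:
            direction = plane.normal
        else:
            q0, q1, q2 = fr.coords[direction_sel]
            direction = np.cross(q1 - q0, q2 - q0)
            norm = np.linalg.norm(direction)
            if norm <= 1e-8:
                n_excluded += probe_sel.size
                continue
            direction = direction / norm
        for idx, label in zip(probe_sel, probe_labels):
            l_a = fr.coords[idx]
            try:
                res = line_plane_intersection(l_a, l_a + direction, plane)
            except NoIntersectionError:
                n_excluded += 1
                continue
            rows.append(
                (traj.replicate_label, fr.time, label, res.u, res.v)
            )
    df = pd.DataFrame(rows, columns=["replicate", "time_ps", "probe_label", "u", "v"])
    return df, n_excluded
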