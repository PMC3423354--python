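"""Seeded generators for trajectories with known, planted structure.

Every analysis stage in this package can be exercised end-to-end without an
MD engine: these generators produce replicate ligand-in-pocket trajectories
with planted metastable clusters and known interconversion rates, torsion
series from rotamer-jump processes with known relaxation times, harmonic
positional fluctuations with known per-atom amplitudes, docked-pose sets
with planted orientations, and proton-pair ensembles with known rotational
character.  Each generator is deterministic under a fixed seed and returns
its ground truth alongside the data, so recovery tests close the loop
exactly.

State-jump dynamics are sampled as continuous-time Markov chains via
per-step exponential clocks; Gaussian jitter is truncated at 4 sigma so
planted cluster separability guarantees hold exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .clustering import ANTI_PARALLEL, PARALLEL, PERPENDICULAR, DockedPose
from .dihedrals import DihedralDefinition, DihedralSeries
from .errors import AnalysisError
from .noe import ProtonPair
from .trajio import AtomRecord, Frame, Trajectory

__all__ = [
    "gen_rotamer_jump_series",
    "gen_pocket_trajectory",
    "gen_harmonic_protein",
    "gen_pose_set",
    "gen_docked_conformer_set",
    "gen_ring_torsion_ensemble",
    "PocketTrajectoryResult",
    "PoseSetResult",
]


def _truncated_normal(rng, sigma, size, nmax=4.0):
    """Gaussian jitter clipped at ``nmax`` sigma (keeps separability exact)."""
    return np.clip(rng.normal(0.0, 1.0, size), -nmax, nmax) * sigma


def _wrap_angles(a):
    """Map degrees onto (-180, 180]."""
    w = np.mod(a + 180.0, 360.0) - 180.0
    return np.where(w == -180.0, 180.0, w)


def _validate_rate_matrix(q, n_states):
    q = np.asarray(q, dtype=float)
    if q.shape != (n_states, n_states):
        raise AnalysisError(f"rate matrix must be {n_states}x{n_states}")
    off = q[~np.eye(n_states, dtype=bool)]
    if np.any(off < 0):
        raise AnalysisError("off-diagonal rates must be non-negative")
    # accept either a proper generator (rows sum to 0) or bare off-diagonal
    # rates; rebuild the diagonal either way
    q = q.copy()
    np.fill_diagonal(q, 0.0)
    np.fill_diagonal(q, -q.sum(axis=1))
    return q


def _stationary(q):
    n = q.shape[0]
    a = np.vstack([q.T, np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()


def _ctmc_on_grid(q, n_frames, dt, rng, initial_dist=None, initial_state=None):
    """Sample a continuous-time Markov chain at times 0, dt, ..., (n-1) dt."""
    n_states = q.shape[0]
    if initial_state is None:
        p = _stationary(q) if initial_dist is None else np.asarray(initial_dist)
        p = p / p.sum()
        state = int(rng.choice(n_states, p=p))
    else:
        state = int(initial_state)
    out = np.empty(n_frames, dtype=int)
    t = 0.0
    next_jump = np.inf
    rate = -q[state, state]
    if rate > 0:
        next_jump = rng.exponential(1.0 / rate)
    for i in range(n_frames):
        target = i * dt
        while next_jump <= target:
            t = next_jump
            probs = q[state].copy()
            probs[state] = 0.0
            probs = probs / probs.sum()
            state = int(rng.choice(n_states, p=probs))
            rate = -q[state, state]
            next_jump = t + (rng.exponential(1.0 / rate) if rate > 0 else np.inf)
        out[i] = state
    return out


def gen_rotamer_jump_series(
    states,
    rate_matrix,
    n_frames: int,
    dt: float = 1.0,
    seed: int = 0,
    jitter_sigma: float = 4.0,
    label: str = "synthetic_torsion",
):
    """Torsion series from a rotamer-jump (CTMC) process plus angular jitter.

    ``states`` are the rotamer well centres in degrees; ``rate_matrix`` holds
    per-ps transition rates (off-diagonal; the diagonal is rebuilt).  Returns
    ``(DihedralSeries, planted_state_indices)``.  For a symmetric two-state
    process with rate k the cos(chi) autocorrelation decays as exp(-2 k t),
    i.e. the planted relaxation time is 1/(2k).
    """
    states = np.asarray(states, dtype=float)
    if states.size < 1 or len(np.unique(states)) != states.size:
        raise AnalysisError("rotamer states must be distinct")
    if n_frames < 1:
        raise AnalysisError("n_frames must be >= 1")
    q = _validate_rate_matrix(rate_matrix, states.size)
    rng = np.random.default_rng(seed)
    seq = _ctmc_on_grid(q, n_frames, dt, rng)
    angles = _wrap_angles(
        states[seq] + _truncated_normal(rng, jitter_sigma, n_frames)
    )
    times = np.arange(n_frames) * dt
    definition = DihedralDefinition(label, (0, 1, 2, 3))
    return DihedralSeries(definition, times, angles), seq


def _scaffold_atoms():
    """Static toy pocket: a ring of pseudo-Calpha atoms around the origin.

    Three of them carry the residue identities used as plane anchors in the
    hDM2 system (Tyr 56, Met 62, Val 93) so selection expressions written for
    the real protein resolve on the toy system too.
    """
    anchors = [
        ("TYR", 56, np.array([6.0, 0.0, 0.0])),
        ("MET", 62, np.array([-3.0, 5.2, 0.0])),
        ("VAL", 93, np.array([-3.0, -5.2, 0.0])),
    ]
    atoms = []
    for resname, resid, pos in anchors:
        atoms.append(("CA", resname, resid, pos))
    # filler scaffold residues completing the pocket rim, slightly off-plane
    n_fill = 9
    for k in range(n_fill):
        theta = 2 * np.pi * (k + 0.5) / n_fill
        pos = np.array([7.5 * np.cos(theta), 7.5 * np.sin(theta), -1.0])
        atoms.append(("CA", "GLY", 100 + k, pos))
    return atoms


@dataclass
class PocketTrajectoryResult:
    """A planted-cluster pocket trajectory with its ground truth."""

    trajectory: Trajectory
    state_labels: np.ndarray  # planted cluster index per frame (0-based)
    ligand_indices: np.ndarray
    scaffold_indices: np.ndarray
    plane_indices: np.ndarray  # the three anchor pseudo-Calpha atoms
    metadata: dict = field(default_factory=dict)


def gen_pocket_trajectory(
    centers,
    occupancies=None,
    jump_rates=0.0,
    noise_sigma: float = 0.3,
    n_frames: int = 2001,
    dt: float = 10.0,
    seed: int = 0,
    replicate_label: str = "rep",
    state_sequence=None,
) -> PocketTrajectoryResult:
    """Ligand hopping between planted conformations above a static toy pocket.

    ``centers`` is a (K, L, 3) stack of ligand conformations (A).  The ligand
    follows a CTMC over the K centres (``jump_rates``: scalar symmetric rate
    per ps, or a full K x K rate matrix; ``state_sequence`` overrides the
    process with an explicit planted sequence) with isotropic Gaussian jitter
    of ``noise_sigma`` A truncated at 4 sigma.  The scaffold (including the
    three plane-anchor pseudo-Calpha atoms) is static.  Centres closer than
    3 x sigma in RMSD break cluster separability; that is recorded as
    ``metadata["separable"] = False`` rather than an error.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.ndim != 3 or centers.shape[2] != 3:
        raise AnalysisError("centers must stack to (n_states, n_ligand_atoms, 3)")
    k, n_lig = centers.shape[:2]
    if n_frames < 1:
        raise AnalysisError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)

    min_rmsd = np.inf
    for i in range(k):
        for j in range(i + 1, k):
            d = float(np.sqrt(np.mean(np.sum((centers[i] - centers[j]) ** 2, axis=1))))
            min_rmsd = min(min_rmsd, d)
    separable = k < 2 or min_rmsd > 3.0 * noise_sigma

    if state_sequence is not None:
        seq = np.asarray(state_sequence, dtype=int)
        if seq.shape != (n_frames,) or seq.min() < 0 or seq.max() >= k:
            raise AnalysisError("state_sequence must hold n_frames valid state ids")
    elif k == 1:
        seq = np.zeros(n_frames, dtype=int)
    else:
        q = np.asarray(jump_rates, dtype=float)
        if q.ndim == 0:
            q = np.full((k, k), float(q))
        q = _validate_rate_matrix(q, k)
        seq = _ctmc_on_grid(q, n_frames, dt, rng, initial_dist=occupancies)

    scaffold = _scaffold_atoms()
    atoms = []
    serial = 0
    for name, resname, resid, pos in scaffold:
        atoms.append(
            AtomRecord(serial, name, "C", resname, resid, "A", pos)
        )
        serial += 1
    lig_offset = len(atoms)
    for a in range(n_lig):
        atoms.append(
            AtomRecord(serial, f"L{a + 1}", "C", "LIG", 1, "L", centers[0, a])
        )
        serial += 1

    scaffold_coords = np.stack([a.coords for a in atoms[:lig_offset]])
    frames = []
    for i in range(n_frames):
        lig = centers[seq[i]] + _truncated_normal(rng, noise_sigma, (n_lig, 3))
        frames.append(Frame(i * dt, np.vstack([scaffold_coords, lig])))
    traj = Trajectory(atoms, frames, replicate_label=replicate_label)
    return PocketTrajectoryResult(
        trajectory=traj,
        state_labels=seq,
        ligand_indices=np.arange(lig_offset, lig_offset + n_lig),
        scaffold_indices=np.arange(lig_offset),
        plane_indices=np.arange(3),
        metadata={"separable": separable, "min_center_rmsd": float(min_rmsd)},
    )


def default_ligand_centers(n_states: int = 2, separation: float = 4.0, n_atoms: int = 5):
    """Planted ligand conformations: rods above the pocket, shifted in x.

    Successive centres are ``separation`` A apart in RMSD (a pure rigid
    translation), comfortably separable at the default 0.3 A jitter.
    """
    base = np.column_stack(
        [
            np.linspace(-3.0, 3.0, n_atoms),
            0.4 * np.sin(np.linspace(0, np.pi, n_atoms)),
            np.full(n_atoms, 3.0),
        ]
    )
    return np.stack(
        [base + np.array([s * separation, 0.0, 0.0]) for s in range(n_states)]
    )


def gen_harmonic_protein(
    sigmas, n_frames: int, seed: int = 0, dt: float = 10.0,
    replicate_label: str = "harmonic",
):
    """Reference structure plus per-atom isotropic Gaussian jitter.

    Atom i fluctuates with per-coordinate standard deviation ``sigmas[i]``
    (A), so its expected RMSF about the reference is ``sigma * sqrt(3)``.
    Returns ``(Trajectory, reference Frame)``.
    """
    sigmas = np.asarray(sigmas, dtype=float)
    if np.any(sigmas < 0):
        raise AnalysisError("sigmas must be non-negative")
    n_atoms = sigmas.size
    if n_atoms < 3:
        raise AnalysisError("need at least 3 atoms")
    rng = np.random.default_rng(seed)
    # idealised alpha-helical backbone trace as the reference geometry
    t = np.arange(n_atoms) * (2 * np.pi / 3.6)
    ref_coords = np.column_stack(
        [2.3 * np.cos(t), 2.3 * np.sin(t), 1.5 * np.arange(n_atoms)]
    )
    atoms = [
        AtomRecord(i, "CA", "C", "ALA", i + 1, "A", ref_coords[i])
        for i in range(n_atoms)
    ]
    frames = []
    for m in range(n_frames):
        jitter = _truncated_normal(rng, 1.0, (n_atoms, 3)) * sigmas[:, None]
        frames.append(Frame(m * dt, ref_coords + jitter))
    traj = Trajectory(atoms, frames, replicate_label=replicate_label)
    return traj, Frame(0.0, ref_coords)


def _mimetic_template(n_atoms: int = 6, spacing: float = 1.5):
    """Rod-like mimetic scaffold along +x; atom 0 = N anchor, last = C anchor."""
    x = np.arange(n_atoms) * spacing
    y = 0.5 * np.cos(np.arange(n_atoms) * 2.1)
    z = 0.5 * np.sin(np.arange(n_atoms) * 2.1)
    coords = np.column_stack([x, y, z])
    return coords - coords.mean(axis=0)


def _rotation_between(u, v):
    """Proper rotation carrying unit vector u onto unit vector v."""
    u = u / np.linalg.norm(u)
    v = v / np.linalg.norm(v)
    c = float(np.dot(u, v))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:
        # 180 deg about any axis orthogonal to u
        axis = np.cross(u, [1.0, 0.0, 0.0])
        if np.linalg.norm(axis) < 1e-8:
            axis = np.cross(u, [0.0, 1.0, 0.0])
        axis = axis / np.linalg.norm(axis)
        return 2 * np.outer(axis, axis) - np.eye(3)
    w = np.cross(u, v)
    wx = np.array(
        [[0, -w[2], w[1]], [w[2], 0, -w[0]], [-w[1], w[0], 0]]
    )
    return np.eye(3) + wx + wx @ wx / (1 + c)


@dataclass
class PoseSetResult:
    """Docked poses with planted orientations and the reference helix axis."""

    poses: list
    helix_n: np.ndarray
    helix_c: np.ndarray
    true_calls: list
    n_anchor: int = 0
    c_anchor: int = -1


def gen_pose_set(
    n_parallel: int,
    n_anti: int,
    n_perpendicular: int,
    cluster_spread: float = 1.0,
    energies=None,
    seed: int = 0,
) -> PoseSetResult:
    """Docked poses with planted N->C orientations and tight cluster structure.

    Groups are placed at distinct pocket offsets with within-group RMSD below
    ``cluster_spread`` A, so clustering at that cutoff recovers the groups
    and orientation classification recovers the planted calls exactly.
    ``energies``, when given, assigns one score per pose in group order
    (parallel, anti-parallel, perpendicular).
    """
    if min(n_parallel, n_anti, n_perpendicular) < 0:
        raise AnalysisError("pose counts must be non-negative")
    rng = np.random.default_rng(seed)
    helix_n = np.array([0.0, 0.0, 0.0])
    helix_c = np.array([9.0, 0.0, 0.0])
    axis = np.array([1.0, 0.0, 0.0])
    template = _mimetic_template()
    c_anchor = template.shape[0] - 1
    groups = [
        (PARALLEL, axis, np.array([0.0, 0.0, 3.0]), n_parallel),
        (ANTI_PARALLEL, -axis, np.array([0.0, 6.0, 3.0]), n_anti),
        (PERPENDICULAR, np.array([0.0, 0.0, 1.0]), np.array([6.0, 3.0, 3.0]),
         n_perpendicular),
    ]
    poses, calls = [], []
    total_energies = None
    if energies is not None:
        total_energies = list(energies)
        if len(total_energies) != n_parallel + n_anti + n_perpendicular:
            raise AnalysisError("need one energy per pose")
    i_pose = 0
    for call, direction, offset, count in groups:
        rot = _rotation_between(np.array([1.0, 0.0, 0.0]), direction)
        for _ in range(count):
            jitter = _truncated_normal(rng, cluster_spread / 8.0, template.shape)
            coords = (template + jitter) @ rot.T + offset
            e = None if total_energies is None else float(total_energies[i_pose])
            poses.append(DockedPose(coords=coords, energy=e, label=f"pose{i_pose}"))
            calls.append(call)
            i_pose += 1
    return PoseSetResult(
        poses=poses,
        helix_n=helix_n,
        helix_c=helix_c,
        true_calls=calls,
        n_anchor=0,
        c_anchor=c_anchor,
    )


def gen_docked_conformer_set(seed: int = 0) -> PoseSetResult:
    """Synthetic stand-in for a nine-conformer docked starting set.

    Emulates the canonical scenario of nine docked helix-mimetic conformers
    of which five (labelled conf1, conf2, conf3, conf7, conf8) sit
    anti-parallel and four (conf4, conf9, conf10, conf11) parallel to the
    reference p53 helix axis.  Coordinates are synthetic — generated rod
    mimetics, not docking output — but carry the same labels and planted
    orientation split, so orientation classification can be exercised
    without the original pose files.
    """
    rng = np.random.default_rng(seed)
    helix_n = np.array([0.0, 0.0, 0.0])
    helix_c = np.array([9.0, 0.0, 0.0])
    axis = np.array([1.0, 0.0, 0.0])
    template = _mimetic_template()
    plan = [
        ("conf1", ANTI_PARALLEL), ("conf2", ANTI_PARALLEL), ("conf3", ANTI_PARALLEL),
        ("conf4", PARALLEL), ("conf7", ANTI_PARALLEL), ("conf8", ANTI_PARALLEL),
        ("conf9", PARALLEL), ("conf10", PARALLEL), ("conf11", PARALLEL),
    ]
    poses, calls = [], []
    for label, call in plan:
        direction = axis if call == PARALLEL else -axis
        # modest random tilt (< 40 deg) keeps the planted orientation class
        tilt = rng.normal(0.0, 0.3, 3)
        d = direction + tilt - axis * np.dot(tilt, axis)
        d = d / np.linalg.norm(d)
        if np.dot(d, direction) < np.cos(np.radians(40.0)):
            d = direction
        rot = _rotation_between(np.array([1.0, 0.0, 0.0]), d)
        offset = np.array([0.0, 0.0, 3.0]) + rng.normal(0.0, 0.8, 3)
        poses.append(
            DockedPose(coords=template @ rot.T + offset, energy=None, label=label)
        )
        calls.append(call)
    return PoseSetResult(
        poses=poses,
        helix_n=helix_n,
        helix_c=helix_c,
        true_calls=calls,
        n_anchor=0,
        c_anchor=template.shape[0] - 1,
    )


def gen_ring_torsion_ensemble(
    mode: str = "free",
    n_frames: int = 2000,
    seed: int = 0,
    dt: float = 10.0,
):
    """Proton-pair ensemble for an aromatic ring rotating about its bond axis.

    Models an amide proton (HN) near a ring whose H2 and H6 protons sit on
    opposite faces: as the ring torsion chi rotates by 180 deg the two swap
    proximity to HN, while H5 stays remote.  ``mode="free"`` draws chi
    uniformly (free ring rotation: both NH-H2 and NH-H6 come close),
    ``mode="locked"`` keeps chi near 0 within a 15 deg wobble (hindered
    rotation: only NH-H2 comes close).  Returns ``(Trajectory, pairs)`` with
    pairs labelled NH-H2, NH-H5, NH-H6.
    """
    if mode not in ("free", "locked"):
        raise AnalysisError("mode must be 'free' or 'locked'")
    if n_frames < 1:
        raise AnalysisError("n_frames must be >= 1")
    rng = np.random.default_rng(seed)
    if mode == "free":
        chi = rng.uniform(-np.pi, np.pi, n_frames)
    else:
        chi = np.radians(np.clip(rng.normal(0.0, 15.0, n_frames), -60.0, 60.0))
    hn = np.array([0.0, 2.2, 0.0])
    # ring protons on circles about the x axis: (x_i, rho_i cos(chi+phi_i),
    # rho_i sin(chi+phi_i)); phi controls which chi brings them toward HN
    geom = {
        "H2": (2.2, 1.6, 0.0),
        "H6": (2.2, 1.6, np.pi),
        "H5": (4.2, 1.0, np.pi),
    }
    atoms = [AtomRecord(0, "HN", "H", "ARM", 1, "A", hn)]
    for i, name in enumerate(("H2", "H5", "H6"), start=1):
        x, rho, phi = geom[name]
        atoms.append(
            AtomRecord(i, name, "H", "ARM", 2, "A",
                       np.array([x, rho * np.cos(phi), rho * np.sin(phi)]))
        )
    frames = []
    order = ("H2", "H5", "H6")
    for m in range(n_frames):
        coords = [hn]
        for name in order:
            x, rho, phi = geom[name]
            a = chi[m] + phi
            coords.append(np.array([x, rho * np.cos(a), rho * np.sin(a)]))
        frames.append(Frame(m * dt, np.stack(coords)))
    traj = Trajectory(atoms, frames, replicate_label=f"ring_{mode}")
    pairs = [
        ProtonPair("NH-H2", 0, 1),
        ProtonPair("NH-H5", 0, 2),
        ProtonPair("NH-H6", 0, 3),
    ]
    return traj, pairs
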