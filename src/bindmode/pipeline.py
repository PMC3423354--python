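"""Config-driven orchestration of the full analysis over replicate runs.

A single YAML config names the replicate trajectories, the atom selections
(protein fit set, ligand, plane anchors, probes, torsion definitions, proton
pairs) and every threshold; :func:`run_pipeline` then produces the complete
TSV report bundle — stability series, plane projections, dihedral histograms
with sampling labels and relaxation times, pooled cluster assignment with
occupancy timelines and interconversion counts, docked-pose ranking with
orientation calls, and the NOE table — plus a run log recording thresholds,
seed and input hashes.  Reruns on identical inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    circular_histogram,
    classify_orientation,
    classify_sampling,
    com_distance_delta_timeseries,
    contact_count_timeseries,
    cos_autocorrelation,
    daura_cluster,
    dihedral_timeseries,
    fit_relaxation,
    interconversion_counts,
    noe_pattern_table,
    noe_table,
    occupancy_timeline,
    pairwise_rmsd_matrix,
    projection_timeseries,
    rank_pose_clusters,
    read_multimodel_pdb,
    rmsd_timeseries,
    rmsf_per_atom,
    window_subsample,
)
from .clustering import DockedPose
from .dihedrals import DihedralDefinition
from .errors import AnalysisError, BindmodeError
from .noe import ProtonPair

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "DEFAULT_STAGES"]

DEFAULT_STAGES = ("stability", "project", "dihedrals", "cluster", "poses", "noe")


@dataclass
class PipelineConfig:
    """Validated pipeline settings; see ``load_config`` for the YAML schema."""

    trajectories: list  # [{"path": ..., "replicate": ...}, ...]
    selections: dict  # protein_fit, ligand, plane, probes[, direction]
    dihedrals: list = field(default_factory=list)  # [{"label", "atoms": [4]}]
    proton_pairs: list = field(default_factory=list)  # [{"label", "a", "b"}]
    poses: dict | None = None  # {"path", "n_anchor", "c_anchor",
    #                             "helix_n": [x,y,z], "helix_c": [x,y,z]}
    equilibration_cut_ps: float = 3000.0
    sampling_interval_ps: float = 10.0
    acf_window_ps: float | None = None
    contact_cutoff: float = 3.5
    md_cluster_cutoff: float = 1.5
    pose_cluster_cutoff: float = 2.0
    noe_cutoff: float = 4.0
    orientation_cos_threshold: float = 0.3
    cluster_top_k: int = 4
    cluster_superpose: bool = False
    default_dt_ps: float = 10.0
    seed: int = 0

    def __post_init__(self):
        for name in (
            "contact_cutoff",
            "md_cluster_cutoff",
            "pose_cluster_cutoff",
            "noe_cutoff",
            "orientation_cos_threshold",
            "sampling_interval_ps",
        ):
            if getattr(self, name) <= 0:
                raise AnalysisError(f"{name} must be positive")
        if not self.trajectories:
            raise AnalysisError("config lists no trajectories")
        for key in ("protein_fit", "ligand", "plane"):
            if key not in self.selections:
                raise AnalysisError(f"selections must define {key!r}")

    def content_hash(self) -> str:
        payload = yaml.safe_dump(self.__dict__, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise AnalysisError(f"config {path} is not a mapping")
    return PipelineConfig(**raw)


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, created: list) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")
    created.append(path)


def _load_trajectories(config: PipelineConfig):
    trajs = []
    for entry in config.trajectories:
        path = entry["path"]
        if not Path(path).exists():
            raise AnalysisError(f"trajectory file not found: {path}")
        trajs.append(
            read_multimodel_pdb(
                path,
                default_dt=config.default_dt_ps,
                replicate_label=str(entry.get("replicate", Path(path).stem)),
            )
        )
    return trajs


def _stage_stability(config, trajs, outdir, created):
    rows, rmsf_rows = [], []
    for traj in trajs:
        ref = traj.frames[0]
        fit = traj.select(config.selections["protein_fit"])
        lig = traj.select(config.selections["ligand"])
        rmsd_s = rmsd_timeseries(traj, ref, fit, lig)
        contacts = contact_count_timeseries(traj, fit, lig, config.contact_cutoff)
        com = com_distance_delta_timeseries(traj, fit, lig, ref)
        for t, r, c, d in zip(traj.times, rmsd_s.values, contacts.counts, com.delta):
            rows.append((traj.replicate_label, t, r, int(c), d))
        rmsf = rmsf_per_atom(traj, ref, fit)
        for idx, val in rmsf.items():
            rmsf_rows.append((traj.replicate_label, int(idx), val))
    _write(
        pd.DataFrame(
            rows,
            columns=["replicate", "time_ps", "rmsd_A", "n_contacts", "com_delta_A"],
        ),
        outdir / "stability.tsv",
        created,
    )
    _write(
        pd.DataFrame(rmsf_rows, columns=["replicate", "atom_index", "rmsf_A"]),
        outdir / "rmsf.tsv",
        created,
    )


def _stage_project(config, trajs, outdir, created):
    frames = []
    total_excluded = 0
    for traj in trajs:
        probes = traj.select(config.selections["probes"])
        plane = traj.select(config.selections["plane"])
        direction = (
            traj.select(config.selections["direction"])
            if "direction" in config.selections
            else None
        )
        df, n_excl = projection_timeseries(traj, probes, plane, direction)
        total_excluded += n_excl
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    _write(out, outdir / "projection.tsv", created)
    return total_excluded


def _resolve_atom(traj, spec):
    if isinstance(spec, int):
        return spec
    idx = traj.select(str(spec))
    if idx.size != 1:
        raise AnalysisError(f"atom spec {spec!r} resolves to {idx.size} atoms, not 1")
    return int(idx[0])


def _stage_dihedrals(config, trajs, outdir, created):
    hist_rows, tau_rows, class_rows = [], [], []
    by_label = {}
    for traj in trajs:
        defs = [
            DihedralDefinition(
                d["label"], tuple(_resolve_atom(traj, a) for a in d["atoms"])
            )
            for d in config.dihedrals
        ]
        series_list = dihedral_timeseries(traj, defs)
        span = traj.times[-1] - traj.times[0]
        window = (
            config.acf_window_ps if config.acf_window_ps is not None else span / 2
        )
        for series in series_list:
            hist = circular_histogram(series, replicate_label=traj.replicate_label)
            by_label.setdefault(series.definition.label, []).append(hist)
            centers = 0.5 * (hist.bin_edges[:-1] + hist.bin_edges[1:])
            for c, dens in zip(centers, hist.densities):
                hist_rows.append(
                    (traj.replicate_label, series.definition.label, c, dens)
                )
            try:
                acf = cos_autocorrelation(series, window)
                fit = fit_relaxation(acf)
                tau_rows.append(
                    (
                        traj.replicate_label,
                        series.definition.label,
                        fit.tau_ps,
                        fit.tau_integral_ps,
                        "yes" if fit.converged else "exceeds window",
                    )
                )
            except AnalysisError as exc:
                tau_rows.append(
                    (traj.replicate_label, series.definition.label,
                     np.nan, np.nan, f"degenerate: {exc}")
                )
    for label, hists in by_label.items():
        if len(hists) >= 2:
            verdict = classify_sampling(hists)
            class_rows.append(
                (label, verdict.label, int((verdict.missing > 0).sum()))
            )
    _write(
        pd.DataFrame(
            hist_rows, columns=["replicate", "dihedral", "bin_center_deg", "density"]
        ),
        outdir / "dihedral_histograms.tsv",
        created,
    )
    _write(
        pd.DataFrame(
            tau_rows,
            columns=["replicate", "dihedral", "tau_ps", "tau_integral_ps", "converged"],
        ),
        outdir / "relaxation_times.tsv",
        created,
    )
    _write(
        pd.DataFrame(
            class_rows, columns=["dihedral", "label", "replicates_missing_basins"]
        ),
        outdir / "dihedral_classification.tsv",
        created,
    )


def _stage_cluster(config, trajs, outdir, created):
    pooled_coords, rep_of, times = [], [], []
    for traj in trajs:
        end = traj.times[-1]
        win = window_subsample(
            traj, config.equilibration_cut_ps, end, config.sampling_interval_ps
        )
        lig = win.select(config.selections["ligand"])
        coords = win.coords_array()[:, lig]
        pooled_coords.append(coords)
        rep_of.extend([win.replicate_label] * win.n_frames)
        times.extend(win.times)
    pool = np.concatenate(pooled_coords)
    matrix = pairwise_rmsd_matrix(pool, superpose=config.cluster_superpose)
    assignment = daura_cluster(matrix, config.md_cluster_cutoff)
    timeline = occupancy_timeline(assignment, np.array(rep_of), np.array(times))
    inter = interconversion_counts(timeline, top_k=config.cluster_top_k)
    sizes = assignment.sizes()
    top4 = sizes[: min(4, sizes.size)].sum() / sizes.sum()
    _write(
        pd.DataFrame(
            {
                "pool_index": np.arange(len(assignment.labels)),
                "replicate": rep_of,
                "time_ps": times,
                "cluster": assignment.labels,
            }
        ),
        outdir / "cluster_assignment.tsv",
        created,
    )
    _write(
        pd.DataFrame(
            {
                "cluster": np.arange(1, sizes.size + 1),
                "size": sizes,
                "center_pool_index": assignment.centers,
            }
        ),
        outdir / "cluster_sizes.tsv",
        created,
    )
    trans_rows = []
    for rep, m in inter.matrices.items():
        for i in range(inter.top_k):
            for j in range(inter.top_k):
                trans_rows.append((rep, i + 1, j + 1, int(m[i, j])))
    _write(
        pd.DataFrame(
            trans_rows, columns=["replicate", "from_cluster", "to_cluster", "count"]
        ),
        outdir / "transitions.tsv",
        created,
    )
    return {
        "pooled_conformations": int(len(assignment.labels)),
        "n_clusters": int(sizes.size),
        "top4_occupancy": float(top4),
        "interconverting_replicates": sorted(
            rep for rep in inter.matrices if inter.interconverts(rep)
        ),
    }


def _stage_poses(config, outdir, created):
    if config.poses is None:
        return None
    spec = config.poses
    traj = read_multimodel_pdb(spec["path"], default_dt=1.0)
    energies = spec.get("energies")
    poses = []
    for i, fr in enumerate(traj.frames):
        e = None if energies is None else float(energies[i])
        poses.append(DockedPose(coords=fr.coords, energy=e, label=f"pose{i}"))
    ranking = rank_pose_clusters(poses, cutoff=config.pose_cluster_cutoff)
    _write(ranking, outdir / "pose_clusters.tsv", created)
    rows = []
    for pose in poses:
        call = classify_orientation(
            pose,
            int(spec["n_anchor"]),
            int(spec["c_anchor"]),
            np.asarray(spec["helix_n"], dtype=float),
            np.asarray(spec["helix_c"], dtype=float),
            threshold=config.orientation_cos_threshold,
        )
        rows.append((pose.label, call.call, call.cos_angle))
    _write(
        pd.DataFrame(rows, columns=["pose", "orientation", "cos_angle"]),
        outdir / "pose_orientations.tsv",
        created,
    )
    return {"n_poses": len(poses), "n_pose_clusters": int(ranking.shape[0])}


def _stage_noe(config, trajs, outdir, created):
    if not config.proton_pairs:
        return
    rows = []
    for traj in trajs:
        pairs = [
            ProtonPair(
                p["label"],
                _resolve_atom(traj, p["a"]),
                _resolve_atom(traj, p["b"]),
            )
            for p in config.proton_pairs
        ]
        table = noe_table(noe_pattern_table(traj, pairs, cutoff=config.noe_cutoff))
        table.insert(0, "replicate", traj.replicate_label)
        rows.append(table)
    _write(pd.concat(rows, ignore_index=True), outdir / "noe.tsv", created)


def run_pipeline(config: PipelineConfig, outdir, stages=None) -> dict:
    """Run the configured stages and write the TSV report bundle.

    Any stage failure aborts the run with the stage name, and partial outputs
    from this invocation are removed.  Returns a summary dict (also written
    as ``summary.json``).
    """
    stages = tuple(stages) if stages is not None else DEFAULT_STAGES
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    created: list[Path] = []
    summary = {"config_hash": config.content_hash(), "seed": config.seed}
    current_stage = "load"
    try:
        trajs = _load_trajectories(config)
        if "stability" in stages:
            current_stage = "stability"
            _stage_stability(config, trajs, outdir, created)
        if "project" in stages and "probes" in config.selections:
            current_stage = "project"
            summary["projection_excluded"] = _stage_project(
                config, trajs, outdir, created
            )
        if "dihedrals" in stages and config.dihedrals:
            current_stage = "dihedrals"
            _stage_dihedrals(config, trajs, outdir, created)
        if "cluster" in stages:
            current_stage = "cluster"
            summary.update(_stage_cluster(config, trajs, outdir, created))
        if "poses" in stages:
            current_stage = "poses"
            pose_summary = _stage_poses(config, outdir, created)
            if pose_summary:
                summary.update(pose_summary)
        if "noe" in stages:
            current_stage = "noe"
            _stage_noe(config, trajs, outdir, created)
        current_stage = "report"
        log = outdir / "run_log.txt"
        with open(log, "w") as fh:
            fh.write(f"config_hash\t{config.content_hash()}\n")
            fh.write(f"seed\t{config.seed}\n")
            for name in (
                "equilibration_cut_ps",
                "sampling_interval_ps",
                "contact_cutoff",
                "md_cluster_cutoff",
                "pose_cluster_cutoff",
                "noe_cutoff",
                "orientation_cos_threshold",
            ):
                fh.write(f"{name}\t{getattr(config, name)}\n")
            for entry in config.trajectories:
                fh.write(f"input\t{entry['path']}\t{_hash_file(entry['path'])}\n")
        created.append(log)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
        created.append(outdir / "summary.json")
    except BindmodeError as exc:
        for path in created:
            path.unlink(missing_ok=True)
        raise type(exc)(f"pipeline stage {current_stage!r} failed: {exc}") from exc
    return summary
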