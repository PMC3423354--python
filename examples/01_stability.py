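"""Ligand-in-pocket stability: RMSD, RMSF, contacts and COM drift.

Generates one synthetic replicate of a ligand jittering in a toy pocket and
prints the four stability measures a bound-ligand simulation is judged by.
"""

import numpy as np

from bindmode import (
    com_distance_delta_timeseries,
    contact_count_timeseries,
    rmsd_timeseries,
    rmsf_per_atom,
)
from bindmode.synthetic import default_ligand_centers, gen_pocket_trajectory

result = gen_pocket_trajectory(
    default_ligand_centers(n_states=1),
    noise_sigma=0.3,
    n_frames=501,
    dt=10.0,
    seed=1,
    replicate_label="conf1",
)
traj = result.trajectory
ref = traj.frames[0]
scaffold = result.scaffold_indices
ligand = result.ligand_indices

rmsd = rmsd_timeseries(traj, ref, scaffold, ligand)
rmsf = rmsf_per_atom(traj, ref, ligand, fit_sel=scaffold)
# the toy pocket is coarser than a real binding site (one pseudo-atom per
# residue), so a correspondingly coarser contact cutoff is used here; on
# real all-atom trajectories the conventional cutoff is 3.5 A
contacts = contact_count_timeseries(traj, scaffold, ligand, cutoff=5.0)
com = com_distance_delta_timeseries(traj, scaffold, ligand, ref)

print(f"mean ligand RMSD from start : {rmsd.values.mean():.3f} A")
print(f"mean ligand-atom RMSF       : {rmsf.values.mean():.3f} A")
print(f"mean contacts within 5.0 A  : {contacts.counts.mean():.1f}")
print(f"final COM-distance drift    : {com.delta[-1]:+.3f} A")
print()
print("A stably bound ligand keeps RMSD low and flat (here set by the")
print("0.3 A jitter about a single conformation, measured against the")
print("jittered starting frame), a steady contact count, and near-zero COM")
print("drift; a systematic COM decrease would mean the pose is settling.")
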