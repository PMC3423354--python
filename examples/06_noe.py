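"""NOE-style inverse-cubic distance averages for ring-rotation diagnosis.

Compares the predicted NOE presence/absence pattern of a freely rotating
aromatic ring against a torsionally locked one.
"""

from bindmode import noe_pattern_table, noe_table
from bindmode.synthetic import gen_ring_torsion_ensemble

for mode in ("free", "locked"):
    traj, pairs = gen_ring_torsion_ensemble(mode, n_frames=4000, seed=1)
    table = noe_table(noe_pattern_table(traj, pairs, cutoff=4.0))
    print(f"{mode} ring rotation:")
    print(table.round(2).to_string(index=False))
    print()

print("r_eff = <r^-3>^(-1/3) is dominated by the shortest distances the")
print("ensemble visits: free rotation brings both ortho protons (H2, H6)")
print("close to the amide proton, a locked torsion only H2 — matching the")
print("NOESY signature that distinguishes the two rotational regimes.")
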