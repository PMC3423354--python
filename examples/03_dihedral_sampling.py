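"""Cross-replicate torsion sampling quality and relaxation time.

Builds five replicate torsion series from a two-state rotamer-jump process,
labels the cross-replicate sampling quality, and recovers the relaxation
time of the process from the cos(chi) autocorrelation function.
"""

import numpy as np

from bindmode import (
    circular_histogram,
    classify_sampling,
    cos_autocorrelation,
    fit_relaxation,
)
from bindmode.synthetic import gen_rotamer_jump_series

k = 0.005  # switch rate per step; planted tau = 1/(2k) = 100 steps
hists = []
for rep in range(5):
    series, _ = gen_rotamer_jump_series(
        [-60.0, 120.0], [[0.0, k], [k, 0.0]], n_frames=50_000, dt=1.0,
        seed=rep,
    )
    hists.append(circular_histogram(series, replicate_label=f"conf{rep + 1}"))

verdict = classify_sampling(hists)
print(f"sampling label: {verdict.label}")
print("per-basin occupancy by replicate:")
print(verdict.evidence.round(3).to_string())

acf = cos_autocorrelation(series, max_lag=1000.0)
fit = fit_relaxation(acf)
print(f"\nrelaxation time tau = {fit.tau_ps:.1f} steps "
      f"(planted 1/(2k) = {1 / (2 * k):.0f}; numeric ACF integral "
      f"{fit.tau_integral_ps:.1f})")
print()
print("All replicates occupy both rotamer basins, so the torsion is well")
print("sampled; tau near 100 steps confirms many basin exchanges per run.")
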